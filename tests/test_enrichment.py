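"""Rank percentiles, ROC/DeLong, matched-null and quality-null analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from miscan.enrichment_eval import (
    delong_components,
    delong_test_one_tailed,
    matched_null,
    quality_bin_null,
    rank_percentiles,
    roc_compare,
)
from miscan.gp_core import ValidationError


def _scan(p_values, ids=None, maf=0.3, quality=0.9):
    n = len(p_values)
    return pd.DataFrame(
        {
            "variant_id": ids or [f"v{i}" for i in range(n)],
            "p": p_values,
            "maf": np.broadcast_to(maf, n),
            "quality": np.broadcast_to(quality, n),
        }
    )


class TestRankPercentiles:
    def test_extremes(self):
        r = rank_percentiles(_scan([1e-8, 0.5, 0.9, 0.2]))
        assert r["percentile"].iloc[0] == max(r["percentile"])
        assert r["percentile"].iloc[0] == pytest.approx(100 * (1 - 0.5 / 4))

    def test_all_ties_give_50(self):
        r = rank_percentiles(_scan([0.3] * 7))
        np.testing.assert_allclose(r["percentile"], 50.0)

    def test_brute_force_20_variants(self, rng):
        p = rng.uniform(size=20)
        r = rank_percentiles(_scan(p))
        order = np.argsort(np.argsort(p))  # 0 = smallest p
        expected = 100 * (1 - (order + 1 - 0.5) / 20)
        np.testing.assert_allclose(r["percentile"], expected)

    def test_untestable_counted(self):
        r = rank_percentiles(_scan([0.1, np.nan, 0.5]))
        assert r.attrs["n_untestable"] == 1
        assert np.isnan(r["percentile"].iloc[1])

    def test_monotone_transform_invariance(self, rng):
        p = rng.uniform(size=50)
        a = rank_percentiles(_scan(p))["percentile"]
        b = rank_percentiles(_scan(p**3))["percentile"]
        np.testing.assert_allclose(a, b)


def _brute_force_delong(x_scores, y_scores):
    """Direct U-statistic structural components for paired methods."""
    k, m = x_scores.shape
    n = y_scores.shape[1]
    psi = np.empty((k, m, n))
    for r in range(k):
        for i in range(m):
            for j in range(n):
                if x_scores[r, i] > y_scores[r, j]:
                    psi[r, i, j] = 1.0
                elif x_scores[r, i] == y_scores[r, j]:
                    psi[r, i, j] = 0.5
                else:
                    psi[r, i, j] = 0.0
    auc = psi.mean(axis=(1, 2))
    v10 = psi.mean(axis=2)
    v01 = psi.mean(axis=1)
    s10 = np.cov(v10[0], v10[1]) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01[0], v01[1]) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    return auc, cov


class TestDeLong:
    def test_matches_brute_force_micro_fixture(self):
        # <= 10 observations, two methods, with a tie
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 0], dtype=bool)
        a = np.array([0.9, 0.8, 0.4, 0.7, 0.3, 0.2, 0.4, 0.1])
        b = np.array([0.6, 0.9, 0.5, 0.8, 0.4, 0.3, 0.2, 0.6])
        scores = np.vstack([a, b])
        aucs, cov = delong_components(scores, labels)
        bf_auc, bf_cov = _brute_force_delong(
            scores[:, labels], scores[:, ~labels]
        )
        np.testing.assert_allclose(aucs, bf_auc, atol=1e-10)
        np.testing.assert_allclose(cov, bf_cov, atol=1e-10)
        auc_a, auc_b, p = delong_test_one_tailed(a, b, labels)
        var = bf_cov[0, 0] + bf_cov[1, 1] - 2 * bf_cov[0, 1]
        z = (bf_auc[0] - bf_auc[1]) / np.sqrt(var)
        assert p == pytest.approx(stats.norm.sf(z), abs=1e-10)

    def test_one_tailed_complementarity(self, rng):
        labels = rng.uniform(size=200) < 0.2
        a = rng.normal(size=200) + labels
        b = rng.normal(size=200) + 0.5 * labels
        _, _, p_ab = delong_test_one_tailed(a, b, labels)
        _, _, p_ba = delong_test_one_tailed(b, a, labels)
        assert p_ab + p_ba == pytest.approx(1.0)

    def test_auc_equals_mann_whitney(self, rng):
        labels = rng.uniform(size=300) < 0.1
        s = rng.normal(size=300) + 0.8 * labels
        aucs, _ = delong_components(s[None, :], labels)
        u = stats.mannwhitneyu(s[labels], s[~labels]).statistic
        assert aucs[0] == pytest.approx(u / (labels.sum() * (~labels).sum()))


class TestRocCompare:
    def test_perfect_ranking_auc_one(self):
        scan = rank_percentiles(_scan([1e-6, 1e-5, 0.5, 0.6, 0.7, 0.9]))
        comp = roc_compare({"m": scan}, positives={"v0", "v1"})
        assert comp.aucs["m"] == pytest.approx(1.0)
        fpr, tpr = comp.curves["m"]
        assert np.all(np.diff(tpr) >= 0) and np.all(np.diff(fpr) >= 0)

    def test_random_ranking_near_half(self, rng):
        p = rng.uniform(size=2000)
        scan = rank_percentiles(_scan(p))
        pos = set(rng.choice(scan["variant_id"], 50, replace=False))
        comp = roc_compare({"m": scan, "m2": scan}, positives=pos)
        labels = scan["variant_id"].isin(pos).to_numpy()
        _, cov = delong_components(
            scan["percentile"].to_numpy()[None, :], labels
        )
        assert abs(comp.aucs["m"] - 0.5) < 3 * np.sqrt(cov[0, 0])

    def test_empty_positives_rejected(self):
        scan = rank_percentiles(_scan([0.1, 0.2]))
        with pytest.raises(ValidationError):
            roc_compare({"m": scan}, positives=set())

    def test_better_method_wins_one_tailed(self, rng):
        n = 3000
        ids = [f"v{i}" for i in range(n)]
        pos = set(rng.choice(ids, 60, replace=False))
        is_pos = np.isin(ids, list(pos))
        p_good = np.where(is_pos, rng.uniform(0, 0.05, n), rng.uniform(size=n))
        p_bad = np.where(is_pos, rng.uniform(0, 0.5, n), rng.uniform(size=n))
        comp = roc_compare(
            {"good": rank_percentiles(_scan(p_good, ids)),
             "bad": rank_percentiles(_scan(p_bad, ids))},
            positives=pos,
        )
        assert comp.aucs["good"] > comp.aucs["bad"]
        assert comp.delong_p.loc["good", "bad"] < 1e-6


class TestMatchedNull:
    def test_positive_above_all_nulls(self, rng):
        n = 1500
        p = rng.uniform(0.01, 1, size=n)
        p[0] = 1e-9
        scan = rank_percentiles(_scan(p))
        res = matched_null(scan, {"v0"}, n_per=200, seed=1)
        assert res.table["adjusted_percentile"].iloc[0] == 100.0

    def test_null_positive_uniform_adjusted_ranks(self):
        # a positive drawn from the null itself has a uniform adjusted rank
        rng = np.random.default_rng(7)
        adjusted = []
        for _ in range(500):
            p = rng.uniform(size=400)
            scan = rank_percentiles(_scan(p))
            res = matched_null(scan, {"v0"}, n_per=150, seed=int(rng.integers(2**31)))
            adjusted.append(res.table["adjusted_percentile"].iloc[0])
        ks = stats.kstest(np.asarray(adjusted) / 100.0, "uniform")
        assert ks.pvalue > 0.001

    def test_seed_reproducible(self, rng):
        scan = rank_percentiles(_scan(rng.uniform(size=800)))
        a = matched_null(scan, {"v3"}, n_per=100, seed=42)
        b = matched_null(scan, {"v3"}, n_per=100, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_small_pool_warns_and_empty_excludes(self, rng):
        n = 50
        scan = rank_percentiles(_scan(rng.uniform(size=n)))
        scan.loc[0, "quality"] = 0.2  # far from every other variant
        with pytest.warns(UserWarning, match="with replacement"):
            res = matched_null(scan, {"v1"}, n_per=100, seed=0)
        assert res.table["pool_size"].iloc[0] == n - 2
        with pytest.warns(UserWarning, match="no matched null"):
            res = matched_null(scan, {"v0"}, n_per=100, seed=0)
        assert np.isnan(res.table["adjusted_percentile"].iloc[0])

    def test_monotone_transform_invariance(self, rng):
        p = rng.uniform(size=600)
        a = matched_null(rank_percentiles(_scan(p)), {"v5"}, n_per=100, seed=3)
        b = matched_null(
            rank_percentiles(_scan(np.sqrt(p))), {"v5"}, n_per=100, seed=3
        )
        assert a.table["adjusted_percentile"].iloc[0] == pytest.approx(
            b.table["adjusted_percentile"].iloc[0]
        )


class TestQualityBinNull:
    def test_uniform_ranks_no_trend(self, rng):
        n = 5000
        scan = pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(n)],
                "percentile": rng.uniform(0, 100, n),
                "quality": rng.uniform(0.4, 1.0, n),
            }
        )
        table, trend = quality_bin_null(scan)
        pop = table[table["count"] > 50]
        assert np.all(
            np.abs(pop["mean_percentile"] - 50.0) <= 3.5 * pop["se"]
        )
        assert trend["pearson_p"] > 0.001

    def test_downweighted_low_quality_trend(self, rng):
        n = 5000
        quality = rng.uniform(0.4, 1.0, n)
        # percentile depressed for low quality
        perc = np.clip(
            rng.uniform(0, 100, n) * (0.5 + 0.5 * quality), 0, 100
        )
        scan = pd.DataFrame(
            {"variant_id": [f"v{i}" for i in range(n)],
             "percentile": perc, "quality": quality}
        )
        _, trend = quality_bin_null(scan)
        assert trend["pearson_r"] > 0
        assert trend["pearson_p"] < 1e-6
        assert trend["deviation_pearson_r"] < 0

    def test_order_invariance(self, rng):
        n = 1000
        scan = pd.DataFrame(
            {"variant_id": [f"v{i}" for i in range(n)],
             "percentile": rng.uniform(0, 100, n),
             "quality": rng.uniform(0.4, 1.0, n)}
        )
        t1, _ = quality_bin_null(scan)
        t2, _ = quality_bin_null(scan.sample(frac=1, random_state=0))
        pd.testing.assert_frame_equal(t1, t2)
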