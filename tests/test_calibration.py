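"""Discordance strata and probability-consistency diagnostics."""

import numpy as np
import pytest

from miscan import simdata
from miscan.calibration_diag import (
    align_truth,
    bestguess_discordance_strata,
    consistency_curve,
    discordance_strata,
    frequency_baseline,
    select_mask,
)
from miscan.gp_core import ProbMatrix, ValidationError, VariantMeta

FULL_MAF = np.linspace(0.0, 0.5, 11)
FULL_QUAL = np.array([0.0, 0.4, 0.8, 0.9, 1.0])


def _pm(probs, quality=0.95):
    n, m, _ = probs.shape
    return ProbMatrix(
        [f"s{i}" for i in range(n)],
        [VariantMeta(f"v{j}", quality=quality, maf=0.25) for j in range(m)],
        probs,
    )


class TestDiscordanceStrata:
    def test_degenerate_correct_all_zero(self, rng):
        g = rng.integers(0, 3, size=(40, 6))
        probs = np.eye(3)[g]
        table = discordance_strata(_pm(probs), g, FULL_MAF, FULL_QUAL)
        assert np.allclose(table["mean_discordance"], 0.0)

    def test_worked_single_pair(self):
        # dosage 1.4 vs true count 2: discordance 0.3 in its stratum
        probs = np.array([[[0.0, 0.6, 0.4]]])
        table = discordance_strata(
            _pm(probs), np.array([[2]]), FULL_MAF, FULL_QUAL
        )
        assert len(table) == 1
        assert table["mean_discordance"].iloc[0] == pytest.approx(0.3)

    def test_aggregation_recovers_global_mean(self, small_sim):
        table = discordance_strata(
            small_sim.pm, small_sim.truth, FULL_MAF, FULL_QUAL
        )
        weighted = np.average(
            table["mean_discordance"], weights=table["count"]
        )
        d = small_sim.pm.dosages()
        global_mean = (np.abs(small_sim.truth - d) / 2.0).mean()
        assert weighted == pytest.approx(global_mean, rel=1e-10)

    def test_calibrated_sim_matches_analytic_oracle(self):
        sim = simdata.simulate(
            simdata.SimConfig(n_samples=1500, n_variants=250, seed=31)
        )
        maf_edges = np.linspace(0.0, 0.5, 6)
        qual_edges = np.array([0.4, 0.8, 0.9, 1.0])
        table = discordance_strata(sim.pm, sim.truth, maf_edges, qual_edges)
        expected = sim.expected_stratum_discordance(maf_edges, qual_edges)
        merged = table.merge(
            expected,
            left_on=["genotype_class", "maf_bin_left", "quality_bin_left"],
            right_on=["genotype_class", "maf_bin_left", "quality_bin_left"],
        )
        pop = merged[merged["count"] >= 50]
        assert len(pop) >= 20
        inside = (
            np.abs(pop["mean_discordance"] - pop["expected_discordance"])
            <= np.maximum(pop["ci_halfwidth"], 1e-3)
        )
        assert inside.mean() >= 0.90

    def test_no_overlap_errors(self, small_sim):
        with pytest.raises(ValidationError):
            discordance_strata(
                small_sim.pm, small_sim.truth[:, :10], FULL_MAF, FULL_QUAL
            )


class TestBestGuessStrata:
    def test_degenerate_zero(self, rng):
        g = rng.integers(0, 3, size=(30, 4))
        table = bestguess_discordance_strata(
            _pm(np.eye(3)[g]), g, FULL_MAF, FULL_QUAL
        )
        assert np.allclose(table["mean_discordance"], 0.0)

    def test_four_pair_fixture(self):
        # same true class for all four entries, one mismatch: 0.25
        probs = np.array(
            [[[0.9, 0.1, 0.0]], [[0.8, 0.2, 0.0]], [[0.7, 0.3, 0.0]],
             [[0.1, 0.9, 0.0]]]
        )
        truth = np.zeros((4, 1), dtype=int)
        table = bestguess_discordance_strata(
            _pm(probs), truth, FULL_MAF, FULL_QUAL
        )
        assert len(table) == 1
        assert table["mean_discordance"].iloc[0] == pytest.approx(0.25)


class TestConsistencyCurve:
    def test_calibrated_bins_cover_zero(self):
        sim = simdata.simulate(
            simdata.SimConfig(n_samples=1500, n_variants=200, seed=41)
        )
        table = consistency_curve(
            sim.pm, sim.truth, strata_edges=np.array([0.4, 0.9, 1.0])
        )
        pop = table[table["count"] >= 30]
        covers = np.abs(pop["deviation"]) <= pop["ci_halfwidth"]
        assert covers.mean() >= 0.93

    def test_shrinkage_sign_pattern(self):
        # shrinking toward the prior understates high probabilities and
        # overstates low ones: deviation negative in high bins, positive low
        sim = simdata.simulate(
            simdata.SimConfig(
                n_samples=1200, n_variants=150, shrink_lambda=0.3,
                maf_dist=("fixed", 0.3), quality_dist=("fixed", 0.85),
                seed=43,
            )
        )
        table = consistency_curve(
            sim.pm, sim.truth, strata_edges=np.array([0.4, 1.0])
        )
        pop = table[table["count"] >= 200]
        high = pop[pop["prob_bin_left"] >= 0.7]
        low = pop[pop["prob_bin_left"] <= 0.2]
        assert (high["deviation"] < 0).mean() > 0.8
        assert (low["deviation"] > 0).mean() > 0.8

    def test_shrinkage_magnitude_analytic(self):
        # stated p' = (1-l) p + l pi  =>  deviation = l/(1-l) (pi - p')
        lam = 0.3
        maf = 0.3
        sim = simdata.simulate(
            simdata.SimConfig(
                n_samples=1500, n_variants=150, shrink_lambda=lam,
                maf_dist=("fixed", maf), quality_dist=("fixed", 0.85),
                seed=47,
            )
        )
        pi = {"hom_major": (1 - maf) ** 2, "het": 2 * maf * (1 - maf),
              "hom_minor": maf**2}
        table = consistency_curve(
            sim.pm, sim.truth, strata_edges=np.array([0.4, 1.0])
        )
        pop = table[table["count"] >= 300]
        assert len(pop) >= 5
        mid = pop["prob_bin_left"] + 0.01
        expected = (
            lam / (1 - lam)
            * (pop["genotype_class"].map(pi) - mid)
        )
        inside = np.abs(pop["deviation"] - expected) <= (
            pop["ci_halfwidth"] + lam / (1 - lam) * 0.01
        )
        assert inside.mean() >= 0.90

    def test_degenerate_correct_top_bin_zero(self, rng):
        g = rng.integers(0, 3, size=(50, 5))
        table = consistency_curve(
            _pm(np.eye(3)[g]), g, strata_edges=np.array([0.0, 1.0])
        )
        top = table[(table["prob_bin_left"] == 0.98) & (table["count"] > 0)]
        assert np.allclose(top["deviation"], 0.0)

    def test_conservation_over_classes_and_bins(self, small_sim):
        # summing count-weighted deviations over all classes and bins gives
        # (total stated mass) - (total truth indicators) = 0 exactly
        table = consistency_curve(
            small_sim.pm, small_sim.truth,
            strata_edges=np.array([0.0, 1.0]),
        )
        pop = table[table["count"] > 0]
        total = (pop["deviation"] * pop["count"]).sum()
        assert total == pytest.approx(0.0, abs=1e-8)

    def test_class_bias_recovered(self):
        # injected het-vs-hom complementary bias shows opposite-sign
        # deviations for het and homozygote classes
        sim = simdata.simulate(
            simdata.SimConfig(
                n_samples=1200, n_variants=150, class_bias_delta=0.15,
                maf_dist=("fixed", 0.3), quality_dist=("fixed", 0.85),
                seed=53,
            )
        )
        table = consistency_curve(
            sim.pm, sim.truth, strata_edges=np.array([0.4, 1.0])
        )
        pop = table[table["count"] >= 300]
        het = pop[pop["genotype_class"] == "het"]
        hom = pop[pop["genotype_class"] != "het"]
        assert np.average(het["deviation"], weights=het["count"]) > 0
        assert np.average(hom["deviation"], weights=hom["count"]) < 0


class TestFrequencyBaseline:
    def test_examples(self):
        t = frequency_baseline(0.5).set_index("genotype_class")
        assert t.loc["het", "baseline_discordance"] == pytest.approx(0.0)
        t = frequency_baseline(0.1).set_index("genotype_class")
        assert t.loc["hom_minor", "baseline_discordance"] == pytest.approx(0.9)

    def test_hom_major_monotone_in_maf(self):
        vals = [
            frequency_baseline(q).set_index("genotype_class").loc[
                "hom_major", "baseline_discordance"
            ]
            for q in (0.05, 0.2, 0.4)
        ]
        assert vals[0] < vals[1] < vals[2]

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            frequency_baseline(0.0)


class TestAlignTruth:
    def _truth_pm(self, pm, g, swap=(), rename={}):
        n, m = g.shape
        probs = np.eye(3)[g]
        variants = []
        for j, v in enumerate(pm.variants):
            a, b = v.allele_a, v.allele_b
            if j in swap:
                a, b = b, a
                probs[:, j, :] = probs[:, j, ::-1]
            variants.append(
                VariantMeta(rename.get(v.variant_id, v.variant_id),
                            allele_a=a, allele_b=b)
            )
        return ProbMatrix(list(pm.samples), variants, probs)

    def test_swapped_alleles_reconciled(self, rng):
        g = rng.integers(0, 3, size=(20, 4))
        probs = np.eye(3)[g]
        pm = ProbMatrix(
            [f"s{i}" for i in range(20)],
            [VariantMeta(f"v{j}", allele_a="A", allele_b="C")
             for j in range(4)],
            probs,
        )
        truth_pm = self._truth_pm(pm, g, swap=(1,))
        idx, aligned = align_truth(pm, truth_pm)
        np.testing.assert_array_equal(idx, [0, 1, 2, 3])
        np.testing.assert_array_equal(aligned, g)

    def test_ambiguous_excluded(self, rng):
        g = rng.integers(0, 3, size=(10, 2))
        pm = ProbMatrix(
            [f"s{i}" for i in range(10)],
            [VariantMeta("amb", allele_a="A", allele_b="T"),
             VariantMeta("ok", allele_a="A", allele_b="C")],
            np.eye(3)[g],
        )
        truth_pm = self._truth_pm(pm, g)
        idx, _ = align_truth(pm, truth_pm)
        np.testing.assert_array_equal(idx, [1])


class TestSelectMask:
    def test_fraction_and_determinism(self):
        a = select_mask(1000, 0.1, seed=5)
        b = select_mask(1000, 0.1, seed=5)
        np.testing.assert_array_equal(a, b)
        assert len(a) == 100
        assert len(np.unique(a)) == 100
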