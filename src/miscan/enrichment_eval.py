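"""Signal-enrichment evaluation of association scans.

Given per-variant p-values from competing uncertainty-handling methods and a
list of positive-control variants (established trait loci), these tools
measure how well each method ranks the positives: percentile ranks, ROC
curves and AUC, paired one-tailed DeLong comparisons between methods, an
empirical matched-null adjustment (nulls matched on imputation quality
+/- 0.01 and frequency +/- 0.01), and the quality-binned null-distribution
analysis relating imputation quality to rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .gp_core import ValidationError


# -- rank percentiles ---------------------------------------------------------


def rank_percentiles(scan: pd.DataFrame, p_column: str = "p") -> pd.DataFrame:
    """Attach percentile ranks to a scan table (100 = most significant).

    ``percentile = 100 (1 - (rank - 0.5) / M)`` with p-values ranked
    ascending and ties given their average rank.  Variants with non-finite
    p (untestable) receive NaN percentiles and are excluded from M; their
    count is in ``.attrs["n_untestable"]``.
    """
    out = scan.copy()
    p = out[p_column].to_numpy(dtype=np.float64)
    ok = np.isfinite(p)
    perc = np.full(p.shape, np.nan)
    m = int(ok.sum())
    if m:
        ranks = stats.rankdata(p[ok], method="average")
        perc[ok] = 100.0 * (1.0 - (ranks - 0.5) / m)
    out["percentile"] = perc
    out.attrs["n_untestable"] = int((~ok).sum())
    return out


# -- DeLong machinery ---------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_components(scores: np.ndarray, labels: np.ndarray):
    """Paired DeLong AUCs and covariance for k methods on shared cases.

    ``scores`` is (k, n) with larger = more positive; ``labels`` boolean.
    Returns (aucs (k,), covariance (k, k)) using the structural-component
    (midrank) formulation.
    """
    labels = np.asarray(labels, dtype=bool)
    pos = scores[:, labels]
    neg = scores[:, ~labels]
    m, n = pos.shape[1], neg.shape[1]
    if m == 0 or n == 0:
        raise ValidationError("DeLong needs >= 1 positive and >= 1 negative")
    k = scores.shape[0]
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(np.concatenate([pos[r], neg[r]]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v10[r] = (tz[:m] - tx) / n
        v01[r] = 1.0 - (tz[m:] - ty) / m
    s10 = np.cov(v10) if m > 1 else np.zeros((k, k))
    s01 = np.cov(v01) if n > 1 else np.zeros((k, k))
    cov = np.atleast_2d(s10) / m + np.atleast_2d(s01) / n
    return aucs, cov


def delong_test_one_tailed(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """One-tailed paired DeLong test that AUC(A) exceeds AUC(B).

    Returns (auc_a, auc_b, p) with p = P(Z >= z) under the normal
    approximation, z = (auc_a - auc_b) / se of the paired difference.
    """
    aucs, cov = delong_components(np.vstack([scores_a, scores_b]), labels)
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var <= 0:
        p = 0.5 if aucs[0] == aucs[1] else (0.0 if aucs[0] > aucs[1] else 1.0)
    else:
        z = (aucs[0] - aucs[1]) / np.sqrt(var)
        p = float(stats.norm.sf(z))
    return float(aucs[0]), float(aucs[1]), p


# -- ROC comparison -----------------------------------------------------------


@dataclass
class ROCComparison:
    """ROC curves, AUCs, and pairwise one-tailed DeLong p-values."""

    curves: dict[str, tuple[np.ndarray, np.ndarray]]
    aucs: dict[str, float]
    #: delong_p.loc[a, b] = one-tailed p for the alternative AUC(a) > AUC(b)
    delong_p: pd.DataFrame
    n_positive: int = 0
    n_negative: int = 0


def roc_compare(
    scans: dict[str, pd.DataFrame],
    positives: set[str],
    score_column: str = "percentile",
) -> ROCComparison:
    """Compare methods by how their rankings separate positives from the rest.

    ``scans`` maps method name to a table with variant_id and a score column
    (higher = more significant); variants are inner-joined across methods so
    the DeLong comparison is paired.  All non-positive variants are treated
    as negatives.
    """
    if not positives:
        raise ValidationError("empty positive set")
    names = list(scans)
    merged: pd.DataFrame | None = None
    for name in names:
        df = scans[name][["variant_id", score_column]].dropna()
        df = df.rename(columns={score_column: name})
        merged = df if merged is None else merged.merge(df, on="variant_id")
    assert merged is not None
    labels = merged["variant_id"].isin(positives).to_numpy()
    found = set(merged.loc[labels, "variant_id"])
    missing = positives - found
    if missing:
        warnings.warn(
            f"{len(missing)} positive-control variants absent from the "
            "joined scans and ignored"
        )
    if not labels.any():
        raise ValidationError("no positive-control variants present in scans")
    if labels.all():
        raise ValidationError("no negative variants present in scans")
    scores = merged[names].to_numpy(dtype=np.float64).T
    aucs, _ = delong_components(scores, labels)
    curves = {}
    for r, name in enumerate(names):
        fpr, tpr, _ = roc_curve(labels, scores[r])
        curves[name] = (fpr, tpr)
    pmat = pd.DataFrame(np.nan, index=names, columns=names)
    for a in range(len(names)):
        for b in range(len(names)):
            if a == b:
                continue
            _, _, p = delong_test_one_tailed(scores[a], scores[b], labels)
            pmat.iloc[a, b] = p
    return ROCComparison(
        curves=curves,
        aucs={name: float(aucs[r]) for r, name in enumerate(names)},
        delong_p=pmat,
        n_positive=int(labels.sum()),
        n_negative=int((~labels).sum()),
    )


# -- matched-null adjustment --------------------------------------------------


@dataclass
class MatchedNullResult:
    """Per-positive matched-null summaries and the null-adjusted scan."""

    table: pd.DataFrame  # one row per positive
    adjusted_scan: pd.DataFrame  # scan with positives' percentile replaced


def matched_null(
    scan: pd.DataFrame,
    positives: set[str],
    n_per: int = 1000,
    tol_quality: float = 0.01,
    tol_freq: float = 0.01,
    seed: int = 0,
    max_widen: float = 4.0,
) -> MatchedNullResult:
    """Empirical null rank distributions from quality/frequency-matched SNPs.

    For each positive-control variant, samples ``n_per`` non-positive
    variants whose imputation quality is within ``tol_quality`` and whose
    minor allele frequency is within ``tol_freq`` of the positive, and
    scores the positive by its empirical percentile within the matched null
    rank distribution.  Pools smaller than ``n_per`` are sampled with
    replacement (warned); empty pools have their tolerances doubled up to
    ``max_widen`` times the originals, then the positive is excluded
    (reported with NaN).

    The adjusted scan replaces each positive's percentile with its
    null-adjusted percentile so ROC curves can be regenerated controlling
    for the null rank of matched SNPs.
    """
    need = {"variant_id", "percentile", "maf", "quality"}
    if not need <= set(scan.columns):
        raise ValidationError(f"scan table needs columns {sorted(need)}")
    rng = np.random.default_rng(seed)
    df = scan.dropna(subset=["percentile"]).reset_index(drop=True)
    is_pos = df["variant_id"].isin(positives).to_numpy()
    pool_df = df.loc[~is_pos, ["percentile", "maf", "quality"]]
    pool_perc = pool_df["percentile"].to_numpy()
    pool_maf = pool_df["maf"].to_numpy()
    pool_qual = pool_df["quality"].to_numpy()
    rows = []
    adjusted = df.copy()
    for i in np.flatnonzero(is_pos):
        vid = df.loc[i, "variant_id"]
        perc = float(df.loc[i, "percentile"])
        qv, fv = float(df.loc[i, "quality"]), float(df.loc[i, "maf"])
        widen = 1.0
        sel = np.zeros(0, dtype=bool)
        while widen <= max_widen:
            sel = (np.abs(pool_qual - qv) <= tol_quality * widen) & (
                np.abs(pool_maf - fv) <= tol_freq * widen
            )
            if sel.any():
                break
            widen *= 2.0
        pool = pool_perc[sel]
        if pool.size == 0:
            warnings.warn(f"{vid}: no matched null pool; excluded")
            rows.append(
                {"variant_id": vid, "percentile": perc,
                 "adjusted_percentile": float("nan"), "pool_size": 0,
                 "widen_factor": widen, "null_mean": float("nan")}
            )
            continue
        if pool.size >= n_per:
            draw = rng.choice(pool, size=n_per, replace=False)
        else:
            warnings.warn(
                f"{vid}: matched pool has {pool.size} < {n_per} variants; "
                "sampling with replacement"
            )
            draw = rng.choice(pool, size=n_per, replace=True)
        adj = 100.0 * (np.sum(draw < perc) + 0.5 * np.sum(draw == perc)) / n_per
        adjusted.loc[i, "percentile"] = adj
        rows.append(
            {"variant_id": vid, "percentile": perc,
             "adjusted_percentile": adj, "pool_size": int(pool.size),
             "widen_factor": widen, "null_mean": float(draw.mean())}
        )
    return MatchedNullResult(table=pd.DataFrame(rows), adjusted_scan=adjusted)


# -- quality-binned null distribution -----------------------------------------


def quality_bin_null(
    scan: pd.DataFrame, bin_edges: np.ndarray | None = None
) -> tuple[pd.DataFrame, dict]:
    """Deviation of mean rank from 50% across imputation-quality bins.

    Returns (per-bin table, trend statistics).  The per-bin value is
    |mean percentile - 50| with its standard error; the trend statistics
    are the Pearson correlation/slope of percentile on quality (with
    two-sided p) and the Spearman rank-based companion.
    """
    df = scan.dropna(subset=["percentile", "quality"])
    if bin_edges is None:
        bin_edges = np.round(np.arange(0.4, 1.0001, 0.05), 10)
    bin_edges = np.asarray(bin_edges, dtype=np.float64)
    qual = df["quality"].to_numpy()
    perc = df["percentile"].to_numpy()
    idx = np.searchsorted(bin_edges, qual, side="left") - 1
    idx = np.where((qual > bin_edges[0]) & (qual <= bin_edges[-1]), idx, -1)
    rows = []
    for b in range(len(bin_edges) - 1):
        sel = idx == b
        cnt = int(sel.sum())
        if cnt:
            mean = float(perc[sel].mean())
            se = float(perc[sel].std(ddof=1) / np.sqrt(cnt)) if cnt > 1 else 0.0
        else:
            mean, se = float("nan"), float("nan")
        rows.append(
            {"quality_bin_left": bin_edges[b],
             "quality_bin_right": bin_edges[b + 1],
             "abs_dev_from_50": abs(mean - 50.0) if cnt else float("nan"),
             "mean_percentile": mean, "se": se, "count": cnt}
        )
    table = pd.DataFrame(rows)
    if len(df) >= 3 and np.std(qual) > 0 and np.std(perc) > 0:
        pearson = stats.pearsonr(qual, perc)
        slope = stats.linregress(qual, perc)
        spearman = stats.spearmanr(qual, perc)
        trend = {
            "pearson_r": float(pearson.statistic),
            "pearson_p": float(pearson.pvalue),
            "slope": float(slope.slope),
            "slope_p": float(slope.pvalue),
            "spearman_rho": float(spearman.statistic),
            "spearman_p": float(spearman.pvalue),
            "n": int(len(df)),
        }
    else:
        trend = {k: float("nan") for k in
                 ("pearson_r", "pearson_p", "slope", "slope_p",
                  "spearman_rho", "spearman_p")} | {"n": int(len(df))}
    # trend of the |mean rank - 50| deviation itself across quality bins:
    # a method that downweights uncertain variants shows large deviations in
    # low-quality bins shrinking toward 0 at high quality (negative slope)
    pop = table.dropna(subset=["abs_dev_from_50"])
    mids = 0.5 * (pop["quality_bin_left"] + pop["quality_bin_right"])
    if len(pop) >= 3 and np.std(mids) > 0 and np.std(pop["abs_dev_from_50"]) > 0:
        dev = stats.pearsonr(mids, pop["abs_dev_from_50"])
        trend["deviation_pearson_r"] = float(dev.statistic)
        trend["deviation_p"] = float(dev.pvalue)
    else:
        trend["deviation_pearson_r"] = float("nan")
        trend["deviation_p"] = float("nan")
    return table, trend


def read_positives(path) -> set[str]:
    """Read a plain-text positive-control list (one variant ID per line)."""
    with open(path, "r", encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def plot_roc(comparison: ROCComparison, ax=None):
    """ROC curves for all compared methods."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, (fpr, tpr) in comparison.curves.items():
        ax.plot(fpr, tpr, label=f"{name} (AUC {comparison.aucs[name]:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.5)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    return ax
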