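"""Masked-truth diagnostics of imputation output.

Two families of diagnostics, both computed against held-out ("masked") true
genotypes:

* **dosage / best-guess discordance strata** — mean |truth - dosage| / 2
  (or best-guess mismatch fraction) per true genotype class x minor-allele
  frequency bin x imputation-quality bin, with 95% confidence intervals;
* **probability-consistency curves** — for each genotype class and 0.02-wide
  probability bin, the signed mean deviation between the stated class
  probability and the observed indicator that the class is true.  A
  perfectly calibrated imputer has deviation 0 everywhere.

Genotype classes are oriented by the minor allele (hom-major, het,
hom-minor), so variants counting either allele stratify consistently.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gp_core import MISSING, ProbMatrix, ValidationError

CLASS_LABELS = ["hom_major", "het", "hom_minor"]

#: default MAF bins: deciles of width 0.05 over (0, 0.5]
DEFAULT_MAF_EDGES = np.round(np.linspace(0.0, 0.5, 11), 3)

#: default quality bins: (0.8, 0.9] and (0.9, 1]
DEFAULT_QUALITY_EDGES = np.array([0.8, 0.9, 1.0])

#: ambiguous (strand-complementary) allele pairs excluded at reconciliation
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


# -- truth alignment ----------------------------------------------------------


def align_truth(pm: ProbMatrix, truth_pm: ProbMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Match a truth matrix to ``pm`` by variant ID and allele pair.

    Returns (variant index into pm, aligned truth counts (N, K)).  Variants
    whose alleles appear swapped have their counts flipped (2 - g);
    strand-ambiguous variants (A/T, C/G) are excluded, as are variants with
    irreconcilable alleles or mismatched sample sets.
    """
    if truth_pm.samples != pm.samples:
        raise ValidationError("truth and probability matrices differ in samples")
    truth_by_id = {
        v.variant_id: (j, v) for j, v in enumerate(truth_pm.variants)
    }
    truth_calls = truth_pm.best_guess()
    idx, cols = [], []
    for j, v in enumerate(pm.variants):
        hit = truth_by_id.get(v.variant_id)
        if hit is None:
            continue
        tj, tv = hit
        pair = {v.allele_a, v.allele_b}
        if _COMPLEMENT.get(v.allele_a) == v.allele_b:
            continue  # complement-ambiguous: strand unresolvable
        if {tv.allele_a, tv.allele_b} != pair:
            continue
        g = truth_calls[:, tj]
        if tv.allele_b != v.allele_b:  # counted alleles swapped
            g = np.where(g == MISSING, MISSING, 2 - g)
        idx.append(j)
        cols.append(g)
    if not idx:
        raise ValidationError("no overlapping variants between truth and data")
    return np.asarray(idx), np.stack(cols, axis=1)


# -- shared stratification helpers --------------------------------------------


def _minor_class(truth: np.ndarray, counted_freq: np.ndarray) -> np.ndarray:
    """Map counted-allele counts to minor-allele class indices 0/1/2."""
    flip = counted_freq > 0.5
    cls = np.where(flip[None, :], 2 - truth, truth)
    return np.where(truth == MISSING, MISSING, cls)


def _bin_index(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Index of the left-open bin (edges[i], edges[i+1]] containing x; -1 outside."""
    edges = np.asarray(edges, dtype=np.float64)
    i = np.searchsorted(edges, x, side="left") - 1
    out = np.where((x > edges[0]) & (x <= edges[-1]), i, -1)
    return out.astype(np.int64)


def _stratum_frame(values, cls, maf_bin, qual_bin, maf_edges, quality_edges):
    """Aggregate per-entry values into the tidy stratum table."""
    ok = (cls >= 0) & (maf_bin >= 0) & (qual_bin >= 0) & np.isfinite(values)
    df = pd.DataFrame(
        {"cls": cls[ok], "maf_bin": maf_bin[ok], "qual_bin": qual_bin[ok],
         "value": values[ok]}
    )
    g = df.groupby(["cls", "maf_bin", "qual_bin"])["value"]
    agg = g.agg(["mean", "std", "count"]).reset_index()
    agg["ci_halfwidth"] = 1.96 * agg["std"].fillna(0.0) / np.sqrt(agg["count"])
    agg["genotype_class"] = [CLASS_LABELS[c] for c in agg["cls"]]
    agg["maf_bin_left"] = maf_edges[agg["maf_bin"]]
    agg["maf_bin_right"] = maf_edges[agg["maf_bin"] + 1]
    agg["quality_bin_left"] = quality_edges[agg["qual_bin"]]
    agg["quality_bin_right"] = quality_edges[agg["qual_bin"] + 1]
    out = agg[
        ["genotype_class", "maf_bin_left", "maf_bin_right",
         "quality_bin_left", "quality_bin_right", "mean", "ci_halfwidth",
         "count"]
    ].rename(columns={"mean": "mean_discordance"})
    return out


def _expand(pm: ProbMatrix, truth: np.ndarray):
    """Per-entry flattened (class, maf bin source arrays) for stratification."""
    truth = np.asarray(truth)
    if truth.shape != (pm.n_samples, pm.n_variants):
        raise ValidationError(
            f"truth shape {truth.shape} != {(pm.n_samples, pm.n_variants)}"
        )
    meta = pm.variant_frame()
    theta = pm.dosages().mean(axis=0) / 2.0
    maf = meta["maf"].to_numpy()
    maf = np.where(np.isfinite(maf), maf, np.minimum(theta, 1 - theta))
    qual = meta["quality"].to_numpy()
    cls = _minor_class(truth, theta)
    return cls, maf, qual


def discordance_strata(
    pm: ProbMatrix,
    truth: np.ndarray,
    maf_edges: np.ndarray = DEFAULT_MAF_EDGES,
    quality_edges: np.ndarray = DEFAULT_QUALITY_EDGES,
) -> pd.DataFrame:
    """Mean dosage discordance per genotype class x MAF bin x quality bin.

    ``truth`` is an (N, M) array of counted-allele counts aligned to ``pm``
    (use :func:`align_truth` first when sources differ); entries of
    :data:`MISSING` are skipped.  CI is the normal approximation
    1.96 sd / sqrt(n).
    """
    cls, maf, qual = _expand(pm, truth)
    d = pm.dosages()
    disc = np.where(truth == MISSING, np.nan,
                    np.abs(np.where(truth == MISSING, 0, truth) - d) / 2.0)
    maf_bin = _bin_index(maf, maf_edges)
    qual_bin = _bin_index(qual, quality_edges)
    n, m = disc.shape
    return _stratum_frame(
        disc.ravel(), cls.ravel(),
        np.broadcast_to(maf_bin, (n, m)).ravel(),
        np.broadcast_to(qual_bin, (n, m)).ravel(),
        maf_edges, quality_edges,
    )


def bestguess_discordance_strata(
    pm: ProbMatrix,
    truth: np.ndarray,
    maf_edges: np.ndarray = DEFAULT_MAF_EDGES,
    quality_edges: np.ndarray = DEFAULT_QUALITY_EDGES,
    call_threshold: float = 1.0 / 3.0,
) -> pd.DataFrame:
    """Best-guess mismatch fraction per class x MAF bin x quality bin."""
    cls, maf, qual = _expand(pm, truth)
    calls = pm.best_guess(call_threshold)
    mismatch = np.where(
        (truth == MISSING) | (calls == MISSING),
        np.nan,
        (calls != truth).astype(np.float64),
    )
    maf_bin = _bin_index(maf, maf_edges)
    qual_bin = _bin_index(qual, quality_edges)
    n, m = mismatch.shape
    return _stratum_frame(
        mismatch.ravel(), cls.ravel(),
        np.broadcast_to(maf_bin, (n, m)).ravel(),
        np.broadcast_to(qual_bin, (n, m)).ravel(),
        maf_edges, quality_edges,
    )


# -- probability consistency --------------------------------------------------


def consistency_curve(
    pm: ProbMatrix,
    truth: np.ndarray,
    bin_width: float = 0.02,
    stratify: str = "quality",
    strata_edges: np.ndarray | None = None,
) -> pd.DataFrame:
    """Signed calibration deviation per genotype class and probability bin.

    For each class c and probability bin b, the deviation is the mean of
    ``P(class = c) - 1{truth = c}`` over entries whose stated P(class = c)
    falls in b: positive deviation means the imputer overstates the class
    probability.  Stratified by imputation quality (default) or MAF.
    Empty bins are reported with count 0 and NaN deviation.
    """
    if stratify not in ("quality", "maf"):
        raise ValidationError("stratify must be 'quality' or 'maf'")
    cls, maf, qual = _expand(pm, truth)
    if strata_edges is None:
        strata_edges = (
            DEFAULT_QUALITY_EDGES if stratify == "quality" else DEFAULT_MAF_EDGES
        )
    strata_edges = np.asarray(strata_edges, dtype=np.float64)
    svals = qual if stratify == "quality" else maf
    sbin = _bin_index(svals, strata_edges)
    n_bins = int(np.ceil(1.0 / bin_width))
    theta = pm.dosages().mean(axis=0) / 2.0
    flip = theta > 0.5
    rows = []
    valid = truth != MISSING
    for ci, label in enumerate(CLASS_LABELS):
        # probability assigned to minor-oriented class ci
        pcol = np.where(flip[None, :], pm.probs[:, :, 2 - ci], pm.probs[:, :, ci])
        ind = (cls == ci).astype(np.float64)
        pbin = np.minimum((pcol / bin_width).astype(np.int64), n_bins - 1)
        for sb in range(len(strata_edges) - 1):
            mask_s = valid & (sbin[None, :] == sb)
            pb = pbin[mask_s]
            dev = (pcol - ind)[mask_s]
            for b in range(n_bins):
                sel = pb == b
                cnt = int(sel.sum())
                if cnt:
                    mean = float(dev[sel].mean())
                    sd = float(dev[sel].std(ddof=1)) if cnt > 1 else 0.0
                    ci_hw = 1.96 * sd / np.sqrt(cnt)
                else:
                    mean, ci_hw = float("nan"), float("nan")
                rows.append(
                    {"stratum": stratify,
                     "stratum_left": strata_edges[sb],
                     "stratum_right": strata_edges[sb + 1],
                     "genotype_class": label,
                     "prob_bin_left": round(b * bin_width, 10),
                     "deviation": mean, "ci_halfwidth": ci_hw,
                     "count": cnt}
                )
    return pd.DataFrame(rows)


def frequency_baseline(maf: float, counted_is_minor: bool = True) -> pd.DataFrame:
    """Expected discordance per true class for a frequency-only predictor.

    The no-LD baseline predicts the same dosage 2q (twice the counted-allele
    frequency) for every sample, so a true class with count g has expected
    discordance |g - 2q| / 2.  This is one reading of a
    haplotype-independence baseline; it is labeled as such in output.
    """
    if not (0.0 < maf <= 0.5):
        raise ValidationError(f"maf {maf} outside (0, 0.5]")
    q = maf if counted_is_minor else 1.0 - maf
    rows = []
    for g, label in enumerate(CLASS_LABELS):
        count = g if counted_is_minor else 2 - g
        rows.append(
            {"genotype_class": label,
             "baseline_discordance": abs(count - 2.0 * q) / 2.0}
        )
    return pd.DataFrame(rows)


def select_mask(
    n_variants: int, fraction: float = 0.1, seed: int = 0
) -> np.ndarray:
    """Random variant indices to hold out when preparing masked-truth input."""
    if not (0.0 < fraction < 1.0):
        raise ValidationError(f"fraction {fraction} outside (0, 1)")
    rng = np.random.default_rng(seed)
    k = max(1, int(round(fraction * n_variants)))
    return np.sort(rng.choice(n_variants, size=k, replace=False))


# -- optional plotting --------------------------------------------------------


def plot_discordance_strata(table: pd.DataFrame, ax=None):
    """Bar panel of mean discordance by MAF bin, grouped by genotype class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    width = 0.25
    for i, label in enumerate(CLASS_LABELS):
        sub = table[table["genotype_class"] == label]
        x = sub["maf_bin_left"].to_numpy() + width * 0.05 * i
        ax.bar(x + i * width * 0.05, sub["mean_discordance"],
               width=width * 0.05, yerr=sub["ci_halfwidth"], label=label)
    ax.set_xlabel("minor allele frequency bin")
    ax.set_ylabel("mean discordance")
    ax.legend()
    return ax


def plot_consistency_curve(table: pd.DataFrame, ax=None):
    """Calibration-deviation curve per genotype class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label in CLASS_LABELS:
        sub = table[(table["genotype_class"] == label) & (table["count"] > 0)]
        ax.errorbar(sub["prob_bin_left"], sub["deviation"],
                    yerr=sub["ci_halfwidth"], label=label, fmt=".-")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("stated class probability bin")
    ax.set_ylabel("deviation (stated - observed)")
    ax.legend()
    return ax
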