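"""Core types and elementary transforms for genotype probability triples.

A biallelic imputed genotype is a posterior distribution over the three
genotype classes, stored as a triple ``(p0, p1, p2)`` where the index is the
number of copies of the *counted* allele carried by the sample.  Everything
downstream — allelic dosage, best-guess calls, random genotype draws for
multiple imputation, and per-variant quality metrics — is a transform of
these triples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

# -- module-wide constants ---------------------------------------------------

#: tolerance on |p0+p1+p2 - 1| accepted at parse time (text files truncate)
PROB_SUM_TOL = 1e-3

#: sentinel for a missing genotype call in integer genotype arrays
MISSING = -1

#: default imputation-quality threshold: variants below it are removed
DEFAULT_QUALITY_THRESHOLD = 0.4

#: default number of multiple-imputation draws
DEFAULT_DRAWS = 10

#: below this, a between-draw variance is treated as exactly zero
SB2_EPS = 1e-12


class ValidationError(ValueError):
    """Malformed input data (non-normalizable triple, bad file record...)."""


class UndefinedQualityError(ValueError):
    """Quality metric undefined (monomorphic column or too few samples)."""


# -- domain types ------------------------------------------------------------


@dataclass(frozen=True)
class VariantMeta:
    """Identity and summary metadata for one biallelic variant.

    ``allele_b`` is the counted allele: genotype integers and dosages count
    copies of it.  ``quality`` is the producer-supplied imputation quality
    (IMPUTE2 info or minimac r2 dialect; NaN when absent and not yet
    computed).
    """

    variant_id: str
    chrom: str = "0"
    pos: int = 0
    allele_a: str = "A"
    allele_b: str = "B"
    maf: float = float("nan")
    quality: float = float("nan")

    def __post_init__(self) -> None:
        if np.isfinite(self.maf) and not (0.0 <= self.maf <= 0.5):
            raise ValidationError(
                f"{self.variant_id}: maf {self.maf} outside [0, 0.5]"
            )
        if np.isfinite(self.quality) and self.quality < 0:
            raise ValidationError(
                f"{self.variant_id}: negative quality {self.quality}"
            )


@dataclass
class ProbMatrix:
    """N samples x M variants of genotype probability triples.

    ``probs`` has shape (N, M, 3), axis 2 ordered as (hom non-counted,
    het, hom counted).  Triples are renormalized at construction.
    """

    samples: list[str]
    variants: list[VariantMeta]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        n, m = len(self.samples), len(self.variants)
        if self.probs.shape != (n, m, 3):
            raise ValidationError(
                f"probs shape {self.probs.shape} != ({n}, {m}, 3)"
            )
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate variant IDs: {dupes[:5]}")
        self.probs = validate_triples(self.probs)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def dosages(self) -> np.ndarray:
        """Expected counted-allele count per sample x variant, in [0, 2]."""
        return dosage(self.probs)

    def best_guess(self, call_threshold: float = 1.0 / 3.0) -> np.ndarray:
        """Hard calls (N, M) int8 with :data:`MISSING` below threshold."""
        return best_guess(self.probs, call_threshold)

    def variant_frame(self) -> pd.DataFrame:
        """Variant metadata as a DataFrame (one row per variant, in order)."""
        return pd.DataFrame(
            {
                "variant_id": [v.variant_id for v in self.variants],
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "allele_a": [v.allele_a for v in self.variants],
                "allele_b": [v.allele_b for v in self.variants],
                "maf": [v.maf for v in self.variants],
                "quality": [v.quality for v in self.variants],
            }
        )

    def subset_variants(self, index: Sequence[int]) -> "ProbMatrix":
        index = list(index)
        return ProbMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in index],
            probs=self.probs[:, index, :],
        )

    def with_computed_metadata(self, metric: str = "impute2") -> "ProbMatrix":
        """Fill NaN maf/quality from the probability columns themselves."""
        fn = impute2_info if metric == "impute2" else minimac_r2
        new = []
        for j, v in enumerate(self.variants):
            col = self.probs[:, j, :]
            theta = float(np.mean(dosage(col)) / 2.0)
            maf = v.maf if np.isfinite(v.maf) else min(theta, 1.0 - theta)
            qual = v.quality
            if not np.isfinite(qual):
                try:
                    qual = fn(col)
                except UndefinedQualityError:
                    qual = float("nan")
            new.append(replace(v, maf=maf, quality=qual))
        return ProbMatrix(list(self.samples), new, self.probs.copy())


# -- elementary transforms ---------------------------------------------------


def validate_triples(probs: np.ndarray) -> np.ndarray:
    """Validate and renormalize an array of triples (last axis length 3).

    Components must be non-negative and each triple must sum to 1 within
    :data:`PROB_SUM_TOL`; accepted triples are rescaled to sum exactly to 1.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if probs.shape[-1] != 3:
        raise ValidationError(f"last axis must be 3, got {probs.shape}")
    if np.any(probs < 0) or not np.all(np.isfinite(probs)):
        bad = np.argwhere(~np.all((probs >= 0) & np.isfinite(probs), axis=-1))
        raise ValidationError(
            f"negative or non-finite probability at index {tuple(bad[0])}"
        )
    s = probs.sum(axis=-1)
    off = np.abs(s - 1.0) > PROB_SUM_TOL
    if np.any(off):
        bad = np.argwhere(off)
        raise ValidationError(
            f"triple sums to {s[tuple(bad[0])]:.6g} at index {tuple(bad[0])}"
            f" (tolerance {PROB_SUM_TOL})"
        )
    return probs / s[..., None]


def dosage(probs: np.ndarray) -> np.ndarray:
    """Allelic dosage 2*p2 + p1: expected counted-allele count in [0, 2]."""
    probs = np.asarray(probs, dtype=np.float64)
    return 2.0 * probs[..., 2] + probs[..., 1]


def discordance(d, g):
    """Fraction difference |g - d| / 2 between dosage and true count.

    ``d`` is a dosage in [0, 2], ``g`` a true genotype count in {0, 1, 2};
    the result lies in [0, 1].  Pairs with missing ``g`` must be excluded
    by the caller (use a mask of ``g != MISSING``).
    """
    d = np.asarray(d, dtype=np.float64)
    g = np.asarray(g)
    if np.any(g == MISSING):
        raise ValidationError("missing genotype in discordance input")
    return np.abs(np.asarray(g, dtype=np.float64) - d) / 2.0


def best_guess(probs: np.ndarray, call_threshold: float = 1.0 / 3.0) -> np.ndarray:
    """Most-probable genotype class, thresholded.

    Returns int8 counts; entries whose maximal class probability is below
    ``call_threshold`` are :data:`MISSING`.  Ties are broken toward the
    lower allele count (p0 over p1 over p2).
    """
    if not (1.0 / 3.0 - 1e-12 <= call_threshold <= 1.0):
        raise ValidationError(f"call_threshold {call_threshold} not in [1/3, 1]")
    probs = validate_triples(probs)
    # np.argmax returns the first maximum: index order 0,1,2 = count order,
    # which is exactly the documented tie-break.
    calls = np.argmax(probs, axis=-1)
    top = np.max(probs, axis=-1)
    return np.where(top < call_threshold, MISSING, calls).astype(np.int8)


def draw_genotypes(
    probs: np.ndarray, rng: np.random.Generator, n_draws: int = 1
) -> np.ndarray:
    """Sample integer genotypes from triples.

    ``probs`` has shape (..., 3); the result has shape (n_draws, ...), int8.
    The same generator state yields the same draws.
    """
    probs = validate_triples(probs)
    c0 = probs[..., 0]
    c01 = probs[..., 0] + probs[..., 1]
    u = rng.random(size=(n_draws,) + probs.shape[:-1])
    return ((u >= c0).astype(np.int8) + (u >= c01).astype(np.int8))


def variant_rng(seed: int, variant_index: int) -> np.random.Generator:
    """Counter-derived RNG substream for one variant.

    Uses the Philox counter-based generator keyed by the root seed and
    advanced to a per-variant offset, so draws for a variant are identical
    whatever order variants are processed in.
    """
    bg = np.random.Philox(key=seed)
    bg.advance(int(variant_index) * (1 << 64))
    return np.random.Generator(bg)


# -- per-variant quality metrics ---------------------------------------------


def _theta_hat(col: np.ndarray) -> float:
    e = dosage(col)
    return float(np.sum(e) / (2.0 * e.shape[0]))


def impute2_info(col: np.ndarray) -> float:
    """IMPUTE2-style info metric for one variant's probability column.

    With per-sample expected count ``e_j = 2 p2 + p1`` and expected squared
    count ``f_j = p1 + 4 p2``, info is ``1 - sum(f_j - e_j^2) /
    (2 N theta (1 - theta))`` where ``theta`` is the estimated counted-allele
    frequency.  The ratio term is the mean posterior genotype variance over
    the binomial variance expected at that frequency.  Clamped to [0, 1].
    """
    col = validate_triples(np.asarray(col, dtype=np.float64))
    if col.ndim != 2 or col.shape[0] < 2:
        raise UndefinedQualityError("need >= 2 samples for a quality metric")
    e = dosage(col)
    theta = _theta_hat(col)
    if theta <= 0.0 or theta >= 1.0:
        raise UndefinedQualityError(f"monomorphic column (theta={theta})")
    f = col[:, 1] + 4.0 * col[:, 2]
    n = col.shape[0]
    info = 1.0 - np.sum(f - e**2) / (2.0 * n * theta * (1.0 - theta))
    return float(min(1.0, max(0.0, info)))


def minimac_r2(col: np.ndarray) -> float:
    """minimac-style r2: empirical dosage variance over binomial variance.

    Not clamped: values above 1 indicate dosage variance exceeding the
    Hardy-Weinberg binomial expectation.
    """
    col = validate_triples(np.asarray(col, dtype=np.float64))
    if col.ndim != 2 or col.shape[0] < 2:
        raise UndefinedQualityError("need >= 2 samples for a quality metric")
    e = dosage(col)
    theta = _theta_hat(col)
    if theta <= 0.0 or theta >= 1.0:
        raise UndefinedQualityError(f"monomorphic column (theta={theta})")
    return float(np.var(e) / (2.0 * theta * (1.0 - theta)))


def quality_filter(
    variants: Sequence[VariantMeta],
    threshold: float = DEFAULT_QUALITY_THRESHOLD,
) -> list[VariantMeta]:
    """Variants passing the quality filter (quality >= threshold).

    Mirrors the standard post-imputation step of removing variants with a
    quality metric below 0.4; the boundary is retained ("less than ...
    removed").  Variants with NaN quality are removed.
    """
    return [
        v
        for v in variants
        if np.isfinite(v.quality) and v.quality >= threshold
    ]


def quality_filter_mask(
    qualities: np.ndarray, threshold: float = DEFAULT_QUALITY_THRESHOLD
) -> np.ndarray:
    """Boolean retain-mask over an array of quality values."""
    q = np.asarray(qualities, dtype=np.float64)
    return np.isfinite(q) & (q >= threshold)
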