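"""Synthetic genotype-probability data with controllable quality and bias.

The generator emulates the statistical structure of imputed GWAS data
without modeling linkage disequilibrium (single-variant analyses only need
per-variant marginals):

* true genotypes are drawn from Hardy-Weinberg equilibrium at a per-variant
  minor allele frequency;
* each genotype is passed through a symmetric allele-flip observation
  channel (each of the two alleles is misread independently with
  probability eps), and the emitted probability triple is the exact
  posterior P(g | observation) under the HWE prior — calibrated by
  construction;
* the channel error rate is root-found per variant so the *expected*
  IMPUTE2-style info metric of the column equals a target quality drawn
  from a spectrum shaped like real post-imputation quality distributions
  (about 40% of variants above 0.9, about 18% in (0.8, 0.9], the remainder
  spread down to the conventional 0.4 filter threshold);
* optional distortions then emulate imputer miscalibration: shrinkage of
  the posterior toward the HWE prior (lambda) and a class-specific shift of
  probability mass between the heterozygote and the homozygote classes
  (delta), mirroring the complementary het-vs-hom bias pattern seen in real
  imputation output;
* the quantitative phenotype is sum(beta_j g_j) over causal variants plus
  Gaussian noise, computed from the *true* genotypes.

Closed-form expected dosage discordance per (variant, true class) is
exported so diagnostics can be checked against an analytic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration_diag import CLASS_LABELS
from .gp_core import ProbMatrix, ValidationError, VariantMeta, dosage, variant_rng
from .gp_io import PhenotypeTable, write_gen

#: S2-shaped quality spectrum: (weight, low, high) mixture components
QUALITY_S2_MIXTURE = ((0.42, 0.4, 0.8), (0.18, 0.8, 0.9), (0.40, 0.9, 1.0))

#: bisection tolerance when solving the channel error for a target quality
QUALITY_SOLVE_TOL = 1e-4


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort.

    ``maf_dist`` and ``quality_dist`` are ("uniform", lo, hi),
    ("fixed", value), or ("s2",) for the default quality spectrum.
    ``causal_effects`` maps variant index to per-allele effect (trait
    units/allele); alternatively ``causal_fraction``/``causal_beta`` select
    a random causal set.  ``shrink_lambda`` in [0, 1) shrinks emitted
    triples toward the HWE prior; ``class_bias_delta`` in (-1, 1) moves
    mass toward the heterozygote (positive) or the homozygotes (negative).
    """

    n_samples: int = 2000
    n_variants: int = 2000
    maf_dist: tuple = ("uniform", 0.01, 0.5)
    quality_dist: tuple = ("s2",)
    causal_effects: dict[int, float] | None = None
    causal_fraction: float = 0.0
    causal_beta: float = 0.0
    noise_sd: float = 1.0
    shrink_lambda: float = 0.0
    class_bias_delta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_variants < 1:
            raise ValidationError("need >= 2 samples and >= 1 variant")
        if not (0.0 <= self.shrink_lambda < 1.0):
            raise ValidationError("shrink_lambda must be in [0, 1)")
        if not (-1.0 < self.class_bias_delta < 1.0):
            raise ValidationError("class_bias_delta must be in (-1, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class SimOutput:
    """Simulated cohort: truth, probabilities, phenotype, and oracles."""

    config: SimConfig
    truth: np.ndarray  # (N, M) int8 true counted-allele counts
    pm: ProbMatrix  # emitted probability triples with realized metadata
    phenotypes: PhenotypeTable
    maf: np.ndarray  # configured per-variant minor allele frequency
    target_quality: np.ndarray  # quality targets the channel was solved for
    channel_eps: np.ndarray  # per-variant allele-flip error rates
    causal_effects: dict[int, float]
    expected_discordance: pd.DataFrame  # variant_id x class analytic oracle

    def expected_stratum_discordance(
        self, maf_edges: np.ndarray, quality_edges: np.ndarray
    ) -> pd.DataFrame:
        """Analytic expected mean discordance per stratum.

        Weights each variant's per-class expectation by the realized number
        of truth entries of that class, reproducing what the empirical
        stratum mean estimates.
        """
        meta = self.pm.variant_frame()
        counts = np.stack(
            [(self.truth == g).sum(axis=0) for g in range(3)], axis=1
        )
        # orient classes by the *realized* counted-allele frequency, exactly
        # as the empirical stratification does
        theta = self.pm.dosages().mean(axis=0) / 2.0
        flip = theta > 0.5
        df = self.expected_discordance.merge(
            meta[["variant_id", "maf", "quality"]], on="variant_id"
        )
        g_idx = df["genotype_class"].map(CLASS_LABELS.index).to_numpy()
        flipped = flip[df["variant_index"].to_numpy()]
        label_idx = np.where(flipped, 2 - g_idx, g_idx)
        df["genotype_class"] = [CLASS_LABELS[i] for i in label_idx]
        df["count"] = counts[df["variant_index"].to_numpy(), g_idx]
        df["maf_bin"] = np.searchsorted(maf_edges, df["maf"], side="left") - 1
        df["qual_bin"] = (
            np.searchsorted(quality_edges, df["quality"], side="left") - 1
        )
        ok = (
            (df["maf_bin"] >= 0) & (df["maf_bin"] < len(maf_edges) - 1)
            & (df["qual_bin"] >= 0) & (df["qual_bin"] < len(quality_edges) - 1)
            & (df["count"] > 0)
        )
        df = df[ok]
        grp = df.groupby(["genotype_class", "maf_bin", "qual_bin"])
        out = grp.apply(
            lambda s: np.average(s["expected_discordance"], weights=s["count"]),
            include_groups=False,
        ).rename("expected_discordance").reset_index()
        out["maf_bin_left"] = maf_edges[out["maf_bin"]]
        out["quality_bin_left"] = quality_edges[out["qual_bin"]]
        return out


# -- channel mathematics ------------------------------------------------------


def channel_matrix(eps: np.ndarray) -> np.ndarray:
    """P(observed z | true g) for the symmetric allele-flip channel.

    Shape (..., 3, 3), axis -2 = true genotype, axis -1 = observation.
    """
    e = np.asarray(eps, dtype=np.float64)
    o = 1.0 - e
    c = np.empty(e.shape + (3, 3))
    c[..., 0, 0] = o * o
    c[..., 0, 1] = 2 * e * o
    c[..., 0, 2] = e * e
    c[..., 1, 0] = e * o
    c[..., 1, 1] = o * o + e * e
    c[..., 1, 2] = e * o
    c[..., 2, 0] = e * e
    c[..., 2, 1] = 2 * e * o
    c[..., 2, 2] = o * o
    return c


def hwe_prior(q: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities at counted-allele frequency q."""
    q = np.asarray(q, dtype=np.float64)
    return np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=-1)


def posterior_table(q: np.ndarray, eps: np.ndarray):
    """(posterior P(g | z), marginal P(z)), both shaped (..., 3[, 3]).

    Posterior axis -2 indexes the observation z, axis -1 the genotype g.
    """
    prior = hwe_prior(q)  # (..., g)
    c = channel_matrix(eps)  # (..., g, z)
    joint = prior[..., :, None] * c  # (..., g, z)
    pz = joint.sum(axis=-2)  # (..., z)
    post = np.moveaxis(joint, -2, -1) / pz[..., :, None]  # (..., z, g)
    return post, pz


def expected_info(q: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Expected IMPUTE2-style info of a channel column at frequency q.

    info = 1 - E_z[Var(g | z)] / (2 q (1 - q)): one minus the mean posterior
    variance over the HWE binomial variance.
    """
    post, pz = posterior_table(q, eps)
    g = np.arange(3.0)
    eg = (post * g).sum(axis=-1)
    eg2 = (post * g**2).sum(axis=-1)
    var = np.maximum(eg2 - eg**2, 0.0)
    denom = 2.0 * np.asarray(q) * (1.0 - np.asarray(q))
    return 1.0 - (pz * var).sum(axis=-1) / denom


def solve_channel_eps(
    q: np.ndarray, target: np.ndarray, tol: float = QUALITY_SOLVE_TOL
) -> np.ndarray:
    """Allele-flip rate whose expected info equals the target quality.

    Expected info decreases monotonically from 1 (eps = 0) to 0
    (eps = 0.5, observation independent of truth), so any target in [0, 1]
    is attainable; solved by vectorized bisection.
    """
    q = np.atleast_1d(np.asarray(q, dtype=np.float64))
    target = np.broadcast_to(
        np.asarray(target, dtype=np.float64), q.shape
    ).copy()
    if np.any((target < 0) | (target > 1)):
        raise ValidationError("target quality outside [0, 1]")
    lo = np.zeros_like(q)
    hi = np.full_like(q, 0.5)
    for _ in range(int(np.ceil(np.log2(0.5 / tol))) + 5):
        mid = 0.5 * (lo + hi)
        too_low = expected_info(q, mid) < target
        hi = np.where(too_low, mid, hi)
        lo = np.where(too_low, lo, mid)
    eps = 0.5 * (lo + hi)
    # exact endpoints: a perfect-quality target is the noiseless channel
    eps = np.where(target >= 1.0, 0.0, eps)
    eps = np.where(target <= 0.0, 0.5, eps)
    return eps


def distort_triples(
    triples: np.ndarray,
    prior: np.ndarray,
    shrink_lambda: float = 0.0,
    class_bias_delta: float = 0.0,
) -> np.ndarray:
    """Apply miscalibration distortions to probability triples.

    Shrinkage mixes each triple toward its HWE prior; the class bias moves
    a fraction |delta| of homozygote mass to the heterozygote (delta > 0)
    or of heterozygote mass to the homozygotes, split in proportion to
    their current masses (delta < 0).  Results remain valid triples.
    """
    t = np.asarray(triples, dtype=np.float64).copy()
    if shrink_lambda:
        t = (1.0 - shrink_lambda) * t + shrink_lambda * prior
    d = class_bias_delta
    if d > 0:
        hom = t[..., 0] + t[..., 2]
        t[..., 1] = t[..., 1] + d * hom
        t[..., 0] = t[..., 0] * (1.0 - d)
        t[..., 2] = t[..., 2] * (1.0 - d)
    elif d < 0:
        take = -d * t[..., 1]
        hom = t[..., 0] + t[..., 2]
        w0 = np.where(hom > 0, t[..., 0] / np.where(hom > 0, hom, 1.0), 0.5)
        t[..., 0] = t[..., 0] + take * w0
        t[..., 2] = t[..., 2] + take * (1.0 - w0)
        t[..., 1] = t[..., 1] + d * t[..., 1]
    return t


# -- the generator ------------------------------------------------------------


def _sample_dist(spec: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec[0]
    if kind == "fixed":
        return np.full(size, float(spec[1]))
    if kind == "uniform":
        return rng.uniform(float(spec[1]), float(spec[2]), size)
    if kind == "s2":
        weights = np.array([w for w, _, _ in QUALITY_S2_MIXTURE])
        comp = rng.choice(len(QUALITY_S2_MIXTURE), size=size, p=weights)
        lo = np.array([a for _, a, _ in QUALITY_S2_MIXTURE])[comp]
        hi = np.array([b for _, _, b in QUALITY_S2_MIXTURE])[comp]
        return rng.uniform(lo, hi)
    raise ValidationError(f"unknown distribution spec {spec!r}")


def simulate(config: SimConfig) -> SimOutput:
    """Generate one cohort under the configured study conditions.

    Reproducible: the same config (including seed) yields bit-identical
    output.  Per-variant truth/observation draws use the same counter-based
    substream scheme as the MI engine, so results do not depend on variant
    processing order.
    """
    n, m = config.n_samples, config.n_variants
    rng_global = np.random.default_rng([config.seed, 0x5EED])
    maf = _sample_dist(config.maf_dist, m, rng_global)
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValidationError("maf draws must lie in (0, 0.5]")
    target = np.clip(_sample_dist(config.quality_dist, m, rng_global), 0.0, 1.0)
    eps = solve_channel_eps(maf, target)
    cmat = channel_matrix(eps)  # (m, g, z)
    post, _ = posterior_table(maf, eps)  # (m, z, g)
    prior = hwe_prior(maf)  # (m, g)
    emitted = distort_triples(
        post, prior[:, None, :], config.shrink_lambda, config.class_bias_delta
    )  # (m, z, g)

    truth = np.empty((n, m), dtype=np.int8)
    probs = np.empty((n, m, 3))
    c_cum = np.cumsum(cmat, axis=-1)  # (m, g, z)
    p_cum = np.cumsum(prior, axis=-1)  # (m, g)
    for j in range(m):
        rng = variant_rng(config.seed, j)
        u = rng.random(n)
        g = (u >= p_cum[j, 0]).astype(np.int8) + (u >= p_cum[j, 1]).astype(
            np.int8
        )
        u2 = rng.random(n)
        z = (u2 >= c_cum[j, g, 0]).astype(np.int8) + (
            u2 >= c_cum[j, g, 1]
        ).astype(np.int8)
        truth[:, j] = g
        probs[:, j, :] = emitted[j, z, :]

    causal = dict(config.causal_effects or {})
    if not causal and config.causal_fraction > 0:
        k = int(round(config.causal_fraction * m))
        idx = rng_global.choice(m, size=k, replace=False)
        causal = {int(i): float(config.causal_beta) for i in idx}
    rng_pheno = np.random.default_rng([config.seed, 0xFE40])
    y = rng_pheno.normal(0.0, config.noise_sd, n)
    for j, beta in causal.items():
        y = y + beta * truth[:, j]

    samples = [f"S{i:05d}" for i in range(n)]
    variants = [
        VariantMeta(
            variant_id=f"var{j:06d}", chrom="1", pos=j + 1,
            allele_a="A", allele_b="B",
        )
        for j in range(m)
    ]
    pm = ProbMatrix(samples, variants, probs).with_computed_metadata()
    pheno = PhenotypeTable(
        pd.DataFrame({"trait": y}, index=pd.Index(samples, name="sample_id")),
        trait="trait",
        covariates=[],
    )

    # analytic oracle: E[|g - dosage(emitted)| / 2 | true g] per variant
    e_z = dosage(emitted)  # (m, z)
    g_arr = np.arange(3.0)
    disc = np.einsum(
        "mgz,mgz->mg", cmat, np.abs(g_arr[None, :, None] - e_z[:, None, :]) / 2.0
    )
    oracle = pd.DataFrame(
        {
            "variant_index": np.repeat(np.arange(m), 3),
            "variant_id": np.repeat([v.variant_id for v in variants], 3),
            "genotype_class": CLASS_LABELS * m,
            "expected_discordance": disc.ravel(),
        }
    )
    return SimOutput(
        config=config, truth=truth, pm=pm, phenotypes=pheno, maf=maf,
        target_quality=target, channel_eps=eps, causal_effects=causal,
        expected_discordance=oracle,
    )


def truth_prob_matrix(sim: SimOutput) -> ProbMatrix:
    """The truth genotypes as a degenerate-triple ProbMatrix."""
    n, m = sim.truth.shape
    probs = np.zeros((n, m, 3))
    for g in range(3):
        probs[..., g] = sim.truth == g
    return ProbMatrix(
        list(sim.pm.samples), list(sim.pm.variants), probs
    )


def write_fixture(sim: SimOutput, outdir, gzip_files: bool = False) -> dict[str, str]:
    """Materialize a simulated cohort as the text formats the readers parse.

    Writes probabilities (.gen/.sample), truth (.gen with degenerate
    triples), and the phenotype table; returns the path map.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    ext = ".gz" if gzip_files else ""
    paths = {
        "gen": os.path.join(outdir, f"probs.gen{ext}"),
        "sample": os.path.join(outdir, "probs.sample"),
        "truth_gen": os.path.join(outdir, f"truth.gen{ext}"),
        "truth_sample": os.path.join(outdir, "truth.sample"),
        "phenotypes": os.path.join(outdir, "phenotypes.tsv"),
    }
    write_gen(sim.pm, paths["gen"], paths["sample"])
    write_gen(truth_prob_matrix(sim), paths["truth_gen"], paths["truth_sample"])
    sim.phenotypes.frame.to_csv(paths["phenotypes"], sep="\t")
    return paths


def small_fixture_config(seed: int = 0, **overrides) -> SimConfig:
    """Small test-set conditions (200 samples x 500 variants)."""
    return SimConfig(n_samples=200, n_variants=500, seed=seed, **overrides)


def medium_fixture_config(seed: int = 0, **overrides) -> SimConfig:
    """Medium test-set conditions (2000 samples x 20000 variants)."""
    return SimConfig(n_samples=2000, n_variants=20000, seed=seed, **overrides)
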