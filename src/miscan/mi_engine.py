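"""Multiple-imputation association scans and Rubin's-rules combination.

The central procedure: realize ``d`` complete genotype datasets by sampling
each sample's genotype from its posterior triple, run the association
regression on every draw, and combine the ``d`` per-draw estimates
``{beta_i, s_i^2}`` into a single test with within-draw (s_W^2) and
between-draw (s_B^2) variance components:

    beta_MI = mean(beta_i)
    s_W^2   = mean(s_i^2)
    s_B^2   = var(beta_i)            (sample variance, d - 1 denominator)
    s_MI^2  = s_W^2 + (1 + 1/d) s_B^2
    t       = beta_MI / s_MI
    df      = (d - 1) (1 + d s_W^2 / ((d + 1) s_B^2))^2

with p two-sided from the T distribution; when s_B^2 = 0 the reference is
normal (df infinite).  Comparator scans (allelic dosage, thresholded
best-guess) share the same OLS core so that on perfect-confidence data all
scans agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gp_core import (
    DEFAULT_DRAWS,
    MISSING,
    SB2_EPS,
    ProbMatrix,
    ValidationError,
    draw_genotypes,
    variant_rng,
)
from .gp_io import PhenotypeTable

#: status flags attached to each scanned variant
STATUS_OK = "ok"
STATUS_CONSTANT = "constant_predictor"
STATUS_EXACT = "exact_fit"
STATUS_INSUFFICIENT = "insufficient_samples"


class InsufficientDrawsError(ValidationError):
    pass


# -- ordinary least squares core ---------------------------------------------


def _design_basis(n: int, covariates: np.ndarray | None) -> np.ndarray:
    """Orthonormal basis Q of the nuisance design [intercept | covariates]."""
    if covariates is None:
        x = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=np.float64)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        x = np.column_stack([np.ones(n), covariates])
    q, r = np.linalg.qr(x)
    if np.min(np.abs(np.diag(r))) < 1e-10 * max(1.0, np.max(np.abs(r))):
        raise ValidationError("collinear covariates (design not full rank)")
    return q

def ols_many(
    G: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    q_basis: np.ndarray | None = None,
) -> pd.DataFrame:
    """OLS of ``y`` on each column of ``G`` plus intercept and covariates.

    Closed form via the Frisch-Waugh-Lovell projection: ``y`` and each
    genotype column are residualized against the nuisance design, the
    per-column slope is a simple regression of the residuals, and the
    squared standard error uses the full residual degrees of freedom — so
    results equal a full multiple regression exactly.

    ``G`` may contain NaN (missing per-variant values); those columns are
    recomputed per-column on the complete cases.

    Returns columns ``beta``, ``se2``, ``n``, ``dof``, ``status``.
    """
    G = np.asarray(G, dtype=np.float64)
    if G.ndim == 1:
        G = G[:, None]
    y = np.asarray(y, dtype=np.float64)
    n, m = G.shape
    k = 1 if covariates is None else (
        1 + (1 if np.ndim(covariates) == 1 else np.shape(covariates)[1])
    )
    dof = n - k - 1
    beta = np.full(m, np.nan)
    se2 = np.full(m, np.nan)
    nn = np.full(m, n, dtype=np.int64)
    dofs = np.full(m, max(dof, 0), dtype=np.int64)
    status = np.full(m, STATUS_OK, dtype=object)
    if dof < 1:
        status[:] = STATUS_INSUFFICIENT
        return pd.DataFrame({"beta": beta, "se2": se2, "n": nn,
                             "dof": dofs, "status": status})
    q = q_basis if q_basis is not None else _design_basis(n, covariates)
    yr = y - q @ (q.T @ y)
    yry = float(yr @ yr)

    nanmask = np.isnan(G)
    complete = ~nanmask.any(axis=0)
    if complete.any():
        gc = G[:, complete]
        gr = gc - q @ (q.T @ gc)
        gg = np.einsum("ij,ij->j", gr, gr)
        gy = gr.T @ yr
        ok = gg > 1e-10 * n
        b = np.where(ok, gy / np.where(ok, gg, 1.0), np.nan)
        rss = np.maximum(yry - b**2 * gg, 0.0)
        s2 = np.where(ok, rss / dof / np.where(ok, gg, 1.0), np.nan)
        idx = np.flatnonzero(complete)
        beta[idx], se2[idx] = b, s2
        status[idx[~ok]] = STATUS_CONSTANT
        exact = ok & (rss <= 1e-12 * max(yry, 1.0))
        status[idx[exact]] = STATUS_EXACT
    for j in np.flatnonzero(~complete):
        keep = ~nanmask[:, j]
        nj = int(keep.sum())
        nn[j] = nj
        if nj - k - 1 < 1:
            status[j] = STATUS_INSUFFICIENT
            continue
        cov_j = None
        if covariates is not None:
            cov_j = np.asarray(covariates, dtype=np.float64)
            cov_j = cov_j[keep] if cov_j.ndim == 1 else cov_j[keep, :]
        sub = ols_many(G[keep, j], y[keep], cov_j)
        beta[j] = sub.loc[0, "beta"]
        se2[j] = sub.loc[0, "se2"]
        dofs[j] = sub.loc[0, "dof"]
        status[j] = sub.loc[0, "status"]
    return pd.DataFrame(
        {"beta": beta, "se2": se2, "n": nn, "dof": dofs, "status": status}
    )


def ols_scan(
    g: np.ndarray,
    pheno: PhenotypeTable | np.ndarray,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant OLS scan on arbitrary predictor values (counts or dosages).

    ``g`` is (n,) or (n, m); missing values are NaN.  Adds the classical
    t-test p-value on the residual degrees of freedom.
    """
    if isinstance(pheno, PhenotypeTable):
        y, cov = pheno.arrays()
        if covariates is None:
            covariates = cov
    else:
        y = np.asarray(pheno, dtype=np.float64)
    res = ols_many(g, y, covariates)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = res["beta"] / np.sqrt(res["se2"])
        dofs = np.maximum(res["dof"].to_numpy(), 1)
        res["p"] = 2.0 * stats.t.sf(np.abs(t), dofs)
    return res


# -- Rubin's-rules combination ------------------------------------------------


@dataclass(frozen=True)
class MIResult:
    """Rubin-combined association result for one variant."""

    beta: float
    sw2: float
    sb2: float
    smi2: float
    t: float
    df: float  # may be inf
    p: float
    d: int


def _combine_arrays(B: np.ndarray, S2: np.ndarray):
    """Vectorized Rubin combination over axis 0 (draws)."""
    d = B.shape[0]
    beta = B.mean(axis=0)
    sw2 = S2.mean(axis=0)
    # when every draw agrees exactly (degenerate probabilities) report the
    # common value itself, so perfect-confidence data reproduce the
    # hard-call scan bit for bit
    same_b = B.max(axis=0) == B.min(axis=0)
    beta = np.where(same_b, B[0], beta)
    same_s = S2.max(axis=0) == S2.min(axis=0)
    sw2 = np.where(same_s, S2[0], sw2)
    sb2 = B.var(axis=0, ddof=1)
    sb2 = np.where(same_b, 0.0, sb2)
    smi2 = sw2 + (1.0 + 1.0 / d) * sb2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(smi2)
        df = np.where(
            sb2 > SB2_EPS,
            (d - 1.0) * (1.0 + d * sw2 / ((d + 1.0) * np.where(sb2 > SB2_EPS, sb2, 1.0))) ** 2,
            np.inf,
        )
        p = np.where(
            np.isinf(df),
            2.0 * stats.norm.sf(np.abs(t)),
            2.0 * stats.t.sf(np.abs(t), np.where(np.isfinite(df), df, 1.0)),
        )
    sb2 = np.where(sb2 > SB2_EPS, sb2, 0.0)
    return beta, sw2, sb2, smi2, t, df, p


def rubin_combine(betas, se2s) -> MIResult:
    """Combine d per-draw (beta_i, s_i^2) pairs into one MI result.

    With zero between-draw variance the draws are in perfect agreement and
    the reference distribution is normal (infinite df).
    """
    B = np.asarray(betas, dtype=np.float64).reshape(-1, 1)
    S2 = np.asarray(se2s, dtype=np.float64).reshape(-1, 1)
    if B.shape != S2.shape:
        raise ValidationError("betas and se2s differ in length")
    d = B.shape[0]
    if d < 2:
        raise InsufficientDrawsError(f"need >= 2 draws, got {d}")
    if np.any(S2 < 0):
        raise ValidationError("negative squared standard error")
    beta, sw2, sb2, smi2, t, df, p = _combine_arrays(B, S2)
    return MIResult(
        beta=float(beta[0]), sw2=float(sw2[0]), sb2=float(sb2[0]),
        smi2=float(smi2[0]), t=float(t[0]), df=float(df[0]),
        p=float(p[0]), d=d,
    )


# -- full scans ---------------------------------------------------------------


def _scan_frame(pm: ProbMatrix, body: pd.DataFrame) -> pd.DataFrame:
    meta = pm.variant_frame()
    return pd.concat([meta.reset_index(drop=True),
                      body.reset_index(drop=True)], axis=1)


def _draw_all(pm: ProbMatrix, d: int, seed: int) -> np.ndarray:
    """(d, n, m) int8 genotype draws, one counter substream per variant."""
    n, m = pm.n_samples, pm.n_variants
    out = np.empty((d, n, m), dtype=np.int8)
    for j in range(m):
        rng = variant_rng(seed, j)
        out[:, :, j] = draw_genotypes(pm.probs[:, j, :], rng, d)
    return out


def mi_scan(
    pm: ProbMatrix,
    pheno: PhenotypeTable | np.ndarray,
    covariates: np.ndarray | None = None,
    d: int = DEFAULT_DRAWS,
    seed: int = 0,
) -> pd.DataFrame:
    """Multiple-imputation association scan.

    Draws ``d`` complete datasets (one Philox counter substream per variant,
    so results do not depend on variant processing order), regresses the
    phenotype on each drawn genotype, and Rubin-combines per variant.

    A variant whose predictor is constant in any draw is flagged
    untestable (NaN statistics).  Returns one row per variant with the
    variant metadata plus beta, se2 (total MI variance), sw2, sb2, t, df,
    p, n, d, status.
    """
    if d < 2:
        raise InsufficientDrawsError(f"need >= 2 draws, got {d}")
    if isinstance(pheno, PhenotypeTable):
        pheno = pheno.aligned_to(pm.samples)
        if pheno.sample_ids != pm.samples:
            raise ValidationError(
                "phenotype table does not cover all genotyped samples; "
                "subset the ProbMatrix or the phenotype first"
            )
        y, cov = pheno.arrays()
        if covariates is None:
            covariates = cov
    else:
        y = np.asarray(pheno, dtype=np.float64)
    n, m = pm.n_samples, pm.n_variants
    draws = _draw_all(pm, d, seed)
    q = _design_basis(n, covariates)
    B = np.empty((d, m))
    S2 = np.empty((d, m))
    bad = np.zeros(m, dtype=bool)
    statuses = np.full(m, STATUS_OK, dtype=object)
    for i in range(d):
        res = ols_many(draws[i].astype(np.float64), y, covariates, q_basis=q)
        B[i] = res["beta"].to_numpy()
        S2[i] = res["se2"].to_numpy()
        draw_bad = res["status"].isin([STATUS_CONSTANT, STATUS_INSUFFICIENT])
        newly = draw_bad.to_numpy() & ~bad
        statuses[newly] = res["status"].to_numpy()[newly]
        bad |= draw_bad.to_numpy()
    beta, sw2, sb2, smi2, t, df, p = _combine_arrays(B, S2)
    for arr in (beta, sw2, sb2, smi2, t, df, p):
        arr[bad] = np.nan
    body = pd.DataFrame(
        {"beta": beta, "se2": smi2, "sw2": sw2, "sb2": sb2, "t": t,
         "df": df, "p": p, "n": n, "d": d, "status": statuses}
    )
    return _scan_frame(pm, body)


def dosage_scan(
    pm: ProbMatrix,
    pheno: PhenotypeTable | np.ndarray,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Association scan on the allelic dosage predictor (2 p2 + p1)."""
    if isinstance(pheno, PhenotypeTable):
        pheno = pheno.aligned_to(pm.samples)
        if pheno.sample_ids != pm.samples:
            raise ValidationError("phenotype/genotype sample mismatch")
    res = ols_scan(pm.dosages(), pheno, covariates)
    return _scan_frame(pm, res)


def bestguess_scan(
    pm: ProbMatrix,
    pheno: PhenotypeTable | np.ndarray,
    covariates: np.ndarray | None = None,
    call_threshold: float = 1.0 / 3.0,
) -> pd.DataFrame:
    """Association scan on thresholded best-guess calls.

    Samples whose maximal class probability is below ``call_threshold`` are
    dropped per variant (complete-case within variant).
    """
    if isinstance(pheno, PhenotypeTable):
        pheno = pheno.aligned_to(pm.samples)
        if pheno.sample_ids != pm.samples:
            raise ValidationError("phenotype/genotype sample mismatch")
    calls = pm.best_guess(call_threshold).astype(np.float64)
    calls[calls == MISSING] = np.nan
    res = ols_scan(calls, pheno, covariates)
    return _scan_frame(pm, res)


# -- draw-count convergence diagnostics ---------------------------------------


def draw_count_sweep(
    pm: ProbMatrix,
    pheno: PhenotypeTable | np.ndarray,
    truth_beta: np.ndarray,
    d_values: list[int],
    seed: int = 0,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Convergence of the MI scan in the number of draws.

    Draws are nested (the run at d' > d reuses the first d draws), matching
    the one-more-round reading of the between-draw stability diagnostic.
    For each d reports the Pearson correlation of beta_MI with
    ``truth_beta`` (estimates from the true/masked genotypes) and the
    distribution of |Delta s_B^2| against the previous d in the sweep.
    """
    d_values = sorted(set(int(x) for x in d_values))
    if d_values[0] < 2:
        raise InsufficientDrawsError("draw counts must be >= 2")
    if isinstance(pheno, PhenotypeTable):
        pheno = pheno.aligned_to(pm.samples)
        y, cov = pheno.arrays()
        if covariates is None:
            covariates = cov
    else:
        y = np.asarray(pheno, dtype=np.float64)
    truth_beta = np.asarray(truth_beta, dtype=np.float64)
    d_max = d_values[-1]
    n, m = pm.n_samples, pm.n_variants
    draws = _draw_all(pm, d_max, seed)
    q = _design_basis(n, covariates)
    B = np.empty((d_max, m))
    S2 = np.empty((d_max, m))
    for i in range(d_max):
        res = ols_many(draws[i].astype(np.float64), y, covariates, q_basis=q)
        B[i] = res["beta"].to_numpy()
        S2[i] = res["se2"].to_numpy()
    rows = []
    prev_sb2 = None
    for d in d_values:
        beta, sw2, sb2, *_ = _combine_arrays(B[:d], S2[:d])
        ok = np.isfinite(beta) & np.isfinite(truth_beta)
        if ok.sum() >= 3 and np.std(beta[ok]) > 0 and np.std(truth_beta[ok]) > 0:
            corr = float(np.corrcoef(beta[ok], truth_beta[ok])[0, 1])
        else:
            corr = 1.0 if ok.sum() else float("nan")
        if prev_sb2 is None:
            med = q90 = float("nan")
        else:
            delta = np.abs(sb2 - prev_sb2)
            delta = delta[np.isfinite(delta)]
            med = float(np.median(delta)) if delta.size else float("nan")
            q90 = float(np.quantile(delta, 0.9)) if delta.size else float("nan")
        prev_sb2 = sb2
        rows.append(
            {"d": d, "corr_beta": corr,
             "median_abs_delta_sb2": med, "q90_abs_delta_sb2": q90}
        )
    return pd.DataFrame(rows)


def scan_to_mi_summary(scan: pd.DataFrame) -> pd.DataFrame:
    """Project a scan table onto the MI summary interchange columns."""
    out = scan[["variant_id", "beta", "se2", "sw2", "sb2", "d"]].copy()
    return out.dropna(subset=["beta"])
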