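"""Nested-model meta-analysis of per-cohort multiple-imputation summaries.

Each of M cohorts contributes (beta_MI, s_W^2, s_B^2, d).  The nested
combination adds a between-site variance component on top of the
within-/between-draw components:

    beta_hat    = mean_i beta_MI,i
    sW_hat^2    = mean_i s_W,i^2
    sB_hat^2    = mean_i s_B,i^2
    smeta_hat^2 = sample variance of beta_MI,i        (M - 1 denominator)
    s_hat^2     = sW_hat^2 + (1 + 1/d) sB_hat^2 + (1 - 1/M) smeta_hat^2

The combination assumes a balanced design (equal draw count d across
cohorts); for unbalanced inputs the conservative substitution d = min(d_i)
is applied by default, and ``strict=True`` raises instead.

Degrees of freedom: the Satterthwaite-type expression is implemented as

    df = [ (1/(M (d-1))) ((1 - 1/d) sW_hat^2 / s_hat^2)^2
         + (1/(M-1))     ((1 + 1/M) smeta_hat^2 / s_hat^2)^2 ]^(-1)

i.e. the reciprocal of a sum of squared variance fractions, the standard
shape for such approximations; the raw components are exposed on the result
so an alternative reading can be applied downstream.  With M = 1 the meta
term vanishes and the single-study Rubin df is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gp_core import SB2_EPS, ValidationError


@dataclass(frozen=True)
class StudyMISummary:
    """One cohort's MI summary for one variant."""

    study_id: str
    beta: float
    sw2: float
    sb2: float
    d: int

    def __post_init__(self) -> None:
        if self.sw2 < 0 or self.sb2 < 0:
            raise ValidationError(f"{self.study_id}: negative variance component")
        if self.d < 2:
            raise ValidationError(f"{self.study_id}: d must be >= 2")


@dataclass(frozen=True)
class MetaResult:
    """Nested-model meta-analysis result."""

    beta: float
    sw2: float
    sb2: float
    smeta2: float
    s2: float
    t: float
    df: float
    p: float
    m: int
    d: int


def nested_meta(
    studies: Sequence[StudyMISummary], strict: bool = False
) -> MetaResult:
    """Combine per-cohort MI summaries with the nested-model equations.

    ``strict=True`` refuses unbalanced draw counts; otherwise the
    conservative d = min(d_i) is used for the weighting factors.
    """
    if not studies:
        raise ValidationError("no studies to meta-analyze")
    ds = {s.d for s in studies}
    if len(ds) > 1 and strict:
        raise ValidationError(f"unbalanced draw counts {sorted(ds)} in strict mode")
    d = min(ds)
    m = len(studies)
    betas = np.array([s.beta for s in studies], dtype=np.float64)
    beta = float(betas.mean())
    sw2 = float(np.mean([s.sw2 for s in studies]))
    sb2 = float(np.mean([s.sb2 for s in studies]))
    smeta2 = float(betas.var(ddof=1)) if m >= 2 else 0.0
    s2 = sw2 + (1.0 + 1.0 / d) * sb2 + (1.0 - 1.0 / m) * smeta2
    if s2 <= 0:
        raise ValidationError("total meta variance is zero")
    t = beta / np.sqrt(s2)
    if m == 1:
        # single cohort: plain Rubin reference distribution
        if sb2 > SB2_EPS:
            df = (d - 1.0) * (1.0 + d * sw2 / ((d + 1.0) * sb2)) ** 2
        else:
            df = np.inf
    else:
        inv = (1.0 / (m * (d - 1.0))) * ((1.0 - 1.0 / d) * sw2 / s2) ** 2
        inv += (1.0 / (m - 1.0)) * ((1.0 + 1.0 / m) * smeta2 / s2) ** 2
        df = np.inf if inv <= 0 else 1.0 / inv
    if np.isinf(df):
        p = 2.0 * stats.norm.sf(abs(t))
    else:
        p = 2.0 * stats.t.sf(abs(t), df)
    return MetaResult(
        beta=beta, sw2=sw2, sb2=sb2, smeta2=smeta2, s2=s2,
        t=float(t), df=float(df), p=float(p), m=m, d=d,
    )


def sb2_heterogeneity(studies: Sequence[StudyMISummary]) -> tuple[float, pd.DataFrame]:
    """Normalized dispersion of the between-draw variance components.

    An I^2-style statistic on the per-study s_B^2 values:

        Q_B  = sum_i (s_B,i^2 - mean)^2 / (mean^2 / M)
        stat = max(0, 1 - (M - 1) / Q_B)

    0 means homogeneous uncertainty across cohorts; values toward 1 flag
    cohorts whose imputation uncertainty is aberrant.  This construction is
    this package's own (the underlying heterogeneity test was proposed
    without a formula).  Returns (statistic, per-study component table).
    """
    m = len(studies)
    if m < 2:
        raise ValidationError("heterogeneity needs >= 2 studies")
    v = np.array([s.sb2 for s in studies], dtype=np.float64)
    table = pd.DataFrame(
        {"study_id": [s.study_id for s in studies], "sb2": v}
    )
    mean = v.mean()
    if mean <= 0:
        return 0.0, table
    qb = float(np.sum((v - mean) ** 2) / (mean**2 / m))
    stat = 0.0 if qb <= 0 else max(0.0, 1.0 - (m - 1.0) / qb)
    return stat, table


def meta_analyze_tables(
    summaries: dict[str, pd.DataFrame], strict: bool = False
) -> pd.DataFrame:
    """Variant-wise nested meta-analysis over per-cohort MI summary tables.

    ``summaries`` maps study ID to a table with the MI summary interchange
    columns (variant_id, beta, se2, sw2, sb2, d).  Variants are joined on
    variant_id; only variants present in at least one cohort appear, with
    M reflecting the cohorts actually contributing.  Output columns:
    variant_id, beta, se, sw2, sb2, smeta2, df, p, M, het.
    """
    if not summaries:
        raise ValidationError("no summary tables supplied")
    per_variant: dict[str, list[StudyMISummary]] = {}
    for study_id, df in summaries.items():
        for row in df.itertuples(index=False):
            per_variant.setdefault(str(row.variant_id), []).append(
                StudyMISummary(
                    study_id=study_id, beta=float(row.beta),
                    sw2=float(row.sw2), sb2=float(row.sb2), d=int(row.d),
                )
            )
    rows = []
    for vid, studies in per_variant.items():
        res = nested_meta(studies, strict=strict)
        het = (
            sb2_heterogeneity(studies)[0] if len(studies) >= 2 else float("nan")
        )
        rows.append(
            {"variant_id": vid, "beta": res.beta, "se": np.sqrt(res.s2),
             "sw2": res.sw2, "sb2": res.sb2, "smeta2": res.smeta2,
             "df": res.df, "p": res.p, "M": res.m, "het": het}
        )
    return pd.DataFrame(rows)
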