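"""Readers and writers: .gen/.sample, VCF GP/DS, phenotype tables, MI summaries.

All text inputs may be gzip-compressed (detected by the ``.gz`` suffix).
Parsers preserve sample and variant order and never reorder rows.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gp_core import (
    PROB_SUM_TOL,
    ProbMatrix,
    ValidationError,
    VariantMeta,
    dosage,
)

log = logging.getLogger(__name__)

#: fixed column set of the MI summary interchange format: the effect,
#: its total squared standard error, and the within-/between-draw variance
#: components needed for nested meta-analysis (per-draw results are not).
MI_SUMMARY_COLUMNS = ["variant_id", "beta", "se2", "sw2", "sb2", "d"]

#: documented sex recoding for phenotype tables
SEX_CODES = {"M": 0.0, "F": 1.0, "m": 0.0, "f": 1.0, "male": 0.0, "female": 1.0}


def _open_text(path) -> io.TextIOBase:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


# -- IMPUTE2 .gen / .sample ---------------------------------------------------


def read_sample(sample_path) -> list[str]:
    """Sample IDs from a .sample file (two header rows, IDs from ID_2)."""
    with _open_text(sample_path) as fh:
        header = fh.readline().split()
        if len(header) < 2:
            raise ValidationError(f"{sample_path}: malformed header")
        fh.readline()  # type row ("0 0 0 ...")
        ids = []
        for lineno, line in enumerate(fh, start=3):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise ValidationError(
                    f"{sample_path}:{lineno}: expected >= 2 columns"
                )
            ids.append(parts[1])
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{sample_path}: duplicate sample IDs")
    return ids


def read_gen(gen_path, sample_path, counted_allele: str = "B") -> ProbMatrix:
    """Parse an IMPUTE2-dialect .gen + .sample pair.

    Each .gen line is ``chunk_id rsid pos alleleA alleleB`` followed by one
    probability triple per sample in the order (AA, AB, BB).  By default
    allele B is counted; ``counted_allele="A"`` flips triples and alleles.

    Triples summing to 1 within ``PROB_SUM_TOL`` are renormalized; anything
    else raises a line-numbered :class:`ValidationError`.  maf and quality
    are estimated from the parsed columns.
    """
    if counted_allele not in ("A", "B"):
        raise ValidationError(f"counted_allele must be 'A' or 'B'")
    samples = read_sample(sample_path)
    n = len(samples)
    variants: list[VariantMeta] = []
    rows: list[np.ndarray] = []
    seen: set[str] = set()
    with _open_text(gen_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 5 + 3 * n:
                raise ValidationError(
                    f"{gen_path}:{lineno}: expected {5 + 3 * n} columns "
                    f"({n} samples), got {len(parts)}"
                )
            chrom, rsid, pos, allele_a, allele_b = parts[:5]
            if rsid in seen:
                raise ValidationError(
                    f"{gen_path}:{lineno}: duplicate variant ID {rsid!r}"
                )
            seen.add(rsid)
            try:
                trip = np.array(parts[5:], dtype=np.float64).reshape(n, 3)
            except ValueError as exc:
                raise ValidationError(
                    f"{gen_path}:{lineno}: malformed probability: {exc}"
                ) from None
            s = trip.sum(axis=1)
            if np.any(np.abs(s - 1.0) > PROB_SUM_TOL) or np.any(trip < 0):
                j = int(np.argmax(np.abs(s - 1.0)))
                raise ValidationError(
                    f"{gen_path}:{lineno}: triple for sample {samples[j]!r} "
                    f"sums to {s[j]:.6g}"
                )
            if counted_allele == "A":
                trip = trip[:, ::-1]
                allele_a, allele_b = allele_b, allele_a
            variants.append(
                VariantMeta(
                    variant_id=rsid,
                    chrom=chrom,
                    pos=int(pos),
                    allele_a=allele_a,
                    allele_b=allele_b,
                )
            )
            rows.append(trip)
    probs = (
        np.stack(rows, axis=1) if rows else np.empty((n, 0, 3), dtype=np.float64)
    )
    return ProbMatrix(samples, variants, probs).with_computed_metadata()


def write_gen(pm: ProbMatrix, gen_path, sample_path, precision: int = 6) -> None:
    """Write a ProbMatrix in the .gen/.sample dialect read by :func:`read_gen`."""
    gen_path, sample_path = os.fspath(gen_path), os.fspath(sample_path)
    opener = gzip.open if gen_path.endswith(".gz") else open
    with open(sample_path, "w", encoding="utf-8") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for s in pm.samples:
            fh.write(f"{s} {s} 0\n")
    fmt = f"%.{precision}f"
    with opener(gen_path, "wt", encoding="utf-8") as fh:
        for j, v in enumerate(pm.variants):
            head = f"{v.chrom} {v.variant_id} {v.pos} {v.allele_a} {v.allele_b}"
            body = " ".join(fmt % x for x in pm.probs[:, j, :].ravel())
            fh.write(head + " " + body + "\n")


# -- VCF with GP and/or DS ----------------------------------------------------


def dosage_to_triple(ds: float, freq: float) -> np.ndarray:
    """Complete a dosage into a full triple against a Hardy-Weinberg prior.

    Returns the exponential tilt of the HWE prior at counted-allele
    frequency ``freq`` whose mean equals ``ds`` — the minimum-KL
    (maximum-entropy relative to the prior) triple consistent with the
    dosage.  Deterministic; solved by bisection on the tilt parameter.
    """
    if not (0.0 <= ds <= 2.0):
        raise ValidationError(f"dosage {ds} outside [0, 2]")
    q = min(max(freq, 1e-6), 1.0 - 1e-6)
    prior = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    if ds <= 1e-12:
        return np.array([1.0, 0.0, 0.0])
    if ds >= 2.0 - 1e-12:
        return np.array([0.0, 0.0, 1.0])

    def mean_at(theta: float) -> float:
        w = prior * np.exp(theta * np.arange(3))
        w = w / w.sum()
        return float(w[1] + 2 * w[2])

    lo, hi = -60.0, 60.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_at(mid) < ds:
            lo = mid
        else:
            hi = mid
    theta = 0.5 * (lo + hi)
    w = prior * np.exp(theta * np.arange(3))
    return w / w.sum()


def _gp_is_phred(vcf) -> bool:
    try:
        desc = vcf.get_header_type("GP").get("Description", "")
    except KeyError:
        return False
    return "phred" in desc.lower()


def read_vcf_gp(vcf_path, counted_allele: str = "ALT") -> ProbMatrix:
    """Parse genotype probabilities from a VCF with GP and/or DS fields.

    GP (probability order ref-hom, het, alt-hom) is preferred; DS-only
    records are completed to triples with :func:`dosage_to_triple` using the
    record's alt-allele frequency.  Multi-allelic records, and records with
    neither GP nor DS, are skipped with a warning.  Quality comes from INFO
    R2 when present, otherwise it is computed from the parsed column.
    """
    from cyvcf2 import VCF

    if counted_allele not in ("ALT", "REF"):
        raise ValidationError("counted_allele must be 'ALT' or 'REF'")
    vcf = VCF(os.fspath(vcf_path))
    samples = list(vcf.samples)
    n = len(samples)
    phred = _gp_is_phred(vcf)
    variants: list[VariantMeta] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if len(rec.ALT) != 1:
            warnings.warn(f"{vid}: multi-allelic record skipped")
            continue
        gp = None
        try:
            gp = rec.format("GP")
        except KeyError:
            gp = None
        if gp is not None and gp.shape == (n, 3):
            trip = np.asarray(gp, dtype=np.float64)
            if phred:
                trip = np.power(10.0, -trip / 10.0)
                trip = trip / trip.sum(axis=1, keepdims=True)
        else:
            try:
                ds = rec.format("DS")
            except KeyError:
                ds = None
            if ds is None:
                warnings.warn(f"{vid}: neither GP nor DS; record skipped")
                continue
            ds = np.asarray(ds, dtype=np.float64).reshape(n)
            freq = float(np.mean(ds) / 2.0)
            trip = np.stack([dosage_to_triple(x, freq) for x in ds])
        r2 = rec.INFO.get("R2")
        theta = float(np.mean(dosage(trip)) / 2.0)
        if counted_allele == "REF":
            trip = trip[:, ::-1]
            theta = 1.0 - theta
            allele_a, allele_b = rec.ALT[0], rec.REF
        else:
            allele_a, allele_b = rec.REF, rec.ALT[0]
        variants.append(
            VariantMeta(
                variant_id=vid,
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                allele_a=allele_a,
                allele_b=allele_b,
                maf=min(theta, 1.0 - theta),
                quality=float(r2) if r2 is not None else float("nan"),
            )
        )
        rows.append(trip)
    probs = (
        np.stack(rows, axis=1) if rows else np.empty((n, 0, 3), dtype=np.float64)
    )
    return ProbMatrix(samples, variants, probs).with_computed_metadata()


# -- phenotype tables ---------------------------------------------------------


@dataclass
class PhenotypeTable:
    """Phenotype and covariates, indexed by unique sample ID."""

    frame: pd.DataFrame  # index: sample_id; columns: phenotype + covariates
    trait: str
    covariates: list[str]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def aligned_to(self, samples: list[str]) -> "PhenotypeTable":
        """Restrict to the intersection with ``samples``, in their order."""
        keep = [s for s in samples if s in self.frame.index]
        dropped = len(samples) - len(keep)
        if dropped:
            log.info("phenotype alignment: %d samples without phenotype", dropped)
        return PhenotypeTable(self.frame.loc[keep], self.trait, self.covariates)

    def arrays(self) -> tuple[np.ndarray, np.ndarray | None]:
        """(y, C) with C an (n, k) covariate array or None."""
        y = self.frame[self.trait].to_numpy(dtype=np.float64)
        if not self.covariates:
            return y, None
        c = self.frame[self.covariates].to_numpy(dtype=np.float64)
        return y, c


def read_phenotypes(
    path, trait_column: str, covariate_columns: list[str] | None = None,
    sample_column: str | None = None, sep: str | None = None,
) -> PhenotypeTable:
    """Read a delimited phenotype table.

    The first column is the sample ID unless ``sample_column`` names one.
    Rows with a missing trait are dropped (count logged).  Sex columns coded
    M/F are recoded M=0, F=1.
    """
    covariate_columns = list(covariate_columns or [])
    df = pd.read_csv(path, sep=sep, engine="python")
    idcol = sample_column or df.columns[0]
    for col in [idcol, trait_column, *covariate_columns]:
        if col not in df.columns:
            raise ValidationError(f"{path}: column {col!r} not found")
    df[idcol] = df[idcol].astype(str)
    if df[idcol].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample IDs")
    df = df.set_index(idcol)
    keep = [trait_column, *covariate_columns]
    df = df[keep]
    for col in keep:
        if df[col].dtype == object:
            mapped = df[col].map(lambda v: SEX_CODES.get(str(v).strip(), v))
            df[col] = pd.to_numeric(mapped, errors="raise")
    n0 = len(df)
    df = df.dropna(subset=[trait_column])
    if len(df) < n0:
        log.info("dropped %d rows with missing trait", n0 - len(df))
    if df.empty:
        raise ValidationError(f"{path}: no rows with a non-missing trait")
    for col in covariate_columns:
        if df[col].isna().all():
            raise ValidationError(f"{path}: covariate {col!r} is all-missing")
    return PhenotypeTable(df, trait_column, covariate_columns)


# -- MI summary interchange ---------------------------------------------------


def write_mi_summary(records: pd.DataFrame, path) -> None:
    """Write an MI summary table (tab-separated, full float precision)."""
    missing = [c for c in MI_SUMMARY_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"missing MI summary columns: {missing}")
    out = records[MI_SUMMARY_COLUMNS].copy()
    path = os.fspath(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(MI_SUMMARY_COLUMNS) + "\n")
        for row in out.itertuples(index=False):
            fh.write(
                f"{row.variant_id}\t{float(row.beta)!r}\t{float(row.se2)!r}"
                f"\t{float(row.sw2)!r}\t{float(row.sb2)!r}\t{int(row.d)}\n"
            )


def read_mi_summary(path) -> pd.DataFrame:
    """Read an MI summary table written by :func:`write_mi_summary`."""
    df = pd.read_csv(
        path, sep="\t", dtype={"variant_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in MI_SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing MI summary columns: {missing}")
    df = df[MI_SUMMARY_COLUMNS]
    for col in ("se2", "sw2", "sb2"):
        if (df[col].dropna() < 0).any():
            raise ValidationError(f"{path}: negative values in {col}")
    return df
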