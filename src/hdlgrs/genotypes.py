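"""Genotype input, effect-allele harmonization, and variant-level QC.

Genotypes enter either as a VCF (GT field) or as the package's tabular
dosage dialect and are held as an individuals x SNPs matrix of effect-allele
dosages in {0, 1, 2} with NaN for missing calls.  Harmonization orients raw
allele counts to the catalogued HDL-raising effect allele; QC covers the 95%
call-rate floor, the Hardy-Weinberg chi-square test, and pairwise composite
LD (squared dosage correlation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import SNPRecord

__all__ = [
    "GenotypeMatrix",
    "GenotypeError",
    "HarmonizationError",
    "HWEResult",
    "CallRateReport",
    "read_genotypes",
    "harmonize",
    "call_rate_filter",
    "hwe_test",
    "pairwise_r2",
    "allele_frequencies",
    "hwe_report",
    "write_dosage_table",
]

logger = logging.getLogger(__name__)

MISSING = np.nan

# Strand-ambiguous allele pairs: a flip cannot be distinguished from a strand
# swap, so mismatches involving them are always rejected rather than flipped.
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class GenotypeError(ValueError):
    """Raised for unreadable or schema-violating genotype input."""


class HarmonizationError(GenotypeError):
    """Raised when observed alleles cannot be reconciled with the catalog."""


@dataclass
class GenotypeMatrix:
    """Effect-allele dosages for a cohort.

    ``dosage`` is an (n_samples, n_snps) float array with values in
    {0, 1, 2} or NaN for missing; after mean imputation values are real.
    ``family_ids`` carries the sibship/cluster label per sample.
    """

    sample_ids: np.ndarray
    family_ids: np.ndarray
    snp_ids: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.family_ids = np.asarray(self.family_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if len(self.sample_ids) != n or len(self.family_ids) != n:
            raise GenotypeError("sample/family id length does not match dosage rows")
        if len(self.snp_ids) != m:
            raise GenotypeError("snp id length does not match dosage columns")
        if len(set(self.sample_ids)) != n:
            raise GenotypeError("sample identifiers are not unique")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def snp_index(self, rsid: str) -> int:
        idx = np.nonzero(self.snp_ids == rsid)[0]
        if idx.size == 0:
            raise KeyError(rsid)
        return int(idx[0])

    def subset(
        self,
        sample_mask: np.ndarray | None = None,
        snp_mask: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        sm = np.ones(self.n_samples, bool) if sample_mask is None else sample_mask
        km = np.ones(self.n_snps, bool) if snp_mask is None else snp_mask
        return GenotypeMatrix(
            sample_ids=self.sample_ids[sm],
            family_ids=self.family_ids[sm],
            snp_ids=self.snp_ids[km],
            dosage=self.dosage[np.ix_(sm, km)],
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular dosage dialect: sample_id, family_id, one column per rsid."""
        df = pd.DataFrame(self.dosage, columns=list(self.snp_ids))
        df.insert(0, "family_id", self.family_ids)
        df.insert(0, "sample_id", self.sample_ids)
        return df


def harmonize(
    raw_alleles: tuple[str, str],
    raw_dosage_of_a2: float,
    record: SNPRecord,
) -> float:
    """Orient a raw allele count to the catalogued effect allele.

    ``raw_dosage_of_a2`` counts copies of ``raw_alleles[1]`` (e.g. the VCF
    ALT allele).  Returns the count unchanged when a2 is the effect allele,
    the complement ``2 - count`` when a1 is, and NaN for missing input.

    Raises
    ------
    HarmonizationError
        When the observed allele set does not match the catalog record —
        including apparent strand flips, which are deliberately rejected.
    """
    a1, a2 = (a.strip().upper() for a in raw_alleles)
    catalog_set = {record.major_allele, record.minor_allele}
    if {a1, a2} != catalog_set:
        flipped = {_COMPLEMENT.get(a1, "?"), _COMPLEMENT.get(a2, "?")}
        note = " (possible strand flip; rejected)" if flipped == catalog_set else ""
        raise HarmonizationError(
            f"{record.rsid}: observed alleles {a1}/{a2} do not match catalog "
            f"{record.major_allele}/{record.minor_allele}{note}"
        )
    if raw_dosage_of_a2 is None or (
        isinstance(raw_dosage_of_a2, float) and math.isnan(raw_dosage_of_a2)
    ):
        return MISSING
    count = float(raw_dosage_of_a2)
    if count not in (0.0, 1.0, 2.0):
        raise HarmonizationError(
            f"{record.rsid}: raw dosage {raw_dosage_of_a2!r} not in {{0,1,2}}"
        )
    return count if a2 == record.effect_allele else 2.0 - count


def _read_vcf(path: Path, catalog: Sequence[SNPRecord]) -> GenotypeMatrix:
    from cyvcf2 import VCF

    by_rsid = {r.rsid: r for r in catalog}
    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    columns: dict[str, np.ndarray] = {}
    for variant in vcf:
        rsid = variant.ID
        if rsid not in by_rsid:
            logger.warning("VCF variant %s not in catalog; ignored", rsid)
            continue
        record = by_rsid[rsid]
        if len(variant.ALT) != 1:
            raise GenotypeError(f"{rsid}: multi-allelic records are not supported")
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        alt_counts = np.array(
            [{0: 0.0, 1: 1.0, 2: MISSING, 3: 2.0}[t] for t in variant.gt_types]
        )
        dosages = np.array(
            [
                harmonize((variant.REF, variant.ALT[0]), c, record)
                for c in alt_counts
            ]
        )
        columns[rsid] = dosages
    if not columns:
        raise GenotypeError(
            f"no catalogued SNP found in {path}; expected any of "
            f"{sorted(by_rsid)[:5]}..."
        )
    # keep catalog order for the SNPs that were found
    snp_ids = [r.rsid for r in catalog if r.rsid in columns]
    dosage = np.column_stack([columns[s] for s in snp_ids])
    return GenotypeMatrix(
        sample_ids=samples,
        family_ids=samples.copy(),  # VCF carries no pedigree; singleton clusters
        snp_ids=np.asarray(snp_ids, dtype=object),
        dosage=dosage,
    )


def _read_tabular(path: Path, catalog: Sequence[SNPRecord]) -> GenotypeMatrix:
    df = pd.read_csv(path, na_values=["NA", ""])
    for col in ("sample_id", "family_id"):
        if col not in df.columns:
            raise GenotypeError(f"dosage table {path} lacks column {col!r}")
    known = {r.rsid for r in catalog}
    snp_cols = [c for c in df.columns if c not in ("sample_id", "family_id")]
    unknown = [c for c in snp_cols if c not in known]
    for c in unknown:
        logger.warning("dosage column %s not in catalog; ignored", c)
    kept = [c for c in snp_cols if c in known]
    if not kept:
        raise GenotypeError(f"no catalogued SNP columns found in {path}")
    dosage = df[kept].to_numpy(dtype=float)
    bad = ~(np.isnan(dosage) | np.isin(dosage, (0.0, 1.0, 2.0)))
    if bad.any():
        raise GenotypeError(
            f"dosage table {path} contains values outside {{0,1,2,NA}}"
        )
    # catalog order
    order = [r.rsid for r in catalog if r.rsid in kept]
    dosage = df[order].to_numpy(dtype=float)
    return GenotypeMatrix(
        sample_ids=df["sample_id"].astype(str).to_numpy(dtype=object),
        family_ids=df["family_id"].astype(str).to_numpy(dtype=object),
        snp_ids=np.asarray(order, dtype=object),
        dosage=dosage,
    )


def read_genotypes(
    path: str | Path, catalog: Sequence[SNPRecord]
) -> GenotypeMatrix:
    """Read genotypes restricted to catalogued SNPs, oriented to the effect
    allele.

    VCF input (``.vcf``/``.vcf.gz``) is matched by variant ID and harmonized
    from REF/ALT; the tabular dosage dialect (header ``sample_id, family_id,
    <rsid>, ...``, cells in {0,1,2,NA}) is assumed already effect-allele
    oriented.  Unknown SNP columns are ignored with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise GenotypeError(f"genotype file not found: {path}")
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        return _read_vcf(path, catalog)
    return _read_tabular(path, catalog)


def write_dosage_table(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the tabular dosage dialect (cells in {0,1,2,NA})."""
    df = matrix.to_frame()
    df.to_csv(path, index=False, na_rep="NA")


class CallRateReport(NamedTuple):
    snp_rates: pd.Series
    sample_rates: pd.Series
    dropped_snps: list[str]
    dropped_samples: list[str]
    empty_result: bool


def call_rate_filter(
    matrix: GenotypeMatrix, min_rate: float = 0.95
) -> tuple[GenotypeMatrix, CallRateReport]:
    """Drop SNPs, then samples, whose non-missing fraction is below
    ``min_rate`` (default 0.95, the study's minimum acceptable call rate).
    A zero threshold is vacuous and filters nothing."""
    if not 0 <= min_rate <= 1:
        raise ValueError("min_rate must be in [0, 1]")
    observed = ~np.isnan(matrix.dosage)
    snp_rates = pd.Series(
        observed.mean(axis=0), index=list(matrix.snp_ids), name="call_rate"
    )
    snp_keep = snp_rates.to_numpy() >= min_rate
    trimmed = matrix.subset(snp_mask=snp_keep)
    observed2 = ~np.isnan(trimmed.dosage)
    if trimmed.n_snps == 0:
        sample_rates = pd.Series(
            np.zeros(matrix.n_samples), index=list(matrix.sample_ids),
            name="call_rate",
        )
        sample_keep = np.zeros(matrix.n_samples, bool)
    else:
        sample_rates = pd.Series(
            observed2.mean(axis=1), index=list(trimmed.sample_ids),
            name="call_rate",
        )
        sample_keep = sample_rates.to_numpy() >= min_rate
    result = trimmed.subset(sample_mask=sample_keep)
    report = CallRateReport(
        snp_rates=snp_rates,
        sample_rates=sample_rates,
        dropped_snps=[s for s, k in zip(matrix.snp_ids, snp_keep) if not k],
        dropped_samples=[
            s for s, k in zip(trimmed.sample_ids, sample_keep) if not k
        ],
        empty_result=result.n_samples == 0 or result.n_snps == 0,
    )
    return result, report


class HWEResult(NamedTuple):
    chi_square: float
    p_value: float
    monomorphic: bool = False
    low_expected_counts: bool = False


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> HWEResult:
    """One-degree-of-freedom chi-square test for Hardy-Weinberg equilibrium.

    Compares observed genotype counts with the p², 2pq, q² expectations at
    the sample allele frequency.  A monomorphic SNP (allele frequency 0 or
    1) leaves the test undefined; it is flagged and reported as p = 1.
    Expected counts below 5 set ``low_expected_counts`` (the asymptotic
    approximation is then doubtful).
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p in (0.0, 1.0):
        return HWEResult(0.0, 1.0, monomorphic=True)
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return HWEResult(
        chi_square=chi2,
        p_value=float(stats.chi2.sf(chi2, df=1)),
        low_expected_counts=bool((expected < 5).any()),
    )


def pairwise_r2(dosage_i: np.ndarray, dosage_j: np.ndarray) -> float:
    """Composite LD: squared sample correlation of dosages over complete
    pairs.  Requires >= 2 complete pairs and variance in both vectors."""
    x = np.asarray(dosage_i, float)
    y = np.asarray(dosage_j, float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 2:
        raise ValueError("need at least 2 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("r2 undefined: zero variance in a dosage vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _unrelated_mask(family_ids: np.ndarray) -> np.ndarray:
    """One member per family: the first-listed sample of each cluster."""
    seen: set = set()
    mask = np.zeros(len(family_ids), bool)
    for i, fam in enumerate(family_ids):
        if fam not in seen:
            seen.add(fam)
            mask[i] = True
    return mask


def allele_frequencies(
    matrix: GenotypeMatrix, unrelated_only: bool = True
) -> pd.Series:
    """Effect-allele frequencies from observed dosages.

    With ``unrelated_only`` (default) frequencies are computed from one
    member per family — first-listed — emulating estimation from unrelated
    individuals in a sibship design.
    """
    d = matrix.dosage
    if unrelated_only:
        d = d[_unrelated_mask(matrix.family_ids)]
    with np.errstate(invalid="ignore"):
        freqs = np.nanmean(d, axis=0) / 2.0
    return pd.Series(freqs, index=list(matrix.snp_ids), name="effect_allele_freq")


def hwe_report(
    matrix: GenotypeMatrix,
    threshold: float = 0.05,
    unrelated_only: bool = True,
) -> pd.DataFrame:
    """Per-SNP Hardy-Weinberg test over (by default) one member per family.

    Returns a frame with genotype counts, chi-square, p-value, flags, and a
    ``fails_threshold`` column (p below ``threshold``, default 0.05).  The
    report is informational — failing SNPs are not dropped here.
    """
    d = matrix.dosage
    if unrelated_only:
        d = d[_unrelated_mask(matrix.family_ids)]
    rows = []
    for j, rsid in enumerate(matrix.snp_ids):
        col = d[:, j]
        col = col[~np.isnan(col)]
        n2 = int((col == 2).sum())
        n1 = int((col == 1).sum())
        n0 = int((col == 0).sum())
        res = hwe_test(n2, n1, n0)
        rows.append(
            {
                "rsid": rsid,
                "n_hom_effect": n2,
                "n_het": n1,
                "n_hom_other": n0,
                "chi_square": res.chi_square,
                "p_value": res.p_value,
                "monomorphic": res.monomorphic,
                "low_expected_counts": res.low_expected_counts,
                "fails_threshold": (not res.monomorphic)
                and res.p_value < threshold,
            }
        )
    return pd.DataFrame(rows)
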