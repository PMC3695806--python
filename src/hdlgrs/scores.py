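"""Genetic risk score construction.

An unweighted GRS is the count of HDL-raising effect alleles over a SNP
panel; a weighted GRS multiplies each count by a weight proportional to the
SNP's share of the panel's total HDL effect size.  Weights are normalized as

    w_i = m * beta_i / sum(beta)        (m = number of SNPs in the panel)

so that weights average one and weighted scores live on the same scale as
raw allele counts.  With raw fractions beta_i/sum(beta) a weighted score
could never exceed 2, which is incompatible with weighted cohort means in
the teens; the m-scaled rule reproduces those means from the catalogued
frequencies, and is what this module implements.

Missing genotypes are mean-imputed (the cohort's mean dosage for the SNP)
before scoring, so every individual receives a score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .catalog import SNPRecord
from .genotypes import GenotypeMatrix

__all__ = [
    "ScoreDefinition",
    "ScoreVector",
    "ScoreError",
    "build_definition",
    "impute_missing",
    "compute_grs",
    "expected_moments",
    "assign_tertiles",
    "write_scoring_file",
    "read_scoring_file",
    "STANDARD_LABELS",
]

Scheme = Literal["unweighted", "effectsize_weighted"]

#: Conventional labels: score 1 (HDL-only SNPs) unweighted/weighted,
#: score 2 (pleiotropic SNPs) unweighted/weighted, and the LD-pruned union.
STANDARD_LABELS = ("1a", "1b", "2a", "2b", "combined_unweighted", "combined_weighted")


class ScoreError(ValueError):
    """Raised for invalid score definitions or scoring inputs."""


@dataclass(frozen=True)
class ScoreDefinition:
    """An ordered SNP panel with per-SNP weights.

    Invariants: all weights are 1 for the unweighted scheme; for the
    effect-size-weighted scheme the weights sum to the panel size m, so both
    schemes share the 0..2m score range.
    """

    snp_ids: tuple[str, ...]
    weights: tuple[float, ...]
    scheme: Scheme
    label: str

    def __post_init__(self) -> None:
        if len(self.snp_ids) == 0:
            raise ScoreError("score definition needs at least one SNP")
        if len(self.weights) != len(self.snp_ids):
            raise ScoreError("weights and snp_ids must align")
        w = np.asarray(self.weights, float)
        if not np.all(np.isfinite(w)) or (w < 0).any():
            raise ScoreError("weights must be finite and non-negative")
        if self.scheme == "unweighted" and not np.allclose(w, 1.0):
            raise ScoreError("unweighted definitions must have unit weights")
        if self.scheme == "effectsize_weighted" and not np.isclose(
            w.sum(), len(self.snp_ids)
        ):
            raise ScoreError("weighted definitions must have weights summing to m")

    @property
    def max_score(self) -> float:
        return 2.0 * float(np.sum(self.weights))


@dataclass
class ScoreVector:
    """Per-sample scores for one definition, with optional tertile labels."""

    sample_ids: np.ndarray
    score: np.ndarray
    definition_label: str
    tertile: np.ndarray | None = None

    def to_series(self) -> pd.Series:
        return pd.Series(
            self.score, index=list(self.sample_ids), name=self.definition_label
        )


def build_definition(
    records: Sequence[SNPRecord], scheme: Scheme, label: str = ""
) -> ScoreDefinition:
    """Build a score definition from catalog records.

    Unweighted: all weights 1.  Effect-size weighted: w_i = m*beta_i/sum(beta)
    (weights average one; identical to unweighted when all betas are equal).
    """
    if not records:
        raise ScoreError("no records supplied")
    snp_ids = tuple(r.rsid for r in records)
    m = len(records)
    if scheme == "unweighted":
        weights = tuple(1.0 for _ in records)
    elif scheme == "effectsize_weighted":
        total = float(sum(r.beta for r in records))
        if total <= 0:
            raise ScoreError("total effect size is zero; cannot weight")
        weights = tuple(m * r.beta / total for r in records)
    else:
        raise ScoreError(f"unknown weighting scheme {scheme!r}")
    return ScoreDefinition(
        snp_ids=snp_ids, weights=weights, scheme=scheme, label=label or scheme
    )


def impute_missing(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the per-SNP mean of observed dosages.

    The mean is taken over the analysis cohort itself, mirroring scoring of
    individuals with sporadic missing genotypes; observed cells are
    unchanged.  A SNP with no observed dosage at all is an error.
    """
    d = matrix.dosage.copy()
    all_missing = np.isnan(d).all(axis=0)
    if all_missing.any():
        bad = [s for s, b in zip(matrix.snp_ids, all_missing) if b]
        raise ScoreError(f"SNP(s) with all dosages missing: {bad}")
    col_means = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = col_means[idx[1]]
    return GenotypeMatrix(
        sample_ids=matrix.sample_ids.copy(),
        family_ids=matrix.family_ids.copy(),
        snp_ids=matrix.snp_ids.copy(),
        dosage=d,
    )


def compute_grs(
    matrix: GenotypeMatrix, definition: ScoreDefinition
) -> ScoreVector:
    """Score every sample: score_s = sum_i w_i * dosage_{s,i}.

    The matrix must cover every SNP of the definition and contain no missing
    dosages (run :func:`impute_missing` first).
    """
    try:
        cols = [matrix.snp_index(s) for s in definition.snp_ids]
    except KeyError as exc:
        raise ScoreError(f"matrix lacks SNP column {exc.args[0]!r}") from exc
    sub = matrix.dosage[:, cols]
    if np.isnan(sub).any():
        raise ScoreError("missing dosages present; impute before scoring")
    scores = sub @ np.asarray(definition.weights, float)
    return ScoreVector(
        sample_ids=matrix.sample_ids.copy(),
        score=scores,
        definition_label=definition.label,
    )


def expected_moments(
    records: Sequence[SNPRecord], definition: ScoreDefinition
) -> tuple[float, float]:
    """Analytic score mean and SD under Hardy-Weinberg and linkage
    equilibrium.

    Each dosage is Binomial(2, p_i), so

        mean = sum_i w_i * 2 p_i
        sd   = sqrt( sum_i w_i^2 * 2 p_i (1 - p_i) )

    These are the closed-form twins of the cohort summaries and of large
    Monte-Carlo simulations at the catalogued frequencies.
    """
    by_rsid = {r.rsid: r for r in records}
    missing = [s for s in definition.snp_ids if s not in by_rsid]
    if missing:
        raise ScoreError(f"records lack definition SNP(s): {missing}")
    p = np.array([by_rsid[s].effect_allele_freq for s in definition.snp_ids])
    w = np.asarray(definition.weights, float)
    mean = float(np.sum(w * 2 * p))
    sd = float(np.sqrt(np.sum(w**2 * 2 * p * (1 - p))))
    return mean, sd


def assign_tertiles(scores: ScoreVector) -> ScoreVector:
    """Label samples T1/T2/T3 by the empirical 1/3 and 2/3 score quantiles.

    Samples tied exactly at a boundary fall in the lower tertile
    (deterministic and order-independent).  Requires at least 3 distinct
    score values and three non-empty groups.
    """
    s = scores.score
    if len(np.unique(s)) < 3:
        raise ScoreError("tertiles need at least 3 distinct score values")
    q1, q2 = np.quantile(s, [1 / 3, 2 / 3])
    labels = np.where(s <= q1, "T1", np.where(s <= q2, "T2", "T3"))
    counts = pd.Series(labels).value_counts()
    if set(counts.index) != {"T1", "T2", "T3"}:
        raise ScoreError(
            f"degenerate tertiles (tie pathology): group sizes {dict(counts)}"
        )
    return ScoreVector(
        sample_ids=scores.sample_ids,
        score=scores.score,
        definition_label=scores.definition_label,
        tertile=labels,
    )


def write_scoring_file(
    definition: ScoreDefinition,
    records: Sequence[SNPRecord],
    path: str | Path,
) -> None:
    """Export a definition as a PGS-Catalog-style scoring file
    (rsID, effect_allele, other_allele, effect_weight)."""
    by_rsid = {r.rsid: r for r in records}
    rows = []
    for rsid, w in zip(definition.snp_ids, definition.weights):
        rec = by_rsid[rsid]
        rows.append(
            {
                "rsID": rsid,
                "effect_allele": rec.effect_allele,
                "other_allele": rec.other_allele,
                "effect_weight": w,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_scoring_file(path: str | Path, label: str = "") -> ScoreDefinition:
    """Read a PGS-Catalog-style scoring file back into a definition.

    The scheme is inferred: unit weights -> unweighted, otherwise
    effect-size weighted (weights must sum to the SNP count m).
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("rsID", "effect_weight"):
        if col not in df.columns:
            raise ScoreError(f"scoring file {path} lacks column {col!r}")
    w = df["effect_weight"].to_numpy(float)
    scheme: Scheme = "unweighted" if np.allclose(w, 1.0) else "effectsize_weighted"
    return ScoreDefinition(
        snp_ids=tuple(df["rsID"].astype(str)),
        weights=tuple(w),
        scheme=scheme,
        label=label or Path(path).stem,
    )
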