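"""Catalog of HDL-associated SNPs used to build genetic risk scores.

The package ships a 28-variant catalog of common SNPs robustly associated
with plasma HDL cholesterol.  Thirteen variants ("score 1") affect HDL only;
fifteen ("score 2") are HDL-associated but have reported pleiotropic effects
on LDL cholesterol or triglycerides.  Each record carries the HDL-raising
*effect allele*, its frequency in the study cohort, and the per-allele effect
size in mmol/L, which together drive scoring, harmonization, and simulation.

Two pairs of catalogued variants are in strong linkage disequilibrium
(r² > 0.90): rs2338104/rs7134594 and rs16942887/rs2271293.  Combined scores
over both sets therefore drop one member of each pair (rs7134594 and
rs2271293 by default), leaving 26 variants.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

__all__ = [
    "SNPRecord",
    "LDPair",
    "DEFAULT_LD_PAIRS",
    "CatalogError",
    "load_catalog",
    "select_score_snps",
]

ScoreSet = Literal["score1", "score2"]
ScoreSelection = Literal["score1", "score2", "combined"]

_CATALOG_COLUMNS = [
    "rsid",
    "chrom",
    "pos",
    "gene",
    "major_allele",
    "minor_allele",
    "effect_allele",
    "effect_allele_freq",
    "beta",
    "score_set",
]


class CatalogError(ValueError):
    """Raised when a catalog source violates the catalog schema."""


@dataclass(frozen=True)
class SNPRecord:
    """One catalogued variant.

    Attributes
    ----------
    rsid : dbSNP identifier.
    chrom, pos : chromosome label and 1-based position (genome build 37).
    gene : gene label(s) assigned to the locus.
    major_allele, minor_allele : nucleotide symbols.
    effect_allele : the HDL-raising allele whose dosage the score counts;
        always one of the two catalogued alleles.
    effect_allele_freq : effect-allele frequency in the cohort, in (0, 1).
    beta : per-allele HDL effect in mmol/L, positive by construction (the
        effect allele is the HDL-raising allele).
    score_set : which score the variant belongs to ("score1" or "score2").
    source : genotyping source annotation (informational).
    """

    rsid: str
    chrom: str
    pos: int
    gene: str
    major_allele: str
    minor_allele: str
    effect_allele: str
    effect_allele_freq: float
    beta: float
    score_set: ScoreSet
    source: str = ""

    def __post_init__(self) -> None:
        if self.effect_allele not in (self.major_allele, self.minor_allele):
            raise CatalogError(
                f"{self.rsid}: effect allele {self.effect_allele!r} is not one of "
                f"the catalogued alleles {self.major_allele}/{self.minor_allele}"
            )
        if not 0.0 < self.effect_allele_freq < 1.0:
            raise CatalogError(
                f"{self.rsid}: effect-allele frequency {self.effect_allele_freq} "
                "outside (0, 1)"
            )
        if self.beta <= 0:
            raise CatalogError(f"{self.rsid}: effect size beta must be > 0")
        if self.score_set not in ("score1", "score2"):
            raise CatalogError(f"{self.rsid}: unknown score_set {self.score_set!r}")

    @property
    def other_allele(self) -> str:
        """The non-effect allele."""
        if self.effect_allele == self.major_allele:
            return self.minor_allele
        return self.major_allele


@dataclass(frozen=True)
class LDPair:
    """A pair of catalogued variants in strong LD; ``rsid_drop`` is excluded
    from combined scores in favour of ``rsid_keep``."""

    rsid_keep: str
    rsid_drop: str

    def __post_init__(self) -> None:
        if self.rsid_keep == self.rsid_drop:
            raise CatalogError("LD pair must name two distinct variants")


#: LD pairs with r² > 0.90 in the study cohort; the second member of each
#: pair is dropped from combined scores.
DEFAULT_LD_PAIRS: tuple[LDPair, ...] = (
    LDPair(rsid_keep="rs2338104", rsid_drop="rs7134594"),
    LDPair(rsid_keep="rs16942887", rsid_drop="rs2271293"),
)


def _packaged_catalog_path() -> Path:
    return Path(
        importlib.resources.files("hdlgrs") / "data" / "hdl_snp_catalog.tsv"
    )


def load_catalog(source: str | Path | None = None) -> list[SNPRecord]:
    """Load the SNP catalog from ``source`` (defaults to the packaged table).

    The source must be a tab- or comma-delimited table with the packaged
    schema (``rsid, chrom, pos, gene, [source,] major_allele, minor_allele,
    effect_allele, effect_allele_freq, beta, score_set``).  Records are
    returned in file order with all invariants enforced.

    Raises
    ------
    CatalogError
        On a malformed row, a duplicate rsid, or an invariant violation;
        the message names the offending row.
    """
    path = _packaged_catalog_path() if source is None else Path(source)
    try:
        table = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CatalogError(f"cannot parse catalog {path}: {exc}") from exc

    missing = [c for c in _CATALOG_COLUMNS if c not in table.columns]
    if missing:
        raise CatalogError(f"catalog {path} lacks required columns: {missing}")

    records: list[SNPRecord] = []
    seen: set[str] = set()
    for idx, row in table.iterrows():
        rsid = str(row["rsid"]).strip()
        if rsid in seen:
            raise CatalogError(f"duplicate rsid {rsid!r} at row {idx}")
        seen.add(rsid)
        try:
            records.append(
                SNPRecord(
                    rsid=rsid,
                    chrom=str(row["chrom"]).strip(),
                    pos=int(row["pos"]),
                    gene=str(row["gene"]).strip(),
                    major_allele=str(row["major_allele"]).strip().upper(),
                    minor_allele=str(row["minor_allele"]).strip().upper(),
                    effect_allele=str(row["effect_allele"]).strip().upper(),
                    effect_allele_freq=float(row["effect_allele_freq"]),
                    beta=float(row["beta"]),
                    score_set=str(row["score_set"]).strip(),
                    source=str(row.get("source", "") or ""),
                )
            )
        except CatalogError:
            raise
        except (TypeError, ValueError) as exc:
            raise CatalogError(f"malformed catalog row {idx} ({rsid!r}): {exc}") from exc
    return records


def select_score_snps(
    catalog: Sequence[SNPRecord],
    which: ScoreSelection,
    ld_pairs: Iterable[LDPair] = DEFAULT_LD_PAIRS,
) -> list[SNPRecord]:
    """Select the catalog subset for one score membership.

    ``score1`` and ``score2`` return the respective sets in catalog order.
    ``combined`` returns the union of both sets minus the ``rsid_drop``
    member of each LD pair (26 variants for the packaged catalog and default
    pairs).  The selection is idempotent and order-preserving.
    """
    if which in ("score1", "score2"):
        return [r for r in catalog if r.score_set == which]
    if which == "combined":
        drops = {p.rsid_drop for p in ld_pairs}
        rsids = {r.rsid for r in catalog}
        for pair in ld_pairs:
            # dropping a variant whose LD proxy is absent would lose the
            # locus entirely; a pair fully absent is already pruned (no-op,
            # keeps the selection idempotent)
            if pair.rsid_drop in rsids and pair.rsid_keep not in rsids:
                raise CatalogError(
                    f"LD pair keep-member {pair.rsid_keep!r} not present in "
                    f"catalog while {pair.rsid_drop!r} is"
                )
        return [r for r in catalog if r.rsid not in drops]
    raise CatalogError(f"unknown score selection {which!r}")
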