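import numpy as np
import pytest

from hdlgrs.catalog import load_catalog, select_score_snps
from hdlgrs.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def score1(catalog):
    return select_score_snps(catalog, "score1")


@pytest.fixture(scope="session")
def combined(catalog):
    return select_score_snps(catalog, "combined")


@pytest.fixture(scope="session")
def small_cohort(catalog):
    """A 120-family cohort reused by genotype/score/association tests."""
    config = SimulationConfig(seed=42, n_families=120)
    return simulate_cohort(catalog, config)


def write_vcf(path, sample_ids, variants):
    """Write a minimal VCF v4.2 text fixture.

    ``variants`` is a list of dicts with keys rsid, chrom, pos, ref, alt,
    gts (list of genotype strings like '0/1' or './.').
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in sorted({v["chrom"] for v in variants}, key=str):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids)
    )
    for v in sorted(variants, key=lambda v: (str(v["chrom"]), v["pos"])):
        row = [
            str(v["chrom"]), str(v["pos"]), v["rsid"], v["ref"], v["alt"],
            ".", "PASS", ".", "GT",
        ] + v["gts"]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def vcf_writer():
    return write_vcf


def dosage_from_gt(gt):
    if gt == "./.":
        return np.nan
    a, b = gt.replace("|", "/").split("/")
    return float(int(a) + int(b))
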