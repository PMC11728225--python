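"""Shared fixtures: tiny hand-built matrices, simulated data, and reference
tables transcribed from a published 34-marker mango SSR study."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pytest

from ssrkit import GenotypeMatrix, simulate_genotypes
from ssrkit.fingerprint import FingerprintCodebook

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def locus_reference_table() -> pd.DataFrame:
    """Published per-locus diversity statistics for 34 SSR markers."""
    return pd.read_csv(DATA / "locus_diversity_reference.tsv", sep="\t", index_col=0)


@pytest.fixture(scope="session")
def reference_codebook() -> FingerprintCodebook:
    """Published 16-locus allele codebook (codes 1-9, A by ascending size)."""
    lines = (DATA / "allele_codebook_reference.tsv").read_text().splitlines()
    loci, alleles = [], {}
    for line in lines[1:]:
        cells = line.split("\t")
        loci.append(cells[0])
        alleles[cells[0]] = [int(x) for x in cells[1:] if x]
    return FingerprintCodebook(loci=loci, alleles=alleles)


@pytest.fixture(scope="session")
def reference_fingerprints() -> dict[str, str]:
    """Published 32-character fingerprint strings for ten accessions."""
    lines = (DATA / "fingerprint_reference.tsv").read_text().splitlines()
    return dict(line.split("\t") for line in lines[1:])


@pytest.fixture
def tiny_matrix() -> GenotypeMatrix:
    """3 accessions × 2 loci with one heterozygote and one missing call."""
    return GenotypeMatrix(
        accessions=[("a1", "popA"), ("a2", "popA"), ("a3", "popB")],
        loci=["L1", "L2"],
        calls=[
            [(191, 191), (100, 106)],
            [(191, 203), (100, 100)],
            [(203, 203), None],
        ],
    )


@pytest.fixture(scope="session")
def two_pool_sim():
    """Strongly structured two-pool simulation with ground truth."""
    return simulate_genotypes(
        K=2,
        n_loci=20,
        alleles_per_locus=6,
        n_per_pop=[30, 30],
        freq_concentration=0.3,
        admixture_alpha=0.01,
        seed=42,
    )
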