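"""Allele frequencies and SSR diversity statistics.

Per locus: observed allele count (Na), effective allele count (Ne = 1/Σp²),
Shannon's information index (I = −Σ p ln p, natural log), observed
heterozygosity (Ho, fraction of heterozygous genotyped individuals), expected
heterozygosity (He = 1 − Σp², the plain Gini form used by GenAlEx; an
unbiased 2n/(2n−1) variant is available behind a flag), and Botstein's
polymorphism information content

    PIC = 1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j².

Per population: the across-locus means of the above plus the private allele
count Np (alleles present in exactly one population).

Frequencies are computed from allele-copy counts over non-missing calls only;
a missing call contributes zero copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .io_genotypes import GenotypeMatrix

FreqMap = dict[int, float]  # allele size (bp) -> relative frequency


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele→frequency maps, overall and optionally per population.

    ``freqs[locus]`` maps allele size to frequency (summing to 1 over
    non-missing allele copies); ``n_copies[locus]`` is the number of copies
    the frequencies were estimated from. ``by_population`` holds the same
    structure restricted to each population when requested.
    """

    loci: list[str]
    freqs: dict[str, FreqMap]
    n_copies: dict[str, int]
    by_population: dict[str, dict[str, FreqMap]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, f in self.freqs.items():
            if f and abs(sum(f.values()) - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {locus} do not sum to 1")


def _count_freqs(gm: GenotypeMatrix, rows: list[int]) -> tuple[dict[str, FreqMap], dict[str, int]]:
    freqs: dict[str, FreqMap] = {}
    n_copies: dict[str, int] = {}
    for j, locus in enumerate(gm.loci):
        counts: dict[int, int] = {}
        for i in rows:
            c = gm.calls[i][j]
            if c is None:
                continue
            for a in c:
                counts[a] = counts.get(a, 0) + 1
        total = sum(counts.values())
        n_copies[locus] = total
        freqs[locus] = {a: k / total for a, k in sorted(counts.items())} if total else {}
    return freqs, n_copies


def allele_frequencies(gm: GenotypeMatrix, by_population: bool = False) -> AlleleFrequencyTable:
    """Allele frequencies per locus from allele-copy counts.

    Loci where every call is missing get an empty frequency map (flagged by
    ``n_copies == 0``) and are excluded from downstream statistics.
    """
    if gm.n_accessions == 0:
        raise ValueError("empty genotype matrix")
    all_rows = list(range(gm.n_accessions))
    freqs, n_copies = _count_freqs(gm, all_rows)
    table = AlleleFrequencyTable(loci=list(gm.loci), freqs=freqs, n_copies=n_copies)
    if by_population:
        for pop, rows in gm.population_groups().items():
            pf, _ = _count_freqs(gm, rows)
            table.by_population[pop] = pf
    return table


# -- per-locus statistics ----------------------------------------------------


def _pic(p: list[float]) -> float:
    s2 = sum(x * x for x in p)
    cross = 0.0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            cross += 2.0 * p[i] ** 2 * p[j] ** 2
    return 1.0 - s2 - cross


def _locus_row(
    p: list[float], n_het: int, n_genotyped: int, unbiased_he: bool
) -> dict[str, float]:
    s2 = sum(x * x for x in p)
    he = 1.0 - s2
    if unbiased_he and n_genotyped > 0:
        nn = 2 * n_genotyped
        he = he * nn / (nn - 1) if nn > 1 else he
    return {
        "Na": float(len(p)),
        "Ne": 1.0 / s2,
        "I": -sum(x * math.log(x) for x in p if x > 0),
        "Ho": (n_het / n_genotyped) if n_genotyped else float("nan"),
        "He": he,
        "PIC": _pic(p),
    }


def locus_statistics(
    gm: GenotypeMatrix,
    freqs: AlleleFrequencyTable | None = None,
    unbiased_he: bool = False,
) -> pd.DataFrame:
    """Per-locus diversity statistics plus a Mean row.

    Returns a DataFrame indexed by locus name with columns
    Na, Ne, I, Ho, He, PIC; the final row ``Mean`` averages across loci.
    Monomorphic loci are reported (Na=1, Ne=1, I=He=PIC=0), not errors.
    Loci with zero genotyped calls are dropped.
    """
    if freqs is None:
        freqs = allele_frequencies(gm)
    rows: dict[str, dict[str, float]] = {}
    for j, locus in enumerate(gm.loci):
        p = list(freqs.freqs[locus].values())
        if not p:
            continue
        n_het = sum(
            1 for i in range(gm.n_accessions)
            if gm.calls[i][j] is not None and gm.calls[i][j][0] != gm.calls[i][j][1]
        )
        n_gt = sum(1 for i in range(gm.n_accessions) if gm.calls[i][j] is not None)
        rows[locus] = _locus_row(p, n_het, n_gt, unbiased_he)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.loc["Mean"] = df.mean()
    return df


def statistics_from_frequencies(p: Mapping[int, float] | list[float]) -> dict[str, float]:
    """Closed-form Na/Ne/I/He/PIC from a frequency vector alone (no Ho)."""
    vals = list(p.values()) if isinstance(p, Mapping) else list(p)
    row = _locus_row(vals, 0, 0, unbiased_he=False)
    del row["Ho"]
    return row


def private_alleles(freqs: AlleleFrequencyTable) -> dict[str, int]:
    """Private allele counts Np per population.

    An allele is private to a population iff its frequency is positive there
    and zero in every other population. Requires per-population frequencies
    for at least two populations.
    """
    pops = list(freqs.by_population)
    if len(pops) < 2:
        raise ValueError("private alleles need >= 2 populations")
    np_counts = {pop: 0 for pop in pops}
    for locus in freqs.loci:
        for pop in pops:
            for allele, f in freqs.by_population[pop].get(locus, {}).items():
                if f <= 0:
                    continue
                if all(
                    freqs.by_population[other].get(locus, {}).get(allele, 0.0) == 0.0
                    for other in pops
                    if other != pop
                ):
                    np_counts[pop] += 1
    return np_counts


def population_statistics(gm: GenotypeMatrix, unbiased_he: bool = False) -> pd.DataFrame:
    """Across-locus mean diversity statistics per population, with Np.

    One row per population with the mean Na, Ne, I, Ho, He, PIC over loci
    (computed within that population) and the private allele count Np.
    """
    freqs = allele_frequencies(gm, by_population=True)
    np_counts = private_alleles(freqs) if len(freqs.by_population) >= 2 else {}
    out = {}
    for pop, rows in gm.population_groups().items():
        sub = gm.subset_accessions([gm.accession_ids[i] for i in rows])
        stats = locus_statistics(sub, unbiased_he=unbiased_he)
        mean = stats.loc["Mean"].to_dict()
        mean["Np"] = float(np_counts.get(pop, 0))
        out[pop] = mean
    return pd.DataFrame.from_dict(out, orient="index")
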