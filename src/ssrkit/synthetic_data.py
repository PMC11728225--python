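"""Synthetic diploid SSR genotype generator with known latent structure.

Emulates a germplasm collection drawn from K ancestral gene pools with
admixture: each pool has its own allele frequencies per locus (drawn from a
symmetric Dirichlet), each accession has admixture proportions over pools,
and every allele copy is drawn from the pool its copy originates from.
Allele sizes form capillary-electrophoresis-style ladders: base size 100 bp
plus multiples of the motif length.

The generator returns the matrix together with a :class:`SimTruth` ground
truth so recovery tests (admixture Q alignment, FST behaviour, frequency
convergence) can compare against the simulated latent state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_genotypes import GenotypeMatrix

BASE_ALLELE_SIZE = 100


@dataclass
class SimTruth:
    """Latent state of a simulation run.

    Attributes
    ----------
    K : number of ancestral gene pools.
    pool_freqs : array (K, n_loci, alleles_per_locus) of pool allele frequencies.
    admixture : array (n_accessions, K) of per-accession admixture proportions.
    allele_sizes : array (n_loci, alleles_per_locus) of allele sizes in bp.
    pool_of_origin : array (n_accessions,) — the labeled pool each accession
        was anchored to (its population label).
    seed : the seed that reproduces the run.
    """

    K: int
    pool_freqs: np.ndarray
    admixture: np.ndarray
    allele_sizes: np.ndarray
    pool_of_origin: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if not np.allclose(self.pool_freqs.sum(axis=2), 1.0):
            raise ValueError("pool allele frequencies must sum to 1 per locus per pool")
        if not np.allclose(self.admixture.sum(axis=1), 1.0):
            raise ValueError("admixture rows must sum to 1")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "K": self.K,
            "seed": self.seed,
            "pool_freqs": self.pool_freqs.tolist(),
            "admixture": self.admixture.tolist(),
            "allele_sizes": self.allele_sizes.tolist(),
            "pool_of_origin": self.pool_of_origin.tolist(),
        }
        path.write_text(json.dumps(payload), encoding="utf-8")
        return path


def simulate_genotypes(
    K: int,
    n_loci: int,
    alleles_per_locus: int,
    n_per_pop: list[int],
    motif_len: int = 3,
    freq_concentration: float = 0.3,
    admixture_alpha: float = 0.05,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate a diploid SSR genotype matrix from K admixed gene pools.

    Parameters
    ----------
    K : number of ancestral gene pools; must equal ``len(n_per_pop)``.
    n_loci, alleles_per_locus : panel size and allele ladder length per locus
        (``alleles_per_locus >= 2``).
    n_per_pop : accessions per labeled population; population ``k`` is
        anchored to pool ``k``.
    motif_len : repeat motif length in bp; allele ladders are
        ``100 + motif_len * j`` for ``j = 0 .. alleles_per_locus-1``.
    freq_concentration : symmetric Dirichlet concentration for pool allele
        frequencies; small values give divergent pools.
    admixture_alpha : controls admixture. Accession ``i`` in population ``g``
        draws its admixture row from Dirichlet with concentration
        ``admixture_alpha`` on every pool plus ``1`` on pool ``g``; as
        ``admixture_alpha -> 0`` individuals become near-pure members of
        their labeled pool, large values give heavy admixture.
    missing_rate : per-call probability that a diploid call is missing.
    seed : seed for all draws; identical seeds give identical matrices.

    Returns
    -------
    (GenotypeMatrix, SimTruth)
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if len(n_per_pop) != K:
        raise ValueError("n_per_pop must have one entry per pool")
    if alleles_per_locus < 2:
        raise ValueError("alleles_per_locus must be >= 2")
    if motif_len < 1 or n_loci < 1:
        raise ValueError("motif_len and n_loci must be >= 1")
    if not (0.0 <= missing_rate <= 1.0):
        raise ValueError("missing_rate must be in [0, 1]")
    if freq_concentration <= 0 or admixture_alpha <= 0:
        raise ValueError("concentration parameters must be positive")

    rng = np.random.default_rng(seed)
    n = int(sum(n_per_pop))

    # Fixed draw order: pool frequencies, admixture rows, allele copies, missingness.
    pool_freqs = rng.dirichlet(
        np.full(alleles_per_locus, freq_concentration), size=(K, n_loci)
    )
    allele_sizes = np.array(
        [[BASE_ALLELE_SIZE + motif_len * j for j in range(alleles_per_locus)]] * n_loci
    )

    pool_of_origin = np.repeat(np.arange(K), n_per_pop)
    conc = np.full((n, K), admixture_alpha)
    conc[np.arange(n), pool_of_origin] += 1.0
    admixture = np.vstack([rng.dirichlet(c) for c in conc])

    # Per allele copy: pool of origin, then allele index from that pool's ladder.
    copy_pools = np.empty((n, n_loci, 2), dtype=np.int64)
    for i in range(n):
        copy_pools[i] = rng.choice(K, size=(n_loci, 2), p=admixture[i])
    u = rng.random((n, n_loci, 2))
    cum = np.cumsum(pool_freqs, axis=2)  # (K, L, A)
    copy_cum = cum[copy_pools, np.arange(n_loci)[None, :, None], :]  # (n, L, 2, A)
    allele_idx = (u[..., None] > copy_cum).sum(axis=3)

    miss = rng.random((n, n_loci)) < missing_rate

    accessions = []
    for k, nk in enumerate(n_per_pop):
        for j in range(nk):
            accessions.append((f"P{k + 1}_{j + 1:03d}", f"pop{k + 1}"))

    calls = []
    for i in range(n):
        row = []
        for l in range(n_loci):
            if miss[i, l]:
                row.append(None)
            else:
                a = int(allele_sizes[l, allele_idx[i, l, 0]])
                b = int(allele_sizes[l, allele_idx[i, l, 1]])
                row.append((min(a, b), max(a, b)))
        calls.append(row)

    loci = [f"L{l + 1:03d}" for l in range(n_loci)]
    gm = GenotypeMatrix(accessions=accessions, loci=loci, calls=calls)
    truth = SimTruth(
        K=K,
        pool_freqs=pool_freqs,
        admixture=admixture,
        allele_sizes=allele_sizes,
        pool_of_origin=pool_of_origin,
        seed=seed,
    )
    return gm, truth
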