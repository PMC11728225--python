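"""Genetic distances, UPGMA dendrograms and PCA for SSR genotype data.

Two distances are provided: Nei's (1972) standard genetic distance between
populations, D = −ln( Jxy / √(Jx·Jy) ) with the identity terms
Jxy = Σ p q, Jx = Σ p², Jy = Σ q² averaged arithmetically across loci; and an
individual-level shared-allele distance, 1 − (shared allele copies, counted
with dosage multiplicity) / (2 × loci compared).

UPGMA (average linkage, sizes-weighted) is implemented directly so the merge
tie-break is deterministic: among equally close pairs the pair whose smallest
leaf labels sort first is merged. The result is an ultrametric dendrogram
with a Newick writer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .io_genotypes import Call, GenotypeMatrix

logger = logging.getLogger(__name__)

#: Cap for an infinite Nei distance (disjoint allele support).
NEI_DISTANCE_CAP = 10.0

FreqsByLocus = Mapping[str, Mapping[int, float]]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with ordered labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if np.isnan(self.values).any():
            raise ValueError("NaN entries in distance matrix")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        rows = ["\t".join([""] + self.labels)]
        for lab, row in zip(self.labels, self.values):
            rows.append("\t".join([lab] + [f"{v:.6g}" for v in row]))
        path.write_text("\n".join(rows) + "\n", encoding="utf-8")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        labels = lines[0].split("\t")[1:]
        values = np.array([[float(x) for x in l.split("\t")[1:]] for l in lines[1:]])
        return cls(labels=labels, values=values)


# -- distances ---------------------------------------------------------------


def nei_standard_distance(fA: FreqsByLocus, fB: FreqsByLocus) -> float:
    """Nei's (1972) standard genetic distance between two populations.

    ``fA``/``fB`` map locus -> {allele: frequency}; loci must match. Returns
    0 for identical frequency vectors. Disjoint allele support (Jxy = 0)
    would be infinite and is capped at :data:`NEI_DISTANCE_CAP` with a warning.
    """
    if set(fA) != set(fB):
        raise ValueError("populations must share the same locus set")
    jxy = jx = jy = 0.0
    n_loci = len(fA)
    if n_loci == 0:
        raise ValueError("no loci")
    for locus in fA:
        pa, pb = fA[locus], fB[locus]
        jxy += sum(p * pb.get(a, 0.0) for a, p in pa.items())
        jx += sum(p * p for p in pa.values())
        jy += sum(q * q for q in pb.values())
    jxy, jx, jy = jxy / n_loci, jx / n_loci, jy / n_loci
    if jxy <= 0.0:
        logger.warning("no shared alleles; Nei distance capped at %.1f", NEI_DISTANCE_CAP)
        return NEI_DISTANCE_CAP
    return max(0.0, min(NEI_DISTANCE_CAP, -math.log(jxy / math.sqrt(jx * jy))))


def nei_distance_matrix(freqs_by_pop: Mapping[str, FreqsByLocus]) -> DistanceMatrix:
    """Pairwise Nei (1972) distances between populations."""
    pops = list(freqs_by_pop)
    n = len(pops)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = nei_standard_distance(freqs_by_pop[pops[i]], freqs_by_pop[pops[j]])
    return DistanceMatrix(labels=pops, values=D)


def shared_allele_distance(a: Sequence[Call], b: Sequence[Call]) -> Optional[float]:
    """Shared-allele distance between two accessions' call rows, in [0, 1].

    1 − shared/(2 × loci compared), shared counted with dosage multiplicity
    (e.g. (191,203) vs (191,191) shares one of two shareable copies → 0.5).
    Returns None when no locus is genotyped in both.
    """
    shared = 0
    compared = 0
    for ca, cb in zip(a, b):
        if ca is None or cb is None:
            continue
        compared += 1
        for al in set(ca) | set(cb):
            shared += min((ca[0] == al) + (ca[1] == al), (cb[0] == al) + (cb[1] == al))
    if compared == 0:
        return None
    return 1.0 - shared / (2.0 * compared)


def shared_allele_distance_matrix(gm: GenotypeMatrix) -> DistanceMatrix:
    n = gm.n_accessions
    D = np.zeros((n, n))
    n_flagged = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = shared_allele_distance(gm.calls[i], gm.calls[j])
            if d is None:
                n_flagged += 1
                d = 1.0
            D[i, j] = D[j, i] = d
    if n_flagged:
        logger.warning("%d pairs share no genotyped locus; distance set to 1", n_flagged)
    return DistanceMatrix(labels=gm.accession_ids, values=D)


# -- UPGMA -------------------------------------------------------------------


@dataclass
class DendrogramNode:
    """Node of an ultrametric UPGMA tree; leaves have height 0."""

    height: float
    label: Optional[str] = None
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        return self.children[0].leaves() + self.children[1].leaves()

    def to_newick(self, parent_height: Optional[float] = None) -> str:
        if parent_height is None:
            return f"{self._nwk(self.height)};"
        return self._nwk(parent_height)

    def _nwk(self, parent_height: float) -> str:
        bl = parent_height - self.height
        if self.is_leaf:
            return f"{self.label}:{bl:g}"
        a, b = self.children
        inner = f"({a._nwk(self.height)},{b._nwk(self.height)})"
        if parent_height == self.height:  # root
            return inner
        return f"{inner}:{bl:g}"

    def cophenetic_matrix(self, labels: Sequence[str]) -> np.ndarray:
        """Pairwise cophenetic distances (2 × merge height) in label order."""
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        M = np.zeros((n, n))

        def walk(node: DendrogramNode) -> list[str]:
            if node.is_leaf:
                return [node.label]  # type: ignore[list-item]
            left = walk(node.children[0])
            right = walk(node.children[1])
            for a in left:
                for b in right:
                    M[idx[a], idx[b]] = M[idx[b], idx[a]] = 2.0 * node.height
            return left + right

        walk(self)
        return M


def upgma(d: DistanceMatrix) -> DendrogramNode:
    """UPGMA (average-linkage) clustering of a distance matrix.

    Merge heights are half the average inter-cluster distance; ties are broken
    toward the pair whose smallest member labels sort first, so the result is
    deterministic.
    """
    n = len(d.labels)
    if n < 2:
        raise ValueError("UPGMA needs >= 2 items")
    if np.isnan(d.values).any():
        raise ValueError("NaN entries in distance matrix")

    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(height=0.0, label=lab) for i, lab in enumerate(d.labels)
    }
    sizes = {i: 1 for i in range(n)}
    reps = {i: d.labels[i] for i in range(n)}  # smallest leaf label per cluster
    D = {(i, j): float(d.values[i, j]) for i in range(n) for j in range(i + 1, n)}
    next_id = n

    while len(nodes) > 1:
        best_key = None
        best = None
        for (i, j), v in D.items():
            if i not in nodes or j not in nodes:
                continue
            pair_lab = tuple(sorted((reps[i], reps[j])))
            key = (v, pair_lab)
            if best is None or key < best:
                best = key
                best_key = (i, j)
        i, j = best_key  # type: ignore[misc]
        dist = D[(i, j)]
        new = DendrogramNode(height=dist / 2.0, children=(nodes[i], nodes[j]))
        # order children deterministically by smallest leaf label
        if reps[j] < reps[i]:
            new = DendrogramNode(height=dist / 2.0, children=(nodes[j], nodes[i]))
        ni, nj = sizes[i], sizes[j]
        for k in list(nodes):
            if k in (i, j):
                continue
            dik = D[(min(i, k), max(i, k))]
            djk = D[(min(j, k), max(j, k))]
            D[(min(next_id, k), max(next_id, k))] = (ni * dik + nj * djk) / (ni + nj)
        del nodes[i], nodes[j]
        nodes[next_id] = new
        sizes[next_id] = ni + nj
        reps[next_id] = min(reps[i], reps[j])
        next_id += 1

    return next(iter(nodes.values()))


# -- PCA ---------------------------------------------------------------------


def dosage_matrix(gm: GenotypeMatrix) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Allele-dosage encoding: one 0/1/2 column per (locus, allele).

    Missing calls are imputed with the column mean.
    """
    cols: list[tuple[str, int]] = []
    col_alleles: dict[str, list[int]] = {}
    for j, locus in enumerate(gm.loci):
        alleles = sorted({a for row in gm.calls for c in [row[j]] if c for a in c})
        col_alleles[locus] = alleles
        cols += [(locus, a) for a in alleles]
    X = np.full((gm.n_accessions, len(cols)), np.nan)
    k = 0
    for j, locus in enumerate(gm.loci):
        for a in col_alleles[locus]:
            for i in range(gm.n_accessions):
                c = gm.calls[i][j]
                if c is not None:
                    X[i, k] = (c[0] == a) + (c[1] == a)
            k += 1
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    return X, cols


def pca(gm: GenotypeMatrix, n_components: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the centered allele-dosage matrix.

    Returns ``(coordinates, explained_variance_fractions)``; fractions are
    non-increasing and sum to <= 1 over the returned components. Requires at
    least 2 accessions and 2 polymorphic loci.
    """
    if gm.n_accessions < 2:
        raise ValueError("PCA needs >= 2 accessions")
    X, cols = dosage_matrix(gm)
    Xc = X - X.mean(axis=0)
    poly_loci = {
        loc for k, (loc, _) in enumerate(cols) if np.ptp(X[:, k]) > 0
    }
    if len(poly_loci) < 2:
        raise ValueError("PCA needs >= 2 polymorphic loci")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each axis is positive
    for k in range(len(s)):
        m = np.argmax(np.abs(Vt[k]))
        if Vt[k, m] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    coords = U * s
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    if n_components is not None:
        coords = coords[:, :n_components]
        frac = frac[:n_components]
    return coords, frac
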