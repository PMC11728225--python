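"""Distance-based analysis of molecular variance (AMOVA) for codominant data.

Individual pairwise distances are the codominant squared genetic distance of
Smouse & Peakall: with per-locus allele dosage vectors y (entries 0/1/2
summing to 2), d² = ½ Σ (y_a − y_b)² per locus, summed over loci genotyped in
both individuals. This gives the familiar per-locus table: identical
genotypes 0; ii vs ij 1; ij vs ik 1; ij vs kl 2; ii vs jk 3; ii vs jj 4.

Sums of squares come from the pairwise squared-distance matrix
(SS_total = Σ_{i<j} d²_ij / N within the whole set, SS_within the analogous
per-group sums, SS_among by subtraction). Variance components use
n0 = (N − Σ n_g²/N) / (G − 1); ΦPT = σ²_among / (σ²_among + σ²_within) is the
fixation analogue, with gene flow Nm = 0.25 (1 − ΦPT)/ΦPT under an island
model. Significance is a permutation test over random relabelings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_genotypes import Call, GenotypeMatrix

logger = logging.getLogger(__name__)


def genotype_squared_distance(a: Call, b: Call) -> Optional[int]:
    """Smouse–Peakall squared distance between two single-locus diploid calls.

    Returns None when either call is missing (the locus then does not
    contribute to the summed distance).
    """
    if a is None or b is None:
        return None
    alleles = set(a) | set(b)
    d2 = 0
    for al in alleles:
        ya = (a[0] == al) + (a[1] == al)
        yb = (b[0] == al) + (b[1] == al)
        d2 += (ya - yb) ** 2
    return d2 // 2


def pairwise_squared_distances(gm: GenotypeMatrix) -> np.ndarray:
    """Symmetric matrix of summed squared distances over shared loci.

    Pairs with no locus genotyped in both get NaN (excluded downstream with
    a logged warning).
    """
    n = gm.n_accessions
    D = np.zeros((n, n))
    n_undefined = 0
    for i in range(n):
        for j in range(i + 1, n):
            total = 0
            shared = 0
            for l in range(gm.n_loci):
                d = genotype_squared_distance(gm.calls[i][l], gm.calls[j][l])
                if d is not None:
                    total += d
                    shared += 1
            if shared == 0:
                D[i, j] = D[j, i] = np.nan
                n_undefined += 1
            else:
                D[i, j] = D[j, i] = total
    if n_undefined:
        logger.warning("%d accession pairs share no genotyped locus; excluded", n_undefined)
    return D


@dataclass
class AmovaResult:
    """AMOVA ledger: df/SS/MS, variance components, ΦPT, Nm, permutation p."""

    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ms_among: float
    ms_within: float
    var_among: float
    var_within: float
    phi_pt: float
    nm: Optional[float]
    p_value: Optional[float] = None
    n_permutations: int = 0

    @property
    def ss_total(self) -> float:
        return self.ss_among + self.ss_within

    @property
    def pct_among(self) -> float:
        total = self.var_among + self.var_within
        return 100.0 * self.var_among / total if total > 0 else 0.0

    @property
    def pct_within(self) -> float:
        total = self.var_among + self.var_within
        return 100.0 * self.var_within / total if total > 0 else 100.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Source": ["Among populations", "Within populations", "Total"],
                "df": [self.df_among, self.df_within, self.df_among + self.df_within],
                "SS": [self.ss_among, self.ss_within, self.ss_total],
                "MS": [self.ms_among, self.ms_within, float("nan")],
                "Est. Var.": [self.var_among, self.var_within, self.var_among + self.var_within],
                "%": [self.pct_among, self.pct_within, 100.0],
            }
        )


def _sums_of_squares(D: np.ndarray, groups: list[np.ndarray]) -> tuple[float, float]:
    """(SS_total, SS_within) from a squared-distance matrix; NaN pairs excluded."""
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = D[iu]
    ss_total = float(np.nansum(vals)) / n
    ss_within = 0.0
    for idx in groups:
        sub = D[np.ix_(idx, idx)]
        su = sub[np.triu_indices(len(idx), k=1)]
        ss_within += float(np.nansum(su)) / len(idx)
    return ss_total, ss_within


def _components(
    ss_among: float, ss_within: float, group_sizes: Sequence[int]
) -> tuple[int, int, float, float, float, float]:
    """(df_among, df_within, ms_among, ms_within, var_among, var_within)."""
    sizes = np.asarray(group_sizes, dtype=float)
    N, G = sizes.sum(), len(sizes)
    df_among = int(G - 1)
    df_within = int(N - G)
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    n0 = (N - (sizes**2).sum() / N) / (G - 1)
    var_within = ms_within
    var_among = max(0.0, (ms_among - ms_within) / n0)
    return df_among, df_within, ms_among, ms_within, var_among, var_within


def _phi_pt(D: np.ndarray, groups: list[np.ndarray], sizes: Sequence[int]) -> float:
    ss_total, ss_within = _sums_of_squares(D, groups)
    ss_among = max(0.0, ss_total - ss_within)
    *_, var_among, var_within = _components(ss_among, ss_within, sizes)
    total = var_among + var_within
    return var_among / total if total > 0 else 0.0


def amova(gm: GenotypeMatrix, n_permutations: int = 999, seed: int = 0) -> AmovaResult:
    """Two-level AMOVA over the matrix's population labels.

    Requires >= 2 populations, each non-empty. The permutation p-value is
    Pr(ΦPT_perm >= ΦPT_obs) over random relabelings, with the observed
    statistic included (add-one rule). ``n_permutations=0`` skips the test.
    """
    group_map = gm.population_groups()
    if len(group_map) < 2:
        raise ValueError("AMOVA needs >= 2 populations")
    groups = [np.array(v) for v in group_map.values()]
    sizes = [len(g) for g in groups]
    if min(sizes) < 1:
        raise ValueError("every population must have >= 1 accession")

    D = pairwise_squared_distances(gm)
    ss_total, ss_within = _sums_of_squares(D, groups)
    ss_among = max(0.0, ss_total - ss_within)
    df_among, df_within, ms_among, ms_within, var_among, var_within = _components(
        ss_among, ss_within, sizes
    )
    total_var = var_among + var_within
    if total_var <= 0:
        logger.warning("zero total variance; ΦPT undefined, reported as 0")
        phi = 0.0
    else:
        phi = var_among / total_var
    nm = 0.25 * (1.0 - phi) / phi if phi > 0 else None

    p_value = None
    if n_permutations > 0 and total_var > 0:
        rng = np.random.default_rng(seed)
        labels = np.concatenate([np.full(len(g), k) for k, g in enumerate(groups)])
        order = np.concatenate(groups)
        # reorder D once so labels align with rows
        D_ord = D[np.ix_(order, order)]
        n_ge = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            perm_groups = [np.flatnonzero(perm == k) for k in range(len(groups))]
            if _phi_pt(D_ord, perm_groups, sizes) >= phi - 1e-12:
                n_ge += 1
        p_value = (n_ge + 1) / (n_permutations + 1)

    return AmovaResult(
        df_among=df_among,
        df_within=df_within,
        ss_among=ss_among,
        ss_within=ss_within,
        ms_among=ms_among,
        ms_within=ms_within,
        var_among=var_among,
        var_within=var_within,
        phi_pt=phi,
        nm=nm,
        p_value=p_value,
        n_permutations=n_permutations,
    )


def amova_from_summary(
    ss_among: float, ss_within: float, group_sizes: Sequence[int]
) -> AmovaResult:
    """Variance components and ΦPT from printed sums of squares and group sizes.

    Reconstructs the variance-component arithmetic of a published AMOVA table
    given only SS values and the population sizes.
    """
    df_among, df_within, ms_among, ms_within, var_among, var_within = _components(
        ss_among, ss_within, group_sizes
    )
    total = var_among + var_within
    phi = var_among / total if total > 0 else 0.0
    return AmovaResult(
        df_among=df_among,
        df_within=df_within,
        ss_among=ss_among,
        ss_within=ss_within,
        ms_among=ms_among,
        ms_within=ms_within,
        var_among=var_among,
        var_within=var_within,
        phi_pt=phi,
        nm=0.25 * (1 - phi) / phi if phi > 0 else None,
    )
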