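"""Bayesian admixture inference for diploid SSR genotypes.

A lightweight Structure-style model with admixture and independent allele
frequencies: each accession i has admixture proportions Q_i over K latent
gene pools, each pool k has allele frequencies P_kl per locus l, and every
allele copy originates from pool z with probability Q_ik and then carries
allele a with probability P_kla. Inference is collapsed-free Gibbs sampling:

1. sample the pool of origin of every allele copy given Q and P;
2. sample P rows from Dirichlet(λ + assignment counts), λ = 1;
3. sample Q rows from Dirichlet(α + assignment counts), α = 1.

Missing allele copies are skipped. The model log-evidence is estimated as
mean(log L) − ½ var(log L) over post-burn-in sweeps, and the number of pools
is selected with the Evanno ΔK statistic over replicate runs:

    ΔK(K) = mean_r | L_r(K+1) − 2 L_r(K) + L_r(K−1) | / sd(L(K)),

replicates matched by index, defined for interior K only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class AdmixtureFit:
    """Posterior-mean admixture fit for a fixed pool count K."""

    K: int
    Q: np.ndarray  # (n, K) posterior-mean admixture proportions
    P: np.ndarray  # (K, n_loci, max_alleles) posterior-mean pool frequencies
    allele_sizes: list[list[int]]  # per locus, the sizes backing P's columns
    lnpd: float
    seed: int
    burnin: int
    reps: int

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("Q rows must sum to 1")


def _encode(gm: GenotypeMatrix) -> tuple[np.ndarray, list[list[int]]]:
    """Integer-code calls: (n, L, 2) allele indices, −1 for missing copies."""
    allele_sizes: list[list[int]] = []
    for j in range(gm.n_loci):
        alleles = sorted({a for row in gm.calls for c in [row[j]] if c for a in c})
        allele_sizes.append(alleles)
    lookup = [{a: k for k, a in enumerate(al)} for al in allele_sizes]
    geno = np.full((gm.n_accessions, gm.n_loci, 2), -1, dtype=np.int64)
    for i, row in enumerate(gm.calls):
        for j, c in enumerate(row):
            if c is not None:
                geno[i, j, 0] = lookup[j][c[0]]
                geno[i, j, 1] = lookup[j][c[1]]
    return geno, allele_sizes


def fit_admixture(
    gm: GenotypeMatrix,
    K: int,
    reps: int = 2000,
    burnin: int = 500,
    seed: int = 0,
    alpha: float = 1.0,
    lam: float = 1.0,
) -> AdmixtureFit:
    """Fit the K-pool admixture model by Gibbs sampling.

    Parameters
    ----------
    reps : post-burn-in sweeps used for the posterior means and the
        log-evidence estimate.
    burnin : discarded initial sweeps.
    alpha, lam : Dirichlet prior concentrations for Q rows and pool allele
        frequencies (defaults 1, the customary flat priors).

    Identical seeds give identical fits. Pool labels are arbitrary
    (label switching is a property of the model); align against external
    truth only at evaluation time.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if reps < 1 or burnin < 0:
        raise ValueError("reps must be >= 1 and burnin >= 0")
    n, L = gm.n_accessions, gm.n_loci
    if K > n:
        logger.warning("K=%d exceeds accession count %d (over-parameterized)", K, n)

    geno, allele_sizes = _encode(gm)
    A = max(len(a) for a in allele_sizes)
    valid_allele = np.zeros((L, A), dtype=bool)
    for j, al in enumerate(allele_sizes):
        valid_allele[j, : len(al)] = True
    obs = geno >= 0  # (n, L, 2)
    geno_safe = np.where(obs, geno, 0)
    l_idx = np.broadcast_to(np.arange(L)[None, :, None], geno.shape)
    i_idx = np.broadcast_to(np.arange(n)[:, None, None], geno.shape)
    i_obs = i_idx[obs]
    l_obs = l_idx[obs]
    a_obs = geno_safe[obs]

    rng = np.random.default_rng(seed)
    # init from the priors
    Q = rng.dirichlet(np.full(K, alpha), size=n)
    P = np.zeros((K, L, A))
    for k in range(K):
        for j in range(L):
            m = valid_allele[j].sum()
            P[k, j, :m] = rng.dirichlet(np.full(m, lam))

    Q_sum = np.zeros_like(Q)
    P_sum = np.zeros_like(P)
    logls: list[float] = []
    arangeL = np.arange(L)[None, :, None]

    for sweep in range(burnin + reps):
        # 1. pool-of-origin for every allele copy
        Pal = P[:, arangeL, geno_safe]  # (K, n, L, 2)
        W = Q.T[:, :, None, None] * Pal
        W_sum = W.sum(axis=0)
        if sweep >= burnin:
            # per-copy mixture likelihood Σ_k Q_ik P_kla at the current state
            logls.append(float(np.log(W_sum[obs]).sum()))
        W_sum[W_sum == 0] = 1.0
        cum = np.cumsum(W / W_sum, axis=0)
        u = rng.random((n, L, 2))
        z = (u[None] > cum).sum(axis=0)  # (n, L, 2) in 0..K-1 (clip safety)
        np.clip(z, 0, K - 1, out=z)
        z_obs = z[obs]

        # 2. pool allele frequencies
        countsP = np.bincount(
            (z_obs * L + l_obs) * A + a_obs, minlength=K * L * A
        ).reshape(K, L, A)
        g = rng.gamma(lam + countsP)
        g *= valid_allele[None]
        P = g / g.sum(axis=2, keepdims=True)

        # 3. admixture rows
        countsQ = np.bincount(i_obs * K + z_obs, minlength=n * K).reshape(n, K)
        gq = rng.gamma(alpha + countsQ)
        Q = gq / gq.sum(axis=1, keepdims=True)

        if sweep >= burnin:
            Q_sum += Q
            P_sum += P

    logl = np.asarray(logls)
    lnpd = float(logl.mean() - 0.5 * logl.var())
    Q_mean = Q_sum / reps
    Q_mean /= Q_mean.sum(axis=1, keepdims=True)
    return AdmixtureFit(
        K=K,
        Q=Q_mean,
        P=P_sum / reps,
        allele_sizes=allele_sizes,
        lnpd=lnpd,
        seed=seed,
        burnin=burnin,
        reps=reps,
    )


def run_k_scan(
    gm: GenotypeMatrix,
    k_values: Sequence[int],
    replicates: int = 5,
    reps: int = 2000,
    burnin: int = 500,
    seed: int = 0,
    keep_fits: bool = False,
) -> tuple[dict[int, list[float]], dict[tuple[int, int], AdmixtureFit]]:
    """Replicated fits over a range of K; returns lnpd per K (and fits).

    Replicate r of pool count K uses a seed derived deterministically from
    ``seed``, so the scan is reproducible as a whole.
    """
    lnpd_runs: dict[int, list[float]] = {}
    fits: dict[tuple[int, int], AdmixtureFit] = {}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(k_values) * replicates)
    idx = 0
    for K in k_values:
        lnpd_runs[K] = []
        for r in range(replicates):
            sub_seed = int(children[idx].generate_state(1)[0] % (2**31))
            idx += 1
            fit = fit_admixture(gm, K, reps=reps, burnin=burnin, seed=sub_seed)
            lnpd_runs[K].append(fit.lnpd)
            if keep_fits:
                fits[(K, r)] = fit
    return lnpd_runs, fits


@dataclass
class EvannoTable:
    """Evanno ΔK table over a scanned K range."""

    table: pd.DataFrame  # indexed by K: mean_lnpd, sd_lnpd, l_prime, l_second, delta_k
    best_k: int

    def __repr__(self) -> str:  # pragma: no cover
        return f"EvannoTable(best_k={self.best_k})\n{self.table}"


def evanno_delta_k(lnpd_runs: Mapping[int, Sequence[float]]) -> EvannoTable:
    """Evanno ΔK model selection from replicate lnpd estimates per K.

    Needs at least 3 consecutive K values with >= 2 replicates each.
    ΔK is defined for interior K only; at a K where the replicate standard
    deviation is zero ΔK is undefined (NaN, with a warning). ``best_k`` is
    the argmax of the defined ΔK values.
    """
    ks = sorted(lnpd_runs)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    n_reps = {k: len(lnpd_runs[k]) for k in ks}
    if min(n_reps.values()) < 2:
        raise ValueError("need >= 2 replicates per K")
    r = min(n_reps.values())
    if len(set(n_reps.values())) > 1:
        logger.warning("unequal replicate counts; truncating to %d per K", r)
    L = {k: np.asarray(lnpd_runs[k][:r], dtype=float) for k in ks}

    rows = {}
    for k in ks:
        mean, sd = float(L[k].mean()), float(L[k].std(ddof=1))
        l_prime = float((L[k] - L[k - 1]).mean()) if k - 1 in L else np.nan
        l_second = (
            float(np.abs(L[k + 1] - 2 * L[k] + L[k - 1]).mean())
            if (k - 1 in L and k + 1 in L)
            else np.nan
        )
        if not np.isnan(l_second) and sd == 0:
            logger.warning("sd(lnpd)=0 at K=%d; ΔK undefined there", k)
            delta = np.nan
        else:
            delta = l_second / sd if not np.isnan(l_second) else np.nan
        rows[k] = {
            "mean_lnpd": mean,
            "sd_lnpd": sd,
            "l_prime": l_prime,
            "l_second": l_second,
            "delta_k": delta,
        }
    table = pd.DataFrame.from_dict(rows, orient="index").rename_axis("K")
    defined = table["delta_k"].dropna()
    if defined.empty:
        raise ValueError("ΔK undefined at every interior K")
    return EvannoTable(table=table, best_k=int(defined.idxmax()))


def assign_groups(
    fit: AdmixtureFit, thresholds: Sequence[float] = (0.6, 0.9)
) -> tuple[np.ndarray, dict[float, int]]:
    """Hard group labels (argmax Q, ties to the smaller pool index) and
    counts of accessions whose maximum Q strictly exceeds each threshold."""
    labels = np.argmax(fit.Q, axis=1)
    qmax = fit.Q.max(axis=1)
    counts = {t: int((qmax > t).sum()) for t in thresholds}
    return labels, counts
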