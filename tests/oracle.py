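"""Independent brute-force oracles for the likelihood kernel and the EMs.

Everything here is written from the model definition alone (pure-python
loops, dense grid search over the frequency simplex) and deliberately does
not call into :mod:`mhfreq`, so that it can serve as an independent check
of the package's vectorized likelihoods and EM fixed points.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def flip_error(q: float, e1: float) -> float:
    e2 = 10.0 ** (-q / 10.0)
    return e1 + e2 - 2.0 * e1 * e2


def read_prob(calls: dict[int, tuple[int, int]], hap_states, e1: float) -> float:
    """P(read | haplotype) by direct per-site multiplication."""
    p = 1.0
    for i, (allele, q) in calls.items():
        if i >= len(hap_states):
            continue
        e = flip_error(q, e1)
        p *= (1.0 - e) if allele == hap_states[i] else e
    return p


def readset_genotype_loglik(reads, hap_a, hap_b, e1: float) -> float:
    """log P(reads | genotype): per-read half/half mixture over the pair."""
    ll = 0.0
    for calls in reads:
        ll += math.log(
            0.5 * read_prob(calls, hap_a, e1) + 0.5 * read_prob(calls, hap_b, e1)
        )
    return ll


def _simplex_grid(K: int, step: float) -> np.ndarray:
    """All frequency vectors on the simplex with entries multiple of step."""
    n = round(1.0 / step)
    pts = []
    for comp in itertools.combinations_with_replacement(range(K), n):
        v = [0] * K
        for c in comp:
            v[c] += 1
        pts.append(v)
    return np.unique(np.array(pts, dtype=float), axis=0) / n


def _local_grid(p0: np.ndarray, step: float, per_dim: int = 7) -> np.ndarray:
    """Lattice around p0 in the first K-1 coordinates, projected to simplex."""
    K = len(p0)
    offsets = np.linspace(-step, step, per_dim)
    grids = np.meshgrid(*[p0[i] + offsets for i in range(K - 1)], indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    last = 1.0 - pts.sum(axis=1)
    pts = np.column_stack([pts, last])
    ok = (pts >= 0).all(axis=1) & (pts <= 1).all(axis=1)
    return pts[ok]


def _grid_maximize(loglik_batch, K: int, coarse_step: float = 0.02,
                   levels: int = 7) -> np.ndarray:
    """Dense coarse grid over the simplex followed by local grid refinement."""
    pts = _simplex_grid(K, coarse_step)
    best = pts[int(np.argmax(loglik_batch(pts)))]
    step = coarse_step
    for _ in range(levels):
        step /= 3.0
        pts = _local_grid(best, step * 3.0)
        if len(pts) == 0:
            continue
        best = pts[int(np.argmax(loglik_batch(pts)))]
    return best


def grid_mle_pool(reads, haps, e1: float, coarse_step: float = 0.02) -> np.ndarray:
    """Maximum-likelihood allele frequencies for the pool model by grid search."""
    L = np.array([[read_prob(c, h, e1) for h in haps] for c in reads])

    def loglik_batch(pts: np.ndarray) -> np.ndarray:
        mix = pts @ L.T  # (n_pts, n_reads)
        with np.errstate(divide="ignore"):
            return np.where(mix > 0, np.log(np.maximum(mix, 1e-300)), -np.inf).sum(axis=1)

    return _grid_maximize(loglik_batch, len(haps), coarse_step)


def grid_mle_individual(
    reads_by_ind, haps, e1: float, coarse_step: float = 0.02
) -> np.ndarray:
    """ML allele frequencies for the HWE genotype-mixture model by grid search."""
    K = len(haps)
    pairs = list(itertools.combinations_with_replacement(range(K), 2))
    # per-individual genotype likelihoods (not log, sizes are tiny)
    glik = np.array(
        [
            [
                math.exp(readset_genotype_loglik(reads, haps[a], haps[b], e1))
                for a, b in pairs
            ]
            for reads in reads_by_ind
        ]
    )  # (N, G)
    idx_a = np.array([a for a, _ in pairs])
    idx_b = np.array([b for _, b in pairs])
    het = (idx_a != idx_b).astype(float) + 1.0

    def loglik_batch(pts: np.ndarray) -> np.ndarray:
        w = pts[:, idx_a] * pts[:, idx_b] * het  # (n_pts, G) HWE weights
        mix = w @ glik.T  # (n_pts, N)
        with np.errstate(divide="ignore"):
            return np.where(mix > 0, np.log(np.maximum(mix, 1e-300)), -np.inf).sum(axis=1)

    return _grid_maximize(loglik_batch, K, coarse_step)


def all_haplotypes(m: int) -> list[tuple[int, ...]]:
    return list(itertools.product((0, 1), repeat=m))


def random_tiny_instance(rng: np.random.Generator):
    """A random small estimation problem with identifiable frequencies.

    Up to 2 SNPs, up to 4 candidate haplotypes and up to 8 fully-covering
    reads spread over up to 4 individuals.
    """
    m = int(rng.integers(1, 3))
    pool = all_haplotypes(m)
    K = int(rng.integers(2, min(len(pool), 4) + 1))
    hap_idx = rng.choice(len(pool), size=K, replace=False)
    haps = sorted(pool[i] for i in hap_idx)
    true_p = rng.dirichlet(np.ones(K) * 2.0)
    n_reads = int(rng.integers(4, 9))
    e1 = 0.01
    reads = []
    for _ in range(n_reads):
        hap = haps[int(rng.choice(K, p=true_p))]
        calls = {}
        for i in range(m):
            allele = hap[i]
            q = int(rng.integers(20, 31))
            if rng.random() < flip_error(q, e1):
                allele = 1 - allele
            calls[i] = (allele, q)
        reads.append(calls)
    n_ind = int(rng.integers(1, 5))
    by_ind = [reads[i::n_ind] for i in range(n_ind)]
    by_ind = [r for r in by_ind if r]
    return haps, reads, by_ind, e1
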