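"""EM estimators of microhaplotype allele frequencies, with iterative pruning.

Two mixture-model estimators are provided:

* **individual** -- for low-coverage WGS where reads are assigned to
  individuals.  The unit of observation is the individual, the latent
  variable is its diploid genotype, and the mixture weights are genotype
  frequencies linked to allele (haplotype) frequencies by assuming
  Hardy-Weinberg equilibrium:

      P(R_i | pi) = sum_j pi_j P(R_i | z = G_j)

  with pi_j = p_a^2 for homozygotes and 2 p_a p_b for heterozygotes.

* **pool** -- for pool-seq where reads cannot be assigned to individuals.
  The unit of observation is the read, the latent variable is the haplotype
  it was derived from, and the mixture weights are the population allele
  frequencies directly; no HWE assumption is made.

Because the number of possible haplotypes grows as 2^y with the number of
SNPs y (and the number of genotypes faster still), a locus is fitted by
iteratively growing a prefix of its SNPs: at each step the model is fitted
over the current candidate haplotypes, those with estimated frequency below
a threshold ``c`` are removed, and the survivors are extended by the next
``x`` SNPs.  No haplotype is dropped in the final iteration.  Strong
linkage makes most of the 2^y haplotypes non-existent, so the candidate set
stays small in practice.
"""

from __future__ import annotations

import itertools
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .model import (
    ALT,
    REF,
    ErrorModel,
    Haplotype,
    MicrohapLocus,
    ReadObservation,
    enumerate_genotypes,
    read_hap_loglik_matrix,
)
from .windowing import ALLELE_CAP, SkipReason, locus_skip_reason

__all__ = [
    "EmSettings",
    "EmResult",
    "FrequencyEstimate",
    "em_individual",
    "em_pool",
    "prune_and_estimate",
    "expected_heterozygosity",
]


@dataclass(frozen=True)
class EmSettings:
    """Tuning parameters for the EM fits and the pruning driver.

    ``prune_x`` is the number of SNPs added per pruning iteration and
    ``prune_c`` the frequency below which a candidate haplotype is dropped
    between iterations (defaults 1 and 0.001).  Convergence is declared
    when the largest absolute frequency change falls below ``tol``.
    """

    max_iter: int = 1000
    tol: float = 1e-6
    prune_x: int = 1
    prune_c: float = 0.001
    allele_cap_individual: int = ALLELE_CAP["individual"]
    allele_cap_pool: int = ALLELE_CAP["pool"]

    def __post_init__(self) -> None:
        if self.prune_x < 1:
            raise ValueError("prune_x must be >= 1")
        if not 0.0 <= self.prune_c < 1.0:
            raise ValueError("prune_c must be in [0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")

    def cap(self, method: str) -> int:
        return (
            self.allele_cap_individual
            if method == "individual"
            else self.allele_cap_pool
        )


@dataclass
class EmResult:
    """Outcome of one EM fit: allele frequencies and diagnostics."""

    freqs: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool
    #: total log-likelihood after every iteration (non-decreasing)
    ll_history: list[float] = field(default_factory=list)


@dataclass
class FrequencyEstimate:
    """Per-locus result: surviving haplotypes, frequencies and diagnostics."""

    locus: MicrohapLocus
    method: str
    haplotypes: list[Haplotype]
    pi: np.ndarray
    he: float
    n_reads_used: int
    per_site_depth: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    skip_reason: SkipReason | None = None

    @property
    def skipped(self) -> bool:
        return self.skip_reason is not None


def expected_heterozygosity(pi: Sequence[float]) -> float:
    """He = 1 - sum(pi^2), the chance two random alleles differ."""
    p = np.asarray(pi, dtype=float)
    return float(1.0 - np.sum(p * p))


def _check_finite(ll: float, context: str) -> None:
    if not np.isfinite(ll):
        raise ValueError(f"non-finite log-likelihood while fitting {context}")


def em_pool(
    reads: Sequence[ReadObservation],
    haps: Sequence[Haplotype],
    model: ErrorModel,
    s: EmSettings,
    context: str = "pool locus",
) -> EmResult:
    """Read-level allele-mixture EM for pool-seq data.

    E-step: responsibility of haplotype ``a`` for read ``r`` is
    proportional to pi_a * P(r | a).  M-step: pi_a is the mean
    responsibility over reads.  Initialization is uniform over candidates.
    """
    if not reads:
        raise ValueError("em_pool requires at least one read")
    K = len(haps)
    # (M, K) read-by-haplotype likelihoods are fixed across iterations
    L = np.exp(read_hap_loglik_matrix(list(reads), list(haps), model))
    pi = np.full(K, 1.0 / K)
    history: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, s.max_iter + 1):
        mix = L @ pi  # (M,)
        ll = float(np.sum(np.log(mix)))
        _check_finite(ll, context)
        history.append(ll)
        u = L * pi / mix[:, None]
        new_pi = u.mean(axis=0)
        delta = float(np.max(np.abs(new_pi - pi)))
        pi = new_pi
        if delta < s.tol:
            converged = True
            break
    ll = float(np.sum(np.log(L @ pi)))
    _check_finite(ll, context)
    history.append(ll)
    return EmResult(pi, ll, n_iter, converged, history)


def _genotype_loglik_matrix(
    reads_by_individual: Mapping[str, Sequence[ReadObservation]],
    haps: Sequence[Haplotype],
    model: ErrorModel,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-individual genotype log-likelihoods and genotype->hap indexing.

    Returns ``(loglik, idx_a, idx_b)`` where ``loglik[i, g]`` is
    log P(R_i | G_g) and ``idx_a``/``idx_b`` map each of the
    K(K+1)/2 genotypes to its two haplotype indices.
    """
    K = len(haps)
    idx_a, idx_b = np.array(
        list(itertools.combinations_with_replacement(range(K), 2))
    ).T
    loglik = np.zeros((len(reads_by_individual), len(idx_a)))
    for i, rs in enumerate(reads_by_individual.values()):
        P = np.exp(read_hap_loglik_matrix(list(rs), list(haps), model))  # (M_i, K)
        per_read = 0.5 * (P[:, idx_a] + P[:, idx_b])  # (M_i, G)
        with np.errstate(divide="ignore"):
            loglik[i] = np.sum(np.log(per_read), axis=0)
    return loglik, idx_a, idx_b


def em_individual(
    reads_by_individual: Mapping[str, Sequence[ReadObservation]],
    haps: Sequence[Haplotype],
    model: ErrorModel,
    s: EmSettings,
    context: str = "individual locus",
) -> EmResult:
    """Genotype-mixture EM with the HWE link for individual-level data.

    The free parameters are the K allele frequencies ``p``; genotype
    weights follow from HWE (p_a^2 homozygous, 2 p_a p_b heterozygous).
    E-step: posterior genotype responsibilities per individual.  M-step:
    each allele's frequency is its expected count over 2N gene copies.
    """
    if not reads_by_individual:
        raise ValueError("em_individual requires at least one individual")
    K = len(haps)
    N = len(reads_by_individual)
    loglik, idx_a, idx_b = _genotype_loglik_matrix(reads_by_individual, haps, model)
    het = idx_a != idx_b
    # count matrix C[g, k]: copies of haplotype k in genotype g (rows sum to 2)
    G = len(idx_a)
    C = np.zeros((G, K))
    C[np.arange(G), idx_a] += 1.0
    C[np.arange(G), idx_b] += 1.0

    def genotype_weights(p: np.ndarray) -> np.ndarray:
        w = p[idx_a] * p[idx_b]
        w[het] *= 2.0
        return w

    p = np.full(K, 1.0 / K)
    history: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, s.max_iter + 1):
        with np.errstate(divide="ignore"):
            log_pi = np.log(genotype_weights(p))
        joint = loglik + log_pi  # (N, G)
        ll_i = logsumexp(joint, axis=1)
        ll = float(np.sum(ll_i))
        _check_finite(ll, context)
        history.append(ll)
        w = np.exp(joint - ll_i[:, None])  # responsibilities (N, G)
        new_p = (w @ C).sum(axis=0) / (2.0 * N)
        delta = float(np.max(np.abs(new_p - p)))
        p = new_p
        if delta < s.tol:
            converged = True
            break
    with np.errstate(divide="ignore"):
        ll = float(np.sum(logsumexp(loglik + np.log(genotype_weights(p)), axis=1)))
    _check_finite(ll, context)
    history.append(ll)
    return EmResult(p, ll, n_iter, converged, history)


def _per_site_depth(locus: MicrohapLocus, reads: Sequence[ReadObservation]) -> np.ndarray:
    depth = np.zeros(locus.n_sites, dtype=int)
    for r in reads:
        for i in r.calls:
            depth[i] += 1
    return depth


def _skipped(
    locus: MicrohapLocus,
    method: str,
    reason: SkipReason,
    n_reads: int,
    depth: np.ndarray,
) -> FrequencyEstimate:
    return FrequencyEstimate(
        locus=locus,
        method=method,
        haplotypes=[],
        pi=np.array([]),
        he=float("nan"),
        n_reads_used=n_reads,
        per_site_depth=depth,
        log_likelihood=float("nan"),
        n_iterations=0,
        converged=False,
        skip_reason=reason,
    )


def prune_and_estimate(
    locus: MicrohapLocus,
    reads,
    method: str,
    model: ErrorModel | None = None,
    s: EmSettings | None = None,
) -> FrequencyEstimate:
    """Fit one locus with iterative haplotype pruning.

    ``reads`` is a mapping source_id -> list of ReadObservation for the
    individual method, or a flat sequence of ReadObservation for the pool
    method.  Iteration ``t`` considers the first ``min(t*x, y)`` SNPs; its
    candidate haplotypes are the survivors of the previous iteration
    extended by every combination of the new SNPs' alleles.  After each fit
    (except the last) candidates with estimated frequency below ``c`` are
    removed and the remaining frequencies renormalized.  Each EM fit is
    initialized uniformly over its candidates.

    Loci with a zero-depth SNP, or where the candidate count exceeds the
    method's cap at the start of any iteration, are returned with the
    corresponding ``skip_reason`` and no frequencies.
    """
    if method not in ("individual", "pool"):
        raise ValueError(f"unknown method {method!r}")
    model = model or ErrorModel()
    s = s or EmSettings()

    if method == "individual":
        by_ind: dict[str, list[ReadObservation]] = {
            k: list(v) for k, v in reads.items() if v
        }
        flat = [r for rs in by_ind.values() for r in rs]
    else:
        flat = list(reads)
    flat = [r for r in flat if r.calls]
    depth = _per_site_depth(locus, flat)
    n_reads = len(flat)

    reason = locus_skip_reason(locus, depth, 0, method)
    if reason is not None:
        return _skipped(locus, method, reason, n_reads, depth)
    if n_reads == 0:
        raise ValueError(f"no reads cover locus {locus.chrom}:{locus.positions[0]}")

    y = locus.n_sites
    cap = s.cap(method)
    survivors = [Haplotype(())]
    result: EmResult | None = None
    m = 0
    context = f"{locus.chrom}:{locus.positions[0]}-{locus.positions[-1]} ({method})"
    while m < y:
        m_new = min(m + s.prune_x, y)
        exts = list(itertools.product((REF, ALT), repeat=m_new - m))
        candidates = sorted(h.extend(e) for h in survivors for e in exts)
        if len(candidates) > cap:
            return _skipped(
                locus, method, SkipReason.TOO_MANY_ALLELES, n_reads, depth
            )
        if method == "individual":
            prefix_reads = {
                k: [pr for pr in (r.restrict(m_new) for r in rs) if pr.calls]
                for k, rs in by_ind.items()
            }
            prefix_reads = {k: v for k, v in prefix_reads.items() if v}
            result = em_individual(prefix_reads, candidates, model, s, context)
        else:
            prefix_reads = [
                pr for pr in (r.restrict(m_new) for r in flat) if pr.calls
            ]
            result = em_pool(prefix_reads, candidates, model, s, context)
        if m_new < y:  # no dropping in the final iteration
            keep = result.freqs >= s.prune_c
            if not keep.any():
                keep[int(np.argmax(result.freqs))] = True
            survivors = [h for h, k in zip(candidates, keep) if k]
        else:
            survivors = candidates
        m = m_new

    assert result is not None
    pi = result.freqs / result.freqs.sum()
    return FrequencyEstimate(
        locus=locus,
        method=method,
        haplotypes=list(survivors),
        pi=pi,
        he=expected_heterozygosity(pi),
        n_reads_used=n_reads,
        per_site_depth=depth,
        log_likelihood=result.log_likelihood,
        n_iterations=result.n_iter,
        converged=result.converged,
    )
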