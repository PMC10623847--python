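"""Domain types and the probabilistic kernel for microhaplotype likelihoods.

A microhaplotype locus is a short window (by default 60 bp) containing one
or more known biallelic substitution SNPs.  A sequencing read that covers a
subset of those SNPs carries partial information about the haplotype
("allele") of the DNA molecule it was derived from.  This module defines the
basic value types (SNP sites, loci, haplotypes, genotypes, read
observations) and the likelihood kernel shared by the two estimators:

* ``read_given_haplotype`` -- probability of a read's base calls given the
  haplotype it came from, accounting for base-calling error;
* ``readset_given_genotype`` -- log-probability of all of one individual's
  reads given a diploid genotype, each read an equal mixture over the two
  haplotypes of the genotype.

Base-calling error combines a user-supplied pre-sequencing error rate
(library prep / PCR, default 0.01) with the per-base Phred quality under a
biallelic flip model: the observed allele differs from the true one iff
exactly one of the two stages flipped it, so

    e = e1 + e2 - 2*e1*e2,   e2 = 10**(-Q/10).

Since observations are restricted to the two known alleles of each site,
a mismatch has probability ``e`` (there is exactly one alternative allele),
not ``e/3``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "REF",
    "ALT",
    "SnpSite",
    "MicrohapLocus",
    "Haplotype",
    "Genotype",
    "ErrorModel",
    "ReadObservation",
    "combined_error",
    "read_given_haplotype",
    "readset_given_genotype",
    "enumerate_genotypes",
    "read_hap_loglik_matrix",
]

#: Allele state codes used throughout: 0 = reference allele, 1 = alternate.
REF: int = 0
ALT: int = 1

_BASES = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class SnpSite:
    """One known biallelic substitution SNP.

    ``pos`` is a 1-based reference coordinate, as in the SNP table input.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP position must be >= 1, got {self.pos}")
        for name in ("ref_allele", "alt_allele"):
            b = getattr(self, name)
            if b not in _BASES:
                raise ValueError(
                    f"{name} must be a single base in ACGT, got {b!r} "
                    f"at {self.chrom}:{self.pos}"
                )
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"ref and alt alleles identical ({self.ref_allele}) "
                f"at {self.chrom}:{self.pos}"
            )

    def allele(self, code: int) -> str:
        """Base string for an allele state code (REF/ALT)."""
        return self.ref_allele if code == REF else self.alt_allele


@dataclass(frozen=True)
class MicrohapLocus:
    """An ordered set of SNP sites on one chromosome spanning <= window_bp.

    The span convention is inclusive of both end SNPs: the last and first
    site satisfy ``last.pos - first.pos <= window_bp - 1`` so that a single
    window_bp-base read can cover every SNP of the locus.
    """

    chrom: str
    sites: tuple[SnpSite, ...]
    window_bp: int = 60

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("locus must contain at least one SNP")
        if any(s.chrom != self.chrom for s in self.sites):
            raise ValueError("all sites of a locus must share one chromosome")
        pos = [s.pos for s in self.sites]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"site positions must be strictly increasing: {pos}")
        if pos[-1] - pos[0] > self.window_bp - 1:
            raise ValueError(
                f"locus span {pos[-1] - pos[0] + 1} exceeds window of "
                f"{self.window_bp} bp"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s.pos for s in self.sites)

    def hap_bases(self, hap: "Haplotype") -> str:
        """Render a haplotype over this locus as a base string (e.g. 'AG')."""
        return "".join(self.sites[i].allele(a) for i, a in enumerate(hap.states))

    def hap_from_bases(self, bases: str) -> "Haplotype":
        states = []
        for i, b in enumerate(bases):
            site = self.sites[i]
            if b == site.ref_allele:
                states.append(REF)
            elif b == site.alt_allele:
                states.append(ALT)
            else:
                raise ValueError(
                    f"base {b!r} is neither allele of {site.chrom}:{site.pos}"
                )
        return Haplotype(tuple(states))


@dataclass(frozen=True, order=True)
class Haplotype:
    """Allele states over the first ``m`` sites of a locus.

    During pruning, haplotypes over a prefix of the locus's SNPs are used;
    the full-length haplotype covers all sites.  Ordering is lexicographic
    on the state tuple (REF < ALT).
    """

    states: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.states)

    def extend(self, extra: tuple[int, ...]) -> "Haplotype":
        return Haplotype(self.states + extra)


@dataclass(frozen=True, order=True)
class Genotype:
    """Unordered pair of same-length haplotypes, stored in canonical order."""

    hap_a: Haplotype
    hap_b: Haplotype

    def __post_init__(self) -> None:
        if len(self.hap_a) != len(self.hap_b):
            raise ValueError("genotype haplotypes must have equal length")
        if self.hap_b < self.hap_a:
            a, b = self.hap_a, self.hap_b
            object.__setattr__(self, "hap_a", b)
            object.__setattr__(self, "hap_b", a)

    @property
    def is_homozygous(self) -> bool:
        return self.hap_a == self.hap_b


@dataclass(frozen=True)
class ErrorModel:
    """Pre-sequencing (library prep) error rate, combined with Phred scores."""

    pre_seq_error: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.pre_seq_error < 0.5:
            raise ValueError(
                f"pre_seq_error must be in [0, 0.5), got {self.pre_seq_error}"
            )


@dataclass
class ReadObservation:
    """One sequenced DNA fragment's base calls at a locus's SNP sites.

    ``calls`` maps site index (within the locus) to ``(allele, phred_q)``
    where ``allele`` is REF or ALT.  Bases matching neither known allele are
    dropped upstream (see ``bamio.extract_observations``), so every stored
    call is one of the two alleles of its site.
    """

    source_id: str
    calls: dict[int, tuple[int, int]] = field(default_factory=dict)

    def restrict(self, m: int) -> "ReadObservation":
        """Observation restricted to calls at site indices < m."""
        return ReadObservation(
            self.source_id, {i: c for i, c in self.calls.items() if i < m}
        )


def combined_error(phred_q: float, model: ErrorModel) -> float:
    """Probability the observed allele differs from the true haplotype allele.

    Two independent stages can flip the base between the two known alleles:
    pre-sequencing (rate ``e1``) and sequencing (rate ``e2`` implied by the
    Phred score).  The observation is wrong iff exactly one stage flipped.
    """
    e1 = model.pre_seq_error
    e2 = 10.0 ** (-phred_q / 10.0)
    return e1 + e2 - 2.0 * e1 * e2


def read_given_haplotype(
    read: ReadObservation, hap: Haplotype, model: ErrorModel
) -> float:
    """P(read | haplotype): product over covered sites of (1-e) or e.

    Calls at site indices beyond the haplotype's length (outside the current
    pruning prefix) are ignored.  A read with no calls inside the prefix
    contributes the neutral factor 1.0.
    """
    m = len(hap)
    p = 1.0
    for i, (allele, q) in read.calls.items():
        if i >= m:
            continue
        e = combined_error(q, model)
        p *= (1.0 - e) if allele == hap.states[i] else e
    return p


def readset_given_genotype(
    reads: list[ReadObservation], g: Genotype, model: ErrorModel
) -> float:
    """log P(reads | genotype) for one individual's read set.

    Each read is an equal mixture over the genotype's two haplotypes (each
    chromosome copy equally likely to be the template); reads are
    independent, so the log-likelihoods add.
    """
    ll = 0.0
    for r in reads:
        pa = read_given_haplotype(r, g.hap_a, model)
        pb = read_given_haplotype(r, g.hap_b, model)
        ll += math.log(0.5 * pa + 0.5 * pb)
    return ll


def enumerate_genotypes(haps: list[Haplotype]) -> list[Genotype]:
    """All K*(K+1)/2 unordered haplotype pairs, in lexicographic order."""
    if len(set(haps)) != len(haps):
        raise ValueError("haplotypes must be distinct")
    ordered = sorted(haps)
    return [
        Genotype(a, b) for a, b in itertools.combinations_with_replacement(ordered, 2)
    ]


def read_hap_loglik_matrix(
    reads: list[ReadObservation], haps: list[Haplotype], model: ErrorModel
) -> np.ndarray:
    """(n_reads, n_haps) matrix of log P(read | haplotype).

    Vectorized over haplotypes; the kernel of both EM estimators.  All
    haplotypes must have equal length (the current pruning prefix).
    """
    m = len(haps[0])
    if any(len(h) != m for h in haps):
        raise ValueError("all haplotypes must have equal length")
    H = np.array([h.states for h in haps], dtype=np.int8)  # (K, m)
    out = np.zeros((len(reads), len(haps)))
    for r_idx, r in enumerate(reads):
        idx = [i for i in r.calls if i < m]
        if not idx:
            continue
        alleles = np.array([r.calls[i][0] for i in idx], dtype=np.int8)
        errs = np.array([combined_error(r.calls[i][1], model) for i in idx])
        match = H[:, idx] == alleles  # (K, n_calls)
        with np.errstate(divide="ignore"):
            log_match = np.log1p(-errs)
            log_mismatch = np.log(errs)
        out[r_idx] = np.where(match, log_match, log_mismatch).sum(axis=1)
    return out
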