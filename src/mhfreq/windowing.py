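"""Definition of microhaplotype loci from a genome-ordered SNP table.

Loci are defined by sliding a fixed-size window (default 60 bp, the typical
short-read length) along each chromosome: every SNP anchors a candidate
locus containing all SNPs within the window starting at it, and a candidate
is emitted only if it adds at least one SNP over the previously emitted
locus, so that no locus is a subset of its predecessor.
"""

from __future__ import annotations

import enum
from collections.abc import Sequence

from .model import MicrohapLocus, SnpSite

__all__ = ["SkipReason", "define_loci", "locus_skip_reason"]

#: Candidate-allele caps above which a locus is skipped, per method.
ALLELE_CAP = {"individual": 128, "pool": 256}


class SkipReason(str, enum.Enum):
    """Why no frequency estimate was produced for a locus."""

    ZERO_DEPTH = "ZERO_DEPTH"
    TOO_MANY_ALLELES = "TOO_MANY_ALLELES"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def define_loci(
    snps: Sequence[SnpSite], window_bp: int = 60
) -> list[MicrohapLocus]:
    """Group sorted SNPs into microhaplotype loci.

    For each anchor SNP ``s`` the candidate locus contains every SNP within
    ``window_bp - 1`` bases downstream of ``s`` on the same chromosome
    (inclusive-span convention: all its SNPs fit in one window_bp-base
    read).  A candidate whose SNP set is a subset of the previously emitted
    locus is suppressed -- the window advances until at least one new SNP
    is included.  Every SNP belongs to at least one emitted locus.

    Raises ``ValueError`` on unsorted or duplicated input, naming the
    offending record.
    """
    loci: list[MicrohapLocus] = []
    prev_key = None
    finished_chroms: set[str] = set()
    for s in snps:
        if prev_key is not None and s.chrom == prev_key[0] and s.pos <= prev_key[1]:
            kind = "duplicated" if s.pos == prev_key[1] else "unsorted"
            raise ValueError(f"{kind} SNP record at {s.chrom}:{s.pos}")
        if prev_key is not None and s.chrom != prev_key[0]:
            finished_chroms.add(prev_key[0])
            if s.chrom in finished_chroms:
                raise ValueError(f"unsorted SNP record at {s.chrom}:{s.pos}")
        prev_key = (s.chrom, s.pos)

    n = len(snps)
    prev_sites: tuple[SnpSite, ...] = ()
    for a in range(n):
        anchor = snps[a]
        b = a
        while (
            b + 1 < n
            and snps[b + 1].chrom == anchor.chrom
            and snps[b + 1].pos - anchor.pos <= window_bp - 1
        ):
            b += 1
        cand = tuple(snps[a : b + 1])
        if set(cand) <= set(prev_sites):
            continue
        loci.append(MicrohapLocus(anchor.chrom, cand, window_bp))
        prev_sites = cand
    return loci


def locus_skip_reason(
    locus: MicrohapLocus,
    per_site_depth: Sequence[int],
    n_candidate_alleles: int,
    method: str,
) -> SkipReason | None:
    """Skip rule: zero-depth SNP, or candidate alleles above the method cap.

    Estimates are not attempted when any SNP of the locus has read depth
    zero, or when more than 128 (individual method) / 256 (pool method)
    haplotypes would have to be considered.
    """
    if len(per_site_depth) != locus.n_sites:
        raise ValueError("per_site_depth must align with locus sites")
    if any(d == 0 for d in per_site_depth):
        return SkipReason.ZERO_DEPTH
    if n_candidate_alleles > ALLELE_CAP[method]:
        return SkipReason.TOO_MANY_ALLELES
    return None
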