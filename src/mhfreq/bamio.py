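"""Reading SNP tables and BAM alignments; writing estimate tables.

The SNP table is whitespace-delimited text with columns
``chrom pos ref alt`` (1-based positions, ``#`` comment lines ignored).
Read extraction is CIGAR-aware and fragment-based: the two mates of a pair
are merged into a single observation because they derive from one DNA
molecule, with conflicts at overlapping sites resolved in favour of the
higher base quality (equal qualities drop the call).
"""

from __future__ import annotations

import csv
import os
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .estimators import FrequencyEstimate
from .model import ALT, REF, MicrohapLocus, ReadObservation, SnpSite
from .windowing import SkipReason

__all__ = [
    "ReadFilters",
    "read_snp_table",
    "extract_observations",
    "write_estimates",
    "read_estimates",
]

ESTIMATE_COLUMNS = [
    "chrom",
    "first_snp_pos",
    "last_snp_pos",
    "n_snps",
    "snp_positions",
    "method",
    "n_reads",
    "haplotypes",
    "frequencies",
    "he",
    "converged",
    "skip_reason",
]


@dataclass(frozen=True)
class ReadFilters:
    """Alignment and base filters applied during extraction.

    Defaults follow standard short-read practice: mapping quality >= 20,
    base quality >= 5, and duplicate/secondary/supplementary/unmapped
    records excluded.
    """

    min_mapq: int = 20
    min_baseq: int = 5


def read_snp_table(path: str | os.PathLike) -> list[SnpSite]:
    """Parse and validate a SNP table; returns sites sorted by (chrom, pos).

    Unsorted input is sorted; duplicated (chrom, pos) records are rejected.
    """
    sites: list[SnpSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected 4 columns "
                    f"(chrom pos ref alt), got {len(fields)}"
                )
            chrom, pos_s, ref, alt = fields[:4]
            try:
                pos = int(pos_s)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: position {pos_s!r} is not an integer"
                ) from None
            try:
                sites.append(SnpSite(chrom, pos, ref.upper(), alt.upper()))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    sites.sort()
    for a, b in zip(sites, sites[1:]):
        if (a.chrom, a.pos) == (b.chrom, b.pos):
            raise ValueError(f"{path}: duplicated SNP at {a.chrom}:{a.pos}")
    return sites


def _bam_source_id(bam: pysam.AlignmentFile) -> dict[str, str]:
    """Map read-group ID -> sample name (SM), for individual assignment."""
    out = {}
    for rg in bam.header.to_dict().get("RG", []):
        if "SM" in rg:
            out[rg["ID"]] = rg["SM"]
    return out


def _passes(aln: pysam.AlignedSegment, filters: ReadFilters) -> bool:
    return not (
        aln.is_unmapped
        or aln.is_secondary
        or aln.is_supplementary
        or aln.is_duplicate
        or aln.mapping_quality < filters.min_mapq
    )


def _open_bams(
    bam_paths: Sequence[str | os.PathLike | pysam.AlignmentFile],
) -> list[tuple[pysam.AlignmentFile, bool]]:
    handles = []
    for b in bam_paths:
        if isinstance(b, pysam.AlignmentFile):
            handles.append((b, False))
        else:
            handles.append((pysam.AlignmentFile(os.fspath(b), "rb"), True))
    return handles


def extract_observations(
    bam_paths: Sequence[str | os.PathLike | pysam.AlignmentFile],
    locus: MicrohapLocus,
    mode: str = "individual",
    filters: ReadFilters | None = None,
):
    """Collect per-fragment SNP observations overlapping a locus.

    Returns ``{source_id: [ReadObservation, ...]}`` in individual mode or a
    flat ``[ReadObservation, ...]`` in pool mode (read groups ignored).

    For every alignment passing the filters, the base and Phred quality at
    each locus SNP are read off the aligned segment (deletions yield no
    call); bases matching neither the ref nor the alt allele are dropped,
    and fragments left with no calls are discarded.  Mates sharing a query
    name within one source are merged.  In individual mode the source is
    the read group's SM sample if present, otherwise the BAM file name;
    two BAM files resolving to the same source are an error.
    """
    if mode not in ("individual", "pool"):
        raise ValueError(f"unknown mode {mode!r}")
    filters = filters or ReadFilters()
    site_pos0 = {s.pos - 1: i for i, s in enumerate(locus.sites)}
    start = locus.sites[0].pos - 1
    end = locus.sites[-1].pos

    # (source, fragment name) -> {site index: (allele, qual)}
    fragments: dict[tuple[str, str], dict[int, tuple[int, int]]] = {}
    dropped: set[tuple[tuple[str, str], int]] = set()
    source_of_bam: dict[str, str] = {}

    handles = _open_bams(bam_paths)
    try:
        for bam, _ in handles:
            if not bam.has_index():
                raise ValueError(f"BAM file {bam.filename!r} has no index")
            rg_sample = _bam_source_id(bam) if mode == "individual" else {}
            fallback = Path(os.fsdecode(bam.filename)).name
            if locus.chrom not in bam.references:
                continue
            for aln in bam.fetch(locus.chrom, start, end):
                if not _passes(aln, filters):
                    continue
                if mode == "pool":
                    source = "pool"
                else:
                    rg = aln.get_tag("RG") if aln.has_tag("RG") else None
                    source = rg_sample.get(rg, fallback)
                    prev = source_of_bam.setdefault(source, fallback)
                    if prev != fallback:
                        raise ValueError(
                            f"source {source!r} appears in two BAM files "
                            f"({prev!r} and {fallback!r})"
                        )
                seq = aln.query_sequence
                quals = aln.query_qualities
                if seq is None or quals is None:
                    continue
                key = (source, aln.query_name)
                calls = fragments.setdefault(key, {})
                for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                    i = site_pos0.get(rpos)
                    if i is None:
                        continue
                    q = quals[qpos]
                    if q < filters.min_baseq:
                        continue
                    base = seq[qpos].upper()
                    site = locus.sites[i]
                    if base == site.ref_allele:
                        allele = REF
                    elif base == site.alt_allele:
                        allele = ALT
                    else:
                        continue
                    if (key, i) in dropped:
                        continue
                    if i in calls:
                        old_allele, old_q = calls[i]
                        if old_allele == allele:
                            calls[i] = (allele, max(old_q, q))
                        elif q > old_q:
                            calls[i] = (allele, q)
                        elif q == old_q:  # unresolvable mate conflict
                            del calls[i]
                            dropped.add((key, i))
                    else:
                        calls[i] = (allele, q)
    finally:
        for bam, owned in handles:
            if owned:
                bam.close()

    observations = [
        ReadObservation(source, dict(sorted(calls.items())))
        for (source, _), calls in sorted(fragments.items())
        if calls
    ]
    if mode == "pool":
        return observations
    grouped: dict[str, list[ReadObservation]] = {}
    for obs in observations:
        grouped.setdefault(obs.source_id, []).append(obs)
    return grouped


def write_estimates(
    estimates: Iterable[FrequencyEstimate], path: str | os.PathLike
) -> None:
    """Write per-locus estimates as a TSV; skipped loci keep empty fields."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ESTIMATE_COLUMNS)
        for est in estimates:
            locus = est.locus
            if est.skipped:
                haps = freqs = he = ""
            else:
                haps = ",".join(locus.hap_bases(h) for h in est.haplotypes)
                freqs = ",".join(f"{p:.6f}" for p in est.pi)
                he = f"{est.he:.6f}"
            writer.writerow(
                [
                    locus.chrom,
                    locus.positions[0],
                    locus.positions[-1],
                    locus.n_sites,
                    ",".join(str(p) for p in locus.positions),
                    est.method,
                    est.n_reads_used,
                    haps,
                    freqs,
                    he,
                    est.converged,
                    est.skip_reason.value if est.skip_reason else "",
                ]
            )


def read_estimates(path: str | os.PathLike) -> pd.DataFrame:
    """Parse an estimates TSV back into a DataFrame with list-valued columns.

    ``snp_positions`` becomes a tuple of ints, ``haplotypes`` a tuple of
    base strings and ``frequencies`` a numpy array (empty for skipped loci).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "chrom": str,
            "snp_positions": str,
            "haplotypes": str,
            "frequencies": str,
            "skip_reason": str,
        },
        keep_default_na=False,
    )
    df["snp_positions"] = df["snp_positions"].map(
        lambda s: tuple(int(x) for x in str(s).split(","))
    )
    df["haplotypes"] = df["haplotypes"].map(
        lambda s: tuple(s.split(",")) if s else ()
    )
    df["frequencies"] = df["frequencies"].map(
        lambda s: np.array([float(x) for x in str(s).split(",")])
        if s != ""
        else np.array([])
    )
    df["he"] = pd.to_numeric(df["he"], errors="coerce")
    df["converged"] = df["converged"].astype(str) == "True"
    df["skip_reason"] = df["skip_reason"].map(
        lambda s: SkipReason(s) if s else None
    )
    return df
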