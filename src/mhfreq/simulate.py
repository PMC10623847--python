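"""Synthetic low-coverage WGS / pool-seq data with known microhaplotype truth.

The generator emulates the data the estimators are designed for: diploid
individuals drawn under Hardy-Weinberg equilibrium from a locus haplotype
frequency vector (individual mode), or reads drawn i.i.d. from the allele
pool (pool mode); fixed-length reads placed uniformly over the positions
covering at least one locus SNP; per-base Phred qualities; and substitution
errors applied in two stages, pre-sequencing at a fixed rate and sequencing
at the Phred-implied rate.  Per-individual read counts are Poisson around
the requested mean depth, mirroring a downsampling protocol in which every
individual keeps each read with the same probability.

Only a handful of the 2^y possible haplotypes exist at each simulated
locus (drawn from {2..8}), emulating the strong linkage between nearby
SNPs that makes most haplotypes non-existent in real populations.

Datasets can be produced either in memory (``simulate_truth`` +
``simulate_locus_reads``) for direct use with the estimators, or written
as an indexed BAM, SNP table and truth TSV (``simulate_dataset``).
"""

from __future__ import annotations

import os
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .estimators import expected_heterozygosity
from .model import (
    Genotype,
    Haplotype,
    MicrohapLocus,
    ReadObservation,
    SnpSite,
)

__all__ = [
    "SimulationParams",
    "TruthRecord",
    "SimulatedDataset",
    "simulate_truth",
    "simulate_locus_reads",
    "simulate_dataset",
    "write_truth",
    "read_truth",
    "truth_key",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the generator.

    ``mean_depth`` is the expected per-individual read depth at each SNP
    (the downsampling levels of interest are 0.1-2x); ``snps_per_locus``
    and ``phred_range`` are inclusive uniform ranges; ``dirichlet_conc``
    is the concentration of the symmetric Dirichlet prior on the true
    haplotype frequencies.
    """

    n_individuals: int = 50
    n_loci: int = 100
    snps_per_locus: tuple[int, int] = (2, 6)
    max_true_haplotypes: int = 8
    dirichlet_conc: float = 1.0
    read_length: int = 60
    mean_depth: float = 2.0
    phred_range: tuple[int, int] = (20, 40)
    pre_seq_error: float = 0.01
    window_bp: int = 60
    chrom: str = "chrSim"
    #: if set, draw exactly this many reads per locus (allocated uniformly
    #: over individuals) instead of Poisson counts at ``mean_depth``
    reads_per_locus: int | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_loci < 1 or self.read_length < 1:
            raise ValueError("n_individuals, n_loci and read_length must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        lo, hi = self.snps_per_locus
        if not 1 <= lo <= hi or hi > self.window_bp:
            raise ValueError(f"invalid snps_per_locus range {self.snps_per_locus}")
        if not 0.0 <= self.pre_seq_error < 0.5:
            raise ValueError("pre_seq_error must be in [0, 0.5)")


@dataclass
class TruthRecord:
    """Ground truth for one simulated locus.

    ``freqs`` are the population haplotype frequencies the locus was drawn
    with.  ``observed_freqs`` are the realized allele frequencies among the
    2N gene copies actually carried by the simulated individuals -- the
    quantity a full-depth genotyping of the same sample would report, and
    the reference the evaluation protocol compares estimates against.  In
    pool mode reads are drawn straight from the population pool, so the
    two coincide.
    """

    locus: MicrohapLocus
    haplotypes: list[Haplotype]
    freqs: np.ndarray
    he: float
    #: per-individual genotypes, aligned to individual ids; None in pool mode
    genotypes: list[Genotype] | None = None
    observed_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.observed_freqs is None and self.genotypes is not None:
            counts = np.zeros(len(self.haplotypes))
            index = {h: i for i, h in enumerate(self.haplotypes)}
            for g in self.genotypes:
                counts[index[g.hap_a]] += 1
                counts[index[g.hap_b]] += 1
            self.observed_freqs = counts / counts.sum()

    @property
    def sample_freqs(self) -> np.ndarray:
        """Realized sample frequencies, falling back to population values."""
        return self.observed_freqs if self.observed_freqs is not None else self.freqs

    @property
    def sample_he(self) -> float:
        return expected_heterozygosity(self.sample_freqs)

    def freq_by_bases(self) -> dict[str, float]:
        return {
            self.locus.hap_bases(h): float(f)
            for h, f in zip(self.haplotypes, self.freqs)
        }

    def sample_freq_by_bases(self) -> dict[str, float]:
        return {
            self.locus.hap_bases(h): float(f)
            for h, f in zip(self.haplotypes, self.sample_freqs)
        }


@dataclass
class SimulatedDataset:
    bam_path: Path
    snp_path: Path
    truth_path: Path
    truths: list[TruthRecord] = field(default_factory=list)
    #: per-locus intended observations as written into the BAM, keyed like
    #: the output of bamio.extract_observations for the chosen mode
    observations: list = field(default_factory=list)


def individual_ids(params: SimulationParams) -> list[str]:
    width = max(3, len(str(params.n_individuals - 1)))
    return [f"ind{i:0{width}d}" for i in range(params.n_individuals)]


def truth_key(locus: MicrohapLocus) -> tuple[str, tuple[int, ...]]:
    """Identity of a locus for matching estimates against truth."""
    return (locus.chrom, locus.positions)


def _draw_locus(
    rng: np.random.Generator, params: SimulationParams, first_pos: int
) -> MicrohapLocus:
    y = int(rng.integers(params.snps_per_locus[0], params.snps_per_locus[1] + 1))
    offsets = np.sort(rng.choice(params.window_bp, size=y, replace=False))
    offsets -= offsets[0]
    sites = []
    for off in offsets:
        ref, alt = rng.choice(4, size=2, replace=False)
        sites.append(
            SnpSite(params.chrom, first_pos + int(off), _BASES[ref], _BASES[alt])
        )
    return MicrohapLocus(params.chrom, tuple(sites), params.window_bp)


def _draw_haplotypes(
    rng: np.random.Generator, y: int, params: SimulationParams
) -> tuple[list[Haplotype], np.ndarray]:
    n_possible = 2**y
    n_true = int(
        rng.integers(2, min(n_possible, params.max_true_haplotypes) + 1)
    )
    codes = rng.choice(n_possible, size=n_true, replace=False)
    haps = sorted(
        Haplotype(tuple((int(c) >> (y - 1 - i)) & 1 for i in range(y)))
        for c in codes
    )
    freqs = rng.dirichlet(np.full(n_true, params.dirichlet_conc))
    return haps, freqs


def simulate_truth(
    params: SimulationParams,
    rng: np.random.Generator,
    mode: str = "individual",
) -> list[TruthRecord]:
    """Draw loci, true haplotype sets/frequencies, and (HWE) genotypes.

    Loci are spaced along one chromosome far enough apart that no read can
    overlap two of them.
    """
    if mode not in ("individual", "pool"):
        raise ValueError(f"unknown mode {mode!r}")
    spacing = params.window_bp + 2 * params.read_length
    truths = []
    for j in range(params.n_loci):
        first_pos = 1 + params.read_length + j * spacing
        locus = _draw_locus(rng, params, first_pos)
        haps, freqs = _draw_haplotypes(rng, locus.n_sites, params)
        genotypes = None
        if mode == "individual":
            draws = rng.choice(len(haps), size=(params.n_individuals, 2), p=freqs)
            genotypes = [Genotype(haps[a], haps[b]) for a, b in draws]
        truths.append(
            TruthRecord(locus, haps, freqs, expected_heterozygosity(freqs), genotypes)
        )
    return truths


def _read_starts(locus: MicrohapLocus, read_length: int) -> np.ndarray:
    """1-based start positions from which a read covers >= 1 locus SNP."""
    pos = np.asarray(locus.positions)
    starts = np.arange(pos[0] - read_length + 1, pos[-1] + 1)
    starts = starts[starts >= 1]
    covered = (
        (pos[None, :] >= starts[:, None])
        & (pos[None, :] <= starts[:, None] + read_length - 1)
    ).any(axis=1)
    return starts[covered]


def _sequence_one_read(
    rng: np.random.Generator,
    truth: TruthRecord,
    hap: Haplotype,
    start: int,
    params: SimulationParams,
) -> dict[int, tuple[int, int]]:
    """Calls at the SNPs covered by a read from ``hap`` starting at ``start``.

    Each covered allele is flipped to the other allele with probability
    ``pre_seq_error`` and then, independently, with the error probability
    implied by its drawn Phred score.
    """
    end = start + params.read_length - 1
    calls: dict[int, tuple[int, int]] = {}
    qlo, qhi = params.phred_range
    for i, site in enumerate(truth.locus.sites):
        if not start <= site.pos <= end:
            continue
        allele = hap.states[i]
        if params.pre_seq_error > 0 and rng.random() < params.pre_seq_error:
            allele = 1 - allele
        q = int(rng.integers(qlo, qhi + 1))
        if rng.random() < 10.0 ** (-q / 10.0):
            allele = 1 - allele
        calls[i] = (allele, q)
    return calls


def _poisson_reads(params: SimulationParams, n_starts: int) -> float:
    # lam such that the expected depth at every SNP equals mean_depth:
    # each SNP is covered by exactly read_length of the n_starts placements
    return params.mean_depth * n_starts / params.read_length


@dataclass
class _SimRead:
    source: str
    hap: Haplotype
    start: int
    calls: dict[int, tuple[int, int]]


def _draw_reads(
    truth: TruthRecord,
    params: SimulationParams,
    rng: np.random.Generator,
    mode: str,
) -> list[_SimRead]:
    starts = _read_starts(truth.locus, params.read_length)
    lam = _poisson_reads(params, len(starts))
    out: list[_SimRead] = []
    if mode == "individual":
        assert truth.genotypes is not None
        ids = individual_ids(params)
        if params.reads_per_locus is None:
            counts = rng.poisson(lam, size=len(ids))
        else:  # fixed total, allocated uniformly (Poisson given the sum)
            counts = rng.multinomial(
                params.reads_per_locus, np.full(len(ids), 1.0 / len(ids))
            )
        for ind, g, n in zip(ids, truth.genotypes, counts):
            for _ in range(int(n)):
                hap = g.hap_a if rng.random() < 0.5 else g.hap_b
                start = int(rng.choice(starts))
                out.append(
                    _SimRead(
                        ind, hap, start,
                        _sequence_one_read(rng, truth, hap, start, params),
                    )
                )
    else:
        if params.reads_per_locus is None:
            n = int(rng.poisson(lam * params.n_individuals))
        else:
            n = params.reads_per_locus
        hap_idx = rng.choice(len(truth.haplotypes), size=n, p=truth.freqs)
        for k in range(n):
            hap = truth.haplotypes[int(hap_idx[k])]
            start = int(rng.choice(starts))
            out.append(
                _SimRead(
                    "pool", hap, start,
                    _sequence_one_read(rng, truth, hap, start, params),
                )
            )
    return out


def simulate_locus_reads(
    truth: TruthRecord,
    params: SimulationParams,
    rng: np.random.Generator,
    mode: str = "individual",
):
    """In-memory read observations for one locus.

    Returns ``{individual: [ReadObservation, ...]}`` in individual mode
    (individuals without reads omitted) or a flat list in pool mode.
    """
    sim_reads = _draw_reads(truth, params, rng, mode)
    obs = [ReadObservation(r.source, r.calls) for r in sim_reads if r.calls]
    if mode == "pool":
        return obs
    grouped: dict[str, list[ReadObservation]] = {}
    for o in obs:
        grouped.setdefault(o.source_id, []).append(o)
    return grouped


def _background(
    rng: np.random.Generator, truth: TruthRecord, params: SimulationParams
) -> tuple[int, np.ndarray]:
    """Reference-like base string surrounding a locus (ref alleles at SNPs)."""
    first = truth.locus.positions[0] - params.read_length
    last = truth.locus.positions[-1] + params.read_length
    seq = rng.choice(4, size=last - first + 1)
    bases = _BASES[seq].copy()
    for site in truth.locus.sites:
        bases[site.pos - first] = site.ref_allele
    return first, bases


def simulate_dataset(
    params: SimulationParams,
    out_dir: str | os.PathLike,
    mode: str = "individual",
    seed: int | None = None,
    prefix: str = "sim",
) -> SimulatedDataset:
    """Write a simulated dataset as indexed BAM + SNP table + truth TSV.

    Reads are emitted as single-end, fully-aligned records (CIGAR ``<L>M``,
    mapping quality 60) with one read group per individual.  Base qualities
    at SNP positions are the ones used when simulating the calls, so the
    written BAM round-trips exactly through ``bamio.extract_observations``.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truths = simulate_truth(params, rng, mode)

    snp_path = out_dir / f"{prefix}.snps.tsv"
    with open(snp_path, "w") as fh:
        fh.write("# chrom pos ref alt\n")
        for t in truths:
            for s in t.locus.sites:
                fh.write(f"{s.chrom}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}\n")

    truth_path = out_dir / f"{prefix}.truth.tsv"
    write_truth(truths, truth_path, params if mode == "individual" else None)

    ref_len = truths[-1].locus.positions[-1] + 2 * params.read_length
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": params.chrom, "LN": int(ref_len)}],
        "RG": [
            {"ID": ind, "SM": ind}
            for ind in (individual_ids(params) if mode == "individual" else ["pool"])
        ],
    }

    records = []
    intended: list = []
    qlo, qhi = params.phred_range
    serial = 0
    for t in truths:
        bg_first, bg = _background(rng, t, params)
        site_offset = {s.pos: i for i, s in enumerate(t.locus.sites)}
        locus_obs: list[ReadObservation] = []
        for r in _draw_reads(t, params, rng, mode):
            if not r.calls:
                continue
            locus_obs.append(ReadObservation(r.source, dict(r.calls)))
            L = params.read_length
            seq = bg[r.start - bg_first : r.start - bg_first + L].copy()
            quals = rng.integers(qlo, qhi + 1, size=L)
            for pos, i in site_offset.items():
                if i in r.calls and r.start <= pos <= r.start + L - 1:
                    allele, q = r.calls[i]
                    seq[pos - r.start] = t.locus.sites[i].allele(allele)
                    quals[pos - r.start] = q
            serial += 1
            records.append((r.start - 1, r.source, serial, "".join(seq), quals))
        if mode == "individual":
            grouped: dict[str, list[ReadObservation]] = {}
            for o in locus_obs:
                grouped.setdefault(o.source_id, []).append(o)
            intended.append(grouped)
        else:
            intended.append(locus_obs)

    bam_path = out_dir / f"{prefix}.bam"
    records.sort(key=lambda rec: rec[0])
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
        for pos0, source, serial, seq, quals in records:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = f"read{serial:08d}"
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = 0
            a.reference_start = pos0
            a.mapping_quality = 60
            a.cigarstring = f"{len(seq)}M"
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in quals)
            )
            a.set_tag("RG", source)
            bam.write(a)
    pysam.index(os.fspath(bam_path))
    return SimulatedDataset(bam_path, snp_path, truth_path, truths, intended)


TRUTH_COLUMNS = [
    "chrom",
    "snp_positions",
    "ref_alleles",
    "alt_alleles",
    "haplotypes",
    "frequencies",
    "he",
    "observed_frequencies",
    "observed_he",
    "genotypes",
]


def write_truth(
    truths: Sequence[TruthRecord],
    path: str | os.PathLike,
    params: SimulationParams | None = None,
) -> None:
    """Truth TSV: one row per locus; genotypes column empty in pool mode."""
    rows = []
    for t in truths:
        locus = t.locus
        geno = ""
        if t.genotypes is not None:
            geno = ",".join(
                f"{locus.hap_bases(g.hap_a)}|{locus.hap_bases(g.hap_b)}"
                for g in t.genotypes
            )
        rows.append(
            {
                "chrom": locus.chrom,
                "snp_positions": ",".join(str(p) for p in locus.positions),
                "ref_alleles": "".join(s.ref_allele for s in locus.sites),
                "alt_alleles": "".join(s.alt_allele for s in locus.sites),
                "haplotypes": ",".join(locus.hap_bases(h) for h in t.haplotypes),
                "frequencies": ",".join(f"{f:.8f}" for f in t.freqs),
                "he": f"{t.he:.8f}",
                "observed_frequencies": ",".join(
                    f"{f:.8f}" for f in t.sample_freqs
                ),
                "observed_he": f"{t.sample_he:.8f}",
                "genotypes": geno,
            }
        )
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth(path: str | os.PathLike, window_bp: int = 60) -> list[TruthRecord]:
    """Parse a truth TSV back into TruthRecords (genotypes omitted)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    truths = []
    for row in df.itertuples(index=False):
        positions = [int(p) for p in row.snp_positions.split(",")]
        sites = tuple(
            SnpSite(row.chrom, p, r, a)
            for p, r, a in zip(positions, row.ref_alleles, row.alt_alleles)
        )
        locus = MicrohapLocus(row.chrom, sites, window_bp)
        haps = [locus.hap_from_bases(b) for b in row.haplotypes.split(",")]
        freqs = np.array([float(f) for f in row.frequencies.split(",")])
        observed = None
        if getattr(row, "observed_frequencies", ""):
            observed = np.array(
                [float(f) for f in row.observed_frequencies.split(",")]
            )
        truths.append(
            TruthRecord(locus, haps, freqs, float(row.he), observed_freqs=observed)
        )
    return truths
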