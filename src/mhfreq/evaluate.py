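"""Evaluation of frequency estimates against known (or observed) truth.

Mirrors the panel-design evaluation protocol: loci are binned by the
number of reads that informed the estimate, only loci with at least two
SNPs and observed expected heterozygosity above 0.1 are considered (the
methods target variable microhaplotypes), one allele with observed
frequency above 0.01 is selected at random from each locus in each bin,
and the error is computed as observed minus estimated frequency (an
allele absent from the estimate counts as frequency zero).  "Observed"
means the realized sample allele frequencies -- what full-depth
genotyping of the same individuals would report.  When a locus
contributes more than one estimate to a bin -- e.g. from different
downsampling levels -- one is selected at random.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import FrequencyEstimate
from .simulate import TruthRecord, truth_key

__all__ = ["DEFAULT_BINS", "evaluate_estimates", "evaluate_tables", "parse_bins"]

#: Read-count bins (inclusive bounds), five-read wide up to 45 then open.
DEFAULT_BINS: tuple[tuple[float, float], ...] = tuple(
    [(1 + 5 * k, 5 + 5 * k) for k in range(9)] + [(46, math.inf)]
)


def parse_bins(text: str) -> tuple[tuple[float, float], ...]:
    """Parse bin edges like ``"1-5,6-10,11+"`` into (lo, hi) pairs."""
    bins = []
    for part in text.split(","):
        part = part.strip()
        if part.endswith("+"):
            bins.append((float(part[:-1]), math.inf))
        else:
            lo, hi = part.split("-")
            bins.append((float(lo), float(hi)))
    return tuple(bins)


@dataclass
class _Record:
    key: tuple
    n_snps: int
    true_freqs: dict[str, float]
    true_he: float
    n_reads: int
    est_freqs: dict[str, float]
    est_he: float


def _bin_index(n_reads: int, bins: Sequence[tuple[float, float]]) -> int | None:
    for b, (lo, hi) in enumerate(bins):
        if lo <= n_reads <= hi:
            return b
    return None


def _evaluate(
    records: list[_Record],
    bins: Sequence[tuple[float, float]],
    rng: np.random.Generator,
    min_snps: int,
    min_he: float,
    min_allele_freq: float,
) -> pd.DataFrame:
    kept: dict[tuple[int, tuple], list[_Record]] = {}
    for rec in records:
        if rec.n_snps < min_snps or rec.true_he <= min_he:
            continue
        b = _bin_index(rec.n_reads, bins)
        if b is None:
            continue
        kept.setdefault((b, rec.key), []).append(rec)

    per_bin_err: dict[int, list[float]] = {b: [] for b in range(len(bins))}
    per_bin_he_err: dict[int, list[float]] = {b: [] for b in range(len(bins))}
    # deterministic iteration order so the seeded selections are reproducible
    for (b, _key), recs in sorted(kept.items()):
        rec = recs[int(rng.integers(len(recs)))] if len(recs) > 1 else recs[0]
        eligible = sorted(
            h for h, f in rec.true_freqs.items() if f > min_allele_freq
        )
        if not eligible:
            continue
        hap = eligible[int(rng.integers(len(eligible)))]
        err = rec.true_freqs[hap] - rec.est_freqs.get(hap, 0.0)
        per_bin_err[b].append(err)
        per_bin_he_err[b].append(rec.true_he - rec.est_he)

    rows = []
    for b, (lo, hi) in enumerate(bins):
        errs = np.array(per_bin_err[b])
        he_errs = np.array(per_bin_he_err[b])
        rows.append(
            {
                "bin_low": lo,
                "bin_high": hi,
                "n": len(errs),
                "mean_error": errs.mean() if len(errs) else math.nan,
                "median_error": float(np.median(errs)) if len(errs) else math.nan,
                "mse": float(np.mean(errs**2)) if len(errs) else math.nan,
                "mean_he_error": he_errs.mean() if len(he_errs) else math.nan,
                "he_mse": float(np.mean(he_errs**2)) if len(he_errs) else math.nan,
            }
        )
    return pd.DataFrame(rows)


def evaluate_estimates(
    truths: Sequence[TruthRecord],
    estimates: Sequence[FrequencyEstimate],
    bins: Sequence[tuple[float, float]] | None = None,
    seed: int = 0,
    min_snps: int = 2,
    min_he: float = 0.1,
    min_allele_freq: float = 0.01,
) -> pd.DataFrame:
    """Per-bin bias/MSE table for estimates measured against simulator truth.

    Skipped estimates carry no frequencies and are excluded.  An estimate
    whose locus is missing from the truth set is an error; so is an empty
    truth/estimate intersection.
    """
    bins = tuple(bins) if bins is not None else DEFAULT_BINS
    by_key = {truth_key(t.locus): t for t in truths}
    records = []
    missing = []
    for est in estimates:
        if est.skipped:
            continue
        key = truth_key(est.locus)
        t = by_key.get(key)
        if t is None:
            missing.append(key)
            continue
        records.append(
            _Record(
                key=key,
                n_snps=est.locus.n_sites,
                true_freqs=t.sample_freq_by_bases(),
                true_he=t.sample_he,
                n_reads=est.n_reads_used,
                est_freqs={
                    est.locus.hap_bases(h): float(p)
                    for h, p in zip(est.haplotypes, est.pi)
                },
                est_he=est.he,
            )
        )
    if missing:
        examples = ", ".join(f"{c}:{p[0]}" for c, p in missing[:5])
        raise ValueError(
            f"{len(missing)} estimated loci missing from truth (e.g. {examples})"
        )
    if not records:
        raise ValueError("no loci shared between truth and estimates")
    rng = np.random.default_rng(seed)
    return _evaluate(records, bins, rng, min_snps, min_he, min_allele_freq)


def evaluate_tables(
    truths: Sequence[TruthRecord],
    estimates_df: pd.DataFrame,
    bins: Sequence[tuple[float, float]] | None = None,
    seed: int = 0,
    min_snps: int = 2,
    min_he: float = 0.1,
    min_allele_freq: float = 0.01,
) -> pd.DataFrame:
    """Same evaluation, from parsed truth records and an estimates table.

    ``estimates_df`` is the frame returned by ``bamio.read_estimates``.
    """
    bins = tuple(bins) if bins is not None else DEFAULT_BINS
    by_key = {truth_key(t.locus): t for t in truths}
    records = []
    missing = []
    for row in estimates_df.itertuples(index=False):
        if row.skip_reason is not None or not len(row.haplotypes):
            continue
        key = (row.chrom, row.snp_positions)
        t = by_key.get(key)
        if t is None:
            missing.append(key)
            continue
        records.append(
            _Record(
                key=key,
                n_snps=int(row.n_snps),
                true_freqs=t.sample_freq_by_bases(),
                true_he=t.sample_he,
                n_reads=int(row.n_reads),
                est_freqs={
                    h: float(f) for h, f in zip(row.haplotypes, row.frequencies)
                },
                est_he=float(row.he),
            )
        )
    if missing:
        examples = ", ".join(f"{c}:{p[0]}" for c, p in missing[:5])
        raise ValueError(
            f"{len(missing)} estimated loci missing from truth (e.g. {examples})"
        )
    if not records:
        raise ValueError("no loci shared between truth and estimates")
    rng = np.random.default_rng(seed)
    return _evaluate(records, bins, rng, min_snps, min_he, min_allele_freq)
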