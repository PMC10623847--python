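"""Reusable simulation experiments for validating the estimators.

The central protocol mirrors how the estimators are meant to be assessed:
one set of loci with known truth, re-sequenced at several mean depths (as
if the same samples had been downsampled to different coverages), each
dataset estimated with both methods -- the pool method simply ignores the
read-to-individual assignment -- and all estimates pooled and binned by
the number of reads that informed them.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import replace

import numpy as np

from .estimators import EmSettings, FrequencyEstimate, prune_and_estimate
from .model import ErrorModel
from .simulate import (
    SimulationParams,
    TruthRecord,
    simulate_locus_reads,
    simulate_truth,
)

__all__ = ["depth_sweep_experiment"]


def depth_sweep_experiment(
    params: SimulationParams,
    depths: Sequence[float],
    seed: int,
    methods: Sequence[str] = ("individual", "pool"),
    settings: EmSettings | None = None,
) -> tuple[list[TruthRecord], dict[str, list[FrequencyEstimate]]]:
    """Simulate one truth set, estimate it at several mean depths.

    Returns the truth records and, per method, the estimates from all
    depth levels concatenated (a locus therefore appears once per depth).
    Individual-mode reads are generated once per depth and the pool
    estimator is run on the same reads with individual assignment ignored.
    """
    rng = np.random.default_rng(seed)
    model = ErrorModel(pre_seq_error=params.pre_seq_error)
    settings = settings or EmSettings()
    truths = simulate_truth(params, rng, "individual")
    estimates: dict[str, list[FrequencyEstimate]] = {m: [] for m in methods}
    for depth in depths:
        p_depth = replace(params, mean_depth=depth)
        for truth in truths:
            grouped = simulate_locus_reads(truth, p_depth, rng, "individual")
            if "individual" in estimates:
                estimates["individual"].append(
                    prune_and_estimate(
                        truth.locus, grouped, "individual", model, settings
                    )
                )
            if "pool" in estimates:
                flat = [r for rs in grouped.values() for r in rs]
                estimates["pool"].append(
                    prune_and_estimate(truth.locus, flat, "pool", model, settings)
                )
    return truths, estimates
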