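"""Composition of graph and classic augmentations, and policy grid search.

The composition order is fixed: the graph stage runs first, the classic
stage second.  The graph stage relies on the cohort-level correlation
structure being intact — lead-wise classic perturbations (noise, masking,
time warps) invalidate the very correlations the adjacency matrix encodes,
so mixing after them would blend already-corrupted leads.  ``compose``
therefore offers no reversed order.

``grid_search`` sweeps RandAugment's two knobs — the operation count N and
the shared intensity gamma — over a user grid, training seeded replicates
per cell and reporting mean +- sd validation macro-F1.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .classic import ClassicAugPolicy, apply_classic
from .graph import AugmentationGraph
from .graph_augment import GraphAugConfig, apply_graph_augmentation
from .io import Cohort, WaveformRecord

__all__ = ["compose", "make_augmenter", "grid_search"]


def compose(
    record: WaveformRecord,
    graph: AugmentationGraph | None,
    gcfg: GraphAugConfig | None,
    cpolicy: ClassicAugPolicy | None,
    rng: np.random.Generator,
) -> WaveformRecord:
    """Graph augmentation first, classic augmentations second.

    Either stage may be disabled by passing ``None`` (or p=0 / N=0); the
    input record is never mutated.
    """
    out = record
    if graph is not None and gcfg is not None:
        out = apply_graph_augmentation(out, graph, gcfg, rng)
    if cpolicy is not None:
        out = apply_classic(out, cpolicy, rng)
    if out is record:
        out = WaveformRecord(
            signal=record.signal.copy(),
            lead_names=record.lead_names,
            sampling_rate=record.sampling_rate,
            record_id=record.record_id,
            labels=record.labels,
        )
    return out


def make_augmenter(
    graph: AugmentationGraph | None = None,
    gcfg: GraphAugConfig | None = None,
    cpolicy: ClassicAugPolicy | None = None,
) -> Callable[[WaveformRecord, np.random.Generator], WaveformRecord]:
    """Bind configs into a (record, rng) -> record callable for training loops."""

    def augmenter(record: WaveformRecord, rng: np.random.Generator) -> WaveformRecord:
        return compose(record, graph, gcfg, cpolicy, rng)

    return augmenter


def grid_search(
    train: Cohort,
    val: Cohort,
    graph: AugmentationGraph | None,
    numbers: Sequence[int],
    intensities: Sequence[float],
    trainer: Callable,
    n_repeats: int = 1,
    seed: int = 0,
    gcfg: GraphAugConfig | None = None,
    enabled_ops: Sequence[str] = ("gauss_noise", "time_transform", "smooth", "mask"),
) -> tuple[pd.DataFrame, tuple[int, float]]:
    """Grid-search (N, gamma) for the classic stage at fixed graph settings.

    ``trainer(train, val, augmenter, seed) -> validation macro-F1`` is any
    training procedure; each of the |numbers| x |intensities| cells trains
    ``n_repeats`` seeded replicates.  Returns the full results table and the
    argmax (N, gamma) pair.  Graph-stage parameters are held fixed: the
    graph stage is a single method, tuned separately if at all.
    """
    numbers = list(numbers)
    intensities = list(intensities)
    if not numbers or not intensities:
        raise ValueError("empty grid")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(
        len(numbers) * len(intensities) * n_repeats
    ) % (2**31)
    rows = []
    cell = 0
    for n_ops in numbers:
        for gamma in intensities:
            cpolicy = ClassicAugPolicy(
                gamma=gamma, enabled_ops=tuple(enabled_ops), n_per_record=n_ops
            )
            aug = make_augmenter(graph=graph, gcfg=gcfg, cpolicy=cpolicy)
            f1s = [
                trainer(train, val, aug, int(seeds[cell * n_repeats + r]))
                for r in range(n_repeats)
            ]
            rows.append(
                {
                    "number": n_ops,
                    "intensity": gamma,
                    "mean_val_f1": float(np.mean(f1s)),
                    "sd_val_f1": float(np.std(f1s, ddof=1)) if len(f1s) > 1 else 0.0,
                }
            )
            cell += 1
    table = pd.DataFrame(rows)
    best = table.loc[table["mean_val_f1"].idxmax()]
    return table, (int(best["number"]), float(best["intensity"]))
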