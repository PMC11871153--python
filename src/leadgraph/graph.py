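"""Lead-correlation augmentation graph.

The augmentation graph is a weighted, undirected graph over the leads of a
multi-lead montage.  Edge weight A_ij is the cohort-average Pearson
correlation (cross-correlation at lag 0, normalized so that
self-correlation is 1) between the signals recorded on leads i and j; the
diagonal is fixed to 0.  Weights keep their sign: anatomically opposed
leads (e.g. aVR against lead II) genuinely anti-correlate and that sign
carries real geometry.

The expectation is taken as the unweighted mean over records of a chosen
split — by default the training split only, to keep held-out information
out of the graph.  Records where a lead is constant (zero variance, so the
correlation is undefined) are excluded from that pair's average and the
exclusions are logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "AugmentationGraph",
    "lead_correlation",
    "estimate_graph",
    "save_graph",
    "load_graph",
]

TOOL_VERSION = "0.1.0"


@dataclass
class AugmentationGraph:
    """L x L weighted adjacency of cohort-average lead correlations."""

    weights: np.ndarray
    lead_names: tuple[str, ...]
    n_records: int
    source_split: str = "train"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.lead_names = tuple(str(n) for n in self.lead_names)
        self.validate()

    def validate(self) -> None:
        L = len(self.lead_names)
        if self.weights.shape != (L, L):
            raise ValueError(f"weights shape {self.weights.shape} != ({L}, {L})")
        if np.any(np.abs(np.diag(self.weights)) > 0):
            raise ValueError("nonzero diagonal")
        if np.max(np.abs(self.weights - self.weights.T)) > 1e-12:
            raise ValueError("asymmetric")
        off = self.weights[~np.eye(L, dtype=bool)]
        if off.size and (off.min() < -1 - 1e-12 or off.max() > 1 + 1e-12):
            raise ValueError("off-diagonal weight outside [-1, 1]")

    @property
    def n_leads(self) -> int:
        return len(self.lead_names)


def lead_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation between two equal-length signals.

    Uses the population convention (means and standard deviations divide by
    T) so that the self-correlation of any non-constant signal is exactly 1.
    A constant input has no defined correlation; 0 is returned and the case
    is logged.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.mean(xc * xc))
    sy = np.sqrt(np.mean(yc * yc))
    if sx == 0.0 or sy == 0.0:
        logger.warning("constant input to lead_correlation; returning 0")
        return 0.0
    return float(np.mean(xc * yc) / (sx * sy))


def _record_correlations(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-record correlation matrix and a validity mask for constant leads."""
    centered = signal - signal.mean(axis=1, keepdims=True)
    sd = np.sqrt(np.mean(centered**2, axis=1))
    ok = sd > 0
    z = np.zeros_like(centered)
    z[ok] = centered[ok] / sd[ok, None]
    corr = z @ z.T / signal.shape[1]
    valid = np.outer(ok, ok)
    return corr, valid


def estimate_graph(cohort: Cohort, split: str | None = "train") -> AugmentationGraph:
    """Average per-record lead-pair correlations over a cohort split.

    Each record contributes one Pearson correlation per lead pair; the edge
    weight is their unweighted mean.  Pass ``split=None`` to use every
    record (e.g. for a cohort without split tags).  Pairs for which every
    record was excluded (constant leads) get weight 0 with a warning.
    """
    if split is not None and cohort.split_assignment is not None:
        sub = cohort.subset(split)
    else:
        sub = cohort
        split = split or "all"
    if not sub.records:
        raise ValueError(f"empty split {split!r}")
    L = sub.n_leads
    total = np.zeros((L, L))
    counts = np.zeros((L, L), dtype=np.int64)
    for rec in sub.records:
        corr, valid = _record_correlations(rec.signal)
        total[valid] += corr[valid]
        counts += valid
    excluded = len(sub.records) - counts
    np.fill_diagonal(excluded, 0)
    if excluded.any():
        logger.info(
            "constant-lead exclusions per pair (max %d of %d records)",
            int(excluded.max()), len(sub.records),
        )
    weights = np.zeros((L, L))
    nz = counts > 0
    weights[nz] = total[nz] / counts[nz]
    dead = ~nz & ~np.eye(L, dtype=bool)
    if dead.any():
        logger.warning("all records excluded for %d lead pairs; weight set to 0", int(dead.sum() // 2))
    np.fill_diagonal(weights, 0.0)
    weights = (weights + weights.T) / 2  # remove fp-level asymmetry
    weights = np.clip(weights, -1.0, 1.0)
    return AugmentationGraph(
        weights=weights,
        lead_names=sub.lead_names,
        n_records=len(sub.records),
        source_split=split,
    )


def save_graph(graph: AugmentationGraph, path: str | Path) -> None:
    """Serialize to JSON (full float precision, row-major weights)."""
    payload = {
        "lead_names": list(graph.lead_names),
        "weights": [list(row) for row in graph.weights],
        "n_records": graph.n_records,
        "source_split": graph.source_split,
        "tool_version": TOOL_VERSION,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_graph(path: str | Path) -> AugmentationGraph:
    """Load and re-validate a JSON graph file."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed graph file {path}: {e}") from e
    return AugmentationGraph(
        weights=np.asarray(payload["weights"], dtype=np.float64),
        lead_names=tuple(payload["lead_names"]),
        n_records=int(payload["n_records"]),
        source_split=payload.get("source_split", "train"),
    )
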