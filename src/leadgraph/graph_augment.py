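"""Graph-induced surrogate leads and stochastic convex mixing.

For lead i of a record, the surrogate lead is the linear combination of
all *other* leads weighted by the augmentation graph's row i:

    x_tilde_i = sum_{j != i} A_ij x_j

The augmented lead is the convex combination

    x_hat_i = (1 - lam) x_i + lam x_tilde_i,   lam ~ U(0, alpha),

applied stochastically with probability p.  Surrogates are always computed
from the original, unmixed record, so mixing one lead never contaminates
another lead's surrogate within a single application.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .graph import AugmentationGraph
from .io import WaveformRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GraphAugConfig",
    "surrogate_lead",
    "surrogate_matrix",
    "graph_mix",
    "apply_graph_augmentation",
]


@dataclass
class GraphAugConfig:
    """Stochastic-mixing policy: application probability p and mixing cap alpha.

    ``scope`` chooses whether the Bernoulli(p) gate is drawn once per lead
    (default, each lead independently) or once per record (all leads mixed
    together or none).  ``normalize_weights`` divides each surrogate by the
    sum of absolute weights so its amplitude is comparable to the original;
    the default leaves the raw weighted sum.
    """

    p: float = 0.5
    alpha: float = 0.3
    scope: str = "per-lead"
    normalize_weights: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0,1], got {self.p}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0,1], got {self.alpha}")
        if self.scope not in ("per-lead", "per-record"):
            raise ValueError(f"scope must be per-lead or per-record, got {self.scope!r}")


def _check_leads(record: WaveformRecord, graph: AugmentationGraph) -> None:
    if record.lead_names != graph.lead_names:
        raise ValueError(
            f"lead-name mismatch: record {record.lead_names} vs graph {graph.lead_names}"
        )


def surrogate_lead(
    record: WaveformRecord,
    graph: AugmentationGraph,
    i: int,
    normalize: bool = False,
) -> np.ndarray:
    """Surrogate for lead i: the A-weighted sum of all other leads.

    With ``normalize`` the sum is divided by sum_j |A_ij| (an all-zero row
    yields a zero surrogate with a warning).
    """
    _check_leads(record, graph)
    if not 0 <= i < record.n_leads:
        raise IndexError(f"lead index {i} out of range")
    w = graph.weights[i]  # A_ii = 0, so the full product skips lead i
    out = w @ record.signal
    if normalize:
        denom = np.sum(np.abs(w))
        if denom == 0.0:
            logger.warning("lead %d has all-zero graph weights; surrogate is zero", i)
            return np.zeros(record.n_samples)
        out = out / denom
    return out


def surrogate_matrix(
    record: WaveformRecord, graph: AugmentationGraph, normalize: bool = False
) -> np.ndarray:
    """All L surrogate leads at once, as an (L, T) matrix."""
    _check_leads(record, graph)
    out = graph.weights @ record.signal
    if normalize:
        denom = np.sum(np.abs(graph.weights), axis=1)
        safe = denom > 0
        if not safe.all():
            logger.warning("%d leads have all-zero graph weights", int((~safe).sum()))
        out[safe] /= denom[safe, None]
        out[~safe] = 0.0
    return out


def graph_mix(x: np.ndarray, x_tilde: np.ndarray, lam: float) -> np.ndarray:
    """Convex combination (1 - lam) x + lam x_tilde."""
    x = np.asarray(x, dtype=np.float64)
    x_tilde = np.asarray(x_tilde, dtype=np.float64)
    if x.shape != x_tilde.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_tilde.shape}")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must be in [0,1], got {lam}")
    return (1.0 - lam) * x + lam * x_tilde


def apply_graph_augmentation(
    record: WaveformRecord,
    graph: AugmentationGraph,
    cfg: GraphAugConfig,
    rng: np.random.Generator,
) -> WaveformRecord:
    """Stochastically mix each lead toward its graph surrogate.

    Per-lead scope: each lead draws its own Bernoulli(p) gate; every mixed
    lead draws a fresh lam ~ U(0, alpha).  Per-record scope: one gate for
    the whole record, still one lam per lead.  Surrogates come from the
    original record; labels, lead names and sampling rate pass through.
    Only the supplied random stream is consumed.
    """
    _check_leads(record, graph)
    L = record.n_leads
    if cfg.scope == "per-lead":
        gate = rng.random(L) < cfg.p
    else:
        gate = np.full(L, bool(rng.random() < cfg.p))
    if not gate.any():
        return replace(record, signal=record.signal.copy())
    tilde = surrogate_matrix(record, graph, normalize=cfg.normalize_weights)
    new = record.signal.copy()
    for i in np.flatnonzero(gate):
        lam = rng.uniform(0.0, cfg.alpha)
        new[i] = graph_mix(record.signal[i], tilde[i], lam)
    return replace(record, signal=new)
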