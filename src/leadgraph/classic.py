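"""Classic single-lead augmentations under one shared intensity gamma.

Four traditional waveform augmentations — additive Gaussian noise, a time
cut/pad transform, Gaussian-kernel smoothing, and zero masking — all read
their strength from a single shared intensity parameter gamma, so a
RandAugment-style policy can tune one magnitude for the whole suite.
Noise and smoothing treat gamma as a dimensionless factor; the time
transform and masking read it as a percentage of the signal length.
gamma = 0 makes every operation the exact identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .io import WaveformRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ClassicAugPolicy",
    "gauss_noise",
    "time_transform",
    "smooth",
    "mask",
    "apply_classic",
    "CLASSIC_OPS",
]


def gauss_noise(
    x: np.ndarray, gamma: float, rng: np.random.Generator, absolute: bool = False
) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise to every sample.

    By default the noise variance is gamma times the signal's own variance,
    making gamma dimensionless and comparable across leads and datasets;
    ``absolute=True`` uses variance gamma directly.  A constant signal has
    zero variance, so the default mode leaves it untouched (logged).
    """
    x = np.asarray(x, dtype=np.float64)
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if gamma == 0:
        return x.copy()
    if absolute:
        var = float(gamma)
    else:
        s2 = float(np.var(x))
        if s2 == 0.0:
            logger.info("constant signal: relative-variance gauss_noise is the identity")
            return x.copy()
        var = gamma * s2
    return x + rng.normal(0.0, np.sqrt(var), size=x.shape)


def _window(T: int, gamma: float) -> int:
    # round-half-to-even on T*gamma/100
    return int(np.rint(T * gamma / 100.0))


def time_transform(x: np.ndarray, gamma: float, rng: np.random.Generator) -> np.ndarray:
    """Cut or zero-pad gamma% of the signal, then re-interpolate to length T.

    A fair coin picks cut vs pad.  Cut: a contiguous run of round(T*gamma/100)
    samples at a uniformly random start is deleted and the remainder is
    stretched back to T by linear interpolation.  Pad: the same number of
    zeros is appended at a coin-chosen end and the result compressed back
    to T.  Output length is always T.
    """
    x = np.asarray(x, dtype=np.float64)
    if not 0 <= gamma <= 100:
        raise ValueError("gamma must be in [0, 100] (percent)")
    T = x.size
    w = _window(T, gamma)
    if w == 0:
        return x.copy()
    if w >= T:
        raise ValueError(f"cut/pad window {w} must be < signal length {T}")
    if rng.random() < 0.5:  # cut
        start = int(rng.integers(0, T - w + 1))
        kept = np.delete(x, np.s_[start : start + w])
    else:  # pad
        zeros = np.zeros(w)
        kept = np.concatenate([zeros, x] if rng.random() < 0.5 else [x, zeros])
    src = np.linspace(0.0, 1.0, kept.size)
    dst = np.linspace(0.0, 1.0, T)
    return np.interp(dst, src, kept)


def smooth(x: np.ndarray, gamma: float, rng: np.random.Generator) -> np.ndarray:
    """Weighted moving average with a Gaussian kernel of random half-width.

    The half-width l is drawn uniformly from {1,...,5}; the kernel has
    length 2l+1, standard deviation gamma*l, sums to 1, and edges are
    handled by reflection.  gamma = 0 collapses the kernel to a unit
    impulse, i.e. the identity.
    """
    x = np.asarray(x, dtype=np.float64)
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    l = int(rng.integers(1, 6))
    if gamma == 0:
        return x.copy()
    offsets = np.arange(-l, l + 1, dtype=np.float64)
    kernel = np.exp(-0.5 * (offsets / (gamma * l)) ** 2)
    kernel /= kernel.sum()
    padded = np.pad(x, l, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def mask(x: np.ndarray, gamma: float, rng: np.random.Generator) -> np.ndarray:
    """Zero out one contiguous run of gamma% of the samples at a random start."""
    x = np.asarray(x, dtype=np.float64)
    if not 0 <= gamma <= 100:
        raise ValueError("gamma must be in [0, 100] (percent)")
    T = x.size
    w = _window(T, gamma)
    if w > T:
        raise ValueError(f"mask window {w} exceeds signal length {T}")
    out = x.copy()
    if w == 0:
        return out
    start = int(rng.integers(0, T - w + 1))
    out[start : start + w] = 0.0
    return out


CLASSIC_OPS = {
    "gauss_noise": gauss_noise,
    "time_transform": time_transform,
    "smooth": smooth,
    "mask": mask,
}


@dataclass
class ClassicAugPolicy:
    """RandAugment-style policy over the four classic operations.

    ``n_per_record`` operations are sampled uniformly *with replacement*
    from ``enabled_ops`` per record (RandAugment's convention, so n may
    exceed the number of enabled ops) and applied in sampled order, each
    to every lead independently with fresh randomness.
    """

    gamma: float = 10.0
    enabled_ops: tuple[str, ...] = ("gauss_noise", "time_transform", "smooth", "mask")
    n_per_record: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.enabled_ops = tuple(self.enabled_ops)
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.n_per_record < 0:
            raise ValueError("n_per_record must be >= 0")
        unknown = set(self.enabled_ops) - set(CLASSIC_OPS)
        if unknown:
            raise ValueError(f"unknown ops {sorted(unknown)}")
        if self.n_per_record > 0 and not self.enabled_ops:
            raise ValueError("n_per_record > 0 with no enabled ops")


def apply_classic(
    record: WaveformRecord, policy: ClassicAugPolicy, rng: np.random.Generator
) -> WaveformRecord:
    """Apply a sampled sequence of classic ops lead-wise; labels untouched."""
    if policy.n_per_record == 0:
        return replace(record, signal=record.signal.copy())
    picks = rng.integers(0, len(policy.enabled_ops), size=policy.n_per_record)
    signal = record.signal.copy()
    for k in picks:
        op = CLASSIC_OPS[policy.enabled_ops[int(k)]]
        for i in range(signal.shape[0]):
            signal[i] = op(signal[i], policy.gamma, rng)
    return replace(record, signal=signal)
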