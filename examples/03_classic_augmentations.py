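"""The four classic augmentations under one shared intensity gamma.

gamma is dimensionless for noise/smoothing (noise variance = gamma * signal
variance; kernel sd = gamma * half-width) and a percentage of the signal
length for the time transform and masking.
"""

import numpy as np

from leadgraph import gauss_noise, mask, smooth, time_transform

rng = np.random.default_rng(0)
t = np.arange(500) / 100.0
x = np.sin(2 * np.pi * 1.3 * t) + 0.1 * rng.normal(size=t.size)

gamma = 10.0  # 10% windows for mask/time; strong for noise/smooth
for name, op, g in [
    ("gauss_noise", gauss_noise, 0.25),
    ("time_transform", time_transform, gamma),
    ("smooth", smooth, 1.0),
    ("mask", mask, gamma),
]:
    out = op(x, g, rng)
    rms = np.sqrt(np.mean((out - x) ** 2))
    print(f"{name:15s} gamma={g:5.2f}  length {out.size}  RMS change {rms:.3f}  "
          f"zeros {int(np.sum(out == 0.0))}")
# Length is always preserved; mask shows exactly round(T*gamma/100) = 50
# zeros; gamma = 0 would make every operation the exact identity.
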