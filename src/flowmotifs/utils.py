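"""Small numeric helpers shared across modules."""

from __future__ import annotations

import math

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_phase(x):
    """Wrap angles into the half-open interval (-pi, pi]."""
    x = np.asarray(x, dtype=float)
    return x - TWO_PI * np.ceil((x - np.pi) / TWO_PI)


def round_half_away(v: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    if v >= 0:
        return int(math.floor(v + 0.5))
    return int(math.ceil(v - 0.5))


def pearson(a, b) -> float:
    """Pearson correlation; NaN for fewer than 2 points or zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or a.std() == 0.0 or b.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
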