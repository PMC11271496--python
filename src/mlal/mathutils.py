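"""Small shared numerical helpers."""

from __future__ import annotations

import numpy as np


def smoothstep_down(r: np.ndarray, r_on: float, r_off: float):
    """C² switching function: 1 below ``r_on``, 0 above ``r_off``; returns (s, ds/dr)."""
    r = np.asarray(r, dtype=float)
    t = np.clip((r - r_on) / (r_off - r_on), 0.0, 1.0)
    s = 1.0 - t**3 * (10.0 - 15.0 * t + 6.0 * t**2)
    ds = -(30.0 * t**2 - 60.0 * t**3 + 30.0 * t**4) / (r_off - r_on)
    inside = (r > r_on) & (r < r_off)
    ds = np.where(inside, ds, 0.0)
    return s, ds
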