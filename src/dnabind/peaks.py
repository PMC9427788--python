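"""Sub-grid peak localization shared by the UV and FT-IR analyses."""

from __future__ import annotations

import numpy as np


def refine_peak(x: np.ndarray, y: np.ndarray, lo: float, hi: float
                ) -> tuple[float, bool]:
    """Locate the maximum of ``y`` within the window ``[lo, hi]`` of ``x``.

    ``x`` must be strictly increasing. The grid maximum is refined by
    fitting a parabola through the three points around it (vertex of the
    quadratic), which recovers sub-grid peak positions for smooth bands.

    Returns ``(position, on_edge)``: ``on_edge`` is true when the maximum
    sits on the first or last sample of the window, in which case no
    refinement is possible and the position is unreliable.
    """
    mask = (x >= lo) & (x <= hi)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"window [{lo}, {hi}] outside the grid")
    sub = y[idx]
    k = int(np.argmax(sub))
    i = idx[k]
    if k == 0 or k == idx.size - 1 or i == 0 or i == x.size - 1:
        return float(x[i]), True
    x3, y3 = x[i - 1:i + 2], y[i - 1:i + 2]
    a, b, _ = np.polyfit(x3 - x3[1], y3, 2)
    if a >= 0:  # flat or concave-up triplet: no interior vertex
        return float(x[i]), False
    return float(x3[1] - b / (2 * a)), False


def has_local_maximum(x: np.ndarray, y: np.ndarray, lo: float, hi: float) -> bool:
    """True when the window's maximum is an interior point of the window."""
    mask = (x >= lo) & (x <= hi)
    idx = np.flatnonzero(mask)
    if idx.size < 3:
        return False
    k = int(np.argmax(y[idx]))
    return 0 < k < idx.size - 1
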