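"""Shared distance-bin grids.

Log spacing is the default throughout: it equalizes point density in the
log-log space where the regressions happen, and geometric bin midpoints are
the natural representative distance there.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError


def bin_grid(range_bp: tuple[float, float], n_bins: int,
             spacing: str = "log") -> tuple[np.ndarray, np.ndarray]:
    """Return ``(edges, mids)`` for ``n_bins`` bins spanning ``range_bp``.

    Log spacing uses geometric midpoints, linear spacing arithmetic ones.
    """
    lo, hi = range_bp
    if not (0 < lo < hi):
        raise ValidationError(f"bin range must satisfy 0 < lo < hi, got {range_bp}")
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    if spacing == "log":
        edges = np.geomspace(lo, hi, n_bins + 1)
        mids = np.sqrt(edges[:-1] * edges[1:])
    elif spacing == "linear":
        edges = np.linspace(lo, hi, n_bins + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
    else:
        raise ValidationError(f"spacing must be 'log' or 'linear', got {spacing!r}")
    return edges, mids
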