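"""Angle arithmetic helpers.

All headings in this package are degrees, counterclockwise from the +x axis,
in tank-centered coordinates. Wrapping is always explicit through these
helpers so that 360-degree periodicity never leaks into distance metrics.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap360", "wrap180", "signed_diff", "circ_abs_diff", "unwrap_deg"]


def wrap360(theta):
    """Wrap angle(s) to [0, 360).

    Floating modulo of a tiny negative angle rounds to exactly 360.0, so
    the boundary is folded back to 0 explicitly.
    """
    w = np.asarray(theta, dtype=float) % 360.0
    w = np.where(w == 360.0, 0.0, w)
    return w if w.ndim else float(w)


def wrap180(theta):
    """Wrap angle(s) to [0, 180) — the orientation domain of the LUT."""
    w = np.asarray(theta, dtype=float) % 180.0
    w = np.where(w == 180.0, 0.0, w)
    return w if w.ndim else float(w)


def signed_diff(a, b):
    """Signed smallest difference a - b, in (-180, 180]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    d = np.where(d > 180.0, d - 360.0, d)
    return d if d.ndim else float(d)


def circ_abs_diff(a, b, period: float = 360.0):
    """Absolute circular difference between angles, in [0, period/2]."""
    d = np.abs((np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % period)
    d = np.minimum(d, period - d)
    return d if d.ndim else float(d)


def unwrap_deg(theta):
    """Remove 360-degree jumps from a time-ordered heading trace."""
    return np.degrees(np.unwrap(np.radians(np.asarray(theta, dtype=float))))
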