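"""Trajectory assembly: identity assignment, collision rejection,
smoothing, tail-bend angles, and resampling.

Per-pulse match results become per-animal tracks. With two animals in the
tank each pulse is attributed to the individual whose previously identified
state is nearest (position plus weighted angular distance). Temporally
overlapping ("collided") pulses match the dipole model poorly, so points
with a LUT score below 0.9 are rejected. Position and orientation traces are
median-filtered then triangular-filtered; orientations are unwrapped first
so filters never see 360-degree jumps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal.windows import triang

from .angles import circ_abs_diff, unwrap_deg, wrap360
from .geometry import DipoleState
from .localize import MatchResult

__all__ = [
    "TrackPoint",
    "SmoothingSpec",
    "assign_identity",
    "reject_collisions",
    "resolve_polarity",
    "smooth_trajectory",
    "compute_tail_bend",
    "resample_trajectory",
    "median_filter1d",
    "triangular_filter1d",
]

log = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 0.9  # collision-rejection dot-product threshold
DEFAULT_GATE_CM = 20.0  # max plausible displacement between ~50 Hz pulses
DEFAULT_LAMBDA_CM_PER_DEG = 0.1  # angular weight in the assignment metric


@dataclass
class TrackPoint:
    """One localized pulse on an animal's track."""

    time: float
    state: DipoleState
    score: float
    animal_id: int = 0
    tail_state: Optional[DipoleState] = None
    tail_bend: Optional[float] = None
    excluded_channels: tuple = ()
    flagged: bool = False


@dataclass(frozen=True)
class SmoothingSpec:
    """Median + triangular filter windows (samples).

    Defaults: median 8 (position) / 15 (orientation), triangular 15
    (position) / 30 (orientation).
    """

    median_window_position: int = 8
    median_window_orientation: int = 15
    triangular_window_position: int = 15
    triangular_window_orientation: int = 30

    def __post_init__(self):
        for w in (
            self.median_window_position,
            self.median_window_orientation,
            self.triangular_window_position,
            self.triangular_window_orientation,
        ):
            if w < 1:
                raise ValueError("filter windows must be >= 1")


# ---------------------------------------------------------------------------
# Identity assignment and collision rejection
# ---------------------------------------------------------------------------


def _combined_distance(
    state: DipoleState, other: DipoleState, lam: float
) -> Tuple[float, float]:
    pos = float(np.linalg.norm(state.position - other.position))
    ang = circ_abs_diff(state.theta, other.theta)
    return pos + lam * ang, ang


def assign_identity(
    events: Sequence[Tuple[float, MatchResult]],
    tracks: Dict[int, DipoleState],
    gate: float = DEFAULT_GATE_CM,
    lam: float = DEFAULT_LAMBDA_CM_PER_DEG,
) -> List[TrackPoint]:
    """Label time-ordered match results with animal identities.

    Each event goes to the animal minimizing position distance plus
    ``lam`` (cm/deg) times the angular distance from its last identified
    state; events whose position lies beyond ``gate`` cm of every track are
    left unassigned (logged and skipped). Ties break to the smaller angular
    distance, then to the lower animal id. ``tracks`` (animal id -> last
    confirmed state, e.g. from user-confirmed first pulses) is updated in
    event order.
    """
    labeled: List[TrackPoint] = []
    n_unassigned = 0
    for t, res in events:
        best = None
        for aid in sorted(tracks):
            last = tracks[aid]
            pos_d = float(np.linalg.norm(res.state.position - last.position))
            if pos_d > gate:
                continue
            comb, ang = _combined_distance(res.state, last, lam)
            key = (comb, ang, aid)
            if best is None or key < best[0]:
                best = (key, aid)
        if best is None:
            n_unassigned += 1
            continue
        aid = best[1]
        tracks[aid] = replace(res.state, time=t)
        labeled.append(
            TrackPoint(
                time=t,
                state=res.state,
                score=res.score,
                animal_id=aid,
                excluded_channels=res.excluded_channels,
                flagged=res.flagged,
            )
        )
    if n_unassigned:
        log.info("identity assignment: %d events beyond gate", n_unassigned)
    return labeled


def reject_collisions(
    points: Sequence[TrackPoint], min_score: float = DEFAULT_MIN_SCORE
) -> List[TrackPoint]:
    """Drop points whose |LUT score| falls below ``min_score`` (default
    0.9) — the signature of temporally collided pulses."""
    kept = [p for p in points if abs(p.score) >= min_score]
    removed = len(points) - len(kept)
    if removed:
        log.info("collision rejection: removed %d of %d points", removed, len(points))
    return kept


def resolve_polarity(thetas: np.ndarray) -> np.ndarray:
    """Fix residual 180-degree polarity flips by temporal continuity: each
    heading is flipped if that brings it closer to its predecessor."""
    out = np.asarray(thetas, dtype=float).copy()
    for i in range(1, out.size):
        if circ_abs_diff(out[i], out[i - 1]) > 90.0:
            out[i] = wrap360(out[i] + 180.0)
    return out


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def median_filter1d(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running median; even windows use the lower median so the
    output is always one of the input samples (deterministic). Windows are
    truncated near the edges."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if window <= 1 or n == 0:
        return x.copy()
    half_lo = window // 2
    half_hi = (window - 1) // 2
    out = np.empty_like(x)
    for i in range(n):
        a = max(0, i - half_lo)
        b = min(n, i + half_hi + 1)
        w = b - a
        out[i] = np.sort(x[a:b])[(w - 1) // 2]
    return out


def triangular_filter1d(x: np.ndarray, window: int) -> np.ndarray:
    """Centered triangular (Bartlett) smoothing, unit gain, edge windows
    renormalized so constants pass through exactly."""
    x = np.asarray(x, dtype=float)
    window = min(int(window), x.size)  # short tracks degrade gracefully
    if window <= 1 or x.size == 0:
        return x.copy()
    k = triang(int(window))
    num = np.convolve(x, k, mode="same")
    den = np.convolve(np.ones_like(x), k, mode="same")
    return num / den


def smooth_trajectory(
    times: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    theta: np.ndarray,
    spec: SmoothingSpec = SmoothingSpec(),
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Median + triangular filtering of a single animal's track.

    Positions are filtered per coordinate; orientations are unwrapped
    (accumulating 360-degree jumps), filtered with the wider orientation
    windows, and re-wrapped to [0, 360). Output sample times are unchanged.
    """
    xs = triangular_filter1d(
        median_filter1d(x, spec.median_window_position),
        spec.triangular_window_position,
    )
    ys = triangular_filter1d(
        median_filter1d(y, spec.median_window_position),
        spec.triangular_window_position,
    )
    th = unwrap_deg(theta)
    th = triangular_filter1d(
        median_filter1d(th, spec.median_window_orientation),
        spec.triangular_window_orientation,
    )
    return xs, ys, wrap360(th)


# ---------------------------------------------------------------------------
# Tail bend and resampling
# ---------------------------------------------------------------------------


def compute_tail_bend(central: DipoleState, tail: DipoleState) -> float:
    """Signed tail-bend angle in (-180, 180]: tail orientation minus
    central orientation. Positive means the tail is bent toward the
    animal's left (counterclockwise)."""
    d = (tail.theta - central.theta) % 360.0
    if d > 180.0:
        d -= 360.0
    return float(d)


def resample_trajectory(
    times: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    theta: np.ndarray,
    new_times: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear interpolation of positions and circular interpolation of
    orientation (via unwrapping) at ``new_times``. Extrapolation beyond the
    track span is refused."""
    times = np.asarray(times, dtype=float)
    new_times = np.asarray(new_times, dtype=float)
    if new_times.size and (
        new_times.min() < times.min() - 1e-12
        or new_times.max() > times.max() + 1e-12
    ):
        raise ValueError("resampling times extend beyond the track span")
    xs = np.interp(new_times, times, np.asarray(x, dtype=float))
    ys = np.interp(new_times, times, np.asarray(y, dtype=float))
    th = np.interp(new_times, times, unwrap_deg(theta))
    return xs, ys, wrap360(th)


def resample_at_fps(times, x, y, theta, fps: float = 15.0):
    """Resample a track at regular frame times (default 15 FPS)."""
    times = np.asarray(times, dtype=float)
    t0, t1 = times.min(), times.max()
    frames = np.arange(np.ceil(t0 * fps), np.floor(t1 * fps) + 1) / fps
    xs, ys, th = resample_trajectory(times, x, y, theta, frames)
    return frames, xs, ys, th
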