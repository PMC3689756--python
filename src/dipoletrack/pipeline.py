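"""End-to-end tracking pipeline: waveforms in, trajectories out.

Stages: chunked envelope + pulse detection, phase-locked slope measurement
(central and tail), two-step LUT localization with near-field channel
exclusion, identity assignment, collision rejection, polarity resolution,
smoothing, and optional frame-rate resampling. Each stage is individually
importable; `run_track` wires them together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .angles import circ_abs_diff, wrap360
from .geometry import DipoleState, ElectrodeArray, TankGeometry
from .localize import (
    DEFAULT_EXCLUSION_CM,
    MatchResult,
    SearchCache,
    localize_with_exclusion,
)
from .lut import DEFAULT_FISH_LENGTH, GridSpec, LUT, build_grid, build_lut
from .pulse import (
    DEFAULT_CENTRAL_OFFSET,
    DEFAULT_N_SAMPLES,
    DEFAULT_REFRACTORY,
    DEFAULT_TAIL_OFFSET,
    DEFAULT_TAU,
    WaveformBlock,
    extract_pulses,
)
from .tracking import (
    DEFAULT_GATE_CM,
    DEFAULT_LAMBDA_CM_PER_DEG,
    DEFAULT_MIN_SCORE,
    SmoothingSpec,
    assign_identity,
    compute_tail_bend,
    reject_collisions,
    resample_at_fps,
    resolve_polarity,
    smooth_trajectory,
)

__all__ = ["RunConfig", "run_track", "build_pipeline_lut"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters for one tracking run."""

    tank: TankGeometry
    array: ElectrodeArray
    grid: GridSpec = dataclass_field(default_factory=GridSpec)
    fish_length: float = DEFAULT_FISH_LENGTH
    # pulse measurement
    tau: float = DEFAULT_TAU
    central_offset: float = DEFAULT_CENTRAL_OFFSET
    tail_offset: float = DEFAULT_TAIL_OFFSET
    n_samples: int = DEFAULT_N_SAMPLES
    threshold: Optional[float] = None
    refractory: float = DEFAULT_REFRACTORY
    # localization
    exclusion_cm: float = DEFAULT_EXCLUSION_CM
    # tracking
    smoothing: SmoothingSpec = dataclass_field(default_factory=SmoothingSpec)
    min_score: float = DEFAULT_MIN_SCORE
    gate: float = DEFAULT_GATE_CM
    lam: float = DEFAULT_LAMBDA_CM_PER_DEG
    initial_states: Optional[Sequence[Sequence[float]]] = None
    resample_fps: Optional[float] = None
    chunk_seconds: float = 10.0
    seed: int = 0

    def meta(self) -> dict:
        return {
            "seed": self.seed,
            "exclusion_cm": self.exclusion_cm,
            "min_score": self.min_score,
            "fish_length": self.fish_length,
            "array": self.array.label,
            "coarse": f"{self.grid.coarse_xy_step}cm/{self.grid.coarse_theta_step}deg",
            "fine": f"{self.grid.fine_xy_step}cm/{self.grid.fine_theta_step}deg",
        }


def build_pipeline_lut(config: RunConfig) -> LUT:
    nodes = build_grid(config.tank, config.grid, config.fish_length)
    return build_lut(
        config.array, config.tank, nodes, config.grid, config.fish_length
    )


def _iter_chunks(block: WaveformBlock, chunk_seconds: float, overlap: float):
    """Yield (sub-block, keep_start, keep_end): overlapping chunks with the
    half-open time window whose pulses this chunk is responsible for."""
    n = block.n_samples
    step = max(int(round(chunk_seconds * block.rate)), 1)
    pad = max(int(round(overlap * block.rate)), 1)
    for i0 in range(0, n, step):
        a = max(i0 - pad, 0)
        b = min(i0 + step + pad, n)
        sub = WaveformBlock(
            samples=block.samples[:, a:b],
            rate=block.rate,
            start_time=block.start_time + a / block.rate,
        )
        keep_start = block.start_time + i0 / block.rate
        keep_end = block.start_time + min(i0 + step, n) / block.rate
        yield sub, keep_start, keep_end


def run_track(
    config: RunConfig,
    waveform: Union[WaveformBlock, str],
    lut: Optional[LUT] = None,
) -> Dict[str, object]:
    """Run the full tracking pipeline on a recording.

    Returns a dict with per-pulse and smoothed trajectory DataFrames
    (columns time_s, animal_id, x_cm, y_cm, theta_deg, tail_bend_deg, score,
    n_channels_used, smoothed), the optional resampled trajectory, and
    per-stage counts.
    """
    if isinstance(waveform, (str, bytes)) or hasattr(waveform, "__fspath__"):
        from .io import read_waveforms

        block = read_waveforms(waveform)
    else:
        block = waveform
    if block.n_channels != config.array.n_channels:
        raise ValueError(
            f"waveform has {block.n_channels} channels but the array defines "
            f"{config.array.n_channels}"
        )
    if lut is None:
        lut = build_pipeline_lut(config)

    # --- detection + slope measurement, chunked with overlap ---------------
    overlap = max(4 * config.tau, 2e-3)
    events = []
    for sub, keep_start, keep_end in _iter_chunks(
        block, config.chunk_seconds, overlap
    ):
        for ev in extract_pulses(
            sub,
            tau=config.tau,
            threshold=config.threshold,
            refractory=config.refractory,
            central_offset=config.central_offset,
            tail_offset=config.tail_offset,
            n_samples=config.n_samples,
        ):
            if keep_start <= ev.t_ref < keep_end:
                events.append(ev)
    events.sort(key=lambda e: e.t_ref)
    log.info("detected %d pulses", len(events))

    # --- localization -------------------------------------------------------
    cache = SearchCache(capacity=16)
    matches: List[Tuple[float, MatchResult]] = []
    tail_by_time: Dict[float, MatchResult] = {}
    for ev in events:
        central = localize_with_exclusion(
            ev.slopes_central, lut, threshold=config.exclusion_cm, cache=cache
        )
        tail = localize_with_exclusion(
            ev.slopes_tail, lut, threshold=config.exclusion_cm, cache=cache
        )
        matches.append((ev.t_ref, central))
        tail_by_time[ev.t_ref] = tail

    # --- identity assignment -------------------------------------------------
    if config.initial_states is not None:
        tracks = {
            i: DipoleState(x=s[0], y=s[1], theta=s[2])
            for i, s in enumerate(config.initial_states)
        }
    elif matches:
        tracks = {0: matches[0][1].state}
    else:
        tracks = {}
    labeled = assign_identity(matches, tracks, gate=config.gate, lam=config.lam)
    for p in labeled:
        p.tail_state = tail_by_time.get(p.time).state if p.time in tail_by_time else None
    n_labeled = len(labeled)

    # --- collision rejection -------------------------------------------------
    kept = reject_collisions(labeled, min_score=config.min_score)
    kept_ids = {id(p) for p in kept}
    rejected = pd.DataFrame(
        [
            {
                "time_s": p.time,
                "animal_id": p.animal_id,
                "x_cm": p.state.x,
                "y_cm": p.state.y,
                "theta_deg": p.state.theta,
                "score": p.score,
            }
            for p in labeled
            if id(p) not in kept_ids
        ]
    )
    counts = {
        "pulses_detected": len(events),
        "pulses_labeled": n_labeled,
        "pulses_kept": len(kept),
        "collisions_removed": n_labeled - len(kept),
    }

    # --- per-animal assembly --------------------------------------------------
    per_pulse_rows = []
    smoothed_rows = []
    resampled_rows = []
    for aid in sorted({p.animal_id for p in kept}):
        pts = sorted((p for p in kept if p.animal_id == aid), key=lambda p: p.time)
        t = np.array([p.time for p in pts])
        x = np.array([p.state.x for p in pts])
        y = np.array([p.state.y for p in pts])
        theta = resolve_polarity(np.array([p.state.theta for p in pts]))
        bend = np.full(t.size, np.nan)
        for i, p in enumerate(pts):
            if p.tail_state is not None:
                # align tail polarity to the (resolved) central heading
                tail_theta = p.tail_state.theta
                if circ_abs_diff(tail_theta, theta[i]) > 90.0:
                    tail_theta = wrap360(tail_theta + 180.0)
                bend[i] = compute_tail_bend(
                    DipoleState(x[i], y[i], theta[i]),
                    DipoleState(p.tail_state.x, p.tail_state.y, tail_theta),
                )
        for i, p in enumerate(pts):
            per_pulse_rows.append(
                {
                    "time_s": t[i],
                    "animal_id": aid,
                    "x_cm": x[i],
                    "y_cm": y[i],
                    "theta_deg": theta[i],
                    "tail_bend_deg": bend[i],
                    "score": p.score,
                    "n_channels_used": lut.n_channels - len(p.excluded_channels),
                    "smoothed": 0,
                }
            )
        if t.size:
            xs, ys, ths = smooth_trajectory(t, x, y, theta, config.smoothing)
            bs = bend
            if np.isfinite(bend).all():
                from .tracking import median_filter1d, triangular_filter1d

                bs = triangular_filter1d(
                    median_filter1d(bend, config.smoothing.median_window_orientation),
                    config.smoothing.triangular_window_orientation,
                )
            for i in range(t.size):
                smoothed_rows.append(
                    {
                        "time_s": t[i],
                        "animal_id": aid,
                        "x_cm": xs[i],
                        "y_cm": ys[i],
                        "theta_deg": ths[i],
                        "tail_bend_deg": bs[i],
                        "score": pts[i].score,
                        "n_channels_used": lut.n_channels,
                        "smoothed": 1,
                    }
                )
            if config.resample_fps:
                frames, rx, ry, rth = resample_at_fps(
                    t, xs, ys, ths, config.resample_fps
                )
                for i in range(frames.size):
                    resampled_rows.append(
                        {
                            "time_s": frames[i],
                            "animal_id": aid,
                            "x_cm": rx[i],
                            "y_cm": ry[i],
                            "theta_deg": rth[i],
                            "smoothed": 1,
                        }
                    )

    result = {
        "per_pulse": pd.DataFrame(per_pulse_rows),
        "smoothed": pd.DataFrame(smoothed_rows),
        "resampled": pd.DataFrame(resampled_rows) if config.resample_fps else None,
        "rejected": rejected,
        "counts": counts,
        "lut": lut,
    }
    log.info("pipeline counts: %s", counts)
    return result
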