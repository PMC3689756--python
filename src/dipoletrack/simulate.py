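"""Synthetic-data generation and simulation experiments.

Three layers:

* electrode configurations (`make_configuration`) — the four layouts whose
  localization accuracy is compared by simulation: 4 channels paired at 180
  or 90 degrees on the circular wall, 8 channels paired at 67.5 degrees
  (16 equally spaced wall electrodes), and an 8-channel square-grid layout
  (2 m side, 0.5 m node spacing);
* static noise sweeps (`run_noise_sweep`) — dipoles placed uniformly at
  random, Gaussian noise added to the predicted RSIs with its SD normalized
  to the median |RSI| over the sampled points, localization error statistics
  per configuration and noise level;
* swimming-fish synthesis (`generate_swim`, `synthesize_waveforms`) — a
  smooth random swim emitting ~50 Hz biphasic pulses whose rostral source
  activation precedes the caudal one, rendered onto the electrode array at a
  configurable RSI-domain signal-to-noise ratio (default 46.5 dB, the
  measured SNR of the physical system).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .angles import circ_abs_diff, signed_diff, wrap360
from .field import response_matrix
from .geometry import ElectrodeArray, TankGeometry
from .localize import localize_batch
from .lut import (
    DEFAULT_FISH_LENGTH,
    GridSpec,
    LUT,
    build_grid,
    build_lut,
    state_within_boundary,
)
from .pulse import DEFAULT_RATE

__all__ = [
    "SwimParams",
    "CONFIGURATION_NAMES",
    "make_configuration",
    "sample_states",
    "run_noise_sweep",
    "generate_swim",
    "synthesize_waveforms",
    "error_metrics",
    "DEFAULT_SNR_DB",
]

#: Measured signal-to-noise ratio of the physical recording system (dB),
#: defined in the RSI domain: noise SD = 10**(-SNR/20) * SD of RSI values.
DEFAULT_SNR_DB = 46.5

CONFIGURATION_NAMES = ("4P180", "4P90", "8P67.5", "8Pgrid")


def _wall_electrode(tank: TankGeometry, angle_deg: float) -> tuple:
    a = np.radians(angle_deg)
    return (tank.radius * np.cos(a), tank.radius * np.sin(a))


def make_configuration(name: str, tank: TankGeometry) -> ElectrodeArray:
    """Build one of the four benchmark electrode configurations.

    * ``4P180`` — 8 wall electrodes every 45 deg; 4 diametric channels.
    * ``4P90``  — 8 wall electrodes every 45 deg; 4 channels paired at 90 deg.
    * ``8P67.5`` — 16 wall electrodes every 22.5 deg; 8 channels paired at
      67.5 deg (3 spacing steps), each electrode used once.
    * ``8Pgrid`` — 16 electrodes on a 2 m square lattice (0.5 m spacing);
      8 differential pairs between adjacent nodes, arranged with 4-fold
      rotational symmetry.
    """
    if name == "4P180":
        channels = tuple(
            (_wall_electrode(tank, 45.0 * k), _wall_electrode(tank, 45.0 * k + 180.0))
            for k in range(4)
        )
    elif name == "4P90":
        channels = tuple(
            (_wall_electrode(tank, a), _wall_electrode(tank, a + 90.0))
            for a in (0.0, 45.0, 180.0, 225.0)
        )
    elif name == "8P67.5":
        step = 22.5
        channels = tuple(
            (
                _wall_electrode(tank, step * ((6 * k) % 16)),
                _wall_electrode(tank, step * ((6 * k + 3) % 16)),
            )
            for k in range(8)
        )
    elif name == "8Pgrid":
        base = [
            ((0.0, -100.0), (-50.0, -100.0)),  # edge-parallel pair
            ((50.0, -50.0), (50.0, -100.0)),  # edge-normal pair
        ]

        def rot(p, q):  # 90 deg CCW
            return ((-p[1], p[0]), (-q[1], q[0]))

        channels = []
        for pair in base:
            p = pair
            for _ in range(4):
                channels.append(p)
                p = rot(*p)
        channels = tuple(channels)
    else:
        raise ValueError(f"unknown configuration name: {name!r}")
    return ElectrodeArray(channels=channels, label=name)


def sample_states(
    n: int,
    tank: TankGeometry,
    rng: np.random.Generator,
    fish_length: float = DEFAULT_FISH_LENGTH,
    min_wall_distance: float = 0.0,
) -> np.ndarray:
    """Uniform random dipole states inside the boundary (body endpoints
    included), optionally restricted to the tank interior."""
    out = np.empty((0, 3))
    r_max = tank.radius - min_wall_distance
    while out.shape[0] < n:
        m = max(2 * (n - out.shape[0]), 16)
        xy = rng.uniform(-r_max, r_max, size=(m, 2))
        th = rng.uniform(0.0, 360.0, size=m)
        inside = np.hypot(xy[:, 0], xy[:, 1]) <= r_max
        ok = inside & state_within_boundary(
            xy[:, 0], xy[:, 1], th, tank, fish_length
        )
        out = np.vstack([out, np.column_stack([xy[ok], th[ok]])])
    return out[:n]


def _median_ci(x: np.ndarray, z: float = 1.96) -> tuple:
    """95% confidence interval of the sample median from order statistics
    (binomial ranks n/2 +/- z*sqrt(n)/2; distribution-free)."""
    s = np.sort(x)
    n = s.size
    half = z * np.sqrt(n) / 2.0
    lo = int(np.clip(np.floor(n / 2.0 - half), 0, n - 1))
    hi = int(np.clip(np.ceil(n / 2.0 + half), 0, n - 1))
    return float(s[lo]), float(s[hi])


def run_noise_sweep(
    configs: Sequence[Union[str, ElectrodeArray]],
    n_points: int,
    noise_levels: Sequence[float],
    seed: int,
    tank: Optional[TankGeometry] = None,
    grid: Optional[GridSpec] = None,
    fish_length: float = DEFAULT_FISH_LENGTH,
) -> pd.DataFrame:
    """Static localization-accuracy experiment.

    For each configuration and noise level, ``n_points`` dipole states are
    drawn uniformly (shared across configurations for comparability),
    noiseless RSIs computed with the 2-D ideal dipole model, i.i.d. Gaussian
    noise of SD = level x median(|RSI|) added, and the two-step search run.

    Returns a tidy DataFrame with one row per (configuration, noise level):
    mean/median/Q90 position error (cm) and orientation error (deg).
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    tank = tank or TankGeometry()
    grid = grid or GridSpec()
    rng = np.random.default_rng(seed)
    states = sample_states(n_points, tank, rng, fish_length)
    noise_levels = np.asarray(list(noise_levels), dtype=float)

    rows = []
    for cfg in configs:
        array = cfg if isinstance(cfg, ElectrodeArray) else make_configuration(cfg, tank)
        lut = build_lut(
            array, tank, build_grid(tank, grid, fish_length), grid, fish_length
        )
        clean = response_matrix(states, array, tank)
        med = float(np.median(np.abs(clean)))
        for level in noise_levels:
            noisy = clean + rng.normal(0.0, level * med, size=clean.shape)
            est, scores = localize_batch(noisy, lut)
            pos_err = np.hypot(est[:, 0] - states[:, 0], est[:, 1] - states[:, 1])
            ori_err = circ_abs_diff(est[:, 2], states[:, 2])
            pos_lo, pos_hi = _median_ci(pos_err)
            ori_lo, ori_hi = _median_ci(ori_err)
            rows.append(
                {
                    "configuration": array.label,
                    "noise_level": float(level),
                    "n": n_points,
                    "pos_err_mean": float(pos_err.mean()),
                    "pos_err_median": float(np.median(pos_err)),
                    "pos_err_median_lo": pos_lo,
                    "pos_err_median_hi": pos_hi,
                    "pos_err_q90": float(np.percentile(pos_err, 90)),
                    "ori_err_mean": float(ori_err.mean()),
                    "ori_err_median": float(np.median(ori_err)),
                    "ori_err_median_lo": ori_lo,
                    "ori_err_median_hi": ori_hi,
                    "ori_err_q90": float(np.percentile(ori_err, 90)),
                    "score_median": float(np.median(scores)),
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Swimming-fish synthesis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SwimParams:
    """Smooth-random-swim generator parameters.

    Speeds in cm/s, rates in Hz, angles in degrees. The heading follows a
    mean-reverting turning-rate walk: ``heading_tau`` (s) is the persistence
    time constant and ``heading_sigma`` the turning-rate diffusion
    (deg s^-1 sqrt(s)^-1). The tail bend oscillates sinusoidally with the
    given amplitude and frequency.
    """

    speed_mean: float = 8.0
    speed_sd: float = 3.0
    heading_tau: float = 2.0
    heading_sigma: float = 40.0
    pulse_rate: float = 50.0
    pulse_jitter: float = 0.05
    tail_bend_amp: float = 15.0
    tail_bend_freq: float = 2.0
    fish_length: float = DEFAULT_FISH_LENGTH
    seed: int = 0

    def __post_init__(self):
        positives = (
            self.heading_tau,
            self.pulse_rate,
            self.fish_length,
        )
        if any(v <= 0 for v in positives):
            raise ValueError("rates, time constants and lengths must be positive")
        if self.speed_mean < 0 or self.speed_sd < 0:
            raise ValueError("speed statistics must be non-negative")


def generate_swim(
    params: SwimParams,
    tank: TankGeometry,
    duration: float,
    start: Optional[Sequence[float]] = None,
    anchor: Optional[Sequence[float]] = None,
    anchor_strength: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Ground-truth trajectory sampled at pulse times.

    A mean-reverting heading random walk with wall avoidance; the tail
    dipole sits fish_length/2 behind the central one with the sinusoidal
    bend applied. ``anchor`` (with ``anchor_strength`` in deg/s per deg of
    heading error) softly tethers the fish to a home region — used to build
    non-crossing dyad paths. Deterministic for a fixed seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = rng or np.random.default_rng(params.seed)
    L = params.fish_length
    margin = L / 2.0 + 5.0
    r_safe = tank.radius - margin

    if start is None:
        if anchor is not None:
            pos = np.asarray(anchor, dtype=float).copy()
        else:
            pos = np.zeros(2)
        theta = float(rng.uniform(0.0, 360.0))
    else:
        pos = np.asarray(start[:2], dtype=float).copy()
        theta = float(start[2]) if len(start) > 2 else float(rng.uniform(0, 360))

    phase0 = float(rng.uniform(0.0, 360.0))
    omega = 0.0  # turning rate, deg/s (mean-reverting)
    rows = []
    t = float(rng.uniform(0.0, 1.0 / params.pulse_rate))
    base_dt = 1.0 / params.pulse_rate
    while t <= duration:
        bend = params.tail_bend_amp * np.sin(
            2.0 * np.pi * params.tail_bend_freq * t + np.radians(phase0)
        )
        tail_theta = wrap360(theta + bend)
        back = np.radians(theta + bend / 2.0)
        tail_pos = pos - (L / 2.0) * np.array([np.cos(back), np.sin(back)])
        rows.append(
            {
                "time": t,
                "x": pos[0],
                "y": pos[1],
                "theta": wrap360(theta),
                "bend": bend,
                "tail_x": tail_pos[0],
                "tail_y": tail_pos[1],
                "tail_theta": tail_theta,
            }
        )
        # advance to the next pulse
        dt = base_dt * float(
            np.clip(1.0 + params.pulse_jitter * rng.standard_normal(), 0.5, 1.5)
        )
        speed = max(0.0, params.speed_mean + params.speed_sd * rng.standard_normal())
        steer = 0.0
        r = float(np.hypot(*pos))
        if r > r_safe and r > 0:
            to_center = np.degrees(np.arctan2(-pos[1], -pos[0]))
            steer += 4.0 * signed_diff(to_center, theta)
        elif anchor is not None and anchor_strength > 0:
            delta = np.asarray(anchor, dtype=float) - pos
            if np.hypot(*delta) > 1.0:
                to_anchor = np.degrees(np.arctan2(delta[1], delta[0]))
                steer += anchor_strength * signed_diff(to_anchor, theta)
        # mean-reverting turning rate gives a smooth, persistent heading
        omega += (-omega / params.heading_tau) * dt + params.heading_sigma * np.sqrt(
            dt
        ) * float(rng.standard_normal())
        theta += (omega + steer) * dt
        step = speed * dt * np.array([np.cos(np.radians(theta)), np.sin(np.radians(theta))])
        proposal = pos + step
        if state_within_boundary(
            proposal[0], proposal[1], theta, tank, L
        ) and np.hypot(*proposal) <= tank.radius - L / 2.0:
            pos = proposal
        else:
            # blocked by the wall: stay put and turn toward the center
            to_center = np.degrees(np.arctan2(-pos[1], -pos[0]))
            theta += 0.5 * signed_diff(to_center, theta)
        t += dt
    return pd.DataFrame(rows)


# Biphasic pulse template: a dominant positive Gaussian lobe followed by a
# weaker negative one (head-positive pulse shape), ~1.5 ms total support.
TEMPLATE_SIGMA_MAIN = 150e-6
TEMPLATE_SIGMA_SECOND = 200e-6
TEMPLATE_SECOND_DELAY = 400e-6
TEMPLATE_SECOND_AMP = -0.6
#: Half-width (s) of the rostral-to-caudal source blend around the template
#: reference point. Slope windows at +/-225 us stay clear of the blend, so
#: they sample the pure central / tail dipole responses.
BLEND_HALFWIDTH = 100e-6


def pulse_template(tt: np.ndarray) -> np.ndarray:
    """Biphasic EOD template evaluated at times ``tt`` (s, 0 = main lobe)."""
    main = np.exp(-0.5 * (tt / TEMPLATE_SIGMA_MAIN) ** 2)
    second = TEMPLATE_SECOND_AMP * np.exp(
        -0.5 * ((tt - TEMPLATE_SECOND_DELAY) / TEMPLATE_SIGMA_SECOND) ** 2
    )
    return main + second


def _template_envelope_peak(rate: float, tau: float = 250e-6) -> float:
    """Time (s, relative to the main lobe) of the template's RMS-envelope
    peak — the pulse timing reference the analysis side will detect."""
    from scipy.ndimage import uniform_filter1d

    tt = np.arange(-2e-3 * rate, 2e-3 * rate + 1) / rate
    p = np.abs(pulse_template(tt))
    w = max(int(round(tau * rate)), 2)
    env = np.sqrt(uniform_filter1d(p**2, size=w, mode="nearest"))
    return float(tt[int(np.argmax(env))])


def _slope_gain(rate: float, offset: float, n_samples: int = 5) -> float:
    """Least-squares slope of the template over the analysis window at
    ``offset`` from the envelope peak — the scale factor between a
    channel's RSI and its measured slope."""
    t_peak = _template_envelope_peak(rate)
    center = t_peak + offset
    i0 = int(round(center * rate)) - (n_samples - 1) // 2
    idx = np.arange(i0, i0 + n_samples)
    y = pulse_template(idx / rate)
    t = idx / rate
    t = t - t.mean()
    return float((y - y.mean()) @ t / (t @ t))


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def synthesize_waveforms(
    truths: Union[pd.DataFrame, Sequence[pd.DataFrame]],
    array: ElectrodeArray,
    tank: TankGeometry,
    snr_db: Optional[float] = DEFAULT_SNR_DB,
    rate: float = DEFAULT_RATE,
    amplitude: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    duration: Optional[float] = None,
    blend_halfwidth: float = BLEND_HALFWIDTH,
):
    """Render ground-truth trajectories into multichannel waveforms.

    Every pulse is a shared biphasic template, amplitude-modulated per
    channel by the 2-D dipole response of an effective source state that
    blends from the central-body dipole to the tail dipole across the pulse
    (the rostral-to-caudal activation progression). The blend is centered on
    the template's envelope peak and confined to ±``blend_halfwidth``, so
    slope measurements at -225 us from the detected timing reference see the
    central state and at +225 us the tail state. The tail response is
    rescaled to the central response's norm per pulse (the LUT search is
    scale-invariant, so this only stabilizes the envelope shape).

    Gaussian sensor noise is added such that the SD of slope-measurement
    noise equals 10**(-snr_db/20) times the SD of the clean RSI slope values
    (``snr_db=None`` for a noiseless recording).

    Returns (WaveformBlock, noise_sd_rsi) with noise_sd_rsi in V/s.
    """
    from .pulse import WaveformBlock  # local import avoids a cycle

    if isinstance(truths, pd.DataFrame):
        truths = [truths]
    if duration is None:
        duration = max(tr["time"].max() for tr in truths) + 5e-3
    n = int(np.ceil(duration * rate)) + 1
    wave = np.zeros((array.n_channels, n), dtype=np.float64)

    t_peak = _template_envelope_peak(rate)
    t_lo = -4.0 * TEMPLATE_SIGMA_MAIN
    t_hi = TEMPLATE_SECOND_DELAY + 4.0 * TEMPLATE_SIGMA_SECOND
    slope_scales = []
    all_slopes = []
    for tr in truths:
        central = tr[["x", "y", "theta"]].to_numpy()
        tail = tr[["tail_x", "tail_y", "tail_theta"]].to_numpy()
        resp_c = response_matrix(central, array, tank) * amplitude
        resp_t = response_matrix(tail, array, tank) * amplitude
        # equalize per-pulse energy between the two phases
        bal = np.linalg.norm(resp_c, axis=1) / np.linalg.norm(resp_t, axis=1)
        resp_t = resp_t * bal[:, None]
        all_slopes.append(resp_c)
        all_slopes.append(resp_t)
        for i, t0 in enumerate(tr["time"].to_numpy()):
            i0 = max(int(np.floor((t0 + t_lo) * rate)), 0)
            i1 = min(int(np.ceil((t0 + t_hi) * rate)) + 1, n)
            tt = np.arange(i0, i1) / rate - t0
            p = pulse_template(tt)
            s = _smoothstep(
                (tt - (t_peak - blend_halfwidth)) / (2.0 * blend_halfwidth)
            )
            resp = (
                resp_c[i][:, None] * (1.0 - s)[None, :]
                + resp_t[i][:, None] * s[None, :]
            )
            wave[:, i0:i1] += resp * p[None, :]

    noise_sd_rsi = 0.0
    if snr_db is not None and np.isfinite(snr_db):
        rng = rng or np.random.default_rng(0)
        # measured slopes are RSI * template slope gain at the window
        from .pulse import DEFAULT_CENTRAL_OFFSET, DEFAULT_TAIL_OFFSET

        g_c = _slope_gain(rate, DEFAULT_CENTRAL_OFFSET)
        g_t = _slope_gain(rate, DEFAULT_TAIL_OFFSET)
        sd_rsi = float(
            np.std(
                np.concatenate(
                    [
                        r.ravel() * (g_c if k % 2 == 0 else g_t)
                        for k, r in enumerate(all_slopes)
                    ]
                )
            )
        )
        noise_sd_rsi = sd_rsi * 10.0 ** (-snr_db / 20.0)
        # A least-squares slope over n equally spaced samples has noise
        # gain 1/sqrt(sum (t-tbar)^2); for 5 samples that sum is 10*dt^2.
        dt = 1.0 / rate
        sum_t2 = 10.0 * dt * dt
        sigma_wave = noise_sd_rsi * np.sqrt(sum_t2)
        wave += rng.normal(0.0, sigma_wave, size=wave.shape)
    return WaveformBlock(samples=wave, rate=rate, start_time=0.0), noise_sd_rsi


def error_metrics(
    est: pd.DataFrame,
    truth: pd.DataFrame,
    fold_orientation: bool = False,
) -> Dict[str, float]:
    """Accuracy summary for trajectories on a common time base.

    Both frames need columns x, y, theta (and optionally ``bend``) at
    identical row order/times. Orientation errors are circular absolute
    differences (folded to <= 90 deg when ``fold_orientation``, for
    polarity-agnostic comparison). Returns mean/sd/median/Q90 per metric.
    """
    if len(est) == 0 or len(est) != len(truth):
        raise ValueError("estimate and truth must have equal, non-zero length")
    pos = np.hypot(
        est["x"].to_numpy() - truth["x"].to_numpy(),
        est["y"].to_numpy() - truth["y"].to_numpy(),
    )
    period = 180.0 if fold_orientation else 360.0
    ori = circ_abs_diff(est["theta"].to_numpy(), truth["theta"].to_numpy(), period)
    out: Dict[str, float] = {}
    for label, err in (("position", pos), ("orientation", ori)):
        out[f"{label}_mean"] = float(err.mean())
        out[f"{label}_sd"] = float(err.std())
        out[f"{label}_median"] = float(np.median(err))
        out[f"{label}_q90"] = float(np.percentile(err, 90))
    if "bend" in est.columns and "bend" in truth.columns:
        bend = np.abs(
            signed_diff(est["bend"].to_numpy(), truth["bend"].to_numpy())
        )
        out["bend_mean"] = float(bend.mean())
        out["bend_median"] = float(np.median(bend))
        out["bend_q90"] = float(np.percentile(bend, 90))
    return out
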