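"""EOD pulse measurement: envelope, pulse timing, phase-locked slopes.

The pulse timing reference is the peak of the global pulse envelope — the
rectified, channel-summed waveform smoothed by a moving root-mean-square
filter (tau = 250 us) and, if necessary, extra smoothing until each pulse
has a single local maximum. Per-channel received signal intensities are the
least-squares straight-line slopes over five ADC samples, measured at fixed
offsets from the reference (default -225 us for the central body phase and
+225 us for the tail phase), identically on all channels so the measurement
is phase-locked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks
from scipy.signal.windows import triang

from .geometry import RSIVector

__all__ = [
    "WaveformBlock",
    "PulseEvent",
    "compute_envelope",
    "detect_pulses",
    "measure_slopes",
    "extract_pulses",
    "estimate_threshold",
    "DEFAULT_RATE",
    "DEFAULT_TAU",
    "DEFAULT_CENTRAL_OFFSET",
    "DEFAULT_TAIL_OFFSET",
]

DEFAULT_RATE = 40_000.0  # samples/s per channel
DEFAULT_TAU = 250e-6  # RMS window, seconds
#: Slope-measurement offsets from the envelope peak, seconds. The central
#: phase precedes the reference (electric-organ activation concentrated at
#: the body center), the tail phase follows it.
DEFAULT_CENTRAL_OFFSET = -225e-6
DEFAULT_TAIL_OFFSET = +225e-6
DEFAULT_N_SAMPLES = 5
DEFAULT_REFRACTORY = 5e-3  # seconds (pulse rate ~50 Hz)


@dataclass
class WaveformBlock:
    """Multichannel waveform chunk: (n_channels, n_samples) volts."""

    samples: np.ndarray
    rate: float = DEFAULT_RATE
    start_time: float = 0.0

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size == 0:
            raise ValueError("empty waveform block")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass
class PulseEvent:
    """One detected EOD pulse with its phase-locked slope measurements."""

    t_ref: float
    envelope_peak: float
    slopes_central: Optional[RSIVector] = None
    slopes_tail: Optional[RSIVector] = None


def _triangular_smooth(x: np.ndarray, width: int) -> np.ndarray:
    width = max(int(width), 2)
    k = triang(width)
    k /= k.sum()
    return np.convolve(x, k, mode="same")


def _is_unimodal_per_pulse(env: np.ndarray, threshold: float) -> bool:
    """Check that every above-threshold region has exactly one local max."""
    idx = np.flatnonzero(env > threshold)
    if idx.size == 0:
        return True
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        seg = env[run[0] : run[-1] + 1]
        if seg.size < 3:
            continue
        peaks, _ = find_peaks(seg)
        if peaks.size > 1:
            return False
    return True


def compute_envelope(
    block: WaveformBlock,
    tau: float = DEFAULT_TAU,
    unimodal_threshold: Optional[float] = None,
    max_smooth_passes: int = 3,
) -> np.ndarray:
    """Global pulse envelope of a waveform block.

    Channels are rectified (absolute value, to prevent cancellation between
    channels) and summed, then smoothed with a moving RMS filter of width
    ``tau``. If the result is multimodal within a pulse, additional
    triangular smoothing passes of the same width are applied (up to
    ``max_smooth_passes``) until each pulse carries a single peak.
    """
    if tau <= 1.0 / block.rate:
        raise ValueError("tau must exceed one sample interval")
    rectified_sum = np.abs(block.samples).sum(axis=0)
    w = max(int(round(tau * block.rate)), 2)
    # uniform_filter1d's running mean can dip microscopically negative
    power = uniform_filter1d(rectified_sum**2, size=w, mode="nearest")
    env = np.sqrt(np.maximum(power, 0.0))
    thr = (
        unimodal_threshold
        if unimodal_threshold is not None
        else estimate_threshold(env)
    )
    for i in range(max_smooth_passes):
        if _is_unimodal_per_pulse(env, thr):
            break
        # widen each pass so peaks farther apart than one window still merge
        env = _triangular_smooth(env, w * (i + 1))
    return env


def estimate_threshold(envelope: np.ndarray, k: float = 8.0) -> float:
    """Detection-threshold helper: baseline median + k * MAD of the
    envelope. With no baseline noise (MAD = 0) a small fraction of the
    envelope maximum is used instead."""
    med = float(np.median(envelope))
    mad = float(np.median(np.abs(envelope - med)))
    if mad > 0:
        return med + k * mad
    peak = float(envelope.max())
    return med + 0.1 * (peak - med) if peak > med else np.inf


def detect_pulses(
    envelope: np.ndarray,
    rate: float = DEFAULT_RATE,
    threshold: Optional[float] = None,
    refractory: float = DEFAULT_REFRACTORY,
    start_time: float = 0.0,
) -> List[PulseEvent]:
    """Pulse timing references: envelope local maxima above threshold, at
    least ``refractory`` apart, with sub-sample timing by parabolic
    interpolation around the peak."""
    envelope = np.asarray(envelope, dtype=float)
    if threshold is None:
        threshold = estimate_threshold(envelope)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    distance = max(int(round(refractory * rate)), 1)
    peaks, props = find_peaks(envelope, height=threshold, distance=distance)
    events: List[PulseEvent] = []
    for i in peaks:
        delta = 0.0
        if 0 < i < envelope.size - 1:
            denom = envelope[i - 1] - 2.0 * envelope[i] + envelope[i + 1]
            if denom != 0:
                delta = float(np.clip(
                    0.5 * (envelope[i - 1] - envelope[i + 1]) / denom, -0.5, 0.5
                ))
        events.append(
            PulseEvent(
                t_ref=start_time + (i + delta) / rate,
                envelope_peak=float(envelope[i]),
            )
        )
    return events


def measure_slopes(
    block: WaveformBlock,
    t_ref: float,
    offset: float,
    n_samples: int = DEFAULT_N_SAMPLES,
    phase_tag: str = "central",
) -> RSIVector:
    """Least-squares straight-line slope (V/s) per channel over
    ``n_samples`` ADC samples centered at ``t_ref + offset``.

    All channels share the same sample indices, so the measurement is
    phase-locked across the array.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples for a slope")
    center = (t_ref + offset - block.start_time) * block.rate
    i0 = int(round(center)) - (n_samples - 1) // 2
    i1 = i0 + n_samples
    if i0 < 0 or i1 > block.n_samples:
        raise ValueError(
            f"slope window [{i0}, {i1}) falls outside the waveform block"
        )
    y = block.samples[:, i0:i1].astype(float)
    t = np.arange(n_samples) / block.rate
    t = t - t.mean()
    denom = float(t @ t)
    slopes = (y - y.mean(axis=1, keepdims=True)) @ t / denom
    return RSIVector(values=slopes, pulse_time=t_ref, phase_tag=phase_tag)


def extract_pulses(
    block: WaveformBlock,
    tau: float = DEFAULT_TAU,
    threshold: Optional[float] = None,
    refractory: float = DEFAULT_REFRACTORY,
    central_offset: float = DEFAULT_CENTRAL_OFFSET,
    tail_offset: float = DEFAULT_TAIL_OFFSET,
    n_samples: int = DEFAULT_N_SAMPLES,
) -> List[PulseEvent]:
    """Envelope → pulse detection → central and tail slope measurement.

    Pulses whose slope windows would fall outside the block are dropped
    (callers processing chunked streams overlap blocks so no pulse is lost).
    """
    env = compute_envelope(block, tau=tau, unimodal_threshold=threshold)
    events = detect_pulses(
        env,
        rate=block.rate,
        threshold=threshold,
        refractory=refractory,
        start_time=block.start_time,
    )
    out: List[PulseEvent] = []
    for ev in events:
        try:
            ev.slopes_central = measure_slopes(
                block, ev.t_ref, central_offset, n_samples, phase_tag="central"
            )
            ev.slopes_tail = measure_slopes(
                block, ev.t_ref, tail_offset, n_samples, phase_tag="tail"
            )
        except ValueError:
            continue
        out.append(ev)
    return out
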