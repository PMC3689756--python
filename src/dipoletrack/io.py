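"""File formats: geometry configs, waveforms, RSI tables, trajectories.

Geometry and waveform sidecars are YAML; waveforms are multichannel WAV
(float32 or int16) or long-format CSV (time, channel, value); pulse and
trajectory tables are CSV with provenance comment headers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from . import __version__
from .geometry import ElectrodeArray, RSIVector, TankGeometry
from .pulse import PulseEvent, WaveformBlock

__all__ = [
    "load_geometry",
    "save_geometry",
    "read_waveforms",
    "write_waveforms",
    "write_pulses",
    "read_pulses",
    "write_trajectory",
    "read_trajectory",
    "config_hash",
]


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Geometry config
# ---------------------------------------------------------------------------


def load_geometry(path) -> Tuple[TankGeometry, ElectrodeArray]:
    """Read a tank + electrode-array YAML config.

    Schema::

        label: 8P67.5
        tank:
          radius_cm: 75.0
          water_depth_cm: 10.0
          boundary_contrast: 17.0
        channels:
          - {pos: [x_cm, y_cm], neg: [x_cm, y_cm]}
          - ...
    """
    with open(path) as f:
        doc = yaml.safe_load(f)
    try:
        tank_doc = doc["tank"]
        tank = TankGeometry(
            radius=float(tank_doc["radius_cm"]),
            water_depth=float(tank_doc.get("water_depth_cm", 10.0)),
            boundary_contrast=float(tank_doc.get("boundary_contrast", 17.0)),
        )
        channels = tuple(
            (tuple(map(float, ch["pos"])), tuple(map(float, ch["neg"])))
            for ch in doc["channels"]
        )
    except (KeyError, TypeError) as e:
        raise ValueError(f"{path}: malformed geometry config ({e})") from e
    array = ElectrodeArray(channels=channels, label=str(doc.get("label", "")))
    return tank, array


def save_geometry(path, tank: TankGeometry, array: ElectrodeArray) -> None:
    doc = {
        "label": array.label,
        "tank": {
            "radius_cm": tank.radius,
            "water_depth_cm": tank.water_depth,
            "boundary_contrast": tank.boundary_contrast,
        },
        "channels": [
            {"pos": [float(p[0]), float(p[1])], "neg": [float(n[0]), float(n[1])]}
            for p, n in array.channels
        ],
    }
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)


# ---------------------------------------------------------------------------
# Waveforms
# ---------------------------------------------------------------------------


def read_waveforms(path, sidecar: Optional[Union[str, Path, dict]] = None) -> WaveformBlock:
    """Read a multichannel waveform from WAV or long-format CSV.

    The optional ``sidecar`` (YAML path or dict) supplies gain (V per unit),
    start time, and — for CSV without a time column — the sampling rate.
    Integer WAV data are scaled to [-1, 1) before the gain is applied.
    """
    meta: dict = {}
    if sidecar is not None:
        if isinstance(sidecar, dict):
            meta = sidecar
        else:
            with open(sidecar) as f:
                meta = yaml.safe_load(f) or {}
    gain = float(meta.get("gain", 1.0))
    start_time = float(meta.get("start_time", 0.0))

    path = Path(path)
    if path.suffix.lower() == ".wav":
        rate, data = wavfile.read(path)
        data = np.atleast_2d(data)
        if data.shape[0] > data.shape[1]:  # wavfile returns (samples, channels)
            data = data.T
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(np.float64) / float(np.iinfo(data.dtype).max + 1)
        else:
            data = data.astype(np.float64)
        return WaveformBlock(samples=data * gain, rate=float(rate), start_time=start_time)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, comment="#")
        required = {"time", "channel", "value"}
        if not required.issubset(df.columns):
            missing = sorted(required - set(df.columns))
            raise ValueError(f"{path}: CSV waveform missing columns {missing}")
        wide = df.pivot(index="time", columns="channel", values="value").sort_index()
        if wide.isna().any().any():
            raise ValueError(f"{path}: channels have mismatched sample times")
        times = wide.index.to_numpy(dtype=float)
        if "rate" in meta:
            rate = float(meta["rate"])
        else:
            steps = np.diff(times)
            if steps.size == 0 or not np.allclose(steps, steps[0], rtol=1e-6):
                raise ValueError(f"{path}: non-uniform sample times and no rate given")
            rate = 1.0 / steps[0]
        return WaveformBlock(
            samples=wide.to_numpy().T * gain, rate=rate, start_time=float(times[0])
        )
    raise ValueError(f"unsupported waveform format: {path.suffix}")


def write_waveforms(path, block: WaveformBlock, sidecar: Optional[Union[str, Path]] = None) -> None:
    """Write a float32 WAV plus an optional YAML sidecar."""
    wavfile.write(path, int(round(block.rate)), block.samples.T.astype(np.float32))
    if sidecar is not None:
        with open(sidecar, "w") as f:
            yaml.safe_dump(
                {
                    "rate": float(block.rate),
                    "gain": 1.0,
                    "start_time": float(block.start_time),
                    "n_channels": int(block.n_channels),
                },
                f,
            )


# ---------------------------------------------------------------------------
# Pulse (RSI) and trajectory tables
# ---------------------------------------------------------------------------


def _provenance_header(kind: str, meta: Optional[dict]) -> str:
    meta = dict(meta or {})
    meta.setdefault("writer", f"dipoletrack {__version__}")
    items = " ".join(f"{k}={v}" for k, v in sorted(meta.items()))
    return f"# {kind} {items}\n"


def write_pulses(path, events: Sequence[PulseEvent], meta: Optional[dict] = None) -> None:
    """CSV of pulse timing references plus central/tail per-channel slopes."""
    rows = []
    for ev in events:
        row = {"t_ref": ev.t_ref, "envelope_peak": ev.envelope_peak}
        for tag, rsi in (("central", ev.slopes_central), ("tail", ev.slopes_tail)):
            if rsi is None:
                continue
            for c, (v, m) in enumerate(zip(rsi.values, rsi.mask)):
                row[f"{tag}_slope_{c}"] = v
                row[f"{tag}_mask_{c}"] = int(m)
        rows.append(row)
    with open(path, "w") as f:
        f.write(_provenance_header("pulses", meta))
        pd.DataFrame(rows).to_csv(f, index=False)


def read_pulses(path) -> List[PulseEvent]:
    df = pd.read_csv(path, comment="#")
    events: List[PulseEvent] = []
    tags = ("central", "tail")
    n_ch = {
        tag: sum(c.startswith(f"{tag}_slope_") for c in df.columns) for tag in tags
    }
    for _, row in df.iterrows():
        ev = PulseEvent(
            t_ref=float(row["t_ref"]),
            envelope_peak=float(row.get("envelope_peak", np.nan)),
        )
        for tag in tags:
            if n_ch[tag] == 0:
                continue
            vals = np.array([row[f"{tag}_slope_{c}"] for c in range(n_ch[tag])])
            mask = np.array(
                [bool(row.get(f"{tag}_mask_{c}", 1)) for c in range(n_ch[tag])]
            )
            rsi = RSIVector(
                values=vals, mask=mask, pulse_time=ev.t_ref, phase_tag=tag
            )
            if tag == "central":
                ev.slopes_central = rsi
            else:
                ev.slopes_tail = rsi
        events.append(ev)
    return events


TRAJECTORY_COLUMNS = [
    "time_s",
    "animal_id",
    "x_cm",
    "y_cm",
    "theta_deg",
    "tail_bend_deg",
    "score",
    "n_channels_used",
    "smoothed",
]


def write_trajectory(path, df: pd.DataFrame, meta: Optional[dict] = None) -> None:
    """Trajectory CSV with a provenance comment header (config hash, seed)."""
    with open(path, "w") as f:
        f.write(_provenance_header("trajectory", meta))
        df.to_csv(f, index=False)


def read_trajectory(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
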