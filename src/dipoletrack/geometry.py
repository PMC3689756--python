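"""Domain types: tank, dipole state, electrode array, and RSI vectors.

Coordinates are tank-centered Cartesian in centimeters. Headings are degrees
counterclockwise from +x. A "channel" is one differential electrode pair
(positive electrode minus negative electrode).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .angles import wrap360

__all__ = [
    "TankGeometry",
    "DipoleState",
    "ElectrodeArray",
    "RSIVector",
    "MIN_CHANNELS",
]

#: Minimum number of usable channels required by the inverse search.
MIN_CHANNELS = 4


@dataclass(frozen=True)
class TankGeometry:
    """Circular (or rectangular-extent) shallow-water arena.

    Parameters
    ----------
    radius : float
        Tank radius in cm. The experimental arena is a 1.5 m diameter
        circular tank, i.e. ``radius=75``.
    water_depth : float
        Water depth in cm (shallow: ~10 cm), used only by the 3-D
        image-charge validation utilities.
    boundary_contrast : float
        Permittivity ratio of water to tank wall. It sets the image-dipole
        rescaling factor of the side boundary; the localization pipeline is
        provably insensitive to its value because responses are normalized.
    grid_extent : tuple or None
        Optional (width, height) bounding box in cm for rectangular
        (grid-electrode) layouts.
    """

    radius: float = 75.0
    water_depth: float = 10.0
    boundary_contrast: float = 17.0
    grid_extent: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        if not (self.radius > 0):
            raise ValueError("tank radius must be positive")
        if not (self.water_depth > 0):
            raise ValueError("water depth must be positive")
        if not np.isfinite(self.boundary_contrast):
            raise ValueError("boundary_contrast must be finite")

    def contains(self, x, y) -> np.ndarray:
        """True where (x, y) lies on or inside the circular boundary."""
        return np.asarray(x) ** 2 + np.asarray(y) ** 2 <= self.radius**2 + 1e-9


@dataclass(frozen=True)
class DipoleState:
    """Position, heading and moment of an ideal current dipole.

    ``moment`` is the product of source strength and separation (arbitrary
    units; it cancels under the normalization used by the LUT search).
    """

    x: float
    y: float
    theta: float  # degrees CCW from +x, wrapped to [0, 360)
    moment: float = 1.0
    time: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "theta", wrap360(self.theta))

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    @property
    def heading(self) -> np.ndarray:
        """Unit vector along the dipole axis (negative→positive source)."""
        t = np.radians(self.theta)
        return np.array([np.cos(t), np.sin(t)])

    def endpoints(self, length: float) -> Tuple[np.ndarray, np.ndarray]:
        """Head and tail points at ±length/2 along the heading."""
        h = self.heading * (length / 2.0)
        return self.position + h, self.position - h

    def flipped(self) -> "DipoleState":
        return replace(self, theta=wrap360(self.theta + 180.0))

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.theta], dtype=float)


@dataclass(frozen=True)
class ElectrodeArray:
    """Ordered differential channels; each channel is (positive, negative)
    electrode coordinates in cm."""

    channels: Tuple[Tuple[Tuple[float, float], Tuple[float, float]], ...]
    label: str = ""

    def __post_init__(self):
        chans = tuple(
            (tuple(map(float, p)), tuple(map(float, n))) for p, n in self.channels
        )
        object.__setattr__(self, "channels", chans)
        for p, n in chans:
            if np.allclose(p, n):
                raise ValueError("channel has coincident electrodes")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def pos(self) -> np.ndarray:
        """(n_channels, 2) positive-electrode coordinates."""
        return np.array([p for p, _ in self.channels], dtype=float)

    @property
    def neg(self) -> np.ndarray:
        """(n_channels, 2) negative-electrode coordinates."""
        return np.array([n for _, n in self.channels], dtype=float)

    @property
    def electrodes(self) -> np.ndarray:
        """(2 * n_channels, 2) all electrode coordinates (pos then neg)."""
        return np.vstack([self.pos, self.neg])

    def validate_for_localization(self, tank: Optional[TankGeometry] = None):
        if self.n_channels < MIN_CHANNELS:
            raise ValueError(
                f"localization requires >= {MIN_CHANNELS} channels, "
                f"got {self.n_channels}"
            )
        if tank is not None and not np.all(
            tank.contains(self.electrodes[:, 0], self.electrodes[:, 1])
        ):
            raise ValueError("electrodes must lie on or inside the tank boundary")


@dataclass
class RSIVector:
    """Per-channel signed slope measurements (V/s) for one pulse phase."""

    values: np.ndarray
    mask: np.ndarray = None
    pulse_time: Optional[float] = None
    phase_tag: str = "central"  # {"central", "tail"}

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must have the same length")

    @property
    def n_channels(self) -> int:
        return self.values.size

    @property
    def n_usable(self) -> int:
        return int(self.mask.sum())

    def masked(self, extra_mask: Sequence[bool]) -> "RSIVector":
        """Return a copy with additional channels masked out (False=drop)."""
        return RSIVector(
            values=self.values.copy(),
            mask=self.mask & np.asarray(extra_mask, dtype=bool),
            pulse_time=self.pulse_time,
            phase_tag=self.phase_tag,
        )

    def unit(self) -> np.ndarray:
        """Unit-normalized usable values (masked channels set to 0)."""
        v = np.where(self.mask, self.values, 0.0)
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("cannot normalize an all-zero RSI vector")
        return v / n
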