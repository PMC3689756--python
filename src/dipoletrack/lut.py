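"""Lookup-table construction over a position × orientation grid.

The LUT stores unit-normalized predicted RSI vectors at every grid node
(single precision), together with the node states and a partition of the
rows by strongest-|channel| index. Orientations are enumerated over
[0, 180) only; the inverse search examines both signs of the dot product to
resolve parallel vs anti-parallel headings, which halves the table size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .field import response_matrix
from .geometry import DipoleState, ElectrodeArray, TankGeometry

__all__ = [
    "GridSpec",
    "LUT",
    "build_grid",
    "build_lut",
    "fine_nodes_around",
    "state_within_boundary",
    "DEFAULT_FISH_LENGTH",
]

#: Default body length in cm (animals in the tank were 20-24 cm long).
DEFAULT_FISH_LENGTH = 22.0


@dataclass(frozen=True)
class GridSpec:
    """Coarse/fine grid steps and wall-densification band.

    Defaults follow the tracking system's settings: coarse 2 cm / 4 deg,
    fine 0.5 cm / 1 deg, coarse density doubled within 10 cm of the wall.
    """

    coarse_xy_step: float = 2.0
    coarse_theta_step: float = 4.0
    fine_xy_step: float = 0.5
    fine_theta_step: float = 1.0
    wall_band: float = 10.0

    def __post_init__(self):
        steps = (
            self.coarse_xy_step,
            self.coarse_theta_step,
            self.fine_xy_step,
            self.fine_theta_step,
        )
        if any(s <= 0 for s in steps):
            raise ValueError("all grid steps must be positive")
        if self.fine_xy_step >= self.coarse_xy_step:
            raise ValueError("fine xy step must be smaller than coarse")
        if self.fine_theta_step >= self.coarse_theta_step:
            raise ValueError("fine theta step must be smaller than coarse")
        if self.wall_band < 0:
            raise ValueError("wall_band must be >= 0")


def state_within_boundary(
    x, y, theta, tank: TankGeometry, fish_length: float
) -> np.ndarray:
    """True where both body endpoints (±fish_length/2 along theta) lie
    inside the circular boundary."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = np.radians(np.asarray(theta, dtype=float))
    hx = np.cos(t) * (fish_length / 2.0)
    hy = np.sin(t) * (fish_length / 2.0)
    r2 = tank.radius**2 + 1e-9
    head = (x + hx) ** 2 + (y + hy) ** 2 <= r2
    tail = (x - hx) ** 2 + (y - hy) ** 2 <= r2
    return head & tail


def _position_lattice(tank: TankGeometry, spec: GridSpec) -> np.ndarray:
    """Coarse position lattice inside the disc, density doubled within
    ``wall_band`` of the wall. All points lie on the fine lattice because
    the steps are integer multiples of fine_xy_step."""
    r = tank.radius
    step = spec.coarse_xy_step
    half = step / 2.0

    n = int(np.floor(r / step))
    ax = np.arange(-n, n + 1) * step
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    coarse = np.column_stack([gx.ravel(), gy.ravel()])
    coarse = coarse[np.hypot(coarse[:, 0], coarse[:, 1]) <= r]

    if spec.wall_band > 0:
        m = int(np.floor(r / half))
        axf = np.arange(-m, m + 1)
        gx, gy = np.meshgrid(axf, axf, indexing="ij")
        on_coarse = (gx % 2 == 0) & (gy % 2 == 0)
        dense = np.column_stack([gx.ravel(), gy.ravel()])[~on_coarse.ravel()] * half
        rad = np.hypot(dense[:, 0], dense[:, 1])
        dense = dense[(rad <= r) & (rad >= r - spec.wall_band)]
        coarse = np.vstack([coarse, dense])
    return coarse


def build_grid(
    tank: TankGeometry,
    spec: GridSpec,
    fish_length: float = DEFAULT_FISH_LENGTH,
) -> np.ndarray:
    """Enumerate coarse grid nodes (x, y, theta) inside the boundary.

    The rectangular lattice is intersected with the tank disc; a node is
    kept only if both body endpoints stay inside the wall. Orientations run
    over [0, 180) at the coarse angular step (polarity is resolved by the
    dot-product sign at search time).

    Returns an (n, 3) float array with columns x, y, theta.
    """
    pos = _position_lattice(tank, spec)
    thetas = np.arange(0.0, 180.0, spec.coarse_theta_step)
    if pos.size == 0 or thetas.size == 0:
        raise ValueError("degenerate grid: no nodes")
    xy = np.repeat(pos, thetas.size, axis=0)
    th = np.tile(thetas, pos.shape[0])
    keep = state_within_boundary(xy[:, 0], xy[:, 1], th, tank, fish_length)
    nodes = np.column_stack([xy[keep], th[keep]])
    if nodes.size == 0:
        raise ValueError("degenerate grid: all nodes excluded by the boundary")
    return nodes


def fine_nodes_around(
    state: DipoleState,
    spec: GridSpec,
    tank: TankGeometry,
    fish_length: float = DEFAULT_FISH_LENGTH,
) -> np.ndarray:
    """Fine lattice spanning ±1 coarse step around a coarse estimate.

    Positions cover ±coarse_xy_step at fine_xy_step resolution and
    orientations ±coarse_theta_step at fine_theta_step resolution (for the
    default grids: 9 x 9 positions x 9 orientations), filtered by the same
    boundary rule as `build_grid`. May be empty at extreme wall positions.
    """
    nx = int(round(spec.coarse_xy_step / spec.fine_xy_step))
    nt = int(round(spec.coarse_theta_step / spec.fine_theta_step))
    dx = np.arange(-nx, nx + 1) * spec.fine_xy_step
    dt = np.arange(-nt, nt + 1) * spec.fine_theta_step
    gx, gy, gt = np.meshgrid(dx, dx, dt, indexing="ij")
    cand = np.column_stack(
        [
            state.x + gx.ravel(),
            state.y + gy.ravel(),
            (state.theta + gt.ravel()) % 360.0,
        ]
    )
    keep = state_within_boundary(cand[:, 0], cand[:, 1], cand[:, 2], tank, fish_length)
    return cand[keep]


@dataclass
class LUT:
    """Precomputed table of unit-normalized predicted RSI vectors.

    Attributes
    ----------
    vectors : (n, n_channels) float32
        Unit-norm rows, sorted by strongest-|channel| index.
    states : (n, 3) float
        Grid node (x, y, theta) parallel to ``vectors``.
    partition : dict
        Maps channel index -> (start, stop) row range of nodes whose
        strongest channel is that index.
    """

    vectors: np.ndarray
    states: np.ndarray
    partition: Dict[int, Tuple[int, int]]
    grid: GridSpec
    array: ElectrodeArray
    tank: TankGeometry
    fish_length: float = DEFAULT_FISH_LENGTH

    @property
    def n_rows(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_channels(self) -> int:
        return self.vectors.shape[1]

    def partition_rows(self, channel: int) -> slice:
        start, stop = self.partition.get(int(channel), (0, 0))
        return slice(start, stop)

    def state_at(self, row: int) -> DipoleState:
        x, y, t = self.states[row]
        return DipoleState(x=float(x), y=float(y), theta=float(t))

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Persist to an HDF5 container (/vectors, /states, /partition, /meta)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("vectors", data=self.vectors, dtype="float32")
            f.create_dataset("states", data=self.states)
            part = np.array(
                [(c, a, b) for c, (a, b) in sorted(self.partition.items())],
                dtype=np.int64,
            )
            f.create_dataset("partition", data=part)
            f.create_dataset("pos_electrodes", data=self.array.pos)
            f.create_dataset("neg_electrodes", data=self.array.neg)
            meta = f.create_group("meta")
            meta.attrs["label"] = self.array.label
            meta.attrs["fish_length"] = self.fish_length
            meta.attrs["tank_radius"] = self.tank.radius
            meta.attrs["tank_water_depth"] = self.tank.water_depth
            meta.attrs["tank_boundary_contrast"] = self.tank.boundary_contrast
            for k in (
                "coarse_xy_step",
                "coarse_theta_step",
                "fine_xy_step",
                "fine_theta_step",
                "wall_band",
            ):
                meta.attrs[k] = getattr(self.grid, k)

    @classmethod
    def load(cls, path) -> "LUT":
        import h5py

        with h5py.File(path, "r") as f:
            vectors = f["vectors"][:]
            states = f["states"][:]
            partition = {int(c): (int(a), int(b)) for c, a, b in f["partition"][:]}
            pos = f["pos_electrodes"][:]
            neg = f["neg_electrodes"][:]
            meta = f["meta"].attrs
            array = ElectrodeArray(
                channels=tuple(
                    (tuple(p), tuple(n)) for p, n in zip(pos, neg)
                ),
                label=str(meta["label"]),
            )
            tank = TankGeometry(
                radius=float(meta["tank_radius"]),
                water_depth=float(meta["tank_water_depth"]),
                boundary_contrast=float(meta["tank_boundary_contrast"]),
            )
            grid = GridSpec(
                **{
                    k: float(meta[k])
                    for k in (
                        "coarse_xy_step",
                        "coarse_theta_step",
                        "fine_xy_step",
                        "fine_theta_step",
                        "wall_band",
                    )
                }
            )
            return cls(
                vectors=vectors,
                states=states,
                partition=partition,
                grid=grid,
                array=array,
                tank=tank,
                fish_length=float(meta["fish_length"]),
            )


def drop_electrode_nodes(nodes: np.ndarray, array: ElectrodeArray) -> np.ndarray:
    """Remove nodes whose center coincides exactly with an electrode (the
    potential is singular there). Only grid layouts with electrodes inside
    the search region can trigger this."""
    keep = np.ones(nodes.shape[0], dtype=bool)
    for ex, ey in array.electrodes:
        keep &= ~((nodes[:, 0] == ex) & (nodes[:, 1] == ey))
    return nodes[keep]


def normalized_responses(
    nodes: np.ndarray,
    array: ElectrodeArray,
    tank: TankGeometry,
    dtype=np.float32,
    chunk: int = 500_000,
) -> np.ndarray:
    """Unit-normalized response rows for many nodes, computed in chunks."""
    n = nodes.shape[0]
    out = np.empty((n, array.n_channels), dtype=dtype)
    for i in range(0, n, chunk):
        resp = response_matrix(nodes[i : i + chunk], array, tank)
        norms = np.linalg.norm(resp, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("degenerate (all-zero) response row in the grid")
        out[i : i + chunk] = (resp / norms).astype(dtype)
    return out


def build_lut(
    array: ElectrodeArray,
    tank: TankGeometry,
    nodes: np.ndarray,
    grid: Optional[GridSpec] = None,
    fish_length: float = DEFAULT_FISH_LENGTH,
) -> LUT:
    """Build a LUT from grid nodes: compute responses, unit-normalize each
    row (float32 storage), and partition rows by strongest-|channel| index.

    The build is deterministic (stable sort) and independent of the moment
    and boundary-contrast values, which cancel under normalization.
    """
    array.validate_for_localization()
    nodes = drop_electrode_nodes(np.asarray(nodes, dtype=float), array)
    vectors = normalized_responses(nodes, array, tank)
    strongest = np.argmax(np.abs(vectors), axis=1)
    order = np.argsort(strongest, kind="stable")
    vectors = np.ascontiguousarray(vectors[order])
    states = np.ascontiguousarray(nodes[order])
    strongest = strongest[order]
    partition: Dict[int, Tuple[int, int]] = {}
    for c in range(array.n_channels):
        idx = np.searchsorted(strongest, [c, c + 1])
        partition[c] = (int(idx[0]), int(idx[1]))
    return LUT(
        vectors=vectors,
        states=states,
        partition=partition,
        grid=grid or GridSpec(),
        array=array,
        tank=tank,
        fish_length=fish_length,
    )
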