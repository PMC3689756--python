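"""Inverse solver: match measured RSI vectors to the LUT.

A measurement and every LUT row are unit vectors, so the best-matching grid
node maximizes the |dot product| (|cosine|). The sign of the winning dot
product resolves the dipole polarity: LUT orientations span [0, 180) and a
negative dot product reports theta + 180. The production path is a two-step
search — partition-filtered coarse LUT scan, then an on-the-fly fine-grid
refinement around the coarse winner, with a small LRU cache of fine-search
neighborhoods.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .field import response_matrix
from .geometry import (
    MIN_CHANNELS,
    DipoleState,
    ElectrodeArray,
    RSIVector,
    TankGeometry,
)
from .lut import LUT, fine_nodes_around

__all__ = [
    "MatchResult",
    "SearchCache",
    "InsufficientChannelsError",
    "match_bruteforce",
    "localize_two_step",
    "localize_batch",
    "apply_near_field_exclusion",
    "localize_with_exclusion",
    "estimate_moment",
]

log = logging.getLogger(__name__)

#: Distance (cm) within which a channel's electrode invalidates the
#: ideal-dipole assumption; channels that close to the fish are excluded.
DEFAULT_EXCLUSION_CM = 13.0


class InsufficientChannelsError(ValueError):
    """Fewer than MIN_CHANNELS usable channels remain."""


@dataclass(frozen=True)
class MatchResult:
    """Outcome of one LUT match.

    ``score`` is the dot product evaluated at the reported orientation
    (always >= 0 after polarity resolution); ``polarity`` is the sign of the
    raw dot product against the stored [0, 180) row.
    """

    state: DipoleState
    score: float
    polarity: int
    excluded_channels: Tuple[int, ...] = ()
    flagged: bool = False


class SearchCache:
    """LRU cache of fine-search neighborhoods, keyed by coarse-node identity
    (row index + channel mask). Capacity defaults to 16 histories."""

    def __init__(self, capacity: int = 16):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._entries: OrderedDict = OrderedDict()
        self.hits = 0
        self.misses = 0

    def __len__(self) -> int:
        return len(self._entries)

    def get(self, key):
        if key in self._entries:
            self._entries.move_to_end(key)
            self.hits += 1
            return self._entries[key]
        self.misses += 1
        return None

    def put(self, key, value):
        self._entries[key] = value
        self._entries.move_to_end(key)
        while len(self._entries) > self.capacity:
            self._entries.popitem(last=False)


def _query_unit(rsi: RSIVector) -> Tuple[np.ndarray, np.ndarray]:
    """Compressed (usable channels only) unit query vector and its mask."""
    if rsi.n_usable < MIN_CHANNELS:
        raise InsufficientChannelsError(
            f"need >= {MIN_CHANNELS} usable channels, have {rsi.n_usable}"
        )
    mask = rsi.mask
    v = rsi.values[mask]
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("all-zero RSI vector cannot be localized")
    return v / n, mask


def _masked_rows(vectors: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """LUT rows restricted to unmasked columns, re-normalized per row.

    Rows that vanish on the surviving columns are left as zero (they can
    never win the |dot| comparison)."""
    if mask.all():
        return vectors
    sub = vectors[:, mask].astype(np.float64, copy=True)
    norms = np.linalg.norm(sub, axis=1, keepdims=True)
    np.divide(sub, norms, out=sub, where=norms > 0)
    return sub


def _resolve(state_row: np.ndarray, dot: float, prev: Optional[DipoleState],
             rsi: RSIVector, mask: np.ndarray, flagged: bool = False) -> MatchResult:
    """Turn a winning row + signed dot product into a MatchResult."""
    x, y, theta = (float(v) for v in state_row)
    if dot == 0.0 and prev is not None:
        # Sign-ambiguous: choose the polarity closer to the previous heading.
        from .angles import circ_abs_diff

        sign = 1.0 if circ_abs_diff(theta, prev.theta) <= circ_abs_diff(
            theta + 180.0, prev.theta
        ) else -1.0
    else:
        sign = 1.0 if dot >= 0 else -1.0
    theta_out = theta if sign > 0 else (theta + 180.0) % 360.0
    return MatchResult(
        state=DipoleState(x=x, y=y, theta=theta_out, time=rsi.pulse_time),
        score=abs(float(dot)),
        polarity=int(sign),
        excluded_channels=tuple(np.flatnonzero(~mask)),
        flagged=flagged,
    )


def match_bruteforce(rsi: RSIVector, lut: LUT,
                     prev: Optional[DipoleState] = None) -> MatchResult:
    """Exhaustive |dot| maximization over every LUT row.

    Masked channels are removed from both the query and the LUT columns,
    with re-normalization of both. Ties break to the lowest row index.
    """
    q, mask = _query_unit(rsi)
    rows = _masked_rows(lut.vectors, mask)
    scores = rows @ q
    best = int(np.argmax(np.abs(scores)))
    return _resolve(lut.states[best], float(scores[best]), prev, rsi, mask)


#: Multi-start settings for the coarse->fine hand-off. Near the wall the
#: |cosine| landscape can carry several near-tied lobes; the fine search
#: climbs from up to MAX_STARTS mutually distant coarse candidates whose
#: scores lie within START_MARGIN of the best (others cannot overtake).
MAX_STARTS = 4
START_MARGIN = 0.005


def _nms_starts(
    rows: np.ndarray, scores: np.ndarray, lut: LUT
) -> List[Tuple[int, float]]:
    """Pick up to MAX_STARTS high-scoring, mutually distant coarse rows
    (non-maximum suppression over a +/-2 position-step, +/-3 angle-step box)."""
    sup_xy = 2.0 * lut.grid.coarse_xy_step
    sup_th = 3.0 * lut.grid.coarse_theta_step
    asc = np.abs(scores)
    alive = asc >= asc.max() - START_MARGIN
    st = lut.states[rows]
    starts: List[Tuple[int, float]] = []
    while len(starts) < MAX_STARTS and alive.any():
        i = int(np.argmax(np.where(alive, asc, -1.0)))
        starts.append((int(rows[i]), float(scores[i])))
        dth = np.abs(((st[:, 2] - st[i, 2]) + 90.0) % 180.0 - 90.0)
        near = (
            (np.abs(st[:, 0] - st[i, 0]) <= sup_xy)
            & (np.abs(st[:, 1] - st[i, 1]) <= sup_xy)
            & (dth <= sup_th)
        )
        alive &= ~near
    return starts


def _coarse_search(
    q: np.ndarray, mask: np.ndarray, lut: LUT
) -> List[Tuple[int, float]]:
    """Step 1: coarse LUT scan. With all channels usable, only the rows
    whose strongest or second-strongest channel matches the query's are
    scanned (the partition shortcut); under masking the partition index is
    meaningless and the full table is scanned instead. Returns candidate
    (row, signed dot) starts for the fine refinement, best first."""
    if mask.all():
        order = np.argsort(np.abs(q))
        ch1, ch2 = int(order[-1]), int(order[-2])
        chans = sorted({ch1, ch2})
        rows = np.concatenate(
            [
                np.arange(lut.partition_rows(c).start, lut.partition_rows(c).stop)
                for c in chans
            ]
        )
        if rows.size == 0:  # degenerate partition; fall back to full scan
            rows = np.arange(lut.n_rows)
        scores = lut.vectors[rows].astype(np.float64) @ q
        return _nms_starts(rows, scores, lut)
    masked = _masked_rows(lut.vectors, mask)
    scores = masked.astype(np.float64) @ q
    return _nms_starts(np.arange(lut.n_rows), scores, lut)


#: Maximum fine-refinement re-centering iterations.
MAX_FINE_ITERS = 10


def _fine_neighborhood_at(lut: LUT, center: np.ndarray, mask: np.ndarray):
    nodes = fine_nodes_around(
        DipoleState(float(center[0]), float(center[1]), float(center[2])),
        lut.grid,
        lut.tank,
        lut.fish_length,
    )
    if nodes.shape[0] == 0:
        return nodes, np.empty((0, int(mask.sum())), dtype=np.float32)
    resp = response_matrix(nodes, lut.array, lut.tank, on_singular="zero")[:, mask]
    norms = np.linalg.norm(resp, axis=1, keepdims=True)
    np.divide(resp, norms, out=resp, where=norms > 0)
    # round to single precision exactly as LUT rows are stored, so a node
    # scores identically whether recomputed here or read from a cached LUT
    return nodes, resp.astype(np.float32)


def localize_two_step(
    rsi: RSIVector,
    lut: LUT,
    cache: Optional[SearchCache] = None,
    prev: Optional[DipoleState] = None,
) -> MatchResult:
    """Coarse partition-filtered LUT search followed by an iterated
    fine-grid refinement around the coarse winner.

    The fine scan spans one coarse step around the current center at fine
    resolution; it is re-centered on its winner and repeated while the
    score strictly improves (the coarse winner can sit more than one step
    from the true optimum where the response landscape is flat, e.g. near
    the wall). Fine neighborhoods are computed on the fly and memoized in
    the 16-entry LRU ``cache`` keyed on the center node, so repeated
    visits skip the response computation. An empty fine neighborhood (an
    extreme wall position) falls back to the coarse result with a warning.
    """
    q, mask = _query_unit(rsi)
    starts = _coarse_search(q, mask, lut)

    overall_state = None
    overall_dot = 0.0
    flagged = False
    for row, coarse_dot in starts:
        center = lut.states[row]
        best_state = center
        best_dot = coarse_dot
        for it in range(MAX_FINE_ITERS):
            key = (round(center[0], 6), round(center[1], 6),
                   round(center[2], 6), mask.tobytes())
            entry = cache.get(key) if cache is not None else None
            if entry is None:
                entry = _fine_neighborhood_at(lut, center, mask)
                if cache is not None:
                    cache.put(key, entry)
            nodes, vecs = entry
            if nodes.shape[0] == 0:
                if it == 0:
                    log.warning(
                        "empty fine neighborhood at row %d; keeping coarse node", row
                    )
                    flagged = True
                break
            scores = vecs.astype(np.float64) @ q
            i = int(np.argmax(np.abs(scores)))
            if it > 0 and abs(scores[i]) <= abs(best_dot):
                break  # no strict improvement
            best_state = nodes[i]
            best_dot = float(scores[i])
            if np.all(nodes[i] == center):
                break  # converged on the center node
            center = nodes[i]
        if overall_state is None or abs(best_dot) > abs(overall_dot):
            overall_state = best_state
            overall_dot = best_dot
    return _resolve(overall_state, overall_dot, prev, rsi, mask, flagged=flagged)


# ---------------------------------------------------------------------------
# Vectorized batch search (simulation experiments)
# ---------------------------------------------------------------------------


def _fine_offsets_split(lut: LUT):
    g = lut.grid
    nx = int(round(g.coarse_xy_step / g.fine_xy_step))
    nt = int(round(g.coarse_theta_step / g.fine_theta_step))
    dx = np.arange(-nx, nx + 1) * g.fine_xy_step
    dt = np.arange(-nt, nt + 1) * g.fine_theta_step
    gx, gy = np.meshgrid(dx, dx, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()]), dt


def localize_batch(
    values: np.ndarray,
    lut: LUT,
    chunk: int = 2000,
) -> Tuple[np.ndarray, np.ndarray]:
    """Two-step search for many unmasked queries at once.

    Parameters
    ----------
    values : (n_queries, n_channels)
        Raw (un-normalized) RSI values.

    Returns
    -------
    states : (n_queries, 3) with columns x, y, theta (polarity-resolved,
        [0, 360)), and scores : (n_queries,) |dot| at the fine winner.

    Functionally identical to calling `localize_two_step` per query (same
    partition shortcut, same fine neighborhoods); vectorized so the static
    noise-sweep experiments run at desk scale.
    """
    V = np.asarray(values, dtype=float)
    if V.ndim != 2 or V.shape[1] != lut.n_channels:
        raise ValueError("values must be (n_queries, n_channels)")
    norms = np.linalg.norm(V, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("all-zero query vector")
    Q = (V / norms).astype(np.float32)
    nq = Q.shape[0]

    # Step 1: partition-filtered coarse scan, grouped by channel. Scores
    # are computed query-major so the |dot| argmax scans contiguously.
    # Each query keeps the winner of each scanned partition (up to two
    # starts for the fine refinement).
    order = np.argsort(np.abs(Q), axis=1)
    ch12 = order[:, -2:]  # second-strongest, strongest
    win_rows = np.full((nq, 2), -1, dtype=np.int64)
    win_dots = np.zeros((nq, 2), dtype=np.float64)
    win_n = np.zeros(nq, dtype=np.int64)
    for c in range(lut.n_channels):
        sel = np.flatnonzero((ch12[:, 0] == c) | (ch12[:, 1] == c))
        sl = lut.partition_rows(c)
        if sel.size == 0 or sl.stop <= sl.start:
            continue
        block = lut.vectors[sl]
        scores = Q[sel] @ block.T  # (n_sel, rows)
        np.abs(scores, out=scores)
        idx = np.argmax(scores, axis=1)
        rows = sl.start + idx
        # recover the signed dot at each winner (float64, matches scalar path)
        dots = np.einsum(
            "ij,ij->i", block[idx].astype(np.float64), Q[sel].astype(np.float64)
        )
        slot = win_n[sel]
        win_rows[sel, slot] = rows
        win_dots[sel, slot] = dots
        win_n[sel] = slot + 1
    missing = np.flatnonzero(win_n == 0)
    if missing.size:
        scores = Q[missing] @ lut.vectors.T
        np.abs(scores, out=scores)
        idx = np.argmax(scores, axis=1)
        win_rows[missing, 0] = idx
        win_dots[missing, 0] = np.einsum(
            "ij,ij->i",
            lut.vectors[idx].astype(np.float64),
            Q[missing].astype(np.float64),
        )
        win_n[missing] = 1

    # order each query's starts best-first; drop the runner-up if it ties
    # the winner's row or falls outside the score margin
    adot = np.abs(win_dots)
    swap = (win_n == 2) & (adot[:, 1] > adot[:, 0])
    win_rows[swap] = win_rows[swap][:, ::-1]
    win_dots[swap] = win_dots[swap][:, ::-1]
    adot = np.abs(win_dots)
    second_ok = (
        (win_n == 2)
        & (win_rows[:, 1] != win_rows[:, 0])
        & (adot[:, 1] >= adot[:, 0] - START_MARGIN)
    )
    q_idx = np.concatenate([np.arange(nq), np.flatnonzero(second_ok)])
    e_rows = np.concatenate([win_rows[:, 0], win_rows[second_ok, 1]])
    e_dots = np.concatenate([win_dots[:, 0], win_dots[second_ok, 1]])
    best_row, best_dot = e_rows, e_dots  # expanded starts, grouped by q_idx

    # Step 2: iterated fine refinement over the expanded start set, chunked.
    # Responses are linear in (cos theta, sin theta), so two basis responses
    # per candidate position cover the whole orientation scan; the scan is
    # re-centered on each winner while the score strictly improves, as in
    # `localize_two_step`.
    ne = best_row.size
    ent_states = np.empty((ne, 3), dtype=float)
    ent_abs = np.empty(ne, dtype=float)
    ent_sign = np.empty(ne, dtype=float)
    for i in range(0, ne, chunk):
        rows = best_row[i : i + chunk]
        centers = lut.states[rows].copy()  # (m, 3)
        m = rows.size
        Qc = Q[q_idx[i : i + chunk]].astype(np.float64)
        best_state = centers.copy()
        best = np.abs(best_dot[i : i + chunk]).copy()
        sign = np.sign(best_dot[i : i + chunk])
        sign[sign == 0] = 1.0
        active = np.ones(m, dtype=bool)
        for it in range(MAX_FINE_ITERS):
            w_state, w_dot, has_cand = _fine_scan_chunk(
                centers[active], Qc[active], lut
            )
            ia = np.flatnonzero(active)
            # first pass always adopts the fine winner (it includes the
            # center); later passes require strict improvement
            improve = has_cand if it == 0 else has_cand & (np.abs(w_dot) > best[ia])
            upd = ia[improve]
            best_state[upd] = w_state[improve]
            best[upd] = np.abs(w_dot[improve])
            sign[upd] = np.where(w_dot[improve] >= 0, 1.0, -1.0)
            moved = np.any(w_state[improve] != centers[upd], axis=1)
            centers[upd] = w_state[improve]
            still = np.zeros(m, dtype=bool)
            still[upd[moved]] = True
            active = still
            if not active.any():
                break
        ent_states[i : i + chunk] = best_state
        ent_abs[i : i + chunk] = best
        ent_sign[i : i + chunk] = sign

    # reduce the expanded starts to the best result per query (ties keep
    # the higher-coarse-score start, which comes first)
    order = np.lexsort((np.arange(ne), -ent_abs, q_idx))
    sorted_q = q_idx[order]
    first = np.ones(ne, dtype=bool)
    first[1:] = sorted_q[1:] != sorted_q[:-1]
    pick = order[first]
    sel_states = ent_states[pick]
    out_states = np.empty((nq, 3), dtype=float)
    out_states[:, :2] = sel_states[:, :2]
    theta_out = np.where(
        ent_sign[pick] >= 0, sel_states[:, 2], sel_states[:, 2] + 180.0
    )
    out_states[:, 2] = theta_out % 360.0
    out_scores = ent_abs[pick]
    return out_states, out_scores


def _fine_scan_chunk(centers: np.ndarray, Q: np.ndarray, lut: LUT):
    """One fine-grid scan around each center for a chunk of queries.

    Returns (winner states (m, 3) with theta in [0, 360) as stored on the
    grid, signed dots, has-any-valid-candidate mask).
    """
    off_xy, dthetas = _fine_offsets_split(lut)
    kp = off_xy.shape[0]
    kt = dthetas.size
    m = centers.shape[0]
    L2 = lut.fish_length / 2.0
    r2_tank = lut.tank.radius**2 + 1e-9

    px = centers[:, 0:1] + off_xy[None, :, 0]  # (m, kp)
    py = centers[:, 1:2] + off_xy[None, :, 1]
    thetas = (centers[:, 2:3] + dthetas[None, :]) % 360.0  # (m, kt)

    flat_pos = np.column_stack([px.ravel(), py.ravel()])
    basis = np.empty((2, m * kp, lut.n_channels))
    for bi, ang in enumerate((0.0, 90.0)):
        st = np.column_stack([flat_pos, np.full(m * kp, ang)])
        basis[bi] = response_matrix(st, lut.array, lut.tank, on_singular="zero")
    A = basis[0].reshape(m, kp, -1)
    B = basis[1].reshape(m, kp, -1)
    a = np.einsum("mpc,mc->mp", A, Q)
    b = np.einsum("mpc,mc->mp", B, Q)
    nA = np.einsum("mpc,mpc->mp", A, A)
    nB = np.einsum("mpc,mpc->mp", B, B)
    nAB = np.einsum("mpc,mpc->mp", A, B)

    ct = np.cos(np.radians(thetas))  # (m, kt)
    st_ = np.sin(np.radians(thetas))
    # scores (m, kp, kt): (c*a + s*b) / sqrt(c^2 nA + 2cs nAB + s^2 nB)
    num = a[:, :, None] * ct[:, None, :] + b[:, :, None] * st_[:, None, :]
    den2 = (
        nA[:, :, None] * ct[:, None, :] ** 2
        + 2.0 * nAB[:, :, None] * ct[:, None, :] * st_[:, None, :]
        + nB[:, :, None] * st_[:, None, :] ** 2
    )
    hx = ct * L2  # (m, kt)
    hy = st_ * L2
    head = (px[:, :, None] + hx[:, None, :]) ** 2 + (
        py[:, :, None] + hy[:, None, :]
    ) ** 2 <= r2_tank
    tail = (px[:, :, None] - hx[:, None, :]) ** 2 + (
        py[:, :, None] - hy[:, None, :]
    ) ** 2 <= r2_tank
    valid = head & tail & (den2 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(valid, num / np.sqrt(den2), 0.0)

    flat = scores.reshape(m, kp * kt)
    idx = np.argmax(np.abs(flat), axis=1)
    dots = flat[np.arange(m), idx]
    ip, it_ = np.unravel_index(idx, (kp, kt))
    w = np.column_stack(
        [px[np.arange(m), ip], py[np.arange(m), ip], thetas[np.arange(m), it_]]
    )
    return w, dots, valid.reshape(m, kp * kt).any(axis=1)


def match_bruteforce_batch(
    values: np.ndarray,
    lut: LUT,
    row_chunk: int = 100_000,
) -> Tuple[np.ndarray, np.ndarray]:
    """Exhaustive |dot| maximization over every LUT row for many queries,
    chunked over rows so very large (e.g. fine-resolution) tables fit in
    memory. Same tie-break as `match_bruteforce` (lowest row index).

    Returns (states (n, 3) with polarity-resolved theta, |dot| scores).
    """
    V = np.asarray(values, dtype=float)
    norms = np.linalg.norm(V, axis=1, keepdims=True)
    Q = (V / norms).astype(np.float32)
    nq = Q.shape[0]
    best_row = np.zeros(nq, dtype=np.int64)
    best_abs = np.full(nq, -1.0, dtype=np.float64)
    Q64 = Q.astype(np.float64)
    for start in range(0, lut.n_rows, row_chunk):
        block = lut.vectors[start : start + row_chunk].astype(np.float64)
        scores = Q64 @ block.T
        np.abs(scores, out=scores)
        idx = np.argmax(scores, axis=1)
        vals = scores[np.arange(nq), idx]
        upd = vals > best_abs  # strict: earlier chunks win ties
        best_row[upd] = start + idx[upd]
        best_abs[upd] = vals[upd]
    dots = np.einsum(
        "ij,ij->i", lut.vectors[best_row].astype(np.float64), Q.astype(np.float64)
    )
    states = lut.states[best_row].copy()
    states[:, 2] = np.where(dots >= 0, states[:, 2], states[:, 2] + 180.0) % 360.0
    return states, np.abs(dots)


# ---------------------------------------------------------------------------
# Near-field exclusion & moment estimation
# ---------------------------------------------------------------------------


def apply_near_field_exclusion(
    rsi: RSIVector,
    estimate: DipoleState,
    array: ElectrodeArray,
    threshold: float = DEFAULT_EXCLUSION_CM,
) -> RSIVector:
    """Mask every channel with an electrode within ``threshold`` cm of the
    estimated fish center (where the ideal-dipole assumption fails).

    Raises InsufficientChannelsError if fewer than MIN_CHANNELS remain; the
    caller should then keep the unmasked estimate and flag it.
    """
    p = estimate.position
    d_pos = np.linalg.norm(array.pos - p, axis=1)
    d_neg = np.linalg.norm(array.neg - p, axis=1)
    keep = (d_pos >= threshold) & (d_neg >= threshold)
    out = rsi.masked(keep)
    if out.n_usable < MIN_CHANNELS:
        raise InsufficientChannelsError(
            f"near-field exclusion leaves {out.n_usable} channels"
        )
    return out


def localize_with_exclusion(
    rsi: RSIVector,
    lut: LUT,
    threshold: float = DEFAULT_EXCLUSION_CM,
    cache: Optional[SearchCache] = None,
    prev: Optional[DipoleState] = None,
    max_rounds: int = 2,
) -> MatchResult:
    """All-channel first pass, then near-field masking and re-localization.

    Masking is iterated at most ``max_rounds`` times to avoid oscillation.
    If masking would leave too few channels the last estimate is kept and
    flagged.
    """
    result = localize_two_step(rsi, lut, cache=cache, prev=prev)
    current = rsi
    for _ in range(max_rounds):
        try:
            masked = apply_near_field_exclusion(
                current, result.state, lut.array, threshold
            )
        except InsufficientChannelsError:
            return MatchResult(
                state=result.state,
                score=result.score,
                polarity=result.polarity,
                excluded_channels=result.excluded_channels,
                flagged=True,
            )
        if np.array_equal(masked.mask, current.mask):
            return result
        current = masked
        result = localize_two_step(current, lut, cache=cache, prev=prev)
    return result


def estimate_moment(
    rsi: RSIVector,
    state: DipoleState,
    array: ElectrodeArray,
    tank: TankGeometry,
) -> Tuple[float, float]:
    """Least-squares scale between observed RSIs and the unit-moment
    prediction at ``state``: the dipole-moment estimate.

    Returns (moment, residual_norm). Masked channels are ignored.
    """
    pred = response_matrix(state.as_array()[None, :], array, tank)[0]
    mask = rsi.mask
    p = pred[mask]
    o = rsi.values[mask]
    denom = p @ p
    if denom == 0:
        raise ValueError("predicted response is all-zero at this state")
    m = float((p @ o) / denom)
    resid = float(np.linalg.norm(o - m * p))
    return m, resid
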