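"""Inverse-search tests: brute-force matching, two-step search, caching,
near-field exclusion, moment estimation, and the search invariances."""

import numpy as np
import pytest

from dipoletrack import (
    DipoleState,
    GridSpec,
    RSIVector,
    SearchCache,
    build_grid,
    build_lut,
)
from dipoletrack.angles import circ_abs_diff
from dipoletrack.field import response_matrix
from dipoletrack.localize import (
    InsufficientChannelsError,
    apply_near_field_exclusion,
    estimate_moment,
    localize_batch,
    localize_two_step,
    localize_with_exclusion,
    match_bruteforce,
)
from dipoletrack.simulate import sample_states


def query_at(state_row, array, tank, moment=1.0):
    vals = response_matrix(np.atleast_2d(state_row), array, tank, moment=moment)[0]
    return RSIVector(values=vals)


class TestMatchBruteforce:
    def test_self_match_scores_one(self, small_lut):
        row = 137
        q = RSIVector(values=small_lut.vectors[row].astype(float))
        res = match_bruteforce(q, small_lut)
        assert res.score == pytest.approx(1.0, abs=1e-6)
        assert res.state.as_array()[:2] == pytest.approx(small_lut.states[row][:2])
        assert res.polarity == 1

    def test_negated_row_flips_polarity(self, small_lut):
        row = 137
        q = RSIVector(values=-small_lut.vectors[row].astype(float))
        res = match_bruteforce(q, small_lut)
        assert res.score == pytest.approx(1.0, abs=1e-6)
        assert res.polarity == -1
        assert res.state.theta == pytest.approx(
            (small_lut.states[row][2] + 180.0) % 360.0
        )

    def test_matches_naive_python_loop(self, small_lut, small_array, small_tank, rng):
        """Off-grid noiseless queries: vectorized argmax must agree with an
        explicit one-row-at-a-time cosine loop."""
        states = sample_states(100, small_tank, rng, fish_length=10.0)
        for s in states:
            q = query_at(s, small_array, small_tank)
            res = match_bruteforce(q, small_lut)
            u = q.values / np.linalg.norm(q.values)
            best_i, best = 0, -1.0
            for i in range(small_lut.n_rows):
                c = abs(float(np.dot(small_lut.vectors[i], u)))
                if c > best:
                    best, best_i = c, i
            assert res.state.as_array()[:2] == pytest.approx(
                small_lut.states[best_i][:2]
            )
            assert res.score == pytest.approx(best, abs=1e-6)

    def test_insufficient_channels(self, small_lut):
        q = RSIVector(
            values=np.ones(8), mask=[True, True, True, False, False, False, False, False]
        )
        with pytest.raises(InsufficientChannelsError):
            match_bruteforce(q, small_lut)


class TestTwoStep:
    def test_recovers_coarse_node_exactly(self, small_lut, small_array, small_tank):
        node = small_lut.states[250]
        q = query_at(node, small_array, small_tank)
        res = localize_two_step(q, small_lut)
        assert res.score >= 0.9999
        assert abs(res.state.x - node[0]) <= small_lut.grid.fine_xy_step
        assert abs(res.state.y - node[1]) <= small_lut.grid.fine_xy_step
        assert circ_abs_diff(res.state.theta, node[2], 180.0) <= (
            small_lut.grid.fine_theta_step
        )

    def test_repeat_query_bit_identical_and_cached(self, small_lut, small_array, small_tank):
        q = query_at([5.7, -3.2, 41.0], small_array, small_tank)
        cache = SearchCache(capacity=16)
        r1 = localize_two_step(q, small_lut, cache=cache)
        first_misses = cache.misses
        assert cache.hits == 0 and first_misses >= 1
        r2 = localize_two_step(q, small_lut, cache=cache)
        # second identical query is served entirely from cache
        assert cache.misses == first_misses
        assert cache.hits == first_misses
        assert r1.state == r2.state
        assert r1.score == r2.score

    def test_cache_eviction_is_lru(self):
        c = SearchCache(capacity=2)
        c.put("a", 1)
        c.put("b", 2)
        assert c.get("a") == 1
        c.put("c", 3)  # evicts "b" (least recently used)
        assert c.get("b") is None
        assert c.get("a") == 1 and c.get("c") == 3

    def test_scale_invariance(self, small_lut, small_array, small_tank):
        q = query_at([10.0, 4.0, 200.0], small_array, small_tank)
        base = localize_two_step(q, small_lut)
        scaled = localize_two_step(
            RSIVector(values=q.values * 137.5), small_lut
        )
        assert base.state == scaled.state
        assert base.score == pytest.approx(scaled.score, rel=1e-12)

    def test_negation_flips_orientation_exactly(self, small_lut, small_array, small_tank):
        q = query_at([10.0, 4.0, 20.0], small_array, small_tank)
        base = localize_two_step(q, small_lut)
        neg = localize_two_step(RSIVector(values=-q.values), small_lut)
        assert neg.state.x == base.state.x and neg.state.y == base.state.y
        assert neg.state.theta == pytest.approx((base.state.theta + 180.0) % 360.0)
        assert neg.polarity == -base.polarity

    def test_batch_agrees_with_scalar_path(self, small_lut, small_array, small_tank, rng):
        states = sample_states(50, small_tank, rng, fish_length=10.0)
        V = response_matrix(states, small_array, small_tank)
        est, scores = localize_batch(V, small_lut)
        for i in range(len(states)):
            r = localize_two_step(RSIVector(values=V[i]), small_lut)
            assert est[i] == pytest.approx(r.state.as_array())
            assert scores[i] == pytest.approx(r.score, abs=1e-6)

    def test_rotational_equivariance_at_center(self, tank, array8):
        """Rotating a centered dipole by the array's 45-degree symmetry
        step rotates the estimate by exactly 45 degrees (the theta grid
        step divides 45 so the LUT itself maps onto itself)."""
        grid = GridSpec(coarse_xy_step=3.0, coarse_theta_step=5.0,
                        fine_xy_step=1.0, fine_theta_step=1.0, wall_band=0.0)
        lut = build_lut(array8, tank, build_grid(tank, grid), grid)
        for theta in (12.0, 103.4, 217.0):
            q1 = query_at([0.0, 0.0, theta], array8, tank)
            q2 = query_at([0.0, 0.0, theta + 45.0], array8, tank)
            r1 = localize_two_step(q1, lut)
            r2 = localize_two_step(q2, lut)
            assert r2.state.theta == pytest.approx((r1.state.theta + 45.0) % 360.0)
            # center position rotates onto itself
            assert (r2.state.x, r2.state.y) == (r1.state.x, r1.state.y)


class TestNearFieldExclusion:
    def test_center_estimate_masks_nothing(self, array8):
        rsi = RSIVector(values=np.ones(8))
        out = apply_near_field_exclusion(rsi, DipoleState(0, 0, 0), array8, 13.0)
        assert out.mask.all()

    def test_close_electrode_masked(self, array8):
        # 5 cm from the channel-0 positive electrode (on the wall at 0 deg)
        est = DipoleState(70.0, 0.0, 0.0)
        rsi = RSIVector(values=np.ones(8))
        out = apply_near_field_exclusion(rsi, est, array8, 13.0)
        d = np.minimum(
            np.linalg.norm(array8.pos - est.position, axis=1),
            np.linalg.norm(array8.neg - est.position, axis=1),
        )
        assert np.array_equal(out.mask, d >= 13.0)
        assert not out.mask.all()

    def test_insufficient_channels_raises(self, small_array):
        rsi = RSIVector(values=np.ones(8))
        with pytest.raises(InsufficientChannelsError):
            # huge threshold masks everything
            apply_near_field_exclusion(
                rsi, DipoleState(0, 0, 0), small_array, threshold=1000.0
            )

    def test_exclusion_reduces_near_wall_error(self, full_lut, array8, tank, rng):
        """Near-wall dipoles with a distorting perturbation on the nearest
        channel: median position error with exclusion <= without."""
        n = 120
        angles = rng.uniform(0, 2 * np.pi, n)
        radii = rng.uniform(tank.radius - 18, tank.radius - 12, n)
        err_with, err_without = [], []
        for a, r in zip(angles, radii):
            x, y = r * np.cos(a), r * np.sin(a)
            theta = np.degrees(a) + 90.0  # tangential so the body fits
            vals = response_matrix(np.array([[x, y, theta]]), array8, tank)[0]
            # distort the channel nearest to the fish by 50%
            d = np.minimum(
                np.linalg.norm(array8.pos - [x, y], axis=1),
                np.linalg.norm(array8.neg - [x, y], axis=1),
            )
            nearest = int(np.argmin(d))
            vals_pert = vals.copy()
            vals_pert[nearest] *= 1.5
            plain = localize_two_step(RSIVector(values=vals_pert), full_lut)
            excl = localize_with_exclusion(
                RSIVector(values=vals_pert), full_lut, threshold=13.0
            )
            err_without.append(np.hypot(plain.state.x - x, plain.state.y - y))
            err_with.append(np.hypot(excl.state.x - x, excl.state.y - y))
        assert np.median(err_with) <= np.median(err_without)


class TestEstimateMoment:
    def test_exact_scale_recovery(self, small_array, small_tank):
        state = DipoleState(5.0, 8.0, 120.0)
        pred = response_matrix(state.as_array()[None], small_array, small_tank)[0]
        m, resid = estimate_moment(
            RSIVector(values=3.0 * pred), state, small_array, small_tank
        )
        assert m == pytest.approx(3.0, rel=1e-12)
        assert resid == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_noise_leaves_moment(self, small_array, small_tank, rng):
        state = DipoleState(5.0, 8.0, 120.0)
        pred = response_matrix(state.as_array()[None], small_array, small_tank)[0]
        noise = rng.standard_normal(pred.size)
        noise -= (noise @ pred) / (pred @ pred) * pred  # orthogonalize
        m, _ = estimate_moment(
            RSIVector(values=2.0 * pred + noise), state, small_array, small_tank
        )
        assert m == pytest.approx(2.0, rel=1e-10)

    def test_recovery_at_system_snr(self, array8, tank, rng):
        """Randomized true moments recovered within 1% at the measured
        46.5 dB system SNR."""
        states = sample_states(1000, tank, rng, min_wall_distance=13.0)
        resp = response_matrix(states, array8, tank)
        sd = resp.std()
        sigma = sd * 10 ** (-46.5 / 20.0)
        moments = rng.uniform(0.5, 2.0, len(states))
        errs = []
        for i, s in enumerate(states):
            obs = moments[i] * resp[i] + rng.normal(0, sigma, resp.shape[1])
            m, _ = estimate_moment(
                RSIVector(values=obs), DipoleState(*s), array8, tank
            )
            errs.append(abs(m - moments[i]) / moments[i])
        assert np.median(errs) < 0.01

    def test_masked_channels_ignored(self, small_array, small_tank):
        state = DipoleState(5.0, 8.0, 120.0)
        pred = response_matrix(state.as_array()[None], small_array, small_tank)[0]
        obs = 2.5 * pred
        obs[0] = 1e6  # corrupted channel
        mask = np.ones(8, dtype=bool)
        mask[0] = False
        m, resid = estimate_moment(
            RSIVector(values=obs, mask=mask), state, small_array, small_tank
        )
        assert m == pytest.approx(2.5, rel=1e-12)
        assert resid == pytest.approx(0.0, abs=1e-9)


class TestNoiseDegradation:
    def test_median_errors_monotone_in_noise(self, small_lut, small_array, small_tank, rng):
        states = sample_states(300, small_tank, rng, fish_length=10.0)
        V = response_matrix(states, small_array, small_tank)
        med = np.median(np.abs(V))
        pos_meds, ori_meds = [], []
        for level in (0.0, 3e-3, 3e-2, 3e-1):
            noisy = V + rng.normal(0, level * med, V.shape)
            est, _ = localize_batch(noisy, small_lut)
            pos_meds.append(np.median(np.hypot(est[:, 0] - states[:, 0],
                                               est[:, 1] - states[:, 1])))
            ori_meds.append(np.median(circ_abs_diff(est[:, 2], states[:, 2])))
        # non-decreasing up to sampling fluctuation at the grid floor
        pos_meds = np.array(pos_meds)
        ori_meds = np.array(ori_meds)
        assert np.all(np.diff(pos_meds) >= -0.05 * pos_meds[:-1])
        assert np.all(np.diff(ori_meds) >= -0.05 * ori_meds[:-1])
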