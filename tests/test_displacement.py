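import numpy as np
import pytest

from hfmaze import box_scaling, count_steps, field_from_counts, rasterize
from hfmaze.displacement import DIRECTIONS, LatticeSpec, P0, StepCounts
from hfmaze.trajectory import Trajectory


def _traj_from_xy(xy, rate=30.0):
    xy = np.asarray(xy, float)
    return Trajectory(t=np.arange(len(xy)) / rate, x=xy[:, 0], y=xy[:, 1])


def _counts_from_sequences(seqs, L=11):
    """Independent brute-force recount: scan every consecutive pair."""
    S = {}
    for seq in seqs:
        for a, b in zip(seq[:-1], seq[1:]):
            a, b = tuple(a), tuple(b)
            step = (b[0] - a[0], b[1] - a[1])
            name = {(1, 0): "right", (-1, 0): "left", (0, 1): "up", (0, -1): "down"}.get(step)
            if name is not None:
                S[(a, name)] = S.get((a, name), 0) + 1
    return S


def _oracle_field(seqs, L=11):
    """Direct evaluation of the published weight equations, per site."""
    S = _counts_from_sequences(seqs, L)
    out = {}
    sites = {a for (a, _) in S}
    for site in sites:
        counts = {d: S.get((site, d), 0) for d in DIRECTIONS}
        ns = sum(counts.values())
        W = {d: counts[d] / ns + P0 - (counts[d] / ns) * P0 for d in DIRECTIONS}
        Wout = sum(W.values())
        P = {d: W[d] / Wout for d in DIRECTIONS}
        out[site] = {
            "P": P,
            "M": (P["right"] - P["left"], P["up"] - P["down"]),
        }
    return out


class TestRasterize:
    def test_stationary_single_site(self):
        lat = LatticeSpec(L=11, half_extent=60)
        tr = _traj_from_xy([[3.0, 3.0]] * 20)
        seq = rasterize(tr, lat)
        assert len(seq) == 1

    def test_horizontal_sweep_strictly_rightward(self):
        lat = LatticeSpec(L=11, half_extent=60)
        xs = np.linspace(-55, 55, 400)
        tr = _traj_from_xy(np.column_stack([xs, np.zeros(400)]))
        seq = rasterize(tr, lat)
        steps = np.diff(seq, axis=0)
        assert np.all(steps[:, 0] == 1) and np.all(steps[:, 1] == 0)

    def test_diagonal_jump_decomposed_horizontal_first(self):
        lat = LatticeSpec(L=11, half_extent=60)
        # two samples one box apart in both x and y
        tr = _traj_from_xy([[0.0, 0.0], [11.0, 11.0]])
        seq = rasterize(tr, lat)
        assert len(seq) == 3
        assert tuple(seq[1] - seq[0]) == (1, 0)  # right first
        assert tuple(seq[2] - seq[1]) == (0, 1)  # then up

    def test_drop_mode_skips_nonadjacent(self):
        lat = LatticeSpec(L=11, half_extent=60)
        tr = _traj_from_xy([[0.0, 0.0], [22.0, 0.0]])
        seq = rasterize(tr, lat, decompose_diagonals=False)
        counts = count_steps([seq], L=11)
        assert counts.ns == 0  # the two-box jump is a break, not steps

    def test_point_outside_square_raises(self):
        lat = LatticeSpec(L=11, half_extent=60)
        tr = _traj_from_xy([[0.0, 0.0], [0.0, 61.0]])
        with pytest.raises(ValueError):
            rasterize(tr, lat)


class TestCountSteps:
    def test_hand_counted_sequence(self):
        seq = np.array([[3, 3], [3, 4], [3, 3]])
        c = count_steps([seq], L=11)
        assert c.S[2, 2, 2] == 1  # up out of (3,3)
        assert c.S[2, 3, 3] == 1  # down out of (3,4)
        assert c.ns == 2

    def test_two_identical_mice_double_counts(self):
        seq = np.array([[1, 1], [2, 1], [2, 2]])
        c1 = count_steps([seq], L=11)
        c2 = count_steps([seq, seq], L=11)
        np.testing.assert_array_equal(c2.S, 2 * c1.S)

    def test_random_walks_match_naive_recount(self):
        rng = np.random.default_rng(9)
        seqs = []
        for _ in range(3):
            pos = np.array([6, 6])
            seq = [pos.copy()]
            for _ in range(200):
                step = [(1, 0), (-1, 0), (0, 1), (0, -1)][rng.integers(4)]
                nxt = np.clip(pos + step, 1, 11)
                if not np.all(nxt == pos):
                    seq.append(nxt.copy())
                pos = nxt
            seqs.append(np.array(seq))
        c = count_steps(seqs, L=11)
        oracle = _counts_from_sequences([s.tolist() for s in seqs])
        dir_idx = {d: i for i, d in enumerate(DIRECTIONS)}
        for ((x, y), d), n in oracle.items():
            assert c.S[x - 1, y - 1, dir_idx[d]] == n
        assert c.ns == sum(oracle.values())


class TestFieldFromCounts:
    def test_published_worked_example_exact(self):
        S = np.zeros((11, 11, 4), dtype=int)
        S[2, 2, 2] = 2  # two passes up out of (3,3)
        S[2, 2, 3] = 1  # one pass down
        f = field_from_counts(StepCounts(L=11, S=S, ns=3))
        assert f.W[2, 2, 2] == pytest.approx(3 / 4)
        assert f.W[2, 2, 3] == pytest.approx(1 / 2)
        assert f.W[2, 2, 0] == f.W[2, 2, 1] == pytest.approx(1 / 4)
        assert f.P[2, 2, 2] == pytest.approx(3 / 7)   # 0.4286 -> printed 0.43
        assert f.P[2, 2, 3] == pytest.approx(2 / 7)   # 0.2857 -> printed 0.29
        assert f.P[2, 2, 0] == pytest.approx(1 / 7)   # 0.1429 -> printed 0.14
        np.testing.assert_allclose(f.M[2, 2], [0.0, 1 / 7])

    def test_empty_site_is_null(self):
        S = np.zeros((5, 5, 4), dtype=int)
        S[0, 0, 0] = 3
        f = field_from_counts(StepCounts(L=5, S=S, ns=3))
        np.testing.assert_allclose(f.P[2, 2], 0.25)
        np.testing.assert_allclose(f.M[2, 2], 0.0)

    def test_all_steps_rightward_saturates(self):
        """W_right = 1 when every observed step leaves rightward."""
        S = np.zeros((5, 5, 4), dtype=int)
        S[1, 1, 0] = 7
        f = field_from_counts(StepCounts(L=5, S=S, ns=7))
        assert f.W[1, 1, 0] == pytest.approx(1.0)
        # direct symbolic evaluation: P_right = 1/(1+3*P0), Mh = P_right - P0/(1+3*P0)
        p_right = 1.0 / (1.0 + 3 * P0)
        assert f.P[1, 1, 0] == pytest.approx(p_right)
        assert f.M[1, 1, 0] == pytest.approx(p_right - P0 / (1.0 + 3 * P0))

    def test_zero_step_trial_all_null(self):
        f = field_from_counts(StepCounts(L=5, S=np.zeros((5, 5, 4), int), ns=0))
        np.testing.assert_allclose(f.P, 0.25)
        np.testing.assert_allclose(f.M, 0.0)

    def test_per_site_normalization_everywhere(self):
        rng = np.random.default_rng(2)
        S = rng.integers(0, 6, size=(11, 11, 4))
        f = field_from_counts(StepCounts(L=11, S=S, ns=int(S.sum())))
        np.testing.assert_allclose(f.P.sum(axis=-1), 1.0, atol=1e-12)

    def test_negative_counts_rejected(self):
        S = np.zeros((5, 5, 4), int)
        S[0, 0, 0] = -1
        with pytest.raises(ValueError):
            StepCounts(L=5, S=S, ns=0)

    def test_oracle_equivalence_on_short_sequences(self):
        """Implementation matches direct evaluation of the printed formulas."""
        seqs = [
            [(3, 3), (3, 4), (3, 3), (4, 3)],
            [(5, 5), (5, 6), (6, 6), (6, 5), (5, 5)],
            [(1, 1), (2, 1), (2, 2), (2, 1)],
            [(7, 7), (7, 8)],
            [(9, 2), (9, 3), (9, 2), (9, 3)],
        ]
        arr = [np.array(s) for s in seqs]
        f = field_from_counts(count_steps(arr, L=11))
        oracle = _oracle_field(seqs)
        dir_idx = {d: i for i, d in enumerate(DIRECTIONS)}
        for (x, y), vals in oracle.items():
            for d, i in dir_idx.items():
                assert f.P[x - 1, y - 1, i] == pytest.approx(vals["P"][d], abs=1e-12)
            np.testing.assert_allclose(f.M[x - 1, y - 1], vals["M"], atol=1e-12)

    def test_mirror_symmetry_negates_horizontal(self):
        rng = np.random.default_rng(4)
        xy = np.cumsum(rng.normal(0, 2, size=(300, 2)), axis=0)
        xy = np.clip(xy, -55, 55)
        lat = LatticeSpec(L=11, half_extent=60)
        f = field_from_counts(count_steps([rasterize(_traj_from_xy(xy), lat)], L=11))
        mirrored = xy.copy()
        mirrored[:, 0] *= -1
        fm = field_from_counts(
            count_steps([rasterize(_traj_from_xy(mirrored), lat)], L=11)
        )
        np.testing.assert_allclose(fm.M[..., 0], -f.M[::-1, :, 0], atol=1e-12)
        np.testing.assert_allclose(fm.M[..., 1], f.M[::-1, :, 1], atol=1e-12)


class TestBoxScaling:
    def test_straight_diameter_linear(self):
        xs = np.linspace(-59, 59, 3000)
        tr = _traj_from_xy(np.column_stack([xs, np.zeros_like(xs)]))
        counts, slope, r2 = box_scaling(tr, list(range(5, 31)))
        assert r2 > 0.999
        assert slope > 0

    def test_single_point_slope_zero(self):
        tr = _traj_from_xy([[1.0, 1.0], [1.0, 1.0]])
        counts, slope, r2 = box_scaling(tr, [5, 11, 21])
        assert np.all(counts == 1) and slope == 0.0

    def test_search_trajectory_scales_linearly(self, small_static_dataset):
        tr = small_static_dataset.trials[0].trajectory
        _, slope, r2 = box_scaling(tr, list(range(5, 31, 5)))
        assert r2 > 0.98
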