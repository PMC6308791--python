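import numpy as np
import pytest

from biokey import mdi
from biokey import signal_model as sm


def _mlrecord(leads, rate=100.0):
    return sm.MultiLeadRecord("x", "1", np.asarray(leads, float), rate)


def _seq(coords, values, u=32, order="lex"):
    return mdi.SparseElementSequence(
        np.asarray(coords, int), np.asarray(values, int), u=u, order=order
    )


class TestReduceMap:
    def test_zero_signal_maps_to_offset(self):
        rec = _mlrecord(np.zeros((2, 4)))
        pts = mdi.reduce_map(rec, mdi.ReductionSpec(R=1.0, delta_theta=20, u=32))
        assert (pts.points == 20).all()

    def test_lower_clamp(self):
        rec = _mlrecord(np.full((2, 3), -25.0))  # -25/1 + 20 = -5 -> 1
        pts = mdi.reduce_map(rec, mdi.ReductionSpec(R=1.0, delta_theta=20, u=32))
        assert (pts.points == 1).all()

    def test_upper_clamp(self):
        rec = _mlrecord(np.full((2, 3), 19.0))  # 19 + 20 = 39 -> u = 32
        pts = mdi.reduce_map(rec, mdi.ReductionSpec(R=1.0, delta_theta=20, u=32))
        assert (pts.points == 32).all()

    def test_round_half_up(self):
        rec = _mlrecord([[0.5, 1.49], [0.5, 1.49]])
        pts = mdi.reduce_map(rec, mdi.ReductionSpec(R=1.0, delta_theta=0, u=32))
        assert pts.points[0].tolist() == [1, 1]
        assert pts.points[1].tolist() == [1, 1]
        rec = _mlrecord([[2.5], [3.5]])
        pts = mdi.reduce_map(rec, mdi.ReductionSpec(R=1.0, delta_theta=0, u=32))
        assert pts.points[0].tolist() == [3, 4]

    def test_growing_u_only_unclamps(self):
        rec = _mlrecord(np.random.default_rng(0).normal(0, 5, size=(3, 50)))
        small = mdi.reduce_map(rec, mdi.ReductionSpec(R=1.0, delta_theta=10, u=16))
        large = mdi.reduce_map(rec, mdi.ReductionSpec(R=1.0, delta_theta=10, u=64))
        unclamped = small.points < 16
        assert np.array_equal(small.points[unclamped], large.points[unclamped])


class TestAccumulate:
    def test_identical_points_single_element(self):
        pts = mdi.PointSequence(np.full((9, 3), 7), u=32)
        seq = mdi.accumulate_sparse(pts)
        assert len(seq) == 1 and seq.values[0] == 9

    def test_distinct_points_unit_values(self):
        pts = mdi.PointSequence(np.arange(1, 13).reshape(4, 3), u=32)
        seq = mdi.accumulate_sparse(pts)
        assert len(seq) == 4 and (seq.values == 1).all()

    def test_occupancy_conservation(self):
        rng = np.random.default_rng(5)
        pts = mdi.PointSequence(rng.integers(1, 9, size=(300, 5)), u=32)
        assert mdi.accumulate_sparse(pts).total() == 300

    def test_time_order_preserves_first_occupancy(self):
        pts = mdi.PointSequence(np.array([[5, 5], [1, 1], [5, 5]]), u=8)
        seq = mdi.accumulate_sparse(pts, order="time")
        assert seq.coords[0].tolist() == [5, 5]
        assert seq.values.tolist() == [2, 1]

    def test_lex_order_is_sorted(self):
        rng = np.random.default_rng(6)
        pts = mdi.PointSequence(rng.integers(1, 5, size=(40, 3)), u=8)
        seq = mdi.accumulate_sparse(pts)
        rows = [tuple(c) for c in seq.coords]
        assert rows == sorted(rows)


class TestWindowReduce:
    def test_identity_at_m_one(self):
        seq = _seq([[1, 2], [3, 4]], [2, 3], u=8)
        assert mdi.window_reduce(seq, 1) == seq

    def test_coordinates_halved(self):
        rng = np.random.default_rng(7)
        pts = mdi.PointSequence(rng.integers(1, 33, size=(200, 5)), u=32)
        red = mdi.window_reduce(mdi.accumulate_sparse(pts), 2)
        assert red.u == 16
        assert red.coords.min() >= 1 and red.coords.max() <= 16

    def test_merge_conserves_and_shrinks(self):
        rng = np.random.default_rng(8)
        for m in (2, 3, 4):
            pts = mdi.PointSequence(rng.integers(1, 33, size=(150, 4)), u=32)
            seq = mdi.accumulate_sparse(pts)
            red = mdi.window_reduce(seq, m)
            assert red.total() == seq.total() == 150
            assert len(red) <= len(seq)
            # brute-force merge oracle
            expected = {}
            for coord, v in zip(seq.coords, seq.values):
                key = tuple(-(-int(c) // m) for c in coord)
                expected[key] = expected.get(key, 0) + int(v)
            got = {tuple(c): int(v) for c, v in zip(red.coords, red.values)}
            assert got == expected


def brute_force_dtw(a, b):
    """Minimum cumulative cost over all monotone alignment paths."""
    n, m = len(a), len(b)
    cost = {
        (i, j): float(((a[i] - b[j]) ** 2).sum())
        for i in range(n)
        for j in range(m)
    }
    best = {}

    def rec(i, j):
        if (i, j) in best:
            return best[(i, j)]
        if i == 0 and j == 0:
            val = cost[(0, 0)]
        else:
            prev = []
            if i > 0:
                prev.append(rec(i - 1, j))
            if j > 0:
                prev.append(rec(i, j - 1))
            if i > 0 and j > 0:
                prev.append(rec(i - 1, j - 1))
            val = cost[(i, j)] + min(prev)
        best[(i, j)] = val
        return val

    return rec(n - 1, m - 1)


class TestDtw:
    def test_identical_sequences_zero(self):
        seq = _seq([[1, 2], [3, 4], [5, 6]], [1, 2, 3], u=8)
        assert mdi.dtw_distance(seq, seq) == 0.0

    def test_equal_length_direct_sum(self):
        a = _seq([[1, 1], [4, 4]], [2, 5], u=8)
        b = _seq([[2, 1], [4, 6]], [2, 4], u=8)
        # position-wise squared Euclidean over (c1, c2, v)
        expected = (1 + 0 + 0) + (0 + 4 + 1)
        assert mdi.dtw_distance(a, b) == expected

    def test_unequal_lengths_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            la, lb = rng.integers(1, 6, size=2)
            while la == lb:
                lb = int(rng.integers(1, 6))
            ca = rng.integers(1, 9, size=(la, 3))
            cb = rng.integers(1, 9, size=(lb, 3))
            a = _seq(np.unique(ca, axis=0), [1] * len(np.unique(ca, axis=0)), u=8)
            b = _seq(np.unique(cb, axis=0), [1] * len(np.unique(cb, axis=0)), u=8)
            if len(a) == len(b):
                continue
            va = np.hstack([a.coords, a.values[:, None]]).astype(float)
            vb = np.hstack([b.coords, b.values[:, None]]).astype(float)
            assert mdi.dtw_distance(a, b) == pytest.approx(brute_force_dtw(va, vb))

    def test_symmetric_nonnegative(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            la, lb = rng.integers(1, 15, size=2)
            a = mdi.accumulate_sparse(
                mdi.PointSequence(rng.integers(1, 6, size=(la, 2)), u=8)
            )
            b = mdi.accumulate_sparse(
                mdi.PointSequence(rng.integers(1, 6, size=(lb, 2)), u=8)
            )
            d_ab = mdi.dtw_distance(a, b)
            assert d_ab >= 0.0
            assert d_ab == pytest.approx(mdi.dtw_distance(b, a))

    def test_value_component_optional(self):
        a = _seq([[1, 1]], [5], u=8)
        b = _seq([[1, 1]], [2], u=8)
        assert mdi.dtw_distance(a, b) == 9.0
        assert mdi.dtw_distance(a, b, include_value=False) == 0.0

    def test_empty_sequence_rejected(self):
        a = _seq([[1, 1]], [1], u=8)
        empty = mdi.SparseElementSequence(
            np.empty((0, 2), int), np.empty(0, int), u=8
        )
        with pytest.raises(ValueError):
            mdi.dtw_distance(a, empty)

    def test_mismatched_spaces_rejected(self):
        a = _seq([[1, 1]], [1], u=8)
        b = _seq([[1, 1]], [1], u=16)
        with pytest.raises(ValueError):
            mdi.dtw_distance(a, b)


class TestPipeline:
    def test_occupancy_invariant_through_chain(self, one_individual):
        rec = sm.simulate_multilead(one_individual, n_leads=5, duration_s=5, seed=2)
        spec = mdi.ReductionSpec()
        pts = mdi.reduce_map(rec, spec)
        for m in (1, 2, 4):
            seq = mdi.window_reduce(mdi.accumulate_sparse(pts), m)
            assert seq.total() == len(pts) == len(rec)

    def test_identify_own_template(self, one_individual):
        rec = sm.simulate_multilead(
            one_individual, n_leads=5, duration_s=5, seed=3, individual_id="me"
        )
        other = sm.simulate_multilead(
            sm.draw_individual(np.random.default_rng(99)),
            n_leads=5, duration_s=5, seed=4, individual_id="other",
        )
        ts = mdi.enroll_mdi([rec, other])
        best, dist, accept = mdi.mdi_identify(rec, ts, threshold=1.0)
        assert best == "me" and dist == 0.0 and accept

    def test_strict_zero_threshold_rejects_noisy_probe(self, one_individual):
        a = sm.simulate_multilead(one_individual, 5, 5, seed=5, individual_id="me")
        b = sm.simulate_multilead(one_individual, 5, 5, seed=6, individual_id="me")
        ts = mdi.enroll_mdi([a])
        _, dist, accept = mdi.mdi_identify(b, ts, threshold=0.0)
        assert dist > 0 and not accept

    def test_lead_count_mismatch_rejected(self, one_individual):
        a = sm.simulate_multilead(one_individual, 5, 5, seed=5)
        b = sm.simulate_multilead(one_individual, 3, 5, seed=5)
        ts = mdi.enroll_mdi([a])
        with pytest.raises(ValueError):
            mdi.mdi_identify(b, ts, threshold=1.0)

    def test_self_match_below_cross_match(self):
        within, between = [], []
        for seed in range(3):
            cohort = sm.simulate_multilead_cohort(
                n_individuals=5, duration_s=5.0, seed=seed
            )
            ts = mdi.enroll_mdi(cohort)
            for a, b, d in ts.training_scores:
                (within if a == b else between).append(d)
        assert np.mean(within) < np.mean(between)

    def test_element_text_round_trip(self, tmp_path, one_individual):
        rec = sm.simulate_multilead(one_individual, 4, 3, seed=1)
        seq = mdi.encode_session(rec, mdi.ReductionSpec())
        path = tmp_path / "x.elems"
        mdi.write_elements(path, seq)
        assert mdi.read_elements(path) == seq
        first = path.read_bytes()
        mdi.write_elements(path, mdi.read_elements(path))
        assert path.read_bytes() == first
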