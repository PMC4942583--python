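import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rubic
from rubic.break_stats import (
    AggregateProfile,
    NullConfig,
    ScalePair,
    aggregate,
    break_score,
    cyclic_shift,
    estimate_euler_curves,
    euler_characteristic,
    score_track,
    significance,
)
from rubic.data_io import CopyNumberMatrix, InputError
from conftest import make_probe_map
from _reference import brute_force_euler, brute_force_track, exhaustive_euler_curves


def _agg(values, chrom_sizes=None):
    values = np.asarray(values, dtype=float)
    pm = make_probe_map(chrom_sizes or {"chr1": len(values)})
    return AggregateProfile(values, pm, 1)


class TestAggregate:
    def test_sum_over_samples(self, probes2):
        m = CopyNumberMatrix(["a", "b"], np.tile([1.0, 2.0], (2, 5)), probes2)
        np.testing.assert_allclose(aggregate(m).values, np.tile([2.0, 4.0], 5))

    def test_single_sample_identity(self, probes2):
        v = np.arange(10.0)[None, :]
        np.testing.assert_allclose(aggregate(CopyNumberMatrix(["a"], v, probes2)).values, v[0])

    def test_sample_order_irrelevant(self, probes2):
        v = np.random.default_rng(0).normal(size=(3, 10))
        m1 = CopyNumberMatrix(["a", "b", "c"], v, probes2)
        m2 = CopyNumberMatrix(["c", "b", "a"], v[::-1], probes2)
        np.testing.assert_allclose(aggregate(m1).values, aggregate(m2).values)


class TestBreakScore:
    def test_step_profile(self):
        agg = _agg([1, 1, 1, 5, 5, 5])
        assert break_score(agg, 3, ScalePair(3, 3)) == pytest.approx(4.0)

    def test_constant_profile_zero_everywhere(self):
        agg = _agg([2.0] * 8)
        for g0 in range(1, 8):
            w = min(g0, 8 - g0)
            assert break_score(agg, g0, (w, w)) == 0.0

    def test_single_probe_windows(self):
        assert break_score(_agg([0, 2]), 1, (1, 1)) == pytest.approx(2.0)

    def test_window_crossing_chromosome_is_error(self):
        agg = _agg(np.arange(10.0), {"chr1": 6, "chr2": 4})
        with pytest.raises(InputError):
            break_score(agg, 5, (2, 2))  # right window would cross into chr2
        with pytest.raises(InputError):
            break_score(agg, 6, (1, 1))  # chromosome boundary itself


class TestScoreTrack:
    def test_flat_profile_all_zero(self):
        tr = score_track(_agg([3.0] * 12, {"chr1": 7, "chr2": 5}), (2, 2))
        assert all((v == 0).all() for v in tr.values)

    def test_track_length_per_chromosome(self):
        tr = score_track(_agg(np.arange(12.0), {"chr1": 7, "chr2": 5}), (2, 3))
        assert [len(v) for v in tr.values] == [7 - 2 - 3 + 1, 5 - 2 - 3 + 1]

    def test_short_chromosome_empty(self):
        tr = score_track(_agg(np.arange(9.0), {"chr1": 6, "chr2": 3}), (2, 2))
        assert len(tr.values[1]) == 0

    def test_single_step_maximal_at_step(self):
        v = [0.0] * 10 + [4.0] * 10
        tr = score_track(_agg(v), (3, 3))
        expect = brute_force_track(np.array(v), 3, 3)
        np.testing.assert_allclose(tr.values[0], expect)
        assert tr.boundaries[0][np.argmax(np.abs(tr.values[0]))] == 10


class TestEulerCharacteristic:
    @pytest.mark.parametrize(
        "track,t0,expect",
        [([0, 2, 0, -2, 0], 1, 2), ([0, 0, 0], 1, 0), ([3, 3, 3], 1, 1)],
    )
    def test_examples(self, track, t0, expect):
        assert euler_characteristic(np.array(track, dtype=float), t0) == expect

    @settings(deadline=None, max_examples=100)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=1000),
        st.floats(0, 4, allow_nan=False),
    )
    def test_matches_brute_force(self, track, t0):
        track = np.asarray(track)
        assert euler_characteristic(track, t0) == brute_force_euler(track, t0)

    def test_runs_do_not_span_chromosomes(self):
        parts = [np.array([2.0, 2.0]), np.array([2.0, 2.0])]
        assert euler_characteristic(parts, 1.0) == 2

    def test_negative_threshold_rejected(self):
        with pytest.raises(InputError):
            euler_characteristic(np.zeros(3), -1.0)


class TestCyclicShift:
    def test_zero_offset_identity(self, probes2):
        m = CopyNumberMatrix(["a"], np.arange(10.0)[None, :], probes2)
        np.testing.assert_array_equal(cyclic_shift(m, [0]).values, m.values)

    def test_rotation_convention(self):
        pm = make_probe_map({"chr1": 3})
        m = CopyNumberMatrix(["a"], np.array([[1.0, 2.0, 3.0]]), pm)
        np.testing.assert_array_equal(cyclic_shift(m, [1]).values, [[3.0, 1.0, 2.0]])

    def test_multiset_and_total_preserved(self, probes2):
        rng = np.random.default_rng(3)
        m = CopyNumberMatrix(["a", "b"], rng.normal(size=(2, 10)), probes2)
        shifted = cyclic_shift(m, [4, 9])
        for r in range(2):
            np.testing.assert_allclose(
                np.sort(shifted.values[r]), np.sort(m.values[r])
            )
        assert shifted.values.sum() == pytest.approx(m.values.sum())

    def test_break_multiset_invariant(self):
        # run-length jump values are preserved up to the wrap-around break
        pm = make_probe_map({"chr1": 8})
        row = np.array([0.0, 0.0, 2.0, 2.0, 2.0, 1.0, 1.0, 0.0])
        m = CopyNumberMatrix(["a"], row[None, :], pm)
        for off in range(8):
            v = cyclic_shift(m, [off]).values[0]
            jumps = sorted(np.diff(np.concatenate([v, v[:1]])))
            assert jumps == sorted(np.diff(np.concatenate([row, row[:1]])))


class TestEstimateEulerCurves:
    def test_exhaustive_matches_enumeration(self):
        rng = np.random.default_rng(1)
        pm = make_probe_map({"chr1": 14, "chr2": 10})
        row = rng.normal(size=24)
        m = CopyNumberMatrix(["s1"], row[None, :], pm)
        thr = np.linspace(0.0, 3.0, 16)
        tab = estimate_euler_curves(
            m,
            NullConfig(
                seed=0, exhaustive=True, scale_grid=np.array([1, 2, 4]), threshold_grid=thr
            ),
        )
        pairs = [(a, b) for i, a in enumerate([1, 2, 4]) for b in [1, 2, 4][i:]]
        expect = exhaustive_euler_curves(row, pm, pairs, thr)
        np.testing.assert_allclose(tab.raw_curves, expect)

    def test_per_pair_threshold_grids(self, toy_table):
        # every pair carries its own grid spanning its own null |t| range
        thr = toy_table.thresholds
        assert thr.ndim == 2 and thr.shape[0] == len(toy_table.curves)
        assert (thr[:, 0] == 0).all() and (np.diff(thr, axis=1) > 0).all()
        assert len({float(x) for x in thr[:, -1]}) > 1  # grids genuinely differ

    def test_monotone_in_threshold(self, toy_table):
        assert (np.diff(toy_table.curves, axis=1) <= 1e-12).all()
        assert (toy_table.curves >= 0).all()

    def test_seeded_determinism(self, toy_cohort):
        gains, _ = rubic.split_gains_losses(toy_cohort)
        t1 = estimate_euler_curves(gains, NullConfig(n_perm=1, seed=9))
        t2 = estimate_euler_curves(gains, NullConfig(n_perm=1, seed=9))
        np.testing.assert_array_equal(t1.raw_curves, t2.raw_curves)

    def test_oversized_scales_dropped(self, toy_cohort):
        gains, _ = rubic.split_gains_losses(toy_cohort)
        tab = estimate_euler_curves(
            gains, NullConfig(n_perm=2, seed=0, scale_grid=np.array([1, 2, 10_000]))
        )
        assert tab.scales.tolist() == [1, 2]

    def test_cache_roundtrip(self, toy_cohort, tmp_path):
        gains, _ = rubic.split_gains_losses(toy_cohort)
        cfg = NullConfig(n_perm=3, seed=5)
        t1 = estimate_euler_curves(gains, cfg, cache_path=tmp_path / "t.json")
        t2 = estimate_euler_curves(gains, cfg, cache_path=tmp_path / "t.json")
        np.testing.assert_array_equal(t1.curves, t2.curves)
        assert t1.significance(1.3, 2, 5) == t2.significance(1.3, 2, 5)


class TestSignificance:
    def test_t0_equals_tabulated(self, toy_table):
        r = toy_table.pair_row(2, 4)
        assert toy_table.significance(0.0, 2, 4) == pytest.approx(toy_table.curves[r, 0])

    def test_monotone_in_t(self, toy_table):
        ts = np.linspace(0, 3 * toy_table.thresholds.max(), 200)
        vals = [toy_table.significance(t, 3, 7) for t in ts]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_symmetric_in_scales(self, toy_table):
        for t in (0.0, 0.7, 5.0):
            for wl, wr in [(1, 8), (3, 5), (2, 100)]:
                assert toy_table.significance(t, wl, wr) == toy_table.significance(t, wr, wl)

    def test_fit_disabled_equals_tabulated_mean(self, toy_cohort):
        gains, _ = rubic.split_gains_losses(toy_cohort)
        tab = estimate_euler_curves(gains, NullConfig(n_perm=10, seed=2, fit_tail=False))
        for wl, wr in [(1, 1), (2, 8)]:
            r = tab.pair_row(wl, wr)
            for k in [0, 5, 20]:
                if tab.curves[r, k] > 0:
                    assert significance(tab, tab.thresholds[r, k], (wl, wr)) == pytest.approx(
                        tab.curves[r, k]
                    )

    def test_out_of_grid_scales_clamped(self, toy_table):
        big = max(toy_table.scales)
        assert toy_table.significance(1.0, big * 4, big * 4) == toy_table.significance(
            1.0, big, big
        )
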