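import logging

import numpy as np
import pandas as pd
import pytest

import rubic
from rubic.break_stats import NullConfig
from rubic.calling import (
    CallingConfig,
    adaptive_threshold,
    call_local_maxima,
    refine_null,
    run_rubic,
)
from rubic.data_io import CopyNumberMatrix, InputError
from rubic.segmentation import SegmentationResult
from conftest import make_probe_map


def _seg_result(amplitudes, widths=None, chrom_sizes=None, E=10.0, probes=None):
    """Build a SegmentationResult from per-segment amplitudes on one chromosome."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    widths = np.asarray(widths if widths is not None else [2] * len(amplitudes))
    P = int(widths.sum())
    probes = probes or make_probe_map(chrom_sizes or {"chr1": P})
    starts = np.concatenate(([0], np.cumsum(widths)[:-1]))
    ends = np.cumsum(widths)
    jumps = np.diff(amplitudes)
    return SegmentationResult(
        probes=probes,
        E=E,
        seg_chrom=np.array(["chr1"] * len(amplitudes), dtype=object),
        seg_start=starts,
        seg_end=ends,
        amplitude=amplitudes,
        bound_pos=ends[:-1],
        bound_jump=jumps,
        bound_sig=np.full(len(jumps), 0.1),
    )


class TestCallLocalMaxima:
    def test_interior_peak_called(self):
        regions = call_local_maxima(_seg_result([1.0, 3.0, 2.0]))
        assert len(regions) == 1
        r = regions.iloc[0]
        assert r["amplitude"] == 3.0
        assert (r["_start_probe"], r["_end_probe"]) == (2, 4)
        # bp extent: first base of first probe to base before next probe
        assert (r["start"], r["end"]) == (200, 400)

    def test_monotone_profile_no_calls(self):
        # terminal segments lack one bounding break and are never called
        assert len(call_local_maxima(_seg_result([1.0, 2.0, 3.0]))) == 0

    def test_flat_single_segment_no_calls(self):
        assert len(call_local_maxima(_seg_result([2.0]))) == 0

    def test_valley_not_called(self):
        assert len(call_local_maxima(_seg_result([3.0, 1.0, 2.5]))) == 0

    def test_interior_shoulder_not_called(self):
        # monotone rise then fall: only the summit qualifies
        regions = call_local_maxima(_seg_result([1.0, 2.0, 4.0, 3.0, 0.5]))
        assert list(regions["amplitude"]) == [4.0]

    def test_direction_label(self):
        regions = call_local_maxima(_seg_result([0.0, 5.0, 1.0]), direction="loss")
        assert set(regions["direction"]) == {"loss"}

    def test_both_bounding_sigs_reported(self):
        regions = call_local_maxima(_seg_result([1.0, 3.0, 2.0]))
        r = regions.iloc[0]
        assert r["_left_bound"] == 2 and r["_right_bound"] == 4
        assert r["left_sig"] == 0.1 and r["right_sig"] == 0.1


class TestAdaptiveThreshold:
    def test_worked_example_stable_100_regions(self):
        calls = []

        def stub(E):
            calls.append(E)
            return pd.DataFrame({"i": range(100)})

        E, regions = adaptive_threshold(stub, CallingConfig(fdr=0.25))
        assert E == 50.0
        assert len(regions) == 100
        assert calls[0] == 0.5  # started from E0 = 2 x FDR

    def test_empty_at_initial_threshold(self):
        E, regions = adaptive_threshold(lambda E: pd.DataFrame(), CallingConfig(fdr=0.25))
        assert E == 0.5 and len(regions) == 0

    def test_tiny_fdr_limit(self):
        E, regions = adaptive_threshold(lambda E: pd.DataFrame(), CallingConfig(fdr=1e-6))
        assert E == pytest.approx(2e-6) and len(regions) == 0

    def test_oscillation_returns_smaller_count(self, caplog):
        def stub(E):
            # counts cycle 10 -> 20 -> 10 as E walks 0.5 -> 5 -> 10
            if E <= 0.5 or E > 5:
                n = 10
            else:
                n = 20
            return pd.DataFrame({"i": range(n)})

        with caplog.at_level(logging.WARNING, logger="rubic.calling"):
            E, regions = adaptive_threshold(stub, CallingConfig(fdr=0.25))
        assert len(regions) == 10
        assert any("oscillat" in r.message for r in caplog.records)

    def test_growth_converges(self):
        def stub(E):
            return pd.DataFrame({"i": range(min(50, max(1, int(E * 20))))})

        E, regions = adaptive_threshold(stub, CallingConfig(fdr=0.25))
        assert len(regions) == 50 and E == 25.0


class TestRefineNull:
    def _m(self, rows, chrom_sizes):
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        pm = make_probe_map(chrom_sizes)
        return CopyNumberMatrix([f"s{i}" for i in range(len(rows))], rows, pm, "gains")

    def test_no_breaks_in_windows_unchanged(self):
        m = self._m([[0, 0, 2, 2]], {"chr1": 4})
        out = refine_null(m, [1])  # window at boundary 1; sample break is at 2
        np.testing.assert_array_equal(out.values, m.values)

    def test_break_removed_by_weighted_mean(self):
        m = self._m([[0, 0, 2, 2]], {"chr1": 4})
        out = refine_null(m, [2])
        np.testing.assert_allclose(out.values, [[1, 1, 1, 1]])

    def test_weighted_mean_uses_lengths(self):
        m = self._m([[0, 0, 0, 4]], {"chr1": 4})
        out = refine_null(m, [3])
        np.testing.assert_allclose(out.values, [[1, 1, 1, 1]])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        row = np.repeat(rng.normal(size=5), [3, 2, 4, 1, 2])
        m = self._m([row], {"chr1": 12})
        once = refine_null(m, [3, 9])
        twice = refine_null(once, [3, 9])
        np.testing.assert_array_equal(once.values, twice.values)

    def test_chromosome_edges_never_merged(self):
        m = self._m([[1, 1, 5, 5]], {"chr1": 2, "chr2": 2})
        out = refine_null(m, [2])  # boundary 2 is the chr1/chr2 junction
        np.testing.assert_array_equal(out.values, m.values)

    def test_margin_widens_window(self):
        m = self._m([[0, 0, 2, 2]], {"chr1": 4})
        assert np.allclose(refine_null(m, [1], margin=1).values, [[1, 1, 1, 1]])


class TestRunRubic:
    @pytest.fixture(scope="class")
    @staticmethod
    def driver_cohort():
        genome = rubic.GenomeModel(("chr1", "chr2"), (20_000_000, 15_000_000), probe_spacing=200_000)
        m, probes, drivers = rubic.simulate_cohort(
            10, genome=genome, n_drivers=5, seed=7, coeff_sd=3.0
        )
        return m, probes, drivers

    def test_mirror_symmetry(self, driver_cohort):
        """The loss pipeline on negated data reproduces the gain calls exactly."""
        m, _, _ = driver_cohort
        neg = CopyNumberMatrix(m.sample_ids, -m.values, m.probes)
        cfg = CallingConfig(fdr=0.25, require_gene_overlap=False, max_region_width=None)
        ncfg = NullConfig(n_perm=20, seed=5)
        g1, l1, _ = run_rubic(m, cfg=cfg, null_cfg=ncfg)
        g2, l2, _ = run_rubic(neg, cfg=cfg, null_cfg=ncfg)
        cols = ["chrom", "start", "end", "amplitude", "left_sig", "right_sig"]
        pd.testing.assert_frame_equal(
            g1[cols].reset_index(drop=True), l2[cols].reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(
            l1[cols].reset_index(drop=True), g2[cols].reset_index(drop=True)
        )

    def test_strong_driver_recovered(self):
        genome = rubic.GenomeModel(("chr1", "chr2"), (20_000_000, 15_000_000), probe_spacing=200_000)
        drivers = rubic.DriverSet(
            rubic.GeneTable(
                np.array(["onc"], dtype=object),
                np.array(["chr1"], dtype=object),
                np.array([8_000_000]),
                np.array([8_300_000]),
            ),
            np.array([10.0]),
        )
        m, probes, _ = rubic.simulate_cohort(20, genome=genome, drivers=drivers, seed=11)
        cfg = CallingConfig(fdr=0.25, require_gene_overlap=False, max_region_width=None)
        gains, _, _ = run_rubic(m, cfg=cfg, null_cfg=NullConfig(n_perm=20, seed=3))
        hit = (
            (gains["chrom"] == "chr1")
            & (gains["start"] < 8_300_000)
            & (gains["end"] > 8_000_000)
        )
        assert hit.any()

    def test_filters_and_annotation(self, driver_cohort):
        m, probes, drivers = driver_cohort
        cfg = CallingConfig(fdr=0.25, require_gene_overlap=True, max_region_width=None)
        gains, losses, report = run_rubic(
            m, genes=drivers.genes, cfg=cfg, null_cfg=NullConfig(n_perm=20, seed=5)
        )
        for df in (gains, losses):
            assert all(len(g) > 0 for g in df["genes"])
        assert report["gain"]["n_regions_prefilter"] >= len(gains)

    def test_report_structure(self, driver_cohort):
        m, probes, drivers = driver_cohort
        cfg = CallingConfig(fdr=0.25, require_gene_overlap=False, max_region_width=None)
        _, _, report = run_rubic(m, cfg=cfg, null_cfg=NullConfig(n_perm=10, seed=1))
        for d in ("gain", "loss"):
            assert report[d]["rounds"][0]["trajectory"][0][0] == 0.5
            assert "E_final" in report[d]
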