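"""Scan planning: dose arithmetic, pattern geometry, gating and accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lilack.colony_sim import DIFF, UNDIFF, LabelMask
from lilack.patch_cnn import ProbabilityMap
from lilack.scan_planner import (
    CircleRegion,
    LaserParams,
    RectRegion,
    dose_per_length,
    energy_flux,
    gate_path,
    path_stats,
    plan_pattern,
    read_path,
    skip_empty_lines,
    throughput,
    write_path,
)


class TestDoseModel:
    def test_reference_dose_and_flux(self):
        assert dose_per_length(1.0, 100.0) == pytest.approx(0.01)
        assert energy_flux(1.0, 100.0, 50.0) == pytest.approx(0.2)

    def test_zero_power_zero_dose(self):
        assert dose_per_length(0.0, 123.0) == 0.0

    def test_iso_dose_power_speed_pairs(self):
        pairs = [(2.5, 500.0), (2.0, 400.0), (1.6, 320.0), (1.0, 200.0)]
        doses = {dose_per_length(p, v) for p, v in pairs}
        assert len(doses) == 1
        fluxes = [energy_flux(p, v, 50.0) for p, v in pairs]
        assert np.allclose(fluxes, fluxes[0])

    def test_flux_linear_in_power(self):
        assert energy_flux(3.0, 100.0, 50.0) == pytest.approx(3 * energy_flux(1.0, 100.0, 50.0))

    def test_flux_consistent_with_dose_over_width(self):
        assert energy_flux(0.8, 100.0, 50.0) == pytest.approx(
            dose_per_length(0.8, 100.0) / 0.05
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            dose_per_length(1.0, 0.0)
        with pytest.raises(ValueError):
            energy_flux(1.0, 100.0, -1.0)


class TestThroughput:
    def test_cells_per_second_claims(self):
        assert throughput(100.0, 10.0) == pytest.approx(10_000)
        assert throughput(1000.0, 10.0) == pytest.approx(100_000)

    def test_inverse_in_cell_diameter(self):
        assert throughput(100.0, 20.0) == pytest.approx(throughput(100.0, 10.0) / 2)


class TestPlanPattern:
    def test_lattice_line_count_over_square(self):
        L, d = 1000.0, 90.0
        laser = LaserParams(1.0, 100.0, 50.0, d)
        path = plan_pattern("lattice", RectRegion(0, 0, L, L), laser)
        assert len(path.segments) == 2 * (int(L // d) + 1)

    def test_raster_chord_sum_approaches_area_over_interval(self):
        d_um = 100.0
        region = CircleRegion.from_area_cm2(1.0)
        laser = LaserParams(1.0, 100.0, 50.0, d_um)
        path = plan_pattern("raster", region, laser)
        total_um = sum(s.length_um for s in path.segments)
        expected_um = 1.0e8 / d_um  # area / interval
        assert total_um == pytest.approx(expected_um, rel=0.01)

    def test_line_kind_single_segment(self):
        laser = LaserParams(1.0, 100.0)
        path = plan_pattern("line", RectRegion(0, 0, 500, 500), laser)
        assert len(path.segments) == 1

    def test_interval_larger_than_region_yields_single_line(self):
        laser = LaserParams(1.0, 100.0, 50.0, 1e6)
        path = plan_pattern("raster", RectRegion(0, 0, 400, 400), laser)
        assert len(path.segments) == 1

    def test_planned_segments_fully_on(self):
        laser = LaserParams(1.0, 100.0)
        path = plan_pattern("raster", RectRegion(0, 0, 300, 300), laser)
        for s in path.segments:
            assert s.on_length_um() == pytest.approx(s.length_um)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            RectRegion(0, 0, 0, 0)


class TestGating:
    @staticmethod
    def _square_mask(size=400, lo=100, hi=301):
        # rows/cols 100..300 inclusive: a 200 µm square at 1 µm/px
        lab = np.full((size, size), UNDIFF, dtype=np.uint8)
        lab[lo:hi, lo:hi] = DIFF
        return LabelMask(lab, 1.0)

    def test_threshold_zero_fully_on(self):
        probs = ProbabilityMap(np.random.default_rng(0).random((200, 200)), 1.0)
        laser = LaserParams(1.0, 100.0, 50.0, 40.0)
        path = plan_pattern("raster", RectRegion(0, 0, 199, 199), laser)
        gated = gate_path(path, probs, threshold=0.0)
        for s in gated.segments:
            assert s.on_length_um() == pytest.approx(s.length_um, abs=1.0)

    def test_threshold_above_one_fully_off(self):
        probs = ProbabilityMap(np.random.default_rng(0).random((200, 200)), 1.0)
        laser = LaserParams(1.0, 100.0, 50.0, 40.0)
        path = plan_pattern("raster", RectRegion(0, 0, 199, 199), laser)
        gated = gate_path(path, probs, threshold=1.1)
        assert all(not s.on_intervals for s in gated.segments)

    def test_square_target_on_length_matches_geometry(self):
        """200 µm square target under a 25 µm raster: without dilation the ON
        arc length is (200/25 + 1) lines x 200 µm."""
        mask = self._square_mask()
        laser = LaserParams(0.8, 100.0, 50.0, 25.0)
        path = plan_pattern("raster", RectRegion(0, 0, 399, 399), laser)
        gated = gate_path(path, mask, threshold=0.5, dilate_um=0.0)
        total_on = sum(s.on_length_um() for s in gated.segments)
        n_lines = 200 // 25 + 1
        assert total_on == pytest.approx(n_lines * 200.0, rel=0.05)

    def test_dilation_extends_coverage_by_half_beam(self):
        mask = self._square_mask()
        laser = LaserParams(0.8, 100.0, 50.0, 25.0)
        path = plan_pattern("raster", RectRegion(0, 0, 399, 399), laser)
        bare = sum(s.on_length_um() for s in gate_path(path, mask, dilate_um=0.0).segments)
        dilated = sum(s.on_length_um() for s in gate_path(path, mask).segments)
        assert dilated > bare
        # dilated coverage approx (250/25 + 1) lines x 250 µm
        assert dilated == pytest.approx((250 // 25 + 1) * 250.0, rel=0.1)

    def test_gating_conserves_energy_bound(self):
        mask = self._square_mask()
        laser = LaserParams(0.8, 100.0, 50.0, 25.0)
        path = plan_pattern("raster", RectRegion(0, 0, 399, 399), laser)
        gated = gate_path(path, mask, threshold=0.5)
        assert path_stats(gated).delivered_energy_J <= path_stats(path).delivered_energy_J
        assert sum(s.on_length_um() for s in gated.segments) <= sum(
            s.length_um for s in path.segments
        )

    @given(thr_lo=st.floats(0.1, 0.5), thr_delta=st.floats(0.0, 0.4))
    @settings(max_examples=15, deadline=None)
    def test_lower_threshold_never_decreases_on_length(self, thr_lo, thr_delta):
        rng = np.random.default_rng(7)
        probs = ProbabilityMap(rng.random((120, 120)), 1.0)
        laser = LaserParams(1.0, 100.0, 50.0, 30.0)
        path = plan_pattern("raster", RectRegion(0, 0, 119, 119), laser)
        lo = sum(s.on_length_um() for s in
                 gate_path(path, probs, thr_lo, dilate_um=0.0).segments)
        hi = sum(s.on_length_um() for s in
                 gate_path(path, probs, thr_lo + thr_delta, dilate_um=0.0).segments)
        assert lo >= hi

    def test_skip_empty_lines_drops_only_off_segments(self):
        mask = self._square_mask()
        laser = LaserParams(0.8, 100.0, 50.0, 25.0)
        path = plan_pattern("raster", RectRegion(0, 0, 399, 399), laser)
        gated = gate_path(path, mask, dilate_um=0.0)
        shortened = skip_empty_lines(gated)
        assert len(shortened.segments) < len(gated.segments)
        assert sum(s.on_length_um() for s in shortened.segments) == pytest.approx(
            sum(s.on_length_um() for s in gated.segments)
        )


class TestPathStats:
    def test_single_line_time(self):
        laser = LaserParams(1.0, 100.0)
        path = plan_pattern("line", RectRegion(0, 0, 30_000.0, 100.0), laser)
        assert path_stats(path).total_time_s == pytest.approx(0.3)

    def test_turnaround_overhead_counted(self):
        laser = LaserParams(1.0, 100.0, 50.0, 100.0)
        path = plan_pattern("raster", RectRegion(0, 0, 1000.0, 1000.0), laser)
        t0 = path_stats(path).total_time_s
        path.turnaround_s = 0.1
        t1 = path_stats(path).total_time_s
        assert t1 == pytest.approx(t0 + 0.1 * (len(path.segments) - 1))

    def test_delivered_energy_identity(self):
        """delivered energy equals power x active length / speed."""
        laser = LaserParams(0.8, 100.0, 50.0, 25.0)
        path = plan_pattern("raster", RectRegion(0, 0, 2000.0, 500.0), laser)
        st_ = path_stats(path)
        assert st_.delivered_energy_J == pytest.approx(
            0.8 * st_.active_length_mm / 100.0
        )
        assert st_.dose_J_per_mm == pytest.approx(0.008)

    def test_roundtrip_io(self, tmp_path):
        laser = LaserParams(0.8, 100.0, 50.0, 25.0)
        path = plan_pattern("raster", RectRegion(0, 0, 500.0, 200.0), laser)
        write_path(tmp_path / "p", path)
        back = read_path(tmp_path / "p")
        assert len(back.segments) == len(path.segments)
        assert path_stats(back).total_time_s == pytest.approx(
            path_stats(path).total_time_s
        )
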