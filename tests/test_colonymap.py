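"""Sliding-window mapping, coverage percentages, calibration, compilation."""

import numpy as np
import pandas as pd
import pytest

from coralrhythm.colonymap import (
    ChlCalibration,
    StatusMap,
    calibrate_chlorophyll,
    compile_series,
    segment_frame,
    status_percentages,
    truth_to_grid,
)
from coralrhythm.fixtures import (
    CLASS_IDS,
    SeriesSpec,
    generate_colony_image,
    generate_series,
    scene_for_coverage,
    truth_percentages,
)


class _MeanColorStub:
    """Cheap deterministic stand-in classifier: softmax from window mean color."""

    def predict_proba(self, patches):
        x = np.asarray(patches, dtype=float)
        red = x[..., 0].mean(axis=(1, 2))
        green = x[..., 1].mean(axis=(1, 2))
        logits = np.stack([
            -red / 32.0,              # background: dark
            (red - 120) / 16.0,       # bloated: bright red
            green / 64.0 - 1.0,       # semi
            (red - 60) / 16.0 - 1.0,  # non-bloated
        ], axis=1)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)


class TestSegmentFrame:
    @pytest.mark.parametrize("h,w,window,step,g1,g2", [
        (100, 80, 30, 10, 8, 6),
        (30, 30, 30, 10, 1, 1),
        (2751, 2206, 30, 10, 273, 218),  # full observatory frame geometry
    ])
    def test_grid_dimensions_follow_stride_formula(self, h, w, window, step, g1, g2):
        if h > 500:  # large frame: check the arithmetic without rendering it
            assert ((h - window) // step + 1, (w - window) // step + 1) == (g1, g2)
            return
        img = np.zeros((h, w, 3), np.uint8)
        smap = segment_frame(img, _MeanColorStub(), window, step)
        assert smap.grid.shape == (g1, g2)

    def test_step_equal_window_matches_independent_classification(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (120, 90, 3), dtype=np.uint8)
        stub = _MeanColorStub()
        smap = segment_frame(img, stub, window=30, step=30)
        for i in range(smap.grid.shape[0]):
            for j in range(smap.grid.shape[1]):
                win = img[i * 30 : i * 30 + 30, j * 30 : j * 30 + 30]
                probs = stub.predict_proba(win[None])
                assert smap.grid[i, j] == probs.argmax()

    def test_fixture_frame_cell_agreement(self, trained_model):
        spec = scene_for_coverage(65.0, 15.0, seed=99)
        img, truth = generate_colony_image(spec)
        smap = segment_frame(img, trained_model)
        tgrid = truth_to_grid(truth)
        assert (smap.grid == tgrid.grid).mean() >= 0.85

    def test_fixture_bloated_percentage_within_tolerance(self, trained_model, two_band_scene):
        _, img, truth = two_band_scene
        smap = segment_frame(img, trained_model)
        blo, semi, non, empty = status_percentages(smap)
        assert not empty
        assert abs(blo - truth_percentages(truth)["bloated"]) <= 5.0

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError, match="step"):
            segment_frame(np.zeros((40, 40, 3), np.uint8), _MeanColorStub(), 30, 0)


class TestStatusPercentages:
    def test_fraction_arithmetic(self):
        grid = np.array([CLASS_IDS["bloated"]] * 300 + [CLASS_IDS["non_bloated"]] * 100).reshape(20, 20)
        blo, semi, non, empty = status_percentages(StatusMap(grid, 30, 10))
        assert (blo, semi, non, empty) == (75.0, 0.0, 25.0, False)

    def test_all_background_flagged(self):
        blo, semi, non, empty = status_percentages(StatusMap(np.zeros((4, 4), int), 30, 10))
        assert empty and (blo, semi, non) == (0.0, 0.0, 0.0)

    def test_invariant_to_transpose_and_flip(self):
        rng = np.random.default_rng(1)
        grid = rng.integers(0, 4, (15, 9))
        base = status_percentages(StatusMap(grid, 30, 10))
        for g in (grid.T, grid[::-1], grid[:, ::-1]):
            assert status_percentages(StatusMap(g, 30, 10)) == base

    def test_percentages_sum_to_100_with_coral(self):
        rng = np.random.default_rng(2)
        grid = rng.integers(1, 4, (10, 10))
        blo, semi, non, _ = status_percentages(StatusMap(grid, 30, 10))
        assert blo + semi + non == pytest.approx(100.0, abs=1e-9)


class TestChlorophyllCalibration:
    @pytest.mark.parametrize("fl,t,expected", [
        (0.0, "2018-04-23 12:00", 1.0129),   # day intercept
        (1.0, "2018-04-23 12:00", 2.0629),   # 1.050*1 + 1.0129
        (2.0, "2018-04-23 23:00", 2.1419),   # 0.963*2 + 0.2159
    ])
    def test_published_formula_values(self, fl, t, expected):
        assert calibrate_chlorophyll(fl, np.datetime64(t)) == pytest.approx(expected, abs=1e-9)

    def test_day_window_boundaries(self):
        cal = ChlCalibration()
        at = lambda clock: calibrate_chlorophyll(0.0, np.datetime64(f"2018-04-23 {clock}"), cal)
        assert at("06:00") == pytest.approx(cal.day_intercept)    # dawn starts the day
        assert at("05:59") == pytest.approx(cal.night_intercept)
        assert at("21:30") == pytest.approx(cal.night_intercept)  # dusk ends it
        assert at("21:29") == pytest.approx(cal.day_intercept)

    def test_vectorized_over_series(self):
        ts = pd.date_range("2018-03-01", periods=48, freq="1h")
        out = calibrate_chlorophyll(np.ones(48), ts.to_numpy())
        assert out.shape == (48,)
        assert {round(v, 4) for v in out} == {2.0629, 1.1789}

    def test_negative_fluorescence_rejected(self):
        with pytest.raises(ValueError, match="fluorescence"):
            calibrate_chlorophyll(-1.0, np.datetime64("2018-03-01 12:00"))


def _toy_map(bloated_cells: int, total: int = 4) -> StatusMap:
    grid = np.full(total, CLASS_IDS["non_bloated"])
    grid[:bloated_cells] = CLASS_IDS["bloated"]
    return StatusMap(grid.reshape(2, -1), 30, 10)


class TestCompileSeries:
    def test_exact_timestamp_join(self):
        ocean = generate_series(SeriesSpec(n_hours=24, seed=0))
        frames = [(ocean.index[3], _toy_map(2))]
        out = compile_series(frames, ocean)
        assert len(out) == 1
        assert out.iloc[0]["temperature_C"] == pytest.approx(ocean.iloc[3]["temperature_C"])
        assert out.iloc[0]["bloated_pct"] == 50.0

    def test_sensor_gap_keeps_behavior_only(self):
        ocean = generate_series(SeriesSpec(
            n_hours=48, gap_windows=(("2018-02-02 05:00", "2018-02-02 20:00"),), seed=1))
        frames = [(ocean.index[10], _toy_map(1))]  # inside the gap
        out = compile_series(frames, ocean)
        assert np.isnan(out.iloc[0]["temperature_C"])
        assert out.iloc[0]["bloated_pct"] == 25.0

    def test_no_match_beyond_tolerance(self):
        ocean = generate_series(SeriesSpec(n_hours=24, seed=2))
        far = ocean.index[-1] + pd.Timedelta("6h")
        out = compile_series([(far, _toy_map(1))], ocean, tolerance="30min")
        assert np.isnan(out.iloc[0]["salinity_PSU"])

    def test_duplicate_timestamps_rejected(self):
        t = pd.Timestamp("2018-02-02 10:30")
        with pytest.raises(ValueError, match="duplicate"):
            compile_series([(t, _toy_map(1)), (t, _toy_map(2))], None)

    def test_many_frames_sorted_and_complete(self):
        ocean = generate_series(SeriesSpec(n_hours=96, seed=3))
        frames = [(ocean.index[i], _toy_map(i % 5)) for i in range(72)][::-1]  # shuffled in
        out = compile_series(frames, ocean, chl_cal=ChlCalibration())
        assert len(out) == 72
        assert out.index.is_monotonic_increasing
        assert "chl_a" in out.columns and out["chl_a"].notna().all()


class TestTruthToGrid:
    def test_anchor_pixel_labels(self):
        truth = np.zeros((60, 60), np.uint8)
        truth[10:40, 10:40] = CLASS_IDS["bloated"]
        grid = truth_to_grid(truth, window=30, step=10).grid
        assert grid.shape == (4, 4)
        assert grid[0, 0] == truth[15, 15]
        assert grid[2, 2] == truth[35, 35]
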