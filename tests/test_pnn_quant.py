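"""Rolling-ball background, per-ROI intensity and PV classification."""

import numpy as np
import pandas as pd
import pytest
from matplotlib.path import Path as MplPath

from pnnkit.geometry import ParameterError
from pnnkit.pnn import (
    average_by_subregion,
    classify_pv,
    count_pnns,
    measure_pnn,
    subtract_background,
)
from pnnkit.rois import RoiPolygon
from pnnkit.synthetic import SectionParams, generate_section


def square_roi(x0, y0, side, pixel_size=0.2, roi_id="sq", subregion=None):
    v = [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)]
    return RoiPolygon(roi_id, np.array(v, float), pixel_size, subregion)


class TestSubtractBackground:
    def test_constant_image_becomes_zero(self):
        img = np.full((64, 64), 80.0)
        assert np.allclose(subtract_background(img, 10), 0.0)

    def test_small_spot_preserved_on_flat_background(self):
        img = np.full((128, 128), 40.0)
        img[60:63, 60:63] += 150.0
        out = subtract_background(img, 50)
        assert out[61, 61] == pytest.approx(150.0, rel=0.05)
        spot = np.zeros_like(img, dtype=bool)
        spot[58:65, 58:65] = True
        assert np.median(out[~spot]) == pytest.approx(0.0, abs=1.0)

    def test_output_never_exceeds_input(self, rng):
        img = rng.uniform(0, 255, size=(96, 96))
        out = subtract_background(img, 20)
        assert np.all(out <= img + 1e-9) and np.all(out >= 0)

    def test_constant_offset_removed_before_measurement(self):
        img = np.full((96, 96), 10.0)
        img[40:50, 40:50] = 110.0
        roi = square_roi(41, 41, 8)
        base = measure_pnn(subtract_background(img, 30), [roi])
        shifted = measure_pnn(subtract_background(img + 60.0, 30), [roi])
        assert base["mean_intensity"][0] == pytest.approx(
            shifted["mean_intensity"][0], rel=0.02)

    def test_invalid_radius(self):
        with pytest.raises(ParameterError):
            subtract_background(np.zeros((32, 32)), 0.5)
        with pytest.raises(ParameterError):
            subtract_background(np.zeros((32, 32)), 64)


class TestMeasure:
    def test_uniform_field_mean(self):
        img = np.full((64, 64), 100.0)
        out = measure_pnn(img, [square_roi(10, 10, 20)])
        assert out["mean_intensity"][0] == pytest.approx(100.0)

    def test_half_split_roi_matches_pixel_center_oracle(self):
        img = np.zeros((60, 60))
        img[:, 30:] = 200.0
        roi = square_roi(20.5, 20.5, 19.0)
        measured = measure_pnn(img, [roi])["mean_intensity"][0]
        # independent pixel-centre even-odd oracle
        yy, xx = np.mgrid[0:60, 0:60]
        inside = MplPath(roi.vertices).contains_points(
            np.column_stack([xx.ravel(), yy.ravel()])).reshape(60, 60)
        assert measured == pytest.approx(img[inside].mean(), abs=1e-9)
        assert measured == pytest.approx(100.0, abs=12.0)

    def test_roi_outside_image_rejected(self):
        img = np.zeros((32, 32))
        with pytest.raises(ParameterError, match="far"):
            measure_pnn(img, [square_roi(100, 100, 10, roi_id="far")])

    def test_recovers_section_truth_within_tolerance(self):
        channels, truth = generate_section(
            SectionParams(snr=10.0, puncta={}, image_size_px=360), seed=21)
        wfa = subtract_background(channels["WFA"], 50.0)
        out = measure_pnn(wfa, truth.rois)
        rel = np.abs(out["mean_intensity"].to_numpy()
                     - np.asarray(truth.wfa_mean)) / np.asarray(truth.wfa_mean)
        assert np.all(rel < 0.05)


class TestClassifyPv:
    def test_blank_pv_channel_all_negative(self):
        img = np.zeros((64, 64))
        rois = [square_roi(5, 5, 10), square_roi(30, 30, 10, roi_id="b")]
        assert classify_pv(img, rois) == [False, False]

    def test_missing_channel_skips_with_warning(self):
        with pytest.warns(UserWarning):
            assert classify_pv(None, [square_roi(5, 5, 10)]) is None

    def test_threshold_above_signal_all_negative(self):
        img = np.full((64, 64), 10.0)
        img[10:20, 10:20] = 30.0
        rois = [square_roi(10, 10, 9)]
        assert classify_pv(img, rois, k_sd=1e6) == [False]

    def test_recovers_section_truth(self):
        channels, truth = generate_section(
            SectionParams(snr=10.0, puncta={}, image_size_px=360), seed=22)
        pv = subtract_background(channels["PV"], 50.0)
        assert classify_pv(pv, truth.rois) == truth.pv_positive


class TestSuggestRois:
    def test_recovers_ring_positions_on_synthetic_section(self):
        from scipy.spatial import cKDTree

        from pnnkit.pnn import suggest_rois

        channels, truth = generate_section(
            SectionParams(snr=10.0, puncta={}, image_size_px=360), seed=21)
        auto = suggest_rois(subtract_background(channels["WFA"], 50.0))
        assert len(auto) == len(truth.rois)
        tc = np.array([r.centroid() for r in truth.rois])
        ac = np.array([r.centroid() for r in auto])
        d, _ = cKDTree(ac).query(tc)
        assert np.all(d < 3.0)  # px

    def test_blank_image_suggests_nothing(self):
        from pnnkit.pnn import suggest_rois

        assert suggest_rois(np.zeros((64, 64)), pixel_size=0.1) == []


class TestCounts:
    @pytest.fixture
    def records(self):
        rows = []
        for i in range(10):
            rows.append({
                "animal_id": "a1",
                "subregion": "DG" if i < 4 else "CA1",
                "pv_positive": i % 2 == 0,
            })
        return pd.DataFrame(rows)

    def test_subregion_counts(self, records):
        out = count_pnns(records)
        assert out.set_index("subregion")["n_total"]["DG"] == 4

    def test_pv_classes_conserve_total(self, records):
        out = count_pnns(records)
        assert (out["n_pv_pos"] + out["n_pv_neg"]).equals(out["n_total"])

    def test_subregion_average(self):
        df = pd.DataFrame({
            "subregion": ["DG", "DG", "CA1"],
            "mean_intensity": [100.0, 120.0, 80.0],
        })
        out = average_by_subregion(df).set_index("subregion")
        assert out.loc["DG", "mean_intensity"] == pytest.approx(110.0)
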