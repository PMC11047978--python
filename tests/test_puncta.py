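"""Puncta detection, summaries and the component-labeling oracle."""

import math
from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage import measure

from pnnkit.geometry import ParameterError
from pnnkit.pnn import subtract_background
from pnnkit.puncta import (
    PunctaDetectParams,
    PunctaRecord,
    detect_puncta,
    summarize_puncta,
)
from pnnkit.rois import RoiPolygon
from pnnkit.synthetic import PunctaChannelParams, SectionParams, generate_section


def big_roi(size=64, pixel_size=0.1):
    v = [(1, 1), (size - 2, 1), (size - 2, size - 2), (1, size - 2)]
    return RoiPolygon("roi", np.array(v, float), pixel_size)


def disk(img, cy, cx, r, value=200.0):
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = value


class TestDetect:
    def test_blank_channel_no_puncta(self):
        assert detect_puncta(np.zeros((64, 64)), big_roi()) == []

    def test_size_filter_drops_small_components(self):
        img = np.zeros((64, 64))
        disk(img, 10, 10, 1.3)   # 5 px
        disk(img, 30, 30, 1.3)   # 5 px
        img[50, 50] = 200.0
        img[50, 51] = 200.0      # 2 px
        recs = detect_puncta(img, big_roi(),
                             PunctaDetectParams(threshold=100.0,
                                                min_size_px=3,
                                                split_touching=False))
        assert len(recs) == 2

    def test_min_above_max_size_rejected(self):
        with pytest.raises(ParameterError):
            PunctaDetectParams(min_size_px=10, max_size_px=3)

    def test_roi_clipping_and_centroid_rule(self):
        img = np.zeros((64, 64))
        disk(img, 32, 40, 2.2)   # fully inside
        # wholly outside the ROI (vertices start at x=1): nothing to clip
        img[10, 0] = 200.0
        recs = detect_puncta(img, big_roi(),
                             PunctaDetectParams(threshold=100.0, min_size_px=1,
                                                split_touching=False))
        assert len(recs) == 1
        # edge-straddling punctum: kept, measured on its clipped pixels
        disk(img, 32, 2, 2.2)
        recs = detect_puncta(img, big_roi(),
                             PunctaDetectParams(threshold=100.0, min_size_px=1,
                                                split_touching=False))
        assert len(recs) == 2

    def test_threshold_monotonicity_on_separated_blobs(self):
        # distinct disks of graded brightness: raising the threshold can
        # only remove whole puncta, never create new ones
        img = np.zeros((64, 64))
        rng = np.random.default_rng(17)
        for i, amp in enumerate((60, 100, 140, 180, 220)):
            disk(img, 10 + 11 * i, 32, 2.2, value=amp)
        img += rng.uniform(0, 5, size=img.shape)  # faint noise floor
        counts = [
            len(detect_puncta(img, big_roi(),
                              PunctaDetectParams(threshold=t, min_size_px=3,
                                                 split_touching=False)))
            for t in (30.0, 80.0, 120.0, 200.0, 256.0)]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == 5 and counts[-1] == 0

    def test_min_size_monotonicity(self):
        rng = np.random.default_rng(18)
        img = (rng.uniform(0, 1, size=(64, 64)) > 0.6) * 200.0
        counts = [
            len(detect_puncta(img, big_roi(),
                              PunctaDetectParams(threshold=100.0, min_size_px=m,
                                                 split_touching=False)))
            for m in (1, 2, 4, 8)]
        assert counts == sorted(counts, reverse=True)

    @pytest.mark.parametrize("density", [0.1, 0.3])
    def test_density_recovery_on_synthetic_section(self, density):
        det, true = [], []
        for seed in (0, 1):
            sp = SectionParams(
                puncta={"VGAT": PunctaChannelParams(density=density)},
                snr=10.0)
            channels, truth = generate_section(sp, seed=seed)
            sub = subtract_background(channels["VGAT"], 50.0)
            for roi, rec in zip(truth.rois, truth.puncta["VGAT"]):
                recs = detect_puncta(sub, roi, PunctaDetectParams(), "VGAT")
                det.append(len(recs) / roi.area)
                true.append(rec["density"])
        assert np.mean(det) == pytest.approx(np.mean(true), rel=0.15)


class TestSummaries:
    def _rec(self, i, area_um2=0.2, intensity=150.0):
        return PunctaRecord("roi", "VGAT", (float(i), float(i)), 5,
                            area_um2, intensity)

    def test_density_is_count_over_area(self):
        roi = big_roi(size=102, pixel_size=0.1)  # 100x100 px = 100 µm²
        recs = [self._rec(i) for i in range(25)]
        s = summarize_puncta(recs, roi, "VGAT")
        assert s.density == pytest.approx(25 / roi.area)
        assert s.density * roi.area == pytest.approx(25, abs=1e-9)

    def test_mean_size(self):
        roi = big_roi()
        recs = [self._rec(0, 0.1), self._rec(1, 0.3)]
        assert summarize_puncta(recs, roi).mean_size == pytest.approx(0.2)

    def test_empty_roi_flagged(self):
        s = summarize_puncta([], big_roi(), "VGlut1")
        assert s.n_puncta == 0 and s.density == 0.0
        assert math.isnan(s.mean_size) and math.isnan(s.mean_intensity)

    def test_foreign_records_rejected(self):
        other = PunctaRecord("other", "VGAT", (0, 0), 5, 0.1, 10.0)
        with pytest.raises(ParameterError):
            summarize_puncta([other], big_roi())


def flood_fill_label(mask: np.ndarray) -> int:
    """8-connected component count by BFS — oracle for skimage.label."""
    seen = np.zeros_like(mask, dtype=bool)
    n = 0
    for sy, sx in zip(*np.nonzero(mask)):
        if seen[sy, sx]:
            continue
        n += 1
        q = deque([(sy, sx)])
        seen[sy, sx] = True
        while q:
            y, x = q.popleft()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    yy, xx = y + dy, x + dx
                    if (0 <= yy < mask.shape[0] and 0 <= xx < mask.shape[1]
                            and mask[yy, xx] and not seen[yy, xx]):
                        seen[yy, xx] = True
                        q.append((yy, xx))
    return n


class TestLabelingOracle:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_component_count_matches_flood_fill(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.uniform(0, 1, size=(48, 48)) > 0.7
        assert measure.label(mask, connectivity=2).max() == \
            flood_fill_label(mask)
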