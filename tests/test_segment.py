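"""Segmentation operators: thresholds, background correction, size/shape gates."""

import numpy as np
import pytest

from osteoscreen.model import Role
from osteoscreen.segment import (
    DetectionMode,
    DetectionParams,
    LabelMap,
    classify_ki67,
    correct_background_median,
    detect_round_objects,
    detect_spots_background_global,
    segment_field,
    segment_nuclei_otsu,
    tophat_correct,
)
from osteoscreen.simulate import SimulationConfig, simulate_well

PX = 1.29  # um per pixel


class TestNucleiOtsu:
    params = DetectionParams()

    def test_constant_image_zero_objects(self):
        lm = segment_nuclei_otsu(np.full((128, 128), 7.0), self.params, PX)
        assert lm.object_count == 0

    def test_planted_disks_counted_exactly(self, make_disk_image):
        centers = [(30, 30), (30, 90), (64, 64), (100, 30), (100, 100)]
        img = make_disk_image((128, 128), centers, radius=4, amplitude=3000, background=100)
        lm = segment_nuclei_otsu(img, self.params, PX)
        assert lm.object_count == 5

    def test_undersized_disks_filtered(self, make_disk_image):
        # 2 um disks (below the 4 um minimum) alongside 3 valid ~10 um disks
        img = make_disk_image((128, 128), [(30, 30), (30, 90), (90, 60)], 4, 3000, 100)
        img = np.maximum(img, make_disk_image((128, 128), [(64, 20), (110, 110)], 0.8, 3000, 0))
        lm = segment_nuclei_otsu(img, self.params, PX)
        assert lm.object_count == 3

    def test_touching_disks_split_by_watershed(self, make_disk_image):
        img = make_disk_image((64, 64), [(32, 26), (32, 35)], 5, 3000, 100)
        split = segment_nuclei_otsu(img, DetectionParams(split_touching=True), PX)
        merged = segment_nuclei_otsu(img, DetectionParams(split_touching=False), PX)
        assert split.object_count == 2
        assert merged.object_count == 1


class TestMedianBackgroundCorrection:
    def test_constant_background_fully_removed(self):
        out = correct_background_median(np.full((64, 64), 37.0))
        np.testing.assert_allclose(out, 0.0)

    def test_impulse_preserved(self):
        img = np.full((64, 64), 10.0)
        img[32, 32] += 500.0
        out = correct_background_median(img)
        assert out[32, 32] == pytest.approx(500.0, rel=0.05)

    def test_output_nonnegative(self):
        rng = np.random.default_rng(0)
        out = correct_background_median(rng.uniform(0, 100, (64, 64)))
        assert out.min() >= 0


class TestBackgroundGlobalSpots:
    params = DetectionParams()

    def test_all_zero_gives_no_spots(self):
        assert detect_spots_background_global(np.zeros((64, 64)), self.params).object_count == 0

    def test_planted_spots_on_zero_background(self, make_disk_image):
        rng = np.random.default_rng(1)
        centers = [(r, c) for r in range(10, 120, 25) for c in range(10, 120, 25)]
        img = make_disk_image((128, 128), centers[:20], radius=2, amplitude=2000)
        lm = detect_spots_background_global(img, self.params)
        assert lm.object_count == 20

    def test_threshold_translation_invariant(self, make_disk_image):
        img = make_disk_image((128, 128), [(30, 30), (80, 90)], 2, 2000, 5)
        rolled = np.roll(img, (17, -9), axis=(0, 1))
        a = detect_spots_background_global(img, self.params)
        b = detect_spots_background_global(rolled, self.params)
        assert a.object_count == b.object_count == 2


class TestTophat:
    def test_constant_image_zeroed(self):
        np.testing.assert_allclose(tophat_correct(np.full((64, 64), 42.0), 20), 0.0)

    def test_ramp_suppressed_disk_kept(self, make_disk_image):
        ramp = np.tile(np.linspace(0, 200, 96), (96, 1))
        img = ramp + make_disk_image((96, 96), [(48, 48)], 3, 1000)
        out = tophat_correct(img, 20)
        peak = out[48, 48]
        background = out.copy()
        background[40:57, 40:57] = 0
        assert background.max() < 0.05 * peak

    def test_near_idempotent(self, make_disk_image):
        img = make_disk_image((96, 96), [(30, 30), (60, 70)], 3, 1000, 50)
        once = tophat_correct(img, 20)
        twice = tophat_correct(once, 20)
        assert np.abs(twice - once).max() <= 0.01 * once.max()


class TestRoundObjectDetection:
    def test_tiny_disk_rejected_by_size(self, make_disk_image):
        # 1 um disk at 0.645 um/px (unbinned) rasterizes below the 1.3 um gate
        img = make_disk_image((64, 64), [(32, 32)], 0.775, 3000)
        lm = detect_round_objects(img, (1.3, 8.0), 1000, 0.645)
        assert lm.object_count == 0

    def test_dim_disk_rejected_by_threshold(self, make_disk_image):
        img = make_disk_image((64, 64), [(32, 32)], 4, 150)
        lm = detect_round_objects(img, (4.0, 21.22), 200, PX)
        assert lm.object_count == 0

    def test_elongated_bar_rejected_by_circularity(self, make_disk_image):
        disk = make_disk_image((64, 64), [(20, 32)], 4, 3000)
        bar = np.zeros((64, 64))
        bar[45:48, 10:28] = 3000.0  # same-order area, circularity well below 0.6
        lm = detect_round_objects(disk + bar, (1.3, 25.0), 1000, PX)
        assert lm.object_count == 1


class TestKi67:
    def _nuclei(self, make_disk_image):
        mask = make_disk_image((64, 64), [(20, 20), (44, 44)], 5, 1) > 0
        return LabelMap.from_mask(mask)

    def test_zero_raster_zero_positive(self, make_disk_image):
        _, n = classify_ki67(self._nuclei(make_disk_image), np.zeros((64, 64)), 300)
        assert n == 0

    def test_strictly_above_threshold_is_positive(self, make_disk_image):
        nuclei = self._nuclei(make_disk_image)
        flags, n = classify_ki67(nuclei, np.full((64, 64), 301.0), 300)
        assert n == 2 and flags.all()
        _, n_eq = classify_ki67(nuclei, np.full((64, 64), 300.0), 300)
        assert n_eq == 0

    def test_planted_fraction_recovered_exactly(self):
        cfg = SimulationConfig(
            baseline_cells_per_well=60,
            n_fields=1,
            field_shape=(256, 256),
            read_noise_sd=2.0,
            noise_cv=0.05,
            ki67_positive_fraction=0.4,
            seed=5,
        )
        imgs, wt = simulate_well("p", "A1", Role.MOCK, "", None, cfg)
        nuclei, _, _, ki67_count = segment_field(imgs[0], DetectionParams())
        truth = wt.fields[0]
        assert nuclei.object_count == truth.n_nuclei
        assert ki67_count == int(truth.ki67_positive.sum())


class TestLabelMapInvariants:
    def test_labels_consecutive_enforced(self):
        lab = np.zeros((8, 8), dtype=int)
        lab[0, 0], lab[4, 4] = 1, 3
        with pytest.raises(ValueError):
            LabelMap(lab, 2)
        lm = LabelMap.from_labels(lab)
        assert lm.object_count == 2 and set(np.unique(lm.labels)) == {0, 1, 2}

    def test_objects_disjoint_partition(self, small_sim_config):
        imgs, _ = simulate_well("p", "B3", Role.MOCK, "", None, small_sim_config)
        nuclei, spots, _, _ = segment_field(imgs[0], DetectionParams())
        for lm in (nuclei, spots):
            present = np.unique(lm.labels)
            assert present[0] == 0 or lm.object_count == len(present)
            assert lm.labels.max() == lm.object_count


def test_intensity_equivariance(make_disk_image):
    """Scaling image and thresholds by c scales spot intensity, keeps counts."""
    img = make_disk_image((96, 96), [(30, 30), (60, 70)], 2, 2000)
    c = 3.7
    lm1 = detect_round_objects(img, (1.3, 8.0), 1000, PX)
    lm2 = detect_round_objects(c * img, (1.3, 8.0), c * 1000, PX)
    assert lm1.object_count == lm2.object_count == 2
    np.testing.assert_array_equal(lm1.labels > 0, lm2.labels > 0)
    s1 = img[lm1.labels > 0].sum()
    s2 = (c * img)[lm2.labels > 0].sum()
    assert s2 == pytest.approx(c * s1, rel=1e-9)
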