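"""Blob detection, uptake suppression, threshold baseline, candidate filtering."""

import numpy as np
import pytest
from scipy import ndimage

import promisequant as pq
from promisequant.detection import (
    CompartmentConfig,
    FilterRules,
    blob_detect,
    body_mask,
    detect_lesions,
    filter_candidates,
    fit_suppression,
    suppress,
    threshold_detect,
)
from promisequant.grid import VoxelGrid
from promisequant.segmentation import quantify


def _blurred_sphere_grid(centers_mm, diameter_mm=10.0, peak=8.0, background=1.0,
                         shape=(50, 50, 50), spacing=(3.0, 3.0, 3.0), fwhm=6.0):
    X, Y, Z = [np.arange(n) * s for n, s in zip(shape, spacing)]
    X, Y, Z = X[:, None, None], Y[None, :, None], Z[None, None, :]
    data = np.full(shape, background)
    for c in centers_mm:
        inside = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= (diameter_mm / 2) ** 2
        data[inside] = peak
    sigma = fwhm / 2.3548
    data = ndimage.gaussian_filter(data, [sigma / s for s in spacing])
    return VoxelGrid(data=data, spacing=spacing)


class TestBlobDetect:
    CFG = CompartmentConfig()

    def test_single_sphere_found_at_center_and_scale(self):
        center = (75.0, 75.0, 75.0)
        g = _blurred_sphere_grid([center])
        cands = blob_detect(g, np.ones(g.shape, bool), self.CFG, "x")
        assert len(cands) == 1
        c = cands[0]
        assert np.all(np.abs(np.array(c.seed_index) - 25) <= 1)
        # scale within one step of the 10 mm ground truth (scale list 9,12,...)
        assert c.scale_mm in (9.0, 12.0)

    def test_uniform_field_no_candidates(self):
        g = VoxelGrid(data=np.full((30, 30, 30), 2.0), spacing=(3, 3, 3))
        assert blob_detect(g, np.ones(g.shape, bool), self.CFG) == []

    def test_two_spheres_40mm_apart(self):
        g = _blurred_sphere_grid([(60.0, 75.0, 75.0), (100.0, 75.0, 75.0)])
        cands = blob_detect(g, np.ones(g.shape, bool), self.CFG)
        assert len(cands) == 2
        xs = sorted(c.seed_index[0] for c in cands)
        assert abs(xs[0] - 20) <= 1 and abs(xs[1] - 33) <= 1

    def test_empty_mask_empty_list(self):
        g = _blurred_sphere_grid([(75.0, 75.0, 75.0)])
        assert blob_detect(g, np.zeros(g.shape, bool), self.CFG) == []

    def test_deterministic(self):
        g = _blurred_sphere_grid([(60.0, 75.0, 75.0), (100.0, 75.0, 75.0)])
        a = blob_detect(g, np.ones(g.shape, bool), self.CFG)
        b = blob_detect(g, np.ones(g.shape, bool), self.CFG)
        assert [c.__dict__ for c in a] == [c.__dict__ for c in b]

    def test_translation_equivariance(self):
        g = _blurred_sphere_grid([(75.0, 75.0, 75.0)])
        shifted = VoxelGrid(data=np.roll(g.data, (2, 3, 4), axis=(0, 1, 2)),
                            spacing=g.spacing)
        a = blob_detect(g, np.ones(g.shape, bool), self.CFG)
        b = blob_detect(shifted, np.ones(g.shape, bool), self.CFG)
        assert len(a) == len(b) == 1
        assert tuple(np.array(a[0].seed_index) + (2, 3, 4)) == b[0].seed_index


class TestSuppression:
    def test_kidney_uptake_suppressed(self, quiet_phantom):
        suv, labels, _ = quiet_phantom
        sup = fit_suppression(suv, labels)
        out = suppress(suv, sup)
        kidney = labels.data == 4
        assert out.data[kidney].mean() < 0.1 * suv.data[kidney].mean()

    def test_no_modeled_organs_zero_field(self):
        g = VoxelGrid(data=np.ones((20, 20, 20)), spacing=(3, 3, 3))
        labels = VoxelGrid(data=np.zeros((20, 20, 20), np.int16), spacing=(3, 3, 3))
        sup = fit_suppression(g, labels)
        assert np.all(sup.field == 0)

    def test_distant_lesion_barely_affected(self, lesion_phantom):
        suv, labels, truth = lesion_phantom
        lymph = next(l for l in truth.lesions if l.compartment == "lymph")
        sup = fit_suppression(suv, labels)
        out = suppress(suv, sup)
        before = suv.data[lymph.mask].max()
        after = out.data[lymph.mask].max()
        assert abs(after - before) / before < 0.05

    def test_field_nonnegative(self, quiet_phantom):
        suv, labels, _ = quiet_phantom
        sup = fit_suppression(suv, labels)
        assert sup.field.min() >= 0
        assert suppress(suv, sup).data.min() >= 0


class TestThresholdDetect:
    def test_sub_threshold_lesion_missed_then_found(self):
        # plateau realized max ~3.5 after blur
        g = _blurred_sphere_grid([(75.0, 75.0, 75.0)], peak=4.1, background=0.4)
        m = np.ones(g.shape, bool)
        realized = g.data.max()
        assert 3.0 < realized < 4.3
        assert threshold_detect(g, m, 4.3) == []
        assert len(threshold_detect(g, m, 3.0)) == 1

    def test_touching_spheres_one_component(self):
        g = _blurred_sphere_grid([(70.0, 75.0, 75.0), (82.0, 75.0, 75.0)], peak=8.0)
        cands = threshold_detect(g, np.ones(g.shape, bool), 4.0)
        assert len(cands) == 1

    def test_invalid_threshold(self):
        g = _blurred_sphere_grid([(75.0, 75.0, 75.0)])
        with pytest.raises(ValueError):
            threshold_detect(g, np.ones(g.shape, bool), 0.0)


class TestFilterCandidates:
    def _record(self, suv, labels, seed, value):
        mask = np.zeros(suv.shape, bool)
        mask[seed] = True
        from promisequant.detection import LesionCandidate

        cand = LesionCandidate(seed_index=seed, position_mm=(0, 0, 0), scale_mm=9.0,
                               response=1.0, compartment="lymph")
        return quantify(suv, mask, cand)

    @pytest.fixture
    def setting(self):
        suv = VoxelGrid(data=np.full((10, 10, 10), 1.2), spacing=(3, 3, 3))
        labels = VoxelGrid(data=np.zeros((10, 10, 10), np.int16), spacing=(3, 3, 3))
        labels.data[5, 5, 5] = 6  # bladder
        suv.data[2, 2, 2] = 1.2
        suv.data[7, 7, 7] = 9.0
        return suv, labels

    def test_low_suvmax_rejected_with_reason(self, setting):
        suv, labels = setting
        rec = self._record(suv, labels, (2, 2, 2), 1.2)
        kept, rej = filter_candidates([rec], labels, FilterRules(min_suvmax=2.0,
                                                                min_volume_ml=0.0))
        assert kept == [] and rej[0][1] == "SUVmax"

    def test_empty_rules_keep_all(self, setting):
        suv, labels = setting
        rec = self._record(suv, labels, (2, 2, 2), 1.2)
        rules = FilterRules(min_suvmax=0.0, min_suvmax_rel_blood_pool=0.0,
                            min_volume_ml=0.0, excluded_location_ids=[])
        kept, rej = filter_candidates([rec], labels, rules)
        assert len(kept) == 1 and rej == []

    def test_bladder_seed_rejected_as_location(self, setting):
        suv, labels = setting
        rec = self._record(suv, labels, (5, 5, 5), 9.0)
        kept, rej = filter_candidates([rec], labels, FilterRules(min_volume_ml=0.0))
        assert rej[0][1] == "location"


class TestDetectLesions:
    def test_bone_and_lymph_lesions_found(self, lesion_phantom):
        suv, labels, truth = lesion_phantom
        cands, _ = detect_lesions(suv, labels)
        comps = {}
        for truth_lesion in truth.lesions:
            centre = tuple(int(round(c / 3)) for c in truth_lesion.center_mm)
            near = [
                c for c in cands
                if np.linalg.norm(np.array(c.seed_index) - np.array(centre)) <= 3
            ]
            assert near, f"no candidate near {truth_lesion.compartment} lesion"
            comps[truth_lesion.compartment] = near[0].compartment
        assert comps["bone"] == "bone"
        assert comps["lymph"] == "lymph"

    def test_no_lesion_phantom_no_bone_candidates(self, quiet_phantom):
        suv, labels, _ = quiet_phantom
        cands, _ = detect_lesions(suv, labels)
        assert [c for c in cands if c.compartment == "bone"] == []

    def test_missing_prostate_warns_and_skips(self, caplog):
        import logging

        spec = pq.default_spec(seed=4, include_prostate=False)
        suv, labels, _ = pq.make_phantom(spec)
        with caplog.at_level(logging.WARNING):
            cands, _ = detect_lesions(suv, labels)
        assert [c for c in cands if c.compartment == "prostate"] == []
        assert any("prostate" in r.message for r in caplog.records)

    def test_missing_bones_error(self):
        g = VoxelGrid(data=np.ones((20, 20, 20)), spacing=(3, 3, 3))
        labels = VoxelGrid(data=np.zeros((20, 20, 20), np.int16), spacing=(3, 3, 3))
        labels.data[5:8, 5:8, 5:8] = 1
        labels.data[10:12, 10:12, 10:12] = 2
        with pytest.raises(ValueError, match="bone"):
            detect_lesions(g, labels, blood_pool=1.0)


def test_body_mask_is_largest_component(quiet_phantom):
    suv, labels, _ = quiet_phantom
    m = body_mask(suv, 1.8)
    # the trunk fills a large contiguous share of the grid
    assert 0.2 < m.mean() < 0.9
    lab, n = ndimage.label(m, structure=np.ones((3, 3, 3), bool))
    assert n == 1
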