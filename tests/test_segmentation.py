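"""Evidence extraction, MRF labeling, morphology, filtering, and expert edits."""

import numpy as np
import pytest
from scipy import ndimage

from conftest import rasterize_annulus, rasterize_disk
from vesiclepop.errors import CorrectionError, ParameterError
from vesiclepop.segmentation import (
    CorrectionEdit,
    FilterRules,
    MrfParams,
    apply_corrections,
    close_and_fill,
    compensate_band,
    label_and_filter,
    mrf_segment,
    preprocess,
)


def ring_image(radius=30, width=3, shape=140, contrast=80.0, background=200.0):
    ring = rasterize_annulus(radius, width, shape=shape)
    return background - contrast * ring.astype(float)


class TestPreprocess:
    def test_constant_image_gives_zero_evidence(self):
        assert np.all(preprocess(np.full((80, 80), 50.0)) == 0.0)

    def test_dark_ring_lights_up_a_closed_annulus(self):
        evidence = preprocess(ring_image())
        strong = evidence > 0.3
        filled = ndimage.binary_fill_holes(strong)
        # the strong evidence forms one closed loop: filling it claims the interior
        assert filled.sum() > strong.sum() > 0
        _, n = ndimage.label(strong)
        assert n == 1

    def test_illumination_ramp_invariance(self):
        base = ring_image()
        ramp = np.linspace(0, 25, base.shape[1])[None, :]
        ev_flat = preprocess(base)
        ev_ramp = preprocess(base + ramp)
        det_flat = ndimage.binary_fill_holes(ev_flat > 0.3)
        det_ramp = ndimage.binary_fill_holes(ev_ramp > 0.3)
        # same detection: overwhelming overlap between the two filled regions
        inter = (det_flat & det_ramp).sum()
        union = (det_flat | det_ramp).sum()
        assert inter / union > 0.95

    def test_rejects_non_2d(self):
        with pytest.raises(ParameterError):
            preprocess(np.zeros((4, 4, 3)))


class TestMrfSegment:
    def test_zero_evidence_is_all_background(self):
        result = mrf_segment(np.zeros((32, 32)))
        assert result.degenerate and not result.mask.any()

    def test_beta_zero_equals_pointwise_rule(self):
        rng = np.random.default_rng(0)
        evidence = np.clip(rng.normal(0.2, 0.1, (64, 64)), 0, 1)
        evidence[20:40, 20:40] = np.clip(rng.normal(0.8, 0.1, (20, 20)), 0, 1)
        result = mrf_segment(evidence, MrfParams(beta=0.0, max_iters=1))
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(evidence)
        init = evidence > thr
        mu0, mu1 = evidence[~init].mean(), evidence[init].mean()
        sd0, sd1 = evidence[~init].std(), evidence[init].std()
        d0 = (evidence - mu0) ** 2 / (2 * sd0**2) + np.log(sd0)
        d1 = (evidence - mu1) ** 2 / (2 * sd1**2) + np.log(sd1)
        assert np.array_equal(result.mask, d1 < d0)

    def test_smoothing_removes_isolated_errors(self):
        rng = np.random.default_rng(1)
        truth = rasterize_annulus(25, 4, shape=100)
        evidence = np.clip(0.15 + 0.55 * truth + rng.normal(0, 0.18, truth.shape), 0, 1)
        errors_b0 = (mrf_segment(evidence, MrfParams(beta=0.0)).mask != truth).sum()
        errors_b15 = (mrf_segment(evidence, MrfParams(beta=1.5)).mask != truth).sum()
        assert errors_b15 < errors_b0

    def test_deterministic_and_shift_invariant(self):
        rng = np.random.default_rng(2)
        evidence = np.clip(rng.normal(0.3, 0.2, (48, 48)), 0, 1)
        a = mrf_segment(evidence).mask
        b = mrf_segment(evidence).mask
        c = mrf_segment(evidence + 0.17).mask
        assert np.array_equal(a, b) and np.array_equal(a, c)

    def test_invalid_params(self):
        with pytest.raises(ParameterError):
            MrfParams(beta=-1.0).validate()
        with pytest.raises(ParameterError):
            MrfParams(neighborhood=6).validate()


class TestCloseAndFill:
    def test_solid_disk_unchanged(self):
        disk_mask = rasterize_disk(20).astype(bool)
        assert np.array_equal(close_and_fill(disk_mask), disk_mask)

    def test_gapped_annulus_becomes_solid_disk(self):
        # 3 px gap at radius 25 -> gap arc ~3 px wide
        ring = rasterize_annulus(25, 3, gap_deg=np.degrees(3.0 / 25.0))
        solid = close_and_fill(ring)
        filled_area = solid.sum()
        assert filled_area > np.pi * 23**2  # interior got claimed
        _, n = ndimage.label(solid)
        assert n == 1

    def test_nearby_annuli_not_merged(self):
        shape = 160
        a = rasterize_annulus(20, 3, shape=shape, center=(80, 50))
        b = rasterize_annulus(20, 3, shape=shape, center=(80, 100))
        # edges are 10 px apart (centers 50 px, radii 20+20)
        solid = close_and_fill(a | b)
        _, n = ndimage.label(solid)
        assert n == 2


class TestCompensateBand:
    def test_shrinks_by_half_width(self):
        disk_mask = rasterize_disk(20).astype(bool)
        out = compensate_band(disk_mask, 3)
        r_eff = np.sqrt(out.sum() / np.pi)
        assert r_eff == pytest.approx(17, abs=0.5)

    def test_small_objects_survive(self):
        tiny = rasterize_disk(2).astype(bool)
        out = compensate_band(tiny, 3)
        assert out.sum() == tiny.sum()  # kept at uneroded extent


class TestLabelAndFilter:
    def test_empty_mask(self):
        mask, report = label_and_filter(np.zeros((32, 32), bool))
        assert mask.n_labels == 0 and report.total_found == 0

    def test_subminimum_object_rejected(self):
        # 2 px diameter at 0.25 um/px = 0.5 um < 1 um minimum
        mask = np.zeros((40, 40), bool)
        mask[20:22, 20:22] = True
        label_mask, report = label_and_filter(mask, pixel_size_um=0.25)
        assert label_mask.n_labels == 0 and report.too_small == 1

    def test_border_touching_excluded_and_counted(self):
        yy, xx = np.mgrid[:80, :80]
        bisected = (yy - 0) ** 2 + (xx - 40) ** 2 <= 12**2  # disk cut by the top border
        label_mask, report = label_and_filter(bisected, pixel_size_um=0.25)
        assert label_mask.n_labels == 0 and report.border_touching == 1

    def test_all_accepted_labels_satisfy_rules(self, rendered_scene):
        from vesiclepop.segmentation import segment_mosaic

        rules = FilterRules()
        label_mask, _ = segment_mosaic(rendered_scene.image, 0.25, filter_rules=rules)
        for lab in label_mask.label_ids():
            area = (label_mask.labels == lab).sum()
            diameter = 2 * np.sqrt(area / np.pi) * 0.25
            assert rules.min_diameter_um <= diameter <= rules.max_diameter_um
        # no accepted region touches the border
        border = np.concatenate([
            label_mask.labels[0], label_mask.labels[-1],
            label_mask.labels[:, 0], label_mask.labels[:, -1],
        ])
        assert np.all(border == 0)

    def test_labeling_is_stable(self):
        mask = rasterize_disk(10, shape=120).astype(bool)
        mask |= np.roll(rasterize_disk(8, shape=120), (30, 35), (0, 1)).astype(bool)
        m1, _ = label_and_filter(mask, pixel_size_um=0.25)
        m2, _ = label_and_filter(mask, pixel_size_um=0.25)
        assert np.array_equal(m1.labels, m2.labels)
        assert m1.label_ids() == list(range(1, m1.n_labels + 1))

    def test_invalid_rules(self):
        with pytest.raises(ParameterError):
            FilterRules(min_diameter_um=10, max_diameter_um=5).validate()


class TestApplyCorrections:
    @pytest.fixture
    def two_label_mask(self):
        arr = np.zeros((80, 80), bool)
        arr |= rasterize_disk(10, shape=80).astype(bool)
        arr |= np.roll(rasterize_disk(6, shape=80), (25, 25), (0, 1)).astype(bool)
        mask, _ = label_and_filter(arr, pixel_size_um=0.25)
        return mask

    def test_empty_edit_list_marks_corrected(self, two_label_mask):
        out = apply_corrections(two_label_mask, [])
        assert np.array_equal(out.labels, two_label_mask.labels)
        assert out.provenance == "corrected"

    def test_delete_all_labels_empties_mask(self, two_label_mask):
        edits = [CorrectionEdit("delete", lab) for lab in two_label_mask.label_ids()]
        out = apply_corrections(two_label_mask, edits)
        assert out.n_labels == 0

    def test_add_polygon_creates_label(self, two_label_mask):
        verts = [(60.0, 10.0), (60.0, 25.0), (75.0, 25.0), (75.0, 10.0)]
        out = apply_corrections(two_label_mask, [CorrectionEdit("add_polygon", verts)])
        assert out.n_labels == two_label_mask.n_labels + 1

    def test_merge_unions_labels(self, two_label_mask):
        ids = two_label_mask.label_ids()
        out = apply_corrections(two_label_mask, [CorrectionEdit("merge", ids)])
        assert out.n_labels == 1

    def test_split_dumbbell_yields_two_labels(self):
        dumbbell = np.zeros((60, 120), bool)
        yy, xx = np.mgrid[:60, :120]
        dumbbell |= (yy - 30) ** 2 + (xx - 35) ** 2 <= 14**2
        dumbbell |= (yy - 30) ** 2 + (xx - 85) ** 2 <= 14**2
        dumbbell[28:33, 35:86] = True  # the neck
        mask, _ = label_and_filter(dumbbell, FilterRules(solidity_flag_threshold=0.0), 0.25)
        assert mask.n_labels == 1
        neck = [(20.0, 60.0), (40.0, 60.0)]
        out = apply_corrections(mask, [CorrectionEdit("split_polyline", (1, neck))])
        assert out.n_labels == 2

    def test_dangling_reference_names_edit_index(self, two_label_mask):
        edits = [CorrectionEdit("delete", 1), CorrectionEdit("delete", 99)]
        with pytest.raises(CorrectionError, match="edit 1"):
            apply_corrections(two_label_mask, edits)
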