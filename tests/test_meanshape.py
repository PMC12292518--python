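"""Rigid mean-shape construction and rotation tracking.

Test shapes are rasterized from polygons, the same way recording masks are
produced, and carry a tilted base orientation: perfectly axis-aligned
rasterizations are a degenerate special case (maximal grid aliasing) that
real vertebra masks never present.
"""

import numpy as np
import pytest

from spinetrack import (
    MeanShape,
    MeanShapeError,
    build_mean_shape,
    fit_mean_shape,
    mean_shape_agreement,
    track_recording,
)
from spinetrack._geom import rasterize_polygon, rotation_matrix_deg
from spinetrack.meanshape import TRACKED_LABELS, render_fit
from spinetrack.metrics import iou

# notched rectangle (the notch breaks symmetry) and an L-shape, in px
BLOCK_POLY = np.array(
    [(-22, -15), (22, -15), (22, 15), (-22, 15), (-22, -9), (-14, -9), (-14, -15)],
    dtype=float,
)
L_POLY = np.array(
    [(-10, -15), (2, -15), (2, 5), (20, 5), (20, 15), (-10, 15)], dtype=float
)
TILT = 13.4  # base orientation of all constructed targets


def _place(poly, angle, centroid=(110.0, 110.0), shape=(220, 220)):
    verts = poly @ rotation_matrix_deg(TILT + angle).T + np.asarray(centroid)
    return rasterize_polygon(verts, shape)


def _build(poly, angles=(-4.0, -2.0, 0.0, 2.0, 4.0), **kwargs):
    return build_mean_shape([_place(poly, a) for a in angles], **kwargs)


class TestBuildMeanShape:
    def test_identical_frames_recover_mask(self):
        masks = [_place(BLOCK_POLY, 0.0)] * 5
        shape = build_mean_shape(masks, label="C3")
        fit = fit_mean_shape(shape, masks[0])
        assert fit.overlap_iou >= 0.92
        assert abs(fit.angle_deg) <= 0.1

    def test_rotated_frames_recover_template(self):
        shape = _build(BLOCK_POLY, angles=np.linspace(-12, 12, 7))
        fit = fit_mean_shape(shape, _place(BLOCK_POLY, 0.0))
        assert fit.overlap_iou >= 0.9
        assert abs(fit.angle_deg) <= 0.2

    def test_fragments_use_largest_component(self):
        masks = []
        for a in (-4.0, 0.0, 4.0):
            m = _place(BLOCK_POLY, a)
            m[2:5, 2:12] = 1  # small spurious fragment far from the body
            masks.append(m)
        shape = build_mean_shape(masks, label="C5")
        assert shape.template.sum() < 1.2 * _place(BLOCK_POLY, 0.0).sum()

    def test_too_few_frames_error(self):
        empty = np.zeros((220, 220), np.uint8)
        with pytest.raises(MeanShapeError):
            build_mean_shape([_place(BLOCK_POLY, 0.0), empty, empty], label="C1")

    def test_inconsistent_shapes_error(self, rng):
        masks = [(rng.uniform(size=(60, 60)) > 0.5).astype(np.uint8) for _ in range(6)]
        with pytest.raises(MeanShapeError):
            build_mean_shape(masks, label="C2", min_align_iou=0.95)

    def test_centroid_centered(self):
        shape = _build(BLOCK_POLY, angles=(-3.0, 0.0, 3.0))
        rows, cols = np.nonzero(shape.template)
        center = (shape.template.shape[0] - 1) / 2
        assert abs(rows.mean() - center) <= 0.5
        assert abs(cols.mean() - center) <= 0.5


class TestFitMeanShape:
    def test_exact_identity_target(self):
        """Target equal to the template itself: angle 0 +/- 0.05, IoU ~ 1."""
        shape = _build(BLOCK_POLY)
        target = np.zeros((220, 220), np.uint8)
        h, w = shape.template.shape
        target[60 : 60 + h, 70 : 70 + w] = shape.template
        fit = fit_mean_shape(shape, target)
        assert abs(fit.angle_deg) <= 0.05
        # the sub-pixel centroid offset keeps the soft overlap just below 1
        assert fit.overlap_iou >= 0.98

    @pytest.mark.parametrize("angle", [5.0, -7.5])
    def test_known_rotation_recovered(self, angle):
        shape = _build(BLOCK_POLY)
        fit = fit_mean_shape(shape, _place(BLOCK_POLY, angle))
        assert fit.angle_deg == pytest.approx(angle, abs=0.1)

    def test_l_shape_90_degrees(self):
        shape = _build(L_POLY)
        fit = fit_mean_shape(shape, _place(L_POLY, 90.0), half_range=120.0)
        assert fit.angle_deg == pytest.approx(90.0, abs=0.1)

    def test_rotation_equivariance(self):
        """Fitting a target rotated by delta shifts the angle by delta."""
        shape = _build(BLOCK_POLY)
        base = fit_mean_shape(shape, _place(BLOCK_POLY, 2.0)).angle_deg
        for delta in (4.0, 9.0):
            fit = fit_mean_shape(shape, _place(BLOCK_POLY, 2.0 + delta))
            assert fit.angle_deg - base == pytest.approx(delta, abs=0.2)

    def test_empty_target_sentinel(self):
        shape = MeanShape(template=_place(BLOCK_POLY, 0.0)[80:140, 70:160], label="C3")
        fit = fit_mean_shape(shape, np.zeros((50, 50), np.uint8), frame=4)
        assert not fit.converged
        assert np.isnan(fit.angle_deg)


class TestTrackRecording:
    def test_constant_pose(self):
        masks = np.stack([_place(BLOCK_POLY, 3.0)] * 6)
        shape = build_mean_shape(masks)
        angles = [f.angle_deg for f in track_recording(shape, masks)]
        assert max(angles) - min(angles) <= 0.1

    def test_linear_sweep(self):
        true = np.linspace(0.0, 30.0, 31)
        # template >= 40 px tall: the regime the tracker is specified for
        masks = np.stack([_place(1.4 * BLOCK_POLY, a) for a in true])
        shape = build_mean_shape(masks)
        fits = track_recording(shape, masks)
        est = np.array([f.angle_deg for f in fits])
        err = est - true
        err -= err.mean()  # template reference orientation is arbitrary
        assert np.abs(err).max() <= 0.5

    def test_tracking_failure_on_empty_frames(self):
        good = [_place(BLOCK_POLY, 0.0)] * 4
        masks = np.stack(good + [np.zeros((220, 220), np.uint8)] * 4)
        shape = build_mean_shape(good)
        with pytest.raises(Exception, match="unfittable"):
            track_recording(shape, masks)

    def test_c0_not_tracked(self):
        assert "C0" not in TRACKED_LABELS
        assert TRACKED_LABELS == ("C1", "C2", "C3", "C4", "C5", "C6", "C7")


class TestAgreement:
    def test_self_agreement(self):
        masks = np.stack([_place(BLOCK_POLY, a) for a in (0.0, 5.0, 10.0)])
        shape = build_mean_shape(masks)
        fits = track_recording(shape, masks)
        assert mean_shape_agreement(shape, fits, masks) >= 0.9

    def test_empty_frames_excluded(self):
        masks = np.stack([_place(BLOCK_POLY, 0.0)] * 4)
        shape = build_mean_shape(masks)
        fits = track_recording(shape, masks)
        masks_with_hole = masks.copy()
        masks_with_hole[2] = 0
        a = mean_shape_agreement(shape, fits, masks_with_hole)
        b = mean_shape_agreement(shape, fits, masks)
        assert a == pytest.approx(b, abs=1e-6)

    def test_meanshape_beats_fragmented_prediction(self, rng):
        """On fragmentation-corrupted masks the fitted mean shape is closer
        to the truth than the raw corrupted prediction."""
        angles = np.linspace(-8, 8, 7)
        clean = np.stack([_place(BLOCK_POLY, a) for a in angles])
        corrupted = clean.copy()
        for i in range(len(corrupted)):
            rr, cc = np.nonzero(corrupted[i])
            drop = rng.uniform(size=rr.size) < 0.12
            corrupted[i][rr[drop], cc[drop]] = 0
        shape = build_mean_shape(list(corrupted))
        fits = track_recording(shape, corrupted)
        fitted_vs_gt = mean_shape_agreement(shape, fits, clean)
        raw_vs_gt = np.mean([iou(corrupted[i], clean[i]) for i in range(len(clean))])
        assert fitted_vs_gt >= raw_vs_gt

    def test_serialization_roundtrip(self, tmp_path):
        shape = _build(BLOCK_POLY, angles=(-2.0, 0.0, 2.0))
        from spinetrack.meanshape import read_mean_shape, write_mean_shape

        write_mean_shape(tmp_path / "C3.tif", shape)
        back = read_mean_shape(tmp_path / "C3.tif")
        np.testing.assert_array_equal(back.template, shape.template)
        assert back.label == shape.label and back.source == shape.source

    def test_render_fit_roundtrip(self):
        masks = np.stack([_place(BLOCK_POLY, 0.0)] * 3)
        shape = build_mean_shape(masks)
        fits = track_recording(shape, masks)
        rendered = render_fit(shape, fits[0], masks[0].shape)
        assert iou(rendered, masks[0]) >= 0.9
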