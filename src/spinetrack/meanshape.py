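"""Rigid mean shapes and rotation tracking.

A vertebra is a rigid body: its true outline cannot change during a
recording, while per-frame segmentations jitter.  To exploit this, one
binary *mean shape* per vertebra per recording is built by rotationally
aligning every frame's (largest-component) segmentation to a reference
frame, averaging the aligned occupancy maps and thresholding at 0.5.

The mean shape is then fitted back to each frame: it is placed on the
centroid of the frame's segmentation and rotated until the overlap (IoU)
with that segmentation is maximal.  The rotation search is an exhaustive
grid — coarse 1° steps over a window around the previous frame's angle
(±45° around 0 for the first frame), a 10x refinement (0.1° steps) around
the optimum, and a final parabolic-vertex interpolation of the refined
overlap curve.  The overlap objective uses
the bilinearly resampled (continuous-valued) rotated template against the
binary target, which makes the objective smooth in the angle and gives
sub-degree accuracy even for templates a few dozen pixels tall.

Mean shapes are built for C1-C7 only; the skull base C0 is excluded
because its apparent shape varies too much across frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._geom import rotation_matrix_deg
from .thresholding import largest_component

TRACKED_LABELS: tuple[str, ...] = ("C1", "C2", "C3", "C4", "C5", "C6", "C7")

DEFAULT_STEPS: tuple[float, ...] = (1.0, 0.1)  # coarse step, fine step (deg)
FIRST_FRAME_HALF_RANGE = 45.0
TRACKING_HALF_RANGE = 10.0


class MeanShapeError(RuntimeError):
    """Mean-shape construction failed (too few or too inconsistent frames)."""


class TrackingError(RuntimeError):
    """Too large a fraction of frames could not be fitted."""


@dataclass
class MeanShape:
    """Rigid binary template of one vertebra in centered local coordinates."""

    template: np.ndarray  # (s, s) uint8, centroid at the canvas center
    label: str
    recording_id: str = ""
    source: str = "ground_truth"  # or "model"

    @property
    def center(self) -> np.ndarray:
        s = self.template.shape
        return np.array([(s[1] - 1) / 2.0, (s[0] - 1) / 2.0])


@dataclass
class ShapeFit:
    """Pose of a mean shape fitted to one frame."""

    frame: int
    angle_deg: float
    centroid: np.ndarray  # (x, y)
    overlap_iou: float
    converged: bool


# --------------------------------------------------------------------------
# Rotated-template evaluation (batched over candidate angles)
# --------------------------------------------------------------------------

class _RotatedTemplate:
    """Evaluates a template under many candidate rotations in one call."""

    def __init__(self, template: np.ndarray, center: np.ndarray):
        self.template = np.asarray(template, dtype=np.float32)
        self.center = np.asarray(center, dtype=float)
        self.area = float(self.template.sum())

    def sample(self, angles_deg: np.ndarray, rel_xy: np.ndarray) -> np.ndarray:
        """Template values at output points ``rel_xy`` (2, M) rotated by each angle.

        ``rel_xy`` holds (x, y) offsets of the output pixel centers from
        the placement centroid.  Returns an (A, M) array.
        """
        angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
        th = np.deg2rad(-angles)  # inverse map: output -> template coords
        c, s = np.cos(th), np.sin(th)
        x, y = rel_xy
        xs = c[:, None] * x + s[:, None] * y + self.center[0]
        ys = -s[:, None] * x + c[:, None] * y + self.center[1]
        vals = ndimage.map_coordinates(
            self.template, [ys.ravel(), xs.ravel()], order=1, cval=0.0
        )
        return vals.reshape(len(angles), -1)


def _crop_grid(center_xy: np.ndarray, radius: int, image_shape) -> tuple:
    """Pixel grid of a square crop around a point, as slices + relative coords."""
    h, w = image_shape
    cx, cy = center_xy
    r0 = max(0, int(np.floor(cy)) - radius)
    r1 = min(h, int(np.ceil(cy)) + radius + 1)
    c0 = max(0, int(np.floor(cx)) - radius)
    c1 = min(w, int(np.ceil(cx)) + radius + 1)
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    rel = np.stack([cols.ravel() - cx, rows.ravel() - cy])
    return (slice(r0, r1), slice(c0, c1)), rel


def _overlap_curve(
    rot: _RotatedTemplate, target: np.ndarray, centroid: np.ndarray, angles: np.ndarray
) -> np.ndarray:
    """Soft IoU between the rotated template at ``centroid`` and the target."""
    radius = int(np.ceil(np.hypot(*rot.template.shape) / 2)) + 2
    sl, rel = _crop_grid(centroid, radius, target.shape)
    gvals = target[sl].astype(np.float32).ravel()
    gsum = float(target.sum())
    tvals = rot.sample(angles, rel)
    inter = tvals @ gvals
    union = tvals.sum(axis=1) + gsum - inter
    return inter / np.maximum(union, 1e-9)


def _grid_search(curve_fn, center: float, half_range: float, steps=DEFAULT_STEPS):
    """Exhaustive coarse-to-fine angle search with a parabolic finish.

    A coarse grid over ``center`` ± ``half_range`` is refined by a fine
    grid around the optimum; the final angle is the vertex of a quadratic
    fitted to the fine-grid overlap values.  The quadratic fit matters:
    the overlap of two *rasterized* shapes carries a grid-aliasing ripple
    of up to ~0.5° when their orientations nearly coincide, and the
    smooth-curve vertex averages that ripple out where a plain argmax
    locks onto it.  Falls back to the fine-grid argmax when the sampled
    curve is not concave.  Returns (angle, objective at that angle).
    """
    coarse_step, fine_step = steps[0], steps[1] if len(steps) > 1 else steps[0] / 10
    n = int(round(float(half_range) / coarse_step))
    grid = float(center) + coarse_step * np.arange(-n, n + 1)
    vals = curve_fn(grid)
    best = float(grid[int(np.argmax(vals))])  # ties -> lowest candidate angle

    m = int(round(2.0 * coarse_step / fine_step))
    fine = best + fine_step * np.arange(-m, m + 1)
    fvals = np.asarray(curve_fn(fine))
    i = int(np.argmax(fvals))
    best = float(fine[i])

    coeffs = np.polyfit(fine, fvals, 2)
    if coeffs[0] < 0:
        resid = fvals - np.polyval(coeffs, fine)
        spread = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        if resid[i] <= max(4.0 * spread, 0.01):
            # ripple-scale deviation: the smooth-curve vertex is the better
            # estimate than the aliased argmax
            best = float(np.clip(-coeffs[1] / (2.0 * coeffs[0]), fine[0], fine[-1]))
        # else: a genuine localized optimum (e.g. exact binary identity)
    best_val = float(np.asarray(curve_fn(np.array([best])))[0])
    return best, best_val


# --------------------------------------------------------------------------
# Mean-shape construction
# --------------------------------------------------------------------------

def _centered_occupancy(mask: np.ndarray, canvas: int) -> np.ndarray:
    """Resample a component onto a canvas with its centroid at the center."""
    rows, cols = np.nonzero(mask)
    centroid = np.array([cols.mean(), rows.mean()])
    cc = (canvas - 1) / 2.0
    yy, xx = np.mgrid[0:canvas, 0:canvas].astype(float)
    xs = xx - cc + centroid[0]
    ys = yy - cc + centroid[1]
    return ndimage.map_coordinates(mask.astype(np.float32), [ys, xs], order=1, cval=0.0)


def build_mean_shape(
    masks,
    label: str = "",
    recording_id: str = "",
    source: str = "ground_truth",
    min_align_iou: float = 0.3,
    steps=(1.0, 0.1),
) -> MeanShape:
    """Build a rigid mean shape from per-frame masks of one vertebra.

    Each frame's largest component is translated to centroid-origin, the
    median usable frame serves as the rotational reference, every other
    frame is aligned to it by the IoU-maximizing rotation, and the aligned
    occupancy maps are averaged and thresholded at 0.5.

    Raises :class:`MeanShapeError` when fewer than 3 frames are usable or
    when more than half of the frames cannot be aligned with IoU >=
    ``min_align_iou`` — the situation in which no meaningful rigid
    template exists for the recording.
    """
    comps = []
    for m in masks:
        m = np.asarray(m)
        if m.sum() == 0:
            continue
        comps.append(largest_component(m))
    if len(comps) < 3:
        raise MeanShapeError(
            f"{label or 'vertebra'}: only {len(comps)} usable frames (need >= 3)"
        )

    extents = []
    for c in comps:
        rows, cols = np.nonzero(c)
        extents.append(max(np.ptp(rows) + 1, np.ptp(cols) + 1))
    canvas = int(np.ceil(max(extents) * 1.45)) + 8
    canvas += 1 - canvas % 2  # odd, so the center is a pixel

    centered = [_centered_occupancy(c, canvas) for c in comps]
    ref_idx = len(centered) // 2
    ref = centered[ref_idx]
    cc = np.array([(canvas - 1) / 2.0] * 2)

    accum = np.zeros((canvas, canvas), dtype=np.float64)
    failures = 0
    for i, occ in enumerate(centered):
        if i == ref_idx:
            accum += occ
            continue
        rot = _RotatedTemplate(occ, cc)
        angle, best = _grid_search(
            lambda a: _overlap_curve(rot, ref, cc, a), 0.0, FIRST_FRAME_HALF_RANGE, steps
        )
        if best < min_align_iou:
            failures += 1
            continue
        yy, xx = np.mgrid[0:canvas, 0:canvas].astype(float)
        rel = np.stack([(xx - cc[0]).ravel(), (yy - cc[1]).ravel()])
        accum += rot.sample(np.array([angle]), rel).reshape(canvas, canvas)

    if failures > len(centered) / 2:
        raise MeanShapeError(
            f"{label or 'vertebra'}: {failures}/{len(centered)} frames failed "
            f"rotational alignment (IoU < {min_align_iou})"
        )
    template = (accum / (len(centered) - failures) >= 0.5).astype(np.uint8)
    if template.sum() == 0:
        raise MeanShapeError(f"{label or 'vertebra'}: mean occupancy below 0.5 everywhere")

    # recenter: integer shift putting the centroid within 0.5 px of the center
    rows, cols = np.nonzero(template)
    shift = np.rint([cc[1] - rows.mean(), cc[0] - cols.mean()]).astype(int)
    template = np.roll(template, shift, axis=(0, 1))
    return MeanShape(template=template, label=label, recording_id=recording_id, source=source)


# --------------------------------------------------------------------------
# Fitting and tracking
# --------------------------------------------------------------------------

def fit_mean_shape(
    shape: MeanShape,
    target: np.ndarray,
    frame: int = 0,
    center_deg: float = 0.0,
    half_range: float = FIRST_FRAME_HALF_RANGE,
    steps=DEFAULT_STEPS,
) -> ShapeFit:
    """Fit the mean shape to one frame's mask by centroid placement + rotation.

    The template is pinned to the target's centroid and the angle that
    maximizes the overlap is found by the coarse-to-fine grid search.  An
    empty target yields a non-converged sentinel fit.
    """
    target = np.asarray(target)
    if target.sum() == 0:
        return ShapeFit(
            frame=frame,
            angle_deg=float("nan"),
            centroid=np.array([np.nan, np.nan]),
            overlap_iou=0.0,
            converged=False,
        )
    rows, cols = np.nonzero(target)
    centroid = np.array([cols.mean(), rows.mean()])
    rot = _RotatedTemplate(shape.template, shape.center)
    angle, best = _grid_search(
        lambda a: _overlap_curve(rot, target, centroid, a), center_deg, half_range, steps
    )
    return ShapeFit(
        frame=frame, angle_deg=angle, centroid=centroid, overlap_iou=best, converged=True
    )


def track_recording(
    shape: MeanShape,
    masks: np.ndarray,
    frames: list[int] | None = None,
    max_unfittable_frac: float = 0.2,
    steps=DEFAULT_STEPS,
) -> list[ShapeFit]:
    """Fit the mean shape to every predicted frame of a recording.

    The search window of each frame is centered on the previous frame's
    angle (±10°), enforcing temporal continuity; the first frame searches
    ±45° around 0.  Frames whose mask is empty after largest-component
    selection keep the previous angle and are marked non-converged; if
    more than ``max_unfittable_frac`` of the frames are unfittable a
    :class:`TrackingError` is raised naming them.
    """
    masks = np.asarray(masks)
    if frames is None:
        frames = list(range(masks.shape[0]))
    fits: list[ShapeFit] = []
    prev_angle: float | None = None
    unfittable: list[int] = []
    for i, fr in enumerate(frames):
        target = largest_component(masks[i])
        if target.sum() == 0:
            unfittable.append(fr)
            angle = prev_angle if prev_angle is not None else 0.0
            fits.append(
                ShapeFit(
                    frame=fr,
                    angle_deg=angle,
                    centroid=np.array([np.nan, np.nan]),
                    overlap_iou=0.0,
                    converged=False,
                )
            )
            continue
        if prev_angle is None:
            fit = fit_mean_shape(shape, target, fr, 0.0, FIRST_FRAME_HALF_RANGE, steps)
        else:
            fit = fit_mean_shape(shape, target, fr, prev_angle, TRACKING_HALF_RANGE, steps)
        prev_angle = fit.angle_deg
        fits.append(fit)
    if len(unfittable) >= max_unfittable_frac * len(frames):
        raise TrackingError(
            f"{shape.label or 'vertebra'}: unfittable frames {unfittable}"
        )
    return fits


def write_mean_shape(path, shape: MeanShape) -> None:
    """Serialize a mean shape as TIFF plus a JSON metadata sidecar."""
    import json
    import pathlib

    import tifffile

    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, shape.template)
    path.with_suffix(".json").write_text(
        json.dumps(
            {"label": shape.label, "recording_id": shape.recording_id, "source": shape.source}
        )
    )


def read_mean_shape(path) -> MeanShape:
    import json
    import pathlib

    import tifffile

    path = pathlib.Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return MeanShape(template=tifffile.imread(path).astype(np.uint8), **meta)


def render_fit(shape: MeanShape, fit: ShapeFit, image_shape) -> np.ndarray:
    """Binary rasterization of the mean shape at a fitted pose."""
    out = np.zeros(image_shape, dtype=np.uint8)
    if not fit.converged or not np.isfinite(fit.centroid).all():
        return out
    rot = _RotatedTemplate(shape.template, shape.center)
    radius = int(np.ceil(np.hypot(*shape.template.shape) / 2)) + 2
    sl, rel = _crop_grid(fit.centroid, radius, image_shape)
    vals = rot.sample(np.array([fit.angle_deg]), rel)[0]
    h = sl[0].stop - sl[0].start
    w = sl[1].stop - sl[1].start
    out[sl] = (vals.reshape(h, w) >= 0.5).astype(np.uint8)
    return out


def mean_shape_agreement(
    shape: MeanShape, fits: list[ShapeFit], masks: np.ndarray
) -> float:
    """Mean IoU over frames between the fitted mean shape and comparison masks.

    Frames with an empty comparison mask or a non-converged fit are
    excluded from the mean.
    """
    from .metrics import iou

    masks = np.asarray(masks)
    vals = []
    for i, fit in enumerate(fits):
        if not fit.converged or masks[i].sum() == 0:
            continue
        vals.append(iou(render_fit(shape, fit, masks[i].shape), masks[i]))
    return float(np.mean(vals)) if vals else float("nan")
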