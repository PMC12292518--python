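"""Relative-rotation trajectories and the sequence of segmental contribution.

For a vertebra C with orientation angle θ_C(t), the per-frame relative
rotation is dθ_C(t) = θ_C(t) − θ_C(t−1), with dθ_C = 0 on the first frame
(no preceding frame) and on frames a 2D+t model did not predict.  For a
segment of two adjacent vertebrae Ck, Cl the segmental relative rotation
is dθ_R(t) = dθ_Ck(t) − dθ_Cl(t).

The motion pattern of interest is the *sequence of segmental
contribution*: the order in which the C4-C7 segments reach their peak
dθ_R relative to the cumulative rotation of vertebrae C4-C7 during
extension.  Outliers (trajectory values outside the range of the gold
standard) and negative mean ICCs trigger recording-level exclusion before
any ICC summary is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import LABELS, SEGMENTS


@dataclass
class RotationTrajectory:
    """Per-frame relative rotation dθ_C of one vertebra over a recording."""

    label: str
    dtheta_deg: np.ndarray  # (n_frames,), zero outside predicted frames
    predicted_frames: list[int]
    source: str = "mean_shape_fit"  # or "ground_truth"


@dataclass
class SegmentTrajectory:
    """Per-frame segmental relative rotation dθ_R for a vertebra pair."""

    pair: tuple[str, str]
    dtheta_deg: np.ndarray
    predicted_frames: list[int]
    outlier_flags: np.ndarray | None = None

    @property
    def name(self) -> str:
        return f"{self.pair[0]}-{self.pair[1]}"


@dataclass
class ExclusionReport:
    """Whether a recording is excluded at one level, and why."""

    recording_id: str
    level: str
    excluded: bool
    reason: str  # "negative_mean_icc" | "outlier_present" | "none"


def vertebra_rotation_series(
    angles_deg,
    predicted_frames: list[int],
    n_frames: int | None = None,
    label: str = "",
    source: str = "mean_shape_fit",
) -> RotationTrajectory:
    """Difference an angle series into a relative-rotation trajectory.

    ``angles_deg`` holds θ_C(t) for each entry of ``predicted_frames`` (a
    contiguous run of middle frames).  dθ_C is zero on the first predicted
    frame (no preceding prediction) and on all frames outside the
    predicted set.  A NaN at an interior predicted frame is an error.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.shape[0] != len(predicted_frames):
        raise ValueError("angle series and predicted_frames length mismatch")
    if np.isnan(angles).any():
        bad = [predicted_frames[i] for i in np.nonzero(np.isnan(angles))[0]]
        raise ValueError(f"missing angle at predicted frames {bad}")
    if n_frames is None:
        n_frames = (max(predicted_frames) + 1) if predicted_frames else 0
    dtheta = np.zeros(n_frames)
    for i in range(1, len(predicted_frames)):
        dtheta[predicted_frames[i]] = angles[i] - angles[i - 1]
    return RotationTrajectory(
        label=label,
        dtheta_deg=dtheta,
        predicted_frames=list(predicted_frames),
        source=source,
    )


def segment_rotation_series(
    a: RotationTrajectory, b: RotationTrajectory
) -> SegmentTrajectory:
    """dθ_R = dθ_Ck − dθ_Cl on a shared frame grid."""
    if a.dtheta_deg.shape != b.dtheta_deg.shape or a.predicted_frames != b.predicted_frames:
        raise ValueError("trajectories are on different frame grids")
    return SegmentTrajectory(
        pair=(a.label, b.label),
        dtheta_deg=a.dtheta_deg - b.dtheta_deg,
        predicted_frames=list(a.predicted_frames),
    )


def detect_outliers(
    values, gt_min: float, gt_max: float, margin: float = 0.0
) -> np.ndarray:
    """Flag frames whose value leaves [gt_min − margin, gt_max + margin].

    The reference bounds are the min/max raw values of the gold-standard
    trajectory for the same recording and level.
    """
    v = np.asarray(
        values.dtheta_deg if isinstance(values, (RotationTrajectory, SegmentTrajectory)) else values,
        dtype=float,
    )
    return (v < gt_min - margin) | (v > gt_max + margin)


def apply_exclusions(records) -> list[ExclusionReport]:
    """Apply the recording-level exclusion rules.

    ``records`` is an iterable of (recording_id, level, mean_icc,
    outlier_flags).  A recording/level is excluded when its mean ICC is
    negative or when at least one frame is flagged as an outlier.
    """
    reports = []
    for rec_id, level, mean_icc, flags in records:
        has_outlier = bool(np.any(flags)) if flags is not None else False
        if mean_icc is not None and mean_icc < 0:
            reports.append(ExclusionReport(rec_id, level, True, "negative_mean_icc"))
        elif has_outlier:
            reports.append(ExclusionReport(rec_id, level, True, "outlier_present"))
        else:
            reports.append(ExclusionReport(rec_id, level, False, "none"))
    return reports


# --------------------------------------------------------------------------
# Sequence of segmental contribution
# --------------------------------------------------------------------------

CONTRIBUTION_SEGMENTS: tuple[str, ...] = ("C4-C5", "C5-C6", "C6-C7")
CONTRIBUTION_VERTEBRAE: tuple[str, ...] = ("C4", "C5", "C6", "C7")


@dataclass
class ContributionSequence:
    """Segments ordered by where their dθ_R peaks on the cumulative rotation."""

    order: list[str]
    peak_frames: dict[str, int]
    cumulative_at_peak: dict[str, float]
    ambiguous: dict[str, bool] = field(default_factory=dict)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge shrinkage."""
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


def contribution_sequence(
    segment_trajs: dict[str, SegmentTrajectory],
    vertebra_trajs: dict[str, RotationTrajectory],
    window: int = 5,
) -> ContributionSequence:
    """Order the C4-C7 segments by their peak contribution to extension.

    The cumulative rotation is the running sum of dθ_C over vertebrae
    C4-C7.  Each segment's dθ_R series is smoothed with a centered moving
    average (default window 5 frames) and the cumulative-rotation value at
    its maximum located.  Segments are returned ordered by that value;
    within-series ties go to the earlier frame and are flagged ambiguous,
    as are segments whose peak locations coincide exactly.
    """
    missing = [s for s in CONTRIBUTION_SEGMENTS if s not in segment_trajs]
    if missing:
        raise ValueError(f"missing segment trajectories: {missing}")
    missing_v = [v for v in CONTRIBUTION_VERTEBRAE if v not in vertebra_trajs]
    if missing_v:
        raise ValueError(f"missing vertebra trajectories: {missing_v}")

    total = np.sum(
        [vertebra_trajs[v].dtheta_deg for v in CONTRIBUTION_VERTEBRAE], axis=0
    )
    cumulative = np.cumsum(total)

    peak_frames: dict[str, int] = {}
    cum_at_peak: dict[str, float] = {}
    ambiguous: dict[str, bool] = {}
    flat: dict[str, bool] = {}
    for seg in CONTRIBUTION_SEGMENTS:
        smoothed = _smooth(segment_trajs[seg].dtheta_deg, window)
        peak_val = smoothed.max()
        peaks = np.nonzero(smoothed == peak_val)[0]
        peak_frames[seg] = int(peaks[0])  # tie -> earlier frame
        ambiguous[seg] = len(peaks) > 1
        flat[seg] = bool(smoothed.max() == smoothed.min())  # never contributes
        cum_at_peak[seg] = float(cumulative[peak_frames[seg]])

    # exact coincidence of peak positions leaves the order undefined
    for s1 in CONTRIBUTION_SEGMENTS:
        for s2 in CONTRIBUTION_SEGMENTS:
            if s1 < s2 and cum_at_peak[s1] == cum_at_peak[s2] and flat[s1] == flat[s2]:
                ambiguous[s1] = ambiguous[s2] = True

    # contributing segments ordered by peak position; flat ones trail
    order = sorted(
        CONTRIBUTION_SEGMENTS,
        key=lambda s: (flat[s], cum_at_peak[s], peak_frames[s]),
    )
    return ContributionSequence(
        order=order,
        peak_frames=peak_frames,
        cumulative_at_peak=cum_at_peak,
        ambiguous=ambiguous,
    )


def trajectories_from_angles(
    angle_matrix: np.ndarray,
    predicted_frames: list[int],
    n_frames: int,
    source: str = "ground_truth",
) -> dict[str, RotationTrajectory]:
    """Vertebra trajectories for all labels from a (T, 8) angle matrix."""
    trajs = {}
    for ci, lab in enumerate(LABELS):
        trajs[lab] = vertebra_rotation_series(
            angle_matrix[predicted_frames, ci],
            predicted_frames,
            n_frames=n_frames,
            label=lab,
            source=source,
        )
    return trajs


def segment_trajectories(
    vertebra_trajs: dict[str, RotationTrajectory],
    segments=SEGMENTS,
) -> dict[str, SegmentTrajectory]:
    """All adjacent-pair segment trajectories available from the input."""
    out = {}
    for seg in segments:
        upper, lower = seg.split("-")
        if upper in vertebra_trajs and lower in vertebra_trajs:
            out[seg] = segment_rotation_series(
                vertebra_trajs[upper], vertebra_trajs[lower]
            )
    return out
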