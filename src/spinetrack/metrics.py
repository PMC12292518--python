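"""Overlap metrics between predicted and ground-truth masks.

IoU(A, B) = |A ∩ B| / |A ∪ B| and DSC(A, B) = 2|A ∩ B| / (|A| + |B|);
the two are linked by DSC = 2 IoU / (1 + IoU), so the IoU always penalizes
a mismatch at least as hard.  By the field's convention scores above 0.7
are good, 0.5-0.7 moderate and below 0.5 poor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class OverlapScore:
    """IoU/DSC of one vertebra in one frame (of one recording/model)."""

    iou: float
    dsc: float
    vertebra: str
    frame: int
    recording_id: str = ""
    model_id: str = ""


def _counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    inter = int(np.count_nonzero(a & b))
    return inter, int(np.count_nonzero(a)), int(np.count_nonzero(b))


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union; both masks empty counts as perfect (1)."""
    inter, na, nb = _counts(a, b)
    union = na + nb - inter
    if union == 0:
        warnings.warn("IoU of two empty masks defined as 1", stacklevel=2)
        return 1.0
    return inter / union


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient; both masks empty counts as perfect (1)."""
    inter, na, nb = _counts(a, b)
    if na + nb == 0:
        warnings.warn("DSC of two empty masks defined as 1", stacklevel=2)
        return 1.0
    return 2.0 * inter / (na + nb)


def aggregate_scores(scores) -> pd.DataFrame:
    """Per-(model, vertebra) mean IoU/DSC over frames.

    Frames whose ground truth was empty are expected to have been skipped
    upstream; the paired frame-level values stay available in the input
    list for significance testing.
    """
    if not scores:
        raise ValueError("no scores to aggregate")
    df = pd.DataFrame([s.__dict__ for s in scores])
    return (
        df.groupby(["model_id", "vertebra"], sort=True)[["iou", "dsc"]]
        .mean()
        .reset_index()
    )


def scores_to_frame(scores) -> pd.DataFrame:
    """Flat table (recording, frame, vertebra, iou, dsc) for CSV export."""
    return pd.DataFrame([s.__dict__ for s in scores])
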