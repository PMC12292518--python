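"""Per-vertebra probability thresholding via PR-curve F1 maximization.

The segmenter outputs per-pixel class probabilities; each vertebra channel
is binarized independently with its own threshold.  Candidate thresholds
run from 0.1 to 0.9 in steps of 0.1; for each, precision and recall are
computed from pixel counts pooled over all supplied frames, and the
threshold with the highest F1 (harmonic mean) wins, ties going to the
lowest threshold.  Fragmented masks are cleaned by keeping only the
largest 8-connected component.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synthetic import LABELS
from .unet import ProbabilityMaps

logger = logging.getLogger(__name__)

THRESHOLD_GRID: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 10))

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass
class ThresholdTable:
    """One optimized threshold per vertebra label, with provenance."""

    thresholds: dict[str, float]
    provenance: dict = None  # e.g. {"subset": "val", "model_id": "k3"}

    def __getitem__(self, label: str) -> float:
        return self.thresholds[label]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"thresholds": self.thresholds, "provenance": self.provenance or {}},
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "ThresholdTable":
        with open(path) as fh:
            doc = json.load(fh)
        if "thresholds" not in doc:  # bare mapping form
            doc = {"thresholds": doc, "provenance": {}}
        return cls(
            thresholds={k: float(v) for k, v in doc["thresholds"].items()},
            provenance=doc.get("provenance") or {},
        )


@dataclass
class BinaryMasks:
    """Binarized per-frame, per-vertebra masks with their provenance."""

    masks: dict[str, np.ndarray]  # label -> (n_frames, H, W) uint8
    frames: list[int]
    provenance: dict


def pr_points(
    probs: np.ndarray,
    gt: np.ndarray,
    thresholds=THRESHOLD_GRID,
) -> list[tuple[float, float, float, float]]:
    """(threshold, precision, recall, F1) for each candidate threshold.

    Pixel counts are pooled over everything passed in, so ``probs``/``gt``
    may cover a single frame or a whole validation subset.  An empty
    prediction has precision defined as 0.  Ground truth without any
    foreground leaves recall undefined and raises.
    """
    probs = np.asarray(probs, dtype=float).ravel()
    gt = np.asarray(gt).ravel().astype(bool)
    if probs.shape != gt.shape:
        raise ValueError("probs and gt are not aligned")
    if not gt.any():
        raise ValueError("ground truth has no foreground pixels; recall undefined")
    points = []
    for th in thresholds:
        pred = probs >= th
        tp = int(np.count_nonzero(pred & gt))
        fp = int(np.count_nonzero(pred & ~gt))
        fn = int(np.count_nonzero(~pred & gt))
        precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
        recall = tp / (tp + fn)
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
        points.append((float(th), precision, recall, f1))
    return points


def select_threshold(points) -> float:
    """Threshold with maximal F1; ties broken by the lowest threshold."""
    if not points:
        raise ValueError("no PR points supplied")
    best_f1 = max(p[3] for p in points)
    if best_f1 == 0.0:
        logger.warning("all F1 scores are 0; falling back to threshold 0.5")
        return 0.5
    return min(p[0] for p in points if p[3] == best_f1)


def optimize_thresholds(
    probs_by_label: dict[str, np.ndarray],
    gt_by_label: dict[str, np.ndarray],
    thresholds=THRESHOLD_GRID,
    provenance: dict | None = None,
) -> ThresholdTable:
    """Select one threshold per vertebra from pooled validation pixels."""
    table = {}
    for lab in probs_by_label:
        table[lab] = select_threshold(
            pr_points(probs_by_label[lab], gt_by_label[lab], thresholds)
        )
    return ThresholdTable(thresholds=table, provenance=provenance or {})


def binarize(
    probs: ProbabilityMaps, table: ThresholdTable, model_id: str = ""
) -> BinaryMasks:
    """Apply per-vertebra thresholds; a pixel at the threshold is included."""
    missing = [lab for lab in LABELS if lab not in table.thresholds]
    if missing:
        raise ValueError(f"threshold table lacks vertebrae: {missing}")
    masks = {
        lab: (probs.channel(lab) >= table[lab]).astype(np.uint8) for lab in LABELS
    }
    return BinaryMasks(
        masks=masks,
        frames=list(probs.frames),
        provenance={"model_id": model_id, "thresholds": dict(table.thresholds)},
    )


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected component of a binary mask.

    Size ties are broken by the component containing the smallest row-major
    pixel index.  An empty mask is returned unchanged.
    """
    labeled, n = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    if n <= 1:
        return np.asarray(mask, dtype=np.uint8)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    best = np.max(sizes)
    candidates = np.nonzero(sizes == best)[0] + 1
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        flat = labeled.ravel()
        first_idx = {
            c: np.argmax(flat == c) for c in candidates
        }  # argmax finds the first occurrence
        keep = min(candidates, key=lambda c: first_idx[c])
    return (labeled == keep).astype(np.uint8)
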