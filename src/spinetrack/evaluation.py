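"""Agreement statistics and report assembly.

The primary outcome of the pipeline is the intraclass correlation
coefficient between a tracked relative-rotation trajectory and the ground
truth, computed per recording and summarized as mean [min-max] with the
number of retained recordings.  The ICC form is the two-way mixed-effects,
consistency, single-measures coefficient ICC(3,1): frames are rows, the
two raters (ground truth, model) are fixed columns, and consistency is
used because a constant angular offset between the tracker and the ground
truth should not be penalized.  From the two-way ANOVA decomposition with
n frames and k = 2 raters,

    ICC(3,1) = (MS_rows − MS_error) / (MS_rows + (k − 1) MS_error),

which can be negative when the two series move in opposite directions.

Model comparisons use the two-sided Wilcoxon signed-rank test on paired
scores (exact null distribution up to n = 25, computed by dynamic
programming over doubled midranks so that tied differences are handled
exactly; normal approximation with tie correction beyond).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy import stats as sps


@dataclass
class ICCResult:
    """ICC summary for one level (vertebra or segment) under one model."""

    level: str
    model_id: str
    icc: float  # mean over retained recordings
    n: int
    icc_min: float = float("nan")
    icc_max: float = float("nan")
    per_recording: dict[str, float] = field(default_factory=dict)


@dataclass
class ModelComparison:
    """Wilcoxon comparison of one metric between two models."""

    metric: str
    model_a: str
    model_b: str
    p_value: float
    significant: bool  # at alpha = 0.05


# --------------------------------------------------------------------------
# ICC
# --------------------------------------------------------------------------

def icc_two_way_mixed(x, y) -> float:
    """Two-way mixed, consistency, single-measures ICC(3,1) of two series.

    ``x`` and ``y`` are the paired raters (e.g. ground-truth and tracked
    trajectories) over at least three frames.  Returns NaN with a warning
    when neither series varies (the coefficient is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    n = x.size
    if n < 3:
        raise ValueError("ICC requires at least 3 paired observations")
    data = np.stack([x, y], axis=1)  # rows = frames, cols = raters
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err
    if denom <= 0:
        warnings.warn("zero variance in both series; ICC undefined", stacklevel=2)
        return float("nan")
    return float((ms_rows - ms_err) / denom)


def trajectory_icc(
    model_series: dict[str, np.ndarray],
    gt_series: dict[str, np.ndarray],
    excluded: set[str] | None = None,
    level: str = "",
    model_id: str = "",
) -> ICCResult:
    """Per-recording ICCs summarized as mean [min-max] over retained recordings.

    ``model_series``/``gt_series`` map recording ids to paired trajectories
    over frames.  Recordings in ``excluded`` do not contribute.
    """
    excluded = excluded or set()
    per_rec = {}
    for rec_id, series in model_series.items():
        if rec_id in excluded or rec_id not in gt_series:
            continue
        per_rec[rec_id] = icc_two_way_mixed(gt_series[rec_id], series)
    vals = [v for v in per_rec.values() if np.isfinite(v)]
    if not vals:
        return ICCResult(level=level, model_id=model_id, icc=float("nan"), n=0)
    return ICCResult(
        level=level,
        model_id=model_id,
        icc=float(np.mean(vals)),
        n=len(vals),
        icc_min=float(np.min(vals)),
        icc_max=float(np.max(vals)),
        per_recording=per_rec,
    )


# --------------------------------------------------------------------------
# Wilcoxon signed-rank test
# --------------------------------------------------------------------------

def _exact_signed_rank_p(ranks2: np.ndarray, w2: int) -> float:
    """Exact two-sided p over all sign assignments, by DP on doubled ranks."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped.  For n <= 25 the p-value is exact (the
    full null distribution of the positive rank sum is enumerated, tied
    |differences| receiving midranks); for larger n the normal
    approximation with the standard tie correction is used.  All
    differences zero yields p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    if n <= 25:
        ranks2 = np.rint(2 * ranks).astype(int)  # doubled midranks are integers
        w2 = int(round(2 * w_plus))
        return _exact_signed_rank_p(ranks2, w2)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w_plus - mean) / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


# --------------------------------------------------------------------------
# Report assembly
# --------------------------------------------------------------------------

@dataclass
class Report:
    """Assembled evaluation tables for a set of trained models."""

    overlap: pd.DataFrame  # per vertebra x model IoU/DSC with best/significance flags
    vertebra_icc: pd.DataFrame
    segment_icc: pd.DataFrame
    comparisons: list[ModelComparison]

    def to_markdown(self) -> str:
        parts = ["# Evaluation report", "", "## Overlap (test set)", ""]
        parts.append(self.overlap.to_markdown(index=False))
        if len(self.vertebra_icc):
            parts += ["", "## ICC, individual vertebrae", "", self.vertebra_icc.to_markdown(index=False)]
        if len(self.segment_icc):
            parts += ["", "## ICC, vertebral segments", "", self.segment_icc.to_markdown(index=False)]
        return "\n".join(parts) + "\n"


def _icc_table(results: list[ICCResult]) -> pd.DataFrame:
    rows = [
        {
            "level": r.level,
            "model": r.model_id,
            "icc": r.icc,
            "icc_min": r.icc_min,
            "icc_max": r.icc_max,
            "n": r.n,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def build_report(
    overlap_scores,
    vertebra_iccs: list[ICCResult] | None = None,
    segment_iccs: list[ICCResult] | None = None,
    alpha: float = 0.05,
) -> Report:
    """Assemble per-vertebra overlap and ICC tables across models.

    For each vertebra and metric the best-scoring model is flagged; an
    asterisk marks best models whose paired frame-level scores differ
    significantly (Wilcoxon, p <= alpha) from *every* other model.  With a
    single model no comparisons are computed.
    """
    df = pd.DataFrame([s.__dict__ for s in overlap_scores])
    models = sorted(df["model_id"].unique())
    comparisons: list[ModelComparison] = []
    rows = []
    for vert, sub in df.groupby("vertebra", sort=True):
        row: dict = {"vertebra": vert}
        for metric in ("iou", "dsc"):
            means = sub.groupby("model_id")[metric].mean()
            best_model = means.idxmax()
            row.update({f"{metric}_{m}": means.get(m, np.nan) for m in models})
            row[f"{metric}_best"] = best_model
            significant = len(models) > 1
            pivot = sub.pivot_table(
                index=["recording_id", "frame"], columns="model_id", values=metric
            )
            for other in models:
                if other == best_model:
                    continue
                paired = pivot[[best_model, other]].dropna()
                if len(paired) == 0:
                    significant = False
                    continue
                p = wilcoxon_signed_rank(paired[best_model], paired[other])
                comparisons.append(
                    ModelComparison(
                        metric=f"{metric}:{vert}",
                        model_a=best_model,
                        model_b=other,
                        p_value=p,
                        significant=p <= alpha,
                    )
                )
                if p > alpha:
                    significant = False
            row[f"{metric}_significant"] = significant
        rows.append(row)
    return Report(
        overlap=pd.DataFrame(rows),
        vertebra_icc=_icc_table(vertebra_iccs or []),
        segment_icc=_icc_table(segment_iccs or []),
        comparisons=comparisons,
    )
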