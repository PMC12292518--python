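"""Dataset handling, subject-level splitting, configuration and the pipeline.

Recordings are always allocated to train/validation/test *per individual*:
two recordings of the same subject must never straddle the split, or the
segmenter would be evaluated on anatomy it has seen.  Normalization
statistics come from the training subset only and thresholds from the
validation subset only; both carry provenance so the constraint is
checkable.

``run_pipeline`` chains the whole method: simulate -> split -> train ->
predict -> threshold -> analyze -> evaluate, with every stage's outputs
serialized under the run directory and a per-stage marker enabling
resumption.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import meanshape, metrics, motion, thresholding, unet
from .evaluation import ICCResult, build_report, icc_two_way_mixed, trajectory_icc
from .synthetic import LABELS, KinematicsConfig, make_recording, read_recording, write_recording
from .unet import ModelConfig, NormalizationStats, ProbabilityMaps

logger = logging.getLogger(__name__)

SUBSETS = ("train", "val", "test")
STAGES = ("simulate", "split", "train", "predict", "threshold", "analyze", "evaluate")


def setup_logging(log_file=None, level=logging.INFO) -> None:
    """Structured logging to console and, optionally, a file."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


# --------------------------------------------------------------------------
# Manifest and subject-level splitting
# --------------------------------------------------------------------------

@dataclass
class RecordingEntry:
    id: str
    individual: str
    direction: str
    path: str
    subset: str | None = None


@dataclass
class DatasetManifest:
    """Recording inventory with (optional) subset assignment."""

    entries: list[RecordingEntry]

    def validate(self) -> None:
        by_ind: dict[str, set] = {}
        for e in self.entries:
            if e.subset is not None:
                by_ind.setdefault(e.individual, set()).add(e.subset)
        bad = {i: s for i, s in by_ind.items() if len(s) > 1}
        if bad:
            raise ValueError(f"individuals straddle subsets: {bad}")

    def subset(self, name: str) -> list[RecordingEntry]:
        return [e for e in self.entries if e.subset == name]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([dataclasses.asdict(e) for e in self.entries], fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DatasetManifest":
        with open(path) as fh:
            return cls(entries=[RecordingEntry(**d) for d in json.load(fh)])


def split_dataset(
    manifest: DatasetManifest,
    fractions=(0.55, 0.20, 0.25),
    seed: int = 0,
) -> DatasetManifest:
    """Assign individuals to train/val/test, matching recording fractions.

    Greedy bin packing: individuals are visited in seeded random order,
    largest recording count first, and each goes to the subset with the
    largest remaining deficit relative to its target recording count.
    Every recording of an individual lands in the same subset.
    """
    individuals: dict[str, list[RecordingEntry]] = {}
    for e in manifest.entries:
        individuals.setdefault(e.individual, []).append(e)
    if len(individuals) < len(SUBSETS):
        raise ValueError(
            f"need at least {len(SUBSETS)} individuals, got {len(individuals)}"
        )
    total = len(manifest.entries)
    targets = np.array(fractions, dtype=float) / np.sum(fractions) * total
    assigned = np.zeros(len(SUBSETS))

    rng = np.random.default_rng(seed)
    names = list(individuals)
    rng.shuffle(names)
    names.sort(key=lambda n: -len(individuals[n]))  # stable: keeps seeded order in ties

    assignment: dict[str, str] = {}
    for name in names:
        deficit = targets - assigned
        subset_i = int(np.argmax(deficit))
        assignment[name] = SUBSETS[subset_i]
        assigned[subset_i] += len(individuals[name])
    # guarantee non-empty subsets
    for si, s in enumerate(SUBSETS):
        if assigned[si] == 0:
            donor = max(assignment, key=lambda n: assigned[SUBSETS.index(assignment[n])])
            assigned[SUBSETS.index(assignment[donor])] -= len(individuals[donor])
            assignment[donor] = s
            assigned[si] += len(individuals[donor])

    entries = [
        dataclasses.replace(e, subset=assignment[e.individual]) for e in manifest.entries
    ]
    out = DatasetManifest(entries=entries)
    out.validate()
    return out


# --------------------------------------------------------------------------
# Pipeline configuration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration; all randomness funnels through ``seed``."""

    out_dir: str
    seed: int = 0
    n_individuals: int = 6
    recordings_per_individual: int = 2
    fractions: tuple[float, float, float] = (0.55, 0.20, 0.25)
    kinematics: dict = field(default_factory=dict)  # KinematicsConfig overrides
    ks: tuple[int, ...] = (1,)
    n_levels: int = 4
    base_filters: int = 8
    learning_rate: float = 2e-3
    batch_size: int = 8
    max_epochs: int = 45
    patience: int = 8
    min_delta: float = 1e-3
    ce_weights: dict = field(default_factory=lambda: {1: 0.5, 3: 0.1})
    outlier_margin: float = 0.0
    smoothing_window: int = 5

    def validate(self) -> None:
        if self.n_individuals < 3:
            raise ValueError("need at least 3 individuals")
        if any(k % 2 != 1 for k in self.ks):
            raise ValueError("temporal windows must be odd")
        KinematicsConfig(**{**self.kinematics, "seed": 0}).validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        for key in ("fractions", "ks"):
            if key in doc:
                doc[key] = tuple(doc[key])
        if "kinematics" in doc:
            for k2 in ("image_size", "contrast_range", "segment_peak_order"):
                if k2 in doc["kinematics"]:
                    doc["kinematics"][k2] = tuple(doc["kinematics"][k2])
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def kin_for(self, seed: int) -> KinematicsConfig:
        return KinematicsConfig(**{**self.kinematics, "seed": seed})

    def model_config(self, k: int) -> ModelConfig:
        kin = self.kin_for(0)
        return ModelConfig(
            n_levels=self.n_levels,
            in_frames=k,
            base_filters=self.base_filters,
            image_size=tuple(kin.image_size),
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            min_delta=self.min_delta,
            ce_weight=float(self.ce_weights.get(k, 0.1)),
            seed=self.seed,
        )


# --------------------------------------------------------------------------
# Checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(path, model: unet.UNet, stats: NormalizationStats, history=None) -> None:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.params)
    sidecar = {
        "config": dataclasses.asdict(model.cfg),
        "stats": {"mean": stats.mean, "sd": stats.sd},
    }
    if history is not None:
        sidecar["history"] = {
            "train_loss": history["train_loss"],
            "val_loss": history["val_loss"],
        }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_checkpoint(path) -> tuple[unet.UNet, NormalizationStats]:
    path = pathlib.Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_doc = sidecar["config"]
    for key in ("image_size", "augment_contrast"):
        cfg_doc[key] = tuple(cfg_doc[key])
    model = unet.UNet(ModelConfig(**cfg_doc))
    with np.load(path) as data:
        model.params = {k: data[k] for k in data.files}
    stats = NormalizationStats(**sidecar["stats"])
    return model, stats


# --------------------------------------------------------------------------
# Pipeline stages
# --------------------------------------------------------------------------

def _paths(cfg: PipelineConfig) -> dict[str, pathlib.Path]:
    out = pathlib.Path(cfg.out_dir)
    return {
        "out": out,
        "recordings": out / "recordings",
        "manifest": out / "manifest.json",
        "models": out / "models",
        "probs": out / "probs",
        "thresholds": out / "thresholds",
        "analysis": out / "analysis",
        "report": out / "report",
    }


def _load_pairs(cfg: PipelineConfig, entries):
    pairs = []
    for e in entries:
        rec, ann = read_recording(e.path)
        pairs.append((e, rec, ann))
    return pairs


def stage_simulate(cfg: PipelineConfig) -> DatasetManifest:
    """Generate the synthetic dataset and its manifest (no subsets yet)."""
    p = _paths(cfg)
    entries = []
    for ind in range(cfg.n_individuals):
        for j in range(cfg.recordings_per_individual):
            seed = cfg.seed * 100003 + ind * 101 + j  # < 2^31 for desk-scale seeds
            kin = cfg.kin_for(seed)
            rec_id = f"ind{ind:02d}_rec{j}"
            rec, ann = make_recording(kin, recording_id=rec_id)
            rec_dir = p["recordings"] / rec_id
            write_recording(rec_dir, rec, ann, kin)
            entries.append(
                RecordingEntry(
                    id=rec_id,
                    individual=f"ind{ind:02d}",
                    direction=kin.direction,
                    path=str(rec_dir),
                )
            )
            logger.info("simulated %s", rec_id)
    manifest = DatasetManifest(entries=entries)
    manifest.to_json(p["manifest"])
    return manifest


def stage_split(cfg: PipelineConfig) -> DatasetManifest:
    p = _paths(cfg)
    manifest = DatasetManifest.from_json(p["manifest"])
    manifest = split_dataset(manifest, cfg.fractions, seed=cfg.seed)
    manifest.to_json(p["manifest"])
    for s in SUBSETS:
        logger.info("subset %s: %d recordings", s, len(manifest.subset(s)))
    return manifest


def stage_train(cfg: PipelineConfig) -> None:
    p = _paths(cfg)
    manifest = DatasetManifest.from_json(p["manifest"])
    train_pairs = [(r, a) for _, r, a in _load_pairs(cfg, manifest.subset("train"))]
    val_pairs = [(r, a) for _, r, a in _load_pairs(cfg, manifest.subset("val"))]
    for k in cfg.ks:
        mcfg = cfg.model_config(k)
        model = unet.build_unet(mcfg)
        train_samples = unet.build_training_samples(train_pairs, k)
        val_samples = unet.build_training_samples(val_pairs, k)
        logger.info("training k=%d on %d samples", k, len(train_samples))
        history = unet.train(model, train_samples, val_samples)
        save_checkpoint(p["models"] / f"k{k}" / "checkpoint.npz", model, history["stats"], history)


def stage_predict(cfg: PipelineConfig) -> None:
    p = _paths(cfg)
    manifest = DatasetManifest.from_json(p["manifest"])
    for k in cfg.ks:
        model, stats = load_checkpoint(p["models"] / f"k{k}" / "checkpoint.npz")
        for subset in ("val", "test"):
            for e in manifest.subset(subset):
                rec, _ = read_recording(e.path)
                probs = unet.predict(model, rec, stats)
                out = p["probs"] / f"k{k}"
                out.mkdir(parents=True, exist_ok=True)
                np.savez_compressed(
                    out / f"{e.id}.npz",
                    maps=probs.maps.astype(np.float16),
                    frames=np.array(probs.frames),
                )
                logger.info("predicted %s (k=%d)", e.id, k)


def _load_probs(path) -> ProbabilityMaps:
    with np.load(path) as data:
        return ProbabilityMaps(
            maps=data["maps"].astype(np.float32), frames=data["frames"].tolist()
        )


def stage_threshold(cfg: PipelineConfig) -> None:
    """Per-vertebra threshold selection on pooled validation pixels."""
    p = _paths(cfg)
    manifest = DatasetManifest.from_json(p["manifest"])
    for k in cfg.ks:
        probs_by_label: dict[str, list] = {lab: [] for lab in LABELS}
        gt_by_label: dict[str, list] = {lab: [] for lab in LABELS}
        for e in manifest.subset("val"):
            probs = _load_probs(p["probs"] / f"k{k}" / f"{e.id}.npz")
            _, ann = read_recording(e.path)
            for lab in LABELS:
                probs_by_label[lab].append(probs.channel(lab).ravel())
                gt_by_label[lab].append(ann.masks[lab][probs.frames].ravel())
        table = thresholding.optimize_thresholds(
            {lab: np.concatenate(v) for lab, v in probs_by_label.items()},
            {lab: np.concatenate(v) for lab, v in gt_by_label.items()},
            provenance={"subset": "val", "model_id": f"k{k}"},
        )
        p["thresholds"].mkdir(parents=True, exist_ok=True)
        table.to_json(p["thresholds"] / f"k{k}.json")
        logger.info("thresholds k=%d: %s", k, table.thresholds)


def stage_analyze(cfg: PipelineConfig) -> None:
    """Binarize test predictions, score overlap, build mean shapes, track."""
    p = _paths(cfg)
    manifest = DatasetManifest.from_json(p["manifest"])
    for k in cfg.ks:
        table = thresholding.ThresholdTable.from_json(p["thresholds"] / f"k{k}.json")
        out = p["analysis"] / f"k{k}"
        out.mkdir(parents=True, exist_ok=True)
        score_rows = []
        agreement_rows = []
        for e in manifest.subset("test"):
            probs = _load_probs(p["probs"] / f"k{k}" / f"{e.id}.npz")
            rec, ann = read_recording(e.path)
            bm = thresholding.binarize(probs, table, model_id=f"k{k}")
            n_frames = rec.n_frames

            for lab in LABELS:
                for i, fr in enumerate(bm.frames):
                    gt = ann.masks[lab][fr]
                    if gt.sum() == 0:
                        continue
                    score_rows.append(
                        metrics.OverlapScore(
                            iou=metrics.iou(bm.masks[lab][i], gt),
                            dsc=metrics.dsc(bm.masks[lab][i], gt),
                            vertebra=lab,
                            frame=fr,
                            recording_id=e.id,
                            model_id=f"k{k}",
                        )
                    )

            gt_trajs = motion.trajectories_from_angles(
                ann.angle_matrix(), bm.frames, n_frames, source="ground_truth"
            )
            traj_rows = []
            fit_rows = []
            model_trajs: dict[str, motion.RotationTrajectory] = {}
            for lab in meanshape.TRACKED_LABELS:
                try:
                    shape = meanshape.build_mean_shape(
                        bm.masks[lab], label=lab, recording_id=e.id, source="model"
                    )
                    fits = meanshape.track_recording(shape, bm.masks[lab], bm.frames)
                except (meanshape.MeanShapeError, meanshape.TrackingError) as err:
                    logger.warning("%s k=%d %s: %s", e.id, k, lab, err)
                    continue
                meanshape.write_mean_shape(
                    out / "mean_shapes" / f"{e.id}_{lab}.tif", shape
                )
                agreement_rows.append(
                    {
                        "recording_id": e.id,
                        "vertebra": lab,
                        "iou_vs_ground_truth": meanshape.mean_shape_agreement(
                            shape, fits, ann.masks[lab][bm.frames]
                        ),
                        "iou_vs_prediction": meanshape.mean_shape_agreement(
                            shape, fits, bm.masks[lab]
                        ),
                    }
                )
                for f in fits:
                    fit_rows.append(
                        {
                            "vertebra": lab,
                            "frame": f.frame,
                            "angle_deg": f.angle_deg,
                            "cx": f.centroid[0],
                            "cy": f.centroid[1],
                            "iou": f.overlap_iou,
                        }
                    )
                angles = [f.angle_deg for f in fits]
                traj = motion.vertebra_rotation_series(
                    angles, bm.frames, n_frames=n_frames, label=lab
                )
                model_trajs[lab] = traj
                gt_d = gt_trajs[lab].dtheta_deg
                flags = motion.detect_outliers(
                    traj, gt_d.min(), gt_d.max(), cfg.outlier_margin
                )
                for fr in range(n_frames):
                    traj_rows.append(
                        {
                            "level": lab,
                            "frame": fr,
                            "dtheta_deg": traj.dtheta_deg[fr],
                            "gt_dtheta_deg": gt_d[fr],
                            "outlier": bool(flags[fr]),
                        }
                    )
            model_segs = motion.segment_trajectories(model_trajs)
            gt_segs = motion.segment_trajectories(gt_trajs)
            for seg, straj in model_segs.items():
                gt_d = gt_segs[seg].dtheta_deg
                flags = motion.detect_outliers(
                    straj, gt_d.min(), gt_d.max(), cfg.outlier_margin
                )
                for fr in range(n_frames):
                    traj_rows.append(
                        {
                            "level": seg,
                            "frame": fr,
                            "dtheta_deg": straj.dtheta_deg[fr],
                            "gt_dtheta_deg": gt_d[fr],
                            "outlier": bool(flags[fr]),
                        }
                    )
            pd.DataFrame(traj_rows).to_csv(out / f"{e.id}_trajectories.csv", index=False)
            pd.DataFrame(fit_rows).to_csv(out / f"{e.id}_fits.csv", index=False)
            if all(s in model_segs for s in motion.CONTRIBUTION_SEGMENTS):
                seq = motion.contribution_sequence(model_segs, model_trajs, cfg.smoothing_window)
                gt_seq = motion.contribution_sequence(gt_segs, gt_trajs, cfg.smoothing_window)
                (out / f"{e.id}_sequence.json").write_text(
                    json.dumps(
                        {
                            "order": seq.order,
                            "peak_frames": seq.peak_frames,
                            "ambiguous": seq.ambiguous,
                            "ground_truth_order": gt_seq.order,
                        }
                    )
                )
        metrics.scores_to_frame(score_rows).to_csv(out / "scores.csv", index=False)
        pd.DataFrame(agreement_rows).to_csv(out / "meanshape_agreement.csv", index=False)


def stage_evaluate(cfg: PipelineConfig) -> dict:
    """ICCs with exclusions, Wilcoxon comparisons and the report tables."""
    p = _paths(cfg)
    report_dir = p["report"]
    report_dir.mkdir(parents=True, exist_ok=True)

    all_scores = []
    vertebra_iccs: list[ICCResult] = []
    segment_iccs: list[ICCResult] = []
    summary: dict = {}
    for k in cfg.ks:
        out = p["analysis"] / f"k{k}"
        scores = pd.read_csv(out / "scores.csv")
        all_scores.append(scores)

        model_series: dict[str, dict[str, np.ndarray]] = {}
        gt_series: dict[str, dict[str, np.ndarray]] = {}
        exclusion_records = []
        for traj_file in sorted(out.glob("*_trajectories.csv")):
            rec_id = traj_file.name.replace("_trajectories.csv", "")
            df = pd.read_csv(traj_file)
            for level, sub in df.groupby("level"):
                m = sub["dtheta_deg"].to_numpy()
                g = sub["gt_dtheta_deg"].to_numpy()
                model_series.setdefault(level, {})[rec_id] = m
                gt_series.setdefault(level, {})[rec_id] = g
                exclusion_records.append(
                    (rec_id, level, icc_two_way_mixed(g, m), sub["outlier"].to_numpy())
                )
        reports = motion.apply_exclusions(exclusion_records)
        excluded_by_level: dict[str, set] = {}
        for r in reports:
            if r.excluded:
                excluded_by_level.setdefault(r.level, set()).add(r.recording_id)
        pd.DataFrame([r.__dict__ for r in reports]).to_csv(
            out / "exclusions.csv", index=False
        )
        unfiltered: dict[str, float] = {}
        for level in sorted(model_series):
            res = trajectory_icc(
                model_series[level],
                gt_series[level],
                excluded_by_level.get(level, set()),
                level=level,
                model_id=f"k{k}",
            )
            (segment_iccs if "-" in level else vertebra_iccs).append(res)
            unfiltered[level] = trajectory_icc(
                model_series[level], gt_series[level], set(), level=level
            ).icc
        summary[f"k{k}"] = {
            "mean_iou": float(scores["iou"].mean()),
            "mean_dsc": float(scores["dsc"].mean()),
            "iou_by_vertebra": scores.groupby("vertebra")["iou"].mean().to_dict(),
            "dsc_by_vertebra": scores.groupby("vertebra")["dsc"].mean().to_dict(),
            "icc_unfiltered": unfiltered,  # per level, before exclusion rules
        }

    scores_df = pd.concat(all_scores, ignore_index=True)
    overlap_scores = [
        metrics.OverlapScore(**row) for row in scores_df.to_dict("records")
    ]
    report = build_report(overlap_scores, vertebra_iccs, segment_iccs)
    report.overlap.to_csv(report_dir / "overlap.csv", index=False)
    report.vertebra_icc.to_csv(report_dir / "vertebra_icc.csv", index=False)
    report.segment_icc.to_csv(report_dir / "segment_icc.csv", index=False)
    (report_dir / "report.md").write_text(report.to_markdown())
    summary["vertebra_icc"] = {
        f"{r.model_id}:{r.level}": r.icc for r in vertebra_iccs
    }
    summary["segment_icc"] = {
        f"{r.model_id}:{r.level}": r.icc for r in segment_iccs
    }
    (report_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "split": stage_split,
    "train": stage_train,
    "predict": stage_predict,
    "threshold": stage_threshold,
    "analyze": stage_analyze,
    "evaluate": stage_evaluate,
}


def run_pipeline(cfg: PipelineConfig, resume_from: str | None = None):
    """Run all stages in order; ``resume_from`` skips completed earlier stages."""
    cfg.validate()
    p = _paths(cfg)
    p["out"].mkdir(parents=True, exist_ok=True)
    (p["out"] / "run_config.json").write_text(
        json.dumps(dataclasses.asdict(cfg), indent=1)
    )
    start = STAGES.index(resume_from) if resume_from else 0
    result = None
    for stage in STAGES[start:]:
        marker = p["out"] / f".stage_{stage}.done"
        logger.info("=== stage %s ===", stage)
        try:
            result = _STAGE_FUNCS[stage](cfg)
        except Exception as err:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
        marker.write_text("done")
    return result
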