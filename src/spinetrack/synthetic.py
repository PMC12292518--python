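"""Synthetic dynamic-radiograph generator with exact ground truth.

Real videofluoroscopy of the cervical spine (frame stacks of up to
1024x1024 px at 15 fps, roughly 10 s of flexion/extension) is clinical data
and cannot ship with the package.  This module generates seeded recordings
that emulate the features the downstream pipeline has to cope with:

* eight rigid vertebra-like shapes labeled C0-C7 stacked in a curved column
  (C0 an arc-like skull-base region, C1/C2 distinctive, C3-C7 a family of
  near-congruent quadrilaterals that a segmenter can confuse);
* a global extension sweep decomposed into per-segment contributions whose
  relative-rotation peaks follow a configurable order -- the "sequence of
  segmental contribution" the motion analysis has to recover;
* intensity rendering over a low-frequency textured background with
  Gaussian noise, a per-recording contrast factor and optional shading of
  the lower vertebrae emulating shoulder occlusion.

Every pixel of every ground-truth mask and every true angle is exact by
construction, so the whole pipeline can be validated closed-loop.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._geom import polygon_area, rasterize_polygon, rotation_matrix_deg

LABELS: tuple[str, ...] = ("C0", "C1", "C2", "C3", "C4", "C5", "C6", "C7")
SEGMENTS: tuple[str, ...] = tuple(f"C{i}-C{i + 1}" for i in range(7))

DEFAULT_PEAK_ORDER: tuple[str, ...] = (
    "C6-C7", "C5-C6", "C4-C5", "C3-C4", "C2-C3", "C1-C2", "C0-C1",
)  # caudal-to-cranial unrolling, the pattern described for asymptomatic extension


class SimulationError(ValueError):
    """Invalid kinematics configuration or out-of-bounds rendering."""


# --------------------------------------------------------------------------
# Vertebra templates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VertebraTemplate:
    """A rigid 2D vertebra outline in local template coordinates (px).

    The polygon is a simple (non-self-intersecting) vertex loop roughly
    centered on the origin; ``nominal_height`` is its vertical extent.
    """

    label: str
    polygon: np.ndarray  # (N, 2) float, (x, y)
    nominal_height: float

    @property
    def area(self) -> float:
        return polygon_area(self.polygon)


def _base_quadrilateral() -> np.ndarray:
    # vertebral body: wider than tall, slightly trapezoidal
    return np.array(
        [(-0.75, -0.50), (0.72, -0.47), (0.78, 0.50), (-0.78, 0.47)]
    )


def _axis_polygon() -> np.ndarray:
    # C2: body with the dens pointing up (negative y)
    return np.array(
        [
            (-0.80, -0.30), (-0.16, -0.30), (-0.14, -0.80), (0.14, -0.80),
            (0.16, -0.30), (0.80, -0.30), (0.86, 0.52), (-0.86, 0.52),
        ]
    )


def _atlas_polygon() -> np.ndarray:
    # C1: wide flat arch
    return np.array(
        [
            (-1.05, 0.0), (-0.60, -0.30), (0.60, -0.30),
            (1.05, 0.0), (0.60, 0.30), (-0.60, 0.30),
        ]
    )


def _skull_base_polygon() -> np.ndarray:
    # C0: open arc-like band (clivus / sella-turcica midline region)
    ang = np.deg2rad(np.linspace(25.0, 155.0, 9))
    outer = np.stack([1.15 * np.cos(ang), -0.80 * np.sin(ang)], axis=1)
    inner = np.stack([0.72 * np.cos(ang[::-1]), -0.50 * np.sin(ang[::-1]) + 0.12], axis=1)
    return np.vstack([outer, inner])


def generate_templates(seed: int, height_px: float = 22.0) -> list[VertebraTemplate]:
    """Generate the eight seeded vertebra templates C0-C7.

    C3-C7 are jittered copies of one base quadrilateral (their mutual
    resemblance is intentional: lower cervical vertebrae look alike and are
    the classic source of label confusion); C0-C2 have distinct shapes.
    Identical seeds yield identical templates.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7E3D]))
    templates: list[VertebraTemplate] = []
    for label in LABELS:
        if label == "C0":
            poly = _skull_base_polygon()
            jitter = 0.0
        elif label == "C1":
            poly = _atlas_polygon()
            jitter = 0.02
        elif label == "C2":
            poly = _axis_polygon()
            jitter = 0.02
        else:
            poly = _base_quadrilateral()
            jitter = 0.06
        poly = poly + rng.uniform(-jitter, jitter, size=poly.shape)
        poly = poly * height_px
        poly = poly - poly.mean(axis=0)  # approximate centroid at origin
        height = float(poly[:, 1].max() - poly[:, 1].min())
        templates.append(VertebraTemplate(label=label, polygon=poly, nominal_height=height))
    return templates


# --------------------------------------------------------------------------
# Kinematics
# --------------------------------------------------------------------------

@dataclass
class KinematicsConfig:
    """Study conditions for one synthetic recording.

    The defaults mirror a typical clinical extension recording: ~52 frames
    at 15 fps, a global range of motion of 30 degrees, and seven motion
    segments whose relative-rotation peaks unroll from caudal to cranial
    with a few degrees of amplitude each.  Rendering parameters (noise,
    contrast, occlusion of C6/C7 by the shoulders) are stated conventions,
    not values fitted to real recordings.
    """

    n_frames: int = 52
    total_rom_deg: float = 30.0
    segment_peak_order: tuple[str, ...] = DEFAULT_PEAK_ORDER
    segment_amplitudes_deg: dict[str, float] | float = 2.5
    noise_sd: float = 0.02
    contrast_range: tuple[float, float] = (0.9, 1.1)
    occlusion_strength: float = 0.3
    seed: int = 0
    # geometry / rendering plumbing (desk-scale defaults; sizes configurable)
    image_size: tuple[int, int] = (256, 256)  # (H, W)
    vertebra_height_px: float = 22.0
    spacing_px: float = 28.0
    foreground_contrast: float = 0.35
    ramp_half_width_frames: float | None = None  # None -> auto from n_frames
    monotonic: bool = True
    direction: str = "extension"
    frame_rate: float = 15.0

    def amplitudes(self) -> dict[str, float]:
        if isinstance(self.segment_amplitudes_deg, dict):
            return {s: float(self.segment_amplitudes_deg.get(s, 0.0)) for s in SEGMENTS}
        return {s: float(self.segment_amplitudes_deg) for s in SEGMENTS}

    def validate(self) -> None:
        if self.n_frames < 3:
            raise SimulationError("n_frames must be >= 3")
        if sorted(self.segment_peak_order) != sorted(set(self.segment_peak_order)):
            raise SimulationError("segment_peak_order contains duplicates")
        unknown = set(self.segment_peak_order) - set(SEGMENTS)
        if unknown:
            raise SimulationError(f"unknown segment labels: {sorted(unknown)}")
        amps = self.amplitudes()
        if any(a < 0 for a in amps.values()):
            raise SimulationError("segment amplitudes must be >= 0")
        if self.monotonic and sum(amps.values()) > abs(self.total_rom_deg) + 1e-12:
            raise SimulationError(
                "segment amplitudes sum above total_rom_deg with monotonic motion"
            )


@dataclass
class Poses:
    """Per-frame rigid pose of every vertebra: angle (deg) and centroid (px)."""

    angles_deg: np.ndarray  # (T, 8)
    centroids: np.ndarray  # (T, 8, 2), (x, y)
    config: KinematicsConfig


def _smoothstep(t: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Cubic ramp 0 -> 1 over [center - hw, center + hw]; single-peaked slope."""
    u = np.clip((t - (center - half_width)) / (2.0 * half_width), 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def simulate_kinematics(cfg: KinematicsConfig) -> Poses:
    """Simulate per-frame vertebra poses for a global extension sweep.

    The global rotation (of C0, relative to the first frame) equals
    ``total_rom_deg`` at the last frame.  Each motion segment contributes a
    smooth ramp of its configured amplitude; ramp centers are placed so the
    per-frame relative-rotation series of the segments peak in exactly
    ``segment_peak_order``.  Whatever rotation the segments do not account
    for is carried by the base vertebra C7 as a concentrated mid-recording
    burst.  Ramps are deliberately narrow (a few frames): clinically,
    individual vertebrae rotate about 2-3.5 degrees between frames during
    the active phase of the sweep rather than drifting uniformly.
    """
    cfg.validate()
    T = cfg.n_frames
    t = np.arange(T, dtype=float)
    amps = cfg.amplitudes()
    active = [s for s in cfg.segment_peak_order if amps[s] > 0]
    n_act = len(active)

    margin = max(1.5, 0.06 * (T - 1))
    span = (T - 1) - 2.0 * margin
    if n_act and span / n_act < 1.0:
        raise SimulationError(
            f"{T} frames are too few for {n_act} distinct segment peaks"
        )
    hw_auto = max(2.0, 0.05 * (T - 1))
    hw_cfg = cfg.ramp_half_width_frames or hw_auto

    # ramp center for the i-th peaking segment, snapped to k + 0.5 so the
    # discrete difference series has a unique argmax
    seg_phi: dict[str, np.ndarray] = {}
    for i, seg in enumerate(active):
        c = margin + (i + 0.5) / n_act * span
        c = np.floor(c) + 0.5
        hw = min(c, (T - 1) - c, hw_cfg)
        seg_phi[seg] = amps[seg] * _smoothstep(t, c, hw)
    for seg in SEGMENTS:
        if seg not in seg_phi:
            seg_phi[seg] = np.zeros(T)

    residual = cfg.total_rom_deg - sum(amps.values())
    c_base = np.floor((T - 1) / 2.0) + 0.5
    hw_base = min(c_base, (T - 1) - c_base, max(4.0, 2.0 * hw_cfg))
    base = residual * _smoothstep(t, c_base, hw_base) - cfg.total_rom_deg / 2.0

    angles = np.zeros((T, 8))
    angles[:, 7] = base
    for j in range(6, -1, -1):  # vertebra Cj sits on segment Cj-C(j+1)
        angles[:, j] = angles[:, j + 1] + seg_phi[f"C{j}-C{j + 1}"]

    H, W = cfg.image_size
    centroids = np.zeros((T, 8, 2))
    base_pos = np.array([W / 2.0, H - 1.5 * cfg.vertebra_height_px])
    centroids[:, 7] = base_pos
    for j in range(6, -1, -1):
        th = np.deg2rad(angles[:, j])
        offset = cfg.spacing_px * np.stack([-np.sin(th), -np.cos(th)], axis=1)
        centroids[:, j] = centroids[:, j + 1] + offset
    return Poses(angles_deg=angles, centroids=centroids, config=cfg)


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

@dataclass
class Recording:
    """An ordered grayscale frame stack, the package's recording container."""

    frames: np.ndarray  # (T, H, W) float32 in [0, 1]
    frame_rate: float
    direction: str
    id: str

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass
class AnnotationSet:
    """Per-frame, per-vertebra ground truth: masks, contours, true angles."""

    masks: dict[str, np.ndarray]  # label -> (T, H, W) uint8
    contours: dict[str, list[np.ndarray]]  # label -> per-frame (N, 2) polygons
    true_angle_deg: dict[str, np.ndarray]  # label -> (T,)

    def angle_matrix(self) -> np.ndarray:
        """(T, 8) matrix of true angles ordered C0..C7."""
        return np.stack([self.true_angle_deg[lab] for lab in LABELS], axis=1)


def _background(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Low-frequency smoothed noise, mid-gray: soft-tissue-like texture."""
    h, w = shape
    coarse = rng.standard_normal((max(h // 16, 2), max(w // 16, 2)))
    bg = ndimage.zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]), order=3)
    bg = bg[:h, :w]
    lo, hi = bg.min(), bg.max()
    return (0.25 + 0.20 * (bg - lo) / max(hi - lo, 1e-9)).astype(np.float64)


_OCCLUSION_FACTOR = {"C6": 0.55, "C7": 0.85}  # fraction of contrast removed at strength 1


def render_recording(
    templates: list[VertebraTemplate],
    poses: Poses,
    cfg: KinematicsConfig | None = None,
    recording_id: str | None = None,
) -> tuple[Recording, AnnotationSet]:
    """Rasterize posed templates into frames and exact annotations.

    Frames are the textured background plus an additive intensity step per
    vertebra (scaled down for C6/C7 according to ``occlusion_strength``),
    a per-recording multiplicative contrast factor and per-frame Gaussian
    noise.  Masks equal the rasterized polygons exactly and
    ``true_angle_deg`` equals the simulated angles.
    """
    cfg = cfg if cfg is not None else poses.config
    H, W = cfg.image_size
    T = cfg.n_frames
    ss = np.random.SeedSequence([int(cfg.seed), 0xA11CE])
    rng_bg, rng_contrast, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    bg = _background((H, W), rng_bg)
    contrast = rng_contrast.uniform(*cfg.contrast_range)

    by_label = {tpl.label: tpl for tpl in templates}
    masks = {lab: np.zeros((T, H, W), dtype=np.uint8) for lab in LABELS}
    contours: dict[str, list[np.ndarray]] = {lab: [] for lab in LABELS}
    frames = np.empty((T, H, W), dtype=np.float32)

    for ti in range(T):
        img = bg.copy()
        for ci, lab in enumerate(LABELS):
            tpl = by_label[lab]
            R = rotation_matrix_deg(poses.angles_deg[ti, ci])
            verts = tpl.polygon @ R.T + poses.centroids[ti, ci]
            if (
                verts[:, 0].min() < 0 or verts[:, 0].max() > W - 1
                or verts[:, 1].min() < 0 or verts[:, 1].max() > H - 1
            ):
                raise SimulationError(
                    f"vertebra {lab} leaves the image bounds at frame {ti}"
                )
            mask = rasterize_polygon(verts, (H, W))
            masks[lab][ti] = mask
            contours[lab].append(verts)
            occ = 1.0 - cfg.occlusion_strength * _OCCLUSION_FACTOR.get(lab, 0.0)
            img[mask.astype(bool)] += cfg.foreground_contrast * occ
        img = 0.35 + contrast * (img - 0.35)
        img += rng_noise.normal(0.0, cfg.noise_sd, size=(H, W))
        frames[ti] = np.clip(img, 0.0, 1.0)

    rec = Recording(
        frames=frames,
        frame_rate=cfg.frame_rate,
        direction=cfg.direction,
        id=recording_id or f"synthetic-{cfg.seed}",
    )
    ann = AnnotationSet(
        masks=masks,
        contours=contours,
        true_angle_deg={lab: poses.angles_deg[:, i].copy() for i, lab in enumerate(LABELS)},
    )
    return rec, ann


def make_recording(
    cfg: KinematicsConfig, recording_id: str | None = None
) -> tuple[Recording, AnnotationSet]:
    """Convenience: templates + kinematics + rendering from one config."""
    templates = generate_templates(cfg.seed, cfg.vertebra_height_px)
    poses = simulate_kinematics(cfg)
    return render_recording(templates, poses, cfg, recording_id=recording_id)


# --------------------------------------------------------------------------
# Serialization (multi-page TIFF + JSON)
# --------------------------------------------------------------------------

def write_recording(out_dir, rec: Recording, ann: AnnotationSet, cfg: KinematicsConfig | None = None) -> None:
    """Write frames and masks as multi-page TIFF, contours/angles as JSON."""
    import pathlib

    import tifffile

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "recording.tif", rec.frames)
    for lab in LABELS:
        tifffile.imwrite(out / f"mask_{lab}.tif", ann.masks[lab])
    doc = {
        "id": rec.id,
        "frame_rate": rec.frame_rate,
        "direction": rec.direction,
        "true_angle_deg": {lab: ann.true_angle_deg[lab].tolist() for lab in LABELS},
        "contours": {
            lab: [c.tolist() for c in ann.contours[lab]] for lab in LABELS
        },
    }
    if cfg is not None:
        doc["config"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        }
    (out / "annotations.json").write_text(json.dumps(doc))


def read_recording(in_dir) -> tuple[Recording, AnnotationSet]:
    """Inverse of :func:`write_recording`."""
    import pathlib

    import tifffile

    src = pathlib.Path(in_dir)
    doc = json.loads((src / "annotations.json").read_text())
    frames = tifffile.imread(src / "recording.tif").astype(np.float32)
    masks = {lab: tifffile.imread(src / f"mask_{lab}.tif").astype(np.uint8) for lab in LABELS}
    rec = Recording(
        frames=frames,
        frame_rate=float(doc["frame_rate"]),
        direction=doc["direction"],
        id=doc["id"],
    )
    ann = AnnotationSet(
        masks=masks,
        contours={lab: [np.asarray(c) for c in doc["contours"][lab]] for lab in LABELS},
        true_angle_deg={lab: np.asarray(doc["true_angle_deg"][lab]) for lab in LABELS},
    )
    return rec, ann
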