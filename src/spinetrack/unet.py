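"""Multi-class U-Net segmentation of vertebrae, implemented in NumPy.

The segmenter is an encoder/decoder U-Net with skip connections, nine
output channels (eight vertebrae C0-C7 plus background) and a per-pixel
softmax.  It supports a plain 2D configuration (one input frame) and a
2D+t configuration in which k consecutive frames enter as input channels
and only the middle frame is segmented; boundary frames without full
temporal context are simply not predicted.

Training minimizes a class-weighted Dice loss.  For each class c with
ground-truth indicator g and predicted probability p over the N pixels of
an image,

    L_c = 1 - 2 sum_i p_i g_i / (sum_i p_i^2 + sum_i g_i^2),
    W_c = 1 / (sum_i g_i)^2,

and the total loss averages L_c over the images of a batch and combines
the classes as sum_c W_c L_c / sum_c W_c.  The quadratic inverse
foreground count counteracts the extreme class imbalance between a
vertebral body and the full radiograph.  Classes absent from a batch get
weight zero (the weight is undefined there) and are logged.  Training
adds three stabilizers against the failure modes of softmax-Dice
optimization with near-congruent classes — the background enters the
combination at the rarest vertebra's weight, the final-layer bias is a
frozen background prior, and a small cross-entropy term keeps logit
gradients alive for underflowed channels; docs/methods.md discusses each.

All layers (3x3 "same" convolutions via im2col + GEMM, 2x2 max pooling,
fixed-stencil bilinear 2x upsampling) carry hand-written backward passes;
optimization is Adam with step decay.  Everything is float32 and fully
seeded, so two runs with the same configuration and seed are
bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .synthetic import LABELS, Recording

logger = logging.getLogger(__name__)

CHANNELS: tuple[str, ...] = LABELS + ("background",)
BACKGROUND = len(LABELS)  # channel index of the background class


# --------------------------------------------------------------------------
# Configuration and simple preprocessing operations
# --------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """U-Net architecture and training hyper-parameters.

    ``n_levels`` counts resolution levels (5 with 16 base filters is the
    full-scale configuration; desk-scale experiments use 4 levels and 8
    filters).  ``in_frames`` is the temporal context k; k = 1 is the 2D
    model.  Learning rate 1e-4, batch size 8 and the 300-epoch cap are the
    full-scale defaults.
    """

    n_levels: int = 5
    in_frames: int = 1
    out_channels: int = 9
    base_filters: int = 16
    image_size: tuple[int, int] = (256, 256)
    learning_rate: float = 1e-4
    batch_size: int = 8
    max_epochs: int = 300
    seed: int = 0
    patience: int = 25
    min_delta: float = 0.0  # improvement below this does not reset patience
    loss_prob_floor: float = 1e-3
    ce_weight: float = 0.1  # cross-entropy stabilizer; see train()
    freeze_output_bias: bool = True  # keep the background-prior bias fixed
    augment: bool = True
    augment_noise_sd: float = 0.02
    augment_contrast: tuple[float, float] = (0.9, 1.1)

    def validate(self) -> None:
        if self.in_frames % 2 != 1:
            raise ValueError("in_frames must be odd")
        if self.out_channels != 9:
            raise ValueError("the segmenter is defined for 9 output channels")
        h, w = self.image_size
        d = 2 ** (self.n_levels - 1)
        if h % d or w % d:
            raise ValueError(
                f"image size {self.image_size} not divisible by 2^(n_levels-1)={d}"
            )


@dataclass(frozen=True)
class NormalizationStats:
    """Mean/SD of training-subset pixel intensities (train frames only)."""

    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("normalization sd must be > 0")


def compute_normalization_stats(frames: np.ndarray) -> NormalizationStats:
    """Pixel-intensity mean/SD over an array of training frames."""
    arr = np.asarray(frames, dtype=np.float64)
    sd = float(arr.std())
    if sd == 0:
        raise ValueError("training frames have zero intensity variance")
    return NormalizationStats(mean=float(arr.mean()), sd=sd)


def normalize(frames: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Standardize intensities: (x - mean) / sd."""
    return ((np.asarray(frames, dtype=np.float32) - stats.mean) / stats.sd).astype(
        np.float32
    )


def augment(
    frame: np.ndarray,
    seed: int,
    noise_sd: float = 0.02,
    contrast_range: tuple[float, float] = (0.9, 1.1),
) -> np.ndarray:
    """Training-time augmentation: contrast jitter plus Gaussian noise.

    Centered intensities are scaled by a factor drawn uniformly from
    ``contrast_range``, then zero-mean Gaussian noise of SD ``noise_sd`` is
    added.  Fully determined by ``seed``.
    """
    rng = np.random.default_rng(seed)
    frame = np.asarray(frame, dtype=np.float32)
    factor = rng.uniform(*contrast_range)
    mean = frame.mean()
    out = mean + factor * (frame - mean)
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=frame.shape)
    return out.astype(np.float32)


def predicted_frame_indices(n_frames: int, k: int) -> list[int]:
    """Frames with full temporal context for a k-frame input window."""
    half = (k - 1) // 2
    return list(range(half, n_frames - half))


def make_temporal_input(rec: Recording, t: int, k: int) -> np.ndarray | None:
    """Stack the k frames centered on t as input channels.

    Returns ``None`` (the "no prediction" sentinel) when frame t lacks full
    temporal context, i.e. near the start or end of the recording.
    """
    if k % 2 != 1:
        raise ValueError("temporal window k must be odd")
    half = (k - 1) // 2
    if t - half < 0 or t + half >= rec.n_frames:
        return None
    return rec.frames[t - half : t + half + 1].astype(np.float32)


# --------------------------------------------------------------------------
# Weighted Dice loss
# --------------------------------------------------------------------------

def class_weights(gt_masks: np.ndarray) -> np.ndarray:
    """Per-class weights W_c = 1 / (sum_i g_i)^2 from binary ground truth.

    ``gt_masks`` has shape (C, ...) with one binary map per class.  A class
    with no foreground pixels has an undefined weight; it receives weight 0
    and a warning is logged.
    """
    gt = np.asarray(gt_masks)
    counts = gt.reshape(gt.shape[0], -1).sum(axis=1).astype(np.float64)
    w = np.zeros_like(counts)
    nz = counts > 0
    w[nz] = 1.0 / counts[nz] ** 2
    if not nz.all():
        logger.warning(
            "classes with zero foreground pixels assigned weight 0: %s",
            np.nonzero(~nz)[0].tolist(),
        )
    return w


def weighted_dice_loss(p: np.ndarray, gt: np.ndarray, w: np.ndarray) -> float:
    """Class-weighted Dice loss, normalized to [0, 1].

    ``p`` and ``gt`` have shape (C, ...); ``w`` has shape (C,).  Per class
    L_c = 1 - 2 sum(p g) / (sum p^2 + sum g^2); the result is
    sum_c w_c L_c / sum_c w_c over classes with positive weight.
    """
    p = np.asarray(p, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if p.shape != gt.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs gt {gt.shape}")
    w = np.asarray(w, dtype=np.float64)
    wsum = w.sum()
    if wsum == 0:
        logger.warning("all class weights are zero; loss defined as 0")
        return 0.0
    pf = p.reshape(p.shape[0], -1)
    gf = gt.reshape(gt.shape[0], -1)
    inter = (pf * gf).sum(axis=1)
    denom = (pf**2).sum(axis=1) + (gf**2).sum(axis=1)
    per_class = np.ones(p.shape[0])
    ok = denom > 0
    per_class[ok] = 1.0 - 2.0 * inter[ok] / denom[ok]
    return float((w * per_class).sum() / wsum)


def _dice_loss_and_grad(
    probs: np.ndarray, gt: np.ndarray, w: np.ndarray, prob_floor: float = 0.0
) -> tuple[float, np.ndarray]:
    """Loss and gradient w.r.t. the softmax probabilities.

    ``probs``/``gt`` shaped (N, C, H, W).  The Dice sums run per image —
    the pixel index of the loss formula ranges over one network output —
    and the per-class terms are averaged over the batch before the
    class-weighted combination.

    ``prob_floor`` mixes a uniform floor into the probabilities before the
    loss, p' = (1 - eps) p + eps / C.  Without it a class whose softmax
    output underflows to 0 has a vanishing logit gradient and can never
    recover — the dead-channel failure mode of Dice-trained multi-class
    networks when several classes look alike.
    """
    n, c, h, wd = probs.shape
    if prob_floor > 0.0:
        probs = (1.0 - prob_floor) * probs + prob_floor / c
    pf = probs.reshape(n, c, -1).astype(np.float64)
    gf = gt.reshape(n, c, -1).astype(np.float64)
    wsum = w.sum()
    spg = np.einsum("ncp,ncp->nc", pf, gf)
    spp = np.einsum("ncp,ncp->nc", pf, pf)
    sgg = gf.sum(axis=2)  # g binary: sum g^2 = sum g
    den = spp + sgg
    ok = (sgg > 0) & (w > 0)  # class absent from an image: no term there
    frac = np.where(ok, 2.0 * spg / np.where(den > 0, den, 1.0), 1.0)
    counts = np.maximum(ok.sum(axis=0), 1)  # images contributing per class
    per_class = 1.0 - np.where(ok, frac, 0.0).sum(axis=0) / counts
    per_class[w == 0] = 0.0
    loss = float((w * per_class).sum() / wsum)

    scale = (w / wsum / counts)[None, :, None] * ok[..., None]
    dldp = -2.0 * (gf * den[..., None] - 2.0 * pf * spg[..., None]) / (
        np.where(den > 0, den, 1.0) ** 2
    )[..., None] * scale
    if prob_floor > 0.0:
        dldp *= 1.0 - prob_floor
    grad = dldp.reshape(n, c, h, wd).astype(np.float32)
    return loss, grad


# --------------------------------------------------------------------------
# Layers (forward + hand-written backward)
# --------------------------------------------------------------------------

def _he_init(rng, c_out: int, c_in: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    fan_in = c_in * k * k
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
    return w.astype(np.float32), np.zeros(c_out, dtype=np.float32)


def _conv_forward(x, w, b, cache=None, name=None):
    """'Same' convolution on NHWC data; 3x3 via im2col + GEMM, 1x1 a plain GEMM.

    Internally the network keeps activations channels-last: the im2col
    gather then needs a single copy and the GEMM output is already in
    layout, which is what makes a pure-NumPy training loop viable.
    """
    n, h, wd, c = x.shape
    c_out, _, k, _ = w.shape
    wm = w.transpose(1, 2, 3, 0).reshape(-1, c_out)  # (C_in*k*k, C_out)
    if k == 1:
        cols = x.reshape(-1, c)
    else:
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N,H,W,C,3,3)
        cols = np.ascontiguousarray(win).reshape(n * h * wd, c * 9)
    y = cols @ wm + b
    if cache is not None:
        cache[name] = (cols, x.shape)
    return y.reshape(n, h, wd, c_out)


def _conv_backward(dy, w, cache_entry):
    cols, x_shape = cache_entry
    n, h, wd, c = x_shape
    c_out, _, k, _ = w.shape
    dmat = dy.reshape(-1, c_out)
    dwm = cols.T @ dmat  # (C_in*k*k, C_out)
    dw = dwm.reshape(c, k, k, c_out).transpose(3, 0, 1, 2)
    db = dmat.sum(axis=0)
    if k == 1:
        wm = w.transpose(1, 2, 3, 0).reshape(-1, c_out)
        return (dmat @ wm.T).reshape(n, h, wd, c), dw, db
    # input gradient as a correlation with the flipped kernel — one im2col
    # of dy plus a GEMM beats scattering nine strided slices
    dyp = np.pad(dy, ((0, 0), (1, 1), (1, 1), (0, 0)))
    dwin = sliding_window_view(dyp, (3, 3), axis=(1, 2))  # (N,H,W,C_out,3,3)
    dcols = np.ascontiguousarray(dwin).reshape(n * h * wd, c_out * 9)
    wrot = np.ascontiguousarray(
        w[:, :, ::-1, ::-1].transpose(0, 2, 3, 1)
    ).reshape(c_out * 9, c)
    return (dcols @ wrot).reshape(n, h, wd, c), dw, db


def _maxpool_forward(x, cache=None, name=None):
    quads = np.stack(
        [x[:, 0::2, 0::2, :], x[:, 0::2, 1::2, :], x[:, 1::2, 0::2, :], x[:, 1::2, 1::2, :]],
        axis=-1,
    )
    idx = quads.argmax(axis=-1)
    y = np.take_along_axis(quads, idx[..., None], axis=-1)[..., 0]
    if cache is not None:
        cache[name] = (idx, x.shape)
    return y


def _maxpool_backward(dy, cache_entry):
    idx, x_shape = cache_entry
    dquads = np.zeros(dy.shape + (4,), dtype=np.float32)
    np.put_along_axis(dquads, idx[..., None], dy[..., None], axis=-1)
    dx = np.zeros(x_shape, dtype=np.float32)
    dx[:, 0::2, 0::2, :] = dquads[..., 0]
    dx[:, 0::2, 1::2, :] = dquads[..., 1]
    dx[:, 1::2, 0::2, :] = dquads[..., 2]
    dx[:, 1::2, 1::2, :] = dquads[..., 3]
    return dx


def _up1d(x, axis):
    """Bilinear 2x upsampling along one axis (half-pixel centers, edge clamp)."""
    x = np.moveaxis(x, axis, -1)
    xl = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)
    xr = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)
    y = np.empty(x.shape[:-1] + (2 * x.shape[-1],), dtype=x.dtype)
    y[..., 0::2] = 0.75 * x + 0.25 * xl
    y[..., 1::2] = 0.75 * x + 0.25 * xr
    return np.moveaxis(y, -1, axis)


def _up1d_adjoint(dy, axis):
    dy = np.moveaxis(dy, axis, -1)
    de, do = dy[..., 0::2], dy[..., 1::2]
    dx = 0.75 * (de + do)
    dx[..., :-1] += 0.25 * de[..., 1:]
    dx[..., 0] += 0.25 * de[..., 0]
    dx[..., 1:] += 0.25 * do[..., :-1]
    dx[..., -1] += 0.25 * do[..., -1]
    return np.moveaxis(dx, -1, axis)


def _upsample_forward(x):
    return _up1d(_up1d(x, 1), 2)


def _upsample_backward(dy):
    return _up1d_adjoint(_up1d_adjoint(dy, 2), 1)


def _softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z, dtype=np.float32)
    return e / e.sum(axis=-1, keepdims=True)


# --------------------------------------------------------------------------
# The U-Net
# --------------------------------------------------------------------------

class UNet:
    """Encoder/decoder U-Net over NumPy arrays.

    ``forward(x)`` maps a float32 batch (N, k, H, W) to per-pixel softmax
    probabilities (N, 9, H, W).  ``train_step`` style usage goes through
    :func:`train`, which owns augmentation, batching and Adam.
    """

    def __init__(self, cfg: ModelConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x0E7]))
        L, F = cfg.n_levels, cfg.base_filters
        self.params: dict[str, np.ndarray] = {}

        def add(name, c_out, c_in, k=3):
            w, b = _he_init(rng, c_out, c_in, k)
            self.params[name + "_W"] = w
            self.params[name + "_b"] = b

        c_in = cfg.in_frames
        for i in range(L):
            c = F * 2**i
            add(f"enc{i}a", c, c_in)
            add(f"enc{i}b", c, c)
            c_in = c
        for i in range(L - 2, -1, -1):
            c = F * 2**i
            add(f"dec{i}u", c, 2 * c)  # conv after bilinear upsampling
            add(f"dec{i}a", c, 2 * c)  # conv after skip concatenation
            add(f"dec{i}b", c, c)
        add("out", cfg.out_channels, F, k=1)
        # prior-probability initialization: start with the background class
        # dominant everywhere.  With the 1/area^2 class weights the
        # background is almost free, so a vertebra channel that happens to
        # leak over the background early in training sits in a stable
        # pathological optimum (its own Dice gradient vanishes as the
        # false-positive mass grows); starting background-dominant keeps
        # every vertebra channel local from the first step.
        self.params["out_b"][:] = -2.0
        self.params["out_b"][BACKGROUND] = 2.0

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """Return softmax probabilities; optionally keep the backward cache."""
        cfg = self.cfg
        if x.shape[2:] != tuple(cfg.image_size):
            raise ValueError(
                f"input frames {x.shape[2:]} do not match model size {cfg.image_size}"
            )
        p = self.params
        cache: dict | None = {} if keep_cache else None
        L = cfg.n_levels
        h = np.ascontiguousarray(x.astype(np.float32).transpose(0, 2, 3, 1))
        skips = []
        for i in range(L):
            for tag in ("a", "b"):
                name = f"enc{i}{tag}"
                h = _conv_forward(h, p[name + "_W"], p[name + "_b"], cache, name)
                mask = h > 0
                h *= mask
                if cache is not None:
                    cache[name + "_relu"] = mask
            if i < L - 1:
                skips.append(h)
                h = _maxpool_forward(h, cache, f"pool{i}")
        for i in range(L - 2, -1, -1):
            h = _upsample_forward(h)
            name = f"dec{i}u"
            h = _conv_forward(h, p[name + "_W"], p[name + "_b"], cache, name)
            mask = h > 0
            h *= mask
            if cache is not None:
                cache[name + "_relu"] = mask
            h = np.concatenate([skips[i], h], axis=-1)
            for tag in ("a", "b"):
                name = f"dec{i}{tag}"
                h = _conv_forward(h, p[name + "_W"], p[name + "_b"], cache, name)
                mask = h > 0
                h *= mask
                if cache is not None:
                    cache[name + "_relu"] = mask
        logits = _conv_forward(h, p["out_W"], p["out_b"], cache, "out")
        probs = _softmax(logits)  # NHWC
        if keep_cache:
            cache["probs"] = probs
            self._cache = cache
        return np.ascontiguousarray(probs.transpose(0, 3, 1, 2))

    # -- backward ----------------------------------------------------------

    def backward(
        self, dprobs: np.ndarray, dlogits_extra: np.ndarray | None = None
    ) -> dict[str, np.ndarray]:
        """Backpropagate a gradient w.r.t. the softmax output; return grads.

        ``dlogits_extra`` is an optional gradient injected directly at the
        logits (bypassing the softmax jacobian); the cross-entropy
        stabilizer uses it, since its analytic logit gradient (p - g) stays
        alive even where the softmax output has underflowed to zero.
        """
        cache = self._cache
        probs = cache["probs"]  # NHWC
        dprobs = dprobs.transpose(0, 2, 3, 1)
        # softmax jacobian-vector product
        inner = (dprobs * probs).sum(axis=-1, keepdims=True)
        dlogits = probs * (dprobs - inner)
        if dlogits_extra is not None:
            dlogits = dlogits + dlogits_extra.transpose(0, 2, 3, 1)

        p = self.params
        grads: dict[str, np.ndarray] = {}
        L, F = self.cfg.n_levels, self.cfg.base_filters

        dh, dw, db = _conv_backward(dlogits, p["out_W"], cache["out"])
        grads["out_W"], grads["out_b"] = dw, db
        dskips: dict[int, np.ndarray] = {}
        for i in range(L - 1):
            c = F * 2**i
            for tag in ("b", "a"):
                name = f"dec{i}{tag}"
                dh = dh * cache[name + "_relu"]
                dh, dw, db = _conv_backward(dh, p[name + "_W"], cache[name])
                grads[name + "_W"], grads[name + "_b"] = dw, db
            dskips[i] = dh[..., :c]
            dh = np.ascontiguousarray(dh[..., c:])
            name = f"dec{i}u"
            dh = dh * cache[name + "_relu"]
            dh, dw, db = _conv_backward(dh, p[name + "_W"], cache[name])
            grads[name + "_W"], grads[name + "_b"] = dw, db
            dh = _upsample_backward(dh)
        for i in range(L - 1, -1, -1):
            if i < L - 1:
                dh = _maxpool_backward(dh, cache[f"pool{i}"])
                dh = dh + dskips[i]
            for tag in ("b", "a"):
                name = f"enc{i}{tag}"
                dh = dh * cache[name + "_relu"]
                dh, dw, db = _conv_backward(dh, p[name + "_W"], cache[name])
                grads[name + "_W"], grads[name + "_b"] = dw, db
        self._cache = None
        return grads


def build_unet(cfg: ModelConfig) -> UNet:
    """Construct a seeded U-Net for the given configuration."""
    return UNet(cfg)


# --------------------------------------------------------------------------
# Training and inference
# --------------------------------------------------------------------------

def _combination_weights(y_batch: np.ndarray) -> np.ndarray:
    """Class weights used to combine the per-class Dice terms in training.

    The vertebra classes carry their quadratic inverse-foreground weights.
    The background participates at the scale of the rarest vertebra
    instead of its own 1/N^2: at 1/N^2 a mislabeled background is
    essentially free, which opens a stable pathological optimum where one
    vertebra channel claims the whole background and its own saturating
    Dice gradient can no longer undo it.
    """
    w = class_weights(y_batch)
    vert = w[:BACKGROUND]
    if (vert > 0).any():
        w[BACKGROUND] = vert[vert > 0].min()
    return w


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            g = g.astype(np.float32)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def build_training_samples(
    pairs, k: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Turn (Recording, AnnotationSet) pairs into (input, one-hot target) samples.

    Only frames with full temporal context contribute.  Targets are the
    nine-channel one-hot stack [C0..C7, background].
    """
    samples = []
    for rec, ann in pairs:
        h, w = rec.frames.shape[1:]
        for t in predicted_frame_indices(rec.n_frames, k):
            x = make_temporal_input(rec, t, k)
            y = np.zeros((9, h, w), dtype=np.uint8)
            for ci, lab in enumerate(LABELS):
                y[ci] = ann.masks[lab][t]
            y[BACKGROUND] = (y[:BACKGROUND].sum(axis=0) == 0).astype(np.uint8)
            samples.append((x, y))
    return samples


def train(
    model: UNet,
    train_samples: list[tuple[np.ndarray, np.ndarray]],
    val_samples: list[tuple[np.ndarray, np.ndarray]],
    stats: NormalizationStats | None = None,
) -> dict:
    """Train with Adam on the weighted Dice loss; early-stop on validation loss.

    Normalization statistics are computed from the training inputs only
    (unless supplied).  Class weights are recomputed per batch from that
    batch's ground truth.  The parameters of the best-validation-loss epoch
    are restored before returning.  Returns a history dict with per-epoch
    train/val losses and the normalization stats used.
    """
    if not train_samples or not val_samples:
        raise ValueError("training and validation sets must be non-empty")
    cfg = model.cfg
    if stats is None:
        stats = compute_normalization_stats(
            np.concatenate([x.reshape(-1) for x, _ in train_samples])
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x7124]))
    opt = _Adam(model.params, cfg.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_params = None
    bad_epochs = 0

    xs_val = [normalize(x, stats) for x, _ in val_samples]
    ys_val = [y for _, y in val_samples]

    for epoch in range(cfg.max_epochs):
        # step decay: large steps explore early, small steps stabilize the
        # endgame (late-stage oscillation can re-open the background leak)
        if epoch >= 0.8 * cfg.max_epochs:
            opt.lr = 0.25 * cfg.learning_rate
        elif epoch >= 0.6 * cfg.max_epochs:
            opt.lr = 0.5 * cfg.learning_rate
        order = rng.permutation(len(train_samples))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = [], []
            for i in idx:
                x, y = train_samples[i]
                if cfg.augment:
                    # one draw per sample so the k temporal channels share
                    # the same contrast factor
                    aug_seed = int(rng.integers(0, 2**31 - 1))
                    x = augment(
                        x, aug_seed, cfg.augment_noise_sd, cfg.augment_contrast
                    )
                xb.append(normalize(x, stats))
                yb.append(y)
            xb = np.stack(xb)
            yb = np.stack(yb).astype(np.float32)
            w = _combination_weights(yb.transpose(1, 0, 2, 3))
            probs = model.forward(xb, keep_cache=True)
            loss, dprobs = _dice_loss_and_grad(probs, yb, w, cfg.loss_prob_floor)
            dlogits_extra = None
            if cfg.ce_weight > 0:
                # cross-entropy stabilizer: pure Dice training cannot revive
                # a class whose softmax output underflows (its logit
                # gradient is proportional to p); the CE logit gradient
                # p - g does not vanish, so no channel can die permanently
                ce = -float(
                    (yb * np.log(np.maximum(probs, 1e-12))).sum()
                ) / (probs.shape[0] * probs.shape[2] * probs.shape[3])
                loss += cfg.ce_weight * ce
                dlogits_extra = (
                    cfg.ce_weight
                    * (probs - yb)
                    / (probs.shape[0] * probs.shape[2] * probs.shape[3])
                )
            grads = model.backward(dprobs, dlogits_extra)
            if cfg.freeze_output_bias:
                # a learnable global offset is the engine of the
                # background-leak pathology; the prior bias stays fixed and
                # per-class calibration is the threshold stage's job
                grads.pop("out_b", None)
            opt.step(model.params, grads)
            epoch_losses.append(loss)
        history["train_loss"].append(float(np.mean(epoch_losses)))

        val_losses = []
        for start in range(0, len(xs_val), cfg.batch_size):
            xb = np.stack(xs_val[start : start + cfg.batch_size])
            yb = np.stack(ys_val[start : start + cfg.batch_size]).astype(np.float32)
            w = _combination_weights(yb.transpose(1, 0, 2, 3))
            probs = model.forward(xb)
            vloss_b, _ = _dice_loss_and_grad(probs, yb, w)
            if cfg.ce_weight > 0:
                vloss_b += cfg.ce_weight * -float(
                    (yb * np.log(np.maximum(probs, 1e-12))).sum()
                ) / (probs.shape[0] * probs.shape[2] * probs.shape[3])
            val_losses.append(vloss_b)
        vloss = float(np.mean(val_losses))
        history["val_loss"].append(vloss)
        logger.info("epoch %d: train %.4f val %.4f", epoch, history["train_loss"][-1], vloss)

        if vloss < best_val - max(cfg.min_delta, 1e-6):
            best_val = vloss
            best_params = {k: v.copy() for k, v in model.params.items()}
            bad_epochs = 0
        elif vloss < best_val:  # still the best checkpoint, just not by much
            best_val = vloss
            best_params = {k: v.copy() for k, v in model.params.items()}
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                logger.info("early stop at epoch %d", epoch)
                break
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                logger.info("early stop at epoch %d", epoch)
                break

    if best_params is not None:
        model.params = best_params
    history["stats"] = stats
    history["best_val_loss"] = float(best_val)
    return history


@dataclass
class ProbabilityMaps:
    """Per-frame nine-channel class probabilities for the predicted frames."""

    maps: np.ndarray  # (n_predicted, 9, H, W) float32
    frames: list[int]  # recording frame indices with a prediction

    def channel(self, label: str) -> np.ndarray:
        """(n_predicted, H, W) probabilities of one vertebra (or background)."""
        return self.maps[:, CHANNELS.index(label)]


def predict(
    model: UNet, rec: Recording, stats: NormalizationStats, batch_size: int = 8
) -> ProbabilityMaps:
    """Segment every frame of a recording that has full temporal context."""
    k = model.cfg.in_frames
    if rec.frames.shape[1:] != tuple(model.cfg.image_size):
        raise ValueError(
            f"recording frames {rec.frames.shape[1:]} do not match model "
            f"size {model.cfg.image_size}"
        )
    frames = predicted_frame_indices(rec.n_frames, k)
    out = np.empty((len(frames), 9) + tuple(model.cfg.image_size), dtype=np.float32)
    for start in range(0, len(frames), batch_size):
        chunk = frames[start : start + batch_size]
        xb = np.stack([normalize(make_temporal_input(rec, t, k), stats) for t in chunk])
        out[start : start + len(chunk)] = model.forward(xb)
    return ProbabilityMaps(maps=out, frames=frames)
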