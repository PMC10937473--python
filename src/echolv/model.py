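"""U-Net heatmap regression: configuration, augmentation, training, inference.

The network maps a 3-channel working-resolution frame to a 5-channel heatmap
stack (4 keypoints + pseudo-line) and is trained with a masked mean-squared
error: channels whose keypoint a rater could not localise carry zero loss
weight, and the pseudo-line channel carries a configurable weight.  The
learning rate starts at ``lr_init`` and is divided by ``plateau_factor``
whenever the held-out loss fails to improve for ``plateau_patience``
consecutive epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.transform import resize as _sk_resize

from .annotation import Annotation, Dataset, FrameRecord, KeypointName
from .heatmap import (
    DEFAULT_CONFIDENCE_FLOOR,
    PSEUDO_LINE_CHANNEL,
    HeatmapStack,
    coords_working_to_native,
    decode_heatmap,
    encode_keypoints,
)
from .nn import UNet, make_optimizer

__all__ = [
    "NetConfig", "TrainConfig", "AffineRanges", "KeypointModel",
    "PlateauScheduler", "augment_pair", "masked_mse", "masked_mse_grad",
    "train", "predict_keypoints", "prepare_image",
]


@dataclass(frozen=True)
class NetConfig:
    depth: int = 2
    base_channels: int = 8
    in_channels: int = 3
    out_channels: int = 5
    working_size: tuple[int, int] = (320, 320)

    def __post_init__(self) -> None:
        h, w = self.working_size
        if h % 2 ** self.depth or w % 2 ** self.depth:
            raise ValueError("working_size must be divisible by 2^depth")


@dataclass(frozen=True)
class AffineRanges:
    """Augmentation ranges; the all-zero/identity instance disables augmentation."""

    rotation_deg: float = 10.0
    translation_frac: float = 0.05
    scale_min: float = 0.9
    scale_max: float = 1.1
    gamma_min: float = 0.7
    gamma_max: float = 1.4

    @classmethod
    def identity(cls) -> "AffineRanges":
        return cls(rotation_deg=0.0, translation_frac=0.0,
                   scale_min=1.0, scale_max=1.0, gamma_min=1.0, gamma_max=1.0)

    def is_identity(self) -> bool:
        return (self.rotation_deg == 0 and self.translation_frac == 0
                and self.scale_min == self.scale_max == 1.0
                and self.gamma_min == self.gamma_max == 1.0)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    lr_init: float = 0.001
    plateau_factor: float = 5.0
    plateau_patience: int = 20
    batch_size: int = 8
    seed: int = 0
    optimizer: str = "TADAM"
    augmentation: AffineRanges = field(default_factory=AffineRanges)
    augment: bool = True
    sigma_px: float = 15.0
    pseudo_line_loss_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.lr_init <= 0:
            raise ValueError("lr_init must be positive")
        if self.plateau_factor <= 1:
            raise ValueError("plateau_factor must exceed 1")
        if self.pseudo_line_loss_weight < 0:
            raise ValueError("pseudo_line_loss_weight must be >= 0")


class PlateauScheduler:
    """Reduce-on-plateau learning-rate state machine.

    The LR is divided by ``factor`` after ``patience`` consecutive epochs
    without improvement of the monitored loss; the bad-epoch counter then
    resets (the best value is retained).
    """

    def __init__(self, lr_init: float, factor: float, patience: int):
        self.lr = lr_init
        self.factor = factor
        self.patience = patience
        self.best = np.inf
        self.bad_epochs = 0

    def update(self, loss: float) -> float:
        """Report one epoch's monitored loss; returns the LR for the next epoch."""
        if loss < self.best:
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.lr /= self.factor
                self.bad_epochs = 0
        return self.lr


def _channel_weights(pseudo_line_weight: float) -> np.ndarray:
    w = np.ones(5)
    w[PSEUDO_LINE_CHANNEL] = pseudo_line_weight
    return w


def masked_mse(pred: np.ndarray, target: np.ndarray, loss_mask: np.ndarray,
               pseudo_line_weight: float = 1.0) -> float:
    """Masked MSE over channel-pixels.

    ``pred``/``target``: (..., 5, H, W); ``loss_mask``: (..., 5) in {0, 1}.
    The mean is taken over unmasked channel-pixels; the pseudo-line channel's
    squared-error term is multiplied by ``pseudo_line_weight``.  Returns 0 if
    every channel is masked.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError("pred and target shapes differ")
    mask = np.asarray(loss_mask, dtype=np.float64)
    denom = float(mask.sum()) * pred.shape[-1] * pred.shape[-2]
    if denom == 0:
        return 0.0
    w = _channel_weights(pseudo_line_weight)
    se = ((pred - target) ** 2).sum(axis=(-1, -2))  # (..., 5)
    num = float((se * mask * w).sum())
    return num / denom


def masked_mse_grad(pred: np.ndarray, target: np.ndarray, loss_mask: np.ndarray,
                    pseudo_line_weight: float = 1.0) -> np.ndarray:
    """Gradient of :func:`masked_mse` with respect to ``pred``."""
    mask = np.asarray(loss_mask, dtype=np.float64)
    denom = float(mask.sum()) * pred.shape[-1] * pred.shape[-2]
    if denom == 0:
        return np.zeros_like(pred)
    w = (_channel_weights(pseudo_line_weight) * mask)[..., None, None]
    return (2.0 / denom) * w * (pred - target)


def _affine_matrix(angle_rad: float, scale: float, shift_xy: tuple[float, float],
                   shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-map matrix/offset for scipy.ndimage.affine_transform (row, col)."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    fwd = scale * np.array([[c, -s], [s, c]])  # acts on (row, col) offsets
    inv = np.linalg.inv(fwd)
    center = np.array([cy, cx])
    shift = np.array([shift_xy[1], shift_xy[0]])  # (row, col)
    offset = center - inv @ (center + shift)
    return inv, offset


def sample_affine(
    r: AffineRanges, shape: tuple[int, int], seed: int,
) -> tuple[float, float, tuple[float, float], float]:
    """Draw one augmentation: (angle_rad, scale, shift_xy_px, gamma), per seed."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xA06]))
    angle = np.deg2rad(rng.uniform(-r.rotation_deg, r.rotation_deg))
    scale = rng.uniform(r.scale_min, r.scale_max)
    h, w = shape
    shift = (rng.uniform(-r.translation_frac, r.translation_frac) * w,
             rng.uniform(-r.translation_frac, r.translation_frac) * h)
    gamma = rng.uniform(r.gamma_min, r.gamma_max)
    return float(angle), float(scale), shift, float(gamma)


def augment_pair(
    image: np.ndarray, stack: HeatmapStack, config: TrainConfig, seed: int,
) -> tuple[np.ndarray, HeatmapStack]:
    """Sample one affine + gamma augmentation and apply it to an image/target pair.

    The same affine warp is applied to the image and every heatmap channel
    (bilinear, zero fill); gamma applies to the image only; the loss mask is
    unchanged.  Deterministic per seed.  With identity ranges the pair is
    returned unchanged.
    """
    r = config.augmentation
    if not config.augment or r.is_identity():
        return image, stack
    h, w = image.shape[:2]
    angle, scale, shift, gamma = sample_affine(r, (h, w), seed)

    inv, offset = _affine_matrix(angle, scale, shift, (h, w))

    def warp(plane: np.ndarray) -> np.ndarray:
        return ndi.affine_transform(plane.astype(np.float64), inv, offset=offset,
                                    order=1, mode="constant", cval=0.0)

    if image.ndim == 2:
        img_out = warp(image)
    else:
        img_out = np.stack([warp(image[..., c]) for c in range(image.shape[-1])], axis=-1)
    img_out = np.clip(img_out, 0.0, 1.0) ** gamma
    planes = np.stack([warp(p) for p in stack.planes]).astype(np.float32)
    out_stack = HeatmapStack(planes=planes, sigma_px=stack.sigma_px,
                             loss_mask=stack.loss_mask.copy(),
                             scale_to_native=stack.scale_to_native)
    return img_out.astype(image.dtype), out_stack


def prepare_image(image: np.ndarray, working_size: tuple[int, int]) -> np.ndarray:
    """Normalise to float32 [0, 1], resize bilinearly, and stack to 3 channels."""
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img.astype(np.float32) / 255.0
    elif img.dtype == np.uint16:
        img = img.astype(np.float32) / 65535.0
    else:
        img = img.astype(np.float32)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    if img.shape != tuple(working_size):
        img = _sk_resize(img, working_size, order=1, preserve_range=True,
                         anti_aliasing=False).astype(np.float32)
    return np.repeat(img[..., None], 3, axis=-1).astype(np.float32)


@dataclass
class KeypointModel:
    """A trained network plus everything needed for inference."""

    net: UNet
    net_config: NetConfig
    train_config: TrainConfig
    history: list[dict] = field(default_factory=list)

    def forward(self, batch: np.ndarray) -> np.ndarray:
        return self.net.forward(batch)


def _build_samples(dataset: Dataset, images: dict[str, np.ndarray],
                   net: NetConfig, cfg: TrainConfig):
    samples = []
    for ann in dataset.annotations:
        frame = dataset.frame(ann.frame_id)
        if ann.frame_id not in images:
            raise ValueError(f"no image supplied for frame {ann.frame_id}")
        img = prepare_image(images[ann.frame_id], net.working_size)
        stack = encode_keypoints(ann, frame, net.working_size, cfg.sigma_px)
        samples.append((img, stack))
    return samples


def _epoch_loss(model_net: UNet, samples, cfg: TrainConfig, batch: int) -> float:
    tot_num = 0.0
    tot_den = 0.0
    for i in range(0, len(samples), batch):
        chunk = samples[i:i + batch]
        x = np.stack([s[0] for s in chunk])
        pred = model_net.forward(x)  # (N, H, W, 5)
        for j, (_, stack) in enumerate(chunk):
            m = float(stack.loss_mask.sum()) * stack.planes.shape[-1] * stack.planes.shape[-2]
            tot_num += masked_mse(pred[j].transpose(2, 0, 1), stack.planes,
                                  stack.loss_mask, cfg.pseudo_line_loss_weight) * m
            tot_den += m
    return tot_num / tot_den if tot_den else 0.0


def train(
    train_set: Dataset,
    test_set: Dataset,
    images: dict[str, np.ndarray],
    net: NetConfig,
    cfg: TrainConfig,
) -> KeypointModel:
    """Train the heatmap network; returns the best-held-out-loss checkpoint.

    Per-epoch train/test losses and the LR are recorded in
    ``model.history``.  Fully seeded: same configs and seeds give identical
    histories on CPU.
    """
    if not train_set.annotations or not test_set.annotations:
        raise ValueError("train and test datasets must be non-empty")
    overlap = {f.frame_id for f in train_set.frames} & {f.frame_id for f in test_set.frames}
    if overlap:
        raise ValueError(f"train/test frames overlap: {sorted(overlap)[:5]}")

    train_samples = _build_samples(train_set, images, net, cfg)
    test_samples = _build_samples(test_set, images, net, cfg)

    unet = UNet(net.depth, net.base_channels, net.in_channels, net.out_channels,
                seed=cfg.seed)
    opt = make_optimizer(cfg.optimizer, unet.tensors(), cfg.lr_init)
    sched = PlateauScheduler(cfg.lr_init, cfg.plateau_factor, cfg.plateau_patience)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, 0x77]))

    history: list[dict] = []
    best_loss = np.inf
    best_weights = unet.get_weights()
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_samples))
        running = 0.0
        nb = 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xs, stacks = [], []
            for k in idx:
                img, stack = train_samples[k]
                img, stack = augment_pair(img, stack, cfg,
                                          seed=int(rng.integers(0, 2**31 - 1)))
                xs.append(img)
                stacks.append(stack)
            x = np.stack(xs)
            pred = unet.forward(x)  # (N, H, W, 5)
            target = np.stack([s.planes.transpose(1, 2, 0) for s in stacks])
            mask = np.stack([s.loss_mask for s in stacks])  # (N, 5)
            predc = pred.transpose(0, 3, 1, 2)
            targetc = target.transpose(0, 3, 1, 2)
            loss = masked_mse(predc, targetc, mask, cfg.pseudo_line_loss_weight)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, step {step}")
            grad = masked_mse_grad(predc, targetc, mask, cfg.pseudo_line_loss_weight)
            unet.backward(grad.transpose(0, 2, 3, 1).astype(np.float32))
            opt.lr = sched.lr
            opt.step()
            running += loss
            nb += 1
            step += 1
        test_loss = _epoch_loss(unet, test_samples, cfg, cfg.batch_size)
        if not np.isfinite(test_loss):
            raise FloatingPointError(f"non-finite test loss at epoch {epoch}")
        if test_loss < best_loss:
            best_loss = test_loss
            best_weights = unet.get_weights()
        lr_now = sched.lr
        sched.update(test_loss)
        history.append({"epoch": epoch, "train_loss": running / max(nb, 1),
                        "test_loss": test_loss, "lr": lr_now})
    unet.set_weights(best_weights)
    return KeypointModel(net=unet, net_config=net, train_config=cfg, history=history)


def predict_keypoints(
    model: KeypointModel,
    frame: FrameRecord,
    image: np.ndarray,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
    refine: str = "quadratic",
) -> dict[KeypointName, tuple[float, float, float] | None]:
    """Run inference on one frame; returns native-space (x, y, confidence) per point.

    The image is resized to the working grid, passed through the network, each
    keypoint channel is decoded to sub-pixel working coordinates, and the
    result is mapped back to native pixels.  Channels whose peak falls below
    ``confidence_floor`` give ``None``.
    """
    ws = model.net_config.working_size
    x = prepare_image(image, ws)[None]
    pred = model.forward(x)[0]  # (H, W, 5)
    scale = (frame.width_px / ws[1], frame.height_px / ws[0])
    out: dict[KeypointName, tuple[float, float, float] | None] = {}
    for i, name in enumerate(KeypointName):
        dec = decode_heatmap(pred[..., i], confidence_floor=confidence_floor,
                             refine=refine)
        if dec is None:
            out[name] = None
            continue
        nx, ny = coords_working_to_native((dec[0], dec[1]), scale)
        nx = float(np.clip(nx, 0.0, frame.width_px - 1e-6))
        ny = float(np.clip(ny, 0.0, frame.height_px - 1e-6))
        out[name] = (nx, ny, dec[2])
    return out


def predict_annotation(model: KeypointModel, frame: FrameRecord, image: np.ndarray,
                       rater_id: str = "AI", **kw) -> Annotation:
    """Convenience wrapper: inference as an :class:`Annotation` (confidences dropped)."""
    preds = predict_keypoints(model, frame, image, **kw)
    pts = {k: (None if v is None else (v[0], v[1])) for k, v in preds.items()}
    return Annotation(frame_id=frame.frame_id, rater_id=rater_id, repeat_index=1,
                      points=pts)
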