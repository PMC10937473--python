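"""Gaussian heatmap encoding, pseudo-line rendering, and sub-pixel decoding.

A keypoint is represented as a peak-normalised Gaussian confidence map:
value at pixel q is exp(-||q - p||^2 / (2 sigma^2)), amplitude 1 at the true
location p.  Peak normalisation (rather than unit integral) keeps the decoded
peak value directly interpretable as a confidence.  Missing points get an
all-zero channel with a zero loss weight, so they contribute nothing to a
masked loss.

A fifth channel carries the pseudo-line: a Gaussian ridge along the polyline
joining the four keypoints in anatomical order.  It is a geometric-consistency
target that encourages near-collinear, correctly ordered point predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import Annotation, FrameRecord, KeypointName

__all__ = [
    "HeatmapStack",
    "PSEUDO_LINE_CHANNEL",
    "encode_keypoints",
    "render_pseudo_line",
    "decode_heatmap",
    "coords_working_to_native",
    "coords_native_to_working",
]

PSEUDO_LINE_CHANNEL = 4
DEFAULT_WORKING_SIZE = (320, 320)
DEFAULT_SIGMA_PX = 15.0
DEFAULT_CONFIDENCE_FLOOR = 0.1


@dataclass
class HeatmapStack:
    """Five target/prediction planes plus loss mask and native-scale mapping.

    ``planes``: float32 array (5, H, W) — four keypoint channels in
    :class:`KeypointName` order then the pseudo-line channel; values in [0, 1].
    ``loss_mask``: per-channel weight in {0, 1}; masked channels are all-zero.
    ``scale_to_native``: (sx, sy) multipliers mapping working to native pixels.
    """

    planes: np.ndarray
    sigma_px: float
    loss_mask: np.ndarray
    scale_to_native: tuple[float, float]

    def __post_init__(self) -> None:
        if self.planes.ndim != 3 or self.planes.shape[0] != 5:
            raise ValueError("planes must have shape (5, H, W)")
        if self.loss_mask.shape != (5,):
            raise ValueError("loss_mask must have shape (5,)")

    @property
    def working_size(self) -> tuple[int, int]:
        return self.planes.shape[1], self.planes.shape[2]


def coords_native_to_working(
    xy: tuple[float, float], scale_to_native: tuple[float, float],
) -> tuple[float, float]:
    return xy[0] / scale_to_native[0], xy[1] / scale_to_native[1]


def coords_working_to_native(
    xy: tuple[float, float], scale_to_native: tuple[float, float],
) -> tuple[float, float]:
    """Invert the working-resolution resize: pure per-axis scaling."""
    sx, sy = scale_to_native
    if sx <= 0 or sy <= 0:
        raise ValueError("scale factors must be positive")
    return xy[0] * sx, xy[1] * sy


def _gaussian_plane(
    shape: tuple[int, int], center: tuple[float, float], sigma: float,
) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    d2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2
    return np.exp(-d2 / (2.0 * sigma * sigma))


def render_pseudo_line(
    points: dict[KeypointName, tuple[float, float] | None],
    working_size: tuple[int, int],
    sigma_px: float,
) -> tuple[np.ndarray, int]:
    """Gaussian ridge along the polyline through the present points in order.

    Value at q is exp(-d(q)^2 / (2 sigma^2)) with d the Euclidean distance to
    the polyline.  Returns (plane, mask); fewer than 2 present points yields
    an all-zero plane with mask 0.
    """
    h, w = working_size
    present = [np.asarray(points[k], dtype=np.float64)
               for k in KeypointName if points.get(k) is not None]
    if len(present) < 2:
        return np.zeros((h, w), dtype=np.float64), 0
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    d2 = np.full((h, w), np.inf)
    for a, b in zip(present[:-1], present[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            dx, dy = xx - a[0], yy - a[1]
            d2 = np.minimum(d2, dx * dx + dy * dy)
            continue
        t = ((xx - a[0]) * ab[0] + (yy - a[1]) * ab[1]) / denom
        np.clip(t, 0.0, 1.0, out=t)
        dx = xx - (a[0] + t * ab[0])
        dy = yy - (a[1] + t * ab[1])
        d2 = np.minimum(d2, dx * dx + dy * dy)
    return np.exp(-d2 / (2.0 * sigma_px * sigma_px)), 1


def encode_keypoints(
    annotation: Annotation,
    frame: FrameRecord,
    working_size: tuple[int, int] = DEFAULT_WORKING_SIZE,
    sigma_px: float = DEFAULT_SIGMA_PX,
) -> HeatmapStack:
    """Encode an annotation as a 5-channel Gaussian heatmap stack.

    Native coordinates are rescaled to the working grid; targets are rendered
    directly at working resolution (never image-resized), so the unit peak is
    preserved exactly.  Missing points give all-zero channels with mask 0.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    h, w = working_size
    if h <= 0 or w <= 0:
        raise ValueError("working_size must be positive")
    sx = frame.width_px / w
    sy = frame.height_px / h
    scale = (sx, sy)
    planes = np.zeros((5, h, w), dtype=np.float64)
    mask = np.zeros(5, dtype=np.float64)
    working_pts: dict[KeypointName, tuple[float, float] | None] = {}
    for i, name in enumerate(KeypointName):
        p = annotation.points[name]
        if p is None:
            working_pts[name] = None
            continue
        wp = coords_native_to_working(p, scale)
        working_pts[name] = wp
        planes[i] = _gaussian_plane((h, w), wp, sigma_px)
        mask[i] = 1.0
    planes[PSEUDO_LINE_CHANNEL], mask[PSEUDO_LINE_CHANNEL] = render_pseudo_line(
        working_pts, (h, w), sigma_px)
    return HeatmapStack(
        planes=planes.astype(np.float32),
        sigma_px=float(sigma_px),
        loss_mask=mask,
        scale_to_native=scale,
    )


def _quadratic_offset(vm: float, v0: float, vp: float) -> float:
    """Sub-pixel offset of a log-parabola through three samples at -1, 0, +1.

    Exact for a sampled Gaussian (whose log is quadratic).  Values are clamped
    to a tiny positive floor before the log; a non-concave fit falls back to 0.
    """
    eps = 1e-12
    lm, l0, lp = (np.log(max(v, eps)) for v in (vm, v0, vp))
    denom = lm - 2.0 * l0 + lp
    if denom >= -eps:
        return 0.0
    off = 0.5 * (lm - lp) / denom
    return float(np.clip(off, -0.5, 0.5))


def decode_heatmap(
    plane: np.ndarray,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
    refine: str = "quadratic",
) -> tuple[float, float, float] | None:
    """Locate the heatmap peak and refine it to sub-pixel precision.

    The global maximum pixel is found first (ties broken toward the smallest
    row-major index).  ``refine`` selects the sub-pixel step:

    - ``"quadratic"`` (default): per-axis log-parabolic 3-point fit around the
      peak — exact for Gaussian-shaped peaks;
    - ``"centroid"``: intensity-weighted centroid of the 7x7 window around the
      peak (window clipped at borders);
    - ``"none"``: integer argmax only.

    Returns ``(x, y, confidence)`` with confidence the peak value, or ``None``
    when the peak is below ``confidence_floor``.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2 or plane.size == 0:
        raise ValueError("plane must be a non-empty 2-D array")
    if not np.all(np.isfinite(plane)):
        raise ValueError("plane contains non-finite values")
    flat_idx = int(np.argmax(plane))  # argmax returns the first (row-major) maximum
    r0, c0 = divmod(flat_idx, plane.shape[1])
    peak = float(plane[r0, c0])
    if peak < confidence_floor:
        return None
    h, w = plane.shape
    if refine == "none":
        return float(c0), float(r0), peak
    if refine == "quadratic":
        x, y = float(c0), float(r0)
        if 1 <= c0 < w - 1:
            x += _quadratic_offset(plane[r0, c0 - 1], peak, plane[r0, c0 + 1])
        if 1 <= r0 < h - 1:
            y += _quadratic_offset(plane[r0 - 1, c0], peak, plane[r0 + 1, c0])
        return x, y, peak
    if refine == "centroid":
        r_lo, r_hi = max(0, r0 - 3), min(h, r0 + 4)
        c_lo, c_hi = max(0, c0 - 3), min(w, c0 + 4)
        win = plane[r_lo:r_hi, c_lo:c_hi]
        total = float(win.sum())
        if total <= 0:
            return float(c0), float(r0), peak
        yy, xx = np.mgrid[r_lo:r_hi, c_lo:c_hi].astype(np.float64)
        return float((xx * win).sum() / total), float((yy * win).sum() / total), peak
    raise ValueError(f"unknown refine mode {refine!r}")
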