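"""Synthetic long-axis echo phantoms with known keypoints, and a rater simulator.

The phantom emulates the right parasternal 4-chamber appearance relevant to
linear LV measurement: a fan-shaped imaging sector containing two bright,
near-parallel wall bands (septum and free wall) crossed by the measurement
axis, with multiplicative speckle texture and a gamma curve.  The measurement
axis is the central ray of the sector, so the longitudinal position of the
true caliper points is geometrically recoverable from the image (midline of
the visible band segment) and the learning task is well-posed.

Ground truth: the four keypoints are the intersections of the axis with the
band edges; consecutive Euclidean gaps equal the IVS / LVD / FW dimensions
converted to pixels.

The rater simulator mirrors the structure of a multi-expert validation study:
``n_raters`` observers each label every frame ``n_repeats`` times.  Noise
perpendicular to the walls (i.e. along the measurement axis) perturbs
thickness; noise along the walls moves the measurement site; each rater
additionally carries a fixed apical/basal (along-wall) bias, reflecting the
observation that observers agree on wall thickness much more than on where
along the wall to measure.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from .annotation import Annotation, Dataset, FrameRecord, KeypointName, Phase

__all__ = [
    "PhantomSpec",
    "RaterModel",
    "generate_phantom",
    "generate_cohort",
    "simulate_raters",
    "DEFAULT_COHORT_RANGES",
    "TINY_COHORT_RANGES",
]

_RAYLEIGH_MEAN = float(np.sqrt(np.pi / 2.0))  # E[R], R ~ Rayleigh(scale=1)


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one synthetic frame.

    Lengths are in cm; ``spacing_cm_per_px`` converts them to pixels
    (isotropic).  ``axis_origin`` is the SEPT_ANT location; the axis points in
    the direction ``axis_angle`` (radians, image convention: y down).  The
    sector apex sits ``apex_offset_px`` before the origin along the axis.
    """

    size_px: int = 320
    axis_origin: tuple[float, float] = (160.0, 60.0)
    axis_angle: float = np.pi / 2  # pointing down the image
    ivs_cm: float = 0.8
    lvd_cm: float = 2.6
    fw_cm: float = 0.7
    spacing_cm_per_px: float = 0.025
    wall_halfwidth_cm: float = 1.0
    wall_brightness: float = 0.85
    chamber_brightness: float = 0.2
    speckle_strength: float = 0.3
    gamma: float = 1.0
    sector_half_angle: float = 0.6
    apex_offset_px: float = 30.0

    def __post_init__(self) -> None:
        if min(self.ivs_cm, self.lvd_cm, self.fw_cm) <= 0:
            raise ValueError("dimensions must be positive")
        if self.spacing_cm_per_px <= 0:
            raise ValueError("spacing must be positive")
        if not self.wall_brightness > self.chamber_brightness:
            raise ValueError("wall_brightness must exceed chamber_brightness")
        if self.speckle_strength < 0 or self.gamma <= 0:
            raise ValueError("invalid noise parameters")

    @property
    def total_cm(self) -> float:
        return self.ivs_cm + self.lvd_cm + self.fw_cm

    def truth_points(self) -> dict[KeypointName, tuple[float, float]]:
        """The four axis/band-edge intersections, in pixels."""
        ux, uy = np.cos(self.axis_angle), np.sin(self.axis_angle)
        px_gaps = np.array([0.0, self.ivs_cm, self.lvd_cm, self.fw_cm]) / self.spacing_cm_per_px
        dists = np.cumsum(px_gaps)
        x0, y0 = self.axis_origin
        return {
            name: (x0 + ux * d, y0 + uy * d)
            for name, d in zip(KeypointName, dists)
        }


@dataclass(frozen=True)
class RaterModel:
    """Stochastic model of a panel of raters labelling the same frames."""

    n_raters: int = 13
    n_repeats: int = 2
    sigma_transverse_px: float = 1.5
    sigma_longitudinal_px: float = 6.0
    rater_longitudinal_bias_sd_px: float = 4.0
    miss_probability: float = 0.0

    def __post_init__(self) -> None:
        if self.n_raters < 1 or self.n_repeats < 1:
            raise ValueError("need at least one rater and one repeat")
        for s in (self.sigma_transverse_px, self.sigma_longitudinal_px,
                  self.rater_longitudinal_bias_sd_px):
            if not np.isfinite(s) or s < 0:
                raise ValueError("noise SDs must be finite and non-negative")
        if not (0.0 <= self.miss_probability < 1.0):
            raise ValueError("miss_probability must be in [0, 1)")


def _check_fits(spec: PhantomSpec) -> None:
    margin = 2.0
    for name, (x, y) in spec.truth_points().items():
        if not (margin <= x < spec.size_px - margin and margin <= y < spec.size_px - margin):
            raise ValueError(
                f"phantom geometry does not fit: {name.name} at ({x:.1f}, {y:.1f}) "
                f"outside {spec.size_px}x{spec.size_px} image")


def generate_phantom(
    spec: PhantomSpec, seed: int, frame_id: str = "phantom", study_id: str = "study",
    phase: Phase = Phase.UNKNOWN,
) -> tuple[FrameRecord, np.ndarray, Annotation]:
    """Render one phantom frame.

    Returns the frame record, the image as float32 in [0, 1] of shape
    (size, size), and the ground-truth annotation (``rater_id="TRUTH"``).
    Deterministic per seed.
    """
    _check_fits(spec)
    n = spec.size_px
    ux, uy = np.cos(spec.axis_angle), np.sin(spec.axis_angle)
    x0, y0 = spec.axis_origin

    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    # longitudinal coordinate: signed distance along the axis from SEPT_ANT
    t = (xx - x0) * ux + (yy - y0) * uy
    # lateral coordinate: signed distance from the axis (along the walls)
    lat = -(xx - x0) * uy + (yy - y0) * ux

    ivs_px = spec.ivs_cm / spec.spacing_cm_per_px
    lvd_px = spec.lvd_cm / spec.spacing_cm_per_px
    fw_px = spec.fw_cm / spec.spacing_cm_per_px
    hw_px = spec.wall_halfwidth_cm / spec.spacing_cm_per_px

    # walls are compact bright segments centred on the measurement axis: the
    # caliper site sits at the lateral midpoint of the visible band, so the
    # true keypoints are recoverable from local image structure
    img = np.full((n, n), spec.chamber_brightness, dtype=np.float64)
    in_band = np.abs(lat) <= hw_px
    in_septum = (t >= 0) & (t < ivs_px) & in_band
    in_freewall = (t >= ivs_px + lvd_px) & (t < ivs_px + lvd_px + fw_px) & in_band
    img[in_septum | in_freewall] = spec.wall_brightness

    # fan sector about the axis, apex behind SEPT_ANT
    ax, ay = x0 - ux * spec.apex_offset_px, y0 - uy * spec.apex_offset_px
    ang = np.arctan2(yy - ay, xx - ax)
    dang = np.angle(np.exp(1j * (ang - spec.axis_angle)))
    img[np.abs(dang) > spec.sector_half_angle] = 0.0

    if spec.speckle_strength > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5EC]))
        r = rng.rayleigh(scale=1.0, size=(n, n))
        img *= 1.0 + spec.speckle_strength * (r - _RAYLEIGH_MEAN)
    np.clip(img, 0.0, 1.0, out=img)
    if spec.gamma != 1.0:
        img **= spec.gamma

    frame = FrameRecord(
        study_id=study_id, frame_id=frame_id, image_path="",
        height_px=n, width_px=n,
        spacing_x_cm=spec.spacing_cm_per_px, spacing_y_cm=spec.spacing_cm_per_px,
        phase=phase,
    )
    truth = Annotation(frame_id=frame_id, rater_id="TRUTH", repeat_index=1,
                       points=spec.truth_points())
    return frame, img.astype(np.float32), truth


# parameter ranges: (low, high) per PhantomSpec field that generate_cohort draws
DEFAULT_COHORT_RANGES: dict[str, tuple[float, float]] = {
    "axis_origin_x": (140.0, 180.0),
    "axis_origin_y": (50.0, 70.0),
    "axis_angle": (np.pi / 2 - 0.15, np.pi / 2 + 0.15),
    "ivs_cm": (0.5, 1.1),
    "lvd_cm": (2.0, 3.2),
    "fw_cm": (0.5, 1.0),
    "wall_halfwidth_cm": (0.8, 1.2),
    "wall_brightness": (0.75, 0.95),
    "chamber_brightness": (0.12, 0.28),
    "speckle_strength": (0.2, 0.4),
    "gamma": (0.9, 1.1),
    "sector_half_angle": (0.5, 0.65),
}

# scaled-down geometry for 128 px working frames (small-dog hearts)
TINY_COHORT_RANGES: dict[str, tuple[float, float]] = {
    "axis_origin_x": (56.0, 72.0),
    "axis_origin_y": (20.0, 28.0),
    "axis_angle": (np.pi / 2 - 0.12, np.pi / 2 + 0.12),
    "ivs_cm": (0.28, 0.38),
    "lvd_cm": (0.90, 1.20),
    "fw_cm": (0.28, 0.38),
    "wall_halfwidth_cm": (0.36, 0.50),
    "wall_brightness": (0.75, 0.95),
    "chamber_brightness": (0.12, 0.28),
    "speckle_strength": (0.10, 0.20),
    "gamma": (0.9, 1.1),
    "sector_half_angle": (0.50, 0.62),
}


def generate_cohort(
    n: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> tuple[Dataset, dict[str, np.ndarray]]:
    """Generate ``n`` phantom frames with parameters drawn uniformly from ranges.

    Frames are paired into pseudo-studies of one ED and one ES frame each,
    mirroring a validation cohort of 2 frames per scan.  Returns the dataset
    (truth annotations attached, ``rater_id="TRUTH"``) and a mapping
    frame_id -> image.  Reproducible: each frame derives its own substream
    from ``seed`` and its index, independent of generation order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = dict(DEFAULT_COHORT_RANGES if ranges is None else ranges)
    base = base_spec if base_spec is not None else PhantomSpec()
    unknown = set(ranges) - (set(DEFAULT_COHORT_RANGES) | {"spacing_cm_per_px"})
    if unknown:
        raise ValueError(f"unknown range key(s): {sorted(unknown)}")
    for k, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"infeasible range for {k}: ({lo}, {hi})")

    frames: list[FrameRecord] = []
    annotations: list[Annotation] = []
    images: dict[str, np.ndarray] = {}
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, i]))
        draw = {k: rng.uniform(lo, hi) for k, (lo, hi) in ranges.items()}
        spec = replace(
            base,
            axis_origin=(draw.pop("axis_origin_x", base.axis_origin[0]),
                         draw.pop("axis_origin_y", base.axis_origin[1])),
            **draw,
        )
        study = f"S{i // 2:04d}"
        phase = Phase.ED if i % 2 == 0 else Phase.ES
        fid = f"F{i:04d}"
        frame_seed = int(rng.integers(0, 2**31 - 1))
        try:
            frame, img, truth = generate_phantom(
                spec, seed=frame_seed, frame_id=fid, study_id=study, phase=phase)
        except ValueError as exc:
            raise ValueError(f"infeasible ranges: {exc}") from exc
        frames.append(frame)
        annotations.append(truth)
        images[fid] = img
    return Dataset(frames=frames, annotations=annotations), images


def _axis_direction(truth: Annotation) -> np.ndarray:
    p0 = np.array(truth.points[KeypointName.SEPT_ANT])
    p3 = np.array(truth.points[KeypointName.FW_POST])
    d = p3 - p0
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise ValueError("degenerate truth annotation: zero-length axis")
    return d / nrm


def _substream(seed: int, *keys: int | str) -> np.random.Generator:
    ints = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        ints.append(zlib.crc32(str(k).encode()) if isinstance(k, str) else int(k))
    return np.random.default_rng(np.random.SeedSequence(ints))


def rater_bias_px(model: RaterModel, seed: int, rater_index: int) -> float:
    """Fixed per-rater apical/basal offset, constant across frames and repeats."""
    rng = _substream(seed, 0xB1A5, rater_index)
    return float(rng.normal(0.0, model.rater_longitudinal_bias_sd_px))


def simulate_raters(
    truth: Annotation, frame: FrameRecord, model: RaterModel, seed: int,
) -> list[Annotation]:
    """Simulate a panel labelling one frame.

    Each point is displaced by transverse noise N(0, sigma_t^2) along the
    measurement axis (perpendicular to the walls; affects thickness) and
    longitudinal noise N(bias_r, sigma_l^2) perpendicular to it (along the
    walls; affects measurement site), with bias_r fixed per rater across
    frames and repeats.  Points are independently set MISSING with
    ``miss_probability``.  Displaced points are clipped to frame bounds.
    """
    if not truth.is_complete():
        raise ValueError("truth annotation must have all 4 points")
    u = _axis_direction(truth)           # along axis = perpendicular to walls
    v = np.array([-u[1], u[0]])          # along walls
    out: list[Annotation] = []
    for r in range(model.n_raters):
        bias = rater_bias_px(model, seed, r)
        for rep in range(1, model.n_repeats + 1):
            rng = _substream(seed, frame.frame_id, r, rep)
            pts: dict[KeypointName, tuple[float, float] | None] = {}
            for name in KeypointName:
                if rng.uniform() < model.miss_probability:
                    pts[name] = None
                    continue
                p = np.array(truth.points[name], dtype=np.float64)
                p = (p
                     + rng.normal(0.0, model.sigma_transverse_px) * u
                     + (bias + rng.normal(0.0, model.sigma_longitudinal_px)) * v)
                x = float(np.clip(p[0], 0.0, frame.width_px - 1e-6))
                y = float(np.clip(p[1], 0.0, frame.height_px - 1e-6))
                pts[name] = (x, y)
            out.append(Annotation(
                frame_id=frame.frame_id, rater_id=f"E{r:02d}",
                repeat_index=rep, points=pts))
    return out
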