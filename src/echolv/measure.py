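"""Caliper-style derivation of IVS / LVD / FW from the four keypoints.

Each dimension is the full Euclidean distance between consecutive landmarks,
computed in cm-space (per-axis pixel spacing applied to the coordinate deltas
before the norm), matching electronic-caliper behaviour.  Geometric sanity
flags — out-of-order points along the best-fit line, or excessive departure
from collinearity ("diagonal path" across the ventricle) — are advisory: they
mark a triplet invalid but the numbers are still reported when computable.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .annotation import Dataset, KeypointName

__all__ = ["GeometryFlag", "MeasurementTriplet", "derive_measurements",
           "check_geometry", "measurement_rows", "SITES"]

SITES = ("IVS", "LVD", "FW")
DEFAULT_COLLINEARITY_TOL_DEG = 15.0


class GeometryFlag(str, enum.Enum):
    OUT_OF_ORDER = "OUT_OF_ORDER"
    NON_COLLINEAR = "NON_COLLINEAR"
    MISSING_POINT = "MISSING_POINT"


@dataclass(frozen=True)
class MeasurementTriplet:
    """IVS / LVD / FW in px and cm with validity flags (NaN where undefined)."""

    ivs_cm: float
    lvd_cm: float
    fw_cm: float
    ivs_px: float
    lvd_px: float
    fw_px: float
    flags: frozenset[GeometryFlag] = field(default_factory=frozenset)

    @property
    def valid(self) -> bool:
        return not self.flags

    def cm_by_site(self) -> dict[str, float]:
        return {"IVS": self.ivs_cm, "LVD": self.lvd_cm, "FW": self.fw_cm}


def _gap(p: tuple[float, float], q: tuple[float, float],
         spacing: tuple[float, float]) -> tuple[float, float]:
    """(px, cm) Euclidean distance with anisotropic calibration."""
    dx, dy = q[0] - p[0], q[1] - p[1]
    sx, sy = spacing
    return math.hypot(dx, dy), math.hypot(dx * sx, dy * sy)


def check_geometry(
    points: dict[KeypointName, tuple[float, float]],
    collinearity_tol_deg: float = DEFAULT_COLLINEARITY_TOL_DEG,
    order_check: bool = True,
) -> set[GeometryFlag]:
    """Flag non-monotone ordering or departure from collinearity.

    Points are projected onto the total-least-squares line through them;
    OUT_OF_ORDER if the projections are not monotone in anatomical order,
    NON_COLLINEAR if the largest perpendicular deviation exceeds
    tan(tol) * span (span = extent of projections along the line).
    """
    pts = np.array([points[k] for k in KeypointName], dtype=np.float64)
    if pts.shape != (4, 2) or not np.all(np.isfinite(pts)):
        raise ValueError("need 4 finite points")
    centered = pts - pts.mean(axis=0)
    # principal direction of the 4 points = best-fit (TLS) line
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    u = vt[0]
    proj = centered @ u
    perp = centered @ np.array([-u[1], u[0]])
    flags: set[GeometryFlag] = set()
    if order_check:
        d = np.diff(proj)
        if not (np.all(d > 0) or np.all(d < 0)):
            flags.add(GeometryFlag.OUT_OF_ORDER)
    span = float(proj.max() - proj.min())
    if span > 0:
        tol = math.tan(math.radians(collinearity_tol_deg)) * span
        if float(np.abs(perp).max()) > tol:
            flags.add(GeometryFlag.NON_COLLINEAR)
    return flags


def derive_measurements(
    points: dict[KeypointName, tuple[float, float] | None],
    spacing: tuple[float, float],
    collinearity_tol_deg: float = DEFAULT_COLLINEARITY_TOL_DEG,
) -> MeasurementTriplet:
    """Compute the measurement triplet from (possibly incomplete) keypoints.

    ``spacing`` is (cm/px in x, cm/px in y).  A missing point sets the
    MISSING_POINT flag and leaves the dimensions that touch it as NaN; the
    geometry checks run only when all four points are present.
    """
    sx, sy = spacing
    if sx <= 0 or sy <= 0:
        raise ValueError("spacing must be positive")
    pts = {k: points.get(k) for k in KeypointName}
    pairs = {
        "IVS": (KeypointName.SEPT_ANT, KeypointName.SEPT_POST),
        "LVD": (KeypointName.SEPT_POST, KeypointName.FW_ANT),
        "FW": (KeypointName.FW_ANT, KeypointName.FW_POST),
    }
    px: dict[str, float] = {}
    cm: dict[str, float] = {}
    flags: set[GeometryFlag] = set()
    for site, (a, b) in pairs.items():
        if pts[a] is None or pts[b] is None:
            px[site], cm[site] = math.nan, math.nan
            flags.add(GeometryFlag.MISSING_POINT)
        else:
            px[site], cm[site] = _gap(pts[a], pts[b], spacing)
    if all(pts[k] is not None for k in KeypointName):
        flags |= check_geometry({k: pts[k] for k in KeypointName},
                                collinearity_tol_deg)
    return MeasurementTriplet(
        ivs_cm=cm["IVS"], lvd_cm=cm["LVD"], fw_cm=cm["FW"],
        ivs_px=px["IVS"], lvd_px=px["LVD"], fw_px=px["FW"],
        flags=frozenset(flags),
    )


def measurement_rows(dataset: Dataset, include_invalid: bool = True) -> list[tuple]:
    """Derive one (frame, phase, site, rater, repeat, value_cm) row per caliper.

    Long-format rows suitable for the consensus-validation framework.  Sites
    whose value is undefined (missing endpoint) are skipped; triplets with
    advisory geometry flags are kept unless ``include_invalid`` is False.
    """
    rows: list[tuple] = []
    for ann in dataset.annotations:
        frame = dataset.frame(ann.frame_id)
        trip = derive_measurements(ann.points,
                                   (frame.spacing_x_cm, frame.spacing_y_cm))
        if not include_invalid and not trip.valid:
            continue
        for site, value in trip.cm_by_site().items():
            if math.isnan(value):
                continue
            rows.append((frame.frame_id, frame.phase.value, site,
                         ann.rater_id, ann.repeat_index, value))
    return rows
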