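"""Planar morphometry of the optic nerve head from delineated OCT landmarks.

The measurements implemented here quantify how far the central retinal
vascular trunk (CRVT) sits from the centre of the Bruch's membrane opening
(BMO).  The BMO margin is a closed planar polygon (millimetres, image
plane) delineated on radial OCT scans; the CRVT is a single landmark
point.  Two statistics are produced per eye:

* the **offset index** ``a / b`` — the distance from the BMO centre to the
  CRVT (``a``) divided by the distance from the centre to the BMO margin
  along the same direction (``b``).  It is dimensionless, lies in
  ``[0, 1]``, and is defined as exactly ``1.0`` when the CRVT lies outside
  the BMO (where ``a`` and ``b`` cannot be measured);
* the **angular deviation** — the direction of the centre→CRVT vector in
  right-eye orientation, with the nasal horizontal midline at 0° and
  superior positive.

All angles are reported in degrees in ``(-180, 180]``.  The internal
coordinate convention is right-eye: ``+x`` nasal, ``+y`` superior.  Left
eyes (OS) are mirrored about the vertical axis before any angle is
computed, so that OD and OS measurements are directly comparable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from shapely.geometry import Point, Polygon

__all__ = [
    "GeometryError",
    "EyeDelineation",
    "CRVTMeasurement",
    "RNFLDefectMeasurement",
    "PPAMeasurement",
    "bmo_center_and_area",
    "boundary_distance",
    "measure_crvt",
    "angular_deviation",
    "rnfl_defect_angle",
    "ppa_areas",
    "wrap_angle_deg",
    "nasal_to_temporal_deg",
]


class GeometryError(ValueError):
    """Raised when a delineation is geometrically unusable."""


def wrap_angle_deg(angle: float) -> float:
    """Wrap an angle in degrees to the interval ``(-180, 180]``."""
    wrapped = math.fmod(angle, 360.0)
    if wrapped <= -180.0:
        wrapped += 360.0
    elif wrapped > 180.0:
        wrapped -= 360.0
    return wrapped


def nasal_to_temporal_deg(angle_nasal: float) -> float:
    """Convert a nasal-midline angle to the temporal-midline convention.

    Both conventions take superior as positive; the temporal midline points
    opposite the nasal one, so a direction at nasal-angle ``α`` has
    temporal-angle ``180° − α`` (wrapped).
    """
    return wrap_angle_deg(180.0 - angle_nasal)


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EyeDelineation:
    """Raw per-eye delineation: BMO margin polygon plus landmark points.

    Coordinates are millimetres in the image plane of the eye as acquired.
    ``rnfl_defects`` are (start, end) boundary angles in degrees,
    temporal-midline convention (anatomical, hence laterality-free).
    ``crvt_point`` is absent exactly when ``crvt_outside_bmo`` is set: an
    invisible trunk confirmed outside the BMO has no measurable location.
    """

    patient_id: str
    laterality: str  # "OD" | "OS"
    margin_points: np.ndarray  # (n, 2) float, ordered, implicitly closed
    crvt_point: Optional[Tuple[float, float]] = None
    crvt_outside_bmo: bool = False
    rnfl_defects: Tuple[Tuple[float, float], ...] = ()
    rpeo_area: Optional[float] = None
    cdm_area: Optional[float] = None
    bmo_area_input: Optional[float] = None

    def __post_init__(self) -> None:
        margin = np.asarray(self.margin_points, dtype=float)
        if margin.ndim != 2 or margin.shape[1] != 2 or margin.shape[0] < 8:
            raise GeometryError(
                "margin_points must be an (n, 2) array with n >= 8"
            )
        object.__setattr__(self, "margin_points", margin)
        if self.laterality not in ("OD", "OS"):
            raise GeometryError(f"laterality must be OD or OS, got {self.laterality!r}")
        if self.crvt_outside_bmo and self.crvt_point is not None:
            raise GeometryError("crvt_point must be absent when crvt_outside_bmo is set")
        if not self.crvt_outside_bmo and self.crvt_point is None:
            raise GeometryError("crvt_point required unless crvt_outside_bmo is set")
        if self.crvt_point is not None:
            object.__setattr__(
                self, "crvt_point", (float(self.crvt_point[0]), float(self.crvt_point[1]))
            )
        object.__setattr__(
            self,
            "rnfl_defects",
            tuple((float(a), float(b)) for a, b in self.rnfl_defects),
        )
        # validate polygon once here so downstream operations can assume it
        _as_polygon(margin)

    def to_right_eye(self) -> "EyeDelineation":
        """Return this delineation in right-eye orientation.

        OD records are returned unchanged.  OS records are mirrored about
        the vertical axis (``x → -x``); RNFL-defect angles are anatomical
        (temporal-midline) and therefore unaffected by the mirroring.
        """
        if self.laterality == "OD":
            return self
        margin = self.margin_points * np.array([-1.0, 1.0])
        crvt = None if self.crvt_point is None else (-self.crvt_point[0], self.crvt_point[1])
        return replace(self, laterality="OD", margin_points=margin, crvt_point=crvt)


@dataclass(frozen=True)
class CRVTMeasurement:
    """Offset index and angular deviation of the vascular trunk.

    ``center_to_crvt`` is the distance *a*, ``center_to_margin`` the
    distance *b* along the same ray; both are NaN on the outside-BMO
    branch where the ratio is fixed at 1.0 by definition.
    ``angular_deviation_deg`` is NaN when undefined (trunk outside the BMO
    or exactly at the centre).
    """

    offset_index: float
    center_to_crvt: float
    center_to_margin: float
    angular_deviation_deg: float
    flags: Tuple[str, ...] = ()

    @property
    def angle_defined(self) -> bool:
        return not math.isnan(self.angular_deviation_deg)


@dataclass(frozen=True)
class RNFLDefectMeasurement:
    """Circular midpoint and width of the widest RNFL defect (degrees)."""

    midpoint_angle_deg: float
    angular_width_deg: float


@dataclass(frozen=True)
class PPAMeasurement:
    """Parapapillary atrophy zone areas in mm²."""

    beta_zone_area: float
    gamma_zone_area: float
    flags: Tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def _as_polygon(margin_points: np.ndarray) -> Polygon:
    poly = Polygon(np.asarray(margin_points, dtype=float))
    if not poly.is_valid or not poly.is_simple:
        raise GeometryError("margin polygon is self-intersecting or otherwise invalid")
    if poly.area <= 0.0:
        raise GeometryError("margin polygon has zero area")
    return poly


def bmo_center_and_area(
    margin_points: Sequence[Sequence[float]],
) -> Tuple[Tuple[float, float], float]:
    """Area centroid and shoelace area of the BMO margin polygon.

    Both quantities are invariant under cyclic rotation and reversal of the
    vertex order, and equivariant/invariant under translation.

    Parameters
    ----------
    margin_points
        Ordered ``(n, 2)`` vertices in mm, ``n >= 8``, implicitly closed.

    Returns
    -------
    ((cx, cy), area) in mm and mm².
    """
    margin = np.asarray(margin_points, dtype=float)
    if margin.ndim != 2 or margin.shape[1] != 2 or margin.shape[0] < 8:
        raise GeometryError("margin_points must be an (n, 2) array with n >= 8")
    poly = _as_polygon(margin)
    c = poly.centroid
    return (c.x, c.y), poly.area


def boundary_distance(
    center: Sequence[float],
    direction_deg: float,
    margin_points: Sequence[Sequence[float]],
) -> float:
    """Distance from an interior point to the margin along a given ray.

    Casts a ray from ``center`` at ``direction_deg`` (degrees,
    counter-clockwise from +x) and returns the distance to the *first*
    crossing of the polygon boundary: the smallest strictly positive ray
    parameter over all boundary-segment intersections.  A ray that grazes
    a vertex hits both adjacent segments at the same parameter, so the
    minimum rule resolves the tie naturally.  Non-convex margins are
    permitted (with a warning) since the first crossing remains well
    defined.
    """
    margin = np.asarray(margin_points, dtype=float)
    poly = _as_polygon(margin)
    cx, cy = float(center[0]), float(center[1])
    if not poly.contains(Point(cx, cy)):
        raise GeometryError("center must lie strictly inside the margin polygon")
    if not poly.equals(poly.convex_hull):
        warnings.warn(
            "margin polygon is non-convex; using first ray-boundary crossing",
            stacklevel=2,
        )

    theta = math.radians(direction_deg)
    dx, dy = math.cos(theta), math.sin(theta)

    # segment i runs a_i -> b_i; solve  c + t*d = a + s*(b - a),  t > 0, s in [0, 1]
    a = margin
    b = np.roll(margin, -1, axis=0)
    ex, ey = (b - a)[:, 0], (b - a)[:, 1]
    denom = dx * ey - dy * ex
    with np.errstate(divide="ignore", invalid="ignore"):
        acx, acy = a[:, 0] - cx, a[:, 1] - cy
        t = (acx * ey - acy * ex) / denom
        s = (acx * dy - acy * dx) / denom
    eps = 1e-12
    valid = (np.abs(denom) > eps) & (t > eps) & (s >= -eps) & (s <= 1.0 + eps)
    if not np.any(valid):
        raise GeometryError("ray does not intersect the margin polygon boundary")
    return float(np.min(t[valid]))


def measure_crvt(delineation: EyeDelineation) -> CRVTMeasurement:
    """Measure the offset index and angular deviation of one eye.

    The BMO centre is the area centroid of the margin polygon.  If the
    trunk is flagged outside the BMO the offset index is 1.0 by definition
    and the angle is undefined.  A trunk exactly at the centre has offset
    0 and an undefined angle.  The ratio is clipped to ``[0, 1]``: a trunk
    inside the polygon cannot meaningfully exceed the margin.
    """
    if delineation.crvt_outside_bmo:
        return CRVTMeasurement(
            offset_index=1.0,
            center_to_crvt=float("nan"),
            center_to_margin=float("nan"),
            angular_deviation_deg=float("nan"),
            flags=("crvt_outside_bmo",),
        )
    eye = delineation.to_right_eye()
    (cx, cy), area = bmo_center_and_area(eye.margin_points)
    px, py = eye.crvt_point  # type: ignore[misc]
    a = math.hypot(px - cx, py - cy)
    # coincidence with the centre up to floating-point noise in the
    # centroid computation, relative to the polygon scale
    if a <= 1e-12 * math.sqrt(area):
        return CRVTMeasurement(
            offset_index=0.0,
            center_to_crvt=0.0,
            center_to_margin=float("nan"),
            angular_deviation_deg=float("nan"),
            flags=("crvt_at_center",),
        )
    direction = math.degrees(math.atan2(py - cy, px - cx))
    if not Polygon(eye.margin_points).contains(Point(px, py)):
        # on or numerically beyond the discretised margin: ratio clips to 1
        flags: Tuple[str, ...] = ("crvt_on_or_beyond_margin",)
    else:
        flags = ()
    b = boundary_distance((cx, cy), direction, eye.margin_points)
    index = min(max(a / b, 0.0), 1.0)
    return CRVTMeasurement(
        offset_index=index,
        center_to_crvt=a,
        center_to_margin=b,
        angular_deviation_deg=wrap_angle_deg(direction),
        flags=flags,
    )


def angular_deviation(
    center: Sequence[float],
    crvt_point: Sequence[float],
    laterality: str,
) -> float:
    """Angle of the centre→CRVT vector, right-eye orientation, degrees.

    0° is the nasal horizontal midline, +90° superior, −90° inferior.  OS
    inputs are mirrored about the vertical axis (only the sign of the x
    component of the displacement matters) before the angle is taken.
    Returns NaN when the trunk coincides with the centre.
    """
    dx = float(crvt_point[0]) - float(center[0])
    dy = float(crvt_point[1]) - float(center[1])
    if laterality == "OS":
        dx = -dx
    elif laterality != "OD":
        raise GeometryError(f"laterality must be OD or OS, got {laterality!r}")
    if dx == 0.0 and dy == 0.0:
        return float("nan")
    return wrap_angle_deg(math.degrees(math.atan2(dy, dx)))


def _circular_midpoint_and_width(start: float, end: float) -> Tuple[float, float]:
    """Midpoint (shorter arc) and width of an angular interval, degrees."""
    diff = wrap_angle_deg(end - start)
    width = abs(diff)
    mid = wrap_angle_deg(start + diff / 2.0)
    return mid, width


def rnfl_defect_angle(
    defects: Sequence[Tuple[float, float]],
    laterality: str = "OD",
) -> Optional[RNFLDefectMeasurement]:
    """Midpoint angle of the widest RNFL defect, temporal midline 0°.

    Boundary angles are anatomical (temporal-midline convention, superior
    positive) and therefore identical for OD and OS; ``laterality`` is
    accepted for interface symmetry and validated only.  When several
    defects are present the measurement is taken on the one of maximal
    angular width.  Returns None for an empty defect list.
    """
    if laterality not in ("OD", "OS"):
        raise GeometryError(f"laterality must be OD or OS, got {laterality!r}")
    if not defects:
        return None
    best: Optional[RNFLDefectMeasurement] = None
    for start, end in defects:
        mid, width = _circular_midpoint_and_width(float(start), float(end))
        if not 0.0 < width < 180.0:
            raise GeometryError(
                f"defect width must be in (0, 180) degrees, got {width:.3f}"
            )
        if best is None or width > best.angular_width_deg:
            best = RNFLDefectMeasurement(midpoint_angle_deg=mid, angular_width_deg=width)
    return best


def ppa_areas(rpeo_area: float, cdm_area: float, bmo_area: float) -> PPAMeasurement:
    """Parapapillary atrophy zone areas from delineated boundary areas.

    β-zone = RPE-opening area − clinical-disc-margin area;
    γ-zone = BMO area − clinical-disc-margin area.  Negative results point
    at inconsistent delineations; they are flagged and still returned.
    """
    for name, v in (("rpeo_area", rpeo_area), ("cdm_area", cdm_area), ("bmo_area", bmo_area)):
        if v < 0:
            raise GeometryError(f"{name} must be non-negative, got {v}")
    beta = rpeo_area - cdm_area
    gamma = bmo_area - cdm_area
    flags = []
    if beta < 0:
        flags.append("negative_beta_zone")
    if gamma < 0:
        flags.append("negative_gamma_zone")
    if flags:
        warnings.warn(
            f"inconsistent delineation: {', '.join(flags)}", stacklevel=2
        )
    return PPAMeasurement(beta_zone_area=beta, gamma_zone_area=gamma, flags=tuple(flags))
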