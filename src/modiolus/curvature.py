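"""Pre-curvature and tip fold-over critical-radius profiles.

``r_pre(IA)`` is the local radius of curvature a perfectly perimodiolar
preformed array needs at insertion angle IA to follow the offset
trajectory.  ``r_fold(IA)`` is the critical arc radius below which the
array tip can "stand up" perpendicularly on the modiolar wall while the
array body still runs along a path ``d_LW`` inside the lateral wall —
tip curvatures at or below this radius make a fold-over likely.  Both
profiles are computed in the planar (plane-of-rotation) projection on a
1-degree grid from 90 to 720 degrees, and compared to locate the angular
positions where a constant-curvature array design becomes risky.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .insertion import InsertionTrajectory, offset_trajectory
from .spiral import WallSpiral, resample

__all__ = [
    "CurvatureProfile",
    "circumradius",
    "precurve_radius",
    "critical_fold_radius",
    "curvature_profile",
    "fold_risk_intersection",
]

DEFAULT_D_LW = 0.4  # mm; typical apical array radius
IA_GRID_START = 90.0
IA_GRID_STOP = 720.0
BASAL_LIMIT = 270.0
CONTACT_WINDOW_DEG = 45.0


def circumradius(p1, p2, p3) -> float:
    """Radius of the circle through three planar points (inf if collinear)."""
    p1, p2, p3 = (np.asarray(p, float)[:2] for p in (p1, p2, p3))
    a = np.linalg.norm(p2 - p3)
    b = np.linalg.norm(p1 - p3)
    c = np.linalg.norm(p1 - p2)
    cross = (p2[0] - p1[0]) * (p3[1] - p1[1]) - (p2[1] - p1[1]) * (p3[0] - p1[0])
    area2 = abs(cross)
    if area2 < 1e-14:
        return np.inf
    return float(a * b * c / (2.0 * area2))


@dataclass(frozen=True)
class CurvatureProfile:
    """r_pre and r_fold sampled on the 1-degree IA grid, with risk angles.

    basal_max_r_fold:
        maximum of r_fold over the basal region (IA <= 270 deg) — the
        fold-critical radius an array released in the base must exceed.
    risk_angle:
        first IA beyond 270 deg where r_pre drops to or below
        basal_max_r_fold (None if never): an array pre-curved for that
        position could fold over if released in the base.
    crossover_angle:
        first IA where r_pre falls below r_fold itself (None if never):
        beyond it fold-over is nearly inevitable for a matched array.
    """

    ia_deg: np.ndarray
    r_pre: np.ndarray
    r_fold: np.ndarray
    d_off: float
    d_LW: float
    basal_max_r_fold: float
    risk_angle: float | None
    crossover_angle: float | None
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ia = np.asarray(self.ia_deg, float)
        if not np.allclose(np.diff(ia), 1.0):
            raise ValueError("IA grid step must be exactly 1 degree")


def precurve_radius(traj: InsertionTrajectory, ia_deg: float) -> float:
    """Local radius of curvature of the planar curved segment at IA.

    Computed as the circumradius of three consecutive 1-degree samples
    centred on IA.  Queries on the straight section return ``inf``
    (unbounded radius), not an error.
    """
    ia = float(ia_deg)
    if ia <= traj.transition.IA_str:
        return np.inf
    hi = traj.curved_theta_deg[-1]
    if ia > hi:
        raise ValueError(f"IA beyond trajectory range (max {hi:.1f} deg)")
    grid = np.array([ia - 1.0, ia, ia + 1.0])
    grid = np.clip(grid, traj.curved_theta_deg[0], hi)
    x = np.interp(grid, traj.curved_theta_deg, traj.curved_points[:, 0])
    y = np.interp(grid, traj.curved_theta_deg, traj.curved_points[:, 1])
    return circumradius((x[0], y[0]), (x[1], y[1]), (x[2], y[2]))


def _point_polyline_distance(point: np.ndarray, poly: np.ndarray) -> float:
    """Min distance from a 2D point to a polyline (vectorized over segments)."""
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    ap = point - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", ap, ab) / np.maximum(denom, 1e-30), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.min(np.linalg.norm(point - proj, axis=1)))


def critical_fold_radius(
    modiolar: WallSpiral,
    lateral: WallSpiral,
    d_LW: float,
    ia_deg: float,
    *,
    contact_window_deg: float = CONTACT_WINDOW_DEG,
    _cache: dict | None = None,
) -> float:
    """Critical tip fold-over radius at insertion angle IA.

    Planar construction: an arc of radius r ends on the modiolar wall at
    angle IA with its tangent perpendicular to the wall (the tip
    "standing up"), so the arc centre lies along the local wall tangent
    at distance r; the opposite end merges tangentially into the path
    offset ``d_LW`` inside the lateral wall.  r is solved by a
    bracketing root search on the tangency residual; the path contact is
    searched within +/-45 deg of IA.  Returns NaN when no arc radius
    solves the construction at this IA.
    """
    if d_LW < 0:
        raise ValueError("d_LW must be non-negative")
    cache = _cache if _cache is not None else {}
    if "mod" not in cache:
        cache["mod"] = resample(modiolar, 0.25)
        from .insertion import offset_curve  # path = lateral wall shifted inward

        lat = resample(lateral, 0.25)
        phi, pts = offset_curve(lat, -d_LW) if d_LW else (lat.theta_deg, lat.points)
        cache["path_phi"] = phi
        cache["path_xy"] = pts[:, :2]
    mod = cache["mod"]
    phi = cache["path_phi"]
    path_xy = cache["path_xy"]

    ia = float(ia_deg)
    if not (mod.theta_deg[0] <= ia <= mod.theta_deg[-1]):
        raise ValueError("IA outside the modiolar spiral range")
    r_m = float(mod.radius_at(ia))
    th = np.radians(ia)
    m_pt = np.array([r_m * np.cos(th), r_m * np.sin(th)])
    # wall tangent (direction of increasing theta) from neighbouring samples
    eps = 0.5
    lo, hi = max(mod.theta_deg[0], ia - eps), min(mod.theta_deg[-1], ia + eps)
    p_lo = np.array([mod.radius_at(lo) * np.cos(np.radians(lo)),
                     mod.radius_at(lo) * np.sin(np.radians(lo))])
    p_hi = np.array([mod.radius_at(hi) * np.cos(np.radians(hi)),
                     mod.radius_at(hi) * np.sin(np.radians(hi))])
    tang = p_hi - p_lo
    tang = tang / np.linalg.norm(tang)

    window = (phi >= ia - contact_window_deg) & (phi <= ia + contact_window_deg)
    if window.sum() < 2:
        return np.nan
    wpoly = path_xy[window]

    def residual(r: float) -> float:
        centre = m_pt + r * tang
        return _point_polyline_distance(centre, wpoly) - r

    r0 = 1e-6
    if residual(r0) <= 0:
        return 0.0  # wall touches the path: degenerate, no room for a tip
    r_max = float(np.interp(ia, phi, np.hypot(path_xy[:, 0], path_xy[:, 1]))) + 1.0
    step = r_max / 64.0
    r_lo, r_hi = r0, None
    r = r0 + step
    while r <= r_max:
        if residual(r) <= 0:
            r_lo, r_hi = r - step, r
            break
        r = r + step
    else:
        return np.nan
    return float(brentq(residual, r_lo, r_hi, xtol=1e-6))


def curvature_profile(
    modiolar: WallSpiral,
    lateral: WallSpiral,
    d_off: float,
    d_LW: float = DEFAULT_D_LW,
    traj: InsertionTrajectory | None = None,
    contact_window_deg: float = CONTACT_WINDOW_DEG,
) -> CurvatureProfile:
    """r_pre and r_fold over IA = 90..720 deg in 1-degree steps."""
    if traj is None:
        traj = offset_trajectory(modiolar, lateral, d_off)
    stop = min(IA_GRID_STOP, np.floor(traj.curved_theta_deg[-1]))
    ia = np.arange(IA_GRID_START, stop + 0.5, 1.0)
    r_pre = np.array([precurve_radius(traj, a) for a in ia])
    cache: dict = {}
    r_fold = np.array(
        [
            critical_fold_radius(
                modiolar, lateral, d_LW, a,
                contact_window_deg=contact_window_deg, _cache=cache,
            )
            for a in ia
        ]
    )
    basal = ia <= BASAL_LIMIT
    basal_max = float(np.nanmax(r_fold[basal])) if np.any(basal) else np.nan
    risk = _first_angle(ia, (ia > BASAL_LIMIT) & (r_pre <= basal_max))
    crossover = _first_angle(ia, r_pre < r_fold)
    return CurvatureProfile(
        ia_deg=ia,
        r_pre=r_pre,
        r_fold=r_fold,
        d_off=float(d_off),
        d_LW=float(d_LW),
        basal_max_r_fold=basal_max,
        risk_angle=risk,
        crossover_angle=crossover,
        provenance={"d_off": float(d_off), "d_LW": float(d_LW)},
    )


def _first_angle(ia: np.ndarray, mask: np.ndarray) -> float | None:
    mask = mask & np.isfinite(ia)
    idx = np.nonzero(mask)[0]
    return float(ia[idx[0]]) if idx.size else None


def fold_risk_intersection(profile: CurvatureProfile) -> tuple[float | None, float | None]:
    """(risk_angle, crossover_angle) of a computed curvature profile.

    risk_angle: first IA > 270 deg with r_pre <= max basal r_fold;
    crossover_angle: first IA with r_pre < r_fold.  Either may be None.
    """
    ia = profile.ia_deg
    risk = _first_angle(
        ia, (ia > BASAL_LIMIT) & (profile.r_pre <= profile.basal_max_r_fold)
    )
    crossover = _first_angle(ia, profile.r_pre < profile.r_fold)
    return risk, crossover
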