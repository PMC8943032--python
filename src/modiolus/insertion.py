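"""Composite perimodiolar insertion trajectories.

An electrode array held straight by a stylet enters along the A-axis at
the lateral wall, runs straight until its line of advance becomes
tangent to the perimodiolar path (the modiolar wall displaced outward by
the array offset ``d_off``), and from that tangency point follows the
offset path around the modiolus.  The module builds this composite path,
maps electrode insertion depth (EID, mm of array inside the cochlea) to
insertion angle (IA, degrees from the round window) and back, extracts
the tangential-transition quantities (l_str, IA_str, l_crit), and tunes
``d_off`` against clinical EID/IA anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .spiral import WallSpiral, project_height, resample

__all__ = [
    "InsertionTrajectory",
    "TangentialTransition",
    "ElectrodeSpec",
    "ELECTRODES",
    "offset_curve",
    "offset_trajectory",
    "tangential_transition",
    "tune_doff",
    "eid_ia_surface",
]

DEFAULT_STEP_DEG = 0.25


class GeometryInfeasibleError(ValueError):
    """Raised when an offset curve would cross the lateral wall."""


@dataclass(frozen=True)
class TangentialTransition:
    """Straight-segment quantities of a perimodiolar insertion.

    l_str:
        planar distance from the entry point to the tangency point on
        the offset path — the depth after which the array may be safely
        released from the straightener.
    IA_str:
        insertion angle (deg) of the tangency point.
    l_crit:
        planar distance from the entry point, along the same ray, to the
        first re-intersection with the lateral wall — the depth at which
        a still-straight array would hit the lateral wall.
    """

    l_str: float
    IA_str: float
    l_crit: float

    def __post_init__(self) -> None:
        if not (0 <= self.l_str <= self.l_crit):
            raise ValueError("requires 0 <= l_str <= l_crit")
        if not (0 <= self.IA_str < 90):
            raise ValueError("IA_str must lie in [0, 90) degrees")


@dataclass(frozen=True)
class ElectrodeSpec:
    """A perimodiolar array: its modiolar offset and clinical anchor."""

    name: str
    d_off: float  # mm
    anchor_eid_mm: float
    anchor_ia_deg: float
    anchor_eid_sd_mm: float = np.nan
    anchor_ia_sd_deg: float = np.nan

    def __post_init__(self) -> None:
        if not (0.0 <= self.d_off <= 1.5):
            raise ValueError("d_off must lie in [0, 1.5] mm")


#: the three perimodiolar arrays studied, with published EID/IA anchors
ELECTRODES: dict[str, ElectrodeSpec] = {
    "contour_advance": ElectrodeSpec("contour_advance", 0.8, 16.6, 348.0, 1.1, 36.0),
    "mid_scala": ElectrodeSpec("mid_scala", 1.0, 19.2, 398.0, 0.9, 41.0),
    "slim_modiolar": ElectrodeSpec("slim_modiolar", 0.3, 15.4, 406.0, 1.1, 33.0),
}


@dataclass(frozen=True)
class InsertionTrajectory:
    """Composite straight + curved electrode path at offset ``d_off``.

    ``theta_deg``/``arclength_mm`` form the monotone EID(IA) map over the
    whole composite path (straight part included: while the tip advances
    along the straight segment its polar angle grows from 0 to IA_str).
    """

    d_off: float
    entry_point: np.ndarray  # (3,)
    straight_points: np.ndarray  # (m, 3), entry -> tangency
    curved_points: np.ndarray  # (k, 3), tangency -> apex-most angle
    curved_theta_deg: np.ndarray  # (k,)
    theta_deg: np.ndarray  # (n,) composite monotone angle grid
    arclength_mm: np.ndarray  # (n,) cumulative 3D arc length from entry
    transition: TangentialTransition
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.arclength_mm) > 0):
            raise ValueError("arc length must increase strictly with theta")

    # -- EID <-> IA ---------------------------------------------------
    @property
    def theta_range(self) -> tuple[float, float]:
        return float(self.theta_deg[0]), float(self.theta_deg[-1])

    @property
    def eid_range(self) -> tuple[float, float]:
        return float(self.arclength_mm[0]), float(self.arclength_mm[-1])

    def eid_of_ia(self, ia_deg):
        """Electrode insertion depth (mm) at insertion angle(s) IA (deg)."""
        ia = np.asarray(ia_deg, float)
        lo, hi = self.theta_range
        if np.any(ia < lo - 1e-9) or np.any(ia > hi + 1e-9):
            raise ValueError(f"IA out of range; valid interval is [{lo:.2f}, {hi:.2f}] deg")
        out = np.interp(ia, self.theta_deg, self.arclength_mm)
        return float(out) if np.isscalar(ia_deg) else out

    def ia_of_eid(self, eid_mm):
        """Insertion angle (deg) at electrode insertion depth(s) EID (mm)."""
        s = np.asarray(eid_mm, float)
        lo, hi = self.eid_range
        if np.any(s < lo - 1e-9) or np.any(s > hi + 1e-9):
            raise ValueError(f"EID out of range; valid interval is [{lo:.3f}, {hi:.3f}] mm")
        out = np.interp(s, self.arclength_mm, self.theta_deg)
        return float(out) if np.isscalar(eid_mm) else out


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def offset_curve(modiolar: WallSpiral, d_off: float, step_deg: float = DEFAULT_STEP_DEG):
    """Displace the modiolar wall outward (toward the lateral wall) by d_off.

    Returns ``(theta_deg, points)`` of the offset curve re-parametrized
    by its own polar angle on a monotone grid.  The displacement is
    along the in-plane outward normal; at samples where the normal
    offset would destroy monotone winding a radial offset is used.
    """
    mw = resample(modiolar, step_deg)
    xy = mw.points[:, :2]
    tang = np.gradient(xy, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = np.column_stack([tang[:, 1], -tang[:, 0]])  # outward for CCW winding
    rad = np.linalg.norm(xy, axis=1, keepdims=True)
    radial = xy / rad
    # guard: keep the outward orientation even if sampling noise flips a tangent
    flip = np.sum(normal * radial, axis=1) < 0
    normal[flip] *= -1
    q = xy + d_off * normal
    phi = np.degrees(np.unwrap(np.arctan2(q[:, 1], q[:, 0])))
    phi += np.round((mw.theta_deg[0] - phi[0]) / 360.0) * 360.0
    bad = np.diff(phi) <= 0
    if np.any(bad):
        # fall back to radial offset at non-monotone samples
        idx = np.unique(np.concatenate([np.nonzero(bad)[0], np.nonzero(bad)[0] + 1]))
        q[idx] = xy[idx] + d_off * radial[idx]
        phi = np.degrees(np.unwrap(np.arctan2(q[:, 1], q[:, 0])))
        phi += np.round((mw.theta_deg[0] - phi[0]) / 360.0) * 360.0
        if np.any(np.diff(phi) <= 0):
            raise GeometryInfeasibleError(
                "offset curve does not wind monotonically even with radial fallback"
            )
    pts = np.column_stack([q, mw.points[:, 2]])
    return phi, pts


def _first_ray_hit(origin: np.ndarray, direction: np.ndarray, polyline_xy: np.ndarray,
                   min_dist: float = 1e-9) -> float:
    """Distance from origin to the first polyline crossing along a ray."""
    length = 100.0
    ray = LineString([origin, origin + length * direction])
    wall = LineString(polyline_xy)
    hit = ray.intersection(wall)
    if hit.is_empty:
        raise GeometryInfeasibleError("ray does not re-intersect the lateral wall")
    pts = []
    for geom in getattr(hit, "geoms", [hit]):
        pts.extend(np.asarray(geom.coords))
    d = np.linalg.norm(np.asarray(pts) - origin, axis=1)
    d = d[d > min_dist]
    if d.size == 0:
        raise GeometryInfeasibleError("ray does not re-intersect the lateral wall")
    return float(np.min(d))


def _tangency(entry_xy: np.ndarray, phi: np.ndarray, q_xy: np.ndarray) -> int | None:
    """Index bracketing the first tangency of the line entry->curve.

    The tangency condition is cross(q - E, dq) = 0; returns the sample
    index i such that the sign change lies in [i, i+1], searching theta
    in (0, 90) degrees, or None.
    """
    dq = np.gradient(q_xy, axis=0)
    rel = q_xy - entry_xy
    c = rel[:, 0] * dq[:, 1] - rel[:, 1] * dq[:, 0]
    mask = (phi > 0.0) & (phi < 90.0)
    idx = np.nonzero(mask[:-1] & (np.sign(c[:-1]) != np.sign(c[1:])))[0]
    if idx.size == 0:
        return None
    return int(idx[0])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def offset_trajectory(
    modiolar: WallSpiral,
    lateral: WallSpiral,
    d_off: float,
    step_deg: float = DEFAULT_STEP_DEG,
    theta_max: float | None = None,
    truncate: bool = False,
) -> InsertionTrajectory:
    """Build the composite insertion trajectory at modiolar offset d_off.

    The curved segment is the modiolar wall displaced by ``d_off`` along
    the in-plane outward normal, carrying the lateral wall's height
    profile; the straight segment runs from the entry point (A-axis ∩
    lateral wall on the round-window side) to the first tangency with
    the offset curve.  Tangency and l_crit are solved in the planar
    projection; EID is 3D arc length of the composite path.

    ``theta_max`` limits the construction to angles up to that value.
    If the offset curve crosses the lateral wall within the requested
    range a geometry-infeasible error names the first offending theta,
    unless ``truncate`` is set, in which case the trajectory is cut just
    before the crossing and flagged in its provenance.
    """
    if d_off < 0:
        raise ValueError("d_off must be non-negative")
    mod = project_height(lateral, modiolar)
    phi, q = offset_curve(mod, d_off, step_deg)

    lat = resample(lateral, step_deg)
    if theta_max is not None:
        keep_req = phi <= theta_max
        if keep_req.sum() < 4:
            raise ValueError("theta_max leaves too little of the offset curve")
        phi, q = phi[keep_req], q[keep_req]
    # feasibility: offset curve must stay inside the lateral wall
    lat_r_at = np.interp(phi, lat.theta_deg, lat.radius_mm)
    q_r = np.hypot(q[:, 0], q[:, 1])
    inside = q_r < lat_r_at + 1e-9
    truncated_at = None
    if not np.all(inside):
        first_bad = int(np.argmin(inside))
        theta_bad = float(phi[first_bad])
        if not truncate or theta_bad <= 90.0:
            raise GeometryInfeasibleError(
                f"offset curve reaches the lateral wall first at theta = {theta_bad:.1f} deg"
            )
        phi, q, q_r = phi[:first_bad], q[:first_bad], q_r[:first_bad]
        truncated_at = theta_bad

    entry = np.array([float(lat.radius_at(0.0)), 0.0, float(lat.height_at(0.0))])
    e_xy = entry[:2]

    q_r0 = float(np.interp(0.0, phi, q_r)) if phi[0] <= 0.0 else float(q_r[0])
    entry_r = float(np.hypot(*e_xy))
    if entry_r < q_r0 - 1e-6:
        raise GeometryInfeasibleError("entry point lies inside the offset curve")

    if abs(entry_r - q_r0) <= 1e-6:
        # degenerate: entry sits on the offset curve
        t_xy = e_xy.copy()
        ia_str = 0.0
    elif (i := _tangency(e_xy, phi, q[:, :2])) is None:
        # no interior tangency: if the curve already falls away from the
        # entry sight-line at its basal start, the start point itself is
        # the release point; otherwise the geometry is degenerate
        dq0 = np.gradient(q[:, :2], axis=0)
        rel0 = q[:, :2] - e_xy
        c0 = rel0[:, 0] * dq0[:, 1] - rel0[:, 1] * dq0[:, 0]
        j = int(np.argmax(phi >= 0.0))
        if c0[j] >= 0:
            base = np.array(
                [np.interp(0.0, phi, q[:, 0]), np.interp(0.0, phi, q[:, 1])]
            ) if phi[0] <= 0.0 else q[j, :2]
            t_xy = base
            ia_str = 0.0
        else:
            raise GeometryInfeasibleError(
                "no tangency with the offset curve within theta in (0, 90) deg"
            )
    else:
        # linear refinement of the tangency parameter between samples i, i+1
        dq = np.gradient(q[:, :2], axis=0)
        rel = q[:, :2] - e_xy
        c = rel[:, 0] * dq[:, 1] - rel[:, 1] * dq[:, 0]
        w = c[i] / (c[i] - c[i + 1])
        t_xy = (1 - w) * q[i, :2] + w * q[i + 1, :2]
        ia_str = float((1 - w) * phi[i] + w * phi[i + 1])

    l_str = float(np.linalg.norm(t_xy - e_xy))
    if l_str > 1e-9:
        u = (t_xy - e_xy) / l_str
        # lateral wall polyline over the basal turn for the l_crit ray hit
        basal = lat.points[lat.theta_deg <= 360.0, :2]
        try:
            l_crit = _first_ray_hit(e_xy, u, basal, min_dist=1e-6)
        except GeometryInfeasibleError:
            l_crit = l_str  # grazing ray: contact coincides with tangency
    else:
        l_crit = 0.0
    transition = TangentialTransition(l_str=l_str, IA_str=ia_str, l_crit=max(l_crit, l_str))

    # --- composite sampled path -------------------------------------
    keep = phi > ia_str
    t_z = float(np.interp(ia_str, phi, q[:, 2]))
    tangency_pt = np.array([t_xy[0], t_xy[1], t_z])
    m = max(int(np.ceil(l_str / 0.05)), 2)
    frac = np.linspace(0.0, 1.0, m)[:, None]
    straight = entry[None, :] * (1 - frac) + tangency_pt[None, :] * frac
    curved = np.vstack([tangency_pt, q[keep]])
    curved_theta = np.concatenate([[ia_str], phi[keep]])

    # tip polar angle along the straight segment (monotone 0 -> IA_str)
    s_straight = np.linalg.norm(straight[:, :2] - e_xy, axis=1)
    ang_straight = np.degrees(np.arctan2(straight[:, 1], straight[:, 0]))
    len3d_straight = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(straight, axis=0), axis=1))]
    )
    len3d_curved = len3d_straight[-1] + np.cumsum(
        np.linalg.norm(np.diff(curved, axis=0), axis=1)
    )
    theta_all = np.concatenate([ang_straight, curved_theta[1:]])
    s_all = np.concatenate([len3d_straight, len3d_curved])
    ok = np.concatenate([[True], np.diff(theta_all) > 0])
    theta_all, s_all = theta_all[ok], s_all[ok]

    return InsertionTrajectory(
        d_off=float(d_off),
        entry_point=entry,
        straight_points=straight,
        curved_points=curved,
        curved_theta_deg=curved_theta,
        theta_deg=theta_all,
        arclength_mm=s_all,
        transition=transition,
        provenance={
            "modiolar": dict(modiolar.provenance),
            "lateral": dict(lateral.provenance),
            "step_deg": step_deg,
            "truncated_at_deg": truncated_at,
        },
    )


def tangential_transition(
    modiolar: WallSpiral, lateral: WallSpiral, d_off: float,
    step_deg: float = DEFAULT_STEP_DEG,
) -> TangentialTransition:
    """l_str, IA_str and l_crit for an array at offset ``d_off``.

    The transition quantities live in the basal turn, so the trajectory
    is allowed to truncate where the offset curve meets the lateral wall
    apically.
    """
    return offset_trajectory(modiolar, lateral, d_off, step_deg, truncate=True).transition


def tune_doff(
    mean_anatomy: tuple[WallSpiral, WallSpiral],
    anchor: tuple[float, float],
    grid: Sequence[float] = tuple(np.round(np.arange(0.0, 1.51, 0.1), 2)),
    refine_to: float | None = None,
) -> float:
    """Offset d_off whose trajectory best matches a clinical (EID, IA) anchor.

    Scans the grid (default 0 to 1.5 mm in 0.1 mm steps) minimizing
    |EID(IA_anchor) - EID_anchor|; ties resolve to the smaller d_off.
    ``refine_to`` optionally bisects around the grid optimum down to the
    given resolution (e.g. 0.01 mm).
    """
    modiolar, lateral = mean_anatomy
    eid_anchor, ia_anchor = float(anchor[0]), float(anchor[1])
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("d_off grid must be nonempty")
    if not all(0.0 <= g <= 1.5 for g in grid):
        raise ValueError("d_off grid must lie within [0, 1.5] mm")

    def err(d: float) -> float:
        traj = offset_trajectory(
            modiolar, lateral, d, theta_max=ia_anchor + 10.0, truncate=True
        )
        if traj.theta_range[1] < ia_anchor:
            # this offset cannot reach the anchor angle in this anatomy
            return np.inf
        return abs(traj.eid_of_ia(ia_anchor) - eid_anchor)

    errors = [err(g) for g in grid]
    if not np.any(np.isfinite(errors)):
        raise ValueError(f"anchor IA {ia_anchor:.0f} deg beyond trajectory range")
    best = int(np.argmin(errors))  # argmin takes the first (smallest d_off) on ties
    d_best = grid[best]
    if refine_to is not None and len(grid) > 1:
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        while hi - lo > refine_to:
            third = (hi - lo) / 3.0
            m1, m2 = lo + third, hi - third
            if err(m1) <= err(m2):
                hi = m2
            else:
                lo = m1
        d_best = 0.5 * (lo + hi)
    return float(d_best)


def eid_ia_surface(
    cohort: Iterable[tuple[WallSpiral, WallSpiral]],
    d_off_grid: Sequence[float],
    ia_grid: Sequence[float],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean EID over a cohort on a (d_off x IA) grid.

    For every anatomy and every d_off an EID(IA) profile is computed;
    profiles are averaged per d_off.  Anatomies whose trajectory does
    not reach a requested IA are excluded from that cell's mean; the
    companion table counts contributing anatomies per cell.
    """
    d_off_grid = [float(d) for d in d_off_grid]
    ia_grid = [float(a) for a in ia_grid]
    cohort = list(cohort)
    if not cohort or not d_off_grid or not ia_grid:
        raise ValueError("cohort and grids must be nonempty")
    sums = np.zeros((len(d_off_grid), len(ia_grid)))
    counts = np.zeros_like(sums, dtype=int)
    for modiolar, lateral in cohort:
        for i, d in enumerate(d_off_grid):
            traj = offset_trajectory(
                modiolar, lateral, d, theta_max=max(ia_grid) + 5.0, truncate=True
            )
            lo, hi = traj.theta_range
            for j, ia in enumerate(ia_grid):
                if lo <= ia <= hi:
                    sums[i, j] += traj.eid_of_ia(ia)
                    counts[i, j] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    idx = pd.Index(d_off_grid, name="d_off_mm")
    cols = pd.Index(ia_grid, name="IA_deg")
    return (
        pd.DataFrame(means, index=idx, columns=cols),
        pd.DataFrame(counts, index=idx, columns=cols),
    )
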