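"""Sampled wall-spiral templates and their individualization.

The cochlear lateral and modiolar walls are represented as sampled 3D
curves in the consensus cochlear coordinate system (CCCS): the modiolar
axis is z, the x-axis runs through the round-window center (the A-axis),
and the angle theta (degrees) is measured from the round window,
increasing from base to apex.  A template stores in-plane radius and
height versus theta together with the A/B reference dimensions measured
on the template itself; an individual cochlea is obtained by anisotropic
in-plane scaling to its own A and B values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "SpiralTemplate",
    "WallSpiral",
    "load_template",
    "save_template",
    "scale_template",
    "project_height",
    "resample",
    "arc_length",
    "circle_template",
    "parametric_template",
    "PACKAGED_TEMPLATES",
]

#: identifiers of templates shipped with the package
PACKAGED_TEMPLATES = ("modiolar_mean", "lateral_mean")


def _measure_AB(theta_deg: np.ndarray, radius_mm: np.ndarray) -> tuple[float, float]:
    """A/B dimensions of a sampled polar curve.

    A is the diameter along the A-axis (radius at 0 deg plus radius at
    180 deg), B the perpendicular width (90 deg plus 270 deg).  Radii at
    the four cardinal angles are interpolated monotone-cubically.
    """
    interp = PchipInterpolator(theta_deg, radius_mm)
    need = np.array([0.0, 90.0, 180.0, 270.0])
    if theta_deg[0] > need[0] or theta_deg[-1] < need[-1]:
        raise ValueError("curve must cover theta in [0, 270] deg to measure A/B")
    r = interp(need)
    return float(r[0] + r[2]), float(r[1] + r[3])


@dataclass(frozen=True)
class SpiralTemplate:
    """Mean wall spiral sampled on an angular grid.

    Parameters
    ----------
    wall:
        ``"lateral"`` or ``"modiolar"``.
    theta_deg, radius_mm, height_mm:
        Strictly increasing angles from the round window and the
        corresponding in-plane radii (> 0) and heights along the
        modiolar axis (0 at the basal reference plane).
    reference_A, reference_B:
        A/B dimensions measured on the template curve itself; they must
        agree with :func:`_measure_AB` of the samples (self-consistency).
    """

    wall: str
    theta_deg: np.ndarray
    radius_mm: np.ndarray
    height_mm: np.ndarray
    reference_A: float
    reference_B: float
    version: str = "unversioned"

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta_deg", np.asarray(self.theta_deg, float))
        object.__setattr__(self, "radius_mm", np.asarray(self.radius_mm, float))
        object.__setattr__(self, "height_mm", np.asarray(self.height_mm, float))
        if self.wall not in ("lateral", "modiolar"):
            raise ValueError(f"unknown wall kind: {self.wall!r}")
        t = self.theta_deg
        if t.ndim != 1 or t.size < 4:
            raise ValueError("theta grid must be 1-D with at least 4 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("theta grid must be strictly increasing")
        if self.radius_mm.shape != t.shape or self.height_mm.shape != t.shape:
            raise ValueError("radius/height arrays must match the theta grid")
        if not np.all(self.radius_mm > 0):
            raise ValueError("all template radii must be positive")
        a, b = _measure_AB(t, self.radius_mm)
        if not (
            np.isclose(a, self.reference_A, rtol=5e-3)
            and np.isclose(b, self.reference_B, rtol=5e-3)
        ):
            raise ValueError(
                "template not self-consistent: measured A/B "
                f"({a:.4f}, {b:.4f}) != reference ({self.reference_A}, {self.reference_B})"
            )


@dataclass(frozen=True)
class WallSpiral:
    """An individualized wall curve: ordered 3D points with polar angles.

    ``theta_deg`` holds the actual (unwrapped) polar angle of each point
    about the modiolar axis; after anisotropic scaling this differs from
    the template grid, so the curve is re-parametrized by its own angle.
    """

    wall: str
    theta_deg: np.ndarray
    points: np.ndarray  # (n, 3) x, y, z in mm
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta_deg", np.asarray(self.theta_deg, float))
        object.__setattr__(self, "points", np.asarray(self.points, float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if self.theta_deg.shape[0] != self.points.shape[0]:
            raise ValueError("theta grid and points must have equal length")
        if not np.all(np.diff(self.theta_deg) > 0):
            raise ValueError("spiral must wind monotonically (theta increasing)")

    # -- sampled scalar profiles -------------------------------------
    @property
    def radius_mm(self) -> np.ndarray:
        return np.hypot(self.points[:, 0], self.points[:, 1])

    @property
    def height_mm(self) -> np.ndarray:
        return self.points[:, 2]

    def radius_at(self, theta_deg) -> np.ndarray:
        return PchipInterpolator(self.theta_deg, self.radius_mm)(theta_deg)

    def height_at(self, theta_deg) -> np.ndarray:
        return PchipInterpolator(self.theta_deg, self.height_mm)(theta_deg)

    def measure_AB(self) -> tuple[float, float]:
        return _measure_AB(self.theta_deg, self.radius_mm)

    @property
    def theta_max(self) -> float:
        return float(self.theta_deg[-1])


# ---------------------------------------------------------------------------
# template I/O
# ---------------------------------------------------------------------------

def _template_paths(source: str | Path) -> tuple[Path, Path]:
    p = Path(source)
    if p.suffix == "":
        p = p.with_suffix(".csv")
    return p, p.with_suffix(".json")


def load_template(source: str | Path) -> SpiralTemplate:
    """Load a template from a packaged identifier or a CSV/JSON file pair.

    A packaged identifier is one of :data:`PACKAGED_TEMPLATES`.  A file
    source names a CSV with columns ``theta_deg, radius_mm, height_mm``
    and a JSON sidecar of the same stem carrying wall kind, reference
    A/B and version.
    """
    if isinstance(source, str) and source in PACKAGED_TEMPLATES:
        root = resources.files("modiolus") / "data"
        csv_text = (root / f"{source}.csv").read_text()
        meta = json.loads((root / f"{source}.json").read_text())
        rows = _parse_template_csv(csv_text)
    else:
        csv_path, json_path = _template_paths(source)
        if not csv_path.exists() or not json_path.exists():
            raise FileNotFoundError(f"template files not found for {source!r}")
        rows = _parse_template_csv(csv_path.read_text())
        meta = json.loads(json_path.read_text())
    return SpiralTemplate(
        wall=meta["wall"],
        theta_deg=rows[:, 0],
        radius_mm=rows[:, 1],
        height_mm=rows[:, 2],
        reference_A=float(meta["reference_A"]),
        reference_B=float(meta["reference_B"]),
        version=str(meta.get("version", "unversioned")),
    )


def _parse_template_csv(text: str) -> np.ndarray:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    header = [h.strip() for h in lines[0].split(",")]
    if header != ["theta_deg", "radius_mm", "height_mm"]:
        raise ValueError(f"malformed template header: {header}")
    try:
        rows = np.array([[float(v) for v in ln.split(",")] for ln in lines[1:]])
    except ValueError as exc:
        raise ValueError("malformed template row") from exc
    if rows.ndim != 2 or rows.shape[1] != 3:
        raise ValueError("template rows must have 3 columns")
    return rows


def save_template(template: SpiralTemplate, dest: str | Path) -> None:
    """Write a template as a CSV + JSON sidecar (inverse of load_template)."""
    csv_path, json_path = _template_paths(dest)
    lines = ["theta_deg,radius_mm,height_mm"]
    for t, r, h in zip(template.theta_deg, template.radius_mm, template.height_mm):
        lines.append(f"{float(t)!r},{float(r)!r},{float(h)!r}")
    csv_path.write_text("\n".join(lines) + "\n")
    json_path.write_text(
        json.dumps(
            {
                "wall": template.wall,
                "reference_A": template.reference_A,
                "reference_B": template.reference_B,
                "version": template.version,
            },
            indent=1,
        )
        + "\n"
    )


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------

def circle_template(
    radius: float,
    wall: str = "modiolar",
    theta_max: float = 720.0,
    step_deg: float = 22.5,
    height: float | np.ndarray = 0.0,
) -> SpiralTemplate:
    """Constant-radius template (circle phantom) — mainly for verification."""
    theta = np.arange(0.0, theta_max + 0.5 * step_deg, step_deg)
    h = np.broadcast_to(np.asarray(height, float), theta.shape).copy()
    return SpiralTemplate(
        wall=wall,
        theta_deg=theta,
        radius_mm=np.full_like(theta, float(radius)),
        height_mm=h,
        reference_A=2.0 * radius,
        reference_B=2.0 * radius,
        version="circle-phantom",
    )


def parametric_template(
    wall: str,
    A: float,
    B: float,
    tau_deg: float,
    shape_q: float = 1.0,
    height_total: float = 4.2,
    height_exp: float = 1.4,
    theta_max: float = 990.0,
    step_deg: float = 22.5,
    version: str = "parametric",
) -> SpiralTemplate:
    """Smooth, monotonically tightening spiral with prescribed A/B.

    The radius law is a plateau-exponential,

        r(theta) = c + a * exp(-(theta/tau)**q),

    which tightens monotonically from the round window to the apex; the
    two linear coefficients (c, a) are solved so the curve's A and B
    dimensions equal the requested values, leaving (tau, q) as shape
    parameters.  Height rises as ``height_total * (theta/theta_max)**height_exp``.
    """
    if A <= 0 or B <= 0:
        raise ValueError("A and B must be positive")

    def decay(theta):
        return np.exp(-((np.asarray(theta, float) / tau_deg) ** shape_q))

    f90, f180, f270 = decay([90.0, 180.0, 270.0])
    # [2c + a(1 + f180) = A], [2c + a(f90 + f270) = B]
    denom = 1.0 + f180 - f90 - f270
    a = (A - B) / denom
    c = 0.5 * (A - a * (1.0 + f180))
    theta = np.arange(0.0, theta_max + 0.5 * step_deg, step_deg)
    radius = c + a * decay(theta)
    if np.any(radius <= 0):
        raise ValueError("shape parameters give non-positive radii; adjust tau/q")
    height = height_total * (theta / theta_max) ** height_exp
    return SpiralTemplate(
        wall=wall,
        theta_deg=theta,
        radius_mm=radius,
        height_mm=height,
        reference_A=A,
        reference_B=B,
        version=version,
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def scale_template(template: SpiralTemplate, A: float, B: float) -> WallSpiral:
    """Individualize a template by anisotropic in-plane scaling.

    x is multiplied by ``A / reference_A`` (the A-axis direction) and y
    by ``B / reference_B``; heights are kept (the lateral height profile
    is attached separately via :func:`project_height`).  The scaled curve
    is re-parametrized by its own polar angle, under which its measured
    A and B equal the requested values.
    """
    if A <= 0 or B <= 0:
        raise ValueError("A and B must be positive")
    sa = A / template.reference_A
    sb = B / template.reference_B
    th = np.radians(template.theta_deg)
    x = template.radius_mm * np.cos(th) * sa
    y = template.radius_mm * np.sin(th) * sb
    z = template.height_mm.copy()
    # polar angle of the scaled points; atan2(sb sin, sa cos) is a strictly
    # increasing reparametrization of theta, unwrapped to stay monotone
    phi = np.degrees(np.unwrap(np.arctan2(y, x)))
    phi -= phi[0] - _principal(template.theta_deg[0], phi[0])
    return WallSpiral(
        wall=template.wall,
        theta_deg=phi,
        points=np.column_stack([x, y, z]),
        provenance={
            "template_version": template.version,
            "wall": template.wall,
            "A": float(A),
            "B": float(B),
        },
    )


def _principal(theta0: float, phi0: float) -> float:
    """Unwrap offset: keep the first point's angle near the template's."""
    k = round((theta0 - phi0) / 360.0)
    return phi0 + 360.0 * k


def project_height(lateral: WallSpiral, modiolar: WallSpiral) -> WallSpiral:
    """Attach the lateral wall's height profile to the modiolar spiral.

    Returns the modiolar spiral with z at each theta replaced by the
    lateral spiral's height at the same theta (monotone-cubic
    interpolation, clamped at the lateral range ends); in-plane
    coordinates are unchanged.
    """
    lo = max(lateral.theta_deg[0], modiolar.theta_deg[0])
    hi = min(lateral.theta_deg[-1], modiolar.theta_deg[-1])
    if hi <= lo:
        raise ValueError("lateral and modiolar spirals have no overlapping theta range")
    interp = PchipInterpolator(lateral.theta_deg, lateral.height_mm)
    th = np.clip(modiolar.theta_deg, lateral.theta_deg[0], lateral.theta_deg[-1])
    pts = modiolar.points.copy()
    pts[:, 2] = interp(th)
    prov = dict(modiolar.provenance)
    prov["height"] = "projected-from-lateral"
    return WallSpiral(modiolar.wall, modiolar.theta_deg, pts, prov)


def resample(spiral: WallSpiral, step_deg: float) -> WallSpiral:
    """Resample radius and height monotone-cubically on a uniform grid.

    The grid runs from the spiral's first to its last angle in steps of
    ``step_deg``; both endpoints are preserved.
    """
    if step_deg <= 0:
        raise ValueError("step must be positive")
    t0, t1 = spiral.theta_deg[0], spiral.theta_deg[-1]
    grid = np.arange(t0, t1, step_deg)
    if grid.size == 0 or not np.isclose(grid[-1], t1):
        grid = np.append(grid, t1)
    r = PchipInterpolator(spiral.theta_deg, spiral.radius_mm)(grid)
    z = PchipInterpolator(spiral.theta_deg, spiral.height_mm)(grid)
    th = np.radians(grid)
    pts = np.column_stack([r * np.cos(th), r * np.sin(th), z])
    return WallSpiral(spiral.wall, grid, pts, dict(spiral.provenance))


def arc_length(spiral: WallSpiral) -> float:
    """Total 3D arc length (chord sum over the sampled points)."""
    return float(np.sum(np.linalg.norm(np.diff(spiral.points, axis=0), axis=1)))
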