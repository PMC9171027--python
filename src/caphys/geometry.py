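"""Parametric coronary vessel geometry and two-view reconstruction.

A reconstructed coronary artery is represented by its centerline: an ordered
sequence of 3-D points (mm) with a lumen radius at each point.  Synthetic
vessels stand in for segmented angiographic geometry; two orthographic
"gantry" projections of a centerline can be reconstructed back into 3-D
provided the viewing axes are at least 30 degrees apart, mirroring the
two-posture acquisition requirement of angiography-based physiology systems.

Conventions: right-handed coordinates, millimetres, vessel inlet at
arclength 0, arc positions in the half-open interval [0, L).  Point
correspondence between the two views is by index (normalized arclength),
not by epipolar search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Centerline",
    "StenosisSpec",
    "ViewProjection",
    "FlowMesh",
    "make_vessel",
    "project",
    "reconstruct",
    "discretize",
    "read_centerline_csv",
    "write_centerline_csv",
    "read_projection_csv",
    "write_projection_csv",
]

MIN_VIEW_SEPARATION_DEG = 30.0


@dataclass(frozen=True)
class StenosisSpec:
    """Focal narrowing of the lumen.

    severity is the fractional *diameter* reduction in [0, 1); severity >= 1
    would be an occlusive lesion, which is excluded (occlusive and severely
    distorted calcified lesions are outside the method's applicability).
    The taper is cosine-smoothed over ``length`` so the radius profile is
    continuously differentiable.
    """

    center_s: float
    length: float
    severity: float
    shape: str = "cosine"

    def __post_init__(self) -> None:
        if not (0.0 <= self.severity < 1.0):
            raise ValueError(
                f"stenosis severity must be in [0, 1); got {self.severity} "
                "(severity >= 1 is occlusive and not supported)"
            )
        if self.length <= 0:
            raise ValueError("stenosis length must be positive")
        if self.shape != "cosine":
            raise ValueError(f"unknown stenosis shape {self.shape!r}")

    def radius_factor(self, s: np.ndarray) -> np.ndarray:
        """Multiplicative radius factor at arclength positions ``s``."""
        s = np.asarray(s, dtype=float)
        half = self.length / 2.0
        x = (s - self.center_s) / half
        inside = np.abs(x) <= 1.0
        reduction = np.zeros_like(s)
        reduction[inside] = self.severity * 0.5 * (1.0 + np.cos(np.pi * x[inside]))
        return 1.0 - reduction


@dataclass(frozen=True)
class Centerline:
    """Ordered 3-D centerline with per-point lumen radius (all mm).

    ``arclength`` is the cumulative Euclidean distance along ``points``,
    starting at 0; it is recomputed from the points at construction so the
    consistency invariant cannot be violated.
    """

    points: np.ndarray  # (n, 3)
    radius: np.ndarray  # (n,)
    arclength: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        rad = np.asarray(self.radius, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        if pts.shape[0] < 2:
            raise ValueError("a centerline needs at least 2 points")
        if rad.shape != (pts.shape[0],):
            raise ValueError("radius must be one value per point")
        if not np.all(np.isfinite(pts)) or not np.all(np.isfinite(rad)):
            raise ValueError("non-finite values in centerline")
        if np.any(rad <= 0):
            raise ValueError("all lumen radii must be positive")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("consecutive centerline points must be distinct")
        s = np.concatenate([[0.0], np.cumsum(seg)])
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "radius", rad)
        object.__setattr__(self, "arclength", s)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def length(self) -> float:
        """Total arclength (mm)."""
        return float(self.arclength[-1])

    def radius_at(self, s: np.ndarray | float) -> np.ndarray:
        """Lumen radius interpolated at arclength position(s) ``s``."""
        return np.interp(s, self.arclength, self.radius)


@dataclass(frozen=True)
class ViewProjection:
    """Orthographic projection of a centerline under two gantry angles.

    ``gantry_angles`` = (rotation about y, rotation about x) in degrees,
    applied in that order; the image plane is the rotated x-y plane and the
    viewing axis is the rotated z axis.  Under the orthographic,
    circular-cross-section assumption the projected radius equals the true
    radius.
    """

    gantry_angles: tuple[float, float]
    points2d: np.ndarray  # (n, 2)
    proj_radius: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points2d, dtype=float)
        rad = np.asarray(self.proj_radius, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points2d must have shape (n, 2)")
        if rad.shape != (pts.shape[0],):
            raise ValueError("proj_radius must be one value per point")
        object.__setattr__(self, "points2d", pts)
        object.__setattr__(self, "proj_radius", rad)
        object.__setattr__(self, "gantry_angles", tuple(float(a) for a in self.gantry_angles))

    @property
    def n_points(self) -> int:
        return self.points2d.shape[0]


@dataclass(frozen=True)
class FlowMesh:
    """1-D finite-volume discretization of the lumen along the vessel."""

    cell_s: np.ndarray  # arclength at cell centers (mm)
    cell_area: np.ndarray  # lumen cross-section area (mm^2)
    cell_ds: np.ndarray  # cell length (mm)

    def __post_init__(self) -> None:
        s = np.asarray(self.cell_s, dtype=float)
        a = np.asarray(self.cell_area, dtype=float)
        ds = np.asarray(self.cell_ds, dtype=float)
        if not (s.shape == a.shape == ds.shape) or s.ndim != 1:
            raise ValueError("cell_s, cell_area, cell_ds must be equal-length 1-D arrays")
        if not np.all(np.isfinite(a)) or np.any(a <= 0):
            raise ValueError("all cell areas must be finite and positive")
        if np.any(np.diff(s) <= 0):
            raise ValueError("cell_s must be strictly increasing")
        object.__setattr__(self, "cell_s", s)
        object.__setattr__(self, "cell_area", a)
        object.__setattr__(self, "cell_ds", ds)

    @property
    def n_cells(self) -> int:
        return self.cell_s.size

    @property
    def total_length(self) -> float:
        return float(self.cell_ds.sum())


def make_vessel(
    length_mm: float,
    proximal_radius_mm: float,
    stenosis: StenosisSpec | None = None,
    tortuosity_amplitude_mm: float = 0.0,
    n_points: int = 201,
    tortuosity_waves: float = 1.5,
) -> Centerline:
    """Build a synthetic coronary vessel centerline.

    The vessel runs nominally along +x with an optional sinusoidal in-plane
    tortuosity of the given amplitude; the curve is rescaled so its total
    *arclength* equals ``length_mm`` exactly.  The radius profile is the
    proximal radius everywhere except within the stenosis taper, whose
    minimum is ``proximal_radius_mm * (1 - severity)``.
    """
    if length_mm <= 0 or proximal_radius_mm <= 0:
        raise ValueError("vessel length and proximal radius must be positive")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if tortuosity_amplitude_mm < 0:
        raise ValueError("tortuosity amplitude must be non-negative")

    t = np.linspace(0.0, 1.0, n_points)
    x = t * length_mm
    y = tortuosity_amplitude_mm * np.sin(2.0 * np.pi * tortuosity_waves * t)
    z = np.zeros_like(t)
    pts = np.column_stack([x, y, z])
    # rescale so cumulative arclength hits length_mm exactly
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    raw_len = seg.sum()
    pts *= length_mm / raw_len
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])

    radius = np.full(n_points, proximal_radius_mm, dtype=float)
    if stenosis is not None:
        if not (0.0 <= stenosis.center_s <= length_mm):
            raise ValueError("stenosis center must lie on the vessel")
        radius = proximal_radius_mm * stenosis.radius_factor(s)
    return Centerline(points=pts, radius=radius)


def _rotation_matrix(gantry_angles: tuple[float, float]) -> np.ndarray:
    """World->camera rotation: Ry(alpha) then Rx(beta), angles in degrees."""
    alpha, beta = (np.deg2rad(a) for a in gantry_angles)
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    ry = np.array([[ca, 0.0, sa], [0.0, 1.0, 0.0], [-sa, 0.0, ca]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cb, -sb], [0.0, sb, cb]])
    return rx @ ry


def project(centerline: Centerline, gantry_angles: tuple[float, float]) -> ViewProjection:
    """Orthographic projection of a centerline under the given gantry rotation.

    The projected radius equals the true radius (parallel rays, circular
    cross-section).
    """
    r = _rotation_matrix(gantry_angles)
    rotated = centerline.points @ r.T
    return ViewProjection(
        gantry_angles=tuple(gantry_angles),
        points2d=rotated[:, :2].copy(),
        proj_radius=centerline.radius.copy(),
    )


def view_separation_deg(view_a: ViewProjection, view_b: ViewProjection) -> float:
    """Angle between the two viewing axes, folded into [0, 90] degrees."""
    na = _rotation_matrix(view_a.gantry_angles)[2]
    nb = _rotation_matrix(view_b.gantry_angles)[2]
    c = np.clip(abs(float(na @ nb)), -1.0, 1.0)
    return float(np.rad2deg(np.arccos(c)))


def reconstruct(view_a: ViewProjection, view_b: ViewProjection) -> Centerline:
    """Recover a 3-D centerline from two orthographic views.

    Each 3-D point is the least-squares solution of the four linear image
    constraints (two per view); the reconstructed radius is the arithmetic
    mean of the two projected radii.  The two viewing axes must be separated
    by at least 30 degrees, matching the two-posture acquisition rule.
    """
    if view_a.n_points != view_b.n_points:
        raise ValueError(
            f"views have mismatched point counts ({view_a.n_points} vs {view_b.n_points}); "
            "correspondence is by index"
        )
    sep = view_separation_deg(view_a, view_b)
    if sep < MIN_VIEW_SEPARATION_DEG:
        raise ValueError(
            f"view separation {sep:.1f} deg is below the required "
            f"{MIN_VIEW_SEPARATION_DEG:.0f} deg between the two postures"
        )
    ra = _rotation_matrix(view_a.gantry_angles)
    rb = _rotation_matrix(view_b.gantry_angles)
    m = np.vstack([ra[:2], rb[:2]])  # (4, 3)
    b = np.hstack([view_a.points2d, view_b.points2d])  # (n, 4)
    pinv = np.linalg.pinv(m)  # (3, 4)
    pts = b @ pinv.T
    radius = 0.5 * (view_a.proj_radius + view_b.proj_radius)
    return Centerline(points=pts, radius=radius)


def discretize(centerline: Centerline, n_cells: int) -> FlowMesh:
    """Discretize the lumen into ``n_cells`` equal-arclength cells.

    Cell areas are pi * r(s)^2 with the radius interpolated at cell centers;
    cell lengths sum to the total arclength exactly (to rounding).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    total = centerline.length
    edges = np.linspace(0.0, total, n_cells + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ds = np.diff(edges)
    r = centerline.radius_at(centers)
    return FlowMesh(cell_s=centers, cell_area=np.pi * r**2, cell_ds=ds)


# ---------------------------------------------------------------------------
# CSV / JSON I/O


def write_centerline_csv(centerline: Centerline, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "s_mm": centerline.arclength,
            "x_mm": centerline.points[:, 0],
            "y_mm": centerline.points[:, 1],
            "z_mm": centerline.points[:, 2],
            "r_mm": centerline.radius,
        }
    )
    df.to_csv(path, index=False)


def read_centerline_csv(path: str | Path) -> Centerline:
    df = pd.read_csv(path)
    required = {"x_mm", "y_mm", "z_mm", "r_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"centerline CSV {path} is missing columns: {sorted(missing)}")
    pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    return Centerline(points=pts, radius=df["r_mm"].to_numpy(dtype=float))


def write_projection_csv(view: ViewProjection, path: str | Path) -> None:
    """Write a projection as CSV plus a JSON sidecar holding the gantry angles."""
    path = Path(path)
    n = view.n_points
    # index-based normalized arc position; true arclength is a 3-D quantity
    df = pd.DataFrame(
        {
            "s_norm": np.linspace(0.0, 1.0, n),
            "u_mm": view.points2d[:, 0],
            "v_mm": view.points2d[:, 1],
            "r_mm": view.proj_radius,
        }
    )
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"gantry_angles_deg": list(view.gantry_angles)}))


def read_projection_csv(path: str | Path) -> ViewProjection:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    return ViewProjection(
        gantry_angles=tuple(meta["gantry_angles_deg"]),
        points2d=df[["u_mm", "v_mm"]].to_numpy(dtype=float),
        proj_radius=df["r_mm"].to_numpy(dtype=float),
    )
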