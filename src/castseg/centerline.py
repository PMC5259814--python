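"""Centerline fitting, multiplanar reformation and radial contours.

The vessel centerline is a cubic spline through ordered, manually picked
center points, resampled at uniform arc length.  Orthonormal in-plane frames
(u, v) are propagated along the curve with the double-reflection
rotation-minimizing transport, which is well defined on straight segments
(unlike Frenet frames) and keeps consecutive frames from twisting.

Cross-sections are 2D HU images sampled by trilinear interpolation on the
plane perpendicular to the tangent; lumen contours are represented as radial
functions r(θ) about the centerline point, sampled at K uniform angles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import map_coordinates

from .volume import ImageVolume

__all__ = ["Centerline", "CrossSection", "Contour", "fit_centerline",
           "extract_cross_section", "interp_border_contour",
           "init_contour_circle", "read_seed_points", "write_contours",
           "read_contours"]


@dataclass
class Centerline:
    """Arc-length parameterized curve with rotation-minimizing frames.

    ``samples`` (N, 3) mm at uniform arc-length spacing; ``tangents``,
    ``u``, ``v`` are unit vectors forming a right-handed frame at each
    sample; ``arc_length`` (N,) mm.
    """

    samples: np.ndarray
    tangents: np.ndarray
    u: np.ndarray
    v: np.ndarray
    arc_length: np.ndarray

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def frame_at(self, s: float):
        """Point, tangent and (u, v) basis at arc position s (mm).

        Linear interpolation between the bracketing samples, re-orthonormalized.
        """
        if not (self.arc_length[0] <= s <= self.arc_length[-1]):
            raise ValueError(f"s={s} outside centerline range "
                             f"[{self.arc_length[0]}, {self.arc_length[-1]}] mm")
        i = int(np.clip(np.searchsorted(self.arc_length, s) - 1, 0,
                        len(self.arc_length) - 2))
        w = (s - self.arc_length[i]) / (self.arc_length[i + 1] - self.arc_length[i])
        p = (1 - w) * self.samples[i] + w * self.samples[i + 1]
        t = (1 - w) * self.tangents[i] + w * self.tangents[i + 1]
        t /= np.linalg.norm(t)
        u = (1 - w) * self.u[i] + w * self.u[i + 1]
        u -= t * (u @ t)
        u /= np.linalg.norm(u)
        v = np.cross(t, u)
        return p, t, u, v


@dataclass
class CrossSection:
    """Planar HU image perpendicular to the centerline at arc position s.

    ``image[a, b]`` is sampled at world point
    ``origin + (a*spacing - half_width) * u + (b*spacing - half_width) * v``
    with ``spacing`` in mm; plane coordinates used by contours are µm
    relative to ``origin``.
    """

    image: np.ndarray
    spacing: float       # mm between plane samples
    origin: np.ndarray   # (3,) mm, centerline point
    u: np.ndarray
    v: np.ndarray
    s: float             # mm arc position
    half_width: float    # mm

    def plane_to_pixel(self, a_um, b_um):
        """Convert in-plane µm coordinates (about the centerline point) to
        fractional pixel indices of ``image``."""
        a = (np.asarray(a_um, dtype=float) / 1000.0 + self.half_width) / self.spacing
        b = (np.asarray(b_um, dtype=float) / 1000.0 + self.half_width) / self.spacing
        return a, b

    def sample(self, a_um, b_um):
        """Bilinear interpolation of the plane image at µm coordinates."""
        a, b = self.plane_to_pixel(a_um, b_um)
        return map_coordinates(self.image.astype(float),
                               np.vstack([np.ravel(a), np.ravel(b)]),
                               order=1, mode="nearest").reshape(np.shape(a))


@dataclass
class Contour:
    """Closed lumen boundary as a radial function about the centerline point.

    ``radii`` (K,) in µm at uniform angles θ_k = 2πk/K measured in the (u, v)
    plane basis.  ``origin``/``u``/``v`` tie the contour to world space (mm);
    they may be None for purely planar contours.
    """

    radii: np.ndarray
    s: float
    origin: np.ndarray | None = None
    u: np.ndarray | None = None
    v: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        if np.any(self.radii <= 0):
            raise ValueError("contour radii must be positive")

    @property
    def K(self) -> int:
        return len(self.radii)

    @property
    def angles(self) -> np.ndarray:
        return 2 * np.pi * np.arange(self.K) / self.K

    def radius_at(self, theta) -> np.ndarray:
        """Periodic linear interpolation of r(θ)."""
        th = np.mod(np.asarray(theta, dtype=float), 2 * np.pi)
        grid = np.append(self.angles, 2 * np.pi)
        vals = np.append(self.radii, self.radii[0])
        return np.interp(th, grid, vals)

    def polygon(self) -> np.ndarray:
        """(K, 2) in-plane polygon vertices, µm."""
        th = self.angles
        return np.column_stack([self.radii * np.cos(th), self.radii * np.sin(th)])

    def area(self) -> float:
        """Shoelace polygon area, µm²."""
        p = self.polygon()
        x, y = p[:, 0], p[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def world_points(self) -> np.ndarray:
        """(K, 3) world coordinates (mm) of the contour vertices."""
        if self.origin is None or self.u is None or self.v is None:
            raise ValueError("contour has no world frame attached")
        p = self.polygon() / 1000.0
        return self.origin + p[:, :1] * self.u + p[:, 1:2] * self.v


def fit_centerline(seed_points: np.ndarray, sample_spacing: float = 0.04) -> Centerline:
    """Fit a smooth centerline through ordered seed points.

    Parameters
    ----------
    seed_points : (M, 3) array
        Ordered center points (mm), proximal to distal, M >= 4, no repeated
        consecutive points.
    sample_spacing : float
        Target uniform arc-length spacing of the resampled curve, mm.
    """
    pts = np.asarray(seed_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
        raise ValueError("need at least 4 ordered 3D seed points")
    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(chord == 0):
        raise ValueError("duplicate consecutive seed points")

    t = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(t, pts, axis=0)

    # densify, measure arc length, then invert to uniform arc samples
    t_dense = np.linspace(0.0, t[-1], max(20 * len(pts), 1000))
    p_dense = spline(t_dense)
    seg = np.linalg.norm(np.diff(p_dense, axis=0), axis=1)
    arc_dense = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc_dense[-1]
    n = max(int(round(total / sample_spacing)) + 1, 2)
    arc = np.linspace(0.0, total, n)
    t_arc = np.interp(arc, arc_dense, t_dense)
    samples = spline(t_arc)
    tangents = spline(t_arc, 1)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)

    u = np.empty_like(samples)
    v = np.empty_like(samples)
    u[0] = _any_normal(tangents[0])
    v[0] = np.cross(tangents[0], u[0])
    for i in range(len(samples) - 1):
        u[i + 1] = _double_reflection(samples[i], tangents[i], u[i],
                                      samples[i + 1], tangents[i + 1])
        v[i + 1] = np.cross(tangents[i + 1], u[i + 1])
    return Centerline(samples=samples, tangents=tangents, u=u, v=v, arc_length=arc)


def _any_normal(t: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(t @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - t * (ref @ t)
    return u / np.linalg.norm(u)


def _double_reflection(p0, t0, u0, p1, t1) -> np.ndarray:
    """Rotation-minimizing frame transport (double-reflection method)."""
    d1 = p1 - p0
    c1 = d1 @ d1
    if c1 < 1e-300:
        return u0.copy()
    uL = u0 - (2.0 / c1) * (d1 @ u0) * d1
    tL = t0 - (2.0 / c1) * (d1 @ t0) * d1
    d2 = t1 - tL
    c2 = d2 @ d2
    if c2 < 1e-300:
        u1 = uL
    else:
        u1 = uL - (2.0 / c2) * (d2 @ uL) * d2
    u1 -= t1 * (u1 @ t1)
    return u1 / np.linalg.norm(u1)


def extract_cross_section(volume: ImageVolume, centerline: Centerline, s: float,
                          half_width: float = 1.0,
                          spacing: float = 0.01) -> CrossSection:
    """Sample the HU image on the plane normal to the centerline at s.

    ``half_width`` and ``spacing`` in mm; ``spacing`` must not exceed the
    voxel size (no undersampling).  Raises if any plane sample falls outside
    the volume, naming the offending arc position.
    """
    if spacing > volume.voxel_size + 1e-12:
        raise ValueError("plane spacing must not exceed the voxel size")
    p, t, u, v = centerline.frame_at(s)
    n = int(round(2 * half_width / spacing)) + 1
    coords_1d = np.linspace(-half_width, half_width, n)
    pts = (p[None, None, :]
           + coords_1d[:, None, None] * u[None, None, :]
           + coords_1d[None, :, None] * v[None, None, :])
    idx = volume.world_to_index(pts.reshape(-1, 3))
    hi = np.array(volume.shape) - 1
    if np.any(idx < -1e-9) or np.any(idx > hi + 1e-9):
        raise ValueError(f"cross-section plane at s={s:.3f} mm exits the volume")
    img = map_coordinates(volume.data.astype(float), idx.T, order=1).reshape(n, n)
    return CrossSection(image=img, spacing=spacing, origin=p, u=u, v=v, s=s,
                        half_width=half_width)


def interp_border_contour(border_points, K: int = 72, s: float = 0.0) -> Contour:
    """Build a contour from manually placed border samples.

    ``border_points`` is a sequence of (θ, r) pairs (radians, µm) coming
    from border placement on longitudinal planes at rotations 0°/60°/120°
    (each rotation contributes two opposite border samples); at least 6
    samples covering >= 3 distinct rotations are required.  A periodic cubic
    spline through the samples is resampled at K uniform angles.
    """
    bp = np.asarray(border_points, dtype=float)
    if bp.ndim != 2 or bp.shape[1] != 2 or bp.shape[0] < 6:
        raise ValueError("need at least 6 (theta, r) border samples")
    if np.any(bp[:, 1] <= 0):
        raise ValueError("border radii must be positive")
    theta = np.mod(bp[:, 0], 2 * np.pi)
    rotations = np.unique(np.round(np.mod(theta, np.pi), 6))
    if len(rotations) < 3:
        raise ValueError("border samples must cover at least 3 distinct rotations")
    order = np.argsort(theta)
    theta, r = theta[order], bp[order, 1]
    th_p = np.append(theta, theta[0] + 2 * np.pi)
    r_p = np.append(r, r[0])
    spline = CubicSpline(th_p, r_p, bc_type="periodic")
    th_out = 2 * np.pi * np.arange(K) / K
    radii = spline(np.where(th_out < th_p[0], th_out + 2 * np.pi, th_out))
    return Contour(radii=radii, s=s)


def init_contour_circle(cross_section: CrossSection, radius_estimate: float,
                        K: int = 72) -> Contour:
    """Circle of the given radius (µm) centered on the centerline point."""
    if radius_estimate <= 0:
        raise ValueError("radius_estimate must be positive")
    return Contour(radii=np.full(K, float(radius_estimate)), s=cross_section.s,
                   origin=cross_section.origin, u=cross_section.u,
                   v=cross_section.v)


def read_seed_points(path: str | Path) -> np.ndarray:
    """Read ordered centerline seed points from CSV with columns x,y,z (mm)."""
    df = pd.read_csv(path)
    cols = [c for c in ("x", "y", "z") if c in df.columns]
    if len(cols) == 3:
        return df[cols].to_numpy(dtype=float)
    return df.iloc[:, :3].to_numpy(dtype=float)


def write_contours(contours, path: str | Path) -> None:
    """Write a contour stack as long-format CSV (s_mm, theta_rad, r_um)."""
    rows = []
    for c in contours:
        for th, r in zip(c.angles, c.radii):
            rows.append((c.s, th, r))
    pd.DataFrame(rows, columns=["s_mm", "theta_rad", "r_um"]).to_csv(
        path, index=False)


def read_contours(path: str | Path) -> list[Contour]:
    df = pd.read_csv(path)
    out = []
    for s, grp in df.groupby("s_mm", sort=True):
        grp = grp.sort_values("theta_rad")
        out.append(Contour(radii=grp["r_um"].to_numpy(), s=float(s)))
    return out
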