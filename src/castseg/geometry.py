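"""Vessel geometry: diameter/wall-thickness profiles and surface building.

Contour stacks from segmentation are reduced to an equivalent-area diameter
profile D(s) = 2·sqrt(A(s)/π), compared against the known tapering cast
(the only in-vivo landmark of true dimension), and lofted into a watertight
triangulated lumen surface suitable for CFD preprocessing: volume-preserving
Taubin smoothing and straight flow extensions of 5× the end radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh
from scipy import sparse

from .centerline import Contour
from .phantom import CastSpec

__all__ = ["DiameterProfile", "WallThicknessProfile", "VesselSurface",
           "diameter_profile", "cast_inner_diameter", "compare_to_cast",
           "wall_thickness", "loft_surface", "smooth_surface",
           "add_flow_extensions"]


@dataclass
class DiameterProfile:
    """Per-slice lumen area (µm²) and equivalent diameter (µm)."""

    s: np.ndarray
    area: np.ndarray
    diameter: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"s_mm": self.s, "D_um": self.diameter,
                             "A_um2": self.area})


@dataclass
class WallThicknessProfile:
    """w(s) = (D_cast − D_vessel)/2 inside the cast; negatives are flagged
    as segmentation overshoot, not raised."""

    s: np.ndarray
    thickness: np.ndarray     # µm
    cast_diameter: np.ndarray  # µm
    overshoot: np.ndarray     # bool, w < 0

    @property
    def mean(self) -> float:
        return float(self.thickness.mean())

    @property
    def sd(self) -> float:
        return float(np.std(self.thickness, ddof=1)) if len(self.thickness) > 1 else 0.0


@dataclass
class VesselSurface:
    """Triangulated lumen surface with watertightness and volume bookkeeping.

    ``end_vertices`` records the inlet/outlet ring and cap-apex vertex
    indices; smoothing keeps these fixed so the end planes stay planar for
    downstream CFD boundary conditions.
    """

    mesh: trimesh.Trimesh
    watertight: bool
    volume: float  # mm³
    end_vertices: np.ndarray | None = None

    @classmethod
    def from_mesh(cls, mesh: trimesh.Trimesh,
                  end_vertices: np.ndarray | None = None) -> "VesselSurface":
        areas = mesh.area_faces
        if np.any(areas <= 1e-12):
            mesh.update_faces(areas > 1e-12)
        return cls(mesh=mesh, watertight=bool(mesh.is_watertight),
                   volume=float(abs(mesh.volume)), end_vertices=end_vertices)

    def export(self, path) -> None:
        self.mesh.export(path)


def diameter_profile(contours: list[Contour]) -> DiameterProfile:
    """Equivalent-area diameter per slice, D = 2·sqrt(A/π)."""
    if len(contours) < 1:
        raise ValueError("need at least one contour")
    s = np.array([c.s for c in contours])
    areas = np.array([c.area() for c in contours])
    bad = np.flatnonzero(areas <= 0)
    if bad.size:
        raise ValueError(f"self-intersecting contour (non-positive area) "
                         f"at s={s[bad[0]]:.3f} mm")
    return DiameterProfile(s=s, area=areas, diameter=2 * np.sqrt(areas / np.pi))


def cast_inner_diameter(cast: CastSpec, s) -> np.ndarray:
    """Cast inner diameter (µm) at arc position(s) s (mm); errors outside."""
    return cast.inner_diameter(s)


def _cast_slices(profile: DiameterProfile, cast: CastSpec, s=None):
    s_arr = profile.s if s is None else np.asarray(s, dtype=float)
    if len(s_arr) != len(profile.s):
        raise ValueError("s override must match the profile length")
    mask = cast.contains(s_arr)
    return s_arr, mask


def compare_to_cast(profile: DiameterProfile, cast: CastSpec, s=None
                    ) -> tuple[float, float]:
    """Mean ± SD percent undersizing of the vessel relative to the cast.

    100·(D_cast − D_vessel)/D_cast averaged over the slices inside the cast
    extent.  ``s`` optionally overrides the per-slice positions used for the
    cast lookup (e.g. axial positions when the profile is indexed by arc
    length along a curved centerline).
    """
    s_arr, mask = _cast_slices(profile, cast, s)
    if mask.sum() < 3:
        raise ValueError("need at least 3 slices inside the cast extent")
    d_cast = cast.inner_diameter(s_arr[mask])
    pct = 100.0 * (d_cast - profile.diameter[mask]) / d_cast
    return float(pct.mean()), float(np.std(pct, ddof=1))


def wall_thickness(profile: DiameterProfile, cast: CastSpec, s=None
                   ) -> WallThicknessProfile:
    """Apparent wall thickness inside the cast, w = (D_cast − D_vessel)/2."""
    s_arr, mask = _cast_slices(profile, cast, s)
    if mask.sum() < 3:
        raise ValueError("need at least 3 slices inside the cast extent")
    d_cast = cast.inner_diameter(s_arr[mask])
    w = (d_cast - profile.diameter[mask]) / 2.0
    return WallThicknessProfile(s=s_arr[mask], thickness=w, cast_diameter=d_cast,
                                overshoot=w < 0)


def loft_surface(contours: list[Contour], cap: bool = True) -> VesselSurface:
    """Loft a stack of world-framed contours into a triangulated surface.

    Adjacent rings (each resampled at the same K angles in their
    rotation-minimized frames, so the angular origin is transported
    consistently) are joined by triangle strips; the open ends are capped
    with fans to the ring centroid, giving a watertight mesh.
    """
    if len(contours) < 2:
        raise ValueError("need at least two contours to loft")
    K = contours[0].K
    if any(c.K != K for c in contours):
        raise ValueError("all contours must share the same angular sampling K")
    rings = []
    for i, c in enumerate(contours):
        rings.append(c.world_points())
        if i > 0:
            d = contours[i].origin - contours[i - 1].origin
            n_prev = np.cross(contours[i - 1].u, contours[i - 1].v)
            if d @ n_prev <= 0:
                raise ValueError(
                    f"connecting strip between s={contours[i-1].s:.3f} and "
                    f"s={contours[i].s:.3f} mm self-intersects (planes out of order)")
    verts = np.concatenate(rings, axis=0)
    faces = []
    n = len(contours)
    for i in range(n - 1):
        a0, b0 = i * K, (i + 1) * K
        for k in range(K):
            k1 = (k + 1) % K
            faces.append([a0 + k, b0 + k, a0 + k1])
            faces.append([a0 + k1, b0 + k, b0 + k1])
    if cap:
        c0 = verts[:K].mean(axis=0)
        c1 = verts[-K:].mean(axis=0)
        i0 = len(verts)
        i1 = len(verts) + 1
        verts = np.vstack([verts, c0, c1])
        for k in range(K):
            k1 = (k + 1) % K
            faces.append([i0, k1, k])                       # inlet cap
            faces.append([i1, (n - 1) * K + k, (n - 1) * K + k1])  # outlet cap
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
    mesh.fix_normals()
    if mesh.volume < 0:
        mesh.invert()
    ends = np.concatenate([np.arange(K), np.arange((n - 1) * K, n * K),
                           [len(verts) - 2, len(verts) - 1] if cap else []])
    return VesselSurface.from_mesh(mesh, end_vertices=ends.astype(int))


def _umbrella(mesh: trimesh.Trimesh) -> sparse.csr_matrix:
    """Uniform Laplacian L with L v = mean(neighbours) − v."""
    e = mesh.edges_unique
    n = len(mesh.vertices)
    i = np.concatenate([e[:, 0], e[:, 1]])
    j = np.concatenate([e[:, 1], e[:, 0]])
    w = sparse.coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n)).tocsr()
    deg = np.asarray(w.sum(axis=1)).ravel()
    inv = sparse.diags(1.0 / np.maximum(deg, 1))
    return (inv @ w - sparse.identity(n)).tocsr()


def smooth_surface(surface: VesselSurface, passes: int = 20,
                   lamb: float = 0.5, mu: float = -0.53) -> VesselSurface:
    """Taubin band-pass smoothing with a 1 % volume-preservation gate.

    Alternates a shrinking Laplacian step (factor ``lamb`` > 0) with an
    inflating step (``mu`` < −lamb), which removes high-frequency surface
    noise without the systematic shrinkage of plain Laplacian smoothing.
    Raises if the band-pass iteration alone drifts the enclosed volume by
    more than 1 % (a sign of unstable parameters); the residual drift —
    mostly end-cap rounding — is then removed exactly by an isotropic
    rescale about the volume centroid.
    """
    if not surface.watertight:
        raise ValueError("smoothing requires a watertight mesh")
    if passes < 0:
        raise ValueError("passes must be >= 0")
    if passes == 0:
        return surface
    mesh = surface.mesh.copy()
    L = _umbrella(mesh)
    v = mesh.vertices.copy()
    pinned = surface.end_vertices
    fixed = None if pinned is None else v[pinned].copy()
    for _ in range(passes):
        v = v + lamb * (L @ v)
        if fixed is not None:
            v[pinned] = fixed
        v = v + mu * (L @ v)
        if fixed is not None:
            v[pinned] = fixed
    out = trimesh.Trimesh(vertices=v, faces=mesh.faces.copy(), process=False)
    result = VesselSurface.from_mesh(out, end_vertices=pinned)
    v0 = surface.volume
    if v0 > 0 and abs(result.volume - v0) / v0 > 0.01:
        raise ValueError(
            f"smoothing changed the enclosed volume by "
            f"{100 * abs(result.volume - v0) / v0:.2f}% (> 1 %); reduce "
            "passes or bring mu closer to -lamb")
    if v0 > 0 and result.volume > 0:
        center = out.center_mass
        scale = (v0 / result.volume) ** (1.0 / 3.0)
        out = trimesh.Trimesh(vertices=center + scale * (v - center),
                              faces=mesh.faces.copy(), process=False)
        result = VesselSurface.from_mesh(out, end_vertices=pinned)
    return result


def add_flow_extensions(contours: list[Contour], factor: float = 5.0,
                        n_rings: int = 8) -> list[Contour]:
    """Extrude both end contours along the end tangents.

    Each extension has constant cross-section (a copy of the end contour)
    and length ``factor`` × the end's equivalent radius, ensuring the flow
    entering or leaving the region of interest is fully developed.
    ``factor`` = 0 returns the stack unchanged.
    """
    if factor < 0:
        raise ValueError("extension factor must be >= 0")
    if len(contours) < 2:
        raise ValueError("need at least two contours")
    if factor == 0:
        return list(contours)
    out = list(contours)
    for end, sign in ((0, -1.0), (-1, 1.0)):
        c = contours[end]
        if c.origin is None:
            raise ValueError("end contour has no world frame")
        normal = np.cross(c.u, c.v) * sign          # outward axial direction
        r_eq_mm = np.sqrt(c.area() / np.pi) / 1000.0
        length = factor * r_eq_mm                   # mm
        offs = length * np.arange(1, n_rings + 1) / n_rings
        rings = [Contour(radii=c.radii.copy(), s=c.s + sign * o,
                         origin=c.origin + o * normal, u=c.u.copy(), v=c.v.copy())
                 for o in offs]
        if end == 0:
            out = rings[::-1] + out
        else:
            out = out + rings
    return out
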