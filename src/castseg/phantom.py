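"""Synthetic contrast-enhanced micro-CT phantoms of a cast-constricted carotid.

The phantom emulates a murine right common carotid artery (RCCA) with a rigid
tapering cast cuff around it, imaged with a blood-pool contrast agent at
40 µm cubic voxels.  Voxel intensities follow the measured regime of
eXIA 160-enhanced imaging: bright lumen (~339 HU outside the cast, ~257 HU
inside it, where the reduced blood volume lowers the contrast signal),
soft-tissue background (~53 HU), and a dark cast annulus (~−97 HU).  Axial
signal fluctuation, Gaussian noise and partial-volume averaging are modeled
so that threshold-based segmentation of the phantom shows the same biases as
segmentation of real scans.

All world coordinates are mm; radii, voxel sizes and HU settings are given
in the units stated on each field.  The phantom ships with its ground truth
(centerline, lumen radius profile, cast geometry), making it usable as an
oracle for segmentation accuracy experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import ImageVolume

__all__ = ["CastSpec", "PhantomConfig", "GroundTruth", "generate_phantom",
           "write_ground_truth", "read_ground_truth"]


@dataclass
class CastSpec:
    """Geometry of the tapering shear-modifying cast.

    The cast is a rigid cuff whose inner lumen tapers linearly from
    ``proximal_inner_diameter`` to ``distal_inner_diameter`` (µm) over
    ``cast_length`` (mm), starting at arc position ``cast_start_s`` (mm)
    along the vessel centerline.
    """

    proximal_inner_diameter: float = 400.0   # µm
    distal_inner_diameter: float = 200.0     # µm
    cast_length: float = 1.5                 # mm
    cast_outer_diameter: float = 1400.0      # µm
    cast_start_s: float = 7.0                # mm

    def __post_init__(self) -> None:
        if not self.proximal_inner_diameter > self.distal_inner_diameter > 0:
            raise ValueError("need proximal_inner_diameter > distal_inner_diameter > 0")
        if self.cast_outer_diameter <= self.proximal_inner_diameter:
            raise ValueError("cast_outer_diameter must exceed proximal_inner_diameter")
        if self.cast_length <= 0:
            raise ValueError("cast_length must be positive")

    @property
    def cast_end_s(self) -> float:
        return self.cast_start_s + self.cast_length

    def contains(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return (s >= self.cast_start_s) & (s <= self.cast_end_s)

    def inner_diameter(self, s) -> np.ndarray:
        """Inner diameter (µm) at arc position s (mm); linear taper.

        Raises outside the cast extent.
        """
        s = np.asarray(s, dtype=float)
        if np.any(~self.contains(s)):
            raise ValueError(
                f"arc position outside cast extent "
                f"[{self.cast_start_s}, {self.cast_end_s}] mm")
        frac = (s - self.cast_start_s) / self.cast_length
        return (self.proximal_inner_diameter
                + frac * (self.distal_inner_diameter - self.proximal_inner_diameter))


@dataclass
class PhantomConfig:
    """Settings of the synthetic acquisition.

    HU defaults reproduce the cohort-average contrast statistics of the
    eXIA 160 protocol (lumen 339/257 HU outside/inside the cast, soft-tissue
    background 53 HU, cast material −97 HU).  Partial volume is modeled by
    supersample-and-average (``supersample``³ subsamples per voxel); the
    axial signal fluctuation seen along real vessels is modeled as a
    sinusoidal modulation of the lumen HU with amplitude
    ``fluctuation_amplitude`` × (lumen − background contrast).
    """

    grid_shape: tuple[int, int, int] = (160, 160, 300)
    voxel_size: float = 40.0                 # µm
    lumen_hu_noncast: float = 339.0          # HU
    lumen_hu_cast: float = 257.0             # HU
    background_hu_noncast: float = 53.0      # HU
    cast_hu: float = -97.0                   # HU
    noise_sd: float = 30.0                   # HU
    fluctuation_amplitude: float = 0.10      # fraction of lumen-background contrast
    fluctuation_period: float = 1.5          # mm
    supersample: int = 3
    wall_thickness_in_cast: float = 13.5     # µm
    vessel_radius_noncast: float = 250.0     # µm
    centerline_curvature_amplitude: float = 200.0  # µm
    centerline_curvature_period: float = 8.0       # mm
    taper_transition: float = 0.3            # mm, radius blend on each side of the cast
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Known construction of a phantom: centerline, radii and intensity model."""

    centerline: np.ndarray          # (N, 3) mm, ordered proximal -> distal
    arc_length: np.ndarray          # (N,) mm, measured along the curve
    axial_position: np.ndarray      # (N,) mm, z of each sample (radius parameter)
    true_radius_profile: np.ndarray  # (N,) µm lumen radius
    cast: CastSpec = field(default_factory=CastSpec)
    hu_params: dict = field(default_factory=dict)

    def radius_at(self, s) -> np.ndarray:
        """Interpolated true lumen radius (µm) at axial position s (mm)."""
        return np.interp(np.asarray(s, dtype=float),
                         self.axial_position, self.true_radius_profile)


def _true_radius_um(z_mm, config: PhantomConfig, cast: CastSpec) -> np.ndarray:
    """Ground-truth lumen radius (µm) as a function of axial position (mm).

    Constant outside the cast, (cast inner radius − wall thickness) inside,
    with a linear blend over ``taper_transition`` on each side so the
    profile is continuous.
    """
    z = np.atleast_1d(np.asarray(z_mm, dtype=float))
    r = np.full(z.shape, config.vessel_radius_noncast)
    s0, s1 = cast.cast_start_s, cast.cast_end_s
    w = config.wall_thickness_in_cast
    r_in = cast.proximal_inner_diameter / 2 - w
    r_out = cast.distal_inner_diameter / 2 - w
    dz = config.taper_transition

    inside = cast.contains(z)
    if np.any(inside):
        r[inside] = cast.inner_diameter(z[inside]) / 2 - w
    if dz > 0:
        pre = (z >= s0 - dz) & (z < s0)
        r[pre] = np.interp(z[pre], [s0 - dz, s0],
                           [config.vessel_radius_noncast, r_in])
        post = (z > s1) & (z <= s1 + dz)
        r[post] = np.interp(z[post], [s1, s1 + dz],
                            [r_out, config.vessel_radius_noncast])
    return r


def _lumen_hu(z_mm, config: PhantomConfig, cast: CastSpec) -> np.ndarray:
    z = np.atleast_1d(np.asarray(z_mm, dtype=float))
    base = np.where(cast.contains(z), config.lumen_hu_cast, config.lumen_hu_noncast)
    contrast = config.lumen_hu_noncast - config.background_hu_noncast
    fluct = (config.fluctuation_amplitude * contrast
             * np.sin(2 * np.pi * z / config.fluctuation_period))
    return base + fluct


def _centerline_xy(z_mm, config: PhantomConfig, center_xy: np.ndarray):
    """In-plane centerline position (mm) at axial position z (mm)."""
    z = np.asarray(z_mm, dtype=float)
    amp = config.centerline_curvature_amplitude / 1000.0
    cx = center_xy[0] + amp * np.sin(2 * np.pi * z / config.centerline_curvature_period)
    cy = np.broadcast_to(center_xy[1], z.shape)
    return cx, cy


def generate_phantom(config: PhantomConfig | None = None,
                     cast: CastSpec | None = None) -> tuple[ImageVolume, GroundTruth]:
    """Synthesize a micro-CT volume of the cast-constricted vessel.

    Each voxel is the average over ``supersample``³ analytic samples of the
    piecewise-constant tissue model (lumen / cast annulus / soft tissue),
    which produces partial-volume mixing at boundaries; i.i.d. Gaussian
    noise of sd ``noise_sd`` HU is then added and values are rounded to
    int16, as in a reconstructed HU volume.

    Returns the volume together with its :class:`GroundTruth`.
    """
    config = config or PhantomConfig()
    cast = cast or CastSpec()

    nx, ny, nz = config.grid_shape
    h = config.voxel_size / 1000.0  # mm
    origin = np.zeros(3)
    center_xy = origin[:2] + h * (np.array([nx, ny]) - 1) / 2.0

    # the vessel (and 10-voxel background margin) must fit in-plane
    reach_mm = (max(cast.cast_outer_diameter, 2 * config.vessel_radius_noncast) / 2
                + config.centerline_curvature_amplitude) / 1000.0
    half_extent = h * (min(nx, ny) - 1) / 2.0
    if reach_mm + 10 * h > half_extent:
        raise ValueError(
            f"vessel reach {reach_mm:.2f} mm plus 10-voxel margin exceeds "
            f"grid half-extent {half_extent:.2f} mm")

    ss = config.supersample
    # supersample coordinates: voxel i covers [x_i - h/2, x_i + h/2]
    sub = ((np.arange(ss) + 0.5) / ss - 0.5) * h
    xs = (origin[0] + h * np.arange(nx))[:, None] + sub[None, :]  # (nx, ss)
    ys = (origin[1] + h * np.arange(ny))[:, None] + sub[None, :]
    xs = xs.ravel()
    ys = ys.ravel()

    cast_r_out_mm = cast.cast_outer_diameter / 2000.0
    data = np.empty((nx, ny, nz), dtype=np.float64)
    for k in range(nz):
        zc = origin[2] + h * k
        slab = np.zeros((nx, ny))
        for dz in sub:
            z = zc + dz
            cx, cy = _centerline_xy(z, config, center_xy)
            r2 = (xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2  # mm², (nx*ss, ny*ss)
            hu = np.full(r2.shape, config.background_hu_noncast)
            if cast.contains(z):
                cast_r_in_mm = float(cast.inner_diameter(z)) / 2000.0
                ann = (r2 >= cast_r_in_mm ** 2) & (r2 <= cast_r_out_mm ** 2)
                hu[ann] = config.cast_hu
            r_lum_mm = float(_true_radius_um(z, config, cast)[0]) / 1000.0
            hu[r2 < r_lum_mm ** 2] = float(_lumen_hu(z, config, cast)[0])
            slab += hu.reshape(nx, ss, ny, ss).mean(axis=(1, 3))
        data[:, :, k] = slab / ss

    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        data += rng.normal(0.0, config.noise_sd, size=data.shape)
    data = np.clip(np.rint(data), -32768, 32767).astype(np.int16)
    volume = ImageVolume(data=data, voxel_size=h, origin=origin)

    z_samples = origin[2] + h * np.arange(nz)
    cx, cy = _centerline_xy(z_samples, config, center_xy)
    pts = np.column_stack([cx, cy, z_samples])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    truth = GroundTruth(
        centerline=pts,
        arc_length=arc,
        axial_position=z_samples,
        true_radius_profile=_true_radius_um(z_samples, config, cast),
        cast=cast,
        hu_params={k: v for k, v in asdict(config).items()
                   if k not in ("grid_shape",)},
    )
    return volume, truth


def write_ground_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    """Write ground truth as JSON (cast + HU params) and CSV (profiles)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"cast": asdict(truth.cast), "hu_params": truth.hu_params}
    (out / "ground_truth.json").write_text(json.dumps(meta, indent=2))
    pd.DataFrame({
        "s_mm": truth.arc_length,
        "z_mm": truth.axial_position,
        "true_radius_um": truth.true_radius_profile,
        "x_mm": truth.centerline[:, 0],
        "y_mm": truth.centerline[:, 1],
        "z_center_mm": truth.centerline[:, 2],
    }).to_csv(out / "ground_truth.csv", index=False)


def read_ground_truth(out_dir: str | Path) -> GroundTruth:
    out = Path(out_dir)
    meta = json.loads((out / "ground_truth.json").read_text())
    df = pd.read_csv(out / "ground_truth.csv")
    return GroundTruth(
        centerline=df[["x_mm", "y_mm", "z_center_mm"]].to_numpy(),
        arc_length=df["s_mm"].to_numpy(),
        axial_position=df["z_mm"].to_numpy(),
        true_radius_profile=df["true_radius_um"].to_numpy(),
        cast=CastSpec(**meta["cast"]),
        hu_params=meta["hu_params"],
    )
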