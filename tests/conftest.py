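"""Shared fixtures.

The default phantom and its segmentations are expensive (minutes), so they
are built once per session and shared by the accuracy, bias and
reproducibility tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from castseg.centerline import CrossSection
from castseg.phantom import CastSpec, PhantomConfig, generate_phantom
from castseg.pipeline import segment_phantom

PHANTOM_SEED = 1


@pytest.fixture(scope="session")
def default_phantom():
    """Default HU-calibrated phantom (fixed seed) with ground truth."""
    return generate_phantom(PhantomConfig(seed=PHANTOM_SEED), CastSpec())


@pytest.fixture(scope="session")
def local_seg(default_phantom):
    volume, truth = default_phantom
    return segment_phantom(volume, truth, mode="local")


@pytest.fixture(scope="session")
def global_seg(default_phantom):
    volume, truth = default_phantom
    return segment_phantom(volume, truth, mode="global")


@pytest.fixture(scope="session")
def repro_result(default_phantom):
    """Two local-mode segmentations from independently jittered contours."""
    from castseg.pipeline import reproducibility_experiment
    volume, truth = default_phantom
    return reproducibility_experiment(volume, truth, jitter_seeds=(101, 202))


@pytest.fixture(scope="session")
def small_phantom_config():
    """Fast phantom for pipeline smoke tests: coarse grid, no curvature."""
    cast = CastSpec(cast_outer_diameter=1000.0, cast_start_s=1.8)
    cfg = PhantomConfig(grid_shape=(64, 64, 120), supersample=2,
                        centerline_curvature_amplitude=0.0, seed=7)
    return cfg, cast


def make_disk_section(radius_um: float = 200.0, lumen_hu: float = 339.0,
                      background_hu: float = 53.0, spacing_mm: float = 0.01,
                      half_width_mm: float = 0.5,
                      edge_width_um: float | None = None) -> CrossSection:
    """Analytic disk image: value = background + contrast × coverage.

    Coverage falls linearly across an edge of one pixel width (or
    ``edge_width_um``), so the midway threshold crossing sits exactly at
    ``radius_um`` — a closed-form oracle for boundary refinement.
    """
    n = int(round(2 * half_width_mm / spacing_mm)) + 1
    coord = (np.arange(n) * spacing_mm - half_width_mm) * 1000.0
    rho = np.hypot(coord[:, None], coord[None, :])
    w = edge_width_um if edge_width_um is not None else spacing_mm * 1000.0
    coverage = np.clip((radius_um - rho) / w + 0.5, 0.0, 1.0)
    img = background_hu + (lumen_hu - background_hu) * coverage
    return CrossSection(image=img, spacing=spacing_mm, origin=np.zeros(3),
                        u=np.array([1.0, 0.0, 0.0]), v=np.array([0.0, 1.0, 0.0]),
                        s=0.0, half_width=half_width_mm)
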