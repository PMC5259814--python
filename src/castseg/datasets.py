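"""Published per-animal measurements for the eXIA 160 / carotid-cast protocol.

Reference values from the eight-mouse ApoE−/− cohort in which a tapering
cast (400→200 µm over 1.5 mm) was placed around the right common carotid
artery and contrast-enhanced micro-CT was acquired with eXIA 160.  These
per-animal summaries (region contrast statistics, inlet flow rates and
inlet wall shear stress) serve as calibration inputs for the phantom and as
inputs to the cohort report functions.

Contrast statistics are per-animal means ± SD in HU over the lumen and
background regions, split by non-cast / cast segments.  Flow rates are
mm³/s, WSS in Pa; animal 3 has no usable Doppler data (NaN).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["exia160_contrast_table", "inlet_flow_table",
           "WORKED_EXAMPLE_LUMEN_HU", "WORKED_EXAMPLE_BACKGROUND_HU"]

# Single-animal worked example: lumen and background region intensities.
WORKED_EXAMPLE_LUMEN_HU = 330.0
WORKED_EXAMPLE_BACKGROUND_HU = 41.0

# columns: per-animal mean (m) and SD (sd); regions: noncast / cast;
# quantities: lumen, background, contrast difference
_CONTRAST_ROWS = [
    # mouse, nc_lum, nc_lum_sd, nc_bg, nc_bg_sd, nc_diff, nc_diff_sd,
    #        c_lum,  c_lum_sd,  c_bg,  c_bg_sd,  c_diff,  c_diff_sd
    (1, 428, 58, 95, 36, 323, 61, 325, 90,  -47, 51, 372, 124),
    (2, 372, 35, 76, 42, 296, 47, 299, 47,  -93, 47, 392, 87),
    (3, 286, 41, 32, 54, 254, 45, 199, 54, -169, 33, 368, 65),
    (4, 328, 49, 67, 40, 261, 41, 247, 62,  -93, 33, 340, 71),
    (5, 330, 38, 41, 31, 289, 34, 241, 53, -135, 45, 376, 85),
    (6, 281, 33, 41, 29, 240, 39, 191, 71,  -96, 56, 287, 111),
    (7, 306, 33, 42, 35, 264, 45, 255, 67,  -46, 39, 301, 98),
    (8, 383, 65, 31, 36, 352, 67, 299, 90, -100, 49, 399, 128),
]

_FLOW_ROWS = [
    # mouse, mean flow mm³/s, flow sd, inlet WSS Pa, WSS sd
    (1, 25.8, 0.2, 5.0, 0.6),
    (2, 15.5, 0.1, 2.5, 0.5),
    (3, np.nan, np.nan, np.nan, np.nan),
    (4, 13.7, 0.2, 1.8, 0.2),
    (5, 9.4, 0.2, 1.6, 0.2),
    (6, 20.2, 0.2, 3.3, 0.2),
    (7, 39.0, 0.4, 6.4, 0.1),
    (8, 14.8, 0.2, 2.2, 0.1),
]


def exia160_contrast_table() -> pd.DataFrame:
    """Per-animal contrast statistics (HU), indexed by mouse number."""
    cols = ["noncast_lumen", "noncast_lumen_sd",
            "noncast_background", "noncast_background_sd",
            "noncast_contrast", "noncast_contrast_sd",
            "cast_lumen", "cast_lumen_sd",
            "cast_background", "cast_background_sd",
            "cast_contrast", "cast_contrast_sd"]
    df = pd.DataFrame([r[1:] for r in _CONTRAST_ROWS], columns=cols,
                      index=pd.Index([r[0] for r in _CONTRAST_ROWS],
                                     name="mouse"))
    return df.astype(float)


def inlet_flow_table() -> pd.DataFrame:
    """Per-animal inlet flow rate (mm³/s) and inlet WSS (Pa)."""
    cols = ["flow_mm3_s", "flow_sd", "wss_pa", "wss_sd"]
    return pd.DataFrame([r[1:] for r in _FLOW_ROWS], columns=cols,
                        index=pd.Index([r[0] for r in _FLOW_ROWS],
                                       name="mouse")).astype(float)
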