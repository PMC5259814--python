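# castseg

Local-threshold lumen segmentation and wall-shear-stress (WSS) analysis for
cast-constricted murine carotid arteries imaged with contrast-enhanced
micro-CT.

## The problem

To study how WSS drives atherosclerosis, a rigid tapering cast (inner
diameter 400 → 200 µm over 1.5 mm) is placed around the right common
carotid artery (RCCA) of ApoE⁻/⁻ mice, imposing defined shear patterns.
Computing WSS requires the 3D lumen geometry from contrast-enhanced
micro-CT (40 µm cubic voxels) — but the blood-pool contrast signal drops
inside the cast and fluctuates along the vessel, so a single global
threshold badly underestimates the narrowed lumen exactly where the
hemodynamics are most interesting.

`castseg` implements the local midway-threshold protocol. For each
cross-sectional contour along the centerline, a lumen region (contour
shrunk by 20 %) and a background region (the 20–40 % expansion annulus)
give mean intensities L_i and B_i; the local threshold is the midway value

    T_i = (L_i + B_i) / 2,

and the conventional global comparator is T_g = mean(T_i). Contours are
refined to the sub-pixel threshold crossing by ray casting, lofted into a
watertight surface (volume-preserving Taubin smoothing, flow extensions of
5× the end radius), and WSS metrics are computed with a quasi-1D
Poiseuille model, τ(s,t) = 4µQ(t)/(πr(s)³), with

    TAWSS(s) = (1/T) ∫₀ᵀ |τ| dt,    OSI(s) = ½ (1 − |∫₀ᵀ τ dt| / ∫₀ᵀ |τ| dt),

using blood viscosity µ = 3.5×10⁻³ kg/m/s and density ρ = 1060 kg/m³.

Because no image data from the original cohort is public, the package
ships a synthetic phantom generator calibrated to the cohort's published
Hounsfield statistics (lumen 339/257 HU outside/inside the cast,
soft tissue 53 HU, cast −97 HU, noise, axial fluctuation, partial-volume
blur) with known ground truth, so the whole pipeline is testable end to
end. See `docs/methods.md` for the model details and limitations.

## Worked example

Generate a small phantom, segment it with local thresholds, and compare
the recovered geometry with the known cast:

```bash
cat > small.json <<'EOF'
{"phantom": {"grid_shape": [64,64,120], "supersample": 2,
             "centerline_curvature_amplitude": 0.0},
 "cast": {"cast_outer_diameter": 1000.0, "cast_start_s": 1.8},
 "segmentation": {"margin_mm": 0.4}}
EOF
castseg run --config small.json --seed 3 --out run/
cat run/geometry.json run/hemodynamics.json
```

prints (abridged):

```
{
  "cast_undersizing_pct_mean": 7.01,
  "wall_thickness_um_mean": 9.88,
  "surface_volume_mm3": 0.9996,
  "watertight": true
}
{
  "mean_flow_mm3_s": 19.65,
  "inlet_radius_um": 247.6,
  "reynolds": 15.3
}
```

Reading these numbers: the segmented lumen inside the cast is on average
7 % smaller than the cast's inner bore — the gap is the vessel wall, here
read as ~9.9 µm per side against a constructed truth of 13.5 µm (the
midway threshold has a small outward bias at the lumen|wall|cast edge;
`docs/methods.md` explains why). The lofted surface is watertight, the
synthetic Doppler-derived inlet flow is ~19.7 mm³/s — the scale of the
published cohort average — and the inlet Reynolds number of ~15 confirms
a viscous-dominated regime. Running `castseg compare` on the same volume
shows the global threshold underestimating the cast-region lumen more
than twice as badly as the local method (16.1 % vs 7.0 %,
wall-thickness t-test p ≈ 10⁻³²), the failure mode the local protocol
removes. The per-slice TAWSS/OSI table lands in
`run/wss_summary.csv` (upstream TAWSS ≈ 6 Pa, OSI 0 without flow
reversal).

The same steps are available as library calls (`castseg.phantom`,
`castseg.segmentation`, `castseg.geometry`, `castseg.hemodynamics`,
`castseg.pipeline`) and as separate subcommands (`castseg phantom`,
`segment`, `geometry`, `hemo`, `compare`); `castseg config` prints every
default.

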