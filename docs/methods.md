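# Methods

## Problem and approach

Wall shear stress (WSS) patterns in the mouse carotid are studied with a
rigid tapering cast cuff placed around the right common carotid artery
(RCCA): the taper (inner diameter 400 → 200 µm over 1.5 mm) imposes low
shear upstream and oscillatory shear downstream. Computing WSS requires an
accurate 3D lumen geometry, reconstructed from contrast-enhanced micro-CT
at 40 µm cubic voxels. The difficulty is that the contrast signal is not
stationary along the vessel: blood HU drops inside the cast (less blood
volume, less contrast agent) and fluctuates axially, so a single global
threshold mis-places the lumen boundary exactly where geometry matters
most — in the narrowed cast segment.

`castseg` implements the local midway-threshold protocol: per-contour
lumen/background region statistics, local thresholds
T_i = (L_i + B_i)/2, a global comparator T_g = mean(T_i), sub-pixel
boundary refinement, surface building, and a quasi-1D WSS model. Because
no image data from the original cohort is deposited, the pipeline is
exercised on a synthetic phantom calibrated to the cohort's published HU
statistics, with known ground truth.

## Phantom

The phantom is a piecewise-constant tissue model sampled onto a
160×160×300 grid of 40 µm cubic voxels (6.4×6.4×12 mm — the RCCA region of
interest, not the scanner's full 512³ field of view, to keep runs fast):

* lumen: 339 HU outside the cast, 257 HU inside (the cohort-average
  values), modulated by a sinusoidal axial fluctuation of amplitude 10 % of
  the lumen–background contrast with period 1.5 mm, standing in for the
  axial signal fluctuation seen along real vessels;
* soft-tissue background: 53 HU;
* cast annulus: −97 HU, inner surface tapering 400 → 200 µm over 1.5 mm,
  outer diameter 1400 µm (wide enough that the background annulus of every
  in-cast contour samples cast material, as in the real images);
* vessel wall inside the cast: 13.5 µm of soft tissue between lumen and
  cast (the cohort's reported in-cast wall thickness), so true lumen
  diameter = cast inner diameter − 27 µm;
* non-cast lumen radius 250 µm (typical murine common carotid; not
  reported by the cohort);
* a gentle in-plane sinusoidal centerline curvature (amplitude 200 µm,
  period 8 mm) so cross-sections are genuinely oblique to the grid.

Partial volume is modeled by supersample-and-average (default 3³ analytic
samples per voxel); no detector PSF is simulated. Gaussian noise
(sd 30 HU) is added after averaging and values are rounded to int16.
Everything is deterministic given the seed.

Two modeling choices were open:

* **Taper transition.** The outside-cast radius (250 µm) and the in-cast
  entry radius (186.5 µm) differ; a vessel entering a cuff necks down
  smoothly, so the truth radius blends linearly over 0.3 mm on each side
  of the cast. This keeps the truth profile continuous; the steepest part
  of the true geometry is therefore the exit blend (~545 µm/mm).
* **Arc length vs axial position.** The phantom's radius/HU profiles are
  parameterized by the axial coordinate z; with the default curvature the
  relative difference between z and true arc length is < 0.1 %. Consumers
  that index segmentations by fitted-centerline arc length map back to z
  through the ground-truth arc table before comparing against the cast.

What the phantom does **not** emulate: beam hardening, ring artifacts,
contrast pharmacokinetics, plaque, bifurcations, non-circular lumen
cross-sections. Passing tests therefore show that the thresholding logic
and its biases behave as designed under realistic intensity statistics —
not that the pipeline handles every artifact of real scans.

## Segmentation

The centerline is a cubic spline through ordered (in practice manually
picked; for the phantom, subsampled ground-truth) center points, resampled
at uniform arc length (default 40 µm = one voxel, the slice spacing along
the vessel) with rotation-minimizing (double-reflection) frames — Frenet
frames are undefined on straight segments. Cross-sections are sampled by
trilinear interpolation on planes perpendicular to the tangent (10 µm
in-plane spacing, 1 mm half-width). The original protocol traces borders
on longitudinal planes at three rotations (0°/60°/120°); perpendicular
planes make the radial shrink/expand regions and equivalent diameters
well defined and automatable, and carry the same information.
Longitudinal border input is still honored through the periodic-spline
contour interpolator.

Per slice, the lumen region is the current contour shrunk to 0.8× and the
background region the 1.2–1.4× annulus (20 % of the 5-pixel distal lumen
is one pixel, which is the rationale for the 20 % figures). Region means
give T_i and, averaged, T_g. Boundary refinement casts 72 rays (5°
resolution) from the centerline point, samples the plane at quarter-pixel
steps, and takes the first crossing below the threshold with linear
sub-pixel interpolation; the refined radial function is low-passed by
periodic Fourier truncation at 8 harmonics to remove single-ray noise
spikes. Rays without a crossing are filled by periodic interpolation
across angle unless more than 10 % fail, in which case the slice errors
(lumen not closed). The on-lumen precondition for the ray origin is
evaluated on a one-pixel neighbourhood mean, so a single noisy pixel
cannot abort a slice. Slices whose plane or background annulus leaves the
volume, or whose refinement fails, are dropped with a WARN log entry.

**Iteration.** Starting from automated circular contours (the stand-in for
manual initial border placement), the region statistics of the first pass
are computed from wrong regions wherever the circle is far from the true
boundary (most severely inside the cast, where a 250 µm circle spans
lumen, wall and cast material). The region → threshold → refine loop is
therefore iterated, re-deriving regions from the refined contours, until
the maximum radial change falls below one tenth of a voxel (4 µm); with
default settings this converges in 4–5 passes and the cap is 10. A single
pass is appropriate only when the initial contours are already
near-correct, as with careful manual placement.

**Known bias.** At a two-material edge (lumen/soft tissue) the midway
threshold bisects the partial-volume ramp and the refined boundary is
unbiased. Inside the cast the edge is three-material — lumen, a sub-voxel
53 HU wall, then −97 HU cast — while B_i is measured in the cast annulus;
the midway value (≈ 80 HU) then sits below the half-way intensity of the
physical lumen edge, displacing the boundary outward by ~5 µm at 40 µm
voxels. Consequently the recovered in-cast wall thickness underestimates
the constructed 13.5 µm truth by a few µm (typically 11 ± 1.5 µm on the
default phantom), and the same mechanism applies to measurements on real
images. The equivalent-area diameter (2·√(A/π)) is used for all
single-number diameters because it is rotation-invariant.

## Geometry

Contours are lofted in their transported frames into a watertight
triangulated surface (quad strips split into triangles, fan caps to the
end-ring centroids). Smoothing is Taubin band-pass (λ = 0.5, µ = −0.53,
20 passes, uniform umbrella Laplacian) with the end rings and cap apexes
pinned so the inlet/outlet planes stay planar; parameters sit in the
standard stability band of the shrink/inflate alternation. The iteration
must not drift the enclosed volume by more than 1 % (else it errors,
advising parameter reduction); the small residual drift is removed exactly
by an isotropic rescale about the volume centroid, making the smoothing
volume-preserving by construction. Flow extensions extrude each end
contour along the end tangent for 5× the end's equivalent radius, giving
the flow room to develop before the region of interest.

## Hemodynamics

The inlet waveform comes from a Doppler velocity trace: consecutive
cardiac cycles are detected peak-to-peak, resampled to a 100-point phase
grid, ensemble-averaged (default 5 cycles) and low-passed by Fourier
truncation at 8 harmonics. Doppler velocity is interpreted as the
centerline peak of a parabolic profile, Q = (U/2)·πr² (plug flow, Q =
U·πr², is selectable); the conversion convention is not fixed by the
measurement itself. Blood is Newtonian with µ = 3.5×10⁻³ kg/m/s and
ρ = 1060 kg/m³.

WSS along the vessel uses the quasi-1D Poiseuille surrogate
τ(s,t) = 4µQ(t)/(πr(s)³), signed with Q. At the Reynolds numbers of the
murine carotid (Re = 4ρQ/(πµD) ≈ 15 at the cohort-average flow and a
500 µm inlet; the flow regime is viscous-dominated) the axial TAWSS
distribution is captured well away from the cast exit, but the surrogate
cannot reproduce the asymmetric exit jet, downstream recirculation, or
any secondary flow — those require a 3D transient solver, and the module
accepts externally computed τ(s,t) tables so TAWSS/OSI post-processing is
solver-agnostic. The Womersley (pulsatility) correction is omitted: at
murine heart rates and r ≈ 250 µm the Womersley number is small; this is
a documented limitation, and a flag is reserved for it.

TAWSS(s) = (1/T)∫|τ|dt and OSI(s) = ½(1 − |∫τ dt|/∫|τ|dt) are evaluated
by trapezoidal quadrature on the closed periodic grid; OSI is defined as
0 where ∫|τ|dt vanishes and is clipped to [0, 0.5].

## Numerical conventions

* World coordinates mm; radii and HU-plane coordinates µm; WSS Pa;
  flow mm³/s. Voxels are node-centered, indices 0-based, volumes stored
  as int16 HU.
* Contours are radial functions r(θ) at K = 72 uniform angles; polygon
  (shoelace) area defines A(s). A 72-gon underestimates a circle's area
  by the fixed factor sin(2π/K)/(2π/K) ≈ 0.13 %, below every tolerance
  used.
* Cross-slice aggregates of contrast difference average the per-slice
  C_i = L_i − B_i values; cross-animal aggregates average per-animal
  summaries with sample SD (ddof = 1).
* Per-animal published tables retain their printed precision; missing
  entries (one animal's Doppler data) are excluded pairwise.

## Problem sizes in the shipped tests

The test suite and the acceptance script regenerate everything they
measure: the default 160×160×300 phantom is built once per session and
segmented in local and global modes plus twice more from ±15 %-jittered
initial contours for the reproducibility experiment; smoke tests of the
full pipeline use a coarser 64×64×120 phantom. These sizes were chosen so
the whole suite completes in a few minutes on one CPU while keeping the
distal cast lumen at its physically meaningful ~5-voxel diameter.

## Known limitations

* Star-convex lumens only: ray-cast refinement flags but does not handle
  non-star-convex cross-sections (out of scope, as are bifurcations).
* The midway-threshold outward bias at three-material edges (above) is
  inherent to the protocol, not corrected.
* The Poiseuille surrogate's validity ends at the cast exit jet; OSI from
  the surrogate is 0 wherever flow never reverses.
* The phantom's fluctuation model is a fixed-period sinusoid; the spatial
  correlation of the real fluctuation is unknown.
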