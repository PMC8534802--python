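# Methods

This note documents the models, numerical choices and synthetic study
conditions behind `aortoflow`, in the order the analysis stages use them.

## Study design

Blood flow through a descending-aorta analogue is simulated for eight
cases crossing three factors: wall configuration (dissected — an intimal
flap separating a true and a false lumen — vs. repaired, the same outline
without the flap), hematocrit (Hct = 0.40, the clinically measured value,
vs. 0.50, emulating increased flow resistance), and inlet intensity (the
measured "real" waveform vs. a "high" waveform at 1.5× its amplitude).
All other settings are identical across cases, so paired differences
isolate the factor effects. Verification artefacts — phantom images for
the segmentation stage and paired pseudo-Doppler flows for the agreement
stage — are generated synthetically; no external data are used.

## Synthetic angio-CT phantoms and segmentation QC

The phantom is a straight contrast-filled lumen (radius 10 mm) on a
darker soft-tissue background, sampled on a 64×64×40 grid at
0.78×0.78×1 mm voxels, with iid Gaussian noise. Intensities use an
8-bit-like arbitrary scale. The default regime (object 100,
background 87, noise SD 3.59) reproduces the two ROI image-quality
statistics of clinical angio-CT simultaneously: brightness-to-noise
BI = object mean / noise ≈ 27.9 and contrast-to-noise
CNR = (object − background) / noise ≈ 3.6. Noise is defined as the SD of
two 100 mm² background ROIs (left and right), averaged; the object ROI
(94 mm² by default) sits at the lumen centre; all metrics are computed
per slice and averaged.

Segmentation is seeded region growing (6-connectivity) inside the window
`I(seed) ± tolerance`, followed by per-slice morphological hole filling
(2-D, 4-connectivity). Two protocol choices matter at this low contrast
(the object–background separation is only ≈3.6 noise SDs):

* **Seed selection.** The seed voxel is the one nearest the local median
  intensity in a 5×5×5 neighbourhood of the lumen centre, so a single
  noisy voxel cannot shift the window.
* **Tolerance.** The default is the *half-contrast rule*,
  `tolerance = (object − background)/2`, which places the window edge at
  the midpoint between the class means — the same operating point a
  two-class intensity threshold would choose. Any tolerance that admits
  the background mean into the window (here, anything ≳ 2× the
  half-contrast) makes a connected-threshold grower flood the whole
  volume, so tolerances of that order are not meaningful at this regime.

Scattered interior voxels missed by the window are recovered by hole
filling; the residual error is surface-localized. Over ten phantoms the
maximum volume error against the ground-truth mask is ≈1%, well inside
the 5% radiologist-agreement bound used as the acceptance gate. The
phantom does not emulate contrast-bolus dynamics, partial-volume blur,
beam hardening or anatomical curvature, so the QC result shows the
algorithm's behaviour at the stated contrast/noise operating point, not
clinical segmentation accuracy.

## Blood rheology

Blood is a generalized Newtonian fluid with the Quemada closure

    mu(γ) = mu_p (1 − K(γ) f(Hct))⁻²,
    K(γ)  = (k0 + k∞ √(γ/γc)) / (1 + √(γ/γc)),

with density ρ = 1040 kg/m³. Two readings of the hematocrit factor are
implemented behind a switch: `printed` (f = Hct², the default) and
`classic` (f = Hct/2, the classical Quemada form). Parameters not fixed
by the study are standard literature values for mid-range hematocrit:
k0 = 4.33, k∞ = 2.07, γc = 1.88 s⁻¹, mu_p = 1.32 mPa·s, all configurable
and logged.

A shear-rate floor regularizes stagnant zones. With the parameters
above, the printed form diverges (1 − K·Hct² ≤ 0) below γ ≈ 0.06 s⁻¹ at
Hct = 0.50, so the floor must sit above that; the default is
γ_floor = 0.5 s⁻¹ (K ≈ 3.56, denominator 0.11, mu ≈ 0.11 Pa·s), checked
at construction so inadmissible (Hct, floor) combinations fail fast.
The floor only binds in near-stagnant recirculation cores; wall shear
rates in all simulated cases are orders of magnitude above it.

## Geometry and meshing

The domain is a 2-D planar channel (unit depth), 12 cm long and 3 cm
wide: inlet on the left, distal outlet on the right, and two branch
outlets (visceral and renal analogues, 8 and 7 mm wide at x = 4.5 and
7.5 cm) opening through the true-lumen wall. Dissected cases insert a
1.2 mm intimal flap from x = 3 to 10 cm at half depth, interrupted by a
proximal entry tear (8 mm at x = 3.8 cm) and a distal tear (7 mm at
x = 8.8 cm). The flap attaches to the outer wall at its proximal end
(the false lumen is a pouch fed only through the tears and the open
distal end), which reproduces the characteristic slow recirculating
false-lumen flow adjacent to the entry tear. The 3-D, curved,
multi-branch anatomy of a real aorta is deliberately out of scope; the
2-D analogue preserves the factorial's physics (pulsatile shear-thinning
flow, lumen competition, tear jets) at desk scale.

Channel width (3 cm) and the "real" mean inlet velocity (0.06 m/s) were
chosen together so that (a) the start-up transient's viscous time
constant h²/(π²ν) ≈ 30 s makes successive late cycles differ by well
under 1% of peak velocity — the condition under which a 3-cycle discard
is defensible — and (b) the peak Reynolds number of the high-intensity
waveform stays below the 2300 laminar threshold (measured peak Re ≈ 900
with the Hct-0.40 viscosity at the 100 s⁻¹ reference shear).

Meshing is a tensor-product rectilinear grid: uniform axial spacing at
the bulk size with grid lines snapped exactly to outlet edges, flap ends
and tear edges; wall-normal spacing graded geometrically from every wall
(first layer, expansion ratio 1.15, five layers by default) including
both flap faces, with the flap itself blocked as solid rows. Boundary
layer audit: the first five rows follow `t·r^(k−1)` exactly
(e.g. 0.1 mm/1.15 → 0.674 mm total depth). The verification meshes use
the 0.1 mm first layer; the factorial cases use 0.25 mm, a desk-scale
resolution choice that still places ≈4 cells across the ≈1 mm Stokes
layer. The surface outline is exportable as a watertight binary STL
(rectilinear decomposition, extruded 1 cm).

## Flow solver

Incompressible laminar Navier–Stokes on a staggered (MAC) grid with an
incremental pressure-correction (projection) scheme, first order in
time:

1. apparent viscosity per cell from the previous step's shear-rate field
   (Picard lagging), γ = √(2 D:D) with D from the wall-aware discrete
   gradient;
2. momentum predictor: explicit first-order upwind advection, explicit
   old-pressure gradient, implicit (backward-Euler) variable-viscosity
   diffusion — solved as narrow-banded systems by LAPACK;
3. pressure-increment Poisson solve (direct sparse factorization, built
   once per mesh) with Dirichlet pressure on outlet faces, homogeneous
   Neumann elsewhere;
4. velocity correction and pressure accumulation.

The incremental form matters: without the old-pressure gradient in the
predictor, the projection's O(dt) wall-slip error (≈ dt·|∇p|/ρ) reaches
~10% of the first-cell velocity at the steady-solver step sizes and
corrupts WSS. With it, the steady channel benchmark reproduces the
Poiseuille centerline within 0.9% and the analytic wall shear stress
6·mu·U/h within 2.1% on the default grid (0.2%/0.5% refined).

Boundary conditions: velocity inlet (plug profile for the cases,
parabolic for the channel benchmark) scaled by a raised-cosine-systole
waveform (systole occupies 35% of the 1 s cycle, peak/mean = 2.5, the
"high" label scales the whole waveform by 1.5); fixed static gauge
pressure with zero tangential stress at outlets (distal 0 Pa; branch
outlets −1.5 Pa so they carry a ≈25% resting flow share, mirroring
per-vessel outlet pressures); no-slip rigid walls everywhere else.
Walls are rigid and the fluid incompressible by construction.

Time stepping uses fixed 1 ms macro steps (phases therefore align
exactly across cycles) with CFL-limited substeps inside each macro step:
the substep count is chosen to keep the advective Courant number near
0.6, re-evaluated as the field evolves. The primitive `step` refuses any
step whose Courant number exceeds 0.9. After every projection the
discrete per-cell divergence is ≤10⁻⁸ relative (direct solves leave
~10⁻¹²) and global outlet-vs-inlet imbalance is ≤0.5% (measured ~10⁻¹³).

The cycle protocol runs five 1 s cycles from a quiescent start and
discards the first three. The per-cycle convergence metric is the RMS
phase-matched velocity difference between successive cycles normalized
by the peak velocity; on the default cases cycle-4 vs cycle-5 is below
0.3%, supporting the discard rule. Snapshots are phase-addressable, so
any in-cycle display time can be requested.

## Post-processing

Wall shear stress is reported as a magnitude, mu_w·|u_t|/d, per wall
face, with u_t the tangential cell-centre velocity, d the half-cell
distance to the wall and mu_w the Quemada viscosity at the wall shear
rate; the same gradient operator feeds the solver's viscosity update and
the reported shear-rate maps, so the two are identical by construction.
Outlet flows are face-flux integrals per unit depth; mL/s values use a
nominal 1 cm out-of-plane depth (logged). Per-case summaries aggregate
the retained snapshots: cycle-mean outlet flows, peak velocity and its
location, area-weighted mean WSS per wall region and overall, viscosity
statistics, and — for dissected cases — the false-lumen share of axial
flux at the flap midpoint. The tear-adjacency metric is the ratio of
peak-systole WSS within one tear length of a tear edge to the median
WSS on walls more than three tear lengths from every tear (three, not
more, because the 12 cm vessel offers no wall farther than ~5 tear
lengths from both tears).

## Verification statistics

Bland–Altman: d = a − b, bias = mean(d), SD with the n−1 denominator,
limits bias ± 1.96·SD; both the difference span and the pair-mean span
are reported because published "range" figures can refer to either.
Student's test: Shapiro–Wilk on each sample and a two-sided F-test on
the variance ratio (α = 0.05, configurable) select the pooled- or
Welch-variant two-sided t-test; constant samples force the Welch path.
No multiple-testing correction is applied; reports carry the number of
comparisons. The factorial's verification pairs each case/outlet
cycle-mean CFD flow with a pseudo-Doppler value of controlled bias and
spread (default bias 0, SD 0.05 mL/s, seeded).

## Directional findings and a known limitation

On the matched factorial the dissected cases show lower distal
velocities (the steeper true-lumen pressure gradient diverts flow to the
branch outlets) and higher mean WSS (halved lumen width, tear jets) than
repaired cases in all four pairs; tear-adjacent WSS exceeds twice the
remote-wall median; raising Hct raises viscosity everywhere.

One reported direction is *not* reproduced: higher hematocrit does not
lower the cycle-mean WSS here. With a prescribed inlet flux in a rigid
channel, the wall traction integrates the axial pressure gradient, which
rises with apparent viscosity for any generalized-Newtonian closure
(∝ mu in the steady limit, ∝ √(ρ·mu·ω) in the high-Womersley limit), and
the factorial measures exactly that increase. Reproducing a WSS decrease
with Hct would require mechanisms outside this model class — patient-
specific inflow differences, compliant walls, or 3-D secondary-flow
suppression — so the corresponding acceptance check fails by design of
the physics, and is retained as an honest negative.

## Problem sizes

Phantoms 64×64×40 voxels (ten per QC run); factorial meshes ≈60×35
cells (≈1300–2000 fluid cells), five 1 s cycles at 1 ms macro steps;
channel benchmarks ≈950 and ≈2900 cells. These sizes are the package's
desk-scale operating point: every acceptance property they probe
(conservation, convergence order, sign structure) is resolution-checked
rather than resolution-tuned.
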