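# Methods

## Force sensing model

The specimen sits between two cantilevers: a stationary ("fixed") arm and
an actuator-driven ("moving") arm.  Compression is quasi-static — the
actuation steps are slow enough that viscous forces in the tissue are
neglected and every element is a linear spring.  Force balance at the
fixed tip reads `F cos θ1 = k_c1 d_c1`: `d_c1` is the tip deflection
(the fixed arm's base does not move, so tip motion equals bending) and
`θ1` the angle between the cantilever and the local sample tangent.  The
specimen is modelled as two equal springs of constant `k_s` in series,
one per contact, so with the total indentation `D_s = d_s1 + d_s2` the
balanced forces give `k_s D_s = 2F` and

    k_s = 2 k_c1 d_c1 / (D_s cos θ1).

Only the fixed arm's deflection is required.  When the moving arm's
deflection and angle are also supplied, the two single-arm estimates are
both computed and their relative discrepancy is reported as a quality
metric — in a well-aligned experiment it should be small.

Units: the laboratory-facing API takes millimetres and converts to SI
(m, N, Pa) exactly once at ingest.  Compressive strain is positive,
`strain = (L_ref − L_now)/L_ref`, matching the sign of indentation.

### Beam spring constants

`k = E W T^3 / (4 L^3)` for a tip-loaded rectangular beam
(`I = W T^3/12`).  Slender-beam theory degrades for stubby beams, so
`L/T < 5` warns rather than errors.  The inversion
`E = 4 k L^3/(W T^3)` round-trips to machine precision and is the basis
of the reference-material check (0.151 N/m with 20×1×0.13 mm gives
2.20 GPa).

### Degenerate steps

Steps with `D_s` at or below a floor (default one pixel-equivalent in
mm, configurable) are flagged and excluded rather than allowed to
produce exploding `k_s` from a near-zero denominator.  The first step of
a series is the zero-indentation reference and is flagged by
construction; it does not demote a run to "partial".

## Tracking

The matcher is the plain cosine similarity: the tile (default 50×50 px)
is flattened and L2-normalised, every integer placement inside the scan
window (default 100×100 px, centred on the previous match and clipped at
frame borders) is normalised the same way, and the placement with the
maximum dot product wins; ties go to the first occurrence in row-major
order.  No mean subtraction is applied by default — cosine similarity is
brightness-offset sensitive, and a zero-mean NCC variant is available
behind a flag.  Candidate norms come from an integral image; degenerate
(all-zero) candidates are skipped, and an all-degenerate window returns
a flagged zero-score result instead of raising.  Matching is strictly
integer-pixel; sub-pixel interpolation is out of scope.

### Template policy

Three policies are provided, because per-frame template update and
integer matching interact badly on slow motion:

- `every_step` (library default): the matched area of each new frame
  becomes the next template.  Follows appearance change, but each step
  contributes its own rounding error `round(v) − v` for per-step motion
  `v`, and on steady sub-pixel motion the cumulative drift grows
  linearly (a ~0.7 px/step scene ratchets by ~8 px over 30 steps).
- `adaptive` (pipeline default): the template is kept while the best
  score stays above a refresh threshold (0.85) and re-cut only when the
  appearance has genuinely changed.  On slowly evolving scenes this
  anchors the track to one reference and keeps cumulative error at the
  matcher's ~0.5–1 px floor, which is what the stiffness chain needs.
- `never`: always match the step-0 template.

The derived quantities are geometric: the compression axis is the unit
vector between the initial contact positions; `d_c1` is the magnitude of
the fixed-tip motion projected on that axis (only axial bending does
work); `D_s` is the decrease of the along-axis contact separation,
clamped at zero.  Cantilever angles can be given as a constant, as a
per-step file, or estimated from two tiles tracked on the same beam (the
angle between their segment and the axis normal).

## Calibration

Both stages use through-origin least squares, matching the proportional
physics: the load-cell stage fits `F = k_ref δ` and reports the
uncentred `R² = 1 − SS_res/Σy²` (the standard no-intercept convention);
the transfer stage regresses `k_ref δ_ref` on `δ_c`, which equals the
per-step ratio `k_ref (δ_ref/δ_c)` exactly on noise-free data and damps
small-denominator steps otherwise.  Per-step ratios are still reported
for dispersion diagnostics, and `δ_c = 0` steps are excluded with a
warning.  Batch summaries use the sample SD (ddof = 1), with the modulus
computed per cantilever from its own dimensions before averaging.

## Synthetic scenes

The generator is the test bed for the whole chain: four springs in
series (fixed cantilever, two sample half-springs, moving cantilever)
solved exactly per step, then rendered.  With tilt, the per-arm axial
compliance is `cos θ_i / k_c_i`, chosen so that the tracked axial tip
travel is the `d_c` entering the force balance; at θ = 0 this reduces to
`F = Δ/(1/k_c1 + 1/k_c2 + 2/k_s)`.  The identities `F = k_c1 d_c1 =
k_c2 d_c2 = k_s D_s/2` and `Δ = d_c1 + d_c2 + D_s` hold to machine
precision in the ground truth.

Default conditions (chosen once as the regime the instrument targets):
two 1.48e-2 N/m working cantilevers; sample spring 5.9e-3 N/m (mid-range
of measured embryo stiffness); 30 steps of 0.01 mm closure (0.3 mm
total — roughly a third of the 0.7 mm specimen width by the final step);
964×1288 px frames at 0.002 mm/px (a 5× objective on the instrument's
CCD; the true scale is not published and this value is an assumption);
Gaussian noise with σ = 2% of the dynamic range.  A saturating
(piezo-like) closure profile is available besides the linear default.

Rendering draws two bright beams whose ends sit at the ground-truth
contact positions, a two-lobe ellipse whose width shrinks by `D_s`, a
band-limited sinusoidal speckle field rigidly attached to each tracked
landmark (continuous sub-pixel translation, so tiles are non-degenerate
and motion is not grid-locked), and a small saturated blob at each
contact whose brightest pixel marks the ground-truth tip to within a
pixel.  All randomness derives from the scene seed via independent
streams per landmark and per frame; identical seeds give byte-identical
frames and CSVs.  The renderer does not attempt photorealism: no optical
PSF, no motion blur, no internal strain field (surface-attached texture
moves rigidly with its landmark).  Consequently, passing end-to-end
tests demonstrates the correctness of the tracking-to-stiffness chain
under realistic contrast and noise, not robustness to out-of-plane
motion, deformable texture, or illumination drift in real footage.

## Modulus estimation

The inverse problem takes the measured body and yolk strains at a known
tip force and fits the two Young's moduli.  The forward surrogate
reduces the specimen to two elastic compartments loaded in parallel
between the tips with a uniform contact pressure: the force partitions
in proportion to the contact areas (defaults 0.2 mm and 0.35 mm contact
heights × 0.5 mm effective depth), every compartment sees
`σ = F/(A_body + A_yolk)`, and `strain_i = σ/E_i`.  A shared-displacement
closure was considered and rejected: it makes the two strains rigidly
proportional (`u/h_i`), so the two-observation inversion is rank-one and
the pair of moduli is not identifiable.  The uniform-pressure closure
keeps the expected physics — equal moduli with equal geometry give equal
strains, a rigid compartment's strain vanishes, strain falls
monotonically with its own modulus — and makes the inversion well posed.
The surrogate deliberately stands in for a full finite-element forward
model behind the same `parameters → strains` interface; absolute moduli
fitted through it on real data are not claimed to match a 3-D FEM fit.
The 170 Pa / 48 Pa body/yolk pair is used as the canonical
parameter-recovery fixture, not as a validated tissue result.

The optimizer is coordinate-wise hill climbing: evaluate ± the current
step on each parameter, accept the single best improving move, shrink
all steps by 0.5 when nothing improves, stop when every step is below
tolerance (1e-7 decades) or at the iteration cap.  It runs in log10
modulus space (positivity for free; moduli span decades) from 100 Pa
with half-decade initial steps and bounds of 1e-3–1e12 Pa.  It is
deterministic, never accepts a worsening move, and logs the full
accepted-state trace.  On the noise-free surrogate it recovers random
modulus pairs over three decades to better than 1%.

## Pipeline

One YAML config describes a run: frame source (multi-page TIFF or glob),
scale, initial tiles, cantilever (either `k` or modulus-plus-dimensions),
the θ source (exactly one of fixed / file / estimated), an optional
contact-start step, template policy, indentation floor, and an optional
covariate for the stiffness trend fit (through-origin for calibration
lines, intercept-included for stiffness-vs-time).  Outputs: per-tile
track CSVs, the per-step deflection/stiffness CSV with quality flags, a
summary JSON (`ks_mean` over usable steps and `ks_fit`, the
through-origin regression of `2F` on `D_s`, which weights the
well-resolved large-indentation steps), and a step-granular log.  Exit
codes: 0 clean, 2 partial (flagged steps or truncated tracks), 1
failure.

## Problem sizes

Unit tests run on compact scenes (400×500 px, 8–12 steps); the
system-level suite exercises the full default scene (964×1288 px,
30 steps) at three sample stiffnesses spanning 25×, the 100-case
matcher-vs-brute-force sweep, and the 100-pair modulus recovery.

## Known limitations

- Integer-pixel tracking bounds single-step displacement resolution at
  half a pixel; with the `every_step` template policy this becomes a
  systematic ratchet on steady sub-pixel motion (see Template policy).
- Linear elasticity throughout: no viscoelasticity, no large-deflection
  beam theory, no contact mechanics beyond the two-spring sample model.
- The two-compartment surrogate is a deliberately coarse forward model;
  plugging in a genuine FEM adapter changes only the forward call.
- The scene renderer validates the algorithms, not the optics of any
  particular microscope.
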