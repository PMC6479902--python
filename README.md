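# microtweezer

Image-based force sensing for micro-mesoscale soft specimens (hundreds of
micrometres to a millimetre — embryos, spheroids, organoids) squeezed
between a pair of compliant cantilever "chopsticks".  Neither cantilever
carries a strain gauge: both arms are watched by a microscope camera, and
every mechanical quantity is obtained by tracking small image tiles
through the stepped compression sequence.  The package provides the full
chain a lab would run:

1. **tracking** — a normalized-dot-product (cosine similarity) tile
   matcher that follows the cantilever tips and the specimen contact
   points through the frame stack, integer-pixel, exhaustive within a
   scan window;
2. **mechanics** — rectangular-beam spring constants and the conversion
   of tracked deflections into force, sample stiffness and strain;
3. **calibration** — the two-stage spring-constant chain (load cell →
   stiff reference cantilever → soft working cantilever);
4. **synthetic** — a ground-truthed scene generator (solved series-spring
   mechanics plus rendered, textured, noisy frames) so the whole chain is
   testable without a microscope;
5. **estimation** — a hill-climbing inverse fit of body and yolk Young's
   moduli against measured strains through a pluggable forward model;
6. **pipeline / CLI** — config-driven end-to-end runs writing CSV/JSON.

## The model

A cantilever of length `L`, width `W` and thickness `T` loaded at the tip
acts as a spring

    k = 3 E I / L^3 = E W T^3 / (4 L^3),      I = W T^3 / 12,

with `E` the Young's modulus of the beam material.  When the tweezers
compress a specimen, Hooke's law at the fixed-arm tip gives the contact
force `F cos θ1 = k_c1 d_c1`, where `d_c1` is the tracked tip deflection
and `θ1` the cantilever-to-sample-tangent angle.  Modelling the specimen
as two equal springs `k_s` in series (one per contact) and measuring the
total indentation `D_s = d_s1 + d_s2`,

    k_s D_s = 2 F      =>      k_s = 2 k_c1 d_c1 / (D_s cos θ1).

Calibration is transitive: a stiff reference beam is calibrated against a
load cell by a through-origin fit `F = k_ref δ`, then pressed tip-to-tip
against the soft working cantilever so that `k_c = k_ref (δ_ref / δ_c)`.
Compartment moduli are estimated by minimising the squared relative
mismatch between measured and model-predicted strains with a
deterministic coordinate-wise hill climber in log-modulus space.

Conventions: lengths cross the API in **mm** and are converted to SI once
at ingest; compressive strain is positive; tile positions are top-left,
0-based `(row, col)`.

## Worked example

Invert the beam formula for the calibrated reference cantilever
(`k_ref = 0.151 N/m`, `L×W×T = 20×1×0.13 mm`):

```python
>>> import microtweezer as mt
>>> geom = mt.CantileverGeometry(length=20.0, width=1.0, thickness=0.13)
>>> mt.youngs_modulus(geom, 0.151) / 1e9
2.199362767410104
```

2.20 GPa — squarely in the 2–2.7 GPa range expected for PET film.

Run the whole measurement chain on a synthetic experiment with a known
answer:

```python
>>> from microtweezer import SceneParams, make_experiment
>>> from microtweezer.pipeline import ExperimentConfig, run_stiffness
>>> params = SceneParams(seed=7)           # ks = 5.9e-3 N/m ground truth
>>> scene = make_experiment(params, "exp") # 30 frames + ground_truth.csv
>>> # exp/params.yaml records the initial tile positions; point a run
>>> # config at exp/frames.tif and call:
>>> summary, status = run_stiffness(config, "out")
>>> summary["ks_fit"]
0.005929449321628094
```

The through-origin fit of `2F` against `D_s` over the 29 usable steps
recovers the generator's 5.9e-3 N/m sample spring constant to 0.5%
(`ks_mean` = 5.999e-3, R² = 0.999).  `out/` contains the per-tile track
CSVs, the per-step deflection/stiffness series with quality flags, a
summary JSON, and a step-granular run log.

The same chain is available from the shell:

```bash
microtweezer simulate --out exp --seed 7
microtweezer stiffness --config run.yaml --out out
microtweezer calibrate --config cal.yaml --out out-cal
microtweezer estimate  --config est.yaml --out out-est
```

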