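# bonequal

Multiscale **bone material quality** analysis for cortical bone, built
around fracture-resistance (J-integral R-curve) evaluation of notched
three-point bend tests, with the accompanying modalities used to explain
toughness differences between donor groups:

* **Fracture mechanics** — elastic, plastic and total J-integral R-curves
  from load–displacement records of single-edge-notched bend (SENB) beams,
  with second-order R-curve fits and 95 % confidence bands;
* **Raman spectroscopy** — six bone-matrix composition indices
  (mineral-to-matrix vs amide I and amide III, carbonate-to-phosphate,
  carbonate-to-amide I, crystallinity, amide I subpeak ratio 1666/1685);
* **qBEI** — calibrated backscattered-electron images to calcium-wt% maps
  and bone mineralization density distribution statistics (CaMean, CaPeak,
  CaWidth);
* **Nanoindentation** — Oliver–Pharr hardness and modulus, including
  continuous-stiffness (CSM) depth profiles;
* **Micro-CT** — cortical porosity and sphere-fitting canal diameter /
  separation on binary volumes;
* **Group statistics** — normality-gated two-group comparisons (Student's
  t vs Mann–Whitney U, α = 0.05);
* **Synthetic data** — ground-truth-known generators for every modality,
  including a virtual bend-test machine, so the whole pipeline is testable
  without access to cadaveric specimens.

It is aimed at skeletal-biomechanics labs that run notched-beam toughness
tests on bone (or analyze the multimodal material-quality data around
them) and want a tested, scriptable alternative to per-lab MATLAB/ImageJ
routines.

## The core computation

For an SENB beam (thickness *B*, height *W*, span *S*, crack length *a*,
ligament *b = W − a*) loaded with force *P*, the mode-I stress intensity is

    K_I = P·S / (B·W^{3/2}) · f(a/W)

with the standard SENB geometry factor

    f(x) = 3√x [1.99 − x(1−x)(2.15 − 3.93x + 2.7x²)] / (2(1+2x)(1−x)^{3/2}).

The J-integral is split into an elastic part computed from K and a plastic
part computed from dissipated area:

    J_el = K_I² (1 − ν²) / E
    J_pl = 2·A_pl / (B·(W − a))
    J_tot = J_el + J_pl

where *A_pl* is the plastic area under the load–displacement curve between
two crack-growth events, enclosed by parallel lines at the initial loading
slope, and J_pl accumulates over events with the ligament at the start of
each increment.  J_tot plotted against crack extension Δa is the R-curve;
a rising R-curve indicates extrinsic toughening.  Defaults follow the
targeted testing protocol: E = 19.5 GPa, ν = 0.3, 2×3×12 mm beams on a
10 mm span notched to a₀ = W/2, 1 Hz sampling, partial unloads triggered
at −0.45 N/µm over 15 points, termination at Δa ≈ 700 µm (≈47 % of b).

## Worked example

Simulate a bend test of a virtual specimen whose true resistance law is
J(Δa) = 100 + 0.5·Δa + 1.5·10⁻³·Δa² (J/m², Δa in µm), then analyze it:

```python
from bonequal import build_r_curve, fit_r_curve
from bonequal.simulate import (VirtualSpecimen, simulate_bend_test,
                               default_geometry, default_material)

vs = VirtualSpecimen(seed=1)
rec, cracks = simulate_bend_test(vs)
rc = build_r_curve(rec, cracks, default_geometry(), default_material())
fit = fit_r_curve(rc.delta_a_um, rc.j_tot)
```

This prints (via the snippet in `docs/methods.md`):

```
1137 samples, 28 crack-growth events
first event: da = 25 um, J_el = 110.6, J_pl = 10.0 J/m^2
last event:  da = 700 um, J_tot = 1217.5 J/m^2
fitted R-curve: J = 106.4 + 0.533 da + 1.50e-03 da^2
95% CI half-width at da = 350 um: 0.9 J/m^2
```

The virtual machine produced a 1137-second record with 28 discrete growth
events up to 700 µm of extension; the fitted second-order R-curve recovers
the generator's coefficients (100, 0.5, 1.5·10⁻³) within 10 %, and the
confidence band quantifies the fit uncertainty of the mean R-curve.

The same loop exists on the command line:

```sh
bonequal simulate bend --seed 1 --out sim/
bonequal fracture --record sim/record.csv --cracks sim/cracks.csv --out out/
```

Other stages work the same way (`bonequal raman|qbei|indent|microct|stats`
and `bonequal simulate raman|qbei|indent|volume|cohort`).

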