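# Methods

This note documents the models, estimators and numerical choices behind
each pipeline stage, what the synthetic generators do and do not emulate,
and the known limitations.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Units

Units are fixed at the file boundary — newtons, micrometres, millimetres,
GPa, cm⁻¹, wt% — and converted to SI exactly once inside each computation
(J values in J/m², K in Pa·√m).  This single conversion point is a
deliberate guard against the unit mixing that plagues ad-hoc scripts.

## Fracture mechanics

**Model.**  Elastic-plastic fracture resistance of an SENB beam, evaluated
at discrete crack-growth events:

* K_I = P·S/(B·W^{3/2})·f(a/W) with the closed-form SENB geometry factor;
  f is evaluated literally for the configured span, including the
  non-standard S/W = 10/3 of short-span bone fixtures (the standard form
  assumes S/W = 4; reproducing short-span practice takes precedence over
  strict ASTM geometry, and the span ratio is visible in the logged
  configuration).
* J_el = K_I²(1−ν²)/E with E = 19.5 GPa, ν = 0.3 by default (cortical
  bone values; both are `MaterialConstants` fields).
* J_pl = 2A_pl/(B(W−a)) accumulated incrementally: the plastic area of
  each between-event increment is normalized by the ligament at the start
  of that increment.  No crack-growth (η/γ) correction is applied — the
  per-area formula is used literally, which slightly overstates J_pl
  relative to the full incremental ASTM procedure for long growth.
* J_el uses the instantaneous crack length at each event by default
  (`jel_crack_length = "initial"` switches to a₀; the choice matters
  little before ~10 % ligament consumption).

**Plastic area.**  A_pl between events i and j is the area enclosed
between the recorded curve, two parallel lines through the event points at
the *initial* loading slope k, and the zero-load axis:

    A_pl = ∫ P dδ + (P_i² − P_j²) / (2k),

integrated trapezoidally on the raw 1 Hz samples with no smoothing (the
records are not filtered upstream either).  The construction is exact for
the two textbook cases (two events on one elastic line → 0; a constant-load
plastic offset → P₀·d_p).  **Known property:** because k is held at the
initial slope, the elastic energy released by the compliance increase of a
growing crack is partly attributed to A_pl.  The first growth increment is
free of this effect (the crack is stationary before it), which is where
the elastic-specimen consistency check is performed.  The virtual machine
tracks J_pl with the same fixed-slope accounting, so simulation and
analysis agree by construction; on real records this term is a bias of the
method itself, not of this implementation.

**Segmentation.**  Preload = leading samples at ≤ 2 N; partial unloads are
displacement reversals; crack events announce themselves through a rolling
straight-line slope over 15 samples crossing −0.45 N/µm (both machine
parameters, configurable).  The initial loading slope is a least-squares
fit over 20–80 % of the first-event load — the window avoids the preload
toe and the near-event nonlinearity; the protocol itself does not
prescribe an estimator.

**R-curve fit.**  Ordinary least squares of configurable degree (default
2, the conventional rising-R-curve description) with pointwise confidence
bands from the coefficient covariance and Student's t quantile.  The
implementation is plain normal equations; the test suite cross-checks
coefficients and bands against statsmodels OLS and verifies ~95 % Monte
Carlo coverage.

## Virtual bend test

The generator emulates the displacement-controlled machine: preload to 2 N
at 2 µm/s, ramp at 1 µm/s to 15 N, then 0.15 µm/s, sampled at 1 Hz;
Gaussian load noise (σ = 0.05 N default); unload trigger as above with
reloading at the slow rate after unloading to half the trigger load.

* **Compliance.**  C(a) is derived from the K formula itself via
  G = K²(1−ν²)/E = (P²/2B)·dC/da, integrated numerically in a and added to
  the uncracked-beam bending compliance S³/(48EI).  This guarantees the
  simulated record is energetically consistent with the analyzer's K-based
  J_el without importing an external compliance polynomial.
* **Crack growth.**  Resistance follows a quadratic law
  J(Δa) = c₀ + c₁Δa + c₂Δa², discretized in 25 µm increments up to 700 µm
  (the protocol's termination point, ≈47 % of the ligament).  The crack
  advances to the next increment as soon as the total J there — elastic
  part from the relaxed load at the longer crack plus the accumulated
  plastic term — reaches the law.  Advances produce load drops at fixed
  displacement, as in the real machine.
* **Plasticity.**  Each advance inserts a plastic displacement equal to
  `plasticity_fraction` times the elastic displacement gained from the
  compliance increase; 0 gives a perfectly elastic specimen.
* **Default law.**  (c₀, c₁, c₂) = (100 J/m², 0.5 J/m²/µm,
  1.5·10⁻³ J/m²/µm²): a convex rising R-curve from ~100 J/m² at initiation
  to ~1.2 kJ/m² at 700 µm, in the range reported for human cortical bone,
  with a curvature term large enough to be identifiable from ~28 events.
* **Not emulated:** crack bridging/deflection micro-mechanics, anelastic
  unload hysteresis, thermal drift, and the manual-restart dwell after
  unloads (the simulator resumes immediately; a dwell changes nothing at
  1 Hz).

Passing recovery tests therefore show the *analysis chain* is correct and
self-consistent; they do not validate the fixed-slope construction against
real bone plasticity.

## Raman

Chain: cosmic-ray removal → per-specimen averaging → per-band linear
baseline → band areas / peak fits.

* **Despiking:** channels whose discrete-Laplacian robust z-score (MAD
  scale) exceeds 8 are replaced by linear interpolation; runs of up to two
  adjacent spikes are handled.  The MAD scale keeps genuine bands from
  inflating the threshold.
* **Baseline:** a straight line through the mean of 5-channel anchor
  windows at the edges of each integration region.  Corrected intensities
  are *not* clipped at zero by default — rectifying noise would bias band
  areas upward by several percent at SNR 50 (clipping is available as an
  argument).
* **Regions (cm⁻¹, config defaults):** phosphate ν₁ 910–990 (wide enough
  that the 962 band's tails are negligible at the anchors), carbonate
  1040–1100, amide III 1215–1365, amide I 1600–1720.
* **Crystallinity:** 1/FWHM of a single-Gaussian fit to the ν₁ band —
  fitted FWHM rather than raw-data FWHM for noise robustness.
* **Amide I decomposition:** four Gaussians initialized at 1610, 1640,
  1666, 1685 cm⁻¹, centers bounded ±8 cm⁻¹, non-negative areas (standard
  bone amide-I practice); the reported subpeak ratio is area(1666)/
  area(1685).  Failed fits are flagged, not raised.
* **Areas vs heights:** ratios use band areas by default; peak heights
  for the 962/1070 bands are a config switch, since conventions differ
  between labs.

The map generator is a sum of Gaussian bands on a linear baseline with
Gaussian noise (SNR defined against the phosphate peak height) and
Poisson-placed spikes, on an inclusive-endpoint grid (200×30 µm at 5 µm →
287 spectra).  Band positions are chosen so every region edge is
effectively signal-free — real bone spectra are busier, so baseline bias
on real data will exceed the synthetic case.  Ground-truth index values
use region-truncated analytic areas (erf), making recovery a pure
estimator test.

## qBEI / BMDD

Measured carbon/aluminum standard grays are affinely rescaled onto fixed
anchors (25/225); a fixed linear relation converts anchored gray to
Ca wt%.  The default line (0.17330 wt%/gray, −4.3325 wt% intercept) places
osteoid near 0 wt% and pure hydroxyapatite near 39.86 wt% at gray 255 —
convention constants, explicitly configurable, and all tests rely on
generator self-consistency rather than on these numbers.

BMDD: histogram in 0.1 wt% bins aligned to bin-width multiples (fine
enough to resolve CaPeak, coarse enough that 8-bit quantization spikes do
not dominate the mode).  CaMean and CaWidth come from the raw pixel
population (mean, sample SD) and are bin-independent; CaPeak is the modal
bin center.  CaWidth is reported as the SD of the distribution; the
classical FWHM variant is a config switch (`cawidth_estimator="fwhm"`),
since both definitions circulate.  Images of one specimen are pooled at
the pixel level (five images per specimen in the targeted protocol).  The
default bone mask is Otsu plus removal of components under 50 px.

## Nanoindentation

Oliver–Pharr with ideal Berkovich area A = 24.56 h_c², ε = 0.75,
β = 1.034, diamond constants E_i = 1141 GPa, ν_i = 0.07, sample ν = 0.3 —
standard values, none measured here, all configurable.  The unloading
power law P = α(h−h_f)^m is fitted over 50–90 % of P_max; exponents
outside [1, 2.5] flag the indent.  CSM profiles apply the same contact
relations per sample and average over 1000–2000 nm by default (below
~1000 nm surface roughness and tip-defect effects dominate real data).
Both end-of-test and CSM-averaged values are produced and labeled, since
reporting conventions differ.  No tip-area calibration, creep or drift
correction is attempted.  The forward generator is the exact inverse of
the analysis relations (Kick loading, self-similar S(h) ∝ h), so round
trips isolate implementation errors.

## Micro-CT microstructure

Porosity is a voxel count ratio over the envelope.  Local thickness
follows the Hildebrand–Rüegsegger sphere-fitting definition, computed by
Euclidean distance transform plus sphere painting in decreasing-radius
order with a covered-region short-circuit; the result is voxel-exact
against an exhaustive inscribed-sphere search (tested on small random
volumes).  Canal diameter / separation are mean thickness over pore / bone
phase.  TMD is out of computational scope (it requires a scanner
calibration phantom); an Otsu helper is provided for synthetic grayscale
stacks, and for beam samples the envelope defaults to the full volume
(configurable) since the tissue boundary definition is acquisition
specific.  The cylinder phantom is voxel-center aligned; porosity
voxelization error is assessed at a realistic canal density (porosity
≈3 %), where it stays below 0.2 percentage points at 6 µm voxels.

## Group statistics

Each parameter: normality test per group, then Student's t (both normal)
or Mann–Whitney U, two-sided, α = 0.05, no multiple-testing correction
(matching common practice in the targeted studies; readers should treat
per-parameter p-values accordingly).  The normality gate defaults to the
Lilliefors correction because a raw KS test against a normal with
*estimated* parameters is strongly anticonservative; the raw variant
remains available for strict protocol emulation.  Groups of n = 3 fall
back to the raw KS gate (Lilliefors tables need n ≥ 4).  The gated
procedure's type-I error is calibrated by simulation at the default group
sizes (18 vs 11).  The cohort generator draws independent Gaussians per
parameter (defaults mirror typical elderly-male cortical-bone control
values); it does not model between-parameter correlation, and unbounded
Gaussians can produce physically impossible draws (e.g. negative
porosity) in the tails.

## Problem sizes used in tests and the acceptance script

Raman bias: 100 replicate maps at SNR 50.  qBEI: one 1024² image.
Oliver–Pharr: 3×3 (E, H) grid.  Local thickness: 32³ cylinder phantom and
16³ random volumes for the brute-force cross-check.  Type-I calibration:
10 000 null replicates at n = 18 vs 11.  R-curve coverage: 1000 Monte
Carlo replicates.  These sizes give sampling error comfortably below the
tolerances they are checked against.
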