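# Methods

## The band-ratio algorithms

A mid-IR absorbance trace of cotton fiber, `I(ν)` on a 4 cm⁻¹ grid over
4000–600 cm⁻¹, is reduced to two indices:

- **Maturity** `M_IR = (R1 − 0.14)/0.45` with
  `R1 = (I956 − I1500)/(I1032 − I1500)`. The 1032 cm⁻¹ C–O stretching cluster
  is the dominant cellulose feature; 956 cm⁻¹ grows with secondary-cell-wall
  thickening; 1500 cm⁻¹ sits in a low-absorbance valley and serves as a local
  baseline reference.
- **Crystallinity** `CI_IR (%) = ((R2 − 1.4)/2.0)·100` with
  `R2 = (I708 − I800)/(I730 − I800)`, built from the weak 800–700 cm⁻¹ bands
  associated with the crystal forms of native cellulose.

Every `I` is a multi-point intensity average. The placement rule, which the
method description leaves open, is fixed here as: the grid point nearest the
nominal center plus `(window_points − 1)/2` neighbours on each side (default
three points for all six bands); a tie between two equally near grid points
breaks toward the higher wavenumber. The rule is symmetric, deterministic and
resolution-independent. No interpolation is done — centers snap to the native
grid — and no baseline correction is applied anywhere: both ratios are exactly
invariant under affine maps `a·I + b` of the trace, which the test suite checks
to 1e−9.

Indices are never clipped. Values outside a plausible range trigger a warning
(they indicate a degenerate spectrum) but are reported unaltered, because
clipping would silently hide the problem.

**Class labels.** Maturity: mature > 0.80, intermediate 0.59–0.80, immature
< 0.59. Crystallinity: high > 80 %, middle 59–80 %, low < 59 %. Boundary
inclusivity is not stated where these thresholds are quoted; both boundaries
are assigned to the middle class, matching the strict ">" printed for the top
class.

**Replicates.** Each fiber sample is measured at least five times by
re-sampling the tuft. Indices are computed per replicate and then averaged —
not the spectra — so each replicate's scaling cancels individually and the SEM
(sample sd / √n, undefined at n = 1) describes repeatability on the index
scale. Whether published per-boll values are replicate means or single
measurements is unstated; this pipeline always reports replicate means with
SEM.

## Plant map

A boll's coordinate is "mainstem node – fruiting position" (cotyledon node =
0; fruiting branches from about node 6; positions count outward along the
sympodial branch). Plant-level lint percentage is the ratio of totals
(100·Σlint/Σseed-cotton) and is reported only when every boll carries a
seed-cotton mass — never imputed; a mean of per-boll percentages is exposed
separately because summary tables can be read either way. Across-plant
combination averages the per-plant per-boll indices at each location; the
physical analogue (blending fibers from the same location and re-measuring)
cannot be done in silico, and averaging matches what a per-location mean
reports.

## Phenology

Growing degree days follow the DD60 convention: daily contribution
`(Tmax + Tmin)/2 − Tt` with `Tt = 15.6 °C (60 °F)`, negative contributions
clamped at zero by default (a switch preserves the unclamped sum; the clamped
accumulator is nondecreasing). Temperature series may be Celsius or
Fahrenheit; thresholds are converted internally and the accumulated GDD comes
back in the series' units.

Flowering dates form an additive lattice anchored at node 6, position 1
(60 days after planting): +3 days per node up the mainstem, +6 days per
position out the branch. Boll development takes 42 days. Event thresholds
(emergence at 50 GDD, squaring at 431 GDD) are configuration constants in
Fahrenheit degree-days — the only unit system in which those magnitudes are
consistent with a spring planting — and are converted when the series is
Celsius.

Defoliant sprays at 139 and 146 days after planting truncate late boll
development: a boll maturing after day 146 is flagged **severe**, in
(139, 146] **mild**, otherwise **none**. No quantitative mild/severe rule is
published; this spray-window rule is an inference and is carried through
reports as a flag only.

## Synthetic spectra and virtual plants

No raw fiber spectra are available to this package, so validation rests on a
generator whose ground truth is known by construction.

**Band model.** A spectrum is a sum of Gaussian (optionally Lorentzian) bands
on a 600–4000 cm⁻¹ grid at 2 cm⁻¹: O–H/C–H stretches (3340, 2900), the
adsorbed-water bend (1620), C–H bends (1422, 1366, 1312), the C–O cluster
(1160, 1110, 1060, 1032, 1000), the β-glycosidic band (895), and the
crystal-form region (800, 730, 708). Widths and decoy amplitudes are design
choices, not claims about real fibers. Deliberately, no band sits at
1500 cm⁻¹, so `I1500` behaves as the local baseline the algorithm treats it
as.

**Inversion.** Given targets (M_IR, CI_IR), the amplitudes of the 956 and
708 cm⁻¹ bands are solved so the rendered spectrum's band averages hit
`R1 = 0.45·M_IR + 0.14` and `R2 = 1.4 + 2·CI_IR/100` exactly. Band averages
are linear in band amplitudes, so the two constraints form a 2×2 linear system
(cross-leakage of each adjustable band into the other ratio's windows is
included). Targets requiring negative amplitudes raise an error. The noiseless
closed loop — targets → spectrum → band extraction → indices — closes to
machine precision (~1e−13), tested over M_IR ∈ [0.3, 1.0] × CI_IR ∈ [40, 100].

**Virtual plants.** True per-boll maturity follows a quadratic profile over
mainstem node at position 1 (defaults: peak 0.87 at node 13, ~0.67 at node 6,
~0.61 at node 21 — a mid-canopy maximum), minus 0.02 per position step, minus
a defoliation penalty (0.12, halved for mildly affected bolls) where the
phenology timeline flags the location. True crystallinity is
`CI = −2 + 105·M + N(0, 3)` — a strong positive maturity–crystallinity
relation with biological scatter. Occupancy probabilities per position
(0.95, 0.70, 0.35, 0.15, 0.05) thin the lattice the way real plants set bolls
mostly at positions 1–2. Each boll gets five replicate spectra with i.i.d.
Gaussian absorbance noise (σ = 0.001). All randomness derives from one master
seed through hierarchical streams keyed by (plant, node, position, replicate),
so every dataset is reproducible and streams are independent.

**What the generator does not emulate:** ATR penetration-depth dispersion,
water-vapor line structure, detector drift, scattering baselines, or any
claim that real cotton spectra have these exact band shapes. Passing tests
establish that the *algorithms and plumbing* are correct and stable under
measurement noise — not that the indices are accurate on real fibers, which is
a calibration question the original instrument work answers.

**Error budget.** With noise σ = 0.001 on ~0.7 absorbance denominators,
3-point windows and 5 replicates, propagation predicts per-boll M_IR error of
about 0.002; the recovery experiment's acceptance tolerance is 0.02 (an order
of magnitude of headroom), and the recovered position-1 quadratic must locate
the generating peak node within ±1. The defoliation penalty on terminal nodes
pulls the fitted vertex slightly below the generating peak (≈12.6 vs 13 at
defaults) — a real feature of the surface, well inside the tolerance.

## Statistics

Pearson r with a two-sided t-test p-value (scipy); significance stars at
p < 0.05 (\*), 0.01 (\*\*), 0.001 (\*\*\*), 0.0001 (\*\*\*\*), a p equal to a
threshold taking the weaker label. Polynomial fits are unweighted least
squares (intercept-first coefficients), `R² = 1 − SS_res/SS_tot`, with a
constant-y input treated as an error rather than R² = 0. Model selection fits
linear, quadratic and exponential (`y = a·e^{bx}` by log-linear least squares,
R² evaluated on the original y scale; skipped with a notice when any y ≤ 0)
and picks the highest R², ties within 1e−12 going to the simpler model.
Quadratic fits are unweighted (per-point SEMs are not used as weights).

## Problem sizes

Default test and acceptance runs use a 15×13 closed-loop target grid, 100
random spectra for the invariance bound, 1000 random series for the GDD
monotonicity property, and a 3-plant experiment of ~100 bolls × 5 replicates
(~500 rendered spectra of 1701 points); the full suite runs in a few seconds
on one CPU.

## Known limitations

- The JCAMP-DX dialect is the fixed-abscissa `XYDATA=(X++(Y..Y))` form only;
  compressed (DIF/DUP/SQZ) encodings and binary .spc files are out of scope.
- The mild/severe defoliation split is an inferred rule, not a measured one.
- Lint percentage at plant level cannot be validated without per-boll
  seed-cotton masses; it is computed only when they are supplied.
- The exponential model's functional form in model selection is the simplest
  standard reading; alternatives (offset exponentials) are not fitted.
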