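# Methods

## Transport model

The engine propagates photon *packets* (continuous-absorption Monte Carlo)
through an axis-aligned grid of cubic voxels, each holding one material
label. Per packet the loop is: resolve the material at the current position;
sample a free path `s = -ln(ξ)/μt`; move with an Amanatides–Woo voxel
traversal; if the traversal crosses into a different label before the step
is consumed, relocate the packet to the ray/face intersection and reflect or
refract there; deposit `ΔW = W·μa/μt` at the interaction site; redirect by
the Henyey–Greenstein (HG) phase function; apply Russian roulette below the
weight cutoff. Termination is by transmission into ambient, roulette kill,
a maximum elapsed time, or an interaction-count cap (a guard against
degenerate loops; capped weight is tallied separately and reported).

Units are mm, mm⁻¹ and ns throughout, with c = 299.792458 mm/ns. Elapsed
time accrues as `d·n/c` per traversed distance `d` in a medium of index
`n`; exit weights are binned by elapsed time (default 10 ps bins up to
1 ns — the transit times of interest here are well under that).

Choices worth calling out:

- **Interface handling.** The boundary test is a *label* change; the
  crossing face, intersection point and axis-aligned outward normal are
  recovered by the traversal itself. After the reflect/refract decision the
  packet deposits `ΔW` and scatters *at the relocated point*, in the medium
  it ends up in; the unused remainder of the sampled step is resampled in
  that medium. An MCML-style dimensionless-step carry (`step_rule="carry"`)
  is available for physics comparisons; under it the interface is not an
  interaction site.
- **Reflectance.** The default model squares the Schlick coefficient
  (`R = r(θ)²`). Schlick's `r(θ)` itself already approximates the power
  reflectance, so the square is non-standard and makes interfaces
  unusually transparent; it is retained as the default for fidelity to the
  algorithm this engine reproduces, with `schlick_direct` and
  `fresnel_exact` (unpolarized average) selectable per run. Total internal
  reflection forces `R = 1` under every model, since a Snell solution does
  not exist there.
- **HG sampling.** The inverse CDF uses the squared inner fraction
  `cosθ = (1+g² − [(1−g²)/(1−g+2gξ)]²)/2g`, the form whose mean deflection
  cosine equals `g` (verified to 3 SE at 10⁶ draws for g up to 0.995, the
  whole-blood anisotropy). The direction update uses the standard rotation
  with the polar special case when `|uz| > 1−10⁻⁶`.
- **Ambient.** Outside-tissue space is an explicit vacuum-like material
  (μa = μs = 0, n = 1): packets traverse it in straight lines, reflect or
  refract on entering tissue (no deposit at the entry face — there is no
  μt to interact with), and are terminated and recorded when they leave the
  grid. A packet transmitted from tissue into ambient is recorded as an
  exit at the tissue-side boundary voxel and terminated; re-entrant paths
  across concavities are neglected.
- **Energy bookkeeping.** Every unit of launched weight ends in exactly one
  tally (exited, absorbed, roulette, timeout, cap). Roulette survivors'
  weight boost `(rc−1)·W` is *netted against* the roulette tally, so the
  per-run balance is exact to float precision, not merely in expectation;
  the net roulette tally is itself a mean-zero quantity.
- **RNG.** Each photon index gets its own SplitMix64 stream seeded from
  (run seed, index), so results are bit-reproducible and independent of
  execution order.

## Tissue model

Materials: ambient, composite skin, nail, fat, muscle, bone, artery, vein,
tabulated at 465/525/615 nm (the median wavelengths of an RGB color
sensor). Lookups at other wavelengths fail loudly rather than extrapolate —
the chromophore tables are three-point, not spectra.

The skin label is *composite*: its six sublayers (stratum corneum 0.02 mm,
epidermis 0.25, papillary dermis 0.10, upper blood net 0.08, reticular
dermis 0.20, deep blood net 0.30; cumulative 0.95 mm) are resolved at run
time by bucketing the distance from the photon position to the nearest
outer-surface reference point. Reference points are the centroids of skin
voxels with an ambient 6-neighbor; the nearest-neighbor Euclidean rule is
the simplest one consistent with a surface-offset reading, and queries use
a per-voxel candidate list so the kernel stays allocation-free. Two
consequences are worth knowing: depth zero sits at the outer voxel
*centroids* (≈ quarter-pitch inside the physical surface), and a sublayer
change does not trigger an optical interface — sublayers share μs, g and n
by construction, so only μa varies with depth.

Absorption models, evaluated per wavelength λ (nm):

- Skin baseline: `7.8375e8 · λ^(−3.255)` in cm⁻¹, divided by 10. The
  exponent −3.255 is the standard literature fit and reproduces the
  package's tabulated baseline row (0.163/0.110/0.066 mm⁻¹) to three
  decimals; an often-miscopied variant (−3.48) does not, yielding
  0.041 mm⁻¹ at 465 nm. Both coefficient and exponent are configurable on
  `ChromophoreLibrary`.
- Stratum corneum: `((0.1 − 0.3e−4·λ) + 0.125·μa_baseline)(1−Vw) + Vw·μa_water`,
  evaluated in the cm⁻¹ convention of its literature source and converted.
- Epidermis: melanin/baseline mixture diluted by water (fractions
  Vmelanin = 0.1, Vwater = 0.2), computed directly in mm⁻¹.
- Blood-bearing dermis: volume-fraction mixture of arterial blood, venous
  blood, water and baseline. In systole both blood fractions double. For
  the upper blood net dermis (0.15 + 0.15 + 0.6 water) the doubled
  fractions exceed unity; the mixture is kept linear — the residual
  baseline weight goes slightly negative — because that is the only
  reading under which the systolic/diastolic difference is exactly the
  added blood volume, and total μa remains positive throughout the
  physiological grid (asserted over HbA1c 3–14 %, SpO₂ 70–100 %).
- Blood: the three-species HHb/HbO/HbA1c mixture with
  `P_HbO = SpO2·(1−HbA1c)` and `P_HbA1c = HbA1c`; the tabulated species
  coefficients are whole-blood-referenced and mixed without concentration
  scaling. Venous SpO₂ is arterial minus 0.10 (clamped), with the same
  HbA1c fraction.

Parameters the tables do not fix, chosen once and exposed as configurable
constants: water absorption (1.06e-5 / 4.2e-5 / 2.7e-4 mm⁻¹ — Pope &
Fry-order values, numerically negligible against blood and melanin) and the
skin sublayers' scattering (single shared μs of 30/25/20 mm⁻¹ at
465/525/615 nm, g = 0.9, n = 1.4 — standard dermis-scale values; results
do depend on them, which is why they are arguments rather than constants).

## Phantoms

Synthetic stand-ins for segmented anatomy, all deterministic functions of
their spec:

- **Slab**: z-stacked homogeneous layers (validation geometries; thickness
  rounds to whole voxels, half away from zero).
- **Digit**: concentric half-capped cylinder — bone core, muscle, fat,
  0.95 mm composite-skin shell — with an optional nail patch on the dorsal
  face near the tip. Defaults give a ~16 × 36 × 16 mm grid at 0.5 mm pitch.
- **Wrist**: elliptical limb with skin/fat shells over muscle, two bone
  cylinders, and artery/vein cylinders at a configurable depth below the
  dorsal surface.

Volumes serialize to NIfTI-1 with a JSON sidecar (pitch, origin,
label→material map); loading rejects anisotropic voxels and unknown labels.

## Experiments and estimation

Four layouts: fingertip transmission (source ventral, detector on the
nail), fingertip reflection (detector 2 mm from the source), wrist
single-PD (2 mm separation, three wavelengths) and wrist multi-PD (three
detectors at 2/4/6 mm, 615 nm only — the most penetrating of the three
wavelengths). Detectors are circular collection regions (default radius
0.5 mm, full angular acceptance) summing recorded exit weights; a
variance-ranking helper picks multi-PD positions by intensity variance
across a coarse sweep, ties broken by source distance.

A sweep enumerates HbA1c × SpO₂ × phase (26 × 11 × 2 = 572 configurations
by default, densest in the clinically common ranges) per wavelength
channel. The systolic/diastolic pair of each cell shares one RNG seed:
with common random numbers the paired difference AC = I_dia − I_sys is far
less noisy than independent runs would give, which matters because AC is a
small difference of large numbers. DC = I_dia by default (`mean` is
available). Ratios follow the 525/615 and 465/615 AC/DC quotients, or
sensor1/3 and sensor2/3 for multi-PD.

Inversion is k-nearest-neighbor inverse-distance weighting (k = 4) in
standardized (R1, R2) space, exact at LUT nodes, flagging queries far
outside the covered region. It deliberately replaces any device-specific
learned calibration: the package's scope ends at simulated ratios, and the
`RatioInverter` estimator interface is the slot where a feature-based
calibrator against real device PPG would plug in.

Synthetic PPG is a raised-cosine pulse train per channel
(`DC − AC·(1−cos 2πft)/2`, default 1.25 Hz, 100 Hz sampling) plus optional
white noise; extraction segments the signal into beats and takes mean
peak-to-trough as AC and the mean diastolic peak as DC — the same
convention the LUT uses, which is what makes the noiseless round trip
exact. What the synthetic PPG does *not* emulate: dicrotic notches,
baseline wander, motion artifacts, beat-to-beat variability, sensor
quantization. Passing round-trip tests therefore demonstrate pipeline
self-consistency, not robustness to real device signals.

Metrics: MSE, ME, MAD, RMSE, Pearson r, RCF = mean(1 − |ref−est|/100) on
percent-scale values, Bland–Altman bias with ±1.96·SD limits (the SD is
also exposed separately), and error-grid zones — A within 20 % of
reference, B within 40 % (a package-defined boundary; only zone A has a
canonical definition here), C beyond. SD-based quantities are NaN for a
single record rather than an error.

## Validation problem sizes

The test suite runs the analytic checks at the sizes where their
tolerances are meaningful: Beer–Lambert transmission and energy balance at
10⁵ packets (3 binomial SE), HG moments at 10⁶ draws (3 SE), the
HbA1c-intensity trend at 10⁵ packets per point on a reduced digit phantom
(outer radius 5 mm), and the pipeline identity on a 3 × 3 physiological
sub-grid at 10⁵ packets per configuration. These photon budgets trade
smooth LUT surfaces for runtime; the identity and conservation properties
are exact at any budget, while ratio-surface smoothness improves as
1/√N.

## Known limitations

- No polarization, fluorescence, or variance reduction beyond roulette and
  the paired-seed sweep; voxel (not mesh) geometry only.
- The squared-Schlick default underestimates specular reflection; use
  `fresnel_exact` for physically standard interfaces.
- Composite depth is measured from surface voxel centroids, biasing
  sublayer boundaries ~0.25 mm inward at default pitch.
- Chromophore data exist only at 465/525/615 nm; sources are monochromatic
  (no LED bandwidth), detectors are ideal (no responsivity or aperture).
- Absorption at a truncated interface step is deposited once at the
  relocated point with no partial-path Beer weighting — an approximation
  inherited from the printed-order interaction loop.
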