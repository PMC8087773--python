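# Methods

This note documents the models, the measurement conventions, the
synthetic-data generator and the numerical choices behind `retinostat`,
and states what the synthetic validation does and does not establish
about real recordings.

## Response models

**Saturation (B-wave).** The peak B-wave amplitude as a function of
flash intensity follows the hyperbolic law

    B / B_max = S_B I / (1 + S_B I)

with `S_B` the inverse half-saturating intensity (units: inverse flash
intensity — scotopic or photopic cd·s/m², or R*/rod) and `B_max` the
saturated amplitude (µV). With exactly two flash intensities the model
is exactly identified: `1/B` is linear in `1/I`, so `SaturationModel`
solves the two-point case in closed form (slope and intercept of that
line must both be positive, otherwise the data are inconsistent with
saturating kinetics and a `FitError` is raised). With more intensities
it minimizes squared amplitude error in a log parametrisation
(positivity for free), started from the two-point-style initial guess
and two scale variants.

**Activation (rising phase).** The A-wave and rod-photocurrent rising
phases follow the delayed-Gaussian activation model

    A(I, t) / A_max = 1 − exp(−S_A I (t − t_d)²),   t > t_d

with `S_A` the amplification (intensity⁻¹·s⁻²), `A_max` the saturated
response and `t_d` a fixed delay. `RisingPhaseModel` fits all three
jointly over every rising window of a flash family, sharing `t_d`
across flashes. Delay bounds default to the observed physiological
ranges — 3.4–4.4 ms (ERG A-wave) and 14–17 ms (rod photocurrent) — and
are configurable.

*Rising windows.* Rod mode: a fixed 60 ms window starting at
`t_flash + t_d` (dim flashes never saturate inside it). ERG mode: from
`t_flash + t_d` to the response peak; when that period exceeds 5 ms the
window ends 5 ms before the peak. The latter rule has a second reading
("cap the window at 5 ms length"); both are implemented,
`end-before-peak` being the default literal reading and `cap-length` a
config switch. Windows are fixed using the midpoint of the `t_d`
bounds before optimisation; re-selecting them per candidate `t_d`
would make the least-squares cost discontinuous.

*Optimiser.* Bounded trust-region least squares (`scipy
least_squares`), `S_A` and `A_max` in log space, `t_d` box-constrained;
five deterministic multistarts spanning a 400-fold `S_A` range;
tolerances 1e-14. On noise-free families the generating parameters are
recovered to better than 1e-6 relative error (tested), far inside the
0.1% round-trip requirement.

*Polarity.* Photocurrents are stored response-positive, ERG traces
corneal-positive; A-wave fitting negates the ERG segment.

## Filtering and derived measurements

All filters are 6th-order Butterworth designs: 22.5 Hz low-pass for
B-waves and rod currents, 1 kHz for A-waves, 75–300 Hz band-pass for
oscillatory potentials. They are applied forward-backward (zero phase)
by default so that peak times — which drive window selection — are not
shifted; a single-pass causal mode exists, and the −3 dB point of that
single-pass design at the cutoff is verified in the tests. Cutoffs at
or above Nyquist are rejected.

**B-wave amplitude** is the post-flash maximum minus the mean of the
50 ms pre-flash baseline (the measurement convention is not uniquely
standard; a trough-to-peak mode is available). **OP amplitude** is
measured on the band-passed trace between the flash and the B-wave
peak (located on a 22.5 Hz low-passed copy): among consecutive
negative→positive extremum pairs the largest upswing is taken — "the
intermediate peak" has no unique operational definition, so the choice
is explicit and configurable (`first` selects the earliest pair). A
trace with no oscillation cycle returns amplitude 0 with
`found=False`. Flash photon densities convert to photoisomerizations
through the 0.5 µm² rod collecting area.

## Puncta quantification

Stacks are normalized channel-wise by the mean ONL (outer nuclear
layer) intensity, putting all values in units of the non-specific
background; every downstream number is invariant to global intensity
rescaling of a slide (tested exactly).

* **OPL mean**: the OPL ROI of the z-averaged image is thresholded at
  the ONL mean; pixels at or below threshold contribute zero and the
  rest contribute `value − 1`, averaged over all ROI pixels. The
  thresholded mean is therefore background-subtracted — the reading
  under which a KO/WT intensity scaling of the stain maps exactly onto
  the reported ratio; an unsubtracted mode is available, as is the
  choice of excluding thresholded pixels from the denominator.
* **Tip detection**: strict 26-neighbour local maxima of the reference
  (mGluR6) channel in the 3-D ROI volume; plateaus yield no maximum,
  making detection deterministic; maxima are ordered by intensity with
  lexicographic (z, y, x) tie-break, and only maxima above background
  are kept.
* **Tip mask**: pixels of the z-averaged reference image above the ONL
  mean, with connected components smaller than 2×2 pixels removed as
  speckle. The mask criteria in the source protocol ("potential OBC
  dendritic tip areas") are not fully specified; this reconstruction is
  deliberately minimal and the threshold multiplier is configurable.
* **Classification**: the mask run through the maximum's row, along the
  OPL-parallel axis (cone patches are horizontally elongated). Rod: the
  run extends at most 0.5 µm on each side of the centre. Cone: the run
  extends more than 1.1 µm from the centre, the centre pixel counted
  with the longer arm — the only reading under which an 0.8 µm-per-side
  component satisfies neither criterion and is excluded, as the
  protocol implies. Anything between the criteria is excluded.
* **Window sums**: per channel, the sum of `value − 1` over the
  1.1 × 1.1 µm window (nearest odd pixel count at the configured pixel
  size) of the z-averaged image centred on the maximum; windows
  crossing the image edge flag and exclude the punctum. Negative
  contributions are kept by default (clipping at zero is optional).

Coordinates are 0-based (z, y, x); ROI rectangles are half-open in
pixel space.

## Paired statistics

The jackknife chain implements, exactly, the ratio-of-sums `r`, the
leave-one-out ratios `r_i`, the jackknife SD `s` (1/n-normalised spread
of `r_i` about `r`), the bias-corrected `r_c = n r − (n−1)/n Σ r_i`,
and the corrected SD `s_c` (1/(n−1)-normalised spread about `r_c`).
For `y = c·x` the chain returns (c, c, 0, 0) identically. Batch
pre-processing normalizes the mean of each blot/slide to 1, then the
mean of each WT/KO pair to 1, so per-batch exposure factors cancel.

Welch's t from summary statistics (mean, SEM, size) uses the
Satterthwaite degrees of freedom with `SEM⁴/(n−1)` denominators and the
two-sided p computed directly as the regularized incomplete beta
function I_{v/(v+t²)}(v/2, ½); the double-difference form compares two
log-ratios with four-term Satterthwaite freedom. Correlation p-values
(Pearson on values, Spearman on average ranks) use the t-transform
`t = r √((n−2)/(1−r²))` with n−2 degrees of freedom for both
coefficients. All p-values are two-sided; no multiple-testing
correction is applied (raw p's are reported, as in the source
protocol); degenerate inputs (zero SEMs, zero variance, non-positive
denominators) raise instead of being regularized.

A note on bias: when WT and KO intensities share their pair-level
factor (`y = R·x·η`, the default synthetic model), the ratio-of-sums
is already exactly unbiased — the shared factor cancels. The O(1/n)
bias the jackknife targets arises when numerator and denominator noise
are independent; the generator exposes that regime
(`independent_noise=True`), and the Monte-Carlo validation of the
bias order runs there: |bias(r_c)| < |bias(r)| at n ∈ {4, 8, 16, 32}
with a visibly steeper log-log decay.

## Synthetic-data generator

The generator emulates the structure of the study data, not retinal
anatomy. Defaults are the study conditions: 0.2 ms ERG sampling, 1 ms
rod sampling, 7 littermate pairs with two eyes each, scotopic flashes
of 0.00022 and 0.011 cd·s/m² and photopic flashes of 1 and
1000 cd·s/m², a 105 × 7.5 µm OPL ROI at 0.1 µm pixels and 0.3 µm
slices, and KO/WT staining ratios in the ≈1.3–1.4 regime. Baseline
sensitivities (scotopic S_B = 1000, photopic S_B = 0.2 (cd·s/m²)⁻¹;
B_max = 400/150 µV) place the dim flashes at 15–20% of saturation and
the saturating flashes above 90%, matching the dim/saturating design;
between-pair and between-eye lognormal spreads default to 15% and 3%.

* **B-wave kinetics** are not constrained by the saturation law beyond
  the peak; a gamma-function rise `(t/τ)² e^{2(1−t/τ)}` (peak at
  τ = 60 ms, snapped to the sample grid so the sampled maximum equals
  the analytic peak) carries the Eq.-style peak amplitude. OPs are
  damped 120 Hz sinusoids added on the rising phase; frequencies
  outside 75–300 Hz are generated but warned about.
* **Rising-phase traces** follow the activation model exactly, with an
  optional plateau that freezes the response after a configurable rise
  duration (only the rising phase is modeled).
* **Cohorts** share per-eye jitters across genotypes within a pair, so
  a unity sensitivity factor with zero noise produces bit-identical
  WT/KO sessions (and the paired test returns p = 1 by symmetry). KO
  sensitivity is the littermate value times the configured factor
  (default 1.5); saturated amplitudes are genotype-independent. OP
  amplitudes optionally track sensitivity (`op_coupling`) to emulate
  the downstream inner-retinal correlation.
* **Stacks** place truncated-Gaussian blobs (hard support cutoff — the
  only construction giving an unambiguous above-background footprint on
  a noise-free background): rods ±0.3 µm isotropic, cones ±1.3 µm
  horizontally, both well clear of the 0.5/1.1 µm classification
  boundaries. Centres sit on a jittered grid with ≥3 µm separation
  (generation fails loudly if the ROI cannot hold the requested count);
  both channels share centres; WT/KO pair stacks share geometry and
  differ only in injected target amplitude. Optional Poisson–Gaussian
  noise is available but the exactness guarantees hold only noise-free.
* **Determinism**: a single root seed is spawned into per-object
  streams (`numpy` `SeedSequence`); identical configurations give
  bit-identical outputs, and pipeline reports rerun byte-identically
  from their config snapshots.

**What passing tests show — and don't.** Noise-free closure (generator →
analysis recovers ground truth exactly) validates the estimator
algebra, the detection/classification geometry and the unit
conventions. It does not validate robustness to real-world departures:
correlated photon noise, optical blur and chromatic offsets between
channels, eye movements and blink artifacts, mis-drawn ROIs, or
staining backgrounds that differ between layers. The cohort-level
pattern checks (significant sensitivity shift, null amplitude shift,
positive OP correlation) are qualitative by design: the underlying
animal-level numbers are not reproducible from published summaries, so
the simulated cohorts only need to occupy the same regime.

## Problem sizes

Validation runs use desk-scale sizes chosen to keep the full suite
fast while leaving every statistical check well-powered: 10⁵
Monte-Carlo replicates for the bias-order study, 10⁴ null simulations
per test for type-I rates, 1000 random draws for the two-point/numeric
equivalence, 40–105 µm ROIs with 7–15 puncta per synthetic section, and
3–7 simulated littermate pairs per cohort.

## Known limitations

* The two-sample Welch helpers take summary statistics, not raw
  samples; callers are responsible for the SEM convention.
* The OP peak-pair rule measures one (the largest) cycle; multi-cycle
  OP energy measures are out of scope.
* The tip mask is a reconstruction; on real images its threshold and
  speckle-size parameters will need tuning against visual confirmation.
* The supplementary non-parametric paired test mentioned alongside the
  source figures is unspecified there and is not implemented.
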