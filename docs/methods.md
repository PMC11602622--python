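# Methods

This note records the models, parameter choices and numerical conventions
behind each stage of the pipeline, the design decisions made where several
reasonable options existed, and what the synthetic-data generator does and
does not emulate.

## Acquisition model and frame conventions

All window constants live in `AcquisitionProtocol`, counted 1-based with
inclusive endpoints (frame 1 = first frame recorded); internal arrays are
0-based and every conversion goes through `ortune._frames`. The two presets
encode the experimental designs the pipeline targets:

| preset | baseline (F₀/R₀) | stimulus | response window | pre-stim ref | bleach-fit exclusion |
|--------|------------------|----------|-----------------|--------------|----------------------|
| bee    | 10–14            | 15–20    | 17–19           | 9–11         | 15–40                |
| fly    | 10–14            | 15–20    | 17–31           | —            | 15–40                |

Both assume 100 frames at 5 Hz (20 s) with a 1 s stimulus starting at
frame 15. The bleach-exclusion end is stimulus onset plus 5 s (25 frames
at 5 Hz, frames 15–40). The fly amplitude is read as the mean ΔF/F₀ over
frames 17–31 relative to the F₀-defined zero; a literal difference
"between F₀ and the window average" would mix absolute and relative units,
so the relative reading is used, and the baseline term is retained in the
implementation so the amplitude stays correct on offset traces.

## Bleach correction

Two corrections are provided, matching the two preparations:

* **Blank subtraction** (fly): the ΔF/F₀ of a stimulus-free recording is
  subtracted framewise. Exact when the blank shares the recording's decay.
* **Logarithmic fit** (bee): f(t) = a + b·ln(t + 1) (t = 0-based frame) is
  least-squares fitted to the trace outside the exclusion window and
  subtracted everywhere. The logarithmic family was chosen as the
  correction model; an exponential a·exp(−t/τ) + c variant is available via
  `model="exp"` for sensitivity checks. A constant input makes the fit
  degenerate; the function then subtracts the mean and warns. Whether the
  original analyses fitted the global image median or per-ROI traces is not
  determinable; this implementation fits per trace (after ROI averaging),
  which is exact for spatially uniform decay.

## Median filter

"Width-3 median in x, y and t" is implemented as three separable per-axis
passes (x, then y, then t), each with reflect padding — not a 3×3×3 cube
median. Axes shorter than 3 samples are skipped with a warning. The filter
never widens the value range and preserves the interior of piecewise-
constant regions, which is why noiseless planted amplitudes survive it
exactly.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions, fixed once:

* **Trace model**: F(t) = F_base · bleach(t) · (1 + A·k(t)) + noise, with
  F_base = 1000 a.u. and Gaussian noise SD 5 a.u. (0.5% of baseline) by
  default; a Poisson shot-noise mode is available. Default bleach is the
  logarithmic profile 1 − 0.02·ln(t + 1) (≈9% decay over 100 frames),
  i.e. the same family the correction fits; an exponential mode exists for
  robustness tests.
* **Transient kernel** k(t): linear rise over 2 frames from stimulus onset,
  plateau of 15 frames, then exponential decay (τ = 3 frames). Response
  kinetics are not numerically specified anywhere authoritative, so the
  kernel is a convention: the plateau covers both amplitude windows
  (frames 17–19 and 17–31), reflecting the sustained calcium-indicator
  response during and after a 1 s stimulus, and making the planted
  amplitude the exact window mean on noiseless data. All three parameters
  are configurable.
* **Ratiometric stacks**: inside each ROI, F340 is scaled by (1 + α·k) and
  F380 by (1 − α·k) with α = A/(2 + A), so the ratio change at the plateau
  equals the planted ΔR/R amplitude A exactly. Both channels share one
  bleach profile, which cancels in the ratio — as it does for a
  wavelength-independent bleaching mechanism.
* **Dose series**: responses follow the four-parameter logistic at the
  9-step ladder 0.1–1000 μg, with a 0 μg solvent point at the bottom
  asymptote. Default EC₅₀ 174.8 μg and Hill 4.71 (the reported 9-ODA
  values for one receptor ortholog); per-measurement Gaussian noise with
  SD 15% of the dynamic range, chosen to produce dose-wise SEMs of a few
  percent ΔF/F₀ at n = 12 animals, similar to the published error bars
  (no numeric noise level is reported, so this is the package's own
  calibration).
* **Spike trains**: piecewise-homogeneous Poisson (baseline rate outside
  the stimulus interval, stimulus rate inside) with a 3 ms absolute
  refractory period, as in a real neuron; a `regular` mode emits periodic
  trains for deterministic frequency tests. Rendered voltage traces place
  a ~2 ms biphasic waveform at each spike time on optional Gaussian noise.
* **Determinism**: every generator draws from
  `SeedSequence(seed, spawn_key=(replicate, ...))`, so replicate *i* is a
  pure function of (seed, *i*) — identical configs give byte-identical
  output and growing the replicate count never reshuffles earlier
  replicates.

What the generator does **not** emulate: optics/PSF blur, motion artifacts,
focal drift, mechanistic calcium dynamics (buffering, indicator
saturation), correlated (pink) noise, and inter-animal response-shape
variability beyond additive amplitude noise. Recovery results on synthetic
data therefore validate the arithmetic and statistical behavior of the
chain, not its robustness to those real-data artifacts.

## Sparseness

Negative amplitudes are clamped to zero *on the across-animal mean
spectrum* before evaluating the formula (the statistic is defined on the
response distribution); the number clamped is reported, and per-animal
clamping is available by preparing the matrix accordingly. The spectrum
includes all panel stimuli (controls included) by default;
`mean_spectra(exclude_stimuli=...)` supports sensitivity analyses without
controls. An all-zero spectrum after clamping has no defined tuning breadth
and raises rather than returning a silent 0 or 1.

## Dose-response fitting

The model is the variable-slope four-parameter logistic on log₁₀ dose.
Numerical choices:

* 0 μg solvent replicates enter the loss as direct observations of the
  bottom asymptote (never at a fake position on the log axis).
* Bounded trust-region least squares with an analytic Jacobian;
  deterministic multi-start over the EC₅₀ initialization (half-max
  crossing of the dose means plus a log-spaced grid). Hill coefficient
  bounded to (10⁻³, 50]; asymptote bounds extend 10× the observed response
  span beyond the data, since an asymptote need not be observed within the
  tested range.
* Steep curves at realistic noise have a nearly flat likelihood in the
  Hill direction (EC₅₀ stays well determined); iteration-capped runs whose
  gradient has collapsed are polished once and then accepted as converged.
  As a consequence the per-animal Hill coefficient is recovered with large
  upward spread at study-like noise — consistent with the very large Hill
  uncertainties reported for steep receptor curves — while median EC₅₀
  recovery error stays under 10%.
* Standard errors come from the Jacobian at the optimum (σ² = SSR/dof);
  the EC₅₀ SE is mapped from the log₁₀ scale by the delta method. Fits
  whose EC₅₀ falls outside the tested dose range carry an `extrapolated`
  flag and a warning rather than failing.
* Per-animal fitting is the default for between-receptor comparisons
  (rank tests need one value per animal); pooled fitting is available
  where a single curve per receptor is wanted.

## Hypothesis tests

All statistics are computed from the formulas (ranks, sums of squares)
rather than delegated, so intermediates are inspectable; scipy and
pingouin serve as independent cross-checks in the test suite only.

* **Friedman**: tie-robust χ² = (k−1)·Σ(Rⱼ − n(k+1)/2)²/(A − C) on
  within-row ranks. Exact permutation p-values enumerate all (k!)ⁿ row
  permutations (capped at 5·10⁵).
* **Kruskal–Wallis**: H = (N−1)·between-rank-SS/total-rank-SS (tie-robust);
  exact mode enumerates all group assignments.
* **Dunn post hoc**: z on mean ranks (variance k(k+1)/6n within subjects,
  tie-corrected N(N+1)/12 between groups), Bonferroni-adjusted by default
  with Holm available — the Bonferroni variant is the documented behavior
  of the software the analyses are usually run in.
* **RM-ANOVA**: classical two-way (animal × condition) decomposition;
  Greenhouse–Geisser ε = (tr Σ̃)²/((k−1)·ΣΣ̃²ᵢⱼ) from the double-centered
  condition covariance, applied to both degrees of freedom.
* **Dunnett**: many-to-one comparisons share the control, giving
  equicorrelation ½ among the t statistics; the familywise two-sided tail
  probability is computed by deterministic Gauss–Legendre × Gauss–Hermite
  quadrature (96 nodes each) over the scale-mixture representation of the
  equicorrelated multivariate t. Agreement with an adaptive-integration
  reference implementation is ~10⁻⁶, well inside the 10⁻⁴ target.
* Normality screening (Shapiro–Wilk) is reported by `normality_report` but
  never switches tests automatically — test choice is an explicit analysis
  decision.

Null calibration runs at the study-like layouts: Friedman at 12 animals ×
22 stimuli, Kruskal–Wallis at 4 groups × 12, and RM-ANOVA at 16 animals ×
4 conditions (the repeated-measures design used for electrophysiology-style
data, where k must stay below n for the sphericity estimate to be
well-conditioned). Empirical type-I error at α = 0.05 over 2000 null
replicates falls in [0.03, 0.07] for all three; the Greenhouse–Geisser
test is mildly conservative under exact sphericity, as expected.

## Spike analysis

Detection: zero-phase 300 Hz high-pass, threshold k·MAD/0.6745 with k = 5,
upward-crossing events merged within a 2 ms refractory window and timed at
the local maximum. On (near-)noiseless traces the MAD measures filter
ripple rather than noise, so the threshold falls back to half the peak
amplitude; an all-flat trace returns an empty train with a warning. These
parameters are package defaults, not facts about any particular recording
software, and all are configurable. Instantaneous frequency assigns 1/ISI
to each inter-spike interval and zero outside the spiking epoch; mean
response rate is the stimulus-window count rate minus the baseline-window
count rate (subtraction optional).

## Clustering

Dendrograms use Euclidean distance on mean (optionally min–max normalized)
spectra with average (UPGMA) linkage. The metric/linkage pair is not
dictated by anything in the analysis design, so the conventional choice is
used and always recorded in the `DendrogramResult`; Newick export derives
branch lengths from merge-height differences.

## Problem sizes

The test suite and acceptance script use: 200 Monte-Carlo dose series of
12 animals for EC₅₀ recovery; 2000 null replicates per test family for
type-I calibration; 100 panel seeds for clustering separation; 20 random
10×10×10 stacks for the median-filter oracle; 10⁴ random spectra for the
sparseness bound. These sizes give Monte-Carlo standard errors comfortably
below the tolerances being checked.

## Known limitations

* No image registration or movement correction; ROIs are assumed static.
* No glomerulus segmentation — ROI placement is the user's.
* The logarithmic bleach model is a convention (see above); traces whose
  decay is strongly non-logarithmic should use the blank-subtraction or
  exponential paths.
* Exact permutation modes are exponential in table size and refuse beyond
  5·10⁵ arrangements.
* The Hill coefficient is weakly identified on steep curves at realistic
  noise; compare EC₅₀s, not Hill slopes, unless the design is dense around
  the EC₅₀.
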