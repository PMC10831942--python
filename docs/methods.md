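# Methods

This note documents the models behind `smlmdiff`, the parameters that matter,
what the synthetic-data generator does and does not emulate, the numerical
choices, and the known limitations — in particular the estimator biases a
user must keep in mind when reading absolute diffusivities off the outputs.

## Imaging model and synthetic data

The generator (`smlmdiff.synthdata`) emulates sparse-photoactivation
single-molecule imaging of membrane proteins: each molecule appears at a
uniformly random position and start frame, performs 2-D Brownian motion with
per-axis per-frame displacement variance 2·D·Δt, and disappears after a
geometrically distributed number of frames (memoryless photobleaching; the
geometric law is the simplest model consistent with a constant per-frame
survival probability). Observed positions are the true positions plus
isotropic Gaussian noise of SD `sigma_loc`. Defaults mirror the imaging
regime the analysis was designed for:

| parameter        | default | unit  | meaning                                   |
|------------------|---------|-------|-------------------------------------------|
| `dt`             | 0.03    | s     | camera dwell time / frame interval        |
| `sigma_loc`      | 30      | nm    | localization precision (SD per axis)      |
| `mean_track_len` | 8       | frames| mean trajectory length before bleaching   |
| `pixel_size`     | 109     | nm    | camera pixel in the sample plane          |
| `fov`            | 20×20   | µm    | field of view                             |
| `n_frames`       | 10 000  | —     | movie length                              |

Molecules whose true position leaves the field of view are truncated there
(they leave the evanescent TIRF excitation field) rather than reflected. In
lesion-gradient mode a molecule's D is evaluated once, at its initial radial
distance r from the lesion center, from D(r) = D₀·e^(−r/r₀) + D∞; it is not
re-evaluated as the molecule moves, because the downstream annulus analysis
also bins whole trajectories. Per-localization quality columns are drawn as
|N(30, 8)| nm precision and N(140, 15) nm spot SD so the quality filters
operate on realistic inputs. The frame renderer draws each emitter as a
Gaussian PSF of SD 1.3 px with Poisson shot noise and a constant camera
offset.

Not emulated: photoconversion photophysics and blinking (trajectories have no
gaps, matching the linker's no-gap rule), EM-gain noise statistics, sample
drift, and spatially varying background. Consequently, passing tests
demonstrate correctness of the analysis chain under the stated statistical
model — they do not certify performance on data with drift, heavy blinking or
structured background.

Emitter density is not fixed by the model; the pipeline logs the realized
spots/µm²/frame as a diagnostic. Linking was validated at densities up to
0.05 spots/µm²/frame (≥ 99% ground-truth link agreement); defaults keep
simulations well below that.

## Localization and filtering

Spots are local maxima fit with a plain least-squares 2-D Gaussian
(offset + amplitude, 7×7 px window). The localizer is deliberately simple:
downstream analysis needs only positions, a spot-size and a precision
estimate. Precision is the shot-noise proxy spot_sd/√N with N the integrated
photon count; it reproduces the 1/√N scaling but ignores pixelation and
background terms of more complete treatments, so it should be read as a
relative, not absolute, uncertainty. Filtering keeps localizations with spot
SD ≥ 109 nm **and** precision ≤ 70 nm; both rejections are strict
inequalities, and the operation is idempotent.

## Linking

Localizations in consecutive frames are matched by the Hungarian algorithm on
squared displacement, with pairs beyond the 500 nm search radius masked by a
penalty chosen just above the largest feasible total cost — the solver then
maximizes the number of feasible links first and minimizes summed squared
displacement second, and the penalty stays small enough that genuine cost
differences are never lost to floating-point absorption. There is no gap
closing, merging or splitting. Exact cost ties (measure zero for continuous
coordinates) resolve by the solver's deterministic order. Per-frame-pair
assignment is equivalent to global multi-frame optimization at the low
densities of sparse photoactivation.

## Diffusion estimation

For each trajectory of length L ≥ 9 frames the time-averaged MSD is computed
for lags n = 1 … L−4, so every retained lag averages at least four
displacement pairs, and an unweighted ordinary-least-squares line
msd = 4·D·t + c is fit over those (≥ 4) lag points. The intercept c absorbs
the localization-error offset 4·σ²_loc and is reported as fitted, negative
values included. D = |slope|/4: near-immobile molecules frequently produce
negative noisy slopes, and folding them keeps those events in the analysis at
the price of a positive bias on arithmetic means at very low D. `max_lag`
optionally restricts the regression to the first lags; the default uses all
retained lags.

**Distribution of the estimates.** For a well-defined D, the per-trajectory
estimates from short tracks scatter approximately log-normally, which is why
the analysis is carried out on D̃ = log₁₀(D/1 µm²s⁻¹) and why histograms of
D̃ are modeled with Gaussians. The approximation is good but not exact: the
modulus rule folds near-zero slopes into a left tail (skewness ≈ −1 under the
default conditions), so formal normality tests on large samples reject. A
single log-Gaussian still captures ≥ 85% of the histogram variance for a
single population, which is the operational sense in which the mixture model
is used.

**Calibration.** On simulated single-population data (D = 0.1 µm²/s,
σ_loc = 30 nm, Δt = 30 ms, lengths 9–15, ~10⁴ trajectories) the mean of the
D estimates is within 5% of truth and the mean intercept within 20% of
4σ²_loc = 0.0036 µm².

## Mixture decomposition

D̃ values are histogrammed with bin width 0.2, edges anchored at integer
multiples of 0.2 so histograms from different conditions share a grid, and
area-normalized. The mixture model is a sum of J normalized Gaussians on the
D̃ axis with fractions on the simplex. Several histograms are fit in a single
run with centers and the common width shared between them (the model is
written with per-component widths; the default ties them to a single shared
value), leaving only per-dataset fractions free — 3J−1 parameters for one
dataset, J+1 shared plus (J−1) per extra dataset in the global fit.

Numerical choices: fractions are reparameterized through a softmax so the
simplex constraint is exact; centers are bounded to the data range ± one bin;
optimization uses a deterministic quantile-spread start plus 10 seeded random
restarts, best objective wins, ties to the first found. Two objectives are
available:

* `loss="density"` (default) — unweighted least squares between the mixture
  density at the bin centers and the observed densities. Chosen as default
  because it is robust to the mildly skewed component tails that real
  per-trajectory estimates carry.
* `loss="ml"` — multinomial maximum likelihood of the bin counts under
  bin-integrated probabilities. More efficient when the data truly are a
  log-Gaussian mixture, but it can sacrifice a component to an unmodeled
  tail, so it is opt-in.

Fraction uncertainties are asymptotic (least-squares covariance or inverse
observed information, propagated through the softmax by the delta method);
they quantify curvature at the optimum, not model error. J is user-chosen;
no information-criterion selection is attempted.

**Resolution limits.** With 30 000 samples from a true 3-component mixture
(centers −2.63/−1.86/−1.14, shared σ̃ = 0.43) the global fit recovers centers
within ±0.05, the width within ±0.03 and fractions within ±0.03. Through the
full pipeline (simulate → link → estimate → fit) the apparent per-population
distributions widen to σ̃ ≈ 0.57 and acquire the left-skew described above;
populations separated by ≥ 1.1 decades in D are then resolved with fraction
errors ≤ 0.07, while at ~0.7-decade separation the symmetric-Gaussian
decomposition genuinely reallocates mass between neighboring components and
ground-truth fractions are not recoverable to that precision. Interpret
fitted fractions accordingly when populations are closer than about a decade.

The peak diffusivity D_pk of the dominant population is obtained by fitting a
Gaussian to the contiguous run of histogram bins above half the global
maximum (at least 3 bins), D_pk = 10^center.

Population shifts between two conditions are reported relative to the
pre-lesion population-1 fraction: loss = 100·(f₁ᵇ − f₁ᵃ)/f₁ᵇ and, for each
k ≥ 2, gain = 100·(fₖᵃ − fₖᵇ)/f₁ᵇ.

## Annulus profiles

Trajectories are assigned to 2 µm annuli (outer radii 2–10 µm) by the radial
distance of their **mean** position — robust for short tracks; assignment by
first localization is available — with interval convention (inner, outer], r
exactly on an outer edge belonging to the inner annulus and r > 10 µm
excluded. Per annulus the diffusivity is averaged on the logarithmic scale
(geometric mean). Distance fits use the annulus midpoint (outer − 1 µm) as
abscissa: exponential D(r) = D₀·e^(−r/r₀) + D∞ by bounded nonlinear least
squares (initialized at D∞ ← min, D₀ ← range, r₀ ← half the radial span) or a
straight line by OLS; R² = 1 − SS_res/SS_tot with the convention R² = 0 when
SS_tot = 0.

**Known bias.** The geometric mean of per-trajectory estimates is compressed
by a near-constant multiplicative factor (≈ 0.55 under the default
conditions: σ_loc = 30 nm, mean 8 frames, D in the 0.014–0.043 µm²/s range),
because log-averaging penalizes the folded low-|slope| tail. A constant
factor rescales D₀ and D∞ but leaves r₀ — the spatial range of the lesion's
influence — intact; arithmetic per-annulus means are unbiased within ~5% and
can be used when absolute scale matters. This is an intrinsic property of
log-averaged short-track MSD estimates, present equally in measured data, so
profile amplitudes should be compared between conditions, not read as true
diffusion coefficients. The five-point exponential fit on a shallow profile
is also sensitive to small per-annulus wobble; r₀ estimates carry run-to-run
spreads of order 15–30% at ~2000 trajectories per annulus.

## Intensity kinetics

Lesion-site traces are corrected as I(t) = (I_raw(t) − BG)/BL(t). BG is a
scalar (mean of a background ROI) by default, with a per-frame option. BL is
fit on a reference ROI far from the lesion after normalizing to its t = 0
value, as BL(t) = A·e^(−t/τ₁) + (1−A)·e^(−t/τ₂) with A ∈ [0, 1],
τ ∈ [dt, 100 × duration], deterministic initialization (A = 0.5,
τ₁ = duration/10, τ₂ = duration). BL(0) = 1 by construction; a constant
reference drives the τs to the upper bound and the correction becomes the
identity within ~1%. ROI extraction and manual lesion re-centering are
treated as upstream annotation — the module consumes already-extracted mean
traces.

Noise propagation: dividing by BL amplifies the raw-trace noise by 1/BL(t),
so the round-trip accuracy bound (corrected-trace RMSE ≤ 2× the injected
noise SD, verified in the tests at 60 frames × 5 s with A = 0.3, τ₁ = 60 s,
τ₂ = 1000 s) presumes an acquisition in which bleaching stays moderate
(BL ≳ 0.5 over the record) — the regime a low-frame-rate time-lapse protocol
is designed for. Deeply bleached traces are corrected without error, but
their late-time points are proportionally noisier.

## Statistics

Survival endpoints are 2×2 alive/dead counts compared with the two-sided
Fisher exact test (minimum-likelihood convention: sum of all hypergeometric
table probabilities not exceeding that of the observed table — the behavior
of mainstream statistics software, cross-checked in the tests against full
enumeration). Group comparisons use unpaired two-sided Welch t-tests (the
variance assumption is deliberately the weaker one; an equal-variance option
exists) with Holm step-down adjustment across the comparison family.

## Pipeline and reproducibility

`run_pipeline` derives independent per-stage random streams from one master
seed, so toggling a stage does not perturb the others and identical
configurations produce identical outputs. Each run directory contains every
intermediate table, the model file, a machine-readable summary, a log with
all parameters and rejection counts, and a copy of the configuration — enough
to reproduce the run exactly. Distances are stored in nm in all files and
converted to µm at analysis boundaries.

Simulation sizes used by the test suite and the acceptance script: 30 000
molecules for estimator calibration (~10⁴ eligible tracks), 30 000 D̃ samples
for mixture recovery, 240 000 molecules for the lesion-gradient profile
(≥ 2000 eligible trajectories in every annulus), 60-frame intensity traces.
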