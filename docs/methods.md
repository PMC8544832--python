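# Methods

This note documents the models, priors, numerical choices and known
limitations of the package, in the spirit of a statistical methods
appendix.

## Forward model

The baseline CRF is `resp(C) = R_max·C^p/(Z + C²) + 1` with contrast `C`
in percent (0–100).  The percent scale is used throughout: semi-saturation
constants around 100–150 are only meaningful on that scale.  The
denominator exponent is fixed at 2; only the numerator exponent `p` is
free, so the function saturates for p = 2, accelerates above, and
super-saturates below.  The additive 1 expresses the measurement as an
SNR whose noise floor is 1.

Masking is parameterised as `resp(C) = (R_max/r)·C^p/(g·Z + C²) + 1`.
The response-gain weight `r` *divides* the response range; with this
algebra both `r > 1` and `g > 1` are suppressive, which is the convention
used for all credibility calls.  The alternative placement (r multiplying
R_max) was rejected because it would make r > 1 facilitatory and break
that symmetry.  For p = 2 the semi-saturation contrast is `sqrt(g·Z)`:
`g` shifts the curve laterally by `sqrt(g)` while `r` rescales it
vertically without moving it — the two canonical signatures of contrast
gain and response gain.

## Saturation indices

For target-contrast response functions the saturation index is
`SI = (R(c_hi) − R(c_next))/max(R)` over the two largest *tested*
contrasts — taken from the data rather than hard-coded at 48/96%, so
designs whose top contrast was reduced (88% or 68% for some monocular
mask conditions) are handled naturally.  For mask-contrast sweeps the
function is decreasing, so the modified index inverts the difference and
scales by the function minimum: `SI = (R(m_next) − a·R(m_hi))/min(R)`.
The factor `a` (default 1) is an explicit caller-supplied adjustment for
designs where the top mask contrast had to be lowered; no hidden constant
is applied.

## Spectral front-end

Each trial is trimmed by 1 s (onset transient) and a 10-s window is
Fourier transformed, giving 0.1 Hz bins.  Spectra are single-sided
amplitude spectra scaled so that a unit-amplitude sinusoid on an exact
bin yields amplitude 1 (DC and Nyquist are not doubled); the scaling is
irrelevant to SNR, which is invariant to global rescaling, but the
convention is fixed and tested.  Repetitions of a condition are averaged
*coherently* (complex mean), so phase-locked signal is preserved while
phase-random noise cancels as 1/sqrt(T).  SNR at a harmonic is the
amplitude in its bin divided by the mean amplitude of the 10 neighbouring
bins (±0.5 Hz in 0.1 Hz steps, signal bin excluded; the bins immediately
adjacent to the signal bin are *included*, as the ±0.5 Hz specification
implies).  Amplitude, not power, spectra are used throughout.  Defaults
(1 kHz sampling, 5 and 10 Hz harmonics, 6 trials per condition) are all
configurable.  No artifact rejection or re-referencing is implemented.

## Two-stage inference

Stage separation is deliberate: baseline parameters are estimated from
no-mask data only, then frozen, so they cannot trade off against the
suppression weights.  Stage-1 uncertainty is *not* propagated into
stage 2 (point estimates are passed on), mirroring the two-stage design;
this understates stage-2 posterior width when baselines are noisy.

**Simplex path** (meta-analysis, heterogeneous units): Nelder-Mead
minimisation of RMSE on log-parameters (which enforces positivity), best
of 5 jittered restarts plus a polishing run, with tight tolerances
(xatol 1e-10, fatol 1e-12).  The achieved RMSE is oracle-bounded in the
tests against an exhaustive 20³ log-spaced grid.

**Hierarchical path** (experiments, homogeneous units): group means of
`R_max`, `p`, `Z` carry normal hyperpriors N(5, 2), N(2, 0.25),
N(100, 40), truncated to positive values.  Unit-level parameters are
lognormal around the group means (the link is a modelling choice; it
preserves positivity and yields a scale-free spread parameter), with
half-normal(0.5) priors on the log-scale spreads.

**Stage 2**: group-level weights `r` and `g` carry gamma(shape 1.5,
rate 0.5) hyperpriors, whose density peaks at (α−1)/β = 1 — the modal
prior assumption is "no suppression", with more mass above 1 than below.
Unit-level weights follow gamma distributions whose *mode* equals the
group-level weight: shape k = 1 + 1/s², rate 1/(s²m), where s ≈ the
coefficient of variation and carries a half-normal(0.5) prior.  This
mode-matched link keeps the group parameter interpretable as the typical
unit's weight and preserves the mode-at-1 null.  Each mask type is fitted
independently.

**Likelihood**: Gaussian observation noise on SNR with a single noise SD
per fit, given a half-normal(1) prior.  SNR observations are not truly
Gaussian (spectral amplitude ratios are right-skewed), but at the SNR
levels and trial counts of interest the approximation is mild; this is
the main distributional simplification of the package.

**Sampler**: affine-invariant ensemble MCMC (emcee) with
differential-evolution moves (80% DEMove, 20% DESnookerMove), which mix
far better than stretch moves on the correlated, funnel-shaped
hierarchical posteriors here.  All positive parameters are sampled on the
log scale with the appropriate Jacobians.  The default configuration is
4 independent chains (each its own seeded ensemble), 1000 warmup steps,
and 1000 kept draws per chain (the final ensemble states flattened across
walkers).  Split-Rhat and bulk ESS are computed across chains with arviz;
a fit is flagged non-converged when any monitored group parameter has
rhat > 1.05 or ESS < 400 — flagged, never silently returned.  Fixed seed
and chain count give bitwise-identical draws.

**Summaries**: the 95% HDI is the first shortest window of ⌈0.95·n⌉
sorted draws (ties broken by sorted order).  Credibility: suppression if
the HDI lies entirely above 1, facilitation if entirely below, otherwise
not credible.  Directed comparisons use the posterior exceedance
probability — the fraction of one posterior's draws at or above the
other's mean; no multiple-comparison correction is applied, but reports
carry the number of comparisons made.

## Synthetic data

The generators are pure functions of (truth, design, seed) and define the
validation conditions of the package.

*CRF tables*: per unit, baseline parameters are jittered lognormally
(default log-scale SD 0.1) around the group truth
(R_max = 5, p = 2, Z = 120); condition means come from the forward model
and observations add Gaussian noise (default SD 0.3 SNR units) floored at
zero.  A multiplicative lognormal noise option exists for robustness
checks.  The default design is the full main experiment: 6 target
contrasts (0–96%) × (baseline + 4 mask types at the principal mask
contrast) plus a 3-level mask-contrast sweep at a fixed 24% target — 42
conditions.  The stage-2 recovery suites use *pure* weight truths (every
unit exactly at the stated r and g, `weight_jitter = 0`), which isolates
the stage-2 estimator from population heterogeneity in the weights.

*Mask-contrast sweeps*: the generative link between mask contrast and
suppression weight is not part of the fitted model, so the generator
makes it explicit: the weight excess (w − 1) scales with a mask drive
that is quadratic in mask contrast (linear suppressive-signal energy) or,
optionally, passes through a transducer `m^q/(z_m + m²)` whose exponent
q < 2 makes the mask signal super-saturate.  The drive is normalised so
the stated weights hold exactly at the principal mask contrast.

*Epochs*: trials are 11 s at 1 kHz — phase-locked sinusoids at the first
two harmonics of the 5 Hz flicker plus broadband Gaussian noise (white by
default; a 1/f^β option exists since real EEG is pink).  Phases are
constant across trials within a condition.  Harmonic amplitudes are
calibrated so the *expected* SNR after coherently averaging the
condition's trials equals the forward-model prediction: the averaged
noise floor for time-domain SD σ is f = σ·sqrt(π/n)/sqrt(T), and because
the signal bin also contains noise, the required amplitude is
A = f·sqrt(max(S² − 4/π, 0)) — a target SNR of 1 maps to zero amplitude.
The second-harmonic driven component is a configurable fraction (default
0.5) of the first's, since on-off flicker fixes only the harmonic
structure, not the amplitude ratio.  What the generator does *not*
emulate: volume conduction and electrode covariance, eye-movement and
blink artifacts, non-stationary noise, and any true generative link
between stimulus nonlinearity and the second harmonic.  Passing recovery
tests therefore demonstrate correctness of the estimator under the
stated noise model, not robustness to real-EEG pathologies.

## Problem sizes used in validation

Recovery suites use 12 units × 6 contrasts with noise SD 0.3, 20 seeded
replicates per truth direction, and the default sampler settings; the
meta-analysis recovery uses 16 heterogeneous studies × 10 replicates; the
end-to-end check uses 2 electrodes × 2 harmonics × 12 units of simulated
epochs.  These sizes match the emulated experiments while keeping the
full suite fast enough for routine continuous testing.

## Known limitations

* Stage-1 uncertainty is not propagated; with noisy baselines the stage-2
  weights inherit bias (visible in the README example, where g is
  recovered at ~2.4 against a generating value of 3 when baselines come
  from per-unit simplex fits of noisy data).
* `r` and `g` trade off when the masked CRF is shallow (strong
  suppression or few contrasts); the identifiability test records the
  clean-data behaviour, but in noisy regimes the joint posterior is
  ridge-shaped and marginal HDIs can exclude the truth in a minority of
  replicates.
* The Gaussian SNR likelihood is an approximation to the skewed
  distribution of spectral amplitude ratios.
* The ensemble sampler can mix slowly in the small-spread funnel (unit
  spreads near zero); such fits are flagged by the rhat/ESS gates rather
  than repaired automatically.
* Alternative normalization variants (mask-contrast denominator terms,
  tuned gain pools, subtractive inhibition) are out of scope.
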