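# ssvep-gain

Analysis pipeline for asking a classic question in visual neuroscience:
when a mask stimulus suppresses the steady-state visual evoked potential
(SSVEP) response to a target, does it act through **contrast gain**
(shifting the contrast response function laterally) or **response gain**
(scaling it vertically)?  The package is aimed at researchers working with
frequency-tagged EEG who want a tested, reproducible implementation of the
two-stage gain-control analysis, together with synthetic-data generators
that make every step verifiable against known ground truth.

## The model

The baseline contrast response function (CRF) is a divisive gain-control
(hyperbolic-ratio) transducer expressed in signal-to-noise units:

```
resp(C) = R_max · C^p / (Z + C²) + 1
```

where `C` is target Michelson contrast in percent, `R_max` scales the
response range, `Z` positions the function on the contrast axis, and `p`
sets its shape (accelerating for p > 2, saturating at p = 2,
super-saturating below).  The `+1` is the noise floor of an SNR measure.
Masking introduces two weights:

```
resp(C) = (R_max / r) · C^p / (g·Z + C²) + 1
```

`r` (response gain) divides the response range; `g` (contrast gain)
multiplies the semi-saturation constant.  Weights above 1 are
suppressive, below 1 facilitatory, and `r = g = 1` recovers the baseline
model exactly.

Fitting proceeds in two stages so the baseline parameters cannot trade
off against the suppression weights: stage 1 estimates `(R_max, p, Z)`
from the no-mask data (per-unit downhill simplex for heterogeneous
meta-analytic data, or a hierarchical Bayesian fit when all units saw the
same stimuli); stage 2 holds them fixed and estimates `(r, g)`
hierarchically per mask type, with gamma(1.5, 0.5) hyperpriors whose mode
is 1 — the prior assumption of "no suppression".  Suppression is called
credible when the 95% highest-density interval (HDI) of the group
posterior excludes 1.

The spectral front-end converts multi-trial voltage epochs to harmonic
SNRs: trim the onset transient, FFT a 10-s window (0.1 Hz bins),
coherently average the complex spectra across repetitions, and divide the
amplitude at each harmonic by the mean amplitude of the 10 neighbouring
bins (±0.5 Hz in 0.1 Hz steps).

## Worked example

Simulate a 12-participant experiment whose ground truth is pure contrast
gain (`g = 3, r = 1`) for a dichoptic mask, fit baselines per unit, then
estimate the suppression weights hierarchically:

```python
from ssvep_gain import *
from ssvep_gain.inference import SamplerConfig

truth = GroundTruth(weights={"dichoptic": SuppressionWeights(r=1.0, g=3.0)},
                    weight_jitter=0.0)
design = DesignSpec(mask_types=("dichoptic",), sweep_mask_contrasts=(), n_units=12)
table, record = simulate_crf_table(truth, design, seed=1)

baselines = {}
for unit, rows in table[table.mask_type == "none"].groupby("unit"):
    baselines[unit], rmse = fit_baseline_simplex(rows.target_contrast, rows.snr, seed=1)

fit = fit_suppression_hierarchical(table, baselines, SamplerConfig(seed=1))["dichoptic"]
for name in ("g", "r"):
    s = fit.group[name]
    print(f"{name}: mean {s.mean:.2f}  95% HDI ({s.hdi_low:.2f}, {s.hdi_high:.2f})  "
          f"{credible_suppression(s)}  rhat {s.rhat:.3f}")
```

Output:

```
g: mean 2.43  95% HDI (2.06, 2.88)  credible_suppression  rhat 1.023
r: mean 1.00  95% HDI (0.98, 1.02)  not_credible  rhat 1.030
```

The contrast-gain weight is credibly above 1 (its HDI excludes 1) and
close to the generating value of 3 — the shortfall reflects noise in the
per-unit simplex baselines — while the response-gain weight straddles 1:
the analysis correctly attributes the suppression to contrast gain.

A command-line interface wraps the same machinery
(`ssvep-gain simulate | fit-meta | fit-experiment | mask-sweep | report`);
run `ssvep-gain --help` for details.

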