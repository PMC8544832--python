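"""Synthetic-data generators with known ground truth.

Three generators cover every input the pipeline consumes:

* :func:`simulate_crf_table` — tidy contrast-response (SNR) tables from the
  forward gain-control model, with lognormal unit-level parameter jitter
  and additive Gaussian observation noise floored at zero (a multiplicative
  lognormal noise option is provided for robustness checks);
* :func:`simulate_epochs` — phase-locked sinusoidal harmonics embedded in
  broadband noise, calibrated so the expected post-coherent-averaging SNR
  equals the forward-model prediction for each condition;
* :func:`simulate_meta_analysis` — heterogeneous per-study tables
  emulating a literature meta-analysis (different contrast grids, mask
  types, and noise per study).

Every generator is a pure function of (truth, design, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gain_model import GainParams, SuppressionWeights, baseline_response, masked_response
from .spectral import CRF_COLUMNS, EpochSet, Trial

__all__ = [
    "GroundTruth",
    "DesignSpec",
    "StudySpec",
    "simulate_crf_table",
    "simulate_epochs",
    "simulate_meta_analysis",
    "amplitude_for_snr",
]


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters for the synthetic experiment.

    ``weights`` maps mask type to its suppression weights at the principal
    mask contrast.  ``unit_jitter`` and ``weight_jitter`` are lognormal
    standard deviations (on the log scale) of the unit-level variation
    around the group values.  ``noise_sd`` is the additive observation
    noise on SNR.  ``harmonic2_scale`` scales the driven (above-floor)
    component of the second-harmonic response relative to the first.
    ``mask_semisaturation`` switches the mask drive from linear in mask
    energy (None) to a saturating transducer with the given
    semi-saturation constant; ``mask_drive_exponent`` is the numerator
    exponent of that transducer (values below 2 make the mask signal
    super-saturate).  ``electrode_weights`` optionally overrides
    ``weights`` per electrode.
    """

    gain: GainParams = GainParams(r_max=5.0, p=2.0, z=120.0)
    weights: Mapping[str, SuppressionWeights] = field(
        default_factory=lambda: {
            "monocular": SuppressionWeights(r=1.0, g=3.0),
            "dichoptic": SuppressionWeights(r=1.0, g=3.0),
            "aligned": SuppressionWeights(r=1.0, g=2.0),
            "orthogonal": SuppressionWeights(r=1.0, g=2.0),
        }
    )
    unit_jitter: float = 0.1
    weight_jitter: float = 0.1
    noise_sd: float = 0.3
    harmonic2_scale: float = 0.5
    mask_semisaturation: float | None = None
    mask_drive_exponent: float = 2.0
    electrode_weights: Mapping[str, Mapping[str, SuppressionWeights]] | None = None

    def weights_at(self, electrode: str | None = None) -> Mapping[str, SuppressionWeights]:
        if electrode is not None and self.electrode_weights is not None:
            return self.electrode_weights[electrode]
        return self.weights

    def record(self) -> dict:
        """JSON-serialisable record of the ground truth."""

        def enc(obj):
            if isinstance(obj, (GainParams, SuppressionWeights)):
                return asdict(obj)
            if isinstance(obj, Mapping):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        return {k: enc(v) for k, v in asdict(self).items()}


@dataclass(frozen=True)
class DesignSpec:
    """Experimental design: conditions, units, trials and flicker frequency.

    The default enumerates the main experiment: 6 target contrasts crossed
    with baseline plus 4 mask types at the principal mask contrast, plus a
    mask-contrast sweep (3 extra levels x 4 mask types) at a fixed 24%
    target contrast — 42 conditions in total.
    """

    target_contrasts: Sequence[float] = (0.0, 6.0, 12.0, 24.0, 48.0, 96.0)
    mask_types: Sequence[str] = ("monocular", "dichoptic", "aligned", "orthogonal")
    principal_mask_contrast: float = 12.0
    sweep_mask_contrasts: Sequence[float] = (6.0, 48.0, 96.0)
    sweep_target_contrast: float = 24.0
    n_units: int = 12
    trials_per_condition: int = 6
    electrodes: Sequence[str] = ("Oz",)
    flicker_hz: float = 5.0

    def __post_init__(self) -> None:
        for c in (
            *self.target_contrasts,
            self.principal_mask_contrast,
            *self.sweep_mask_contrasts,
            self.sweep_target_contrast,
        ):
            if not 0 <= c <= 100:
                raise ValueError(f"contrast {c!r} outside [0, 100]")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")

    def conditions(self) -> list[dict]:
        """Enumerate all conditions as dicts with id, mask type/contrast, target."""
        conds = []
        for tc in self.target_contrasts:
            conds.append(
                {
                    "condition": f"base_t{tc:g}",
                    "mask_type": "none",
                    "mask_contrast": 0.0,
                    "target_contrast": tc,
                }
            )
        for mt in self.mask_types:
            for tc in self.target_contrasts:
                conds.append(
                    {
                        "condition": f"{mt}_m{self.principal_mask_contrast:g}_t{tc:g}",
                        "mask_type": mt,
                        "mask_contrast": self.principal_mask_contrast,
                        "target_contrast": tc,
                    }
                )
            for mc in self.sweep_mask_contrasts:
                conds.append(
                    {
                        "condition": f"{mt}_m{mc:g}_t{self.sweep_target_contrast:g}",
                        "mask_type": mt,
                        "mask_contrast": mc,
                        "target_contrast": self.sweep_target_contrast,
                    }
                )
        return conds


def _unit_gain(truth: GroundTruth, rng: np.random.Generator) -> GainParams:
    j = truth.unit_jitter
    g = truth.gain
    return GainParams(
        r_max=g.r_max * np.exp(j * rng.standard_normal()),
        p=g.p * np.exp(j * rng.standard_normal()),
        z=g.z * np.exp(j * rng.standard_normal()),
    )


def _unit_weights(w: SuppressionWeights, jitter: float, rng: np.random.Generator) -> SuppressionWeights:
    return SuppressionWeights(
        r=w.r * np.exp(jitter * rng.standard_normal()),
        g=w.g * np.exp(jitter * rng.standard_normal()),
    )


def _mask_drive(mc: float, truth: GroundTruth) -> float:
    """Suppressive drive of a mask at contrast ``mc`` (unnormalised).

    Linear regime (``mask_semisaturation`` None): drive = mc**2, the mask's
    contrast energy.  Otherwise the drive passes through a transducer
    mc**q / (zm + mc**2); q < 2 makes the drive super-saturate (decrease)
    at high mask contrasts.
    """
    if truth.mask_semisaturation is None:
        return mc**2
    zm = truth.mask_semisaturation
    return mc**truth.mask_drive_exponent / (zm + mc**2)


def _effective_weights(
    w: SuppressionWeights, mc: float, principal_mc: float, truth: GroundTruth
) -> SuppressionWeights:
    """Scale the weight excess by the mask drive, normalised to the principal contrast.

    At the principal mask contrast the stated weights hold exactly; at other
    contrasts the suppressive excess (w - 1) scales with the mask drive,
    which is quadratic in mask contrast (linear suppressive signal energy)
    or saturating when ``mask_semisaturation`` is set.
    """
    if mc == principal_mc:
        return w
    scale = _mask_drive(mc, truth) / _mask_drive(principal_mc, truth)
    return SuppressionWeights(
        r=max(1.0 + (w.r - 1.0) * scale, 1e-6),
        g=max(1.0 + (w.g - 1.0) * scale, 1e-6),
    )


def _condition_mean(
    cond: Mapping[str, object],
    gain: GainParams,
    weights: Mapping[str, SuppressionWeights],
    truth: GroundTruth,
    principal_mc: float,
) -> float:
    tc = float(cond["target_contrast"])
    if cond["mask_type"] == "none":
        return baseline_response(tc, gain)
    w = _effective_weights(
        weights[str(cond["mask_type"])], float(cond["mask_contrast"]), principal_mc, truth
    )
    return masked_response(tc, gain, w)


def simulate_crf_table(
    truth: GroundTruth,
    design: DesignSpec,
    seed: int,
    noise: str = "gaussian",
    harmonics: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a tidy contrast-response table directly from the forward model.

    Observation noise is additive Gaussian floored at zero by default;
    ``noise="lognormal"`` switches to multiplicative lognormal noise with
    matched log-scale SD.  Returns the table and a ground-truth record
    (group truth plus realised per-unit parameters).
    """
    if noise not in ("gaussian", "lognormal"):
        raise ValueError(f"unknown noise model {noise!r}")
    rng = np.random.default_rng(seed)
    harmonics = list(harmonics) if harmonics is not None else [design.flicker_hz]
    conds = design.conditions()
    rows = []
    unit_record = {}
    for i in range(design.n_units):
        unit = f"unit{i + 1:02d}"
        gain = _unit_gain(truth, rng)
        unit_record[unit] = {"gain": asdict(gain), "weights": {}}
        for electrode in design.electrodes:
            wmap = {
                mt: _unit_weights(w, truth.weight_jitter, rng)
                for mt, w in truth.weights_at(electrode).items()
            }
            unit_record[unit]["weights"][electrode] = {
                mt: asdict(w) for mt, w in wmap.items()
            }
            for cond in conds:
                mean1 = _condition_mean(
                    cond, gain, wmap, truth, design.principal_mask_contrast
                )
                for h_idx, f in enumerate(harmonics):
                    mean = (
                        mean1
                        if h_idx == 0
                        else 1.0 + (mean1 - 1.0) * truth.harmonic2_scale
                    )
                    if truth.noise_sd == 0:
                        obs = mean
                    elif noise == "gaussian":
                        obs = max(mean + truth.noise_sd * rng.standard_normal(), 0.0)
                    else:
                        obs = mean * np.exp(
                            truth.noise_sd * rng.standard_normal()
                            - truth.noise_sd**2 / 2
                        )
                    rows.append(
                        {
                            "unit": unit,
                            "condition": cond["condition"],
                            "mask_type": cond["mask_type"],
                            "mask_contrast": cond["mask_contrast"],
                            "target_contrast": cond["target_contrast"],
                            "electrode": electrode,
                            "harmonic_hz": f,
                            "snr": obs,
                        }
                    )
    table = pd.DataFrame(rows, columns=CRF_COLUMNS)
    record = {"group": truth.record(), "units": unit_record, "seed": seed}
    return table, record


# --------------------------------------------------------------------------
# epoch simulation
# --------------------------------------------------------------------------

_AMPLITUDE_BIAS = 4.0 / np.pi  # E|A + n|^2 = A^2 + (4/pi) * floor^2 for complex n


def amplitude_for_snr(target_snr: float, floor: float) -> float:
    """Signal-bin amplitude that yields ``target_snr`` after averaging.

    The measured amplitude in the signal bin includes the noise there, so
    E|A + n| ~ sqrt(A^2 + (4/pi) f^2) where f is the mean noise-bin
    amplitude.  Inverting gives A = f * sqrt(max(S^2 - 4/pi, 0)); a target
    of 1 (no signal) maps to amplitude 0.
    """
    return floor * float(np.sqrt(max(target_snr**2 - _AMPLITUDE_BIAS, 0.0)))


def _noise_floor(noise_sd: float, n_samples: int, n_trials: int) -> float:
    """Expected per-bin amplitude of averaged white noise, in spectrum units.

    For time-domain white noise with SD sigma, the single-sided amplitude
    spectrum bins are Rayleigh with mean sigma*sqrt(pi/n); coherent
    averaging of T independent trials shrinks this by sqrt(T).
    """
    return noise_sd * float(np.sqrt(np.pi / n_samples)) / float(np.sqrt(n_trials))


def simulate_epochs(
    truth: GroundTruth,
    design: DesignSpec,
    seed: int,
    noise_sd: float = 1.0,
    spectral_exponent: float = 0.0,
    sample_rate: float = 1000.0,
    trim_start: float = 1.0,
    window: float = 10.0,
) -> tuple[list[EpochSet], dict]:
    """Simulate phase-locked SSVEP epochs for every unit in the design.

    Each trial contains sinusoids at the first and second harmonics of the
    flicker frequency plus broadband Gaussian noise (white by default;
    ``spectral_exponent`` beta > 0 shapes it as 1/f^beta).  Harmonic
    amplitudes are calibrated so the expected SNR after coherently
    averaging ``trials_per_condition`` trials equals the forward-model
    prediction.  Phases are constant across trials within a condition.
    """
    n_win = int(round(window * sample_rate))
    harmonics = (design.flicker_hz, 2 * design.flicker_hz)
    for f in harmonics:
        if abs(f * window - round(f * window)) > 1e-9:
            raise ValueError(
                f"harmonic {f:g} Hz does not fall on the {1 / window:g} Hz bin grid"
            )
    rng = np.random.default_rng(seed)
    n_total = int(round((trim_start + window) * sample_rate))
    t = np.arange(n_total) / sample_rate
    floor = _noise_floor(noise_sd, n_win, design.trials_per_condition)
    conds = design.conditions()

    epoch_sets = []
    unit_record = {}
    for i in range(design.n_units):
        unit = f"unit{i + 1:02d}"
        gain = _unit_gain(truth, rng)
        unit_record[unit] = {"gain": asdict(gain), "weights": {}}
        trials: list[Trial] = []
        for electrode in design.electrodes:
            wmap = {
                mt: _unit_weights(w, truth.weight_jitter, rng)
                for mt, w in truth.weights_at(electrode).items()
            }
            unit_record[unit]["weights"][electrode] = {
                mt: asdict(w) for mt, w in wmap.items()
            }
            for cond in conds:
                mean1 = _condition_mean(
                    cond, gain, wmap, truth, design.principal_mask_contrast
                )
                targets = (mean1, 1.0 + (mean1 - 1.0) * truth.harmonic2_scale)
                phases = rng.uniform(0, 2 * np.pi, size=2)
                signal = np.zeros(n_total)
                for f, s_target, ph in zip(harmonics, targets, phases):
                    amp = amplitude_for_snr(s_target, floor)
                    signal += amp * np.cos(2 * np.pi * f * t + ph)
                for _ in range(design.trials_per_condition):
                    noise = _broadband_noise(
                        rng, n_total, noise_sd, spectral_exponent, sample_rate
                    )
                    trials.append(
                        Trial(
                            condition=str(cond["condition"]),
                            electrode=electrode,
                            voltage=signal + noise,
                        )
                    )
        epoch_sets.append(EpochSet(trials=trials, sample_rate=sample_rate, unit=unit))
    record = {"group": truth.record(), "units": unit_record, "seed": seed}
    return epoch_sets, record


def _broadband_noise(
    rng: np.random.Generator,
    n: int,
    sd: float,
    spectral_exponent: float,
    sample_rate: float,
) -> np.ndarray:
    white = rng.standard_normal(n) * sd
    if spectral_exponent == 0:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    shape = np.ones_like(f)
    shape[1:] = f[1:] ** (-spectral_exponent / 2.0)
    shaped = np.fft.irfft(spec * shape, n=n)
    # renormalise to the requested time-domain SD
    return shaped * (sd / shaped.std())


# --------------------------------------------------------------------------
# meta-analysis simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StudySpec:
    """Generative description of one published study in the meta-analysis."""

    name: str
    contrasts: Sequence[float]
    mask_type: str
    gain: GainParams
    weights: SuppressionWeights
    noise_sd: float = 0.2
    mask_contrast: float = 12.0

    def __post_init__(self) -> None:
        if len(set(self.contrasts)) < 3:
            raise ValueError(
                f"study {self.name!r} has fewer than 3 baseline contrasts; "
                "excluded by the inclusion rule"
            )


def simulate_meta_analysis(
    study_specs: Sequence[StudySpec], seed: int
) -> list[pd.DataFrame]:
    """Simulate one CRF table per study, with study-specific truths.

    Each study contributes a baseline CRF and one masked CRF on its own
    contrast grid; observation noise is additive Gaussian floored at zero.
    """
    if not study_specs:
        raise ValueError("need at least one study spec")
    rng = np.random.default_rng(seed)
    tables = []
    for spec in study_specs:
        rows = []
        for tc in spec.contrasts:
            for mask_type, mean in (
                ("none", baseline_response(tc, spec.gain)),
                (spec.mask_type, masked_response(tc, spec.gain, spec.weights)),
            ):
                obs = (
                    mean
                    if spec.noise_sd == 0
                    else max(mean + spec.noise_sd * rng.standard_normal(), 0.0)
                )
                rows.append(
                    {
                        "unit": spec.name,
                        "condition": mask_type if mask_type != "none" else "baseline",
                        "mask_type": mask_type,
                        "mask_contrast": 0.0 if mask_type == "none" else spec.mask_contrast,
                        "target_contrast": tc,
                        "electrode": "",
                        "harmonic_hz": np.nan,
                        "snr": obs,
                    }
                )
        tables.append(pd.DataFrame(rows, columns=CRF_COLUMNS))
    return tables


def save_truth_record(record: dict, path) -> None:
    """Write a ground-truth record as JSON next to a generated dataset."""
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=float)
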