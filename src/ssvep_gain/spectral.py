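"""Spectral front-end: from multi-trial voltage epochs to harmonic SNRs.

Each trial's voltage series is trimmed (discarding the onset transient),
Fourier transformed, coherently averaged across repetitions of the same
condition (complex mean, so phase-locked signal adds while phase-random
noise cancels), and converted to a signal-to-noise ratio by dividing the
amplitude in the signal bin by the mean amplitude of its neighbouring bins.

Amplitude convention: spectra are single-sided amplitude spectra scaled so
that a unit-amplitude sinusoid at an exact bin frequency yields bin
amplitude 1 (DC and Nyquist bins are not doubled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trial",
    "EpochSet",
    "ComplexSpectrum",
    "trim_and_fft",
    "coherent_average",
    "snr_at",
    "neighbour_offsets",
    "build_crf_table",
    "read_epochs_csv",
    "write_epochs_csv",
]

#: Column order of the tidy contrast-response table produced by this module.
CRF_COLUMNS = [
    "unit",
    "condition",
    "mask_type",
    "mask_contrast",
    "target_contrast",
    "electrode",
    "harmonic_hz",
    "snr",
]


@dataclass(frozen=True)
class Trial:
    """One recorded trial: condition label, electrode label, voltage series."""

    condition: str
    electrode: str
    voltage: np.ndarray


@dataclass
class EpochSet:
    """Trial-wise voltage series for one unit (participant), with metadata."""

    trials: list[Trial]
    sample_rate: float
    unit: str = "unit01"

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


@dataclass(frozen=True)
class ComplexSpectrum:
    """Single-sided complex amplitude spectrum on a uniform bin grid."""

    frequencies: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        if self.frequencies.shape != self.coefficients.shape:
            raise ValueError("frequencies and coefficients must have equal length")

    @property
    def bin_spacing(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def amplitude(self) -> np.ndarray:
        return np.abs(self.coefficients)


def trim_and_fft(
    raw_trial: np.ndarray,
    sample_rate: float,
    trim_start: float = 1.0,
    window: float = 10.0,
) -> ComplexSpectrum:
    """FFT of a fixed-length segment of one trial.

    The first ``trim_start`` seconds are discarded to avoid the stimulus
    onset transient; the following ``window`` seconds are transformed.  Bin
    spacing is 1/window Hz.
    """
    x = np.asarray(raw_trial, dtype=float)
    n = int(round(window * sample_rate))
    i0 = int(round(trim_start * sample_rate))
    if x.size < i0 + n:
        raise ValueError(
            f"series too short: need at least {i0 + n} samples "
            f"({trim_start + window:g} s at {sample_rate:g} Hz), got {x.size}"
        )
    seg = x[i0 : i0 + n]
    coef = np.fft.rfft(seg) / n
    coef[1:] *= 2.0
    if n % 2 == 0:
        coef[-1] /= 2.0  # Nyquist bin is not duplicated in the two-sided spectrum
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    return ComplexSpectrum(frequencies=freqs, coefficients=coef)


def coherent_average(spectra: Sequence[ComplexSpectrum]) -> ComplexSpectrum:
    """Element-wise complex mean of spectra sharing one bin grid."""
    if not spectra:
        raise ValueError("cannot average an empty list of spectra")
    ref = spectra[0].frequencies
    for s in spectra[1:]:
        if s.frequencies.shape != ref.shape or not np.allclose(s.frequencies, ref):
            raise ValueError("all spectra must share the same bin frequencies")
    mean = np.mean([s.coefficients for s in spectra], axis=0)
    return ComplexSpectrum(frequencies=ref, coefficients=mean)


def neighbour_offsets(half_span: float = 0.5, step: float = 0.1) -> np.ndarray:
    """Frequency offsets of the noise-floor bins around a signal bin.

    Offsets are ±step, ±2·step, … up to ±half_span, excluding the signal
    bin itself: 10 neighbours for the defaults (±0.5 Hz in 0.1 Hz steps).
    """
    k = int(round(half_span / step))
    if k < 1:
        raise ValueError("half_span must be at least one step")
    steps = np.arange(1, k + 1) * step
    return np.concatenate([-steps[::-1], steps])


def _bin_index(spectrum: ComplexSpectrum, freq: float) -> int:
    spacing = spectrum.bin_spacing
    idx = int(round(freq / spacing))
    if idx < 0 or idx >= spectrum.frequencies.size or abs(
        spectrum.frequencies[idx] - freq
    ) > 1e-6 * max(spacing, 1.0):
        raise ValueError(
            f"frequency {freq:g} Hz does not fall on the bin grid "
            f"(spacing {spacing:g} Hz)"
        )
    return idx


def snr_at(
    spectrum: ComplexSpectrum,
    freq: float,
    half_span: float = 0.5,
    step: float = 0.1,
) -> float:
    """Amplitude SNR at one frequency: signal bin over the mean neighbour bin.

    The noise floor is the mean amplitude of the bins at ±step … ±half_span
    around ``freq``, excluding the signal bin itself.
    """
    amp = spectrum.amplitude()
    i_sig = _bin_index(spectrum, freq)
    idx = [_bin_index(spectrum, freq + off) for off in neighbour_offsets(half_span, step)]
    floor = float(np.mean(amp[idx]))
    if floor == 0:
        raise ValueError("noise floor is zero; SNR undefined")
    return float(amp[i_sig] / floor)


def build_crf_table(
    epochs: EpochSet,
    conditions: Mapping[str, Mapping[str, object]],
    harmonics: Iterable[float],
    trim_start: float = 1.0,
    window: float = 10.0,
    half_span: float = 0.5,
    step: float = 0.1,
) -> pd.DataFrame:
    """Coherently average each condition and extract harmonic SNRs.

    Parameters
    ----------
    epochs
        Trials for one unit.
    conditions
        Design map ``condition id -> {"mask_type", "mask_contrast",
        "target_contrast"}``; every listed condition must have at least one
        trial at every electrode where it appears.
    harmonics
        Frequencies (Hz) at which to extract SNR; must fall on the bin grid.

    Returns
    -------
    pandas.DataFrame
        One row per (condition, electrode, harmonic) with columns
        ``unit, condition, mask_type, mask_contrast, target_contrast,
        electrode, harmonic_hz, snr``.
    """
    harmonics = list(harmonics)
    by_cell: dict[tuple[str, str], list[np.ndarray]] = {}
    for tr in epochs.trials:
        by_cell.setdefault((tr.condition, tr.electrode), []).append(tr.voltage)

    present = {c for c, _ in by_cell}
    missing = set(conditions) - present
    if missing:
        raise ValueError(f"conditions with zero trials: {sorted(missing)}")

    rows = []
    for (cond, electrode), series in sorted(by_cell.items()):
        if cond not in conditions:
            continue
        spectra = [trim_and_fft(v, epochs.sample_rate, trim_start, window) for v in series]
        avg = coherent_average(spectra)
        meta = conditions[cond]
        for f in harmonics:
            rows.append(
                {
                    "unit": epochs.unit,
                    "condition": cond,
                    "mask_type": meta["mask_type"],
                    "mask_contrast": meta["mask_contrast"],
                    "target_contrast": meta["target_contrast"],
                    "electrode": electrode,
                    "harmonic_hz": f,
                    "snr": snr_at(avg, f, half_span, step),
                }
            )
    return pd.DataFrame(rows, columns=CRF_COLUMNS)


def write_epochs_csv(epochs: EpochSet, path) -> None:
    """Write trials in long format: trial_id, condition, electrode, sample_index, voltage."""
    frames = []
    for i, tr in enumerate(epochs.trials):
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": i,
                    "condition": tr.condition,
                    "electrode": tr.electrode,
                    "sample_index": np.arange(tr.voltage.size),
                    "voltage": tr.voltage,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_epochs_csv(path, sample_rate: float, unit: str = "unit01") -> EpochSet:
    """Read the long-format epoch CSV written by :func:`write_epochs_csv`."""
    df = pd.read_csv(path)
    trials = []
    for (_, cond, elec), grp in df.groupby(["trial_id", "condition", "electrode"], sort=True):
        grp = grp.sort_values("sample_index")
        trials.append(Trial(condition=str(cond), electrode=str(elec), voltage=grp["voltage"].to_numpy()))
    return EpochSet(trials=trials, sample_rate=sample_rate, unit=unit)
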