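"""Divisive gain-control model of the contrast response function.

The baseline model is a hyperbolic-ratio (Naka-Rushton style) transducer

    resp(C) = R_max * C**p / (Z + C**2) + 1

where ``C`` is target Michelson contrast in percent (0-100), ``R_max``
scales the height of the function, ``p`` sets its shape (accelerating for
p > 2, saturating at p = 2, super-saturating for p < 2) and ``Z`` sets its
horizontal position.  The additive 1 is the noise floor that converts the
model output to a signal-to-noise ratio.  The denominator exponent is fixed
at 2; only the numerator exponent is free.

Masking is expressed by two multiplicative weights: a response-gain weight
``r`` dividing the response range (vertical scaling) and a contrast-gain
weight ``g`` multiplying the semi-saturation constant (lateral shift):

    resp(C) = (R_max / r) * C**p / (g*Z + C**2) + 1

Weights above 1 are suppressive, below 1 facilitatory, and r = g = 1
recovers the baseline model exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "GainParams",
    "SuppressionWeights",
    "ContrastPoint",
    "baseline_response",
    "masked_response",
    "saturation_index",
    "mask_saturation_index",
]


def _require_positive_finite(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class GainParams:
    """Baseline gain-control parameters for one unit or group.

    Attributes
    ----------
    r_max : float
        Response-range scale, in SNR units.
    p : float
        Transducer exponent (numerator only; denominator exponent is 2).
    z : float
        Semi-saturation constant on the percent-contrast-squared scale.
    """

    r_max: float
    p: float
    z: float

    def __post_init__(self) -> None:
        _require_positive_finite("r_max", self.r_max)
        _require_positive_finite("p", self.p)
        _require_positive_finite("z", self.z)


@dataclass(frozen=True)
class SuppressionWeights:
    """Response-gain (r) and contrast-gain (g) weights for one mask condition."""

    r: float
    g: float

    def __post_init__(self) -> None:
        _require_positive_finite("r", self.r)
        _require_positive_finite("g", self.g)


@dataclass(frozen=True)
class ContrastPoint:
    """A single contrast-response observation: percent contrast and SNR."""

    contrast: float
    response: float

    def __post_init__(self) -> None:
        if not (0 <= self.contrast <= 100):
            raise ValueError(f"contrast must lie in [0, 100], got {self.contrast!r}")
        if not np.isfinite(self.response):
            raise ValueError(f"response must be finite, got {self.response!r}")


def _validate_contrast(contrast) -> np.ndarray:
    c = np.asarray(contrast, dtype=float)
    if not np.all(np.isfinite(c)) or np.any(c < 0):
        raise ValueError("contrast must be finite and non-negative")
    return c


def baseline_response(contrast, params: GainParams):
    """Evaluate the baseline gain-control model at one or more contrasts.

    Returns exactly 1 at zero contrast (the SNR noise floor).  Accepts a
    scalar or array of percent contrasts and broadcasts accordingly.
    """
    c = _validate_contrast(contrast)
    resp = params.r_max * c**params.p / (params.z + c**2) + 1.0
    return float(resp) if np.isscalar(contrast) else resp


def masked_response(contrast, params: GainParams, weights: SuppressionWeights):
    """Evaluate the masked gain-control model.

    Reduces exactly to :func:`baseline_response` at r = g = 1.
    """
    c = _validate_contrast(contrast)
    resp = (params.r_max / weights.r) * c**params.p / (weights.g * params.z + c**2) + 1.0
    return float(resp) if np.isscalar(contrast) else resp


def _two_highest(levels) -> tuple[float, float]:
    ordered = sorted(levels)
    if len(ordered) < 2:
        raise ValueError(
            f"need responses at the two highest levels; got only {len(ordered)} level(s)"
        )
    return ordered[-1], ordered[-2]


def saturation_index(responses: Mapping[float, float]) -> float:
    """Saturation index of a contrast response function.

    SI = (R(c_hi) - R(c_next)) / max(R), using the two largest *tested*
    contrast levels (so designs whose top contrast was reduced, e.g. to 88%
    or 68%, are handled without hard-coding 48/96).  Positive values mean
    the function is still accelerating at the top of the range, zero means
    saturation, negative super-saturation.
    """
    c_hi, c_next = _two_highest(responses.keys())
    r_max = max(responses.values())
    if r_max == 0:
        raise ValueError("maximum response is zero; saturation index undefined")
    return (responses[c_hi] - responses[c_next]) / r_max


def mask_saturation_index(
    responses: Mapping[float, float],
    top_contrast_adjustment: float = 1.0,
) -> float:
    """Modified saturation index for mask-contrast response functions.

    Because increasing mask contrast *decreases* the target response, the
    index inverts the difference and scales by the function minimum:
    SI = (R(m_next) - R(m_hi)) / min(R).  ``top_contrast_adjustment``
    multiplicatively rescales the response at the highest mask contrast
    before differencing; it compensates designs where the top mask contrast
    had to be lowered (e.g. the monocular overlay case) and defaults to 1
    (no adjustment).
    """
    if top_contrast_adjustment <= 0 or not np.isfinite(top_contrast_adjustment):
        raise ValueError("top_contrast_adjustment must be positive and finite")
    m_hi, m_next = _two_highest(responses.keys())
    r_min = min(responses.values())
    if r_min == 0:
        raise ValueError("minimum response is zero; mask saturation index undefined")
    return (responses[m_next] - top_contrast_adjustment * responses[m_hi]) / r_min
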