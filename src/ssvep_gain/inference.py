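"""Two-stage fitting of the gain-control model, and posterior summaries.

Stage 1 estimates the baseline contrast-response parameters (R_max, p, Z)
either by per-unit downhill-simplex minimisation of RMSE (the meta-analysis
path, where units are heterogeneous published studies) or by a hierarchical
Bayesian fit (the experiment path, where all units saw the same stimuli).
Stage 2 holds those parameters fixed and estimates the response-gain (r)
and contrast-gain (g) suppression weights hierarchically, separately for
each mask type, so the baseline parameters cannot trade off against the
suppression weights.

Priors
------
Group-level suppression weights carry gamma(shape 1.5, rate 0.5) hyperpriors
whose density peaks at 1: the modal prior assumption is "no suppression",
with more mass above 1 than below.  Group-level baseline parameters carry
positive-truncated normal hyperpriors: Z ~ N(100, 40), p ~ N(2, 0.25),
R_max ~ N(5, 2).  The likelihood is Gaussian observation noise on SNR with
a half-normal prior on its standard deviation; the unit-to-group links are
lognormal (stage 1) and mode-matched gamma (stage 2).  All positive
quantities are sampled on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from ._mcmc import SamplerConfig, chain_diagnostics, run_ensemble
from .gain_model import GainParams, SuppressionWeights

__all__ = [
    "SamplerConfig",
    "PosteriorSummary",
    "FitResult",
    "hdi",
    "credible_suppression",
    "posterior_exceedance_p",
    "r_squared",
    "suppression_weight_prior",
    "fit_baseline_simplex",
    "fit_baseline_hierarchical",
    "fit_suppression_hierarchical",
    "BASELINE_HYPERPRIORS",
    "WEIGHT_PRIOR_SHAPE",
    "WEIGHT_PRIOR_RATE",
]

#: Normal hyperpriors (mean, sd) on the group-level baseline parameters,
#: truncated to positive values.
BASELINE_HYPERPRIORS: dict[str, tuple[float, float]] = {
    "r_max": (5.0, 2.0),
    "p": (2.0, 0.25),
    "z": (100.0, 40.0),
}

#: Gamma hyperprior on the group-level suppression weights; mode (α−1)/β = 1.
WEIGHT_PRIOR_SHAPE = 1.5
WEIGHT_PRIOR_RATE = 0.5

#: Scales of the half-normal priors on the unit-spread and noise parameters.
_SPREAD_PRIOR_SCALE = 0.5
_NOISE_PRIOR_SCALE = 1.0


def suppression_weight_prior():
    """The gamma hyperprior on suppression weights, as a frozen distribution."""
    return stats.gamma(WEIGHT_PRIOR_SHAPE, scale=1.0 / WEIGHT_PRIOR_RATE)


# --------------------------------------------------------------------------
# posterior summaries
# --------------------------------------------------------------------------


@dataclass
class PosteriorSummary:
    """Posterior draws and summary statistics for one parameter."""

    name: str
    samples: np.ndarray  # shape (chains, draws)
    mean: float
    hdi_low: float
    hdi_high: float
    rhat: float
    ess: float

    @classmethod
    def from_samples(cls, name: str, samples: np.ndarray, mass: float = 0.95):
        samples = np.atleast_2d(samples)
        low, high = hdi(samples, mass)
        rhat, ess = chain_diagnostics(samples)
        return cls(
            name=name,
            samples=samples,
            mean=float(samples.mean()),
            hdi_low=low,
            hdi_high=high,
            rhat=rhat,
            ess=ess,
        )

    @property
    def flat(self) -> np.ndarray:
        return self.samples.ravel()


@dataclass
class FitResult:
    """Result of one hierarchical (or per-unit) model fit.

    ``group`` maps parameter name to its group-level posterior summary;
    ``unit_estimates`` holds per-unit point estimates (posterior means or
    simplex optima); ``r2`` is the coefficient of determination of the
    per-unit point-estimate predictions.
    """

    group: dict[str, PosteriorSummary]
    unit_estimates: dict[str, object]
    r2: dict[str, float]
    converged: bool
    config: SamplerConfig | None = None
    extra: dict = field(default_factory=dict)


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the samples.

    Computed from the sorted draws: the first (in sorted order) shortest
    window spanning ⌈mass·n⌉ samples.  Requires at least 100 draws.
    """
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError(f"need at least 100 samples for an HDI, got {n}")
    k = int(math.ceil(mass * n))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def credible_suppression(summary: PosteriorSummary, reference: float = 1.0) -> str:
    """Classify a weight posterior against the no-suppression reference.

    ``credible_suppression`` if the whole HDI lies above the reference,
    ``credible_facilitation`` if it lies below, else ``not_credible``.
    """
    if summary.hdi_low > reference:
        return "credible_suppression"
    if summary.hdi_high < reference:
        return "credible_facilitation"
    return "not_credible"


def posterior_exceedance_p(samples_a, reference_mean_b: float) -> float:
    """Fraction of posterior draws that equal or exceed a reference value.

    The Bayesian analogue of a p-value for directed comparisons between
    conditions or electrodes: small values mean distribution A lies almost
    entirely below the reference (typically the posterior mean of B).
    """
    a = np.asarray(samples_a, dtype=float).ravel()
    if a.size < 100:
        raise ValueError(f"need at least 100 samples, got {a.size}")
    return float(np.mean(a >= reference_mean_b))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, 1 − SS_res/SS_tot about the observed mean."""
    y = np.asarray(observed, dtype=float)
    f = np.asarray(predicted, dtype=float)
    if y.shape != f.shape or y.size < 2:
        raise ValueError("observed and predicted must have equal length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values have zero variance; R^2 undefined")
    return 1.0 - float(np.sum((y - f) ** 2)) / ss_tot


# --------------------------------------------------------------------------
# table normalisation
# --------------------------------------------------------------------------

_BASELINE_LABELS = {"none", "baseline"}


def _normalise_table(table: pd.DataFrame) -> pd.DataFrame:
    """Standardise a CRF table to columns unit, mask_type, target_contrast, snr."""
    df = table.copy()
    if "mask_type" not in df.columns:
        if "condition" not in df.columns:
            raise ValueError("table needs a 'mask_type' or 'condition' column")
        df["mask_type"] = df["condition"]
    df["mask_type"] = df["mask_type"].astype(str).str.lower().replace(
        {lbl: "none" for lbl in _BASELINE_LABELS}
    )
    required = {"unit", "mask_type", "target_contrast", "snr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    if (df["snr"] < 0).any():
        raise ValueError("snr values must be non-negative")
    return df


def _baseline_rows(df: pd.DataFrame) -> pd.DataFrame:
    return df[df["mask_type"] == "none"]


# --------------------------------------------------------------------------
# stage 1: per-unit simplex fit
# --------------------------------------------------------------------------


def _rmse_baseline(log_theta: np.ndarray, c: np.ndarray, y: np.ndarray) -> float:
    with np.errstate(over="ignore", invalid="ignore"):
        r_max, p, z = np.exp(log_theta)
        pred = r_max * c**p / (z + c**2) + 1.0
        val = float(np.sqrt(np.mean((pred - y) ** 2)))
    return val if np.isfinite(val) else 1e12


def fit_baseline_simplex(
    contrast,
    snr,
    init: GainParams | None = None,
    restarts: int = 5,
    seed: int = 0,
) -> tuple[GainParams, float]:
    """Fit the baseline model to one unit by Nelder-Mead RMSE minimisation.

    Parameters are optimised on the log scale, which enforces positivity.
    The best of ``restarts`` jittered starts is polished with a second
    simplex run and returned together with the achieved RMSE.
    """
    c = np.asarray(contrast, dtype=float)
    y = np.asarray(snr, dtype=float)
    if c.shape != y.shape:
        raise ValueError("contrast and snr must have equal length")
    if np.unique(c).size < 3:
        raise ValueError("need responses at 3 or more distinct contrasts")
    if init is None:
        init = GainParams(r_max=max(float(y.max()) - 1.0, 0.5), p=2.0, z=100.0)
    x0 = np.log([init.r_max, init.p, init.z])
    rng = np.random.RandomState(seed)
    opts = dict(xatol=1e-10, fatol=1e-12, maxiter=5000, maxfev=5000)

    best = None
    for i in range(max(restarts, 1)):
        start = x0 if i == 0 else x0 + rng.normal(0.0, 0.5, size=3)
        res = optimize.minimize(
            _rmse_baseline, start, args=(c, y), method="Nelder-Mead", options=opts
        )
        if best is None or res.fun < best.fun:
            best = res
    # polish from the best point
    res = optimize.minimize(
        _rmse_baseline, best.x, args=(c, y), method="Nelder-Mead", options=opts
    )
    if res.fun < best.fun:
        best = res
    if not np.all(np.isfinite(best.x)) or not np.isfinite(best.fun):
        raise RuntimeError(f"simplex fit failed to converge: {best}")
    r_max, p, z = np.exp(best.x)
    return GainParams(r_max=float(r_max), p=float(p), z=float(z)), float(best.fun)


# --------------------------------------------------------------------------
# stage 1: hierarchical baseline fit
# --------------------------------------------------------------------------


def _finite_or_neginf(logp: np.ndarray) -> np.ndarray:
    return np.where(np.isfinite(logp), logp, -np.inf)


def fit_baseline_hierarchical(
    table: pd.DataFrame,
    cfg: SamplerConfig | None = None,
    prior_only: bool = False,
) -> FitResult:
    """Hierarchical Bayesian fit of the baseline model across units.

    Unit-level parameters are lognormally distributed around group means
    that carry the positive-truncated normal hyperpriors; the log-scale
    spreads and the observation-noise SD carry half-normal priors.  With
    ``prior_only`` the likelihood is disabled, so the sampler draws from
    the prior (a prior-predictive check).
    """
    cfg = cfg or SamplerConfig()
    df = _baseline_rows(_normalise_table(table))
    units = sorted(df["unit"].unique())
    if len(units) < 2:
        raise ValueError(
            "hierarchical fit requires >= 2 units; use fit_baseline_simplex "
            "for a single unit"
        )
    per_unit = df.groupby("unit")["target_contrast"].nunique()
    if (per_unit < 3).any():
        bad = per_unit[per_unit < 3].index.tolist()
        raise ValueError(f"units with fewer than 3 distinct contrasts: {bad}")

    u_index = {u: i for i, u in enumerate(units)}
    nu = len(units)
    c_obs = df["target_contrast"].to_numpy(dtype=float)
    y_obs = df["snr"].to_numpy(dtype=float)
    row_u = df["unit"].map(u_index).to_numpy()

    names = ["r_max", "p", "z"]
    mu0 = np.array([BASELINE_HYPERPRIORS[n][0] for n in names])
    sd0 = np.array([BASELINE_HYPERPRIORS[n][1] for n in names])
    ndim = 7 + 3 * nu

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        w = theta.shape[0]
        l_mu = theta[:, 0:3]
        l_s = theta[:, 3:6]
        l_sobs = theta[:, 6]
        l_unit = theta[:, 7:].reshape(w, 3, nu)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            mu = np.exp(l_mu)
            s = np.exp(l_s)
            sobs = np.exp(l_sobs)
            # truncated-normal hyperpriors on the group means (+ log Jacobian)
            logp = np.sum(l_mu - 0.5 * ((mu - mu0) / sd0) ** 2, axis=1)
            # half-normal priors on spreads and observation noise
            logp += np.sum(l_s - 0.5 * (s / _SPREAD_PRIOR_SCALE) ** 2, axis=1)
            logp += l_sobs - 0.5 * (sobs / _NOISE_PRIOR_SCALE) ** 2
            # lognormal unit link around the group means
            logp += np.sum(
                -nu * np.log(s)
                - 0.5 * np.sum((l_unit - l_mu[:, :, None]) ** 2, axis=2) / s**2,
                axis=1,
            )
            if not prior_only:
                unit_par = np.exp(l_unit)  # (w, 3, nu)
                rm = unit_par[:, 0, :][:, row_u]
                pp = unit_par[:, 1, :][:, row_u]
                zz = unit_par[:, 2, :][:, row_u]
                pred = rm * c_obs**pp / (zz + c_obs**2) + 1.0
                logp += -c_obs.size * np.log(sobs) - 0.5 * np.sum(
                    ((y_obs - pred) / sobs[:, None]) ** 2, axis=1
                )
        return _finite_or_neginf(logp)

    nw = cfg.n_walkers(ndim)

    def init(rng) -> np.ndarray:
        p0 = np.empty((nw, ndim))
        p0[:, 0:3] = np.log(mu0) + rng.normal(0, 0.2, size=(nw, 3))
        p0[:, 3:6] = np.log(0.2) + rng.normal(0, 0.2, size=(nw, 3))
        p0[:, 6] = np.log(0.3) + rng.normal(0, 0.2, size=nw)
        base = np.repeat(np.log(mu0)[None, :, None], nw, axis=0)
        p0[:, 7:] = (base + rng.normal(0, 0.15, size=(nw, 3, nu))).reshape(nw, -1)
        return p0

    chains = run_ensemble(log_prob, ndim, init, cfg)  # (chains, draws, ndim)

    group = {
        name: PosteriorSummary.from_samples(name, np.exp(chains[:, :, i]))
        for i, name in enumerate(names)
    }
    unit_means = np.exp(chains[:, :, 7:]).reshape(-1, 3, nu).mean(axis=0)  # (3, nu)
    unit_estimates = {
        u: GainParams(
            r_max=float(unit_means[0, i]),
            p=float(unit_means[1, i]),
            z=float(unit_means[2, i]),
        )
        for u, i in u_index.items()
    }
    r2 = {}
    if not prior_only:
        for u, i in u_index.items():
            mask = row_u == i
            pred = (
                unit_means[0, i] * c_obs[mask] ** unit_means[1, i]
                / (unit_means[2, i] + c_obs[mask] ** 2)
                + 1.0
            )
            try:
                r2[u] = r_squared(y_obs[mask], pred)
            except ValueError:
                r2[u] = float("nan")
    converged = all(
        s.rhat <= cfg.rhat_threshold and s.ess >= cfg.ess_threshold
        for s in group.values()
    )
    return FitResult(
        group=group,
        unit_estimates=unit_estimates,
        r2=r2,
        converged=converged,
        config=cfg,
    )


# --------------------------------------------------------------------------
# stage 2: hierarchical suppression-weight fit
# --------------------------------------------------------------------------


def _fit_suppression_one(
    df: pd.DataFrame,
    baseline: Mapping[str, GainParams],
    cfg: SamplerConfig,
) -> FitResult:
    units = sorted(df["unit"].unique())
    u_index = {u: i for i, u in enumerate(units)}
    nu = len(units)
    c_obs = df["target_contrast"].to_numpy(dtype=float)
    y_obs = df["snr"].to_numpy(dtype=float)
    row_u = df["unit"].map(u_index).to_numpy()
    base_rm = np.array([baseline[u].r_max for u in units])[row_u]
    base_p = np.array([baseline[u].p for u in units])[row_u]
    base_z = np.array([baseline[u].z for u in units])[row_u]

    a, b = WEIGHT_PRIOR_SHAPE, WEIGHT_PRIOR_RATE
    ndim = 5 + 2 * nu

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        w = theta.shape[0]
        l_m = theta[:, 0:2]  # group modes: r, g
        l_s = theta[:, 2:4]
        l_sobs = theta[:, 4]
        l_w = theta[:, 5:].reshape(w, 2, nu)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            m = np.exp(l_m)
            s = np.exp(l_s)
            sobs = np.exp(l_sobs)
            # gamma(a, b) hyperprior on the group modes (+ log Jacobian)
            logp = np.sum(a * l_m - b * m, axis=1)
            logp += np.sum(l_s - 0.5 * (s / _SPREAD_PRIOR_SCALE) ** 2, axis=1)
            logp += l_sobs - 0.5 * (sobs / _NOISE_PRIOR_SCALE) ** 2
            # unit weights ~ gamma with mode = group mode m and spread s:
            # shape k = 1 + 1/s^2, rate = (k-1)/m = 1/(s^2 m)
            k = 1.0 + 1.0 / s**2  # (w, 2)
            rate = 1.0 / (s**2 * m)
            wts = np.exp(l_w)  # (w, 2, nu)
            logp += np.sum(nu * (k * np.log(rate) - gammaln(k)), axis=1)
            logp += np.sum(k[:, :, None] * l_w - rate[:, :, None] * wts, axis=(1, 2))
            r_u = wts[:, 0, :][:, row_u]
            g_u = wts[:, 1, :][:, row_u]
            pred = (base_rm / r_u) * c_obs**base_p / (g_u * base_z + c_obs**2) + 1.0
            logp += -c_obs.size * np.log(sobs) - 0.5 * np.sum(
                ((y_obs - pred) / sobs[:, None]) ** 2, axis=1
            )
        return _finite_or_neginf(logp)

    nw = cfg.n_walkers(ndim)

    def init(rng) -> np.ndarray:
        p0 = np.empty((nw, ndim))
        p0[:, 0:2] = rng.normal(0, 0.3, size=(nw, 2))  # group modes near 1
        p0[:, 2:4] = np.log(0.2) + rng.normal(0, 0.2, size=(nw, 2))
        p0[:, 4] = np.log(0.3) + rng.normal(0, 0.2, size=nw)
        p0[:, 5:] = rng.normal(0, 0.2, size=(nw, 2 * nu))
        return p0

    chains = run_ensemble(log_prob, ndim, init, cfg)

    group = {
        "r": PosteriorSummary.from_samples("r", np.exp(chains[:, :, 0])),
        "g": PosteriorSummary.from_samples("g", np.exp(chains[:, :, 1])),
    }
    unit_means = np.exp(chains[:, :, 5:]).reshape(-1, 2, nu).mean(axis=0)
    unit_estimates = {
        u: SuppressionWeights(r=float(unit_means[0, i]), g=float(unit_means[1, i]))
        for u, i in u_index.items()
    }
    r2 = {}
    for u, i in u_index.items():
        mask = row_u == i
        wr, wg = unit_means[0, i], unit_means[1, i]
        pred = (
            (base_rm[mask] / wr) * c_obs[mask] ** base_p[mask]
            / (wg * base_z[mask] + c_obs[mask] ** 2)
            + 1.0
        )
        try:
            r2[u] = r_squared(y_obs[mask], pred)
        except ValueError:
            r2[u] = float("nan")
    converged = all(
        s.rhat <= cfg.rhat_threshold and s.ess >= cfg.ess_threshold
        for s in group.values()
    )
    return FitResult(
        group=group,
        unit_estimates=unit_estimates,
        r2=r2,
        converged=converged,
        config=cfg,
    )


def fit_suppression_hierarchical(
    table: pd.DataFrame,
    baseline: Mapping[str, GainParams],
    cfg: SamplerConfig | None = None,
) -> dict[str, FitResult]:
    """Hierarchical fit of suppression weights, separately per mask type.

    ``baseline`` maps unit id to its fixed stage-1 parameters; it is read
    but never modified, so re-running stage 2 cannot alter stage-1 output.
    Returns one :class:`FitResult` per mask type present in the table.
    """
    cfg = cfg or SamplerConfig()
    df = _normalise_table(table)
    masked = df[df["mask_type"] != "none"]
    if masked.empty:
        raise ValueError("table contains no masked rows")
    missing = sorted(set(masked["unit"].unique()) - set(baseline))
    if missing:
        raise ValueError(f"units with masked data but no baseline fit: {missing}")
    results = {}
    for i, (mask_type, sub) in enumerate(sorted(masked.groupby("mask_type"))):
        sub_cfg = SamplerConfig(
            chains=cfg.chains,
            warmup=cfg.warmup,
            draws=cfg.draws,
            seed=(cfg.seed * 131 + i) % (2**31),
            walkers=cfg.walkers,
            rhat_threshold=cfg.rhat_threshold,
            ess_threshold=cfg.ess_threshold,
        )
        results[mask_type] = _fit_suppression_one(sub, baseline, sub_cfg)
    return results
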