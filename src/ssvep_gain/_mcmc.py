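"""Seeded ensemble-MCMC driver shared by the hierarchical fits.

Each "chain" is an independent affine-invariant ensemble (emcee) run with
its own seed.  After the warmup steps are discarded, the final steps of
every walker are flattened and truncated so that each chain contributes
exactly ``draws`` kept samples.  Convergence diagnostics (split-Rhat and
effective sample size) are computed across chains with arviz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["SamplerConfig", "run_ensemble", "chain_diagnostics"]


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings: independent chains, warmup steps, kept draws per chain."""

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    walkers: int | None = None  # default: max(48, 2*ndim + 2), rounded even
    rhat_threshold: float = 1.05
    ess_threshold: float = 400.0

    def n_walkers(self, ndim: int) -> int:
        if self.walkers is not None:
            return self.walkers
        w = max(48, 2 * ndim + 2)
        return w + (w % 2)


def run_ensemble(log_prob, ndim: int, init, cfg: SamplerConfig) -> np.ndarray:
    """Sample ``cfg.chains`` independent ensembles.

    Parameters
    ----------
    log_prob
        Vectorised log-posterior: maps an (n, ndim) array to an (n,) array.
    init
        Callable ``init(rng) -> (nwalkers, ndim)`` producing overdispersed
        starting positions.
    Returns
    -------
    numpy.ndarray of shape (chains, draws, ndim).
    """
    import emcee

    nw = cfg.n_walkers(ndim)
    keep_steps = int(np.ceil(cfg.draws / nw))
    out = np.empty((cfg.chains, cfg.draws, ndim))
    # differential-evolution moves mix far better than the default stretch
    # move on the correlated, funnel-shaped hierarchical posteriors here
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    for c in range(cfg.chains):
        seed_c = (cfg.seed * 1_000_003 + 7919 * c + 1) % (2**31)
        rng = np.random.RandomState(seed_c)
        p0 = np.asarray(init(rng), dtype=float)
        if p0.shape != (nw, ndim):
            raise ValueError(f"init must return shape ({nw}, {ndim}), got {p0.shape}")
        sampler = emcee.EnsembleSampler(nw, ndim, log_prob, vectorize=True, moves=moves)
        state = emcee.State(p0, random_state=rng.get_state())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sampler.run_mcmc(state, cfg.warmup + keep_steps, progress=False)
        chain = sampler.get_chain(discard=cfg.warmup)  # (keep_steps, nw, ndim)
        out[c] = chain.reshape(-1, ndim)[: cfg.draws]
    return out


def chain_diagnostics(samples_2d: np.ndarray) -> tuple[float, float]:
    """Split-Rhat and bulk ESS for one parameter, shape (chains, draws)."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = float(az.rhat(samples_2d))
        ess = float(az.ess(samples_2d))
    return rhat, ess
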