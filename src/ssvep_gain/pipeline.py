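"""Workflow orchestration: meta-analysis path, experiment path, mask sweep.

The meta-analysis path fits each study's baseline CRF with the downhill
simplex (studies are methodologically heterogeneous, so no pooling at
stage 1) and then pools all studies in the hierarchical stage-2 fit,
separately per mask type.  The experiment path fits both stages
hierarchically, independently for every electrode and harmonic frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gain_model import GainParams, mask_saturation_index
from .inference import (
    FitResult,
    SamplerConfig,
    credible_suppression,
    fit_baseline_hierarchical,
    fit_baseline_simplex,
    fit_suppression_hierarchical,
    posterior_exceedance_p,
    _normalise_table,
)
from .spectral import EpochSet, build_crf_table

__all__ = [
    "MetaResult",
    "SweepResult",
    "run_meta_workflow",
    "run_experiment_workflow",
    "run_mask_sweep_analysis",
]

log = logging.getLogger(__name__)


@dataclass
class MetaResult:
    """Meta-analysis output: per-study baselines and pooled suppression fits."""

    baselines: dict[str, tuple[GainParams, float]]
    suppression: dict[str, FitResult]
    skipped: dict[str, str]
    summary: pd.DataFrame


@dataclass
class SweepResult:
    """Electrode x harmonic x mask-type sweep of suppression weights."""

    table: pd.DataFrame
    comparisons: pd.DataFrame
    fits: dict = field(default_factory=dict)
    baseline_fits: dict = field(default_factory=dict)


def _pre_average(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate study tables, averaging repeated (unit, condition) cells.

    A study contributing several tables (e.g. one per temporal-frequency
    condition) is reduced to a single averaged data set first.
    """
    df = _normalise_table(pd.concat(tables, ignore_index=True))
    keys = ["unit", "mask_type", "target_contrast"]
    if "mask_contrast" in df.columns:
        keys.append("mask_contrast")
    return df.groupby(keys, as_index=False)["snr"].mean()


def _group_summary_rows(mask_type: str, fit: FitResult, extra: dict | None = None):
    rows = []
    for pname, summ in fit.group.items():
        row = {
            "mask_type": mask_type,
            "parameter": pname,
            "mean": summ.mean,
            "hdi_low": summ.hdi_low,
            "hdi_high": summ.hdi_high,
            "classification": credible_suppression(summ),
            "rhat": summ.rhat,
            "ess": summ.ess,
            "converged": fit.converged,
        }
        if extra:
            row.update(extra)
        rows.append(row)
    return rows


def run_meta_workflow(
    tables: Sequence[pd.DataFrame],
    cfg: SamplerConfig | None = None,
    simplex_restarts: int = 5,
) -> MetaResult:
    """Meta-analysis: per-study simplex baselines, pooled suppression weights.

    Studies whose baseline has fewer than 3 distinct contrasts are skipped
    with a logged reason (the inclusion rule), not silently dropped.
    """
    if not tables:
        raise ValueError("no study tables supplied")
    cfg = cfg or SamplerConfig()
    df = _pre_average(tables)
    baselines: dict[str, tuple[GainParams, float]] = {}
    skipped: dict[str, str] = {}
    for unit, sub in df[df["mask_type"] == "none"].groupby("unit"):
        n_contrasts = sub["target_contrast"].nunique()
        if n_contrasts < 3:
            reason = f"baseline has only {n_contrasts} distinct contrasts (need >= 3)"
            skipped[unit] = reason
            log.warning("skipping study %s: %s", unit, reason)
            continue
        params, rmse = fit_baseline_simplex(
            sub["target_contrast"], sub["snr"], restarts=simplex_restarts, seed=cfg.seed
        )
        baselines[unit] = (params, rmse)

    masked = df[(df["mask_type"] != "none") & df["unit"].isin(baselines)]
    if masked.empty:
        raise ValueError("no masked data from included studies")
    fits = fit_suppression_hierarchical(
        masked, {u: p for u, (p, _) in baselines.items()}, cfg
    )
    summary = pd.DataFrame(
        [row for mt, fit in fits.items() for row in _group_summary_rows(mt, fit)]
    )
    return MetaResult(baselines=baselines, suppression=fits, skipped=skipped, summary=summary)


def run_experiment_workflow(
    data: Sequence[EpochSet] | pd.DataFrame,
    cfg: SamplerConfig | None = None,
    harmonics: Sequence[float] = (5.0, 10.0),
    electrodes: Sequence[str] | None = None,
    conditions: Mapping[str, Mapping[str, object]] | None = None,
    comparisons: Sequence[Mapping[str, object]] | None = None,
    spectral_kwargs: Mapping[str, object] | None = None,
) -> SweepResult:
    """Experiment path: spectral front-end, then both stages hierarchically.

    ``data`` is either a list of per-unit :class:`EpochSet` objects (the
    spectral front-end is applied, requiring a ``conditions`` design map)
    or an already-assembled CRF table.  Fitting is fully independent per
    electrode and per harmonic.  ``comparisons`` requests posterior
    exceedance p-values; each entry names a source cell (samples) and a
    reference cell (posterior mean) as dicts with keys ``electrode``,
    ``harmonic``, ``mask_type`` and ``parameter``.
    """
    cfg = cfg or SamplerConfig()
    if isinstance(data, pd.DataFrame):
        table = _normalise_table(data)
    else:
        if conditions is None:
            raise ValueError("a conditions design map is required with epoch input")
        kw = dict(spectral_kwargs or {})
        table = pd.concat(
            [build_crf_table(es, conditions, harmonics, **kw) for es in data],
            ignore_index=True,
        )
        table = _normalise_table(table)

    available = sorted(table["electrode"].unique())
    electrodes = list(electrodes) if electrodes is not None else available
    missing = sorted(set(electrodes) - set(available))
    if missing:
        raise ValueError(
            f"electrode(s) {missing} not present; available: {available}"
        )

    rows = []
    fits: dict[tuple[str, float, str], FitResult] = {}
    baseline_fits: dict[tuple[str, float], FitResult] = {}
    for ei, electrode in enumerate(electrodes):
        for hi, harmonic in enumerate(harmonics):
            cell = table[
                (table["electrode"] == electrode) & (table["harmonic_hz"] == harmonic)
            ]
            if cell.empty:
                raise ValueError(
                    f"no rows for electrode {electrode!r} at {harmonic:g} Hz"
                )
            cell_cfg = SamplerConfig(
                chains=cfg.chains,
                warmup=cfg.warmup,
                draws=cfg.draws,
                seed=(cfg.seed * 977 + 31 * ei + hi) % (2**31),
                walkers=cfg.walkers,
                rhat_threshold=cfg.rhat_threshold,
                ess_threshold=cfg.ess_threshold,
            )
            stage1 = fit_baseline_hierarchical(cell, cell_cfg)
            baseline_fits[(electrode, harmonic)] = stage1
            baseline = {
                u: p for u, p in stage1.unit_estimates.items()
            }
            masked = cell[cell["mask_type"] != "none"]
            stage2 = fit_suppression_hierarchical(masked, baseline, cell_cfg)
            for mt, fit in stage2.items():
                fits[(electrode, harmonic, mt)] = fit
                mean_r2 = float(np.nanmean(list(fit.r2.values()))) if fit.r2 else np.nan
                rows.extend(
                    _group_summary_rows(
                        mt,
                        fit,
                        extra={
                            "electrode": electrode,
                            "harmonic_hz": harmonic,
                            "r2_mean": mean_r2,
                        },
                    )
                )
    sweep_table = pd.DataFrame(rows)

    comp_rows = []
    comparisons = comparisons or []
    for comp in comparisons:
        key_a = (comp["electrode_a"], comp["harmonic_a"], comp["mask_type_a"])
        key_b = (comp["electrode_b"], comp["harmonic_b"], comp["mask_type_b"])
        param = comp.get("parameter", "g")
        samples_a = fits[key_a].group[param].flat
        mean_b = fits[key_b].group[param].mean
        comp_rows.append(
            {
                **{k: comp[k] for k in comp},
                "parameter": param,
                "p_exceedance": posterior_exceedance_p(samples_a, mean_b),
                "n_comparisons": len(comparisons),
            }
        )
    return SweepResult(
        table=sweep_table,
        comparisons=pd.DataFrame(comp_rows),
        fits=fits,
        baseline_fits=baseline_fits,
    )


def run_mask_sweep_analysis(
    table: pd.DataFrame,
    sweep_target_contrast: float = 24.0,
    harmonics: Sequence[float] | None = None,
    top_contrast_adjustment: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask-contrast response functions and modified saturation indices.

    Uses the rows at the fixed sweep target contrast; the baseline (no
    mask) condition at that target supplies the 0% mask-contrast point for
    every mask type.  Units appearing several times (e.g. in both
    sub-experiments) are averaged within unit before averaging across
    units.  Returns the pooled response functions and one modified SI per
    mask type per harmonic.
    """
    df = _normalise_table(table)
    if "harmonic_hz" not in df.columns:
        df["harmonic_hz"] = np.nan
    df = df[df["target_contrast"] == sweep_target_contrast]
    if df.empty:
        raise ValueError(f"no rows at target contrast {sweep_target_contrast:g}%")
    harmonics = (
        list(harmonics) if harmonics is not None else sorted(df["harmonic_hz"].unique())
    )
    adj = dict(top_contrast_adjustment or {})

    # within-unit average first (merges repeated measurements of one unit)
    keys = ["unit", "mask_type", "mask_contrast", "harmonic_hz"]
    df = df.groupby(keys, as_index=False, dropna=False)["snr"].mean()

    func_rows = []
    si_rows = []
    mask_types = sorted(t for t in df["mask_type"].unique() if t != "none")
    if not mask_types:
        raise ValueError("no masked rows at the sweep target contrast")
    for h in harmonics:
        sub_h = df[df["harmonic_hz"].isna()] if pd.isna(h) else df[df["harmonic_hz"] == h]
        base = sub_h[sub_h["mask_type"] == "none"].groupby("mask_contrast")["snr"].mean()
        for mt in mask_types:
            cell = sub_h[sub_h["mask_type"] == mt]
            func = cell.groupby("mask_contrast")["snr"].mean().to_dict()
            if not base.empty:
                func.setdefault(0.0, float(base.mean()))
            if len(func) < 2:
                raise ValueError(
                    f"mask type {mt!r} at {h} Hz has fewer than 2 mask contrasts"
                )
            for mc in sorted(func):
                func_rows.append(
                    {
                        "mask_type": mt,
                        "harmonic_hz": h,
                        "mask_contrast": mc,
                        "snr": func[mc],
                    }
                )
            si_rows.append(
                {
                    "mask_type": mt,
                    "harmonic_hz": h,
                    "saturation_index": mask_saturation_index(
                        func, top_contrast_adjustment=adj.get(mt, 1.0)
                    ),
                }
            )
    return pd.DataFrame(func_rows), pd.DataFrame(si_rows)
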