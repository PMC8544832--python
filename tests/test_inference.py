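"""Inference layer: HDI/exceedance calibration, simplex fits, hierarchical recovery."""

import numpy as np
import pandas as pd
import pytest

from ssvep_gain import (
    DesignSpec,
    GainParams,
    GroundTruth,
    SuppressionWeights,
    baseline_response,
    credible_suppression,
    fit_baseline_hierarchical,
    fit_baseline_simplex,
    fit_suppression_hierarchical,
    hdi,
    masked_response,
    posterior_exceedance_p,
    r_squared,
    simulate_crf_table,
    suppression_weight_prior,
)
from ssvep_gain.inference import BASELINE_HYPERPRIORS, PosteriorSummary, SamplerConfig


class TestHDI:
    def test_degenerate_point_mass(self):
        low, high = hdi(np.full(500, 3.2))
        assert (low, high) == (3.2, 3.2)

    def test_uniform_width(self, rng):
        low, high = hdi(rng.uniform(0, 1, size=1_000_000), mass=0.95)
        assert high - low == pytest.approx(0.95, abs=0.01)

    def test_normal_matches_closed_form(self, rng):
        low, high = hdi(rng.standard_normal(1_000_000), mass=0.95)
        assert low == pytest.approx(-1.96, abs=0.02)
        assert high == pytest.approx(1.96, abs=0.02)

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match="at least 100"):
            hdi(np.arange(50))


class TestExceedance:
    def test_symmetric_distribution_at_its_mean(self, rng):
        samples = rng.standard_normal(100_000) + 2.0
        assert posterior_exceedance_p(samples, 2.0) == pytest.approx(0.5, abs=0.01)

    def test_all_below_reference(self):
        assert posterior_exceedance_p(np.linspace(0, 1, 500), 2.0) == 0.0

    def test_normal_tail_area(self, rng):
        p = posterior_exceedance_p(rng.standard_normal(1_000_000), 1.6449)
        assert p == pytest.approx(0.05, abs=0.002)


class TestCredibility:
    def _summary(self, low, high):
        return PosteriorSummary(
            name="g", samples=np.linspace(low, high, 200).reshape(1, -1),
            mean=(low + high) / 2, hdi_low=low, hdi_high=high, rhat=1.0, ess=1000,
        )

    @pytest.mark.parametrize(
        "low, high, expected",
        [
            (2.1, 3.4, "credible_suppression"),
            (0.8, 1.3, "not_credible"),
            (0.5, 0.9, "credible_facilitation"),
        ],
    )
    def test_classification(self, low, high, expected):
        assert credible_suppression(self._summary(low, high)) == expected


class TestRSquared:
    def test_perfect_fit(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == 1.0

    def test_mean_prediction_scores_zero(self):
        assert r_squared([1, 2, 3], [2, 2, 2]) == 0.0

    def test_hand_value(self):
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            r_squared([2, 2, 2], [1, 2, 3])


class TestWeightPrior:
    def test_mode_is_one(self):
        prior = suppression_weight_prior()
        x = np.linspace(1e-3, 20, 200_001)
        assert x[np.argmax(prior.pdf(x))] == pytest.approx(1.0, abs=1e-3)

    def test_more_mass_above_one_than_below(self):
        prior = suppression_weight_prior()
        assert prior.sf(1.0) > prior.cdf(1.0)


class TestSimplexFit:
    CONTRASTS = np.array([6.0, 12.0, 24.0, 48.0, 96.0])

    def test_noiseless_recovery(self):
        truth = GainParams(5.0, 2.0, 100.0)
        y = baseline_response(self.CONTRASTS, truth)
        params, rmse = fit_baseline_simplex(self.CONTRASTS, y, seed=0)
        assert rmse < 1e-6
        np.testing.assert_allclose(
            baseline_response(self.CONTRASTS, params), y, atol=1e-4
        )

    def test_flat_floor_data_fits_near_one(self):
        y = np.ones_like(self.CONTRASTS)
        params, _ = fit_baseline_simplex(self.CONTRASTS, y, seed=0)
        pred = baseline_response(np.linspace(0, 100, 50), params)
        assert np.all(np.abs(pred - 1.0) < 0.05)

    def test_beats_dense_grid_oracle(self, rng):
        """Simplex RMSE never exceeds the best of an exhaustive log-spaced grid."""
        grid_rm = np.logspace(-1, 1.3, 20)
        grid_p = np.logspace(np.log10(0.5), np.log10(4), 20)
        grid_z = np.logspace(0, 4, 20)
        rm, pp, zz = np.meshgrid(grid_rm, grid_p, grid_z, indexing="ij")
        c = self.CONTRASTS[:, None]
        for trial in range(5):
            truth = GainParams(
                float(rng.uniform(2, 8)), float(rng.uniform(1.5, 2.5)),
                float(rng.uniform(50, 300)),
            )
            y = baseline_response(self.CONTRASTS, truth) + rng.normal(0, 0.3, 5)
            y = np.clip(y, 0, None)
            pred = rm.ravel() * c**pp.ravel() / (zz.ravel() + c**2) + 1.0
            grid_best = np.sqrt(np.mean((pred - y[:, None]) ** 2, axis=0)).min()
            _, rmse = fit_baseline_simplex(self.CONTRASTS, y, seed=trial)
            assert rmse <= grid_best + 1e-6

    def test_requires_three_contrasts(self):
        with pytest.raises(ValueError, match="3 or more"):
            fit_baseline_simplex([6.0, 96.0], [1.5, 4.0])


def _baseline_table(seed, n_units=12):
    truth = GroundTruth(gain=GainParams(5.0, 2.0, 120.0))
    design = DesignSpec(mask_types=(), sweep_mask_contrasts=(), n_units=n_units)
    return simulate_crf_table(truth, design, seed=seed)


class TestBaselineHierarchical:
    def test_recovery_with_hdi_coverage(self):
        """Group posterior near truth; truth inside the 95% HDI in >=90% of replicates."""
        truth = {"r_max": 5.0, "p": 2.0, "z": 120.0}
        n_rep = 20
        covered = 0
        for seed in range(n_rep):
            table, _ = _baseline_table(seed)
            fit = fit_baseline_hierarchical(table, SamplerConfig(seed=seed))
            ok = True
            for name, v in truth.items():
                s = fit.group[name]
                assert abs(s.mean - v) / v <= 0.20
                ok &= s.hdi_low <= v <= s.hdi_high
            covered += ok
        assert covered >= 0.9 * n_rep

    def test_prior_predictive_reproduces_hyperpriors(self):
        """With the likelihood disabled the group samples follow the stated priors."""
        from scipy import stats

        table, _ = _baseline_table(0, n_units=6)
        fit = fit_baseline_hierarchical(
            table, SamplerConfig(seed=3, warmup=1500, draws=1000), prior_only=True
        )
        for name, (mu, sd) in BASELINE_HYPERPRIORS.items():
            a = -mu / sd
            expected = stats.truncnorm.mean(a, np.inf, loc=mu, scale=sd)
            assert fit.group[name].mean == pytest.approx(expected, rel=0.12)

    def test_single_unit_refused_with_guidance(self):
        table, _ = _baseline_table(0, n_units=1)
        with pytest.raises(ValueError, match="simplex"):
            fit_baseline_hierarchical(table, SamplerConfig())


class TestSuppressionHierarchical:
    def test_no_suppression_identity(self, small_sampler):
        """Masked data identical to baseline: both weight HDIs include 1."""
        table, record = _baseline_table(4, n_units=8)
        masked = table.copy()
        masked["mask_type"] = "monocular"
        full = pd.concat([table, masked], ignore_index=True)
        baselines = {u: GainParams(**record["units"][u]["gain"]) for u in record["units"]}
        cfg = SamplerConfig(chains=2, warmup=800, draws=500, seed=4)
        fit = fit_suppression_hierarchical(full, baselines, cfg)["monocular"]
        for name in ("r", "g"):
            s = fit.group[name]
            assert s.hdi_low <= 1.0 <= s.hdi_high

    def test_missing_baseline_unit_errors(self, contrast_gain_dataset):
        table, baselines, _ = contrast_gain_dataset
        partial = {u: p for u, p in list(baselines.items())[:-1]}
        with pytest.raises(ValueError, match="no baseline fit"):
            fit_suppression_hierarchical(table, partial, SamplerConfig())

    def test_stage_separation_baselines_untouched(self, contrast_gain_dataset):
        table, baselines, _ = contrast_gain_dataset
        before = {u: (p.r_max, p.p, p.z) for u, p in baselines.items()}
        cfg = SamplerConfig(chains=2, warmup=200, draws=150, seed=1)
        fit_suppression_hierarchical(table, baselines, cfg)
        assert {u: (p.r_max, p.p, p.z) for u, p in baselines.items()} == before

    def test_relabelling_units_leaves_group_posterior(self, contrast_gain_dataset):
        table, baselines, _ = contrast_gain_dataset
        cfg = SamplerConfig(chains=2, warmup=600, draws=500, seed=9)
        ref = fit_suppression_hierarchical(table, baselines, cfg)["monocular"]
        relabel = {u: f"zz_{u}" for u in baselines}
        table2 = table.assign(unit=table["unit"].map(relabel))
        base2 = {relabel[u]: p for u, p in baselines.items()}
        alt = fit_suppression_hierarchical(table2, base2, cfg)["monocular"]
        assert alt.group["g"].mean == pytest.approx(ref.group["g"].mean, rel=0.1)

    def test_noiseless_weight_identifiability_on_grid(self):
        """The (r, g) RMSE surface for noiseless masked data dips at the truth."""
        params = GainParams(5.0, 2.0, 120.0)
        truth = SuppressionWeights(r=1.5, g=3.0)
        c = np.array([6.0, 12.0, 24.0, 48.0, 96.0])
        y = masked_response(c, params, truth)
        rs = np.linspace(0.5, 4, 36)
        gs = np.linspace(0.5, 6, 56)
        err = np.array(
            [
                [
                    np.sqrt(np.mean((masked_response(c, params, SuppressionWeights(r, g)) - y) ** 2))
                    for g in gs
                ]
                for r in rs
            ]
        )
        i, j = np.unravel_index(np.argmin(err), err.shape)
        assert rs[i] == pytest.approx(truth.r, abs=np.diff(rs)[0])
        assert gs[j] == pytest.approx(truth.g, abs=np.diff(gs)[0])
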