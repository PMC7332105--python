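"""Pooling, the bounded fit with its fallback rules, and genotype contrasts."""
import dataclasses

import numpy as np
import pytest

import conespect as cs
from conespect.fitting import FitConfig, FitResult, Substitution, fit_spectral_model
from conespect.model import ModelParams
from conespect.synth import GenotypePreset


@pytest.fixture(scope="module")
def wt_fit():
    gp = cs.preset("wt_larva")
    data = cs.simulate_genotype_dataset(gp, 17, seed=20_001)
    return data, fit_spectral_model(data)


class TestPooling:
    @pytest.mark.parametrize("n,expected", [(17, 1190), (16, 1120), (12, 840), (1, 70)])
    def test_point_bookkeeping(self, protocol, wt_larva, n, expected):
        datasets, i = [], 0
        while len(datasets) < n:  # apply the stability screen, as the study does
            ds = cs.simulate_amplitude_dataset(wt_larva, protocol, seed=30_000 + i)
            i += 1
            if not ds.excluded:
                datasets.append(ds)
        pooled = cs.normalize_and_pool(datasets, label="wt")
        assert pooled.n_points == expected
        assert pooled.n_source_datasets == n

    def test_each_source_normalized_to_own_peak(self, protocol, wt_larva):
        ds = cs.simulate_amplitude_dataset(wt_larva, protocol, seed=31_000)
        pooled = cs.normalize_and_pool([ds])
        assert pooled.frame["amplitude"].max() == pytest.approx(1.0)

    def test_excluded_dataset_rejected(self, protocol, wt_larva):
        ds = cs.simulate_amplitude_dataset(wt_larva, protocol, seed=31_001)
        ds.excluded = True
        with pytest.raises(ValueError, match="excluded"):
            cs.normalize_and_pool([ds])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cs.normalize_and_pool([])


class TestFit:
    def test_recovers_wt_parameters_within_two_se(self, wt_fit):
        _, fit = wt_fit
        truth = cs.preset("wt_larva").params
        for cone in "rgbu":
            lam, se = fit.peak_estimates()[cone]
            assert abs(lam - truth[cone].lambda_max) < 2 * se + 0.5
            v, sev = fit.estimate(f"vmax_{cone}")
            assert abs(v - truth[cone].vmax) < 3 * sev + 0.01
        assert fit.converged
        assert not fit.substitutions

    def test_residuals_invariant_to_point_order(self, wt_fit):
        data, fit = wt_fit
        shuffled = cs.GenotypeDataset(
            frame=data.frame.sample(frac=1.0, random_state=0).reset_index(drop=True),
            label=data.label,
            n_source_datasets=data.n_source_datasets,
        )
        fit2 = fit_spectral_model(shuffled)
        assert fit2.rss == pytest.approx(fit.rss, rel=1e-6)
        assert fit2.params["r"].lambda_max == pytest.approx(
            fit.params["r"].lambda_max, abs=1e-3
        )

    def test_refit_from_solution_is_fixed_point(self, wt_fit):
        data, fit = wt_fit
        fit2 = fit_spectral_model(data, seeds=fit.params)
        assert fit2.rss == pytest.approx(fit.rss, rel=1e-8)
        for cone in "rgbu":
            assert fit2.params[cone].lambda_max == pytest.approx(
                fit.params[cone].lambda_max, abs=1e-2
            )

    def test_semi_saturation_beyond_bound_is_substituted(self):
        # data generated with log kr above the fit ceiling of 6: the fitted
        # value pins to the bound and the standard fixed value replaces it
        gp = cs.preset("wt_larva")
        hot = gp.params.with_cone(dataclasses.replace(gp.params["r"], log_k=6.5))
        data = cs.simulate_genotype_dataset(
            GenotypePreset("hot_red", hot, "larva"), 17, seed=20_002
        )
        fit = fit_spectral_model(data)
        assert Substitution("log_k_r", "boundary_hit", 4.5) in fit.substitutions
        assert fit.params["r"].fixed_k
        assert "log_k_r" not in fit.free_names

    def test_silent_cone_is_dropped_and_reported_no_fit(self):
        gp = cs.preset("mut_6bp1_larva")
        silent = gp.params.with_cone(dataclasses.replace(gp.params["r"], vmax=0.0))
        data = cs.simulate_genotype_dataset(
            GenotypePreset("no_red", silent, "larva"), 12, seed=20_003
        )
        fit = fit_spectral_model(data)
        assert "r" in fit.no_fit
        assert fit.peak_estimates()["r"] is None
        if fit.params["r"].dropped:
            assert fit.params["r"].vmax == 0.0

    def test_dropping_a_truly_silent_cone_preserves_rss(self):
        # nested-model consistency: removing a cone whose true amplitude is
        # zero cannot change the residual sum of squares beyond noise level
        gp = cs.preset("wt_larva")
        silent = gp.params.with_cone(dataclasses.replace(gp.params["u"], vmax=0.0))
        data = cs.simulate_genotype_dataset(
            GenotypePreset("no_uv", silent, "larva"), 8, seed=20_004
        )
        full = fit_spectral_model(data, FitConfig(drop_threshold=0.0))
        reduced = fit_spectral_model(data, FitConfig(drop_threshold=0.08))
        assert reduced.params["u"].dropped
        assert reduced.rss <= full.rss * 1.05

    def test_too_few_points_rejected(self, wt_larva):
        data = cs.simulate_genotype_dataset(wt_larva, 17, seed=20_005)
        tiny = cs.GenotypeDataset(frame=data.frame.iloc[:8], label="tiny")
        with pytest.raises(ValueError):
            fit_spectral_model(tiny)


class TestContrast:
    def test_identical_fits_give_zero(self, wt_fit):
        _, fit = wt_fit
        res = cs.parameter_contrast(fit, fit, "vmax_r")
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_statistic_arithmetic(self):
        # θA−θB = 2·√(seA²+seB²) must give a statistic of exactly 2
        def mk(val, se, n=100):
            p = cs.default_seeds()
            p = p.with_cone(dataclasses.replace(p["r"], vmax=val))
            names = ["vmax_r"]
            return FitResult(params=p, se={"vmax_r": se}, rss=1.0, n_points=n,
                             converged=True, substitutions=[], no_fit={},
                             free_names=names)

        a = mk(0.5, 0.03)
        b = mk(0.5 - 2 * np.hypot(0.03, 0.04), 0.04)
        res = cs.parameter_contrast(a, b, "vmax_r")
        assert res.statistic == pytest.approx(2.0)
        assert res.df == 100 + 100 - 1 - 1

    def test_uv_gain_is_detected_across_seeds(self):
        # the mutant's elevated UV contribution should be significant at
        # α = 0.01 in essentially every replicate
        wt, mut = cs.preset("wt_larva"), cs.preset("mut_6bp1_larva")
        hits = 0
        n_rep = 10
        for i in range(n_rep):
            fa = fit_spectral_model(cs.simulate_genotype_dataset(wt, 17, seed=21_000 + i))
            fb = fit_spectral_model(cs.simulate_genotype_dataset(mut, 12, seed=22_000 + i))
            res = cs.parameter_contrast(fa, fb, "vmax_u")
            hits += res.p < 0.01
        assert hits >= 0.9 * n_rep

    def test_unavailable_parameter_rejected(self, wt_fit):
        _, fit = wt_fit
        with pytest.raises(ValueError):
            cs.parameter_contrast(fit, fit, "log_k_x")


class TestGenotypeAnova:
    def test_identical_groups_give_null_result(self, wt_larva):
        data = cs.simulate_genotype_dataset(wt_larva, 6, seed=23_000)
        copies = [
            cs.GenotypeDataset(frame=data.frame.copy(), label=f"g{i}",
                               n_source_datasets=6)
            for i in range(3)
        ]
        res = cs.genotype_anova(copies, "vmax_r")
        assert res.F < 0.05
        assert res.p > 0.9

    def test_red_loss_is_detected_with_pointlevel_df(self, wt_larva, het_larva, mut_larva):
        g1 = cs.simulate_genotype_dataset(wt_larva, 17, seed=23_001, label="wt")
        g2 = cs.simulate_genotype_dataset(het_larva, 16, seed=23_002, label="het")
        g3 = cs.simulate_genotype_dataset(mut_larva, 12, seed=23_003, label="mut")
        res = cs.genotype_anova([g1, g2, g3], "vmax_r")
        assert res.df1 == 2
        n_total = g1.n_points + g2.n_points + g3.n_points
        # point-level accounting: up to 12 free parameters per group, fewer
        # if a fallback fixed a semi-saturation
        assert n_total - 36 <= res.df2 <= n_total - 33
        assert res.p < 0.001
        assert all(p < 0.05 for *_ignored, p in res.pairwise)

    def test_single_group_rejected(self, wt_larva):
        data = cs.simulate_genotype_dataset(wt_larva, 4, seed=23_004)
        with pytest.raises(ValueError):
            cs.genotype_anova([data], "vmax_r")
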