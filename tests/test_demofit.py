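"""Demographic-inference tests: mask arithmetic, SFS tallies, the expected-
SFS engine against closed forms and an independent coalescent oracle, the
likelihood machinery, model selection, bootstrap and unit scaling."""

import numpy as np
import pytest

from domcost import demofit
from domcost.demofit import (
    DemographicModelSpec,
    EngineConfig,
    JointSFS,
    OptimizerConfig,
    ScalingConstants,
    build_neutral_mask,
    expected_sfs,
    fit_model,
    joint_sfs,
    loglikelihood,
    model_select,
    scale_to_physical,
)
from domcost.demofit.engine import expected_sfs_coalescent
from domcost.demofit.fit import bootstrap_ci, fit_models_nested


class TestNeutralMask:
    def test_hand_worked_complement(self):
        regions, total = build_neutral_mask(10_000, [(4_000, 5_000)], min_len=1_000)
        assert regions == [(0, 4_000), (5_000, 10_000)] and total == 9_000

    def test_no_masks_gives_whole_contig(self):
        regions, total = build_neutral_mask(5_000, [], min_len=1_000)
        assert regions == [(0, 5_000)] and total == 5_000

    def test_min_len_larger_than_contig_raises(self):
        with pytest.raises(ValueError, match="min_len"):
            build_neutral_mask(500, [], min_len=1_000)

    def test_short_fragments_dropped(self):
        # both flanks are shorter than min_len, so nothing survives
        with pytest.raises(ValueError):
            build_neutral_mask(10_000, [(500, 9_800)], min_len=1_000)


class TestJointSfs:
    def test_toy_tally(self):
        # n1 = n2 = 2 haploid; derived counts (1,0), (1,0), (2,1)
        sfs = joint_sfs([1, 1, 2], [2, 2, 2], [0, 0, 1], [2, 2, 2])
        assert sfs.matrix[1, 0] == 2 and sfs.matrix[2, 1] == 1
        assert sfs.n_sites == 3

    def test_no_variants_raises(self):
        with pytest.raises(ValueError):
            joint_sfs([], [], [], [])

    def test_label_swap_transposes(self, rng):
        d1 = rng.integers(0, 5, 40)
        d2 = rng.integers(0, 5, 40)
        c = np.full(40, 4)
        a = joint_sfs(d1, c, d2, c)
        b = joint_sfs(d2, c, d1, c)
        assert np.array_equal(a.matrix, b.matrix.T)

    def test_total_count_conservation(self, rng):
        n_sites = 200
        d1 = rng.integers(0, 7, n_sites)
        d2 = rng.integers(0, 7, n_sites)
        c = np.full(n_sites, 6)
        pos = np.arange(n_sites) * 10
        regions = [(0, 1_000)]
        pol = rng.random(n_sites) < 0.8
        sfs = joint_sfs(d1, c, d2, c, positions=pos, regions=regions, polarized=pol)
        in_reg = pos < 1_000
        seg = ((d1 + d2) > 0) & ((d1 + d2) < 12) & pol & in_reg
        assert sfs.n_sites == seg.sum()

    def test_projection_preserves_total(self, rng):
        d = rng.integers(0, 9, 100)
        c = np.full(100, 8)
        strict = joint_sfs(d, c, d[::-1], c)
        proj = joint_sfs(d, c, d[::-1], c, project_to=(4, 4))
        seg_after = proj.n_sites
        assert 0 < seg_after <= 100

    def test_corner_masking(self):
        sfs = joint_sfs([0, 2], [2, 2], [1, 2], [2, 2])
        assert sfs.matrix[0, 0] == 0 and sfs.matrix[2, 2] == 0


class TestExpectedSfs:
    def test_linear_in_theta(self):
        spec = DemographicModelSpec("B", dict(nu1=1.0, nu2=0.5, T=0.1, m12=0.5, m21=0.2))
        one = expected_sfs(spec, 6, 6, theta=1.0)
        two = expected_sfs(spec, 6, 6, theta=2.0)
        assert np.allclose(two, 2 * one)

    def test_neutral_limit_combined_spectrum(self):
        spec = DemographicModelSpec("A", dict(nu1=1.0, nu2=1.0, T=1e-3))
        n1 = n2 = 6
        m = expected_sfs(spec, n1, n2)
        comb = np.zeros(n1 + n2 + 1)
        for i in range(n1 + 1):
            for j in range(n2 + 1):
                comb[i + j] += m[i, j]
        k = np.arange(1, n1 + n2)
        assert np.max(np.abs(comb[1:-1] * k - 1.0)) < 0.05

    def test_symmetric_parameters_give_symmetric_spectrum(self):
        spec = DemographicModelSpec(
            "B", dict(nu1=0.7, nu2=0.7, T=0.15, m12=0.4, m21=0.4)
        )
        m = expected_sfs(spec, 8, 8)
        assert np.allclose(m, m.T, rtol=1e-6, atol=1e-9)

    def test_engine_self_convergence(self):
        spec = DemographicModelSpec(
            "C", dict(nu1=1.2, nu2=0.4, nu1F=0.9, nu2F=1.1, T=0.12, m12=0.5, m21=0.2)
        )
        coarse = expected_sfs(spec, 8, 8, config=EngineConfig(dt_max=0.01))
        fine = expected_sfs(spec, 8, 8, config=EngineConfig(dt_max=0.0025))
        rel = np.abs(coarse - fine).sum() / fine.sum()
        assert rel < 0.01

    def test_deterministic_vs_coalescent_oracle(self):
        """Independent Monte-Carlo coalescent (msprime branch averaging)
        agrees with the moment-closure engine."""
        spec = DemographicModelSpec("B", dict(nu1=2.0, nu2=0.3, T=0.1, m12=1.0, m21=0.3))
        det = expected_sfs(spec, 8, 8)
        mc = expected_sfs(spec, 8, 8, engine="coalescent", n_reps=1500, seed=5)
        rel = np.abs(det - mc).sum() / mc.sum()
        assert rel < 0.08

    def test_invalid_engine(self):
        spec = DemographicModelSpec("A", dict(nu1=1, nu2=1, T=0.1))
        with pytest.raises(ValueError):
            expected_sfs(spec, 4, 4, engine="magic")


class TestLikelihood:
    def test_theta_hat_is_count_ratio(self):
        model = np.ones((3, 3))
        data = JointSFS(2 * np.ones((3, 3)), 2, 2)
        _, theta = loglikelihood(model, data)
        assert theta == pytest.approx(data.matrix[data.mask].sum() / model[data.mask].sum())

    def test_region_permutation_invariance(self, rng):
        d1 = rng.integers(0, 5, 60)
        d2 = rng.integers(0, 5, 60)
        c = np.full(60, 4)
        pos = np.arange(60) * 100
        regions = [(0, 2_000), (2_000, 4_000), (4_000, 6_000)]
        a = joint_sfs(d1, c, d2, c, positions=pos, regions=regions)
        b = joint_sfs(d1, c, d2, c, positions=pos, regions=regions[::-1])
        spec = DemographicModelSpec("A", dict(nu1=1, nu2=1, T=0.05))
        m = expected_sfs(spec, 4, 4)
        assert loglikelihood(m, a)[0] == loglikelihood(m, b)[0]

    def test_poisson_and_multinomial_rank_alike(self, rng):
        spec1 = DemographicModelSpec("A", dict(nu1=1, nu2=1, T=0.05))
        spec2 = DemographicModelSpec("A", dict(nu1=2, nu2=0.2, T=0.4))
        truth = expected_sfs(spec1, 6, 6, theta=5000)
        data = JointSFS(rng.poisson(truth), 6, 6)
        for like in ("multinomial", "poisson"):
            l1, _ = loglikelihood(expected_sfs(spec1, 6, 6), data, like)
            l2, _ = loglikelihood(expected_sfs(spec2, 6, 6), data, like)
            assert l1 > l2


class TestFitAndSelect:
    fast = OptimizerConfig(restarts=(3, 2, 1), maxiter=(100, 150, 500))

    def test_nesting_property_migration_data(self, rng):
        truth = DemographicModelSpec("B", dict(nu1=1.0, nu2=0.5, T=0.1, m12=3.0, m21=1.0))
        data = JointSFS(rng.poisson(expected_sfs(truth, 6, 6, theta=8000)), 6, 6)
        fits = fit_models_nested(data, ("A", "B"), config=self.fast, seed=0)
        assert fits[1].loglik > fits[0].loglik

    def test_aic_formula_and_delta(self):
        # AIC = 2k - 2 lnL
        from domcost.demofit.fit import FitResult

        a = FitResult("A", {}, -100.0, 1.0, 3, 2 * 3 - 2 * (-100.0), None, "x")
        b = FitResult("B", {}, -99.0, 1.0, 5, 2 * 5 - 2 * (-99.0), None, "x")
        assert a.aic == 206.0
        table = model_select([a, b])
        assert table.iloc[0]["deltaAIC"] == 0.0
        assert set(table["model"]) == {"A", "B"}

    def test_model_select_rejects_mixed_data(self):
        from domcost.demofit.fit import FitResult

        a = FitResult("A", {}, -10.0, 1.0, 3, 26.0, None, "x")
        b = FitResult("B", {}, -9.0, 1.0, 5, 28.0, None, "y")
        with pytest.raises(ValueError, match="different"):
            model_select([a, b])

    def test_fit_flags_bound_hits(self, rng):
        truth = DemographicModelSpec("A", dict(nu1=1.0, nu2=1.0, T=0.05))
        data = JointSFS(rng.poisson(expected_sfs(truth, 4, 4, theta=2000)), 4, 4)
        spec = DemographicModelSpec("A", bounds={"T": (0.5, 5.0)})  # truth below range
        fit = fit_model(data, spec, config=self.fast, seed=1)
        assert "T" in fit.at_bound


class TestBootstrap:
    def test_identical_regions_zero_width(self, rng):
        spec = DemographicModelSpec("A", dict(nu1=1.0, nu2=1.0, T=0.1))
        block = expected_sfs(spec, 4, 4, theta=200)
        regions = [block.copy() for _ in range(25)]
        total = JointSFS(sum(regions), 4, 4)
        fit = fit_model(
            total, DemographicModelSpec("A"), config=TestFitAndSelect.fast, seed=0
        )
        ci = bootstrap_ci(regions, fit, B=8, seed=1, config=OptimizerConfig(restarts=(1, 1, 1), maxiter=(50, 80, 200)))
        for _, row in ci.iterrows():
            assert row["upper"] - row["lower"] < 1e-3 * max(1.0, row["point"])

    def test_percentile_interval_brackets_point(self, rng):
        spec = DemographicModelSpec("A", dict(nu1=1.2, nu2=0.6, T=0.1))
        blocks = [rng.poisson(expected_sfs(spec, 4, 4, theta=150)).astype(float) for _ in range(25)]
        total = JointSFS(np.sum(blocks, axis=0), 4, 4)
        fit = fit_model(total, DemographicModelSpec("A"), config=TestFitAndSelect.fast, seed=3)
        ci = bootstrap_ci(blocks, fit, B=12, seed=2, config=OptimizerConfig(restarts=(1, 1, 1), maxiter=(50, 80, 200)))
        for _, row in ci.iterrows():
            assert row["lower"] <= row["point"] * 1.05
            assert row["upper"] >= row["point"] * 0.95

    def test_too_few_regions_raises(self):
        from domcost.demofit.fit import FitResult

        fit = FitResult("A", dict(nu1=1, nu2=1, T=0.1), -1.0, 1.0, 3, 8.0, None, "x")
        with pytest.raises(ValueError, match="20"):
            bootstrap_ci([np.ones((3, 3))] * 5, fit, B=4)


class TestPhysicalScaling:
    def test_closed_form_nanc(self):
        from domcost.demofit.fit import FitResult

        # N_anc = theta_hat / (4 mu_gen L): 4 / (4 * 1e-8 * 1e5) = 1000
        fit = FitResult("A", dict(nu1=2.0, nu2=0.5, T=0.25), -1.0, 4.0, 3, 8.0, None, "x")
        consts = ScalingConstants(mu_per_site_per_year=1e-8, generation_time_years=1.0, total_bp=1e5)
        phys = scale_to_physical(fit, consts)
        assert phys["N_anc"] == pytest.approx(1_000.0)
        assert phys["N_1"] == pytest.approx(2_000.0)
        assert phys["T_years"] == pytest.approx(0.25 * 2 * 1_000.0)

    def test_zero_time_maps_to_zero_years(self):
        from domcost.demofit.fit import FitResult

        fit = FitResult("A", dict(nu1=1.0, nu2=1.0, T=0.0), -1.0, 0.004, 3, 8.0, None, "x")
        consts = ScalingConstants(total_bp=1e5)
        assert scale_to_physical(fit, consts)["T_years"] == 0.0

    def test_default_mutation_rate_per_generation(self):
        consts = ScalingConstants(total_bp=1.0)
        assert consts.mu_per_site_per_generation == pytest.approx(1.91e-9)
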