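import numpy as np
import pytest
from scipy import stats as sps

from dhqtl.segregation import (
    FitDiagnostics,
    MixedInheritanceModel,
    ModelSpec,
    NW2_CRITICAL,
    enumerate_dh_models,
    estimate_first_order,
    estimate_second_order,
    goodness_of_fit,
    model_aic,
    select_model,
)
from dhqtl.simulate import simulate_study, variance_matched_config

# the reference analysis's printed G-0 estimates (2011 column)
EFFECTS_2011 = {
    "m": 37.78, "d_a": 20.4, "d_b": 8.59, "d_c": 15.89,
    "i_ab": 3.64, "i_ac": 10.94, "i_bc": -0.86, "i_abc": -5.81,
}
MU_2011 = [90.57, 79.43, 32.23, 12.44, 50.25, 12.44, 12.42, 12.42]

G0 = ModelSpec(k=3, epistasis="full", polygenes=True)


class TestCatalog:
    def test_polygene_only_model(self):
        spec = ModelSpec(k=0, polygenes=True)
        assert spec.n_components == 1
        assert spec.n_params == 2  # mean and variance

    def test_g0_shape(self):
        assert G0.n_components == 8
        assert np.allclose(
            MixedInheritanceModel(np.arange(20.0), 1.0).fit(
                G0, max_iter=1
            ).mixing_proportions,
            1 / 8,
        )

    def test_param_counting_oracle(self):
        for spec in enumerate_dh_models():
            cols = spec.design_matrix().shape[1]
            if spec.polygenes:
                assert spec.n_params == cols + 1
            else:
                assert spec.n_params == cols

    def test_catalog_is_dh_admissible(self):
        specs = enumerate_dh_models()
        assert len(specs) == len(set(s.label for s in specs))
        assert all(s.k <= 3 for s in specs)
        assert any(s == G0 for s in specs)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(k=0, epistasis="digenic")
        with pytest.raises(ValueError):
            ModelSpec(k=2, epistasis="full")
        with pytest.raises(ValueError):
            ModelSpec(k=4)


class TestFirstOrder:
    def test_saturated_involution(self, rng):
        for _ in range(10):
            beta = rng.normal(0, 10, size=8)
            mu = G0.design_matrix() @ beta
            est = estimate_first_order(mu, G0)
            recovered = np.array([est[name] for name in G0.param_names])
            assert np.allclose(recovered, beta, atol=1e-10)
            assert np.allclose(est["_residuals"], 0, atol=1e-10)

    def test_printed_mean_identity(self):
        # equal-weight mean of the printed component means gives m
        est = estimate_first_order(MU_2011, G0)
        assert est["m"] == pytest.approx(np.mean(MU_2011))
        assert round(est["m"], 2) == pytest.approx(37.78, abs=0.005)

    def test_mu1_reconstruction(self):
        # the first genotype class (+,+,+) sums every printed effect
        mu1 = sum(EFFECTS_2011.values())
        assert mu1 == pytest.approx(90.57, abs=0.005)
        design_row = G0.design_matrix()[0]
        assert np.allclose(design_row, 1.0)

    def test_rank_deficient_design_error(self):
        with pytest.raises(np.linalg.LinAlgError):
            estimate_first_order(
                np.zeros(8), G0, weights=[1, 0, 0, 0, 0, 0, 0, 0]
            )

    def test_weighted_solution_matches_lstsq(self, rng):
        spec = ModelSpec(k=2, epistasis="none", polygenes=True)
        mu = rng.normal(size=4)
        w = rng.uniform(0.5, 2.0, size=4)
        est = estimate_first_order(mu, spec, weights=w)
        x = spec.design_matrix()
        oracle = np.linalg.lstsq(np.sqrt(w)[:, None] * x, np.sqrt(w) * mu,
                                 rcond=None)[0]
        got = np.array([est[n] for n in spec.param_names])
        assert np.allclose(got, oracle, atol=1e-10)


class TestSecondOrder:
    def test_reference_partition_2011(self):
        out = estimate_second_order(512.54, 38.94 + 22.38, 22.38)
        assert out["sigma_mg2"] == pytest.approx(451.22, abs=1e-10)
        assert out["h_mg2"] == pytest.approx(88.03, abs=0.01)
        assert out["h_pg2"] == pytest.approx(7.60, abs=0.005)

    def test_reference_partition_2012(self):
        out = estimate_second_order(581.13, 32.81 + 35.62, 35.62)
        assert out["sigma_mg2"] == pytest.approx(512.70, abs=1e-10)
        assert out["h_mg2"] == pytest.approx(88.22, abs=0.005)
        assert out["h_pg2"] == pytest.approx(5.65, abs=0.005)

    def test_partition_closes_exactly(self):
        out = estimate_second_order(100.0, 30.0, 10.0)
        total = out["sigma_mg2"] + out["sigma_pg2"] + out["sigma_e2"]
        assert total == pytest.approx(out["sigma_p2"], abs=1e-12)

    def test_no_polygenes_when_floor_binds(self):
        out = estimate_second_order(50.0, 10.0, 10.0)
        assert out["sigma_pg2"] == 0.0 and out["h_pg2"] == 0.0

    def test_zero_phenotypic_variance(self):
        with pytest.raises(ValueError):
            estimate_second_order(0.0, 1.0, 1.0)


class TestIecmFit:
    def test_single_normal_equals_sample_moments(self, rng):
        y = rng.normal(30, 6, size=400)
        fit = MixedInheritanceModel(y, 0.0).fit(ModelSpec(k=0))
        assert fit.means[0] == pytest.approx(y.mean(), abs=1e-8)
        assert fit.sigma_w2 == pytest.approx(np.var(y), abs=1e-6)

    def test_two_component_recovery(self):
        recovered = []
        for i in range(5):
            rng = np.random.default_rng(100 + i)
            comp = rng.integers(0, 2, size=2000)
            y = np.where(comp == 0, 0.0, 20.0) + rng.normal(0, 2.0, size=2000)
            fit = MixedInheritanceModel(y, 0.0).fit(
                ModelSpec(k=1, polygenes=True), seed=i
            )
            recovered.append(sorted(fit.means))
        recovered = np.array(recovered)
        assert np.all(np.abs(recovered[:, 0] - 0.0) < 0.5)
        assert np.all(np.abs(recovered[:, 1] - 20.0) < 0.5)

    def test_loglik_monotone(self, rng):
        for sigma_e2 in (0.0, 5.0):
            y = np.concatenate(
                [rng.normal(0, 3, 120), rng.normal(15, 3, 140)]
            )
            for spec in (ModelSpec(k=1), ModelSpec(k=2, epistasis="digenic"), G0):
                fit = MixedInheritanceModel(y, sigma_e2).fit(spec, seed=1)
                path = np.array(fit.loglik_path)
                assert np.all(np.diff(path) > -1e-7)

    def test_variance_floor_respected(self, rng):
        y = rng.normal(0, 1, size=300)  # sample variance ~1
        fit = MixedInheritanceModel(y, 25.0).fit(ModelSpec(k=0))
        assert fit.sigma_w2 >= 25.0

    def test_nonconvergence_flagged_not_raised(self, rng):
        y = rng.normal(size=200)
        fit = MixedInheritanceModel(y, 0.0).fit(G0, max_iter=2, n_restarts=1)
        assert fit.converged is False

    def test_aic_arithmetic(self):
        assert model_aic(0.0, 1) == 2.0
        assert model_aic(-100.0, 9) == 218.0


class TestGoodnessOfFit:
    def test_uniform_grid_no_mean_departure(self):
        n = 200
        u = (np.arange(1, n + 1) - 0.5) / n
        diag = goodness_of_fit(u, lambda x: x)
        assert diag.u1 == pytest.approx(0.0, abs=1e-18)
        assert diag.nw2 == pytest.approx(1 / (12 * n), abs=1e-12)

    def test_nw2_critical_band(self):
        # a statistic of 0.50 fails at the 5% level, passes at 1%
        assert NW2_CRITICAL[0.05] < 0.50 < NW2_CRITICAL[0.01]
        diag = FitDiagnostics(
            u1=0, u1_p=1, u2=0, u2_p=1, u3=0, u3_p=1,
            nw2=0.50, nw2_pass_05=0.50 < NW2_CRITICAL[0.05],
            nw2_pass_01=0.50 < NW2_CRITICAL[0.01], dn=0.01, dn_p=0.9,
        )
        assert not diag.nw2_pass_05 and diag.nw2_pass_01
        assert diag.n_passed(0.05) == 4 and diag.n_passed(0.01) == 5

    def test_small_sample_withheld(self):
        with pytest.raises(ValueError):
            goodness_of_fit(np.arange(5.0), lambda x: x / 5)

    def test_type_one_calibration_under_truth(self):
        # u-statistics are chi^2(1) under the true model
        runs = 1000
        rej = np.zeros(5)
        for i in range(runs):
            rng = np.random.default_rng(3000 + i)
            y = rng.normal(10, 2, size=100)
            diag = goodness_of_fit(y, lambda x: sps.norm.cdf(x, 10, 2))
            rej += [
                diag.u1_p < 0.05, diag.u2_p < 0.05, diag.u3_p < 0.05,
                not diag.nw2_pass_05, diag.dn_p < 0.05,
            ]
        rates = rej / runs
        bound = 3 * np.sqrt(0.05 * 0.95 / runs)
        for rate in rates[:4]:
            assert abs(rate - 0.05) < bound
        # Kolmogorov p is asymptotic and slightly conservative at n=100
        assert rates[4] < 0.05 + bound


class TestModelSelection:
    def test_detects_single_normal(self):
        wins = 0
        specs = [
            ModelSpec(k=0), ModelSpec(k=1),
            ModelSpec(k=2, epistasis="digenic"), G0,
        ]
        runs = 10
        for i in range(runs):
            rng = np.random.default_rng(500 + i)
            y = rng.normal(40, 8, size=300)
            sel = MixedInheritanceModel(y, 1.0).fit_catalog(
                specs, seed=i, n_restarts=2
            )
            wins += sel.best.spec.k == 0
        assert wins >= 8

    def test_three_gene_truth_beats_small_models(self):
        k_of_best = []
        for i in range(8):
            cfg = variance_matched_config(
                n_lines=157, n_reps=1, plants_per_line_rep=1, seed=7000 + i
            )
            y = simulate_study(cfg).line_means().to_numpy()
            sel = MixedInheritanceModel(y, 22.38).fit_catalog(
                seed=i, n_restarts=2
            )
            k_of_best.append(sel.best.spec.k)
        k_of_best = np.array(k_of_best)
        assert (k_of_best == 3).sum() > (k_of_best <= 1).sum()

    def test_selection_is_deterministic(self, rng):
        y = rng.normal(size=300)
        m = MixedInheritanceModel(y, 1.0)
        a = m.fit_catalog(seed=4)
        b = m.fit_catalog(seed=4)
        assert a.best.spec == b.best.spec
        assert a.table.equals(b.table)

    def test_summary_renders(self, rng):
        y = rng.normal(size=120)
        sel = MixedInheritanceModel(y, 1.0).fit_catalog(
            [ModelSpec(k=0), ModelSpec(k=1)], seed=0, n_restarts=1
        )
        text = sel.summary()
        assert "selected:" in text and "aic" in text.lower()
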