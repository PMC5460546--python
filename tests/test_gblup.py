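import numpy as np
import pandas as pd
import pytest

from repeatgs.gblup import (
    GeneticParams,
    MixedModelSpec,
    NonConvergenceError,
    SingularModelError,
    VarianceComponents,
    blup_solutions,
    build_design,
    fit_repeatability,
    gebv_accuracy,
    genetic_params,
    gibbs_fit,
    predict_records,
    reml_fit,
)
from repeatgs.kinship import KinshipMatrix
from repeatgs.simulate import SimConfig, simulate_cross


def _toy_kinship(n, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3 * n))
    G = X @ X.T / (3 * n) * scale
    return KinshipMatrix(
        ids=[f"p{i}" for i in range(n)], matrix=G, freqs=np.array([0.5])
    )


def _records(n_plants, years, values=None, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for year in years:
        for i in range(n_plants):
            v = values[k] if values is not None else rng.normal()
            rows.append((f"p{i}", year, "t", v))
            k += 1
    return pd.DataFrame(rows, columns=["plant", "year", "trait", "value"])


class TestBuildDesign:
    def test_dimensions(self):
        K = _toy_kinship(3)
        spec = build_design(_records(3, [1, 2]), K)
        assert spec.y.shape == (6,)
        assert spec.X.shape == (6, 2)
        assert spec.n_plants == 3

    def test_single_year_intercept_only(self):
        K = _toy_kinship(3)
        spec = build_design(_records(3, [1]), K)
        assert spec.X.shape == (3, 1)

    def test_unbalanced_keeps_all_plant_columns(self):
        K = _toy_kinship(3)
        df = _records(3, [1, 2])
        df = df[~((df["plant"] == "p1") & (df["year"] == 2))]
        spec = build_design(df, K)
        assert spec.y.shape == (5,)
        assert spec.n_plants == 3

    def test_unknown_plant_listed(self):
        K = _toy_kinship(2)
        df = _records(3, [1])
        with pytest.raises(ValueError, match="p2"):
            build_design(df, K)


class TestGeneticParams:
    def test_direct_arithmetic(self):
        p = genetic_params(VarianceComponents(1.0, 1.0, 2.0))
        assert p.h2 == pytest.approx(0.25)
        assert p.R == pytest.approx(0.5)

    def test_no_pe_h2_equals_R(self):
        p = genetic_params(VarianceComponents(0.4, 0.0, 0.6))
        assert p.h2 == pytest.approx(p.R)

    def test_published_partition(self):
        # shares 45.6% genetic, 12.4% permanent, 42% temporary
        p = genetic_params(VarianceComponents(0.456, 0.124, 0.420))
        assert p.h2 == pytest.approx(0.456)
        assert p.R == pytest.approx(0.580)
        assert p.partition == pytest.approx((0.456, 0.124, 0.420))

    def test_partition_sums_to_one(self):
        p = genetic_params(VarianceComponents(0.3, 0.25, 0.45))
        assert sum(p.partition) == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            VarianceComponents(0.0, 0.0, 0.0)


class TestGebvAccuracy:
    def test_closed_form(self):
        assert gebv_accuracy(0.5, 0.25) == pytest.approx(1.0)
        assert gebv_accuracy(0.6, 0.36) == pytest.approx(1.0)

    def test_zero_pa(self):
        assert gebv_accuracy(0.0, 0.3) == 0.0

    def test_above_one_flagged(self):
        with pytest.warns(UserWarning, match="> 1"):
            assert gebv_accuracy(0.9, 0.25) == pytest.approx(1.8)

    def test_nonpositive_h2_rejected(self):
        with pytest.raises(ValueError):
            gebv_accuracy(0.5, 0.0)


class TestRemlFit:
    def test_noise_only_recovery(self):
        cfg = SimConfig(
            n_progeny=100, n_snp=400, sigma2_a=1e-12, sigma2_pe=0.0,
            sigma2_e=1.0, n_years=2, year_effects=(0.0, 0.0), seed=15,
        )
        g, records, truth = simulate_cross(cfg)
        fit = reml_fit(build_design(records, truth.kinship))
        assert fit.vc.sigma2_a < 0.1
        assert fit.vc.sigma2_pe < 0.1
        assert abs(fit.vc.sigma2_e - 1.0) < 0.15

    def test_em_loglik_monotone(self, simulated_fit_instance):
        _, _, records, truth = simulated_fit_instance
        fit = reml_fit(build_design(records, truth.kinship), accelerate=False,
                       tol=1e-6, max_iter=2000)
        path = fit.diagnostics["loglik_path"]
        assert all(b >= a - 1e-9 for a, b in zip(path, path[1:]))

    def test_h2_not_above_R(self, simulated_fit_instance):
        _, _, records, truth = simulated_fit_instance
        fit = reml_fit(build_design(records, truth.kinship))
        assert fit.params.h2 <= fit.params.R + 1e-12

    def test_grid_oracle(self):
        """REML beats a 20^3 grid of the restricted likelihood computed
        independently with dense linear algebra (8 plants, 2 years)."""
        cfg = SimConfig(
            n_progeny=8, n_snp=100, sigma2_a=0.5, sigma2_pe=0.3,
            sigma2_e=0.4, n_years=2, year_effects=(0.0, 0.4), seed=19,
        )
        g, records, truth = simulate_cross(cfg)
        spec = build_design(records, truth.kinship)
        fit = reml_fit(spec)

        y, X, idx = spec.y, spec.X, spec.plant_index
        n, q = len(y), spec.n_plants
        Z = np.zeros((n, q))
        Z[np.arange(n), idx] = 1.0
        Gj = spec.G + 1e-6 * np.eye(q)
        ZGZ = Z @ Gj @ Z.T
        ZZ = Z @ Z.T

        def restricted_ll(sa, spe, se):
            V = sa * ZGZ + spe * ZZ + se * np.eye(n)
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
            _, ld_V = np.linalg.slogdet(V)
            _, ld_X = np.linalg.slogdet(XtViX)
            return -0.5 * (ld_V + ld_X + y @ P @ y)

        vary = y.var()
        grid = np.linspace(0.02, 1.5, 20) * vary
        best_grid = max(
            restricted_ll(sa, spe, se)
            for sa in grid for spe in grid for se in grid
        )
        ll_hat = restricted_ll(
            max(fit.vc.sigma2_a, 1e-12),
            max(fit.vc.sigma2_pe, 1e-12),
            max(fit.vc.sigma2_e, 1e-12),
        )
        assert ll_hat >= best_grid - 1e-6

    def test_blup_equals_mme_oracle(self):
        """Fixed-component BLUPs match an independently assembled
        mixed-model-equation solve to 1e-8."""
        cfg = SimConfig(
            n_progeny=10, n_snp=120, n_years=2, year_effects=(0.0, 0.3),
            seed=23,
        )
        g, records, truth = simulate_cross(cfg)
        spec = build_design(records, truth.kinship)
        vc = VarianceComponents(0.4, 0.25, 0.35)
        beta, a_hat, pe_hat = blup_solutions(spec, vc)

        y, X, idx = spec.y, spec.X, spec.plant_index
        n, q, p = len(y), spec.n_plants, spec.X.shape[1]
        Z = np.zeros((n, q))
        Z[np.arange(n), idx] = 1.0
        Ginv = np.linalg.inv(spec.G + 1e-6 * np.eye(q))
        se, sa, spe = vc.sigma2_e, vc.sigma2_a, vc.sigma2_pe
        C = np.block(
            [
                [X.T @ X, X.T @ Z, X.T @ Z],
                [Z.T @ X, Z.T @ Z + se / sa * Ginv, Z.T @ Z],
                [Z.T @ X, Z.T @ Z, Z.T @ Z + se / spe * np.eye(q)],
            ]
        )
        rhs = np.concatenate([X.T @ y, Z.T @ y, Z.T @ y])
        sol = np.linalg.solve(C, rhs)
        assert np.abs(sol[:p] - beta).max() < 1e-8
        assert np.abs(sol[p:p + q] - a_hat).max() < 1e-8
        assert np.abs(sol[p + q:] - pe_hat).max() < 1e-8

    def test_too_few_records_singular(self):
        K = _toy_kinship(2)
        df = _records(2, [1])[:1]
        with pytest.raises(SingularModelError):
            reml_fit(build_design(df, K))

    def test_zero_variance_response_singular(self):
        K = _toy_kinship(5)
        df = _records(5, [1, 2], values=np.ones(10))
        with pytest.raises(SingularModelError):
            reml_fit(build_design(df, K))


class TestGibbsFit:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_progeny=25, n_snp=150, seed=29)
        g, records, truth = simulate_cross(cfg)
        spec = build_design(records, truth.kinship)
        f1 = gibbs_fit(spec, n_iter=400, burn_in=100, seed=5)
        f2 = gibbs_fit(spec, n_iter=400, burn_in=100, seed=5)
        assert f1.vc.sigma2_a == f2.vc.sigma2_a
        assert np.array_equal(f1.a, f2.a)

    def test_zero_variance_response_near_zero_components(self):
        K = _toy_kinship(6)
        df = _records(6, [1, 2], values=np.full(12, 3.0))
        spec = build_design(df, K)
        fit = gibbs_fit(spec, n_iter=600, burn_in=200, seed=2)
        assert fit.vc.sigma2_a < 1e-6
        assert fit.vc.sigma2_pe < 1e-6

    def test_concordance_with_reml(self, simulated_fit_instance):
        _, _, records, truth = simulated_fit_instance
        spec = build_design(records, truth.kinship)
        fr = reml_fit(spec)
        fg = gibbs_fit(spec, n_iter=3000, burn_in=1000, seed=3)
        assert abs(fr.params.h2 - fg.params.h2) < 0.07

    def test_diagnostics_present(self):
        cfg = SimConfig(n_progeny=20, n_snp=100, seed=31)
        g, records, truth = simulate_cross(cfg)
        fit = gibbs_fit(build_design(records, truth.kinship),
                        n_iter=300, burn_in=100, seed=1)
        assert fit.diagnostics["n_samples"] == 40
        assert fit.diagnostics["ess_h2"] > 0


class TestPredictRecords:
    def _fit(self):
        cfg = SimConfig(
            n_progeny=40, n_snp=200, n_years=2, year_effects=(0.0, 0.7),
            mu=5.0, seed=37,
        )
        g, records, truth = simulate_cross(cfg)
        spec = build_design(records, truth.kinship)
        return reml_fit(spec), records

    def test_year_difference_structure(self):
        fit, records = self._fit()
        plant = records["plant"].iloc[0]
        pred = predict_records(fit, [(plant, 1), (plant, 2)])
        assert pred[1] - pred[0] == pytest.approx(fit.year_effects[2])

    def test_zero_blup_is_mean_plus_year(self):
        fit, records = self._fit()
        fit.a[:] = 0.0
        fit.pe[:] = 0.0
        plant = records["plant"].iloc[0]
        pred = predict_records(fit, [(plant, 2)])
        assert pred[0] == pytest.approx(fit.intercept + fit.year_effects[2])

    def test_unknown_plant_rejected(self):
        fit, _ = self._fit()
        with pytest.raises(ValueError, match="absent"):
            predict_records(fit, [("nope", 1)])

    def test_noiseless_recovery(self):
        cfg = SimConfig(
            n_progeny=50, n_snp=300, sigma2_a=1.0, sigma2_pe=0.5,
            sigma2_e=1e-6, year_effects=(0.0, 0.5, -0.5), seed=41,
        )
        g, records, truth = simulate_cross(cfg)
        spec = build_design(records, truth.kinship)
        fit = fit_repeatability(spec)
        targets = list(zip(records["plant"], records["year"]))
        pred = predict_records(fit, targets)
        y = records["value"].to_numpy()
        rms = np.sqrt(np.mean((pred - y) ** 2))
        assert rms < 0.01 * y.std()

    def test_unseen_year_uses_mean_effect(self):
        fit, records = self._fit()
        plant = records["plant"].iloc[0]
        pred = predict_records(fit, [(plant, 99)])
        mean_eff = np.mean(list(fit.year_effects.values()))
        i = list(fit.plant_ids).index(plant)
        expected = fit.intercept + mean_eff + fit.a[i] + fit.pe[i]
        assert pred[0] == pytest.approx(expected)


class TestSolverPolicy:
    def test_auto_falls_back_to_mcmc(self):
        # zero-variance response: REML raises, Gibbs handles
        K = _toy_kinship(6)
        df = _records(6, [1, 2], values=np.full(12, 3.0))
        spec = build_design(df, K)
        fit = fit_repeatability(
            spec, solver="auto",
            gibbs_kwargs={"n_iter": 400, "burn_in": 100},
        )
        assert fit.solver == "MCMC"

    def test_explicit_solvers(self, simulated_fit_instance):
        _, _, records, truth = simulated_fit_instance
        spec = build_design(records, truth.kinship)
        assert fit_repeatability(spec, solver="reml").solver == "REML"
        f = fit_repeatability(
            spec, solver="mcmc",
            gibbs_kwargs={"n_iter": 300, "burn_in": 100},
        )
        assert f.solver == "MCMC"

    def test_unknown_solver(self, simulated_fit_instance):
        _, _, records, truth = simulated_fit_instance
        spec = build_design(records, truth.kinship)
        with pytest.raises(ValueError):
            fit_repeatability(spec, solver="magic")
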