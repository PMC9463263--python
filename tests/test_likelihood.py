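import numpy as np
import pytest
from scipy.stats import multivariate_normal as scipy_mvn

from conftest import make_univariate_config, univariate_ae
from twinsleep.biometric import VarianceComponents, expected_covariance
from twinsleep.datatypes import ComponentSpec, TwinPairRecord
from twinsleep.likelihood import (MeanThresholdModel, compare, confidence_intervals,
                                  dataset_minus2ll, fit, pair_loglik, profile_interval,
                                  _profiled_m2ll)
from twinsleep.models import (build_multivariate, build_univariate_standardized)
from twinsleep.simulate import generate

CONT = {"x": ComponentSpec("continuous")}
ORD4 = {"x": ComponentSpec("ordinal", 4)}
ORD2 = {"x": ComponentSpec("ordinal", 2)}


def _mt(p=1, thresholds=None):
    return MeanThresholdModel(np.zeros(p), np.zeros(p), np.zeros(p), thresholds or {})


def _rec(values, zygosity="MZm"):
    values = np.asarray(values, float)
    return TwinPairRecord(0, zygosity, (1.0, 1.0), 0.0, values)


class TestContinuousLikelihood:
    def test_bivariate_closed_form_at_origin(self):
        vc = univariate_ae(0.3)
        ll = pair_loglik(_rec([[0.0], [0.0]]), vc, _mt(), CONT)
        assert ll == pytest.approx(-np.log(2 * np.pi) - 0.5 * np.log(1 - 0.09),
                                   abs=1e-12)

    def test_matches_multivariate_normal_density(self):
        rng = np.random.default_rng(0)
        la = rng.normal(size=(2, 2)) * 0.3
        vc = VarianceComponents("AE", A=la @ la.T, CorD=None,
                                E=np.eye(2) * 0.6, trait_names=("a", "b"))
        mt = MeanThresholdModel([0.2, -0.1], np.zeros(2), np.zeros(2), {})
        specs = {"a": ComponentSpec("continuous"), "b": ComponentSpec("continuous")}
        x = np.array([[0.3, -0.5], [1.1, 0.2]])
        ll = pair_loglik(_rec(x, "DZo"), vc, mt, specs)
        sigma = expected_covariance(vc, "DZo")
        mu = np.array([0.2, -0.1, 0.2, -0.1])
        ref = scipy_mvn.logpdf(x.reshape(-1), mean=mu, cov=sigma)
        assert ll == pytest.approx(ref, abs=1e-10)

    def test_twin_order_permutation_leaves_m2ll_unchanged(self):
        """Exchangeability: swapping twin 1 and twin 2 in every pair leaves
        the likelihood unchanged (the covariance blocks are symmetric)."""
        from twinsleep.datatypes import TwinDataset
        data = generate(make_univariate_config(n_mz=80, n_dz=80, seed=2))
        spec = build_multivariate("AE", ("x",), CONT)
        theta = spec.start(data)
        swapped = data.wide.copy()
        swapped[["x_t1", "x_t2"]] = swapped[["x_t2", "x_t1"]].to_numpy()
        swapped[["sex_t1", "sex_t2"]] = swapped[["sex_t2", "sex_t1"]].to_numpy()
        data2 = TwinDataset(swapped, CONT, ("x",))
        assert dataset_minus2ll(spec, data2, theta) == pytest.approx(
            dataset_minus2ll(spec, data, theta), abs=1e-8)

    def test_missing_co_twin_reduces_to_marginal(self):
        vc = univariate_ae(0.4)
        ll = pair_loglik(_rec([[0.7], [np.nan]]), vc, _mt(), CONT)
        ref = scipy_mvn.logpdf([0.7], mean=[0.0], cov=[[1.0]])
        assert ll == pytest.approx(ref, abs=1e-12)

    def test_fast_path_equals_general_path(self):
        data = generate(make_univariate_config(n_mz=60, n_dz=60, complete_frac=0.8,
                                               seed=3))
        spec = build_multivariate("AE", ("x",), CONT)
        res = fit(spec, data, seed=0, n_restarts=0)
        assert dataset_minus2ll(spec, data, res.theta) == pytest.approx(
            res.minus2ll, abs=1e-6)


class TestOrdinalLikelihood:
    def test_singleton_two_categories_symmetric_threshold(self):
        vc = univariate_ae(0.4)
        mt = _mt(thresholds={"x": np.array([0.0])})
        ll = pair_loglik(_rec([[1.0], [np.nan]]), vc, mt, ORD2)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_pair_rectangle_matches_grid_oracle(self):
        """Ordinal pair rectangle equals dense trapezoid quadrature of the
        bivariate liability density to 1e-6."""
        tau = np.array([-0.5, 0.4, 1.2])
        vc = univariate_ae(0.4)  # MZ liability correlation 0.4
        mt = _mt(thresholds={"x": tau})
        ll = pair_loglik(_rec([[1.0], [2.0]]), vc, mt, ORD4)
        g1 = np.linspace(-0.5, 0.4, 1501)
        g2 = np.linspace(0.4, 1.2, 1501)
        xx, yy = np.meshgrid(g1, g2, indexing="ij")
        pdf = scipy_mvn.pdf(np.dstack([xx, yy]), mean=[0, 0],
                            cov=[[1, 0.4], [0.4, 1]])
        ref = np.log(np.trapezoid(np.trapezoid(pdf, g2, axis=1), g1))
        assert ll == pytest.approx(ref, abs=1e-6)

    def test_mixed_continuous_ordinal_matches_decomposed_oracle(self):
        """One continuous + one ordinal trait: likelihood factors into the
        continuous density times the conditional rectangle."""
        A = np.array([[0.4, 0.15], [0.15, 0.3]])
        E = np.array([[0.6, 0.1], [0.1, 0.7]])
        vc = VarianceComponents("AE", A=A, CorD=None, E=E, trait_names=("c", "o"))
        tau = np.array([-0.3, 0.5, 1.3])
        mt = MeanThresholdModel(np.zeros(2), np.zeros(2), np.zeros(2), {"o": tau})
        specs = {"c": ComponentSpec("continuous"), "o": ComponentSpec("ordinal", 4)}
        rec = TwinPairRecord(0, "MZf", (0.0, 0.0), 0.0,
                             np.array([[0.2, 1.0], [-0.4, np.nan]]))
        ll = pair_loglik(rec, vc, mt, specs, n_points=2 ** 14)
        sigma = expected_covariance(vc, "MZf")
        ci = [0, 2]   # continuous obs: both twins' trait "c"
        oi = [1]      # ordinal obs: twin 1 trait "o"
        s_cc = sigma[np.ix_(ci, ci)]
        x_c = np.array([0.2, -0.4])
        ll_c = scipy_mvn.logpdf(x_c, mean=np.zeros(2), cov=s_cc)
        s_oc = sigma[np.ix_(oi, ci)]
        m_cond = s_oc @ np.linalg.solve(s_cc, x_c)
        v_cond = sigma[np.ix_(oi, oi)] - s_oc @ np.linalg.solve(s_cc, s_oc.T)
        from scipy.stats import norm
        sd = float(np.sqrt(v_cond[0, 0]))
        pr = norm.cdf((0.5 - m_cond[0]) / sd) - norm.cdf((-0.3 - m_cond[0]) / sd)
        assert ll == pytest.approx(ll_c + np.log(pr), abs=1e-8)

    def test_rectangle_probabilities_conserve_mass(self):
        """Sum over every category combination of a 2-ordinal-trait pair
        (4 categories each, four dimensions) is one."""
        A = np.array([[0.4, 0.2], [0.2, 0.5]])
        E = np.array([[0.6, 0.1], [0.1, 0.5]])
        vc = VarianceComponents("AE", A=A, CorD=None, E=E, trait_names=("u", "v"))
        tau = {"u": np.array([-0.8, 0.0, 0.9]), "v": np.array([-0.5, 0.6, 1.4])}
        mt = MeanThresholdModel(np.zeros(2), np.zeros(2), np.zeros(2), tau)
        specs = {"u": ComponentSpec("ordinal", 4), "v": ComponentSpec("ordinal", 4)}
        total = 0.0
        for cu1 in range(4):
            for cv1 in range(4):
                for cu2 in range(4):
                    for cv2 in range(4):
                        rec = TwinPairRecord(0, "DZm", (1.0, 1.0), 0.0, np.array(
                            [[cu1, cv1], [cu2, cv2]], float))
                        total += np.exp(pair_loglik(rec, vc, mt, specs))
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_non_psd_sigma_returns_flagged_penalty(self):
        vc = VarianceComponents("AE", A=np.array([[2.0]]), CorD=None,
                                E=np.array([[-1.5]]), trait_names=("x",))
        flags = []
        ll = pair_loglik(_rec([[0.3], [0.1]]), vc, _mt(), CONT, flags=flags)
        assert ll == pytest.approx(-1e8) and flags


class TestFit:
    def test_univariate_ae_parameter_recovery(self):
        data = generate(make_univariate_config(h2=0.4, n_mz=2000, n_dz=2000, seed=42))
        res = fit(build_univariate_standardized("x"), data, seed=0)
        assert res.converged
        assert res.estimates["h2"] == pytest.approx(0.4, abs=0.05)
        assert res.aic == pytest.approx(res.minus2ll + 2 * res.n_params)

    def test_e_only_truth_not_rejected_by_lrt(self):
        """Type-I behaviour: with no familial resemblance, AE vs E is
        non-significant at alpha = 0.05 in >= 90% of replicates."""
        vc_e = VarianceComponents("E", A=None, CorD=None, E=np.eye(1),
                                  trait_names=("x",))
        keep = 0
        n_rep = 50
        for r in range(n_rep):
            from twinsleep.simulate import SimulationConfig
            cfg = SimulationConfig(
                group_sizes={"MZm": (150, 150), "DZm": (150, 150)},
                components_true=vc_e, thresholds_true={}, specs=CONT,
                skew_traits=(), seed=9000 + r)
            data = generate(cfg)
            ae = fit(build_multivariate("AE", ("x",), CONT), data, seed=r,
                     n_restarts=0)
            e = fit(build_multivariate("E", ("x",), CONT), data, seed=r,
                    n_restarts=0)
            if compare(ae, e).p_value > 0.05:
                keep += 1
        assert keep >= 0.9 * n_rep

    def test_ordinal_univariate_recovery(self):
        data = generate(make_univariate_config(h2=0.5, n_mz=300, n_dz=300, seed=77,
                                               ordinal=True))
        res = fit(build_multivariate("AE", ("x",), ORD4), data, seed=1, n_restarts=0)
        assert res.converged
        assert res.estimates["A_x_x"] == pytest.approx(0.5, abs=0.15)
        tau = res.mean_thresholds().thresholds["x"]
        np.testing.assert_allclose(tau, [-0.5, 0.4, 1.2], atol=0.2)

    def test_covariate_effects_recovered(self):
        from twinsleep.simulate import SimulationConfig
        cfg = SimulationConfig(group_sizes={"MZm": (800, 800), "DZm": (800, 800)},
                               components_true=univariate_ae(0.4), thresholds_true={},
                               specs=CONT, skew_traits=(),
                               beta_age={"x": 0.8}, beta_sex={}, seed=55)
        data = generate(cfg)
        spec = build_multivariate("AE", ("x",), CONT, include_covariates=True)
        res = fit(spec, data, seed=0, n_restarts=0)
        assert res.estimates["bage_x"] == pytest.approx(0.8, abs=0.2)


class TestCompare:
    def test_identical_models(self):
        data = generate(make_univariate_config(n_mz=100, n_dz=100, seed=5))
        res = fit(build_multivariate("AE", ("x",), CONT), data, seed=0, n_restarts=0)
        out = compare(res, res)
        assert (out.chi2, out.df, out.p_value, out.delta_aic) == (0.0, 0, 1.0, 0.0)

    def test_chi_square_quantile_identity(self):
        from dataclasses import replace
        data = generate(make_univariate_config(n_mz=100, n_dz=100, seed=6))
        full = fit(build_multivariate("AE", ("x",), CONT), data, seed=0, n_restarts=0)
        nested = fit(build_multivariate("E", ("x",), CONT), data, seed=0, n_restarts=0)
        nested = replace(nested, minus2ll=full.minus2ll + 3.841458820694124)
        out = compare(full, nested)
        assert out.df == 1 and out.p_value == pytest.approx(0.05, abs=1e-6)

    def test_strong_heritability_rejects_e_model(self):
        data = generate(make_univariate_config(h2=0.6, n_mz=1500, n_dz=1500, seed=7))
        ae = fit(build_multivariate("AE", ("x",), CONT), data, seed=0, n_restarts=0)
        e = fit(build_multivariate("E", ("x",), CONT), data, seed=0, n_restarts=0)
        assert compare(ae, e).p_value < 0.001

    def test_under_optimized_full_model_detected(self):
        from dataclasses import replace
        data = generate(make_univariate_config(n_mz=100, n_dz=100, seed=8))
        full = fit(build_multivariate("AE", ("x",), CONT), data, seed=0, n_restarts=0)
        broken = replace(full, minus2ll=full.minus2ll + 5.0)
        nested = fit(build_multivariate("E", ("x",), CONT), data, seed=0, n_restarts=0)
        if nested.minus2ll < broken.minus2ll:
            with pytest.raises(RuntimeError, match="refit"):
                compare(broken, nested)


class TestConfidenceIntervals:
    def test_quadratic_surface_gives_wald_bounds(self):
        """On an exactly quadratic -2LL with unit curvature the profile
        bounds are MLE +- 1.96."""
        prof = lambda v: (v - 2.0) ** 2  # noqa: E731
        lo, hi, flags = profile_interval(prof, 2.0, 0.0, level=0.95)
        assert lo == pytest.approx(2.0 - 1.959964, abs=1e-4)
        assert hi == pytest.approx(2.0 + 1.959964, abs=1e-4)
        assert not any(flags.values())

    def test_boundary_adjacent_h2_reports_zero_lower_bound(self):
        prof = lambda v: 8.0 * v  # noqa: E731  (monotone: MLE at the 0 boundary)
        lo, hi, flags = profile_interval(prof, 0.0, 0.0, lower_bound=0.0,
                                         upper_bound=1.0)
        assert lo == 0.0 and flags["lower_at_boundary"]

    def test_profile_ci_covers_generating_h2(self):
        """~95% coverage of the generating heritability across scaled-down
        replicates."""
        n_rep = 150
        cover = 0
        for r in range(n_rep):
            data = generate(make_univariate_config(h2=0.4, n_mz=120, n_dz=130,
                                                   seed=2_000 + r))
            res = fit(build_univariate_standardized("x"), data, seed=r, n_restarts=0)
            lo, hi = confidence_intervals(res, ["h2"])["h2"]
            cover += lo <= 0.4 <= hi
        assert 0.89 * n_rep <= cover <= 0.995 * n_rep

    def test_unconverged_fit_rejected(self):
        from dataclasses import replace
        data = generate(make_univariate_config(n_mz=50, n_dz=50, seed=3))
        res = fit(build_univariate_standardized("x"), data, seed=0, n_restarts=0)
        bad = replace(res, converged=False)
        with pytest.raises(ValueError):
            confidence_intervals(bad, ["h2"])
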