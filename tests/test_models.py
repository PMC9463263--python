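import numpy as np
import pytest

from conftest import make_univariate_config
from twinsleep.biometric import VarianceComponents
from twinsleep.datatypes import ComponentSpec, TRAITS
from twinsleep.likelihood import dataset_minus2ll, fit
from twinsleep.models import (build_common_pathway, build_independent_pathway,
                              build_multivariate, ip_start_from_cp, mv_start_from_ip,
                              selection_driver)
from twinsleep.pipeline import _pathway_shares
from twinsleep.simulate import SimulationConfig, generate

CONT7 = {t: ComponentSpec("continuous") for t in TRAITS}


def cp_truth(latent_a2=0.32):
    """A one-factor common-pathway ground truth with unit trait variances."""
    lam = np.array([0.55, 0.6, 0.65, 0.55, 0.7, 0.35, 0.4])
    a_s = np.array([0.15, 0.1, 0.08, 0.2, 0.08, 0.3, 0.25])
    e_s = 1.0 - lam ** 2 - a_s
    A = latent_a2 * np.outer(lam, lam) + np.diag(a_s)
    E = (1 - latent_a2) * np.outer(lam, lam) + np.diag(e_s)
    return VarianceComponents("AE", A=A, CorD=None, E=E, trait_names=TRAITS)


def small_cohort(vc, n=600, seed=0):
    return generate(SimulationConfig(
        group_sizes={"MZm": (n // 2, n // 2), "DZm": (n // 2, n // 2)},
        components_true=vc, liability_scale=True, seed=seed))


class TestParameterCounts:
    def test_multivariate_ae_component_count(self):
        spec = build_multivariate("AE", TRAITS, CONT7)
        comp = [n for n in spec.param_names if n.startswith(("A_", "E_"))]
        assert len(comp) == 2 * 7 * 8 // 2  # 56

    def test_e_only_two_traits(self):
        spec = build_multivariate("E", TRAITS[:2], None)
        comp = [n for n in spec.param_names if n.startswith("E_")]
        assert len(comp) == 3

    def test_ace_univariate(self):
        spec = build_multivariate("ACE", ("x",), None)
        comp = [n for n in spec.param_names if n.startswith(("A_", "CorD_", "E_"))]
        assert len(comp) == 3

    def test_common_pathway_bookkeeping(self):
        # 7 loadings + 1 latent split + 7 + 7 specifics = 22 structural params
        spec = build_common_pathway("one_factor", TRAITS, CONT7)
        structural = [n for n in spec.param_names if not n.startswith("mean_")]
        assert len(structural) == 22

    def test_independent_pathway_bookkeeping(self):
        # 14 common loadings + 14 specifics before means
        spec = build_independent_pathway(TRAITS, CONT7)
        structural = [n for n in spec.param_names if not n.startswith("mean_")]
        assert len(structural) == 28

    @pytest.mark.parametrize("builder", [
        lambda: build_multivariate("AE", TRAITS, CONT7),
        lambda: build_multivariate("ADE", TRAITS[:3], None),
        lambda: build_common_pathway("one_factor", TRAITS, CONT7),
        lambda: build_common_pathway("cole", TRAITS, CONT7),
        lambda: build_independent_pathway(TRAITS, CONT7),
    ])
    def test_parameter_names_are_distinct(self, builder):
        """Symbol-level audit: the reported free-parameter count equals the
        number of distinct named entries in the specification."""
        spec = builder()
        assert len(set(spec.param_names)) == len(spec.param_names)
        assert len(spec.bounds) == len(spec.param_names)

    def test_ordinal_trait_drops_e_diagonal(self):
        specs = dict(CONT7)
        specs["medication"] = ComponentSpec("ordinal", 4)
        spec = build_multivariate("AE", TRAITS, specs)
        assert "E_medication_medication" not in spec.param_names
        assert "tau1_medication" in spec.param_names


class TestBuilderValidation:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            build_multivariate("AD", TRAITS, None)

    def test_unassigned_trait_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            build_common_pathway({"f1": TRAITS[:3]}, TRAITS, CONT7)

    def test_independent_pathway_needs_two_traits(self):
        with pytest.raises(ValueError):
            build_independent_pathway(("x",), None)


class TestStructuralIdentities:
    def test_zero_specifics_give_rank_one_common_part(self):
        spec = build_common_pathway("one_factor", TRAITS, CONT7)
        theta = spec.start(small_cohort(cp_truth(), n=40, seed=1))
        theta[spec.as_idx] = 0.0
        for t, j in spec._es_map.items():
            theta[spec.es_idx[j]] = 1e-6
        vc, _ = spec.unpack(theta)
        assert np.linalg.matrix_rank(vc.A, tol=1e-8) == 1

    def test_zero_common_loadings_collapse_to_univariate_sum(self):
        """With all common loadings zero the independent-pathway -2LL is
        the sum of the per-trait univariate -2LLs (separability)."""
        data = small_cohort(cp_truth(), n=200, seed=2)
        two = ("latency", "duration")
        from twinsleep.datatypes import TwinDataset
        sub = TwinDataset(data.wide, {t: ComponentSpec("continuous") for t in two}, two)
        ip = build_independent_pathway(two, None)
        theta = ip.start(sub).copy()
        theta[ip.a_idx] = 0.0
        theta[ip.e_idx] = 0.0
        joint = dataset_minus2ll(ip, sub, theta)
        total = 0.0
        for t in two:
            uni = TwinDataset(data.wide, {t: ComponentSpec("continuous")}, (t,))
            u = build_multivariate("AE", (t,), None)
            th = np.zeros(len(u.param_names))
            th[u.comp_idx["A"][(0, 0)]] = theta[ip.a_idx[list(two).index(t)]] ** 2 + \
                theta[ip.as_idx[list(two).index(t)]]
            th[u.comp_idx["E"][(0, 0)]] = theta[ip.es_idx[ip._es_map[t]]]
            th[u.layout.mean_idx[t]] = theta[ip.layout.mean_idx[t]]
            total += dataset_minus2ll(u, uni, th)
        assert joint == pytest.approx(total, rel=1e-10)

    def test_warm_start_mappings_preserve_likelihood(self):
        """The common-pathway optimum maps into the independent-pathway and
        free multivariate parameterizations with identical -2LL (exact
        nesting of the implied covariances)."""
        data = small_cohort(cp_truth(), n=400, seed=3)
        cp = fit(build_common_pathway("one_factor", TRAITS, CONT7), data, seed=0,
                 n_restarts=0)
        ip_spec = build_independent_pathway(TRAITS, CONT7)
        theta_ip = ip_start_from_cp(cp, ip_spec)
        assert dataset_minus2ll(ip_spec, data, theta_ip) == pytest.approx(
            cp.minus2ll, rel=1e-10)
        ip = fit(ip_spec, data, seed=0, n_restarts=0, start=theta_ip)
        mv_spec = build_multivariate("AE", TRAITS, CONT7)
        theta_mv = mv_start_from_ip(ip, mv_spec)
        assert dataset_minus2ll(mv_spec, data, theta_mv) == pytest.approx(
            ip.minus2ll, rel=1e-10)

    def test_pathway_shares_sum_to_one(self):
        data = small_cohort(cp_truth(), n=400, seed=4)
        for spec in (build_common_pathway("one_factor", TRAITS, CONT7),
                     build_independent_pathway(TRAITS, CONT7)):
            res = fit(spec, data, seed=0, n_restarts=0)
            shares = _pathway_shares(res)
            np.testing.assert_allclose(shares.sum(axis=1), 1.0, atol=1e-8)


class TestRecovery:
    def test_common_pathway_latent_heritability_recovered(self):
        data = small_cohort(cp_truth(0.32), n=3000, seed=11)
        res = fit(build_common_pathway("one_factor", TRAITS, CONT7), data, seed=1,
                  n_restarts=1)
        assert res.converged
        assert res.estimates["latent_a2_sleep_quality_factor"] == pytest.approx(
            0.32, abs=0.08)

    def test_independent_pathway_negligible_common_loadings_recovered(self):
        """Traits given (near) zero common genetic loadings in the truth are
        recovered as such."""
        a = np.array([0.5, 0.02, 0.02, 0.45, 0.55, 0.3, 0.35])
        e = np.array([0.5, 0.55, 0.6, 0.5, 0.55, 0.3, 0.35])
        a_s = np.full(7, 0.15)
        e_s = 1.0 - a ** 2 - e ** 2 - a_s
        vc = VarianceComponents("AE", A=np.outer(a, a) + np.diag(a_s), CorD=None,
                                E=np.outer(e, e) + np.diag(e_s), trait_names=TRAITS)
        data = small_cohort(vc, n=3000, seed=12)
        res = fit(build_independent_pathway(TRAITS, CONT7), data, seed=2, n_restarts=1)
        est = res.estimates
        assert abs(est["a_load_duration"]) < 0.15
        assert abs(est["a_load_efficiency"]) < 0.15
        assert abs(est["a_load_sleep_quality"]) > 0.3


class TestSelectionDriver:
    def test_ace_screen_prefers_ace_when_dz_large(self):
        vc = VarianceComponents("ACE", A=np.array([[0.3]]), CorD=np.array([[0.3]]),
                                E=np.array([[0.4]]), trait_names=("x",))
        cfg = SimulationConfig(group_sizes={"MZm": (800, 800), "DZf": (800, 800)},
                               components_true=vc, thresholds_true={},
                               specs={"x": ComponentSpec("continuous")},
                               skew_traits=(), seed=21)
        table, fits = selection_driver(generate(cfg), seed=0)
        assert "multivariate_ACE" in set(table["model"])

    def test_nesting_order_of_minus2ll(self):
        """-2LL(multivariate) <= -2LL(independent) <= -2LL(common), to
        optimizer tolerance, on an arbitrary dataset."""
        data = small_cohort(cp_truth(), n=500, seed=22)
        _, fits = selection_driver(
            data, models=["multivariate_AE", "common_pathway_1f",
                          "independent_pathway_AE"], seed=0)
        mv = fits["multivariate_AE"].minus2ll
        ip = fits["independent_pathway_AE"].minus2ll
        cp = fits["common_pathway_1f"].minus2ll
        tol = 1e-6 * (1 + abs(cp))
        assert mv <= ip + tol
        assert ip <= cp + tol

    def test_common_pathway_truth_ranked_above_independent(self):
        wins = 0
        n_rep = 8
        for r in range(n_rep):
            data = small_cohort(cp_truth(), n=1200, seed=300 + r)
            table, _ = selection_driver(
                data, models=["common_pathway_1f", "independent_pathway_AE"],
                seed=r)
            ranked = table.set_index("model")["aic"]
            wins += ranked["common_pathway_1f"] < ranked["independent_pathway_AE"]
        assert wins >= n_rep - 2
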