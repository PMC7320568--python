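"""ICER/NMB algebra, samplers, PSA, tornado, thresholds, age stratification."""

import numpy as np
import pytest
import scipy.stats

import sinocea as sc
from sinocea.errors import (
    AgeRangeError,
    InfeasibleMomentsError,
    NoCrossingError,
    NoThresholdInRangeError,
)
from sinocea.markov import CohortTrace
from sinocea.sensitivity import Z_90, compare_spec

from conftest import make_spec


def stub_result(cost, qaly, name="S"):
    """Minimal RunResult carrying only totals (for pure-algebra tests)."""
    occ = np.array([[1.0, 0.0, 0.0]])
    z = np.zeros(1)
    trace = CohortTrace(47, occ, z, z, z, z)
    return sc.RunResult(name, cost, qaly, np.ones(1), trace)


class TestCompareAndNmb:
    def test_icer_is_delta_cost_over_delta_effect(self):
        res = sc.compare(stub_result(100.0, 2.0), stub_result(50.0, 1.0))
        assert res.delta_cost == 50.0 and res.delta_effect == 1.0
        assert res.icer == 50.0 and res.dominance == "none"

    def test_identical_results_tie_with_undefined_icer(self):
        res = sc.compare(stub_result(70.0, 3.0), stub_result(70.0, 3.0))
        assert res.icer is None and res.dominance == "tie"
        assert res.delta_cost == 0.0 and res.delta_effect == 0.0

    def test_dominance_flags(self):
        assert sc.compare(stub_result(10, 2.0), stub_result(20, 1.0)).dominance == "a_dominates"
        assert sc.compare(stub_result(20, 1.0), stub_result(10, 2.0)).dominance == "b_dominates"

    def test_nmb_identity(self):
        res = sc.ComparisonResult(0.0, 1.0, None, "none")
        assert sc.net_monetary_benefit(res, 30_828.0) == 30_828.0
        with pytest.raises(ValueError):
            sc.net_monetary_benefit(res, 0.0)

    def test_nmb_sign_flips_exactly_at_icer(self, base_results):
        cmp_ = base_results.comparison
        icer = cmp_.icer
        assert sc.net_monetary_benefit(cmp_, icer) == pytest.approx(0.0, abs=1e-6)
        assert sc.net_monetary_benefit(cmp_, icer * 1.001) > 0
        assert sc.net_monetary_benefit(cmp_, icer * 0.999) < 0

    @pytest.mark.parametrize("lam", [5_000.0, 30_828.0, 80_000.0, 200_000.0])
    def test_nmb_positive_iff_icer_below_wtp(self, base_results, lam):
        cmp_ = base_results.comparison  # delta_effect > 0 here
        assert (sc.net_monetary_benefit(cmp_, lam) > 0) == (cmp_.icer < lam)


class TestFitDistribution:
    def test_symmetric_ci_gives_symmetric_beta(self):
        s = sc.fit_distribution(
            sc.ParameterDistribution("p", "beta", 0.5, (0.4, 0.6))
        )
        x = s.draw(np.random.default_rng(0), 200_000)
        assert np.mean(x) == pytest.approx(0.5, abs=2e-3)
        assert scipy.stats.skew(x) == pytest.approx(0.0, abs=0.02)

    def test_beta_reproduces_90ci_quantiles(self):
        # moment-matched beta for the proton eradication probability
        dist = sc.ParameterDistribution(
            "strategy_a.p_eradicate", "beta", 0.9, (0.833, 0.957)
        )
        x = sc.fit_distribution(dist).draw(np.random.default_rng(1), 1_000_000)
        assert np.percentile(x, 5) == pytest.approx(0.833, abs=0.01)
        assert np.percentile(x, 95) == pytest.approx(0.957, abs=0.01)
        # independent cross-check of the implied quantiles via scipy
        m, v = dist.mean, dist.sd**2
        alpha = m * (m * (1 - m) / v - 1)
        beta = alpha * (1 - m) / m
        assert scipy.stats.beta.ppf(0.05, alpha, beta) == pytest.approx(0.833, abs=0.01)
        assert scipy.stats.beta.ppf(0.95, alpha, beta) == pytest.approx(0.957, abs=0.01)

    def test_normal_reproduces_90ci_quantiles(self):
        dist = sc.ParameterDistribution(
            "disease.c_followup", "normal", 1000.0, (872.1, 1127.8)
        )
        x = sc.fit_distribution(dist).draw(np.random.default_rng(2), 1_000_000)
        assert np.percentile(x, 5) == pytest.approx(872.1, rel=0.005)
        assert np.percentile(x, 95) == pytest.approx(1127.8, rel=0.005)

    def test_truncated_normal_never_negative(self):
        dist = sc.ParameterDistribution("c", "normal", 100.0, (0.0, 400.0))
        x = sc.fit_distribution(dist).draw(np.random.default_rng(3), 100_000)
        assert np.all(x >= 0.0)

    def test_degenerate_ci_is_point_mass(self):
        s = sc.fit_distribution(sc.ParameterDistribution("p", "beta", 0.3, (0.3, 0.3)))
        assert np.all(s.draw(np.random.default_rng(0), 100) == 0.3)

    def test_infeasible_beta_moments_rejected(self):
        with pytest.raises(InfeasibleMomentsError):
            sc.fit_distribution(
                sc.ParameterDistribution("p", "beta", 0.02, (0.0, 0.9))
            )

    def test_sd_from_ci_halfwidth(self):
        dist = sc.ParameterDistribution("x", "normal", 10.0, (5.0, 15.0))
        assert dist.sd == pytest.approx(5.0 / Z_90)


class TestRunPsa:
    def test_fixed_seed_bit_identical(self, base_model):
        a = sc.run_psa(base_model.spec, base_model.distributions, 500, 42, 30_828.0)
        b = sc.run_psa(base_model.spec, base_model.distributions, 500, 42, 30_828.0)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_effect, b.delta_effect)
        assert a.fraction_favoring_a == b.fraction_favoring_a

    def test_degenerate_distributions_repeat_base_case(self, base_model, base_results):
        dists = [
            sc.ParameterDistribution(d.path, d.kind, d.mean, (d.mean, d.mean))
            for d in base_model.distributions
        ]
        res = sc.run_psa(base_model.spec, dists, 50, 0, 30_828.0)
        # base ICER is below this WTP, so every iteration favors A
        assert res.fraction_favoring_a == 1.0
        assert np.allclose(res.delta_effect, base_results.delta_effect, atol=1e-12)
        assert np.allclose(res.delta_cost, base_results.delta_cost, atol=1e-9)

    def test_fast_path_matches_per_iteration_engine(self, base_model):
        res = sc.run_psa(base_model.spec, base_model.distributions, 40, 7, 30_828.0)
        for i in range(res.n_iterations):
            spec_i = base_model.spec
            for path, draws in res.samples.items():
                spec_i = spec_i.with_value(path, float(draws[i]))
            ref = compare_spec(spec_i)
            assert res.delta_cost[i] == pytest.approx(ref.delta_cost, abs=1e-8)
            assert res.delta_effect[i] == pytest.approx(ref.delta_effect, abs=1e-11)

    def test_sample_means_near_distribution_means(self, base_model):
        res = sc.run_psa(base_model.spec, base_model.distributions, 20_000, 11, 30_828.0)
        for dist in base_model.distributions:
            x = res.samples[dist.path]
            se = dist.sd / np.sqrt(len(x))
            # truncation at 0 is immaterial for these CIs, so 3 SE applies
            assert abs(x.mean() - dist.mean) < 3 * se

    def test_two_seeds_agree_within_binomial_noise(self, base_model):
        f = [
            sc.run_psa(base_model.spec, base_model.distributions, 4000, s, 30_828.0).fraction_favoring_a
            for s in (1, 2)
        ]
        p = np.mean(f)
        se = np.sqrt(p * (1 - p) / 4000)
        assert abs(f[0] - f[1]) < 3 * np.sqrt(2) * se

    def test_chemo_cost_draw_cancels_in_deltas(self, base_model):
        dists = [sc.ParameterDistribution("c_chemo", "normal", 5000.0, (3710.4, 6284.7))]
        res = sc.run_psa(base_model.spec, dists, 50, 3, 30_828.0)
        assert np.allclose(res.delta_cost, res.delta_cost[0])
        assert np.allclose(res.delta_effect, res.delta_effect[0])


class TestTornado:
    def test_entries_are_permutation_sorted_by_spread(self, base_model):
        entries = sc.tornado(base_model.spec, base_model.distributions)
        assert sorted(e.path for e in entries) == sorted(
            d.path for d in base_model.distributions
        )
        spreads = [e.spread for e in entries]
        assert spreads == sorted(spreads, reverse=True)
        assert all(s >= 0 for s in spreads)

    def test_eradication_probabilities_and_proton_cost_lead(self, base_model):
        top3 = {e.path for e in sc.tornado(base_model.spec, base_model.distributions)[:3]}
        assert top3 == {
            "strategy_a.p_eradicate",
            "strategy_b.p_eradicate",
            "strategy_a.c_radiotherapy",
        }

    def test_followup_cost_less_influential_than_proton_cost(self, base_model):
        by_path = {
            e.path: e.spread
            for e in sc.tornado(base_model.spec, base_model.distributions)
        }
        assert by_path["disease.c_followup"] < by_path["strategy_a.c_radiotherapy"]

    def test_degenerate_ci_ranks_last_with_zero_spread(self, base_model):
        dists = list(base_model.distributions) + [
            sc.ParameterDistribution("disease.c_palliative", "normal", 5000.0, (5000.0, 5000.0))
        ]
        # replace the real palliative distribution to keep paths unique
        dists = [d for d in dists if d.ci90 != (3724.0, 6269.1)]
        entries = sc.tornado(base_model.spec, dists)
        assert entries[-1].spread == 0.0
        assert entries[-1].path == "disease.c_palliative"

    def test_requires_distributions(self, base_model):
        with pytest.raises(ValueError):
            sc.tornado(base_model.spec, [])


class TestOneWayThreshold:
    def test_fixed_point_at_base_icer(self, base_model, base_results):
        lam = base_results.icer
        thr = sc.one_way_threshold(
            base_model.spec, "strategy_a.c_radiotherapy", lam, (10_000.0, 200_000.0)
        )
        assert thr == pytest.approx(50_000.0, rel=1e-4)

    @pytest.mark.parametrize(
        "path,bounds",
        [
            ("strategy_a.c_radiotherapy", (10_000.0, 400_000.0)),
            ("strategy_a.p_eradicate", (0.74, 1.0)),
            ("strategy_b.p_eradicate", (0.3, 0.89)),
        ],
    )
    def test_threshold_self_consistency(self, base_model, path, bounds):
        lam = 30_828.0
        thr = sc.one_way_threshold(base_model.spec, path, lam, bounds)
        icer_at_thr = sc.compare_spec(base_model.spec.with_value(path, thr)).icer
        assert abs(icer_at_thr - lam) / lam < 1e-4

    def test_no_sign_change_raises(self, base_model):
        with pytest.raises(NoThresholdInRangeError):
            sc.one_way_threshold(
                base_model.spec, "strategy_a.c_radiotherapy", 30_828.0, (0.0, 20_000.0)
            )


class TestAgeStratification:
    def test_icer_non_decreasing_in_age(self, base_model):
        strata = sc.age_stratified_icer(base_model.spec, range(0, 80, 10))
        icers = [res.icer for _, res in strata]
        assert np.all(np.diff(icers) >= 0)

    def test_each_stratum_runs_to_endpoint(self, base_model):
        [(age, res)] = sc.age_stratified_icer(base_model.spec, [40])
        # horizon 77 - 40 = 37 cycles; comparison carries full-horizon deltas
        assert res.delta_effect > 0

    def test_age_at_or_above_endpoint_rejected(self, base_model):
        with pytest.raises(AgeRangeError):
            sc.age_stratified_icer(base_model.spec, [77])

    def test_age_threshold_crossings(self, base_model):
        # λ far above every stratum ICER: cost-effective everywhere
        with pytest.raises(NoCrossingError) as exc:
            sc.age_threshold(base_model.spec, 1e9)
        assert exc.value.direction == "all"
        with pytest.raises(NoCrossingError) as exc:
            sc.age_threshold(base_model.spec, 1.0)
        assert exc.value.direction == "none"


class TestParameterPaths:
    def test_with_value_roundtrip(self, base_model):
        spec2 = base_model.spec.with_value("disease.u_no_cancer", 0.8)
        assert spec2.disease.u_no_cancer == 0.8
        assert base_model.spec.disease.u_no_cancer == 0.94  # original untouched

    def test_chemo_alias_sets_both_arms(self, base_model):
        spec2 = base_model.spec.with_value("c_chemo", 7000.0)
        assert spec2.strategy_a.c_chemo == 7000.0
        assert spec2.strategy_b.c_chemo == 7000.0

    def test_unknown_path_rejected(self, base_model):
        with pytest.raises(KeyError):
            base_model.spec.with_value("disease.nonexistent", 1.0)
        with pytest.raises(KeyError):
            base_model.spec.with_value("nonsense", 1.0)
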