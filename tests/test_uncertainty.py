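"""PSA and DSA: distribution fitting, sampling, reproducibility, sweeps."""
import numpy as np
import pytest
from scipy import stats

from pandemic_cea import (
    ParameterDistribution,
    PSAConfig,
    bundled_scenario,
    one_way_dsa,
    run_psa,
    run_scenario,
)
from pandemic_cea.uncertainty import (
    beta_from_ci,
    gamma_from_ci,
    get_param,
    lognormal_from_ci,
    sample_distribution,
    set_param,
)


@pytest.fixture(scope="module")
def depression(bundled):
    return bundled["depression"]


class TestQuantileMatching:
    @pytest.mark.parametrize("low, high", [(1.20, 2.56), (0.5, 0.9), (5.34, 8.0)])
    def test_lognormal_quantiles_match_bounds(self, low, high):
        mu, sigma = lognormal_from_ci(low, high)
        assert stats.lognorm.ppf(0.025, sigma, scale=np.exp(mu)) == pytest.approx(low)
        assert stats.lognorm.ppf(0.975, sigma, scale=np.exp(mu)) == pytest.approx(high)

    @pytest.mark.parametrize("low, high", [(0.1, 0.4), (0.05, 0.16), (0.6, 0.95)])
    def test_beta_quantiles_match_bounds(self, low, high):
        a, b = beta_from_ci(low, high)
        assert stats.beta.ppf(0.025, a, b) == pytest.approx(low, rel=1e-5)
        assert stats.beta.ppf(0.975, a, b) == pytest.approx(high, rel=1e-5)

    @pytest.mark.parametrize("low, high", [(100.0, 900.0), (1e6, 3e6)])
    def test_gamma_quantiles_match_bounds(self, low, high):
        a, s = gamma_from_ci(low, high)
        assert stats.gamma.ppf(0.025, a, scale=s) == pytest.approx(low, rel=1e-5)
        assert stats.gamma.ppf(0.975, a, scale=s) == pytest.approx(high, rel=1e-5)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            lognormal_from_ci(2.0, 1.0)
        with pytest.raises(ValueError):
            beta_from_ci(0.5, 0.4)

    def test_nonpositive_bounds_rejected_for_log_scale(self):
        with pytest.raises(ValueError):
            lognormal_from_ci(0.0, 2.0)
        with pytest.raises(ValueError):
            gamma_from_ci(-1.0, 2.0)


class TestSampleDistribution:
    def test_point_mass_always_returns_value(self):
        d = ParameterDistribution("condition.rr_pandemic", "point", {"value": 1.37})
        rng = np.random.default_rng(0)
        assert all(sample_distribution(d, rng) == 1.37 for _ in range(10))

    def test_degenerate_uniform(self):
        d = ParameterDistribution("intervention.efficacy", "uniform", {"low": 0.3, "high": 0.3})
        assert sample_distribution(d, np.random.default_rng(0)) == 0.3

    def test_pert_stays_in_support(self):
        d = ParameterDistribution(
            "intervention.efficacy", "pert", {"low": 0.1, "mode": 0.25, "high": 0.4}
        )
        draws = sample_distribution(d, np.random.default_rng(0), size=2000)
        assert draws.min() >= 0.1 and draws.max() <= 0.4

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ParameterDistribution("condition.rr_pandemic", "triangular", {})

    def test_missing_params_rejected(self):
        with pytest.raises(ValueError, match="needs"):
            ParameterDistribution("condition.rr_pandemic", "uniform", {"low": 1.0})

    def test_bad_root_rejected(self):
        with pytest.raises(ValueError, match="rooted"):
            ParameterDistribution("schedule.year1", "point", {"value": 1.0})


class TestParameterPaths:
    def test_get_and_set_round_trip(self, depression):
        import copy

        sc = copy.deepcopy(depression)
        assert get_param(sc, "condition.rr_pandemic") == 1.37
        set_param(sc, "intervention.efficacy", 0.5)
        assert sc.intervention.efficacy == 0.5

    def test_setting_rr_outside_range_widens_range(self, depression):
        import copy

        sc = copy.deepcopy(depression)
        set_param(sc, "condition.rr_pandemic", 3.5)
        assert sc.condition.rr_range[1] == 3.5

    def test_unresolvable_path_raises(self, depression):
        with pytest.raises(AttributeError, match="nonsense"):
            get_param(depression, "condition.nonsense")

    def test_invalid_value_rejected_by_revalidation(self, depression):
        import copy

        sc = copy.deepcopy(depression)
        with pytest.raises(ValueError):
            set_param(sc, "intervention.efficacy", 1.5)


class TestRunPSA:
    def test_all_point_masses_equal_deterministic_run(self, depression):
        cfg = PSAConfig(
            distributions=[
                ParameterDistribution("condition.rr_pandemic", "point", {"value": 1.37}),
                ParameterDistribution("intervention.efficacy", "point",
                                      {"value": depression.intervention.efficacy}),
            ],
            n_draws=20,
            seed=5,
        )
        res = run_psa(depression, cfg)
        _, det = run_scenario(depression)
        s = res.summaries["qalys_gained_total"]
        assert s["lower"] == s["upper"] == det.qalys_gained_total
        assert s["mean"] == pytest.approx(det.qalys_gained_total, rel=1e-14)
        assert res.summaries["net_savings_lifetime"]["mean"] == pytest.approx(
            det.net_savings_by_horizon["lifetime"], rel=1e-14
        )

    def test_identical_seed_bit_identical_summaries(self, depression):
        cfg = PSAConfig(
            distributions=[
                ParameterDistribution(
                    "condition.rr_pandemic", "lognormal-from-95CI", {"low": 1.2, "high": 2.56}
                )
            ],
            n_draws=300,
            seed=42,
        )
        assert run_psa(depression, cfg).summaries == run_psa(depression, cfg).summaries

    def test_interval_ordering_and_mean_between_bounds(self, depression):
        cfg = PSAConfig(
            distributions=[
                ParameterDistribution(
                    "condition.rr_pandemic", "lognormal-from-95CI", {"low": 1.2, "high": 2.56}
                )
            ],
            n_draws=400,
            seed=3,
        )
        for s in run_psa(depression, cfg).summaries.values():
            assert s["lower"] <= s["mean"] <= s["upper"]

    def test_mean_of_linear_output_matches_distribution_mean(self, depression):
        """QALYs gained are linear in efficacy, so the PSA mean under a uniform
        efficacy must converge to the deterministic run at the midpoint."""
        import copy

        e = depression.intervention.efficacy
        cfg = PSAConfig(
            distributions=[
                ParameterDistribution(
                    "intervention.efficacy", "uniform", {"low": 0.8 * e, "high": 1.2 * e}
                )
            ],
            n_draws=4000,
            seed=11,
        )
        res = run_psa(depression, cfg)
        _, det = run_scenario(depression)
        assert res.summaries["qalys_gained_total"]["mean"] == pytest.approx(
            det.qalys_gained_total, rel=0.01
        )

    def test_depression_savings_reliably_positive(self, depression):
        """RR, efficacy and cost uncertainty: lifetime net savings keep their
        sign in at least 95% of draws."""
        e = depression.intervention.efficacy
        c = depression.intervention.cost_per_participant
        cfg = PSAConfig(
            distributions=[
                ParameterDistribution(
                    "condition.rr_pandemic", "lognormal-from-95CI", {"low": 1.2, "high": 2.56}
                ),
                ParameterDistribution(
                    "intervention.efficacy", "beta-from-95CI", {"low": 0.8 * e, "high": 1.2 * e}
                ),
                ParameterDistribution(
                    "intervention.cost_per_participant", "gamma-from-95CI",
                    {"low": 0.8 * c, "high": 1.2 * c},
                ),
            ],
            n_draws=1500,
            seed=7,
            keep_draws=True,
        )
        res = run_psa(depression, cfg)
        frac_positive = (res.draws["net_savings_lifetime"] > 0).mean()
        assert frac_positive >= 0.95
        assert (res.draws["qalys_gained_total"] > 0).all()

    def test_excessive_rejection_rate_errors(self, depression):
        # a prevalence distribution that nearly always makes total prevalence > 1
        cfg = PSAConfig(
            distributions=[
                ParameterDistribution(
                    "condition.baseline_prevalence", "uniform", {"low": 0.72, "high": 0.999}
                )
            ],
            n_draws=50,
            seed=0,
        )
        with pytest.raises(RuntimeError, match="rejection"):
            run_psa(depression, cfg)


class TestOneWayDSA:
    def test_base_case_value_reproduces_base_run(self, depression):
        _, det = run_scenario(depression)
        row = one_way_dsa(depression, "condition.rr_pandemic", [1.37]).iloc[0]
        assert row["qalys_gained_total"] == det.qalys_gained_total
        assert row["net_savings_lifetime"] == det.net_savings_by_horizon["lifetime"]

    def test_efficacy_sweep_monotone_in_qalys(self, depression):
        table = one_way_dsa(
            depression, "intervention.efficacy", list(np.linspace(0.0, 1.0, 11))
        )
        assert table["qalys_gained_total"].is_monotonic_increasing

    def test_homelessness_rr_quartered(self, bundled):
        """Quartering the homelessness relative risk must shrink QALYs gained
        and savings, flip the first-year net negative while a later horizon
        stays positive, and leave the strategy dominant."""
        table = one_way_dsa(
            bundled["homelessness"], "condition.rr_pandemic", [6.67, 1.67]
        )
        base, low = table.iloc[0], table.iloc[1]
        assert low["qalys_gained_total"] < base["qalys_gained_total"]
        # year1 excluded: the program cost shrinks with the eligible pool, so
        # the year-1 net cost shrinks in magnitude while staying negative
        for h in ("year3", "year10", "lifetime"):
            assert low[f"net_savings_{h}"] < base[f"net_savings_{h}"]
        assert low["net_savings_year1"] < 0
        assert low["net_savings_year3"] > 0
        assert low["ce_class"] == "dominant"

    def test_unresolvable_path_raises(self, depression):
        with pytest.raises(AttributeError):
            one_way_dsa(depression, "condition.bogus", [1.0])
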