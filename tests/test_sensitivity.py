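"""Distribution fitting, tornado analysis, PSA and acceptability curves."""

import numpy as np
import pytest

from fvcea.economics import run_cea
from fvcea.parameters import ParameterSet, ParameterValue
from fvcea.sensitivity import (
    DistributionFitError,
    ceac,
    default_wtp_grid,
    fit_beta_from_mean_ci,
    fit_gamma_cv20,
    fit_lognormal_rr,
    fit_parameter,
    one_way_dsa,
    run_psa,
    tornado,
)


class TestBetaFit:
    def test_progression_probability_fit(self):
        spec = fit_beta_from_mean_ci(0.06873, 0.0665, 0.0710)
        assert spec.family == "beta"
        assert spec.shape["alpha"] == pytest.approx(3338.2, rel=1e-3)
        assert spec.shape["beta"] == pytest.approx(45231.0, rel=1e-3)
        # method of moments reproduces the mean by construction
        a, b = spec.shape["alpha"], spec.shape["beta"]
        assert a / (a + b) == pytest.approx(0.06873, rel=1e-12)

    def test_gic_success_fit(self):
        spec = fit_beta_from_mean_ci(0.63, 0.49, 0.74)
        assert spec.shape["alpha"] == pytest.approx(35.48, rel=1e-3)
        assert spec.shape["beta"] == pytest.approx(20.83, rel=1e-3)

    def test_zero_width_collapses_to_point_mass(self):
        spec = fit_beta_from_mean_ci(0.5, 0.5, 0.5)
        assert spec.family == "fixed"
        assert spec.sample(np.random.default_rng(0)) == 0.5

    def test_excess_variance_rejected(self):
        with pytest.raises(DistributionFitError, match="variance"):
            fit_beta_from_mean_ci(0.01, 0.0, 0.9)

    def test_sampler_mean_recovers_target(self):
        spec = fit_beta_from_mean_ci(0.06873, 0.0665, 0.0710)
        draws = spec.sample(np.random.default_rng(1), 10_000)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.06873) < 3 * se


class TestGammaFit:
    @pytest.mark.parametrize("mean, scale", [(118.50, 4.74), (78.00, 3.12)])
    def test_cv20_closed_form(self, mean, scale):
        spec = fit_gamma_cv20(mean)
        assert spec.shape["shape"] == 25.0
        assert spec.shape["scale"] == pytest.approx(scale, rel=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(DistributionFitError):
            fit_gamma_cv20(0.0)

    def test_sampler_mean_recovers_target(self):
        spec = fit_gamma_cv20(118.50)
        draws = spec.sample(np.random.default_rng(2), 10_000)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 118.50) < 3 * se


class TestLognormalFit:
    def test_relative_risk_fit(self):
        spec = fit_lognormal_rr(0.88, 0.81, 0.95)
        assert spec.shape["mu"] == pytest.approx(-0.127833, abs=1e-6)
        assert spec.shape["sigma"] == pytest.approx(0.0406711, abs=1e-6)

    def test_zero_width_collapses(self):
        spec = fit_lognormal_rr(0.88, 0.88, 0.88)
        assert spec.family == "fixed"

    def test_nonpositive_bounds_rejected(self):
        with pytest.raises(DistributionFitError):
            fit_lognormal_rr(0.88, -0.1, 0.95)

    def test_sampled_median_near_point_estimate(self):
        spec = fit_lognormal_rr(0.88, 0.81, 0.95)
        draws = spec.sample(np.random.default_rng(3), 10_000)
        # median of a lognormal is exp(mu); MC error on the median is small
        assert np.median(draws) == pytest.approx(0.88, abs=0.005)
        assert draws.mean() == pytest.approx(np.exp(-0.127833 + 0.040670**2 / 2), abs=0.005)


class TestTornado:
    def test_effectiveness_has_widest_bar(self, params):
        """The varnish relative risk drives the ICER more than any other input."""
        for mode in ("ever_cavity_avoided", "daly"):
            entries = tornado(params, mode)
            assert entries[0].parameter_id == "eff_rr"
            assert entries[0].width > entries[1].width

    def test_one_bar_per_independent_parameter(self, params):
        from fvcea.parameters import FV_DERIVED_IDS

        entries = tornado(params, "ever_cavity_avoided")
        uncertain = [
            pid
            for pid in params.ids()
            if params.value(pid).distribution != "fixed"
            and pid not in FV_DERIVED_IDS
        ]
        assert sorted(e.parameter_id for e in entries) == sorted(uncertain)

    def test_derived_rows_varied_only_on_request(self, params):
        entries = tornado(
            params, "ever_cavity_avoided", varied_ids=["fv_p_nocav_cavity"]
        )
        assert [e.parameter_id for e in entries] == ["fv_p_nocav_cavity"]

    def test_degenerate_bounds_give_zero_width(self, params):
        collapsed = params.with_value("c_gic", params.c_gic)
        pv = collapsed.value("c_gic")
        entry = one_way_dsa(
            ParameterSet(
                [
                    v if v.id != "c_gic" else ParameterValue(
                        "c_gic", "cost", "both", pv.baseline, pv.baseline, pv.baseline,
                        "gamma", "",
                    )
                    for v in (collapsed.value(p) for p in collapsed.ids())
                ]
            ),
            "ever_cavity_avoided",
            "c_gic",
        )
        assert entry.width == 0.0

    def test_icer_increasing_in_fv_cost(self, params):
        """The varnish price enters only the incremental cost, positively."""
        entry = one_way_dsa(params, "ever_cavity_avoided", "c_fv")
        assert entry.increases_icer is True
        assert entry.icer_low < entry.icer_high

    def test_fv_rows_varied_at_printed_bounds(self, params):
        entry = one_way_dsa(params, "ever_cavity_avoided", "fv_p_nocav_cavity")
        low = run_cea(params, "ever_cavity_avoided",
                      overrides={"fv_p_nocav_cavity": 0.0586})
        assert entry.icer_low == pytest.approx(low.icer, rel=1e-12)


def _degenerate_params(params):
    """All uncertainty collapsed: low == high == baseline everywhere."""
    return ParameterSet(
        [
            ParameterValue(
                v.id, v.role, v.arm, v.baseline, v.baseline, v.baseline,
                v.distribution, v.note,
            )
            for v in (params.value(pid) for pid in params.ids())
        ]
    )


class TestPSA:
    def test_fixed_seed_reproducible_byte_exact(self, params):
        a = run_psa(params, n_iter=20, seed=11)
        b = run_psa(params, n_iter=20, seed=11)
        assert a.samples.to_csv(index=False) == b.samples.to_csv(index=False)

    def test_different_seeds_differ(self, params):
        a = run_psa(params, n_iter=5, seed=1)
        b = run_psa(params, n_iter=5, seed=2)
        assert not a.samples["d_cost"].equals(b.samples["d_cost"])

    def test_record_count_and_columns(self, params):
        s = run_psa(params, n_iter=15, seed=4, modes=("ever_cavity_avoided", "daly"))
        assert len(s.samples) == 15
        assert {"d_cost", "d_effect_ever_cavity_avoided", "d_effect_daly"} <= set(
            s.samples.columns
        )

    def test_degenerate_psa_equals_base_case(self, params):
        degenerate = _degenerate_params(params)
        s = run_psa(degenerate, n_iter=5, seed=9, modes=("ever_cavity_avoided",))
        base = run_cea(degenerate, "ever_cavity_avoided")
        assert (s.samples["d_cost"] == base.incr_cost).all()
        assert (s.samples["d_effect_ever_cavity_avoided"] == base.incr_effect).all()

    def test_sampled_rr_mean_matches_lognormal_moment(self, params):
        spec = fit_parameter(params.value("eff_rr"))
        draws = spec.sample(np.random.default_rng(5), 10_000)
        expected = np.exp(spec.shape["mu"] + spec.shape["sigma"] ** 2 / 2)
        assert expected == pytest.approx(0.88073, abs=1e-4)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * se


@pytest.fixture(scope="module")
def psa_samples(params):
    return run_psa(params, n_iter=200, seed=17)


class TestCEAC:

    def test_zero_wtp_zero_acceptance_when_costlier(self, psa_samples):
        assert (psa_samples.d_cost() > 0).all()
        curve = ceac(psa_samples, np.array([0.0]), "ever_cavity_avoided")
        assert curve.probability[0] == 0.0

    def test_monotone_when_all_effects_positive(self, params, psa_samples):
        assert (psa_samples.d_effect("ever_cavity_avoided") > 0).all()
        base = run_cea(params, "ever_cavity_avoided")
        curve = ceac(psa_samples, default_wtp_grid(base.icer), "ever_cavity_avoided")
        assert (np.diff(curve.probability) >= 0).all()

    def test_certain_acceptance_at_huge_wtp(self, psa_samples):
        curve = ceac(psa_samples, np.array([1e12]), "ever_cavity_avoided")
        assert curve.probability[0] == 1.0

    def test_crossing_near_deterministic_icer(self, params, psa_samples):
        base = run_cea(params, "ever_cavity_avoided")
        curve = ceac(
            psa_samples, default_wtp_grid(base.icer, 400), "ever_cavity_avoided"
        )
        assert curve.crossing() == pytest.approx(base.icer, rel=0.3)

    def test_empty_grid_rejected(self, psa_samples):
        with pytest.raises(ValueError, match="grid"):
            ceac(psa_samples, np.array([]))
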