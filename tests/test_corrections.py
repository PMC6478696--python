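"""Bonferroni, group-sequential calibration, and Wald SPRT."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq

from seqstop.corrections import (
    InterimDesign,
    SPRTConfig,
    bonferroni_alpha,
    calibrate_per_look_alpha,
    interim_test,
    overall_type1_rate,
    sprt_bounds,
    sprt_llr_increment,
    sprt_operating_characteristics,
    sprt_run,
)
from seqstop.simulate import fdr_curve
from .conftest import H0_CONFIG


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha, k, expected", [(0.05, 3, 0.0167), (0.05, 1, 0.05), (0.10, 4, 0.025)]
    )
    def test_values(self, alpha, k, expected):
        assert bonferroni_alpha(alpha, k) == pytest.approx(expected, abs=5e-5)

    def test_partition_identity(self):
        for k in (1, 2, 7):
            assert k * bonferroni_alpha(0.05, k) == pytest.approx(0.05, abs=1e-15)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestInterimTest:
    def test_alpha_one_rejects_first_look(self):
        rng = np.random.default_rng(0)
        design = InterimDesign((5, 10), 1.0)
        r = interim_test(rng.standard_normal(10), rng.standard_normal(10), design)
        assert r.rejected and r.look_index == 0 and r.look_n == 5

    def test_identical_groups_never_reject(self):
        x = np.arange(100, dtype=float)
        r = interim_test(x, x, InterimDesign((50, 100), 0.029))
        assert not r.rejected
        assert r.p_values == (1.0, 1.0)

    def test_data_beyond_rejecting_look_untouched(self):
        # strongly separated at look 1; garbage afterwards must not matter
        a = [0.0] * 5 + [math.nan] * 5
        b = [10.0, 11.0, 10.0, 11.0, 10.0] + [math.nan] * 5
        r = interim_test(a, b, InterimDesign((5, 10), 0.05))
        assert r.rejected and r.look_index == 0

    def test_short_data_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            interim_test([1.0] * 40, [1.0] * 40, InterimDesign((50,), 0.05))

    def test_design_validation(self):
        with pytest.raises(ValueError):
            InterimDesign((), 0.05)
        with pytest.raises(ValueError):
            InterimDesign((50, 50), 0.05)
        with pytest.raises(ValueError):
            InterimDesign((1, 10), 0.05)
        with pytest.raises(ValueError):
            InterimDesign((50,), 0.0)


class TestOverallType1Rate:
    def test_single_look_is_a_fixed_n_test(self):
        est = overall_type1_rate(InterimDesign((50,), 0.05), 50_000, seed=1)
        assert abs(est.rate - 0.05) < 3 * est.se

    def test_two_uncorrected_looks_inflate(self):
        est = overall_type1_rate(InterimDesign((50, 100), 0.05), 50_000, seed=2)
        assert est.rate > 0.05 + 3 * est.se

    def test_paper_design_hits_five_percent(self):
        """Looks 50/100 at level 0.029 give overall size 0.05."""
        est = overall_type1_rate(InterimDesign((50, 100), 0.029), 100_000, seed=3)
        assert est.rate == pytest.approx(0.05, abs=0.005)

    def test_monotone_in_per_look_alpha(self):
        """Common random numbers make the rate monotone — bisection's basis."""
        rates = [
            overall_type1_rate(InterimDesign((30, 60), a), 20_000, seed=4).rate
            for a in (0.01, 0.03, 0.09)
        ]
        assert rates[0] < rates[1] < rates[2]

    def test_consistent_with_sequential_simulator(self, h0_result):
        """Looks at every n from 2..25 reproduce the optional-stopping rate.

        Two independently coded simulators (per-replicate substreams vs
        chunked batch) must agree on the same familywise error.
        """
        seq = fdr_curve(h0_result, caps=[25])
        est = overall_type1_rate(
            InterimDesign(tuple(range(2, 26)), H0_CONFIG.alpha), 10_000, seed=5
        )
        gap_se = math.sqrt(seq.se[0] ** 2 + est.se**2)
        assert abs(seq.rates[0] - est.rate) < 3 * gap_se


def _pocock_two_look_oracle(n1, n2, overall):
    """Constant per-look level via the bivariate-normal z-approximation.

    The two z-statistics at looks n1 < n2 are jointly normal with
    correlation sqrt(n1/n2); solve for the critical value whose rectangle
    probability is 1 - overall.
    """
    rho = math.sqrt(n1 / n2)
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])

    def both_inside(z):
        return (
            mvn.cdf([z, z]) - mvn.cdf([z, -z]) - mvn.cdf([-z, z]) + mvn.cdf([-z, -z])
        )

    z = brentq(lambda c: both_inside(c) - (1.0 - overall), 1.0, 4.0, xtol=1e-10)
    return 2.0 * stats.norm.sf(z)


class TestCalibration:
    def test_single_look_returns_overall(self):
        a = calibrate_per_look_alpha([60], 0.05, reps=100_000, seed=6)
        assert a == pytest.approx(0.05, abs=0.003)

    def test_two_look_paper_value(self):
        a = calibrate_per_look_alpha([50, 100], 0.05, reps=100_000, seed=7)
        assert a == pytest.approx(0.029, abs=0.002)

    def test_matches_bivariate_normal_oracle(self):
        oracle = _pocock_two_look_oracle(50, 100, 0.05)
        assert oracle == pytest.approx(0.0294, abs=3e-4)
        a = calibrate_per_look_alpha([50, 100], 0.05, reps=100_000, seed=8)
        assert a == pytest.approx(oracle, abs=0.002)

    def test_deterministic_given_seed(self):
        a1 = calibrate_per_look_alpha([40, 80], 0.05, reps=20_000, seed=9)
        a2 = calibrate_per_look_alpha([40, 80], 0.05, reps=20_000, seed=9)
        assert a1 == a2

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            calibrate_per_look_alpha([50, 100], 1.5, reps=1000, seed=0)


class TestSPRTBounds:
    def test_closed_form(self):
        a, b = sprt_bounds(0.05, 0.05)
        assert b == pytest.approx(math.log(19.0), abs=1e-12)
        assert a == pytest.approx(-math.log(19.0), abs=1e-12)

    def test_symmetric_when_alpha_equals_beta(self):
        for e in (0.01, 0.1, 0.2):
            a, b = sprt_bounds(e, e)
            assert a == pytest.approx(-b, abs=1e-12)

    def test_upper_bound_grows_as_alpha_shrinks(self):
        uppers = [sprt_bounds(a, 0.1)[1] for a in (0.2, 0.1, 0.05, 0.01)]
        assert uppers == sorted(uppers)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            sprt_bounds(0.5, 0.05)
        with pytest.raises(ValueError):
            sprt_bounds(0.05, 0.0)


class TestSPRTIncrement:
    def test_midpoint_is_zero(self):
        cfg = SPRTConfig(theta0=-1.0, theta1=3.0, sigma=2.0)
        assert sprt_llr_increment(1.0, cfg) == 0.0

    def test_plug_in(self):
        cfg = SPRTConfig(theta0=0.0, theta1=1.0, sigma=1.0)
        assert sprt_llr_increment(1.0, cfg) == pytest.approx(0.5, abs=1e-15)

    def test_nonfinite_rejected(self):
        cfg = SPRTConfig(theta0=0.0, theta1=1.0)
        with pytest.raises(ValueError):
            sprt_llr_increment(math.nan, cfg)

    def test_density_evaluation_oracle(self):
        """Summed increments equal the exact log-likelihood ratio."""
        cfg = SPRTConfig(theta0=0.3, theta1=1.7, sigma=1.4)
        rng = np.random.default_rng(10)
        x = rng.normal(1.0, 1.4, size=200)
        total = sum(sprt_llr_increment(xi, cfg) for xi in x)
        exact = stats.norm.logpdf(x, 1.7, 1.4).sum() - stats.norm.logpdf(x, 0.3, 1.4).sum()
        assert total == pytest.approx(exact, abs=1e-10)


class TestSPRTRun:
    def test_midpoint_stream_never_decides(self):
        cfg = SPRTConfig(theta0=0.0, theta1=1.0, n_max=50)
        r = sprt_run([0.5] * 200, cfg)
        assert r.decision == "undecided_at_cap" and r.stop_n == 50
        assert np.all((r.llr_path > cfg.log_lower) & (r.llr_path < cfg.log_upper))

    def test_exhausted_stream_is_undecided(self):
        cfg = SPRTConfig(theta0=0.0, theta1=1.0)
        r = sprt_run([], cfg)
        assert r.decision == "undecided_at_cap" and r.stop_n == 0

    def test_decision_boundary_invariants(self):
        cfg = SPRTConfig(theta0=0.0, theta1=1.0, n_max=500)
        rng = np.random.default_rng(13)
        for mean in (0.0, 1.0):
            for _ in range(30):
                r = sprt_run(rng.normal(mean, 1.0, size=500), cfg)
                if r.decision == "reject_H0":
                    assert r.llr_path[-1] >= cfg.log_upper
                    assert np.all(r.llr_path[:-1] < cfg.log_upper)
                elif r.decision == "accept_H0":
                    assert r.llr_path[-1] <= cfg.log_lower

    def test_scalar_and_vectorized_paths_agree(self):
        cfg = SPRTConfig(theta0=0.0, theta1=1.0, n_max=300)
        reps, seed = 200, 14
        oc = sprt_operating_characteristics(cfg, reps, seed, truth="H0")
        rng = np.random.default_rng(seed)
        x = rng.normal(cfg.theta0, cfg.sigma, size=(reps, cfg.n_max))
        runs = [sprt_run(row, cfg) for row in x]
        assert np.mean([r.decision == "reject_H0" for r in runs]) == oc.reject_rate
        assert np.mean([r.stop_n for r in runs]) == pytest.approx(oc.mean_stop_n)


class TestSPRTOperatingCharacteristics:
    def test_error_control_both_hypotheses(self):
        """Wald's guarantee: empirical errors at most nominal (+3 MC se)."""
        cfg = SPRTConfig(theta0=0.0, theta1=1.0, alpha=0.05, beta=0.05, n_max=400)
        se = math.sqrt(0.05 * 0.95 / 10_000)
        h0 = sprt_operating_characteristics(cfg, 10_000, 15, truth="H0")
        assert h0.reject_rate <= 0.05 + 3 * se
        h1 = sprt_operating_characteristics(cfg, 10_000, 16, truth="H1")
        assert h1.accept_rate <= 0.05 + 3 * se

    def test_sample_efficiency_vs_fixed_design(self):
        """SPRT needs far fewer observations than a matched fixed-n test."""
        cfg = SPRTConfig(theta0=0.0, theta1=1.0, alpha=0.05, beta=0.05, n_max=400)
        h1 = sprt_operating_characteristics(cfg, 10_000, 17, truth="H1")
        # fixed one-sample z-test n for the same (alpha, beta) at d = 1;
        # any interim design needs at least this at its final look
        n_fixed = (stats.norm.isf(0.025) + stats.norm.isf(0.05)) ** 2
        assert h1.mean_stop_n < n_fixed

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SPRTConfig(theta0=1.0, theta1=1.0)
        with pytest.raises(ValueError):
            SPRTConfig(theta0=0.0, theta1=1.0, sigma=-1.0)
        with pytest.raises(ValueError):
            SPRTConfig(theta0=0.0, theta1=1.0, log_lower=1.0, log_upper=2.0)
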