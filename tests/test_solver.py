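import math

import numpy as np
import pytest

from radgrowth import (
    FractionalSpec,
    GrowthParameters,
    ModelSpec,
    RadiationParameters,
    TreatmentProtocol,
    compare_death_models,
    lq_survival_fraction,
    mittag_leffler,
    solve_caputo_abm,
    solve_impulsive,
    solve_treated,
)
from radgrowth.errors import DomainError, UnsupportedCombinationError
from radgrowth.solver import solve_impulsive_spec


def brute_force_abm(rhs, v0, mu, h, n_steps, corrector_iterations=1):
    """Independent direct evaluation of the discretized Volterra sums.

    Written from the published weight formulas with plain Python loops; no
    shared code with the solver under test.
    """
    t = [j * h for j in range(n_steps + 1)]
    v = [v0]
    f = [rhs(0.0, v0)]
    gm = math.gamma(mu)
    for n in range(n_steps):
        b = [(h**mu / mu) * ((n + 1 - j) ** mu - (n - j) ** mu) for j in range(n + 1)]
        pred = v0 + sum(bj * fj for bj, fj in zip(b, f)) / gm
        fp = rhs(t[n + 1], pred)
        vn1 = pred
        for _ in range(corrector_iterations):
            total = 0.0
            for j in range(n + 2):
                if j == 0:
                    w = (h**mu / (mu * (mu + 1))) * (n ** (mu + 1) - (n - mu) * (n + 1) ** mu)
                elif j <= n:
                    w = (h**mu / (mu * (mu + 1))) * (
                        (n - j + 2) ** (mu + 1) + (n - j) ** (mu + 1) - 2 * (n - j + 1) ** (mu + 1)
                    )
                else:
                    w = h**mu / (mu * (mu + 1))
                total += w * (f[j] if j <= n else fp)
            vn1 = v0 + total / gm
            fp = rhs(t[n + 1], vn1)
        v.append(vn1)
        f.append(fp)
    return np.array(v)


class TestCaputoABM:
    def test_zero_rhs_constant(self):
        for mu in (0.5, 0.8, 1.0):
            traj = solve_caputo_abm(lambda t, v: 0.0, 5.0, 1.0, FractionalSpec(mu=mu, h=0.1))
            np.testing.assert_allclose(traj.v, 5.0)

    def test_mu_one_matches_exponential(self):
        traj = solve_caputo_abm(
            lambda t, v: 0.0118 * v, 20.0, 10.0, FractionalSpec(mu=1.0, h=1 / 288)
        )
        assert traj.end_volume == pytest.approx(20.0 * math.exp(0.118), rel=1e-4)

    def test_fractional_matches_mittag_leffler(self):
        a, mu, t_end = 0.05, 0.8, 5.0
        traj = solve_caputo_abm(lambda t, v: a * v, 1.0, t_end, FractionalSpec(mu=mu, h=1 / 288))
        exact = mittag_leffler(mu, a * t_end**mu)
        assert traj.end_volume == pytest.approx(exact, rel=1e-3)

    @pytest.mark.parametrize("mu", [0.6, 0.9, 1.0])
    def test_matches_brute_force_volterra(self, mu):
        rhs = lambda t, v: 0.3 * v * (1 - v / 8.0)
        brute = brute_force_abm(rhs, 2.0, mu, 0.25, 10)
        traj = solve_caputo_abm(rhs, 2.0, 2.5, FractionalSpec(mu=mu, h=0.25))
        np.testing.assert_allclose(traj.v, brute, rtol=1e-13)

    def test_step_refinement_monotone(self):
        a, mu, t_end = 0.05, 0.8, 5.0
        exact = mittag_leffler(mu, a * t_end**mu)
        errs = []
        for h in (1 / 72, 1 / 144, 1 / 288, 1 / 576):
            traj = solve_caputo_abm(lambda t, v: a * v, 1.0, t_end, FractionalSpec(mu=mu, h=h))
            errs.append(abs(traj.end_volume - exact) / exact)
        assert all(e2 < e1 for e1, e2 in zip(errs, errs[1:]))
        # empirical order ~ min(2, 1+mu)
        order = math.log2(errs[1] / errs[3]) / 2
        assert order == pytest.approx(min(2.0, 1.0 + mu), abs=0.35)

    def test_smaller_mu_slower_early_growth(self):
        # ordering holds beyond the 1-day time unit (below it t^mu > t and
        # the fractional solutions transiently lead)
        specs = {mu: solve_caputo_abm(lambda t, v: 0.05 * v, 1.0, 5.0,
                                      FractionalSpec(mu=mu, h=1 / 96))
                 for mu in (0.6, 0.8, 1.0)}
        v_06, v_08, v_10 = (specs[m].end_volume for m in (0.6, 0.8, 1.0))
        assert v_06 < v_08 < v_10
        assert all(np.all(tr.v > 0) for tr in specs.values())

    def test_invalid_mu(self):
        with pytest.raises(DomainError):
            FractionalSpec(mu=1.2)
        with pytest.raises(DomainError):
            FractionalSpec(mu=0.0)

    def test_corrector_iterations_zero_is_predictor_only(self):
        rhs = lambda t, v: 0.1 * v
        t0 = solve_caputo_abm(rhs, 1.0, 1.0, FractionalSpec(mu=0.9, h=0.1), corrector_iterations=0)
        t1 = solve_caputo_abm(rhs, 1.0, 1.0, FractionalSpec(mu=0.9, h=0.1), corrector_iterations=1)
        assert t0.end_volume != t1.end_volume
        brute = brute_force_abm(rhs, 1.0, 0.9, 0.1, 10, corrector_iterations=0)
        np.testing.assert_allclose(t0.v, brute, rtol=1e-13)


class TestSolveTreated:
    def test_compiled_matches_generic(self, exp_spec, short_protocol):
        from radgrowth.models import treated_rhs

        g, r = exp_spec.growth, exp_spec.radiation
        rhs = lambda t, v: treated_rhs(g, r, short_protocol, t, max(v, 0.0))
        for mu in (1.0, 0.9):
            spec = ModelSpec(growth=g, radiation=r, mu=mu)
            fast = solve_treated(spec, short_protocol, 25.0, 5.0, h=1 / 96)
            slow = solve_caputo_abm(rhs, 25.0, 5.0, FractionalSpec(mu=mu, h=1 / 96))
            np.testing.assert_allclose(fast.v, slow.v, rtol=1e-10)

    def test_mu1_matches_continuous_closed_form(self, exp_spec):
        # linear treated ODE: v(T) = v0 exp(aT - n_windows*(1-SF)) once all
        # windows are complete
        proto = TreatmentProtocol(2.0, (1.0, 2.0), tw=1 / 96)
        sf = lq_survival_fraction(exp_spec.radiation, 2.0)
        traj = solve_treated(exp_spec, proto, 20.0, 4.0)
        exact = 20.0 * math.exp(0.0118 * 4.0 - 2 * (1 - sf))
        assert traj.end_volume == pytest.approx(exact, rel=1e-5)

    def test_limit_error_monotone_in_tw(self, exp_spec):
        # error against the impulsive closed form is monotone (non-
        # increasing within solver tolerance) as tw shrinks
        sf = lq_survival_fraction(exp_spec.radiation, 2.0)
        impulsive_exact = 20.0 * math.exp(0.0118 * 3.0) * sf
        errs = []
        for tw in (1 / 48, 1 / 96, 1 / 144, 1 / 288):
            proto = TreatmentProtocol(2.0, (1.0,), tw=tw)
            traj = solve_treated(exp_spec, proto, 20.0, 3.0)
            errs.append(abs(traj.end_volume - impulsive_exact))
        tol = 5e-4 * 20.0  # discretization allowance; deviation floor is O((1-SF)^2)
        assert all(e2 <= e1 + tol for e1, e2 in zip(errs, errs[1:]))


class TestMittagLeffler:
    def test_mu_one_is_exp(self):
        assert mittag_leffler(1.0, 1.0) == pytest.approx(math.e, rel=1e-12)

    def test_half_order_identity(self):
        from scipy.special import erfc

        assert mittag_leffler(0.5, 1.0) == pytest.approx(math.e * erfc(-1.0), rel=1e-10)
        assert mittag_leffler(0.5, -2.0) == pytest.approx(math.exp(4.0) * erfc(2.0), rel=1e-8)

    def test_zero_argument(self):
        for mu in (0.3, 0.7, 1.0):
            assert mittag_leffler(mu, 0.0) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            mittag_leffler(0.8, 25.0)
        with pytest.raises(DomainError):
            mittag_leffler(1.5, 1.0)


class TestImpulsive:
    def test_no_fractions_matches_growth(self, exp_growth, radiation, empty_protocol):
        traj = solve_impulsive(exp_growth, radiation, empty_protocol, 20.0, 10.0)
        assert traj.end_volume == pytest.approx(20.0 * math.exp(0.118), rel=1e-8)

    def test_single_fraction_closed_form(self, exp_growth, radiation):
        proto = TreatmentProtocol(2.0, (1.0,), tw=1 / 96)
        sf = lq_survival_fraction(radiation, 2.0)
        traj = solve_impulsive(exp_growth, radiation, proto, 20.0, 3.0)
        assert traj.end_volume == pytest.approx(20.0 * math.exp(0.0118 * 3) * sf, rel=1e-6)

    def test_zero_alpha_identical_to_untreated(self, exp_growth, full_protocol):
        r0 = RadiationParameters(alpha=0.0, beta=0.0)
        traj = solve_impulsive(exp_growth, r0, full_protocol, 20.0, 52.0)
        assert traj.end_volume == pytest.approx(20.0 * math.exp(0.0118 * 52), rel=1e-8)

    def test_records_pre_and_post_impulse(self, exp_growth, radiation):
        proto = TreatmentProtocol(2.0, (1.0,), tw=1 / 96)
        traj = solve_impulsive(exp_growth, radiation, proto, 20.0, 2.0)
        at_tau = traj.v[np.isclose(traj.t, 1.0)]
        assert at_tau.size == 2
        sf = lq_survival_fraction(radiation, 2.0)
        assert at_tau[1] / at_tau[0] == pytest.approx(sf, rel=1e-12)

    def test_fractional_rejected(self, exp_spec):
        frac = ModelSpec(growth=exp_spec.growth, radiation=exp_spec.radiation, mu=0.9)
        proto = TreatmentProtocol(2.0, (1.0,), tw=1 / 96)
        with pytest.raises(UnsupportedCombinationError):
            solve_impulsive_spec(frac, proto, 20.0, 3.0)


class TestCompareDeathModels:
    def test_zero_kill_deviation_tiny(self, exp_growth):
        r0 = RadiationParameters(alpha=0.0, beta=0.0)
        proto = TreatmentProtocol(2.0, (1.0,), tw=1 / 96)
        recs = compare_death_models(exp_growth, r0, proto, 20.0, 3.0, [1 / 48, 1 / 96])
        for rec in recs:
            assert rec["max_off_window_deviation"] < 1e-6

    def test_deviation_monotone_within_tolerance(self, exp_growth, radiation):
        proto = TreatmentProtocol(2.0, (1.0,), tw=1 / 96)
        recs = compare_death_models(
            exp_growth, radiation, proto, 20.0, 3.0, [1 / 48, 1 / 96, 1 / 144, 1 / 288]
        )
        devs = [rec["max_off_window_deviation"] for rec in recs]
        tol = 5e-4 * 20.0
        assert all(d2 <= d1 + tol for d1, d2 in zip(devs, devs[1:]))

    def test_unresolved_tw_rejected(self, exp_growth, radiation):
        proto = TreatmentProtocol(2.0, (1.0,), tw=1 / 100)
        with pytest.raises(DomainError):
            compare_death_models(exp_growth, radiation, proto, 20.0, 3.0, [1 / 100])


class TestTrajectory:
    def test_negative_state_flagged(self):
        traj = solve_caputo_abm(lambda t, v: -5.0, 1.0, 1.0, FractionalSpec(mu=1.0, h=0.05))
        assert traj.negative_state

    def test_interpolation_outside_span_rejected(self, exp_spec, empty_protocol):
        traj = solve_treated(exp_spec, empty_protocol, 20.0, 1.0)
        with pytest.raises(DomainError):
            traj.at([2.0])
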