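"""Well-mixed analysis: equilibrium, persistence, pendulum reduction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import rpworld as rp

rates = st.floats(0.005, 2.0, allow_nan=False, allow_infinity=False)


# ---------------------------------------------------------------------------
# persistence margin
# ---------------------------------------------------------------------------

class TestPersistenceMargin:
    def test_symmetric_boundary_is_zero(self):
        par = rp.PDEParams(aR=0.7, dR=0.3, dP=0.3, m=0.0, sigma_a=0.0,
                           aP0=0.7)
        assert rp.persistence_margin(par, aP=0.7) == pytest.approx(0.0)

    def test_survival_regime_well_mixed_agents(self):
        # kR = 1.0, kP = 0.6, equal decay, no miscopy: margin 0.4 > 0
        par = rp.PDEParams(aR=1.0, dR=0.1, dP=0.1, m=0.0)
        assert rp.persistence_margin(par, aP=0.6) == pytest.approx(0.4)

    def test_domain_errors(self):
        par = rp.PDEParams(dP=0.0)
        with pytest.raises(rp.ParameterError):
            rp.persistence_margin(par, aP=0.5)
        with pytest.raises(rp.ParameterError):
            rp.persistence_margin(rp.PDEParams(aR=0.0), aP=0.5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(aR=st.floats(0.2, 1.5), aP=st.floats(0.05, 1.0),
           dR=st.floats(0.05, 0.5), dP=st.floats(0.05, 0.5),
           m=st.floats(0.01, 0.6))
    def test_margin_sign_predicts_long_run_parasite_fate(
            self, aR, aP, dR, dP, m):
        """Sign of the closed-form margin agrees with the long-run fate
        of the integrated well-mixed system (interior coexistence vs
        replicase-side collapse of the parasite population)."""
        n0 = 0.2
        par = rp.PDEParams(aR=aR, aP0=min(aP, 1.0), dR=dR, dP=dP, m=m,
                           n0=n0, sigma_a=0.0)
        margin = rp.persistence_margin(par, aP=aP)
        if abs(margin) < 0.05:
            return  # boundary region: finite-horizon fate is ambiguous
        # keep the explicit integrator well inside its stability region
        stiffness = aR * (n0 / dR) ** 2 + n0 / dR
        dt = min(0.02, 0.2 / stiffness)
        horizon = 600.0 / min(dR, dP)
        if margin > 0:
            st_ = rp.steady_state(par, aP=aP)
            red = rp.pendulum_coefficients(par, aP=aP, p_fixed=st_.p)
            if red.yE >= 0.8 * red.yC:
                # equilibrium at/beyond the critical point: the margin
                # guarantees existence, not stability — no prediction
                return
            init = (st_.n, st_.r * 1.05, st_.p * 0.9)
            traj = rp.integrate_well_mixed(par, aP=aP, init=init,
                                           horizon=horizon, dt=dt)
            assert traj.p[-1] > 0.1 * st_.p
            assert traj.r[-1] > 0.1 * st_.r
        else:
            traj = rp.integrate_well_mixed(par, aP=aP, init=(1.0, 1.0, 1.0),
                                           horizon=horizon, dt=dt)
            # parasites cannot settle at a positive interior level
            # alongside replicases when the inequality fails
            if traj.r[-1] > 1e-6:
                assert traj.p[-1] < 1e-3 * max(traj.p.max(), 1e-30)


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

class TestSteadyState:
    def test_residuals_vanish(self, interior_params):
        state = rp.steady_state(interior_params)
        res = rp.steady_state_residuals(interior_params, state)
        assert max(abs(x) for x in res) < 1e-12

    def test_p_equals_A_times_r(self, interior_params):
        state = rp.steady_state(interior_params)
        assert state.p == pytest.approx(state.A * state.r, rel=1e-12)
        assert state.r > 0 and state.p > 0 and state.n > 0

    def test_m_one_is_ineffective_replication(self):
        par = rp.PDEParams(m=1.0, sigma_a=0.0)
        with pytest.raises(rp.IneffectiveReplicationError):
            rp.steady_state(par)

    def test_m_zero_degenerate_signal(self):
        # knife edge aR*dP == aP*dR: any proportion coexists
        par = rp.PDEParams(aR=1.0, dR=0.02, dP=0.01, m=0.0, sigma_a=0.0)
        with pytest.raises(rp.DegenerateCoexistenceError) as exc:
            rp.steady_state(par, aP=0.5)
        assert exc.value.coexistence_possible
        with pytest.raises(rp.DegenerateCoexistenceError) as exc:
            rp.steady_state(par, aP=0.7)
        assert not exc.value.coexistence_possible

    def test_margin_sign_coherent_with_existence(self):
        par = rp.PDEParams(aR=1.0, dR=0.05, dP=0.01, m=0.1, sigma_a=0.0)
        assert rp.persistence_margin(par, aP=0.5) < 0
        with pytest.raises(rp.NoSteadyStateError):
            rp.steady_state(par, aP=0.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(aR=rates, aP=st.floats(0.01, 1.0), dR=rates, dP=rates,
           m=st.floats(1e-4, 0.99), n0=st.floats(0.01, 5.0))
    def test_residual_property(self, aR, aP, dR, dP, m, n0):
        """Any admissible parameter set with positive margin yields an
        equilibrium whose balance-equation residuals vanish."""
        par = rp.PDEParams(aR=aR, aP0=min(aP, 1.0), dR=dR, dP=dP, m=m,
                           n0=n0, sigma_a=0.0)
        if rp.persistence_margin(par, aP=aP) <= 0:
            with pytest.raises(rp.NoSteadyStateError):
                rp.steady_state(par, aP=aP)
            return
        state = rp.steady_state(par, aP=aP)
        res = rp.steady_state_residuals(par, state, aP=aP)
        assert max(abs(x) for x in res) < 1e-10


# ---------------------------------------------------------------------------
# linear growth rate
# ---------------------------------------------------------------------------

class TestLinearGrowthRate:
    def test_zero_cases(self):
        par = rp.PDEParams(m=1.0, sigma_a=0.0)
        assert rp.linear_growth_rate(par, n=1.0, r=1.0) == 0.0
        assert rp.linear_growth_rate(rp.PDEParams(sigma_a=0.0),
                                     n=0.0, r=3.0) == 0.0

    def test_positive_at_interior_equilibrium(self, interior_params):
        state = rp.steady_state(interior_params)
        rate = rp.linear_growth_rate(interior_params, n=state.n, r=state.r)
        par = interior_params
        assert rate == pytest.approx((1 - par.m) * par.aR * state.n * state.r)
        assert rate > 0.0  # local instability of the linearization


# ---------------------------------------------------------------------------
# pendulum reduction
# ---------------------------------------------------------------------------

class TestPendulumCoefficients:
    def test_closed_forms_at_zero_parasites(self):
        par = rp.PDEParams(aR=1.0, dR=0.01, dP=0.01, m=0.0, n0=1.0,
                           sigma_a=0.0)
        red = rp.pendulum_coefficients(par, aP=0.5, p_fixed=0.0)
        assert red.yE == pytest.approx(0.01)
        assert red.yC == pytest.approx(np.sqrt(par.aR / par.dR))  # = 10

    def test_matches_numeric_root_finding(self):
        par = rp.PDEParams(aR=0.8, dR=0.07, dP=0.07, m=0.15, n0=1.3,
                           sigma_a=0.0, aP0=0.6)
        red = rp.pendulum_coefficients(par, aP=0.6, p_fixed=2.0)
        yE_num = brentq(lambda y: float(red.P(y)), 1e-6, 1e6)
        assert red.yE == pytest.approx(yE_num, rel=1e-9)
        yC_num = brentq(lambda y: float(red.Q(y)), red.yE * 1e-6, 1e9)
        assert red.yC == pytest.approx(yC_num, rel=1e-9)
        assert float(red.P(red.yE)) == pytest.approx(0.0, abs=1e-12)

    def test_force_sign_sweep(self):
        par = rp.PDEParams(aR=1.0, dR=0.1, dP=0.1, m=0.0, n0=0.05,
                           sigma_a=0.0, aP0=0.2)
        red = rp.pendulum_coefficients(par, aP=0.2, p_fixed=1.0)
        ys = np.linspace(red.yE * 0.05, red.yE * 20, 200)
        P = red.P(ys)
        assert np.all(P[ys < red.yE] > 0)
        assert np.all(P[ys > red.yE] < 0)

    def test_overcrowded_parasites_error(self):
        par = rp.PDEParams(aR=1.0, dR=0.1, dP=0.1, m=0.0, n0=1.0,
                           sigma_a=0.0)
        p_crit = par.n0 * par.aR / (par.dR * 0.5)
        with pytest.raises(rp.NoSteadyStateError):
            rp.pendulum_coefficients(par, aP=0.5, p_fixed=p_crit * 1.01)


class TestIntegratePendulum:
    par = rp.PDEParams(aR=1.0, dR=0.1, dP=0.1, m=0.0, n0=0.05,
                       sigma_a=0.0, aP0=0.2)

    def red(self):
        return rp.pendulum_coefficients(self.par, aP=0.2, p_fixed=1.0)

    def test_damped_oscillation_below_critical(self):
        """Below the critical point the system is a pendulum with
        friction: y oscillates around yE with decaying amplitude."""
        red = self.red()
        assert red.yE < red.yC
        tr = rp.integrate_pendulum(red, y0=red.yE * 0.9, v0=0.0,
                                   horizon=3000.0, dt=0.05)
        assert not tr.diverged
        crossings = np.sum(np.diff(np.sign(tr.y - red.yE)) != 0)
        assert crossings >= 6  # genuine oscillation, not creeping
        early = np.abs(tr.y[:len(tr.y) // 4] - red.yE).max()
        late = np.abs(tr.y[-200:] - red.yE).max()
        assert late < 1e-3 * early
        assert tr.y[-1] == pytest.approx(red.yE, rel=1e-6)

    def test_divergence_past_critical_point(self):
        """Past yC friction pumps energy in: with outward velocity the
        inverse density grows monotonically without bound (replicase
        collapse)."""
        red = self.red()
        tr = rp.integrate_pendulum(red, y0=red.yC * 1.5, v0=0.5,
                                   horizon=50000.0, dt=0.05)
        assert tr.diverged
        assert np.all(np.diff(tr.y) > 0)
        assert tr.y[-1] > 1e5 * red.yE

    def test_equivalence_with_clamped_well_mixed(self):
        """y(t) from the pendulum equation equals 1/r(t) of the full
        well-mixed integrator with the parasite density clamped."""
        red = self.red()
        y0, v0 = red.yE * 0.9, 0.0
        # v0 = dR*y0 - (1-m)*aR*n  fixes the consistent initial resource
        n_init = (self.par.dR * y0 - v0) / ((1 - self.par.m) * self.par.aR)
        tr = rp.integrate_pendulum(red, y0=y0, v0=v0, horizon=2000.0, dt=0.05)
        wm = rp.integrate_well_mixed(self.par, aP=0.2,
                                     init=(n_init, 1.0 / y0, red.p_fixed),
                                     horizon=2000.0, dt=0.05, clamp_p=True)
        rel = np.abs(1.0 / wm.r - tr.y) / np.abs(tr.y)
        assert rel.max() < 1e-3

    def test_y0_must_be_positive(self):
        with pytest.raises(rp.ParameterError):
            rp.integrate_pendulum(self.red(), y0=-1.0)


# ---------------------------------------------------------------------------
# well-mixed integration
# ---------------------------------------------------------------------------

class TestIntegrateWellMixed:
    def test_fixed_point_is_stationary(self, gentle_params):
        state = rp.steady_state(gentle_params)
        traj = rp.integrate_well_mixed(
            gentle_params, init=(state.n, state.r, state.p),
            horizon=200.0, dt=0.1)
        for series, ref in ((traj.n, state.n), (traj.r, state.r),
                            (traj.p, state.p)):
            assert np.abs(series - ref).max() / ref < 1e-9

    def test_perturbation_damps_back(self, gentle_params):
        """A small replicase perturbation of a persistent equilibrium
        produces an oscillation of 1/r that damps away."""
        state = rp.steady_state(gentle_params)
        traj = rp.integrate_well_mixed(
            gentle_params, init=(state.n, state.r * 1.02, state.p),
            horizon=6000.0, dt=0.1)
        y = 1.0 / traj.r
        yE = 1.0 / state.r
        half = len(y) // 2
        assert np.abs(y[half:] - yE).max() < 0.5 * np.abs(y[:half] - yE).max()
        assert traj.r[-1] == pytest.approx(state.r, rel=1e-2)

    def test_negative_margin_drives_replicase_collapse(self):
        """With the persistence inequality violated the parasites grow
        transiently, overconsume, and the replicase density collapses."""
        par = rp.PDEParams(aR=1.0, dR=0.05, dP=0.01, m=0.1, n0=1.0,
                           sigma_a=0.0)
        assert rp.persistence_margin(par, aP=0.8) < 0
        traj = rp.integrate_well_mixed(par, aP=0.8, init=(1.0, 1.0, 1.0),
                                       horizon=20000.0, dt=0.05)
        assert traj.r[-1] < 1e-6
        assert traj.p.max() > traj.p[0]      # transient parasite growth
        assert traj.p[-1] < 1e-2 * traj.p.max()   # then decay

    def test_nonnegativity_preserved(self):
        par = rp.PDEParams(aR=1.0, dR=1.0, dP=1.0, m=0.5, n0=0.0,
                           sigma_a=0.0)
        traj = rp.integrate_well_mixed(par, init=(0.5, 2.0, 1.0),
                                       horizon=100.0, dt=0.1)
        assert (traj.n >= 0).all() and (traj.r >= 0).all() \
            and (traj.p >= 0).all()
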