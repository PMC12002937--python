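"""Bone-formation ODEs: RHS algebra, conservation, analytic limits, lag."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import magbone as mb
from magbone.remodelling import compute_lag, hill_gate, remodelling_rhs


def _params(**kw):
    base = dict(k1=0.3880, v1=0.0164, r1=0.4915, r2=23.1846, k3=0.5744, m2=0.0)
    base.update(kw)
    return mb.RemodellingParams(**base)


class TestRHS:
    def test_initial_state_ti(self):
        # at (1, 0, 1, 0, 0) with m2 = 0: no mineral flux yet, nucleators appear
        p = _params()
        dx1, dx2, dI, dN, dH = remodelling_rhs([1, 0, 1, 0, 0], 0.0, p)
        assert dH == 0.0
        assert dN == pytest.approx(p.k2 * p.k1)
        assert dx1 == -dx2 == pytest.approx(-p.k1)

    def test_decayed_matrix_limit_flux_removal(self, deg_mg10):
        # with x1 = 0 under flux-coupled removal, only the Mg source remains
        p = _params(m2=84.0455, inhibitor_removal="maturation_flux")
        vr = lambda t: mb.volume_loss_rate(deg_mg10, t)
        d = remodelling_rhs([0, 1, 0.5, 0.2, 0.1], 5.0, p, vr)
        assert d[0] == d[1] == 0.0
        assert d[2] == pytest.approx(p.m2 * vr(5.0))

    def test_hill_gate_value_and_bounds(self):
        assert hill_gate(1.0) == pytest.approx(1 / 1001)
        assert hill_gate(0.0) == 1.0
        for I in np.linspace(0, 20, 50):
            assert 0 < hill_gate(I) <= 1

    def test_nonfinite_state_rejected(self):
        with pytest.raises(ValueError):
            remodelling_rhs([np.nan, 0, 1, 0, 0], 0.0, _params())

    def test_fixed_constants_defaults(self):
        p = _params()
        assert (p.k2, p.a, p.b) == (1.0, 10.0, 0.001)


class TestSimulation:
    def test_zero_growth_keeps_mineral_constant(self, grid230):
        # k3 ~ 0 and m2 = 0: H can never leave its initial value
        p = _params(k3=1e-12)
        traj = mb.simulate_remodelling(p, None, grid230, H0=0.3)
        assert np.allclose(traj.data["H"], 0.3, atol=1e-9)

    def test_matrix_conservation_and_analytic_decay(self, ti_trajectory, grid230):
        df = ti_trajectory.data
        assert np.max(np.abs(df.x1 + df.x2 - 1)) < 1e-8
        x1_exact = np.exp(-0.3880 * grid230)
        assert np.max(np.abs(df.x1 - x1_exact)) < 1e-6 * np.max(x1_exact)
        assert np.allclose(df.x2, 1 - x1_exact, atol=1e-6)

    def test_ti_mineral_monotone_sigmoid(self, ti_trajectory):
        H = ti_trajectory.data["H"].to_numpy()
        assert np.all(np.diff(H) >= -1e-10)
        dH = np.gradient(H, ti_trajectory.times)
        i = np.argmax(dH)
        assert 0 < i < len(H) - 1  # interior inflection: sigmoid-like

    def test_mg_mineralization_delayed_relative_to_ti(self, truth, grid230, deg_mg10):
        ti = mb.simulate_remodelling(truth["Ti"].rem, None, grid230)
        mg = mb.simulate_remodelling(truth["Mg-10Gd"].rem, deg_mg10, grid230)
        lag_ti = compute_lag(grid230, ti.data["H"].to_numpy())
        lag_mg = compute_lag(grid230, mg.data["H"].to_numpy())
        assert lag_mg > lag_ti

    @settings(deadline=None, max_examples=25)
    @given(
        k1=st.floats(0.05, 5.0),
        v1=st.floats(0.001, 2.0),
        r1=st.floats(0.02, 10.0),
        r2=st.floats(1.0, 100.0),
        k3=st.floats(0.1, 10.0),
        m2=st.floats(0.0, 150.0),
    )
    def test_invariants_across_parameter_space(self, k1, v1, r1, r2, k3, m2):
        """Conservation, nonnegativity and H monotonicity hold everywhere."""
        p = mb.RemodellingParams(k1=k1, v1=v1, r1=r1, r2=r2, k3=k3, m2=m2)
        deg = mb.DegradationParams("surface_rate", r_prime=0.062, d_prime=0.068) if m2 else None
        grid = np.linspace(0, 230, 47)
        traj = mb.simulate_remodelling(p, deg, grid)
        df = traj.data
        assert np.max(np.abs(df.x1 + df.x2 - 1)) < 1e-8
        assert (df[["x1", "x2", "I", "N"]].to_numpy() > -1e-8).all()
        assert np.all(np.diff(df.H) >= -1e-8)

    def test_stronger_inhibition_never_speeds_mineralization(self, deg_mg10, grid230):
        # raising m2 with everything else fixed cannot increase H(t)
        prev = None
        for m2 in (0.0, 20.0, 84.0455, 150.0):
            p = _params(k3=6.9291, m2=m2)
            H = mb.simulate_remodelling(p, deg_mg10, grid230).data["H"].to_numpy()
            if prev is not None:
                assert np.all(H <= prev + 1e-8)
            prev = H


class TestLag:
    def test_flat_trajectory_is_an_error(self):
        t = np.linspace(0, 10, 50)
        with pytest.raises(ValueError):
            compute_lag(t, np.full_like(t, 3.0))

    def test_logistic_oracle(self):
        # H = 1/(1+exp(-(t-10))): slope 1/4 at t = 10 -> lag = 10 - 0.5/0.25
        t = np.linspace(0, 30, 3001)
        h = 1 / (1 + np.exp(-(t - 10)))
        assert compute_lag(t, h) == pytest.approx(8.0, abs=0.05)

    def test_ti_lag_order_of_magnitude(self, truth):
        grid = np.linspace(0, 230, 2301)
        traj = mb.simulate_remodelling(truth["Ti"].rem, None, grid)
        lag = compute_lag(grid, traj.data["H"].to_numpy())
        assert 1.0 < lag < 15.0
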