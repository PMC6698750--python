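"""ODE engine: closed forms, steady states, cross-checks, dose-response shape."""

import numpy as np
import pytest

from litersim import (
    LightProgram,
    RateParams,
    build_circuit,
    dose_response_curve,
    integrate,
    solve_steady_state,
)
from litersim.network import CircuitSpec, make_reaction
from litersim.params import RateParams as RP

from conftest import birth_death_spec


def test_birth_death_matches_closed_form():
    """x(t) = (a/d)(1 - e^{-dt}) for zeroth-order birth, first-order death."""
    spec = birth_death_spec(a=10.0, d=1.0)
    prog = LightProgram.constant(0.0, total_duration=10.0)
    traj = integrate(spec, prog, t_end=5.0, n_points=26)
    expected = 10.0 * (1.0 - np.exp(-traj["time"]))
    assert np.allclose(traj["X"], expected, atol=1e-6)
    assert traj["X"].iloc[-1] == pytest.approx(10.0 * (1 - np.exp(-5.0)), abs=1e-6)


def test_birth_death_steady_state_exact():
    ss = solve_steady_state(birth_death_spec(a=10.0, d=1.0), 0.0)
    assert ss["X"] == pytest.approx(10.0, rel=1e-9)
    assert ss.converged


def test_zero_synthesis_zero_trajectory(params):
    p = params.replace(a_G=0.0, a_T=0.0, l_G=0.0, l_T=0.0)
    spec = build_circuit("liter1", "tip", p)
    traj = integrate(spec, LightProgram.constant(1000.0, 24.0), t_end=24.0)
    for sp in ("mG", "mT", "Td", "Tl", "G"):
        assert np.allclose(traj[sp], 0.0, atol=1e-12)


def test_integrate_converges_to_steady_state(liter1_tip):
    """Long-horizon integration endpoint agrees with the root solver."""
    ss = solve_steady_state(liter1_tip, 0.0)
    traj = integrate(liter1_tip, LightProgram.constant(0.0, 400.0), t_end=400.0, n_points=3)
    rel = abs(traj["G"].iloc[-1] - ss["G"]) / ss["G"]
    assert rel < 1e-6


def _fixed_point_oracle(p: RP, tol=1e-12):
    """Independent basal (u=0) solution of the TIP liter1 equations.

    Sequential two-site occupancy in quasi-equilibrium at free TetR level T:
    state weights (1, 2r, r^2) with r = k_on*T/k_off, so the unrepressed
    fraction is P0 = 1/(1+r)^2.  Self-consistency: T = b_T*m_T/d_p with
    m_T = (a_T*P0 + l_T*(1-P0))/d_m, and the reporter follows the same form.
    """
    T = 0.0
    for _ in range(100_000):
        r = p.k_on * T / p.k_off
        P0 = 1.0 / (1.0 + r) ** 2
        m_T = (p.a_T * P0 + p.l_T * (1 - P0)) / p.d_m
        T_new = p.b_T * m_T / p.d_p
        if abs(T_new - T) < tol:
            T = T_new
            break
        T = 0.5 * T + 0.5 * T_new
    r = p.k_on * T / p.k_off
    P0 = 1.0 / (1.0 + r) ** 2
    m_G = (p.a_G * P0 + p.l_G * (1 - P0)) / p.d_m
    return p.b_G * m_G / p.d_p


@pytest.mark.parametrize("p", [
    RP(),
    RP(a_T=100.0, l_T=2.0),          # tx_50-style asymmetry
    RP(b_T=5.0),                     # tl_50-style asymmetry
], ids=["equal", "tx50", "tl50"])
def test_liter1_basal_matches_fixed_point_oracle(p):
    spec = build_circuit("liter1", "tip", p)
    ss = solve_steady_state(spec, 0.0)
    assert ss["G"] == pytest.approx(_fixed_point_oracle(p), rel=1e-7)


def test_liter1_liter2_equal_basal(liter1_tip, liter2_tip):
    g1 = solve_steady_state(liter1_tip, 0.0)["G"]
    g2 = solve_steady_state(liter2_tip, 0.0)["G"]
    assert abs(g1 - g2) / g2 < 1e-8


def test_occupancy_conserved_along_trajectory(liter1_tip):
    prog = LightProgram.duty_cycle(1000.0, 0.25, total_duration=12.0)
    traj = integrate(liter1_tip, prog, t_end=12.0, n_points=49)
    for group, total in liter1_tip.conservations:
        sums = traj[list(group)].sum(axis=1)
        assert np.allclose(sums, total, atol=1e-7)


def test_steady_state_nonnegative_with_converged_flag(liter2_tip):
    ss = solve_steady_state(liter2_tip, 750.0)
    assert (ss.state >= 0).all()
    assert ss.converged and ss.residual < 1e-9


class TestDoseResponse:
    def test_single_dose_equals_steady_state(self, liter2_tip):
        df = dose_response_curve(liter2_tip, [0.0], mode="steady_state")
        assert len(df) == 1
        assert df["gfp"].iloc[0] == pytest.approx(solve_steady_state(liter2_tip, 0.0)["G"])

    def test_unsorted_grid_rejected(self, liter2_tip):
        with pytest.raises(ValueError):
            dose_response_curve(liter2_tip, [100.0, 0.0])
        with pytest.raises(ValueError):
            dose_response_curve(liter2_tip, [])

    @pytest.mark.parametrize("variant", ["tip", "degron"])
    def test_monotone_nondecreasing_in_intensity(self, variant, params):
        spec = build_circuit("liter2", variant, params)
        df = dose_response_curve(spec, [0, 50, 150, 400, 1000, 2500, 4095])
        assert (np.diff(df["gfp"]) >= -1e-9).all()

    def test_raising_k_rev_shifts_half_max_right(self, params):
        """Faster LOV2 dark reversion needs more light for the same induction."""
        def half_max_dose(p):
            spec = build_circuit("liter1", "tip", p)
            df = dose_response_curve(spec, list(np.linspace(0, 4095, 40)))
            y = df["gfp"].to_numpy()
            return np.interp(y[0] + 0.5 * (y[-1] - y[0]), y, df["dose"].to_numpy())

        assert half_max_dose(params.replace(k_rev=8.0)) > half_max_dose(params)

    def test_basal_positive_when_leaky(self, params):
        spec = build_circuit("liter2", "tip", params)
        assert solve_steady_state(spec, 0.0)["G"] > 0

    def test_basal_increases_with_leak(self, params):
        """Reducing transcriptional leak reduces dark-state expression."""
        basal = [
            solve_steady_state(build_circuit("liter2", "tip",
                               params.replace(l_G=l, l_T=l)), 0.0)["G"]
            for l in (0.0, 2.0, 4.0)
        ]
        assert basal[0] < basal[1] < basal[2]


def test_integration_error_reports_diagnostics():
    """Unbounded autocatalysis must fail loudly, not silently overflow."""
    from litersim.deterministic import IntegrationError

    spec = CircuitSpec(
        architecture="open_loop", variant="none", params=RateParams(),
        species=("X",), initial=(("X", 1),),
        reactions=(make_reaction("boom", {"X": 1}, {"X": 2}, 50.0),),
        reporter="X",
    )
    with pytest.raises((IntegrationError, OverflowError)):
        integrate(spec, LightProgram.constant(0.0, 2000.0), t_end=2000.0)
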