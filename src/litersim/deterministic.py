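"""Deterministic (mass-action ODE) engine.

The rate equations are dx/dt = S^T a(x, u) with the same propensities the
stochastic engine samples, interpreted as continuous rates.  Light programs
are piecewise constant, so integration proceeds segment by segment with the
light factor folded into per-segment effective rate constants; switch points
are hit exactly rather than discovered by the step controller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .light import DEFAULT_T_END, LightProgram
from .network import CircuitSpec, CompiledNetwork

RTOL = 1e-8
ATOL = 1e-10


class IntegrationError(RuntimeError):
    pass


_STATE_CAP = 1e12  # copy numbers beyond this indicate a runaway network


def _rhs(net: CompiledNetwork, c_eff: np.ndarray):
    stoich_T = net.stoich.T.astype(float)

    def f(t, x):
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > _STATE_CAP:
            raise IntegrationError(
                f"non-finite or runaway state at t={t:g} h (|x|max={np.max(np.abs(x)):.3g})"
            )
        return stoich_T @ net.propensities(np.maximum(x, 0.0), c_eff)

    return f


def _initial_vector(spec: CircuitSpec, net: CompiledNetwork, initial) -> np.ndarray:
    if initial is None:
        return net.initial.copy()
    if isinstance(initial, dict):
        idx = spec.species_index()
        x0 = np.zeros(len(spec.species))
        for sp, v in initial.items():
            x0[idx[sp]] = v
        return x0
    x0 = np.asarray(initial, dtype=float)
    if x0.shape != (len(spec.species),):
        raise ValueError(f"initial state must have {len(spec.species)} entries")
    return x0.copy()


def integrate(
    spec: CircuitSpec,
    program: LightProgram,
    t_end: float | None = None,
    initial=None,
    n_points: int = 201,
) -> pd.DataFrame:
    """Integrate the rate equations under a light program.

    Returns a DataFrame with a ``time`` column (hours) and one column per
    species.  ``initial`` may be a species->value dict, a vector in species
    order, or None for the circuit's default initial state.
    """
    if t_end is None:
        t_end = min(program.total_duration, DEFAULT_T_END.get(spec.architecture, 72.0))
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    net = spec.compile()
    x = _initial_vector(spec, net, initial)
    grid = np.linspace(0.0, t_end, n_points)
    out_t, out_x = [0.0], [x.copy()]
    for t0, t1, u in program.segments(t_end):
        c_eff = net.effective_rates(u)
        t_eval = grid[(grid > t0) & (grid <= t1)]
        sol = solve_ivp(
            _rhs(net, c_eff), (t0, t1), x, method="LSODA",
            rtol=RTOL, atol=ATOL,
            t_eval=np.unique(np.concatenate([t_eval, [t1]])),
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise IntegrationError(
                f"ODE integration failed on [{t0:g}, {t1:g}] h (u={u:g}): {sol.message}"
            )
        for k, tk in enumerate(sol.t):
            if tk in t_eval:
                out_t.append(float(tk))
                out_x.append(sol.y[:, k])
        x = sol.y[:, -1]
    df = pd.DataFrame(np.vstack(out_x), columns=list(spec.species))
    df.insert(0, "time", out_t)
    return df


@dataclass(frozen=True)
class SteadyState:
    """Steady-state solution of the rate equations at constant light."""

    state: pd.Series          # species -> copy number
    residual: float           # max-norm of dx/dt at the solution
    converged: bool

    def __getitem__(self, species: str) -> float:
        return float(self.state[species])


def solve_steady_state(
    spec: CircuitSpec,
    u_const: float = 0.0,
    t_relax: float = 500.0,
    tol: float = 1e-9,
) -> SteadyState:
    """Solve dx/dt = 0 at constant light intensity ``u_const``.

    A long relaxation integration from the circuit's initial state selects
    the biologically reached fixed point; a bounded least-squares root
    refinement (rate equations plus the promoter conservation constraints)
    then polishes it.  Non-convergence is flagged, with the residual reported.
    """
    net = spec.compile()
    c_eff = net.effective_rates(u_const)
    rhs = _rhs(net, c_eff)
    sol = solve_ivp(rhs, (0.0, t_relax), net.initial.copy(), method="LSODA",
                    rtol=RTOL, atol=ATOL)
    if not sol.success:
        raise IntegrationError(f"relaxation integration failed: {sol.message}")
    x = np.maximum(sol.y[:, -1], 0.0)

    C, totals = spec.conservation_matrix()

    def residuals(z):
        r = rhs(0.0, z)
        if len(totals):
            r = np.concatenate([r, C @ z - totals])
        return r

    res = least_squares(residuals, x, bounds=(0.0, np.inf), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    x_star = res.x
    resid = float(np.max(np.abs(rhs(0.0, x_star))))
    converged = resid < tol
    state = pd.Series(x_star, index=list(spec.species))
    return SteadyState(state=state, residual=resid, converged=converged)


def dose_response_curve(
    spec: CircuitSpec,
    u_grid,
    terminal_time: float | None = None,
    mode: str = "terminal",
    program_kind: str = "constant",
    **program_kwargs,
) -> pd.DataFrame:
    """Mean reporter output across a grid of constant-light doses.

    Parameters
    ----------
    u_grid
        Nonempty, sorted grayscale intensities.
    terminal_time
        Hours at which the reporter is read in ``terminal`` mode; defaults to
        the architecture's experimental terminal time (72 h LITers, 24 h
        open loop).
    mode : {"terminal", "steady_state"}
        ``terminal`` mirrors the experimental protocol (value at the terminal
        time point); ``steady_state`` solves dx/dt = 0 instead.

    Returns
    -------
    DataFrame with columns ``dose``, ``gfp`` and ``converged``.  Solver
    failures at individual doses are flagged rather than fatal.
    """
    u_grid = list(u_grid)
    if not u_grid:
        raise ValueError("u_grid must be nonempty")
    if sorted(u_grid) != u_grid:
        raise ValueError("u_grid must be sorted ascending")
    if terminal_time is None:
        terminal_time = DEFAULT_T_END.get(spec.architecture, 72.0)
    rows = []
    for u in u_grid:
        try:
            if mode == "steady_state":
                ss = solve_steady_state(spec, u)
                rows.append((u, ss[spec.reporter], ss.converged))
            elif mode == "terminal":
                prog = LightProgram.constant(u, total_duration=terminal_time)
                traj = integrate(spec, prog, t_end=terminal_time, n_points=2)
                rows.append((u, float(traj[spec.reporter].iloc[-1]), True))
            else:
                raise ValueError(f"unknown mode {mode!r}")
        except IntegrationError:
            rows.append((u, np.nan, False))
    return pd.DataFrame(rows, columns=["dose", "gfp", "converged"])
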