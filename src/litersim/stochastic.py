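"""Exact stochastic simulation (Gillespie direct method) and ensemble statistics.

Light programs are piecewise constant, so the jump process has piecewise-
constant propensities: within each light segment the direct method applies
unchanged, and each exponential waiting time is capped at the next light
switch, where propensities are recomputed and the clock re-drawn (memoryless,
hence statistically exact).

Ensembles derive one child seed per run from a master seed via
``numpy.random.SeedSequence``, so results are reproducible and independent
of the order in which runs execute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .light import DEFAULT_T_END, LightProgram
from .network import CircuitSpec


class SimulationError(RuntimeError):
    pass


@njit(cache=True)
def _ssa_core(x, stoich, ridx, c_segs, seg_ends, seed, record, max_events):
    """Direct-method SSA over consecutive constant-light segments.

    Returns (n_recorded, times, states, terminal_state).  When ``record`` is
    false only the terminal state is meaningful.
    """
    np.random.seed(seed)
    n_rx = stoich.shape[0]
    n_sp = stoich.shape[1]
    a = np.empty(n_rx)
    cap = max_events if record else 1
    times = np.empty(cap)
    states = np.empty((cap, n_sp), dtype=np.int64)
    n_rec = 0
    t = 0.0
    for s in range(len(seg_ends)):
        t_stop = seg_ends[s]
        c = c_segs[s]
        while True:
            a_tot = 0.0
            for j in range(n_rx):
                aj = c[j]
                i0 = ridx[j, 0]
                if i0 >= 0:
                    aj *= x[i0]
                i1 = ridx[j, 1]
                if i1 >= 0:
                    aj *= x[i1]
                a[j] = aj
                a_tot += aj
            if not np.isfinite(a_tot):
                return -1, times, states, x
            if a_tot <= 0.0:
                t = t_stop
                break
            tau = -np.log(np.random.random()) / a_tot
            if t + tau >= t_stop:
                t = t_stop
                break
            t += tau
            r = np.random.random() * a_tot
            acc = 0.0
            mu = n_rx - 1
            for j in range(n_rx):
                acc += a[j]
                if r < acc:
                    mu = j
                    break
            for i in range(n_sp):
                x[i] += stoich[mu, i]
            if record:
                if n_rec >= max_events:
                    return -2, times, states, x
                times[n_rec] = t
                for i in range(n_sp):
                    states[n_rec, i] = x[i]
                n_rec += 1
    return n_rec, times, states, x


def _segment_arrays(spec: CircuitSpec, program: LightProgram, t_end: float):
    net = spec.compile()
    segs = program.segments(t_end)
    c_segs = np.stack([net.effective_rates(u) for _, _, u in segs])
    seg_ends = np.array([t1 for _, t1, _ in segs])
    return net, c_segs, seg_ends


def _int_initial(spec: CircuitSpec, initial) -> np.ndarray:
    if initial is None:
        x0 = spec.compile().initial
    elif isinstance(initial, dict):
        idx = spec.species_index()
        x0 = np.zeros(len(spec.species))
        for sp, v in initial.items():
            x0[idx[sp]] = v
    else:
        x0 = np.asarray(initial, dtype=float)
    if not np.all(x0 == np.round(x0)):
        raise SimulationError("stochastic initial state must be integer copy numbers")
    return x0.astype(np.int64)


def ssa_trajectory(
    spec: CircuitSpec,
    program: LightProgram,
    t_end: float | None = None,
    seed: int = 0,
    initial=None,
    max_events: int = 5_000_000,
) -> pd.DataFrame:
    """One statistically exact sample path; every reaction event is recorded.

    Returns a DataFrame with ``time`` and one integer column per species,
    starting with the initial state at t = 0 and ending with the terminal
    state at ``t_end``.
    """
    if t_end is None:
        t_end = min(program.total_duration, DEFAULT_T_END.get(spec.architecture, 72.0))
    net, c_segs, seg_ends = _segment_arrays(spec, program, t_end)
    x0 = _int_initial(spec, initial)
    child = np.random.SeedSequence(seed).generate_state(1)[0] >> 1  # numba seed < 2^31
    n, times, states, x_T = _ssa_core(
        x0.copy(), net.stoich, net.reactant_idx, c_segs, seg_ends,
        np.int64(child), True, max_events,
    )
    if n == -1:
        raise SimulationError("non-finite total propensity encountered")
    if n == -2:
        raise SimulationError(f"trajectory exceeded max_events={max_events}")
    t_all = np.concatenate([[0.0], times[:n], [t_end]])
    x_all = np.vstack([x0, states[:n], x_T])
    df = pd.DataFrame(x_all, columns=list(spec.species))
    df.insert(0, "time", t_all)
    return df


@dataclass(frozen=True)
class EnsembleSummary:
    """Population summary of terminal states (or of a measured cell sample).

    CV is std/mean; it is reported as NaN with ``cv_defined=False`` when the
    mean is zero, and the ``degenerate`` flag marks single-run (n = 1)
    summaries whose variance is trivially zero.
    """

    stats: pd.DataFrame           # index: species; columns: mean, variance, cv
    n_runs: int
    terminal_time: float
    seed: int | None = None
    reporter: str = "G"
    degenerate: bool = False
    terminal_states: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def mean(self) -> float:
        return float(self.stats.loc[self.reporter, "mean"])

    @property
    def variance(self) -> float:
        return float(self.stats.loc[self.reporter, "variance"])

    @property
    def cv(self) -> float:
        return float(self.stats.loc[self.reporter, "cv"])

    @property
    def cv_defined(self) -> bool:
        return np.isfinite(self.stats.loc[self.reporter, "cv"])

    @property
    def sem(self) -> float:
        """Standard error of the ensemble mean of the reporter."""
        return float(np.sqrt(self.variance / self.n_runs))

    def to_cell_table(self, dose: float = 0.0, replicate: int = 1) -> pd.DataFrame:
        """Per-run terminal reporter counts in the shared per-cell CSV schema."""
        if self.terminal_states is None:
            raise ValueError("ensemble was summarised without terminal states")
        vals = self.terminal_states[self.reporter].to_numpy()
        return pd.DataFrame(
            {
                "dose": dose,
                "replicate": replicate,
                "cell_id": np.arange(len(vals)),
                "fluorescence": vals,
            }
        )


def _summary_frame(samples: np.ndarray, species) -> pd.DataFrame:
    mean = samples.mean(axis=0)
    var = samples.var(axis=0, ddof=1) if samples.shape[0] > 1 else np.zeros(samples.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, np.sqrt(var) / mean, np.nan)
    return pd.DataFrame({"mean": mean, "variance": var, "cv": cv}, index=list(species))


def run_ensemble(
    spec: CircuitSpec,
    program: LightProgram,
    t_end: float | None = None,
    n_runs: int = 10_000,
    seed: int = 0,
    initial=None,
    keep_states: bool = True,
) -> EnsembleSummary:
    """Terminal-state statistics over ``n_runs`` independent SSA runs."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if t_end is None:
        t_end = min(program.total_duration, DEFAULT_T_END.get(spec.architecture, 72.0))
    net, c_segs, seg_ends = _segment_arrays(spec, program, t_end)
    x0 = _int_initial(spec, initial)
    children = np.random.SeedSequence(seed).generate_state(n_runs) >> 1
    terminal = np.empty((n_runs, len(spec.species)), dtype=np.int64)
    for k in range(n_runs):
        n, _, _, x_T = _ssa_core(
            x0.copy(), net.stoich, net.reactant_idx, c_segs, seg_ends,
            np.int64(children[k]), False, 0,
        )
        if n == -1:
            raise SimulationError("non-finite total propensity encountered")
        terminal[k] = x_T
    stats = _summary_frame(terminal.astype(float), spec.species)
    states = pd.DataFrame(terminal, columns=list(spec.species)) if keep_states else None
    return EnsembleSummary(
        stats=stats, n_runs=n_runs, terminal_time=float(t_end), seed=seed,
        reporter=spec.reporter, degenerate=n_runs == 1, terminal_states=states,
    )


def summarize_population(samples, name: str = "fluorescence") -> EnsembleSummary:
    """Mean, unbiased variance and CV of a per-cell sample.

    Accepts any 1-D array-like of per-cell values (SSA terminal states and
    synthetic flow-cytometry samples share this entry point).
    """
    values = np.asarray(samples, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot summarise an empty sample")
    stats = _summary_frame(values[:, None], [name])
    return EnsembleSummary(
        stats=stats, n_runs=values.size, terminal_time=np.nan,
        reporter=name, degenerate=values.size == 1,
    )
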