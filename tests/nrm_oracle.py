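"""Independent SSA oracle: Anderson's modified next-reaction method.

Test-only reference implementation, coded independently of the package's
direct-method engine (its own propensity evaluation straight from the
Reaction objects, per-reaction internal clocks instead of a single
exponential, pure Python).  Both samplers target the same jump process, so
their terminal distributions must be statistically indistinguishable; this
module plays the role of an external cross-validation simulator.

Piecewise-constant light is handled exactly: at a light switch every
reaction's integrated internal time is advanced with the old propensity and
the propensities are recomputed, which is valid because the per-reaction
Poisson clocks are defined through integrated intensities.
"""

from __future__ import annotations

import math
import random

import numpy as np


def _propensity(rx, counts: dict[str, int], u: float) -> float:
    a = rx.rate * rx.light_factor(u)
    for sp, order in rx.reactants:
        for k in range(order):
            a *= counts[sp] - k
    return max(a, 0.0)


def nrm_terminal_state(spec, program, t_end: float, seed: int) -> dict[str, int]:
    """Terminal state of one exact sample path at time t_end."""
    rng = random.Random(seed)
    counts = {sp: 0 for sp in spec.species}
    counts.update(spec.initial_state)
    reactions = list(spec.reactions)
    R = len(reactions)
    # internal clocks: P = next firing threshold, T = integrated propensity
    P = [-math.log(rng.random()) for _ in range(R)]
    T = [0.0] * R
    t = 0.0
    for t0, t_stop, u in program.segments(t_end):
        a = [_propensity(rx, counts, u) for rx in reactions]
        while True:
            # time to each reaction's next firing under constant propensities
            dt_min, j_min = math.inf, -1
            for j in range(R):
                if a[j] > 0:
                    dt = (P[j] - T[j]) / a[j]
                    if dt < dt_min:
                        dt_min, j_min = dt, j
            if t + dt_min >= t_stop or j_min < 0:
                for j in range(R):
                    T[j] += a[j] * (t_stop - t)
                t = t_stop
                break
            for j in range(R):
                T[j] += a[j] * dt_min
            t += dt_min
            rx = reactions[j_min]
            for sp, n in rx.reactants:
                counts[sp] -= n
            for sp, n in rx.products:
                counts[sp] += n
            P[j_min] += -math.log(rng.random())
            a = [_propensity(rx2, counts, u) for rx2 in reactions]
    return counts


def nrm_terminal_ensemble(spec, program, t_end: float, n_runs: int, seed: int,
                          species: str = "G") -> np.ndarray:
    """Terminal copy numbers of one species over n_runs independent paths."""
    seeds = np.random.SeedSequence(seed).generate_state(n_runs)
    return np.array([
        nrm_terminal_state(spec, program, t_end, int(s))[species] for s in seeds
    ], dtype=float)
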