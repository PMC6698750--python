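"""Reaction-network container shared by the deterministic and stochastic engines.

A :class:`CircuitSpec` is a list of elementary reactions over named species.
Each reaction carries a mass-action rate constant (statistical factors such
as the number of free operator sites are folded into the constant) and a
light-coupling mode describing how the propensity scales with the grayscale
light input ``u``:

``none``    propensity = c * prod(x_i)
``linear``  propensity = c * u * prod(x_i)
``hill``    propensity = c * (b + (1-b) * u^h / (K^h + u^h)) * prod(x_i)

Light programs are piecewise constant, so both engines fold the light factor
into an effective rate constant per light segment; :meth:`CircuitSpec.compile`
lowers the network to flat arrays for that purpose.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .params import CircuitConfigError, RateParams

LIGHT_MODES = ("none", "linear", "hill")


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction.

    ``reactants``/``products`` map species name -> stoichiometric count.
    All propensities are mass-action of order <= 2 with distinct reactant
    species; combinatorial weights live in ``rate``.
    """

    name: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate: float
    light: str = "none"
    hill: tuple[float, float, float] | None = None  # (K, h, basal)

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise CircuitConfigError(f"reaction {self.name}: negative rate {self.rate}")
        if self.light not in LIGHT_MODES:
            raise CircuitConfigError(f"reaction {self.name}: unknown light mode {self.light!r}")
        if self.light == "hill" and self.hill is None:
            raise CircuitConfigError(f"reaction {self.name}: hill mode requires hill parameters")

    def light_factor(self, u: float) -> float:
        """Dimensionless light multiplier of the propensity at intensity u."""
        if self.light == "none":
            return 1.0
        if self.light == "linear":
            return float(u)
        K, h, basal = self.hill
        if u <= 0:
            return basal
        return basal + (1.0 - basal) * u**h / (K**h + u**h)

    def propensity(self, state: dict[str, float], u: float) -> float:
        a = self.rate * self.light_factor(u)
        for sp, order in self.reactants:
            a *= state[sp] ** order
        return a


def _as_items(d: dict[str, int]) -> tuple[tuple[str, int], ...]:
    return tuple(sorted(d.items()))


def make_reaction(name, reactants, products, rate, light="none", hill=None) -> Reaction:
    return Reaction(name, _as_items(reactants), _as_items(products), float(rate), light, hill)


@dataclass(frozen=True)
class CompiledNetwork:
    """Flat-array lowering of a CircuitSpec for the numerical engines."""

    species: tuple[str, ...]
    stoich: np.ndarray          # (n_reactions, n_species) int64
    reactant_idx: np.ndarray    # (n_reactions, 2) int64, -1 = unused slot
    rate: np.ndarray            # (n_reactions,) float64
    light_mode: np.ndarray      # (n_reactions,) int8: 0 none, 1 linear, 2 hill
    hill_params: np.ndarray     # (n_reactions, 3) float64 (K, h, basal)
    initial: np.ndarray         # (n_species,) float64

    def effective_rates(self, u: float) -> np.ndarray:
        """Rate constants with the light factor folded in, for constant u."""
        c = self.rate.copy()
        lin = self.light_mode == 1
        c[lin] *= u
        for j in np.nonzero(self.light_mode == 2)[0]:
            K, h, basal = self.hill_params[j]
            if u <= 0:
                c[j] *= basal
            else:
                c[j] *= basal + (1.0 - basal) * u**h / (K**h + u**h)
        return c

    def propensities(self, x: np.ndarray, c_eff: np.ndarray) -> np.ndarray:
        a = c_eff.copy()
        for k in range(2):
            idx = self.reactant_idx[:, k]
            used = idx >= 0
            a[used] *= x[idx[used]]
        return a


@dataclass(frozen=True)
class CircuitSpec:
    """A complete circuit model: species, initial state, reactions, conserved totals.

    ``conservations`` lists (species group, total): each promoter's occupancy
    states always sum to its copy number.
    """

    architecture: str
    variant: str
    params: RateParams
    species: tuple[str, ...]
    initial: tuple[tuple[str, int], ...]
    reactions: tuple[Reaction, ...]
    conservations: tuple[tuple[tuple[str, ...], int], ...] = ()
    reporter: str = "G"

    @property
    def initial_state(self) -> dict[str, int]:
        return dict(self.initial)

    def species_index(self) -> dict[str, int]:
        return {sp: i for i, sp in enumerate(self.species)}

    def compile(self) -> CompiledNetwork:
        idx = self.species_index()
        R, S = len(self.reactions), len(self.species)
        stoich = np.zeros((R, S), dtype=np.int64)
        ridx = np.full((R, 2), -1, dtype=np.int64)
        rate = np.zeros(R)
        mode = np.zeros(R, dtype=np.int8)
        hillp = np.zeros((R, 3))
        for j, rx in enumerate(self.reactions):
            slot = 0
            for sp, order in rx.reactants:
                stoich[j, idx[sp]] -= order
                for _ in range(order):
                    if slot >= 2:
                        raise CircuitConfigError(f"reaction {rx.name}: order > 2 unsupported")
                    ridx[j, slot] = idx[sp]
                    slot += 1
            for sp, order in rx.products:
                stoich[j, idx[sp]] += order
            rate[j] = rx.rate
            mode[j] = LIGHT_MODES.index(rx.light)
            if rx.hill is not None:
                hillp[j] = rx.hill
        x0 = np.zeros(S)
        for sp, n in self.initial:
            x0[idx[sp]] = n
        return CompiledNetwork(self.species, stoich, ridx, rate, mode, hillp, x0)

    def conservation_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(C, totals): C @ x == totals along every trajectory."""
        idx = self.species_index()
        C = np.zeros((len(self.conservations), len(self.species)))
        totals = np.zeros(len(self.conservations))
        for i, (group, total) in enumerate(self.conservations):
            for sp in group:
                C[i, idx[sp]] = 1.0
            totals[i] = total
        return C, totals

    def spec_hash(self) -> str:
        """Stable content hash for manifests."""
        payload = json.dumps(
            {
                "architecture": self.architecture,
                "variant": self.variant,
                "params": self.params.to_dict(),
                "species": self.species,
                "initial": self.initial,
                "reactions": [
                    (r.name, r.reactants, r.products, r.rate, r.light, r.hill)
                    for r in self.reactions
                ],
            },
            sort_keys=True,
            default=list,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def describe(self) -> str:
        """Human-readable network dump: species, reactions, rate laws."""
        lines = [
            f"circuit: {self.architecture} (variant: {self.variant})",
            f"species ({len(self.species)}):",
        ]
        init = self.initial_state
        for sp in self.species:
            lines.append(f"  {sp:12s} initial = {init.get(sp, 0)}")
        lines.append(f"reactions ({len(self.reactions)}):")
        for rx in self.reactions:
            lhs = " + ".join(f"{n if n > 1 else ''}{sp}".strip() for sp, n in rx.reactants) or "0"
            rhs = " + ".join(f"{n if n > 1 else ''}{sp}".strip() for sp, n in rx.products) or "0"
            law = f"{rx.rate:g}"
            if rx.light == "linear":
                law += " * u(t)"
            elif rx.light == "hill":
                K, h, basal = rx.hill
                law += f" * ({basal:g} + {1 - basal:g}*u^{h:g}/({K:g}^{h:g}+u^{h:g}))"
            for sp, order in rx.reactants:
                law += f" * [{sp}]" + (f"^{order}" if order > 1 else "")
            lines.append(f"  {rx.name:28s} {lhs:>18s} -> {rhs:<18s} propensity = {law}")
        if self.conservations:
            lines.append("conserved totals:")
            for group, total in self.conservations:
                lines.append(f"  {' + '.join(group)} = {total}")
        return "\n".join(lines)
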