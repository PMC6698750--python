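"""Kinetic parameters for LITer circuit models.

:class:`RateParams` is the single home of every kinetic constant used by the
reaction networks: transcription/translation/degradation rates, TetR-operator
binding kinetics, and the light-coupling constants of the LOV2 photoswitch.

All rates are per hour; light intensity is expressed in the LPA's grayscale
units (g.s., 0-4095), so ``k_act * u`` is a first-order conversion rate of
dark TetR into its light-exposed (lit) form.

The shipped defaults are patterned on chemically inducible TetR linearizer
models: mRNA half-life of ~15 min, protein half-life/dilution of several
hours, one promoter copy per circuit (single genomic integration), two TetO
operator sites per promoter, and a 2% transcriptional leak through a
repressor-bound promoter.  Expression is transcription-dominated (weak
translational amplification, basal reporter levels of a few hundred
molecules), placing the circuits in the regime where the stochastic model
quantitatively matches the deterministic one; see docs/methods.md.  Every
value is configurable; model conclusions exercised by the test suite are
orderings and analytic limits that are robust to the exact numbers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


class CircuitConfigError(ValueError):
    """Invalid circuit architecture/variant/parameter combination."""


_RATE_FIELDS = (
    "a_G", "a_T", "l_G", "l_T", "b_G", "b_T",
    "d_m", "d_p", "k_on", "k_off",
    "k_act", "k_rev", "d_deg", "d_bound",
    "ol_K", "ol_h", "ol_basal", "ol_act", "ol_deact",
)


@dataclass(frozen=True)
class RateParams:
    """Kinetic constants of the LITer reaction networks.

    Parameters
    ----------
    a_G, a_T
        Maximal transcription rates (transcripts/h) of the reporter (GFP)
        and repressor (TetR) genes from an unrepressed promoter.  LITer2.0
        co-transcribes both genes, so construction requires ``a_T == a_G``.
    l_G, l_T
        Leaky transcription rates (transcripts/h) through an operator-bound
        (repressed) promoter.
    b_G, b_T
        Translation rates (proteins per transcript per hour).
    d_m
        mRNA degradation rate (1/h).
    d_p
        Protein degradation/dilution rate (1/h); applies to free proteins.
    k_on
        TetR-operator association rate constant (1/(molecule*h)) per free
        operator site.
    k_off
        TetR-operator dissociation rate (1/h) per bound repressor.
    n_op
        Number of TetO operator sites per promoter (the circuits carry
        TetOx2, hence the default 2).
    k_act
        Light activation coefficient (1/(h*g.s.)): dark->lit TetR conversion
        proceeds at ``k_act * u(t)`` per molecule.
    k_rev
        Lit->dark reversion rate (1/h) of the LOV2 domain refolding in the
        dark, which re-hides the TIP or degron tag.
    d_deg
        Extra degradation rate (1/h) of lit TetR in the Degron variant
        (light-exposed RRRG tag); zero for TIP.
    d_bound
        Degradation rate (1/h) of DNA-bound TetR; default 0 (toggle used in
        the architecture-comparison experiments).
    ol_K, ol_h, ol_basal
        Open-loop benchmark activation: half-max light dose (g.s.), Hill
        steepness, and dark basal fraction of the maximal activation rate.
    ol_act, ol_deact
        Open-loop promoter switching (1/h): maximal light-driven activation
        rate and constant deactivation rate of the two-state promoter.  Slow
        switching is what gives activator systems their broad expression
        distributions.
    """

    a_G: float = 1600.0
    a_T: float = 1600.0
    l_G: float = 32.0
    l_T: float = 32.0
    b_G: float = 2.5
    b_T: float = 2.5
    d_m: float = 2.77
    d_p: float = 0.1
    k_on: float = 1.0
    k_off: float = 10.0
    n_op: int = 2
    k_act: float = 0.02
    k_rev: float = 2.0
    d_deg: float = 2.0
    d_bound: float = 0.0
    ol_K: float = 200.0
    ol_h: float = 2.0
    ol_basal: float = 0.02
    ol_act: float = 0.5
    ol_deact: float = 0.5

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            value = getattr(self, name)
            if not (value >= 0):
                raise CircuitConfigError(f"rate parameter {name} must be >= 0, got {value!r}")
        if not (isinstance(self.n_op, int) and self.n_op >= 1):
            raise CircuitConfigError(f"n_op must be an integer >= 1, got {self.n_op!r}")
        if self.ol_basal > 1:
            raise CircuitConfigError("ol_basal is a fraction and must lie in [0, 1]")

    def replace(self, **changes) -> "RateParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RateParams":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise CircuitConfigError(f"unknown rate parameters: {sorted(unknown)}")
        return cls(**d)
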