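"""Construction of the LITer circuit reaction networks.

Three architectures are supported:

``liter1``
    Two-promoter autorepression: a TetR-LOV2 fusion and a GFP reporter are
    transcribed from two independent TetO-containing promoters, and TetR
    represses both.  Light exposes either a TetR-inhibiting peptide (TIP
    variant: lit TetR loses operator binding) or an RRRG degron (Degron
    variant: lit TetR keeps binding but is destabilised).

``liter2``
    Single-promoter polycistronic version: one promoter produces one
    transcript translated into both TetR and GFP (P2A-style), which forces
    the repressor and reporter synthesis parameters to be equal.

``open_loop``
    A no-feedback benchmark: transcription activated directly by light
    through a Hill function, standing in for activator systems such as VVD
    so that noise comparisons are expressible in silico.  This model is a
    deliberately generic stand-in, not a mechanistic activator model.

Operator occupancy uses sequential binding states.  TIP promoters track the
number of (dark) TetR molecules bound, 0..n_op; full-rate transcription only
from the empty state, leak otherwise.  Degron promoters track (dark, lit)
bound counts so that lit TetR carries its extra degradation while on the DNA.
The repressing unit is treated as one TetR molecule.
"""

from __future__ import annotations

from .network import CircuitSpec, Reaction, make_reaction
from .params import CircuitConfigError, RateParams

ARCHITECTURES = ("liter1", "liter2", "open_loop")
VARIANTS = ("tip", "degron", "none")


def _tip_promoter(prefix: str, a: float, leak: float, mrna: str, p: RateParams):
    """Species/reactions for one TetO promoter with a TIP-variant repressor.

    States ``{prefix}{i}`` hold i dark TetR bound (lit TIP-TetR cannot bind);
    a bound TetR hit by light unbinds immediately and is released lit.
    """
    n = p.n_op
    species = [f"{prefix}{i}" for i in range(n + 1)]
    rx: list[Reaction] = []
    for i in range(n + 1):
        state = f"{prefix}{i}"
        rate = a if i == 0 else leak
        rx.append(make_reaction(f"tx_{mrna}_{state}", {state: 1}, {state: 1, mrna: 1}, rate))
        if i < n:
            rx.append(make_reaction(
                f"bind_{prefix}{i}", {state: 1, "Td": 1}, {f"{prefix}{i+1}": 1},
                p.k_on * (n - i)))
        if i > 0:
            rx.append(make_reaction(
                f"unbind_{prefix}{i}", {state: 1}, {f"{prefix}{i-1}": 1, "Td": 1},
                p.k_off * i))
            rx.append(make_reaction(
                f"photostrip_{prefix}{i}", {state: 1}, {f"{prefix}{i-1}": 1, "Tl": 1},
                p.k_act * i, light="linear"))
            if p.d_bound > 0:
                rx.append(make_reaction(
                    f"bounddeg_{prefix}{i}", {state: 1}, {f"{prefix}{i-1}": 1},
                    p.d_bound * i))
    conservation = (tuple(species), 1)
    initial = {species[0]: 1}
    return species, initial, rx, conservation


def _degron_promoter(prefix: str, a: float, leak: float, mrna: str, p: RateParams):
    """Species/reactions for one TetO promoter with a Degron-variant repressor.

    States ``{prefix}_{d}{l}`` hold d dark and l lit TetR bound (d+l <= n_op).
    Lit TetR binds/unbinds like dark TetR but degrades at d_deg on the DNA;
    LOV2 photoconversion and dark reversion act on bound molecules in place.
    """
    n = p.n_op
    states = [(d, l) for tot in range(n + 1) for d in range(tot, -1, -1) for l in [tot - d]]
    name = {dl: f"{prefix}_{dl[0]}{dl[1]}" for dl in states}
    species = [name[dl] for dl in states]
    rx: list[Reaction] = []
    for d, l in states:
        st = name[(d, l)]
        rate = a if (d, l) == (0, 0) else leak
        rx.append(make_reaction(f"tx_{mrna}_{st}", {st: 1}, {st: 1, mrna: 1}, rate))
        free = n - d - l
        if free > 0:
            rx.append(make_reaction(
                f"bindD_{st}", {st: 1, "Td": 1}, {name[(d + 1, l)]: 1}, p.k_on * free))
            rx.append(make_reaction(
                f"bindL_{st}", {st: 1, "Tl": 1}, {name[(d, l + 1)]: 1}, p.k_on * free))
        if d > 0:
            rx.append(make_reaction(
                f"unbindD_{st}", {st: 1}, {name[(d - 1, l)]: 1, "Td": 1}, p.k_off * d))
            rx.append(make_reaction(
                f"photoconv_{st}", {st: 1}, {name[(d - 1, l + 1)]: 1},
                p.k_act * d, light="linear"))
            if p.d_bound > 0:
                rx.append(make_reaction(
                    f"bounddegD_{st}", {st: 1}, {name[(d - 1, l)]: 1}, p.d_bound * d))
        if l > 0:
            rx.append(make_reaction(
                f"unbindL_{st}", {st: 1}, {name[(d, l - 1)]: 1, "Tl": 1}, p.k_off * l))
            rx.append(make_reaction(
                f"revert_{st}", {st: 1}, {name[(d + 1, l - 1)]: 1}, p.k_rev * l))
            rx.append(make_reaction(
                f"litdeg_{st}", {st: 1}, {name[(d, l - 1)]: 1},
                (p.d_deg + p.d_bound) * l))
    conservation = (tuple(species), 1)
    initial = {name[(0, 0)]: 1}
    return species, initial, rx, conservation


def _free_tetr_reactions(variant: str, p: RateParams) -> list[Reaction]:
    rx = [
        make_reaction("photoact_Td", {"Td": 1}, {"Tl": 1}, p.k_act, light="linear"),
        make_reaction("revert_Tl", {"Tl": 1}, {"Td": 1}, p.k_rev),
        make_reaction("deg_Td", {"Td": 1}, {}, p.d_p),
    ]
    d_lit = p.d_p + (p.d_deg if variant == "degron" else 0.0)
    rx.append(make_reaction("deg_Tl", {"Tl": 1}, {}, d_lit))
    return rx


def _validate(architecture: str, variant: str, p: RateParams) -> None:
    if architecture not in ARCHITECTURES:
        raise CircuitConfigError(f"unknown architecture {architecture!r}")
    if variant not in VARIANTS:
        raise CircuitConfigError(f"unknown variant {variant!r}")
    if architecture == "open_loop":
        if variant != "none":
            raise CircuitConfigError("open_loop takes variant 'none'")
        return
    if variant == "none":
        raise CircuitConfigError(f"{architecture} requires variant 'tip' or 'degron'")
    if architecture == "liter2":
        mismatched = [
            pair for pair in (("a_T", "a_G"), ("l_T", "l_G"), ("b_T", "b_G"))
            if getattr(p, pair[0]) != getattr(p, pair[1])
        ]
        if mismatched:
            raise CircuitConfigError(
                "liter2 co-transcribes TetR and GFP from one promoter; "
                f"unequal synthesis parameters {mismatched} are not allowed"
            )


def build_circuit(architecture: str, variant: str, params: RateParams | None = None) -> CircuitSpec:
    """Build the reaction network of one circuit architecture/variant.

    Parameters
    ----------
    architecture : {"liter1", "liter2", "open_loop"}
    variant : {"tip", "degron", "none"}
        ``none`` only (and always) for the open-loop benchmark.
    params
        Kinetic constants; defaults to :class:`RateParams()`.

    Returns
    -------
    CircuitSpec
        Complete network with promoter-occupancy conservation laws recorded.
    """
    p = params if params is not None else RateParams()
    _validate(architecture, variant, p)
    if architecture != "open_loop" and variant == "tip":
        p = p.replace(d_deg=0.0)

    if architecture == "open_loop":
        # Two-state (telegraph) promoter turned ON by light with Hill-type
        # dose dependence; slow ON/OFF switching is what gives activator
        # systems their broad expression distributions.
        reactions = (
            make_reaction("activate_P", {"Poff": 1}, {"Pon": 1}, p.ol_act,
                          light="hill", hill=(p.ol_K, p.ol_h, p.ol_basal)),
            make_reaction("deactivate_P", {"Pon": 1}, {"Poff": 1}, p.ol_deact),
            make_reaction("tx_mG_on", {"Pon": 1}, {"Pon": 1, "mG": 1}, p.a_G),
            make_reaction("tx_mG_off", {"Poff": 1}, {"Poff": 1, "mG": 1}, p.l_G),
            make_reaction("deg_mG", {"mG": 1}, {}, p.d_m),
            make_reaction("tl_G", {"mG": 1}, {"mG": 1, "G": 1}, p.b_G),
            make_reaction("deg_G", {"G": 1}, {}, p.d_p),
        )
        return CircuitSpec(
            architecture, variant, p,
            species=("Poff", "Pon", "mG", "G"),
            initial=(("Poff", 1),),
            reactions=reactions,
            conservations=((("Poff", "Pon"), 1),),
        )

    promoter = _tip_promoter if variant == "tip" else _degron_promoter
    species: list[str] = []
    initial: dict[str, int] = {}
    reactions: list[Reaction] = []
    conservations = []

    if architecture == "liter1":
        blocks = [("PG", p.a_G, p.l_G, "mG"), ("PT", p.a_T, p.l_T, "mT")]
    else:  # liter2: one promoter, one polycistronic transcript
        blocks = [("P", p.a_G, p.l_G, "m")]
    for prefix, a, leak, mrna in blocks:
        sp, init, rx, cons = promoter(prefix, a, leak, mrna, p)
        species += sp
        initial.update(init)
        reactions += rx
        conservations.append(cons)

    if architecture == "liter1":
        species += ["mG", "mT", "Td", "Tl", "G"]
        reactions += [
            make_reaction("deg_mG", {"mG": 1}, {}, p.d_m),
            make_reaction("deg_mT", {"mT": 1}, {}, p.d_m),
            make_reaction("tl_G", {"mG": 1}, {"mG": 1, "G": 1}, p.b_G),
            make_reaction("tl_T", {"mT": 1}, {"mT": 1, "Td": 1}, p.b_T),
        ]
    else:
        species += ["m", "Td", "Tl", "G"]
        reactions += [
            make_reaction("deg_m", {"m": 1}, {}, p.d_m),
            make_reaction("tl_G", {"m": 1}, {"m": 1, "G": 1}, p.b_G),
            make_reaction("tl_T", {"m": 1}, {"m": 1, "Td": 1}, p.b_T),
        ]
    reactions += _free_tetr_reactions(variant, p)
    reactions.append(make_reaction("deg_G", {"G": 1}, {}, p.d_p))

    return CircuitSpec(
        architecture, variant, p,
        species=tuple(species),
        initial=tuple(sorted(initial.items())),
        reactions=tuple(reactions),
        conservations=tuple(conservations),
    )


def set_bound_tetr_degradation(spec: CircuitSpec, d_bound: float) -> CircuitSpec:
    """Return a copy of the circuit with DNA-bound TetR degrading at ``d_bound``.

    The bound repressor is destroyed and its operator site freed; promoter
    copy-number conservation is untouched.  ``d_bound = 0`` restores the
    default network (no bound degradation reactions).
    """
    if d_bound < 0:
        raise CircuitConfigError(f"d_bound must be >= 0, got {d_bound}")
    if spec.architecture == "open_loop":
        raise CircuitConfigError("open_loop benchmark has no TetR to degrade")
    return build_circuit(spec.architecture, spec.variant, spec.params.replace(d_bound=float(d_bound)))
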