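"""Circuit construction: architecture rules, invariants, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litersim import CircuitConfigError, RateParams, build_circuit, set_bound_tetr_degradation
from litersim.config import circuit_from_dict, circuit_to_dict


def test_rate_params_reject_negative_rates():
    with pytest.raises(CircuitConfigError):
        RateParams(a_G=-1.0)
    with pytest.raises(CircuitConfigError):
        RateParams(n_op=0)
    with pytest.raises(CircuitConfigError):
        RateParams.from_dict({"a_G": 10.0, "bogus": 1.0})


@pytest.mark.parametrize("arch,variant", [
    ("liter1", "tip"), ("liter1", "degron"),
    ("liter2", "tip"), ("liter2", "degron"),
    ("open_loop", "none"),
])
def test_build_circuit_valid_combinations(arch, variant, params):
    spec = build_circuit(arch, variant, params)
    assert spec.architecture == arch and spec.variant == variant
    assert len(spec.reactions) > 0
    # reaction count is fixed per architecture/variant
    assert len(spec.reactions) == len(build_circuit(arch, variant, params).reactions)


@pytest.mark.parametrize("arch,variant", [
    ("open_loop", "tip"), ("liter1", "none"), ("bogus", "tip"),
])
def test_build_circuit_invalid_combinations(arch, variant, params):
    with pytest.raises(CircuitConfigError):
        build_circuit(arch, variant, params)


def test_liter2_rejects_unequal_synthesis_params():
    p = RateParams(a_T=100.0, a_G=200.0)
    with pytest.raises(CircuitConfigError, match="co-transcribes"):
        build_circuit("liter2", "degron", p)
    # liter1 happily accepts the same asymmetry
    build_circuit("liter1", "degron", p)


def test_liter1_has_two_promoters_liter2_one(liter1_tip, liter2_tip, params):
    assert len(liter1_tip.conservations) == 2
    assert len(liter2_tip.conservations) == 1
    # two operator sites per promoter -> n_op+1 occupancy states
    group, total = liter1_tip.conservations[0]
    assert len(group) == params.n_op + 1 and total == 1
    # liter2: single transcript translated into both proteins
    tl = [r for r in liter2_tip.reactions if r.name in ("tl_G", "tl_T")]
    assert {r.reactants[0][0] for r in tl} == {"m"}


def test_liter2_polycistronic_transcription_is_single_reaction(liter2_tip):
    tx = [r for r in liter2_tip.reactions
          if any(sp == "m" for sp, _ in r.products)
          and not any(sp == "m" for sp, _ in r.reactants)]
    # one transcription reaction per promoter occupancy state, all emitting the
    # same mRNA species
    assert all(r.name.startswith("tx_m") for r in tx)
    assert len({p for r in tx for p, _ in r.products if p.startswith("m")}) == 1


def test_lit_tetr_species_and_light_reactions_present(liter1_tip, liter2_tip):
    for spec in (liter1_tip, liter2_tip):
        assert "Tl" in spec.species
        assert any(r.light == "linear" for r in spec.reactions)


def test_tip_dark_state_has_no_lit_production(liter1_tip):
    """At u = 0 every light-coupled propensity is identically zero."""
    state = {sp: 5 for sp in liter1_tip.species}
    for rx in liter1_tip.reactions:
        if rx.light == "linear":
            assert rx.propensity(state, 0.0) == 0.0
    # and lit TIP-TetR never binds an operator
    for rx in liter1_tip.reactions:
        assert not (rx.name.startswith("bind") and any(s == "Tl" for s, _ in rx.reactants))


def test_degron_lit_tetr_retains_binding(params):
    spec = build_circuit("liter1", "degron", params)
    assert any(
        r.name.startswith("bindL") and any(s == "Tl" for s, _ in r.reactants)
        for r in spec.reactions
    )


def test_open_loop_has_no_self_repression(open_loop):
    """No propensity depends on a repressor the network itself produces."""
    produced = {sp for r in open_loop.reactions for sp, _ in r.products}
    promoter_rx = [r for r in open_loop.reactions if r.name in ("activate_P", "deactivate_P")]
    for rx in promoter_rx:
        assert not any(sp in ("mG", "G") for sp, _ in rx.reactants)
    assert "Td" not in produced and "Tl" not in produced


def test_propensities_nonnegative_over_state_and_light_grid(liter1_tip):
    rng = np.random.default_rng(0)
    for _ in range(50):
        state = {sp: int(v) for sp, v in zip(liter1_tip.species, rng.integers(0, 50, len(liter1_tip.species)))}
        for u in (0.0, 1.0, 500.0, 4095.0):
            for rx in liter1_tip.reactions:
                assert rx.propensity(state, u) >= 0.0


@settings(deadline=None, derandomize=True, max_examples=25)
@given(steps=st.lists(st.integers(0, 10_000), min_size=1, max_size=60),
       variant=st.sampled_from(["tip", "degron"]))
def test_promoter_conservation_under_reachable_states(steps, variant):
    """Firing any reachable reaction sequence conserves each promoter total."""
    spec = build_circuit("liter1", variant, RateParams())
    state = {sp: 0 for sp in spec.species}
    state.update(spec.initial_state)
    state["Td"] = 5
    state["Tl"] = 5
    for pick in steps:
        feasible = [r for r in spec.reactions
                    if all(state[sp] >= n for sp, n in r.reactants)
                    and r.propensity({**state}, 100.0) > 0]
        if not feasible:
            break
        rx = feasible[pick % len(feasible)]
        for sp, n in rx.reactants:
            state[sp] -= n
        for sp, n in rx.products:
            state[sp] += n
        for group, total in spec.conservations:
            assert sum(state[sp] for sp in group) == total
        assert all(v >= 0 for v in state.values())


def test_set_bound_tetr_degradation(liter1_tip):
    with pytest.raises(CircuitConfigError):
        set_bound_tetr_degradation(liter1_tip, -0.5)
    same = set_bound_tetr_degradation(liter1_tip, 0.0)
    assert same.spec_hash() == liter1_tip.spec_hash()
    toggled = set_bound_tetr_degradation(liter1_tip, 1.0)
    assert any(r.name.startswith("bounddeg") for r in toggled.reactions)
    assert toggled.conservations == liter1_tip.conservations
    # bound degradation frees the operator without releasing TetR
    rx = next(r for r in toggled.reactions if r.name.startswith("bounddeg"))
    assert not any(sp in ("Td", "Tl") for sp, _ in rx.products)


def test_circuit_config_round_trip_is_lossless(liter1_tip, tmp_path):
    from litersim.config import read_circuit, write_circuit

    path = tmp_path / "circuit.yaml"
    write_circuit(liter1_tip, path)
    again = read_circuit(path)
    assert again.spec_hash() == liter1_tip.spec_hash()
    assert circuit_from_dict(circuit_to_dict(liter1_tip)).spec_hash() == liter1_tip.spec_hash()


def test_describe_lists_species_and_reactions(liter2_tip):
    text = liter2_tip.describe()
    for sp in liter2_tip.species:
        assert sp in text
    assert "propensity" in text and "u(t)" in text
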