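import numpy as np
import pytest

from litersim import LightProgram, RateParams, build_circuit
from litersim.network import CircuitSpec, make_reaction


@pytest.fixture(scope="session")
def params() -> RateParams:
    return RateParams()


@pytest.fixture(scope="session")
def liter1_tip(params) -> CircuitSpec:
    return build_circuit("liter1", "tip", params)


@pytest.fixture(scope="session")
def liter2_tip(params) -> CircuitSpec:
    return build_circuit("liter2", "tip", params)


@pytest.fixture(scope="session")
def open_loop(params) -> CircuitSpec:
    return build_circuit("open_loop", "none", params)


def birth_death_spec(a: float = 10.0, d: float = 1.0) -> CircuitSpec:
    """Minimal zeroth-order synthesis / first-order decay network, x0 = 0."""
    return CircuitSpec(
        architecture="open_loop",
        variant="none",
        params=RateParams(),
        species=("X",),
        initial=(),
        reactions=(
            make_reaction("birth", {}, {"X": 1}, a),
            make_reaction("death", {"X": 1}, {}, d),
        ),
        reporter="X",
    )


@pytest.fixture(scope="session")
def dark() -> LightProgram:
    return LightProgram.constant(0.0, total_duration=400.0)


@pytest.fixture(scope="session", autouse=True)
def _warm_numba(dark):
    """Compile the SSA kernel once up front so individual tests time cleanly."""
    from litersim import run_ensemble

    run_ensemble(birth_death_spec(), dark, t_end=1.0, n_runs=2, seed=0, keep_states=False)
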