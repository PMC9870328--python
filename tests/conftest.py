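import pytest

from pqnsim.analysis import SpikeTrain, detect_spikes, segment_bursts
from pqnsim.dynamics import StimulusProgram, find_equilibrium, simulate
from pqnsim.params import ModeID, PQNParams, complete_parameters, load_mode_params


@pytest.fixture(scope="session")
def eb_summaries():
    """Burst statistics of the elliptic burster across its drive range."""
    p = load_mode_params("eb")
    eq = find_equilibrium(p)
    out = {}
    for amp in (3.8, 4.0, 4.2, 4.4):
        tr = simulate(p, StimulusProgram.constant(amp), t_max=8.0, init=eq)
        spikes = [t for t in detect_spikes(tr).times if t > 2.0]
        out[amp] = segment_bursts(SpikeTrain(tuple(spikes)))
    return out


@pytest.fixture
def toy2var() -> PQNParams:
    """f(v)=v^2 on both branches, g(v)=2v^2, unit time scales, I0=0."""
    return complete_parameters(
        PQNParams(
            mode=ModeID.TOY2VAR,
            phi=1.0, tau=1.0, I0=0.0, k=1.0,
            a_fn=1.0, b_fn=0.0, c_fn=0.0, a_fp=1.0,
            a_gn=2.0, b_gn=0.0, c_gn=0.0, a_gp=2.0, r_g=0.0,
            dt=1e-4,
        )
    )


@pytest.fixture
def toy2var_eq() -> PQNParams:
    """Same toy system with I0=0.25, giving a transversal rest at v=-0.5."""
    return complete_parameters(
        PQNParams(
            mode=ModeID.TOY2VAR,
            phi=1.0, tau=1.0, I0=0.25, k=1.0,
            a_fn=1.0, b_fn=0.0, c_fn=0.0, a_fp=1.0,
            a_gn=2.0, b_gn=0.0, c_gn=0.0, a_gp=2.0, r_g=0.0,
            dt=1e-4,
        )
    )


@pytest.fixture
def toy_oscillator() -> PQNParams:
    """Two-variable relaxation oscillator with millisecond time scales.

    Same nullcline geometry as the bundled Class II mode; spikes
    periodically under moderate constant drive.
    """
    return complete_parameters(
        PQNParams(
            mode=ModeID.TOY2VAR,
            phi=1.0, tau=1e-3, I0=-0.8225, k=1.0,
            a_fn=2.0, b_fn=-0.5, c_fn=0.0, a_fp=-2.0,
            a_gn=1.0, b_gn=-2.0, c_gn=-3.5, a_gp=4.0, r_g=0.0,
            dt=1e-4,
        )
    )
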