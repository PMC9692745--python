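import numpy as np
import pytest

import blmpore as bp


@pytest.fixture(scope="session")
def ctx():
    """Default membrane: h = 5 nm, g = 1.04 S/m, 25 mV, 21 degC."""
    return bp.MembraneContext()


@pytest.fixture(scope="session")
def quiet_chain():
    """Recording chain with no noise and no ADC, for exact-value tests."""
    return bp.RecordingChain(noise_sd_pS=0.0, adc_bits=None)


def make_trace(level_sequence, model=None, noise_sd_pS=0.0, seed=0,
               baseline_pS=0.0, fs=1000.0):
    """Render a hand-written (conductance_pS, duration_s) sequence.

    Builds an explicit state per distinct conductance so tests can write
    traces directly in observable units.
    """
    distinct = sorted({g for g, _ in level_sequence})
    states = [
        bp.PoreState.from_conductance(f"s{i}", g) for i, g in enumerate(distinct)
    ]
    lookup = {g: f"s{i}" for i, g in enumerate(distinct)}
    # a chain topology with dummy kinetics; only the rendering is used
    transitions = []
    for a, b in zip(states, states[1:]):
        transitions.append(bp.Transition(a.state_id, b.state_id, rate_per_s=1.0))
        transitions.append(bp.Transition(b.state_id, a.state_id, rate_per_s=1.0))
    model = bp.PoreStateModel(
        states=states,
        transitions=transitions,
        membrane=bp.MembraneContext(),
        baseline_conductance_pS=baseline_pS,
    )
    t, dwells = 0.0, []
    for g, dur in level_sequence:
        dwells.append((lookup[g], t, t + dur))
        t += dur
    events = bp.EventSequence(dwells=dwells, total_duration_s=t)
    chain = bp.RecordingChain(
        sampling_rate_hz=fs, noise_sd_pS=noise_sd_pS, adc_bits=None
    )
    return bp.render_trace(events, model, chain, seed=seed)


@pytest.fixture(scope="session")
def trace_factory():
    return make_trace
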