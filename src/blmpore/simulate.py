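"""Generative stand-in for experimental BLM recordings.

Pore gating is modelled as a continuous-time Markov chain over metastable
pore states.  The escape rate from state ``i`` along an edge with barrier
``E_max`` follows the attempt-rate relation ``k = nu * V_i *
exp(-(E_max - E_i))`` (energies in kT), i.e. the reciprocal of the mean
dwell time that the same relation assigns to the state.  The closed
(intact-bilayer) state has no observable fluctuation volume, so opening
rates are specified directly as rates rather than derived from a barrier.

The latent state path is rendered through the recording chain of a
patch-clamp-style amplifier: conductance -> current at the holding
voltage, a single-pole low-pass with the amplifier integration constant
(discretised exactly for piecewise-constant inputs), additive Gaussian
instrument noise injected after the filter, and optional ADC
quantisation.  Defaults mirror a 1 kHz / 16-bit acquisition at 25 mV with
a 20 ms integration constant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .io import TraceRecord
from .model import (
    DEFAULT_MEMBRANE,
    MembraneContext,
    PoreState,
    dwell_from_energy,
    volume_to_concentration,
)

__all__ = [
    "Transition",
    "PoreStateModel",
    "RecordingChain",
    "EventSequence",
    "build_two_state_model",
    "build_metastable_pair_model",
    "simulate_events",
    "render_trace",
    "lowpass_filter",
    "simulate_dose_response",
    "aggregate_dose_response",
]

CLOSED = "closed"


@dataclass(frozen=True)
class Transition:
    """Directed edge of the gating graph.

    Exactly one of ``barrier_kT`` (rate from the attempt-rate relation
    using the source state's fluctuation volume and energy) or
    ``rate_per_s`` (explicit rate, used for opening from the closed state)
    must be given.
    """

    source: str
    target: str
    barrier_kT: float | None = None
    rate_per_s: float | None = None

    def __post_init__(self) -> None:
        if (self.barrier_kT is None) == (self.rate_per_s is None):
            raise ValueError(
                f"transition {self.source}->{self.target}: give exactly one of "
                "barrier_kT or rate_per_s"
            )
        if self.rate_per_s is not None and not self.rate_per_s > 0:
            raise ValueError(
                f"transition {self.source}->{self.target}: rate must be positive"
            )


@dataclass
class PoreStateModel:
    """Kinetic model of one pore: states, transitions, attempt-rate density.

    ``baseline_conductance_pS`` is the intact-membrane (leak) conductance
    added to every state's pore conductance when rendering.
    """

    states: list[PoreState]
    transitions: list[Transition]
    nu: float = 5e32
    membrane: MembraneContext = field(default_factory=MembraneContext)
    baseline_conductance_pS: float = 5.0

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError("attempt rate density nu must be strictly positive")
        ids = [s.state_id for s in self.states]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate state ids")
        self._by_id = {s.state_id: s for s in self.states}
        for t in self.transitions:
            for sid in (t.source, t.target):
                if sid not in self._by_id:
                    raise ValueError(f"transition references unknown state {sid!r}")
            if t.barrier_kT is not None and self._by_id[t.source].fluctuation_volume_m3 <= 0:
                raise ValueError(
                    f"state {t.source!r} has zero fluctuation volume; "
                    "specify its outgoing rates directly (rate_per_s)"
                )
        self._check_connected()
        for s in self.states:
            for rate in self.escape_rates(s.state_id).values():
                if not (np.isfinite(rate) and rate > 0):
                    raise ValueError(f"non-finite or non-positive rate out of {s.state_id!r}")

    def _check_connected(self) -> None:
        if len(self.states) <= 1:
            return
        adj: dict[str, set[str]] = {s.state_id: set() for s in self.states}
        for t in self.transitions:
            adj[t.source].add(t.target)
            adj[t.target].add(t.source)
        seen = {self.states[0].state_id}
        stack = [self.states[0].state_id]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if len(seen) != len(self.states):
            raise ValueError("transition graph is not connected")

    def state(self, state_id: str) -> PoreState:
        return self._by_id[state_id]

    def transition_rate(self, t: Transition) -> float:
        if t.rate_per_s is not None:
            return t.rate_per_s
        src = self._by_id[t.source]
        return self.nu * src.fluctuation_volume_m3 * math.exp(
            -(t.barrier_kT - src.energy_kT)
        )

    def escape_rates(self, state_id: str) -> dict[str, float]:
        """Per-target escape rates out of a state (1/s)."""
        return {
            t.target: self.transition_rate(t)
            for t in self.transitions
            if t.source == state_id
        }

    def mean_dwell_s(self, state_id: str) -> float:
        """Mean dwell time of a state (inf if absorbing)."""
        total = sum(self.escape_rates(state_id).values())
        return math.inf if total == 0 else 1.0 / total

    def level_conductance_pS(self, state_id: str) -> float:
        return self.baseline_conductance_pS + self._by_id[state_id].conductance_pS


@dataclass(frozen=True)
class RecordingChain:
    """Recording-chain characteristics of the acquisition setup."""

    sampling_rate_hz: float = 1000.0
    integration_tau_s: float = 0.020
    noise_sd_pS: float = 2.0
    holding_voltage_mV: float = 25.0
    adc_bits: int | None = 16
    adc_full_scale_pA: float = 2000.0  # +-2 nA span of a 5 GOhm headstage

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be strictly positive")
        if self.integration_tau_s < 0 or self.noise_sd_pS < 0:
            raise ValueError("integration constant and noise SD must be non-negative")
        if self.holding_voltage_mV == 0:
            raise ValueError("holding voltage must be non-zero")


@dataclass
class EventSequence:
    """The latent gating path: contiguous (state, t_start, t_end) dwells."""

    dwells: list[tuple[str, float, float]]
    total_duration_s: float

    def __post_init__(self) -> None:
        if not self.dwells:
            raise ValueError("event sequence must contain at least one dwell")
        t = 0.0
        for sid, t0, t1 in self.dwells:
            if not (abs(t0 - t) < 1e-9 and t1 > t0):
                raise ValueError("dwells must be contiguous and forward in time")
            t = t1
        if abs(t - self.total_duration_s) > 1e-9:
            raise ValueError("dwells must cover [0, total_duration]")

    def __len__(self) -> int:
        return len(self.dwells)

    def state_ids(self) -> list[str]:
        return [d[0] for d in self.dwells]


def build_two_state_model(
    r_open_nm: float,
    barrier_open_kT: float,
    opening_rate_per_s: float,
    ctx: MembraneContext = DEFAULT_MEMBRANE,
    nu: float = 5e32,
    baseline_conductance_pS: float = 5.0,
) -> PoreStateModel:
    """Closed <-> open model: rare openings, long-lived open state.

    The open-state mean dwell equals ``exp(barrier)/(nu*V_open)``; the
    closed->open rate is given directly (the intact bilayer has no
    observable attempt volume).  ``barrier_open_kT = inf`` makes the open
    state absorbing.
    """
    if r_open_nm <= 0:
        raise ValueError("open-state radius must be strictly positive")
    if barrier_open_kT < 0:
        raise ValueError("barrier must be non-negative")
    open_state = PoreState.from_radius("open", r_open_nm, energy_kT=0.0, ctx=ctx)
    transitions = [Transition(CLOSED, "open", rate_per_s=opening_rate_per_s)]
    if math.isfinite(barrier_open_kT):
        transitions.append(Transition("open", CLOSED, barrier_kT=barrier_open_kT))
    return PoreStateModel(
        states=[PoreState.closed(), open_state],
        transitions=transitions,
        nu=nu,
        membrane=ctx,
        baseline_conductance_pS=baseline_conductance_pS,
    )


def build_metastable_pair_model(
    r_a_nm: float,
    r_b_nm: float,
    delta_e_kT: float,
    mean_dwell_b_s: float,
    ctx: MembraneContext = DEFAULT_MEMBRANE,
    nu: float = 5e32,
    baseline_conductance_pS: float = 0.0,
) -> PoreStateModel:
    """Two open sub-states A <-> B of one pore, E_b - E_a = ``delta_e_kT``.

    State A is lower in energy by ``delta_e_kT`` (so it dwells longer);
    the shared barrier is placed so that B's mean dwell equals
    ``mean_dwell_b_s``.  This is the synthetic twin of a pore hopping
    between two conductance levels.
    """
    state_b = PoreState.from_radius("B", r_b_nm, energy_kT=0.0, ctx=ctx)
    state_a = PoreState.from_radius("A", r_a_nm, energy_kT=-delta_e_kT, ctx=ctx)
    # tau_b = exp(Emax - E_b)/(nu*V_b)  =>  Emax = ln(tau_b*nu*V_b) + E_b
    emax = math.log(mean_dwell_b_s * nu * state_b.fluctuation_volume_m3)
    return PoreStateModel(
        states=[state_a, state_b],
        transitions=[
            Transition("A", "B", barrier_kT=emax),
            Transition("B", "A", barrier_kT=emax),
        ],
        nu=nu,
        membrane=ctx,
        baseline_conductance_pS=baseline_conductance_pS,
    )


def simulate_events(
    model: PoreStateModel,
    duration_s: float,
    seed: int,
    initial_state: str | None = None,
) -> EventSequence:
    """Gillespie simulation of the gating chain for ``duration_s`` seconds.

    Dwell in each state is exponential with mean 1/(total escape rate);
    the successor is drawn with probability proportional to edge rates.
    The same (model, duration, seed) triple reproduces the sequence
    exactly.
    """
    if duration_s <= 0:
        raise ValueError("duration must be strictly positive")
    rng = np.random.default_rng(seed)
    if initial_state is None:
        ids = [s.state_id for s in model.states]
        initial_state = CLOSED if CLOSED in ids else ids[0]
    dwells: list[tuple[str, float, float]] = []
    t, state = 0.0, initial_state
    while t < duration_s:
        rates = model.escape_rates(state)
        total = sum(rates.values())
        if total == 0.0:  # absorbing
            dwells.append((state, t, duration_s))
            t = duration_s
            break
        dt = rng.exponential(1.0 / total)
        t_end = min(t + dt, duration_s)
        dwells.append((state, t, t_end))
        if t_end >= duration_s:
            break
        targets = list(rates)
        probs = np.array([rates[k] for k in targets]) / total
        state = targets[rng.choice(len(targets), p=probs)]
        t = t_end
    return EventSequence(dwells=dwells, total_duration_s=duration_s)


def lowpass_filter(x: np.ndarray, sampling_rate_hz: float, tau_s: float) -> np.ndarray:
    """Single-pole low-pass, ``y[n] = y[n-1] + alpha*(x[n] - y[n-1])``.

    ``alpha = 1 - exp(-dt/tau)`` makes the discretisation exact for
    piecewise-constant inputs: a step reaches ``1 - exp(-3)`` (95.0 %) of
    its amplitude 3 tau after the transition, and the DC gain is exactly 1.
    The filter state is initialised to ``x[0]`` (no start-up transient).
    """
    x = np.asarray(x, dtype=float)
    if tau_s == 0:
        return x.copy()
    alpha = 1.0 - math.exp(-1.0 / (sampling_rate_hz * tau_s))
    y, _ = lfilter([alpha], [1.0, -(1.0 - alpha)], x, zi=[(1.0 - alpha) * x[0]])
    return y


def _ideal_conductance(
    events: EventSequence, model: PoreStateModel, fs: float
) -> np.ndarray:
    n_total = round(events.total_duration_s * fs)
    bounds = np.round(np.array([d[2] for d in events.dwells]) * fs).astype(int)
    bounds = np.clip(bounds, 0, n_total)
    counts = np.diff(np.concatenate([[0], bounds]))
    if np.any(counts[:-1] == 0) or counts[-1] == 0:
        warnings.warn(
            "some dwells are shorter than one sample; they are invisible "
            "at this sampling rate",
            stacklevel=3,
        )
    levels = np.array(
        [model.level_conductance_pS(sid) for sid in events.state_ids()]
    )
    return np.repeat(levels, counts)


def render_trace(
    events: EventSequence,
    model: PoreStateModel,
    chain: RecordingChain,
    seed: int,
) -> TraceRecord:
    """Render a gating path through the recording chain into a TraceRecord.

    Pipeline: baseline + state conductance -> current at the holding
    voltage -> single-pole low-pass -> additive Gaussian noise (after the
    filter, where the amplifier's output noise dominates) -> optional ADC
    quantisation.
    """
    rng = np.random.default_rng(seed)
    fs = chain.sampling_rate_hz
    g_ideal = _ideal_conductance(events, model, fs)
    i_ideal = g_ideal * chain.holding_voltage_mV * 1e-3  # pS * mV -> pA
    i_filt = lowpass_filter(i_ideal, fs, chain.integration_tau_s)
    if chain.noise_sd_pS > 0:
        noise_pA = chain.noise_sd_pS * abs(chain.holding_voltage_mV) * 1e-3
        i_filt = i_filt + rng.normal(0.0, noise_pA, size=i_filt.size)
    if chain.adc_bits is not None:
        lsb = 2.0 * chain.adc_full_scale_pA / 2**chain.adc_bits
        i_filt = np.clip(
            np.round(i_filt / lsb) * lsb,
            -chain.adc_full_scale_pA,
            chain.adc_full_scale_pA,
        )
    return TraceRecord(
        current_pA=i_filt,
        sampling_rate_hz=fs,
        holding_voltage_mV=chain.holding_voltage_mV,
        membrane=model.membrane,
        annotations={"seed": int(seed), "noise_sd_pS": chain.noise_sd_pS},
    )


def simulate_dose_response(
    effect_curve: dict[float, tuple[float, float]],
    n_membranes: int,
    scatter_sd_log: float,
    seed: int,
    shell: str = "HSA",
    particle_nm: float = 27.0,
    stock_mg_per_mL: float = 1.0,
    chamber_volume_mL: float = 2.5,
    se_pS: float = 5.0,
) -> pd.DataFrame:
    """Per-membrane dose-response table around a given effect curve.

    ``effect_curve`` maps cumulative added volume (uL) to (mean pore
    count, unit pore conductance pS); the expected membrane conductance at
    a volume is count * unit.  Per-membrane values are drawn mean-
    preservingly log-normal with log-SD ``scatter_sd_log``, emulating the
    order-of-magnitude membrane-to-membrane scatter of pore formation
    (rare openings make the conductance at a fixed observation time highly
    variable).  Zero expected conductance stays exactly zero.
    """
    if n_membranes < 1:
        raise ValueError("need at least one membrane")
    volumes = list(effect_curve)
    if any(v < 0 for v in volumes) or any(
        v2 <= v1 for v1, v2 in zip(volumes, volumes[1:])
    ):
        raise ValueError("volumes must be non-negative and strictly increasing")
    rng = np.random.default_rng(seed)
    rows = []
    for m in range(n_membranes):
        for vol in volumes:
            count, unit = effect_curve[vol]
            expected = count * unit
            if expected > 0 and scatter_sd_log > 0:
                g = expected * math.exp(
                    rng.normal(-0.5 * scatter_sd_log**2, scatter_sd_log)
                )
            else:
                g = expected
            rows.append(
                {
                    "volume_uL": vol,
                    "concentration_ug_per_mL": volume_to_concentration(
                        vol, stock_mg_per_mL, chamber_volume_mL
                    ),
                    "shell": shell,
                    "particle_nm": particle_nm,
                    "membrane_id": f"m{m + 1}",
                    "mean_pS": g,
                    "se_pS": se_pS,
                }
            )
    return pd.DataFrame(rows)


def aggregate_dose_response(df: pd.DataFrame) -> pd.DataFrame:
    """Across-membrane aggregate: mean and standard error per volume."""
    per_membrane = df[df["membrane_id"] != "aggregate"]
    out = []
    for (vol, shell, size), grp in per_membrane.groupby(
        ["volume_uL", "shell", "particle_nm"], sort=True
    ):
        vals = grp["mean_pS"].to_numpy(dtype=float)
        out.append(
            {
                "volume_uL": vol,
                "concentration_ug_per_mL": grp["concentration_ug_per_mL"].iloc[0],
                "shell": shell,
                "particle_nm": size,
                "membrane_id": "aggregate",
                "mean_pS": vals.mean(),
                "se_pS": vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else 0.0,
            }
        )
    return pd.DataFrame(out)
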