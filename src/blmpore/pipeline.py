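"""End-to-end run: (simulate | read) -> segment -> kinetics -> energetics.

``RunConfig`` collects every knob of the chain with defaults matching the
reference recording configuration (5 nm membrane, 1.04 S/m electrolyte,
25 mV holding voltage, 1 kHz sampling, 20 ms integration constant, 3-tau
short-event rule).  Unknown config keys are rejected rather than ignored.
The report is deterministic for a fixed (config, seed) pair and carries
its own provenance: package version, config hash, seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io import TraceRecord, read_trace, write_events, write_levels, write_trace
from .kinetics import closed_fraction, dwell_statistics, opening_frequency, visits
from .model import (
    MembraneContext,
    NU_LITERATURE_RANGE,
    PoreState,
    barrier_interval,
    energy_difference,
    fluctuation_volume,
    pore_radius,
    radius_uncertainty,
)
from .segmentation import segment_trace
from .simulate import (
    EventSequence,
    PoreStateModel,
    RecordingChain,
    Transition,
    build_metastable_pair_model,
    build_two_state_model,
    render_trace,
    simulate_events,
)

__all__ = ["RunConfig", "run_pipeline", "build_model_from_config", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"unknown {section} config keys: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    seed: int = 0
    membrane: MembraneContext = field(default_factory=MembraneContext)
    chain: RecordingChain = field(default_factory=RecordingChain)
    simulate: dict | None = None
    input_trace: str | None = None
    baseline_window_s: tuple[float, float] | None = None
    segmentation: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)
    nu_range: tuple[float, float] = NU_LITERATURE_RANGE
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_trace is None):
            raise ValueError("give exactly one of 'simulate' or 'input_trace'")
        _check_keys(
            "segmentation",
            self.segmentation,
            {"min_step_pS", "nsigma", "detect_window_s", "min_event_s",
             "merge_tolerance_pS", "filter_tau_s"},
        )
        _check_keys("kinetics", self.kinetics, {"exclude_short", "settling_s"})

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        _check_keys(
            "top-level",
            cfg,
            {"seed", "membrane", "chain", "simulate", "input_trace",
             "baseline_window_s", "segmentation", "kinetics", "nu_range",
             "output_dir"},
        )
        membrane = MembraneContext(**(cfg.get("membrane") or {}))
        chain_cfg = dict(cfg.get("chain") or {})
        chain_cfg.setdefault("holding_voltage_mV", membrane.holding_voltage_mV)
        chain = RecordingChain(**chain_cfg)
        bw = cfg.get("baseline_window_s")
        return cls(
            seed=int(cfg.get("seed", 0)),
            membrane=membrane,
            chain=chain,
            simulate=cfg.get("simulate"),
            input_trace=cfg.get("input_trace"),
            baseline_window_s=tuple(bw) if bw is not None else None,
            segmentation=dict(cfg.get("segmentation") or {}),
            kinetics=dict(cfg.get("kinetics") or {}),
            nu_range=tuple(cfg.get("nu_range", NU_LITERATURE_RANGE)),
            output_dir=cfg.get("output_dir"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def build_model_from_config(
    spec: dict, membrane: MembraneContext, default_nu: float = 5e32
) -> tuple[PoreStateModel, float]:
    """Build a gating model from the ``simulate`` config section.

    Supported kinds: ``two_state`` (closed <-> open), ``metastable_pair``
    (two open sub-states of one pore) and ``explicit`` (full state and
    transition lists).  Returns (model, duration_s).
    """
    spec = dict(spec)
    kind = spec.pop("kind", "two_state")
    duration = float(spec.pop("duration_s"))
    nu = float(spec.pop("nu", default_nu))
    baseline = float(spec.pop("baseline_pS", 5.0))
    if kind == "two_state":
        _check_keys(
            "simulate(two_state)", spec,
            {"r_open_nm", "barrier_open_kT", "opening_rate_per_min"},
        )
        model = build_two_state_model(
            r_open_nm=float(spec["r_open_nm"]),
            barrier_open_kT=float(spec["barrier_open_kT"]),
            opening_rate_per_s=float(spec["opening_rate_per_min"]) / 60.0,
            ctx=membrane,
            nu=nu,
            baseline_conductance_pS=baseline,
        )
    elif kind == "metastable_pair":
        _check_keys(
            "simulate(metastable_pair)", spec,
            {"r_a_nm", "r_b_nm", "delta_e_kT", "mean_dwell_b_s"},
        )
        model = build_metastable_pair_model(
            r_a_nm=float(spec["r_a_nm"]),
            r_b_nm=float(spec["r_b_nm"]),
            delta_e_kT=float(spec["delta_e_kT"]),
            mean_dwell_b_s=float(spec["mean_dwell_b_s"]),
            ctx=membrane,
            nu=nu,
            baseline_conductance_pS=baseline,
        )
    elif kind == "explicit":
        _check_keys("simulate(explicit)", spec, {"states", "transitions"})
        states = []
        for s in spec["states"]:
            if "radius_nm" in s:
                states.append(
                    PoreState.from_radius(
                        s["id"], float(s["radius_nm"]),
                        float(s.get("energy_kT", 0.0)), membrane,
                    )
                )
            else:
                states.append(
                    PoreState.from_conductance(
                        s["id"], float(s.get("conductance_pS", 0.0)),
                        float(s.get("energy_kT", 0.0)), membrane,
                    )
                )
        transitions = [
            Transition(
                t["source"], t["target"],
                barrier_kT=t.get("barrier_kT"),
                rate_per_s=t.get("rate_per_s"),
            )
            for t in spec["transitions"]
        ]
        model = PoreStateModel(
            states=states, transitions=transitions, nu=nu,
            membrane=membrane, baseline_conductance_pS=baseline,
        )
    else:
        raise ValueError(f"unknown simulate kind {kind!r}")
    return model, duration


def _config_hash(config: RunConfig) -> str:
    def default(o):
        return getattr(o, "__dict__", str(o))

    blob = json.dumps(config, default=default, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chain and return the report dictionary.

    Stages: obtain a trace (simulated or from disk), idealise it into
    events and levels, compute dwell/opening/closed-time kinetics, and
    convert levels to pore radii and state energetics.  If
    ``config.output_dir`` is set, the trace, event and level tables and
    the JSON report are written there.
    """
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # --- stage: trace -----------------------------------------------------
    try:
        if config.simulate is not None:
            model, duration = build_model_from_config(
                config.simulate, config.membrane
            )
            events_seq = simulate_events(model, duration, seed=config.seed)
            trace = render_trace(events_seq, model, config.chain, seed=config.seed + 1)
        else:
            trace = read_trace(config.input_trace)
    except FileNotFoundError:
        raise
    except (ValueError, KeyError) as exc:
        raise PipelineError(f"trace stage failed: {exc}") from exc

    # --- stage: segmentation ---------------------------------------------
    try:
        segments, levelset, baseline_est = segment_trace(
            trace,
            baseline_window=config.baseline_window_s,
            **config.segmentation,
        )
    except ValueError as exc:
        raise PipelineError(f"segmentation stage failed: {exc}") from exc

    baseline_pS = (
        baseline_est[0] if baseline_est is not None else levelset.baseline.mean_pS
    )
    baseline_id = levelset.baseline_level_id

    # --- stage: kinetics --------------------------------------------------
    exclude_short = bool(config.kinetics.get("exclude_short", True))
    run_list = visits(segments, exclude_short=exclude_short, drop_censored=False)
    dwell_summaries = {}
    for lv in levelset.levels:
        try:
            dwell_summaries[lv.level_id] = dwell_statistics(
                segments, lv.level_id, exclude_short=exclude_short
            )
        except ValueError:
            continue  # level never visited outside censored edges
    freq = opening_frequency(
        segments, trace.duration_s, baseline_id, exclude_short=exclude_short
    )
    closed_pct = closed_fraction(segments, baseline_level_id=baseline_id)

    # --- stage: energetics ------------------------------------------------
    level_rows = []
    for lv in levelset.levels:
        g_pore = max(0.0, lv.mean_pS - baseline_pS)
        row = {
            "level_id": lv.level_id,
            "mean_pS": lv.mean_pS,
            "sd_pS": lv.sd_pS,
            "occupancy_s": lv.occupancy_s,
            "pore_conductance_pS": g_pore,
            "radius_nm": pore_radius(g_pore, config.membrane),
            "radius_sd_nm": (
                radius_uncertainty(g_pore, lv.sd_pS, config.membrane)
                if g_pore > 0
                else 0.0
            ),
        }
        ds = dwell_summaries.get(lv.level_id)
        if ds is not None and lv.level_id != baseline_id and g_pore > 0:
            lo, hi = barrier_interval(
                ds.mean_dwell_s,
                fluctuation_volume(row["radius_nm"], config.membrane),
                config.nu_range,
            )
            row["mean_dwell_s"] = ds.mean_dwell_s
            row["n_visits"] = ds.n_visits
            row["barrier_kT_interval"] = [lo, hi]
        level_rows.append(row)

    open_summaries = [
        (lid, ds) for lid, ds in dwell_summaries.items() if lid != baseline_id
    ]
    delta_e = None
    if len(open_summaries) >= 2:
        (la, da), (lb, db) = sorted(
            open_summaries, key=lambda t: t[1].n_visits, reverse=True
        )[:2]
        ra = next(r["radius_nm"] for r in level_rows if r["level_id"] == la)
        rb = next(r["radius_nm"] for r in level_rows if r["level_id"] == lb)
        if ra > 0 and rb > 0:
            lo_id, hi_id = (la, lb) if da.mean_dwell_s >= db.mean_dwell_s else (lb, la)
            d_lo = dwell_summaries[lo_id]
            d_hi = dwell_summaries[hi_id]
            r_lo = ra if lo_id == la else rb
            r_hi = rb if lo_id == la else ra
            value = energy_difference(
                d_lo.mean_dwell_s, r_lo, d_hi.mean_dwell_s, r_hi
            )
            se_terms = [
                (d.se_dwell_s / d.mean_dwell_s) ** 2
                for d in (d_lo, d_hi)
                if d.se_dwell_s is not None
            ]
            delta_e = {
                "lower_state_level_id": lo_id,
                "upper_state_level_id": hi_id,
                "delta_E_kT": value,
                "se_kT": math.sqrt(sum(se_terms)) if se_terms else None,
            }

    report = {
        "provenance": {
            "package": "blmpore",
            "version": __version__,
            "seed": config.seed,
            "config_sha256": _config_hash(config),
        },
        "trace": {
            "n_samples": trace.n_samples,
            "duration_s": trace.duration_s,
            "sampling_rate_hz": trace.sampling_rate_hz,
            "holding_voltage_mV": trace.holding_voltage_mV,
        },
        "baseline_pS": baseline_pS,
        "n_events": len(segments),
        "n_visits": len(run_list),
        "levels": level_rows,
        "kinetics": {
            "opening_frequency_per_min": freq,
            "closed_fraction_pct": closed_pct,
        },
        "energetics": {"state_energy_difference": delta_e},
    }

    if out:
        write_trace(trace, out / "trace.csv")
        write_events(segments, out / "events.tsv")
        write_levels(levelset, out / "levels.tsv")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
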