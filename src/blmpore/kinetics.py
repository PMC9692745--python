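"""Kinetic and dose-response statistics on idealised event tables.

A *visit* is a maximal run of consecutive segments assigned the same
level; short-flagged segments are dropped before runs are formed (they
cannot be resolved against the recording filter), so a spurious split
inside one long dwell does not fragment the visit.  The first and last
visits of a recording are censored — their true durations are unknown —
and excluded from dwell means by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AdditionSchedule, TraceRecord
from .model import volume_to_concentration
from .segmentation import EventSegment

__all__ = [
    "DwellSummary",
    "visits",
    "dwell_statistics",
    "opening_frequency",
    "closed_fraction",
    "per_addition_conductance",
    "sign_test",
]


@dataclass(frozen=True)
class DwellSummary:
    """Dwell-time summary for one conductance level."""

    level_id: int
    n_visits: int
    mean_dwell_s: float
    se_dwell_s: float | None  # None when only one visit was observed


def visits(
    events: list[EventSegment],
    exclude_short: bool = True,
    drop_censored: bool = True,
) -> list[tuple[int, float]]:
    """Collapse an event table into (level_id, duration) visits."""
    kept = [e for e in events if not (exclude_short and e.flag_short)]
    if not kept:
        return []
    runs: list[tuple[int, float]] = []
    for e in kept:
        if e.level_id is None:
            raise ValueError("events must carry level ids; run cluster_levels first")
        if runs and runs[-1][0] == e.level_id:
            runs[-1] = (e.level_id, runs[-1][1] + e.duration_s)
        else:
            runs.append((e.level_id, e.duration_s))
    if drop_censored:
        runs = runs[1:-1] if len(runs) > 2 else []
    return runs


def dwell_statistics(
    events: list[EventSegment],
    level_id: int,
    exclude_short: bool = True,
    drop_censored: bool = True,
) -> DwellSummary:
    """Mean and standard error of the dwell time at one level."""
    durations = [
        d for lid, d in visits(events, exclude_short, drop_censored) if lid == level_id
    ]
    if not durations:
        raise ValueError(f"no uncensored visits to level {level_id}")
    arr = np.asarray(durations)
    se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else None
    return DwellSummary(
        level_id=level_id,
        n_visits=arr.size,
        mean_dwell_s=float(arr.mean()),
        se_dwell_s=se,
    )


def opening_frequency(
    events: list[EventSegment],
    total_time_s: float,
    baseline_level_id: int = 1,
    exclude_short: bool = True,
) -> float:
    """Pore openings per minute: baseline -> any-pore-level transitions.

    8 openings over 100 minutes gives 0.08 1/min.
    """
    if total_time_s <= 0:
        raise ValueError("total_time_s must be strictly positive")
    runs = visits(events, exclude_short=exclude_short, drop_censored=False)
    n_open = sum(
        1
        for (a, _), (b, _) in zip(runs, runs[1:])
        if a == baseline_level_id and b != baseline_level_id
    )
    return n_open / (total_time_s / 60.0)


def closed_fraction(
    events: list[EventSegment],
    observation_window_s: tuple[float, float] | None = None,
    baseline_level_id: int = 1,
) -> float:
    """Percentage of the observation window spent at the baseline level.

    By default the window opens at the first transition away from
    baseline (pore-formation kinetics are scored only once a pore has
    appeared) and closes at the end of the record; pass an explicit
    window to override.  With no opening at all the answer is 100 %.
    """
    if not events:
        raise ValueError("no events")
    if observation_window_s is None:
        first_open = next(
            (e.t_start_s for e in events if e.level_id != baseline_level_id), None
        )
        if first_open is None:
            return 100.0
        observation_window_s = (first_open, events[-1].t_end_s)
    w0, w1 = observation_window_s
    if not w1 > w0:
        raise ValueError("observation window must have positive length")
    closed = sum(
        max(0.0, min(e.t_end_s, w1) - max(e.t_start_s, w0))
        for e in events
        if e.level_id == baseline_level_id
    )
    return 100.0 * closed / (w1 - w0)


def per_addition_conductance(
    trace: TraceRecord,
    schedule: AdditionSchedule | None = None,
    settling_s: float = 5.0,
    stock_mg_per_mL: float = 1.0,
    chamber_volume_mL: float = 2.5,
    membrane_id: str = "m1",
    shell: str = "HSA",
    particle_nm: float = 27.0,
) -> pd.DataFrame:
    """Mean conductance per inter-addition interval (dose-response rows).

    Each interval runs from ``settling_s`` after an addition (the addition
    itself injects electrical noise) to the next addition; the last
    interval runs to the end of the recording, and a leading row covers
    the control period before the first addition.  Intervals shorter than
    the settling margin are flagged and carry NaN statistics.
    """
    if schedule is None:
        schedule = trace.schedule
    g = trace.conductance_pS()
    fs = trace.sampling_rate_hz
    times = [a.time_s for a in schedule if a.chamber == "cis"]
    cis_volumes = [a.volume_uL for a in schedule if a.chamber == "cis"]
    if any(t >= trace.duration_s for t in times):
        raise ValueError("addition times must lie within the trace")
    bounds = times + [trace.duration_s]
    cumvol = np.concatenate([[0.0], np.cumsum(cis_volumes)])
    starts = [0.0] + [t + settling_s for t in times]
    rows = []
    for vol, t0, t1 in zip(cumvol, starts, bounds):
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        flagged = i1 <= i0
        seg = g[i0:i1]
        rows.append(
            {
                "volume_uL": float(vol),
                "concentration_ug_per_mL": volume_to_concentration(
                    vol, stock_mg_per_mL, chamber_volume_mL
                ),
                "shell": shell,
                "particle_nm": particle_nm,
                "membrane_id": membrane_id,
                "mean_pS": float(seg.mean()) if not flagged else math.nan,
                "se_pS": (
                    float(seg.std(ddof=1) / math.sqrt(seg.size))
                    if not flagged and seg.size > 1
                    else math.nan
                ),
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


def sign_test(differences, alternative: str = "greater") -> float:
    """Exact sign test on paired differences.

    Zero differences are dropped; ``alternative='greater'`` tests for a
    positive median difference (one-sided, the default, matching a
    directional comparison such as "coating A raises conductance more
    than coating B"), ``'less'`` the opposite direction, and
    ``'two-sided'`` doubles the smaller tail (capped at 1).
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero; the sign test is undefined")
    n = d.size
    k = int((d > 0).sum())
    p_greater = float(stats.binom.sf(k - 1, n, 0.5))  # P(X >= k)
    p_less = float(stats.binom.cdf(k, n, 0.5))
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(p_greater, p_less))
    raise ValueError("alternative must be 'greater', 'less' or 'two-sided'")
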