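"""Trace idealisation: baseline, change points, levels, occupancy.

The recording amplifier integrates the membrane current with a known
single-pole time constant (20 ms by default), so every conductance step
appears as an exponential ramp spanning ~3 tau.  Rather than correcting
detected breakpoints for that delay heuristically, the detector first
*restores* the step signal by exactly inverting the discrete single-pole
filter,

    x[n] = (y[n] - (1 - alpha) * y[n-1]) / alpha,    alpha = 1 - exp(-dt/tau),

which maps a filtered piecewise-constant signal back onto the original
one with transitions at their true sample positions.  Restoration leaves
segment means (and hence level estimates) unbiased; it amplifies white
post-filter noise into large two-sample spikes, but binary segmentation
over cumulative sums only ever compares segment means, in which those
spikes average out.  Detected breakpoints are therefore reported at the
true transition sample, without a delay-correction step.

Change points are found in two stages.  Detection runs a moving
two-window jump statistic (MOSUM) over the *filtered* series — the
difference of adjacent w-sample window means, rescaled by the known
attenuation of a filtered step over a w-sample window — and accepts local
peaks exceeding ``max(min_step_pS, nsigma * noise_sd)``.  A global
least-squares search (plain binary segmentation) would miss exactly the
events this domain cares about: a few seconds of pore closure inside a
ten-minute open stretch barely moves whole-trace means, while the local
statistic sees the full step amplitude.  Localisation then refines each
candidate by an exact single-breakpoint least-squares split of the
*restored* signal in a window around the peak, which on noiseless input
lands on the true transition sample.  Events shorter than three filter
time constants (60 ms at the defaults) cannot be confidently resolved
and are flagged — retained for audit, excluded from level building and
kinetics by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .io import TraceRecord

__all__ = [
    "EventSegment",
    "Level",
    "LevelSet",
    "restore_steps",
    "estimate_baseline",
    "detect_changepoints",
    "build_segments",
    "filter_short_events",
    "cluster_levels",
    "infer_pore_occupancy",
    "segment_trace",
    "level_histogram",
]


@dataclass(frozen=True)
class EventSegment:
    """One contiguous dwell at a conductance level."""

    t_start_s: float
    t_end_s: float
    level_id: int | None
    mean_pS: float
    sd_pS: float
    flag_short: bool = False

    def __post_init__(self) -> None:
        if not self.t_end_s > self.t_start_s:
            raise ValueError("t_end must exceed t_start")

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


@dataclass(frozen=True)
class Level:
    level_id: int
    mean_pS: float
    sd_pS: float
    occupancy_s: float


@dataclass(frozen=True)
class LevelSet:
    """Discrete conductance levels of a trace, numbered 1 (baseline) upward."""

    levels: list[Level]
    baseline_level_id: int = 1

    def __post_init__(self) -> None:
        means = [lv.mean_pS for lv in self.levels]
        if any(m2 <= m1 for m1, m2 in zip(means, means[1:])):
            raise ValueError("level means must be strictly increasing with id")

    def __len__(self) -> int:
        return len(self.levels)

    def level(self, level_id: int) -> Level:
        for lv in self.levels:
            if lv.level_id == level_id:
                return lv
        raise KeyError(level_id)

    @property
    def baseline(self) -> Level:
        return self.level(self.baseline_level_id)


def restore_steps(g: np.ndarray, sampling_rate_hz: float, tau_s: float) -> np.ndarray:
    """Exact inverse of the single-pole recording filter.

    Returns the step-restored series; on a noiselessly filtered
    piecewise-constant input this reproduces the original signal with
    sharp transitions (up to float round-off).
    """
    g = np.asarray(g, dtype=float)
    if tau_s == 0 or g.size < 2:
        return g.copy()
    alpha = 1.0 - math.exp(-1.0 / (sampling_rate_hz * tau_s))
    x = np.empty_like(g)
    x[0] = g[0]
    x[1:] = (g[1:] - (1.0 - alpha) * g[:-1]) / alpha
    return x


def _mad_noise_sd(g: np.ndarray) -> float:
    """Robust noise SD from scaled MAD of first differences.

    Steps are sparse in the difference series, so the median absolute
    difference is driven by noise alone; /sqrt(2) undoes the differencing.
    """
    d = np.diff(np.asarray(g, dtype=float))
    if d.size == 0:
        return 0.0
    return float(np.median(np.abs(d - np.median(d)))) / 0.6744897501960817 / math.sqrt(2.0)


def estimate_baseline(
    g: np.ndarray,
    sampling_rate_hz: float,
    window: tuple[float, float],
    filter_tau_s: float | None = 0.020,
) -> tuple[float, float]:
    """Robust baseline (mean, SD) in pS from a control window (seconds).

    Location is the median, scale the normal-consistent scaled MAD.  If
    the window itself contains a detectable conductance step (e.g. a pore
    opened during the control period) a warning is emitted — the baseline
    is then bimodal and the robust location tracks the majority mode.
    """
    i0 = int(round(window[0] * sampling_rate_hz))
    i1 = int(round(window[1] * sampling_rate_hz))
    seg = np.asarray(g, dtype=float)[max(i0, 0) : i1]
    if seg.size == 0:
        raise ValueError("baseline window is empty or outside the trace")
    med = float(np.median(seg))
    sd = float(1.4826 * np.median(np.abs(seg - med)))
    w = int(round(0.040 * sampling_rate_hz))
    if seg.size >= 2 * w + 1:
        noise = _mad_noise_sd(seg)
        bps = detect_changepoints(
            seg,
            sampling_rate_hz,
            min_step_pS=max(20.0, 5.0 * noise),
            filter_tau_s=filter_tau_s,
        )
        if bps.size:
            warnings.warn(
                "baseline window contains a conductance step; the estimate "
                "tracks the majority mode",
                stacklevel=2,
            )
    return med, sd


def _refine_breakpoint(z: np.ndarray, lo: int, hi: int) -> int | None:
    """Exact single-breakpoint least-squares split of ``z[lo:hi]``."""
    seg = z[lo:hi]
    if seg.size < 2:
        return None
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    k = np.arange(1, seg.size)
    mean_left = cum[k] / k
    mean_right = (cum[-1] - cum[k]) / (seg.size - k)
    gain = k * (seg.size - k) / seg.size * (mean_left - mean_right) ** 2
    return lo + int(np.argmax(gain)) + 1


def detect_changepoints(
    g: np.ndarray,
    sampling_rate_hz: float,
    min_step_pS: float = 20.0,
    nsigma: float = 5.0,
    detect_window_s: float = 0.040,
    filter_tau_s: float | None = 0.020,
    noise_sd_pS: float | None = None,
) -> np.ndarray:
    """Sample indices of conductance-level transitions.

    Each reported index is the first sample of the new level.  Transitions
    are resolvable when the dwells on both sides last at least roughly the
    detection window; steps within one window of the series edges may be
    missed.

    Parameters
    ----------
    g
        Conductance series, pS.
    min_step_pS
        Absolute floor on an accepted step (default 20 pS, below the
        smallest step one would interpret as a pore-size change).
    nsigma
        Step threshold in units of the local noise SD; the effective
        threshold is ``max(min_step_pS, nsigma * noise_sd)``.
    detect_window_s
        Half-width of the moving jump statistic; sets the dwell-time
        resolution floor of the detector.
    filter_tau_s
        Integration constant of the recording filter (inverted for the
        localisation stage); ``None`` if the series was not filtered.
    noise_sd_pS
        Noise SD; estimated robustly from the series when omitted.
    """
    from scipy.signal import find_peaks

    g = np.asarray(g, dtype=float)
    if min_step_pS <= 0:
        raise ValueError("min_step_pS must be strictly positive")
    w = max(2, int(round(detect_window_s * sampling_rate_hz)))
    n = g.size
    if n < 2 * w:
        raise ValueError(
            f"series of {n} samples is shorter than twice the detection "
            f"window ({w} samples)"
        )
    if noise_sd_pS is None:
        noise_sd_pS = _mad_noise_sd(g)
    threshold = max(min_step_pS, nsigma * noise_sd_pS)

    # Moving two-window jump statistic on the filtered series, rescaled by
    # the attenuation a filtered step suffers over a w-sample window mean.
    if filter_tau_s:
        m = filter_tau_s * sampling_rate_hz
        kappa = 1.0 - (m / w) * (1.0 - math.exp(-w / m))
    else:
        kappa = 1.0
    cum = np.concatenate([[0.0], np.cumsum(g)])
    i = np.arange(w, n - w + 1)
    jump = ((cum[i + w] - cum[i]) / w - (cum[i] - cum[i - w]) / w) / kappa
    abs_jump = np.zeros(n + 1)
    abs_jump[i] = np.abs(jump)
    peaks, _ = find_peaks(
        abs_jump, height=threshold, distance=w, prominence=threshold / 2
    )

    z = restore_steps(g, sampling_rate_hz, filter_tau_s) if filter_tau_s else g
    breakpoints = []
    for j, p in enumerate(peaks):
        lo, hi = max(0, p - w), min(n, p + w)
        if j > 0:
            lo = max(lo, (p + peaks[j - 1]) // 2)
        if j < len(peaks) - 1:
            hi = min(hi, (p + peaks[j + 1]) // 2 + 1)
        bp = _refine_breakpoint(z, int(lo), int(hi))
        if bp is not None and 0 < bp < n:
            breakpoints.append(bp)
    return np.array(sorted(set(breakpoints)), dtype=int)


def build_segments(
    g: np.ndarray,
    sampling_rate_hz: float,
    breakpoints: np.ndarray,
    filter_tau_s: float | None = 0.020,
    t_offset_s: float = 0.0,
) -> list[EventSegment]:
    """Turn breakpoints into event segments with level means and SDs.

    Means are computed on the step-restored series (unbiased even across
    the filter ramp); SDs on the filtered series with the first 3 tau of
    each segment excluded, so they reflect within-level noise rather than
    the settling transient.
    """
    g = np.asarray(g, dtype=float)
    z = restore_steps(g, sampling_rate_hz, filter_tau_s) if filter_tau_s else g
    transient = (
        int(math.ceil(3 * filter_tau_s * sampling_rate_hz)) if filter_tau_s else 0
    )
    bounds = np.concatenate([[0], np.asarray(breakpoints, dtype=int), [g.size]])
    segments = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        core = g[s + transient : e] if e - s > 2 * transient else g[s:e]
        segments.append(
            EventSegment(
                t_start_s=t_offset_s + s / sampling_rate_hz,
                t_end_s=t_offset_s + e / sampling_rate_hz,
                level_id=None,
                mean_pS=float(np.mean(z[s:e])),
                sd_pS=float(np.std(core, ddof=1)) if core.size > 1 else 0.0,
            )
        )
    return segments


def filter_short_events(
    segments: list[EventSegment], min_duration_s: float = 0.060
) -> list[EventSegment]:
    """Flag events shorter than ``min_duration_s`` (default 3 tau = 60 ms).

    Flagged events are retained — they are excluded from level building
    and kinetics downstream, never deleted.  An event of exactly the
    minimum duration is kept unflagged.
    """
    if min_duration_s < 0:
        raise ValueError("min_duration_s must be non-negative")
    return [
        replace(s, flag_short=s.duration_s < min_duration_s - 1e-12)
        for s in segments
    ]


def cluster_levels(
    segments: list[EventSegment],
    merge_tolerance_pS: float = 20.0,
    include_short: bool = False,
) -> tuple[LevelSet, list[EventSegment]]:
    """Group segment means into discrete conductance levels.

    Sorted segment means are split wherever adjacent means differ by more
    than ``merge_tolerance_pS``; each cluster becomes one level with an
    occupancy-weighted mean.  Levels are numbered ascending from the
    baseline (= lowest mean = level 1).  Short-flagged segments do not
    shape the levels (unless ``include_short``) but every segment is
    assigned the nearest level id in the returned copy.
    """
    if not segments:
        raise ValueError("need at least one segment")
    shaping = [s for s in segments if include_short or not s.flag_short]
    if not shaping:
        shaping = list(segments)
    order = sorted(shaping, key=lambda s: s.mean_pS)
    clusters: list[list[EventSegment]] = [[order[0]]]
    for seg in order[1:]:
        if seg.mean_pS - clusters[-1][-1].mean_pS > merge_tolerance_pS:
            clusters.append([seg])
        else:
            clusters[-1].append(seg)
    levels = []
    for i, cl in enumerate(clusters, start=1):
        w = np.array([c.duration_s for c in cl])
        m = np.array([c.mean_pS for c in cl])
        sd = np.array([c.sd_pS for c in cl])
        levels.append(
            Level(
                level_id=i,
                mean_pS=float(np.average(m, weights=w)),
                sd_pS=float(np.average(sd, weights=w)),
                occupancy_s=float(w.sum()),
            )
        )
    levelset = LevelSet(levels=levels)
    means = np.array([lv.mean_pS for lv in levels])
    assigned = [
        replace(s, level_id=int(np.argmin(np.abs(means - s.mean_pS))) + 1)
        for s in segments
    ]
    return levelset, assigned


def infer_pore_occupancy(
    levelset: LevelSet,
    unit_conductance_pS: float,
    tolerance_pS: float | None = None,
    baseline_pS: float | None = None,
) -> dict[int, dict]:
    """Number of simultaneously open pores explaining each level.

    For each level the pore count ``n`` minimises
    ``|mean - baseline - n * unit_conductance|``; assignments whose
    residual exceeds ``tolerance_pS`` (default: a quarter of the unit
    conductance) are flagged ambiguous.
    """
    if unit_conductance_pS <= 0:
        raise ValueError("unit conductance must be strictly positive")
    if tolerance_pS is None:
        tolerance_pS = unit_conductance_pS / 4.0
    if baseline_pS is None:
        baseline_pS = levelset.baseline.mean_pS
    out = {}
    for lv in levelset.levels:
        excess = lv.mean_pS - baseline_pS
        n = max(0, int(round(excess / unit_conductance_pS)))
        residual = excess - n * unit_conductance_pS
        out[lv.level_id] = {
            "n_pores": n,
            "residual_pS": float(residual),
            "ambiguous": abs(residual) > tolerance_pS,
        }
    return out


def segment_trace(
    trace: TraceRecord,
    min_step_pS: float = 20.0,
    nsigma: float = 5.0,
    detect_window_s: float = 0.040,
    min_event_s: float = 0.060,
    merge_tolerance_pS: float = 20.0,
    filter_tau_s: float | None = 0.020,
    baseline_window: tuple[float, float] | None = None,
) -> tuple[list[EventSegment], LevelSet, tuple[float, float] | None]:
    """Full idealisation of a trace: detect, flag, cluster.

    Returns (segments with level ids, level set, baseline (mean, sd) or
    None if no control window was given).
    """
    g = trace.conductance_pS()
    baseline = (
        estimate_baseline(g, trace.sampling_rate_hz, baseline_window, filter_tau_s)
        if baseline_window is not None
        else None
    )
    bps = detect_changepoints(
        g,
        trace.sampling_rate_hz,
        min_step_pS=min_step_pS,
        nsigma=nsigma,
        detect_window_s=detect_window_s,
        filter_tau_s=filter_tau_s,
    )
    segments = build_segments(g, trace.sampling_rate_hz, bps, filter_tau_s)
    segments = filter_short_events(segments, min_event_s)
    levelset, segments = cluster_levels(segments, merge_tolerance_pS)
    return segments, levelset, baseline


def level_histogram(
    g: np.ndarray, levelset: LevelSet, bin_width_pS: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Conductance histogram (counts, bin edges) for level-structure plots.

    Default bin width is the median level SD (floored at 1 pS).
    """
    g = np.asarray(g, dtype=float)
    if bin_width_pS is None:
        bin_width_pS = max(1.0, float(np.median([lv.sd_pS for lv in levelset.levels])))
    lo = math.floor(g.min() / bin_width_pS) * bin_width_pS
    hi = math.ceil(g.max() / bin_width_pS) * bin_width_pS
    edges = np.arange(lo, hi + bin_width_pS, bin_width_pS)
    counts, edges = np.histogram(g, bins=edges)
    return counts, edges
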