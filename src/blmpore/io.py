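"""Readers and writers for traces, events, levels and dose-response tables.

On-disk formats are deliberately plain text:

* trace: two-column CSV ``time_s,current_pA`` plus a YAML metadata sidecar
  (``<stem>.meta.yaml``) holding the sampling rate, holding voltage,
  membrane constants and annotations such as the nanoparticle addition
  schedule.  The sidecar is mandatory on read: a trace without a sampling
  rate or holding voltage cannot be interpreted.
* events: tab-separated ``t_start_s  t_end_s  level_id  mean_pS  sd_pS
  flag_short``.
* levels: tab-separated ``level_id  mean_pS  sd_pS  occupancy_s``.
* dose-response: CSV with one row per (membrane, addition).

Readers validate rather than repair: malformed or non-finite rows raise
with the offending line number; unit-inconsistent metadata is rejected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .model import MembraneContext

__all__ = [
    "TraceRecord",
    "Addition",
    "AdditionSchedule",
    "TraceFormatError",
    "read_trace",
    "write_trace",
    "current_to_conductance",
    "read_events",
    "write_events",
    "read_levels",
    "write_levels",
    "read_dose_response",
    "write_dose_response",
    "sidecar_path",
]

logger = logging.getLogger(__name__)

_TIME_TOL_S = 1e-6  # max deviation of the time column from uniformity

EVENT_COLUMNS = ["t_start_s", "t_end_s", "level_id", "mean_pS", "sd_pS", "flag_short"]
LEVEL_COLUMNS = ["level_id", "mean_pS", "sd_pS", "occupancy_s"]
DOSE_COLUMNS = [
    "volume_uL",
    "concentration_ug_per_mL",
    "shell",
    "particle_nm",
    "membrane_id",
    "mean_pS",
    "se_pS",
]


class TraceFormatError(ValueError):
    """A file failed validation; the message names the file and line."""


@dataclass(frozen=True)
class Addition:
    """One nanoparticle addition: time from recording start, chamber, volume."""

    time_s: float
    chamber: str  # "cis" or "trans"
    volume_uL: float

    def __post_init__(self) -> None:
        if self.chamber not in ("cis", "trans"):
            raise ValueError(f"chamber must be 'cis' or 'trans', got {self.chamber!r}")
        if self.volume_uL <= 0:
            raise ValueError("addition volume must be strictly positive")


@dataclass(frozen=True)
class AdditionSchedule:
    """Ordered nanoparticle additions; times strictly increasing."""

    additions: tuple[Addition, ...]

    def __post_init__(self) -> None:
        times = [a.time_s for a in self.additions]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("addition times must be strictly increasing")

    def __iter__(self):
        return iter(self.additions)

    def __len__(self) -> int:
        return len(self.additions)

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "AdditionSchedule":
        return cls(tuple(Addition(**r) for r in records))

    def to_records(self) -> list[dict]:
        return [asdict(a) for a in self.additions]


@dataclass
class TraceRecord:
    """A uniformly sampled membrane-current recording.

    ``current_pA`` is the amplifier output; conductance follows from Ohm's
    law at the holding voltage.  Additions and provenance live in
    ``annotations`` — they describe the recording, they never mutate it.
    """

    current_pA: np.ndarray
    sampling_rate_hz: float
    holding_voltage_mV: float
    membrane: MembraneContext = field(default_factory=MembraneContext)
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be strictly positive")

    @property
    def n_samples(self) -> int:
        return self.current_pA.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def conductance_pS(self) -> np.ndarray:
        return current_to_conductance(self)

    @property
    def schedule(self) -> AdditionSchedule:
        return AdditionSchedule.from_records(self.annotations.get("additions", []))


def current_to_conductance(trace: TraceRecord) -> np.ndarray:
    """Elementwise Ohm's law: G[pS] = I[pA] / V[mV] * 1000.

    (1 pA / 1 mV = 1 nS = 1000 pS; a 2.75 pA current at 25 mV is 110 pS.)
    """
    if trace.holding_voltage_mV == 0:
        raise ValueError("holding voltage is zero; conductance is undefined")
    return trace.current_pA / trace.holding_voltage_mV * 1000.0


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".meta.yaml")


def write_trace(trace: TraceRecord, path: str | Path) -> None:
    """Write a trace as ``time_s,current_pA`` CSV plus a YAML sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {"time_s": trace.times_s, "current_pA": trace.current_pA}
    )
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "sampling_rate_hz": float(trace.sampling_rate_hz),
        "holding_voltage_mV": float(trace.holding_voltage_mV),
        "membrane": {
            "thickness_nm": trace.membrane.thickness_nm,
            "conductivity_S_per_m": trace.membrane.conductivity_S_per_m,
            "holding_voltage_mV": trace.membrane.holding_voltage_mV,
            "temperature_K": trace.membrane.temperature_K,
        },
        "annotations": trace.annotations,
    }
    with open(sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_trace(path: str | Path) -> TraceRecord:
    """Read a trace CSV and its metadata sidecar; validate both."""
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise TraceFormatError(f"{path}: metadata sidecar {side.name} is missing")
    with open(side) as fh:
        meta = yaml.safe_load(fh) or {}
    for key in ("sampling_rate_hz", "holding_voltage_mV"):
        if key not in meta:
            raise TraceFormatError(f"{side}: required metadata key {key!r} is missing")

    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["time_s", "current_pA"]:
        raise TraceFormatError(
            f"{path}: expected header 'time_s,current_pA', got {list(df.columns)}"
        )
    for col in df.columns:
        bad = np.flatnonzero(~np.isfinite(df[col].to_numpy(dtype=float)))
        if bad.size:
            # +2: one for the header line, one for 1-based numbering
            raise TraceFormatError(
                f"{path}: non-finite value in column {col!r} at line {bad[0] + 2}"
            )

    fs = float(meta["sampling_rate_hz"])
    if fs <= 0:
        raise TraceFormatError(f"{side}: sampling_rate_hz must be positive")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size >= 2:
        expected = t[0] + np.arange(t.size) / fs
        off = np.abs(t - expected)
        if off.max() > _TIME_TOL_S:
            raise TraceFormatError(
                f"{path}: time column deviates from uniform sampling at "
                f"{fs} Hz by {off.max():.3g} s at line {int(off.argmax()) + 2}"
            )

    mem_meta = meta.get("membrane") or {}
    membrane = MembraneContext(
        thickness_nm=mem_meta.get("thickness_nm", 5.0),
        conductivity_S_per_m=mem_meta.get("conductivity_S_per_m", 1.04),
        holding_voltage_mV=mem_meta.get(
            "holding_voltage_mV", float(meta["holding_voltage_mV"])
        ),
        temperature_K=mem_meta.get("temperature_K", 294.15),
    )
    return TraceRecord(
        current_pA=df["current_pA"].to_numpy(dtype=float),
        sampling_rate_hz=fs,
        holding_voltage_mV=float(meta["holding_voltage_mV"]),
        membrane=membrane,
        annotations=meta.get("annotations") or {},
    )


def _events_to_frame(segments) -> pd.DataFrame:
    from .segmentation import EventSegment  # local import to avoid a cycle

    rows = []
    for s in segments:
        if not isinstance(s, EventSegment):
            raise TypeError(f"expected EventSegment, got {type(s).__name__}")
        rows.append(
            {
                "t_start_s": s.t_start_s,
                "t_end_s": s.t_end_s,
                "level_id": -1 if s.level_id is None else s.level_id,
                "mean_pS": s.mean_pS,
                "sd_pS": s.sd_pS,
                "flag_short": int(s.flag_short),
            }
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events(segments, path: str | Path) -> None:
    """Write an event table as TSV (``level_id`` -1 encodes 'unassigned')."""
    _events_to_frame(segments).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_events(path: str | Path):
    """Read an event TSV back into ``EventSegment`` objects.

    Out-of-order rows are sorted with a logged notice; overlapping
    segments are a validation error.
    """
    from .segmentation import EventSegment

    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing event columns {missing}")
    if len(df) == 0:
        return []
    if not df["t_start_s"].is_monotonic_increasing:
        logger.info("%s: events out of order; sorting by t_start_s", path)
        df = df.sort_values("t_start_s", kind="stable").reset_index(drop=True)
    starts = df["t_start_s"].to_numpy(dtype=float)
    ends = df["t_end_s"].to_numpy(dtype=float)
    overlap = np.flatnonzero(starts[1:] < ends[:-1] - 1e-12)
    if overlap.size:
        raise TraceFormatError(
            f"{path}: overlapping segments at rows {overlap[0] + 1} and {overlap[0] + 2}"
        )
    out = []
    for _, row in df.iterrows():
        lid = int(row["level_id"])
        out.append(
            EventSegment(
                t_start_s=float(row["t_start_s"]),
                t_end_s=float(row["t_end_s"]),
                level_id=None if lid < 0 else lid,
                mean_pS=float(row["mean_pS"]),
                sd_pS=float(row["sd_pS"]),
                flag_short=bool(row["flag_short"]),
            )
        )
    return out


def write_levels(levelset, path: str | Path) -> None:
    from .segmentation import LevelSet

    if not isinstance(levelset, LevelSet):
        raise TypeError("write_levels expects a LevelSet")
    df = pd.DataFrame(
        [
            {
                "level_id": lv.level_id,
                "mean_pS": lv.mean_pS,
                "sd_pS": lv.sd_pS,
                "occupancy_s": lv.occupancy_s,
            }
            for lv in levelset.levels
        ],
        columns=LEVEL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_levels(path: str | Path):
    from .segmentation import Level, LevelSet

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in LEVEL_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing level columns {missing}")
    levels = [
        Level(
            level_id=int(r["level_id"]),
            mean_pS=float(r["mean_pS"]),
            sd_pS=float(r["sd_pS"]),
            occupancy_s=float(r["occupancy_s"]),
        )
        for _, r in df.iterrows()
    ]
    return LevelSet(levels=levels)


def write_dose_response(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in DOSE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"dose-response table missing columns {missing}")
    df.to_csv(path, index=False, float_format="%.17g")


def read_dose_response(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in DOSE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing dose-response columns {missing}")
    if (df["mean_pS"].to_numpy(dtype=float) < 0).any():
        warnings.warn(f"{path}: negative mean conductances present", stacklevel=2)
    return df
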