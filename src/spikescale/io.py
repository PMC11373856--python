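"""Data model and CSV I/O for spike trains, unit metadata and result tables.

File dialect: comma-separated, UTF-8, '.' decimal, mandatory header row.
Spike times are stored in seconds; all timescale results are reported in
milliseconds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPIKE_COLUMNS = ["unit_id", "spike_time_s"]
META_COLUMNS = [
    "unit_id",
    "mouse_id",
    "area",
    "group",
    "hierarchy_score",
    "firing_rate_hz",
    "rf_flag",
]
#: column order of the per-unit results table; missing measures stay empty
RESULT_COLUMNS = [
    "unit_id",
    "tau_C_ms",
    "tau_sec_ms",
    "tau_R_ms",
    "R_tot",
    "fit_converged",
    "fit_residual",
    "n_spikes",
    "flagged",
]

GROUPS = ("thalamus", "V1", "higher_cortical")

#: units with fewer spikes than this in the analysis window are flagged
#: (kept, not dropped) as low-quality for timescale/predictability estimation
MIN_SPIKES = 100


class FormatError(ValueError):
    """Raised when an input table is missing required columns."""


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (seconds) of one unit within a recording span."""

    unit_id: str
    spike_times: np.ndarray
    t_start: float
    t_stop: float

    def __post_init__(self):
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if self.t_stop <= self.t_start:
            raise ValueError("t_stop must exceed t_start")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("spike_times must be strictly increasing")
            if times[0] < self.t_start or times[-1] > self.t_stop:
                raise ValueError("spike times outside [t_start, t_stop]")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    @property
    def rate(self) -> float:
        """Mean firing rate in Hz."""
        return self.n_spikes / self.duration


@dataclass
class UnitRecord:
    """Per-unit metadata plus (optionally) computed measures.

    ``hierarchy_score`` is the anatomical hierarchy score shifted so that V1
    sits at zero; ``rf_flag`` marks units with a significant receptive field
    on screen.  ``measures`` may carry tau_C (ms), tau_sec (ms), tau_R (ms)
    and R_tot (dimensionless in [0, 1]).
    """

    unit_id: str
    mouse_id: str
    area: str
    group: str
    hierarchy_score: float
    firing_rate: float
    rf_flag: int
    measures: dict = field(default_factory=dict)
    flagged: bool = False

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if not self.firing_rate > 0:
            raise ValueError("firing_rate must be positive")
        if int(self.rf_flag) not in (0, 1):
            raise ValueError("rf_flag must be 0 or 1")
        self.rf_flag = int(self.rf_flag)
        for key in ("tau_C", "tau_sec", "tau_R"):
            v = self.measures.get(key)
            if v is not None and not v > 0:
                raise ValueError(f"measure {key} must be positive, got {v}")
        r = self.measures.get("R_tot")
        if r is not None and not (0.0 <= r <= 1.0):
            raise ValueError(f"R_tot must lie in [0, 1], got {r}")


def read_spike_table(
    spikes_path: str | Path,
    meta_path: str | Path | None = None,
) -> tuple[list[SpikeTrain], list[UnitRecord]]:
    """Read a spike-time CSV and (optionally) its unit-metadata CSV.

    The spike file needs columns ``unit_id, spike_time_s``.  Rows may appear
    in any order; times are sorted per unit (with a warning if they were not
    already sorted).  Units listed in the metadata but absent from the spike
    file are retained with an empty train.  The recording span is taken from
    optional metadata columns ``t_start_s``/``t_stop_s`` when present, else
    inferred as [0, max spike time] over the whole file.

    Returns
    -------
    (trains, records)
        ``records`` is empty when no metadata path is given.
    """
    spikes = pd.read_csv(spikes_path)
    missing = [c for c in SPIKE_COLUMNS if c not in spikes.columns]
    if missing:
        raise FormatError(f"spike file missing columns: {missing}")
    if (spikes["spike_time_s"] < 0).any():
        raise ValueError("negative spike times in spike file")

    records: list[UnitRecord] = []
    spans: dict[str, tuple[float, float]] = {}
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path)
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise FormatError(f"metadata file missing columns: {missing}")
        for _, row in meta.iterrows():
            records.append(
                UnitRecord(
                    unit_id=str(row["unit_id"]),
                    mouse_id=str(row["mouse_id"]),
                    area=str(row["area"]),
                    group=str(row["group"]),
                    hierarchy_score=float(row["hierarchy_score"]),
                    firing_rate=float(row["firing_rate_hz"]),
                    rf_flag=int(row["rf_flag"]),
                )
            )
            if "t_start_s" in meta.columns and "t_stop_s" in meta.columns:
                spans[str(row["unit_id"])] = (
                    float(row["t_start_s"]),
                    float(row["t_stop_s"]),
                )

    default_stop = float(spikes["spike_time_s"].max()) if len(spikes) else 1.0
    unit_ids = [str(u) for u in spikes["unit_id"].astype(str).unique()]
    if meta is not None:
        # metadata order defines the unit order; spike-only units appended
        meta_ids = [r.unit_id for r in records]
        unit_ids = meta_ids + [u for u in unit_ids if u not in set(meta_ids)]

    by_unit = {
        str(uid): grp["spike_time_s"].to_numpy(dtype=float)
        for uid, grp in spikes.groupby(spikes["unit_id"].astype(str), sort=False)
    }
    trains = []
    for uid in unit_ids:
        times = by_unit.get(uid, np.empty(0))
        if times.size and np.any(np.diff(times) <= 0):
            logger.warning("unit %s: spike times not sorted; repairing", uid)
            times = np.unique(times)
        t_start, t_stop = spans.get(uid, (0.0, max(default_stop, 1e-9)))
        trains.append(SpikeTrain(uid, times, t_start, t_stop))
    return trains, records


def write_results_table(
    records: Iterable[UnitRecord | Mapping],
    path: str | Path,
) -> pd.DataFrame:
    """Write per-unit measures as CSV with a deterministic column order.

    Accepts UnitRecords (measures pulled from ``.measures``) or plain
    mappings keyed like :data:`RESULT_COLUMNS`.  Missing measures are
    written as empty fields.  Returns the frame that was written.
    """
    rows = []
    for rec in records:
        if isinstance(rec, UnitRecord):
            m = rec.measures
            row = {
                "unit_id": rec.unit_id,
                "tau_C_ms": m.get("tau_C"),
                "tau_sec_ms": m.get("tau_sec"),
                "tau_R_ms": m.get("tau_R"),
                "R_tot": m.get("R_tot"),
                "fit_converged": m.get("fit_converged"),
                "fit_residual": m.get("fit_residual"),
                "n_spikes": m.get("n_spikes"),
                "flagged": rec.flagged,
            }
        else:
            row = {c: rec.get(c) for c in RESULT_COLUMNS}
        rows.append(row)
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    frame.to_csv(path, index=False)
    return frame


def write_spike_table(
    trains: Sequence[SpikeTrain],
    spikes_path: str | Path,
    records: Sequence[UnitRecord] | None = None,
    meta_path: str | Path | None = None,
) -> None:
    """Inverse of :func:`read_spike_table` (round-trips to 12 digits)."""
    parts = [
        pd.DataFrame({"unit_id": tr.unit_id, "spike_time_s": tr.spike_times})
        for tr in trains
    ]
    frame = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(columns=SPIKE_COLUMNS)
    )
    frame.to_csv(spikes_path, index=False)
    if records is not None:
        if meta_path is None:
            raise ValueError("meta_path required when records are given")
        spans = {tr.unit_id: (tr.t_start, tr.t_stop) for tr in trains}
        meta = pd.DataFrame(
            [
                {
                    "unit_id": r.unit_id,
                    "mouse_id": r.mouse_id,
                    "area": r.area,
                    "group": r.group,
                    "hierarchy_score": r.hierarchy_score,
                    "firing_rate_hz": r.firing_rate,
                    "rf_flag": r.rf_flag,
                    "t_start_s": spans.get(r.unit_id, (0.0, np.nan))[0],
                    "t_stop_s": spans.get(r.unit_id, (0.0, np.nan))[1],
                }
                for r in records
            ]
        )
        meta.to_csv(meta_path, index=False)


def flag_low_count(train: SpikeTrain, record: UnitRecord | None = None) -> bool:
    """Quality gate: flag units with fewer than MIN_SPIKES spikes."""
    low = train.n_spikes < MIN_SPIKES
    if low and record is not None:
        record.flagged = True
    return low
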