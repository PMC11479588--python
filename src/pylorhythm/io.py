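"""Domain containers and CSV readers/writers.

Spike times are kept as plain ascending ``numpy`` arrays in seconds; the
temperature trace is a pair of (times, values) arrays.  Files are RFC-4180
CSV with a header row.  Missing per-cycle events serialise as empty fields,
never as zeros.
"""

from __future__ import annotations

import csv
import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

CONDITIONS = ("saline", "Cs", "Cs+PTX")

#: canonical column order of a cycle table CSV
CYCLE_TABLE_COLUMNS = [
    "start_s", "period_s", "freq_hz", "temp_c",
    "pd_off_phase", "lp_on_phase", "lp_off_phase", "py_on_phase",
    "py_off_phase", "pd_duration_s", "lp_duty", "temp_state", "freq_state",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one identified unit, strictly ascending, in seconds."""

    unit_label: str
    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if t.size and (not np.all(np.isfinite(t)) or t[0] < 0):
            raise ValueError(f"{self.unit_label}: spike times must be finite and >= 0")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError(f"{self.unit_label}: spike times must be strictly ascending")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class TemperatureTrace:
    """Sampled bath temperature: ascending times (s) and values (°C)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.size != v.size:
            raise ValueError("times and values must have equal length")
        if t.size < 2:
            raise ValueError("temperature trace needs at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperature times must be strictly ascending")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("temperature trace contains non-finite values")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class ExperimentRecord:
    """One recording session: labelled spike trains plus the bath temperature."""

    condition: str
    trains: Mapping[str, SpikeTrain]
    temperature: TemperatureTrace
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )

    def require_pd(self) -> SpikeTrain:
        if "PD" not in self.trains:
            raise ValueError("rhythm analysis requires a train labelled 'PD'")
        return self.trains["PD"]


def _open_rows(path: str | Path):
    text = Path(path).read_text()
    return list(csv.reader(_io.StringIO(text)))


def read_spike_trains(
    path: str | Path,
    *,
    time_unit: str = "s",
    unit_label: str | None = None,
) -> dict[str, SpikeTrain]:
    """Read spike times from CSV.

    Two layouts are accepted: two columns ``time, unit`` (one file for the
    whole experiment) or a single ``time`` column (one file per unit, label
    given by ``unit_label`` or the file stem).  A header row is required.
    ``time_unit`` may be ``"s"`` or ``"ms"``; times are converted to seconds
    on ingest.  Duplicate timestamps within a unit are collapsed with a
    warning; an unparseable or negative time raises, naming the data line.
    """
    if time_unit not in ("s", "ms"):
        raise ValueError("time_unit must be 's' or 'ms'")
    scale = 1.0 if time_unit == "s" else 1e-3
    rows = _open_rows(path)
    if not rows:
        warnings.warn(f"{path}: empty spike file", stacklevel=2)
        return {}
    header, data = rows[0], rows[1:]
    single = len(header) == 1
    default_label = unit_label or Path(path).stem
    raw: dict[str, list[float]] = {}
    for lineno, row in enumerate(data, start=1):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            t = float(row[0]) * scale
        except ValueError as exc:
            raise ValueError(f"{path}: unparseable time at line {lineno}: {row[0]!r}") from exc
        if not np.isfinite(t) or t < 0:
            raise ValueError(f"{path}: invalid (negative/non-finite) time at line {lineno}")
        label = default_label if single else (row[1].strip() if len(row) > 1 else "")
        if not label:
            raise ValueError(f"{path}: missing unit label at line {lineno}")
        raw.setdefault(label, []).append(t)
    out: dict[str, SpikeTrain] = {}
    for label, times in raw.items():
        arr = np.sort(np.asarray(times))
        uniq = np.unique(arr)
        if uniq.size < arr.size:
            warnings.warn(
                f"{path}: collapsed {arr.size - uniq.size} duplicate "
                f"timestamp(s) in unit {label}", stacklevel=2,
            )
        out[label] = SpikeTrain(label, uniq)
    if not out:
        warnings.warn(f"{path}: no spikes parsed", stacklevel=2)
    return out


def read_temperature(path: str | Path, *, time_unit: str = "s") -> TemperatureTrace:
    """Read a two-column (time, °C) CSV into a :class:`TemperatureTrace`."""
    if time_unit not in ("s", "ms"):
        raise ValueError("time_unit must be 's' or 'ms'")
    scale = 1.0 if time_unit == "s" else 1e-3
    rows = _open_rows(path)
    times, values = [], []
    for lineno, row in enumerate(rows[1:], start=1):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            t, v = float(row[0]) * scale, float(row[1])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: unparseable row at line {lineno}") from exc
        if not (np.isfinite(t) and np.isfinite(v)):
            raise ValueError(f"{path}: non-finite value at line {lineno}")
        times.append(t)
        values.append(v)
    if len(times) < 2:
        raise ValueError(f"{path}: temperature trace needs at least 2 samples")
    t = np.asarray(times)
    if not np.all(np.diff(t) > 0):
        raise ValueError(f"{path}: temperature times not strictly ascending")
    return TemperatureTrace(t, np.asarray(values))


def write_spike_trains(trains: Mapping[str, SpikeTrain], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "unit"])
        merged = sorted(
            (t, label) for label, tr in trains.items() for t in tr.times
        )
        for t, label in merged:
            w.writerow([f"{t:.17g}", label])


def write_temperature(trace: TemperatureTrace, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "temp_c"])
        for t, v in zip(trace.times, trace.values):
            w.writerow([f"{t:.17g}", f"{v:.17g}"])


def write_cycle_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-cycle table to CSV; NaN serialises as an empty field."""
    cols = [c for c in CYCLE_TABLE_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=False, float_format="%.17g", na_rep="")


def read_cycle_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("temp_state", "freq_state"):
        if col in df.columns:
            df[col] = df[col].astype("string")
    return df
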