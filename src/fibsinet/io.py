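"""Readers/writers and run configuration.

Traces travel as plain CSV/TSV, either long format
(``recording_id, cell_id, t_s, value``) or wide format (``t_s`` plus one
column per cell). Event tables are tidy CSV with a stable column order
and 9-significant-digit floats. Every artifact embeds the resolved
configuration hash as a ``#``-comment header line so runs can be traced
back to their settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .fibsi import EVENT_COLUMNS, Trace

__all__ = [
    "TraceTable",
    "RunConfig",
    "TraceValidationError",
    "NonMonotoneTimeError",
    "RaggedCellsError",
    "NonFiniteValueError",
    "read_traces",
    "write_traces",
    "read_events",
    "write_events",
]


class TraceValidationError(ValueError):
    """Base class for trace-table validation failures."""


class NonMonotoneTimeError(TraceValidationError):
    pass


class RaggedCellsError(TraceValidationError):
    pass


class NonFiniteValueError(TraceValidationError):
    pass


@dataclass
class TraceTable:
    """A set of co-recorded traces plus units/modality metadata."""

    traces: list[Trace]
    recording_id: str = "rec0"
    units: str = "AU"
    modality: str = "calcium"

    def __iter__(self):
        return iter(self.traces)

    def __len__(self):
        return len(self.traces)


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with defaults.

    The resolved config is emitted with each run; unknown keys are
    rejected on load so typos cannot silently fall back to defaults.
    """

    calcium_window_s: float = 5.0
    current_window_s: float = 0.050
    epsilon_multiplier: float = 2.0
    epsilon_multiplier_current: float = 6.0
    cutoff_fraction: float = 0.10
    silent_threshold_au: float = 5.0
    lowpass_hz: float = 200.0
    match_tolerance_ms: float = 5.0
    k_min: int = 2
    k_max: int = 6
    wave_bin_s: float = 2.0
    wave_min_fraction: float = 0.5
    iei_definition: str = "peak_to_peak"
    standardize_features: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _config_header(config: RunConfig | None) -> str:
    if config is None:
        return ""
    return f"# config_hash: {config.hash()}\n"


def _read_csv(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, comment="#")


def read_traces(path, modality: str = "calcium") -> TraceTable:
    """Load a long- or wide-format trace CSV/TSV.

    Long format needs columns ``cell_id, t_s, value`` (optionally
    ``recording_id``); anything else with a ``t_s`` column is treated as
    wide (one column per cell). Validates finiteness, monotone time and
    equal per-cell sampling; violations raise named errors.
    """
    df = _read_csv(path)
    if {"cell_id", "t_s", "value"}.issubset(df.columns):
        rec = str(df["recording_id"].iloc[0]) if "recording_id" in df else "rec0"
        if df[["t_s", "value"]].isna().any().any():
            bad = df[df[["t_s", "value"]].isna().any(axis=1)].index[0]
            raise NonFiniteValueError(f"NaN value in long-format table at row {bad}")
        if df.duplicated(["cell_id", "t_s"]).any():
            raise TraceValidationError("duplicate (cell_id, t_s) pairs")
        groups = {str(cid): sub.sort_values("t_s")
                  for cid, sub in df.groupby("cell_id", sort=True)}
        if len({len(sub) for sub in groups.values()}) > 1:
            raise RaggedCellsError("cells have differing sample counts")
        traces = []
        for cid, sub in groups.items():
            t = sub["t_s"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise NonMonotoneTimeError(f"non-monotone time for cell {cid}")
            traces.append(Trace(cid, t, sub["value"].to_numpy(dtype=float),
                                modality=modality))
        return TraceTable(traces, recording_id=rec,
                          units="pA" if modality == "current" else "AU",
                          modality=modality)
    if "t_s" in df.columns:
        t = df["t_s"].to_numpy(dtype=float)
        if df.isna().any().any():
            col = df.columns[df.isna().any()][0]
            row = int(df[df[col].isna()].index[0])
            raise NonFiniteValueError(f"NaN value at row {row}, column {col!r}")
        if np.any(np.diff(t) <= 0):
            raise NonMonotoneTimeError("non-monotone t_s column")
        traces = [
            Trace(str(c), t, df[c].to_numpy(dtype=float), modality=modality)
            for c in df.columns
            if c != "t_s"
        ]
        return TraceTable(traces, units="pA" if modality == "current" else "AU",
                          modality=modality)
    raise TraceValidationError("unrecognized trace table: need t_s (+cell_id,value)")


def write_traces(table: TraceTable, path, fmt: str = "long",
                 config: RunConfig | None = None) -> None:
    """Write traces as long (default) or wide CSV."""
    if fmt == "long":
        frames = [
            pd.DataFrame(
                {
                    "recording_id": table.recording_id,
                    "cell_id": tr.cell_id,
                    "t_s": tr.t,
                    "value": tr.y,
                }
            )
            for tr in table.traces
        ]
        df = pd.concat(frames, ignore_index=True)
    elif fmt == "wide":
        df = pd.DataFrame({"t_s": table.traces[0].t})
        for tr in table.traces:
            df[tr.cell_id] = tr.y
    else:
        raise ValueError("fmt must be 'long' or 'wide'")
    with open(path, "w") as fh:
        fh.write(_config_header(config))
        df.to_csv(fh, index=False, float_format="%.9g")


def write_events(events, path, config: RunConfig | None = None) -> None:
    """Write a tidy event table; an empty list yields a header-only file.

    Floats keep 9 significant digits; flags serialize as
    semicolon-joined tokens.
    """
    if isinstance(events, pd.DataFrame):
        df = events
    else:
        from .fibsi import events_to_frame

        df = events_to_frame(list(events))
        if df.empty:
            df = pd.DataFrame(columns=EVENT_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_config_header(config))
        df.to_csv(fh, index=False, float_format="%.9g")


def read_events(path) -> pd.DataFrame:
    df = _read_csv(path)
    if "flags" in df.columns:
        df["flags"] = df["flags"].fillna("")
    return df
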