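"""Trace data model and I/O for two-channel smFRET intensity time series.

A :class:`Trace` holds one immobilized molecule's donor and acceptor
intensity series sampled at a fixed camera frame period (50 ms by default),
together with the experiment metadata needed downstream: the frame at which
reaction buffer was injected, the window in which the acceptor was directly
excited (those frames carry no FRET information), and a free-form condition
label such as ``"Mg 30 mM"``.

Two on-disk layouts are supported:

* ``csv`` — a long-form table (one row per trace per frame) with header
  ``trace_id,frame,time_s,donor,acceptor`` plus a sidecar metadata table
  ``<name>.meta.csv`` keyed by ``trace_id`` with columns
  ``frame_period_s,injection_frame,dex_start,dex_end,condition``.
  Condition-level metadata (ion species, concentration) is stored in the
  sidecar as ``#condition <label> ion=<ion> concentration_mM=<c>`` comment
  lines.  This dialect is diff-able and round-trips bit-exactly.
* ``container`` — an HDF5 file with one group per trace holding float
  ``donor``/``acceptor`` datasets and metadata as attributes, for large sets.

Frame indexing is 0-based everywhere and windows are half-open
``[start, end)``.  Intensities are arbitrary camera units; the FRET
efficiency is a ratio, so no unit conversion is ever attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "TraceSet",
    "TraceFormatError",
    "read_traces",
    "write_traces",
]


class TraceFormatError(ValueError):
    """Raised when a trace file or a trace's fields violate the format contract."""


def _as_float_series(name: str, values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise TraceFormatError(f"{name} must be a 1-D series, got shape {arr.shape}")
    return arr


@dataclass
class Trace:
    """One molecule's two-channel intensity time series plus metadata.

    Parameters
    ----------
    trace_id : str
        Unique identifier within a :class:`TraceSet`.
    donor, acceptor : array-like of float
        Per-frame intensities in arbitrary camera units; equal length >= 2.
    frame_period : float
        Camera integration time per frame in seconds (default 0.05).
    injection_frame : int or None
        Frame at which reaction buffer entered the flow cell, if recorded.
    direct_excitation_window : (int, int) or None
        Half-open frame range during which the acceptor was directly excited.
    condition : str
        Free-form condition label, e.g. ``"Mg 30 mM"``.
    """

    trace_id: str
    donor: np.ndarray
    acceptor: np.ndarray
    frame_period: float = 0.05
    injection_frame: int | None = None
    direct_excitation_window: tuple[int, int] | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        self.donor = _as_float_series("donor", self.donor)
        self.acceptor = _as_float_series("acceptor", self.acceptor)
        if len(self.donor) != len(self.acceptor):
            raise TraceFormatError(
                f"trace {self.trace_id!r}: donor length {len(self.donor)} != "
                f"acceptor length {len(self.acceptor)}"
            )
        if len(self.donor) < 2:
            raise TraceFormatError(
                f"trace {self.trace_id!r}: series must have length >= 2"
            )
        if not (self.frame_period > 0):
            raise TraceFormatError(
                f"trace {self.trace_id!r}: frame_period must be > 0, "
                f"got {self.frame_period}"
            )
        if self.injection_frame is not None:
            inj = int(self.injection_frame)
            if not 0 <= inj < self.n_frames:
                raise TraceFormatError(
                    f"trace {self.trace_id!r}: injection_frame {inj} outside "
                    f"[0, {self.n_frames})"
                )
            self.injection_frame = inj
        if self.direct_excitation_window is not None:
            s, e = (int(v) for v in self.direct_excitation_window)
            if not (0 <= s < e <= self.n_frames):
                raise TraceFormatError(
                    f"trace {self.trace_id!r}: direct_excitation_window "
                    f"[{s}, {e}) is not a non-empty range within the trace"
                )
            self.direct_excitation_window = (s, e)

    @property
    def n_frames(self) -> int:
        return len(self.donor)

    @property
    def duration(self) -> float:
        """Total observation time in seconds."""
        return self.n_frames * self.frame_period

    @property
    def times(self) -> np.ndarray:
        """Frame start times in seconds."""
        return np.arange(self.n_frames) * self.frame_period

    @property
    def total(self) -> np.ndarray:
        """Summed donor + acceptor intensity per frame."""
        return self.donor + self.acceptor

    def copy(self) -> "Trace":
        return replace(self, donor=self.donor.copy(), acceptor=self.acceptor.copy())


@dataclass
class TraceSet:
    """An ordered collection of traces with per-condition metadata."""

    traces: list[Trace] = field(default_factory=list)
    condition_metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.trace_id for t in self.traces]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise TraceFormatError(f"duplicate trace_ids in set: {dup}")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[Trace]:
        return iter(self.traces)

    def __getitem__(self, key: int | str) -> Trace:
        if isinstance(key, str):
            for t in self.traces:
                if t.trace_id == key:
                    return t
            raise KeyError(key)
        return self.traces[key]

    @property
    def ids(self) -> list[str]:
        return [t.trace_id for t in self.traces]


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_MAIN_COLUMNS = ["trace_id", "frame", "time_s", "donor", "acceptor"]
_META_COLUMNS = [
    "trace_id",
    "frame_period_s",
    "injection_frame",
    "dex_start",
    "dex_end",
    "condition",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.csv")


def _fmt(x: float) -> str:
    # shortest round-trip decimal representation of a float64
    return repr(float(x))


def _write_csv(ts: TraceSet, path: Path) -> None:
    lines = [",".join(_MAIN_COLUMNS)]
    for t in ts:
        for f in range(t.n_frames):
            lines.append(
                f"{t.trace_id},{f},{_fmt(f * t.frame_period)},"
                f"{_fmt(t.donor[f])},{_fmt(t.acceptor[f])}"
            )
    path.write_text("\n".join(lines) + "\n")

    meta_lines = []
    for label, info in ts.condition_metadata.items():
        ion = info.get("ion", "")
        conc = info.get("concentration", "")
        # tab-delimited so labels may contain spaces
        meta_lines.append(f"#condition\t{label}\tion={ion}\tconcentration_mM={conc}")
    meta_lines.append(",".join(_META_COLUMNS))
    for t in ts:
        dex = t.direct_excitation_window
        meta_lines.append(
            ",".join(
                [
                    t.trace_id,
                    _fmt(t.frame_period),
                    "" if t.injection_frame is None else str(t.injection_frame),
                    "" if dex is None else str(dex[0]),
                    "" if dex is None else str(dex[1]),
                    t.condition,
                ]
            )
        )
    _sidecar_path(path).write_text("\n".join(meta_lines) + "\n")


def _parse_condition_comments(path: Path) -> dict[str, dict]:
    meta: dict[str, dict] = {}
    for line in path.read_text().splitlines():
        if not line.startswith("#condition\t"):
            continue
        try:
            _, label, ion_kv, conc_kv = line.split("\t", 3)
            ion = ion_kv.split("=", 1)[1]
            conc_s = conc_kv.split("=", 1)[1]
        except (ValueError, IndexError) as exc:
            raise TraceFormatError(f"malformed condition line: {line!r}") from exc
        info: dict = {"ion": ion}
        if conc_s != "":
            info["concentration"] = float(conc_s)
        meta[label] = info
    return meta


def _read_csv(path: Path) -> TraceSet:
    try:
        main = pd.read_csv(path, dtype={"trace_id": str}, float_precision="round_trip")
    except Exception as exc:  # malformed / ragged rows
        raise TraceFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _MAIN_COLUMNS if c not in main.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing column(s) {missing}")

    side = _sidecar_path(path)
    meta_rows: dict[str, dict] = {}
    condition_metadata: dict[str, dict] = {}
    if side.exists():
        condition_metadata = _parse_condition_comments(side)
        meta = pd.read_csv(side, comment="#", dtype={"trace_id": str},
                           float_precision="round_trip")
        missing = [c for c in _META_COLUMNS if c not in meta.columns]
        if missing:
            raise TraceFormatError(f"{side}: missing column(s) {missing}")
        for _, row in meta.iterrows():
            meta_rows[row["trace_id"]] = row

    traces = []
    # preserve file order of first appearance
    for tid, grp in main.groupby("trace_id", sort=False):
        frames = grp["frame"].to_numpy()
        if not np.array_equal(frames, np.arange(len(frames))):
            raise TraceFormatError(
                f"trace {tid!r}: frame indices are not contiguous from 0"
            )
        row = meta_rows.get(tid)
        frame_period = 0.05
        injection = None
        dex = None
        condition = ""
        if row is not None:
            frame_period = float(row["frame_period_s"])
            if frame_period <= 0:
                raise TraceFormatError(
                    f"trace {tid!r}: negative or zero frame_period_s"
                )
            if pd.notna(row["injection_frame"]):
                injection = int(row["injection_frame"])
            if pd.notna(row["dex_start"]) and pd.notna(row["dex_end"]):
                dex = (int(row["dex_start"]), int(row["dex_end"]))
            if pd.notna(row["condition"]):
                condition = str(row["condition"])
        traces.append(
            Trace(
                trace_id=str(tid),
                donor=grp["donor"].to_numpy(),
                acceptor=grp["acceptor"].to_numpy(),
                frame_period=frame_period,
                injection_frame=injection,
                direct_excitation_window=dex,
                condition=condition,
            )
        )
    return TraceSet(traces=traces, condition_metadata=condition_metadata)


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------


def _write_container(ts: TraceSet, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["condition_metadata"] = json.dumps(ts.condition_metadata)
        h5.attrs["trace_order"] = json.dumps(ts.ids)
        for t in ts:
            g = h5.create_group(t.trace_id)
            g.create_dataset("donor", data=t.donor)
            g.create_dataset("acceptor", data=t.acceptor)
            g.attrs["frame_period"] = t.frame_period
            g.attrs["condition"] = t.condition
            if t.injection_frame is not None:
                g.attrs["injection_frame"] = t.injection_frame
            if t.direct_excitation_window is not None:
                g.attrs["dex_window"] = t.direct_excitation_window


def _read_container(path: Path) -> TraceSet:
    import h5py

    traces = []
    with h5py.File(path, "r") as h5:
        condition_metadata = json.loads(h5.attrs.get("condition_metadata", "{}"))
        order = json.loads(h5.attrs.get("trace_order", "null")) or sorted(h5.keys())
        for tid in order:
            g = h5[tid]
            dex = g.attrs.get("dex_window")
            traces.append(
                Trace(
                    trace_id=tid,
                    donor=g["donor"][:],
                    acceptor=g["acceptor"][:],
                    frame_period=float(g.attrs["frame_period"]),
                    injection_frame=(
                        int(g.attrs["injection_frame"])
                        if "injection_frame" in g.attrs
                        else None
                    ),
                    direct_excitation_window=(
                        (int(dex[0]), int(dex[1])) if dex is not None else None
                    ),
                    condition=str(g.attrs.get("condition", "")),
                )
            )
    return TraceSet(traces=traces, condition_metadata=condition_metadata)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def read_traces(path: str | Path, format: str = "csv") -> TraceSet:
    """Read a :class:`TraceSet` from ``path``.

    ``format`` is ``"csv"`` (long-form table + sidecar metadata) or
    ``"container"`` (HDF5).  Any trace violating a :class:`Trace` invariant
    raises :class:`TraceFormatError` naming the offending trace; nothing is
    silently repaired.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv(path)
    if format == "container":
        return _read_container(path)
    raise ValueError(f"unknown format {format!r}")


def write_traces(ts: TraceSet, path: str | Path, format: str = "csv") -> None:
    """Write ``ts`` so that :func:`read_traces` restores every field.

    The CSV dialect uses shortest round-trip float formatting, so a
    write -> read -> write cycle is byte-identical.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        _write_csv(ts, path)
    elif format == "container":
        _write_container(ts, path)
    else:
        raise ValueError(f"unknown format {format!r}")
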