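"""Plain-text readers and writers for every pipeline artifact.

All files are delimited text with ``#``-prefixed header metadata lines
(``# key: value``) followed by a CSV header row and data rows, so every
output embeds the parameters that produced it.  Raw 10 kHz recordings may
alternatively be stored in a single-file binary container (``.npz``) for
compactness.  Malformed rows raise :class:`~photoscratch.errors.ParseError`
with the offending line number.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import OccupancyRecord
from .coloc import CellTable
from .correct import CorrectedTrace, ScalingFit
from .demod import ChannelTrace, ModulatedRecording
from .errors import ConfigurationError, ParseError
from .perievent import EventTrain, PeriEventMatrix


def _write_meta(fh, kind: str, meta: dict):
    fh.write(f"# photoscratch {kind}\n")
    for k, v in meta.items():
        if v is None:
            continue
        if isinstance(v, (dict, list)):
            v = json.dumps(v)
        fh.write(f"# {k}: {v}\n")


def _read_meta(path: Path) -> tuple[dict, int]:
    """Header metadata and the number of leading comment lines."""
    meta = {}
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
    return meta, n


def _read_table(path: Path, kind: str) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    meta, _ = _read_meta(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 — surface any malformation as ParseError
        raise ParseError(f"cannot parse {kind} file {path}: {exc}") from exc
    return df, meta


def _require_columns(df: pd.DataFrame, cols: list[str], path, kind: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{kind} file {path} lacks column(s) {missing}", column=missing[0])


def _numeric(df: pd.DataFrame, col: str, path, n_header: int) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = np.flatnonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())
    if df[col].isna().any():
        bad = np.append(bad, np.flatnonzero(df[col].isna().to_numpy()))
    if len(bad):
        # +2: header row plus 1-based numbering
        raise ParseError(
            f"non-numeric value in column {col!r} of {path}",
            line=int(bad.min()) + n_header + 2, column=col,
        )
    return vals.to_numpy(dtype=float)


# ---------------------------------------------------------------- recordings

def write_recording(path, rec: ModulatedRecording):
    """Write a raw recording; ``.npz`` gives the binary container, anything
    else columnar text (time_s, voltage)."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(
            path, samples=rec.samples, sample_rate_hz=rec.sample_rate_hz,
            t0_s=rec.t0_s, carrier_map=json.dumps({str(k): v for k, v in rec.carrier_map.items()}),
        )
        return
    with open(path, "w") as fh:
        _write_meta(fh, "recording", {
            "sample_rate_hz": rec.sample_rate_hz, "t0_s": rec.t0_s,
            "carrier_map": {str(k): v for k, v in rec.carrier_map.items()},
        })
        fh.write("time_s,voltage\n")
        np.savetxt(fh, np.column_stack([rec.times(), rec.samples]),
                   fmt="%.6f,%.9g", delimiter=",")


def read_recording(path) -> ModulatedRecording:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            carrier = {int(k): float(v) for k, v in json.loads(str(z["carrier_map"])).items()}
            return ModulatedRecording(
                samples=z["samples"], sample_rate_hz=float(z["sample_rate_hz"]),
                carrier_map=carrier, t0_s=float(z["t0_s"]),
            )
    df, meta = _read_table(path, "recording")
    _require_columns(df, ["time_s", "voltage"], path, "recording")
    n_header = len(meta) + 1
    times = _numeric(df, "time_s", path, n_header)
    volts = _numeric(df, "voltage", path, n_header)
    if "sample_rate_hz" in meta:
        rate = float(meta["sample_rate_hz"])
    elif len(times) > 1:
        rate = 1.0 / float(np.median(np.diff(times)))
    else:
        raise ParseError(f"recording {path} lacks a sample_rate_hz header")
    carrier = json.loads(meta.get("carrier_map", '{"405": 211.0, "470": 537.0}'))
    return ModulatedRecording(
        samples=volts, sample_rate_hz=rate,
        carrier_map={int(k): float(v) for k, v in carrier.items()},
        t0_s=float(meta.get("t0_s", times[0] if len(times) else 0.0)),
    )


# -------------------------------------------------------------------- traces

def write_trace(path, trace):
    """Write a ChannelTrace or CorrectedTrace as (time_s, value, settling) text."""
    is_dff = isinstance(trace, CorrectedTrace)
    values = trace.dff if is_dff else trace.values
    rate = trace.source_rate_hz if is_dff else trace.sample_rate_hz
    meta = {
        "kind": "dff" if is_dff else "channel",
        "sample_rate_hz": rate,
        "t0_s": trace.t0_s,
    }
    if is_dff:
        meta.update({"dff_mode": trace.mode, "mean_corrected": trace.mean_corrected})
        if trace.fit is not None:
            meta.update({"fit_gain_a": trace.fit.gain_a, "fit_offset_b": trace.fit.offset_b,
                         "fit_residual_rms": trace.fit.residual_rms,
                         "fit_n_samples": trace.fit.n_samples})
    else:
        meta.update({"wavelength_nm": trace.wavelength_nm, "lowpass_hz": trace.lowpass_hz,
                     "source_mean": trace.source_mean})
    with open(path, "w") as fh:
        _write_meta(fh, "trace", meta)
        fh.write("time_s,value,settling\n")
        np.savetxt(fh, np.column_stack([trace.times(), values,
                                        trace.settling_mask.astype(int)]),
                   fmt="%.6f,%.17g,%d", delimiter=",")


def read_trace(path):
    """Read a trace file back into a ChannelTrace or CorrectedTrace."""
    df, meta = _read_table(path, "trace")
    _require_columns(df, ["time_s", "value"], path, "trace")
    n_header = len(meta) + 1
    values = _numeric(df, "value", path, n_header)
    times = _numeric(df, "time_s", path, n_header)
    if "settling" in df.columns:
        try:
            mask = df["settling"].to_numpy(dtype=float).astype(bool)
        except (ValueError, TypeError) as exc:
            raise ParseError(f"non-boolean settling column in {path}",
                             column="settling") from exc
    else:
        mask = None
    try:
        if "sample_rate_hz" in meta:
            rate = float(meta["sample_rate_hz"])
        elif len(times) > 1:
            rate = 1.0 / float(np.median(np.diff(times)))
        else:
            raise ParseError(f"trace {path} lacks a sample_rate_hz header")
        t0 = float(meta.get("t0_s", times[0] if len(times) else 0.0))
        return _build_trace(values, mask, rate, t0, meta)
    except ParseError:
        raise
    except (ConfigurationError, ValueError, TypeError) as exc:
        raise ParseError(f"invalid trace in {path}: {exc}") from exc


def _build_trace(values, mask, rate, t0, meta):
    if meta.get("kind") == "dff":
        fit = None
        if "fit_gain_a" in meta:
            fit = ScalingFit(
                gain_a=float(meta["fit_gain_a"]), offset_b=float(meta["fit_offset_b"]),
                residual_rms=float(meta["fit_residual_rms"]),
                n_samples=int(meta["fit_n_samples"]),
            )
        return CorrectedTrace(
            dff=values, mean_corrected=float(meta.get("mean_corrected", "nan")),
            fit=fit, source_rate_hz=rate, settling_mask=mask,
            mode=meta.get("dff_mode", "session-mean"), t0_s=t0,
        )
    wl = meta.get("wavelength_nm")
    lp = meta.get("lowpass_hz")
    sm = meta.get("source_mean")
    return ChannelTrace(
        values=values, sample_rate_hz=rate,
        wavelength_nm=int(wl) if wl not in (None, "None") else None,
        lowpass_hz=float(lp) if lp not in (None, "None") else None,
        settling_mask=mask, t0_s=t0,
        source_mean=float(sm) if sm not in (None, "None") else None,
    )


# -------------------------------------------------------------------- events

def write_events(path, events: EventTrain):
    with open(path, "w") as fh:
        _write_meta(fh, "events", {"session_duration_s": events.session_duration_s})
        if events.durations_s is None:
            fh.write("onset_s\n")
            for t in events.onsets_s:
                fh.write(f"{t:.6f}\n")
        else:
            fh.write("onset_s,duration_s\n")
            for t, d in zip(events.onsets_s, events.durations_s):
                fh.write(f"{t:.6f},{d:.6f}\n")


def read_events(path, session_duration_s: float | None = None) -> EventTrain:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    meta, _ = _read_meta(path)
    onsets, durations = [], []
    header = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                if header[0] != "onset_s":
                    raise ParseError("event file must start with an onset_s column",
                                     line=lineno, column=header[0])
                continue
            parts = line.split(",")
            try:
                onset = float(parts[0])
            except ValueError:
                raise ParseError("non-numeric onset", line=lineno, column="onset_s")
            if onsets and onset <= onsets[-1]:
                raise ParseError(
                    f"onset {onset} is not greater than the previous onset {onsets[-1]}",
                    line=lineno, column="onset_s",
                )
            onsets.append(onset)
            if len(header) > 1:
                if len(parts) < 2:
                    raise ParseError("missing duration", line=lineno, column="duration_s")
                try:
                    durations.append(float(parts[1]))
                except ValueError:
                    raise ParseError("non-numeric duration", line=lineno, column="duration_s")
    if session_duration_s is None:
        if "session_duration_s" in meta:
            session_duration_s = float(meta["session_duration_s"])
        else:
            session_duration_s = onsets[-1] if onsets else 1.0
    try:
        return EventTrain(
            onsets_s=np.asarray(onsets),
            durations_s=np.asarray(durations) if durations else None,
            session_duration_s=session_duration_s,
        )
    except ConfigurationError as exc:
        raise ParseError(f"invalid event train in {path}: {exc}") from exc


# ----------------------------------------------------------------- occupancy

def write_occupancy(path, rec: OccupancyRecord, dialect: str = "interval"):
    with open(path, "w") as fh:
        _write_meta(fh, "occupancy", {
            "zone_set": sorted(str(z) for z in rec.zone_set),
            "session_id": rec.session_id or None, "phase": rec.phase,
            "session_end_s": float(rec.ends_s[-1]),
        })
        if dialect == "interval":
            fh.write("start_s,end_s,zone\n")
            for s, e, z in zip(rec.starts_s, rec.ends_s, rec.zones):
                fh.write(f"{s:.6f},{e:.6f},{z}\n")
        elif dialect == "sample":
            fh.write("time_s,zone\n")
            for s, z in zip(rec.starts_s, rec.zones):
                fh.write(f"{s:.6f},{z}\n")
        else:
            raise ConfigurationError(f"unknown occupancy dialect {dialect!r}")


def read_occupancy(path) -> OccupancyRecord:
    df, meta = _read_table(path, "occupancy")
    zone_set = json.loads(meta["zone_set"].replace("'", '"')) if "zone_set" in meta else None
    kw = {"session_id": meta.get("session_id", ""), "phase": meta.get("phase", "test")}
    n_header = len(meta) + 1
    try:
        if {"start_s", "end_s", "zone"} <= set(df.columns):
            return OccupancyRecord.from_intervals(
                _numeric(df, "start_s", path, n_header),
                _numeric(df, "end_s", path, n_header),
                df["zone"].astype(str).to_numpy(), zone_set=zone_set, **kw,
            )
        if {"time_s", "zone"} <= set(df.columns):
            end = float(meta["session_end_s"]) if "session_end_s" in meta else None
            return OccupancyRecord.from_samples(
                _numeric(df, "time_s", path, n_header),
                df["zone"].astype(str).to_numpy(),
                session_end_s=end, zone_set=zone_set, **kw,
            )
    except ConfigurationError as exc:
        raise ParseError(f"invalid occupancy record in {path}: {exc}") from exc
    raise ParseError(
        f"occupancy file {path} needs either (start_s, end_s, zone) or (time_s, zone) columns"
    )


# --------------------------------------------------------------- cell tables

def write_cell_table(path, table: CellTable):
    with open(path, "w") as fh:
        _write_meta(fh, "cells", {"thresholds": table.thresholds or None})
        table.data.to_csv(fh, index=False)


def read_cell_table(path) -> CellTable:
    df, meta = _read_table(path, "cell table")
    _require_columns(df, ["cell_id"], path, "cell table")
    thresholds = json.loads(meta["thresholds"].replace("'", '"')) if "thresholds" in meta else {}
    try:
        return CellTable(data=df, thresholds=thresholds)
    except (ConfigurationError, TypeError, ValueError) as exc:
        raise ParseError(f"invalid cell table in {path}: {exc}") from exc


# ------------------------------------------------------------------ matrices

def write_matrix(path, m: PeriEventMatrix):
    with open(path, "w") as fh:
        _write_meta(fh, "perievent-matrix", {
            "pre_s": m.pre_s, "post_s": m.post_s, "bin_s": m.bin_s, "units": m.units,
            "onsets_s": [float(x) for x in (m.onsets_s if m.onsets_s is not None else [])],
            "excluded_trials": [[int(i), r] for i, r in m.excluded_trials],
        })
        buf = _io.StringIO()
        np.savetxt(buf, m.values, fmt="%.17g", delimiter=",")
        fh.write(",".join(f"bin{i}" for i in range(m.n_bins)) + "\n")
        fh.write(buf.getvalue())


def read_matrix(path) -> PeriEventMatrix:
    df, meta = _read_table(path, "peri-event matrix")
    for key in ("pre_s", "post_s", "bin_s"):
        if key not in meta:
            raise ParseError(f"matrix file {path} lacks {key} header")
    onsets = json.loads(meta["onsets_s"]) if "onsets_s" in meta else None
    excluded = [tuple(x) for x in json.loads(meta.get("excluded_trials", "[]"))]
    return PeriEventMatrix(
        values=df.to_numpy(dtype=float),
        pre_s=float(meta["pre_s"]), post_s=float(meta["post_s"]),
        bin_s=float(meta["bin_s"]), units=meta.get("units", "dff"),
        onsets_s=np.asarray(onsets, float) if onsets is not None else None,
        excluded_trials=excluded,
    )
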