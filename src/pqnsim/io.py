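"""Readers and writers for traces, spike trains, and stimulus specs.

Traces go to CSV with header ``time,v,n,q,u,I_stim`` (columns the variant
lacks are omitted), one row per grid point, full-precision decimal floats
(repr round-trips IEEE doubles exactly).  Spike trains are single-column
CSV.  Stimulus programs are described either by compact CLI spec strings

    const:amp=<a>    step:t0=<s>,amp=<a>    pulse:t0=<s>,dur=<s>,amp=<a>

or by two-column breakpoint CSV files (time,amplitude).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .dynamics import StimulusProgram, Trace

__all__ = [
    "write_trace",
    "read_trace",
    "write_spikes",
    "read_spikes",
    "parse_stimulus_spec",
    "read_stimulus_csv",
    "TraceParseError",
]


class TraceParseError(ValueError):
    """Malformed trace/stimulus CSV; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def write_trace(trace: Trace, path: str | Path) -> None:
    cols = trace.columns()
    names = list(cols)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(names)
        for row in zip(*(cols[c] for c in names)):
            w.writerow([repr(float(x)) for x in row])


def read_trace(path: str | Path) -> Trace:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TraceParseError("empty file", line=1) from None
        required = {"time", "v", "n", "I_stim"}
        missing = required - set(header)
        if missing:
            raise TraceParseError(f"missing column(s): {', '.join(sorted(missing))}", line=1)
        idx = {name: header.index(name) for name in header}
        data: dict[str, list[float]] = {name: [] for name in header}
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise TraceParseError(
                    f"expected {len(header)} fields, got {len(row)}", line=lineno
                )
            for name in header:
                try:
                    data[name].append(float(row[idx[name]]))
                except ValueError:
                    raise TraceParseError(
                        f"bad float {row[idx[name]]!r} in column {name}", line=lineno
                    ) from None
    times = np.asarray(data["time"])
    meta = {"dt": float(times[1] - times[0]) if len(times) > 1 else 0.0,
            "source": str(path)}
    return Trace(
        times=times,
        v=np.asarray(data["v"]),
        n=np.asarray(data["n"]),
        q=np.asarray(data["q"]) if "q" in data else None,
        u=np.asarray(data["u"]) if "u" in data else None,
        stimulus=np.asarray(data["I_stim"]),
        meta=meta,
    )


def write_spikes(times, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["spike_time"])
        for t in times:
            w.writerow([repr(float(t))])


def read_spikes(path: str | Path) -> list[float]:
    out: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (lineno == 1 and not _is_float(row[0])):
                continue  # header or blank
            try:
                out.append(float(row[0]))
            except ValueError:
                raise TraceParseError(f"bad spike time {row[0]!r}", line=lineno) from None
    return out


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _parse_kv(body: str, spec: str) -> dict[str, float]:
    out: dict[str, float] = {}
    if not body:
        return out
    for item in body.split(","):
        if "=" not in item:
            raise ValueError(f"bad stimulus spec {spec!r}: expected key=value, got {item!r}")
        key, val = item.split("=", 1)
        try:
            out[key.strip()] = float(val)
        except ValueError:
            raise ValueError(f"bad stimulus spec {spec!r}: non-numeric {val!r}") from None
    return out


def parse_stimulus_spec(spec: str) -> StimulusProgram:
    """Parse a CLI stimulus string or a path to a breakpoint CSV."""
    if ":" not in spec:
        path = Path(spec)
        if path.exists():
            return read_stimulus_csv(path)
        raise ValueError(f"bad stimulus spec {spec!r} (not a known form or file)")
    kind, _, body = spec.partition(":")
    kv = _parse_kv(body, spec)
    try:
        if kind == "const":
            return StimulusProgram.constant(kv["amp"])
        if kind == "step":
            return StimulusProgram.step(kv["t0"], kv["amp"])
        if kind == "pulse":
            return StimulusProgram.pulse(kv["t0"], kv["dur"], kv["amp"])
    except KeyError as e:
        raise ValueError(f"stimulus spec {spec!r} missing key {e.args[0]!r}") from None
    raise ValueError(f"unknown stimulus kind {kind!r} (const/step/pulse or a CSV path)")


def read_stimulus_csv(path: str | Path) -> StimulusProgram:
    """Breakpoint file: two columns (time, amplitude), optional header."""
    bps: list[float] = []
    amps: list[float] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            if lineno == 1 and not _is_float(row[0]):
                continue
            if len(row) < 2:
                raise TraceParseError("need two columns: time,amplitude", line=lineno)
            try:
                bps.append(float(row[0]))
                amps.append(float(row[1]))
            except ValueError:
                raise TraceParseError(f"bad number in {row!r}", line=lineno) from None
    return StimulusProgram(tuple(bps), tuple(amps))
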