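"""CSV interchange for raw signals and epoch counts.

Raw-signal files follow ActiGraph raw-CSV conventions loosely: a
``#``-prefixed comment preamble carrying site, sample rate and provenance,
then ``timestamp,axis1,axis2,axis3`` rows with ISO-8601 timestamps and
values in g.  Epoch-count files are ``timestamp,axis1,axis2,axis3,vm``.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AccelTrace
from .counts import EpochCounts

__all__ = [
    "write_raw_csv",
    "read_raw_csv",
    "write_counts_csv",
    "read_counts_csv",
]

#: Arbitrary wall-clock origin for session-relative timestamps.
SESSION_EPOCH = dt.datetime(2018, 6, 1, 10, 0, 0)


def _to_wallclock(seconds: np.ndarray) -> pd.DatetimeIndex:
    return pd.DatetimeIndex([SESSION_EPOCH + dt.timedelta(seconds=float(s))
                             for s in seconds])


def write_raw_csv(trace: AccelTrace, path: str | Path,
                  provenance: list[str] | None = None) -> None:
    path = Path(path)
    header = [
        f"# toddleracc raw signal, site={trace.site}, sample_rate={trace.sample_rate} Hz, units=g",
    ] + [f"# {line}" for line in (provenance or [])]
    df = pd.DataFrame(trace.samples, columns=["axis1", "axis2", "axis3"])
    df.insert(0, "timestamp", _to_wallclock(trace.times()).strftime("%Y-%m-%dT%H:%M:%S.%f"))
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False)


def read_raw_csv(path: str | Path, site: str | None = None) -> AccelTrace:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line.lstrip("# ").strip().split(", "):
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#")
    required = {"timestamp", "axis1", "axis2", "axis3"}
    if not required <= set(df.columns):
        raise ValueError(f"raw CSV missing columns: {sorted(required - set(df.columns))}")
    ts = pd.to_datetime(df["timestamp"])
    start = (ts.iloc[0] - SESSION_EPOCH).total_seconds()
    if len(ts) > 1:
        sample_rate = 1.0 / np.median(np.diff(ts.astype("int64")) / 1e9)
    else:
        sample_rate = float(meta.get("sample_rate", "30 Hz").split()[0])
    if "sample_rate" in meta:
        sample_rate = float(meta["sample_rate"].split()[0])
    return AccelTrace(
        site=site or meta.get("site", "hip"),
        sample_rate=round(sample_rate, 6),
        samples=df[["axis1", "axis2", "axis3"]].to_numpy(dtype=float),
        start_time=round(start, 6),
    )


def write_counts_csv(counts: EpochCounts, path: str | Path,
                     provenance: list[str] | None = None) -> None:
    path = Path(path)
    header = [
        f"# toddleracc epoch counts, epoch_length={counts.epoch_length} s",
    ] + [f"# {line}" for line in (provenance or [])]
    df = counts.to_frame()
    df["timestamp"] = _to_wallclock(df["timestamp"].to_numpy()).strftime("%Y-%m-%dT%H:%M:%S")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False)


def read_counts_csv(path: str | Path) -> EpochCounts:
    path = Path(path)
    epoch_length = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "epoch_length=" in first:
            epoch_length = float(first.split("epoch_length=")[1].split()[0])
    df = pd.read_csv(path, comment="#")
    ts = pd.to_datetime(df["timestamp"])
    if epoch_length is None:
        if len(ts) < 2:
            raise ValueError("cannot infer epoch length from a single row")
        epoch_length = float((ts.iloc[1] - ts.iloc[0]).total_seconds())
    start = (ts.iloc[0] - SESSION_EPOCH).total_seconds()
    return EpochCounts(
        epoch_length=epoch_length,
        counts=df[["axis1", "axis2", "axis3"]].to_numpy(dtype=np.int64),
        start_time=round(start, 6),
    )
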