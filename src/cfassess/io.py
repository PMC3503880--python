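"""Reading and writing recordings: EDF, BrainVision, and a CSV fixture dialect.

The EDF support is a deliberately small, self-contained implementation of the
16-bit European Data Format (one data record per second).  Events always
travel in a sidecar TSV (``<stem>.events.tsv`` with columns
``onset_sample<TAB>condition``) because classic EDF has no annotation stream.

The CSV dialect is: a header row of channel labels, one row per sample,
values in microvolts, written with enough digits to round-trip float64
exactly.  Its sampling rate lives in a ``<stem>.meta.json`` sidecar.
"""

from __future__ import annotations

import configparser
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .core import RawRecording, events_frame

__all__ = [
    "write_recording",
    "read_recording",
    "read_edf",
    "write_edf",
    "read_csv_recording",
    "write_csv_recording",
    "read_brainvision",
    "read_events_tsv",
    "write_events_tsv",
]

_DIG_MAX = 32767


def _events_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".events.tsv") if path.suffix == "" else path.with_name(path.stem + ".events.tsv")


def write_events_tsv(events: pd.DataFrame, path) -> None:
    events[["onset_sample", "condition"]].to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"condition": str})
    if len(df) == 0:
        return events_frame([], [])
    return events_frame(df["onset_sample"].to_numpy(), df["condition"].to_numpy())


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(recording: RawRecording, path) -> Path:
    """Write a 16-bit EDF file plus the events sidecar TSV.

    The physical range is chosen symmetrically to cover the signal, so the
    round-trip error is at most one quantisation step.  The final data record
    is padded by repeating the last sample; readers should trust the sidecar
    or the caller for the exact length.
    """
    path = Path(path)
    data = recording.data
    if not np.all(np.isfinite(data)):
        raise ValueError("cannot write non-finite samples to EDF")
    sfreq = recording.sfreq
    spr = sfreq  # one-second records
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(spr))
    n_ch = recording.n_channels
    n_records = max(1, math.ceil(recording.n_samples / spr))

    amax = float(np.abs(data).max()) if data.size else 1.0
    phys = max(amax * 1.0001, 1e-6)
    pmin, pmax = -phys, phys

    header = b""
    header += _ascii("0", 8)
    header += _ascii("synthetic", 80)
    header += _ascii("cfassess", 80)
    header += _ascii("01.01.00", 8)
    header += _ascii("00.00.00", 8)
    header += _ascii(256 * (1 + n_ch), 8)
    header += _ascii("", 44)
    header += _ascii(n_records, 8)
    header += _ascii(1, 8)  # record duration, seconds
    header += _ascii(n_ch, 4)

    def field(values, width):
        return b"".join(_ascii(v, width) for v in values)

    header += field(recording.ch_names, 16)
    header += field([""] * n_ch, 80)  # transducer
    header += field(["uV"] * n_ch, 8)
    header += field([f"{pmin:.6g}"] * n_ch, 8)
    header += field([f"{pmax:.6g}"] * n_ch, 8)
    header += field([-_DIG_MAX] * n_ch, 8)
    header += field([_DIG_MAX] * n_ch, 8)
    header += field([""] * n_ch, 80)  # prefiltering
    header += field([spr] * n_ch, 8)
    header += field([""] * n_ch, 32)

    padded = np.empty((n_ch, n_records * spr))
    padded[:, : recording.n_samples] = data
    if n_records * spr > recording.n_samples:
        padded[:, recording.n_samples:] = data[:, -1:]
    scale = (pmax - pmin) / (2 * _DIG_MAX)
    digital = np.round(padded / scale).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        # records are channel-blocked: rec0ch0, rec0ch1, ..., rec1ch0, ...
        fh.write(
            digital.reshape(n_ch, n_records, spr)
            .transpose(1, 0, 2)
            .tobytes()
        )
    write_events_tsv(recording.events, _events_path(path))
    return path


def read_edf(path, n_samples: int | None = None) -> RawRecording:
    """Read an EDF file written by :func:`write_edf` (or any 16-bit EDF with a
    uniform sampling rate).  ``n_samples`` optionally trims record padding."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_records = int(head[236:244].decode().strip())
        record_dur = float(head[244:252].decode().strip())
        n_ch = int(head[252:256].decode().strip())
        sig = fh.read(256 * n_ch)

        def fields(offset, width):
            base = offset * n_ch
            return [
                sig[base + i * width: base + (i + 1) * width].decode().strip()
                for i in range(n_ch)
            ]

        labels = fields(0, 16)
        pmins = [float(v) for v in fields(16 + 80 + 8, 8)]
        pmaxs = [float(v) for v in fields(16 + 80 + 8 + 8, 8)]
        dmins = [int(v) for v in fields(16 + 80 + 8 + 16, 8)]
        dmaxs = [int(v) for v in fields(16 + 80 + 8 + 24, 8)]
        sprs = [int(v) for v in fields(16 + 80 + 8 + 4 * 8 + 80, 8)]
        if len(set(sprs)) != 1:
            raise ValueError("mixed per-signal sampling rates are unsupported")
        spr = sprs[0]
        raw = np.frombuffer(fh.read(n_records * n_ch * spr * 2), dtype="<i2")

    raw = raw.reshape(n_records, n_ch, spr).transpose(1, 0, 2).reshape(n_ch, -1)
    data = np.empty(raw.shape)
    for ci in range(n_ch):
        scale = (pmaxs[ci] - pmins[ci]) / (dmaxs[ci] - dmins[ci])
        offset = pmaxs[ci] - scale * dmaxs[ci]
        data[ci] = raw[ci] * scale + offset
    if n_samples is not None:
        data = data[:, :n_samples]
    sfreq = spr / record_dur

    ev_path = _events_path(path)
    events = read_events_tsv(ev_path) if ev_path.exists() else events_frame([], [])
    return RawRecording(data, sfreq, labels, events)


# ---------------------------------------------------------------------------
# CSV fixture dialect
# ---------------------------------------------------------------------------

def write_csv_recording(recording: RawRecording, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(",".join(recording.ch_names) + "\n")
        np.savetxt(fh, recording.data.T, fmt="%.17g", delimiter=",")
    with open(path.with_name(path.stem + ".meta.json"), "w") as fh:
        json.dump({"sampling_rate": recording.sfreq}, fh)
    write_events_tsv(recording.events, _events_path(path))
    return path


def read_csv_recording(path, sfreq: float | None = None) -> RawRecording:
    path = Path(path)
    if sfreq is None:
        meta = path.with_name(path.stem + ".meta.json")
        if not meta.exists():
            raise ValueError("sampling rate not given and no .meta.json sidecar found")
        sfreq = float(json.loads(meta.read_text())["sampling_rate"])
    with open(path) as fh:
        labels = fh.readline().strip().split(",")
        data = np.loadtxt(fh, delimiter=",", ndmin=2).T
    ev_path = _events_path(path)
    events = read_events_tsv(ev_path) if ev_path.exists() else events_frame([], [])
    return RawRecording(data, sfreq, labels, events)


# ---------------------------------------------------------------------------
# BrainVision (reader only)
# ---------------------------------------------------------------------------

_BV_DTYPES = {"IEEE_FLOAT_32": "<f4", "INT_16": "<i2", "INT_32": "<i4"}


def read_brainvision(vhdr_path) -> RawRecording:
    """Read a binary multiplexed BrainVision triplet (.vhdr/.eeg/.vmrk).

    Stimulus marker descriptions become event conditions verbatim (leading
    ``S``-codes are kept as-is; map them downstream if needed).
    """
    vhdr_path = Path(vhdr_path)
    cp = configparser.ConfigParser(strict=False)
    text = vhdr_path.read_text(encoding="utf-8", errors="replace")
    cp.read_string(text[text.index("["):])

    common = cp["Common Infos"]
    if common.get("DataFormat", "BINARY").upper() != "BINARY":
        raise ValueError("only binary BrainVision data is supported")
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise ValueError("only multiplexed orientation is supported")
    n_ch = int(common["NumberOfChannels"])
    sfreq = 1e6 / float(common["SamplingInterval"])
    fmt = cp["Binary Infos"]["BinaryFormat"].upper()
    if fmt not in _BV_DTYPES:
        raise ValueError(f"unsupported BinaryFormat {fmt!r}")

    labels, resolutions = [], []
    for i in range(1, n_ch + 1):
        parts = cp["Channel Infos"][f"Ch{i}"].split(",")
        labels.append(parts[0])
        res = parts[2] if len(parts) > 2 and parts[2] else "1"
        resolutions.append(float(res))

    raw = np.fromfile(vhdr_path.with_name(common["DataFile"]), dtype=_BV_DTYPES[fmt])
    data = raw.reshape(-1, n_ch).T.astype(np.float64)
    data *= np.asarray(resolutions)[:, None]

    onsets, conds = [], []
    marker_file = common.get("MarkerFile")
    if marker_file:
        mp = vhdr_path.with_name(marker_file)
        if mp.exists():
            mcp = configparser.ConfigParser(strict=False)
            mtext = mp.read_text(encoding="utf-8", errors="replace")
            mcp.read_string(mtext[mtext.index("["):])
            for key, value in mcp["Marker Infos"].items():
                parts = value.split(",")
                if parts[0].strip().lower() != "stimulus":
                    continue
                onsets.append(int(parts[2]) - 1)  # BrainVision is 1-based
                conds.append(parts[1].strip())
    order = np.argsort(onsets, kind="stable") if onsets else []
    events = events_frame(
        np.asarray(onsets, dtype=np.int64)[order] if len(onsets) else [],
        np.asarray(conds, dtype=object)[order] if len(conds) else [],
    )
    return RawRecording(data, sfreq, labels, events)


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def write_recording(recording: RawRecording, path, format: str = "edf") -> Path:
    """Write ``recording`` to ``path`` as ``'edf'`` or ``'csv'``."""
    fmt = format.lower()
    if fmt == "edf":
        return write_edf(recording, path)
    if fmt == "csv":
        return write_csv_recording(recording, path)
    raise ValueError(f"unknown format {format!r} (use 'edf' or 'csv')")


def read_recording(path, **kwargs) -> RawRecording:
    """Read a recording, dispatching on the file extension."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".edf":
        return read_edf(path, **kwargs)
    if ext in (".csv", ".tsv"):
        return read_csv_recording(path, **kwargs)
    if ext == ".vhdr":
        return read_brainvision(path)
    raise ValueError(f"cannot infer format from extension {ext!r}")
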