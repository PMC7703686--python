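"""Plain-text waveform and annotation file formats.

The waveform file is a CSV with a structured comment header::

    # autoreg-waveform v1
    # fs_hz: 125.0
    # start_s: 0.0
    # channels: abp:mmHg,fvl:cm/s,fvr:cm/s
    # meta: {"config_digest": "..."}
    time_s,abp,fvl,fvr
    0.000000,91.23,54.1,55.7

Values are written with 17 significant digits so that read(write(x)) is
bit-exact for finite float64 values.  Missing samples are empty fields and
come back masked.  Time is seconds from recording start (0-based) and must
advance uniformly at 1/fs within 1e-6 s.

Compression-episode annotations are CSVs with columns side,start_s,end_s
(half-open intervals, seconds from recording start).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .recording import CHANNEL_UNITS, WaveformRecording

MAGIC = "# autoreg-waveform v1"
TIME_TOL_S = 1e-6


class ParseError(ValidationError):
    """Malformed waveform or annotation file."""


def write_waveform(rec: WaveformRecording, path: Union[str, Path]) -> None:
    """Write a recording to the tabular waveform format."""
    path = Path(path)
    names = list(rec.channels)
    header_channels = ",".join(
        f"{n}:{CHANNEL_UNITS.get(n, 'unknown')}" for n in names
    )
    meta = {
        k: v
        for k, v in rec.meta.items()
        if isinstance(v, (str, int, float, bool))
    }
    t = rec.times
    cols = [np.char.mod("%.6f", t)]
    for n in names:
        x = rec.channels[n]
        col = np.char.mod("%.17g", x)
        col = np.where(np.isfinite(x), col, "")
        cols.append(col)
    body = "\n".join(",".join(row) for row in zip(*cols))
    with open(path, "w") as fh:
        fh.write(MAGIC + "\n")
        fh.write(f"# fs_hz: {rec.fs!r}\n")
        fh.write(f"# start_s: {rec.start_s!r}\n")
        fh.write(f"# channels: {header_channels}\n")
        fh.write(f"# meta: {json.dumps(meta, sort_keys=True)}\n")
        fh.write("time_s," + ",".join(names) + "\n")
        fh.write(body + "\n")


def read_waveform(path: Union[str, Path]) -> WaveformRecording:
    """Read a waveform file; missing values come back masked.

    Raises :class:`ParseError` naming the offending line for malformed
    headers, unit mismatches, or timestamps inconsistent with the declared
    sampling rate.
    """
    path = Path(path)
    header: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != MAGIC:
            raise ParseError(f"{path}:1: not a waveform file (missing {MAGIC!r})")
        n_header = 1
        for line in fh:
            n_header += 1
            line = line.rstrip("\n")
            if not line.startswith("#"):
                column_line = line
                break
            try:
                key, value = line[1:].split(":", 1)
            except ValueError:
                raise ParseError(f"{path}:{n_header}: malformed header line {line!r}")
            header[key.strip()] = value.strip()
        else:
            raise ParseError(f"{path}: no column header found")
    for req in ("fs_hz", "channels"):
        if req not in header:
            raise ParseError(f"{path}: header missing {req!r}")
    try:
        fs = float(header["fs_hz"])
        start_s = float(header.get("start_s", "0"))
    except ValueError as exc:
        raise ParseError(f"{path}: bad numeric header field: {exc}")
    declared_units: dict[str, str] = {}
    for item in header["channels"].split(","):
        try:
            name, unit = item.split(":")
        except ValueError:
            raise ParseError(f"{path}: malformed channels header entry {item!r}")
        declared_units[name.strip()] = unit.strip()
    for name, unit in declared_units.items():
        expected = CHANNEL_UNITS.get(name)
        if expected is not None and unit != expected:
            raise ParseError(
                f"{path}: unit mismatch for channel {name!r}: "
                f"declared {unit!r}, expected {expected!r}"
            )

    columns = column_line.split(",")
    if columns[0] != "time_s":
        raise ParseError(f"{path}:{n_header}: first column must be time_s")
    names = columns[1:]
    if set(names) != set(declared_units):
        raise ParseError(
            f"{path}: column names {names} do not match channels header "
            f"{sorted(declared_units)}"
        )
    df = pd.read_csv(path, comment="#", header=0, dtype=np.float64,
                     float_precision="round_trip")
    t = df["time_s"].to_numpy()
    if len(t) == 0:
        raise ParseError(f"{path}: no samples")
    expected_t = start_s + np.arange(len(t)) / fs
    bad = np.flatnonzero(np.abs(t - expected_t) > TIME_TOL_S)
    if len(bad):
        line_no = n_header + 1 + int(bad[0])
        raise ParseError(
            f"{path}:{line_no}: timestamp {t[bad[0]]!r} inconsistent with "
            f"fs={fs} Hz (expected {expected_t[bad[0]]!r})"
        )
    channels = {}
    masks = {}
    for name in names:
        x = df[name].to_numpy(dtype=np.float64)
        channels[name] = x
        masks[name] = ~np.isfinite(x)
    meta = {}
    if "meta" in header:
        try:
            meta = json.loads(header["meta"])
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: malformed meta header: {exc}")
    meta.setdefault("source_file", str(path))
    return WaveformRecording(channels=channels, fs=fs, start_s=start_s,
                             masks=masks, meta=meta)


# --- annotations ------------------------------------------------------------

def write_annotations(
    intervals: Sequence[dict], path: Union[str, Path]
) -> None:
    """Write compression-episode annotations (side, start_s, end_s)."""
    df = pd.DataFrame(intervals, columns=["side", "start_s", "end_s"])
    df.to_csv(path, index=False)


def read_annotations(path: Union[str, Path]) -> list[dict]:
    df = pd.read_csv(path)
    required = {"side", "start_s", "end_s"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: annotation file needs columns {sorted(required)}")
    out = []
    for i, row in df.iterrows():
        side = str(row["side"]).lower()
        if side not in ("left", "right"):
            raise ParseError(f"{path}: row {i}: side must be left/right, got {side!r}")
        start, end = float(row["start_s"]), float(row["end_s"])
        if end <= start:
            raise ParseError(f"{path}: row {i}: end_s must exceed start_s")
        out.append({"side": side, "start_s": start, "end_s": end})
    return out


def write_truth_sidecar(rec: WaveformRecording, path: Union[str, Path],
                        artefact_truth: Optional[dict] = None) -> None:
    """Write generator ground truth (coupling gain, episode intervals,
    artefact-mask runs) to a JSON sidecar next to a waveform file."""
    payload: dict = {
        "coupling_gain": rec.meta.get("coupling_gain"),
        "seed": rec.meta.get("seed"),
        "config_digest": rec.meta.get("config_digest"),
        "thrt_truth": rec.meta.get("thrt_truth"),
    }
    if artefact_truth is not None:
        runs = {}
        for name, mask in artefact_truth.items():
            idx = np.flatnonzero(np.diff(np.r_[0, mask.astype(np.int8), 0]))
            runs[name] = [[int(a), int(b)] for a, b in zip(idx[::2], idx[1::2])]
        payload["artefact_mask_runs"] = runs
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
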