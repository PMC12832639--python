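"""Reading and writing the formats the pipeline touches.

EDF support is deliberately minimal: classic EDF (not EDF+), 16-bit
samples, one data record per second, physical range set per channel
from the data extremes.  That dialect is sufficient for resting-state
recordings and round-trips within one 16-bit quantization step.

Feature tables are CSV with a comment header documenting the sex
encoding (male = 1, female = 0).
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .montage import Montage, standard_1020
from .recording import EEGRecording, validate_feature_table

_HEADER_FIXED = 256
_HEADER_PER_SIGNAL = 256

SEX_ENCODING_NOTE = "# sex: male=1, female=0; outcome: 1=PSCI-like"


class EDFParseError(ValueError):
    """Malformed EDF header, naming the offending field."""


def _field(raw: bytes, start: int, length: int) -> str:
    return raw[start:start + length].decode("ascii", errors="replace").strip()


def _num(raw: bytes, start: int, length: int, name: str, cast=float):
    text = _field(raw, start, length)
    try:
        return cast(text)
    except ValueError as exc:
        raise EDFParseError(
            f"EDF header field {name!r} is not numeric: {text!r}") from exc


def write_edf(recording: EEGRecording, path) -> None:
    """Write a recording as classic EDF (16-bit, 1 s data records).

    Requires an integer sampling rate.  A final partial record is
    zero-padded on disk; the true sample count is stored in the
    reserved header field and honoured by :func:`read_edf`.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samples = recording.data.shape
    n_records = int(np.ceil(n_samples / fs))

    pmin = recording.data.min(axis=1)
    pmax = recording.data.max(axis=1)
    flat = pmax - pmin <= 0
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)

    def pad(text, width):
        b = str(text)[:width].encode("ascii")
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8),
        pad(recording.subject_id or "X", 80),
        pad("Startdate 01-JAN-2000", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(_HEADER_FIXED + _HEADER_PER_SIGNAL * n_ch, 8),
        pad(f"n_samples={n_samples}", 44),
        pad(n_records, 8), pad(1, 8), pad(n_ch, 4),
    ])
    names = recording.montage.channel_names
    header += b"".join(pad(nm, 16) for nm in names)
    header += b"".join(pad("AgAgCl electrode", 80) for _ in names)
    header += b"".join(pad("uV", 8) for _ in names)
    header += b"".join(pad(f"{v:.8g}"[:8], 8) for v in pmin)
    header += b"".join(pad(f"{v:.8g}"[:8], 8) for v in pmax)
    header += b"".join(pad(dmin, 8) for _ in names)
    header += b"".join(pad(dmax, 8) for _ in names)
    header += b"".join(pad("", 80) for _ in names)
    header += b"".join(pad(fs, 8) for _ in names)
    header += b"".join(pad("", 32) for _ in names)

    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :n_samples] = recording.data
    digital = np.round(
        (padded - pmin[:, None]) / scale[:, None] + dmin).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())


def read_edf(path, montage: Montage | None = None) -> EEGRecording:
    """Read a classic EDF file into an :class:`EEGRecording`.

    Channels are reordered by name into the montage's canonical order
    (default: the standard 19-channel 10-20 montage).  If the on-disk
    channel set does not match the montage, an explicit ``montage`` of
    matching size must be supplied.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_FIXED:
        raise EDFParseError("file too short to contain an EDF header")
    header_bytes = _num(raw, 184, 8, "header bytes", int)
    n_records = _num(raw, 236, 8, "number of data records", int)
    record_dur = _num(raw, 244, 8, "record duration")
    n_sig = _num(raw, 252, 4, "number of signals", int)
    if n_sig <= 0:
        raise EDFParseError("number of signals must be positive")
    if record_dur <= 0:
        raise EDFParseError("record duration must be positive")
    sig = raw[_HEADER_FIXED:header_bytes]
    if len(sig) < _HEADER_PER_SIGNAL * n_sig:
        raise EDFParseError("truncated per-signal header block")

    def sig_fields(offset, width):
        base = offset * n_sig
        return [sig[base + i * width: base + (i + 1) * width] for i in range(n_sig)]

    labels = [b.decode("ascii", errors="replace").strip()
              for b in sig_fields(0, 16)]

    def sig_nums(char_offset, width, name):
        base = char_offset * n_sig
        out = []
        for i in range(n_sig):
            chunk = sig[base + i * width: base + (i + 1) * width]
            text = chunk.decode("ascii", errors="replace").strip()
            try:
                out.append(float(text))
            except ValueError as exc:
                raise EDFParseError(
                    f"EDF signal field {name!r} is not numeric: {text!r}"
                ) from exc
        return np.array(out)

    pmin = sig_nums(16 + 80 + 8, 8, "physical minimum")
    pmax = sig_nums(16 + 80 + 8 + 8, 8, "physical maximum")
    dmin = sig_nums(16 + 80 + 8 + 8 + 8, 8, "digital minimum")
    dmax = sig_nums(16 + 80 + 8 + 8 + 8 + 8, 8, "digital maximum")
    spr = sig_nums(16 + 80 + 8 * 5 + 80, 8, "samples per record").astype(int)
    if len(set(spr)) != 1:
        raise EDFParseError("channels with differing sampling rates")
    fs = spr[0] / record_dur

    body = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    expected = n_records * int(spr.sum())
    if body.size < expected:
        raise EDFParseError("data section shorter than header declares")
    body = body[:expected].reshape(n_records, n_sig, spr[0])
    digital = body.transpose(1, 0, 2).reshape(n_sig, -1).astype(np.float64)
    scale = (pmax - pmin) / (dmax - dmin)
    data = (digital - dmin[:, None]) * scale[:, None] + pmin[:, None]

    reserved = _field(raw, 192, 44)
    if reserved.startswith("n_samples="):
        try:
            data = data[:, :int(reserved.split("=", 1)[1])]
        except ValueError:
            pass

    montage = montage or standard_1020()
    if set(labels) == set(montage.channel_names):
        order = [labels.index(nm) for nm in montage.channel_names]
        data = data[order]
    elif n_sig != montage.n_channels:
        raise EDFParseError(
            f"{n_sig} signals do not match the {montage.n_channels}-channel "
            "montage; pass an explicit montage")
    subject_id = _field(raw, 8, 80)
    return EEGRecording(data=data, fs=fs, montage=montage,
                        subject_id=subject_id)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as CSV (10 significant digits), with a
    comment line documenting the sex/outcome encoding."""
    with open(path, "w") as fh:
        fh.write(SEX_ENCODING_NOTE + "\n")
        table.to_csv(fh, index=False, float_format="%.10g")


def read_feature_table(path, require_outcome: bool = True) -> pd.DataFrame:
    """Read a feature-table CSV, validating that all 26 candidate
    predictors (and the outcome, unless disabled) are present.  Unknown
    extra columns are preserved."""
    table = pd.read_csv(path, comment="#")
    validate_feature_table(table, require_outcome=require_outcome)
    return table


def write_cohort(recordings, metadata: pd.DataFrame, out_dir) -> Path:
    """Write a cohort as one EDF per subject plus a subjects.csv
    (subject_id, group, age, sex, outcome)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_edf(rec, out / f"{rec.subject_id}.edf")
    with open(out / "subjects.csv", "w") as fh:
        fh.write(SEX_ENCODING_NOTE + "\n")
        metadata.to_csv(fh, index=False)
    return out


def read_cohort(in_dir, montage: Montage | None = None):
    """Read back a cohort directory written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    metadata = pd.read_csv(in_dir / "subjects.csv", comment="#")
    recordings = [read_edf(in_dir / f"{sid}.edf", montage=montage)
                  for sid in metadata["subject_id"]]
    return recordings, metadata


def load_config(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(_io.StringIO(text))


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default))
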