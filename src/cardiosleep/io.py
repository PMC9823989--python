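"""Readers and writers for on-disk artifacts.

Formats are deliberately plain text:

* RR series — two delimited columns, beat time in seconds and interval in
  milliseconds; ``#`` starts a comment; comma or whitespace delimited; an
  optional header line is skipped.
* Hypnograms — CSV with columns ``epoch_index,label``.  Labels outside the
  four-stage alphabet are collapsed through a mapping
  (default ``N1,N2 -> L``; ``N3 -> D``; ``REM -> R``).
* Feature tables — CSV keyed by ``(record_id, epoch_index)``.
* ECG — single-column text plus a stated sampling rate (either a ``rate=``
  argument or a ``# rate: <Hz>`` comment in the file).
* Model bundles — a single JSON document holding every fitted parameter.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import Hypnogram, RRSeries, STAGES

#: Default collapse of five-stage AASM labels onto the four-stage alphabet.
DEFAULT_LABEL_MAP: dict[str, str] = {
    "W": "W",
    "R": "R",
    "L": "L",
    "D": "D",
    "N1": "L",
    "N2": "L",
    "N3": "D",
    "REM": "R",
}


class ParseError(ValueError):
    """Raised when an on-disk artifact cannot be parsed."""


def _split_line(line: str) -> list[str]:
    line = line.strip()
    if "," in line:
        return [f.strip() for f in line.split(",")]
    return line.split()


def read_rr(path: str | Path, record_id: str | None = None) -> RRSeries:
    """Read a two-column RR text file (time s, interval ms).

    Comment lines start with ``#``; a non-numeric first row is treated as a
    header and skipped.  Beat times must be strictly increasing.
    """
    path = Path(path)
    times: list[float] = []
    intervals: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_line(line)
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                t, rr = float(fields[0]), float(fields[1])
            except ValueError:
                if not times:  # header row
                    continue
                raise ParseError(f"{path}:{lineno}: non-numeric row {line!r}")
            if times and t <= times[-1]:
                raise ParseError(
                    f"{path}:{lineno}: beat time {t} not after previous {times[-1]}"
                )
            times.append(t)
            intervals.append(rr)
    if not times:
        raise ParseError(f"{path}: no beats found")
    return RRSeries(
        np.asarray(times), np.asarray(intervals), record_id=record_id or path.stem
    )


def write_rr(rr: RRSeries, path: str | Path) -> None:
    """Write an RR series as two-column comma-delimited text.

    Only valid beats are written, so ``read_rr(write_rr(x))`` round-trips
    the valid subset losslessly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# beat_time_s,interval_ms\n")
        for t, iv in zip(rr.beat_time[rr.valid], rr.interval[rr.valid]):
            fh.write(f"{t:.6f},{iv:.6f}\n")


def read_hypnogram(
    path: str | Path,
    label_map: Mapping[str, str] | None = None,
    source: str = "annotation",
) -> Hypnogram:
    """Read a per-epoch hypnogram CSV (``epoch_index,label``).

    ``label_map`` collapses extended stage alphabets onto ``{W,R,L,D}``;
    the default maps N1/N2 to light sleep and N3 to deep sleep.  An
    unmapped label raises with the offending name.
    """
    path = Path(path)
    mapping = dict(DEFAULT_LABEL_MAP if label_map is None else label_map)
    rows: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_line(line)
            if len(fields) == 1:
                idx, lab = len(rows), fields[0]
            else:
                try:
                    idx = int(fields[0])
                except ValueError:
                    if not rows:
                        continue
                    raise ParseError(f"{path}:{lineno}: bad epoch index {fields[0]!r}")
                lab = fields[1]
            lab = lab.strip().upper()
            if lab not in mapping:
                raise ParseError(
                    f"{path}:{lineno}: unknown stage label {lab!r} "
                    f"(known: {sorted(mapping)})"
                )
            rows.append((idx, mapping[lab]))
    if not rows:
        raise ParseError(f"{path}: no epochs found")
    rows.sort(key=lambda r: r[0])
    return Hypnogram(np.asarray([lab for _, lab in rows]), source=source)


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch_index,label\n")
        for i, lab in enumerate(hyp.labels):
            fh.write(f"{i},{lab}\n")


def read_ecg(path: str | Path, rate: float | None = None) -> tuple[np.ndarray, float]:
    """Read a single-column text ECG waveform; return ``(signal, rate_hz)``.

    The sampling rate must be supplied either as the ``rate`` argument or
    as a ``# rate: <Hz>`` comment line in the file; a missing rate raises.
    """
    path = Path(path)
    samples: list[float] = []
    file_rate: float | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                low = line.lstrip("#").strip().lower()
                if low.startswith("rate"):
                    file_rate = float(low.split(":", 1)[1]) if ":" in low else float(
                        low.split("=", 1)[1]
                    )
                continue
            samples.append(float(_split_line(line)[0]))
    rate = rate if rate is not None else file_rate
    if rate is None:
        raise ParseError(f"{path}: sampling rate not stated (pass rate= or add '# rate: <Hz>')")
    if not samples:
        raise ParseError(f"{path}: empty waveform")
    return np.asarray(samples), float(rate)


def write_ecg(signal: np.ndarray, rate: float, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# rate: {rate}\n")
        np.savetxt(fh, np.asarray(signal), fmt="%.6f")


# ---------------------------------------------------------------------------
# Feature tables


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature-table CSV indexed by ``(record_id, epoch_index)``."""
    df = pd.read_csv(path)
    if not {"record_id", "epoch_index"} <= set(df.columns):
        raise ParseError(f"{path}: feature table needs record_id and epoch_index columns")
    return df.set_index(["record_id", "epoch_index"])


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=True)


# ---------------------------------------------------------------------------
# Model bundles


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def save_bundle(bundle: dict, path: str | Path) -> None:
    """Serialise a model-parameter bundle as a single JSON document."""
    with open(path, "w") as fh:
        json.dump(_jsonify(bundle), fh, indent=1)
        fh.write("\n")


def load_bundle(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
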