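"""Core in-memory containers for RR-interval sleep analysis.

The substrate of the whole pipeline is a night of heartbeats: an
:class:`RRSeries` holds the beat times and the intervals between them,
with a per-beat validity flag so that artifact rejection never destroys
data.  Sleep structure is carried by a :class:`Hypnogram`, a sequence of
30-second epochs labelled with one of four stages:

* ``W`` — wakefulness
* ``R`` — REM sleep
* ``L`` — light sleep (AASM stages N1 and N2 collapsed)
* ``D`` — deep sleep (stage N3)

Feature extraction operates on :class:`AnalysisWindow` objects: each
30-s epoch together with the 4-min-30-s stretch of beats centred on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

#: The canonical four-stage alphabet.
STAGES = ("W", "R", "L", "D")

#: Epoch length in seconds; fixed by the annotation convention.
EPOCH_LEN_S = 30.0

#: Feature-context window length: 4 min 30 s centred on the epoch.
WINDOW_LEN_S = 270.0


class RRSeriesError(ValueError):
    """Raised when an RR series violates its structural invariants."""


@dataclass
class RRSeries:
    """A night of heartbeats: beat times, RR intervals and validity flags.

    Parameters
    ----------
    beat_time : array of float
        Seconds from record start for each beat; strictly increasing.
    interval : array of float
        RR interval ending at each beat, in milliseconds; positive.
    valid : array of bool, optional
        Per-beat validity flag.  Defaults to all-valid.  Invalid beats are
        retained in the container but excluded from feature computation.
    record_id : str
    start_clock : str or None
        Optional wall-clock timestamp of the first sample.
    """

    beat_time: np.ndarray
    interval: np.ndarray
    valid: np.ndarray | None = None
    record_id: str = ""
    start_clock: str | None = None

    def __post_init__(self) -> None:
        self.beat_time = np.asarray(self.beat_time, dtype=float)
        self.interval = np.asarray(self.interval, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.beat_time.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.beat_time.ndim != 1:
            raise RRSeriesError("beat_time must be one-dimensional")
        if not (self.beat_time.shape == self.interval.shape == self.valid.shape):
            raise RRSeriesError("beat_time, interval and valid must share a shape")
        if self.beat_time.size == 0:
            raise RRSeriesError("empty RR series")
        dt = np.diff(self.beat_time)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 1
            raise RRSeriesError(
                f"beat times must be strictly increasing (violation at beat {bad})"
            )
        if np.any(self.interval <= 0):
            bad = int(np.argmax(self.interval <= 0))
            raise RRSeriesError(f"intervals must be positive (violation at beat {bad})")

    def __len__(self) -> int:
        return int(self.beat_time.size)

    @property
    def duration_s(self) -> float:
        """Record duration in seconds (time of the last beat)."""
        return float(self.beat_time[-1])

    def valid_intervals(self) -> np.ndarray:
        """Intervals (ms) of the valid beats only."""
        return self.interval[self.valid]

    def slice_time(self, t0: float, t1: float) -> "RRSeries":
        """Beats with ``t0 <= beat_time < t1`` as a new series."""
        m = (self.beat_time >= t0) & (self.beat_time < t1)
        if not m.any():
            raise RRSeriesError(f"no beats in [{t0}, {t1})")
        return RRSeries(
            self.beat_time[m],
            self.interval[m],
            self.valid[m],
            record_id=self.record_id,
            start_clock=self.start_clock,
        )

    def copy(self) -> "RRSeries":
        return RRSeries(
            self.beat_time.copy(),
            self.interval.copy(),
            self.valid.copy(),
            record_id=self.record_id,
            start_clock=self.start_clock,
        )


@dataclass
class Hypnogram:
    """Per-epoch (30 s) sleep-stage labels over ``{W, R, L, D}``."""

    labels: np.ndarray
    epoch_len: float = EPOCH_LEN_S
    source: str = "annotation"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="<U1")
        if self.labels.size < 1:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = set(np.unique(self.labels)) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage label(s): {sorted(bad)}")

    def __len__(self) -> int:
        return int(self.labels.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return (
            self.epoch_len == other.epoch_len
            and self.labels.shape == other.labels.shape
            and bool(np.all(self.labels == other.labels))
        )

    @property
    def n_epochs(self) -> int:
        return len(self)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_len

    def stage_counts(self) -> dict[str, int]:
        return {s: int(np.sum(self.labels == s)) for s in STAGES}

    def copy(self) -> "Hypnogram":
        return Hypnogram(self.labels.copy(), self.epoch_len, self.source)


@dataclass
class AnalysisWindow:
    """One 30-s epoch plus its 4-min-30-s feature context.

    Epoch ``i`` covers ``[30 i, 30 (i+1))`` seconds; its window covers the
    270 s centred on the epoch midpoint, truncated at the record edges.
    A window is ``usable`` for training only when it is full-length and —
    when stage annotations are given — spans at most two distinct stages.
    """

    epoch_index: int
    t_start: float
    t_end: float
    beat_slice: slice
    usable: bool = True
    center_epoch_label: str | None = None

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start


@dataclass
class ScreeningReport:
    """Outcome of whole-recording screening.

    ``kept`` is true iff ``reasons`` is empty; ``skipped`` lists rules that
    could not be evaluated because their metadata was absent.
    """

    record_id: str
    reasons: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    @property
    def kept(self) -> bool:
        return not self.reasons


def epoch_of_time(t: float | np.ndarray, epoch_len: float = EPOCH_LEN_S):
    """Epoch index containing time ``t`` (0-based, half-open epochs)."""
    return np.floor(np.asarray(t) / epoch_len).astype(int)


def hypnogram_from_labels(labels: Iterable[str], source: str = "annotation") -> Hypnogram:
    """Convenience constructor from any label iterable."""
    return Hypnogram(np.asarray(list(labels)), source=source)
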