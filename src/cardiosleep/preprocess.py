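"""From raw ECG or raw RR series to screened, epoch-aligned analysis windows.

The preprocessing chain is:

1. R-peak detection on the ECG (Pan–Tompkins derivative/energy detector)
   when the input is a waveform rather than an RR series.
2. Artifact flagging on the RR series: physiologically impossible gaps
   (> 2 s or < 0.35 s) and ectopic-like beats whose interval deviates
   > 20 % from the local median are marked invalid.
3. Leading-wake trimming: everything before the last 5 min of an initial
   wake run is discarded.
4. Window construction: one 4-min-30-s analysis window centred on every
   30-s epoch.
5. Whole-recording screening against the study inclusion rules
   (length, AHI, sleep efficiency, leading/trailing wake, noise burden).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps
from scipy.ndimage import median_filter

from .datatypes import (
    EPOCH_LEN_S,
    WINDOW_LEN_S,
    AnalysisWindow,
    Hypnogram,
    RRSeries,
    ScreeningReport,
)

# Artifact-flagging bounds on a single RR interval, ms.
RR_MAX_MS = 2000.0
RR_MIN_MS = 350.0
#: Relative deviation from the local median beyond which a beat is ectopic-like.
IRREGULAR_TOL = 0.20


def detect_r_peaks(
    ecg: np.ndarray,
    rate: float,
    refractory_s: float = 0.2,
) -> np.ndarray:
    """Detect R peaks with the Pan–Tompkins energy detector.

    Stages: band-pass 5–15 Hz, differentiation, squaring, 150-ms
    moving-window integration, then adaptive dual-threshold peak picking
    with a 200-ms refractory period.  Each accepted detection is refined
    to the local extremum of the band-passed signal.

    Parameters
    ----------
    ecg : array
        Sampled waveform.
    rate : float
        Sampling rate in Hz (>= 100).

    Returns
    -------
    ndarray of int
        Strictly increasing sample indices of the detected R peaks.
    """
    ecg = np.asarray(ecg, dtype=float)
    if rate < 100:
        raise ValueError("sampling rate must be at least 100 Hz")
    if ecg.size < 10 * rate:
        raise ValueError("need at least 10 s of signal")
    if np.ptp(ecg) == 0:
        warnings.warn("flat-line ECG: no peaks detected", stacklevel=2)
        return np.empty(0, dtype=int)

    nyq = rate / 2.0
    b, a = sps.butter(2, [5.0 / nyq, 15.0 / nyq], btype="band")
    band = sps.filtfilt(b, a, ecg)
    deriv = np.gradient(band)
    squared = deriv**2
    win = max(int(round(0.150 * rate)), 1)
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(refractory_s * rate))
    cand, _ = sps.find_peaks(mwi, distance=max(refractory, 1))
    if cand.size == 0:
        warnings.warn("no candidate peaks found", stacklevel=2)
        return np.empty(0, dtype=int)

    # Adaptive dual thresholds on the integrated signal (signal / noise
    # running estimates, threshold between them).
    spki = float(np.percentile(mwi[cand], 75))
    npki = float(np.percentile(mwi[cand], 25))
    accepted: list[int] = []
    for idx in cand:
        peak = mwi[idx]
        thresh = npki + 0.25 * (spki - npki)
        if peak > thresh:
            spki = 0.125 * peak + 0.875 * spki
            accepted.append(int(idx))
        else:
            npki = 0.125 * peak + 0.875 * npki
    if not accepted:
        warnings.warn("no peaks above adaptive threshold", stacklevel=2)
        return np.empty(0, dtype=int)

    # Refine to the band-passed extremum within +-100 ms.
    half = int(round(0.1 * rate))
    refined = []
    for idx in accepted:
        lo, hi = max(idx - half, 0), min(idx + half + 1, ecg.size)
        refined.append(lo + int(np.argmax(np.abs(band[lo:hi]))))
    peaks = np.unique(refined)
    # Enforce the refractory period after refinement.
    keep = [int(peaks[0])]
    for p in peaks[1:]:
        if p - keep[-1] >= refractory:
            keep.append(int(p))
    return np.asarray(keep, dtype=int)


def rr_from_peaks(peaks: np.ndarray, rate: float, record_id: str = "") -> RRSeries:
    """Convert R-peak sample indices to an RR series (first peak dropped)."""
    t = np.asarray(peaks, dtype=float) / rate
    if t.size < 2:
        raise ValueError("need at least two peaks to form RR intervals")
    return RRSeries(t[1:], np.diff(t) * 1000.0, record_id=record_id)


def clean_rr(rr: RRSeries, irregular_tol: float = IRREGULAR_TOL) -> RRSeries:
    """Flag artifact beats; never deletes samples.

    A beat is invalid when its interval exceeds 2 s, is under 0.35 s, or
    deviates more than ``irregular_tol`` from the median of the 5
    surrounding valid intervals.  The local-median rule is iterated to a
    fixed point so that runs of ectopic-like beats are fully flagged and
    the operation is idempotent.
    """
    out = rr.copy()
    valid = out.valid & (out.interval <= RR_MAX_MS) & (out.interval >= RR_MIN_MS)
    for _ in range(20):
        x = out.interval[valid]
        if x.size < 3:
            break
        med = median_filter(x, size=5, mode="nearest")
        ok = np.abs(x - med) <= irregular_tol * med
        if ok.all():
            break
        idx = np.flatnonzero(valid)
        valid[idx[~ok]] = False
    out.valid = valid
    return out


def trim_leading_wake(
    rr: RRSeries, hyp: Hypnogram, keep_wake_epochs: int = 10
) -> tuple[RRSeries, Hypnogram]:
    """Cut excess leading wakefulness, keeping the final 5 min of it.

    If the initial contiguous run of W epochs exceeds ``keep_wake_epochs``
    (10 epochs = 5 min), all but the last 10 are dropped together with
    their beats; beat times are shifted so epoch alignment is preserved.
    """
    run = 0
    for lab in hyp.labels:
        if lab != "W":
            break
        run += 1
    if run <= keep_wake_epochs:
        return rr, hyp
    drop = run - keep_wake_epochs
    t0 = drop * hyp.epoch_len
    m = rr.beat_time >= t0
    if not m.any():
        raise ValueError("trimming would remove every beat")
    new_rr = RRSeries(
        rr.beat_time[m] - t0,
        rr.interval[m],
        rr.valid[m],
        record_id=rr.record_id,
        start_clock=rr.start_clock,
    )
    new_hyp = Hypnogram(hyp.labels[drop:], hyp.epoch_len, hyp.source)
    return new_rr, new_hyp


def build_windows(
    rr: RRSeries,
    hyp: Hypnogram | None = None,
    training: bool = False,
    window_len_s: float = WINDOW_LEN_S,
    epoch_len_s: float = EPOCH_LEN_S,
) -> list[AnalysisWindow]:
    """One analysis window per 30-s epoch.

    In training mode a window is unusable when it is truncated at a record
    edge or spans more than two distinct annotated stages; in inference
    mode every window is kept usable.
    """
    total = hyp.duration_s if hyp is not None else rr.duration_s
    n_epochs = len(hyp) if hyp is not None else int(total // epoch_len_s)
    if total < window_len_s or n_epochs == 0:
        warnings.warn("record shorter than one analysis window", stacklevel=2)
        return []
    half = window_len_s / 2.0
    windows: list[AnalysisWindow] = []
    for i in range(n_epochs):
        center = (i + 0.5) * epoch_len_s
        t0, t1 = center - half, center + half
        truncated = t0 < 0 or t1 > total
        t0c, t1c = max(t0, 0.0), min(t1, total)
        lo = int(np.searchsorted(rr.beat_time, t0c, side="left"))
        hi = int(np.searchsorted(rr.beat_time, t1c, side="left"))
        usable = True
        label = None
        if hyp is not None:
            label = str(hyp.labels[i])
        if training:
            if truncated:
                usable = False
            elif hyp is not None:
                e0 = int(np.floor(t0c / epoch_len_s))
                e1 = int(np.ceil(t1c / epoch_len_s))
                if len(set(hyp.labels[e0:e1])) > 2:
                    usable = False
        windows.append(
            AnalysisWindow(
                epoch_index=i,
                t_start=t0c,
                t_end=t1c,
                beat_slice=slice(lo, hi),
                usable=usable,
                center_epoch_label=label,
            )
        )
    return windows


def objective_sleep_efficiency(hyp: Hypnogram) -> float:
    """Fraction of non-W epochs between the first and last non-W epoch."""
    non_w = np.flatnonzero(hyp.labels != "W")
    if non_w.size == 0:
        return 0.0
    span = hyp.labels[non_w[0] : non_w[-1] + 1]
    return float(np.mean(span != "W"))


def screen_recording(
    rr: RRSeries | None,
    hyp: Hypnogram | None,
    meta: dict | None = None,
    min_hours: float = 5.0,
    max_ahi: float = 5.0,
    min_efficiency: float = 0.75,
    max_leading_wake_min: float = 45.0,
    max_trailing_wake_min: float = 30.0,
    max_noise_fraction: float = 0.25,
) -> ScreeningReport:
    """Evaluate the study inclusion rules on one recording.

    Rules whose metadata is absent are skipped and listed in
    ``report.skipped``; every violated rule appears in ``report.reasons``.
    AHI >= 5 excludes the recording (sleep-disordered breathing), as do
    nights shorter than 5 h, objective sleep efficiency below 75 %, more
    than 45 min of leading or 30 min of trailing wakefulness, and more
    than 25 % of the data lost to noise.
    """
    meta = dict(meta or {})
    record_id = meta.get("record_id") or (rr.record_id if rr is not None else "")
    report = ScreeningReport(record_id=record_id)

    if rr is None and hyp is None:
        report.reasons.append("data_error")
        return report

    duration_s = hyp.duration_s if hyp is not None else rr.duration_s
    if duration_s < min_hours * 3600.0:
        report.reasons.append("too_short")

    ahi = meta.get("AHI", meta.get("ahi"))
    if ahi is None:
        report.skipped.append("ahi")
    elif ahi >= max_ahi:
        report.reasons.append("ahi")

    if hyp is None:
        report.skipped.extend(["low_efficiency", "leading_wake", "trailing_wake"])
    else:
        if objective_sleep_efficiency(hyp) < min_efficiency:
            report.reasons.append("low_efficiency")
        labels = hyp.labels
        lead = 0
        for lab in labels:
            if lab != "W":
                break
            lead += 1
        trail = 0
        for lab in labels[::-1]:
            if lab != "W":
                break
            trail += 1
        if lead * hyp.epoch_len > max_leading_wake_min * 60.0:
            report.reasons.append("leading_wake")
        if trail * hyp.epoch_len > max_trailing_wake_min * 60.0:
            report.reasons.append("trailing_wake")

    noise = meta.get("noise_fraction")
    if noise is None and rr is not None:
        noise = float(np.mean(~rr.valid))
    if noise is None:
        report.skipped.append("noise")
    elif noise > max_noise_fraction:
        report.reasons.append("noise")

    return report
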