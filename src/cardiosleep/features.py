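"""HRV feature extraction per 4-min-30-s analysis window.

Twenty-three candidate features describe each window (time-domain,
spectral, respiratory, nonlinear and time-irreversibility statistics of
the RR tachogram), and twenty contextual features relate the window to
its 3-min neighbourhood and to the whole night.

All features return ``nan`` as the explicit missing marker when their
preconditions (minimum beat count / duration) are not met; they never
raise on short input.

Conventions that the field leaves open and this package fixes:

* The tachogram is resampled with a cubic spline at 4 Hz before any
  spectral analysis; spectra are Welch periodograms (128-s Hann
  segments, 50 % overlap).  Bands: VLF 0.0033–0.04 Hz, LF 0.04–0.15 Hz,
  HF 0.15–0.4 Hz.
* ``resf`` is the dominant tachogram frequency in the respiratory band
  0.15–0.5 Hz; ``strf`` is the standard deviation of ``resf`` over five
  90-s sub-windows sliding across the 270-s unit.
* ``coRR`` correlates the valid-interval sequence with its second-order
  smoothed version (two passes of a centred 3-point moving average).
* DFA is order-1 over scales 4–64 beats; ``alpha1`` is the slope and
  ``alpha2`` the intercept (offset) of the log10 F(n) vs log10 n fit.
  A conventional dual-exponent variant (slopes over scales 4–11 and
  11–64) is available via ``dual_exponent=True``.
* Sample entropy uses m=2, r=0.2·SD, Chebyshev distance, self-matches
  excluded; fuzzy entropy uses Gaussian membership exp(−(d/r)²) on
  baseline-removed templates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .datatypes import EPOCH_LEN_S, AnalysisWindow, Hypnogram, RRSeries

# Spectral band edges, Hz.
VLF_BAND = (0.0033, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)
RESP_BAND = (0.15, 0.5)

RESAMPLE_HZ = 4.0

#: The 23 per-window HRV candidate feature names.
HRV_FEATURES = (
    "HR", "SDNN", "RMSSD", "SDSD", "PNN50",
    "VLF", "LF", "HF", "LF_HF", "LFn", "HFn",
    "coRR", "resf", "strf",
    "alpha1", "alpha2", "SE", "FE", "SD1", "SD2",
    "P1", "G1", "corr2",
)

#: The 20 contextual (neighbourhood/overnight) feature names.
CONTEXT_FEATURES = tuple(
    f"{side}{sig}_t{i}_b{j}"
    for side in ("a", "z")
    for sig in ("HRs", "ress")
    for i in (1, 2)
    for j in (1, 2)
) + ("HRm_m1", "resm_m1", "HRm_ma", "resm_ma")

ALL_FEATURES = HRV_FEATURES + CONTEXT_FEATURES


def _tx(rr) -> tuple[np.ndarray, np.ndarray]:
    """Coerce input to (beat_time_s, interval_ms) arrays of valid beats."""
    if isinstance(rr, RRSeries):
        return rr.beat_time[rr.valid], rr.interval[rr.valid]
    t, x = rr
    return np.asarray(t, dtype=float), np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# Time domain


def time_domain(rr, min_beats: int = 10) -> dict[str, float]:
    """HR (bpm), SDNN, RMSSD, SDSD (ms) and PNN50 (%)."""
    _, x = _tx(rr)
    if x.size < min_beats:
        return {k: np.nan for k in ("HR", "SDNN", "RMSSD", "SDSD", "PNN50")}
    d = np.diff(x)
    return {
        "HR": 60000.0 / float(np.mean(x)),
        "SDNN": float(np.std(x, ddof=1)),
        "RMSSD": float(np.sqrt(np.mean(d**2))),
        "SDSD": float(np.std(d, ddof=1)),
        "PNN50": 100.0 * float(np.mean(np.abs(d) > 50.0)),
    }


# ---------------------------------------------------------------------------
# Spectral machinery


def _resample_tachogram(
    t: np.ndarray, x: np.ndarray, fs: float = RESAMPLE_HZ
) -> tuple[np.ndarray, np.ndarray]:
    """Evenly resample the tachogram with a cubic spline (gaps bridged)."""
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    if grid.size < 8:
        raise ValueError("window too short to resample")
    return grid, CubicSpline(t, x)(grid)


def _psd(y: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    y = y - np.mean(y)
    nperseg = min(int(128 * fs), y.size)
    return sps.welch(y, fs=fs, nperseg=nperseg, noverlap=nperseg // 2, window="hann")


def _tachogram_psd(
    t: np.ndarray, x: np.ndarray, fs: float = RESAMPLE_HZ
) -> tuple[np.ndarray, np.ndarray]:
    _, y = _resample_tachogram(t, x, fs)
    return _psd(y, fs)


def _band_power(f: np.ndarray, p: np.ndarray, band: tuple[float, float]) -> float:
    m = (f >= band[0]) & (f < band[1])
    if m.sum() < 2:
        return 0.0
    return float(np.trapezoid(p[m], f[m]))


def frequency_domain(
    rr, min_duration_s: float = 60.0, _resampled: np.ndarray | None = None
) -> dict[str, float]:
    """Band powers (ms²) of the resampled tachogram and their ratios.

    ``LFn + HFn == 1`` by construction.
    """
    keys = ("VLF", "LF", "HF", "LF_HF", "LFn", "HFn")
    t, x = _tx(rr)
    if t.size < 8 or t[-1] - t[0] < min_duration_s:
        return {k: np.nan for k in keys}
    if _resampled is not None:
        f, p = _psd(_resampled, RESAMPLE_HZ)
    else:
        f, p = _tachogram_psd(t, x)
    vlf = _band_power(f, p, VLF_BAND)
    lf = _band_power(f, p, LF_BAND)
    hf = _band_power(f, p, HF_BAND)
    tot = lf + hf
    return {
        "VLF": vlf,
        "LF": lf,
        "HF": hf,
        "LF_HF": lf / hf if hf > 0 else np.nan,
        "LFn": lf / tot if tot > 0 else np.nan,
        "HFn": hf / tot if tot > 0 else np.nan,
    }


def _smooth3(x: np.ndarray) -> np.ndarray:
    """Centred 3-point moving average with edge replication."""
    padded = np.concatenate([x[:1], x, x[-1:]])
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def _resf_of_psd(f: np.ndarray, p: np.ndarray) -> float:
    m = (f >= RESP_BAND[0]) & (f <= RESP_BAND[1])
    if not m.any() or np.all(p[m] == 0):
        return np.nan
    return float(f[m][np.argmax(p[m])])


def dominant_respiratory_frequency(t: np.ndarray, x: np.ndarray) -> float:
    """argmax of the tachogram spectrum within the 0.15–0.5 Hz band."""
    return _resf_of_psd(*_tachogram_psd(t, x))


def _strf_from_resampled(
    y: np.ndarray, fs: float, n_subwindows: int, subwindow_s: float
) -> float:
    """std of resf over sub-windows of an already-resampled tachogram."""
    n_sub = int(round(subwindow_s * fs))
    if n_subwindows < 2 or y.size < n_sub:
        return np.nan
    step = (y.size - n_sub) / (n_subwindows - 1)
    vals = []
    for i in range(n_subwindows):
        lo = int(round(i * step))
        vals.append(_resf_of_psd(*_psd(y[lo : lo + n_sub], fs)))
    vals = [v for v in vals if np.isfinite(v)]
    if len(vals) < 2:
        return np.nan
    return float(np.std(vals))


def respiration_features(
    rr,
    min_duration_s: float = 60.0,
    n_subwindows: int = 5,
    subwindow_s: float = 90.0,
    _resampled: np.ndarray | None = None,
) -> dict[str, float]:
    """``coRR``, ``resf`` and ``strf``.

    ``strf`` slides ``n_subwindows`` sub-windows of ``subwindow_s`` across
    the unit and takes the standard deviation of their ``resf``.
    """
    t, x = _tx(rr)
    if t.size < 8 or t[-1] - t[0] < min_duration_s:
        return {"coRR": np.nan, "resf": np.nan, "strf": np.nan}
    smoothed = _smooth3(_smooth3(x))
    if np.std(x) == 0 or np.std(smoothed) == 0:
        co = np.nan
    else:
        co = float(np.corrcoef(x, smoothed)[0, 1])
    y = (
        _resampled
        if _resampled is not None
        else _resample_tachogram(t, x, RESAMPLE_HZ)[1]
    )
    resf = _resf_of_psd(*_psd(y, RESAMPLE_HZ))
    strf = _strf_from_resampled(y, RESAMPLE_HZ, n_subwindows, subwindow_s)
    return {"coRR": co, "resf": resf, "strf": strf}


# ---------------------------------------------------------------------------
# Detrended fluctuation analysis


def _dfa_fluctuations(
    x: np.ndarray, scales: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    profile = np.cumsum(x - np.mean(x))
    n = profile.size
    used, fl = [], []
    for s in scales:
        s = int(s)
        n_win = n // s
        if n_win < 2:
            continue
        # forward and backward segmentation
        segs = np.concatenate(
            [
                profile[: n_win * s].reshape(n_win, s),
                profile[n - n_win * s :].reshape(n_win, s),
            ]
        )
        tt = np.arange(s, dtype=float)
        design = np.vstack([tt, np.ones(s)]).T
        coef, *_ = np.linalg.lstsq(design, segs.T, rcond=None)
        resid = segs.T - design @ coef
        fl.append(np.sqrt(np.mean(resid**2)))
        used.append(s)
    return np.asarray(used, dtype=float), np.asarray(fl)


def dfa(
    rr,
    min_beats: int = 100,
    scale_range: tuple[int, int] = (4, 64),
    dual_exponent: bool = False,
) -> dict[str, float]:
    """Order-1 DFA of the valid-interval sequence.

    By default ``alpha1`` is the slope and ``alpha2`` the intercept of the
    single log10 F(n) – log10 n regression over scales 4–64.  With
    ``dual_exponent=True`` the conventional two-slope variant is returned
    instead (``alpha1``: scales 4–11, ``alpha2``: scales 11–64).
    """
    _, x = _tx(rr)
    if x.size < min_beats or np.std(x) == 0:
        return {"alpha1": np.nan, "alpha2": np.nan}
    lo, hi = scale_range
    scales = np.unique(np.round(np.geomspace(lo, hi, 14)).astype(int))
    s, f = _dfa_fluctuations(x, scales)
    ok = f > 0
    s, f = s[ok], f[ok]
    if s.size < 3:
        return {"alpha1": np.nan, "alpha2": np.nan}
    ls, lf = np.log10(s), np.log10(f)
    if not dual_exponent:
        slope, intercept = np.polyfit(ls, lf, 1)
        return {"alpha1": float(slope), "alpha2": float(intercept)}
    m1 = s <= 11
    m2 = s >= 11
    a1 = np.polyfit(ls[m1], lf[m1], 1)[0] if m1.sum() >= 3 else np.nan
    a2 = np.polyfit(ls[m2], lf[m2], 1)[0] if m2.sum() >= 3 else np.nan
    return {"alpha1": float(a1), "alpha2": float(a2)}


# ---------------------------------------------------------------------------
# Entropies


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r) with Chebyshev distance, self-matches excluded.

    Both template lengths use the same ``n − m`` template starts so the
    counts are comparable.  Degenerate (constant) input returns 0 by
    convention; an undefined ratio (no matches) returns ``nan``.
    """
    x = np.asarray(x, dtype=float)
    sd = np.std(x)
    if sd == 0:
        return 0.0
    if r is None:
        r = 0.2 * sd
    n_t = x.size - m
    if n_t < 2:
        return np.nan
    close = np.abs(x[:, None] - x[None, :]) <= r
    match = close[:n_t, :n_t].copy()
    for k in range(1, m):
        match &= close[k : k + n_t, k : k + n_t]
    b = (int(match.sum()) - n_t) // 2  # symmetric; drop the diagonal
    match &= close[m : m + n_t, m : m + n_t]
    a = (int(match.sum()) - n_t) // 2
    if a == 0 or b == 0:
        return np.nan
    return float(-np.log(a / b))


def fuzzy_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Fuzzy entropy with Gaussian membership exp(−(d/r)²), m=2, r=0.2·SD.

    Templates are baseline-removed (their own mean subtracted) before the
    Chebyshev distance is taken.
    """
    x = np.asarray(x, dtype=float)
    sd = np.std(x)
    if sd == 0:
        return 0.0
    if r is None:
        r = 0.2 * sd

    def phi(mm: int) -> float:
        n_t = x.size - m  # same template count for both lengths
        if n_t < 2:
            return np.nan
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)[:n_t]
        emb = emb - emb.mean(axis=1, keepdims=True)
        d = np.abs(np.subtract.outer(emb[:, 0], emb[:, 0]))
        for k in range(1, mm):
            np.maximum(d, np.abs(np.subtract.outer(emb[:, k], emb[:, k])), out=d)
        mu = np.exp(-((d / r) ** 2))
        # symmetric with unit diagonal: average over the i<j pairs only
        return float((mu.sum() - n_t) / (n_t * (n_t - 1)))

    pm, pm1 = phi(m), phi(m + 1)
    if not (np.isfinite(pm) and np.isfinite(pm1)) or pm1 <= 0 or pm <= 0:
        return np.nan
    return float(np.log(pm) - np.log(pm1))


def entropy(rr, min_beats: int = 100) -> dict[str, float]:
    """Sample and fuzzy entropy of the valid-interval sequence."""
    _, x = _tx(rr)
    if x.size < min_beats:
        return {"SE": np.nan, "FE": np.nan}
    return {"SE": sample_entropy(x), "FE": fuzzy_entropy(x)}


# ---------------------------------------------------------------------------
# Poincaré, irreversibility, lag-2 autocorrelation


def poincare(rr, min_beats: int = 10) -> dict[str, float]:
    """Poincaré ellipse semi-axes: SD1² = var(ΔRR)/2, SD2² = 2·var(RR) − SD1².

    Successive differences are treated as zero-mean, so SD1 = RMSSD/√2
    holds as an identity.
    """
    _, x = _tx(rr)
    if x.size < min_beats:
        return {"SD1": np.nan, "SD2": np.nan}
    d = np.diff(x)
    sd1_sq = np.mean(d**2) / 2.0
    sd2_sq = max(2.0 * np.var(x) - sd1_sq, 0.0)
    return {"SD1": float(np.sqrt(sd1_sq)), "SD2": float(np.sqrt(sd2_sq))}


def irreversibility(rr, min_beats: int = 3) -> dict[str, float]:
    """Time-irreversibility statistics P1 and G1 of the RR increments.

    With ΔRR the successive differences of the valid intervals (zeros
    excluded), P1 is the percentage of negative increments and G1 the
    percentage of increment energy carried by the positive ones:

        P1 = 100 · N(ΔRR−) / (N(ΔRR−) + N(ΔRR+))
        G1 = 100 · Σ ΔRR+² / (Σ ΔRR+² + Σ ΔRR−²)
    """
    _, x = _tx(rr)
    if x.size < min_beats:
        return {"P1": np.nan, "G1": np.nan}
    d = np.diff(x)
    pos, neg = d[d > 0], d[d < 0]
    n_tot = pos.size + neg.size
    if n_tot == 0:
        return {"P1": np.nan, "G1": np.nan}
    p1 = 100.0 * neg.size / n_tot
    energy = float(np.sum(pos**2) + np.sum(neg**2))
    g1 = 100.0 * float(np.sum(pos**2)) / energy
    return {"P1": p1, "G1": g1}


def corr2(rr, min_beats: int = 4) -> float:
    """Pearson correlation of the sequence with itself shifted by two."""
    _, x = _tx(rr)
    if x.size < min_beats:
        return np.nan
    s1, s2 = x[:-2], x[2:]
    if np.std(s1) == 0 or np.std(s2) == 0:
        return np.nan
    return float(np.corrcoef(s1, s2)[0, 1])


# ---------------------------------------------------------------------------
# Contextual features


def _ranked_extrema(y: np.ndarray) -> tuple[list[int], list[int]]:
    """Local maxima/minima (endpoints included) of a short smoothed series,
    maxima ranked by descending value, minima by ascending value."""
    y = _smooth3(y)
    n = y.size
    maxima, minima = [], []
    for i in range(n):
        left = y[i - 1] if i > 0 else -np.inf
        right = y[i + 1] if i < n - 1 else -np.inf
        if y[i] >= left and y[i] >= right:
            maxima.append(i)
        left = y[i - 1] if i > 0 else np.inf
        right = y[i + 1] if i < n - 1 else np.inf
        if y[i] <= left and y[i] <= right:
            minima.append(i)
    maxima.sort(key=lambda i: -y[i])
    minima.sort(key=lambda i: y[i])
    return maxima, minima


def _trend_slopes(y: np.ndarray, epoch_len_s: float) -> dict[str, float]:
    """Slopes (per second) between the two top maxima and two bottom minima."""
    out = {f"t{i}_b{j}": np.nan for i in (1, 2) for j in (1, 2)}
    finite = np.isfinite(y)
    if finite.sum() < 2:
        return out
    idx = np.flatnonzero(finite)
    yy = y[finite]
    maxima, minima = _ranked_extrema(yy)
    ys = _smooth3(yy)
    for i, ti in enumerate(maxima[:2], start=1):
        for j, bj in enumerate(minima[:2], start=1):
            dt = (idx[ti] - idx[bj]) * epoch_len_s
            if dt != 0:
                out[f"t{i}_b{j}"] = float((ys[ti] - ys[bj]) / dt)
    return out


def context_features(
    instant_hr: np.ndarray,
    instant_resp: np.ndarray,
    epoch_index: int,
    epoch_len_s: float = EPOCH_LEN_S,
    context_epochs: int = 6,
    hour_epochs: int = 120,
) -> dict[str, float]:
    """Trend and level features relating one epoch to its neighbourhood.

    ``a``-prefixed slopes come from the 3-min window before the unit and
    ``z``-prefixed ones from the window after; the four slopes per signal
    join the first/second maxima (t1, t2) to the first/second minima
    (b1, b2) of the smoothed series.  ``*_m1`` ratios compare the unit to
    its centred one-hour mean, ``*_ma`` to the overnight mean.
    """
    hr = np.asarray(instant_hr, dtype=float)
    resp = np.asarray(instant_resp, dtype=float)
    i = epoch_index
    out: dict[str, float] = {}
    for side, sl in (("a", slice(max(i - context_epochs, 0), i)),
                     ("z", slice(i + 1, i + 1 + context_epochs))):
        for sig, series in (("HRs", hr), ("ress", resp)):
            seg = series[sl]
            slopes = (
                _trend_slopes(seg, epoch_len_s)
                if seg.size >= 2
                else {f"t{a}_b{b}": np.nan for a in (1, 2) for b in (1, 2)}
            )
            for key, val in slopes.items():
                out[f"{side}{sig}_{key}"] = val

    half_hour = hour_epochs // 2
    sl_hour = slice(max(i - half_hour, 0), i + half_hour + 1)
    for name, series in (("HR", hr), ("res", resp)):
        unit = series[i] if i < series.size else np.nan
        hour_mean = np.nanmean(series[sl_hour]) if np.isfinite(series[sl_hour]).any() else np.nan
        night_mean = np.nanmean(series) if np.isfinite(series).any() else np.nan
        pref = "HRm" if name == "HR" else "resm"
        out[f"{pref}_m1"] = float(unit / hour_mean) if hour_mean and np.isfinite(unit) and np.isfinite(hour_mean) else np.nan
        out[f"{pref}_ma"] = float(unit / night_mean) if night_mean and np.isfinite(unit) and np.isfinite(night_mean) else np.nan
    return out


# ---------------------------------------------------------------------------
# Night-level extraction


def _window_hrv(t: np.ndarray, x: np.ndarray, which: set[str]) -> dict[str, float]:
    row: dict[str, float] = {}
    if which & {"HR", "SDNN", "RMSSD", "SDSD", "PNN50"}:
        row.update(time_domain((t, x)))
    spectral = which & {"VLF", "LF", "HF", "LF_HF", "LFn", "HFn"}
    resp = which & {"coRR", "resf", "strf"}
    if spectral or resp:
        y = None  # resample once, share between the spectral blocks
        if t.size >= 8 and t[-1] - t[0] >= 60.0:
            y = _resample_tachogram(t, x)[1]
        if spectral:
            row.update(frequency_domain((t, x), _resampled=y))
        if resp:
            n_sub = 5 if "strf" in which else 0  # strf is the costly part
            row.update(respiration_features((t, x), n_subwindows=n_sub, _resampled=y))
    if which & {"alpha1", "alpha2"}:
        row.update(dfa((t, x)))
    if "SE" in which or "FE" in which:
        if x.size >= 100:
            if "SE" in which:
                row["SE"] = sample_entropy(x)
            if "FE" in which:
                row["FE"] = fuzzy_entropy(x)
        else:
            row.update({k: np.nan for k in ("SE", "FE") if k in which})
    if which & {"SD1", "SD2"}:
        row.update(poincare((t, x)))
    if which & {"P1", "G1"}:
        row.update(irreversibility((t, x)))
    if "corr2" in which:
        row["corr2"] = corr2((t, x))
    return {k: v for k, v in row.items() if k in which}


def extract_night(
    rr: RRSeries,
    windows: list[AnalysisWindow],
    hyp: Hypnogram | None = None,
    features: tuple[str, ...] | None = None,
    record_id: str | None = None,
) -> pd.DataFrame:
    """Feature table for a whole night: one row per epoch.

    ``features`` restricts the computed column set (a subset of
    :data:`ALL_FEATURES`); contextual features need the per-epoch HR and
    ``resf`` series, which are computed on the fly.  Missing values are
    ``nan`` markers, never errors.
    """
    names = tuple(features) if features is not None else ALL_FEATURES
    unknown = set(names) - set(ALL_FEATURES)
    if unknown:
        raise ValueError(f"unknown feature name(s): {sorted(unknown)}")
    hrv_wanted = set(n for n in names if n in HRV_FEATURES)
    ctx_wanted = [n for n in names if n in CONTEXT_FEATURES]
    if ctx_wanted:
        hrv_wanted |= {"HR", "resf"}

    rid = record_id or rr.record_id or "night"
    tt, xx = rr.beat_time[rr.valid], rr.interval[rr.valid]
    rows = []
    for w in windows:
        lo = int(np.searchsorted(tt, w.t_start, side="left"))
        hi = int(np.searchsorted(tt, w.t_end, side="left"))
        rows.append(_window_hrv(tt[lo:hi], xx[lo:hi], hrv_wanted))
    df = pd.DataFrame(rows)

    if ctx_wanted:
        hr_series = df["HR"].to_numpy()
        resp_series = df["resf"].to_numpy()
        ctx_rows = [
            context_features(hr_series, resp_series, w.epoch_index) for w in windows
        ]
        df = pd.concat([df, pd.DataFrame(ctx_rows)], axis=1)

    df = df.reindex(columns=list(names))
    df.insert(0, "usable", [w.usable for w in windows])
    if hyp is not None:
        df.insert(1, "stage", [str(hyp.labels[w.epoch_index]) for w in windows])
    df.index = pd.MultiIndex.from_arrays(
        [[rid] * len(windows), [w.epoch_index for w in windows]],
        names=["record_id", "epoch_index"],
    )
    return df
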