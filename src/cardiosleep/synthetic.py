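"""Synthetic nights and cohorts for end-to-end testing without real data.

The generator produces, from a seed and a configuration only:

* a hypnogram with a wake onset, ~90-min NREM/REM cycling and brief
  awakenings (semi-Markov chain over {W, R, L, D} with geometric bout
  lengths);
* a stage-conditional RR series — per-stage mean interval, a 0.1-Hz
  low-frequency oscillation, a respiratory-frequency oscillation
  (respiratory sinus arrhythmia) and white jitter, plus a configurable
  fraction of artifact beats pushed outside the physiological range;
* optionally a template-pulse ECG waveform for exercising R-peak
  detection;
* cohorts with planted good/poor sleep-quality labels, where poor nights
  are biased toward more and longer wake bouts (more fragmentation,
  lower efficiency).

The stage-parameter defaults encode the qualitative contrasts the
staging method relies on — wakefulness and REM with a faster heart rate
and stronger low-frequency power, deep sleep slow and dominated by
breathing-band variability — and are documented choices, not claims of
physiological truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import EPOCH_LEN_S, Hypnogram, RRSeries, STAGES
from .quality import QualityLabel


@dataclass
class StageRR:
    """Stage-conditional RR generation parameters."""

    mean_rr_ms: float
    jitter_ms: float
    lf_amp_ms: float
    hf_amp_ms: float
    resp_freq_hz: float

    def __post_init__(self) -> None:
        if not 400.0 <= self.mean_rr_ms <= 1500.0:
            raise ValueError("mean RR must be in [400, 1500] ms")
        if not 0.15 <= self.resp_freq_hz <= 0.5:
            raise ValueError("respiratory frequency must be in [0.15, 0.5] Hz")
        for amp in (self.jitter_ms, self.lf_amp_ms, self.hf_amp_ms):
            if amp < 0:
                raise ValueError("amplitudes must be non-negative")


#: Default stage-conditional RR parameters.  Heart rate rises W > R > L > D;
#: LF power dominates wake/REM, the respiratory band dominates NREM; the
#: respiratory frequency is stage-specific so that ``resf`` is informative.
DEFAULT_STAGE_RR: dict[str, StageRR] = {
    "W": StageRR(mean_rr_ms=800.0, jitter_ms=25.0, lf_amp_ms=45.0, hf_amp_ms=10.0, resp_freq_hz=0.30),
    "R": StageRR(mean_rr_ms=860.0, jitter_ms=20.0, lf_amp_ms=35.0, hf_amp_ms=16.0, resp_freq_hz=0.34),
    "L": StageRR(mean_rr_ms=950.0, jitter_ms=10.0, lf_amp_ms=12.0, hf_amp_ms=22.0, resp_freq_hz=0.26),
    "D": StageRR(mean_rr_ms=1010.0, jitter_ms=15.0, lf_amp_ms=3.0, hf_amp_ms=8.0, resp_freq_hz=0.21),
}

#: Mean bout lengths, minutes.
DEFAULT_BOUT_MIN: dict[str, float] = {"W": 2.0, "L": 18.0, "D": 12.0, "R": 12.0}

#: Transition weights out of each stage (self-transitions excluded).
DEFAULT_TRANSITIONS: dict[str, dict[str, float]] = {
    "W": {"L": 0.85, "R": 0.15},
    "L": {"D": 0.40, "R": 0.35, "W": 0.25},
    "D": {"L": 0.75, "W": 0.25},
    "R": {"L": 0.60, "W": 0.40},
}


@dataclass
class NightConfig:
    """Everything that determines one synthetic night."""

    night_hours: float = 8.0
    lead_wake_min: float = 10.0
    bout_min: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BOUT_MIN))
    transitions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(w) for s, w in DEFAULT_TRANSITIONS.items()}
    )
    stage_rr: dict[str, StageRR] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_RR)
    )
    artifact_rate: float = 0.01
    seed: int = 0

    @property
    def n_epochs(self) -> int:
        return int(round(self.night_hours * 3600.0 / EPOCH_LEN_S))


@dataclass
class CohortConfig:
    """A cohort of nights with planted good/poor quality labels."""

    n_subjects: int = 40
    fraction_poor: float = 0.35
    night: NightConfig = field(default_factory=NightConfig)
    #: Multiplier on transition weights into W for poor sleepers.
    poor_wake_bias: float = 4.0
    #: Multiplier on the W mean bout length for poor sleepers.
    poor_wake_bout_factor: float = 2.5
    #: Multiplier on the sleep-stage (L/D/R) mean bout lengths for poor
    #: sleepers: shorter bouts mean more fragmented sleep and more stage
    #: transitions.
    poor_fragmentation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_poor < 1.0:
            raise ValueError("fraction_poor must be in (0, 1)")
        if self.n_subjects < 4:
            raise ValueError("need at least 4 subjects")


def _geometric_bout(rng: np.random.Generator, mean_min: float) -> int:
    """Bout length in epochs, geometric with the given mean (>= 1 epoch)."""
    mean_ep = max(mean_min * 60.0 / EPOCH_LEN_S, 1.0)
    return int(rng.geometric(min(1.0 / mean_ep, 1.0)))


def simulate_hypnogram(cfg: NightConfig, seed: int | None = None) -> Hypnogram:
    """One night of 30-s stage labels from the semi-Markov chain.

    The night opens with a wake bout of roughly ``lead_wake_min`` and then
    alternates stage bouts with geometric lengths; the default bout means
    and transition weights produce NREM/REM cycling on the ~90-min scale.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_epochs
    labels: list[str] = []
    lead = max(int(round(cfg.lead_wake_min * 60.0 / EPOCH_LEN_S)), 1)
    labels.extend("W" * min(lead, n))
    stage = "L"
    while len(labels) < n:
        bout = _geometric_bout(rng, cfg.bout_min[stage])
        labels.extend(stage * bout)
        weights = cfg.transitions[stage]
        names = list(weights)
        p = np.asarray([weights[s] for s in names], dtype=float)
        stage = str(rng.choice(names, p=p / p.sum()))
    return Hypnogram(np.asarray(labels[:n]), source="annotation")


def simulate_rr(
    hyp: Hypnogram,
    cfg: NightConfig,
    seed: int | None = None,
    record_id: str = "synthetic",
    return_artifacts: bool = False,
):
    """Stage-conditional RR series for a hypnogram.

    Beats are laid down sequentially; each interval is the stage mean
    plus a 0.1-Hz LF sinusoid, an HF sinusoid at the stage's respiratory
    frequency, and Gaussian jitter.  A fraction ``cfg.artifact_rate`` of
    beats is perturbed outside the physiological range (mimicking missed
    or spurious detections).  With ``return_artifacts=True`` the planted
    artifact index array is returned alongside the series.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    duration = hyp.duration_s
    phase_lf = rng.uniform(0, 2 * np.pi)
    phase_hf = rng.uniform(0, 2 * np.pi)
    times: list[float] = []
    intervals: list[float] = []
    t = 0.0
    while True:
        epoch = min(int(t // hyp.epoch_len), len(hyp) - 1)
        p = cfg.stage_rr[str(hyp.labels[epoch])]
        rr = (
            p.mean_rr_ms
            + p.lf_amp_ms * np.sin(2 * np.pi * 0.1 * t + phase_lf)
            + p.hf_amp_ms * np.sin(2 * np.pi * p.resp_freq_hz * t + phase_hf)
            + rng.normal(0.0, p.jitter_ms)
        )
        rr = float(np.clip(rr, 400.0, 1500.0))
        t += rr / 1000.0
        if t >= duration:
            break
        times.append(t)
        intervals.append(rr)
    times_arr = np.asarray(times)
    intervals_arr = np.asarray(intervals)

    n_art = int(round(cfg.artifact_rate * intervals_arr.size))
    art_idx = (
        rng.choice(intervals_arr.size, size=n_art, replace=False)
        if n_art > 0
        else np.empty(0, dtype=int)
    )
    for i in art_idx:
        intervals_arr[i] = float(
            rng.choice([rng.uniform(150.0, 300.0), rng.uniform(2100.0, 2900.0)])
        )
    rr_series = RRSeries(times_arr, intervals_arr, record_id=record_id)
    if return_artifacts:
        return rr_series, np.sort(art_idx)
    return rr_series


def simulate_ecg(
    rr: RRSeries,
    rate: float = 250.0,
    noise_std: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Template-pulse ECG: Gaussian R waves at the beat times.

    Returns a waveform of ``ceil(duration * rate)`` samples with unit
    R-wave amplitude on a flat baseline, plus optional white noise.
    """
    rng = np.random.default_rng(seed)
    duration = rr.beat_time[-1] + 0.5
    n = int(np.ceil(duration * rate))
    tt = np.arange(n) / rate
    signal = np.zeros(n)
    sigma = 0.012  # R-wave width, s
    half = int(np.ceil(4 * sigma * rate))
    for bt in rr.beat_time:
        c = int(round(bt * rate))
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        signal[lo:hi] += np.exp(-0.5 * ((tt[lo:hi] - bt) / sigma) ** 2)
    if noise_std > 0:
        signal += rng.normal(0.0, noise_std, size=n)
    return signal


@dataclass
class Subject:
    """One simulated cohort member with its planted ground truth."""

    record_id: str
    hypnogram: Hypnogram
    rr: RRSeries
    quality: QualityLabel


def night_config_for_quality(cfg: CohortConfig, poor: bool, seed: int) -> NightConfig:
    """Night configuration biased by the planted quality label."""
    night = replace(cfg.night, seed=seed)
    if poor:
        trans = {s: dict(w) for s, w in night.transitions.items()}
        for s, w in trans.items():
            if "W" in w:
                w["W"] = w["W"] * cfg.poor_wake_bias
        bouts = {
            s: m * (cfg.poor_wake_bout_factor if s == "W" else cfg.poor_fragmentation)
            for s, m in night.bout_min.items()
        }
        night = replace(night, transitions=trans, bout_min=bouts)
    return night


def simulate_cohort(cfg: CohortConfig, seed: int | None = None) -> list[Subject]:
    """A cohort of nights with planted quality labels.

    Poor sleepers' chains are biased into more and longer wake bouts;
    their questionnaire scores are drawn above the good/poor threshold,
    good sleepers' at or below it.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    subjects = []
    for i in range(cfg.n_subjects):
        poor = bool(rng.random() < cfg.fraction_poor)
        score = int(rng.integers(7, 23)) if poor else int(rng.integers(0, 7))
        night = night_config_for_quality(cfg, poor, seed=int(rng.integers(2**31 - 1)))
        hyp = simulate_hypnogram(night)
        rr = simulate_rr(hyp, night, seed=int(rng.integers(2**31 - 1)),
                         record_id=f"subj{i:03d}")
        subjects.append(
            Subject(
                record_id=f"subj{i:03d}",
                hypnogram=hyp,
                rr=rr,
                quality=QualityLabel(score),
            )
        )
    return subjects
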