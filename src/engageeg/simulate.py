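"""Synthetic cohort generator: EEG, in-game metrics and flow responses.

No public recordings exist for this experimental design, so the package
ships a generator that reproduces the statistical structure the
analysis assumes:

* **EEG** — per channel, a sum of amplitude-modulated sinusoids at the
  theta/alpha/beta band centres over a 1/f (pink) broadband background,
  optionally contaminated with a 60 Hz line component and short
  30-45 Hz muscle bursts. High-engagement sessions get more beta and
  less alpha power than low-engagement ones (beta rises with active
  mental processing; alpha dominates relaxed states). Older-adult
  subjects receive a global amplitude attenuation and an extra
  broadband noise floor, mimicking the poorer effective SNR of aged
  recordings without claiming a physiological model.
* **In-game metrics** — per-level TC/TM/OH counts, non-decreasing in
  level, constructed so the Performance Index peaks exactly at the
  configured level in the noise-free setting: collected rings saturate
  at the peak level while misses and obstacle hits only start growing
  beyond it.
* **Flow responses** — 14 Likert items around a session-dependent mean
  (optimal > easy > hard, the ordering reported for this paradigm),
  with a per-subject engagement offset so some subjects fall below the
  high/low threshold in some sessions (which is what creates the
  retained/excluded split and the class imbalance downstream).

Determinism: all draws derive from ``numpy.random.SeedSequence`` keyed
by (seed, subject index, named substream, session), so identical
configs produce bit-identical outputs and adding a generator never
perturbs the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .calibration import GameMetricsRecord, LevelCalibration, WeightScheme, calibrate_levels
from .exceptions import ConfigurationError, ValidationError
from .flow import FlowScaleResponse, score_and_label
from .preprocess import DEFAULT_FS, EPOCX_CHANNELS, Recording

logger = logging.getLogger(__name__)

SESSIONS = ("easy", "optimal", "hard")

# substream codes keeping generators independent of one another
_STREAMS = {"eeg": 1, "metrics": 2, "flow": 3, "subject": 4}
_SESSION_CODES = {"": 0, "easy": 1, "optimal": 2, "hard": 3}

#: Session labels mirroring the 2:1 high/low imbalance of the paradigm.
DEFAULT_FORCED_LABELS = {"easy": "high", "optimal": "high", "hard": "low"}

__all__ = [
    "SimulationConfig",
    "simulate_eeg",
    "simulate_game_metrics",
    "simulate_flow_responses",
    "simulate_cohort",
    "SubjectData",
    "Cohort",
    "SESSIONS",
    "DEFAULT_FORCED_LABELS",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Band amplitudes are oscillation amplitudes in µV; the corresponding
    expected band power of an amplitude-A oscillation is
    A^2/2 * (1 + depth^2/2) with the default modulation depth.
    """

    n_subjects: int = 16
    n_older: int = 3
    fs: float = DEFAULT_FS
    n_channels: int = 14
    trial_seconds: float = 120.0
    band_freqs: Mapping[str, float] = field(
        default_factory=lambda: {"theta": 6.0, "alpha": 10.5, "beta": 21.5}
    )
    band_amp_high: Mapping[str, float] = field(
        default_factory=lambda: {"theta": 3.0, "alpha": 3.5, "beta": 7.0}
    )
    band_amp_low: Mapping[str, float] = field(
        default_factory=lambda: {"theta": 3.0, "alpha": 8.0, "beta": 2.5}
    )
    mod_depth: float = 0.5
    pink_amp: float = 8.0  # standard deviation of the 1/f background, µV
    pink_exponent: float = 1.0
    line_hz: float = 60.0
    line_amp: float = 2.0
    muscle_burst_rate: float = 2.0  # bursts per minute
    muscle_amp: float = 5.0
    older_attenuation: float = 0.7
    older_extra_noise: float = 3.0  # white-noise std added to older subjects, µV
    metric_peak_level: int = 4
    metric_noise: float = 0.0
    flow_effect: Mapping[str, float] = field(
        default_factory=lambda: {"easy": 4.9, "optimal": 5.5, "hard": 4.6}
    )
    flow_subject_sd: float = 0.6
    flow_item_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError(f"fs must be positive, got {self.fs}")
        if self.trial_seconds <= 0:
            raise ConfigurationError("trial_seconds must be positive")
        if not (1 <= self.metric_peak_level <= 10):
            raise ConfigurationError(
                f"metric_peak_level must be in 1..10, got {self.metric_peak_level}"
            )
        if not (0 <= self.n_older <= self.n_subjects):
            raise ConfigurationError("need 0 <= n_older <= n_subjects")
        amps = [
            *self.band_amp_high.values(),
            *self.band_amp_low.values(),
            self.pink_amp, self.line_amp, self.muscle_amp,
            self.older_extra_noise,
        ]
        if any(a < 0 for a in amps):
            raise ConfigurationError("all amplitudes must be >= 0")
        if self.muscle_burst_rate < 0:
            raise ConfigurationError("muscle_burst_rate must be >= 0")

    def channel_names(self) -> tuple[str, ...]:
        if self.n_channels == len(EPOCX_CHANNELS):
            return EPOCX_CHANNELS
        return tuple(f"CH{i + 1}" for i in range(self.n_channels))

    def subject_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]

    def is_older(self, subject_index: int) -> bool:
        return subject_index < self.n_older


def _rng(cfg: SimulationConfig, stream: str, subject_index: int, session: str = "") -> np.random.Generator:
    ss = np.random.SeedSequence(
        [int(cfg.seed), int(subject_index), _STREAMS[stream], _SESSION_CODES[session]]
    )
    return np.random.default_rng(ss)


def _pink_noise(rng: np.random.Generator, n: int, exponent: float, std: float) -> np.ndarray:
    """1/f^exponent noise by spectral shaping of white noise, unit variance x std."""
    if std == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * scale, n=n)
    s = shaped.std()
    return shaped * (std / s) if s > 0 else shaped


def simulate_eeg(
    cfg: SimulationConfig,
    class_label: str,
    session: str,
    subject_index: int = 0,
) -> Recording:
    """One synthetic gameplay-session recording (channels x samples, µV).

    ``class_label`` selects the high- or low-engagement band amplitudes.
    The oscillators are amplitude-modulated sinusoids at the band
    centres with per-channel random phases; modulation is slow
    (0.1-0.3 Hz) so oscillatory power stays inside its band.
    """
    if class_label not in ("high", "low"):
        raise ValidationError(f"class_label must be 'high' or 'low', got {class_label!r}")
    if session not in _SESSION_CODES:
        raise ValidationError(f"unknown session {session!r}")
    amps = cfg.band_amp_high if class_label == "high" else cfg.band_amp_low
    n = int(round(cfg.trial_seconds * cfg.fs))
    t = np.arange(n) / cfg.fs
    rng = _rng(cfg, "eeg", subject_index, session)
    data = np.zeros((cfg.n_channels, n))

    for ch in range(cfg.n_channels):
        x = np.zeros(n)
        for band, f_c in cfg.band_freqs.items():
            a = float(amps.get(band, 0.0))
            phase = rng.uniform(0, 2 * np.pi)
            f_m = rng.uniform(0.1, 0.3)
            phase_m = rng.uniform(0, 2 * np.pi)
            if a > 0:
                env = 1.0 + cfg.mod_depth * np.sin(2 * np.pi * f_m * t + phase_m)
                x += a * env * np.sin(2 * np.pi * f_c * t + phase)
            # draws above happen regardless of amplitude so that zeroing
            # one band never re-seeds the others
        x += _pink_noise(rng, n, cfg.pink_exponent, cfg.pink_amp)
        if cfg.line_amp > 0:
            x += cfg.line_amp * np.sin(2 * np.pi * cfg.line_hz * t + rng.uniform(0, 2 * np.pi))
        x += _muscle_bursts(rng, cfg, n)
        data[ch] = x

    if cfg.is_older(subject_index):
        data *= cfg.older_attenuation
        if cfg.older_extra_noise > 0:
            data += cfg.older_extra_noise * rng.standard_normal(data.shape)

    return Recording(
        data=data,
        fs=cfg.fs,
        channel_names=cfg.channel_names(),
        subject_id=cfg.subject_ids()[subject_index],
        session=session,
    )


def _muscle_bursts(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> np.ndarray:
    out = np.zeros(n)
    expected = cfg.muscle_burst_rate * cfg.trial_seconds / 60.0
    n_bursts = int(rng.poisson(expected)) if expected > 0 else 0
    if cfg.muscle_amp == 0:
        return out
    for _ in range(n_bursts):
        dur = int(0.3 * cfg.fs)
        if dur >= n:
            continue
        start = int(rng.integers(0, n - dur))
        f_b = rng.uniform(30.0, 44.0)
        tt = np.arange(dur) / cfg.fs
        burst = (
            cfg.muscle_amp
            * np.hanning(dur)
            * np.sin(2 * np.pi * f_b * tt + rng.uniform(0, 2 * np.pi))
        )
        out[start : start + dur] += burst
    return out


def simulate_game_metrics(
    cfg: SimulationConfig, subject_index: int = 0
) -> list[GameMetricsRecord]:
    """Per-level TC/TM/OH counts for levels 1..10.

    Collected rings grow concavely and saturate at the configured peak
    level; misses and obstacle hits stay flat until the peak and grow
    thereafter. Under min-max normalisation this puts the Performance
    Index maximum exactly at ``metric_peak_level`` when
    ``metric_noise`` is 0. Noise jitters the counts and is followed by
    a running maximum so levels stay non-decreasing.
    """
    peak = cfg.metric_peak_level
    levels = np.arange(1, 11)
    conc = lambda x: 1.0 - np.exp(-x / 3.0)  # noqa: E731 - small local shape

    tc = 30 + np.round(100 * conc(np.minimum(levels, peak)) / conc(peak)).astype(int)
    after = np.maximum(levels - peak, 0)
    span = max(10 - peak, 1)
    tm = np.round(150 * (after / span) ** 1.2).astype(int)
    oh = 3 + np.round(50 * (after / span) ** 1.5).astype(int)

    if cfg.metric_noise > 0:
        rng = _rng(cfg, "metrics", subject_index)
        for arr in (tc, tm, oh):
            arr += np.round(rng.normal(0, cfg.metric_noise, size=10)).astype(int)
            np.maximum(arr, 0, out=arr)
            np.maximum.accumulate(arr, out=arr)

    return [
        GameMetricsRecord(int(l), int(a), int(b), int(c))
        for l, a, b, c in zip(levels, tc, tm, oh)
    ]


def simulate_flow_responses(
    cfg: SimulationConfig, session: str, subject_index: int = 0
) -> FlowScaleResponse:
    """One 14-item questionnaire response for a session.

    Items are drawn around ``flow_effect[session]`` plus a per-subject
    engagement offset (same offset in every session), rounded and
    clipped into 0..7.
    """
    if session not in SESSIONS:
        raise ValidationError(f"session must be one of {SESSIONS}, got {session!r}")
    subj_rng = _rng(cfg, "subject", subject_index)
    offset = subj_rng.normal(0.0, cfg.flow_subject_sd)
    rng = _rng(cfg, "flow", subject_index, session)
    mu = float(cfg.flow_effect[session]) + offset
    items = np.clip(np.round(rng.normal(mu, cfg.flow_item_sd, size=14)), 0, 7)
    return FlowScaleResponse(
        items=tuple(int(v) for v in items),
        subject_id=cfg.subject_ids()[subject_index],
        session=session,
    )


@dataclass(frozen=True)
class SubjectData:
    """Everything generated for one synthetic subject."""

    subject_id: str
    age_group: str  # "older" | "young"
    metrics: list[GameMetricsRecord]
    calibration: LevelCalibration
    responses: dict[str, FlowScaleResponse]
    labels: dict[str, str]
    rated_scores: dict[str, float]
    recordings: dict[str, Recording]
    eeg_classes: dict[str, str]


@dataclass(frozen=True)
class Cohort:
    config: SimulationConfig
    subjects: list[SubjectData]

    def label_table(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": s.subject_id,
                "session": sess,
                "rated_score": s.rated_scores[sess],
                "label": s.labels[sess],
            }
            for s in self.subjects
            for sess in SESSIONS
        ]
        return pd.DataFrame(rows)

    def age_groups(self) -> dict[str, str]:
        return {s.subject_id: s.age_group for s in self.subjects}


def simulate_cohort(
    cfg: SimulationConfig,
    label_source: str = "flow",
    forced_labels: Mapping[str, str] | None = None,
    weights: WeightScheme | None = None,
) -> Cohort:
    """Generate a full cohort: metrics, calibration, flow labels and EEG.

    With ``label_source='flow'`` each session's engagement label comes
    from its simulated questionnaire (neutral possible), and the EEG
    class is high/low according to the rated score relative to the 4.5
    threshold. ``label_source='forced'`` stamps ``forced_labels``
    (default easy=high, optimal=high, hard=low) on every subject, which
    pins the cohort to the canonical retained-subject layout.
    """
    if label_source not in ("flow", "forced"):
        raise ConfigurationError("label_source must be 'flow' or 'forced'")
    forced = dict(forced_labels or DEFAULT_FORCED_LABELS)
    subjects = []
    for idx, sid in enumerate(cfg.subject_ids()):
        metrics = simulate_game_metrics(cfg, idx)
        calib = calibrate_levels(metrics, w=weights)
        responses, labels, scores, recs, classes = {}, {}, {}, {}, {}
        for sess in SESSIONS:
            resp = simulate_flow_responses(cfg, sess, idx)
            lab = score_and_label(resp)
            responses[sess] = resp
            scores[sess] = lab.rated_score
            if label_source == "forced":
                labels[sess] = forced[sess]
                classes[sess] = forced[sess]
            else:
                labels[sess] = lab.label
                classes[sess] = "high" if lab.rated_score >= 4.5 else "low"
            recs[sess] = simulate_eeg(cfg, classes[sess], sess, idx)
        subjects.append(
            SubjectData(
                subject_id=sid,
                age_group="older" if cfg.is_older(idx) else "young",
                metrics=metrics,
                calibration=calib,
                responses=responses,
                labels=labels,
                rated_scores=scores,
                recordings=recs,
                eeg_classes=classes,
            )
        )
    logger.info("simulated cohort of %d subjects (%d older)", cfg.n_subjects, cfg.n_older)
    return Cohort(config=cfg, subjects=subjects)
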