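"""EEG preprocessing: band-pass filtering, optional ICA cleaning, epoching.

The recordings are 14-channel, 128 Hz, 2-minute gameplay sessions from a
consumer saline-electrode headset. Preprocessing follows a deliberately
simple offline pipeline:

1. zero-phase 4th-order Butterworth band-pass, 0.5-45 Hz (suppresses
   slow drift and ECG below, muscle noise and the 60 Hz line above);
2. optionally, infomax ICA with automatic flagging of muscle components
   by their high/low frequency power ratio, plus manual exclusions;
3. segmentation into contiguous, non-overlapping 1-second epochs of
   128 samples each (a 2-minute trial yields exactly 120 epochs).

Filtering runs forwards and backwards (``sosfiltfilt``), so the
magnitude response is that of an 8th-order filter and the group delay
is zero — band-power epochs stay aligned with gameplay time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .exceptions import ConfigurationError, DecompositionError, ValidationError

logger = logging.getLogger(__name__)

#: Emotiv EPOCX montage, in device order.
EPOCX_CHANNELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

DEFAULT_FS = 128.0

__all__ = [
    "Recording",
    "EpochArray",
    "bandpass_filter",
    "remove_artifact_components",
    "epoch",
    "EPOCX_CHANNELS",
    "DEFAULT_FS",
]


@dataclass(frozen=True)
class Recording:
    """A continuous multi-channel EEG recording (channels x samples, µV)."""

    data: np.ndarray
    fs: float = DEFAULT_FS
    channel_names: tuple[str, ...] = EPOCX_CHANNELS
    subject_id: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValidationError(f"data must be 2-D (channels x samples), got {data.shape}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if self.fs <= 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        if data.shape[0] != len(self.channel_names):
            raise ValidationError(
                f"{data.shape[0]} data rows but {len(self.channel_names)} channel names"
            )
        if not np.isfinite(data).all():
            raise ValidationError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class EpochArray:
    """Contiguous non-overlapping epochs: channels x n_epochs x epoch_len."""

    epochs: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    subject_id: str = ""
    session: str = ""
    label: str = ""
    epoch_seconds: float = 1.0

    def __post_init__(self) -> None:
        ep = np.asarray(self.epochs, dtype=float)
        if ep.ndim != 3:
            raise ValidationError(
                f"epochs must be 3-D (channels x epochs x samples), got {ep.shape}"
            )
        object.__setattr__(self, "epochs", ep)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        expected = int(round(self.fs * self.epoch_seconds))
        if ep.shape[2] != expected:
            raise ValidationError(
                f"epoch length {ep.shape[2]} != fs*epoch_seconds = {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[1]

    @property
    def epoch_len(self) -> int:
        return self.epochs.shape[2]

    def to_continuous(self) -> np.ndarray:
        """Concatenate epochs back into the truncated continuous record."""
        ch, n_ep, ln = self.epochs.shape
        return self.epochs.reshape(ch, n_ep * ln)


def bandpass_filter(
    rec: Recording, lo: float = 0.5, hi: float = 45.0, order: int = 4
) -> Recording:
    """Zero-phase Butterworth band-pass of the continuous recording."""
    nyq = rec.fs / 2.0
    if not (0 < lo < hi):
        raise ConfigurationError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi >= nyq:
        raise ConfigurationError(f"high edge {hi} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=filtered)


def _component_band_ratio(
    sources: np.ndarray, fs: float, hi_band: tuple[float, float], lo_band: tuple[float, float]
) -> np.ndarray:
    """Per-component (hi_band power)/(lo_band power) via Welch PSD."""
    nper = min(sources.shape[1], int(4 * fs))
    freqs, psd = sps.welch(sources, fs=fs, nperseg=nper, axis=1)
    def bp(band):
        m = (freqs >= band[0]) & (freqs <= band[1])
        return np.trapezoid(psd[:, m], freqs[m], axis=1)
    hi = bp(hi_band)
    lo = bp(lo_band)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lo > 0, hi / np.maximum(lo, 1e-30), np.inf)
    ratio = np.where((hi == 0) & (lo == 0), 0.0, ratio)
    return ratio


def remove_artifact_components(
    rec: Recording,
    method: str = "none",
    auto_flag: bool = True,
    manual_exclude: Sequence[int] = (),
    muscle_ratio_threshold: float = 1.0,
    random_state: int = 97,
) -> tuple[Recording, dict]:
    """Optionally remove muscle-artifact ICA components.

    ``method='none'`` is the identity (an empty report). With
    ``method='ica-infomax'`` the recording is decomposed by infomax ICA;
    components whose 20-45 Hz power exceeds ``muscle_ratio_threshold``
    times their 0.5-20 Hz power are flagged as muscle (when
    ``auto_flag``), merged with ``manual_exclude``, zeroed, and the
    recording reconstructed. The report lists the per-component ratios
    and the excluded indices so the automatic decision is auditable.
    """
    if method == "none":
        report = {"method": "none", "excluded": [], "ratios": []}
        if manual_exclude:
            raise ConfigurationError("manual_exclude requires an ICA method")
        return rec, report
    if method != "ica-infomax":
        raise ConfigurationError(f"unknown artifact-removal method {method!r}")
    if rec.n_channels < 2:
        raise ValidationError("ICA needs at least 2 channels")

    import mne

    rank = np.linalg.matrix_rank(rec.data @ rec.data.T / rec.n_samples)
    if rank < rec.n_channels:
        raise DecompositionError(
            f"data rank {rank} < {rec.n_channels} channels; "
            "ICA decomposition is ill-posed (duplicated or silent channels?)"
        )

    info = mne.create_info(list(rec.channel_names), rec.fs, ch_types="eeg")
    # mne works in volts; recordings are µV
    raw = mne.io.RawArray(rec.data * 1e-6, info, verbose="error")
    # extended infomax: also separates sub-Gaussian sources (line, oscillations)
    ica = mne.preprocessing.ICA(
        n_components=rec.n_channels,
        method="infomax",
        fit_params={"extended": True},
        random_state=random_state,
        max_iter="auto",
        verbose="error",
    )
    try:
        ica.fit(raw, verbose="error")
    except Exception as exc:  # pragma: no cover - mne failure modes vary
        raise DecompositionError(f"infomax ICA failed: {exc}") from exc

    sources = ica.get_sources(raw).get_data()
    ratios = _component_band_ratio(sources, rec.fs, (20.0, 45.0), (0.5, 20.0))
    flagged = (
        [int(i) for i in np.nonzero(ratios > muscle_ratio_threshold)[0]]
        if auto_flag
        else []
    )
    excluded = sorted(set(flagged) | {int(i) for i in manual_exclude})
    ica.exclude = excluded
    cleaned = ica.apply(raw.copy(), verbose="error").get_data() * 1e6
    report = {
        "method": "ica-infomax",
        "auto_flagged": flagged,
        "manual_exclude": sorted(int(i) for i in manual_exclude),
        "excluded": excluded,
        "ratios": [float(r) for r in ratios],
        "threshold": muscle_ratio_threshold,
    }
    logger.info(
        "ICA removed %d/%d components (auto %s)", len(excluded), rec.n_channels, flagged
    )
    return replace(rec, data=cleaned), report


def epoch(rec: Recording, seconds: float = 1.0) -> EpochArray:
    """Cut the recording into contiguous non-overlapping epochs.

    Epoch k covers samples [k*L, (k+1)*L) with L = fs*seconds; any
    trailing remainder shorter than one epoch is dropped (logged).
    """
    if seconds <= 0:
        raise ConfigurationError("epoch length must be positive")
    epoch_len = int(round(rec.fs * seconds))
    n_epochs = rec.n_samples // epoch_len
    if n_epochs < 1:
        raise ValidationError(
            f"recording of {rec.n_samples} samples shorter than one "
            f"{epoch_len}-sample epoch"
        )
    dropped = rec.n_samples - n_epochs * epoch_len
    if dropped:
        logger.info("dropped %d trailing samples (< one epoch)", dropped)
    trimmed = rec.data[:, : n_epochs * epoch_len]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, epoch_len)
    return EpochArray(
        epochs=epochs,
        fs=rec.fs,
        channel_names=rec.channel_names,
        subject_id=rec.subject_id,
        session=rec.session,
        epoch_seconds=seconds,
    )
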