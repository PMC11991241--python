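"""SNR-based per-channel signal quality index (SQI).

Consumer EEG headsets vary widely in contact quality, so each channel
is scored by a signal-to-noise ratio in decibels:

    SNR = 10 * log10(signal power / noise power)

where the signal power is the summed theta + alpha + beta band power
and the noise power combines the 30-45 Hz muscle band with a +/-1 Hz
window around the powerline frequency. The SNR is computed on the
*unfiltered* recording: after the 45 Hz low-pass the line component is
gone and the ratio would no longer measure acquisition quality.

Per subject, channel SNRs are averaged across the easy/optimal/hard
session recordings and flagged: <= 0 dB bad, < 3 dB marginal, > 10 dB
excellent, otherwise good.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import ValidationError
from .preprocess import Recording
from .spectral import BandDefinition

logger = logging.getLogger(__name__)

#: dB ceiling applied when the noise bands carry (numerically) zero power.
SNR_CEILING_DB = 60.0

FLAG_THRESHOLDS = {"bad": 0.0, "marginal": 3.0, "excellent": 10.0}

__all__ = ["SQIReport", "channel_snr", "sqi_report", "quality_flag", "SNR_CEILING_DB"]


def quality_flag(snr_db: float) -> str:
    if snr_db <= FLAG_THRESHOLDS["bad"]:
        return "bad"
    if snr_db < FLAG_THRESHOLDS["marginal"]:
        return "marginal"
    if snr_db > FLAG_THRESHOLDS["excellent"]:
        return "excellent"
    return "good"


@dataclass(frozen=True)
class SQIReport:
    """Per-subject, per-channel SNR table plus subject averages and flags.

    ``table``: rows = subjects; one column per channel (dB), plus
    ``avg_eeg_db`` (arithmetic channel mean) and ``flag``.
    """

    table: pd.DataFrame
    metadata: dict

    def subject(self, subject_id: str) -> pd.Series:
        return self.table.loc[subject_id]


def channel_snr(
    rec: Recording, bands: BandDefinition | None = None
) -> np.ndarray:
    """Per-channel SNR in dB of one (pre-filter) recording.

    PSD is estimated with Welch's method (1-s mean over 2-s segments),
    i.e. the trial-averaged spectrum of the 2-minute window.
    """
    bands = bands or BandDefinition()
    if rec.duration < 2.0:
        raise ValidationError("SNR needs a recording of at least 2 s")
    nper = min(rec.n_samples, int(2 * rec.fs))
    freqs, psd = sps.welch(rec.data, fs=rec.fs, nperseg=nper, axis=1)

    def bp(lo: float, hi: float) -> np.ndarray:
        m = (freqs >= lo) & (freqs <= hi)
        return np.trapezoid(psd[:, m], freqs[m], axis=1)

    sig = (
        bp(*bands.theta) + bp(*bands.alpha) + bp(*bands.beta)
    )
    noise = bp(*bands.noise_muscle)
    line_lo, line_hi = bands.line_hz - 1.0, bands.line_hz + 1.0
    if line_lo < freqs[-1]:  # line band only if inside the spectrum
        noise = noise + bp(line_lo, min(line_hi, float(freqs[-1])))

    snr = np.full(rec.n_channels, SNR_CEILING_DB)
    ok = noise > 0
    with np.errstate(divide="ignore"):
        snr[ok] = 10.0 * np.log10(sig[ok] / noise[ok])
    if (~ok).any():
        logger.warning(
            "zero noise power on %d channel(s); SNR capped at %.0f dB",
            int((~ok).sum()), SNR_CEILING_DB,
        )
    snr = np.minimum(snr, SNR_CEILING_DB)
    return snr


def sqi_report(
    recordings: Mapping[str, Sequence[Recording]],
    bands: BandDefinition | None = None,
) -> SQIReport:
    """SQI table across subjects.

    ``recordings`` maps subject id -> recordings at the easy, optimal
    and hard levels. Per-channel SNR (dB) is averaged across the
    sessions; the subject average is the mean over channels.
    """
    bands = bands or BandDefinition()
    rows = {}
    channel_names: tuple[str, ...] | None = None
    for sid, recs in recordings.items():
        if len(recs) == 0:
            raise ValidationError(f"subject {sid}: no recordings")
        names = recs[0].channel_names
        if channel_names is None:
            channel_names = names
        for r in recs:
            if r.channel_names != channel_names:
                raise ValidationError(
                    f"subject {sid}: channel set differs across recordings/subjects"
                )
        snrs = np.vstack([channel_snr(r, bands) for r in recs])
        rows[sid] = snrs.mean(axis=0)

    assert channel_names is not None
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(channel_names))
    table["avg_eeg_db"] = table[list(channel_names)].mean(axis=1)
    table["flag"] = table["avg_eeg_db"].map(quality_flag)
    table.index.name = "subject_id"
    low, high = table["avg_eeg_db"].min(), table["avg_eeg_db"].max()
    logger.info("subject-average SQI range: %.2f .. %.2f dB", low, high)
    meta = {
        "noise_bands": {
            "muscle": bands.noise_muscle,
            "line": (bands.line_hz - 1.0, bands.line_hz + 1.0),
        },
        "line_measured_prefilter": True,
        "flag_thresholds": FLAG_THRESHOLDS,
    }
    return SQIReport(table=table, metadata=meta)
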