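"""Multitaper band power and EEG engagement indices.

Per 1-second epoch and channel, the power spectral density is estimated
with the multitaper method (DPSS tapers) and integrated over the
canonical bands theta [4, 8) Hz, alpha [8, 13) Hz and beta [13, 30) Hz.
Three engagement indices are computed from the band powers:

    index 1 = beta / (theta + alpha)    (the classic NASA engagement index)
    index 2 = beta / alpha
    index 3 = 1 / alpha

Beta power rises with active mental processing while alpha and theta
power dominate in relaxed, disengaged states, so all three indices grow
with engagement. Index 1 and 2 are ratios of powers and therefore
invariant to overall signal scale; index 3 tracks (inverse) workload
through alpha suppression alone.

The time-bandwidth product defaults to NW = 2 (3 tapers). For 1-second
epochs that concentrates each spectral line within +/-2 Hz, narrow
enough to keep a mid-alpha oscillation inside its 5 Hz band; larger NW
trades that band fidelity for estimator variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .preprocess import EpochArray

logger = logging.getLogger(__name__)

DEFAULT_NW = 2.0
EPS_POWER = 1e-12  # µV² floor guarding the index divisions

__all__ = [
    "BandDefinition",
    "multitaper_psd",
    "band_power",
    "engagement_indices",
    "build_feature_table",
    "epoch_band_powers",
    "feature_columns",
    "DEFAULT_NW",
    "EPS_POWER",
]


@dataclass(frozen=True)
class BandDefinition:
    """Frequency bands (Hz). Band membership is half-open [lo, hi)."""

    theta: tuple[float, float] = (4.0, 8.0)
    alpha: tuple[float, float] = (8.0, 13.0)
    beta: tuple[float, float] = (13.0, 30.0)
    noise_muscle: tuple[float, float] = (30.0, 45.0)
    line_hz: float = 60.0

    def __post_init__(self) -> None:
        bands = [self.theta, self.alpha, self.beta, self.noise_muscle]
        for lo, hi in bands:
            if not (0 < lo < hi):
                raise ConfigurationError(f"invalid band ({lo}, {hi})")
        for (_, hi1), (lo2, _) in zip(bands, bands[1:]):
            if lo2 < hi1:
                raise ConfigurationError("bands must not overlap")

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {
            "theta": self.theta,
            "alpha": self.alpha,
            "beta": self.beta,
            "noise_muscle": self.noise_muscle,
        }


def multitaper_psd(
    x: np.ndarray, fs: float, nw: float = DEFAULT_NW
) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper PSD of one or many signals.

    Parameters
    ----------
    x : array, shape (..., n_samples)
        Signal(s); the PSD is estimated along the last axis.
    fs : float
        Sampling rate, Hz.
    nw : float
        Time-bandwidth product; 2*nw - 1 DPSS tapers are used.

    Returns
    -------
    freqs : array, shape (n_freqs,)
        One-sided frequency grid, 0..fs/2.
    psd : array, shape (..., n_freqs)
        Power spectral density, input-units^2 per Hz. Integrating over
        the full grid recovers the signal variance (Parseval).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[-1] < 8:
        raise ValidationError(f"epoch too short for PSD: {x.shape[-1]} samples")
    if fs <= 0:
        raise ConfigurationError("fs must be positive")
    from mne.time_frequency import psd_array_multitaper

    # mne parameterises by half-bandwidth in Hz: W = nw / T
    bandwidth = 2.0 * nw * fs / x.shape[-1]
    psd, freqs = psd_array_multitaper(
        x,
        sfreq=fs,
        fmin=0.0,
        fmax=fs / 2.0,
        bandwidth=bandwidth,
        adaptive=False,
        low_bias=True,
        normalization="full",
        verbose="error",
    )
    return freqs, psd


def band_power(
    psd: np.ndarray, freqs: np.ndarray, band: tuple[float, float]
) -> np.ndarray:
    """Trapezoidal integral of the PSD over ``band`` (units^2).

    Adjacent bands that share an edge partition the spectrum exactly:
    the integrals add up to the integral over the union.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    lo, hi = band
    if hi <= freqs[0] or lo >= freqs[-1]:
        raise ValidationError(
            f"band ({lo}, {hi}) does not intersect grid [{freqs[0]}, {freqs[-1]}]"
        )
    lo = max(lo, freqs[0])
    hi = min(hi, freqs[-1])
    inside = (freqs > lo) & (freqs < hi)
    grid = np.concatenate(([lo], freqs[inside], [hi]))
    # interpolate the density at the exact band edges per signal
    flat = psd.reshape(-1, freqs.size)
    lo_v = np.array([np.interp(lo, freqs, row) for row in flat])
    hi_v = np.array([np.interp(hi, freqs, row) for row in flat])
    vals = np.concatenate(
        [lo_v[:, None], flat[:, inside], hi_v[:, None]], axis=1
    )
    power = np.trapezoid(vals, grid, axis=1)
    return power.reshape(psd.shape[:-1])


def engagement_indices(
    p_theta: np.ndarray | float,
    p_alpha: np.ndarray | float,
    p_beta: np.ndarray | float,
    eps: float = EPS_POWER,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three band-power engagement indices, floored against division by ~0.

    Degenerate denominators (below ``eps``) are clamped and logged so
    flat epochs yield finite, flagged values instead of infinities.
    """
    p_theta = np.asarray(p_theta, dtype=float)
    p_alpha = np.asarray(p_alpha, dtype=float)
    p_beta = np.asarray(p_beta, dtype=float)
    if (p_theta < 0).any() or (p_alpha < 0).any() or (p_beta < 0).any():
        raise ValidationError("band powers must be non-negative")
    denom1 = np.maximum(p_theta + p_alpha, eps)
    denom2 = np.maximum(p_alpha, eps)
    n_floored = int(np.sum(p_alpha < eps) + np.sum(p_theta + p_alpha < eps))
    if n_floored:
        logger.warning("engagement indices floored for %d degenerate value(s)", n_floored)
    e1 = p_beta / denom1
    e2 = p_beta / denom2
    e3 = 1.0 / denom2
    return e1, e2, e3


def epoch_band_powers(
    epochs: EpochArray, bands: BandDefinition | None = None, nw: float = DEFAULT_NW
) -> dict[str, np.ndarray]:
    """Theta/alpha/beta band power per (channel, epoch) of an EpochArray."""
    bands = bands or BandDefinition()
    freqs, psd = multitaper_psd(epochs.epochs, epochs.fs, nw=nw)
    return {
        name: band_power(psd, freqs, band)
        for name, band in (
            ("theta", bands.theta),
            ("alpha", bands.alpha),
            ("beta", bands.beta),
        )
    }


def build_feature_table(
    epoch_arrays: Iterable[EpochArray],
    bands: BandDefinition | None = None,
    feature_set: str = "combined",
    channel_mode: str = "per-channel",
    nw: float = DEFAULT_NW,
    eps: float = EPS_POWER,
) -> tuple[pd.DataFrame, dict]:
    """Per-epoch engagement-index features with high/low labels.

    Each labeled EpochArray (one subject/session) contributes one row
    per epoch. In ``per-channel`` mode every index yields one column per
    channel (42 columns for the combined set of 3 indices x 14
    channels); ``channel-mean`` averages each index across channels
    (used by the group statistics). Neutral-labeled sessions are
    excluded and counted in the returned metadata.
    """
    bands = bands or BandDefinition()
    valid_sets = ("e1", "e2", "e3", "combined")
    if feature_set not in valid_sets:
        raise ConfigurationError(f"feature_set must be one of {valid_sets}")
    if channel_mode not in ("per-channel", "channel-mean"):
        raise ConfigurationError("channel_mode must be 'per-channel' or 'channel-mean'")

    rows: list[pd.DataFrame] = []
    n_excluded = 0
    for ep in epoch_arrays:
        if ep.label == "neutral":
            n_excluded += ep.n_epochs
            logger.info(
                "excluding neutral session %s/%s (%d epochs)",
                ep.subject_id, ep.session, ep.n_epochs,
            )
            continue
        if ep.label not in ("high", "low"):
            raise ValidationError(
                f"session {ep.subject_id}/{ep.session} has no engagement label"
            )
        powers = epoch_band_powers(ep, bands=bands, nw=nw)
        e1, e2, e3 = engagement_indices(
            powers["theta"], powers["alpha"], powers["beta"], eps=eps
        )  # each: channels x epochs
        index_arrays = {"e1": e1, "e2": e2, "e3": e3}
        wanted = ("e1", "e2", "e3") if feature_set == "combined" else (feature_set,)
        data: dict[str, np.ndarray] = {}
        if channel_mode == "per-channel":
            for name in wanted:
                for ci, ch in enumerate(ep.channel_names):
                    data[f"{name}_{ch}"] = index_arrays[name][ci]
        else:
            for name in wanted:
                data[f"{name}_mean"] = index_arrays[name].mean(axis=0)
        frame = pd.DataFrame(data)
        frame.insert(0, "subject_id", ep.subject_id)
        frame.insert(1, "session", ep.session)
        frame.insert(2, "epoch_index", np.arange(ep.n_epochs))
        frame["label"] = ep.label
        rows.append(frame)

    if not rows:
        raise ValidationError("no labeled (non-neutral) sessions to build features from")
    table = pd.concat(rows, ignore_index=True)
    meta = {
        "bands": bands.as_dict(),
        "nw": nw,
        "n_tapers": int(2 * nw - 1),
        "eps": eps,
        "feature_set": feature_set,
        "channel_mode": channel_mode,
        "n_rows": int(len(table)),
        "n_excluded_neutral_epochs": n_excluded,
    }
    return table, meta


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The feature columns of a table built by :func:`build_feature_table`."""
    return [
        c for c in table.columns
        if c not in ("subject_id", "session", "epoch_index", "label")
    ]
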