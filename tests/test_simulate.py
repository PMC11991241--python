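"""Synthetic generator contracts: spectra, metrics shape, flow effects,
determinism."""

import dataclasses

import numpy as np
import pytest
from scipy.signal import periodogram

from engageeg.calibration import calibrate_levels
from engageeg.exceptions import ConfigurationError, ValidationError
from engageeg.flow import rated_score
from engageeg.simulate import (
    SESSIONS,
    SimulationConfig,
    simulate_cohort,
    simulate_eeg,
    simulate_flow_responses,
    simulate_game_metrics,
)


def _band_fraction(x: np.ndarray, fs: float, lo: float, hi: float,
                   total_lo: float = 0.5, total_hi: float = 45.0) -> float:
    f, p = periodogram(x, fs=fs, axis=-1)
    def integ(a, b):
        m = (f >= a) & (f <= b)
        return np.trapezoid(p[..., m], f[m], axis=-1).sum()
    return integ(lo, hi) / integ(total_lo, total_hi)


class TestSimulateEEG:
    def test_all_zero_amplitudes_give_silence(self):
        cfg = SimulationConfig(
            band_amp_high={"theta": 0, "alpha": 0, "beta": 0},
            pink_amp=0, line_amp=0, muscle_amp=0, older_extra_noise=0,
            trial_seconds=5,
        )
        rec = simulate_eeg(cfg, "high", "easy", 3)  # subject 3 is young
        assert np.all(rec.data == 0)

    def test_high_class_has_more_beta_everywhere(self):
        cfg = SimulationConfig(trial_seconds=20, seed=2)
        hi = simulate_eeg(cfg, "high", "optimal", 3)
        lo = simulate_eeg(cfg, "low", "optimal", 3)
        f, ph = periodogram(hi.data, fs=cfg.fs, axis=1)
        _, pl = periodogram(lo.data, fs=cfg.fs, axis=1)
        m = (f >= 13) & (f < 30)
        beta_hi = np.trapezoid(ph[:, m], f[m], axis=1)
        beta_lo = np.trapezoid(pl[:, m], f[m], axis=1)
        assert (beta_hi > beta_lo).all()
        # and less alpha
        ma = (f >= 8) & (f < 13)
        assert (
            np.trapezoid(ph[:, ma], f[ma], axis=1)
            < np.trapezoid(pl[:, ma], f[ma], axis=1)
        ).all()

    def test_pure_alpha_oscillator_stays_in_band(self):
        cfg = SimulationConfig(
            band_freqs={"alpha": 10.0},
            band_amp_high={"alpha": 5.0},
            pink_amp=0, line_amp=0, muscle_amp=0, older_extra_noise=0,
            trial_seconds=20, n_channels=2,
        )
        rec = simulate_eeg(cfg, "high", "easy", 3)
        assert _band_fraction(rec.data, cfg.fs, 8, 13, 4, 30) >= 0.99

    def test_oscillation_only_config_spectrally_faithful(self):
        """<1% of 0.5-45 Hz power falls outside the configured bands."""
        cfg = SimulationConfig(
            pink_amp=0, line_amp=0, muscle_amp=0, older_extra_noise=0,
            trial_seconds=20, n_channels=4,
        )
        rec = simulate_eeg(cfg, "low", "hard", 3)
        in_bands = sum(
            _band_fraction(rec.data, cfg.fs, lo - 0.5, hi + 0.5)
            for lo, hi in [(4, 8), (8, 13), (13, 30)]
        )
        assert in_bands > 0.99

    def test_line_and_muscle_contamination_present_when_configured(self):
        cfg = SimulationConfig(trial_seconds=30, seed=5,
                               muscle_burst_rate=30, muscle_amp=8)
        rec = simulate_eeg(cfg, "high", "easy", 3)
        f, p = periodogram(rec.data, fs=cfg.fs, axis=1)
        m_line = (f >= 59) & (f <= 61)
        quiet = dataclasses.replace(cfg, line_amp=0.0, muscle_amp=0.0)
        rec0 = simulate_eeg(quiet, "high", "easy", 3)
        _, p0 = periodogram(rec0.data, fs=cfg.fs, axis=1)
        assert p[:, m_line].sum() > 5 * p0[:, m_line].sum()

    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(trial_seconds=10, seed=9)
        a = simulate_eeg(cfg, "high", "optimal", 1)
        b = simulate_eeg(cfg, "high", "optimal", 1)
        assert a.data.tobytes() == b.data.tobytes()

    def test_older_subjects_attenuated_and_noisier(self):
        cfg = SimulationConfig(n_subjects=4, n_older=2, trial_seconds=10,
                               seed=4, line_amp=0, muscle_amp=0)
        old = simulate_eeg(cfg, "high", "easy", 0)
        young = simulate_eeg(cfg, "high", "easy", 3)
        # extra broadband noise floor shows up above 30 Hz
        f, po = periodogram(old.data, fs=cfg.fs, axis=1)
        _, py = periodogram(young.data, fs=cfg.fs, axis=1)
        m = f >= 45
        assert po[:, m].mean() > py[:, m].mean()

    def test_invalid_inputs_rejected(self):
        cfg = SimulationConfig(trial_seconds=5)
        with pytest.raises(ValidationError):
            simulate_eeg(cfg, "medium", "easy")
        with pytest.raises(ConfigurationError):
            SimulationConfig(trial_seconds=-1)
        with pytest.raises(ConfigurationError):
            SimulationConfig(fs=0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(metric_peak_level=11)
        with pytest.raises(ConfigurationError):
            SimulationConfig(pink_amp=-1)


class TestSimulateGameMetrics:
    @pytest.mark.parametrize("peak", list(range(1, 11)))
    def test_noise_free_pi_peaks_at_configured_level(self, peak):
        cfg = SimulationConfig(metric_peak_level=peak, metric_noise=0)
        records = simulate_game_metrics(cfg)
        calib = calibrate_levels(records)
        assert calib.optimal_level == peak

    def test_counts_nonnegative_and_nondecreasing(self):
        cfg = SimulationConfig(metric_peak_level=6, metric_noise=3.0, seed=8)
        records = simulate_game_metrics(cfg, subject_index=2)
        for attr in ("tc", "tm", "oh"):
            vals = [getattr(r, attr) for r in records]
            assert all(v >= 0 for v in vals)
            assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_seeds_differ_but_invariants_hold(self):
        a = simulate_game_metrics(SimulationConfig(metric_noise=4.0, seed=1))
        b = simulate_game_metrics(SimulationConfig(metric_noise=4.0, seed=2))
        assert [r.tc for r in a] != [r.tc for r in b]
        for recs in (a, b):
            tc = [r.tc for r in recs]
            assert all(y >= x for x, y in zip(tc, tc[1:]))

    def test_determinism(self):
        cfg = SimulationConfig(metric_noise=2.0, seed=3)
        assert simulate_game_metrics(cfg, 1) == simulate_game_metrics(cfg, 1)


class TestSimulateFlowResponses:
    def test_ceiling_and_floor(self):
        hi = SimulationConfig(flow_effect={"easy": 99, "optimal": 99, "hard": 99},
                              flow_item_sd=0.01, flow_subject_sd=0.0)
        lo = SimulationConfig(flow_effect={"easy": -99, "optimal": -99, "hard": -99},
                              flow_item_sd=0.01, flow_subject_sd=0.0)
        assert rated_score(simulate_flow_responses(hi, "easy")) == 7.0
        assert rated_score(simulate_flow_responses(lo, "hard")) == 0.0

    def test_session_ordering_of_means(self):
        """Monte-Carlo: optimal > easy > hard in expected rated score."""
        means = {s: [] for s in SESSIONS}
        for rep in range(300):
            cfg = SimulationConfig(seed=10_000 + rep)
            for sess in SESSIONS:
                means[sess].append(rated_score(simulate_flow_responses(cfg, sess, 0)))
        m = {s: np.mean(v) for s, v in means.items()}
        assert m["optimal"] > m["easy"] > m["hard"]

    def test_items_valid(self):
        r = simulate_flow_responses(SimulationConfig(seed=1), "optimal", 2)
        assert len(r.items) == 14
        assert all(0 <= v <= 7 for v in r.items)

    def test_unknown_session_rejected(self):
        with pytest.raises(ValidationError):
            simulate_flow_responses(SimulationConfig(), "medium")


class TestSimulateCohort:
    def test_forced_labels_and_classes(self, small_cohort):
        for s in small_cohort.subjects:
            assert s.labels == {"easy": "high", "optimal": "high", "hard": "low"}
            assert s.eeg_classes == s.labels

    def test_age_groups_assigned(self, small_cfg, small_cohort):
        groups = small_cohort.age_groups()
        assert sum(g == "older" for g in groups.values()) == small_cfg.n_older

    def test_flow_labels_follow_rated_scores(self):
        cfg = SimulationConfig(n_subjects=3, n_older=0, trial_seconds=4, seed=21)
        cohort = simulate_cohort(cfg, label_source="flow")
        for s in cohort.subjects:
            for sess in SESSIONS:
                score = s.rated_scores[sess]
                if s.labels[sess] == "neutral":
                    assert 3.75 <= score <= 4.25
                elif s.labels[sess] == "high":
                    assert score >= 4.5
                else:
                    assert score < 4.5

    def test_cohort_deterministic(self, small_cfg):
        a = simulate_cohort(small_cfg, label_source="forced")
        b = simulate_cohort(small_cfg, label_source="forced")
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.labels == sb.labels
            for sess in SESSIONS:
                assert (
                    sa.recordings[sess].data.tobytes()
                    == sb.recordings[sess].data.tobytes()
                )
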