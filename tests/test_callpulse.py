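"""Pulse segmentation, call features, QCF/FM split, buzz rule, approach onset."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from batforage import callpulse, synthio
from batforage.callpulse import (BuzzRuleParams, classify_call,
                                 detect_approach_onset, detect_feeding_buzzes,
                                 detect_pulses, extract_features)

FS = 250_000


def tone_pulse(f_khz, duration_ms, amplitude=1.0):
    return amplitude * synthio._call_waveform(duration_ms * 1e-3, f_khz * 1e3,
                                              f_khz * 1e3, FS)


def place(pulses_at, n_samples, noise=1e-4, seed=0):
    """Assemble a waveform from (time_s, samples) pairs over background noise."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, noise, n_samples)
    for t0, w in pulses_at:
        i = int(t0 * FS)
        x[i:i + len(w)] += w
    return x


class TestDetectPulses:
    def test_silence_yields_no_pulses(self):
        assert len(detect_pulses(np.zeros(10000), FS)) == 0
        rng = np.random.default_rng(0)
        assert len(detect_pulses(rng.normal(0, 1e-4, 100000), FS)) == 0

    def test_rectangular_pulse_duration_recovered(self):
        # a rectangular 20 ms envelope has its -15 dB edges at the nominal
        # boundaries, up to envelope smoothing
        n = int(0.020 * FS)
        t = np.arange(n) / FS
        x = place([(0.1, np.sin(2 * np.pi * 20e3 * t))], FS // 2)
        pulses = detect_pulses(x, FS)
        assert len(pulses) == 1
        assert pulses["duration_ms"].iloc[0] == pytest.approx(20.0, abs=0.5)
        assert pulses["start_s"].iloc[0] == pytest.approx(0.1, abs=5e-4)

    def test_ramped_pulse_edges_inside_nominal_duration(self):
        # raised-cosine onset/offset ramps pull the -15 dB points inward
        x = place([(0.1, tone_pulse(20.0, 20.0))], FS // 2)
        pulses = detect_pulses(x, FS)
        assert len(pulses) == 1
        assert 17.0 < pulses["duration_ms"].iloc[0] <= 20.2

    def test_each_pulse_measured_against_its_own_peak(self):
        # peaks differing by 20 dB: both detected, durations comparable
        x = place([(0.05, tone_pulse(20.0, 15.0, 1.0)),
                   (0.15, tone_pulse(20.0, 15.0, 0.1))], FS // 4, noise=3e-5)
        pulses = detect_pulses(x, FS, snr_floor_db=10.0)
        assert len(pulses) == 2
        d1, d2 = pulses["duration_ms"]
        assert d1 == pytest.approx(d2, abs=1.0)

    def test_faint_pulse_below_floor_discarded(self):
        x = place([(0.05, tone_pulse(20.0, 15.0, 1.0)),
                   (0.15, tone_pulse(20.0, 15.0, 0.0001))], FS // 4, noise=1e-4)
        pulses = detect_pulses(x, FS, snr_floor_db=10.0)
        assert len(pulses) == 1


class TestExtractFeatures:
    def test_pure_tone_peak_frequency_and_narrow_band(self):
        x = place([(0.1, tone_pulse(19.0, 20.9))], FS // 2)
        pulses = detect_pulses(x, FS)
        feats = extract_features(x, pulses, FS)
        assert feats["f_peak_khz"].iloc[0] == pytest.approx(19.0, abs=0.2)
        assert feats["bandwidth_khz"].iloc[0] < 1.0  # window-limited
        assert feats["call_type"].iloc[0] == "QCF"

    def test_linear_sweep_min_frequency_and_bandwidth(self):
        w = synthio._call_waveform(14.5e-3, 28.7e3, 15.0e3, FS)
        x = place([(0.1, w)], FS // 2)
        pulses = detect_pulses(x, FS)
        feats = extract_features(x, pulses, FS)
        assert feats["f_min_khz"].iloc[0] == pytest.approx(15.0, abs=0.7)
        assert feats["bandwidth_khz"].iloc[0] == pytest.approx(13.7, abs=1.0)
        assert feats["call_type"].iloc[0] == "FM"

    def test_ipi_is_start_to_start(self):
        x = place([(0.1, tone_pulse(20.0, 10.0)),
                   (0.4, tone_pulse(20.0, 10.0))], FS)
        feats = extract_features(x, detect_pulses(x, FS), FS)
        assert feats["ipi_ms"].iloc[0] == pytest.approx(300.0, abs=1.0)
        assert np.isnan(feats["ipi_ms"].iloc[-1])

    def test_every_finite_pulse_classified_qcf_or_fm(self, short_recording):
        audio, fs, _, _, _ = short_recording
        pulses = detect_pulses(audio[:, 0], fs)
        feats = extract_features(audio[:, 0], pulses, fs)
        finite = feats[np.isfinite(feats["bandwidth_khz"])]
        assert set(finite["call_type"]) <= {"QCF", "FM"}
        assert len(finite) > 0


class TestClassifyCall:
    @pytest.mark.parametrize("duration,bandwidth,expected", [
        (20.9, 7.78, "QCF"),   # shallow sweep: 0.372 kHz/ms
        (14.5, 13.7, "FM"),    # steep sweep: 0.945 kHz/ms
        (10.0, 6.0, "QCF"),    # exactly 0.60: boundary belongs to QCF
        (10.0, 6.01, "FM"),
    ])
    def test_sweep_rate_rule(self, duration, bandwidth, expected):
        assert classify_call(duration, bandwidth) == expected

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            classify_call(0.0, 5.0)


def train_from_ipis(ipis_ms, t0=0.0):
    return t0 + np.concatenate([[0.0], np.cumsum(ipis_ms)]) * 1e-3


class TestBuzzRule:
    def test_six_pulses_at_15_ms_form_one_buzz(self):
        buzzes = detect_feeding_buzzes(train_from_ipis([15] * 5))
        assert len(buzzes) == 1
        assert buzzes[0].n_pulses == 6
        assert buzzes[0].mean_ipi_ms == pytest.approx(15.0)

    def test_four_pulses_below_minimum_count_no_buzz(self):
        assert detect_feeding_buzzes(train_from_ipis([10] * 3)) == []

    def test_runs_merged_across_short_gap_but_not_long(self):
        run = [12.0] * 4  # five pulses per run
        merged = detect_feeding_buzzes(train_from_ipis(run + [60.0] + run))
        assert len(merged) == 1 and merged[0].n_pulses == 10
        split = detect_feeding_buzzes(train_from_ipis(run + [150.0] + run))
        assert [b.n_pulses for b in split] == [5, 5]

    def test_sub_runs_satisfy_ipi_threshold_after_merging(self):
        buzzes = detect_feeding_buzzes(
            train_from_ipis([12.0] * 4 + [60.0] + [12.0] * 4))
        members = buzzes[0].member_ids
        ipis = np.diff(train_from_ipis([12.0] * 4 + [60.0] + [12.0] * 4)[members]) * 1e3
        below = ipis[ipis < 20.0]
        assert len(below) == 8 and buzzes[0].mean_ipi_ms == pytest.approx(12.0)

    def test_non_monotonic_timestamps_rejected(self):
        with pytest.raises(ValueError):
            detect_feeding_buzzes(np.array([0.0, 0.1, 0.05]))

    def test_fewer_than_two_timestamps_empty(self):
        assert detect_feeding_buzzes(np.array([0.3])) == []

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=3.0, max_value=400.0),
                    min_size=5, max_size=60),
           st.floats(min_value=5.0, max_value=25.0))
    def test_raising_threshold_never_loses_member_pulses(self, ipis, thresh):
        times = train_from_ipis(ipis)
        lo = detect_feeding_buzzes(times, BuzzRuleParams(ipi_threshold_ms=thresh))
        hi = detect_feeding_buzzes(times, BuzzRuleParams(ipi_threshold_ms=thresh + 5))
        assert sum(b.n_pulses for b in hi) >= sum(b.n_pulses for b in lo)

    def test_waveform_and_event_stream_detections_agree(self, short_recording):
        # the rule is amplitude-free: timestamps from the waveform and the
        # logger's onset stream give the same buzzes (up to propagation delay)
        audio, fs, sched, truth, scene = short_recording
        pulses = detect_pulses(audio[:, 0], fs)
        from_wav = detect_feeding_buzzes(pulses)
        from_events = detect_feeding_buzzes(sched["time_s"].to_numpy())
        assert len(from_wav) == len(from_events) == 1
        assert from_wav[0].n_pulses == from_events[0].n_pulses
        # waveform start is late by the propagation delay only (< 150 ms here)
        assert abs(from_wav[0].start_s - from_events[0].start_s) < 0.15

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BuzzRuleParams(min_pulses=0)


class TestApproachOnset:
    def test_step_drop_in_ipi_found_at_first_fast_pulse(self):
        ipis = [300.0] * 12 + [100.0] * 5 + [15.0] * 6
        times = train_from_ipis(ipis)
        buzz = detect_feeding_buzzes(times)[0]
        ev = detect_approach_onset(times, buzz)
        assert ev.detected
        assert ev.onset_id == 12  # the first pulse whose IPI dropped to 100 ms

    def test_constant_ipi_train_has_no_onset(self):
        # no approach-phase drop before the buzz: the criterion never triggers
        ipis = [200.0] * 15 + [15.0] * 6
        times = train_from_ipis(ipis)
        buzz = detect_feeding_buzzes(times)[0]
        assert not detect_approach_onset(times, buzz).detected
        # a sustained pre-buzz drop is required for an onset
        ipis2 = [200.0] * 12 + [50.0] * 4 + [15.0] * 6
        times2 = train_from_ipis(ipis2)
        buzz2 = detect_feeding_buzzes(times2)[0]
        ev = detect_approach_onset(times2, buzz2)
        assert ev.detected and ev.onset_id == 12

    def test_buzz_at_train_start_no_onset(self):
        times = train_from_ipis([15.0] * 6)
        buzz = detect_feeding_buzzes(times)[0]
        assert not detect_approach_onset(times, buzz).detected

    def test_simulated_onsets_recovered_within_one_pulse(self):
        # labelled approach phases from the generator: detection within one
        # pulse of the label in at least 90% of seeded simulations
        hits = 0
        n_sims = 100
        for seed in range(n_sims):
            sched = synthio.make_call_schedule(25.0, seed=seed, n_attacks=1)
            times = sched["time_s"].to_numpy()
            buzzes = detect_feeding_buzzes(times)
            if len(buzzes) != 1:
                continue
            ev = detect_approach_onset(times, buzzes[0])
            true_onset = sched.attrs["approach_onsets"][0]
            if ev.detected and abs(ev.onset_id - true_onset) <= 1:
                hits += 1
        assert hits >= 0.90 * n_sims
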