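import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgage.beats import NNSeries, detect_r_peaks, delineate_beats
from ecgage.features import (
    dfa_alpha,
    edr_breathing,
    fragmentation_pas,
    frequency_domain,
    mfdfa_summary,
    record_feature_vector,
    sdann_index,
    sr_beat_features,
    time_domain_hrv,
)
from tests.conftest import make_nn


# -------- independent brute-force oracles (straight from the definitions) --

def oracle_time_domain(x):
    x = np.asarray(x, dtype=float)
    d = np.diff(x)
    return {
        "SDNN": np.sqrt(np.sum((x - x.mean()) ** 2) / (len(x) - 1)),
        "RMSSD": np.sqrt(np.mean(d**2)),
        "pNN20": 100.0 * np.sum(np.abs(d) > 20) / len(d),
        "pNN50": 100.0 * np.sum(np.abs(d) > 50) / len(d),
        "MCVNN": np.median(np.abs(x - np.median(x))) / np.median(x),
    }


class TestTimeDomain:
    def test_constant_series_is_all_zero(self):
        td = time_domain_hrv(make_nn([800, 800, 800]))
        assert td["SDNN"] == td["RMSSD"] == td["pNN20"] == td["MCVNN"] == 0.0

    def test_hand_worked_example(self):
        td = time_domain_hrv(make_nn([750, 800, 850]))
        assert td["SDNN"] == pytest.approx(50.0)
        assert td["RMSSD"] == pytest.approx(50.0)
        assert td["pNN20"] == 100.0
        assert td["pNN50"] == 0.0

    def test_pnn_uses_strict_inequality(self):
        td = time_domain_hrv(make_nn([1000, 1021, 1000]))
        assert td["pNN20"] == 100.0
        assert td["pNN50"] == 0.0
        td = time_domain_hrv(make_nn([1000, 1020, 1000]))
        assert td["pNN20"] == 0.0

    def test_insufficient_intervals_give_nan_not_error(self):
        td = time_domain_hrv(make_nn([800]))
        assert np.isnan(td["SDNN"])

    @given(
        st.lists(st.floats(min_value=400, max_value=1800), min_size=3, max_size=50)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_property_matches_bruteforce_oracle(self, intervals):
        td = time_domain_hrv(make_nn(intervals))
        ref = oracle_time_domain(intervals)
        for key, val in ref.items():
            assert td[key] == pytest.approx(val, rel=1e-9, abs=1e-12)


class TestSdannIndex:
    def test_constant_series_gives_zero(self):
        nn = make_nn([1000.0] * 700, t0=0.5)  # ~11.7 min
        assert sdann_index(nn, 5.0) == 0.0

    def test_two_explicit_windows_average(self):
        # window [0,60): sd 10; window [60,120): sd 30; the interval at
        # t=120 falls into the discarded trailing window
        x = 30.0 / np.sqrt(2.0)
        intervals = np.array([990, 1000, 1010, 1000 - x, 1000 + x, 1234], dtype=float)
        ts = np.array([10, 20, 30, 70, 80, 120], dtype=float)
        nn = NNSeries(intervals_ms=intervals, timestamps_s=ts, n_rejected=0)
        assert sdann_index(nn, 1.0) == pytest.approx(20.0)

    def test_single_full_window_is_missing(self):
        nn = make_nn([1000.0] * 540, t0=0.0)  # 9 minutes
        assert np.isnan(sdann_index(nn, 5.0))


class TestPas:
    def test_monotone_series_has_no_alternation(self):
        assert fragmentation_pas(make_nn(np.arange(800, 900, 10))) == 0.0

    def test_perfect_alternation_is_100_percent(self):
        x = 1000 + 20 * (-1.0) ** np.arange(20)
        assert fragmentation_pas(make_nn(x)) == 100.0

    def test_partial_alternation_run(self):
        # one alternating run of 3 successive differences = 4 member intervals
        x = [800, 820, 800, 820, 900, 910, 920, 930, 940]
        assert fragmentation_pas(make_nn(x)) == pytest.approx(100.0 * 4 / 9)

    def test_zero_differences_break_runs(self):
        x = [800, 820, 800, 800, 820, 800, 820, 800, 820]
        # diffs: +,-,0,+,-,+,-,+  -> run after the zero has 5 diffs (6 intervals)
        assert fragmentation_pas(make_nn(x)) == pytest.approx(100.0 * 6 / 9)


class TestDfa:
    def test_white_and_integrated_noise_limits(self):
        rng = np.random.default_rng(11)
        whites, browns = [], []
        for _ in range(3):
            e = rng.standard_normal(10000)
            whites.append(dfa_alpha(make_nn(1000 + e))[0])
            browns.append(dfa_alpha(make_nn(1000 + np.cumsum(e)))[0])
        assert abs(np.mean(whites) - 0.5) < 0.1
        assert abs(np.mean(browns) - 1.5) < 0.1

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        x = 1000 + 30 * rng.standard_normal(2000)
        a = dfa_alpha(make_nn(x))
        b = dfa_alpha(make_nn(x * 3.7))
        assert a[0] == pytest.approx(b[0], abs=1e-9)
        assert a[1] == pytest.approx(b[1], abs=1e-9)

    def test_short_series_gives_nan(self):
        a1, a2 = dfa_alpha(make_nn(1000 + np.random.default_rng(0).standard_normal(50)))
        assert np.isnan(a1) and np.isnan(a2)


class TestMfdfa:
    def test_monofractal_noise_has_narrow_spectrum(self):
        rng = np.random.default_rng(5)
        widths = [mfdfa_summary(make_nn(1000 + rng.standard_normal(2000)))[1] for _ in range(5)]
        assert np.mean(widths) <= 0.3

    def test_constant_series_flagged_missing(self):
        m, w = mfdfa_summary(make_nn([1000.0] * 600))
        assert np.isnan(m) and np.isnan(w)

    def test_alpha_mean_consistent_with_alpha1_for_monofractal(self):
        rng = np.random.default_rng(6)
        diffs = []
        for _ in range(5):
            x = 1000 + rng.standard_normal(4000)
            nn = make_nn(x)
            diffs.append(mfdfa_summary(nn)[0] - dfa_alpha(nn)[0])
        assert abs(np.mean(diffs)) <= 0.15


class TestFrequencyDomain:
    def test_constant_series_has_no_power(self):
        lf, hf = frequency_domain(make_nn([1000.0] * 200, t0=0.0))
        assert lf < 1e-6 and hf < 1e-6

    def test_hf_tone_lands_in_hf_band(self):
        t = np.cumsum(np.full(400, 1.0))
        x = 1000 + 50 * np.sin(2 * np.pi * 0.25 * t)
        nn = NNSeries(x, t, 0)
        lf, hf = frequency_domain(nn)
        assert hf / lf >= 10

    def test_lf_tone_lands_in_lf_band(self):
        t = np.cumsum(np.full(400, 1.0))
        x = 1000 + 50 * np.sin(2 * np.pi * 0.10 * t)
        nn = NNSeries(x, t, 0)
        lf, hf = frequency_domain(nn)
        assert lf / hf >= 10


class TestEdr:
    def _signal_with_modulated_r(self, f_mod, fs=100.0, duration=240.0, hr=60.0):
        n = int(duration * fs)
        x = np.zeros(n)
        rpeaks = np.arange(int(fs), n - int(fs), int(fs * 60 / hr))
        x[rpeaks] = 1.0 + 0.1 * np.sin(2 * np.pi * f_mod * rpeaks / fs)
        return x, rpeaks

    @pytest.mark.parametrize("f_mod,expected", [(0.25, 15.0), (0.20, 12.0)])
    def test_modulation_frequency_recovered(self, f_mod, expected):
        x, rp = self._signal_with_modulated_r(f_mod)
        rate, sd = edr_breathing(x, rp, 100.0)
        assert rate == pytest.approx(expected, abs=0.5)
        assert sd > 0

    def test_unmodulated_amplitudes_give_near_zero_sd(self):
        x, rp = self._signal_with_modulated_r(0.25)
        x[rp] = 1.0
        _, sd = edr_breathing(x, rp, 100.0)
        assert sd < 1e-9

    def test_too_few_peaks_give_nan(self):
        x = np.zeros(10000)
        rate, sd = edr_breathing(x, np.arange(0, 2000, 100), 100.0)
        assert np.isnan(rate) and np.isnan(sd)


class TestShortRange:
    def test_generator_amplitudes_recovered(self, clean_record):
        rec = clean_record
        rp = detect_r_peaks(rec.signal, rec.fs)
        fid = delineate_beats(rec.signal, rec.fs, rp)
        sr = sr_beat_features(rec.signal, rec.fs, fid, rp)
        p_true = rec.truth["waves"]["P"][0]
        assert sr["SR_p_mV"].mean() == pytest.approx(p_true, abs=0.02)
        rr_true = 60000.0 / rec.truth["mean_hr_bpm"]
        assert sr["SR_RR"].mean() == pytest.approx(rr_true, abs=10)

    def test_absent_fiducial_propagates_to_missing_field(self, clean_record):
        rec = clean_record
        rp = detect_r_peaks(rec.signal, rec.fs)
        fid = delineate_beats(rec.signal, rec.fs, rp)
        fid.loc[0, ["P_onset", "P_peak", "P_offset"]] = np.nan
        sr = sr_beat_features(rec.signal, rec.fs, fid, rp)
        assert np.isnan(sr.iloc[0]["SR_p_mV"])
        assert np.isnan(sr.iloc[0]["SR_PR"])


class TestRecordVector:
    def test_sr_fields_are_means_over_present_beats(self, clean_record):
        fv = record_feature_vector(clean_record)
        rec = clean_record
        rp = detect_r_peaks(rec.signal, rec.fs)
        fid = delineate_beats(rec.signal, rec.fs, rp)
        sr = sr_beat_features(rec.signal, rec.fs, fid, rp)
        assert fv["SR_t_mV"] == pytest.approx(sr["SR_t_mV"].dropna().mean())

    def test_missing_wave_propagates_to_record_level(self):
        from ecgage.synthetic import SyntheticCohortConfig, default_age_profile, synthesize_record

        prof = default_age_profile()
        for gp in prof.groups.values():
            gp.waves["P"].amplitude_mv = 0.0
        cfg = SyntheticCohortConfig(
            subjects_per_group=1, duration_s=60, noise_std_mv=0.0, seed=1,
            amplitude_jitter_rel=0.0,
        )
        fv = record_feature_vector(synthesize_record(0, prof, cfg, seed=4))
        assert np.isnan(fv["SR_p_mV"])

    def test_offset_invariance_of_nn_features(self):
        """Adding a constant to the NN series leaves every NN-derived feature
        unchanged except MCVNN, which rescales by its definition."""
        rng = np.random.default_rng(8)
        x = 900 + 40 * rng.standard_normal(700)
        nn_a, nn_b = make_nn(x), make_nn(x + 300)

        td_a, td_b = time_domain_hrv(nn_a), time_domain_hrv(nn_b)
        for key in ("SDNN", "RMSSD", "pNN20", "pNN50"):
            assert td_a[key] == pytest.approx(td_b[key], rel=1e-12)
        med = np.median(x)
        assert td_b["MCVNN"] == pytest.approx(td_a["MCVNN"] * med / (med + 300), rel=1e-9)

        assert fragmentation_pas(nn_a) == fragmentation_pas(nn_b)
        a1a, a2a = dfa_alpha(nn_a)
        a1b, a2b = dfa_alpha(nn_b)
        assert a1a == pytest.approx(a1b, abs=1e-9)
        assert a2a == pytest.approx(a2b, abs=1e-9)
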