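"""Generator contracts: configured moments are recovered, seeds are honored."""

import numpy as np
import pytest
from scipy import integrate, stats

from sudephys.study import WEANING_DAY
from sudephys.synth import (
    CalibrationError, ConfigError, StudyConfig, calibrate_mixture_weight,
    calibrate_spo2, gen_airflow, gen_ecg_segments, gen_eeg_emg,
    gen_spo2_stream, gen_survival,
)

OK_COLS = [f"ok_{i}" for i in range(1, 9)]


class TestGenSurvival:
    def test_zero_sem_degenerates_to_the_mean(self):
        t = gen_survival(10, 57.4, 0.0, seed=0)
        assert (t == 57).all()

    def test_seeded_sample_mean_near_target(self):
        # KO-SD configuration: mean 57, SEM 2, n 22
        means = [gen_survival(22, 57, 2, seed=s).mean() for s in range(30)]
        assert abs(np.mean(means) - 57) < 3 * 2

    def test_truncation_bound(self):
        for s in range(20):
            assert gen_survival(22, 57, 2, seed=s).min() >= WEANING_DAY + 1

    def test_overtruncated_config_rejected(self):
        with pytest.raises(ConfigError):
            gen_survival(100, 21.5, 30.0, seed=0)

    def test_deterministic_given_seed(self):
        assert (gen_survival(22, 57, 2, seed=5) == gen_survival(22, 57, 2, seed=5)).all()


class TestCalibrateMixtureWeight:
    LOW, HIGH, THR = (620.0, 30.0), (770.0, 43.0), 684.0

    def test_boundary_targets(self):
        p_hi = stats.norm.cdf(self.THR, *self.HIGH)
        p_lo = stats.norm.cdf(self.THR, *self.LOW)
        assert calibrate_mixture_weight(p_hi, self.THR, self.LOW, self.HIGH) == pytest.approx(0.0)
        assert calibrate_mixture_weight(p_lo, self.THR, self.LOW, self.HIGH) == pytest.approx(1.0)

    @pytest.mark.parametrize("target", [0.05, 0.1, 0.25, 0.457, 0.7, 0.9])
    def test_against_quadrature_oracle(self, target):
        w = calibrate_mixture_weight(target, self.THR, self.LOW, self.HIGH)

        def mixture_pdf(x):
            return w * stats.norm.pdf(x, *self.LOW) + (1 - w) * stats.norm.pdf(x, *self.HIGH)

        mass, _ = integrate.quad(mixture_pdf, -np.inf, self.THR)
        assert mass == pytest.approx(target, abs=1e-6)

    def test_unreachable_target_reports_range(self):
        with pytest.raises(CalibrationError, match="attainable"):
            calibrate_mixture_weight(0.999, self.THR, self.LOW, self.HIGH)


class TestGenEcgSegments:
    def test_wt_draws_are_pure_reference_gaussian(self, config):
        hr, _ = gen_ecg_segments("WT-SD", 1, config, n_segments=20000,
                                 noise_fraction=0.0, seed=1)
        inside = np.mean(np.abs(hr - 770) < 2 * 43)
        assert inside == pytest.approx(0.954, abs=0.01)

    def test_all_noisy_when_noise_fraction_one(self, config):
        _, noisy = gen_ecg_segments("KO-SD", 1, config, noise_fraction=1.0, seed=2)
        assert noisy.all()

    def test_ko_bin1_below_threshold_mass(self, config):
        hr, _ = gen_ecg_segments("KO-SD", 1, config, n_segments=40000,
                                 noise_fraction=0.0, seed=3)
        assert np.mean(hr < 684) == pytest.approx(0.457, abs=0.01)


class TestGenAirflow:
    def test_ground_truth_marks_criterion(self):
        _, truth = gen_airflow(60, 120, [(10, 3, 0.95), (30, 3, 0.5)], seed=0)
        flags = {round(e["onset_s"]): e["meets_criterion"] for e in truth}
        assert flags[10] is True and flags[30] is False

    def test_short_pause_below_two_cycles_flagged(self):
        _, truth = gen_airflow(60, 120, [(10, 1.5, 0.95)], seed=0)
        assert truth[0]["meets_criterion"] is False

    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            gen_airflow(60, 120, [(10, 4, 0.95), (11, 4, 0.95)], seed=0)

    def test_event_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            gen_airflow(60, 120, [(59.5, 3, 0.95)], seed=0)


class TestCalibrateSpo2:
    @pytest.mark.parametrize(
        "mean,frac", [(90.05, 0.33), (93.92, 0.08), (95.13, 0.02), (96.48, 0.0)]
    )
    def test_mixture_moments_match_targets(self, mean, frac):
        w, base_mean = calibrate_spo2(mean, frac)
        mix_mean = w * 85.0 + (1 - w) * base_mean
        mix_frac = w * stats.norm.cdf(90, 85, 3) + (1 - w) * stats.norm.cdf(90, base_mean, 1)
        assert mix_mean == pytest.approx(mean, abs=1e-6)
        assert mix_frac == pytest.approx(frac, abs=1e-6)
        # baseline component sits above the demarcation line
        assert base_mean > 90.0

    def test_unreachable_pair_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_spo2(99.9, 0.6)


class TestGenSpo2Stream:
    def test_error_free_fraction_matches_rate(self):
        df = gen_spo2_stream(3600, error_rate=0.25, seed=4)
        frac = df[OK_COLS].all(axis=1).mean()
        se = np.sqrt(0.25 * 0.75 / len(df))
        assert abs(frac - 0.75) < 4 * se

    def test_error_rate_one_leaves_no_error_free_samples(self):
        df = gen_spo2_stream(100, error_rate=1.0, seed=5)
        assert not df[OK_COLS].all(axis=1).any()

    def test_clean_wt_stream_has_no_hypoxemia(self):
        df = gen_spo2_stream(600, target_mean=96.48, target_hypox_fraction=0.0,
                             error_rate=0.0, seed=6)
        assert (df["sao2_pct"] >= 90).all()
        assert df["sao2_pct"].mean() == pytest.approx(96.48, abs=0.1)
        assert (df["sao2_pct"] <= 100).all()

    def test_hypoxemic_fraction_recovered_on_large_n(self):
        df = gen_spo2_stream(7200, target_mean=90.05, target_hypox_fraction=0.33,
                             error_rate=0.0, seed=7)
        assert (df["sao2_pct"] < 90).mean() == pytest.approx(0.33, abs=0.02)


class TestGenEegEmg:
    def test_epoch_count_and_occupancy_degenerate(self):
        eeg, emg, truth = gen_eeg_emg(300, occupancy=(1.0, 0.0, 0.0),
                                      sample_rate=100, seed=8)
        assert len(truth) == 30
        assert (truth["state"] == "WAKE").all()
        assert len(eeg) == len(emg) == 30 * 1000

    def test_occupancy_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            gen_eeg_emg(100, occupancy=(0.5, 0.4, 0.2), sample_rate=100, seed=0)

    def test_duration_must_tile_epochs(self):
        with pytest.raises(ConfigError):
            gen_eeg_emg(95, sample_rate=100, seed=0)

    def test_seizure_epochs_flagged(self):
        _, _, truth = gen_eeg_emg(200, sample_rate=100, seizure_epochs=[3, 7], seed=9)
        assert set(truth.loc[truth["is_seizure"], "epoch_index"]) == {3, 7}

    def test_same_seed_reproduces_different_seed_preserves_moments(self):
        a = gen_eeg_emg(600, sample_rate=100, seed=10)
        b = gen_eeg_emg(600, sample_rate=100, seed=10)
        assert np.array_equal(a[0], b[0]) and a[2].equals(b[2])
        c = gen_eeg_emg(600, sample_rate=100, seed=11)
        assert not np.array_equal(a[0], c[0])


def test_config_yaml_and_json_round_trip(tmp_path):
    cfg = StudyConfig()
    for name in ("cfg.yaml", "cfg.json"):
        cfg.save(tmp_path / name)
        again = StudyConfig.load(tmp_path / name)
        assert again == cfg


def test_config_validation_rejects_bad_fields():
    with pytest.raises(ConfigError):
        StudyConfig(wt_hr_sd=-1)
    with pytest.raises(ConfigError):
        StudyConfig(sleep_occupancy={"WT-SD": (0.5, 0.4, 0.2)})
    with pytest.raises(ConfigError):
        StudyConfig(spo2_targets={("KO-SD", 1): (90.0, 1.5)})
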