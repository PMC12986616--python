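"""Epoch features, PCA/k-means staging, exclusions, and occupancy."""

import numpy as np
import pandas as pd
import pytest

from sudephys.sleep import (
    StagingError, apply_exclusions, band_power, classify_states,
    epoch_features, occupancy,
)
from sudephys.study import ContractError
from sudephys.synth import gen_eeg_emg


class TestEpochFeatures:
    def test_one_row_per_complete_epoch(self):
        fs = 100.0
        eeg = np.zeros(int(125 * fs))  # 12 complete epochs + half an epoch
        feats = epoch_features(eeg, eeg, fs=fs)
        assert len(feats) == 12

    def test_delta_sinusoid_concentrates_in_delta_band(self):
        fs = 200.0
        t = np.arange(int(10 * fs)) / fs
        eeg = np.sin(2 * np.pi * 2.0 * t)  # 2 Hz, inside 0.5-4 Hz
        assert band_power(eeg, fs, (0.5, 4.0)) > 50 * band_power(eeg, fs, (10.0, 40.0))

    def test_zero_signal_gives_zero_power(self):
        fs = 100.0
        feats = epoch_features(np.zeros(int(20 * fs)), np.zeros(int(20 * fs)), fs=fs)
        assert (feats["delta_power"] == 0).all()
        assert (feats["emg_power"] == 0).all()

    def test_mismatched_traces_rejected(self):
        with pytest.raises(ContractError):
            epoch_features(np.zeros(2000), np.zeros(1999), fs=100.0)


class TestClassifyStates:
    def test_recovers_separable_synthetic_states(self):
        eeg, emg, truth = gen_eeg_emg(
            1800, occupancy=(0.5, 0.4, 0.1), sample_rate=100, seed=12
        )
        feats = epoch_features(eeg, emg, fs=100.0)
        labels = classify_states(feats)
        agreement = (labels.to_numpy() == truth["state"].to_numpy()).mean()
        assert agreement >= 0.95

    def test_identical_features_raise_staging_error(self):
        feats = pd.DataFrame(
            {"epoch_index": range(10), "delta_power": 1.0, "emg_power": 2.0}
        )
        with pytest.raises(StagingError):
            classify_states(feats)

    def test_mapping_is_rule_based_not_index_based(self):
        # three tight clusters with the canonical state geometry, in several
        # input orders: the delta-first mapping must label them identically
        rng = np.random.default_rng(3)
        blocks = {
            "NREM": (100.0, 1.0),
            "WAKE": (1.0, 100.0),
            "REM": (1.0, 0.1),
        }
        frames = []
        for name, (d, e) in blocks.items():
            frames.append(
                pd.DataFrame(
                    {
                        "delta_power": d * rng.lognormal(0, 0.05, 40),
                        "emg_power": e * rng.lognormal(0, 0.05, 40),
                        "truth": name,
                    }
                )
            )
        for order in ([0, 1, 2], [2, 0, 1], [1, 2, 0]):
            df = pd.concat([frames[i] for i in order], ignore_index=True)
            df["epoch_index"] = range(len(df))
            labels = classify_states(df)
            assert (labels.to_numpy() == df["truth"].to_numpy()).all()

    def test_too_few_epochs_rejected(self):
        feats = pd.DataFrame(
            {"epoch_index": [0, 1], "delta_power": [1.0, 2.0], "emg_power": [1.0, 3.0]}
        )
        with pytest.raises(StagingError):
            classify_states(feats)


class TestExclusions:
    @staticmethod
    def _labels(n):
        return pd.Series(["WAKE"] * n, index=pd.RangeIndex(n), name="state")

    def test_no_intervals_no_exclusions(self):
        out = apply_exclusions(self._labels(10))
        assert (out["state"] == "WAKE").all()

    def test_epoch_aligned_seizure_excludes_three_epochs(self):
        # 25 s starting exactly at an epoch boundary covers epochs 2, 3, 4
        out = apply_exclusions(self._labels(10), seizure_intervals=[(20.0, 45.0)])
        assert (out["state"] == "EXCLUDED").sum() == 3
        assert set(out.loc[out["state"] == "EXCLUDED", "epoch_index"]) == {2, 3, 4}

    def test_phase_shifted_seizure_excludes_four_epochs(self):
        out = apply_exclusions(self._labels(10), seizure_intervals=[(15.0, 40.5)])
        assert (out["state"] == "EXCLUDED").sum() == 4

    def test_reasons_recorded(self):
        out = apply_exclusions(
            self._labels(10),
            seizure_intervals=[(0.0, 5.0)],
            check_intervals=[(90.0, 95.0)],
        )
        reasons = out.set_index("epoch_index")["exclusion_reason"]
        assert reasons[0] == "SEIZURE" and reasons[9] == "CHECK"

    def test_epoch_count_conservation(self):
        out = apply_exclusions(self._labels(50), seizure_intervals=[(100, 130)])
        occ = occupancy(out)
        assert occ["n_analyzed"] + occ["n_excluded"] == 50


class TestOccupancy:
    def test_all_wake(self):
        s = pd.Series(["WAKE"] * 7)
        occ = occupancy(s)
        assert (occ["wake"], occ["nrem"], occ["rem"]) == (1.0, 0.0, 0.0)

    def test_equal_thirds(self):
        s = pd.Series(["WAKE", "NREM", "REM"] * 5)
        occ = occupancy(s)
        assert occ["wake"] == occ["nrem"] == occ["rem"] == pytest.approx(1 / 3)

    def test_sums_to_one_excluding_excluded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = pd.Series(rng.choice(["WAKE", "NREM", "REM", "EXCLUDED"], size=200))
            occ = occupancy(s)
            assert occ["wake"] + occ["nrem"] + occ["rem"] == pytest.approx(1.0, abs=1e-9)

    def test_no_analyzable_epochs_rejected(self):
        with pytest.raises(ContractError):
            occupancy(pd.Series(["EXCLUDED"] * 3))

    def test_generator_occupancy_recovered_within_binomial_ci(self):
        target = (0.5, 0.4, 0.1)
        _, _, truth = gen_eeg_emg(3600, occupancy=target, sample_rate=100, seed=13)
        occ = occupancy(truth["state"].rename("state"))
        n = len(truth)
        # Markov-chain draws are correlated; allow the effective-sample-size
        # inflation of the binomial CI for persistence 0.9 (factor ~ sqrt(19))
        for frac, p in zip((occ["wake"], occ["nrem"], occ["rem"]), target):
            se = np.sqrt(p * (1 - p) / n) * np.sqrt(19)
            assert abs(frac - p) < 4 * se
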