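"""Synthetic-data generator: ROI maps, ground truth, signals, mixing."""

import numpy as np
import pytest

from cssynergy import (
    ConfigurationError,
    EpochedDataset,
    SynergyConfig,
    TrialDesign,
    forward_mix,
    inverse_estimate,
    make_ground_truth,
    make_roi_map,
    synthesize_cs,
)
from cssynergy.datasets import ROI_NAMES
from cssynergy.simulate import _trial_amplitudes
from cssynergy.coordinates import int_label


class TestRoiMap:
    def test_equal_division(self):
        roi = make_roi_map(60, seed=1)
        assert all(c == 10 for c in roi.counts.values())

    def test_uneven_division_leaves_remainder_unassigned(self):
        roi = make_roi_map(13, seed=1)
        # floor(13/6) = 2 per ROI, one channel left over
        assert all(c >= 2 for c in roi.counts.values())
        assert int(np.sum(roi.assignment == -1)) <= 1

    def test_zero_proportion_roi_rejected(self):
        props = {name: 0.2 for name in ROI_NAMES}
        props["SMA"] = 0.0
        with pytest.raises(ConfigurationError):
            make_roi_map(20, proportions=props)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ConfigurationError):
            make_roi_map(6)

    def test_blocks_are_disjoint(self):
        roi = make_roi_map(40)
        assigned = roi.assignment[roi.assignment >= 0]
        assert sum(roi.counts.values()) == assigned.size


class TestGroundTruth:
    def test_single_multi_roi_mix(self):
        roi = make_roi_map(60)
        gt = make_ground_truth(roi, 8, SynergyConfig(single_roi_fraction=0.5), seed=7)
        n_single = sum(len(r) == 1 for r in gt.rois)
        n_multi = sum(2 <= len(r) <= 3 for r in gt.rois)
        assert n_single == 4 and n_multi == 4

    def test_unit_norm_columns(self):
        gt = make_ground_truth(make_roi_map(30), 5, seed=3)
        norms = np.linalg.norm(gt.W_true, axis=0)
        assert np.allclose(norms, 1.0, atol=1e-12)

    def test_weight_mass_confined_to_assigned_rois(self):
        roi = make_roi_map(48)
        gt = make_ground_truth(roi, 6, seed=5)
        for j, rois in enumerate(gt.rois):
            ch = np.concatenate([roi.channels_in(r) for r in rois])
            in_mass = np.sum(gt.W_true[ch, j] ** 2)
            assert in_mass >= 0.9 * np.sum(gt.W_true[:, j] ** 2)

    def test_seeded_determinism(self):
        roi = make_roi_map(30)
        a = make_ground_truth(roi, 5, seed=9)
        b = make_ground_truth(roi, 5, seed=9)
        assert np.array_equal(a.W_true, b.W_true)
        assert np.array_equal(a.peak_time, b.peak_time)

    def test_too_many_synergies_rejected(self):
        roi = make_roi_map(12)
        with pytest.raises(ConfigurationError):
            make_ground_truth(roi, 12)


class TestSynthesize:
    def test_noiseless_rank1_is_outer_product(self, rank1_gt):
        design = TrialDesign(n_epochs_per_condition=1)
        ds = synthesize_cs(rank1_gt, design, snr=np.inf, seed=0)
        g = np.exp(-0.5 * ((design.times - 0.3) / 0.1) ** 2)
        expected = rank1_gt.W_true[:, 0][:, None] * (1.5 * g)[None, :]
        for trial in range(ds.n_trials):
            np.testing.assert_allclose(ds.signals[trial], expected, atol=1e-12)

    def test_paper_scale_trial_count(self):
        # 80 epochs per target per elbow angle -> 8 * 2 * 80 trials
        roi = make_roi_map(12)
        gt = make_ground_truth(roi, 2, seed=0)
        ds = synthesize_cs(gt, TrialDesign(), snr=np.inf, seed=0)
        assert ds.n_trials == 8 * 2 * 80
        for (tgt, ang), idx in ds.condition_indices().items():
            assert idx.size == 80

    def test_intrinsic_tuning_is_angle_invariant(self):
        """Trials sharing a movement id have equal mean amplitude at both angles."""
        roi = make_roi_map(12)
        cfg = SynergyConfig(frames=("intrinsic",), kappa=1.0, amp_noise=0.1)
        gt = make_ground_truth(roi, 2, config=cfg, seed=4)
        rng = np.random.default_rng(0)
        n = 400  # >= 200 trials per cell
        target = rng.integers(1, 9, 4 * n)
        angle = np.where(rng.random(4 * n) < 0.5, 0, 90)
        amps = _trial_amplitudes(gt, target, angle, rng)
        move = int_label(target, angle)
        for m in (1, 4, 7):
            m0 = amps[(move == m) & (angle == 0), 0]
            m90 = amps[(move == m) & (angle == 90), 0]
            se = np.sqrt(m0.var() / m0.size + m90.var() / m90.size)
            assert abs(m0.mean() - m90.mean()) < 4 * se + 1e-3

    def test_snr_calibration_within_ten_percent(self):
        roi = make_roi_map(24)
        gt = make_ground_truth(roi, 4, seed=2)
        design = TrialDesign(n_epochs_per_condition=8)  # 128 trials
        clean = synthesize_cs(gt, design, snr=np.inf, seed=2)
        noisy = synthesize_cs(gt, design, snr=5.0, seed=2)
        noise = noisy.signals - clean.signals
        sig_p = np.mean(clean.signals**2, axis=(0, 2))
        snr_emp = sig_p / np.mean(noise**2, axis=(0, 2))
        carrying = sig_p > 0  # channels outside every planted ROI carry no signal
        assert carrying.sum() >= 12
        assert np.all(np.abs(snr_emp[carrying] - 5.0) / 5.0 < 0.10)

    def test_seeded_determinism(self, rank1_gt):
        d1 = synthesize_cs(rank1_gt, TrialDesign(n_epochs_per_condition=1), 5.0, seed=3)
        d2 = synthesize_cs(rank1_gt, TrialDesign(n_epochs_per_condition=1), 5.0, seed=3)
        assert np.array_equal(d1.signals, d2.signals)

    def test_invalid_snr_rejected(self, rank1_gt):
        with pytest.raises(ConfigurationError):
            synthesize_cs(rank1_gt, TrialDesign(n_epochs_per_condition=1), snr=0.0)


class TestMixing:
    @pytest.fixture()
    def tiny_cs(self):
        roi = make_roi_map(16)
        gt = make_ground_truth(roi, 3, seed=6)
        return synthesize_cs(gt, TrialDesign(n_epochs_per_condition=1), 20.0, seed=6)

    def test_identity_mixing_is_lossless(self, tiny_cs):
        eeg, model = forward_mix(tiny_cs, 16, sensor_noise=0.0, seed=0, identity=True)
        np.testing.assert_array_equal(eeg.signals, tiny_cs.signals)

    def test_labels_pass_through(self, tiny_cs):
        eeg, _ = forward_mix(tiny_cs, 8, sensor_noise=0.1, seed=0)
        assert np.array_equal(eeg.target, tiny_cs.target)
        assert np.array_equal(eeg.angle, tiny_cs.angle)

    def test_sensor_shape(self, tiny_cs):
        eeg, model = forward_mix(tiny_cs, 8, sensor_noise=0.0, seed=1)
        assert eeg.signals.shape == (tiny_cs.n_trials, 8, tiny_cs.n_samples)
        assert model.L.shape == (8, 16)

    def test_mixing_is_linear(self, tiny_cs):
        two = EpochedDataset(
            signals=2.0 * tiny_cs.signals, target=tiny_cs.target,
            angle=tiny_cs.angle, fs=tiny_cs.fs, times=tiny_cs.times,
            kind="cs_true", roi_map=tiny_cs.roi_map,
        )
        e1, _ = forward_mix(tiny_cs, 8, sensor_noise=0.0, seed=2)
        e2, _ = forward_mix(two, 8, sensor_noise=0.0, seed=2)
        np.testing.assert_allclose(e2.signals, 2.0 * e1.signals, atol=1e-12)

    def test_inverse_recovers_with_identity_mixing(self, tiny_cs):
        eeg, model = forward_mix(
            tiny_cs, 16, sensor_noise=0.0, lam=1e-10, seed=0, identity=True
        )
        est = inverse_estimate(eeg, model)
        err = np.linalg.norm(est.signals - tiny_cs.signals) / np.linalg.norm(
            tiny_cs.signals
        )
        assert err < 1e-6
        assert est.kind == "cs_estimated"
        assert est.roi_map is tiny_cs.roi_map

    def test_inverse_output_is_rank_limited(self, tiny_cs):
        eeg, model = forward_mix(tiny_cs, 6, sensor_noise=0.0, seed=3)
        est = inverse_estimate(eeg, model)
        flat = est.signals.transpose(1, 0, 2).reshape(16, -1)
        assert np.linalg.matrix_rank(flat) <= 6

    def test_inverse_of_zero_is_zero(self, tiny_cs):
        eeg, model = forward_mix(tiny_cs, 8, sensor_noise=0.0, seed=4)
        zero = EpochedDataset(
            signals=np.zeros_like(eeg.signals), target=eeg.target,
            angle=eeg.angle, fs=eeg.fs, times=eeg.times, kind="eeg",
        )
        est = inverse_estimate(zero, model)
        assert np.all(est.signals == 0.0)

    def test_sensor_count_mismatch_raises(self, tiny_cs):
        eeg, model = forward_mix(tiny_cs, 8, sensor_noise=0.0, seed=5)
        bad = EpochedDataset(
            signals=np.zeros((eeg.n_trials, 5, eeg.n_samples)),
            target=eeg.target, angle=eeg.angle, fs=eeg.fs, times=eeg.times,
            kind="eeg",
        )
        with pytest.raises(ValueError):
            inverse_estimate(bad, model)

    def test_too_few_sensors_rejected(self, tiny_cs):
        with pytest.raises(ConfigurationError):
            forward_mix(tiny_cs, 1, sensor_noise=0.0, seed=0)
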