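"""PCA + temporal-ICA factorization: oracles, round trips, invariants."""

import warnings

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from sklearn.exceptions import ConvergenceWarning

from cssynergy import (
    ConfigurationError,
    DegenerateInputError,
    EpochedDataset,
    PCAICA,
    SynergyConfig,
    TrialDesign,
    concat_trials,
    explained_variance,
    fit_pcaica,
    make_ground_truth,
    make_roi_map,
    project,
    reconstruct,
    synthesize_cs,
)
from tests.conftest import IDENTIFIABLE


def _random_dataset(n_trials=4, n_ch=5, fs=500.0, seed=0):
    rng = np.random.default_rng(seed)
    design = TrialDesign()
    n_s = design.n_samples
    return EpochedDataset(
        signals=rng.normal(size=(n_trials, n_ch, n_s)),
        target=np.tile(np.arange(1, 9), n_trials * 2)[:n_trials],
        angle=np.zeros(n_trials, dtype=int),
        fs=fs,
        times=design.times,
        kind="cs_true",
    )


class TestConcatTrials:
    def test_default_window_gives_fifty_columns_per_trial(self):
        ds = _random_dataset(n_trials=40)
        B = concat_trials(ds, window=(0.0, 1.0), fs_target=50.0)
        assert B.values.shape == (5, 2000)
        assert B.samples_per_trial == 50
        assert B.n_trials == 40

    def test_identity_path_is_raw_reshape(self):
        ds = _random_dataset(n_trials=3)
        B = concat_trials(ds, window=(-1.0, 2.0), fs_target=ds.fs)
        np.testing.assert_array_equal(B.per_trial(), ds.signals)

    def test_decimation_preserves_constant_channels(self):
        ds = _random_dataset(n_trials=2)
        ds.signals[:, 2, :] = 3.25
        B = concat_trials(ds)
        np.testing.assert_allclose(B.values[2], 3.25, atol=1e-9)

    def test_window_outside_epoch_rejected(self):
        ds = _random_dataset()
        with pytest.raises(ConfigurationError):
            concat_trials(ds, window=(1.5, 3.5))

    def test_noninteger_ratio_rejected(self):
        ds = _random_dataset()
        with pytest.raises(ConfigurationError):
            concat_trials(ds, fs_target=60.0)


def _planted_factorization(M=40, N=8, T=2000, seed=0):
    rng = np.random.default_rng(seed)
    W0 = rng.normal(size=(M, N))
    C0 = rng.laplace(size=(N, T))  # independent super-Gaussian rows
    return W0, C0, W0 @ C0


class TestFitPCAICA:
    def test_exact_factorization_reconstructs(self):
        _, _, B = _planted_factorization()
        m = PCAICA(n_components=8, random_state=0).fit(B.T)
        rec = m.inverse_transform(m.transform(B.T)).T
        assert np.linalg.norm(rec - B) / np.linalg.norm(B) < 1e-8

    def test_planted_weights_recovered_up_to_permutation_and_sign(self):
        W0, _, B = _planted_factorization()
        m = PCAICA(n_components=8, random_state=0).fit(B.T)
        W0n = W0 / np.linalg.norm(W0, axis=0)
        cos = np.abs(W0n.T @ (m.W_ / np.linalg.norm(m.W_, axis=0)))
        r, c = linear_sum_assignment(-cos)
        assert cos[r, c].mean() > 0.99

    def test_full_rank_fit_is_exact_and_matches_pca(self):
        rng = np.random.default_rng(3)
        B = rng.normal(size=(6, 500))
        m = PCAICA(n_components=6, random_state=0).fit(B.T)
        rec = m.inverse_transform(m.transform(B.T)).T
        assert np.linalg.norm(rec - B) / np.linalg.norm(B) < 1e-10

    def test_structural_invariants_on_every_fit(self):
        rng = np.random.default_rng(4)
        B = rng.normal(size=(10, 800)) + 0.1 * rng.laplace(size=(10, 800))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            m = PCAICA(n_components=5, random_state=1).fit(B.T)
        # orthonormal PCA basis
        assert np.max(np.abs(m.W_pca_.T @ m.W_pca_ - np.eye(5))) < 1e-8
        # invertible ICA mixing, exact composition
        assert abs(np.linalg.det(m.W_ica_)) > 0
        np.testing.assert_allclose(m.W_, m.W_pca_ @ m.W_ica_, atol=1e-15)

    def test_deterministic_under_fixed_seed(self):
        _, _, B = _planted_factorization(seed=5)
        m1 = PCAICA(n_components=8, random_state=7).fit(B.T)
        m2 = PCAICA(n_components=8, random_state=7).fit(B.T)
        assert np.array_equal(m1.W_, m2.W_)
        assert np.array_equal(m1.activations_, m2.activations_)

    def test_rank_deficient_request_rejected(self):
        rng = np.random.default_rng(6)
        low = rng.normal(size=(8, 3)) @ rng.normal(size=(3, 400))
        with pytest.raises(ConfigurationError):
            PCAICA(n_components=5).fit(low.T)

    def test_nonconvergence_is_flagged_not_fatal(self):
        rng = np.random.default_rng(7)
        B = rng.normal(size=(6, 2000))  # Gaussian data: ICA cannot converge fast
        with pytest.warns(ConvergenceWarning):
            m = PCAICA(n_components=4, max_iter=1, random_state=0).fit(B.T)
        assert m.converged_ is False
        assert hasattr(m, "W_")


@pytest.fixture(scope="module")
def fitted():
    ds = _random_dataset(n_trials=8, n_ch=12, seed=8)
    B = concat_trials(ds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = fit_pcaica(B, n_components=4, seed=2)
    return model, B


class TestProjection:

    def test_projection_left_inverts_reconstruction(self, fitted):
        model, B = fitted
        rng = np.random.default_rng(9)
        from cssynergy import ActivationMatrix

        C = ActivationMatrix(
            values=rng.normal(size=(4, B.values.shape[1])),
            trial_ids=B.trial_ids, sample_idx=B.sample_idx,
            fs=B.fs, window=B.window,
        )
        back = project(model, reconstruct(model, C))
        np.testing.assert_allclose(back.values, C.values, atol=1e-10)

    def test_training_data_projects_to_stored_activations(self, fitted):
        model, B = fitted
        C = project(model, B)
        np.testing.assert_allclose(C.values, model.activations_, atol=1e-9)

    def test_pseudoinverse_route_agrees(self, fitted):
        model, B = fitted
        Wpinv = np.linalg.pinv(model.W_)
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(30, model.W_.shape[0]))
            via_parts = model.transform(X)
            via_pinv = (X - model.mean_) @ Wpinv.T
            np.testing.assert_allclose(via_parts, via_pinv, atol=1e-10)

    def test_channel_mismatch_raises(self, fitted):
        model, _ = fitted
        with pytest.raises(ValueError):
            model.transform(np.zeros((10, 99)))


class TestReconstruct:
    def test_zero_activation_returns_training_mean(self):
        _, _, B = _planted_factorization(M=10, N=4, T=300, seed=10)
        m = PCAICA(n_components=4, random_state=0).fit(B.T)
        rec = m.inverse_transform(np.zeros((7, 4)))
        np.testing.assert_allclose(rec, np.tile(m.mean_, (7, 1)), atol=1e-12)

    def test_residual_equals_discarded_pca_energy(self):
        rng = np.random.default_rng(11)
        B = rng.normal(size=(12, 600))
        N = 5
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            m = PCAICA(n_components=N, random_state=0).fit(B.T)
        rec = m.inverse_transform(m.transform(B.T)).T
        resid2 = np.sum((B - rec) ** 2)
        s = np.linalg.svd(B - B.mean(axis=1, keepdims=True), compute_uv=False)
        np.testing.assert_allclose(resid2, np.sum(s[N:] ** 2), rtol=1e-10)


class TestExplainedVariance:
    def test_exact_rank_gives_one(self):
        _, _, B = _planted_factorization(M=10, N=4, T=300, seed=12)
        m = PCAICA(n_components=4, random_state=0).fit(B.T)
        assert m.explained_variance(B.T) == pytest.approx(1.0, abs=1e-10)

    def test_single_component_on_isotropic_noise_is_half(self):
        rng = np.random.default_rng(13)
        B = rng.normal(size=(2, 10_000))
        # N >= 2 is required, so measure via the PCA ratio of a 2-fit:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            m = PCAICA(n_components=2, random_state=0).fit(B.T)
        assert m.explained_variance_ratio_[0] == pytest.approx(0.5, abs=0.05)

    def test_matches_plain_pca_explained_variance(self):
        rng = np.random.default_rng(14)
        B = rng.normal(size=(9, 700)) * np.linspace(1, 3, 9)[:, None]
        N = 4
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            m = PCAICA(n_components=N, random_state=0).fit(B.T)
        ev = m.explained_variance(B.T)
        s = np.linalg.svd(B - B.mean(axis=1, keepdims=True), compute_uv=False)
        pca_ev = np.sum(s[:N] ** 2) / np.sum(s**2)
        assert ev == pytest.approx(pca_ev, abs=1e-12)

    def test_zero_variance_input_rejected(self):
        _, _, B = _planted_factorization(M=6, N=3, T=200, seed=15)
        m = PCAICA(n_components=3, random_state=0).fit(B.T)
        with pytest.raises(DegenerateInputError):
            m.explained_variance(np.tile(m.mean_, (50, 1)))


def test_planted_synergy_recovery_under_independent_activations():
    """With well-separated bumps and amplitude-dominated variation the
    planted activations are near-independent and the factorization recovers
    the planted weight columns (mean |cosine| > 0.95 over 10 seeds)."""
    scores = []
    for seed in range(10):
        roi = make_roi_map(60)
        gt = make_ground_truth(roi, 8, config=SynergyConfig(**IDENTIFIABLE), seed=seed)
        cs = synthesize_cs(gt, TrialDesign(n_epochs_per_condition=20), snr=10.0, seed=seed)
        B = concat_trials(cs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            m = fit_pcaica(B, n_components=8, seed=seed)
        Wm = m.W_ / np.linalg.norm(m.W_, axis=0)
        cos = np.abs(gt.W_true.T @ Wm)
        r, c = linear_sum_assignment(-cos)
        scores.append(cos[r, c].mean())
    assert np.mean(scores) > 0.95
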