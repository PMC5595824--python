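"""Brain-activity-synergy factorization: PCA followed by temporal ICA.

Pooled signals ``B`` (channels x concatenated timepoints) are approximated
as ``B ~ W C`` with ``W = W_pca W_ica`` and ``C = C_ica``: PCA reduces the
channel space to ``N`` orthonormal directions, and temporal ICA rotates the
retained subspace so the component time courses are statistically
independent.  Because the ICA mixing matrix is invertible, the PCAICA
reconstruction of any signal equals its plain N-component PCA
reconstruction; ICA only re-expresses the basis within the PCA subspace.

Conventions: rows are centred by the training mean (stored and reused for
projection of held-out data); ``W_ica`` columns are normalized to unit norm
so all scale lives in the activations ``C``; components are ordered by
descending activation variance, with signs flipped so each activation's
largest-magnitude value is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import decimate
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.validation import check_is_fitted

from .datasets import ConfigurationError, DegenerateInputError, EpochedDataset

__all__ = [
    "SignalMatrix",
    "ActivationMatrix",
    "concat_trials",
    "PCAICA",
    "fit_pcaica",
    "project",
    "reconstruct",
    "explained_variance",
]


@dataclass(frozen=True)
class SignalMatrix:
    """Channels x pooled-timepoints matrix with a (trial, sample) column map."""

    values: np.ndarray       # (M, T_pooled)
    trial_ids: np.ndarray    # (T_pooled,) original trial index per column
    sample_idx: np.ndarray   # (T_pooled,) within-window sample index per column
    fs: float
    window: tuple[float, float]

    def __post_init__(self):
        if self.values.shape[1] != self.trial_ids.size or (
            self.values.shape[1] != self.sample_idx.size
        ):
            raise ConfigurationError("column map must cover all pooled columns")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return np.unique(self.trial_ids).size

    @property
    def samples_per_trial(self) -> int:
        return int(np.max(self.sample_idx)) + 1

    def per_trial(self) -> np.ndarray:
        """Reshape back to (n_trials, channels, samples_per_trial).

        Assumes trial-major column ordering, as produced by
        :func:`concat_trials`.
        """
        n, s = self.n_trials, self.samples_per_trial
        return (
            self.values.reshape(self.n_channels, n, s).transpose(1, 0, 2)
        )


@dataclass(frozen=True)
class ActivationMatrix:
    """Synergy-activations counterpart of :class:`SignalMatrix` (N x T)."""

    values: np.ndarray
    trial_ids: np.ndarray
    sample_idx: np.ndarray
    fs: float
    window: tuple[float, float]
    role: str = "train"      # "train" or "decode"

    @property
    def n_components(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return np.unique(self.trial_ids).size

    @property
    def samples_per_trial(self) -> int:
        return int(np.max(self.sample_idx)) + 1

    def per_trial(self) -> np.ndarray:
        n, s = self.n_trials, self.samples_per_trial
        return self.values.reshape(self.n_components, n, s).transpose(1, 0, 2)


def concat_trials(
    dataset: EpochedDataset,
    window: tuple[float, float] = (0.0, 1.0),
    fs_target: float = 50.0,
) -> SignalMatrix:
    """Decimate, window and horizontally concatenate trials.

    Signals are anti-alias filtered (zero-phase FIR) and decimated to
    ``fs_target``, then restricted to ``window`` (start-inclusive,
    end-exclusive) and concatenated trial-major into a channels x
    ``n_trials * samples`` matrix.  With the defaults (50 Hz, 0-1 s) each
    trial contributes 50 columns.  If ``fs_target`` equals the dataset
    rate, no filtering is applied.
    """
    fs = dataset.fs
    ratio = fs / fs_target
    if abs(ratio - round(ratio)) > 1e-9:
        raise ConfigurationError("fs_target must divide the dataset sampling rate")
    q = int(round(ratio))
    if not (dataset.times[0] - 1e-9 <= window[0] < window[1] <= dataset.times[-1] + 1.0 / fs + 1e-9):
        raise ConfigurationError("window must lie within the epoch")

    if q == 1:
        sig = dataset.signals
        times = dataset.times
    else:
        sig = decimate(dataset.signals, q, ftype="fir", zero_phase=True, axis=-1)
        times = dataset.times[::q]

    mask = (times >= window[0] - 1e-9) & (times < window[1] - 1e-9)
    sig = sig[:, :, mask]
    n_trials, n_ch, n_s = sig.shape
    values = sig.transpose(1, 0, 2).reshape(n_ch, n_trials * n_s)
    trial_ids = np.repeat(np.arange(n_trials), n_s)
    sample_idx = np.tile(np.arange(n_s), n_trials)
    return SignalMatrix(
        values=values,
        trial_ids=trial_ids,
        sample_idx=sample_idx,
        fs=fs_target,
        window=(float(window[0]), float(window[1])),
    )


class PCAICA(TransformerMixin, BaseEstimator):
    """PCA followed by temporal ICA within the retained subspace.

    Fit on ``X`` of shape (n_timepoints, n_channels); :meth:`transform`
    returns activations of shape (n_timepoints, n_components).

    Parameters
    ----------
    n_components : int or None
        Number of synergies ``N``.  Defaults to ``min(n_samples, n_features)``.
    max_iter, tol : FastICA stopping rule (tanh/logcosh contrast,
        symmetric decorrelation).
    random_state : seed for the ICA initial rotation.

    Attributes
    ----------
    mean_ : (M,) training channel means.
    W_pca_ : (M, N) orthonormal principal directions.
    W_ica_ : (N, N) invertible ICA mixing with unit-norm columns.
    W_ : (M, N) composed synergy weights ``W_pca_ @ W_ica_``.
    explained_variance_ratio_ : PCA variance fractions of the N components.
    converged_ : whether ICA converged within ``max_iter``.
    """

    def __init__(
        self,
        n_components: int | None = None,
        *,
        max_iter: int = 1000,
        tol: float = 1e-6,
        random_state: int | None = 0,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (timepoints x channels)")
        n_t, n_ch = X.shape
        N = self.n_components if self.n_components is not None else min(n_t, n_ch)
        if N < 2:
            raise ConfigurationError("need at least 2 components")
        if N > min(n_t, n_ch):
            raise ConfigurationError("n_components exceeds min(timepoints, channels)")

        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank = int(np.sum(s > s[0] * max(n_t, n_ch) * np.finfo(float).eps))
        if N > rank:
            raise ConfigurationError(
                f"n_components={N} exceeds the numerical rank {rank} of the data"
            )
        W_pca = Vt[:N].T                                   # (M, N)
        C_pca = Xc @ W_pca                                 # (T, N), zero-mean cols
        total_var = float(np.sum(s**2))
        self.explained_variance_ratio_ = (s[:N] ** 2) / total_var

        ica = FastICA(
            n_components=N,
            whiten="unit-variance",
            fun="logcosh",
            algorithm="parallel",
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.random_state,
        )
        converged = True
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            S = ica.fit_transform(C_pca)                   # (T, N)
        for w in caught:
            if issubclass(w.category, ConvergenceWarning):
                converged = False
                warnings.warn(
                    "FastICA did not converge; result returned with "
                    "converged_=False",
                    ConvergenceWarning,
                    stacklevel=2,
                )
        W_ica = ica.mixing_.copy()                         # (N, N)
        # Absorb the (tiny) ICA mean back: C_pca ~ S @ W_ica.T + ica.mean_.
        # Fold the residual mean into the channel mean for exactness.
        self.mean_ = self.mean_ + W_pca @ ica.mean_
        C = S.T                                            # (N, T)

        # Scale convention: unit-norm W_ica columns, scale in C.
        norms = np.linalg.norm(W_ica, axis=0)
        W_ica /= norms[None, :]
        C *= norms[:, None]
        # Order by descending activation variance; sign so peak is positive.
        order = np.argsort(-np.var(C, axis=1), kind="stable")
        W_ica = W_ica[:, order]
        C = C[order]
        signs = np.sign(C[np.arange(N), np.argmax(np.abs(C), axis=1)])
        signs[signs == 0] = 1.0
        W_ica *= signs[None, :]
        C *= signs[:, None]

        self.W_pca_ = W_pca
        self.W_ica_ = W_ica
        self.W_ica_inv_ = np.linalg.inv(W_ica)
        self.W_ = W_pca @ W_ica
        self.n_components_ = N
        self.converged_ = converged
        self.n_iter_ = int(getattr(ica, "n_iter_", -1))
        self.activations_ = C                              # training C (N, T)
        return self

    def transform(self, X) -> np.ndarray:
        """Project (held-out) signals onto the fitted synergy basis."""
        check_is_fitted(self, "W_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.W_pca_.shape[0]:
            raise ValueError(
                f"channel mismatch: X has {X.shape[1]}, model expects "
                f"{self.W_pca_.shape[0]}"
            )
        return (X - self.mean_) @ self.W_pca_ @ self.W_ica_inv_.T

    def inverse_transform(self, C) -> np.ndarray:
        """Map activations (n_timepoints, N) back to the channel space."""
        check_is_fitted(self, "W_")
        C = np.asarray(C, dtype=float)
        if C.shape[1] != self.n_components_:
            raise ValueError("activation column count must equal n_components")
        return C @ self.W_.T + self.mean_

    def explained_variance(self, X) -> float:
        """Fraction of centred signal variance captured by the N synergies."""
        check_is_fitted(self, "W_")
        X = np.asarray(X, dtype=float)
        Xc = X - self.mean_
        denom = float(np.sum(Xc**2))
        if denom == 0.0:
            raise DegenerateInputError("explained variance undefined for zero-variance input")
        resid = Xc - self.inverse_transform(self.transform(X)) + self.mean_
        return 1.0 - float(np.sum(resid**2)) / denom


# ---------------------------------------------------------------------------
# Functional wrappers over SignalMatrix / ActivationMatrix containers.

def fit_pcaica(
    B: SignalMatrix,
    n_components: int,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int | None = 0,
) -> PCAICA:
    """Fit the synergy factorization on pooled training signals."""
    model = PCAICA(
        n_components=n_components, max_iter=max_iter, tol=tol, random_state=seed
    )
    return model.fit(B.values.T)


def project(model: PCAICA, B: SignalMatrix, role: str = "decode") -> ActivationMatrix:
    """Held-out projection C_dec = W_ica^-1 W_pca^T (B - mean)."""
    values = model.transform(B.values.T).T
    return ActivationMatrix(
        values=values,
        trial_ids=B.trial_ids,
        sample_idx=B.sample_idx,
        fs=B.fs,
        window=B.window,
        role=role,
    )


def reconstruct(model: PCAICA, C: ActivationMatrix) -> SignalMatrix:
    """Map activations back to the channel space: W C + mean."""
    values = model.inverse_transform(C.values.T).T
    return SignalMatrix(
        values=values,
        trial_ids=C.trial_ids,
        sample_idx=C.sample_idx,
        fs=C.fs,
        window=C.window,
    )


def explained_variance(model: PCAICA, B: SignalMatrix) -> float:
    return model.explained_variance(B.values.T)
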