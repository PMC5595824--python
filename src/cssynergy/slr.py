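"""Sparse Bayesian logistic regression with ARD (Laplace approximation).

Each binary decoder places an independent zero-mean Gaussian prior with
precision ``alpha_i`` on every weight (automatic relevance determination);
the logistic likelihood is handled through the Laplace approximation at
the posterior mode.  A feature whose optimized precision diverges is
excluded with its weight exactly zero; the surviving features are the
decoder's *selected* features.

Two ARD optimizers are provided:

``solver="sequential"`` (default)
    Fast marginal-likelihood optimization: starting from an empty model,
    features are added, re-estimated, or deleted one at a time by the
    action that most increases the Laplace-approximate evidence, with the
    posterior mode re-found after every change.  This is the standard
    constructive algorithm of the sparse-Bayes family and remains stable
    when features vastly outnumber trials or form strongly correlated
    blocks.

``solver="prune"``
    The classical iterate-and-prune schedule: Newton-optimize the
    penalized log-likelihood to the mode for the current ``alpha``, update
    every precision in parallel (MacKay effective-degrees rule
    ``alpha_i <- (1 - alpha_i S_ii) / w_i^2``, or the EM rule as a config
    switch), and prune features whose precision exceeds ``alpha_prune``.
    When active features outnumber trials the Newton direction and the
    covariance diagonal are computed through the Woodbury identity in the
    n x n dual space.

With ``ard=False`` the precisions stay fixed at ``alpha_init`` and the fit
reduces exactly to ridge-penalized logistic regression.

Eight such decoders, one per class versus the rest, form the multiclass
decoder: a test trial is assigned the class whose decoder reports the
highest probability (ties broken to the lowest class index).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .datasets import LabelError

__all__ = [
    "FeatureMatrix",
    "SparseLogisticRegressionARD",
    "OneVsRestSLR",
    "fit_binary_slr",
    "fit_ovr",
    "predict",
    "selected_features",
]

_BIAS_ALPHA = 1e-10  # effectively unpenalized; the bias is never pruned


@dataclass
class FeatureMatrix:
    """Trials x features design with a (component, timepoint) feature map."""

    X: np.ndarray                      # (n_trials, n_features)
    feature_map: pd.DataFrame          # columns: feature, component, timepoint, time_s
    labels: np.ndarray | None = None   # per-trial class in 1..8

    def __post_init__(self):
        if self.feature_map.shape[0] != self.X.shape[1]:
            raise ValueError("feature map must cover every column")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.X.shape[0],):
                raise LabelError("labels must match the trial count")


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _log_sigmoid(z):
    return -np.logaddexp(0.0, -z)


class SparseLogisticRegressionARD(BaseEstimator, ClassifierMixin):
    """Binary sparse logistic regression with Laplace-ARD feature selection.

    Parameters
    ----------
    alpha_init : initial/fixed ARD precision (prune solver and ridge mode).
    alpha_prune : precision above which a feature is excluded.
    max_iter : maximum outer iterations (prune) / model updates (sequential).
    tol : convergence threshold on ``max |delta w|`` of the mode search.
    solver : ``"sequential"`` or ``"prune"`` (see module docstring).
    update_rule : ``"mackay"`` or ``"em"`` precision update (prune solver).
    ard : if False, fit ridge-penalized logistic regression at
        ``alpha_init`` with no selection.
    standardize : z-score features by training statistics before fitting
        (ARD decisions are scale-sensitive).  Constant features get unit
        scale.

    Attributes
    ----------
    coef_ : (n_features,) weights on the standardized feature scale;
        excluded features are exactly zero.
    intercept_ : bias term (never penalized, never pruned).
    alpha_ : final precisions (``inf`` for excluded features).
    active_ : boolean mask of selected features.
    converged_, n_iter_ : optimizer convergence information.
    """

    def __init__(
        self,
        alpha_init: float = 1.0,
        alpha_prune: float = 1e8,
        max_iter: int = 500,
        tol: float = 1e-5,
        solver: str = "sequential",
        update_rule: str = "mackay",
        ard: bool = True,
        standardize: bool = True,
    ):
        self.alpha_init = alpha_init
        self.alpha_prune = alpha_prune
        self.max_iter = max_iter
        self.tol = tol
        self.solver = solver
        self.update_rule = update_rule
        self.ard = ard
        self.standardize = standardize

    # ------------------------------------------------------------------
    # shared numerics

    @staticmethod
    def _objective(Xw, y01, w, alpha):
        z = Xw * (2.0 * y01 - 1.0)
        return float(np.sum(_log_sigmoid(z)) - 0.5 * np.sum(alpha * w**2))

    @staticmethod
    def _newton_direction_and_sdiag(X, r, alpha, grad):
        """Solve (A + X^T R X) dw = grad and return diag of the inverse.

        Primal Cholesky when d <= n, Woodbury dual otherwise.
        """
        n, d = X.shape
        if d <= n:
            H = (X.T * r) @ X
            H[np.diag_indices(d)] += alpha
            Hinv = np.linalg.inv(H)
            return Hinv @ grad, np.diag(Hinv).copy()
        Dinv = 1.0 / alpha
        U = X.T * np.sqrt(r)                     # (d, n)
        V = Dinv[:, None] * U
        K = U.T @ V
        K[np.diag_indices(n)] += 1.0
        Kinv = np.linalg.inv(K)
        dw = Dinv * grad - V @ (Kinv @ (V.T @ grad))
        sdiag = Dinv - np.einsum("ij,jk,ik->i", V, Kinv, V)
        return dw, sdiag

    def _newton_to_mode(self, Xa, wa, aa, y01, max_steps=50):
        """Newton with step-halving to the posterior mode for fixed alpha."""
        total_delta = 0.0
        sdiag = None
        for _ in range(max_steps):
            z = Xa @ wa
            p = _sigmoid(z)
            grad = Xa.T @ (y01 - p) - aa * wa
            r = np.clip(p * (1.0 - p), 1e-10, None)
            dw, sdiag = self._newton_direction_and_sdiag(Xa, r, aa, grad)
            j0 = self._objective(z, y01, wa, aa)
            step = 1.0
            for _ in range(30):
                wn = wa + step * dw
                if self._objective(Xa @ wn, y01, wn, aa) >= j0 - 1e-12:
                    break
                step *= 0.5
            else:
                break  # no ascent at machine scale: at the mode
            delta = float(np.max(np.abs(wn - wa)))
            total_delta = max(total_delta, delta)
            wa = wn
            if delta < self.tol:
                break
        return wa, sdiag, total_delta

    # ------------------------------------------------------------------
    # solvers

    def _fit_ridge(self, Xb, y01):
        d1 = Xb.shape[1]
        alpha = np.full(d1, float(self.alpha_init))
        alpha[-1] = _BIAS_ALPHA
        w = np.zeros(d1)
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            w, _, delta = self._newton_to_mode(Xb, w, alpha, y01)
            if delta < self.tol:
                converged = True
                break
        active = np.ones(d1, dtype=bool)
        return w, alpha, active, converged, n_iter

    def _fit_prune(self, Xb, y01):
        n, d1 = Xb.shape
        d = d1 - 1
        w = np.zeros(d1)
        alpha = np.full(d1, float(self.alpha_init))
        alpha[-1] = _BIAS_ALPHA
        active = np.ones(d1, dtype=bool)
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            act = np.flatnonzero(active)
            Xa = Xb[:, act]
            wa, sdiag, delta = self._newton_to_mode(Xa, w[act], alpha[act], y01)
            w[act] = wa
            aa = alpha[act]
            if self.update_rule == "mackay":
                gamma = 1.0 - aa * sdiag
                with np.errstate(divide="ignore", invalid="ignore"):
                    new_alpha = gamma / (wa**2)
            elif self.update_rule == "em":
                new_alpha = 1.0 / (wa**2 + sdiag)
            else:
                raise ValueError(f"unknown update_rule {self.update_rule!r}")
            new_alpha = np.where(
                np.isfinite(new_alpha) & (new_alpha > 0), new_alpha, np.inf
            )
            new_alpha = np.clip(new_alpha, 1e-12, np.inf)
            new_alpha[act == d] = _BIAS_ALPHA
            log_dalpha = float(
                np.max(np.abs(np.log(np.minimum(new_alpha, 1e30))
                              - np.log(np.minimum(aa, 1e30))))
            )
            alpha[act] = new_alpha
            alpha[-1] = _BIAS_ALPHA
            prune = active & (alpha > self.alpha_prune)
            prune[-1] = False
            pruned_now = bool(prune.any())
            if pruned_now:
                w[prune] = 0.0
                active[prune] = False
            # converged: stable mode, settled precisions, nothing pruned
            if delta < self.tol and not pruned_now and log_dalpha < 1e-2:
                converged = True
                break
        return w, alpha, active, converged, n_iter

    def _fit_sequential(self, Xb, y01):
        """Constructive marginal-likelihood ARD (add / re-estimate / delete).

        Maintains the Laplace posterior on the current active set; for
        every feature the sparsity/quality factors ``S, Q`` of the
        approximate evidence are computed through the Woodbury form of
        ``C^-1 = B - B X_S Sigma X_S^T B`` and the action with the largest
        evidence gain is applied.  Stops when no action improves the
        evidence by more than a small threshold.
        """
        n, d1 = Xb.shape
        bias = d1 - 1
        alpha = np.full(d1, np.inf)
        alpha[bias] = _BIAS_ALPHA
        in_model = np.zeros(d1, dtype=bool)
        in_model[bias] = True
        dl_tol = 1e-4

        def refit(S, w0):
            Xa = Xb[:, S]
            aa = alpha[S]
            wa, _, _ = self._newton_to_mode(Xa, w0, aa, y01)
            z = Xa @ wa
            p = _sigmoid(z)
            r = np.clip(p * (1.0 - p), 1e-10, None)
            H = (Xa.T * r) @ Xa
            H[np.diag_indices(len(S))] += aa
            Sigma = np.linalg.inv(H)
            return wa, Sigma, p, r

        S = [bias]
        wa, Sigma, p, r = refit(S, np.zeros(1))
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            Xa = Xb[:, S]
            BX = Xa * r[:, None]                       # (n, |S|)
            T = Xb.T @ BX                              # (d1, |S|)
            Sp = (Xb**2).T @ r - np.einsum("ij,jk,ik->i", T, Sigma, T)
            Bt = BX @ wa + (y01 - p)                   # B @ working response
            Qp = Xb.T @ Bt - T @ (Sigma @ (Xa.T @ Bt))
            Sp = np.clip(Sp, 1e-12, None)

            # leave-one-out factors for in-model features
            s_f = Sp.copy()
            q_f = Qp.copy()
            denom = alpha - Sp
            im = in_model.copy()
            im[bias] = False
            safe = im & (denom > 1e-12)
            s_f[safe] = alpha[safe] * Sp[safe] / denom[safe]
            q_f[safe] = alpha[safe] * Qp[safe] / denom[safe]
            theta = q_f**2 - s_f

            dL = np.full(d1, -np.inf)
            with np.errstate(divide="ignore", invalid="ignore"):
                # additions
                cand = (~in_model) & (theta > 0)
                ratio = Qp[cand] ** 2 / Sp[cand]
                dL[cand] = 0.5 * (ratio - 1.0 - np.log(ratio))
                # deletions (theta <= 0, in model, not bias)
                dele = im & (theta <= 0) & np.isfinite(alpha)
                if dele.any():
                    a = alpha[dele]
                    dL[dele] = 0.5 * (
                        Qp[dele] ** 2 / (Sp[dele] - a) - np.log1p(-Sp[dele] / a)
                    )
                # re-estimations
                rees = im & (theta > 0) & (safe)
                if rees.any():
                    a_new = s_f[rees] ** 2 / theta[rees]
                    inv_d = 1.0 / a_new - 1.0 / alpha[rees]
                    with np.errstate(divide="ignore"):
                        dL[rees] = 0.5 * (
                            Qp[rees] ** 2 / (Sp[rees] + 1.0 / inv_d)
                            - np.log1p(Sp[rees] * inv_d)
                        )
            dL[bias] = -np.inf
            dL[~np.isfinite(dL)] = -np.inf
            best = int(np.argmax(dL))
            if dL[best] <= dl_tol:
                converged = True
                break

            if not in_model[best]:                       # add
                alpha[best] = s_f[best] ** 2 / theta[best]
                if alpha[best] > self.alpha_prune:
                    converged = True
                    break
                in_model[best] = True
                S.append(best)
                wa = np.append(wa, 0.0)
            elif theta[best] > 0:                        # re-estimate
                alpha[best] = s_f[best] ** 2 / theta[best]
                if alpha[best] > self.alpha_prune:       # prune by threshold
                    k = S.index(best)
                    S.pop(k)
                    wa = np.delete(wa, k)
                    in_model[best] = False
                    alpha[best] = np.inf
            else:                                        # delete
                k = S.index(best)
                S.pop(k)
                wa = np.delete(wa, k)
                in_model[best] = False
                alpha[best] = np.inf
            wa, Sigma, p, r = refit(S, wa)

        w = np.zeros(d1)
        w[S] = wa
        active = in_model.copy()
        return w, alpha, active, converged, n_iter

    # ------------------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise LabelError("binary fit requires exactly two classes in y")
        self.classes_ = classes
        y01 = (y == classes[1]).astype(float)

        if self.standardize:
            self.feature_mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0] = 1.0
            self.feature_scale_ = scale
            Xs = (X - self.feature_mean_) / self.feature_scale_
        else:
            self.feature_mean_ = np.zeros(X.shape[1])
            self.feature_scale_ = np.ones(X.shape[1])
            Xs = X

        n = Xs.shape[0]
        Xb = np.hstack([Xs, np.ones((n, 1))])

        if not self.ard:
            w, alpha, active, converged, n_iter = self._fit_ridge(Xb, y01)
        elif self.solver == "sequential":
            w, alpha, active, converged, n_iter = self._fit_sequential(Xb, y01)
        elif self.solver == "prune":
            w, alpha, active, converged, n_iter = self._fit_prune(Xb, y01)
        else:
            raise ValueError(f"unknown solver {self.solver!r}")

        if not converged:
            warnings.warn(
                "SLR did not converge within max_iter; returning last iterate",
                RuntimeWarning,
                stacklevel=2,
            )
        self.coef_ = w[:-1].copy()
        self.intercept_ = float(w[-1])
        self.alpha_ = np.where(active[:-1], alpha[:-1], np.inf)
        self.active_ = active[:-1].copy()
        self.converged_ = converged
        self.n_iter_ = n_iter
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.coef_.size:
            raise ValueError(
                f"feature mismatch: X has {X.shape[1]}, model expects {self.coef_.size}"
            )
        Xs = (X - self.feature_mean_) / self.feature_scale_
        return Xs @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        p = _sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        p = _sigmoid(self.decision_function(X))
        return np.where(p >= 0.5, self.classes_[1], self.classes_[0])


class OneVsRestSLR(BaseEstimator, ClassifierMixin):
    """8-class decoder: one sparse binary decoder per class versus the rest.

    ``predict`` returns the class whose binary decoder assigns the highest
    probability; exact ties go to the lowest class index.
    """

    def __init__(
        self,
        alpha_init: float = 1.0,
        alpha_prune: float = 1e8,
        max_iter: int = 500,
        tol: float = 1e-5,
        solver: str = "sequential",
        update_rule: str = "mackay",
        standardize: bool = True,
    ):
        self.alpha_init = alpha_init
        self.alpha_prune = alpha_prune
        self.max_iter = max_iter
        self.tol = tol
        self.solver = solver
        self.update_rule = update_rule
        self.standardize = standardize

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise LabelError("need at least two classes")
        counts = np.array([np.sum(y == c) for c in self.classes_])
        if np.any(counts < 2):
            raise LabelError("every class needs at least 2 trials")
        self.estimators_ = {}
        for c in self.classes_:
            est = SparseLogisticRegressionARD(
                alpha_init=self.alpha_init,
                alpha_prune=self.alpha_prune,
                max_iter=self.max_iter,
                tol=self.tol,
                solver=self.solver,
                update_rule=self.update_rule,
                standardize=self.standardize,
            )
            est.fit(X, (y == c).astype(int))
            self.estimators_[int(c)] = est
        self.converged_ = all(e.converged_ for e in self.estimators_.values())
        return self

    def predict_proba(self, X):
        """Per-class one-vs-rest probabilities (not normalized across classes)."""
        check_is_fitted(self, "estimators_")
        return np.column_stack(
            [self.estimators_[int(c)].predict_proba(X)[:, 1] for c in self.classes_]
        )

    def predict(self, X):
        proba = self.predict_proba(X)
        # argmax returns the first (lowest-class) index on exact ties
        return self.classes_[np.argmax(proba, axis=1)]

    def selected_features(
        self, feature_map: pd.DataFrame | None = None
    ) -> dict[int, np.ndarray] | pd.DataFrame:
        """Per-class selected feature indices, bias excluded.

        With a ``feature_map`` the result is a tidy frame with columns
        ``class_label, feature, component, timepoint, time_s``.
        """
        check_is_fitted(self, "estimators_")
        sel = {
            int(c): np.flatnonzero(self.estimators_[int(c)].active_)
            for c in self.classes_
        }
        if feature_map is None:
            return sel
        rows = []
        for c, feats in sel.items():
            sub = feature_map.iloc[feats].copy()
            sub.insert(0, "class_label", c)
            rows.append(sub)
        if not rows:
            return pd.DataFrame(columns=["class_label", *feature_map.columns])
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Functional wrappers.

def fit_binary_slr(X, y, **hyper) -> SparseLogisticRegressionARD:
    return SparseLogisticRegressionARD(**hyper).fit(X, y)


def fit_ovr(X, labels, **hyper) -> OneVsRestSLR:
    return OneVsRestSLR(**hyper).fit(X, labels)


def predict(decoder: OneVsRestSLR, X):
    """Predicted class and the per-class probabilities."""
    return decoder.predict(X), decoder.predict_proba(X)


def selected_features(decoder: OneVsRestSLR, feature_map=None):
    return decoder.selected_features(feature_map)
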