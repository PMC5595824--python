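"""Non-parametric permutation tests and Benjamini-Hochberg FDR.

The paired test compares two per-fold accuracy vectors by random sign
flips of the fold-wise differences; the vs-chance test reshuffles true
labels within each fold and rescores.  Both use the add-one p-value
``p = (exceedances + 1) / n_perm`` (capped at 1), so an observed
statistic that beats all 10,000 permutations yields exactly 1.00e-04.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "FDRResult",
    "permutation_test_paired",
    "permutation_test_vs_chance",
    "bh_fdr",
]


@dataclass(frozen=True)
class PermutationResult:
    statistic: float
    n_perm: int
    exceedances: int
    p_value: float
    sided: str
    seed: int | None


@dataclass(frozen=True)
class FDRResult:
    p_values: np.ndarray
    q_values: np.ndarray
    rejected: np.ndarray
    q: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"p": self.p_values, "q_value": self.q_values, "rejected": self.rejected}
        )


def _finalize(stat, null, sided, n_perm, seed):
    if sided == "two":
        exc = int(np.sum(np.abs(null) >= abs(stat) - 1e-12))
    elif sided == "greater":
        exc = int(np.sum(null >= stat - 1e-12))
    elif sided == "less":
        exc = int(np.sum(null <= stat + 1e-12))
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    p = min(1.0, (exc + 1) / n_perm)
    return PermutationResult(
        statistic=float(stat), n_perm=int(n_perm), exceedances=exc,
        p_value=float(p), sided=sided, seed=seed,
    )


def permutation_test_paired(
    acc_a, acc_b, n_perm: int = 10_000, sided: str = "two", seed: int | None = 0
) -> PermutationResult:
    """Sign-flip permutation test on paired per-fold accuracies.

    Statistic: ``mean(acc_a - acc_b)``; null: independent random sign
    flips of the paired differences.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.size == 0 or a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length non-empty fold vectors")
    if a.size < 2:
        raise ValueError("need at least 2 folds")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    d = a - b
    stat = float(np.mean(d))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
    null = (signs * d).mean(axis=1)
    return _finalize(stat, null, sided, n_perm, seed)


def permutation_test_vs_chance(
    predictions,
    true_labels,
    chance: float = 1.0 / 8.0,
    n_perm: int = 10_000,
    seed: int | None = 0,
    fold_ids=None,
    sided: str = "greater",
) -> PermutationResult:
    """Permutation test of decoding accuracy against chance level.

    Statistic: ``accuracy - chance``; null: true labels shuffled within
    each fold (all trials as one fold if ``fold_ids`` is None) and
    rescored against the fixed predictions.
    """
    pred = np.asarray(predictions).ravel()
    true = np.asarray(true_labels).ravel()
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("predictions and labels must be equal-length and non-empty")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    n = pred.size
    fold_ids = (
        np.zeros(n, dtype=int) if fold_ids is None else np.asarray(fold_ids).ravel()
    )
    stat = float(np.mean(pred == true) - chance)
    rng = np.random.default_rng(seed)

    null = np.zeros(n_perm)
    for f in np.unique(fold_ids):
        m = fold_ids == f
        tf, pf = true[m], pred[m]
        k = tf.size
        # vectorized within-fold shuffles: argsort of random keys
        keys = rng.random(size=(n_perm, k))
        order = np.argsort(keys, axis=1)
        null += np.sum(tf[order] == pf[None, :], axis=1)
    null = null / n - chance
    return _finalize(stat, null, sided, n_perm, seed)


def bh_fdr(pvals, q: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up FDR with cumulative-minimum q-values."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return FDRResult(p_values=p, q_values=qvals, rejected=rejected, q=float(q))
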