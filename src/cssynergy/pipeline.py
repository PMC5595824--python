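"""End-to-end decoding pipeline.

Orchestrates the estimation/decoding split, the synergy factorization for
the ``*_synergy`` signal kinds, feature construction over the 0-1 s,
50 Hz analysis window, leave-one-trial-out cross-validated 8-class
decoding under intrinsic and extrinsic labelings, and the four-way signal
comparison (EEG, EEG synergy, CS, CS synergy).

Leakage discipline: the synergy basis is fitted only on the estimation
half; within the decoding half, each CV fold's test trials never enter
decoder training.  Fold membership depends only on the split seed, so all
signal kinds are evaluated on identical test-trial sets and paired
statistics are valid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .coordinates import EXT, INT, LabelScheme, ext_label, int_label
from .datasets import ConfigurationError, EpochedDataset
from .decomposition import PCAICA, ActivationMatrix, concat_trials, fit_pcaica, project
from .slr import FeatureMatrix, OneVsRestSLR

__all__ = [
    "CVConfig",
    "CVResult",
    "split_trials",
    "build_features",
    "run_decoding",
    "compare_signal_types",
    "SIGNAL_KINDS",
]

SIGNAL_KINDS = ("eeg", "eeg_synergy", "cs", "cs_synergy")


@dataclass(frozen=True)
class CVConfig:
    """Configuration of one cross-validated decoding run."""

    signal_kind: str = "cs_synergy"
    n_synergies: int | None = None       # None -> kind-dependent default
    window: tuple[float, float] = (0.0, 1.0)
    fs_target: float = 50.0
    slr: Mapping[str, object] = field(default_factory=dict)
    accuracy_threshold: float = 0.40     # feature-analysis fold filter
    seed: int = 0                        # split seed
    ica_seed: int = 0
    fold_unit: str = "condition"         # "condition" (16/fold) or "class" (8/fold)

    def __post_init__(self):
        if self.signal_kind not in SIGNAL_KINDS:
            raise ConfigurationError(f"unknown signal kind {self.signal_kind!r}")
        if not 0.0 < self.accuracy_threshold < 1.0:
            raise ConfigurationError("accuracy threshold must be in (0, 1)")
        if self.fold_unit not in ("condition", "class"):
            raise ConfigurationError("fold_unit must be 'condition' or 'class'")


@dataclass
class CVResult:
    """Per-fold accuracies, predictions and selected features of one run."""

    fold_accuracies: np.ndarray            # (n_folds,)
    predictions: np.ndarray                # (n_folds, n_test_per_fold)
    true_classes: np.ndarray               # (n_folds, n_test_per_fold)
    test_trials: np.ndarray                # (n_folds, n_test_per_fold) decoding-half rows
    selected: list[pd.DataFrame]           # per fold: class_label/feature/... table
    fold_converged: np.ndarray             # (n_folds,) bool
    feature_map: pd.DataFrame
    config: CVConfig
    scheme: str
    synergy_model: PCAICA | None = None

    @property
    def n_folds(self) -> int:
        return self.fold_accuracies.size

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def split_trials(
    dataset: EpochedDataset, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Split each (target, angle) condition into estimation/decoding halves.

    Returns sorted trial-index arrays ``(estimation, decoding)``; the two
    halves are disjoint and exhaustive, with equal counts per condition.
    """
    rng = np.random.default_rng(seed)
    est, dec = [], []
    for (tgt, ang), idx in dataset.condition_indices().items():
        if idx.size == 0:
            raise ConfigurationError(f"condition (target={tgt}, angle={ang}) has no trials")
        if idx.size % 2:
            raise ConfigurationError(
                f"condition (target={tgt}, angle={ang}) has an odd trial count"
            )
        perm = rng.permutation(idx)
        est.append(perm[: idx.size // 2])
        dec.append(perm[idx.size // 2 :])
    return np.sort(np.concatenate(est)), np.sort(np.concatenate(dec))


def _feature_map(n_components: int, sample_idx: np.ndarray, fs: float,
                 window: tuple[float, float]) -> pd.DataFrame:
    n_s = int(np.max(sample_idx)) + 1
    comp = np.repeat(np.arange(n_components), n_s)
    tp = np.tile(np.arange(n_s), n_components)
    return pd.DataFrame(
        {
            "feature": np.arange(n_components * n_s),
            "component": comp,
            "timepoint": tp,
            "time_s": window[0] + tp / fs,
        }
    )


def build_features(
    source: EpochedDataset | ActivationMatrix,
    window: tuple[float, float] = (0.0, 1.0),
    fs_target: float = 50.0,
) -> FeatureMatrix:
    """Flatten (component x timepoint) per trial into a feature row.

    ``source`` may be an epoched dataset (raw channels become components)
    or an activation matrix from a fitted synergy model.  Feature order is
    component-major: ``feature = component * n_timepoints + timepoint``.
    """
    if isinstance(source, ActivationMatrix):
        if (abs(source.window[0] - window[0]) > 1e-9
                or abs(source.window[1] - window[1]) > 1e-9
                or abs(source.fs - fs_target) > 1e-9):
            raise ConfigurationError(
                "activation window/rate differs from the requested analysis window"
            )
        per_trial = source.per_trial()            # (n, N, T_w)
    else:
        B = concat_trials(source, window=window, fs_target=fs_target)
        per_trial = B.per_trial()
    n, n_comp, n_s = per_trial.shape
    X = per_trial.reshape(n, n_comp * n_s)
    fmap = _feature_map(n_comp, np.arange(n_s), fs_target, window)
    return FeatureMatrix(X=X, feature_map=fmap)


def _fold_assignment(
    classes: np.ndarray, target: np.ndarray, angle: np.ndarray,
    unit: str, seed: int,
) -> np.ndarray:
    """Assign each decoding-half trial to a CV fold.

    Within each fold-unit group (a (target, angle) condition, or a class),
    trials are dealt round-robin to folds after a seeded shuffle; every
    group must contribute exactly one trial to each fold.
    """
    rng = np.random.default_rng(seed + 1)
    if unit == "condition":
        keys = [(int(t), int(a)) for t, a in zip(target, angle)]
    else:
        keys = [int(c) for c in classes]
    folds = np.full(classes.size, -1, dtype=int)
    uniq = list(dict.fromkeys(keys))
    sizes = {k: keys.count(k) for k in uniq}
    n_folds = min(sizes.values())
    if len(set(sizes.values())) != 1:
        raise ConfigurationError("fold-unit groups must have equal trial counts")
    for k in uniq:
        idx = np.flatnonzero([kk == k for kk in keys])
        perm = rng.permutation(idx)
        folds[perm] = np.arange(idx.size) % n_folds
    return folds


def run_decoding(
    dataset: EpochedDataset, scheme: LabelScheme, cfg: CVConfig
) -> CVResult:
    """Leave-one-trial-out cross-validated 8-class decoding.

    For synergy kinds the factorization is fitted once on the estimation
    half and the decoding half is projected onto it; raw kinds use the
    channels directly.  Each fold holds out exactly one decoding-half
    trial per fold-unit group, trains the one-vs-rest SLR decoder on the
    rest, and records accuracy, predictions and per-class selected
    features.
    """
    est_idx, dec_idx = split_trials(dataset, seed=cfg.seed)
    dec_ds = dataset.subset(dec_idx)

    model: PCAICA | None = None
    if cfg.signal_kind.endswith("synergy"):
        n_syn = cfg.n_synergies
        if n_syn is None:
            n_syn = min(dataset.n_channels, 32)
        B_est = concat_trials(dataset.subset(est_idx), cfg.window, cfg.fs_target)
        model = fit_pcaica(B_est, n_components=n_syn, seed=cfg.ica_seed)
        B_dec = concat_trials(dec_ds, cfg.window, cfg.fs_target)
        feats = build_features(project(model, B_dec), cfg.window, cfg.fs_target)
    else:
        feats = build_features(dec_ds, cfg.window, cfg.fs_target)

    classes = scheme.apply(dec_ds.target, dec_ds.angle)
    folds = _fold_assignment(
        classes, dec_ds.target, dec_ds.angle, cfg.fold_unit, cfg.seed
    )
    n_folds = int(folds.max()) + 1

    accs, preds, trues, tests, sels, convs = [], [], [], [], [], []
    for f in range(n_folds):
        test = np.flatnonzero(folds == f)
        train = np.flatnonzero(folds != f)
        dec = OneVsRestSLR(**dict(cfg.slr))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dec.fit(feats.X[train], classes[train])
        if not dec.converged_:
            warnings.warn(
                f"fold {f}: at least one binary decoder did not converge "
                "(fold retained, flagged)",
                RuntimeWarning,
                stacklevel=2,
            )
        yhat = dec.predict(feats.X[test])
        accs.append(np.mean(yhat == classes[test]))
        order = np.argsort(classes[test], kind="stable")
        preds.append(yhat[order])
        trues.append(classes[test][order])
        tests.append(test[order])
        sels.append(dec.selected_features(feats.feature_map))
        convs.append(dec.converged_)

    return CVResult(
        fold_accuracies=np.array(accs),
        predictions=np.array(preds),
        true_classes=np.array(trues),
        test_trials=np.array(tests),
        selected=sels,
        fold_converged=np.array(convs, dtype=bool),
        feature_map=feats.feature_map,
        config=cfg,
        scheme=scheme.name,
        synergy_model=model,
    )


def default_n_synergies(kind: str, n_sensors: int, n_channels: int) -> int:
    """Kind-dependent synergy count: the sensor count for EEG synergy, and
    min(sensor count, channel count) — a sensor-rank proxy — for CS synergy."""
    if kind == "eeg_synergy":
        return n_sensors
    if kind == "cs_synergy":
        return min(n_sensors, n_channels)
    raise ConfigurationError(f"{kind!r} has no synergy count")


def compare_signal_types(
    cs_true: EpochedDataset,
    cs_estimated: EpochedDataset,
    eeg: EpochedDataset,
    schemes: tuple[LabelScheme, ...] = (INT, EXT),
    cfg: CVConfig | None = None,
    n_synergies: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], CVResult]]:
    """Decode all four signal kinds under each labeling with shared folds.

    Returns a tidy table (signal_kind, scheme, mean_accuracy, n_folds) and
    the per-run :class:`CVResult` objects keyed by (kind, scheme).  The CS
    kinds use the inverse-estimated channel signals (the analysis-facing
    analog of estimated cortical currents); ``cs_true`` is checked for
    design consistency.
    """
    cfg = cfg or CVConfig()
    datasets = {"eeg": eeg, "eeg_synergy": eeg, "cs": cs_estimated,
                "cs_synergy": cs_estimated}
    for name, ds in (("cs_true", cs_true), ("cs_estimated", cs_estimated), ("eeg", eeg)):
        if ds.n_trials != cs_true.n_trials or not (
            np.array_equal(ds.target, cs_true.target)
            and np.array_equal(ds.angle, cs_true.angle)
        ):
            raise ConfigurationError(f"dataset {name} does not share the trial design")

    n_sensors = eeg.n_channels
    n_channels = cs_estimated.n_channels
    rows = []
    results: dict[tuple[str, str], CVResult] = {}
    for kind in SIGNAL_KINDS:
        for scheme in schemes:
            if kind.endswith("synergy"):
                if n_synergies and kind in n_synergies:
                    n_syn = n_synergies[kind]
                else:
                    n_syn = default_n_synergies(kind, n_sensors, n_channels)
            else:
                n_syn = None
            run_cfg = CVConfig(
                signal_kind=kind,
                n_synergies=n_syn,
                window=cfg.window,
                fs_target=cfg.fs_target,
                slr=cfg.slr,
                accuracy_threshold=cfg.accuracy_threshold,
                seed=cfg.seed,
                ica_seed=cfg.ica_seed,
                fold_unit=cfg.fold_unit,
            )
            res = run_decoding(datasets[kind], scheme, run_cfg)
            results[(kind, scheme.name)] = res
            rows.append(
                {
                    "signal_kind": kind,
                    "scheme": scheme.name,
                    "mean_accuracy": res.mean_accuracy,
                    "n_folds": res.n_folds,
                }
            )
    return pd.DataFrame(rows), results
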