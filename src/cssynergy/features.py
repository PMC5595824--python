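"""Quantification of decoder-selected features and dominant synergy areas.

Counts how often each (class, feature) pair survives ARD pruning across
cross-validation folds whose accuracy clears a quality threshold (0.40,
i.e. above three times the 12.5% chance level of the 8-class problem),
ranks the top features by selection count over time and brain area, and
assigns each synergy the ROI carrying its highest mean absolute weight
(the synergy's *dominant area*).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ROI_NAMES, ROIMap
from .decomposition import PCAICA
from .pipeline import CVResult

__all__ = [
    "FeatureSelectionCount",
    "DominantAreaTable",
    "count_selected",
    "top_features",
    "dominant_area",
]


@dataclass(frozen=True)
class FeatureSelectionCount:
    """Selection counts per (class, feature) over qualifying folds."""

    counts: pd.DataFrame          # class_label, feature, component, timepoint, time_s, count
    n_qualifying_folds: int
    n_folds: int
    threshold: float
    scheme: str


@dataclass(frozen=True)
class DominantAreaTable:
    """Per-synergy dominant ROI and per-ROI synergy counts (Table-1 analog)."""

    dominant: tuple[str, ...]           # per-synergy ROI name
    counts: pd.Series                   # per-ROI synergy counts (all 6 ROIs)
    mean_weight: pd.DataFrame           # synergy x ROI mean |weight|

    @property
    def n_synergies(self) -> int:
        return len(self.dominant)


def count_selected(cv: CVResult, threshold: float | None = None) -> FeatureSelectionCount:
    """Count (class, feature) selections over folds with accuracy > threshold."""
    thr = cv.config.accuracy_threshold if threshold is None else float(threshold)
    qualifying = [
        sel
        for acc, sel in zip(cv.fold_accuracies, cv.selected)
        if acc > thr
    ]
    if not qualifying:
        warnings.warn(
            f"no folds exceed the {thr:.0%} accuracy threshold; empty counts",
            UserWarning,
            stacklevel=2,
        )
        empty = pd.DataFrame(
            columns=["class_label", "feature", "component", "timepoint",
                     "time_s", "count"]
        )
        return FeatureSelectionCount(empty, 0, cv.n_folds, thr, cv.scheme)
    allsel = pd.concat(qualifying, ignore_index=True)
    counts = (
        allsel.groupby(["class_label", "feature", "component", "timepoint", "time_s"])
        .size()
        .rename("count")
        .reset_index()
    )
    return FeatureSelectionCount(counts, len(qualifying), cv.n_folds, thr, cv.scheme)


def top_features(
    counts: FeatureSelectionCount,
    k: int = 10,
    component_areas: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Top-k features by total selection count across classes.

    Ties are broken by earlier time then lower feature index, so the
    ranking is a deterministic function of the counts.  ``component_areas``
    maps a component id to its brain area (the dominant ROI for synergy
    components, the channel's own ROI for CS channels); if given, an
    ``area`` column is added.  Returns all features if fewer than ``k``
    are distinct.
    """
    df = counts.counts
    if df.empty:
        return pd.DataFrame(
            columns=["feature", "component", "timepoint", "time_s",
                     "count", "n_classes", "area"][: 7 if component_areas else 6]
        )
    agg = (
        df.groupby(["feature", "component", "timepoint", "time_s"])
        .agg(count=("count", "sum"), n_classes=("class_label", "nunique"))
        .reset_index()
        .sort_values(
            ["count", "time_s", "feature"], ascending=[False, True, True],
            kind="stable",
        )
        .head(k)
        .reset_index(drop=True)
    )
    if component_areas is not None:
        agg["area"] = agg["component"].map(component_areas)
    return agg


def dominant_area(
    model: PCAICA | np.ndarray,
    roi_map: ROIMap,
    absolute: bool = True,
) -> DominantAreaTable:
    """Assign each synergy the ROI with the highest mean (|)weight(|).

    ``model`` may be a fitted :class:`PCAICA` (its composed ``W_`` is used)
    or a raw channels x synergies weight matrix.  Unassigned channels are
    excluded; ROIs with zero channels are excluded from the argmax with a
    warning.  Ties break to the first ROI in canonical order.
    """
    W = model.W_ if isinstance(model, PCAICA) else np.asarray(model, dtype=float)
    if W.shape[0] != roi_map.n_channels:
        raise ValueError(
            f"weight rows ({W.shape[0]}) must match roi_map channels "
            f"({roi_map.n_channels})"
        )
    vals = np.abs(W) if absolute else W
    n_syn = W.shape[1]
    means = np.full((n_syn, len(ROI_NAMES)), -np.inf)
    for i, name in enumerate(ROI_NAMES):
        ch = roi_map.channels_in(name)
        if ch.size == 0:
            warnings.warn(
                f"ROI {name} has no channels; excluded from dominance",
                UserWarning,
                stacklevel=2,
            )
            continue
        means[:, i] = vals[ch].mean(axis=0)
    dom_idx = np.argmax(means, axis=1)   # first max wins ties
    dominant = tuple(ROI_NAMES[i] for i in dom_idx)
    cnt = pd.Series(
        [dominant.count(name) for name in ROI_NAMES], index=list(ROI_NAMES),
        name="n_synergies",
    )
    mw = pd.DataFrame(
        np.where(np.isfinite(means), means, np.nan), columns=list(ROI_NAMES)
    )
    mw.index.name = "synergy"
    return DominantAreaTable(dominant=dominant, counts=cnt, mean_weight=mw)
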