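"""Shared fixtures: small seeded synthetic datasets for fast tests."""

from __future__ import annotations

import numpy as np
import pytest

from cssynergy import (
    GroundTruthSynergySet,
    SynergyConfig,
    TrialDesign,
    make_ground_truth,
    make_roi_map,
    synthesize_cs,
)

#: Generator config whose planted activations are close to statistically
#: independent (narrow, well-separated bumps; amplitude variation dominates
#: the shared baseline) — the regime in which temporal ICA is identifiable.
IDENTIFIABLE = dict(
    peak_jitter=0.15, width_range=(0.03, 0.05), baseline=0.2, amp_noise=0.4
)


@pytest.fixture(scope="session")
def small_design():
    return TrialDesign(n_epochs_per_condition=8)


@pytest.fixture(scope="session")
def small_cs(small_design):
    """24 channels, 4 strongly tuned intrinsic synergies, high snr."""
    roi = make_roi_map(24)
    cfg = SynergyConfig(frames=("intrinsic",), kappa=1.5, amp_noise=0.1)
    gt = make_ground_truth(roi, 4, config=cfg, seed=11)
    cs = synthesize_cs(gt, small_design, snr=50.0, seed=11)
    return gt, cs


@pytest.fixture(scope="session")
def rank1_gt():
    """A single hand-built synergy with no tuning and no amplitude noise."""
    roi = make_roi_map(12)
    w = np.zeros(12)
    w[roi.channels_in("PMv")] = [0.6, 0.8]
    return GroundTruthSynergySet(
        W_true=w[:, None],
        rois=(("PMv",),),
        peak_time=np.array([0.3]),
        width=np.array([0.1]),
        frame=("none",),
        phi=np.array([0.0]),
        kappa=np.array([0.0]),
        baseline=np.array([1.5]),
        amp_noise=0.0,
        roi_map=roi,
    )


@pytest.fixture
def informative_problem():
    """2 informative features (class means +-2, unit noise) + 50 noise features."""
    rng = np.random.default_rng(1)
    n = 200
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, 52))
    X[:, 0] += np.where(y == 1, 2.0, -2.0)
    X[:, 1] += np.where(y == 1, -2.0, 2.0)
    Xt = rng.normal(size=(400, 52))
    yt = rng.integers(0, 2, 400)
    Xt[:, 0] += np.where(yt == 1, 2.0, -2.0)
    Xt[:, 1] += np.where(yt == 1, -2.0, 2.0)
    return X, y, Xt, yt
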