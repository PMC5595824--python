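"""Core data containers for epoched cortical-current / EEG-like signals.

The containers mirror the objects that flow through a synergy-decoding
analysis: an epoched multichannel dataset with per-trial task labels, a
channel-to-ROI assignment over the six motor regions of interest, the
trial design of the 8-direction finger-movement task, the planted ground
truth used by the simulator, and the linear sensor mixing/inverse model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: The six motor ROIs, in fixed canonical order.
ROI_NAMES: tuple[str, ...] = ("hand_knob", "M1", "PMd", "PMv", "SMA", "preSMA")

#: Recognised dataset kinds.
DATASET_KINDS: tuple[str, ...] = ("cs_true", "cs_estimated", "eeg", "activation")


class ConfigurationError(ValueError):
    """An invalid analysis or simulation configuration."""


class LabelError(ValueError):
    """An out-of-range or inconsistent task label."""


class DegenerateInputError(ValueError):
    """Input on which the requested quantity is undefined (e.g. zero variance)."""


class FormatError(IOError):
    """A persisted file that cannot be read as the expected format/version."""


@dataclass(frozen=True)
class ROIMap:
    """Assignment of channels to the six motor ROIs.

    ``assignment[c]`` is an index into :data:`ROI_NAMES`, or ``-1`` for an
    unassigned channel.  Every channel maps to at most one ROI.
    """

    assignment: np.ndarray  # (n_channels,) int, -1 = unassigned

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        if a.ndim != 1:
            raise ConfigurationError("ROI assignment must be a 1-D vector")
        if a.size and (a.min() < -1 or a.max() >= len(ROI_NAMES)):
            raise ConfigurationError("ROI assignment indices out of range")
        object.__setattr__(self, "assignment", a)

    @property
    def n_channels(self) -> int:
        return self.assignment.size

    @property
    def roi_names(self) -> tuple[str, ...]:
        return ROI_NAMES

    @property
    def counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.assignment == i))
            for i, name in enumerate(ROI_NAMES)
        }

    def channels_in(self, roi: str | int) -> np.ndarray:
        """Channel indices assigned to ``roi`` (name or index)."""
        idx = ROI_NAMES.index(roi) if isinstance(roi, str) else int(roi)
        return np.flatnonzero(self.assignment == idx)


@dataclass(frozen=True)
class TrialDesign:
    """Trial structure of the 8-target, two-elbow-angle finger task.

    Eight targets 45 degrees apart, performed at elbow angles 0 and 90
    degrees; epochs run from 1 s before to 2 s after target onset, with
    EMG onset around 200 ms and initial cursor movement around 400 ms.
    """

    n_epochs_per_condition: int = 80
    window: tuple[float, float] = (-1.0, 2.0)
    fs_raw: float = 500.0
    emg_onset: float = 0.200
    cursor_onset: float = 0.400
    targets: tuple[int, ...] = tuple(range(1, 9))
    angles: tuple[int, ...] = (0, 90)

    def __post_init__(self) -> None:
        if tuple(self.targets) != tuple(range(1, 9)):
            raise ConfigurationError("design requires the 8 canonical targets 1..8")
        if tuple(self.angles) != (0, 90):
            raise ConfigurationError("design requires elbow angles (0, 90)")
        if not (self.window[0] < 0.0 < self.window[1]):
            raise ConfigurationError("epoch window must straddle target onset")
        if not (0.0 < self.emg_onset < self.cursor_onset < self.window[1]):
            raise ConfigurationError(
                "need 0 < emg_onset < cursor_onset < window end"
            )
        if self.n_epochs_per_condition < 1:
            raise ConfigurationError("need at least one epoch per condition")
        if self.fs_raw <= 0:
            raise ConfigurationError("sampling rate must be positive")

    @property
    def n_conditions(self) -> int:
        return len(self.targets) * len(self.angles)

    @property
    def n_trials(self) -> int:
        return self.n_conditions * self.n_epochs_per_condition

    @property
    def n_samples(self) -> int:
        return int(round((self.window[1] - self.window[0]) * self.fs_raw))

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to target onset (end-exclusive)."""
        return self.window[0] + np.arange(self.n_samples) / self.fs_raw


@dataclass(frozen=True)
class GroundTruthSynergySet:
    """Planted synergies: spatial weights plus temporal/tuning parameters.

    ``W_true`` holds one unit-norm column per synergy; each synergy has an
    ROI support set, a Gaussian temporal bump (peak, width), a tuning frame
    (``intrinsic``/``extrinsic``/``none``), a preferred direction ``phi``,
    tuning depth ``kappa`` and baseline amplitude ``baseline``.
    """

    W_true: np.ndarray                   # (n_channels, n_true)
    rois: tuple[tuple[str, ...], ...]    # per-synergy ROI support
    peak_time: np.ndarray                # (n_true,) seconds
    width: np.ndarray                    # (n_true,) seconds
    frame: tuple[str, ...]               # per-synergy tuning frame
    phi: np.ndarray                      # (n_true,) radians
    kappa: np.ndarray                    # (n_true,) tuning depth
    baseline: np.ndarray                 # (n_true,) baseline amplitude
    amp_noise: float                     # amplitude noise s.d.
    roi_map: ROIMap

    @property
    def n_true(self) -> int:
        return self.W_true.shape[1]

    @property
    def n_channels(self) -> int:
        return self.W_true.shape[0]


@dataclass
class EpochedDataset:
    """Trials x channels x samples signals with per-trial task labels."""

    signals: np.ndarray      # (n_trials, n_channels, n_samples)
    target: np.ndarray       # (n_trials,) int in 1..8
    angle: np.ndarray        # (n_trials,) int in {0, 90}
    fs: float
    times: np.ndarray        # (n_samples,) seconds relative to onset
    kind: str
    roi_map: ROIMap | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.target = np.asarray(self.target, dtype=int)
        self.angle = np.asarray(self.angle, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        if self.signals.ndim != 3:
            raise ConfigurationError("signals must be trials x channels x samples")
        n = self.signals.shape[0]
        if self.target.shape != (n,) or self.angle.shape != (n,):
            raise LabelError("label arrays must match the trial count")
        if self.times.shape != (self.signals.shape[2],):
            raise ConfigurationError("time axis must match the sample count")
        if self.kind not in DATASET_KINDS:
            raise ConfigurationError(f"unknown dataset kind {self.kind!r}")

    @property
    def n_trials(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[2]

    def subset(self, idx: Sequence[int] | np.ndarray) -> "EpochedDataset":
        """A new dataset restricted to the given trial indices."""
        idx = np.asarray(idx, dtype=int)
        return EpochedDataset(
            signals=self.signals[idx],
            target=self.target[idx],
            angle=self.angle[idx],
            fs=self.fs,
            times=self.times,
            kind=self.kind,
            roi_map=self.roi_map,
        )

    def condition_indices(self) -> dict[tuple[int, int], np.ndarray]:
        """Trial indices grouped by (target, angle) condition."""
        out: dict[tuple[int, int], np.ndarray] = {}
        for ang in (0, 90):
            for tgt in range(1, 9):
                out[(tgt, ang)] = np.flatnonzero(
                    (self.target == tgt) & (self.angle == ang)
                )
        return out


@dataclass(frozen=True)
class MixingModel:
    """Linear sensor mixing and its ridge-regularised inverse filter.

    ``L`` maps channel signals to sensors; ``G = L.T (L L.T + lam I)^-1``
    maps sensors back to the channel space.
    """

    L: np.ndarray            # (n_sensors, n_channels)
    G: np.ndarray            # (n_channels, n_sensors)
    lam: float
    sensor_noise: float
    roi_map: ROIMap | None = None

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ConfigurationError("ridge parameter must be positive")

    @property
    def n_sensors(self) -> int:
        return self.L.shape[0]

    @property
    def n_channels(self) -> int:
        return self.L.shape[1]
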