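"""Seeded synthetic cortical-current data with planted synergy structure.

The generator plants ``N_true`` spatial synergies over a 6-ROI channel
space.  Each synergy has a unit-norm weight column supported on one or a
few ROIs, a Gaussian temporal bump peaking near EMG onset (~200 ms) or
cursor onset (~400 ms), and a cosine direction tuning expressed in either
the intrinsic (finger-movement) or extrinsic (target-direction) frame.
A row-correlated random linear mixing stage plus a ridge inverse filter
stand in for the EEG forward/inverse problem, so every downstream stage
(synergy factorization, decoding, feature analysis) can be exercised on
data with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .coordinates import direction_angle, ext_label, int_label
from .datasets import (
    ROI_NAMES,
    ConfigurationError,
    EpochedDataset,
    GroundTruthSynergySet,
    MixingModel,
    ROIMap,
    TrialDesign,
)

__all__ = [
    "SynergyConfig",
    "make_roi_map",
    "make_ground_truth",
    "synthesize_cs",
    "forward_mix",
    "inverse_estimate",
]


def make_roi_map(
    n_channels: int,
    proportions: dict[str, float] | None = None,
    seed: int | None = None,
) -> ROIMap:
    """Assign contiguous channel blocks to the 6 motor ROIs.

    ``proportions`` maps ROI name to the fraction of channels it receives
    (default: equal sixths).  Block sizes are ``floor(n_channels * p)``;
    leftover channels at the end remain unassigned.  Every ROI must end up
    with at least one channel.
    """
    if n_channels < 12:
        raise ConfigurationError("need at least 12 channels for 6 ROIs")
    if proportions is None:
        proportions = {name: 1.0 / 6.0 for name in ROI_NAMES}
    props = [float(proportions.get(name, 0.0)) for name in ROI_NAMES]
    if any(p < 0 for p in props) or sum(props) > 1.0 + 1e-9:
        raise ConfigurationError("proportions must be nonnegative and sum to <= 1")
    counts = [int(np.floor(n_channels * p)) for p in props]
    if any(c < 1 for c in counts):
        raise ConfigurationError(
            "configuration leaves an ROI without channels; "
            "increase n_channels or its proportion"
        )
    assignment = np.full(n_channels, -1, dtype=int)
    start = 0
    for i, c in enumerate(counts):
        assignment[start : start + c] = i
        start += c
    return ROIMap(assignment=assignment)


@dataclass(frozen=True)
class SynergyConfig:
    """Tuning/waveform ranges for planted synergies.

    Peaks alternate between the EMG-onset and cursor-onset epochs with a
    small jitter; tuning frames cycle through ``frames``.  ``kappa`` is the
    cosine tuning depth, ``baseline`` the direction-independent amplitude,
    ``amp_noise`` the s.d. of the trial-to-trial amplitude jitter
    (truncated so amplitudes stay nonnegative).
    """

    single_roi_fraction: float = 0.5
    frames: tuple[str, ...] = ("intrinsic", "extrinsic")
    peak_times: tuple[float, float] = (0.200, 0.400)
    peak_jitter: float = 0.050
    width_range: tuple[float, float] = (0.080, 0.150)
    kappa: float = 0.8
    baseline: float = 1.0
    amp_noise: float = 0.1
    intrinsic_shift: int = 2

    def __post_init__(self):
        if not 0.0 <= self.single_roi_fraction <= 1.0:
            raise ConfigurationError("single_roi_fraction must be in [0, 1]")
        for f in self.frames:
            if f not in ("intrinsic", "extrinsic", "none"):
                raise ConfigurationError(f"unknown tuning frame {f!r}")


def make_ground_truth(
    roi_map: ROIMap,
    n_true: int,
    config: SynergyConfig | None = None,
    seed: int = 0,
) -> GroundTruthSynergySet:
    """Plant ``n_true`` synergies with unit-norm, ROI-localized weights.

    A ``single_roi_fraction`` share of synergies live in a single ROI; the
    rest span 2-3 distant ROIs (the multi-area synchronization pattern).
    Deterministic given ``seed``.
    """
    if n_true < 2:
        raise ConfigurationError("need at least 2 planted synergies")
    if n_true >= roi_map.n_channels:
        raise ConfigurationError("n_true must be smaller than the channel count")
    cfg = config or SynergyConfig()
    rng = np.random.default_rng(seed)
    n_ch = roi_map.n_channels

    n_single = int(round(n_true * cfg.single_roi_fraction))
    W = np.zeros((n_ch, n_true))
    rois: list[tuple[str, ...]] = []
    for j in range(n_true):
        if j < n_single:
            chosen = tuple(rng.choice(ROI_NAMES, size=1, replace=False))
        else:
            k = int(rng.integers(2, 4))  # 2 or 3 ROIs
            chosen = tuple(rng.choice(ROI_NAMES, size=k, replace=False))
        rois.append(chosen)
        for name in chosen:
            ch = roi_map.channels_in(name)
            W[ch, j] = rng.normal(size=ch.size)
        W[:, j] /= np.linalg.norm(W[:, j])

    half = np.arange(n_true) % 2
    peaks = np.where(half == 0, cfg.peak_times[0], cfg.peak_times[1]).astype(float)
    peaks = peaks + rng.uniform(-cfg.peak_jitter, cfg.peak_jitter, size=n_true)
    widths = rng.uniform(*cfg.width_range, size=n_true)
    frames = tuple(cfg.frames[j % len(cfg.frames)] for j in range(n_true))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n_true)
    kappa = np.where(
        np.array(frames) == "none", 0.0, float(cfg.kappa)
    ).astype(float)
    baseline = np.full(n_true, float(cfg.baseline))

    return GroundTruthSynergySet(
        W_true=W,
        rois=tuple(rois),
        peak_time=peaks,
        width=widths,
        frame=frames,
        phi=phi,
        kappa=kappa,
        baseline=baseline,
        amp_noise=float(cfg.amp_noise),
        roi_map=roi_map,
    )


def _activation_waveforms(gt: GroundTruthSynergySet, times: np.ndarray) -> np.ndarray:
    """Unit-peak Gaussian bumps, one row per synergy."""
    t = times[None, :]
    return np.exp(
        -0.5 * ((t - gt.peak_time[:, None]) / gt.width[:, None]) ** 2
    )


def _trial_amplitudes(
    gt: GroundTruthSynergySet,
    target: np.ndarray,
    angle: np.ndarray,
    rng: np.random.Generator,
    intrinsic_shift: int = 2,
) -> np.ndarray:
    """Per-trial, per-synergy amplitudes a_j = b + kappa cos(theta - phi) + eps."""
    n_trials = target.size
    theta_ext = direction_angle(ext_label(target, angle))
    theta_int = direction_angle(int_label(target, angle, shift=intrinsic_shift))
    amps = np.empty((n_trials, gt.n_true))
    for j in range(gt.n_true):
        if gt.frame[j] == "intrinsic":
            theta = theta_int
        elif gt.frame[j] == "extrinsic":
            theta = theta_ext
        else:
            theta = np.zeros(n_trials)
        a = gt.baseline[j] + gt.kappa[j] * np.cos(theta - gt.phi[j])
        if gt.amp_noise > 0:
            a = a + rng.normal(scale=gt.amp_noise, size=n_trials)
        amps[:, j] = np.clip(a, 0.0, None)
    return amps


def synthesize_cs(
    gt: GroundTruthSynergySet,
    design: TrialDesign | None = None,
    snr: float = 10.0,
    seed: int = 0,
    intrinsic_shift: int = 2,
) -> EpochedDataset:
    """Generate epoched cortical-current signals B = W_true C + noise.

    Per trial and synergy j, the activation is ``a_j * g(t; peak_j, width_j)``
    with a task-tuned amplitude ``a_j``.  Additive Gaussian channel noise is
    scaled so the per-channel signal-power / noise-power ratio equals
    ``snr`` (``snr=inf`` for noiseless output).
    """
    if not snr > 0:
        raise ConfigurationError("snr must be positive")
    design = design or TrialDesign()
    rng = np.random.default_rng(seed)

    target = np.concatenate(
        [
            np.full(design.n_epochs_per_condition, t)
            for a in design.angles
            for t in design.targets
        ]
    )
    angle = np.concatenate(
        [
            np.full(design.n_epochs_per_condition, a)
            for a in design.angles
            for t in design.targets
        ]
    )
    times = design.times
    G = _activation_waveforms(gt, times)                  # (N, T)
    amps = _trial_amplitudes(gt, target, angle, rng, intrinsic_shift)
    C = amps[:, :, None] * G[None, :, :]                  # (trials, N, T)
    signals = np.einsum("cj,njt->nct", gt.W_true, C)

    if np.isfinite(snr):
        power = np.mean(signals**2, axis=(0, 2))          # per-channel
        power = np.where(power > 0, power, np.median(power[power > 0]))
        noise_std = np.sqrt(power / snr)
        signals = signals + rng.normal(size=signals.shape) * noise_std[None, :, None]

    return EpochedDataset(
        signals=signals,
        target=target,
        angle=angle,
        fs=design.fs_raw,
        times=times,
        kind="cs_true",
        roi_map=gt.roi_map,
    )


def forward_mix(
    cs: EpochedDataset,
    n_sensors: int = 32,
    sensor_noise: float = 1.0,
    lam: float = 1e-2,
    seed: int = 0,
    identity: bool = False,
) -> tuple[EpochedDataset, MixingModel]:
    """Mix channel signals into sensor space through a smooth random matrix.

    ``L`` is a spatially smoothed (row-correlated) Gaussian random matrix
    with unit-norm rows; ``identity=True`` forces ``L = I`` (requires
    ``n_sensors == n_channels``).  Sensor noise s.d. is ``sensor_noise``
    times the RMS of the mixed signals.  The returned :class:`MixingModel`
    carries the ridge inverse filter ``G = L.T (L L.T + lam I)^-1``.
    """
    if cs.kind != "cs_true":
        raise ConfigurationError("forward_mix expects a cs_true dataset")
    if n_sensors < 2:
        raise ConfigurationError("need at least 2 sensors")
    rng = np.random.default_rng(seed)
    n_ch = cs.n_channels
    if identity:
        if n_sensors != n_ch:
            raise ConfigurationError("identity mixing requires n_sensors == n_channels")
        L = np.eye(n_ch)
    else:
        L = rng.normal(size=(n_sensors, n_ch))
        L = gaussian_filter(L, sigma=(1.0, 2.0), mode="nearest")
        L /= np.linalg.norm(L, axis=1, keepdims=True)

    G = L.T @ np.linalg.inv(L @ L.T + lam * np.eye(n_sensors))

    mixed = np.einsum("sc,nct->nst", L, cs.signals)
    if sensor_noise > 0:
        rms = np.sqrt(np.mean(mixed**2))
        mixed = mixed + rng.normal(size=mixed.shape) * (sensor_noise * rms)

    eeg = EpochedDataset(
        signals=mixed,
        target=cs.target.copy(),
        angle=cs.angle.copy(),
        fs=cs.fs,
        times=cs.times,
        kind="eeg",
        roi_map=None,
    )
    model = MixingModel(
        L=L, G=G, lam=float(lam), sensor_noise=float(sensor_noise),
        roi_map=cs.roi_map,
    )
    return eeg, model


def inverse_estimate(eeg: EpochedDataset, model: MixingModel) -> EpochedDataset:
    """Apply the inverse filter G to sensor signals, channel space restored."""
    if eeg.kind != "eeg":
        raise ConfigurationError("inverse_estimate expects an eeg dataset")
    if eeg.n_channels != model.n_sensors:
        raise ValueError(
            f"sensor count mismatch: data has {eeg.n_channels}, "
            f"model expects {model.n_sensors}"
        )
    est = np.einsum("cs,nst->nct", model.G, eeg.signals)
    return EpochedDataset(
        signals=est,
        target=eeg.target.copy(),
        angle=eeg.angle.copy(),
        fs=eeg.fs,
        times=eeg.times,
        kind="cs_estimated",
        roi_map=model.roi_map,
    )
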