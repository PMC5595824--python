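"""HDF5 persistence, run configuration, and end-to-end orchestration."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import __version__
from .coordinates import EXT, INT
from .datasets import (
    DATASET_KINDS,
    ConfigurationError,
    EpochedDataset,
    FormatError,
    ROIMap,
    TrialDesign,
)
from .decomposition import PCAICA
from .features import count_selected, dominant_area, top_features
from .pipeline import CVConfig, compare_signal_types
from .simulate import (
    SynergyConfig,
    forward_mix,
    inverse_estimate,
    make_ground_truth,
    make_roi_map,
    synthesize_cs,
)
from .stats import bh_fdr, permutation_test_paired

log = logging.getLogger("cssynergy")

FORMAT_VERSION = "1"


# ---------------------------------------------------------------------------
# Dataset / model persistence

def write_dataset(dataset: EpochedDataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["kind"] = dataset.kind
        f.attrs["fs"] = dataset.fs
        f.attrs["time0"] = float(dataset.times[0])
        f.create_dataset("signals", data=dataset.signals)
        f.create_dataset("times", data=dataset.times)
        g = f.create_group("labels")
        g.create_dataset("target", data=dataset.target)
        g.create_dataset("angle", data=dataset.angle)
        if dataset.roi_map is not None:
            f.create_dataset("roi_assignment", data=dataset.roi_map.assignment)
            f.attrs["roi_names"] = json.dumps(list(dataset.roi_map.roi_names))


def read_dataset(path) -> EpochedDataset:
    try:
        with h5py.File(path, "r") as f:
            version = f.attrs.get("format_version")
            if version != FORMAT_VERSION:
                raise FormatError(
                    f"unsupported dataset format: expected version "
                    f"{FORMAT_VERSION!r}, found {version!r}"
                )
            kind = str(f.attrs["kind"])
            if kind not in DATASET_KINDS:
                raise FormatError(f"unknown dataset kind tag {kind!r}")
            roi_map = None
            if "roi_assignment" in f:
                roi_map = ROIMap(assignment=f["roi_assignment"][()])
            return EpochedDataset(
                signals=f["signals"][()],
                target=f["labels/target"][()],
                angle=f["labels/angle"][()],
                fs=float(f.attrs["fs"]),
                times=f["times"][()],
                kind=kind,
                roi_map=roi_map,
            )
    except OSError as err:
        raise FormatError(f"cannot read {path} as an HDF5 dataset: {err}") from err


def write_model(model: PCAICA, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["n_components"] = model.n_components_
        f.attrs["converged"] = bool(model.converged_)
        f.attrs["random_state"] = -1 if model.random_state is None else model.random_state
        f.create_dataset("W_pca", data=model.W_pca_)
        f.create_dataset("W_ica", data=model.W_ica_)
        f.create_dataset("mean", data=model.mean_)
        f.create_dataset("explained_variance_ratio", data=model.explained_variance_ratio_)


def read_model(path) -> PCAICA:
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format_version") != FORMAT_VERSION:
                raise FormatError(f"unsupported model format in {path}")
            model = PCAICA(n_components=int(f.attrs["n_components"]))
            model.W_pca_ = f["W_pca"][()]
            model.W_ica_ = f["W_ica"][()]
            model.mean_ = f["mean"][()]
            model.explained_variance_ratio_ = f["explained_variance_ratio"][()]
            model.W_ica_inv_ = np.linalg.inv(model.W_ica_)
            model.W_ = model.W_pca_ @ model.W_ica_
            model.n_components_ = int(f.attrs["n_components"])
            model.converged_ = bool(f.attrs["converged"])
            model.n_iter_ = -1
            rs = int(f.attrs["random_state"])
            model.random_state = None if rs < 0 else rs
            return model
    except OSError as err:
        raise FormatError(f"cannot read {path} as an HDF5 model: {err}") from err


# ---------------------------------------------------------------------------
# Run configuration

@dataclass
class RunConfig:
    """Validated configuration of a full synthetic-benchmark run."""

    n_channels: int = 60
    n_sensors: int = 32
    n_true: int = 8
    n_epochs_per_condition: int = 20
    snr: float = 10.0
    sensor_noise: float = 1.0
    lam: float = 1e-2
    window: tuple[float, float] = (0.0, 1.0)
    fs_target: float = 50.0
    slr: dict = field(default_factory=dict)
    n_perm: int = 10_000
    fdr_q: float = 0.05
    accuracy_threshold: float = 0.40
    top_k: int = 10
    seeds: dict = field(
        default_factory=lambda: {
            "simulation": 0, "mixing": 1, "split": 2, "ica": 3, "permutation": 4,
        }
    )

    REQUIRED_SEEDS = ("simulation", "mixing", "split", "ica", "permutation")

    def __post_init__(self):
        for name in self.REQUIRED_SEEDS:
            if name not in self.seeds:
                raise ConfigurationError(f"config is missing seed {name!r}")
        if self.n_epochs_per_condition % 2:
            raise ConfigurationError("epochs per condition must be even (half split)")
        self.window = (float(self.window[0]), float(self.window[1]))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def with_global_seed(cls, seed: int, **kwargs) -> "RunConfig":
        """Derive the five stage seeds deterministically from one seed."""
        ss = np.random.SeedSequence(seed).spawn(5)
        seeds = {
            name: int(s.generate_state(1)[0] % (2**31))
            for name, s in zip(cls.REQUIRED_SEEDS, ss)
        }
        return cls(seeds=seeds, **kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig, outdir) -> dict:
    """Simulate, mix/invert, factorize, decode, test, and summarize.

    Writes all artifacts under ``outdir`` and returns (and writes) a
    manifest mapping each output file to its SHA-256 hash.  On a stage
    failure a partial manifest noting completed stages is written before
    the exception propagates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {**asdict(config)},
        "stages": [],
        "files": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def _record(name: str, *paths: Path):
        manifest["stages"].append(name)
        for p in paths:
            manifest["files"][p.name] = _sha256(p)

    try:
        t0 = time.time()
        roi_map = make_roi_map(config.n_channels)
        gt = make_ground_truth(roi_map, config.n_true, seed=config.seeds["simulation"])
        design = TrialDesign(n_epochs_per_condition=config.n_epochs_per_condition)
        cs = synthesize_cs(gt, design, snr=config.snr, seed=config.seeds["simulation"])
        p_cs = outdir / "cs_true.h5"
        write_dataset(cs, p_cs)
        _record("simulate", p_cs)
        log.info("simulate: %d trials in %.1fs", cs.n_trials, time.time() - t0)

        t0 = time.time()
        eeg, mix = forward_mix(
            cs, n_sensors=config.n_sensors, sensor_noise=config.sensor_noise,
            lam=config.lam, seed=config.seeds["mixing"],
        )
        cs_est = inverse_estimate(eeg, mix)
        p_eeg, p_est = outdir / "eeg.h5", outdir / "cs_estimated.h5"
        write_dataset(eeg, p_eeg)
        write_dataset(cs_est, p_est)
        _record("mix_inverse", p_eeg, p_est)
        log.info("mix/inverse done in %.1fs", time.time() - t0)

        t0 = time.time()
        cfg = CVConfig(
            window=config.window, fs_target=config.fs_target, slr=config.slr,
            accuracy_threshold=config.accuracy_threshold,
            seed=config.seeds["split"], ica_seed=config.seeds["ica"],
        )
        table, results = compare_signal_types(cs, cs_est, eeg, (INT, EXT), cfg)
        p_table = outdir / "comparison.csv"
        table.to_csv(p_table, index=False)
        cv_paths = []
        for (kind, scheme), res in results.items():
            p = outdir / f"cv_{kind}_{scheme}.csv"
            np.savetxt(p, res.fold_accuracies, header="fold_accuracy", comments="")
            cv_paths.append(p)
        _record("decode", p_table, *cv_paths)
        log.info("decoding done in %.1fs", time.time() - t0)

        t0 = time.time()
        rows = []
        for scheme in ("int", "ext"):
            ref = results[("cs_synergy", scheme)].fold_accuracies
            for kind in ("cs", "eeg_synergy", "eeg"):
                other = results[(kind, scheme)].fold_accuracies
                r = permutation_test_paired(
                    ref, other, n_perm=config.n_perm,
                    seed=config.seeds["permutation"],
                )
                rows.append(
                    {"comparison": f"cs_synergy_vs_{kind}", "scheme": scheme,
                     "statistic": r.statistic, "p": r.p_value}
                )
        fdr = bh_fdr([r["p"] for r in rows], q=config.fdr_q)
        for row, qv, rej in zip(rows, fdr.q_values, fdr.rejected):
            row["q_value"] = qv
            row["rejected"] = bool(rej)
        import pandas as pd

        p_stats = outdir / "stats.csv"
        pd.DataFrame(rows).to_csv(p_stats, index=False)
        _record("stats", p_stats)
        log.info("stats done in %.1fs", time.time() - t0)

        t0 = time.time()
        res_syn = results[("cs_synergy", "int")]
        dom = dominant_area(res_syn.synergy_model, roi_map)
        p_dom = outdir / "dominant_area.csv"
        dom.counts.to_csv(p_dom)
        areas = {i: r for i, r in enumerate(dom.dominant)}
        counts = count_selected(res_syn)
        tops = top_features(counts, k=config.top_k, component_areas=areas)
        p_top = outdir / "top_features.csv"
        tops.to_csv(p_top, index=False)
        _record("features", p_dom, p_top)
        log.info("feature analysis done in %.1fs", time.time() - t0)
    finally:
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    return manifest
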