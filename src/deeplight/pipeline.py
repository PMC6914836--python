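"""End-to-end orchestration: simulate -> preprocess -> train -> decode ->
relevance -> maps -> evaluate, with a reproducibility manifest.

Each stage reads only artifacts produced by earlier stages; a missing
upstream artifact raises a dependency error before any work is done. The
manifest records the config snapshot, the seeds, the package version, and a
checksum for every file the pipeline writes, so that deterministic stages
re-run bit-identically from the same manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import validate_config
from .evaluate import accuracy, confusion_matrix
from .io import REST, write_map_nifti
from .lrp import decompose_batch
from .maps import group_map, select_decomposable, subject_map, threshold_percentile
from .model import build_model, decode_batch, save_checkpoint
from .preprocess import compute_brain_mask, preprocess_run
from .synth import SyntheticConfig, generate_dataset, write_run
from .train import TrainConfig, task_samples, train

STAGE_ORDER = ["simulate", "preprocess", "train", "decode", "relevance", "maps", "evaluate"]

_DEPENDENCIES = {
    "preprocess": ["simulate"],
    "train": ["preprocess"],
    "decode": ["train"],
    "relevance": ["decode"],
    "maps": ["relevance"],
    "evaluate": ["decode"],
}


class DependencyError(RuntimeError):
    pass


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    stages_run: list[str] = field(default_factory=list)
    timestamps: dict[str, float] = field(default_factory=dict)

    def record(self, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[str(path)] = digest

    def save(self, path: Path) -> None:
        payload = {
            "config": self.config,
            "version": self.version,
            "outputs": self.outputs,
            "stages_run": self.stages_run,
            "timestamps": self.timestamps,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def _check_dependencies(stages: list[str]) -> None:
    seen: set[str] = set()
    for stage in stages:
        for dep in _DEPENDENCIES.get(stage, []):
            if dep not in seen:
                raise DependencyError(f"stage {stage!r} requires {dep!r} to run first")
        seen.add(stage)


def run_pipeline(config: dict | str | None, out_dir: str | Path | None = None) -> RunManifest:
    """Execute the configured stages in order on a synthetic dataset.

    Returns the manifest; a failed stage raises, leaving earlier outputs and
    a partial manifest on disk.
    """
    cfg = validate_config(config)
    stages = cfg["pipeline"]["stages"]
    _check_dependencies(stages)
    out = Path(out_dir if out_dir is not None else cfg["pipeline"]["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg)
    state: dict = {}
    for stage in stages:
        manifest.timestamps[stage] = time.time()
        _STAGE_FUNCS[stage](cfg, out, state, manifest)
        manifest.stages_run.append(stage)
        manifest.save(out / "manifest.json")
    return manifest


def _stage_simulate(cfg, out, state, manifest):
    sim = cfg["simulate"]
    synth_cfg = SyntheticConfig(
        grid_shape=tuple(sim["grid_shape"]),
        tr=sim["tr"],
        n_states=sim["n_states"],
        block_length=sim["block_length"],
        blocks_per_state=sim["blocks_per_state"],
        rest_length=sim["rest_length"],
        effect_amplitude=sim["effect_amplitude"],
        noise_sd=sim["noise_sd"],
        drift_slope=sim["drift_slope"],
        drift_sine_period=sim["drift_sine_period"],
    )
    dataset = generate_dataset(synth_cfg, sim["n_subjects"], sim["seed"])
    data_dir = out / "data"
    for i, (volume, truth) in enumerate(dataset):
        write_run(data_dir, f"sub-{i:02d}", volume, truth, synth_cfg)
    for path in sorted(data_dir.glob("*")):
        manifest.record(path)
    state["dataset"] = dataset
    state["synth_cfg"] = synth_cfg


def _stage_preprocess(cfg, out, state, manifest):
    if "dataset" not in state:
        raise DependencyError("preprocess requires the simulate stage's dataset")
    pp = cfg["preprocess"]
    volumes = [v for v, _ in state["dataset"]]
    mask = compute_brain_mask(volumes, pp["mask_fraction"])
    state["mask"] = mask
    state["preprocessed"] = [
        preprocess_run(v, mask, pp["fwhm"], pp["highpass"]) for v in volumes
    ]


def _stage_train(cfg, out, state, manifest):
    if "preprocessed" not in state:
        raise DependencyError("train requires preprocessed runs")
    tr_cfg = cfg["train"]
    runs = state["preprocessed"]
    truths = [t for _, t in state["dataset"]]
    n_test = max(1, len(runs) // 4)
    train_runs, test_runs = runs[:-n_test], runs[-n_test:]
    train_truths, test_truths = truths[:-n_test], truths[-n_test:]
    X = np.concatenate([r.data for r in train_runs])
    y = np.concatenate([t.labels for t in train_truths])
    X, y = task_samples(X, y)
    shape = train_runs[0].spatial_shape
    model = build_model(
        (shape[0], shape[1]),
        n_states=cfg["simulate"]["n_states"],
        hidden_size=tr_cfg["hidden_size"],
        seed=tr_cfg["seed"],
    )
    config = TrainConfig(
        learning_rate=tr_cfg["learning_rate"],
        batch_size=tr_cfg["batch_size"],
        max_epochs=tr_cfg["max_epochs"],
        clip_norm=tr_cfg["clip_norm"],
        patience=tr_cfg["patience"],
        validation_fraction=tr_cfg["validation_fraction"],
        seed=tr_cfg["seed"],
    )
    model, history = train(X, y, config, model)
    ckpt = out / "model.npz"
    save_checkpoint(ckpt, model)
    manifest.record(ckpt)
    log = out / "training_log.tsv"
    pd.DataFrame(
        {
            "epoch": np.arange(len(history.train_loss)),
            "train_loss": history.train_loss,
            "val_loss": history.val_loss or np.nan,
            "val_acc": history.val_accuracy or np.nan,
        }
    ).to_csv(log, sep="\t", index=False)
    manifest.record(log)
    state["model"] = model
    state["test_runs"] = test_runs
    state["test_truths"] = test_truths


def _stage_decode(cfg, out, state, manifest):
    if "model" not in state:
        raise DependencyError("decode requires a trained model")
    rows = []
    predictions = []
    for si, (run, truth) in enumerate(zip(state["test_runs"], state["test_truths"])):
        task = truth.labels >= 0
        preds = np.full(len(truth.labels), REST)
        preds[task] = decode_batch(run.data[task], state["model"])
        predictions.append(preds)
        for t in np.flatnonzero(task):
            rows.append((si, t, truth.labels[t], preds[t]))
    table = pd.DataFrame(rows, columns=["subject", "tr", "true_state", "predicted_state"])
    path = out / "predictions.tsv"
    table.to_csv(path, sep="\t", index=False)
    manifest.record(path)
    state["predictions"] = predictions


def _stage_relevance(cfg, out, state, manifest):
    if "predictions" not in state:
        raise DependencyError("relevance requires decode predictions")
    eps = cfg["relevance"]["epsilon"]
    window = tuple(cfg["relevance"]["window"])
    per_subject = []
    for run, truth, preds in zip(state["test_runs"], state["test_truths"], state["predictions"]):
        idx = select_decomposable(preds, truth.labels, truth.block_onsets, run.tr, window)
        maps_by_state: dict[int, list[np.ndarray]] = {}
        if len(idx):
            values = decompose_batch(run.data[idx], state["model"], truth.labels[idx], eps)
            for j, t in enumerate(idx):
                maps_by_state.setdefault(int(truth.labels[t]), []).append(values[j])
        per_subject.append(maps_by_state)
    state["relevance"] = per_subject


def _stage_maps(cfg, out, state, manifest):
    if "relevance" not in state:
        raise DependencyError("maps requires relevance decompositions")
    mp = cfg["maps"]
    n_states = cfg["simulate"]["n_states"]
    mask = state["mask"]
    group_maps = {}
    for k in range(n_states):
        subj_maps = [
            subject_map(maps[k], k, mp["fwhm"], mask=mask)
            for maps in state["relevance"]
            if maps.get(k)
        ]
        if not subj_maps:
            continue
        gmap = group_map(subj_maps)
        thr = threshold_percentile(gmap, mp["percentile"], mp["positive_only"])
        path = out / f"group_state-{k}_relevance.nii.gz"
        write_map_nifti(path, thr.values)
        manifest.record(path)
        group_maps[k] = thr
    state["group_maps"] = group_maps


def _stage_evaluate(cfg, out, state, manifest):
    if "predictions" not in state:
        raise DependencyError("evaluate requires decode predictions")
    n_states = cfg["simulate"]["n_states"]
    y_true = np.concatenate([t.labels for t in state["test_truths"]])
    y_pred = np.concatenate(state["predictions"])
    task = y_true >= 0
    cm = confusion_matrix(y_true[task], y_pred[task], n_states)
    report = {
        "accuracy": accuracy(y_true[task], y_pred[task]),
        "confusion_matrix": cm.tolist(),
        "n_samples": int(task.sum()),
    }
    path = out / "evaluation.json"
    path.write_text(json.dumps(report, indent=2))
    manifest.record(path)
    state["evaluation"] = report


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "train": _stage_train,
    "decode": _stage_decode,
    "relevance": _stage_relevance,
    "maps": _stage_maps,
    "evaluate": _stage_evaluate,
}
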