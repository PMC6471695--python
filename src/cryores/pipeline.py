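"""End-to-end orchestration: simulate -> preprocess -> train -> evaluate.

The pipeline encodes the linear workflow the classifiers are built for.
``run_pipeline`` drives either the global 3-class track (synthetic
structures rendered at the three training resolutions, split, train a
DNN or 3D CNN, confusion matrix + per-class metrics on the held-out
test set) or the voxel-wise track (local-resolution phantoms, patch
extraction, U-Net training, voxel accuracy).  Every artifact lands in
the run directory; completed stages leave their outputs behind and are
skipped on re-runs, so an interrupted pipeline resumes where it
stopped.  All randomness flows from the single config seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import evaluate as ev
from . import models
from .preprocess import (
    BACKGROUND,
    SplitSpec,
    apply_mask,
    minmax_normalize,
    pad_to_pow2,
    partition_patches,
    split_dataset,
    three_class_label,
)
from .simulate import (
    LocalResolutionPhantomSpec,
    SimulationSpec,
    TRAINING_RESOLUTIONS,
    make_local_res_phantom,
    make_synthetic_model,
    simulate_map,
)

__all__ = ["RunConfig", "run_pipeline", "build_global_corpus", "build_patch_corpus"]


@dataclass
class RunConfig:
    """Parameters for one pipeline run (see module docstring).

    ``track`` selects the global 3-class workflow (``"global"``) or the
    voxel-wise U-Net workflow (``"voxel"``).  Network width parameters
    accept ``None`` to use the full-size published architecture.
    """

    out_dir: str = "run"
    track: str = "global"
    architecture: str = "dnn"
    seed: int = 0
    # data generation
    n_per_class: int = 30
    box: int = 32
    voxel_size: float = 1.0
    n_atoms: int = 1000
    resolutions: tuple[float, ...] = TRAINING_RESOLUTIONS
    n_phantoms: int = 10
    phantom_n_atoms: int = 300
    phantom_resolutions: tuple[float, ...] = (2.5, 12.5)
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    # network width (None -> full published size)
    hidden: tuple[int, int] | None = (200, 50)
    filters: tuple[int, ...] | None = (8, 16, 32)
    dense_units: int = 64
    # training
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 16
    patience: int = 10
    max_epochs: int = 30
    weight_decay: float = 1e-3

    def __post_init__(self) -> None:
        if self.track not in ("global", "voxel"):
            raise ValueError(f"unknown track {self.track!r}")
        if self.track == "global" and self.architecture not in ("dnn", "cnn3d"):
            raise ValueError("global track requires architecture dnn or cnn3d")
        if self.track == "voxel" and self.architecture != "unet3d":
            raise ValueError("voxel track requires architecture unet3d")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("resolutions", "phantom_resolutions", "split", "hidden", "filters"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def build_global_corpus(config: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the 3-class training corpus: one map per structure/resolution."""
    maps, labels = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sub-voxel sigma warnings at 2.5 A
        for class_index, resolution in enumerate(config.resolutions):
            for k in range(config.n_per_class):
                structure = make_synthetic_model(
                    config.n_atoms,
                    extent=0.8 * config.box * config.voxel_size,
                    seed=config.seed + 10_000 * class_index + k,
                )
                rendered = simulate_map(
                    structure,
                    SimulationSpec(resolution, config.box, config.voxel_size),
                )
                maps.append(minmax_normalize(rendered).data)
                labels.append(int(three_class_label(resolution)))
    return np.array(maps, dtype=np.float32), np.array(labels)


def build_patch_corpus(config: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    """Phantom maps -> normalized, masked, padded, 16-cube patch stacks."""
    xs, ys = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(config.n_phantoms):
            phantom, labels = make_local_res_phantom(
                LocalResolutionPhantomSpec(
                    resolutions=config.phantom_resolutions,
                    box=config.box,
                    voxel_size=config.voxel_size,
                    n_atoms=config.phantom_n_atoms,
                    seed=config.seed + 500 + i,
                )
            )
            normalized = minmax_normalize(phantom)
            mask = (labels != BACKGROUND).astype(np.uint8)
            masked = apply_mask(normalized, mask)
            padded, padded_labels = pad_to_pow2(
                masked, seed=config.seed + i, label=labels
            )
            batch = partition_patches(padded, padded_labels, cube=16)
            xs.append(batch.inputs)
            ys.append(batch.labels)
    return np.concatenate(xs), np.concatenate(ys)


def _build_network(config: RunConfig):
    if config.architecture == "dnn":
        kwargs = {} if config.hidden is None else {"hidden": config.hidden}
        return models.build_dnn(input_edge=config.box, seed=config.seed, **kwargs)
    if config.architecture == "cnn3d":
        kwargs = {}
        if config.filters is not None:
            kwargs["filters"] = tuple(config.filters)
            kwargs["dense_units"] = config.dense_units
        return models.build_cnn3d(input_edge=config.box, seed=config.seed, **kwargs)
    kwargs = {} if config.filters is None else {"filters": tuple(config.filters)}
    return models.build_unet3d(input_edge=16, seed=config.seed, **kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the metrics report dict.

    Artifacts written under ``config.out_dir``: ``config.json``,
    ``corpus.npz``, ``model.json``/``model.npz``, ``trace.json`` and
    ``report.json`` (plus ``confusion.csv`` on the global track).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2)

    corpus_file = out / "corpus.npz"
    if corpus_file.exists():
        with np.load(corpus_file) as data:
            x, y = data["x"], data["y"]
    else:
        builder = build_global_corpus if config.track == "global" else build_patch_corpus
        x, y = builder(config)
        np.savez_compressed(corpus_file, x=x, y=y)

    train_ids, val_ids, test_ids = split_dataset(
        list(range(len(x))), SplitSpec(config.split, seed=config.seed)
    )

    model_stem = out / "model"
    trace_file = out / "trace.json"
    train_config = models.TrainConfig(
        optimizer=config.optimizer,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        weight_decay=config.weight_decay,
        patience=config.patience,
        max_epochs=config.max_epochs,
        seed=config.seed,
    )
    if model_stem.with_suffix(".npz").exists() and trace_file.exists():
        net = models.load_model(model_stem)
        with open(trace_file) as fh:
            trace_dict = json.load(fh)
    else:
        net = _build_network(config)
        trace = models.train(
            net, (x[train_ids], y[train_ids]), (x[val_ids], y[val_ids]), train_config
        )
        models.save_model(net, model_stem)
        trace_dict = {
            "val_loss": trace.val_loss,
            "val_acc": trace.val_acc,
            "best_epoch": trace.best_epoch,
        }
        with open(trace_file, "w") as fh:
            json.dump(trace_dict, fh, indent=2)

    predictions = models.predict(net, x[test_ids], batch_size=config.batch_size)
    report: dict = {
        "architecture": config.architecture,
        "n_train": len(train_ids),
        "n_validation": len(val_ids),
        "n_test": len(test_ids),
        "best_epoch": trace_dict["best_epoch"],
        "best_val_loss": min(trace_dict["val_loss"]),
        "best_val_acc": trace_dict["val_acc"][trace_dict["best_epoch"]],
    }
    if config.track == "global":
        cm = ev.confusion_matrix(y[test_ids], predictions)
        report["combined_agreement_pct"] = ev.combined_agreement(cm)
        report["confusion_matrix"] = cm.counts.tolist()
        report["class_metrics_pct"] = json.loads(ev.class_metrics(cm).to_json())
        cm.to_frame().to_csv(out / "confusion.csv")
    else:
        mask = y[test_ids] != BACKGROUND
        report["voxel_accuracy"] = ev.categorical_accuracy(
            predictions, y[test_ids], mask=mask
        )
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
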