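"""Run orchestration: the three experiment shapes from a single config.

Three study shapes cover the ways the method is used in practice:

* **classification study** — train the classifier on labeled classes,
  report the held-out confusion matrix, and optionally force-assign a
  foreign (out-of-sample) class into the trained classes;
* **fingerprint study** — train one embedding network jointly on all
  classes, fit a per-class fingerprint, locate modes, export HDR contour
  tables and nearest-to-mode image galleries, and optionally run pairwise
  goodness-of-fit tests;
* **temporal study** — train the embedder only on designated in-training
  time points, embed held-out time points with the frozen network, and
  test each held-out population against each training fingerprint.

Every run directory receives a config snapshot, a seed record, a
structured text log and the declared artifacts; ``check_run_dir`` verifies
the contract.  One master seed fans out to per-stage seeds through
``numpy.random.SeedSequence(master, spawn_key=(stage,))`` so stages are
individually reproducible without seed reuse.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import fingerprint as fpmod
from . import gof as gofmod
from . import nn
from .synthetic import ClassSpec, DatasetManifest, generate_dataset, load_manifest

__all__ = [
    "RunConfig",
    "run_classification_study",
    "run_fingerprint_study",
    "run_temporal_study",
    "check_run_dir",
    "stage_seed",
]

#: fixed stage indices of the seed fan-out (documented counter scheme)
STAGES = {"simulate": 0, "split": 1, "train": 2, "embed": 3,
          "fingerprint": 4, "gof": 5}


def stage_seed(master: int, stage: str) -> int:
    """Derive the per-stage seed from the master seed (< 2**31)."""
    ss = np.random.SeedSequence(master, spawn_key=(STAGES[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    experiment: str                       # classify | fingerprint | temporal
    out_dir: Path
    seed: int = 0
    # dataset: either a ready manifest directory, or specs to simulate
    manifest_dir: Path | None = None
    specs: list[ClassSpec] = field(default_factory=list)
    n_per_class: int = 200
    split_fractions: tuple[float, float, float] = (0.8, 0.0, 0.2)
    # training
    train: nn.TrainConfig = field(default_factory=nn.TrainConfig)
    # classification extras
    foreign_labels: list[str] = field(default_factory=list)
    # fingerprint / gof parameters
    hdr_masses: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    gallery_k: int = 50
    n_test: int = 100
    alpha: float = 0.05
    pairwise_gof: bool = False
    # temporal study
    holdout_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.experiment not in ("classify", "fingerprint", "temporal"):
            raise ValueError(f"unknown experiment kind {self.experiment!r}")
        self.out_dir = Path(self.out_dir)
        if self.manifest_dir is not None:
            self.manifest_dir = Path(self.manifest_dir)
            if not self.manifest_dir.exists():
                raise ValueError(f"manifest_dir {self.manifest_dir} does not exist")
        elif not self.specs:
            raise ValueError("either manifest_dir or specs must be provided")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        if self.manifest_dir is not None:
            d["manifest_dir"] = str(self.manifest_dir)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "specs" in d:
            d["specs"] = [s if isinstance(s, ClassSpec) else ClassSpec(**s)
                          for s in d["specs"]]
        if "train" in d and not isinstance(d["train"], nn.TrainConfig):
            d["train"] = nn.TrainConfig(**d["train"])
        if "split_fractions" in d:
            d["split_fractions"] = tuple(d["split_fractions"])
        if "hdr_masses" in d:
            d["hdr_masses"] = tuple(d["hdr_masses"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


class _RunLogger:
    """Minimal structured text log with stage timings."""

    def __init__(self, path: Path):
        self.path = path
        self.t0 = time.time()
        path.write_text("")

    def log(self, msg: str) -> None:
        line = f"[{time.time() - self.t0:9.2f}s] {msg}\n"
        with open(self.path, "a") as fh:
            fh.write(line)


def _start_run(config: RunConfig) -> tuple[Path, _RunLogger, list[str]]:
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    (out / "seed.json").write_text(json.dumps(
        {"master_seed": int(config.seed),
         "stage_seeds": {k: stage_seed(config.seed, k) for k in STAGES}}, indent=1))
    logger = _RunLogger(out / "run.log")
    return out, logger, ["config.yaml", "seed.json", "run.log"]


def _obtain_dataset(config: RunConfig, out: Path, logger: _RunLogger) -> DatasetManifest:
    if config.manifest_dir is not None:
        manifest = load_manifest(config.manifest_dir)
        logger.log(f"loaded manifest from {config.manifest_dir} "
                   f"({len(manifest.records)} images)")
    else:
        manifest = generate_dataset(config.specs, config.n_per_class,
                                    config.split_fractions,
                                    stage_seed(config.seed, "simulate"),
                                    out / "dataset")
        logger.log(f"simulated {len(manifest.records)} images "
                   f"({len(config.specs)} classes x {config.n_per_class})")
    return manifest


def _finish_run(out: Path, artifacts: list[str], logger: _RunLogger) -> None:
    (out / "artifacts.json").write_text(json.dumps(sorted(artifacts), indent=1))
    logger.log("done")


def check_run_dir(out_dir: Path | str) -> list[str]:
    """Verify a run directory against its own artifact declaration.

    Returns the list of missing files (empty = contract satisfied).
    """
    out = Path(out_dir)
    required = ["config.yaml", "seed.json", "run.log", "artifacts.json"]
    missing = [f for f in required if not (out / f).exists()]
    if (out / "artifacts.json").exists():
        declared = json.loads((out / "artifacts.json").read_text())
        missing += [f for f in declared if not (out / f).exists()]
    return missing


# ---------------------------------------------------------------------------
# Studies
# ---------------------------------------------------------------------------

def run_classification_study(config: RunConfig):
    """Train the classifier; write the held-out confusion matrix and, if
    foreign classes are configured, their forced assignment rows."""
    out, logger, artifacts = _start_run(config)
    manifest = _obtain_dataset(config, out, logger)

    all_labels = sorted(set(manifest.records["label"]))
    foreign = [l for l in all_labels if l in set(config.foreign_labels)]
    training_labels = [l for l in all_labels if l not in set(config.foreign_labels)]
    if len(training_labels) < 2:
        raise ValueError("classification study needs >= 2 training classes")

    keep = manifest.records["label"].isin(training_labels)
    train_images = [im for im in manifest.load_images("train") if im.label in training_labels]
    test_images = [im for im in manifest.load_images("test") if im.label in training_labels]
    if not train_images or not test_images:
        raise ValueError("train and test splits must both be nonempty")

    tc = dataclasses.replace(config.train, seed=stage_seed(config.seed, "train"))
    model, log = nn.train_classifier({"train": train_images, "test": test_images}, tc)
    log.to_csv(out / "training_log.csv", index=False)
    artifacts.append("training_log.csv")
    logger.log(f"trained classifier on {len(train_images)} images, "
               f"{len(training_labels)} classes, {tc.epochs} epochs")

    pred = nn.predict(model, test_images)
    truth = np.array([im.label for im in test_images])
    cm = nn.confusion_matrix(pred, truth, model.labels)
    cm.to_frame().to_csv(out / "confusion_matrix.csv")
    artifacts.append("confusion_matrix.csv")
    logger.log(f"test confusion diagonal: {np.round(cm.diagonal(), 3).tolist()}")

    model.save(out / "classifier")
    artifacts += ["classifier.npz", "classifier.json"]

    oos_rows = {}
    for label in foreign:
        images = [im for im in manifest.load_images(None) if im.label == label]
        row = nn.classify_out_of_sample(model, images)
        oos_rows[label] = row
        logger.log(f"out-of-sample row for {label}: {np.round(row.to_numpy(), 3).tolist()}")
    if oos_rows:
        pd.DataFrame(oos_rows).T.to_csv(out / "out_of_sample_rows.csv")
        artifacts.append("out_of_sample_rows.csv")

    _finish_run(out, artifacts, logger)
    return model, cm, oos_rows


def _fit_and_export_fingerprints(embedding: nn.EmbeddingSet, labels: Sequence[str],
                                 config: RunConfig, out: Path,
                                 logger: _RunLogger, artifacts: list[str]):
    fps = {}
    hdr_rows = []
    for label in labels:
        fp = fpmod.fit_fingerprint(embedding, subset=label)
        fps[label] = fp
        fp.to_json(out / f"fingerprint_{label}.json")
        artifacts.append(f"fingerprint_{label}.json")
        mode = fpmod.global_mode(fp)
        sub = embedding.filter(label)
        k = min(config.gallery_k, sub.coords.shape[0])
        nearest = fpmod.nearest_to_point(sub, mode.point, k=k)
        ids = (sub.image_ids[nearest] if sub.image_ids is not None
               else nearest.astype(str))
        pd.DataFrame({"rank": np.arange(k), "image_id": ids}).to_csv(
            out / f"mode_gallery_{label}.csv", index=False)
        artifacts.append(f"mode_gallery_{label}.csv")
        lv = fpmod.hdr_levels(fp, config.hdr_masses)
        for m, l in zip(lv.masses, lv.levels):
            hdr_rows.append({"label": label, "mass": m, "level": l,
                             "mode_x": mode.point[0], "mode_y": mode.point[1],
                             "mode_density": mode.density})
        logger.log(f"fingerprint {label}: n={fp.n}, mode={np.round(mode.point, 3).tolist()}")
    pd.DataFrame(hdr_rows).to_csv(out / "hdr_levels.csv", index=False)
    artifacts.append("hdr_levels.csv")
    return fps


def run_fingerprint_study(config: RunConfig):
    """Joint embedder over all classes; per-class fingerprints, modes,
    HDR tables, mode galleries, and optional pairwise GOF tests."""
    out, logger, artifacts = _start_run(config)
    manifest = _obtain_dataset(config, out, logger)
    labels = sorted(set(manifest.records["label"]))
    if len(labels) < 2:
        raise ValueError("fingerprint study needs >= 2 classes")

    train_images = manifest.load_images("train")
    val_images = manifest.load_images("val")
    if not val_images:  # carve a val split out of train when absent
        rng = np.random.default_rng(stage_seed(config.seed, "split"))
        by_label: dict[str, list] = {}
        for im in train_images:
            by_label.setdefault(im.label, []).append(im)
        train_images, val_images = [], []
        for label, ims in sorted(by_label.items()):
            order = rng.permutation(len(ims))
            n_val = max(1, int(round(0.2 * len(ims))))
            val_images += [ims[i] for i in order[:n_val]]
            train_images += [ims[i] for i in order[n_val:]]
        logger.log(f"carved val split: {len(train_images)} train / {len(val_images)} val")

    tc = dataclasses.replace(config.train, seed=stage_seed(config.seed, "train"))
    model, log = nn.train_embedder({"train": train_images, "val": val_images}, tc)
    log.to_csv(out / "training_log.csv", index=False)
    artifacts.append("training_log.csv")
    model.save(out / "embedder")
    artifacts += ["embedder.npz", "embedder.json"]
    logger.log(f"trained embedder: best epoch {log.attrs['best_epoch']} "
               f"(val loss {log.attrs['best_val_loss']:.4f})")

    all_images = manifest.load_images(None)
    embedding = nn.embed_images(model, all_images)
    embedding.to_csv(out / "embeddings.csv")
    artifacts.append("embeddings.csv")

    fps = _fit_and_export_fingerprints(embedding, labels, config, out, logger, artifacts)

    gof_results = {}
    if config.pairwise_gof:
        gseed = stage_seed(config.seed, "gof")
        rows = []
        for null_label in labels:
            for test_label in labels:
                if null_label == test_label:
                    continue
                pts = embedding.filter(test_label).coords
                res = gofmod.subset_rejection_rate(
                    fps[null_label], pts, n_test=config.n_test,
                    alpha=config.alpha, seed=gseed, test_label=test_label)
                gof_results[(null_label, test_label)] = res
                rows.append({"null": null_label, "test": test_label,
                             "rejection_fraction": res.rejection_fraction,
                             "subsets": res.subset_count})
        pd.DataFrame(rows).to_csv(out / "pairwise_gof.csv", index=False)
        artifacts.append("pairwise_gof.csv")

    _finish_run(out, artifacts, logger)
    return model, embedding, fps, gof_results


def run_temporal_study(config: RunConfig):
    """Embedder trained on in-training time points only; held-out time
    points embedded frozen and tested against each training fingerprint."""
    out, logger, artifacts = _start_run(config)
    manifest = _obtain_dataset(config, out, logger)
    labels = sorted(set(manifest.records["label"]))
    holdout = [l for l in labels if l in set(config.holdout_labels)]
    training = [l for l in labels if l not in set(config.holdout_labels)]
    if len(training) < 2:
        raise ValueError("temporal study needs >= 2 in-training time points")

    def of(images, wanted):
        return [im for im in images if im.label in wanted]

    train_images = of(manifest.load_images("train"), training)
    val_images = of(manifest.load_images("val"), training)
    if not val_images:
        rng = np.random.default_rng(stage_seed(config.seed, "split"))
        by_label: dict[str, list] = {}
        for im in train_images:
            by_label.setdefault(im.label, []).append(im)
        train_images, val_images = [], []
        for label, ims in sorted(by_label.items()):
            order = rng.permutation(len(ims))
            n_val = max(1, int(round(0.2 * len(ims))))
            val_images += [ims[i] for i in order[:n_val]]
            train_images += [ims[i] for i in order[n_val:]]

    tc = dataclasses.replace(config.train, seed=stage_seed(config.seed, "train"))
    model, log = nn.train_embedder({"train": train_images, "val": val_images}, tc)
    log.to_csv(out / "training_log.csv", index=False)
    artifacts.append("training_log.csv")
    model.save(out / "embedder")
    artifacts += ["embedder.npz", "embedder.json"]
    logger.log(f"trained embedder on time points {training}")

    all_images = manifest.load_images(None)
    embedding = nn.embed_images(model, all_images)
    embedding.to_csv(out / "embeddings.csv")
    artifacts.append("embeddings.csv")

    fps = _fit_and_export_fingerprints(embedding, labels, config, out, logger, artifacts)

    gseed = stage_seed(config.seed, "gof")
    rows = []
    gof_results = {}
    for h in holdout:
        pts = embedding.filter(h).coords
        for t in training:
            res = gofmod.subset_rejection_rate(
                fps[t], pts, n_test=config.n_test, alpha=config.alpha,
                seed=gseed, test_label=h)
            gof_results[(t, h)] = res
            res.to_json(out / f"gof_{h}_vs_{t}.json")
            artifacts.append(f"gof_{h}_vs_{t}.json")
            rows.append({"holdout": h, "training": t,
                         "rejection_fraction": res.rejection_fraction,
                         "subsets": res.subset_count})
            logger.log(f"GOF {h} vs {t}: rejection {res.rejection_fraction:.3f}")
    pd.DataFrame(rows).to_csv(out / "temporal_gof.csv", index=False)
    artifacts.append("temporal_gof.csv")

    _finish_run(out, artifacts, logger)
    return model, embedding, fps, gof_results
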