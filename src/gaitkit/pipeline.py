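"""Manifest-driven batch pipeline tying all stages together.

Stages (in order): simulate -> segment -> represent -> train -> evaluate ->
explain.  Every stage reads its inputs from, and writes its outputs to, a
working directory laid out as::

    workdir/
      manifest.csv              sequence labels (single source of truth)
      background.png            background-only chroma frame
      raw/<uri>/                RGB frames (simulate)
      truth/<uri>/              generator ground-truth masks (simulate)
      poses/<uri>/              OpenPose-convention documents (simulate)
      masks/<uri>/              extracted silhouettes (segment)
      reps/                     energy images (represent)
      model/                    classifier checkpoint + history (train)
      reports/                  evaluation JSON + confusion CSV (evaluate)
      explain/                  saliency / grad-CAM images (explain)

Re-running a stage with the same configuration and seed reproduces its
outputs, so deleting downstream artifacts and re-running is safe.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import explain as ex
from . import gaitsim, io, represent, segmentation
from .model import GaitClassifier, ModelConfig

logger = logging.getLogger("gaitkit")

STAGES = ("simulate", "segment", "represent", "train", "evaluate", "explain")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    workdir: str = "gaitkit_run"
    seed: int = 0
    n_sessions: int = 2
    target_fps: float = 10.0
    representation_kinds: tuple = ("GEI",)
    per_cycle: bool = False
    walker: dict = field(default_factory=dict)     # WalkerConfig overrides
    model: dict = field(default_factory=dict)      # ModelConfig overrides
    n_folds: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "representation_kinds" in data:
            data["representation_kinds"] = tuple(data["representation_kinds"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["representation_kinds"] = list(self.representation_kinds)
        with open(path, "w") as f:
            yaml.safe_dump(data, f)

    @property
    def root(self) -> Path:
        return Path(self.workdir)

    def model_config(self) -> ModelConfig:
        return ModelConfig(seed=self.seed + 400, **self.model)


def _require(path, stage, what):
    if not Path(path).exists():
        raise StageError(stage, f"missing {what}: {path} "
                                f"(run an earlier stage first)")
    return Path(path)


def _manifest(config, stage) -> pd.DataFrame:
    return io.read_manifest(_require(config.root / "manifest.csv", stage,
                                     "manifest"))


def stage_simulate(config: PipelineConfig) -> None:
    root = config.root
    root.mkdir(parents=True, exist_ok=True)
    manifest = gaitsim.generate_manifest(config.n_sessions, seed=config.seed)
    io.write_manifest(root / "manifest.csv", manifest)
    io.write_image(root / "background.png",
                   gaitsim.background_frame(seed=config.seed + 100))
    base = gaitsim.WalkerConfig(**config.walker)
    for row in manifest.itertuples():
        cfg = gaitsim.config_for_row(row, base=base, seed=config.seed)
        seq = gaitsim.generate_walker_sequence(cfg)
        io.write_frame_sequence(root / "raw" / row.sequence_uri, seq.frames)
        io.write_frame_sequence(root / "truth" / row.sequence_uri,
                                seq.truth_masks, stem="mask")
        io.write_pose_sequence(root / "poses" / row.sequence_uri, seq.poses)
    logger.info("simulate: wrote %d sequences under %s", len(manifest), root)


def stage_segment(config: PipelineConfig) -> None:
    root = config.root
    manifest = _manifest(config, "segment")
    bg = io.read_frame(_require(root / "background.png", "segment",
                                "background frame"))
    model = segmentation.fit_background(bg)
    for row in manifest.itertuples():
        raw_dir = _require(root / "raw" / row.sequence_uri, "segment",
                           "raw frames")
        files = sorted(raw_dir.glob("*.png"))
        masks = np.stack([segmentation.extract_silhouette(io.read_frame(f),
                                                          model)
                          for f in files])
        io.write_frame_sequence(root / "masks" / row.sequence_uri, masks,
                                stem="mask")
    logger.info("segment: extracted silhouettes for %d sequences", len(manifest))


def stage_represent(config: PipelineConfig) -> None:
    root = config.root
    manifest = _manifest(config, "represent")
    rep_dir = root / "reps"
    rep_dir.mkdir(parents=True, exist_ok=True)
    for row in manifest.itertuples():
        seq_id = row.sequence_uri.replace("/", "_")
        for kind in config.representation_kinds:
            if kind == "GEI":
                src_dir = _require(root / "masks" / row.sequence_uri,
                                   "represent", "extracted masks")
                source = io.read_mask_sequence(src_dir, fps=config.target_fps)
            elif kind == "SEI":
                pose_dir = _require(root / "poses" / row.sequence_uri,
                                    "represent", "pose documents")
                sample = io.read_mask_sequence(
                    _require(root / "truth" / row.sequence_uri, "represent",
                             "frame geometry"))
                source = io.read_pose_sequence(pose_dir,
                                               sample.frame_shape,
                                               fps=config.target_fps)
            else:
                raise StageError("represent", f"unknown kind {kind!r}")
            source = represent.resample_framerate(source, config.target_fps)
            source = represent.canonicalize_direction(source, row.direction)
            cycles = None
            if config.per_cycle and kind == "GEI":
                cycles = represent.detect_gait_cycles(source)
            reps = represent.sequence_representations(source, kind=kind,
                                                      cycles=cycles)
            for rep in reps:
                name = io.representation_filename(seq_id, kind, rep.scope,
                                                  rep.cycle_index)
                io.write_representation(rep_dir / name, rep)
    logger.info("represent: wrote representations for %d sequences",
                len(manifest))


def _load_whole_sequence_reps(config, manifest, stage):
    kind = config.representation_kinds[0]
    reps = {}
    for row in manifest.itertuples():
        seq_id = row.sequence_uri.replace("/", "_")
        path = _require(
            config.root / "reps" / io.representation_filename(
                seq_id, kind, "whole_sequence"),
            stage, "representation")
        reps[row.sequence_uri] = io.read_representation(path, kind=kind)
    return reps


def stage_train(config: PipelineConfig) -> None:
    manifest = _manifest(config, "train")
    reps = _load_whole_sequence_reps(config, manifest, "train")
    clf = GaitClassifier(config.model_config())
    clf.train([reps[u] for u in manifest.sequence_uri],
              list(manifest.gait_type))
    model_dir = config.root / "model"
    model_dir.mkdir(parents=True, exist_ok=True)
    clf.save(model_dir / "classifier.h5")
    pd.DataFrame(clf.history).to_csv(model_dir / "history.csv", index=False)
    logger.info("train: final training accuracy %.3f",
                clf.history["accuracy"][-1])


def stage_evaluate(config: PipelineConfig) -> Path:
    manifest = _manifest(config, "evaluate")
    reps = _load_whole_sequence_reps(config, manifest, "evaluate")
    subjects = list(pd.unique(manifest.subject_id))
    scheme = ev.make_folds(subjects, n_folds=config.n_folds)
    report = ev.cross_validate(manifest, reps, config.model_config(), scheme)
    out = config.root / "reports"
    out.mkdir(parents=True, exist_ok=True)
    report.save_json(out / "evaluation.json")
    report.confusion.to_csv(out / "confusion.csv")
    logger.info("evaluate:\n%s", report.format_grid())
    return out / "evaluation.json"


def stage_explain(config: PipelineConfig) -> None:
    manifest = _manifest(config, "explain")
    model_path = _require(config.root / "model" / "classifier.h5", "explain",
                          "trained model")
    clf = GaitClassifier.load(model_path)
    reps = _load_whole_sequence_reps(config, manifest, "explain")
    out = config.root / "explain"
    out.mkdir(parents=True, exist_ok=True)
    row = manifest.iloc[0]
    rep = reps[row.sequence_uri]
    target = int(np.argmax(clf.predict(rep)))
    sal = ex.saliency_map(clf, rep, target)
    cam = ex.grad_cam(clf, rep, target)
    io.write_image(out / "saliency.png", sal.values)
    io.write_image(out / "grad_cam.png", cam.values)
    io.write_image(out / "saliency_overlay.png", ex.overlay(rep, sal))
    io.write_image(out / "grad_cam_overlay.png", ex.overlay(rep, cam))
    logger.info("explain: wrote maps for %s (predicted %s)",
                row.sequence_uri, clf.class_labels[target])


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "segment": stage_segment,
    "represent": stage_represent,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "explain": stage_explain,
}


def run_pipeline(config: PipelineConfig, stages=STAGES) -> dict:
    """Execute the requested stages in canonical order.

    Returns a dict of report paths produced.  Raises :class:`StageError`
    naming the failing stage when an input is missing.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    config.root.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(config.root / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    outputs = {}
    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            result = _STAGE_FUNCS[stage](config)
            if result is not None:
                outputs[stage] = str(result)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outputs
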