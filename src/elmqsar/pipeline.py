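"""End-to-end workflow composition and run configuration.

A run is a pure function of (input bytes, configuration, master seed): the
master seed deterministically spawns one seed per stage (selection,
training, cross-validation, simulation) through a counter scheme, every
artifact is stamped with the configuration hash, and re-running the same
configuration reproduces byte-identical reports (the log file, which
carries timestamps, is the only exception).

Stage seed derivation: ``stage_seed(master, index)`` feeds
``SeedSequence([master, index])`` and reduces the first generated state
word modulo 2**31.  Stage indices are fixed constants, so adding stages
never perturbs existing ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .data_model import (
    CurationRule,
    LabeledDataset,
    load_dataset,
    save_model,
    standardize,
)
from .elm_core import ELMModel, OptimizerConfig, train
from .errors import ConfigError, DegenerateProblemError, ElmError
from .evaluation import kfold_cv, repeat_experiments
from .feature_selection import SelectionConfig, SelectionResult, select_descriptors_ga
from .synthetic import SyntheticConfig, generate

logger = logging.getLogger(__name__)

# fixed stage indices for seed derivation
STAGE_SIMULATE = 0
STAGE_SELECT = 1
STAGE_TRAIN = 2
STAGE_CV = 3


def stage_seed(master_seed: int, stage: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything a full run needs, round-trippable through YAML."""

    input_path: Optional[str] = None
    output_dir: str = "elm_run"
    id_column: Optional[str] = None
    label_column: str = "CLASS"
    label_kind: str = "class"  # "class" or "pic50"
    master_seed: int = 0
    curation: CurationRule = field(default_factory=CurationRule)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    threshold_mode: str = "midpoint"
    cv_folds: int = 10
    cv_repeats: int = 10
    nested_selection: bool = False
    fallback_top_k: int = 10

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (
            ("curation", CurationRule),
            ("selection", SelectionConfig),
            ("optimizer", OptimizerConfig),
            ("synthetic", SyntheticConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(d)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths excluded), so the
        same analysis run into two directories stamps identically."""
        d = self.to_dict()
        d.pop("input_path", None)
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stamp(config: RunConfig) -> dict:
    return {
        "elmqsar_version": __version__,
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
    }


def _write_json(path: str, payload: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def resolve_selected(
    selection: SelectionResult, fallback_top_k: int
) -> list[str]:
    """Selected subset, falling back to the top-k ranking when the usage
    cutoff admits no descriptor (small or noisy datasets)."""
    if selection.selected:
        return list(selection.selected)
    ranking = [d for d, u in selection.ranking() if u > 0]
    if not ranking:
        raise DegenerateProblemError("selection produced no usable descriptor")
    top = ranking[:fallback_top_k]
    logger.warning(
        "usage cutoff selected no descriptor; falling back to top %d by usage",
        len(top),
    )
    return top


def make_trainer(
    descriptor_names: list[str],
    optimizer: OptimizerConfig,
    threshold_mode: str = "midpoint",
):
    """A CV-compatible trainer over a fixed descriptor subset."""

    def trainer(dataset: LabeledDataset, seed: int) -> ELMModel:
        cfg = dataclasses.replace(optimizer, seed=int(seed) % (2**31))
        return train(dataset, descriptor_names, cfg, threshold_mode)

    return trainer


def make_nested_trainer(
    selection_config: SelectionConfig,
    optimizer: OptimizerConfig,
    threshold_mode: str = "midpoint",
    fallback_top_k: int = 10,
):
    """A trainer that re-runs descriptor selection inside each training
    fold (no selection leakage into validation folds)."""

    def trainer(dataset: LabeledDataset, seed: int) -> ELMModel:
        s = int(seed) % (2**31)
        zmat, _ = standardize(dataset.matrix)
        zds = LabeledDataset(zmat, dataset.labels.copy())
        sel = select_descriptors_ga(
            zds, dataclasses.replace(selection_config, seed=s)
        )
        names = resolve_selected(sel, fallback_top_k)
        cfg = dataclasses.replace(optimizer, seed=s)
        return train(dataset, names, cfg, threshold_mode)

    return trainer


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write its artifacts.

    Stages: load or simulate -> curate (pIC50 inputs) -> standardize ->
    select -> train -> cross-validate -> report.  Artifacts written to
    ``config.output_dir``: ``selection.json``, ``model.elm``,
    ``predictions.csv``, ``cv_report.json``, ``run.log`` and the resolved
    ``config.yaml``.  Returns a summary dict of artifact paths.

    Any stage failure is re-raised as :class:`ElmError` naming the stage.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    log_path = os.path.join(config.output_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("elmqsar")
    root.addHandler(handler)
    stage = "setup"
    try:
        config.save(os.path.join(config.output_dir, "config.yaml"))

        stage = "load"
        if config.input_path is None:
            sim = dataclasses.replace(
                config.synthetic,
                seed=stage_seed(config.master_seed, STAGE_SIMULATE),
            )
            dataset, _truth = generate(sim)
            logger.info("simulated dataset: %d x %d", dataset.n_compounds,
                        dataset.matrix.n_descriptors)
        else:
            dataset = load_dataset(
                config.input_path,
                label_column=config.label_column,
                id_column=config.id_column,
                label_kind=config.label_kind,
            )

        if config.label_kind == "pic50":
            stage = "curate"
            from .data_model import curate_by_activity

            dataset, report = curate_by_activity(dataset, config.curation)
            _write_json(
                os.path.join(config.output_dir, "curation.json"),
                {**_stamp(config), **report.to_dict()},
            )

        stage = "select"
        zmat, _ = standardize(dataset.matrix)
        zds = LabeledDataset(zmat, dataset.labels.copy())
        sel_cfg = dataclasses.replace(
            config.selection, seed=stage_seed(config.master_seed, STAGE_SELECT)
        )
        selection = select_descriptors_ga(zds, sel_cfg)
        _write_json(
            os.path.join(config.output_dir, "selection.json"),
            {**_stamp(config), **selection.to_dict()},
        )
        names = resolve_selected(selection, config.fallback_top_k)

        stage = "train"
        opt_cfg = dataclasses.replace(
            config.optimizer, seed=stage_seed(config.master_seed, STAGE_TRAIN)
        )
        model = train(dataset, names, opt_cfg, config.threshold_mode)
        save_model(model, os.path.join(config.output_dir, "model.elm"))

        stage = "predict"
        scores = model.scores(dataset.matrix)
        pred = model.predict(dataset.matrix)
        with open(
            os.path.join(config.output_dir, "predictions.csv"),
            "w", encoding="utf-8",
        ) as fh:
            fh.write("COMPOUND,SCORE,PREDICTED,THRESHOLD\n")
            for cid, s, p in zip(dataset.matrix.compound_ids, scores, pred):
                fh.write(f"{cid},{s!r},{int(p)},{model.threshold!r}\n")

        stage = "cv"
        n_active, n_inactive = dataset.class_counts()
        if min(n_active, n_inactive) < config.cv_folds:
            raise DegenerateProblemError(
                f"cv stage: each class needs >= {config.cv_folds} compounds "
                f"(active={n_active}, inactive={n_inactive})"
            )
        if config.nested_selection:
            trainer = make_nested_trainer(
                config.selection, config.optimizer,
                config.threshold_mode, config.fallback_top_k,
            )
        else:
            trainer = make_trainer(names, config.optimizer, config.threshold_mode)
        summary = repeat_experiments(
            dataset, trainer,
            R=config.cv_repeats, k=config.cv_folds,
            base_seed=stage_seed(config.master_seed, STAGE_CV),
        )
        _write_json(
            os.path.join(config.output_dir, "cv_report.json"),
            {**_stamp(config), **summary.to_dict()},
        )

        return {
            "output_dir": config.output_dir,
            "artifacts": [
                "config.yaml", "selection.json", "model.elm",
                "predictions.csv", "cv_report.json", "run.log",
            ],
            "selected": names,
            "cv_mean_acc": summary.cv_mean["acc"],
            "cv_mean_mcc": summary.cv_mean["mcc"],
        }
    except ElmError as exc:
        raise ElmError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
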