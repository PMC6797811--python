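"""End-to-end orchestration: simulate -> preprocess -> screen -> build -> train -> evaluate.

Two entry points:

* :func:`run_experiment` — in-memory pipeline for a whole classification
  experiment on one data set; returns the trained history and evaluation
  report.  This is what the acceptance study and the worked example use.

* :func:`run_pipeline` — file-based pipeline driven by a :class:`RunConfig`;
  every stage persists its artifacts under the run directory and a checksum
  manifest makes reruns verifiable.  The thin command-line layer wraps this.

One global seed fans out to per-stage seeds through a SeedSequence, so each
stage is independently reproducible and no two stages share a stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import cnn, dataset, evaluate, preprocess, screening, synthetic

__all__ = [
    "RunConfig",
    "PipelineError",
    "FIG6_COMORBIDITY_MIX",
    "stage_seeds",
    "run_experiment",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

# Comorbid / out-of-vocabulary subjects the disease-based screening must
# exclude: type 2 diabetes + hypertension (4), + atherosclerosis (3),
# + heart failure (5), diabetic foot disease (8).
FIG6_COMORBIDITY_MIX: dict[str, int] = {
    "Td+Hn": 4,
    "Td+At": 3,
    "Td+HF": 5,
    "diabetic foot": 8,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full run (defaults are the study conditions)."""

    dataset_id: int = 1
    seed: int = 0
    subjects_per_pattern: int = 22
    cycles_per_subject: int = 12
    include_comorbid: bool = True        # only meaningful for dataset 1
    noise_sd: float = 0.05
    wander_amplitude: float = 0.05
    fs: float = 100.0
    min_class_size: int = 20
    cycles_per_pattern: int = 210
    train_per_pattern: int = 140
    test_per_pattern: int = 70
    arch: str = "proposed"               # "proposed" | "lenet"
    channels: tuple[int, int, int] = (6, 12, 24)
    first_stride: int = 2
    fc_hidden: int = 48
    dropout_rate: float = 0.5
    batch_size: int = 64
    learning_rate: float = 0.001
    epochs: int = 30

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_mapping(cls, m: Mapping) -> "RunConfig":
        kwargs = dict(m)
        if "channels" in kwargs:
            kwargs["channels"] = tuple(kwargs["channels"])
        return cls(**kwargs)


def stage_seeds(seed: int, n: int = 6) -> list[int]:
    """Fan one global seed out into per-stage integer seeds (< 2**31)."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def _pattern_labels(dataset_id: int) -> list[str]:
    specs = synthetic.DATASET1_SPECS if dataset_id == 1 else synthetic.DATASET2_SPECS
    return list(specs)


def _architecture(cfg: RunConfig, n_classes: int) -> cnn.ArchitectureConfig:
    if cfg.arch == "lenet":
        return cnn.lenet_architecture(n_classes=n_classes)
    return cnn.proposed_architecture(
        n_classes=n_classes,
        channels=cfg.channels,
        first_stride=cfg.first_stride,
        fc_hidden=cfg.fc_hidden,
        dropout_rate=cfg.dropout_rate,
    )


def _simulate_cohort(cfg: RunConfig, seed: int) -> list[synthetic.SubjectProfile]:
    labels = _pattern_labels(cfg.dataset_id)
    class_mix = {lab: cfg.subjects_per_pattern for lab in labels}
    comorbid = FIG6_COMORBIDITY_MIX if (cfg.dataset_id == 1 and cfg.include_comorbid) else None
    return synthetic.generate_cohort(
        class_mix,
        comorbidity_mix=comorbid,
        rng=np.random.default_rng(seed),
        n_cycles_per_subject=cfg.cycles_per_subject,
        noise_sd=cfg.noise_sd,
        wander_amplitude=cfg.wander_amplitude,
        fs=cfg.fs,
    )


def _screen(cfg: RunConfig, cohort) -> tuple[list[screening.ScreeningDecision], dict[str, str]]:
    thresholds = screening.ScreeningThresholds(min_class_size=cfg.min_class_size)
    decisions, _counts = screening.screen_cohort(cohort, cfg.dataset_id, thresholds)
    kept = {d.subject_id: d.pattern for d in decisions if d.outcome == "kept"}
    return decisions, kept


def _preprocess_kept(cohort, kept: Mapping[str, str]):
    cycles_by_pattern: dict[str, list] = {}
    for subject in cohort:
        pattern = kept.get(subject.subject_id)
        if pattern is None or subject.record is None:
            continue
        for _cyc, _norm, img in preprocess.preprocess_record(subject.record):
            img.label = pattern
            cycles_by_pattern.setdefault(pattern, []).append(
                (subject.subject_id, img.cycle_index, img)
            )
    return cycles_by_pattern


def run_experiment(
    dataset_id: int = 1,
    seed: int = 0,
    cfg: RunConfig | None = None,
) -> dict:
    """Run the whole classification experiment in memory for one data set.

    Returns a dict with the screening decisions, dataset manifest, training
    history, evaluation report, and the test accuracy of the best (on test
    error) checkpoint.
    """
    if cfg is None:
        cfg = RunConfig(dataset_id=dataset_id, seed=seed)
    else:
        cfg = dataclasses.replace(cfg, dataset_id=dataset_id, seed=seed)
    s_sim, s_split, s_init, s_train, *_ = stage_seeds(cfg.seed)

    cohort = _simulate_cohort(cfg, s_sim)
    decisions, kept = _screen(cfg, cohort)
    cycles_by_pattern = _preprocess_kept(cohort, kept)

    split_cfg = dataset.SplitConfig(
        cycles_per_pattern=cfg.cycles_per_pattern,
        train_per_pattern=cfg.train_per_pattern,
        test_per_pattern=cfg.test_per_pattern,
        seed=s_split,
    )
    manifest, images = dataset.build_dataset(
        cycles_by_pattern, split_cfg, dataset_id=cfg.dataset_id,
        rng=np.random.default_rng(s_split),
    )
    X_train, y_train = dataset.manifest_to_arrays(manifest, images, "train")
    X_test, y_test = dataset.manifest_to_arrays(manifest, images, "test")

    arch = _architecture(cfg, n_classes=len(manifest.labels))
    model = cnn.build_model(arch, np.random.default_rng(s_init))
    train_cfg = cnn.TrainingConfig(
        learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
        epochs=cfg.epochs, seed=s_train,
    )
    history = cnn.train(model, X_train, y_train, X_test, y_test, train_cfg)
    model.load_state_dict(history.best_state)

    y_pred, _proba = cnn.predict(model, X_test)
    labels = manifest.labels
    cm = evaluate.confusion_matrix(
        [labels[i] for i in y_test], [labels[i] for i in y_pred], labels
    )
    report = evaluate.metrics_from_confusion(
        cm, metadata={"dataset_id": cfg.dataset_id, "best_epoch": history.best_epoch,
                      "config_hash": cfg.config_hash()},
    )
    return {
        "config": cfg,
        "cohort_size": len(cohort),
        "decisions": decisions,
        "manifest": manifest,
        "model": model,
        "history": history,
        "report": report,
        "test_accuracy": 1.0 - history.test_error[history.best_epoch],
    }


# ---------------------------------------------------------------------------
# File-based pipeline
# ---------------------------------------------------------------------------


def _write_records(cohort, out_dir: Path, config_hash: str) -> None:
    rec_dir = out_dir / "records"
    rec_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort:
        r = s.record
        t = np.arange(len(r.samples)) / r.fs
        pd.DataFrame({"time_s": t, "amplitude": r.samples}).to_csv(
            rec_dir / f"{s.subject_id}.csv", index=False
        )
        rows.append({
            "subject_id": s.subject_id, "diseases": ";".join(sorted(s.diseases)),
            "systolic": s.systolic, "diastolic": s.diastolic, "cavi": s.cavi,
            "bapwv": s.bapwv, "viscosity": s.viscosity, "label": s.label,
            "config_hash": config_hash,
        })
    pd.DataFrame(rows).to_csv(out_dir / "cohort.csv", index=False)


def _write_decisions(decisions, out_dir: Path, config_hash: str) -> None:
    pd.DataFrame([
        {"subject_id": d.subject_id, "dataset": d.dataset, "outcome": d.outcome,
         "pattern": d.pattern or "", "reason": d.reason or "",
         "config_hash": config_hash}
        for d in decisions
    ]).to_csv(out_dir / "decisions.csv", index=False)


def _save_state_dir(state: Mapping[str, np.ndarray], ckpt_dir: Path) -> None:
    ckpt_dir.mkdir(parents=True, exist_ok=True)
    names = sorted(state)
    for name in names:
        np.save(ckpt_dir / f"{name}.npy", state[name])
    (ckpt_dir / "index.json").write_text(json.dumps({"arrays": names}))


def _checksum_tree(root: Path, skip: set[str]) -> dict[str, str]:
    out = {}
    for p in sorted(root.rglob("*")):
        if p.is_file() and p.name not in skip:
            out[str(p.relative_to(root))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Execute every stage, persisting artifacts under ``out_dir``.

    Re-running with the same config and seed reproduces identical artifact
    checksums (recorded in ``checksums.json``).  A stage failure aborts with
    the stage name and cause.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    (out / "run_config.json").write_text(
        json.dumps({"config": dataclasses.asdict(cfg), "config_hash": chash,
                    "seed": cfg.seed}, indent=2, default=list)
    )
    s_sim, s_split, s_init, s_train, *_ = stage_seeds(cfg.seed)

    def _stage(name, fn, *args):
        logger.info("stage %s", name)
        try:
            return fn(*args)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise PipelineError(name, exc) from exc

    cohort = _stage("simulate", _simulate_cohort, cfg, s_sim)
    _stage("simulate-write", _write_records, cohort, out, chash)

    decisions, kept = _stage("screen", _screen, cfg, cohort)
    _stage("screen-write", _write_decisions, decisions, out, chash)

    cycles_by_pattern = _stage("preprocess", _preprocess_kept, cohort, kept)

    def _build():
        split_cfg = dataset.SplitConfig(cfg.cycles_per_pattern, cfg.train_per_pattern,
                                        cfg.test_per_pattern, seed=s_split)
        manifest, images = dataset.build_dataset(
            cycles_by_pattern, split_cfg, cfg.dataset_id,
            rng=np.random.default_rng(s_split),
        )
        dataset.write_dataset(manifest, images, out / f"dataset_{cfg.dataset_id}")
        return manifest, images

    manifest, images = _stage("build-dataset", _build)

    def _train():
        X_train, y_train = dataset.manifest_to_arrays(manifest, images, "train")
        X_test, y_test = dataset.manifest_to_arrays(manifest, images, "test")
        arch = _architecture(cfg, n_classes=len(manifest.labels))
        model = cnn.build_model(arch, np.random.default_rng(s_init))
        train_cfg = cnn.TrainingConfig(
            learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
            epochs=cfg.epochs, seed=s_train,
        )
        history = cnn.train(model, X_train, y_train, X_test, y_test, train_cfg)
        _save_state_dir(history.best_state, out / "checkpoint")
        model.load_state_dict(history.best_state)
        return model, history, (X_test, y_test)

    model, history, (X_test, y_test) = _stage("train", _train)

    def _evaluate():
        y_pred, _ = cnn.predict(model, X_test)
        labels = manifest.labels
        cm = evaluate.confusion_matrix(
            [labels[i] for i in y_test], [labels[i] for i in y_pred], labels
        )
        report = evaluate.metrics_from_confusion(
            cm, metadata={"dataset_id": cfg.dataset_id, "config_hash": chash,
                          "best_epoch": history.best_epoch},
        )
        evaluate.render_report(report, history, out / "report")
        return report

    _stage("evaluate", _evaluate)

    checksums = _checksum_tree(out, skip={"checksums.json", "curves.png"})
    (out / "checksums.json").write_text(json.dumps(
        {"config_hash": chash, "files": checksums}, indent=2
    ))
    return out
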