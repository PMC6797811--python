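"""Dataset assembly: per-pattern cycle quotas, train/test split, PNG persistence.

The study design draws exactly 210 distinct cycles per pulse pattern and
splits them 140 training / 70 test.  The split is by cycle, not by subject,
so a subject can contribute cycles to both halves; the resulting leakage
fraction is computed and logged, and a subject-wise split is available as a
non-default option.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import N_POINTS, PulseImage, read_png, write_png

__all__ = [
    "SplitConfig",
    "ManifestEntry",
    "DatasetManifest",
    "QuotaError",
    "IntegrityError",
    "build_dataset",
    "write_dataset",
    "read_dataset",
    "manifest_to_arrays",
    "leakage_fraction",
    "dataset_checksum",
]

logger = logging.getLogger(__name__)


class QuotaError(ValueError):
    """A pattern cannot supply the required number of distinct cycles."""


class IntegrityError(RuntimeError):
    """A persisted dataset is inconsistent with its manifest."""


@dataclass(frozen=True)
class SplitConfig:
    cycles_per_pattern: int = 210
    train_per_pattern: int = 140
    test_per_pattern: int = 70
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cycles_per_pattern, self.train_per_pattern, self.test_per_pattern) <= 0:
            raise ValueError("all split sizes must be positive")
        if self.train_per_pattern + self.test_per_pattern != self.cycles_per_pattern:
            raise ValueError("train + test must equal cycles_per_pattern")


@dataclass(frozen=True)
class ManifestEntry:
    subject_id: str
    cycle_index: int
    label: str
    split: str               # "train" | "test"
    path: str | None = None  # set once persisted

    @property
    def key(self) -> tuple[str, int]:
        return (self.subject_id, self.cycle_index)


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry]
    dataset_id: int
    labels: list[str]  # fixed label order -> class indices

    def __post_init__(self) -> None:
        keys = [e.key for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (subject_id, cycle_index) in manifest")

    def split(self, tag: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.split == tag]


def build_dataset(
    cycles_by_pattern: Mapping[str, Sequence[tuple[str, int, PulseImage]]],
    cfg: SplitConfig = SplitConfig(),
    dataset_id: int = 1,
    rng: np.random.Generator | None = None,
) -> tuple[DatasetManifest, dict[tuple[str, int], PulseImage]]:
    """Sample the per-pattern quota and split it into train/test.

    ``cycles_by_pattern`` maps a pattern label to (subject_id, cycle_index,
    image) triples.  Exactly ``cycles_per_pattern`` distinct cycles per
    pattern are drawn uniformly without replacement, then partitioned
    140/70 at random; everything is deterministic given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    labels = sorted(cycles_by_pattern)
    entries: list[ManifestEntry] = []
    images: dict[tuple[str, int], PulseImage] = {}

    for label in labels:
        pool = list(cycles_by_pattern[label])
        if len(pool) < cfg.cycles_per_pattern:
            raise QuotaError(
                f"pattern {label!r} supplies {len(pool)} cycles, "
                f"needs {cfg.cycles_per_pattern}"
            )
        chosen = rng.permutation(len(pool))[: cfg.cycles_per_pattern]
        for rank, idx in enumerate(chosen):
            sid, cyc, img = pool[int(idx)]
            split = "train" if rank < cfg.train_per_pattern else "test"
            entries.append(ManifestEntry(sid, cyc, label, split))
            images[(sid, cyc)] = img

    manifest = DatasetManifest(entries=entries, dataset_id=dataset_id, labels=labels)
    leak = leakage_fraction(manifest)
    logger.info("dataset %d: %d entries, test-subject leakage fraction %.3f",
                dataset_id, len(entries), leak)
    return manifest, images


def leakage_fraction(manifest: DatasetManifest) -> float:
    """Fraction of test cycles whose subject also contributes training cycles."""
    train_subjects = {e.subject_id for e in manifest.split("train")}
    test = manifest.split("test")
    if not test:
        return 0.0
    return sum(e.subject_id in train_subjects for e in test) / len(test)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ["path", "label", "split", "subject_id", "cycle_index"]


def write_dataset(
    manifest: DatasetManifest,
    images: Mapping[tuple[str, int], PulseImage],
    out_dir: str | Path,
) -> DatasetManifest:
    """Persist ``dataset_<id>/<pattern>/<split>/<subject>_<cycle>.png`` + manifest.csv."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    new_entries: list[ManifestEntry] = []
    for e in manifest.entries:
        rel = Path(e.label) / e.split / f"{e.subject_id}_{e.cycle_index}.png"
        dest = root / rel
        dest.parent.mkdir(parents=True, exist_ok=True)
        write_png(images[e.key], dest)
        new_entries.append(ManifestEntry(e.subject_id, e.cycle_index, e.label,
                                         e.split, str(rel)))
    out = DatasetManifest(new_entries, manifest.dataset_id, list(manifest.labels))
    df = pd.DataFrame(
        [(e.path, e.label, e.split, e.subject_id, e.cycle_index) for e in out.entries],
        columns=_MANIFEST_COLUMNS,
    )
    df.insert(0, "dataset_id", manifest.dataset_id)
    df.to_csv(root / "manifest.csv", index=False)
    return out


def read_dataset(out_dir: str | Path) -> tuple[DatasetManifest, dict[tuple[str, int], PulseImage]]:
    """Load a persisted dataset, verifying every image is a 200x200 PNG."""
    root = Path(out_dir)
    mpath = root / "manifest.csv"
    if not mpath.exists():
        raise IntegrityError(f"missing manifest at {mpath}")
    df = pd.read_csv(mpath)
    entries: list[ManifestEntry] = []
    images: dict[tuple[str, int], PulseImage] = {}
    for row in df.itertuples(index=False):
        p = root / str(row.path)
        if not p.exists():
            raise IntegrityError(f"missing image file {p}")
        pixels = read_png(p)
        if pixels.shape != (N_POINTS, N_POINTS):
            raise IntegrityError(f"image {p} has shape {pixels.shape}, expected 200x200")
        e = ManifestEntry(str(row.subject_id), int(row.cycle_index),
                          str(row.label), str(row.split), str(row.path))
        entries.append(e)
        images[e.key] = PulseImage(pixels, label=e.label, subject_id=e.subject_id,
                                   cycle_index=e.cycle_index)
    dataset_id = int(df["dataset_id"].iloc[0]) if len(df) else 0
    labels = sorted(df["label"].unique()) if len(df) else []
    return DatasetManifest(entries, dataset_id, list(labels)), images


def manifest_to_arrays(
    manifest: DatasetManifest,
    images: Mapping[tuple[str, int], PulseImage],
    split: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack one split into (N, 1, 200, 200) float32 inputs and int labels."""
    label_index = {lab: i for i, lab in enumerate(manifest.labels)}
    entries = manifest.split(split)
    X = np.stack([images[e.key].pixels for e in entries]).astype(np.float32) / 255.0
    y = np.array([label_index[e.label] for e in entries], dtype=np.int64)
    return X[:, None, :, :], y


def dataset_checksum(out_dir: str | Path) -> str:
    """SHA-256 over all files of a persisted dataset (order-independent)."""
    root = Path(out_dir)
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(root)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()
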