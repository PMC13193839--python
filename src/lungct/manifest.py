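"""Dataset manifests: class-folder discovery, label encoding, balanced splits.

The train/test protocol mirrors the three-class design the pipeline targets:
a perfectly balanced held-out test set (default 150 images per class, 450
total) drawn without replacement, with the remainder forming the training
set.  On the emulated clinical counts {530, 536, 534} this yields the
70:30-style partition 1,150 / 450 with train counts {380, 386, 384}.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .image_core import load_grayscale

#: Fixed class order (alphabetical); index = one-hot column.
CLASS_NAMES = ("Benign", "Malignant", "Normal")
CLASS_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}

_IMAGE_EXTS = {".png", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class ManifestRecord:
    path: str
    label: str


@dataclass
class Manifest:
    """An ordered list of (image path, class label) records."""

    records: list[ManifestRecord] = field(default_factory=list)
    split_tag: str = "unsplit"

    def __post_init__(self):
        for rec in self.records:
            if rec.label not in CLASS_INDEX:
                raise ValidationError(f"unknown class label {rec.label!r} in manifest")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def counts(self) -> dict[str, int]:
        out = {name: 0 for name in CLASS_NAMES}
        for rec in self.records:
            out[rec.label] += 1
        return out

    @property
    def labels(self) -> list[str]:
        return [rec.label for rec in self.records]

    @property
    def paths(self) -> list[str]:
        return [rec.path for rec in self.records]

    def to_csv(self, path: str | os.PathLike) -> None:
        pd.DataFrame(
            {
                "path": self.paths,
                "label": self.labels,
                "split": self.split_tag,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "Manifest":
        df = pd.read_csv(path)
        tags = set(df["split"]) if "split" in df else {"unsplit"}
        tag = tags.pop() if len(tags) == 1 else "unsplit"
        return cls(
            records=[ManifestRecord(p, l) for p, l in zip(df["path"], df["label"])],
            split_tag=tag,
        )


@dataclass(frozen=True)
class SplitSpec:
    """Balanced held-out split: exactly ``test_per_class`` test images per class."""

    test_per_class: int = 150
    seed: int = 0


def build_manifest(root: str | os.PathLike) -> Manifest:
    """Discover a ``<root>/<Class>/*.{png,jpg}`` dataset.

    Files are ordered lexicographically within each class for determinism.
    Unreadable entries are skipped with a warning rather than aborting.
    """
    root = Path(root)
    records: list[ManifestRecord] = []
    for label in CLASS_NAMES:
        cls_dir = root / label
        if not cls_dir.is_dir():
            raise ConfigurationError(f"missing class folder: {cls_dir}")
        files = sorted(
            p for p in cls_dir.iterdir() if p.suffix.lower() in _IMAGE_EXTS and p.is_file()
        )
        kept = 0
        for p in files:
            try:
                load_grayscale(p)
            except Exception as exc:  # unreadable file: report and skip
                warnings.warn(f"skipping unreadable image {p}: {exc}")
                continue
            records.append(ManifestRecord(path=str(p), label=label))
            kept += 1
        if kept == 0:
            raise ValidationError(f"class folder {cls_dir} contains no decodable images")
    return Manifest(records=records, split_tag="unsplit")


def split(manifest: Manifest, spec: SplitSpec) -> tuple[Manifest, Manifest]:
    """Partition into (train, test) with a balanced test set.

    The test set holds exactly ``spec.test_per_class`` records per class,
    sampled without replacement under ``spec.seed``; the train set is the
    exact complement.  Record order within each output follows the input
    manifest order.
    """
    counts = manifest.counts
    for name in CLASS_NAMES:
        if counts[name] < spec.test_per_class:
            raise ValidationError(
                f"class {name} has only {counts[name]} records; "
                f"cannot hold out {spec.test_per_class}"
            )
    rng = np.random.default_rng(spec.seed)
    test_idx: set[int] = set()
    for name in CLASS_NAMES:
        idx = [i for i, rec in enumerate(manifest.records) if rec.label == name]
        chosen = rng.choice(len(idx), size=spec.test_per_class, replace=False)
        test_idx.update(idx[c] for c in chosen)
    train_records = [r for i, r in enumerate(manifest.records) if i not in test_idx]
    test_records = [r for i, r in enumerate(manifest.records) if i in test_idx]
    if not train_records:
        warnings.warn("split produced an empty training set")
    return (
        Manifest(records=train_records, split_tag="train"),
        Manifest(records=test_records, split_tag="test"),
    )


def encode_labels(labels: list[str]) -> np.ndarray:
    """One-hot encode labels in the fixed class order (rows sum to 1)."""
    out = np.zeros((len(labels), len(CLASS_NAMES)), dtype=np.float64)
    for i, label in enumerate(labels):
        if label not in CLASS_INDEX:
            raise ValidationError(f"unknown class label {label!r}")
        out[i, CLASS_INDEX[label]] = 1.0
    return out


def decode_labels(indices: np.ndarray) -> list[str]:
    """Map class indices back to names."""
    return [CLASS_NAMES[int(i)] for i in indices]
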