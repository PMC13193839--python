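"""End-to-end orchestration: preprocessing, training, evaluation, ablation.

A run executes load -> resize 512 -> lung segmentation (optional) -> nodule
masking (optional) -> backbone-input conversion -> balanced split -> training
-> confusion-matrix evaluation, and writes a fully reproducible run
directory: the resolved configuration with every seed, the split manifests,
the training history, and the evaluation report.  Identical configurations
and seeds produce byte-identical report JSON.

The ablation harness re-runs the pipeline three times with cumulative stage
enablement — segmentation only, + nodule masking, + BiGRU head — holding the
split, seeds, and preprocessed inputs fixed so that row-to-row differences
isolate the stage contribution.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .augment import AugmentConfig
from .errors import ConfigurationError, StageError
from .image_core import PROCESS_SIZE, load_grayscale, resize_to
from .manifest import Manifest, SplitSpec, build_manifest, split
from .metrics import (
    compute_metrics,
    confusion,
    macro_precision_recall,
    render_report,
    report_to_dict,
)
from .model import HybridModel, ModelConfig, TrainConfig, build_model, predict, train
from .nodule import NoduleMaskParams, nodule_focus
from .phantom import PhantomSpec, generate_dataset
from .segmentation import SegmentationParams, segment_lungs

log = logging.getLogger("lungct")


@dataclass(frozen=True)
class PhantomRequest:
    """Generate a phantom dataset instead of reading an existing folder."""

    enabled: bool = False
    n_per_class: int = 60
    spec: PhantomSpec = field(default_factory=PhantomSpec)


@dataclass(frozen=True)
class PipelineConfig:
    data_root: str | None = None
    phantom: PhantomRequest = field(default_factory=PhantomRequest)
    use_clahe_segmentation: bool = True
    use_nodule_masking: bool = True
    use_bigru_head: bool = True
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    nodule: NoduleMaskParams = field(default_factory=NoduleMaskParams)
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0
    out_dir: str = "runs/run"

    def __post_init__(self):
        if self.use_nodule_masking and not self.use_clahe_segmentation:
            raise ConfigurationError(
                "use_nodule_masking requires use_clahe_segmentation: the nodule "
                "candidate rule consumes the segmented lung image"
            )
        if self.data_root is None and not self.phantom.enabled:
            raise ConfigurationError("either data_root or phantom.enabled is required")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        builders = {
            "phantom": _build_phantom,
            "segmentation": SegmentationParams,
            "nodule": NoduleMaskParams,
            "augment": lambda a: AugmentConfig(**_tuplify(a)) if a is not None else None,
            "split": SplitSpec,
            "model": lambda m: ModelConfig(**_tuplify(m)),
            "train": TrainConfig,
        }
        for key, builder in builders.items():
            if key in d and isinstance(d[key], dict):
                d[key] = builder(**d[key]) if builder in (
                    SegmentationParams, NoduleMaskParams, SplitSpec, TrainConfig,
                ) else builder(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def _build_phantom(d: dict) -> PhantomRequest:
    d = dict(d)
    if isinstance(d.get("spec"), dict):
        d["spec"] = PhantomSpec(**_tuplify(d["spec"]))
    return PhantomRequest(**d)


def preprocess_image(
    image: np.ndarray, config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray | None]:
    """Resize to 512 and apply the enabled preprocessing stages.

    Returns the processed gray image (still 512x512; backbone conversion
    happens at training time) and the final lung mask (None when
    segmentation is off).
    """
    img = resize_to(image, PROCESS_SIZE, PROCESS_SIZE)
    lung_mask = None
    if config.use_clahe_segmentation:
        img, lung_mask = segment_lungs(img, config.segmentation)
        log.debug("segmented: mask area=%d, mean=%.1f", int(lung_mask.sum()),
                  float(img[lung_mask.astype(bool)].mean()) if lung_mask.any() else 0.0)
    if config.use_nodule_masking:
        img, cand = nodule_focus(img, lung_mask, config.nodule)
        log.debug("masked: candidate area=%d", int(cand.sum()))
    return img, lung_mask


def _resolve_manifest(config: PipelineConfig, out: Path) -> Manifest:
    if config.phantom.enabled:
        data_dir = out / "data"
        log.info("generating %d phantoms per class", config.phantom.n_per_class)
        return generate_dataset(
            config.phantom.spec, config.phantom.n_per_class, seed=config.seed,
            out_dir=data_dir,
        )
    return build_manifest(config.data_root)


def _load_processed(manifest: Manifest, config: PipelineConfig) -> list[np.ndarray]:
    images = []
    for rec in manifest.records:
        img, _ = preprocess_image(load_grayscale(rec.path), config)
        images.append(img)
    return images


@dataclass
class RunResult:
    run_dir: Path
    history: dict
    report: dict
    accuracy: float


def run_pipeline(config: PipelineConfig, precomputed: dict | None = None) -> RunResult:
    """Execute the full pipeline and write the run directory.

    ``precomputed`` optionally carries ``{"train": (images, labels),
    "test": (images, labels)}`` with already-preprocessed gray images (used
    by the ablation harness to hold inputs fixed across rows).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True, default=str)

    try:
        if precomputed is None:
            manifest = _resolve_manifest(config, out)
            train_man, test_man = split(manifest, config.split)
            train_man.to_csv(out / "train_manifest.csv")
            test_man.to_csv(out / "test_manifest.csv")
            log.info("split: train=%s test=%s", train_man.counts, test_man.counts)
            train_imgs = _load_processed(train_man, config)
            test_imgs = _load_processed(test_man, config)
            train_labels, test_labels = train_man.labels, test_man.labels
        else:
            train_imgs, train_labels = precomputed["train"]
            test_imgs, test_labels = precomputed["test"]
    except StageError:
        raise
    except Exception as exc:
        raise StageError("preprocess", str(exc)) from exc

    try:
        mcfg = dataclasses.replace(config.model, use_bigru_head=config.use_bigru_head)
        model = build_model(mcfg, seed=config.seed)
        tcfg = dataclasses.replace(config.train, seed=config.train.seed or config.seed)
        history = train(
            model, train_imgs, train_labels, test_imgs, test_labels,
            tcfg=tcfg, aug=config.augment,
        )
    except Exception as exc:
        raise StageError("train", str(exc)) from exc

    try:
        _, pred_labels = predict(model, test_imgs)
        cm = confusion(test_labels, pred_labels)
        report = compute_metrics(cm)
        report_dict = report_to_dict(report, cm)
        report_dict["seeds"] = {"run": config.seed, "split": config.split.seed,
                                "train": tcfg.seed}
        model.save_weights(out / "checkpoint.npz")
        with open(out / "history.json", "w") as fh:
            json.dump(history.to_dict(), fh, indent=2, sort_keys=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report_dict, fh, indent=2, sort_keys=True)
        with open(out / "report.txt", "w") as fh:
            fh.write(render_report(report, cm))
    except Exception as exc:
        raise StageError("evaluate", str(exc)) from exc

    return RunResult(
        run_dir=out,
        history=history.to_dict(),
        report=report_dict,
        accuracy=report.accuracy,
    )


@dataclass
class AblationRow:
    stage: str
    accuracy: float
    precision: float
    recall: float


def run_ablation(config: PipelineConfig) -> list[AblationRow]:
    """Three cumulative-stage runs sharing one split and one set of seeds.

    Rows, in order: lung segmentation with a dense head; + nodule masking
    (dense head); + BiGRU head (the full pipeline).  Preprocessed inputs are
    computed once per stage configuration; the train/test membership is
    identical in every row.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _resolve_manifest(config, out)
    train_man, test_man = split(manifest, config.split)
    train_man.to_csv(out / "train_manifest.csv")
    test_man.to_csv(out / "test_manifest.csv")

    stages = [
        ("Baseline + Seg.", dict(use_clahe_segmentation=True,
                                 use_nodule_masking=False, use_bigru_head=False)),
        ("+ Masking", dict(use_clahe_segmentation=True,
                           use_nodule_masking=True, use_bigru_head=False)),
        ("+ BiGRU (Final)", dict(use_clahe_segmentation=True,
                                 use_nodule_masking=True, use_bigru_head=True)),
    ]

    # stage 1 preprocessing (segmentation only) is shared; masking derives from it
    seg_cfg = dataclasses.replace(config, use_nodule_masking=False, use_bigru_head=False)
    seg_train = _load_processed(train_man, seg_cfg)
    seg_test = _load_processed(test_man, seg_cfg)

    def masked(images):
        return [nodule_focus(img, None, config.nodule)[0] for img in images]

    mask_train, mask_test = masked(seg_train), masked(seg_test)

    inputs = {
        "Baseline + Seg.": (seg_train, seg_test),
        "+ Masking": (mask_train, mask_test),
        "+ BiGRU (Final)": (mask_train, mask_test),
    }

    rows: list[AblationRow] = []
    for stage_name, toggles in stages:
        stage_cfg = dataclasses.replace(
            config, out_dir=str(out / stage_name.replace(" ", "_").replace("+", "plus")),
            **toggles,
        )
        tr, te = inputs[stage_name]
        result = run_pipeline(
            stage_cfg,
            precomputed={"train": (tr, train_man.labels), "test": (te, test_man.labels)},
        )
        p, r = macro_precision_recall(compute_metrics(
            np.asarray(result.report["confusion_matrix"])
        ))
        rows.append(AblationRow(stage_name, result.accuracy, p, r))
        log.info("%s: acc=%.3f", stage_name, result.accuracy)

    with open(out / "ablation.json", "w") as fh:
        json.dump([dataclasses.asdict(r) for r in rows], fh, indent=2, sort_keys=True)
    return rows


def render_ablation(rows: list[AblationRow]) -> str:
    lines = [f"{'Stage':<18}{'Accuracy (%)':>16}{'Precision (%)':>15}{'Recall (%)':>12}"]
    prev = None
    for row in rows:
        delta = f" ({100*(row.accuracy - prev):+.1f})" if prev is not None else ""
        acc = f"{100*row.accuracy:.1f}{delta}"
        lines.append(
            f"{row.stage:<18}{acc:>16}{100*row.precision:>15.1f}{100*row.recall:>12.1f}"
        )
        prev = row.accuracy
    return "\n".join(lines)
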