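"""Shared fixtures: phantoms and preprocessed toy datasets.

The expensive fixtures (a 60-per-class preprocessed phantom dataset, a batch
of segmented phantoms) are session-scoped: they are built once and shared by
the segmentation oracle, the masking oracle, and the toy-scale training
checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from lungct.manifest import CLASS_NAMES
from lungct.phantom import PhantomSpec, generate_phantom
from lungct.pipeline import PhantomRequest, PipelineConfig, preprocess_image

N_ORACLE_PHANTOMS = 20


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def oracle_phantoms(phantom_spec):
    """One labelled phantom per (seed, class) pair for the stage oracles."""
    records = []
    per_class = N_ORACLE_PHANTOMS // 2  # benign + malignant carry nodules
    for s in range(per_class):
        for label in ("Benign", "Malignant"):
            records.append(generate_phantom(phantom_spec, label, seed=500 + s))
    return records


@pytest.fixture(scope="session")
def toy_dataset(phantom_spec):
    """60 phantoms per class, preprocessed at both ablation stages.

    Segmentation (the expensive stage) runs once per image; the
    nodule-masked variant is derived from the segmented one.  Returns
    ``(segmented_images, masked_images, labels)``.
    """
    from lungct.nodule import nodule_focus

    seg_config = PipelineConfig(
        phantom=PhantomRequest(enabled=True), use_nodule_masking=False
    )
    seg_images, masked_images, labels = [], [], []
    for label in CLASS_NAMES:
        for k in range(60):
            rec = generate_phantom(phantom_spec, label, seed=1000 + k)
            seg, lung_mask = preprocess_image(rec.image, seg_config)
            seg_images.append(seg)
            masked_images.append(nodule_focus(seg, lung_mask)[0])
            labels.append(label)
    return seg_images, masked_images, labels


def split_toy(images, labels, seed, test_per_class=15):
    """Deterministic balanced holdout used by the toy training checks."""
    rng = np.random.default_rng(seed)
    n_class = len(images) // 3
    test_idx: set[int] = set()
    for c in range(3):
        chosen = rng.choice(n_class, test_per_class, replace=False)
        test_idx.update((c * n_class + chosen).tolist())
    tr = [i for i in range(len(images)) if i not in test_idx]
    te = sorted(test_idx)
    return (
        [images[i] for i in tr], [labels[i] for i in tr],
        [images[i] for i in te], [labels[i] for i in te],
    )
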