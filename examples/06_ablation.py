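"""Cumulative-stage ablation on a small phantom run.

Three runs share one split and one set of seeds: segmentation with a plain
dense head, + nodule masking, + the BiGRU head (full pipeline).  The scale
here is deliberately tiny so the example is quick; the test suite runs the
stage-contribution property at the full desk scale.
"""

from lungct.manifest import SplitSpec
from lungct.model import ModelConfig, TrainConfig
from lungct.phantom import PhantomSpec
from lungct.pipeline import PhantomRequest, PipelineConfig, render_ablation, run_ablation

config = PipelineConfig(
    phantom=PhantomRequest(
        enabled=True,
        n_per_class=12,
        spec=PhantomSpec(image_size=192, benign_nodule_radius=(4.0, 6.0),
                         malignant_nodule_radius=(8.0, 12.0)),
    ),
    augment=None,
    split=SplitSpec(test_per_class=3, seed=0),
    model=ModelConfig.toy(),
    train=TrainConfig(learning_rate=1e-3, batch_size=8, max_epochs=10, patience=5,
                      freeze_policy="none", seed=0),
    seed=0,
    out_dir="scratch/ablation",
)

rows = run_ablation(config)
print(render_ablation(rows))
# Each row adds one stage while train/test membership stays fixed, so the
# accuracy column isolates what segmentation, masking, and the BiGRU head
# each contribute.
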