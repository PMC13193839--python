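"""Apply the nodule-candidate intensity rule to a segmented phantom.

Pixels strictly below intensity 140 (but nonzero, and inside the lung
fields) are kept as candidate-nodule regions; everything else is zeroed.
On a phantom the ground-truth nodule mask measures how much of the true
lesion survives the rule.
"""

from lungct.nodule import candidate_mask
from lungct.phantom import PhantomSpec, generate_phantom
from lungct.segmentation import segment_lungs

record = generate_phantom(PhantomSpec(), "Benign", seed=7)
segmented, lung_mask = segment_lungs(record.image)
candidates = candidate_mask(segmented, lung_mask)

nodule = record.nodule_mask.astype(bool)
recall = (candidates.astype(bool) & nodule).sum() / nodule.sum()

print(f"candidate pixels: {candidates.sum()}")
print(f"true nodule pixels: {nodule.sum()}")
print(f"fraction of nodule pixels flagged: {recall:.3f}")
# A recall near 1 shows the below-140 rule keeps the lesion while discarding
# the zeroed background outside the lungs.
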