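"""Generate a phantom dataset and summarize its statistical structure.

The phantoms emulate what matters to the segmentation task: a small
elongated organ (severe class imbalance), a tumor strictly inside it,
intensity contrast and noise.
"""

import numpy as np

from gwbcoseg import PhantomConfig, generate_dataset

cases = generate_dataset(50, PhantomConfig(), seed=7)

fracs = [c.pancreas_mask.mean() for c in cases]
tumor_fracs = [c.tumor_mask.sum() / max(1, c.pancreas_mask.sum())
               for c in cases if c.has_tumor]
print(f"{len(cases)} cases, {sum(c.has_tumor for c in cases)} with a tumor")
print(f"organ area fraction: {np.min(fracs):.3f}–{np.max(fracs):.3f} "
      f"(background always > 90%)")
print(f"tumor/organ area ratio: median {np.median(tumor_fracs):.2f}")
violations = sum((c.tumor_mask & ~c.pancreas_mask).any() for c in cases)
print(f"tumor-outside-organ violations: {violations}")

c = next(c for c in cases if c.has_tumor)
bg = c.image[c.pancreas_mask == 0].mean()
organ = c.image[(c.pancreas_mask == 1) & (c.tumor_mask == 0)].mean()
tumor = c.image[c.tumor_mask == 1].mean()
print(f"mean intensity background/organ/tumor: {bg:.2f}/{organ:.2f}/{tumor:.2f}")
# The ordering background < organ < tumor mirrors portal-venous contrast.
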