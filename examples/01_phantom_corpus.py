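"""Generate a small phantom corpus and look at one sample.

Each phantom is a torso template with planted pathologies (bright lung
blobs, an enlarged heart, a support line) plus Gaussian noise, paired
with a rule-generated report whose label tokens come first — the same
shape as a labeller-prefixed radiology report.
"""

import numpy as np

import xraycap as xc

spec = xc.PhantomSpec(seed=0)
sample = xc.generate_phantom(spec, index=2)

print("labels      :", sample.labels)
print("impression  :", sample.impression)
print("findings    :", sample.findings)
print("report      :", sample.report)
print("image       :", sample.image.shape, sample.image.dtype,
      f"range [{sample.image.min():.2f}, {sample.image.max():.2f}]")
for kind, mask in sample.masks.items():
    print(f"mask {kind:15s}: {int(mask.sum())} px "
          f"({100 * mask.mean():.2f}% of the image)")

# a corpus on disk: HDF5 images + JSON-lines reports + manifest
from pathlib import Path
Path("scratch").mkdir(exist_ok=True)
manifest = xc.generate_dataset(spec, 20, "scratch/images.h5",
                               "scratch/reports.jsonl")
train, val, test = xc.split_dataset(manifest, seed=0)
print(f"\nwrote {len(manifest)} phantoms; split "
      f"{len(train)}/{len(val)}/{len(test)} (train/val/test)")
# The split fractions default to 75% / 24.75% / 0.25%.
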