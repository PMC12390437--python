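"""Corpus preparation: the 3:1:1 split and the three amplification operators."""

import numpy as np

from stunwatch.dataset import AmplifyConfig, amplify, split_dataset
from stunwatch.datamodel import BoundingBox

split = split_dataset(1024, seed=7)
print(f"split of 1024 images : train={len(split.train)}, "
      f"test={len(split.test)}, validation={len(split.validation)}")

# a tiny stand-in training set: 4 images, one annotated bird each
rng = np.random.default_rng(0)
images = [rng.integers(0, 256, size=(48, 64, 3), dtype=np.uint8) for _ in range(4)]
dataset = [(img, [BoundingBox(30.0, 24.0, 12.0, 16.0)]) for img in images]

out = amplify(dataset, AmplifyConfig(keep_originals=False, seed=7))
print(f"amplified variants   : {len(out)} (HSV dither, flip, +10% scale per image)")
_, flip_boxes = out[1]
print(f"flipped box center   : cx={flip_boxes[0].cx:.1f} (was 30.0 in a 64 px image)")
_, scale_boxes = out[2]
print(f"scaled box size      : w={scale_boxes[0].w:.1f} (was 12.0, +10%)")
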