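"""Weak vs strong augmentation of one ROI, as used by consistency training.

Weak = flips + small integer translations (the reference view); strong =
weak followed by one heavier operator (rotation, scaling, noise, intensity,
blur or cutout).  On the labeled stream one operator — identity included —
is drawn uniformly per sample.
"""

import numpy as np

from nodulefpr.augment import (
    FULL_MENU,
    STRONG_MENU,
    labeled_augment,
    strong_augment,
    weak_augment,
)
from nodulefpr.preprocess import extract_roi, normalize_intensity
from nodulefpr.simulate import generate_phantom_scan, random_layout

layout = random_layout("demo", seed=5, n_nodules=1, grid=(16, 96, 96))
vol, truths = generate_phantom_scan(layout, grid=(16, 96, 96))
roi = extract_roi(normalize_intensity(vol), truths[0].center_world)
patch = roi.patch

weak = weak_augment(patch, seed=1)
strong = strong_augment(patch, seed=1)
print(f"patch {patch.shape}; |weak - original| mean "
      f"{np.abs(weak - patch).mean():.4f}; |strong - original| mean "
      f"{np.abs(strong - patch).mean():.4f}")
print(f"strong menu: {', '.join(STRONG_MENU)}")

counts = {}
for seed in range(2000):
    _, name = labeled_augment(patch[:4, :8, :8], seed=seed, return_name=True)
    counts[name] = counts.get(name, 0) + 1
print("labeled-stream operator draw over 2000 samples "
      f"(uniform over {len(FULL_MENU) + 1} options):")
for name in sorted(counts, key=counts.get, reverse=True):
    print(f"  {name:10s} {counts[name] / 2000:.3f}")
print("All operators preserve patch shape, the [-1, 1] value range and the"
      "\nlabel; the consistency loss pulls the strong view's prediction"
      "\ntoward the weak view's confident hard label.")
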