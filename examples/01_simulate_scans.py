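"""Generate a phantom-mode and a clinical-mode CT scan and describe them.

The phantom scan emulates an anthropomorphic thorax phantom with inserted
synthetic nodules: clean parenchyma, a sparse vascular insert, nodules from
four shape families at three densities.  The clinical scan adds the
structures that make real data hard: parenchymal texture, dense vessels,
airways and scar-like mimics.
"""

import numpy as np

from nodulefpr.simulate import (
    generate_clinical_scan,
    generate_phantom_scan,
    random_layout,
)

layout = random_layout("phantom-demo", seed=7, n_nodules=3, grid=(16, 96, 96))
phantom, phantom_truths = generate_phantom_scan(layout, grid=(16, 96, 96))
clinical, clinical_truths = generate_clinical_scan(
    seed=7, difficulty=1.0, n_nodules=3, grid=(16, 96, 96)
)

print(f"phantom scan: shape {phantom.shape}, spacing {phantom.spacing} mm")
for ann, spec in zip(phantom_truths, layout.nodules):
    print(f"  nodule: {spec.shape_family:10s} d={spec.diameter_mm:5.1f} mm "
          f"at {spec.density_hu:+6.0f} HU, center (x,y,z)="
          f"({ann.center_world[0]:.1f}, {ann.center_world[1]:.1f}, "
          f"{ann.center_world[2]:.1f}) mm")

print(f"\nclinical scan: {len(clinical_truths)} nodules")
print(f"  HU range: [{clinical.data.min():.0f}, {clinical.data.max():.0f}]"
      " — wider than phantom because of calcifications and mimics")
lung_std = np.std(clinical.data[(clinical.data > -950) & (clinical.data < -600)])
print(f"  parenchyma HU spread {lung_std:.0f} (texture + noise; phantom is"
      " noise-only)")
print("\nThe two modes share geometry and protocol, so a classifier trained"
      "\non phantom patches can be evaluated on clinical-like patches to"
      "\nstudy the domain gap.")
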