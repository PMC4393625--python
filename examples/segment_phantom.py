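"""Segment a synthetic SEEG implant and score it against ground truth.

Builds a phantom CT with ten straight depth electrodes (8-18 contacts
each, 0.4 x 0.4 x 0.8 mm voxels), runs the trajectory-guided contact
segmentation, and prints the per-electrode contact counts plus the
distance of every recovered centroid from the phantom's ground truth.
"""

import numpy as np

from seegseg import (
    SegmentationConfig,
    make_phantom,
    segment_implant,
    straight_implant_spec,
)

spec = straight_implant_spec(seed=1)
volume, truth = make_phantom(spec)
config = SegmentationConfig(threshold=spec.truth_threshold)

implant = segment_implant(volume, truth.trajectories,
                          models=truth.models, config=config)

print(f"threshold S = {implant.threshold:.0f}")
print("electrode  contacts  mean err (mm)  max err (mm)")
all_errors = []
for elec in implant.electrodes:
    errors = np.linalg.norm(elec.contacts - truth.contacts[elec.label], axis=1)
    all_errors.append(errors)
    print(f"{elec.label:>9}  {elec.n_contacts:>8}  {errors.mean():>13.3f}"
          f"  {errors.max():>12.3f}")
all_errors = np.concatenate(all_errors)
print(f"\n{implant.n_contacts} contacts reconstructed; "
      f"overall mean error {all_errors.mean():.3f} mm "
      f"(sub-voxel: in-plane pitch is 0.4 mm)")
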