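"""Propose a PET ROI by fractional-SUVmax thresholding.

Builds a small synthetic PET volume containing a hot lesion, proposes an
ROI at 40% of the box-local SUVmax, and reports its size.  In clinical
use the proposal seeds an expert-corrected contour; the rest of the
pipeline accepts any externally supplied mask.
"""

import numpy as np

from locrad import ImageVolume, Modality, roi_volume_cm3, suv_threshold_roi

rng = np.random.default_rng(0)

# 3.3 mm isotropic PET grid: background SUV ~1, hot lesion SUV ~8
vox = rng.normal(1.0, 0.1, size=(20, 32, 32)).clip(0.05)
zz, yy, xx = np.ogrid[:20, :32, :32]
lesion = ((zz - 10) ** 2 + (yy - 16) ** 2 + (xx - 16) ** 2) <= 16
vox[lesion] += 7.0
volume = ImageVolume(vox, (3.3, 3.3, 3.3), Modality.PET)

mask = suv_threshold_roi(volume, seed_box=((5, 15), (8, 24), (8, 24)), fraction=0.4)

print(f"max SUV in seed box : {vox[5:15, 8:24, 8:24].max():.2f}")
print(f"ROI voxels          : {mask.n_voxels}")
print(f"ROI volume          : {roi_volume_cm3(mask):.2f} cm^3")
# The ROI keeps voxels >= 40% of the box SUVmax that connect to the
# hottest voxel, so the background (SUV ~1) is excluded and the printed
# volume approximates the true lesion volume (a radius-4-voxel sphere at
# 3.3 mm pitch is ~9.6 cm^3; the proposal recovers ~9.2 cm^3).
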