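"""Generate labelled hip phantoms, one per condition, and summarise them.

The phantom is the package's stand-in for clinical hip CT: a soft-tissue body
on air, a femur (head + neck + shaft) and pelvis (acetabular cup + iliac
slab) with bright cortical shells, Gaussian noise, 12-bit stored intensities.
"""

import numpy as np

from hipseg import PhantomSpec, generate_phantom, CONDITIONS

for condition in CONDITIONS:
    spec = PhantomSpec(condition=condition, seed=7)
    ct, lab = generate_phantom(spec)
    hu = ct.hu()
    femur = lab.labels == 1
    pelvis = lab.labels == 2
    femur_slices = femur.any(axis=(0, 1)).sum()
    print(
        f"{condition:6s}  shape {ct.shape}, spacing {ct.spacing_mm} mm | "
        f"femur {femur.sum():5d} vox in {femur_slices} slices, "
        f"pelvis {pelvis.sum():5d} vox | "
        f"bone HU median {np.median(hu[femur | pelvis]):7.1f}, "
        f"soft-tissue HU median {np.median(hu[(lab.labels == 0) & (hu > -400)]):7.1f}"
    )

# Each line shows how the disease variants reshape the labels: FNF loses neck
# voxels (the fracture gap), ONFH loses superior head voxels (the crater), OA
# gains rim voxels (osteophytes), DDH loses lateral cup voxels and moves the
# head. Bone stays well above the 200 HU threshold; soft tissue well below.
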