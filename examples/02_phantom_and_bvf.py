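"""Phantom generation and bone-volume-fraction round trip.

Generates a synthetic proximal-femur phantom, maps its grayscale volume
back to bone volume fraction with windowed local thresholding, and
compares against the generator's ground truth.  Also measures the
trochanteric soft-tissue thickness from the masks.
"""

import numpy as np

from femrisk import PhantomSpec, compute_bvf, generate_phantom, measure_stt

ph = generate_phantom(PhantomSpec(seed=0))
nx, ny, nz = ph.volume.data.shape
print(f"phantom grid {nx}x{ny}x{nz} at {ph.spec.voxel_dims} mm voxels, "
      f"{int(ph.mask.bone.sum())} bone voxels")

mapped = compute_bvf(ph.volume, ph.mask)
bone = ph.mask.bone
rms = float(np.sqrt(((mapped.bvf - ph.true_bvf.bvf)[bone] ** 2).mean()))
print(f"BVF round trip: RMS error {rms:.4f} (tolerance for a trustworthy "
      "map is ~0.02)")

stt = measure_stt(ph.mask.bone, ph.mask.body, ph.mask.voxel_dims)
print(f"soft-tissue thickness: measured {stt.stt_mm:.1f} mm on coronal "
      f"slice {stt.slice_index} vs configured {ph.stt_true_mm:.1f} mm")
print("\nA small RMS and an STT within one in-plane voxel mean the imaging")
print("stages invert the generator's forward model faithfully.")
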