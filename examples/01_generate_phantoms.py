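"""Generate synthetic prostate-like phantoms and inspect their geometry.

Each phantom is a bright ellipsoid on a darker background with extra
boundary blur on its first/last occupied slices (the apex/base analogue)
and additive noise; the mask is the clean ellipsoid.
"""

import numpy as np

from mcmunet import PhantomSpec, generate_phantom
from mcmunet.phantom import apex_base_gradient_contrast

spec = PhantomSpec(seed=7)
vol, mask = generate_phantom(spec)

print(f"volume shape          : {vol.shape}, spacing {vol.spacing} mm")
print(f"organ voxels          : {int(mask.grid.sum())} "
      f"({100 * mask.grid.mean():.1f}% of the grid)")
occupied = np.flatnonzero(mask.grid.any(axis=(0, 1)))
print(f"organ occupies slices : {occupied[0]}..{occupied[-1]} "
      f"of {vol.shape[2]} axial slices")

apex_base, mid = apex_base_gradient_contrast(vol, mask)
print(f"boundary gradient     : apex/base {apex_base:.3f} vs mid-gland {mid:.3f}")
print("-> the lower apex/base value reflects the stronger boundary blur at the")
print("   organ poles, mimicking where real prostate MRI boundaries are fuzziest.")
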