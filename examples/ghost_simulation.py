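"""Simulate the half-FOV ghost on the gradient flip-angle phantom.

Builds the 256x256 circular phantom whose flip angle runs linearly from
1 to 90 degrees, computes the two steady-state images, interleaves their
k-spaces line by line (even lines strong, odd lines weak), and measures the
ghost that the period-2 modulation aliases half a field of view away.
"""

import numpy as np

from dualtr import (
    DEFAULT_PARAMS,
    assemble_interleaved,
    forward_kspace,
    ghost_ratio_curve,
    make_gradient_flip_map,
    reconstruct,
    simulate_image_pair,
)

fm = make_gradient_flip_map()
pair = simulate_image_pair(fm, DEFAULT_PARAMS)
assembly = assemble_interleaved(forward_kspace(pair.img_strong),
                                forward_kspace(pair.img_weak))
image = reconstruct(assembly.kspace)
curve = ghost_ratio_curve(image, fm, variant="interleave")

print(f"phantom: {fm.n}x{fm.n}, disc radius {fm.radius_px:.1f} px, "
      f"flip {fm.theta_min_deg:.0f}-{fm.theta_max_deg:.0f} deg")
print(f"weak lines in the assembly: {assembly.weak_lines.sum()} of {fm.n}")
for flip in (15, 45, 90):
    print(f"ghost-to-source at {flip:2d} deg: {curve.at_flip(flip):6.2f}%")
print(f"maximum ghost: {curve.value_pct.max():.2f}% "
      f"at {curve.flip_deg[np.argmax(curve.value_pct)]:.0f} deg")
print("\nThe ghost intensity rises with flip angle because the strong/weak")
print("signal gap does; the ghost sits in the half-FOV-shifted copy of the disc.")
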