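"""Rescale the weak k-space lines by the center-line ratio.

The sequence can acquire the central (ky = 0) line once per effective TR;
the ratio of the two center lines estimates how much weaker the weak lines
are overall, and multiplying them by its inverse lifts them to the strong
level.  With inhomogeneous excitation a single global factor matches only
one flip angle — the ghost nulls near the signal-weighted mean flip angle
and grows again below the crossover.
"""

from dualtr import (
    DEFAULT_PARAMS,
    apply_correction,
    assemble_interleaved,
    crossover_flip,
    estimate_correction_factor,
    forward_kspace,
    ghost_ratio_curve,
    make_gradient_flip_map,
    reconstruct,
    signal_ratio_curve,
    simulate_image_pair,
)

fm = make_gradient_flip_map()
pair = simulate_image_pair(fm, DEFAULT_PARAMS)
ks = forward_kspace(pair.img_strong)
kw = forward_kspace(pair.img_weak)

factor = estimate_correction_factor(ks, kw)
print(f"center-line correction factor (weak/strong): {factor:.4f}")

uncorrected = reconstruct(assemble_interleaved(ks, kw).kspace)
corrected = reconstruct(apply_correction(assemble_interleaved(ks, kw), factor).kspace)

g_un = ghost_ratio_curve(uncorrected, fm, variant="interleave")
g_co = ghost_ratio_curve(corrected, fm, variant="corrected")
gain = signal_ratio_curve(corrected, uncorrected, fm)
low = gain.flip_deg < 10.0

print(f"ghost minimum after correction: {g_co.value_pct.min():.3f}% "
      f"at {g_co.argmin_flip():.1f} deg")
print(f"crossover (correction worse below): {crossover_flip(g_co, g_un):.1f} deg")
print(f"phantom signal gain below 10 deg: "
      f"{(gain.value_pct[low] - 100).mean():.2f}%")
print("\nThe minimum sits near the signal-weighted mean flip angle (~40 deg);")
print("at lower angles the over-boosted weak lines create their own ghost.")
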