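"""Recover the flip-angle map from the two signals (AFI-style B1 mapping).

The same signal difference that causes the ghost carries information: if
the strong and weak lines are reconstructed separately, the ratio of the
two images inverts to the local flip angle via the actual-flip-angle-
imaging (AFI) arccos formula.  On the noise-free phantom the map comes back
to a small fraction of a degree.
"""

import numpy as np

from dualtr import (
    DEFAULT_PARAMS,
    estimate_flip_map,
    make_gradient_flip_map,
    simulate_image_pair,
)

fm = make_gradient_flip_map()
pair = simulate_image_pair(fm, DEFAULT_PARAMS)
estimate = estimate_flip_map(pair, DEFAULT_PARAMS, mask=fm.mask)

err = np.abs(estimate - fm.grid)
sel = fm.mask & (fm.grid >= 10.0)
print(f"flip-angle recovery over the disc (true flip >= 10 deg):")
print(f"  max error  {err[sel].max():.4f} deg")
print(f"  mean error {err[sel].mean():.4f} deg")
for theta in (15.0, 45.0, 90.0):
    col = np.argmin(np.abs(fm.grid[fm.n // 2] - theta))
    sel_col = fm.mask[:, col]
    print(f"  at {theta:4.0f} deg: estimated "
          f"{estimate[sel_col, col].mean():.2f} deg")
print("\nThe short-TR AFI approximation stays within half a degree; errors")
print("grow toward very small angles where the signal ratio approaches 1.")
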