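"""Tabulate the two alternating steady-state signals across flip angles.

With a saturation block before every second excitation the sequence runs
with two effective TRs (here 4 and 7 ms).  The pulse after the longer
recovery produces more signal; the relative gap between the two signals is
what aliases into the half-FOV ghost, and it grows with the flip angle.
"""

from dualtr import DEFAULT_PARAMS, steady_state_signals

print(f"TR1={DEFAULT_PARAMS.tr1_ms} ms, TR2={DEFAULT_PARAMS.tr2_ms} ms, "
      f"T1={DEFAULT_PARAMS.t1_ms} ms, TE={DEFAULT_PARAMS.te_ms} ms\n")
print("flip    s_strong    s_weak      gap/strong   ghost ratio (S1-S2)/(S1+S2)")
for theta in (5, 15, 30, 45, 60, 75, 90):
    pair = steady_state_signals(float(theta), DEFAULT_PARAMS)
    gap = (pair.s_strong - pair.s_weak) / pair.s_strong
    ghost = (pair.s_strong - pair.s_weak) / (pair.s_strong + pair.s_weak)
    print(f"{theta:3d}deg  {pair.s_strong:.6f}    {pair.s_weak:.6f}    "
          f"{100*gap:6.2f}%      {100*ghost:6.2f}%")

print("\nThe last column is the ghost-to-source intensity a uniform phantom")
print("would show when even/odd k-space lines alternate between the two signals:")
print("negligible below ~15deg, above 27% at 90deg.")
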