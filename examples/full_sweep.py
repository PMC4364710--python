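"""Run the complete variant comparison and write the report files.

One call produces the nine-variant comparison (single-signal references,
interleave with/without correction, adaptation, reordering in three
flavors, zero filling), the per-flip-angle curves as CSV, and the scalar
summaries as JSON.
"""

from dualtr import SweepConfig, run_standard_sweep, write_report

result = run_standard_sweep(SweepConfig())
for path in write_report(result, "sweep_out", write_images=True):
    print("wrote", path)

s = result.summary
print("\nkey summaries:")
print(f"  correction factor              {s['correction_factor']:.4f}")
print(f"  adapted theta1 at 70 deg       {s['adapted_theta1_deg']:.2f} deg")
print(f"  max ghost, interleave          {s['max_ghost_pct']['interleave']:.2f}%")
print(f"  max ghost, reordered           {s['max_ghost_pct']['reorder']:.3f}%")
print(f"  corrected-ghost minimum at     {s['corrected_ghost_argmin_deg']:.1f} deg")
print(f"  adaptation crossover           {s['crossover_adapted_vs_uncorrected_deg']:.1f} deg")
print(f"  correction crossover           {s['crossover_corrected_vs_uncorrected_deg']:.1f} deg")
print(f"  zero-fill max oscillation      {s['zero_fill_max_oscillation_pct']:.2f}%")
print("\nOnly reordering suppresses the ghost across the whole flip-angle")
print("range; adaptation and correction help only above their crossovers.")
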