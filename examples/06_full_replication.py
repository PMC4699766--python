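"""The whole pipeline in one call: simulate, gate, describe, compare, invert.

Runs a scaled-down version of the full four-dose study (use
``dose_groups=None`` for the full experimental sizes) and prints the
headline numbers of the resulting report.
"""

import rifvar as rv

groups = {0.0: (5000, 3), 0.5: (2500, 3), 1.0: (2500, 3), 2.0: (2500, 3)}
report = rv.run_replication(seed=1, dose_groups=groups)

print("observed (gated) focus counts:")
for dose, s in report["observed_counts"].items():
    print(f"  {dose:>3} Gy: n {s['n']:>5}, mean {s['mean']:6.2f}, "
          f"SD {s['sd']:5.2f}, SD_rel {s['sd_rel']:.3f}")

print(f"\nSD_rel fold change per dose doubling: "
      + ", ".join(f"{r:.3f}" for r in report["fold_change_sd_rel"])
      + "  (energy model predicts 0.707)")

fit = report["dose_response"]
print(f"dose response: {fit['slope']:.2f} foci/Gy "
      f"(+ intercept {fit['intercept']:.2f}), r^2 {fit['r_squared']:.4f}")

print("\nQ-Q slopes at the matched 1.6 um^3 volume:")
for dose, q in report["qq"]["1.6"].items():
    print(f"  {dose:>3} Gy: slope {q['slope']:.2f}, r^2 {q['r_squared']:.4f}")

inv = report["inverted_volume_um3"]
print("\ninverted target volume per dose: "
      + ", ".join(f"{d} Gy -> {v:.2f}" for d, v in inv.items()))
print(f"mean: {report['inverted_volume_mean_um3']:.2f} um^3 (target: 1.6 um^3)")
print("\nThe inversion recovers, from synthetic counts alone, the sub-nuclear"
      "\ntarget volume whose energy spread explains the count variability.")
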