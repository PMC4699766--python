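"""Simulate an imaging-cytometry population and gate it down to G0/G1.

Generates a 1 Gy dose group of per-nucleus records (focus counts plus DAPI /
gamma-H2AX / KI67 intensities and morphology), derives scatter-plot gates
from the data, and compares the selection against the generator's truth
labels.
"""

import rifvar as rv

study = rv.simulate_study(dose_groups={1.0: (6000, 3)}, seed=42)
morpho, intensity = rv.auto_gate_thresholds(study)
result = rv.apply_gate(study, morpho, intensity)

print(f"simulated nuclei:      {result.n_input}")
print(f"selected (G0/G1 gate): {result.n_selected}")
print(f"rejected morphology:   {result.n_rejected_morphology}"
      f"  intensity: {result.n_rejected_intensity}  both: {result.n_rejected_both}")

sel = study.loc[result.selected]
truth = study[(study.phase_true == "G0G1") & (~study.is_cluster)]
recovered = len(sel[(sel.phase_true == "G0G1") & (~sel.is_cluster)]) / len(truth)
admitted = len(sel[sel.phase_true != "G0G1"]) / max(len(study[study.phase_true != "G0G1"]), 1)
print(f"\ntrue G0/G1 singlets recovered: {recovered:.1%}")
print(f"cycling nuclei admitted:       {admitted:.2%}")

stats = rv.describe_counts(sel["rif_count"])
print(f"\ngated focus counts: mean {stats.mean:.2f}, SD {stats.sd:.2f}, "
      f"SD_rel {stats.sd_rel:.3f}")
print("Holding DNA content constant (2N, non-cycling) is what makes this"
      "\nper-nucleus count spread interpretable as damage variability.")
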