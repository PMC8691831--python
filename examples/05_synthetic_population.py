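"""Generate a synthetic posterior-blastomere population and analyse it.

Samples 60 B3-like cells (sagittal view) with the default stage program
(metaphase tilt 9.6 deg, anaphase tilt 21.3 deg, slight vegetal-ward
anaphase off-centring), re-measures every cell through the spindle
metrics, and reports stage means, box summaries and the paired Wilcoxon
test of the anaphase division prediction against 0.5.
"""

from cleavekit import (
    GeneratorConfig,
    box_summary,
    generate_population,
    ground_truth_table,
    wilcoxon_paired,
)

cfg = GeneratorConfig.defaults("B3_sagittal", n_cells=60, seed=1)
table = ground_truth_table(generate_population(cfg))

for stage in ("metaphase", "anaphase"):
    sub = table[table["stage"] == stage]
    print(f"{stage:9s}: tilt {sub['measured_tilt'].mean():5.2f} deg "
          f"(configured {cfg.tilt_mean[stage]:5.2f}), "
          f"centering {sub['measured_centering'].mean():.3f}, "
          f"relative animal area {sub['relative_animal'].mean():.3f}")

ana = table[table["stage"] == "anaphase"]["relative_animal"]
res = wilcoxon_paired(ana, 0.5)
s = box_summary(ana)
print()
print(f"anaphase relative animal area: median {s.median:.3f} "
      f"[q1 {s.q1:.3f}, q3 {s.q3:.3f}], range [{s.min:.3f}, {s.max:.3f}]")
print(f"Wilcoxon vs 0.5 (equal division): W={res.statistic:.0f}, "
      f"p={res.p_value:.2e}, n={res.n_effective}, method={res.method}")
print()
print("A mean below 0.5 with a small p value reproduces the unequal")
print("cleavage of the posterior lineage: spindle tilt in an anisotropic")
print("cell predicts a larger vegetal daughter.")
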