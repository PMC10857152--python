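"""Full cohort analysis: 19 synthetic phantoms, study-style summary tables.

Simulates the 19-case cohort (8 supine / 6 prone / 5 lateral, 21 lesions),
evaluates every case, and prints the grouped landmark and lesion tables with
Kruskal–Wallis omnibus p-values, plus the DSC-volume correlation from a
controlled equal-misregistration simulation.
"""

from scipy.stats import spearmanr

from navphantom import RunConfig, dsc_volume_simulation, run_pipeline

config = RunConfig(seed=1, outdir="scratch/example_cohort")
report = run_pipeline(config)

print("landmark metrics by surgical position (mm; FN unitless):")
print(report["landmark_table"].round(2).to_string(index=False))
for name, comp in report["landmark_tests"].items():
    print(f"  {name}: Kruskal-Wallis p = {comp.omnibus_p:.3f} "
          f"(post hoc alpha = {comp.alpha_adjusted:.3f})")

print("\nlesion metrics by surgical position:")
print(report["lesion_table"].round(2).to_string(index=False))

df = dsc_volume_simulation(n_lesions=21, translation_mm=3.0, seed=1)
rho, p = spearmanr(df["volume_cm3"], df["dsc"])
print(f"\ncontrolled 21-lesion simulation (fixed 3 mm misregistration):")
print(f"  Spearman rho(DSC, volume) = {rho:.3f} (p = {p:.2g})")
print("  larger lesions lose a smaller fraction of overlap at a fixed")
print("  boundary displacement, hence the positive volume-DSC association.")
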