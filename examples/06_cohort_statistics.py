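"""Cross-sectional cohort run: stage correlations and group comparisons.

Generates a synthetic cohort (eyes nested in patients across the pooled
severity groups), runs every eye through segmentation and region
decomposition, then produces the two report tables: Spearman correlations
of each parameter with the ordinal stage, and pooled-group means with a
GEE Wald test that adjusts for two eyes of the same patient.
"""

from izmap.pipeline import RunConfig, run_cross_sectional

records, tables = run_cross_sectional(RunConfig(seed=0, n_per_group=6))

print(f"{len(records)} eyes analysed\n")
print("Spearman correlation with severity stage:")
print(tables["correlations"].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nGroup means with GEE Wald p (eyes clustered in patients):")
cols = ["parameter", "early_mean", "moderate_mean", "advanced_mean", "gee_p"]
print(tables["by_group"][cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# Telangiectasia and EZ-loss areas rise steeply with stage while the
# overlap with attenuation-only falls: disruption under the vascular
# lesion shifts to the more severe classes as disease advances.
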