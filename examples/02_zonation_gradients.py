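"""Continuous protein-gradient mapping with the random-intercept mixed model.

Simulates a 14-patient cohort (44 cells each, half the proteins zonated,
MNAR dropout), runs QC filters and the per-protein fits
y_ij = beta0 + beta1 * S_ij + u_i + eps_ij, and reports the zonation calls.
The zonation coefficient beta1 is the expression change per unit of the
spatial ratio S: negative = enriched at the central vein, positive = portal.
"""

from zonemap import PipelineConfig, ProteomeSpec, generate_proteome, run_zonation

spec = ProteomeSpec(n_patients=14, cells_per_patient=44, n_proteins=200,
                    frac_zonated=0.5, seed=0)
matrix, truth = generate_proteome(spec)
print(f"cohort: {matrix.values.shape[0]} proteins x {matrix.values.shape[1]} cells, "
      f"{(matrix.values.isna().mean().mean()):.0%} entries missing (MNAR dropout)")

result = run_zonation(matrix, PipelineConfig())
fits = result["fits"]

print(f"proteins passing 70% completeness: {len(fits)}")
print(f"significantly zonated (Q < 0.05): {int(fits['significant'].sum())} "
      f"({fits['significant'].mean():.0%})")
print(f"strongly zonated (|beta1| > 1 and Q < 0.05): {int(fits['strong'].sum())} "
      f"({int((fits['strong'] & (fits['beta1'] < 0)).sum())} central, "
      f"{int((fits['strong'] & (fits['beta1'] > 0)).sum())} portal)")

top = fits[fits["converged"]].sort_values("q").head(5)
cols = ["beta1", "se_beta1", "sigma_u2", "z", "q", "direction"]
print(f"\nmost significantly zonated proteins:\n{top[cols].round(3)}")

comp = result["comparison"]
print(f"\ncontinuous vs 20-bin ANOVA: Spearman rho = {comp['spearman_rho']:.2f}, "
      f"{comp['significant_both']} proteins significant in both, "
      f"{comp['significant_either']} in either")
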