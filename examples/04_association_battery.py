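"""Genotype-concentration association battery on a synthetic cohort.

Runs the indicator-OLS contrasts (EM/EM reference, Bonferroni 0.05/72) and
Spearman/AS 89 correlations for the (Z)-endoxifen outcome and its metabolic
ratio, and prints the per-variant Hardy-Weinberg checks.
"""

from tamoxmr import GeneratorConfig, generate_cohort, run_pipeline

cohort = generate_cohort(GeneratorConfig(seed=2015))
res = run_pipeline(cohort.genotypes, cohort.panels)

ols = res.association.ols["z_endoxifen"]
print(f"(Z)-endoxifen, EM/EM reference mean {ols.reference_mean:.2f} ng/ml")
print(ols.contrasts.round(4).to_string(index=False))
print()
for outcome in ("z_endoxifen", "mr_z_endoxifen"):
    sp = res.association.spearman[outcome]
    print(
        f"{outcome:16s} Spearman r = {sp.r:+.3f}, r2 = {sp.r_squared:.2f}, "
        f"p = {sp.p_value:.2e} ({sp.method.value})"
    )
print()
print(res.hwe_table.round(3).to_string(index=False))
print()
print(
    "Negative significant contrasts for the null-allele groups show reduced\n"
    "(Z)-endoxifen production; the metabolic ratio explains more of the\n"
    "genotype signal than the absolute concentration because it cancels\n"
    "between-patient exposure differences."
)
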