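"""Generate a synthetic cultivar cohort and look at what was planted.

The cohort mimics the screening population: 42 cultivars, a 117-member
transcription-factor family with one planted regulator, 16 pathway anchor
genes, 400 background transcripts, 14 ginsenoside monomers + TOTAL, and
biallelic SNPs including one causal in-ORF SNP on the regulator.
"""

from triadscreen import CohortConfig, generate_cohort, spearman_test

cfg = CohortConfig(seed=7)
expr, traits, geno, truth = generate_cohort(cfg)

print(f"expression matrix: {expr.shape[0]} transcripts x {expr.shape[1]} samples")
print(f"trait table:       {traits.shape[0]} samples x {traits.shape[1]} traits")
print(f"genotype table:    {geno.calls.shape[0]} SNPs")
print(f"planted regulator: {truth.regulator_ids[0]}, causal SNP {truth.causal_snp_ids[0]}")

rho, p, n = spearman_test(expr.loc[truth.regulator_ids[0]], traits["TOTAL"])
print(f"regulator vs TOTAL ginsenoside: Spearman rho = {rho:.3f} (p = {p:.2e}, n = {n})")
print("-> the planted expression-trait coupling the screen is meant to find")
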