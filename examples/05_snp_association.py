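"""Step 2.3: SNP-trait association with t-test / ANOVA + Fisher LSD.

Each SNP's genotype classes are compared per trait; a SNP passes at the
strict 1e-3 threshold (applied to the LSD pairwise contrasts when there are
three classes), and a transcript qualifies when a passing SNP lies in an
open reading frame.  The allele effect is reported as a percentage of the
lower group's mean content.
"""

from triadscreen import CohortConfig, generate_cohort, snp_screen

cfg = CohortConfig(seed=7)
_, traits, geno, truth = generate_cohort(cfg)

results, qualifying = snp_screen(geno, traits)
passing = [r for r in results if r.passes and r.in_orf]
print(f"{len(results)} SNP x trait tests; {len(passing)} strict in-ORF passes; "
      f"{len(qualifying)} qualifying transcripts")

causal = next(r for r in results
              if r.snp_id == truth.causal_snp_ids[0] and r.trait == "Rb1")
print(f"planted SNP {causal.snp_id} on {causal.transcript} vs {causal.trait}: "
      f"{causal.test}, p = {causal.p:.2e}, effect = {causal.effect_percent:.0f}% "
      f"(planted: {truth.effects['Rb1']:.0f}%)")
print(f"regulator qualifies: {truth.regulator_ids[0] in qualifying}")
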