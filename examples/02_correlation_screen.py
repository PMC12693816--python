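"""Step 1: expression-trait Spearman screen with significance tiers.

Every family transcript is correlated against every ginsenoside trait; a
transcript is a candidate if any trait reaches p <= 0.05, and candidates
are tiered into highly significant (p <= 0.01) vs significant.
"""

from triadscreen import CohortConfig, correlation_screen, generate_cohort

cfg = CohortConfig(seed=7)
expr, traits, _, truth = generate_cohort(cfg)

res = correlation_screen(expr.loc[cfg.family_ids], traits)
s = res.summary
print(f"candidates: {s['total']} = {s['strict']} highly significant "
      f"+ {s['lenient_only']} significant-only (of {len(cfg.family_ids)} transcripts)")
reg = truth.regulator_ids[0]
print(f"planted regulator {reg} in candidate set: {reg in res.candidates} "
      f"(tier: {res.transcript_tiers[reg]})")
best = res.results.sort_values('p').head(3)
print("top transcript-trait pairs:")
print(best.to_string(index=False))
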