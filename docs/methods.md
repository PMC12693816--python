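# Methods

## The screen

The pipeline treats candidate prioritization as a conjunction of weak,
largely independent tests.  Let X be a transcripts × samples abundance
matrix, Y a samples × traits table of ginsenoside contents (mg/g DW,
monomers plus their sum TOTAL), and G a table of biallelic SNP calls on the
family's transcripts.

**Step 1 (correlation screen).**  For each transcript i and trait j the
two-tailed Spearman correlation is computed on pairwise-complete samples.
A transcript is a candidate when min_j p_ij ≤ 0.05; its tier comes from the
best pair (p ≤ 0.01 = highly significant).  No multiplicity correction is
applied by default — the screen is deliberately a per-test threshold rule,
with Benjamini–Hochberg available behind a flag.  Combining traits by
minimum p is a choice; per-trait results are always retained, so any other
combination can be derived from the output.

**Step 2.1 (co-clustering).**  Panels (a 14-tissue panel and a 4-age
panel) are processed as log2(x+1) followed by per-transcript z-scoring;
zero-variance rows are dropped with a warning.  Agglomerative clustering
uses Euclidean distance and complete linkage, and the tree is cut into
k = 10 clusters (configurable).  A candidate qualifies when its cluster
contains at least one pathway anchor; panels are unioned (qualifying in
either panel suffices).  Judging co-membership after a flat cut, rather
than by subtree distance, is a declared simplification — the underlying
heatmap practice is visual.

**Step 2.2 (network linkage).**  Over candidates plus the 16 pathway
anchors, an undirected edge joins every pair with two-tailed Spearman
p ≤ 10⁻³.  Isolated nodes are excluded from node counts by default (a
gene that joins no edge does not "form" a network), switchable by flag.
Compactness is operationalized as the raw edge count with edge density
E/C(V,2) reported alongside.  The null draws n = 38 genes (parameter)
uniformly without replacement from the background transcriptome, R = 20
times, builds the same network per draw, and reports the one-sided
empirical p = (1 + #{null edges ≥ observed})/(R + 1) together with a z
score from the null mean/SD.  The add-one convention bounds p in
[1/(R+1), 1] and avoids zero p at small R.

With R = 20 and a strict edge threshold the null statistic is heavily tied
at zero edges, so under a true null the empirical p is conservative
(stochastically larger than uniform) rather than uniform; at looser
thresholds (e.g. 0.05) the edge counts are effectively continuous and the
p is approximately uniform.  The test suite checks exactly these two
properties at their respective thresholds.

**Step 2.3 (SNP association).**  Genotype classes are used as called
(ref-hom / het / alt-hom); optional dominant/recessive collapsing exists
because field practice varies.  Classes smaller than min_group_size = 3
are dropped; SNPs left with fewer than two classes are skipped as
monomorphic.  Two classes are compared with a pooled (Student) two-tailed
t-test — the classical output of mainstream statistics packages — with
Welch behind a flag.  Three classes use one-way ANOVA followed by Fisher's
LSD: unadjusted pairwise t-tests on the pooled within-group mean square.
The strict threshold (α = 10⁻³) is applied to the pairwise group
differences under omnibus protection (ANOVA p ≤ 0.05), since the
homozygote-vs-homozygote contrast is the scientifically relevant one and
an omnibus F dilutes it when the minor homozygote class is small.  The
allele effect is (mean_high − mean_low)/mean_low × 100 %, with the higher
group decided per SNP × trait; it is undefined (flagged) when the lower
mean is not positive.  A transcript qualifies when it carries at least one
passing SNP inside an open reading frame.

**Step 3 (integration).**  Transcript IDs collapse to genes by stripping a
trailing `-NN` isoform suffix; a gene qualifies for a line if any of its
transcripts does.  The final set is the exact triple intersection, with
pairwise intersections and a per-gene flag table retained so every
membership can be replayed from the stored upstream outputs.  A "combined
p ≤ 10⁻⁹" for triple-supported genes would be the product of the three
nominal thresholds; it is rhetoric about the conjunction, not a computed
statistic, and no meta-analytic p-value combination is performed.

## Spearman machinery

ρ is the Pearson correlation of average ranks.  P-values come from either
(a) exact enumeration of all n! orderings of the observed y ranks (tie
pattern preserved), two-tailed by counting |ρ_perm| ≥ |ρ_obs|, or (b) the
classical t approximation t = ρ√((n−2)/(1−ρ²)) on n−2 df.  `auto` uses
exact for n ≤ 8 and t above, matching what SPSS-class software reports at
cohort sizes.  At |ρ| = 1 the t statistic diverges and the exact limit
2/n! is reported instead.  The exact path doubles as the oracle surface:
the suite checks it against an independently written full enumeration for
n ≤ 7 and measures the t-approximation's deviation at n = 8.  Note that
the ≥-counting convention makes the exact p a step function that includes
the whole probability atom at the observed ρ; near ρ = 0 (p near 1) this
inflates the exact p relative to the continuous t approximation by up to
0.024 at n = 8 — a discreteness artifact, not an error in either path.

## ΔΔCt

ΔCt = Ct_target − Ct_reference per replicate; condition means of ΔCt are
taken first, ΔΔCt = mean ΔCt(condition) − mean ΔCt(calibrator), fold =
2^−ΔΔCt (Livak).  The calibrator's fold is exactly 1; folds are invariant
to adding a constant to both channels.  A per-replicate mode (fold per
replicate, then mean ± SD) is available; the two orderings agree only when
replicate ΔCt values are identical, and the condition-mean convention is
the package contract.  Fold–content correlation pairs condition-mean fold
with condition-level content (n = number of timepoints); no
amplification-efficiency correction is attempted.

## The synthetic cohort

A per-sample latent pathway activity f ~ N(0,1) couples everything that
should co-vary.  Expression is log-normal: log2 x = a + b·f + ε with
ε ~ N(0, 1); pathway anchors and planted regulators carry the loading b,
background transcripts are independent.  Traits are
y_j = μ_j(1 + d·f + η), η ~ N(0, cv²), truncated at zero, with TOTAL the
exact row sum of the monomers.  Defaults are the screen's study
conditions: 42 samples, 117 family transcripts (1 planted regulator), 16
pathway anchors, 400 background transcripts, 14 monomers + TOTAL, 367
background SNPs at allele frequency 0.35, one causal in-ORF SNP per
regulator shifting its target trait by 30 % of the lower homozygote
group's mean (additive, half per allele).

Calibration of the loadings is analytic.  For a Spearman target s the
corresponding Pearson correlation is obtained by inverting Moran's
finite-n expectation of the sample Spearman under a bivariate normal —
not the asymptotic 2·sin(πs/6) relation — so that the *measured* Spearman
at the cohort's n has expectation ≈ s.  That correlation is split evenly
between the expression side and the trait side (each contributes √r of
correlation with f), and the trait loading additionally accounts for the
variance injected by the planted allele shift.  Monomer noise scales with
each monomer's baseline (constant CV), because chromatographic
quantification error is proportional to content and a percentage allele
effect should be equally detectable whatever baseline was drawn for the
target trait.  The default trait noise is 0.35 mg/g at the 5 mg/g
reference content (7 % CV), an HPLC-like precision chosen so the planted
positive control has the operating characteristics a recovery fixture
needs; the latent factor, not measurement noise, carries the biological
variation between cultivars.

Tissue/age panels plant a shared profile template: pathway anchors load on
it fully, planted regulators with weight √rho_target (zero when no signal
is planted), and everything else is independent with matched total
variance so clustering sees shape rather than spread.  The MeJA time
course shares a monotone latent trend between target-gene Ct (amplitude 3
cycles over 0–120 h) and contents (2 mg/g swing), with small replicate
noise (0.1–0.2).

What the generator does **not** emulate: read-level sequencing noise,
population structure and kinship among cultivars, linkage between SNPs,
trait–trait correlations beyond the single shared factor, and
heavy-tailed expression outliers.  Passing recovery/calibration tests
therefore shows the pipeline's statistics behave as designed under their
own assumptions, not that the screen is robust to those real-data
complications.

## Numerical and degenerate-input choices

Coordinates are 1-based inclusive everywhere (921 − 479 + 1 = 443).
Correlations use pairwise-complete observations; each SNP test deletes
listwise within its own groups.  Zero rank variance yields NaN ρ with a
flag rather than an exception; zero within-group variance yields t = 0,
p = 1 for equal means and p = 0 otherwise; a degenerate null SD makes the
compactness z undefined while the empirical p is still returned.  Cluster
assignments are deterministic given row order and invariant to sample
column permutation.  All generators run on `numpy` `default_rng` seeded
substreams; a fixed seed gives byte-identical TSV output.

## Problem sizes used in the checks

The calibration checks use 100 replicates of 200 null transcripts × 1
trait × 42 samples (screen) and ~400 null SNPs × 5 traits (strict
threshold); recovery uses 20 independent cohorts at default settings; the
compactness checks use 50–100 cohorts with R = 20 null draws of 38 genes.
These sizes make the binomial error of the measured rates small relative
to the bands being checked.
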