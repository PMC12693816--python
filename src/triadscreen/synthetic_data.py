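"""Synthetic multi-omic cohorts with planted regulators, for screen testing.

The generator emulates the data the screening pipeline expects: a cohort of
42 cultivars with a 117-transcript regulator family, 16 pathway anchor
genes, a background transcriptome, ~15 ginsenoside traits (monomers plus
their TOTAL), biallelic SNPs on transcripts, a 14-tissue expression panel,
and an 8-point elicitor (MeJA) time course.  A per-sample latent pathway
activity ``f`` couples pathway genes, planted regulators and traits; the
latent loadings are calibrated analytically so that the planted
expression--trait Spearman correlation has the requested expectation.

Calibration sketch: on the log2 scale expression and traits are jointly
normal given ``f``.  For a bivariate normal with Pearson correlation r the
population Spearman is (6/pi)*asin(r/2), so a Spearman target s maps to
r = 2*sin(pi*s/6); the loading on each side is then chosen to contribute
sqrt(r) of correlation with the latent factor.  Monotone transforms
(exponentiation, truncation far from the bulk) leave Spearman untouched.

Nothing here simulates reads, alignment or variant calling -- the cohort is
generated at the level of the tables the screen consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "GenotypeTable",
    "TISSUE_NAMES",
    "AGE_NAMES",
    "MONOMER_NAMES",
    "PATHWAY_GENE_NAMES",
    "generate_cohort",
    "generate_tissue_panel",
    "generate_meja_timecourse",
    "engineered_screen_fixture",
]

TISSUE_NAMES = [
    "fiber_root", "leg_root", "main_root_epidermis", "main_root_cortex",
    "rhizome", "arm_root", "stem", "leaf_peduncle", "leaflet_pedicel",
    "leaf_blade", "fruit_peduncle", "fruit_pedicel", "fruit_flesh", "seed",
]

AGE_NAMES = ["year_5", "year_12", "year_18", "year_25"]

MONOMER_NAMES = [
    "Rb1", "Rb2", "Rb3", "Rc", "Rd", "Re", "Rf",
    "Rg1", "Rg2", "Rg3", "Rh1", "Rh2", "F1", "F2",
]

PATHWAY_GENE_NAMES = [
    "PgFPS_22", "PgSS_1", "PgSE2_1", "PgSE2_4", "PgbAS_1", "PgbAS_6",
    "PgDS_1", "PgDS_3", "PgCYP716A53v2_1", "PgCYP716A52v2_3",
    "PgCYP716A47_1", "PgCAS_11", "PgCAS_21", "PgCAS_22", "PgCAS_23",
    "PgUGT71A27_2",
]

MEJA_TIMEPOINTS_H = (0, 6, 12, 24, 48, 72, 96, 120)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the screened population: 42 cultivars, a 117-member
    regulator family with one planted true regulator, 16 pathway anchors,
    14 ginsenoside monomers plus TOTAL, and a planted in-ORF SNP shifting
    its target trait by 30% of the lower genotype group's mean.
    """

    n_samples: int = 42
    n_family: int = 117
    n_pathway: int = 16
    n_background: int = 400
    n_traits: int = 15            # last column is TOTAL
    regulator_ids: tuple[str, ...] | None = None   # default: first family transcript
    rho_target: float = 0.7       # planted regulator-vs-TOTAL Spearman
    snp_effect_pct: float = 30.0  # planted allele effect, % of lower-group mean
    noise_sd: float = 0.35        # trait noise in mg/g at the 5 mg/g reference content (7% CV,
                                  # HPLC-like); each monomer's noise scales with its baseline
    expr_noise_sd: float = 1.0    # log2-scale expression noise
    allele_freq: float = 0.35     # keeps all genotype groups populated at n=42
    n_snps: int = 367             # family-wide SNP count
    orf_fraction: float = 0.6     # share of background SNPs flagged in-ORF
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 8:
            raise ValueError("n_samples must be >= 8")
        for name in ("n_family", "n_pathway", "n_background", "n_traits", "n_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.rho_target <= 1.0:
            raise ValueError("rho_target must lie in [0, 1]")
        if self.noise_sd <= 0 or self.expr_noise_sd <= 0:
            raise ValueError("noise SDs must be positive")
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError("allele_freq must lie in (0, 1)")
        if self.n_traits < 2:
            raise ValueError("need at least one monomer plus TOTAL")

    # -- derived naming -----------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [f"CV{i:02d}" for i in range(1, self.n_samples + 1)]

    @property
    def family_ids(self) -> list[str]:
        return [f"HDZ{i:03d}" for i in range(1, self.n_family + 1)]

    @property
    def pathway_ids(self) -> list[str]:
        if self.n_pathway <= len(PATHWAY_GENE_NAMES):
            return PATHWAY_GENE_NAMES[: self.n_pathway]
        extra = [f"PW{i:02d}" for i in range(len(PATHWAY_GENE_NAMES) + 1, self.n_pathway + 1)]
        return PATHWAY_GENE_NAMES + extra

    @property
    def background_ids(self) -> list[str]:
        return [f"BG{i:04d}" for i in range(1, self.n_background + 1)]

    @property
    def trait_names(self) -> list[str]:
        m = self.n_traits - 1
        names = MONOMER_NAMES[:m]
        if m > len(MONOMER_NAMES):
            names = names + [f"M{i:02d}" for i in range(len(MONOMER_NAMES) + 1, m + 1)]
        return names + ["TOTAL"]

    @property
    def regulators(self) -> tuple[str, ...]:
        if self.regulator_ids is not None:
            return tuple(self.regulator_ids)
        return (self.family_ids[0],)


@dataclass
class GenotypeTable:
    """SNP metadata plus per-sample alt-allele dosages (0/1/2)."""

    snps: pd.DataFrame   # index snp_id; columns transcript, position, ref, alt, in_orf
    calls: pd.DataFrame  # snp_id x sample dosage matrix


@dataclass
class GroundTruth:
    """Record of everything planted, for recovery and calibration tests."""

    regulator_ids: tuple[str, ...]
    causal_snp_ids: tuple[str, ...]
    effects: dict[str, float]      # trait -> planted effect size in %
    latent: pd.Series              # per-sample pathway activity f

    def as_dict(self) -> dict:
        return {
            "regulator_ids": list(self.regulator_ids),
            "causal_snp_ids": list(self.causal_snp_ids),
            "effects": self.effects,
            "latent": {k: float(v) for k, v in self.latent.items()},
        }


def _expected_sample_spearman(rho: float, n: int) -> float:
    """Finite-n expectation of the sample Spearman under a bivariate normal
    with Pearson correlation ``rho`` (Moran's formula)."""
    return (6.0 / (math.pi * (n + 1))) * ((n - 2) * math.asin(rho / 2.0) + math.asin(rho))


def _pearson_from_spearman(s: float, n: int) -> float:
    """Pearson correlation whose expected sample Spearman at size n is ``s``.

    Inverts Moran's expectation by bisection, so the planted correlation is
    calibrated against what a cohort of this size actually measures rather
    than the population (n -> inf) value.
    """
    if s <= 0.0:
        return 0.0
    lo, hi = 0.0, 0.99999
    if _expected_sample_spearman(hi, n) <= s:
        return 0.999
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _expected_sample_spearman(mid, n) < s:
            lo = mid
        else:
            hi = mid
    return min(0.5 * (lo + hi), 0.999)


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, GenotypeTable, GroundTruth]:
    """Expression matrix, trait table, genotype table and ground truth.

    Expression is log-normal (normal on log2, exponentiated); traits are
    baseline + latent loading + planted allele shift + noise, truncated at
    zero; TOTAL is the exact row sum of the monomer columns.
    """
    rng = _rng(config, 0)
    n, m = config.n_samples, config.n_traits - 1
    samples = config.sample_ids
    regs = config.regulators
    family = config.family_ids
    unknown = [r for r in regs if r not in family]
    if unknown:
        raise ValueError(f"regulator_ids not in family transcripts: {unknown}")

    f = rng.standard_normal(n)                      # latent pathway activity
    r_pearson = _pearson_from_spearman(config.rho_target, n)
    side = math.sqrt(r_pearson)                     # per-side correlation with f

    # expression loading: corr(x, f) = b / sqrt(b^2 + sd^2) = side
    b = 0.0 if side == 0 else config.expr_noise_sd * side / math.sqrt(1.0 - side ** 2)

    all_ids = family + config.pathway_ids + config.background_ids
    loaded = set(regs) | set(config.pathway_ids)
    log2x = np.empty((len(all_ids), n))
    intercepts = rng.uniform(3.0, 8.0, size=len(all_ids))
    for i, gene in enumerate(all_ids):
        eps = rng.standard_normal(n) * config.expr_noise_sd
        load = b if gene in loaded else 0.0
        log2x[i] = intercepts[i] + load * f + eps
    expr = pd.DataFrame(np.exp2(log2x), index=all_ids, columns=samples)

    # genotypes: background SNPs across the family, one causal SNP per regulator
    geno = _generate_genotypes(config, rng)

    # traits: monomers share the latent factor; the causal allele shifts the
    # first monomer by snp_effect_pct% of its baseline between hom groups.
    # Both the noise and the latent loading of a monomer scale with its
    # baseline (constant coefficient of variation), so the planted percent
    # effect has the same detectability whatever baseline was drawn; the
    # loading coefficient is solved so that corr(TOTAL, f) = side.
    baselines = rng.uniform(2.0, 8.0, size=m)
    target_trait = config.trait_names[0]
    cv = config.noise_sd / 5.0                  # noise_sd is quoted at 5 mg/g
    s1, s2 = float(baselines.sum()), float((baselines ** 2).sum())
    # latent-free variance of TOTAL: monomer noise plus the planted allele
    # shifts (delta per alt allele, dosage ~ Binomial(2, af)); the loading
    # is solved so corr(TOTAL, f) still hits the calibrated per-side value
    delta = baselines[0] * config.snp_effect_pct / 200.0
    var_shift = len(regs) * delta ** 2 * 2.0 * config.allele_freq * (1.0 - config.allele_freq)
    free_var = cv ** 2 * s2 + var_shift
    dcoef = 0.0 if side == 0 else side * math.sqrt(free_var) / (s1 * math.sqrt(1.0 - side ** 2))
    traits = np.empty((n, m))
    for j in range(m):
        traits[:, j] = baselines[j] * (1.0 + dcoef * f + rng.standard_normal(n) * cv)
    effects: dict[str, float] = {}
    causal_ids = []
    for k, reg in enumerate(regs):
        snp_id = f"SNPC{k + 1:02d}"
        causal_ids.append(snp_id)
        dosage = geno.calls.loc[snp_id].to_numpy()
        delta = baselines[0] * config.snp_effect_pct / 200.0   # per alt allele
        traits[:, 0] += delta * dosage
    effects[target_trait] = float(config.snp_effect_pct)
    traits = np.clip(traits, 0.0, None)
    trait_df = pd.DataFrame(traits, index=samples, columns=config.trait_names[:-1])
    trait_df["TOTAL"] = trait_df.sum(axis=1)

    truth = GroundTruth(
        regulator_ids=regs,
        causal_snp_ids=tuple(causal_ids),
        effects=effects,
        latent=pd.Series(f, index=samples, name="latent"),
    )
    return expr, trait_df, geno, truth


_BASES = np.array(list("ACGT"))


def _generate_genotypes(config: CohortConfig, rng: np.random.Generator) -> GenotypeTable:
    n = config.n_samples
    regs = config.regulators
    family = config.family_ids
    rows, calls = [], []
    # causal SNPs: one per planted regulator, always in-ORF
    for k, reg in enumerate(regs):
        rows.append((f"SNPC{k + 1:02d}", reg, int(rng.integers(100, 800)), True))
        calls.append(rng.binomial(2, config.allele_freq, size=n))
    hosts = rng.choice(family, size=config.n_snps, replace=True)
    for i, host in enumerate(hosts):
        in_orf = bool(rng.random() < config.orf_fraction)
        rows.append((f"SNP{i + 1:04d}", host, int(rng.integers(1, 1500)), in_orf))
        calls.append(rng.binomial(2, config.allele_freq, size=n))
    ref_idx = rng.integers(0, 4, size=len(rows))
    alt_idx = (ref_idx + rng.integers(1, 4, size=len(rows))) % 4
    snps = pd.DataFrame(
        {
            "transcript": [r[1] for r in rows],
            "position": [r[2] for r in rows],
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "in_orf": [r[3] for r in rows],
        },
        index=pd.Index([r[0] for r in rows], name="snp_id"),
    )
    call_df = pd.DataFrame(
        np.asarray(calls, dtype=float), index=snps.index, columns=config.sample_ids
    )
    return GenotypeTable(snps, call_df)


def generate_tissue_panel(config: CohortConfig, panel: str = "tissues") -> pd.DataFrame:
    """Expression across a 14-tissue (or 4-age) panel.

    Pathway genes follow a shared tissue-profile template; planted
    regulators follow it with a loading proportional to ``rho_target`` so
    that a no-signal configuration plants no co-clustering structure.
    Background and non-regulator family profiles are independent.
    """
    if panel == "tissues":
        columns = TISSUE_NAMES
        stream = 1
    elif panel == "ages":
        columns = AGE_NAMES
        stream = 2
    else:
        raise ValueError(f"panel must be 'tissues' or 'ages', not {panel!r}")
    rng = _rng(config, stream)
    k = len(columns)
    template = rng.standard_normal(k)
    template_scale = 2.0
    profile_sd = 0.5
    # independent rows get matching total variance so clustering sees shape, not spread
    free_sd = math.sqrt(template_scale ** 2 + profile_sd ** 2)

    all_ids = config.family_ids + config.pathway_ids + config.background_ids
    regs = set(config.regulators)
    pathway = set(config.pathway_ids)
    out = np.empty((len(all_ids), k))
    intercepts = rng.uniform(3.0, 8.0, size=len(all_ids))
    for i, gene in enumerate(all_ids):
        if gene in pathway:
            load = template_scale
        elif gene in regs:
            load = template_scale * math.sqrt(config.rho_target)
        else:
            load = 0.0
        resid_sd = math.sqrt(max(free_sd ** 2 - load ** 2, profile_sd ** 2))
        out[i] = intercepts[i] + load * template + rng.standard_normal(k) * resid_sd
    return pd.DataFrame(np.exp2(out), index=all_ids, columns=columns)


def generate_meja_timecourse(
    config: CohortConfig,
    trend_strength: float = 1.0,
    timepoints_h: tuple[int, ...] = MEJA_TIMEPOINTS_H,
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct table and trait table for an elicitor induction time course.

    The target gene's expression and the ginsenoside contents share a
    monotone latent trend of amplitude ``trend_strength`` (0 plants no
    signal).  Returns ``(ct_table, trait_table)``: Ct rows are one per
    timepoint x replicate with target and reference Ct; the trait table has
    one row per timepoint (monomers + TOTAL, mg/g).
    """
    if len(timepoints_h) < 2:
        raise ValueError("need at least 2 timepoints")
    if n_replicates < 1:
        raise ValueError("need at least 1 replicate")
    rng = _rng(config, 3)
    tps = list(timepoints_h)
    u = np.linspace(0.0, 1.0, len(tps))      # monotone latent trend
    ct_amplitude = 3.0                       # cycles of target-gene induction
    content_amplitude = 2.0                  # mg/g swing across the course
    ct_noise, ref_noise, content_noise = 0.15, 0.10, 0.20

    rows = []
    for i, tp in enumerate(tps):
        for r in range(1, n_replicates + 1):
            target = 24.0 - ct_amplitude * trend_strength * u[i] + rng.normal(0, ct_noise)
            reference = 20.0 + rng.normal(0, ref_noise)
            rows.append((f"{tp}h_r{r}", f"{tp}h", r, target, reference))
    ct = pd.DataFrame(
        rows, columns=["sample", "timepoint", "replicate", "target_ct", "reference_ct"]
    )

    m = config.n_traits - 1
    baselines = rng.uniform(2.0, 8.0, size=m)
    contents = np.empty((len(tps), m))
    for j in range(m):
        contents[:, j] = (
            baselines[j]
            + content_amplitude * trend_strength * u
            + rng.normal(0, content_noise, size=len(tps))
        )
    contents = np.clip(contents, 0.0, None)
    trait_df = pd.DataFrame(
        contents, index=[f"{tp}h" for tp in tps], columns=config.trait_names[:-1]
    )
    trait_df["TOTAL"] = trait_df.sum(axis=1)
    return ct, trait_df


# ---------------------------------------------------------------------------
# engineered screen fixture


def engineered_screen_fixture(
    n_strict: int = 11,
    n_lenient: int = 30,
    n_null: int = 76,
    n_samples: int = 42,
    seed: int = 2024,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic expression/trait pair with a prescribed tier partition.

    Builds ``n_strict`` transcripts whose best p lands in (0, 0.01],
    ``n_lenient`` in (0.01, 0.05], and ``n_null`` above 0.05, against a
    single trait, by bisecting the noise blend of each transcript profile.
    Used to exercise the screen's reporting identity total = strict +
    lenient-only on a partition shaped like a real family-wide hit list.
    """
    from scipy import stats as _st

    rng = np.random.default_rng(seed)
    y = np.arange(1, n_samples + 1, dtype=float)
    ystd = (y - y.mean()) / y.std()

    def p_of(x):
        rho = np.corrcoef(_st.rankdata(x), _st.rankdata(y))[0, 1]
        if abs(rho) >= 1:
            return 0.0
        t = rho * math.sqrt((n_samples - 2) / (1 - rho * rho))
        return 2 * _st.t.sf(abs(t), n_samples - 2)

    def engineered_vector(lo, hi):
        for _ in range(50):                      # redraw noise until bisection lands
            z = rng.standard_normal(n_samples)
            a, bnd = 0.0, 1.0
            for _ in range(80):
                w = 0.5 * (a + bnd)
                p = p_of((1 - w) * ystd + w * z)
                if lo <= p <= hi:
                    return (1 - w) * ystd + w * z
                if p < lo:
                    a = w
                else:
                    bnd = w
        raise RuntimeError("could not engineer a transcript in the target p band")

    profiles = []
    for _ in range(n_strict):
        profiles.append(engineered_vector(0.002, 0.008))
    for _ in range(n_lenient):
        profiles.append(engineered_vector(0.02, 0.04))
    while len(profiles) < n_strict + n_lenient + n_null:
        z = rng.standard_normal(n_samples)
        if p_of(z) > 0.10:
            profiles.append(z)

    ids = [f"HDZ{i:03d}" for i in range(1, len(profiles) + 1)]
    expr = pd.DataFrame(np.exp2(np.asarray(profiles) + 6.0), index=ids,
                        columns=[f"CV{i:02d}" for i in range(1, n_samples + 1)])
    traits = pd.DataFrame({"TOTAL": y}, index=expr.columns)
    return expr, traits
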