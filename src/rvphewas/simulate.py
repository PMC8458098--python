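"""Synthetic cohort generation.

Generates every input the collapsing PheWAS consumes - annotated variant
table, coded genotype matrix with per-call read metrics, sample table with
ancestry labels and principal components, long-format diagnosis records on a
three-level hierarchy, quantitative measurements, and pairwise kinship
coefficients - with planted gene-phenotype effects so that every downstream
stage is testable without any external data.

The statistical structure is deliberately the simplest that exercises the
pipeline: genotypes are drawn per variant under Hardy-Weinberg equilibrium
within each ancestry stratum with no linkage disequilibrium (gene collapsing
is LD-free by construction), X-chromosome males are drawn haploid and stored
with the homozygous code, binary case status follows a logistic model whose
intercept is solved numerically to hit a target prevalence, and quantitative
traits are an additive carrier effect plus age/sex covariate effects and
unit-variance noise.  A configurable fraction of sites and calls receives
failing QC metrics.  Every draw flows from a single seeded generator, so one
seed fully determines all outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .collapsing import PTV_TERMS, classify_consequence
from .phenotypes import Hierarchy

__all__ = [
    "MafStratum",
    "PlantedEffect",
    "CohortSimConfig",
    "GenotypeMatrix",
    "Cohort",
    "generate_cohort",
]

_PTV_CHOICES = sorted(PTV_TERMS)
_OTHER_CHOICES = ["intron_variant", "5_prime_UTR_variant", "downstream_gene_variant"]
_ANCESTRY_CENTROIDS = {
    "European": np.array([0.0, 0.0, 0.0, 0.0, 0.0]),
    "African": np.array([8.0, -2.0, 0.5, 0.0, 0.0]),
    "SouthAsian": np.array([-3.0, 6.0, -1.0, 0.5, 0.0]),
    "EastAsian": np.array([-5.0, -6.0, 2.0, -0.5, 0.0]),
}


@dataclass(frozen=True)
class MafStratum:
    """One component of the allele-frequency mixture.  ``low`` / ``high`` of
    ``None`` marks the private stratum (frequencies below one heterozygote
    expected, i.e. uniform on (0, 1/(2N)])."""

    name: str
    weight: float
    low: Optional[float] = None
    high: Optional[float] = None


DEFAULT_MAF_SPECTRUM = (
    MafStratum("private", 0.15),
    MafStratum("rare", 0.20, 1e-4, 1e-3),
    MafStratum("low_frequency", 0.35, 1e-3, 1e-2),
    MafStratum("common", 0.30, 1e-2, 1e-1),
)


@dataclass(frozen=True)
class PlantedEffect:
    """A gene-phenotype effect injected into the simulated phenotypes.

    ``effect_scale`` is a log odds ratio for binary traits and a standardized
    beta for quantitative traits; carriers of ``qualifying_class`` variants in
    ``gene`` (dominant: >= 1 allele; recessive: two alleles) receive it.
    """

    gene: str
    trait: str
    mode: str = "dominant"
    effect_scale: float = 2.0
    qualifying_class: str = "ptv"

    def __post_init__(self):
        if self.mode not in ("dominant", "recessive"):
            raise ValueError("mode must be dominant or recessive")


@dataclass
class CohortSimConfig:
    """Study-design knobs of the synthetic cohort.  Defaults describe a
    desk-scale cohort of 2,000 samples whose collapsing tables remain
    statistically informative; demographics (54% female, ages 40-69) follow a
    typical middle-aged population biobank."""

    n_samples: int = 2000
    n_genes: int = 300
    mean_variants_per_gene: float = 20.0
    maf_spectrum: tuple = DEFAULT_MAF_SPECTRUM
    consequence_class_probs: dict = field(default_factory=lambda: {
        "synonymous": 0.25, "missense": 0.45, "ptv": 0.10, "other": 0.20})
    revel_beta: tuple = (1.2, 1.8)          # Beta(a, b) for missense REVEL
    mtr_normal: tuple = (0.9, 0.25)         # clipped normal for missense MTR
    ref_observed_prob: float = 0.95         # non-private variants seen in reference
    n_binary_traits: int = 50
    n_quant_traits: int = 10
    hierarchy_depth: int = 3
    prevalence_range: tuple = (0.05, 0.15)
    planted_effects: tuple = ()
    n_related_pairs: int = 5
    related_kinship: float = 0.25
    n_background_pairs: int = 5             # sub-threshold kinship pairs
    ancestry_mixture: dict = field(default_factory=lambda: {
        "European": 0.90, "African": 0.05, "SouthAsian": 0.03, "EastAsian": 0.02})
    stratum_freq_scale: dict = field(default_factory=dict)   # ancestry -> MAF multiplier
    stratum_trait_shift: dict = field(default_factory=dict)  # ancestry -> quant-trait mean shift
    sex_ratio: float = 0.54                 # fraction female
    x_gene_fraction: float = 0.05
    qc_corruption_rate: float = 0.02
    missing_call_rate: float = 0.002
    age_range: tuple = (40, 69)
    quant_age_effect: float = 0.1           # per s.d. of age
    quant_sex_effect: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValueError("n_samples and n_genes must be positive")
        if self.n_binary_traits < 0 or self.n_quant_traits < 0:
            raise ValueError("trait counts must be non-negative")
        w = sum(s.weight for s in self.maf_spectrum)
        if abs(w - 1.0) > 1e-12:
            raise ValueError(f"maf_spectrum weights sum to {w}, not 1")
        for s in self.maf_spectrum:
            if s.low is not None:
                if not (0.0 <= s.low <= s.high <= 0.5):
                    raise ValueError(f"MAF range of stratum {s.name} outside [0, 0.5]")
        p = sum(self.consequence_class_probs.values())
        if abs(p - 1.0) > 1e-12:
            raise ValueError(f"consequence_class_probs sum to {p}, not 1")
        if any(v < 0 for v in self.consequence_class_probs.values()):
            raise ValueError("consequence probabilities must be non-negative")
        m = sum(self.ancestry_mixture.values())
        if abs(m - 1.0) > 1e-12:
            raise ValueError(f"ancestry_mixture sums to {m}, not 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if not 0.0 <= self.qc_corruption_rate <= 1.0:
            raise ValueError("qc_corruption_rate must lie in [0, 1]")


@dataclass
class GenotypeMatrix:
    """Coded genotypes: 0 hom-ref, 1 het, 2 hom-alt (hemizygous males on X
    share the hom-alt code), -1 missing.  ``calls`` holds per-call read
    metrics for non-reference calls (sparse; hom-ref calls carry no alternate
    reads and cannot toggle carrier status)."""

    codes: np.ndarray                      # int8, (n_samples, n_variants)
    sample_ids: list
    variant_ids: list
    calls: pd.DataFrame                    # sample_idx, variant_idx, depth, gq, alt_reads, total_reads

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.codes.shape[1]


@dataclass
class Cohort:
    """A complete synthetic input set."""

    samples: pd.DataFrame
    variants: pd.DataFrame
    genotypes: GenotypeMatrix
    phenotype_records: pd.DataFrame        # sample_id, code
    measurements: pd.DataFrame             # sample_id, trait_id, value
    kinship: pd.DataFrame                  # sample_a, sample_b, kinship
    hierarchy: Hierarchy
    config: CohortSimConfig


def _draw_site_metrics(rng, n, corrupt_mask):
    """Passing-range site QC metric draws; a corrupted site gets one randomly
    chosen criterion pushed across its threshold."""
    fs = rng.exponential(5.0, n).clip(max=50.0)
    mq = rng.normal(60.0, 2.0, n).clip(45.0, 70.0)
    qual = rng.lognormal(6.0, 0.5, n).clip(min=50.0)
    rprs = rng.normal(0.0, 0.8, n).clip(-1.8, 4.0)
    mqrs = rng.normal(0.0, 1.5, n).clip(-7.5, 7.5)
    status = np.full(n, "PASS", dtype=object)
    frac10 = rng.uniform(0.0, 0.05, n)
    frac_fail = rng.uniform(0.0, 0.02, n)
    cov10 = rng.uniform(0.8, 1.0, n)
    passfrac = rng.uniform(0.9, 1.0, n)
    zscore = rng.normal(0.0, 0.5, n).clip(-1.5, 3.0)
    site_mq = rng.normal(60.0, 2.0, n).clip(45.0, 70.0)
    fail_kind = rng.integers(0, 7, n)
    for i in np.flatnonzero(corrupt_mask):
        k = fail_kind[i]
        if k == 0:
            fs[i] = 300.0
        elif k == 1:
            mq[i] = 20.0
        elif k == 2:
            qual[i] = 10.0
        elif k == 3:
            rprs[i] = -5.0
        elif k == 4:
            mqrs[i] = -20.0
        elif k == 5:
            status[i] = "LowQual"
        else:
            frac10[i] = 0.2
    return dict(fs=fs, mq=mq, qual=qual, rprs=rprs, mqrs=mqrs,
                caller_status=status, frac_below_10x=frac10,
                frac_fail_call_qc=frac_fail, ref_cov10x_frac=cov10,
                ref_pass_frac=passfrac, ref_cov_zscore=zscore, ref_site_mq=site_mq)


def _build_hierarchy(n_leaves: int, depth: int):
    """Synthetic diagnosis tree: CH## chapters, BL### blocks, LF#### leaves
    (chapter = level-1 node).  ``depth`` other than 3 collapses/expands the
    middle level."""
    n_chapters = max(1, min(22, math.ceil(n_leaves / 4)))
    parent: dict = {}
    leaf_codes, chapters = [], []
    for c in range(n_chapters):
        parent[f"CH{c + 1:02d}"] = ""
        chapters.append(f"CH{c + 1:02d}")
    blocks_per_chapter = 2 if depth >= 3 else 0
    blocks = []
    if blocks_per_chapter:
        for c, ch in enumerate(chapters):
            for b in range(blocks_per_chapter):
                code = f"BL{c * blocks_per_chapter + b + 1:03d}"
                parent[code] = ch
                blocks.append(code)
    attach = blocks if blocks else chapters
    for i in range(n_leaves):
        code = f"LF{i + 1:04d}"
        parent[code] = attach[i % len(attach)]
        leaf_codes.append(code)
    return Hierarchy(parent), leaf_codes


def _planted_carriers(effect, variants, codes, gene_is_x, is_male):
    """Raw carrier indicator for a planted effect: carriers of any variant of
    the effect's consequence class in the gene (dominant: >= 1 allele;
    recessive: hom, two distinct hets, or hemizygous male X)."""
    in_gene = (variants["gene"] == effect.gene).to_numpy()
    classes = variants["consequence"].map(lambda s: classify_consequence(str(s).split(",")))
    mask = in_gene & (classes == effect.qualifying_class).to_numpy()
    if not mask.any():
        return np.zeros(codes.shape[0], dtype=bool)
    g = np.where(codes[:, mask] < 0, 0, codes[:, mask])
    if effect.mode == "dominant":
        return (g > 0).any(axis=1)
    return ((g == 2).any(axis=1)) | ((g == 1).sum(axis=1) >= 2)


def _solve_intercept(prevalence: float, eta_offset: np.ndarray) -> float:
    """Logistic intercept such that mean sigmoid(b0 + offset) hits the target
    prevalence (planted effects shift prevalence otherwise)."""

    def f(b0):
        return np.mean(1.0 / (1.0 + np.exp(-(b0 + eta_offset)))) - prevalence

    return optimize.brentq(f, -30.0, 30.0, xtol=1e-10)


def generate_cohort(config: CohortSimConfig) -> Cohort:
    """Generate a complete synthetic cohort from a validated configuration.

    The same config and seed produce byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    # --- samples -----------------------------------------------------------
    sample_ids = [f"S{i + 1:06d}" for i in range(n)]
    sex = np.where(rng.random(n) < config.sex_ratio, "female", "male")
    is_male = sex == "male"
    age = rng.integers(config.age_range[0], config.age_range[1] + 1, n)
    labels = sorted(config.ancestry_mixture)
    probs = np.array([config.ancestry_mixture[l] for l in labels])
    ancestry = rng.choice(labels, size=n, p=probs)
    pcs = np.empty((n, 5))
    for lab in labels:
        m = ancestry == lab
        centroid = _ANCESTRY_CENTROIDS.get(lab, np.zeros(5))
        pcs[m] = centroid + rng.normal(0.0, 0.15, (int(m.sum()), 5))
    ancestry_prob = rng.uniform(0.991, 1.0, n)
    samples = pd.DataFrame({
        "sample_id": sample_ids, "sex": sex, "age": age,
        "ancestry": ancestry, "ancestry_prob": ancestry_prob,
        **{f"pc{k + 1}": pcs[:, k] for k in range(5)},
    })

    # --- variants ----------------------------------------------------------
    n_x_genes = int(round(config.x_gene_fraction * config.n_genes))
    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    gene_chrom = {g: ("X" if i >= config.n_genes - n_x_genes else str(i % 22 + 1))
                  for i, g in enumerate(gene_ids)}
    counts = np.maximum(1, rng.poisson(config.mean_variants_per_gene, config.n_genes))
    classes = list(config.consequence_class_probs)
    class_p = np.array([config.consequence_class_probs[c] for c in classes])
    strata = list(config.maf_spectrum)
    strat_w = np.array([s.weight for s in strata])
    rows = []
    bases = np.array(list("ACGT"))
    for gi, gene in enumerate(gene_ids):
        chrom = gene_chrom[gene]
        pos0 = 1_000_000 * (gi + 1)
        for vi in range(counts[gi]):
            pos = pos0 + int(rng.integers(1, 50_000))
            ref, alt = rng.choice(bases, 2, replace=False)
            if rng.random() < 0.1:  # indel
                ref = ref + "".join(rng.choice(bases, 2))
            cls = classes[int(rng.choice(len(classes), p=class_p))]
            if cls == "ptv":
                term = _PTV_CHOICES[int(rng.integers(len(_PTV_CHOICES)))]
            elif cls == "missense":
                term = "missense_variant"
            elif cls == "synonymous":
                term = "synonymous_variant"
            else:
                term = _OTHER_CHOICES[int(rng.integers(len(_OTHER_CHOICES)))]
            s = strata[int(rng.choice(len(strata), p=strat_w))]
            if s.low is None:
                freq = rng.uniform(0.0, 1.0) / (2.0 * n)
                freq = max(freq, 1e-6)
            else:
                freq = math.exp(rng.uniform(math.log(max(s.low, 1e-6)), math.log(s.high)))
            private = s.low is None
            if private or rng.random() > config.ref_observed_prob:
                gmaf = math.nan
            else:
                gmaf = min(0.5, freq * math.exp(rng.normal(0.0, 0.2)))
            revel = rng.beta(*config.revel_beta) if cls == "missense" else math.nan
            mtr = (max(0.05, rng.normal(*config.mtr_normal))
                   if cls == "missense" else math.nan)
            rows.append((chrom, pos, ref, alt, gene, term, freq, gmaf, revel, mtr))
    variants = pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref", "alt", "gene", "consequence",
        "true_maf", "gnomad_maf", "revel", "mtr"])
    variants = variants.sort_values(["gene", "pos"], kind="stable").reset_index(drop=True)
    variants["variant_id"] = (variants["chrom"].astype(str) + ":" +
                              variants["pos"].astype(str) + ":" +
                              variants["ref"] + ":" + variants["alt"])
    nv = len(variants)
    corrupt = rng.random(nv) < config.qc_corruption_rate
    for k, v in _draw_site_metrics(rng, nv, corrupt).items():
        variants[k] = v
    variants.loc[variants["gnomad_maf"].isna(),
                 ["ref_pass_frac", "ref_cov_zscore", "ref_site_mq"]] = math.nan

    # --- genotypes ---------------------------------------------------------
    codes = np.zeros((n, nv), dtype=np.int8)
    is_x_variant = (variants["chrom"] == "X").to_numpy()
    scale = {lab: config.stratum_freq_scale.get(lab, 1.0) for lab in labels}
    freq_per_sample = np.empty(n)
    ploidy = np.full(n, 2, dtype=np.int64)
    for j in range(nv):
        f = variants["true_maf"].iat[j]
        for lab in labels:
            m = ancestry == lab
            freq_per_sample[m] = min(0.5, f * scale[lab])
        pl = np.where(is_x_variant[j] & is_male, 1, 2)
        draw = rng.binomial(pl, freq_per_sample)
        codes[:, j] = np.where(pl == 1, draw * 2, draw).astype(np.int8)
    if config.missing_call_rate > 0:
        miss = rng.random((n, nv)) < config.missing_call_rate
        codes[miss] = -1

    # --- per-call read metrics (non-reference calls) -----------------------
    carrier_s, carrier_v = np.nonzero(codes > 0)
    nc = carrier_s.size
    depth = rng.poisson(30.0, nc) + 12
    gq = rng.integers(40, 100, nc)
    het = codes[carrier_s, carrier_v] == 1
    ab = np.where(het, rng.uniform(0.35, 0.65, nc), rng.uniform(0.55, 0.80, nc))
    bad_call = rng.random(nc) < config.qc_corruption_rate
    kind = rng.integers(0, 3, nc)
    depth = np.where(bad_call & (kind == 0), 5, depth)
    gq = np.where(bad_call & (kind == 1), 10, gq)
    ab = np.where(bad_call & (kind == 2), 0.08, ab)
    alt_reads = np.round(depth * ab).astype(np.int64)
    calls = pd.DataFrame({
        "sample_idx": carrier_s, "variant_idx": carrier_v,
        "depth": depth.astype(np.int64), "gq": gq.astype(np.int64),
        "alt_reads": alt_reads, "total_reads": depth.astype(np.int64),
    })
    genotypes = GenotypeMatrix(codes, sample_ids, list(variants["variant_id"]), calls)

    # --- phenotypes --------------------------------------------------------
    hierarchy, leaf_codes = _build_hierarchy(config.n_binary_traits, config.hierarchy_depth)
    effects_by_trait: dict = {}
    for eff in config.planted_effects:
        effects_by_trait.setdefault(eff.trait, []).append(eff)
    known_traits = set(leaf_codes) | {f"QT{j + 1:02d}" for j in range(config.n_quant_traits)}
    for eff in config.planted_effects:
        if eff.gene not in set(gene_ids):
            raise ValueError(f"planted effect references unknown gene {eff.gene}")
        if eff.trait not in known_traits:
            raise ValueError(f"planted effect references unknown trait {eff.trait}")

    gene_is_x = {g: gene_chrom[g] == "X" for g in gene_ids}
    rec_rows = []
    prevalences = rng.uniform(*config.prevalence_range, config.n_binary_traits)
    for t, leaf in enumerate(leaf_codes):
        eta = np.zeros(n)
        for eff in effects_by_trait.get(leaf, []):
            carr = _planted_carriers(eff, variants, codes, gene_is_x, is_male)
            eta += eff.effect_scale * carr
        b0 = _solve_intercept(prevalences[t], eta)
        case = rng.random(n) < 1.0 / (1.0 + np.exp(-(b0 + eta)))
        for i in np.flatnonzero(case):
            rec_rows.append((sample_ids[i], leaf))
    phenotype_records = pd.DataFrame(rec_rows, columns=["sample_id", "code"])

    zage = (age - age.mean()) / max(age.std(ddof=0), 1e-9)
    female = (~is_male).astype(float)
    shift = np.array([config.stratum_trait_shift.get(a, 0.0) for a in ancestry])
    meas_rows = []
    for j in range(config.n_quant_traits):
        trait_id = f"QT{j + 1:02d}"
        y = (config.quant_age_effect * zage + config.quant_sex_effect * female
             + shift + rng.normal(0.0, 1.0, n))
        for eff in effects_by_trait.get(trait_id, []):
            carr = _planted_carriers(eff, variants, codes, gene_is_x, is_male)
            y = y + eff.effect_scale * carr
        meas_rows.append(pd.DataFrame(
            {"sample_id": sample_ids, "trait_id": trait_id, "value": y}))
    measurements = (pd.concat(meas_rows, ignore_index=True) if meas_rows
                    else pd.DataFrame(columns=["sample_id", "trait_id", "value"]))

    # --- kinship -----------------------------------------------------------
    n_pairs = config.n_related_pairs + config.n_background_pairs
    kin_rows = []
    if n_pairs > 0 and n >= 2 * n_pairs:
        chosen = rng.choice(n, size=2 * n_pairs, replace=False)
        for p in range(n_pairs):
            a, b = sorted((sample_ids[chosen[2 * p]], sample_ids[chosen[2 * p + 1]]))
            k = (config.related_kinship if p < config.n_related_pairs
                 else rng.uniform(0.01, 0.05))
            kin_rows.append((a, b, k))
    kinship = pd.DataFrame(kin_rows, columns=["sample_a", "sample_b", "kinship"])

    return Cohort(samples=samples, variants=variants, genotypes=genotypes,
                  phenotype_records=phenotype_records, measurements=measurements,
                  kinship=kinship, hierarchy=hierarchy, config=config)
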