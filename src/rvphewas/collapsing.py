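"""Consequence classification, qualifying-variant models and gene x sample
collapsing matrices.

A *collapsing model* is a named qualifying-variant rule set: inheritance mode,
allele-frequency caps (cohort and external reference), a consequence class,
and optional deleteriousness (REVEL) and regional-constraint (MTR) rules.
The engine ships a default set of twelve models - ten dominant, one recessive
and one synonymous empirical-negative-control model - spanning the usual
design space from private variants up to a 5% frequency cap.  These defaults
are implementation choices; the engine is fully config-driven via YAML.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PTV_TERMS",
    "MISSENSE_TERMS",
    "NONSYNONYMOUS_TERMS",
    "SYNONYMOUS_TERMS",
    "classify_consequence",
    "CollapsingModel",
    "CollapsingMatrix",
    "DEFAULT_MODELS",
    "default_models",
    "load_models",
    "dump_models",
    "cohort_maf",
    "is_qualifying",
    "qualifying_mask",
    "build_dominant_matrix",
    "build_recessive_matrix",
]

# Annotation term sets for each consequence class (SnpEff-style terms).
PTV_TERMS = frozenset({
    "exon_loss_variant", "frameshift_variant", "start_lost", "stop_gained",
    "stop_lost", "splice_acceptor_variant", "splice_donor_variant",
    "gene_fusion", "bidirectional_gene_fusion", "rare_amino_acid_variant",
    "transcript_ablation",
})
MISSENSE_TERMS = frozenset({"missense_variant_splice_region_variant", "missense_variant"})
NONSYNONYMOUS_TERMS = PTV_TERMS | MISSENSE_TERMS | frozenset({
    "conservative_inframe_deletion", "conservative_inframe_insertion",
    "disruptive_inframe_insertion", "disruptive_inframe_deletion",
    "protein_altering_variant",
})
SYNONYMOUS_TERMS = frozenset({"synonymous_variant"})

#: severity precedence used to resolve multi-term annotations
_PRECEDENCE = ("ptv", "missense", "nonsynonymous", "synonymous", "other")


def classify_consequence(terms) -> str:
    """Return the most severe consequence class for an annotation term set.

    Precedence: PTV > missense > other-nonsynonymous > synonymous > other.
    """
    terms = set(terms)
    if not terms:
        raise ValueError("empty annotation term set")
    if terms & PTV_TERMS:
        return "ptv"
    if terms & MISSENSE_TERMS:
        return "missense"
    if terms & NONSYNONYMOUS_TERMS:
        return "nonsynonymous"
    if terms & SYNONYMOUS_TERMS:
        return "synonymous"
    return "other"


_CLASS_MATCH = {
    # model class -> variant classes it admits
    "ptv": {"ptv"},
    "missense": {"missense"},
    "nonsynonymous": {"ptv", "missense", "nonsynonymous"},
    "synonymous": {"synonymous"},
}


@dataclass(frozen=True)
class CollapsingModel:
    """A named qualifying-variant rule set.

    ``min_revel`` and ``mtr_rule`` apply to missense variants only (truncating
    variants qualify on consequence alone).  ``private`` restricts to variants
    carried by at most one sample in the cohort and absent from the external
    reference.  ``mtr_rule`` is either ``{"kind": "threshold", "max_mtr": x}``
    or ``{"kind": "percentile", "max_percentile": q}`` (gene-level percentile
    of MTR among that gene's missense variants).
    """

    name: str
    mode: str                                  # dominant | recessive
    consequence_class: str                     # ptv | missense | nonsynonymous | synonymous
    max_ref_maf: Optional[float] = None
    max_cohort_maf: Optional[float] = None
    private: bool = False
    min_revel: Optional[float] = None
    mtr_rule: Optional[dict] = None
    qc_profile: str = "collapsing"

    def __post_init__(self):
        if self.mode not in ("dominant", "recessive"):
            raise ValueError(f"mode must be dominant or recessive, got {self.mode!r}")
        if self.consequence_class not in _CLASS_MATCH:
            raise ValueError(f"unknown consequence class {self.consequence_class!r}")
        for cap in (self.max_ref_maf, self.max_cohort_maf):
            if cap is not None and not (0.0 <= cap <= 0.05):
                raise ValueError("MAF caps must lie in [0, 0.05]")
        if self.mtr_rule is not None and self.mtr_rule.get("kind") not in ("threshold", "percentile"):
            raise ValueError("mtr_rule kind must be 'threshold' or 'percentile'")


def default_models() -> list[CollapsingModel]:
    """The shipped 12-model set: ten dominant, one recessive, one synonymous
    negative control.  Implementation defaults, config-replaceable."""
    return [
        CollapsingModel("ptv", "dominant", "ptv", max_ref_maf=0.001, max_cohort_maf=0.001),
        CollapsingModel("ptv5pcnt", "dominant", "ptv", max_ref_maf=0.05, max_cohort_maf=0.05),
        CollapsingModel("UR", "dominant", "nonsynonymous", private=True),
        CollapsingModel("URmtr", "dominant", "nonsynonymous", private=True,
                        mtr_rule={"kind": "threshold", "max_mtr": 0.78}),
        CollapsingModel("flexnonsyn", "dominant", "nonsynonymous",
                        max_ref_maf=0.001, max_cohort_maf=0.001),
        CollapsingModel("flexnonsynmtr", "dominant", "nonsynonymous",
                        max_ref_maf=0.001, max_cohort_maf=0.001,
                        mtr_rule={"kind": "threshold", "max_mtr": 0.78}),
        CollapsingModel("flexdmg", "dominant", "nonsynonymous",
                        max_ref_maf=0.001, max_cohort_maf=0.001, min_revel=0.5),
        CollapsingModel("raredmg", "dominant", "missense",
                        max_ref_maf=0.005, max_cohort_maf=0.005, min_revel=0.25),
        CollapsingModel("raredmgmtr", "dominant", "missense",
                        max_ref_maf=0.005, max_cohort_maf=0.005, min_revel=0.25,
                        mtr_rule={"kind": "threshold", "max_mtr": 0.78}),
        CollapsingModel("dmg5pcnt", "dominant", "nonsynonymous",
                        max_ref_maf=0.05, max_cohort_maf=0.05, min_revel=0.5),
        CollapsingModel("rec", "recessive", "nonsynonymous",
                        max_ref_maf=0.01, max_cohort_maf=0.01),
        CollapsingModel("syn", "dominant", "synonymous",
                        max_ref_maf=0.05, max_cohort_maf=0.05),
    ]


DEFAULT_MODELS = default_models()


def load_models(path) -> list[CollapsingModel]:
    """Load a model set from YAML (a list of mappings, one per model)."""
    with open(path) as fh:
        blocks = yaml.safe_load(fh)
    return [CollapsingModel(**b) for b in blocks]


def dump_models(models, path) -> None:
    blocks = []
    for m in models:
        d = {"name": m.name, "mode": m.mode, "consequence_class": m.consequence_class}
        for k in ("max_ref_maf", "max_cohort_maf", "min_revel", "mtr_rule"):
            v = getattr(m, k)
            if v is not None:
                d[k] = v
        if m.private:
            d["private"] = True
        blocks.append(d)
    with open(path, "w") as fh:
        yaml.safe_dump(blocks, fh, sort_keys=False)


# ---------------------------------------------------------------------------


def cohort_maf(genotypes: np.ndarray, is_x: np.ndarray, is_male: np.ndarray):
    """Cohort minor-allele frequency and carrier counts per variant.

    ``genotypes`` is the coded matrix (samples x variants, -1 missing); males
    contribute a single allele on the X chromosome (their hemizygous calls are
    stored with the homozygous code).  Returns ``(maf, n_carriers)`` arrays.
    """
    g = genotypes
    nonmiss = g >= 0
    alt = np.where(nonmiss, g, 0).astype(np.int64)
    ac = alt.sum(axis=0, dtype=np.int64)
    an = 2 * nonmiss.sum(axis=0, dtype=np.int64)
    x_cols = np.flatnonzero(is_x)
    if x_cols.size and is_male.any():
        # male X: one allele, and the stored hemizygous code 2 carries one alt
        gx = g[np.ix_(is_male, x_cols)]
        nm = gx >= 0
        ac[x_cols] -= np.where(nm, gx, 0).sum(axis=0, dtype=np.int64)
        ac[x_cols] += np.where(nm, np.minimum(gx, 1), 0).sum(axis=0, dtype=np.int64)
        an[x_cols] -= nm.sum(axis=0, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(an > 0, ac / np.maximum(an, 1), 0.0)
    maf = np.minimum(af, 1.0 - af)
    carriers = (np.where(nonmiss, g, 0) > 0).sum(axis=0)
    return maf, carriers


def is_qualifying(variant, cohort_maf_value: float, model: CollapsingModel,
                  site_pass: bool, n_carriers: Optional[int] = None):
    """Decide qualifying status of one variant under a model.

    ``variant`` is a mapping/row with ``consequence`` (comma-joined terms),
    ``gnomad_maf`` (NaN when absent from the reference), ``revel`` and ``mtr``.
    Returns ``(qualifies, reasons)``.
    """
    reasons: list[str] = []
    if not site_pass:
        reasons.append("site failed collapsing QC")
    terms = str(variant["consequence"]).split(",")
    vclass = classify_consequence(terms)
    if vclass not in _CLASS_MATCH[model.consequence_class]:
        reasons.append(f"consequence class {vclass} not in model class {model.consequence_class}")
    ref_maf = variant.get("gnomad_maf") if hasattr(variant, "get") else variant["gnomad_maf"]
    ref_missing = pd.isna(ref_maf)
    if model.private:
        if n_carriers is None:
            raise ValueError("private models need the cohort carrier count")
        if n_carriers > 1:
            reasons.append("carried by more than one sample")
        if not ref_missing:
            reasons.append("present in external reference")
    if model.max_cohort_maf is not None and cohort_maf_value > model.max_cohort_maf:
        reasons.append(f"cohort MAF > {model.max_cohort_maf:g}")
    if model.max_ref_maf is not None and not ref_missing and ref_maf > model.max_ref_maf:
        reasons.append(f"reference MAF > {model.max_ref_maf:g}")
    if vclass == "missense":
        if model.min_revel is not None:
            revel = variant["revel"]
            if pd.isna(revel):
                reasons.append("missing score: REVEL")
            elif revel < model.min_revel:
                reasons.append(f"REVEL < {model.min_revel:g}")
        if model.mtr_rule is not None and model.mtr_rule["kind"] == "threshold":
            mtr = variant["mtr"]
            if pd.isna(mtr):
                reasons.append("missing score: MTR")
            elif mtr > model.mtr_rule["max_mtr"]:
                reasons.append(f"MTR > {model.mtr_rule['max_mtr']:g}")
        # percentile-band rules need gene context; handled in qualifying_mask
    return (not reasons), reasons


def qualifying_mask(variants: pd.DataFrame, maf: np.ndarray, n_carriers: np.ndarray,
                    model: CollapsingModel, site_pass: np.ndarray) -> np.ndarray:
    """Vectorised qualifying-variant decision over a variant table."""
    classes = variants["consequence"].map(lambda s: classify_consequence(str(s).split(",")))
    ok = classes.isin(_CLASS_MATCH[model.consequence_class]).to_numpy()
    ok &= np.asarray(site_pass, dtype=bool)
    ref_maf = variants["gnomad_maf"].to_numpy(float)
    ref_missing = np.isnan(ref_maf)
    if model.private:
        ok &= (np.asarray(n_carriers) <= 1) & ref_missing
    if model.max_cohort_maf is not None:
        ok &= np.asarray(maf) <= model.max_cohort_maf
    if model.max_ref_maf is not None:
        ok &= ref_missing | (ref_maf <= model.max_ref_maf)
    is_missense = (classes == "missense").to_numpy()
    if model.min_revel is not None:
        revel = variants["revel"].to_numpy(float)
        ok &= ~is_missense | (~np.isnan(revel) & (revel >= model.min_revel))
    if model.mtr_rule is not None:
        mtr = variants["mtr"].to_numpy(float)
        if model.mtr_rule["kind"] == "threshold":
            ok &= ~is_missense | (~np.isnan(mtr) & (mtr <= model.mtr_rule["max_mtr"]))
        else:  # gene-level percentile band: keep missense in the lowest q% of the gene
            q = model.mtr_rule["max_percentile"] / 100.0
            s = pd.Series(mtr, index=variants.index).where(pd.Series(is_missense, index=variants.index))
            pct = s.groupby(variants["gene"]).rank(pct=True)
            ok &= ~is_missense | (~np.isnan(mtr) & (pct.to_numpy(float) <= q))
    return ok


@dataclass
class CollapsingMatrix:
    """Gene x sample qualifying-carrier indicator with per-cell provenance."""

    genes: list
    sample_ids: list
    indicator: np.ndarray                       # bool, (n_genes, n_samples)
    provenance: dict                            # (gene, sample_id) -> tuple of variant ids
    model: CollapsingModel

    def __post_init__(self):
        self._gene_idx = {g: i for i, g in enumerate(self.genes)}
        self._sample_idx = {s: i for i, s in enumerate(self.sample_ids)}

    def carriers(self, gene) -> set:
        i = self._gene_idx[gene]
        row = self.indicator[i]
        return {self.sample_ids[j] for j in np.flatnonzero(row)}

    def carrier_counts(self) -> pd.Series:
        return pd.Series(self.indicator.sum(axis=1), index=self.genes, name="n_carriers")


def _provenance(carrier_cells, genes, sample_ids, per_variant_carrier, variant_ids, gene_of_variant):
    prov: dict = {}
    by_gene: dict = {}
    for v_idx, g in enumerate(gene_of_variant):
        by_gene.setdefault(g, []).append(v_idx)
    for gi, sj in zip(*np.nonzero(carrier_cells)):
        g = genes[gi]
        vids = tuple(
            variant_ids[v] for v in by_gene.get(g, ())
            if per_variant_carrier[sj, v]
        )
        prov[(g, sample_ids[sj])] = vids
    return prov


def _effective_genotypes(genotypes: np.ndarray, calls: Optional[pd.DataFrame],
                         call_pass: Optional[np.ndarray]) -> np.ndarray:
    """Zero out genotype calls that failed call-level QC (fail -> non-carrier)."""
    g = np.where(genotypes < 0, 0, genotypes).astype(np.int8)
    if calls is not None and call_pass is not None:
        bad = ~np.asarray(call_pass, dtype=bool)
        if bad.any():
            g = g.copy()
            g[calls["sample_idx"].to_numpy()[bad], calls["variant_idx"].to_numpy()[bad]] = 0
    return g


def build_dominant_matrix(genotypes: np.ndarray, variants: pd.DataFrame,
                          qualifying: np.ndarray, sample_ids, model: CollapsingModel,
                          calls: Optional[pd.DataFrame] = None,
                          call_pass: Optional[np.ndarray] = None,
                          with_provenance: bool = True) -> CollapsingMatrix:
    """Dominant collapsing: carrier iff >= 1 qualifying het/hom call in the gene."""
    g = _effective_genotypes(genotypes, calls, call_pass)
    qv = np.asarray(qualifying, dtype=bool)
    per_variant = (g > 0) & qv[None, :]
    genes = sorted(variants["gene"].unique())
    gene_of_variant = variants["gene"].to_numpy()
    ind = np.zeros((len(genes), len(sample_ids)), dtype=bool)
    for i, gene in enumerate(genes):
        cols = np.flatnonzero(gene_of_variant == gene)
        if cols.size:
            ind[i] = per_variant[:, cols].any(axis=1)
    prov = (_provenance(ind, genes, list(sample_ids), per_variant,
                        variants["variant_id"].to_numpy(), gene_of_variant)
            if with_provenance else {})
    return CollapsingMatrix(genes, list(sample_ids), ind, prov, model)


def build_recessive_matrix(genotypes: np.ndarray, variants: pd.DataFrame,
                           qualifying: np.ndarray, sample_ids, sample_is_male: np.ndarray,
                           model: CollapsingModel,
                           calls: Optional[pd.DataFrame] = None,
                           call_pass: Optional[np.ndarray] = None,
                           with_provenance: bool = True) -> CollapsingMatrix:
    """Recessive collapsing: carrier iff the sample has a homozygous qualifying
    call, two or more distinct heterozygous qualifying variants in the gene
    (putative compound heterozygote, phase unknown), or a hemizygous qualifying
    call on the X chromosome in a male (stored with the homozygous code)."""
    g = _effective_genotypes(genotypes, calls, call_pass)
    # A male het call on X is biologically inconsistent (single copy); treat it
    # as hemizygous so it qualifies via the homozygous-code rule.
    if "chrom" in variants.columns:
        is_x = (variants["chrom"].astype(str) == "X").to_numpy()
        if is_x.any():
            male = np.asarray(sample_is_male, dtype=bool)
            block = g[np.ix_(male, np.flatnonzero(is_x))]
            block[block == 1] = 2
            g = g.copy()
            g[np.ix_(male, np.flatnonzero(is_x))] = block
    qv = np.asarray(qualifying, dtype=bool)
    hom = (g == 2) & qv[None, :]
    het = (g == 1) & qv[None, :]
    genes = sorted(variants["gene"].unique())
    gene_of_variant = variants["gene"].to_numpy()
    ind = np.zeros((len(genes), len(sample_ids)), dtype=bool)
    for i, gene in enumerate(genes):
        cols = np.flatnonzero(gene_of_variant == gene)
        if cols.size:
            ind[i] = hom[:, cols].any(axis=1) | (het[:, cols].sum(axis=1) >= 2)
    per_variant = (hom | het)
    prov = (_provenance(ind, genes, list(sample_ids), per_variant,
                        variants["variant_id"].to_numpy(), gene_of_variant)
            if with_provenance else {})
    return CollapsingMatrix(genes, list(sample_ids), ind, prov, model)
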