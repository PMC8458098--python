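"""Study-wide significance machinery.

Three complementary devices locate a defensible significance threshold for a
collapsing PheWAS whose tests are far from independent:

* an *n-of-1 permutation* null - every trait's case/control labels (or
  quantitative measurements) are shuffled exactly once, the full model x gene
  test matrix is re-run, and the tail of the resulting p-value distribution
  is inspected;
* the *synonymous negative-control model* - collapsing restricted to
  synonymous variants, expected null, whose smallest p-values (after removing
  allow-listed known-real associations) mark where the null tail begins;
* the genomic inflation factor lambda, the median 1-df chi-square quantile of
  the observed p-values divided by 0.4549, computed after excluding
  exome-wide-significant results (p < 2.6e-6).

Plus exact Bonferroni bookkeeping over the models x phenotypes x genes grid.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import stats

from .association import collapsing_test_binary, collapsing_test_quantitative
from .phenotypes import BinaryTrait, QuantitativeTrait

__all__ = [
    "NullSummary",
    "InflationReport",
    "LAMBDA_EXCLUSION_P",
    "n_of_1_permutation",
    "empirical_null_from_synonymous",
    "genomic_lambda",
    "bonferroni_threshold",
    "enumerate_tests",
    "exwas_test_count",
    "exwas_min_maf_percent",
]

LAMBDA_EXCLUSION_P = 2.6e-6
_CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)   # 0.4549364...


@dataclass
class NullSummary:
    source: str                   # permutation | synonymous
    n_tests: int
    min_p: float
    tail: list                    # sorted k smallest p-values
    suggested_threshold: float
    pvalues: Optional[np.ndarray] = None   # full vector when requested

    def __post_init__(self):
        if self.tail and not math.isclose(self.min_p, self.tail[0], rel_tol=1e-12):
            raise ValueError("min_p must equal the head of the tail")


@dataclass
class InflationReport:
    lambda_gc: float
    n_pvalues_used: int
    excluded_below: float
    low_confidence: bool = False


def _permute_binary(trait: BinaryTrait, rng: np.random.Generator) -> BinaryTrait:
    pool = sorted(trait.cases | trait.controls)
    new_cases = frozenset(rng.choice(pool, size=len(trait.cases), replace=False))
    return replace(trait, cases=new_cases, controls=frozenset(pool) - new_cases)


def _permute_quant(trait: QuantitativeTrait, rng: np.random.Generator) -> QuantitativeTrait:
    keys = sorted(trait.values)
    vals = np.array([trait.values[k] for k in keys], dtype=float)
    rng.shuffle(vals)
    return QuantitativeTrait(trait.trait_id, dict(zip(keys, vals)))


def n_of_1_permutation(binary_traits, quant_traits, matrices: dict, samples,
                       seed: int = 0, tail_k: int = 100,
                       exclude_models: tuple = ("syn",),
                       keep_pvalues: bool = False) -> NullSummary:
    """Shuffle each trait's labels once (seeded per trait) and re-run every
    non-synonymous model x gene test on the shuffled labels.

    Carrier matrices are untouched, so per-gene carrier counts and per-trait
    case counts are preserved exactly.  Returns the null p-value tail; the
    suggested study-wide threshold is the smallest permuted p-value.
    """
    pvals: list[float] = []
    use = {name: m for name, m in matrices.items() if name not in set(exclude_models)}
    for trait in binary_traits:
        rng = np.random.default_rng([seed, zlib.crc32(trait.trait_id.encode())])
        shuffled = _permute_binary(trait, rng)
        for m in use.values():
            pvals.extend(r.p for r in collapsing_test_binary(m, shuffled))
    for trait in quant_traits:
        rng = np.random.default_rng([seed, zlib.crc32(trait.trait_id.encode())])
        shuffled = _permute_quant(trait, rng)
        for m in use.values():
            pvals.extend(r.p for r in collapsing_test_quantitative(m, shuffled, samples)
                         if not r.untestable)
    arr = np.sort(np.asarray(pvals, dtype=float))
    tail = arr[:tail_k].tolist()
    return NullSummary(source="permutation", n_tests=len(arr),
                       min_p=float(arr[0]), tail=tail,
                       suggested_threshold=float(arr[0]),
                       pvalues=arr if keep_pvalues else None)


def empirical_null_from_synonymous(results, allowlist=(), tail_k: int = 100) -> NullSummary:
    """Empirical null from synonymous-model results.

    ``results`` is an iterable of association results (or ``(gene, trait, p)``
    triples); ``allowlist`` holds ``(gene, trait)`` pairs of known-real
    synonymous associations to exclude before reading off the tail.  The
    suggested threshold is the smallest retained p-value - the point where
    the null tail begins.
    """
    allow = set(allowlist)
    pvals = []
    for r in results:
        gene, trait, p = (r.unit, r.trait_id, r.p) if hasattr(r, "p") else r
        if (gene, trait) in allow:
            continue
        pvals.append(p)
    if not pvals:
        raise ValueError("no synonymous-model results after allowlist removal")
    arr = np.sort(np.asarray(pvals, dtype=float))
    tail = arr[:tail_k].tolist()
    return NullSummary(source="synonymous", n_tests=len(arr),
                       min_p=float(arr[0]), tail=tail,
                       suggested_threshold=float(arr[0]))


def genomic_lambda(pvalues, exclude_below: float = LAMBDA_EXCLUSION_P,
                   min_n: int = 100) -> InflationReport:
    """Genomic inflation factor: median observed 1-df chi-square quantile
    over the expected median 0.4549, after dropping exome-wide-significant
    p-values (p < ``exclude_below``)."""
    arr = np.asarray(list(pvalues), dtype=float)
    arr = arr[~np.isnan(arr)]
    arr = arr[arr >= exclude_below]
    if arr.size == 0:
        raise ValueError("no p-values retained after exclusion")
    chi2 = stats.chi2.isf(np.clip(arr, 1e-300, 1.0), 1)
    lam = float(np.median(chi2) / _CHI2_MEDIAN_1DF)
    return InflationReport(lambda_gc=lam, n_pvalues_used=int(arr.size),
                           excluded_below=exclude_below,
                           low_confidence=arr.size < min_n)


def bonferroni_threshold(alpha: float, n_models: int, n_phenotypes: int,
                         n_genes: int) -> float:
    """``alpha / (models x phenotypes x genes)``."""
    for v in (n_models, n_phenotypes, n_genes):
        if v <= 0:
            raise ValueError("counts must be positive")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return alpha / (n_models * n_phenotypes * n_genes)


def enumerate_tests(n_genes: int, n_binary: int, n_quant: int,
                    n_models_nonsyn: int = 11, n_models_total: int = 12) -> dict:
    """Exact integer bookkeeping of the PheWAS test matrix."""
    for v in (n_genes, n_binary, n_quant, n_models_nonsyn, n_models_total):
        if v < 0:
            raise ValueError("counts must be non-negative")
    return {
        "collapsing_total": n_models_total * n_genes * (n_binary + n_quant),
        "synonymous_binary": n_genes * n_binary,
        "synonymous_quantitative": n_genes * n_quant,
        "permutation_binary": n_models_nonsyn * n_genes * n_binary,
        "permutation_quantitative": n_models_nonsyn * n_genes * n_quant,
        "exomewide_analyses": n_models_total * (n_binary + n_quant),
    }


def exwas_test_count(n_variants: int, n_phenotypes: int, n_models: int = 3) -> int:
    """Total single-variant association tests (three genetic models)."""
    return n_models * n_variants * n_phenotypes


def exwas_min_maf_percent(min_participants: int = 6, n_samples: int = 269171) -> float:
    """Smallest testable MAF, in percent, implied by the minimum-carrier rule
    (each participant contributes at least one of 2N alleles)."""
    return 100.0 * min_participants / (2.0 * n_samples)
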