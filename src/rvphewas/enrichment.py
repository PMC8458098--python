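"""Enrichment of significant gene-phenotype associations in external gene
lists (approved drug targets, disease-gene catalogues)."""

from __future__ import annotations

import pandas as pd

from .association import FisherResult, fisher_two_sided

__all__ = ["SIGNIFICANT_P", "SUGGESTIVE_P", "assign_tiers", "list_enrichment"]

SIGNIFICANT_P = 2e-9
SUGGESTIVE_P = 1e-7


def assign_tiers(results: pd.DataFrame,
                 thresholds: tuple = (SIGNIFICANT_P, SUGGESTIVE_P)) -> pd.DataFrame:
    """Per-gene tier assignment keeping only the most significant phenotype.

    ``results`` needs ``unit`` (gene) and ``p`` columns.  Tiers:
    significant (p < 2e-9, strict), suggestive (2e-9 <= p < 1e-7),
    nonsignificant (p >= 1e-7).
    """
    sig, sugg = thresholds
    if "unit" not in results.columns or "p" not in results.columns:
        raise ValueError("results need 'unit' and 'p' columns")
    best = results.dropna(subset=["p"]).groupby("unit", as_index=False)["p"].min()
    best = best.rename(columns={"unit": "gene", "p": "best_p"})

    def tier(p):
        if p < sig:
            return "significant"
        if p < sugg:
            return "suggestive"
        return "nonsignificant"

    best["tier"] = best["best_p"].map(tier)
    return best


def list_enrichment(tiers: pd.DataFrame, gene_list, universe) -> FisherResult:
    """Two-sided exact test of significant-tier membership against gene-list
    membership over the universe of tested genes.

    Duplicated list entries and genes outside the universe are ignored.
    """
    universe = set(universe)
    gene_list = set(gene_list) & universe
    if not universe:
        raise ValueError("empty gene universe")
    if not gene_list:
        raise ValueError("gene list has no overlap with the tested universe")
    significant = set(tiers.loc[tiers["tier"] == "significant", "gene"]) & universe
    a = len(significant & gene_list)
    b = len(significant - gene_list)
    c = len(gene_list - significant)
    d = len(universe - significant - gene_list)
    return fisher_two_sided(a, b, c, d)
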