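"""End-to-end orchestration: cohort -> QC -> collapsing matrices ->
harmonized traits -> association results.

This is the layer the calibration machinery and the CLI drive; each step is
the corresponding module's public API applied in the order a PheWAS runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import association, collapsing, qc
from .phenotypes import harmonize_binary, quantitative_traits_from_table
from .simulate import Cohort

__all__ = ["PhewasRun", "build_matrices", "run_phewas"]


@dataclass
class PhewasRun:
    """All intermediate and final products of one collapsing PheWAS."""

    matrices: dict                        # model name -> CollapsingMatrix
    binary_traits: list
    quant_traits: list
    results_binary: pd.DataFrame
    results_quant: pd.DataFrame
    site_pass: np.ndarray
    cohort_maf: np.ndarray

    def results(self, model: str, binary: bool = True) -> pd.DataFrame:
        df = self.results_binary if binary else self.results_quant
        return df[df["model"] == model]


def build_matrices(cohort: Cohort, models=None, with_provenance: bool = False):
    """Site QC, call QC, cohort MAF and one collapsing matrix per model."""
    models = models if models is not None else collapsing.default_models()
    variants = cohort.variants
    g = cohort.genotypes
    profile = qc.COLLAPSING_PROFILE
    site_ok = qc.site_pass_mask(variants, profile)
    call_ok = qc.call_pass_mask(g.calls, g.codes, profile)
    # failing calls are set missing for allele-frequency purposes
    codes_for_maf = g.codes.copy()
    bad = ~call_ok
    if bad.any():
        codes_for_maf[g.calls["sample_idx"].to_numpy()[bad],
                      g.calls["variant_idx"].to_numpy()[bad]] = -1
    is_x = (variants["chrom"].astype(str) == "X").to_numpy()
    is_male = (cohort.samples["sex"] != "female").to_numpy()
    maf, carriers = collapsing.cohort_maf(codes_for_maf, is_x, is_male)
    matrices = {}
    for model in models:
        qv = collapsing.qualifying_mask(variants, maf, carriers, model, site_ok)
        if model.mode == "dominant":
            m = collapsing.build_dominant_matrix(
                g.codes, variants, qv, g.sample_ids, model,
                calls=g.calls, call_pass=call_ok, with_provenance=with_provenance)
        else:
            m = collapsing.build_recessive_matrix(
                g.codes, variants, qv, g.sample_ids, is_male, model,
                calls=g.calls, call_pass=call_ok, with_provenance=with_provenance)
        matrices[model.name] = m
    return matrices, site_ok, maf


def run_phewas(cohort: Cohort, models=None, min_cases: int = 30,
               min_carriers: int = 5, seed: int = 0,
               unions: Optional[pd.DataFrame] = None) -> PhewasRun:
    """Run the full gene-level collapsing PheWAS on a cohort."""
    matrices, site_ok, maf = build_matrices(cohort, models)
    binary_traits = harmonize_binary(cohort.phenotype_records, cohort.hierarchy,
                                     cohort.samples, unions=unions,
                                     min_cases=min_cases, seed=seed)
    quant_traits = (quantitative_traits_from_table(cohort.measurements)
                    if len(cohort.measurements) else [])
    bin_rows, quant_rows = [], []
    for m in matrices.values():
        for trait in binary_traits:
            bin_rows.extend(r.to_dict()
                            for r in association.collapsing_test_binary(m, trait))
        for trait in quant_traits:
            quant_rows.extend(
                r.to_dict() for r in association.collapsing_test_quantitative(
                    m, trait, cohort.samples, min_carriers=min_carriers))
    results_binary = pd.DataFrame(bin_rows)
    results_quant = pd.DataFrame(quant_rows)
    return PhewasRun(matrices=matrices, binary_traits=binary_traits,
                     quant_traits=quant_traits, results_binary=results_binary,
                     results_quant=results_quant, site_pass=site_ok,
                     cohort_maf=maf)
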