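"""Reading and writing the cohort file set.

All tables are plain TSV; the variant table is additionally emitted as a
minimal VCF 4.2 with the annotation columns in INFO and diploid genotypes
(hemizygous male X calls written as diploid-homozygous).  The TSV set
round-trips losslessly through :func:`read_cohort`.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .phenotypes import Hierarchy
from .simulate import Cohort, CohortSimConfig, GenotypeMatrix

__all__ = ["write_cohort", "read_cohort", "write_vcf"]

VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence", "true_maf",
    "gnomad_maf", "revel", "mtr", "variant_id", "fs", "mq", "qual", "rprs",
    "mqrs", "caller_status", "frac_below_10x", "frac_fail_call_qc",
    "ref_cov10x_frac", "ref_pass_frac", "ref_cov_zscore", "ref_site_mq",
]

_FLOAT_FMT = "%.17g"   # lossless float round-trip


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_cohort(cohort: Cohort, directory) -> dict:
    """Write the full cohort file set; returns a name -> path mapping."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {name: d / fname for name, fname in [
        ("samples", "samples.tsv"), ("variants", "variants.tsv"),
        ("genotypes", "genotypes.tsv"), ("calls", "calls.tsv"),
        ("phenotypes", "phenotypes.tsv"), ("measurements", "measurements.tsv"),
        ("kinship", "kinship.tsv"), ("hierarchy", "hierarchy.tsv"),
        ("vcf", "cohort.vcf"),
    ]}
    _write(cohort.samples, paths["samples"])
    _write(cohort.variants[VARIANT_COLUMNS], paths["variants"])
    geno = pd.DataFrame(cohort.genotypes.codes,
                        columns=cohort.genotypes.variant_ids)
    geno.insert(0, "sample_id", cohort.genotypes.sample_ids)
    _write(geno, paths["genotypes"])
    _write(cohort.genotypes.calls, paths["calls"])
    _write(cohort.phenotype_records, paths["phenotypes"])
    _write(cohort.measurements, paths["measurements"])
    _write(cohort.kinship, paths["kinship"])
    cohort.hierarchy.to_tsv(paths["hierarchy"])
    write_vcf(cohort, paths["vcf"])
    return paths


def read_cohort(directory, config: CohortSimConfig | None = None) -> Cohort:
    """Reconstruct a cohort from a directory written by :func:`write_cohort`."""
    d = Path(directory)
    samples = pd.read_csv(d / "samples.tsv", sep="\t")
    variants = pd.read_csv(d / "variants.tsv", sep="\t",
                           dtype={"chrom": str, "caller_status": str})
    geno = pd.read_csv(d / "genotypes.tsv", sep="\t")
    sample_ids = list(geno["sample_id"])
    variant_ids = list(geno.columns[1:])
    codes = geno.iloc[:, 1:].to_numpy(dtype=np.int8)
    calls = pd.read_csv(d / "calls.tsv", sep="\t")
    phenotypes = pd.read_csv(d / "phenotypes.tsv", sep="\t", dtype=str)
    if phenotypes.empty:
        phenotypes = pd.DataFrame(columns=["sample_id", "code"])
    measurements = pd.read_csv(d / "measurements.tsv", sep="\t")
    kinship = pd.read_csv(d / "kinship.tsv", sep="\t")
    hierarchy = Hierarchy.from_tsv(d / "hierarchy.tsv")
    genotypes = GenotypeMatrix(codes, sample_ids, variant_ids, calls)
    return Cohort(samples=samples, variants=variants, genotypes=genotypes,
                  phenotype_records=phenotypes, measurements=measurements,
                  kinship=kinship, hierarchy=hierarchy,
                  config=config or CohortSimConfig())


_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(cohort: Cohort, path) -> None:
    """Minimal VCF 4.2 companion file.

    Annotation columns go to INFO; genotypes are diploid, so a hemizygous
    male X call (coded 2) is written ``1/1``.
    """
    v = cohort.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">\n')
        fh.write('##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence terms">\n')
        fh.write('##INFO=<ID=GMAF,Number=1,Type=Float,Description="Reference population MAF">\n')
        fh.write('##INFO=<ID=REVEL,Number=1,Type=Float,Description="REVEL score">\n')
        fh.write('##INFO=<ID=MTR,Number=1,Type=Float,Description="Missense tolerance ratio">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted(v["chrom"].unique(), key=str):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(cohort.genotypes.sample_ids) + "\n")
        order = v.sort_values(["chrom", "pos"], kind="stable").index
        codes = cohort.genotypes.codes
        vid_col = {vid: j for j, vid in enumerate(cohort.genotypes.variant_ids)}
        for i in order:
            row = v.loc[i]
            info = [f"GENE={row['gene']}", f"CSQ={row['consequence']}"]
            for key, col in (("GMAF", "gnomad_maf"), ("REVEL", "revel"), ("MTR", "mtr")):
                if not (isinstance(row[col], float) and math.isnan(row[col])):
                    info.append(f"{key}={row[col]:.6g}")
            j = vid_col[row["variant_id"]]
            gts = "\t".join(_GT[int(c)] for c in codes[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t"
                     f"{row['ref']}\t{row['alt']}\t{row['qual']:.2f}\t"
                     f"{row['caller_status']}\t{';'.join(info)}\tGT\t{gts}\n")
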