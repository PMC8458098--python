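"""Site- and call-level genotype quality control.

Two named threshold profiles are shipped, mirroring the two filter lists a
rare-variant PheWAS applies: a single-variant (ExWAS) profile and a stricter
gene-collapsing profile.  Every criterion is evaluated fail-closed: a missing
metric fails with an explicit reason rather than passing silently.

Threshold comparisons are inclusive (``>=``/``<=`` bounds), the
heterozygous allele-balance binomial criterion is a strict ``p > 1e-6``, and
the site "missing in 10% or more" / "failed call QC in 5% or more" rules
fail at exactly the stated fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SiteQCMetrics",
    "CallQCMetrics",
    "QCProfile",
    "EXWAS_PROFILE",
    "COLLAPSING_PROFILE",
    "allele_balance_binomial_p",
    "evaluate_call",
    "evaluate_site",
    "site_pass_mask",
    "call_pass_mask",
]


@dataclass(frozen=True)
class SiteQCMetrics:
    """Per-site metrics as emitted by a germline caller plus external-reference
    (gnomAD-style) summary columns.  ``NaN``/``None`` marks an absent metric."""

    fisher_strand_bias: float = math.nan          # FS
    mapping_quality: float = math.nan             # MQ
    qual: float = math.nan                        # QUAL
    read_pos_rank_sum: float = math.nan           # RPRS
    mapping_quality_rank_sum: float = math.nan    # MQRS
    caller_status: Optional[str] = None           # PASS or other
    fraction_samples_below_10x: float = math.nan
    fraction_samples_failing_call_qc: float = math.nan
    ref_coverage10x_fraction: float = math.nan    # external reference 10x coverage
    ref_pass_fraction: float = math.nan           # NaN when absent from reference
    ref_coverage_zscore: float = math.nan
    ref_site_mq: float = math.nan


@dataclass(frozen=True)
class CallQCMetrics:
    """Per-genotype-call read metrics."""

    depth: float = math.nan
    genotype_quality: float = math.nan
    alt_reads: float = math.nan
    total_reads: float = math.nan

    @property
    def alt_read_fraction(self) -> float:
        if not (self.total_reads and self.total_reads > 0):
            return math.nan
        return float(self.alt_reads) / float(self.total_reads)


@dataclass(frozen=True)
class QCProfile:
    """A named set of thresholds.  ``None`` means the criterion is not part of
    this profile."""

    name: str
    # call level
    min_depth: float = 10.0
    min_gq: float = 20.0
    het_ab_min: float = 0.2
    het_ab_max: Optional[float] = None
    hom_ab_max: Optional[float] = None
    min_het_binom_p: float = 1e-6          # strict >
    # site level
    fs_max_snv: float = 60.0
    fs_max_indel: float = 200.0
    min_mq: float = 40.0
    min_qual: float = 30.0
    min_rprs: float = -2.0
    min_mqrs: float = -8.0
    require_caller_pass: bool = True
    max_missing_fraction: Optional[float] = None      # fail if >= value
    max_call_fail_fraction: Optional[float] = None    # fail if >= value
    min_ref_coverage10x: Optional[float] = None
    min_ref_pass_fraction: Optional[float] = None     # only when observed in reference
    min_ref_coverage_zscore: Optional[float] = None   # only when observed
    min_ref_site_mq: Optional[float] = None           # only when observed

    @classmethod
    def from_dict(cls, d: dict) -> "QCProfile":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown QC profile keys: {sorted(unknown)}")
        return cls(**d)


#: Single-variant association profile: het allele balance >= 0.2 with no upper
#: bound, site missingness and per-site call-failure criteria applied, and the
#: reference criteria "10x coverage in >= 30%" plus "pass fraction >= 50% when
#: the variant is observed in the reference".
EXWAS_PROFILE = QCProfile(
    name="exwas",
    het_ab_min=0.2,
    max_missing_fraction=0.10,
    max_call_fail_fraction=0.05,
    min_ref_coverage10x=0.30,
    min_ref_pass_fraction=0.50,
)

#: Gene-collapsing profile: het allele balance in [0.25, 0.8], hom-alt allele
#: balance <= 0.8, reference 10x coverage >= 25% and, when observed in the
#: reference, coverage z-score >= -2 and reference site MQ >= 30.
COLLAPSING_PROFILE = QCProfile(
    name="collapsing",
    het_ab_min=0.25,
    het_ab_max=0.8,
    hom_ab_max=0.8,
    min_ref_coverage10x=0.25,
    min_ref_coverage_zscore=-2.0,
    min_ref_site_mq=30.0,
)

PROFILES = {"exwas": EXWAS_PROFILE, "collapsing": COLLAPSING_PROFILE}


def allele_balance_binomial_p(alt_reads: int, total_reads: int) -> float:
    """Two-sided exact binomial p-value for departure of the alternate-read
    proportion from 0.5.

    Uses the minimum-likelihood convention (sum of point probabilities no
    larger than the observed one), which for the symmetric p=0.5 binomial
    reduces to ``min(1, 2 * P(X <= min(k, n-k)))``.
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    k, n = int(alt_reads), int(total_reads)
    if not 0 <= k <= n:
        raise ValueError("alt_reads must lie in [0, total_reads]")
    m = min(k, n - k)
    if 2 * m == n:
        return 1.0
    return float(min(1.0, 2.0 * stats.binom.cdf(m, n, 0.5)))


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def evaluate_call(call: CallQCMetrics, genotype: int, profile: QCProfile):
    """Evaluate one genotype call against a profile.

    ``genotype`` uses the package coding 0 hom-ref / 1 het / 2 hom-alt (or
    hemizygous).  Returns ``(passed, reasons)`` where ``reasons`` lists every
    violated criterion.  Absent metrics fail closed.
    """
    reasons: list[str] = []
    if _missing(call.depth):
        reasons.append("missing depth")
    elif call.depth < profile.min_depth:
        reasons.append(f"depth < {profile.min_depth:g}")
    if _missing(call.genotype_quality):
        reasons.append("missing GQ")
    elif call.genotype_quality < profile.min_gq:
        reasons.append(f"GQ < {profile.min_gq:g}")

    if genotype == 1:
        ab = call.alt_read_fraction
        if _missing(ab):
            reasons.append("no reads")
        else:
            if ab < profile.het_ab_min:
                reasons.append(f"het alt fraction < {profile.het_ab_min:g}")
            if profile.het_ab_max is not None and ab > profile.het_ab_max:
                reasons.append(f"het alt fraction > {profile.het_ab_max:g}")
            p = allele_balance_binomial_p(int(call.alt_reads), int(call.total_reads))
            if not p > profile.min_het_binom_p:
                reasons.append(f"het binomial p <= {profile.min_het_binom_p:g}")
    elif genotype == 2 and profile.hom_ab_max is not None:
        ab = call.alt_read_fraction
        if _missing(ab):
            reasons.append("no reads")
        elif ab > profile.hom_ab_max:
            reasons.append(f"hom alt fraction > {profile.hom_ab_max:g}")
    return (not reasons), reasons


def evaluate_site(site: SiteQCMetrics, variant_class: str, profile: QCProfile):
    """Evaluate one variant site.  ``variant_class`` is ``"SNV"`` or
    ``"indel"`` (Fisher strand-bias thresholds are class specific).  Returns
    ``(passed, reasons)``."""
    if variant_class not in ("SNV", "indel"):
        raise ValueError(f"variant_class must be 'SNV' or 'indel', got {variant_class!r}")
    reasons: list[str] = []
    fs_max = profile.fs_max_snv if variant_class == "SNV" else profile.fs_max_indel

    def check_min(value, bound, label):
        if _missing(value):
            reasons.append(f"missing {label}")
        elif value < bound:
            reasons.append(f"{label} < {bound:g}")

    if _missing(site.fisher_strand_bias):
        reasons.append("missing FS")
    elif site.fisher_strand_bias > fs_max:
        reasons.append(f"FS > {fs_max:g}")
    check_min(site.mapping_quality, profile.min_mq, "MQ")
    check_min(site.qual, profile.min_qual, "QUAL")
    check_min(site.read_pos_rank_sum, profile.min_rprs, "RPRS")
    check_min(site.mapping_quality_rank_sum, profile.min_mqrs, "MQRS")
    if profile.require_caller_pass and site.caller_status != "PASS":
        reasons.append("caller status not PASS")
    if profile.max_missing_fraction is not None:
        if _missing(site.fraction_samples_below_10x):
            reasons.append("missing site missingness fraction")
        elif site.fraction_samples_below_10x >= profile.max_missing_fraction:
            reasons.append(f"missing in >= {profile.max_missing_fraction:.0%} of sequences")
    if profile.max_call_fail_fraction is not None:
        if _missing(site.fraction_samples_failing_call_qc):
            reasons.append("missing call-QC failure fraction")
        elif site.fraction_samples_failing_call_qc >= profile.max_call_fail_fraction:
            reasons.append(f"call QC failed in >= {profile.max_call_fail_fraction:.0%} of sequences")
    if profile.min_ref_coverage10x is not None:
        if _missing(site.ref_coverage10x_fraction):
            reasons.append("missing reference 10x coverage")
        elif site.ref_coverage10x_fraction < profile.min_ref_coverage10x:
            reasons.append(f"reference 10x coverage < {profile.min_ref_coverage10x:g}")
    # Criteria conditioned on the variant being observed in the reference:
    # skipped (not failed) when the variant is absent from the reference, which
    # is signalled by a missing ref_pass_fraction.
    observed_in_ref = not _missing(site.ref_pass_fraction)
    if observed_in_ref:
        if profile.min_ref_pass_fraction is not None and site.ref_pass_fraction < profile.min_ref_pass_fraction:
            reasons.append(f"reference pass fraction < {profile.min_ref_pass_fraction:g}")
        if profile.min_ref_coverage_zscore is not None:
            if _missing(site.ref_coverage_zscore):
                reasons.append("missing reference coverage z-score")
            elif site.ref_coverage_zscore < profile.min_ref_coverage_zscore:
                reasons.append(f"reference coverage z-score < {profile.min_ref_coverage_zscore:g}")
        if profile.min_ref_site_mq is not None:
            if _missing(site.ref_site_mq):
                reasons.append("missing reference site MQ")
            elif site.ref_site_mq < profile.min_ref_site_mq:
                reasons.append(f"reference site MQ < {profile.min_ref_site_mq:g}")
    return (not reasons), reasons


# ---------------------------------------------------------------------------
# vectorised bulk paths (used by the collapsing engine / pipeline)

_SITE_COLUMNS = {
    "fisher_strand_bias": "fs",
    "mapping_quality": "mq",
    "qual": "qual",
    "read_pos_rank_sum": "rprs",
    "mapping_quality_rank_sum": "mqrs",
    "caller_status": "caller_status",
    "fraction_samples_below_10x": "frac_below_10x",
    "fraction_samples_failing_call_qc": "frac_fail_call_qc",
    "ref_coverage10x_fraction": "ref_cov10x_frac",
    "ref_pass_fraction": "ref_pass_frac",
    "ref_coverage_zscore": "ref_cov_zscore",
    "ref_site_mq": "ref_site_mq",
}


def site_metrics_from_row(row) -> SiteQCMetrics:
    """Build :class:`SiteQCMetrics` from a variant-table row."""
    kw = {}
    for field_name, col in _SITE_COLUMNS.items():
        v = row[col] if col in row else math.nan
        if col == "caller_status":
            kw[field_name] = None if (isinstance(v, float) and math.isnan(v)) else v
        else:
            kw[field_name] = math.nan if pd.isna(v) else float(v)
    return SiteQCMetrics(**kw)


def site_pass_mask(variants: pd.DataFrame, profile: QCProfile) -> np.ndarray:
    """Vectorised :func:`evaluate_site` over a variant table.

    The variant table uses the package column dialect (``fs``, ``mq``,
    ``qual``, ``rprs``, ``mqrs``, ``caller_status``, ``frac_below_10x``,
    ``frac_fail_call_qc``, ``ref_cov10x_frac``, ``ref_pass_frac``,
    ``ref_cov_zscore``, ``ref_site_mq``, ``ref``, ``alt``).
    """
    n = len(variants)
    ok = np.ones(n, dtype=bool)
    is_snv = (variants["ref"].str.len() == 1) & (variants["alt"].str.len() == 1)
    fs = variants["fs"].to_numpy(float)
    fs_bound = np.where(is_snv, profile.fs_max_snv, profile.fs_max_indel)
    ok &= ~np.isnan(fs) & (fs <= fs_bound)
    for col, bound in (
        ("mq", profile.min_mq),
        ("qual", profile.min_qual),
        ("rprs", profile.min_rprs),
        ("mqrs", profile.min_mqrs),
    ):
        v = variants[col].to_numpy(float)
        ok &= ~np.isnan(v) & (v >= bound)
    if profile.require_caller_pass:
        ok &= (variants["caller_status"] == "PASS").to_numpy()
    if profile.max_missing_fraction is not None:
        v = variants["frac_below_10x"].to_numpy(float)
        ok &= ~np.isnan(v) & (v < profile.max_missing_fraction)
    if profile.max_call_fail_fraction is not None:
        v = variants["frac_fail_call_qc"].to_numpy(float)
        ok &= ~np.isnan(v) & (v < profile.max_call_fail_fraction)
    if profile.min_ref_coverage10x is not None:
        v = variants["ref_cov10x_frac"].to_numpy(float)
        ok &= ~np.isnan(v) & (v >= profile.min_ref_coverage10x)
    observed = ~variants["ref_pass_frac"].isna().to_numpy()
    if profile.min_ref_pass_fraction is not None:
        v = variants["ref_pass_frac"].to_numpy(float)
        ok &= ~observed | (v >= profile.min_ref_pass_fraction)
    if profile.min_ref_coverage_zscore is not None:
        v = variants["ref_cov_zscore"].to_numpy(float)
        ok &= ~observed | (~np.isnan(v) & (v >= profile.min_ref_coverage_zscore))
    if profile.min_ref_site_mq is not None:
        v = variants["ref_site_mq"].to_numpy(float)
        ok &= ~observed | (~np.isnan(v) & (v >= profile.min_ref_site_mq))
    return ok


def call_pass_mask(calls: pd.DataFrame, genotypes: np.ndarray, profile: QCProfile) -> np.ndarray:
    """Vectorised :func:`evaluate_call` over a sparse call table.

    ``calls`` has columns ``sample_idx``, ``variant_idx``, ``depth``, ``gq``,
    ``alt_reads``, ``total_reads``; ``genotypes`` is the full coded matrix
    used to look up each call's genotype.
    """
    gt = genotypes[calls["sample_idx"].to_numpy(), calls["variant_idx"].to_numpy()]
    depth = calls["depth"].to_numpy(float)
    gq = calls["gq"].to_numpy(float)
    alt = calls["alt_reads"].to_numpy(float)
    tot = calls["total_reads"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ab = np.where(tot > 0, alt / tot, np.nan)
    ok = ~np.isnan(depth) & (depth >= profile.min_depth)
    ok &= ~np.isnan(gq) & (gq >= profile.min_gq)
    het = gt == 1
    hom = gt == 2
    ab_ok = ~np.isnan(ab)
    ok &= ~het | (ab_ok & (ab >= profile.het_ab_min))
    if profile.het_ab_max is not None:
        ok &= ~het | (ab_ok & (ab <= profile.het_ab_max))
    # symmetric minlike binomial p for het allele balance, vectorised
    m = np.minimum(alt, tot - alt)
    with np.errstate(invalid="ignore"):
        binom_p = np.minimum(1.0, 2.0 * stats.binom.cdf(m, np.maximum(tot, 1), 0.5))
    binom_p = np.where(2 * m == tot, 1.0, binom_p)
    ok &= ~het | (ab_ok & (binom_p > profile.min_het_binom_p))
    if profile.hom_ab_max is not None:
        ok &= ~hom | (ab_ok & (ab <= profile.hom_ab_max))
    return ok
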