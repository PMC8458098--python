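"""Association statistics for binary and quantitative traits.

Binary traits are tested with a two-sided Fisher's exact test (minimum
likelihood convention: the p-value sums the hypergeometric point
probabilities no larger than the observed table's).  Quantitative traits use
ordinary least squares of the measurement on the carrier indicator (or
genotype coding) with age, sex and age x sex covariates.  Ancestry strata are
combined with the Cochran-Mantel-Haenszel one-degree-of-freedom test and the
Mantel-Haenszel common odds ratio; pan-ancestry quantitative models use
categorical ancestry plus the top five principal components, age and sex.

Odds-ratio confidence intervals use the Woolf (log-OR normal) interval with a
Haldane-Anscombe 0.5 correction when any cell is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "FisherResult",
    "AssociationResult",
    "CMHResult",
    "fisher_two_sided",
    "phred",
    "collapsing_test_binary",
    "collapsing_test_quantitative",
    "exwas_binary",
    "exwas_quantitative",
    "cmh_stratified",
    "pan_ancestry_binary",
    "pan_ancestry_quantitative",
]

_Z975 = stats.norm.ppf(0.975)


def phred(p: float) -> float:
    """Phred score, -10*log10(p)."""
    return -10.0 * math.log10(p)


@dataclass(frozen=True)
class FisherResult:
    p: float
    odds_ratio: float        # NaN when undefined (zero margin)
    ci_low: float
    ci_high: float

    @property
    def phred(self) -> float:
        return phred(self.p)


@lru_cache(maxsize=1 << 20)
def _fisher_cached(a: int, b: int, c: int, d: int):
    n_total = a + b + c + d
    row1 = a + b              # cases
    col1 = a + c              # exposed
    if row1 == 0 or row1 == n_total or col1 == 0 or col1 == n_total:
        return 1.0, math.nan, math.nan, math.nan
    lo = max(0, row1 + col1 - n_total)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    # hypergeometric point masses via log-gamma (hot path: a PheWAS evaluates
    # millions of small tables)
    lg = special.gammaln
    logpmf = (lg(col1 + 1) - lg(support + 1) - lg(col1 - support + 1)
              + lg(n_total - col1 + 1) - lg(row1 - support + 1)
              - lg(n_total - col1 - row1 + support + 1)
              - (lg(n_total + 1) - lg(row1 + 1) - lg(n_total - row1 + 1)))
    pmf = np.exp(logpmf)
    p_obs = pmf[a - lo]
    # minlike two-sided: sum of point probabilities <= observed (with a small
    # relative slack to absorb floating-point ties)
    mask = pmf <= p_obs * (1.0 + 1e-7)
    p = 1.0 if mask.all() else float(pmf[mask].sum())
    p = min(1.0, max(p, float(p_obs)))
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    or_ = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = math.exp(math.log(or_) - _Z975 * se)
    ci_high = math.exp(math.log(or_) + _Z975 * se)
    return p, or_, ci_low, ci_high


def fisher_two_sided(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher's exact test on the 2x2 table ``[[a, b], [c, d]]``
    (rows cases/controls, columns exposed/unexposed).

    Returns p-value, odds ratio ``(a*d)/(b*c)`` (Haldane-Anscombe corrected
    when any cell is zero; NaN when a margin is zero) and the 95% Woolf CI.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be non-negative integers")
    return FisherResult(*_fisher_cached(int(a), int(b), int(c), int(d)))


@dataclass
class AssociationResult:
    """One (unit, trait, model) association."""

    unit: str
    trait_id: str
    model: str
    kind: str                              # fisher | ols | cmh
    p: float = math.nan
    effect: float = math.nan               # odds ratio or beta
    ci_low: float = math.nan
    ci_high: float = math.nan
    counts: Optional[dict] = None          # 2x2 cells for exact tests
    n: Optional[int] = None
    untestable: bool = False
    reason: Optional[str] = None

    @property
    def phred(self) -> float:
        return phred(self.p)

    def to_dict(self) -> dict:
        d = {
            "unit": self.unit, "trait_id": self.trait_id, "model": self.model,
            "kind": self.kind, "p": self.p, "effect": self.effect,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "n": self.n,
            "untestable": self.untestable, "reason": self.reason,
        }
        if self.counts:
            d.update(self.counts)
        if not self.untestable and self.p > 0:
            d["phred"] = self.phred
        return d


# ---------------------------------------------------------------------------
# gene-level collapsing tests


def _trait_indices(matrix, sample_set):
    idx = matrix._sample_idx
    missing = [s for s in sample_set if s not in idx]
    if missing:
        raise ValueError(f"samples absent from collapsing matrix: {sorted(missing)[:5]}")
    return np.fromiter((idx[s] for s in sorted(sample_set)), dtype=np.int64)


def collapsing_test_binary(matrix, trait) -> list[AssociationResult]:
    """Fisher's exact test of carrier status against case status, per gene.

    ``matrix`` is a :class:`~rvphewas.collapsing.CollapsingMatrix` and
    ``trait`` a harmonized :class:`~rvphewas.phenotypes.BinaryTrait`.
    """
    case_idx = _trait_indices(matrix, trait.cases)
    ctrl_idx = _trait_indices(matrix, trait.controls)
    n_cases, n_ctrls = len(case_idx), len(ctrl_idx)
    case_carriers = matrix.indicator[:, case_idx].sum(axis=1)
    ctrl_carriers = matrix.indicator[:, ctrl_idx].sum(axis=1)
    out = []
    for gi, gene in enumerate(matrix.genes):
        a = int(case_carriers[gi]); c = int(ctrl_carriers[gi])
        b = n_cases - a; d = n_ctrls - c
        fr = fisher_two_sided(a, b, c, d)
        out.append(AssociationResult(
            unit=gene, trait_id=trait.trait_id, model=matrix.model.name,
            kind="fisher", p=fr.p, effect=fr.odds_ratio,
            ci_low=fr.ci_low, ci_high=fr.ci_high,
            counts={"case_carriers": a, "case_noncarriers": b,
                    "control_carriers": c, "control_noncarriers": d},
            n=n_cases + n_ctrls))
    return out


def _ols_fit(y: np.ndarray, X: np.ndarray):
    """Closed-form OLS: returns (beta, se, p, df_resid) per coefficient, or
    None when the design is singular."""
    n, k = X.shape
    if n <= k:
        return None
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        return None
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, p, df


def _covariate_design(samples: pd.DataFrame, sample_order, interaction: bool = True):
    sub = samples.set_index("sample_id").loc[list(sample_order)]
    age = sub["age"].to_numpy(float)
    sex = (sub["sex"] == "female").to_numpy(float)
    cols = [np.ones(len(sub)), age, sex]
    if interaction:
        cols.append(age * sex)
    return np.column_stack(cols)


def _ols_result(y, carrier, covars, unit, trait_id, model_name, min_carriers=0):
    n_carr = int(carrier.sum())
    base = AssociationResult(unit=unit, trait_id=trait_id, model=model_name,
                             kind="ols", n=len(y))
    if min_carriers and n_carr < min_carriers:
        base.untestable, base.reason = True, f"fewer than {min_carriers} carriers"
        return base
    if np.ptp(y) <= 1e-12 * max(1.0, abs(float(np.mean(y)))):
        # degenerate response: no variance to explain
        base.p, base.effect, base.ci_low, base.ci_high = 1.0, 0.0, 0.0, 0.0
        return base
    X = np.column_stack([covars, carrier])
    fit = _ols_fit(y, X)
    if fit is None:
        base.untestable, base.reason = True, "singular design"
        return base
    beta, se, p, _ = fit
    base.effect = float(beta[-1])
    base.ci_low = float(beta[-1] - _Z975 * se[-1])
    base.ci_high = float(beta[-1] + _Z975 * se[-1])
    base.p = float(min(1.0, max(p[-1], 5e-324)))
    return base


def collapsing_test_quantitative(matrix, trait, samples: pd.DataFrame,
                                 min_carriers: int = 5) -> list[AssociationResult]:
    """OLS of the measurement on the gene carrier indicator, adjusting for
    age, sex and age x sex.  Genes with fewer than ``min_carriers`` measured
    carriers are flagged untestable."""
    measured = [s for s in sorted(trait.values) if s in matrix._sample_idx]
    if len(measured) < 2:
        raise ValueError("fewer than two measured samples overlap the matrix")
    y = np.array([trait.values[s] for s in measured], dtype=float)
    covars = _covariate_design(samples, measured)
    col_idx = np.fromiter((matrix._sample_idx[s] for s in measured), dtype=np.int64)
    sub = matrix.indicator[:, col_idx]
    out = []
    for gi, gene in enumerate(matrix.genes):
        out.append(_ols_result(y, sub[gi].astype(float), covars, gene,
                               trait.trait_id, matrix.model.name, min_carriers))
    return out


# ---------------------------------------------------------------------------
# single-variant (ExWAS) tests


def _split_genotypes(codes: np.ndarray, idx: np.ndarray):
    g = codes[idx]
    g = g[g >= 0]
    return int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum())


def exwas_binary(codes: np.ndarray, sample_ids, trait, genetic_model: str,
                 variant_id: str = "variant", min_participants: int = 6) -> AssociationResult:
    """Single-variant exact test under an allelic, dominant or recessive coding.

    ``codes`` is the coded genotype vector for one variant over ``sample_ids``.
    AA denotes hom-alt, AB het, BB hom-ref.  The variant must be observed in at
    least ``min_participants`` participants of the tested cohort.
    """
    if genetic_model not in ("allelic", "dominant", "recessive"):
        raise ValueError(f"unknown genetic model {genetic_model!r}")
    pos = {s: i for i, s in enumerate(sample_ids)}
    case_idx = np.fromiter((pos[s] for s in sorted(trait.cases)), dtype=np.int64)
    ctrl_idx = np.fromiter((pos[s] for s in sorted(trait.controls)), dtype=np.int64)
    all_idx = np.concatenate([case_idx, ctrl_idx])
    observed = int((codes[all_idx] > 0).sum())
    res = AssociationResult(unit=variant_id, trait_id=trait.trait_id,
                            model=genetic_model, kind="fisher")
    if observed < min_participants:
        res.untestable = True
        res.reason = f"observed in {observed} < {min_participants} participants"
        return res
    aa1, ab1, bb1 = _split_genotypes(codes, case_idx)
    aa0, ab0, bb0 = _split_genotypes(codes, ctrl_idx)
    if genetic_model == "allelic":
        a, b = 2 * aa1 + ab1, 2 * bb1 + ab1
        c, d = 2 * aa0 + ab0, 2 * bb0 + ab0
    elif genetic_model == "dominant":
        a, b, c, d = aa1 + ab1, bb1, aa0 + ab0, bb0
    else:
        a, b, c, d = aa1, ab1 + bb1, aa0, ab0 + bb0
    fr = fisher_two_sided(a, b, c, d)
    res.p, res.effect, res.ci_low, res.ci_high = fr.p, fr.odds_ratio, fr.ci_low, fr.ci_high
    res.counts = {"case_carriers": a, "case_noncarriers": b,
                  "control_carriers": c, "control_noncarriers": d}
    res.n = len(all_idx)
    return res


def exwas_quantitative(codes: np.ndarray, sample_ids, trait, genetic_model: str,
                       samples: pd.DataFrame, variant_id: str = "variant",
                       min_participants: int = 6) -> AssociationResult:
    """Single-variant linear regression under a genotypic (additive 0/1/2),
    dominant or recessive coding, adjusting for age, sex and age x sex."""
    if genetic_model not in ("genotypic", "dominant", "recessive"):
        raise ValueError(f"unknown genetic model {genetic_model!r}")
    pos = {s: i for i, s in enumerate(sample_ids)}
    measured = [s for s in sorted(trait.values) if s in pos]
    idx = np.fromiter((pos[s] for s in measured), dtype=np.int64)
    g = codes[idx].astype(float)
    keep = g >= 0
    idx, g = idx[keep], g[keep]
    measured = [s for s, k in zip(measured, keep) if k]
    res = AssociationResult(unit=variant_id, trait_id=trait.trait_id,
                            model=genetic_model, kind="ols", n=len(measured))
    observed = int((g > 0).sum())
    if observed < min_participants:
        res.untestable = True
        res.reason = f"observed in {observed} < {min_participants} participants"
        return res
    if genetic_model == "dominant":
        x = (g >= 1).astype(float)
    elif genetic_model == "recessive":
        x = (g == 2).astype(float)
    else:
        x = g
    if np.ptp(x) == 0.0:
        res.untestable, res.reason = True, "monomorphic coding"
        return res
    y = np.array([trait.values[s] for s in measured], dtype=float)
    covars = _covariate_design(samples, measured)
    return _ols_result(y, x, covars, variant_id, trait.trait_id, genetic_model)


# ---------------------------------------------------------------------------
# stratified (pan-ancestry) combination


@dataclass(frozen=True)
class CMHResult:
    p: float
    common_odds_ratio: float
    chi2: float


def cmh_stratified(tables) -> CMHResult:
    """Cochran-Mantel-Haenszel 1-df chi-square (no continuity correction) over
    a list of 2x2 tables ``[[a, b], [c, d]]`` and the Mantel-Haenszel common
    odds ratio ``sum(a_i d_i / n_i) / sum(b_i c_i / n_i)``.

    Strata with a zero total are dropped; if every stratum is degenerate the
    test returns p = 1 with an undefined odds ratio.
    """
    num = var = 0.0
    or_num = or_den = 0.0
    informative = False
    for t in tables:
        (a, b), (c, d) = t
        n = a + b + c + d
        if n == 0:
            continue
        r1, r2 = a + b, c + d
        c1, c2 = a + c, b + d
        or_num += a * d / n
        or_den += b * c / n
        if n > 1 and min(r1, r2, c1, c2) > 0:
            num += a - r1 * c1 / n
            var += r1 * r2 * c1 * c2 / (n * n * (n - 1))
            informative = True
    if not informative or var == 0.0:
        or_ = or_num / or_den if or_den > 0 else math.nan
        return CMHResult(1.0, or_, 0.0)
    chi2 = num * num / var
    p = float(stats.chi2.sf(chi2, 1))
    or_ = or_num / or_den if or_den > 0 else math.inf if or_num > 0 else math.nan
    return CMHResult(max(p, 5e-324), or_, float(chi2))


def pan_ancestry_binary(matrix, trait, ancestry: dict) -> list[AssociationResult]:
    """Per-gene CMH over per-ancestry 2x2 collapsing tables (never a pooled
    Fisher test, guarding against Simpson's paradox).

    ``ancestry`` maps sample_id -> ancestry label; strata are the labels
    present among the trait's cases and controls.
    """
    labels = sorted({ancestry[s] for s in trait.cases | trait.controls})
    strata = []
    for lab in labels:
        cases = {s for s in trait.cases if ancestry[s] == lab}
        ctrls = {s for s in trait.controls if ancestry[s] == lab}
        case_idx = _trait_indices(matrix, cases) if cases else np.array([], dtype=np.int64)
        ctrl_idx = _trait_indices(matrix, ctrls) if ctrls else np.array([], dtype=np.int64)
        strata.append((case_idx, ctrl_idx))
    out = []
    for gi, gene in enumerate(matrix.genes):
        tables = []
        for case_idx, ctrl_idx in strata:
            a = int(matrix.indicator[gi, case_idx].sum())
            c = int(matrix.indicator[gi, ctrl_idx].sum())
            tables.append([[a, len(case_idx) - a], [c, len(ctrl_idx) - c]])
        r = cmh_stratified(tables)
        out.append(AssociationResult(
            unit=gene, trait_id=trait.trait_id, model=matrix.model.name,
            kind="cmh", p=r.p, effect=r.common_odds_ratio,
            n=sum(len(ci) + len(oi) for ci, oi in strata)))
    return out


def pan_ancestry_quantitative(matrix, trait, samples: pd.DataFrame,
                              min_carriers: int = 5) -> list[AssociationResult]:
    """OLS per gene with categorical ancestry, the top five principal
    components, age and sex as covariates (no age x sex term, matching the
    pan-ancestry model rather than the single-ancestry one)."""
    measured = [s for s in sorted(trait.values) if s in matrix._sample_idx]
    if len(measured) < 2:
        raise ValueError("fewer than two measured samples overlap the matrix")
    sub = samples.set_index("sample_id").loc[measured]
    y = np.array([trait.values[s] for s in measured], dtype=float)
    parts = [np.ones(len(measured)),
             sub["age"].to_numpy(float),
             (sub["sex"] == "female").to_numpy(float)]
    present = sorted(sub["ancestry"].unique())
    for lab in present[1:]:  # first label absorbed by the intercept
        parts.append((sub["ancestry"] == lab).to_numpy(float))
    for k in range(1, 6):
        parts.append(sub[f"pc{k}"].to_numpy(float))
    covars = np.column_stack(parts)
    col_idx = np.fromiter((matrix._sample_idx[s] for s in measured), dtype=np.int64)
    carriers = matrix.indicator[:, col_idx]
    out = []
    for gi, gene in enumerate(matrix.genes):
        out.append(_ols_result(y, carriers[gi].astype(float), covars, gene,
                               trait.trait_id, matrix.model.name, min_carriers))
    return out


def results_to_frame(results) -> pd.DataFrame:
    """Flatten a list of :class:`AssociationResult` into a summary table."""
    return pd.DataFrame([r.to_dict() for r in results])
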