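"""Phenotype harmonization: from long-format diagnosis records to testable
binary and quantitative traits.

Diagnosis codes live on a hierarchy (leaf -> block -> chapter).  Every leaf
and every internal node up to the chapter root becomes a candidate binary
trait whose cases are the union of its descendant leaves' cases.  Controls
are restricted to samples with no diagnosis anywhere in the trait's chapter,
union phenotypes merge related codes, control sets are down-sampled to match
the case female fraction when it differs significantly, and traits with fewer
than 30 cases are dropped.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Hierarchy",
    "BinaryTrait",
    "QuantitativeTrait",
    "expand_tree_phenotypes",
    "chapter_case_sets",
    "restrict_chapter_controls",
    "build_union_phenotype",
    "sex_match_controls",
    "filter_min_cases",
    "harmonize_binary",
    "quantitative_traits_from_table",
]

MIN_CASES = 30


class Hierarchy:
    """A diagnosis-code tree given as child -> parent edges; roots (chapters)
    have an empty parent."""

    def __init__(self, parent: dict):
        self.parent = dict(parent)
        self.children: dict = {}
        for child, par in self.parent.items():
            if par:
                self.children.setdefault(par, set()).add(child)

    @classmethod
    def from_tsv(cls, path) -> "Hierarchy":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return cls(dict(zip(df["child_code"], df["parent_code"])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"child_code": list(self.parent), "parent_code": [self.parent[c] for c in self.parent]}
        ).to_csv(path, sep="\t", index=False)

    def __contains__(self, code) -> bool:
        return code in self.parent

    @property
    def nodes(self):
        return list(self.parent)

    def is_leaf(self, code) -> bool:
        return code not in self.children

    def ancestors(self, code) -> list:
        out = []
        cur = self.parent.get(code, "")
        while cur:
            out.append(cur)
            cur = self.parent.get(cur, "")
        return out

    def chapter(self, code) -> str:
        anc = self.ancestors(code)
        return anc[-1] if anc else code

    def descendant_leaves(self, code) -> set:
        if self.is_leaf(code):
            return {code}
        out: set = set()
        stack = [code]
        while stack:
            cur = stack.pop()
            kids = self.children.get(cur)
            if not kids:
                out.add(cur)
            else:
                stack.extend(kids)
        return out


@dataclass
class BinaryTrait:
    """A case/control phenotype anchored at a hierarchy node."""

    trait_id: str
    node: str
    chapter: str
    cases: frozenset
    controls: frozenset = frozenset()
    is_union: bool = False
    untestable: bool = False
    reason: Optional[str] = None

    def __post_init__(self):
        overlap = self.cases & self.controls
        if overlap:
            raise ValueError(f"cases and controls overlap: {sorted(overlap)[:5]}")

    def female_fractions(self, sample_sex: dict):
        fc = sum(1 for s in self.cases if sample_sex[s] == "female")
        fk = sum(1 for s in self.controls if sample_sex[s] == "female")
        nc, nk = len(self.cases), len(self.controls)
        return (fc / nc if nc else float("nan"), fk / nk if nk else float("nan"))


@dataclass
class QuantitativeTrait:
    """A per-sample real-valued measurement."""

    trait_id: str
    values: dict

    def __post_init__(self):
        arr = np.asarray(list(self.values.values()), dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError(f"non-finite measurement in trait {self.trait_id}")
        if len(np.unique(arr)) < 2:
            raise ValueError(f"trait {self.trait_id} needs >= 2 distinct values")


def expand_tree_phenotypes(records: pd.DataFrame, hierarchy: Hierarchy) -> list[BinaryTrait]:
    """One trait per recorded leaf plus one per internal node up to the
    chapter root; an internal node's cases are the union of its descendant
    leaves' cases.  Raises on a record code absent from the hierarchy."""
    unknown = sorted(set(records["code"]) - set(hierarchy.parent))
    if unknown:
        raise ValueError(f"phenotype codes absent from hierarchy: {unknown[:10]}")
    cases_by_node: dict = {}
    for sample, code in zip(records["sample_id"], records["code"]):
        cases_by_node.setdefault(code, set()).add(sample)
        for anc in hierarchy.ancestors(code):
            cases_by_node.setdefault(anc, set()).add(sample)
    traits = []
    for node in sorted(cases_by_node):
        traits.append(BinaryTrait(
            trait_id=node, node=node, chapter=hierarchy.chapter(node),
            cases=frozenset(cases_by_node[node])))
    return traits


def chapter_case_sets(records: pd.DataFrame, hierarchy: Hierarchy) -> dict:
    """Samples holding any diagnosis within each chapter."""
    out: dict = {}
    for sample, code in zip(records["sample_id"], records["code"]):
        out.setdefault(hierarchy.chapter(code), set()).add(sample)
    return out


def restrict_chapter_controls(trait: BinaryTrait, chapter_cases: set,
                              all_samples: Iterable) -> BinaryTrait:
    """Controls = all samples minus anyone with a diagnosis in the trait's
    chapter (the trait's own cases are a subset of those)."""
    controls = frozenset(all_samples) - set(chapter_cases) - set(trait.cases)
    return replace(trait, controls=controls)


def build_union_phenotype(member_traits: list[BinaryTrait], mapping_id: str,
                          chapter_cases: set, all_samples: Iterable) -> BinaryTrait:
    """Union phenotype: cases are the union of the member traits' case sets.
    Members must share a chapter; controls are recomputed chapter-restricted."""
    if not member_traits:
        raise ValueError("union phenotype needs at least one member trait")
    chapters = {t.chapter for t in member_traits}
    if len(chapters) > 1:
        raise ValueError(f"union members span multiple chapters: {sorted(chapters)}")
    cases = frozenset().union(*(t.cases for t in member_traits))
    trait = BinaryTrait(trait_id=mapping_id, node=mapping_id,
                        chapter=chapters.pop(), cases=cases, is_union=True)
    return restrict_chapter_controls(trait, chapter_cases, all_samples)


def _trait_rng(seed: int, trait_id: str) -> np.random.Generator:
    # dedicated stream per trait so per-trait results do not depend on the
    # order traits are processed in
    return np.random.default_rng([seed, zlib.crc32(trait_id.encode())])


def sex_match_controls(trait: BinaryTrait, sample_sex: dict, seed: int = 0) -> BinaryTrait:
    """Down-sample controls so their female fraction matches the cases'.

    If the two-sided exact test comparing female fractions (cases vs available
    controls) gives p >= 0.05 the controls are unchanged.  Single-sex traits
    keep only same-sex controls (untestable when none remain).  Otherwise the
    over-represented control sex is down-sampled with a per-trait seeded RNG:
    the target count for females is ``round(kept_males * fF / (1 - fF))`` where
    fF is the case female fraction (symmetrically for males).
    """
    if not trait.cases or not trait.controls:
        raise ValueError("sex matching needs at least one case and one control")
    f_cases = [s for s in trait.cases if sample_sex[s] == "female"]
    m_cases = [s for s in trait.cases if sample_sex[s] != "female"]
    f_ctrl = sorted(s for s in trait.controls if sample_sex[s] == "female")
    m_ctrl = sorted(s for s in trait.controls if sample_sex[s] != "female")
    if not f_cases or not m_cases:
        keep = f_ctrl if not m_cases else m_ctrl
        if not keep:
            return replace(trait, untestable=True,
                           reason="no same-sex controls for sex-specific trait")
        return replace(trait, controls=frozenset(keep))
    p = stats.fisher_exact([[len(f_cases), len(m_cases)],
                            [len(f_ctrl), len(m_ctrl)]]).pvalue
    if p >= 0.05:
        return trait
    fF = len(f_cases) / len(trait.cases)
    rng = _trait_rng(seed, trait.trait_id)
    ctrl_female_frac = len(f_ctrl) / (len(f_ctrl) + len(m_ctrl))
    if ctrl_female_frac > fF:
        target_f = int(round(len(m_ctrl) * fF / (1.0 - fF)))
        target_f = min(target_f, len(f_ctrl))
        f_ctrl = sorted(rng.choice(f_ctrl, size=target_f, replace=False))
    else:
        target_m = int(round(len(f_ctrl) * (1.0 - fF) / fF))
        target_m = min(target_m, len(m_ctrl))
        m_ctrl = sorted(rng.choice(m_ctrl, size=target_m, replace=False))
    return replace(trait, controls=frozenset(f_ctrl) | frozenset(m_ctrl))


def filter_min_cases(traits: list[BinaryTrait], floor: int = MIN_CASES) -> list[BinaryTrait]:
    """Drop traits with fewer than ``floor`` cases."""
    kept = [t for t in traits if len(t.cases) >= floor]
    return kept


def harmonize_binary(records: pd.DataFrame, hierarchy: Hierarchy,
                     samples: pd.DataFrame, unions: Optional[pd.DataFrame] = None,
                     min_cases: int = MIN_CASES, seed: int = 0) -> list[BinaryTrait]:
    """Full binary-trait harmonization pipeline.

    ``unions``, when given, is a two-column table (union_id, member trait_id).
    Returns the testable trait list: hierarchy-expanded (plus unions),
    chapter-restricted controls, sex-matched, >= ``min_cases`` cases and a
    non-empty control set.
    """
    all_samples = set(samples["sample_id"])
    sample_sex = dict(zip(samples["sample_id"], samples["sex"]))
    traits = expand_tree_phenotypes(records, hierarchy)
    by_chapter = chapter_case_sets(records, hierarchy)
    traits = [restrict_chapter_controls(t, by_chapter[t.chapter], all_samples)
              for t in traits]
    if unions is not None:
        by_id = {t.trait_id: t for t in traits}
        for union_id, grp in unions.groupby("union_id"):
            members = [by_id[m] for m in grp["member_trait_id"] if m in by_id]
            if not members:
                continue
            chapter = members[0].chapter
            traits.append(build_union_phenotype(
                members, str(union_id), by_chapter[chapter], all_samples))
    traits = filter_min_cases(traits, min_cases)
    out = []
    for t in traits:
        if not t.controls:
            continue
        t = sex_match_controls(t, sample_sex, seed=seed)
        if t.untestable or not t.controls:
            continue
        out.append(t)
    return out


def quantitative_traits_from_table(measurements: pd.DataFrame) -> list[QuantitativeTrait]:
    """Build quantitative traits from a long table (sample_id, trait_id, value)."""
    out = []
    for trait_id, grp in measurements.groupby("trait_id"):
        out.append(QuantitativeTrait(str(trait_id),
                                     dict(zip(grp["sample_id"], grp["value"]))))
    return out
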