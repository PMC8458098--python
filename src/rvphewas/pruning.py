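"""Sample-set construction: kinship pruning and principal-component filters.

``prune_related`` reproduces the greedy maximal-unrelated-subset rule: among
samples involved in any pair above the kinship threshold, repeatedly remove
the sample with the most relatives above threshold (ties broken
lexicographically by sample id) until no pair remains.  0.0884 is the
conventional KING-scale cut-off for third-degree relatives.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_KINSHIP_THRESHOLD",
    "ANCESTRY_PROBABILITY_FLOORS",
    "prune_related",
    "pc_outlier_filter",
    "ancestry_cohorts",
]

DEFAULT_KINSHIP_THRESHOLD = 0.0884

#: minimum ancestry-prediction probability for inclusion in a per-ancestry cohort
ANCESTRY_PROBABILITY_FLOORS = {"European": 0.99, "default": 0.95}

MIN_ANCESTRY_N = 1000


def prune_related(pairs, threshold: float = DEFAULT_KINSHIP_THRESHOLD) -> set:
    """Greedy removal of related samples.

    ``pairs`` is an iterable of ``(sample_a, sample_b, kinship)`` or a
    DataFrame with those columns.  Returns the set of removed sample ids; the
    remaining samples contain no pair with kinship above ``threshold``.
    """
    if isinstance(pairs, pd.DataFrame):
        pairs = list(zip(pairs["sample_a"], pairs["sample_b"], pairs["kinship"]))
    adj: dict = {}
    for a, b, k in pairs:
        if a != b and k > threshold:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    removed: set = set()
    while True:
        best = None
        for s in adj:
            deg = len(adj[s])
            if deg == 0:
                continue
            if best is None or deg > best[0] or (deg == best[0] and s > best[1]):
                best = (deg, s)
        if best is None:
            break
        _, victim = best
        for other in adj.pop(victim):
            adj[other].discard(victim)
        removed.add(victim)
    return removed


def pc_outlier_filter(pcs: pd.DataFrame, top_k: int = 4, n_sd: float = 4.0) -> set:
    """Retain samples within mean +/- ``n_sd`` standard deviations on each of
    the first ``top_k`` principal components (single pass, inclusive bounds;
    zero-variance components are skipped).

    ``pcs`` needs a ``sample_id`` column and ``pc1..pcK`` columns.
    """
    if len(pcs) < 2:
        raise ValueError("need at least 2 samples")
    keep = np.ones(len(pcs), dtype=bool)
    for k in range(1, top_k + 1):
        v = pcs[f"pc{k}"].to_numpy(float)
        sd = v.std(ddof=0)
        if sd == 0.0:
            continue
        mu = v.mean()
        keep &= np.abs(v - mu) <= n_sd * sd + 1e-12 * sd
    return set(pcs.loc[keep, "sample_id"])


def ancestry_cohorts(samples: pd.DataFrame,
                     min_probability: dict = ANCESTRY_PROBABILITY_FLOORS,
                     min_n: int = MIN_ANCESTRY_N) -> dict:
    """Per-ancestry cohorts meeting the prediction-probability floor; labels
    with fewer than ``min_n`` qualifying samples are excluded entirely.

    ``samples`` needs ``sample_id``, ``ancestry`` and ``ancestry_prob``.
    """
    out: dict = {}
    for label, grp in samples.groupby("ancestry"):
        floor = min_probability.get(str(label), min_probability.get("default", 0.95))
        members = set(grp.loc[grp["ancestry_prob"] >= floor, "sample_id"])
        if len(members) >= min_n:
            out[str(label)] = members
    return out
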