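"""Partition pairwise assembly results into spatial / temporal / replicate
comparison subsets and aggregate process contributions.

Pairwise comparisons within one habitat fall into four categories:

* ``intra_lake``            — same ecosystem, same year, different replicate;
* ``inter_lake_same_year``  — same year, different ecosystems ("spatial");
* ``inter_year_same_lake``  — same ecosystem, different years ("temporal");
* ``other``                 — different ecosystem AND different year; these
  contribute only to the ``all`` subset.

Replicate comparisons never enter the spatial or temporal subsets.  Within a
subset, pairs are grouped by replicate combination ("comparison type",
canonically unordered: A-A, A-B, B-B); process occurrences are converted to
percentages per type, and the mean, SD and 95% CI of each process are taken
across types with equal weight.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd

from ._seeding import substream
from .datasets import SampleFrame
from .exceptions import DataValidationError, ParameterError
from .nullmodels import PROCESS_LABELS

__all__ = [
    "CATEGORIES",
    "categorize_pairs",
    "contributions",
    "subset_permutation_test",
]

CATEGORIES = ("all", "intra_lake", "inter_lake_same_year", "inter_year_same_lake", "other")

#: Processes that enter contribution percentages (degenerate pairs excluded).
CLASSIFIED_PROCESSES = tuple(p for p in PROCESS_LABELS if p != "undetermined")


def _combo(meta_i, meta_j, ordered: bool) -> str:
    """Replicate-combination label for a pair, e.g. ``A-B``.

    Unordered (default): alphabetical, so A-B and B-A coincide.  Ordered:
    samples are first sorted by (ecosystem, year, replicate) and the
    replicate labels read off in that order, giving four types (A-A, A-B,
    B-A, B-B) for a two-replicate design.
    """
    if not ordered:
        a, b = sorted([meta_i["replicate"], meta_j["replicate"]])
        return f"{a}-{b}"
    key_i = (meta_i["ecosystem"], meta_i["year"], meta_i["replicate"])
    key_j = (meta_j["ecosystem"], meta_j["year"], meta_j["replicate"])
    first, second = (meta_i, meta_j) if key_i <= key_j else (meta_j, meta_i)
    return f"{first['replicate']}-{second['replicate']}"


def categorize_pairs(meta: SampleFrame, pairs=None, ordered_combos: bool = False) -> pd.DataFrame:
    """Assign each unordered sample pair its comparison category and type.

    ``pairs`` defaults to all unordered pairs of samples in ``meta``; all
    samples must share one habitat (habitats are analyzed independently).
    """
    df = meta.data
    habitats = set(df["habitat"])
    if len(habitats) > 1:
        raise DataValidationError(
            f"cross-habitat comparison: {sorted(habitats)}; analyze habitats separately"
        )
    if pairs is None:
        ids = list(df.index)
        pairs = list(combinations(ids, 2))
    rows = []
    for sid_i, sid_j in pairs:
        for sid in (sid_i, sid_j):
            if sid not in df.index:
                raise DataValidationError(f"sample {sid!r} missing from metadata")
        mi, mj = df.loc[sid_i], df.loc[sid_j]
        same_eco = mi["ecosystem"] == mj["ecosystem"]
        same_year = mi["year"] == mj["year"]
        if same_eco and same_year:
            category = "intra_lake"
        elif same_year:
            category = "inter_lake_same_year"
        elif same_eco:
            category = "inter_year_same_lake"
        else:
            category = "other"
        rows.append(
            dict(
                sample_i=sid_i,
                sample_j=sid_j,
                category=category,
                replicate_combo=_combo(mi, mj, ordered_combos),
            )
        )
    return pd.DataFrame(rows)


def _subset_mask(categories: pd.Series, subset: str) -> pd.Series:
    if subset == "all":
        return pd.Series(True, index=categories.index)
    if subset not in CATEGORIES:
        raise ParameterError(f"unknown subset {subset!r}; expected one of {CATEGORIES}")
    return categories == subset


def contributions(records: pd.DataFrame, subset: str = "all") -> pd.DataFrame:
    """Process contribution summary for one comparison subset.

    ``records`` must carry ``category``, ``replicate_combo`` and ``process``
    columns (the merge of classified pairs with their categories).  Per
    replicate-combination type, occurrences of each process are converted to
    percentages of that type's classified pairs; the summary reports the
    mean, SD (ddof=1) and normal-approximation 95% CI half-width
    (1.96 * SD / sqrt(n_types)) across types.  Undetermined (degenerate)
    pairs are excluded from the denominators.
    """
    sub = records[_subset_mask(records["category"], subset)]
    sub = sub[sub["process"] != "undetermined"]
    if sub.empty:
        raise DataValidationError(f"no classified pairs in subset {subset!r}")
    types = sorted(sub["replicate_combo"].unique())
    per_type = pd.DataFrame(
        0.0, index=types, columns=list(CLASSIFIED_PROCESSES)
    )
    for t in types:
        chunk = sub[sub["replicate_combo"] == t]
        counts = chunk["process"].value_counts()
        per_type.loc[t] = [100.0 * counts.get(p, 0) / len(chunk) for p in CLASSIFIED_PROCESSES]
    n_types = len(types)
    rows = []
    for p in CLASSIFIED_PROCESSES:
        vals = per_type[p].to_numpy()
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n_types > 1 else 0.0
        ci = 1.96 * sd / math.sqrt(n_types) if n_types > 1 else 0.0
        rows.append(
            dict(
                subset=subset,
                process=p,
                mean_percent=mean,
                sd_percent=sd,
                ci95_halfwidth=ci,
                n_pairs=int(len(sub)),
                n_types=n_types,
                per_type_percent=list(vals),
            )
        )
    return pd.DataFrame(rows)


def subset_permutation_test(
    values_a,
    values_b,
    n_perm: int = 1000,
    seed: int = 0,
    exact_cap: int = 20000,
) -> float:
    """Exact two-sided permutation test for |mean(a) - mean(b)|.

    ``values_a`` / ``values_b`` are the per-comparison-type percentages of one
    process in two subsets.  All group relabelings are enumerated when their
    number is at most ``exact_cap``; otherwise ``n_perm`` Monte-Carlo
    relabelings are drawn.  The observed statistic is always included, so p
    is never 0.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("both groups need at least one value")
    if len(a) + len(b) < 2:
        raise ParameterError("need at least 2 values in total")
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    obs = abs(a.mean() - b.mean())

    n_comb = math.comb(n, na)
    if n_comb <= exact_cap:
        hits = total = 0
        idx = np.arange(n)
        for pick in combinations(idx, na):
            mask = np.zeros(n, dtype=bool)
            mask[list(pick)] = True
            stat = abs(pooled[mask].mean() - pooled[~mask].mean())
            hits += stat >= obs - 1e-12
            total += 1
        return hits / total
    rng = substream(seed, "subset-permutation")
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = abs(perm[:na].mean() - perm[na:].mean())
        hits += stat >= obs - 1e-12
    return (hits + 1) / (n_perm + 1)
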