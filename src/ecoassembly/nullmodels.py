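"""Null-model engine: betaMNTD / betaNTI, Raup-Crick (Bray-Curtis) and the
five-process classifier.

betaMNTD between communities k and m is the abundance-weighted mean cophenetic
distance from each taxon to its nearest relative in the other community::

    betaMNTD(k, m) = 1/2 * [ sum_i f_ik * min_j d_ij  +  sum_j f_jm * min_i d_ij ]

with i over taxa present in k, j over taxa present in m, f the within-sample
relative abundances (or 1/richness when unweighted) and d the cophenetic
distance; a taxon shared by both communities contributes distance 0.

betaNTI standardizes the observed betaMNTD against a null built by shuffling
taxon labels across the tips of the phylogeny (the de-facto standard
randomization for this framework): one label permutation per null replicate,
applied to all sample pairs, so the whole betaMNTD matrix is recomputed under
each permutation.

RCBray compares the observed Bray-Curtis dissimilarity of a pair to nulls in
which each community is rebuilt by (1) drawing its observed richness of taxa
from the pool without replacement with probability proportional to occupancy,
(2) seeding each drawn taxon with one read and distributing the remaining
reads multinomially proportional to pooled relative abundance.  The index is
rescaled to [-1, 1].

Classification thresholds (strict inequalities):

===================  =======================================
betaNTI < -2         homogeneous selection
betaNTI > +2         variable selection
else RCBray > +0.95  dispersal limitation
else RCBray < -0.95  homogenizing dispersal
otherwise            ecological drift
===================  =======================================

Degenerate pairs (null standard deviation ~ 0, e.g. two identical
communities) are labelled ``undetermined`` and excluded downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import skbio

from ._seeding import substream
from .datasets import CommunityTable
from .exceptions import DataValidationError, ParameterError

__all__ = [
    "PROCESS_LABELS",
    "cophenetic_matrix",
    "beta_mntd",
    "beta_nti",
    "raup_crick_bray",
    "classify_process",
    "assembly_analysis",
]

PROCESS_LABELS = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
    "undetermined",
)

DEGENERATE_SD = 1e-12
TIE_TOL = 1e-12


def cophenetic_matrix(tree: skbio.TreeNode, otu_ids: list[str]) -> np.ndarray:
    """Cophenetic (sum of branch length) distances among ``otu_ids``, in order."""
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(otu_ids) - tips)
    if missing:
        raise DataValidationError(f"OTUs absent from tree: {missing[:10]}")
    dm = tree.tip_tip_distances(endpoints=list(otu_ids))
    order = [dm.index(o) for o in otu_ids]
    return dm.data[np.ix_(order, order)]


def _freq_matrix(counts: np.ndarray, weighted: bool) -> np.ndarray:
    sums = counts.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise DataValidationError("empty community encountered")
    if weighted:
        return counts / sums
    presence = (counts > 0).astype(float)
    return presence / presence.sum(axis=1, keepdims=True)


def _nearest_taxon_matrix(dist: np.ndarray, present: list[np.ndarray]) -> np.ndarray:
    """M[s, i] = distance from taxon i to its nearest taxon present in sample s."""
    n_samples = len(present)
    M = np.empty((n_samples, dist.shape[0]))
    for s, idx in enumerate(present):
        M[s] = dist[:, idx].min(axis=1)
    return M


def _beta_mntd_matrix(freq: np.ndarray, dist: np.ndarray, present: list[np.ndarray]) -> np.ndarray:
    half = freq @ _nearest_taxon_matrix(dist, present).T
    return 0.5 * (half + half.T)


def _prepare(table: CommunityTable, tree: skbio.TreeNode, weighted: bool):
    """Drop empty OTU columns, order the cophenetic matrix, list presences."""
    tab = table.drop_empty_otus()
    counts = tab.counts.astype(float)
    dist = cophenetic_matrix(tree, tab.otu_ids)
    freq = _freq_matrix(counts, weighted)
    present = [np.flatnonzero(counts[s] > 0) for s in range(counts.shape[0])]
    return tab, counts, dist, freq, present


def beta_mntd(table: CommunityTable, tree: skbio.TreeNode, weighted: bool = True) -> skbio.DistanceMatrix:
    """Observed betaMNTD for every sample pair, as a distance matrix."""
    tab, _, dist, freq, present = _prepare(table, tree, weighted)
    mat = _beta_mntd_matrix(freq, dist, present)
    np.fill_diagonal(mat, 0.0)
    return skbio.DistanceMatrix(mat, ids=tab.sample_ids)


def beta_nti(
    table: CommunityTable,
    tree: skbio.TreeNode,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> pd.DataFrame:
    """betaNTI for every unordered sample pair.

    One tip-label permutation per null replicate is applied to the pooled
    taxon set (taxa with non-zero counts anywhere in the table) and the full
    betaMNTD matrix recomputed, so nulls are shared across pairs.

    Returns a long-format frame with columns ``sample_i, sample_j,
    beta_mntd_obs, null_mean, null_sd, beta_nti, n_null, degenerate``.
    """
    if n_null < 99:
        raise ParameterError(f"n_null must be >= 99, got {n_null}")
    tab, _, dist, freq, present = _prepare(table, tree, weighted)
    obs = _beta_mntd_matrix(freq, dist, present)
    rng = substream(seed, "beta-nti")
    n_taxa = dist.shape[0]
    acc = np.zeros_like(obs)
    acc2 = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(n_taxa)
        null = _beta_mntd_matrix(freq, dist[np.ix_(perm, perm)], present)
        acc += null
        acc2 += null**2
    mean = acc / n_null
    var = np.maximum(acc2 / n_null - mean**2, 0.0)
    sd = np.sqrt(var * n_null / max(n_null - 1, 1))
    degenerate = sd < DEGENERATE_SD
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = np.where(degenerate, np.nan, (obs - mean) / np.where(degenerate, 1.0, sd))
    ids = tab.sample_ids
    iu, ju = np.triu_indices(len(ids), k=1)
    return pd.DataFrame(
        {
            "sample_i": [ids[i] for i in iu],
            "sample_j": [ids[j] for j in ju],
            "beta_mntd_obs": obs[iu, ju],
            "null_mean": mean[iu, ju],
            "null_sd": sd[iu, ju],
            "beta_nti": bnti[iu, ju],
            "n_null": n_null,
            "degenerate": degenerate[iu, ju],
        }
    )


# ---------------------------------------------------------------------------
# Raup-Crick with Bray-Curtis


def _bray_curtis_pairs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Bray-Curtis between two equally shaped count blocks."""
    num = np.abs(a - b).sum(axis=-1)
    den = (a + b).sum(axis=-1)
    return num / den


def _null_communities(
    richness: int, total: int, occupancy: np.ndarray, pool_p: np.ndarray, n_null: int, rng
) -> np.ndarray:
    """Null count matrix (n_null x n_taxa) for one sample's (richness, total)."""
    n_taxa = occupancy.size
    if richness > n_taxa:
        raise DataValidationError("community richness exceeds pool size")
    # Weighted sampling without replacement via Gumbel-perturbed log-weights.
    keys = np.log(occupancy)[None, :] + rng.gumbel(size=(n_null, n_taxa))
    chosen = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    out = np.zeros((n_null, n_taxa), dtype=np.int64)
    remaining = total - richness
    for r in range(n_null):
        idx = chosen[r]
        p = pool_p[idx]
        psum = p.sum()
        row = np.ones(richness, dtype=np.int64)
        if remaining > 0:
            if psum <= 0:  # drawn taxa all unobserved in the pool: spread evenly
                p = np.full(richness, 1.0 / richness)
            else:
                p = p / psum
            row += rng.multinomial(remaining, p)
        out[r, idx] = row
    return out


def raup_crick_bray(table: CommunityTable, n_null: int = 999, seed: int = 0) -> pd.DataFrame:
    """RCBray for every unordered sample pair.

    The pool is the whole table (intended use: one habitat at a time);
    occupancy and pooled relative abundance are computed on it.  Null
    communities are drawn once per sample (one stream per sample id, keyed by
    the master seed), and replicate r of pair (k, m) compares null community
    r of k against null community r of m — symmetric by construction and
    independent of pair evaluation order.
    """
    if n_null < 99:
        raise ParameterError(f"n_null must be >= 99, got {n_null}")
    tab = table.drop_empty_otus()
    counts = tab.counts
    sums = counts.sum(axis=1)
    if np.any(sums == 0):
        raise DataValidationError("empty community encountered")
    occupancy = (counts > 0).mean(axis=0)
    pool_p = counts.sum(axis=0) / counts.sum()
    ids = tab.sample_ids
    n_samples = len(ids)
    nulls = np.empty((n_samples, n_null, counts.shape[1]), dtype=np.int64)
    for s, sid in enumerate(ids):
        rng = substream(seed, "raup-crick", sid)
        richness = int((counts[s] > 0).sum())
        nulls[s] = _null_communities(richness, int(sums[s]), occupancy, pool_p, n_null, rng)

    rel = counts / sums[:, None]
    rows = []
    for i in range(n_samples):
        for j in range(i + 1, n_samples):
            bc_obs = 0.5 * np.abs(rel[i] - rel[j]).sum()
            bc_null = _bray_curtis_pairs(nulls[i], nulls[j])
            less = int((bc_null < bc_obs - TIE_TOL).sum())
            ties = int((np.abs(bc_null - bc_obs) <= TIE_TOL).sum())
            rc_raw = (less + 0.5 * ties) / n_null
            rows.append((ids[i], ids[j], bc_obs, 2.0 * (rc_raw - 0.5), n_null))
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "bc_obs", "rc_bray", "n_null"])


# ---------------------------------------------------------------------------
# Classification


def classify_process(beta_nti_values, rc_bray_values, degenerate=None):
    """Map (betaNTI, RCBray) pairs to assembly-process labels (vectorized).

    Thresholds are strict: betaNTI exactly +/-2 is not selection and RCBray
    exactly +/-0.95 is drift.
    """
    b = np.asarray(beta_nti_values, dtype=float)
    r = np.asarray(rc_bray_values, dtype=float)
    if b.shape != r.shape:
        raise ParameterError("betaNTI and RCBray inputs differ in length")
    if degenerate is None:
        degenerate = ~np.isfinite(b)
    else:
        degenerate = np.asarray(degenerate, dtype=bool) | ~np.isfinite(b)
    out = np.full(b.shape, "drift", dtype=object)
    out[r > 0.95] = "dispersal_limitation"
    out[r < -0.95] = "homogenizing_dispersal"
    out[b > 2] = "variable_selection"
    out[b < -2] = "homogeneous_selection"
    out[degenerate] = "undetermined"
    return out


def assembly_analysis(
    table: CommunityTable,
    tree: skbio.TreeNode,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> pd.DataFrame:
    """Run betaNTI + RCBray on one (habitat) table and classify every pair.

    Returns one row per unordered sample pair with both indices and the
    assigned process label.
    """
    bnti = beta_nti(table, tree, n_null=n_null, seed=seed, weighted=weighted)
    rc = raup_crick_bray(table, n_null=n_null, seed=seed)
    merged = bnti.merge(rc, on=["sample_i", "sample_j"], suffixes=("", "_rc"))
    if len(merged) != len(bnti):
        raise DataValidationError("betaNTI and RCBray pair sets do not match")
    merged["process"] = classify_process(
        merged["beta_nti"], merged["rc_bray"], merged["degenerate"]
    )
    return merged
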