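"""Phylogenetic-signal prerequisite for the null-model framework.

Before betaNTI is interpretable, differences in taxa's environmental optima
must correlate with phylogenetic distance at least over short distances.
This module estimates per-OTU optima — scores on the first significant
constrained axis of a canonical correspondence analysis (CCA) of abundant
taxa on the environmental variables, or abundance-weighted means as a
fallback — and tests the correlation with a Mantel correlogram over
phylogenetic distance classes with a progressive Bonferroni correction.

Sign convention: correlogram values are reported so that POSITIVE r in a
distance class means taxa in that class are more similar in their optima
than expected (positive phylogenetic autocorrelation), matching the usual
correlogram reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio
from skbio.stats.ordination import cca as _skbio_cca

from ._seeding import substream
from .datasets import CommunityTable
from .exceptions import DataValidationError, ParameterError
from .nullmodels import cophenetic_matrix

__all__ = [
    "filter_abundant",
    "NicheOptima",
    "cca_optima",
    "abundance_weighted_optima",
    "mantel_correlogram",
    "has_short_distance_signal",
]


def filter_abundant(
    table: CommunityTable, threshold: float = 0.01, mode: str = "any_sample"
) -> CommunityTable:
    """Keep OTUs whose within-sample relative abundance exceeds ``threshold``.

    ``any_sample`` (default) requires exceedance in at least one sample;
    ``every_sample`` in all of them.  The comparison is strict ``>``.
    """
    if not 0 < threshold < 1:
        raise ParameterError(f"threshold must be in (0, 1), got {threshold}")
    if mode not in ("any_sample", "every_sample"):
        raise ParameterError(f"unknown mode {mode!r}")
    rel = table.relative_abundance()
    above = rel > threshold
    keep = above.any(axis=0) if mode == "any_sample" else above.all(axis=0)
    kept = list(rel.columns[keep])
    if not kept:
        raise DataValidationError(
            "no OTU passes the abundance filter; lower the threshold or use any_sample mode"
        )
    return table.subset_otus(kept)


@dataclass
class NicheOptima:
    """Per-OTU environmental optima and how they were obtained."""

    optima: pd.Series
    method: str  # "cca_axis1" or "abundance_weighted_mean"
    p_model: float | None = None
    p_axis1: float | None = None
    has_signal_basis: bool = True

    @property
    def otu_ids(self) -> list[str]:
        return list(self.optima.index)


def _cca_first_eigenvalues(Y: pd.DataFrame, X: pd.DataFrame, n_constrained: int):
    res = _skbio_cca(Y, X)
    ev = res.eigvals.to_numpy()
    return res, float(ev[0]), float(ev[:n_constrained].sum())


def cca_optima(
    table: CommunityTable,
    env: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> NicheOptima:
    """OTU scores on the first significant CCA axis of table ~ environment.

    The community table (typically already restricted to abundant taxa) is
    related to the environmental variables by canonical correspondence
    analysis; the model and the first constrained axis are tested by
    permuting sample rows of the environment (``n_perm`` permutations).  If
    the first axis is not significant at ``alpha`` the result carries
    ``has_signal_basis=False`` and empty optima — callers fall back to
    :func:`abundance_weighted_optima` or halt the pipeline.
    """
    if table.data.shape[0] < 2 or table.data.shape[1] < 2:
        raise ParameterError("CCA needs at least 2 samples and 2 OTUs")
    env = env.loc[table.sample_ids]
    if env.isna().any(axis=None):
        raise DataValidationError("environment table contains missing values")
    X = env.astype(float)
    stds = X.std(axis=0)
    const = sorted(stds.index[stds == 0])
    if const:
        raise DataValidationError(f"constant environmental variables: {const}")
    rank = np.linalg.matrix_rank(X.to_numpy() - X.to_numpy().mean(axis=0))
    if rank < X.shape[1]:
        raise DataValidationError(
            f"collinear environmental variables (rank {rank} < {X.shape[1]}): {list(X.columns)}"
        )
    Y = table.data.astype(float)
    Y = Y.loc[:, Y.sum(axis=0) > 0]
    res, ax1_obs, model_obs = _cca_first_eigenvalues(Y, X, rank)

    rng = substream(seed, "cca-permutation")
    hits_ax1 = hits_model = 0
    idx = np.arange(len(X))
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        Xp = pd.DataFrame(X.to_numpy()[perm], index=X.index, columns=X.columns)
        _, ax1_p, model_p = _cca_first_eigenvalues(Y, Xp, rank)
        hits_ax1 += ax1_p >= ax1_obs
        hits_model += model_p >= model_obs
    p_axis1 = (hits_ax1 + 1) / (n_perm + 1)
    p_model = (hits_model + 1) / (n_perm + 1)
    if p_axis1 >= alpha:
        return NicheOptima(
            optima=pd.Series(dtype=float),
            method="cca_axis1",
            p_model=p_model,
            p_axis1=p_axis1,
            has_signal_basis=False,
        )
    scores = res.features.iloc[:, 0]
    scores.index = list(Y.columns)
    return NicheOptima(optima=scores, method="cca_axis1", p_model=p_model, p_axis1=p_axis1)


def abundance_weighted_optima(table: CommunityTable, env: pd.DataFrame) -> NicheOptima:
    """Fallback optima: abundance-weighted mean of the first environmental
    variable over samples, ``opt_i = sum_s p_is env_s / sum_s p_is``."""
    env = env.loc[table.sample_ids]
    x = env.iloc[:, 0].to_numpy(dtype=float)
    rel = table.relative_abundance().to_numpy()
    weights = rel.sum(axis=0)
    if np.any(weights == 0):
        raise DataValidationError("OTU with zero total abundance")
    opt = (rel * x[:, None]).sum(axis=0) / weights
    return NicheOptima(
        optima=pd.Series(opt, index=table.otu_ids), method="abundance_weighted_mean"
    )


# ---------------------------------------------------------------------------
# Mantel correlogram


def mantel_correlogram(
    optima: NicheOptima | pd.Series,
    tree: skbio.TreeNode,
    n_classes: int = 30,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mantel correlogram of optima differences over phylogenetic distance.

    Phylogenetic distances (cophenetic) are cut into ``n_classes`` equal-width
    classes.  For class k the Mantel statistic is the Pearson correlation
    between |opt_i - opt_j| and the class-membership indicator, negated so
    that positive values mean similar optima at that distance.  Two-sided
    permutation p-values (taxa relabelled) receive a progressive Bonferroni
    correction: class k's p is multiplied by k in order of increasing
    distance, and the ``significant`` flag follows the sequential correlogram
    reading — interpretation stops at the first non-significant class.

    Returns a frame with one row per class: ``class_index, midpoint, n_pairs,
    mantel_r, p_raw, p_corrected, significant``.
    """
    if n_classes < 2:
        raise ParameterError(f"n_classes must be >= 2, got {n_classes}")
    opt = optima.optima if isinstance(optima, NicheOptima) else optima
    if len(opt) < 3:
        raise ParameterError("need at least 3 OTUs for a correlogram")
    ids = list(opt.index)
    D = cophenetic_matrix(tree, ids)
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    dphy = D[iu, ju]
    vals = opt.to_numpy(dtype=float)
    dopt_mat = np.abs(vals[:, None] - vals[None, :])
    dopt = dopt_mat[iu, ju]

    lo, hi = dphy.min(), dphy.max()
    if hi <= lo:
        raise DataValidationError("all phylogenetic distances identical")
    edges = np.linspace(lo, hi, n_classes + 1)
    which = np.clip(np.digitize(dphy, edges[1:-1], right=True), 0, n_classes - 1)
    indicators = np.stack([(which == k).astype(float) for k in range(n_classes)])
    midpoints = (edges[:-1] + edges[1:]) / 2

    sy = dopt.std()
    if sy == 0:
        rows = [
            dict(class_index=k + 1, midpoint=midpoints[k], n_pairs=int(indicators[k].sum()),
                 mantel_r=np.nan, p_raw=np.nan, p_corrected=np.nan, significant=False)
            for k in range(n_classes)
        ]
        return pd.DataFrame(rows)

    def class_correlations(d_vec):
        out = np.full(n_classes, np.nan)
        for k in range(n_classes):
            ind = indicators[k]
            if 0 < ind.sum() < len(ind):
                sx = ind.std()
                if sx > 0:
                    c = np.corrcoef(d_vec, ind)[0, 1]
                    out[k] = -c  # negate: positive = similar optima in class
        return out

    r_obs = class_correlations(dopt)
    rng = substream(seed, "mantel-correlogram")
    exceed = np.zeros(n_classes)
    valid = np.zeros(n_classes)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        d_perm = dopt_mat[np.ix_(perm, perm)][iu, ju]
        r_perm = class_correlations(d_perm)
        ok = ~np.isnan(r_perm) & ~np.isnan(r_obs)
        exceed[ok] += np.abs(r_perm[ok]) >= np.abs(r_obs[ok]) - 1e-15
        valid[ok] += 1

    rows = []
    still_significant = True
    for k in range(n_classes):
        n_pairs = int(indicators[k].sum())
        if np.isnan(r_obs[k]) or valid[k] == 0:
            rows.append(dict(class_index=k + 1, midpoint=midpoints[k], n_pairs=n_pairs,
                             mantel_r=np.nan, p_raw=np.nan, p_corrected=np.nan, significant=False))
            still_significant = False
            continue
        p_raw = (exceed[k] + 1) / (valid[k] + 1)
        p_corr = min(1.0, p_raw * (k + 1))
        sig = bool(still_significant and p_corr < alpha)
        if not sig:
            still_significant = False
        rows.append(dict(class_index=k + 1, midpoint=float(midpoints[k]), n_pairs=n_pairs,
                         mantel_r=float(r_obs[k]), p_raw=float(p_raw),
                         p_corrected=float(p_corr), significant=sig))
    return pd.DataFrame(rows)


def has_short_distance_signal(correlogram: pd.DataFrame, n_short: int = 3) -> bool:
    """Gate for the null-model pipeline: is at least one of the ``n_short``
    shortest distance classes significantly positive?"""
    head = correlogram.head(n_short)
    return bool(((head["mantel_r"] > 0) & head["significant"]).any())
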