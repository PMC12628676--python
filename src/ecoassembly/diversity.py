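"""Alpha diversity, Hellinger/Bray-Curtis beta diversity, ordination and the
associated tests: PERMANOVA, multivariate dispersion homogeneity, and
distance-decay regressions against geographic or temporal separation.

All distance matrices are :class:`skbio.DistanceMatrix` objects; community
input is the package's :class:`~ecoassembly.datasets.CommunityTable`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist, squareform
from skbio.stats.ordination import OrdinationResults, pcoa as _skbio_pcoa

from ._seeding import substream
from .datasets import CommunityTable, SampleFrame
from .exceptions import DataValidationError, ParameterError

__all__ = [
    "alpha_diversity",
    "hellinger",
    "bray_curtis",
    "pcoa",
    "PermanovaResult",
    "permanova",
    "DispersionResult",
    "dispersion_homogeneity",
    "geographic_distance",
    "temporal_distance",
    "DecayFit",
    "distance_decay",
]

EARTH_RADIUS_KM = 6371.0


def alpha_diversity(table: CommunityTable) -> pd.DataFrame:
    """Per-sample OTU richness and Shannon entropy (natural log, nats)."""
    counts = table.counts.astype(float)
    sums = counts.sum(axis=1)
    if np.any(sums == 0):
        bad = [s for s, t in zip(table.sample_ids, sums) if t == 0]
        raise DataValidationError(f"zero-sum samples: {bad}")
    p = counts / sums[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return pd.DataFrame(
        {"richness": (counts > 0).sum(axis=1), "shannon": -plogp.sum(axis=1)},
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


def hellinger(table: CommunityTable) -> pd.DataFrame:
    """Hellinger transform: square root of relative abundances.

    Each transformed row has unit sum of squares, which makes Euclidean-based
    ordinations appropriate for abundance data.
    """
    counts = table.counts.astype(float)
    sums = counts.sum(axis=1)
    if np.any(sums == 0):
        raise DataValidationError("zero-sum sample in Hellinger transform")
    return pd.DataFrame(
        np.sqrt(counts / sums[:, None]), index=table.sample_ids, columns=table.otu_ids
    )


def bray_curtis(matrix) -> skbio.DistanceMatrix:
    """Bray-Curtis dissimilarity between rows of a samples x OTUs matrix.

    Accepts a :class:`CommunityTable` or a DataFrame (e.g. Hellinger-
    transformed abundances).
    """
    if isinstance(matrix, CommunityTable):
        matrix = matrix.data
    values = np.asarray(matrix, dtype=float)
    if np.any(values < 0):
        raise DataValidationError("negative values in Bray-Curtis input")
    if np.any(values.sum(axis=1) == 0):
        raise DataValidationError("all-zero row in Bray-Curtis input")
    dm = squareform(pdist(values, metric="braycurtis"))
    return skbio.DistanceMatrix(dm, ids=[str(i) for i in matrix.index])


def pcoa(dist: skbio.DistanceMatrix) -> OrdinationResults:
    """Principal coordinate analysis (classical metric scaling)."""
    if dist.shape[0] < 3:
        raise ParameterError("PCoA needs at least 3 samples")
    return _skbio_pcoa(dist, method="eigh", number_of_dimensions=0)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    factor: str
    R2: float
    F: float
    p_value: float
    n_permutations: int


def _group_ss(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Total and within-group sums of squared distances (Anderson 2001)."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    dist: skbio.DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    factor: str = "group",
) -> PermanovaResult:
    """One-factor PERMANOVA: pseudo-F from within/between squared distances.

    ``R2 = SS_between / SS_total``; the permutation p-value counts the
    observed statistic among the permuted ones, so it is never 0.
    """
    if n_perm < 99:
        raise ParameterError(f"n_perm must be >= 99, got {n_perm}")
    groups = np.asarray(list(groups))
    if len(groups) != dist.shape[0]:
        raise ParameterError("group labels do not match distance matrix size")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ParameterError("PERMANOVA needs at least 2 groups")
    n, a = len(groups), len(uniq)
    d2 = dist.data**2

    def fstat(g):
        ss_t, ss_w = _group_ss(d2, g)
        ss_a = ss_t - ss_w
        if ss_w <= 0:
            return np.inf, ss_a / ss_t if ss_t > 0 else 0.0
        return (ss_a / (a - 1)) / (ss_w / (n - a)), ss_a / ss_t

    f_obs, r2 = fstat(groups)
    rng = substream(seed, "permanova")
    hits = 0
    for _ in range(n_perm):
        f_perm, _ = fstat(rng.permutation(groups))
        if f_perm >= f_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return PermanovaResult(factor=factor, R2=float(r2), F=float(f_obs), p_value=float(p), n_permutations=n_perm)


# ---------------------------------------------------------------------------
# Multivariate dispersion (betadisper-style)


@dataclass
class DispersionResult:
    group_mean_distance: dict
    F: float
    p_value: float
    n_permutations: int


def _distances_to_centroids(dist: skbio.DistanceMatrix, groups: np.ndarray) -> np.ndarray:
    """Per-sample distance to its group centroid in full PCoA space.

    Axes with negative eigenvalues are retained as imaginary coordinates:
    their squared contribution is subtracted (Anderson 2006), and tiny
    negative squared distances from round-off are clipped to zero.
    """
    A = -0.5 * dist.data**2
    n = A.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    evals, evecs = np.linalg.eigh((G + G.T) / 2)
    pos = evals > 1e-10
    neg = evals < -1e-10
    X = evecs[:, pos] * np.sqrt(evals[pos])
    Y = evecs[:, neg] * np.sqrt(-evals[neg])
    z = np.empty(n)
    for g in np.unique(groups):
        idx = groups == g
        cx = X[idx].mean(axis=0)
        cy = Y[idx].mean(axis=0)
        d2 = ((X[idx] - cx) ** 2).sum(axis=1) - ((Y[idx] - cy) ** 2).sum(axis=1)
        z[idx] = np.sqrt(np.clip(d2, 0.0, None))
    return z


def dispersion_homogeneity(
    dist: skbio.DistanceMatrix, groups, n_perm: int = 999, seed: int = 0
) -> DispersionResult:
    """Test homogeneity of multivariate dispersion among groups.

    Distances to group centroids are computed in PCoA space with the
    imaginary-axis correction; the ANOVA F on those distances is compared to
    its distribution under permutation of the distances across groups.
    """
    if n_perm < 99:
        raise ParameterError(f"n_perm must be >= 99, got {n_perm}")
    groups = np.asarray(list(groups))
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ParameterError("dispersion test needs at least 2 groups")
    if np.any(counts < 2):
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ParameterError(f"groups with a single sample have undefined dispersion: {small}")
    z = _distances_to_centroids(dist, groups)

    def anova_f(vals, g):
        grand = vals.mean()
        ss_b = sum(len(vals[g == u]) * (vals[g == u].mean() - grand) ** 2 for u in uniq)
        ss_w = sum(((vals[g == u] - vals[g == u].mean()) ** 2).sum() for u in uniq)
        df_b, df_w = len(uniq) - 1, len(vals) - len(uniq)
        if ss_w <= 0:
            return np.inf if ss_b > 0 else 0.0
        return (ss_b / df_b) / (ss_w / df_w)

    f_obs = anova_f(z, groups)
    rng = substream(seed, "betadisper")
    hits = 0
    for _ in range(n_perm):
        if anova_f(z, rng.permutation(groups)) >= f_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    means = {str(u): float(z[groups == u].mean()) for u in uniq}
    return DispersionResult(group_mean_distance=means, F=float(f_obs), p_value=float(p), n_permutations=n_perm)


# ---------------------------------------------------------------------------
# Geographic / temporal predictors and distance decay


def geographic_distance(meta: SampleFrame) -> skbio.DistanceMatrix:
    """Great-circle (haversine) distances in km between sample coordinates."""
    df = meta.data
    if df[["latitude", "longitude"]].isna().any(axis=None):
        bad = sorted(df.index[df[["latitude", "longitude"]].isna().any(axis=1)])
        raise DataValidationError(f"samples missing coordinates: {bad}")
    lat = np.radians(df["latitude"].to_numpy())
    lon = np.radians(df["longitude"].to_numpy())
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat[:, None]) * np.cos(lat[None, :]) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return skbio.DistanceMatrix(d, ids=list(df.index))


def temporal_distance(meta: SampleFrame) -> skbio.DistanceMatrix:
    """Absolute elapsed days between sampling dates."""
    dates = pd.to_datetime(meta.data["date"])
    days = dates.astype("int64").to_numpy() / 86_400e9
    d = np.abs(days[:, None] - days[None, :])
    return skbio.DistanceMatrix(d, ids=list(meta.data.index))


@dataclass
class DecayFit:
    predictor: str
    slope: float
    intercept: float
    R2: float
    p_value: float
    n_pairs: int
    n_permutations: int


def distance_decay(
    community_dist: skbio.DistanceMatrix,
    predictor_dist: skbio.DistanceMatrix,
    pairs_filter=None,
    n_perm: int = 999,
    seed: int = 0,
    predictor_name: str = "distance",
) -> DecayFit:
    """OLS of community dissimilarity on a predictor distance over sample pairs.

    Significance comes from a Mantel-style permutation of sample identities in
    the predictor matrix (two-sided on the correlation), which respects the
    non-independence of pairwise values.  ``pairs_filter(id_i, id_j) -> bool``
    restricts the regression to a subset of pairs (e.g. same-year inter-lake
    comparisons) while permutations still act on whole samples.
    """
    ids = list(community_dist.ids)
    if list(predictor_dist.ids) != ids:
        predictor_dist = predictor_dist.filter(ids)
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    if pairs_filter is not None:
        keep = np.array([bool(pairs_filter(ids[i], ids[j])) for i, j in zip(iu, ju)])
    else:
        keep = np.ones(len(iu), dtype=bool)
    if keep.sum() < 3:
        raise ParameterError("fewer than 3 retained pairs for distance decay")
    y = community_dist.data[iu, ju][keep]
    X = predictor_dist.data

    def corr_and_fit(xmat):
        x = xmat[iu, ju][keep]
        sx = x.std()
        sy = y.std()
        if sx == 0 or sy == 0:
            return 0.0, 0.0, float(y.mean()), 0.0
        r = float(np.corrcoef(x, y)[0, 1])
        slope = r * sy / sx
        intercept = float(y.mean() - slope * x.mean())
        return r, float(slope), intercept, r**2
    r_obs, slope, intercept, r2 = corr_and_fit(X)

    rng = substream(seed, "distance-decay")
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r_perm = corr_and_fit(X[np.ix_(p, p)])[0]
        if abs(r_perm) >= abs(r_obs) - 1e-15:
            hits += 1
    pval = (hits + 1) / (n_perm + 1)
    return DecayFit(
        predictor=predictor_name,
        slope=slope,
        intercept=intercept,
        R2=float(r2),
        p_value=float(pval),
        n_pairs=int(keep.sum()),
        n_permutations=n_perm,
    )
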