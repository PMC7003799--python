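"""Pairwise community dissimilarity, geographic distance, and distance-decay.

Bray-Curtis captures compositional turnover irrespective of relatedness;
weighted UniFrac weights each branch of a phylogeny by the difference in
relative abundance flowing through it, so shared abundant close relatives
pull it down even when taxon-level overlap is poor.  Distance-decay is
fitted as a Gaussian identity-link GLM of pairwise dissimilarity on pairwise
great-circle distance, the conventional first-pass test for dispersal
limitation across sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from sklearn.metrics.pairwise import haversine_distances

__all__ = [
    "bray_curtis",
    "weighted_unifrac",
    "great_circle_distances",
    "distance_decay_glm",
    "DecayFit",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class DecayFit:
    """A fitted distance-decay relationship over all site pairs.

    ``deviance_explained`` is 1 - residual/null deviance, which for a
    Gaussian identity GLM equals R^2.  ``p_value`` is the Wald p-value of
    the distance slope; ``permutation_p``, when requested, is a Mantel-style
    p-value from permuting site labels of the dissimilarity matrix.
    """

    slope: float
    intercept: float
    deviance_explained: float
    p_value: float
    n_pairs: int
    permutation_p: float | None = None


def _as_matrix(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    counts = table.to_numpy(dtype=float)
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if (counts < 0).any():
        raise ValueError("negative abundances")
    zero = table.index[counts.sum(axis=1) == 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero total abundance")
    return counts, list(table.index.astype(str))


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) between all sample pairs."""
    counts, ids = _as_matrix(table)
    return DistanceMatrix(squareform(pdist(counts, metric="braycurtis"), checks=False), ids)


def weighted_unifrac(
    table: pd.DataFrame, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """Abundance-weighted UniFrac between all sample pairs.

    Raw variant: sum over branches of length * |p - q| where p, q are the
    two samples' proportional abundances descending through the branch.
    The normalized variant divides by sum of length * (p + q), bounding the
    value in [0, 1].
    """
    counts, ids = _as_matrix(table)
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(map(str, table.columns)) - tips)
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    if len(tree.children) > 2:
        # multifurcating root (e.g. a star tree): resolve with zero-length
        # internal edges, which leaves every branch-sum unchanged
        tree = tree.copy()
        tree.bifurcate()
        for node in tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
    return beta_diversity(
        "weighted_unifrac",
        counts,
        ids=ids,
        taxa=list(map(str, table.columns)),
        tree=tree,
        normalized=normalized,
    )


def great_circle_distances(
    geo: pd.DataFrame, radius_km: float = EARTH_RADIUS_KM
) -> DistanceMatrix:
    """Haversine great-circle distances in km between sites.

    ``geo`` is indexed by site with ``latitude``/``longitude`` columns in
    decimal degrees.
    """
    lat = geo["latitude"].to_numpy(dtype=float)
    lon = geo["longitude"].to_numpy(dtype=float)
    if ((lat < -90) | (lat > 90)).any():
        raise ValueError("latitude out of [-90, 90]")
    if ((lon < -180) | (lon > 180)).any():
        raise ValueError("longitude out of [-180, 180]")
    km = haversine_distances(np.radians(np.column_stack([lat, lon]))) * radius_km
    # enforce exact symmetry against floating-point asymmetry
    km = (km + km.T) / 2.0
    np.fill_diagonal(km, 0.0)
    return DistanceMatrix(km, list(geo.index.astype(str)))


def _upper_triangle(dm: DistanceMatrix, order: list[str]) -> np.ndarray:
    data = dm.filter(order).data
    iu = np.triu_indices(len(order), k=1)
    return data[iu]


def distance_decay_glm(
    distance: DistanceMatrix,
    dissimilarity: DistanceMatrix,
    n_permutations: int = 0,
    seed: int = 0,
) -> DecayFit:
    """Gaussian identity GLM of pairwise dissimilarity on distance.

    Pairs are the n(n-1)/2 upper-triangle entries; their non-independence is
    deliberately ignored in the parametric fit (the field's standard usage).
    ``n_permutations > 0`` adds a Mantel-style permutation p-value for the
    slope as a robustness check.
    """
    labels = sorted(distance.ids)
    if sorted(dissimilarity.ids) != labels:
        raise ValueError(
            f"site labels differ: {sorted(distance.ids)} vs {sorted(dissimilarity.ids)}"
        )
    if len(labels) < 3:
        raise ValueError("need at least 3 sites")
    x = _upper_triangle(distance, labels)
    y = _upper_triangle(dissimilarity, labels)
    # Gaussian identity GLM == ordinary least squares; the OLS fit also
    # matches R glm's t-based slope p-value and degrades gracefully when the
    # response is constant
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        return DecayFit(
            slope=0.0,
            intercept=float(y.mean()),
            deviance_explained=0.0,
            p_value=1.0,
            n_pairs=len(y),
            permutation_p=None,
        )
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    de = 1.0 - fit.ssr / sst
    slope = float(fit.params[1])
    perm_p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        n = len(labels)
        mat = dissimilarity.filter(labels).data
        iu = np.triu_indices(n, k=1)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            yp = mat[np.ix_(perm, perm)][iu]
            b = np.polyfit(x, yp, 1)[0]
            if abs(b) >= abs(slope):
                hits += 1
        perm_p = (hits + 1) / (n_permutations + 1)
    return DecayFit(
        slope=slope,
        intercept=float(fit.params[0]),
        deviance_explained=float(de),
        p_value=float(fit.pvalues[1]),
        n_pairs=len(y),
        permutation_p=perm_p,
    )
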