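"""Mean-nearest-taxon statistics and their taxa-shuffle null models.

Within a community, MNTD is the mean over member taxa of the patristic
distance to the closest co-occurring taxon; between two communities, betaMNTD
averages, in both directions, each taxon's distance to its nearest relative
in the other community.  Standardizing the observed statistic against a null
built by shuffling taxon labels across the tips of the phylogeny yields the
nearest-taxon index:

    alphaNTI = -(MNTD_obs - mean(MNTD_null)) / sd(MNTD_null)
    betaNTI  =  (bMNTD_obs - mean(bMNTD_null)) / sd(bMNTD_null)

alphaNTI > 2 indicates taxa more closely related than chance (phylogenetic
clustering, consistent with environmental filtering), alphaNTI < -2
overdispersion; betaNTI < -2 indicates two communities assembled under a
shared filter, betaNTI > 2 divergent ones.  Nulls preserve each community's
richness and abundance vector; only taxon identity is randomized.  The
standard deviation uses the n-1 (sample) convention, and null replicates are
reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "patristic_matrix",
    "mntd",
    "beta_mntd",
    "alpha_nti",
    "beta_nti",
    "index_t_test",
    "classify_structure",
    "NullEnsemble",
    "AlphaNtiResult",
    "BetaNtiResult",
]

DEFAULT_N_NULL = 999
SES_THRESHOLD = 2.0


@dataclass
class NullEnsemble:
    """An observed statistic, its null replicate values, and the z-index."""

    observed: float
    null_values: np.ndarray
    index: float  # NaN when undefined
    undefined_reason: str | None = None

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=1))

    def standardized_null(self, sign: float) -> np.ndarray:
        """Null replicates on the index scale (mean 0, sd 1, signed)."""
        sd = self.null_sd
        if _degenerate(sd, self.null_mean):
            return np.full_like(self.null_values, np.nan)
        return sign * (self.null_values - self.null_mean) / sd


def patristic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip path-length (patristic) distances."""
    return tree.tip_tip_distances()


def _nearest_taxon_mean(
    sub: np.ndarray, weights_row: np.ndarray | None = None
) -> float:
    """Mean (optionally weighted) of per-row minima of an off-diagonal matrix."""
    m = sub.copy()
    np.fill_diagonal(m, np.inf)
    nearest = m.min(axis=1)
    if weights_row is None:
        return float(nearest.mean())
    w = weights_row / weights_row.sum()
    return float((nearest * w).sum())


def mntd(
    community,
    dist: DistanceMatrix,
    abundance_weighted: bool = False,
) -> float:
    """Mean nearest taxon distance of one community.

    ``community`` is either an iterable of taxon ids (unweighted) or a
    mapping/Series taxon -> abundance; taxa with zero abundance are ignored.
    """
    if isinstance(community, (pd.Series, dict)):
        series = pd.Series(community, dtype=float)
        series = series[series > 0]
        taxa = list(series.index)
        weights = series.to_numpy()
    else:
        taxa = list(community)
        weights = None
    if len(taxa) < 2:
        raise ValueError("MNTD undefined for communities with fewer than 2 taxa")
    idx = np.array([dist.index(t) for t in taxa])
    sub = dist.data[np.ix_(idx, idx)]
    if abundance_weighted:
        if weights is None:
            weights = np.ones(len(taxa))
        return _nearest_taxon_mean(sub, weights)
    return _nearest_taxon_mean(sub)


def _beta_mntd_pair(
    d: np.ndarray,
    ia: np.ndarray,
    ib: np.ndarray,
    wa: np.ndarray | None,
    wb: np.ndarray | None,
) -> float:
    """One pair's betaMNTD, following the reference implementation: the
    unweighted form pools all |A|+|B| nearest-taxon distances into a single
    mean; the weighted form averages the two relative-abundance-weighted
    directed means (identical to pooling weights that sum to 1/2 each)."""
    cross = d[np.ix_(ia, ib)]
    na = cross.min(axis=1)
    nb = cross.min(axis=0)
    if wa is None:
        return float((na.sum() + nb.sum()) / (len(na) + len(nb)))
    return 0.5 * float((na * wa / wa.sum()).sum() + (nb * wb / wb.sum()).sum())


def _prepare(table: pd.DataFrame, dist: DistanceMatrix, weighted: bool):
    """Per-sample tip-index arrays and abundance weights against ``dist``."""
    pos = {t: i for i, t in enumerate(dist.ids)}
    missing = sorted(set(map(str, table.columns)) - set(pos))
    if missing:
        raise ValueError(f"taxa missing from distance matrix: {missing}")
    counts = table.to_numpy(dtype=float)
    members, weights = [], []
    for row in counts:
        present = np.flatnonzero(row > 0)
        if len(present) == 0:
            raise ValueError("sample with no taxa present")
        members.append(
            np.array([pos[str(table.columns[j])] for j in present], dtype=np.intp)
        )
        weights.append(row[present] if weighted else None)
    return members, weights


def beta_mntd(
    table: pd.DataFrame,
    tree: TreeNode | DistanceMatrix,
    abundance_weighted: bool = False,
) -> DistanceMatrix:
    """betaMNTD between all sample pairs of a samples x taxa table."""
    dist = tree if isinstance(tree, DistanceMatrix) else patristic_matrix(tree)
    members, weights = _prepare(table, dist, abundance_weighted)
    n = len(members)
    if n < 2:
        raise ValueError("need at least 2 samples")
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            out[a, b] = out[b, a] = _beta_mntd_pair(
                dist.data, members[a], members[b], weights[a], weights[b]
            )
    return DistanceMatrix(out, list(table.index.astype(str)))


def _null_indexer(rng: np.random.Generator, n_tips: int):
    """One taxa-labels shuffle: a random relabelling of tips."""
    return rng.permutation(n_tips)


def _degenerate(sd: float, mean: float) -> bool:
    """Null variance indistinguishable from floating-point noise."""
    return sd <= 1e-12 * max(1.0, abs(mean))


@dataclass
class AlphaNtiResult:
    """Per-sample alphaNTI ensembles plus a tidy summary table."""

    ensembles: dict[str, NullEnsemble]

    def summary(self) -> pd.DataFrame:
        rows = []
        for sample, ens in self.ensembles.items():
            rows.append(
                {
                    "sample": sample,
                    "observed_mntd": ens.observed,
                    "null_mean": ens.null_mean,
                    "null_sd": ens.null_sd,
                    "alpha_nti": ens.index,
                    "classification": classify_structure(ens.index),
                    "undefined_reason": ens.undefined_reason or "",
                }
            )
        return pd.DataFrame(rows).set_index("sample")

    @property
    def indices(self) -> np.ndarray:
        return np.array([e.index for e in self.ensembles.values()])

    def standardized_null_indices(self) -> np.ndarray:
        vals = [e.standardized_null(-1.0) for e in self.ensembles.values()]
        pooled = np.concatenate(vals)
        return pooled[np.isfinite(pooled)]


def alpha_nti(
    table: pd.DataFrame,
    tree: TreeNode | DistanceMatrix,
    n_null: int = DEFAULT_N_NULL,
    abundance_weighted: bool = False,
    seed: int = 0,
) -> AlphaNtiResult:
    """Per-sample nearest taxon index against a taxa-shuffle null.

    Each null replicate shuffles tip labels across the whole phylogeny
    (independently per sample) and recomputes MNTD.  A zero-variance null —
    e.g. a community spanning every tip, or a star tree — yields an
    undefined index flagged explicitly, never coerced to 0.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    dist = tree if isinstance(tree, DistanceMatrix) else patristic_matrix(tree)
    members, weights = _prepare(table, dist, abundance_weighted)
    n_tips = dist.shape[0]
    d = dist.data
    root = np.random.SeedSequence(seed)
    ensembles: dict[str, NullEnsemble] = {}
    for (sample, idx, w), ss in zip(
        zip(table.index.astype(str), members, weights), root.spawn(len(members))
    ):
        if len(idx) < 2:
            raise ValueError(f"sample {sample!r} has fewer than 2 taxa")
        sub = d[np.ix_(idx, idx)]
        observed = _nearest_taxon_mean(sub, w)
        rng = np.random.default_rng(ss)
        nulls = np.empty(n_null)
        for r in range(n_null):
            perm = _null_indexer(rng, n_tips)
            pidx = perm[idx]
            nulls[r] = _nearest_taxon_mean(d[np.ix_(pidx, pidx)], w)
        sd = np.std(nulls, ddof=1)
        if _degenerate(sd, nulls.mean()):
            ens = NullEnsemble(observed, nulls, np.nan, "zero null variance")
        else:
            ens = NullEnsemble(observed, nulls, float(-(observed - nulls.mean()) / sd))
        ensembles[sample] = ens
    return AlphaNtiResult(ensembles)


@dataclass
class BetaNtiResult:
    """Pairwise betaNTI with observed/null summaries.

    ``index`` is a symmetric DataFrame with NaN on the diagonal and at
    undefined pairs; ``undefined`` marks pairs whose null had zero variance.
    """

    observed: pd.DataFrame
    index: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    undefined: pd.DataFrame
    null_values: np.ndarray = field(repr=False)  # (n_null, n, n)

    @property
    def pair_indices(self) -> np.ndarray:
        """Upper-triangle betaNTI values (finite only)."""
        iu = np.triu_indices(self.index.shape[0], k=1)
        vals = self.index.to_numpy()[iu]
        return vals[np.isfinite(vals)]

    def standardized_null_indices(self) -> np.ndarray:
        n = self.index.shape[0]
        iu = np.triu_indices(n, k=1)
        mu = self.null_mean.to_numpy()[iu]
        sd = self.null_sd.to_numpy()[iu]
        ok = sd > 1e-12 * np.maximum(1.0, np.abs(mu))
        z = (self.null_values[:, iu[0], iu[1]][:, ok] - mu[ok]) / sd[ok]
        return z.ravel()

    def summary(self) -> pd.DataFrame:
        labels = list(self.index.index)
        rows = []
        for a in range(len(labels)):
            for b in range(a + 1, len(labels)):
                rows.append(
                    {
                        "sample_a": labels[a],
                        "sample_b": labels[b],
                        "observed_bmntd": self.observed.iat[a, b],
                        "null_mean": self.null_mean.iat[a, b],
                        "null_sd": self.null_sd.iat[a, b],
                        "beta_nti": self.index.iat[a, b],
                        "classification": classify_structure(
                            self.index.iat[a, b], between=True
                        ),
                        "undefined": bool(self.undefined.iat[a, b]),
                    }
                )
        return pd.DataFrame(rows)


def beta_nti(
    table: pd.DataFrame,
    tree: TreeNode | DistanceMatrix,
    n_null: int = DEFAULT_N_NULL,
    abundance_weighted: bool = False,
    seed: int = 0,
) -> BetaNtiResult:
    """Pairwise betaNTI with a shared taxa-shuffle null.

    Each replicate draws one permutation of tip labels over the full
    phylogeny and recomputes betaMNTD for every sample pair, so all pairs of
    a replicate see the same randomized tree.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    dist = tree if isinstance(tree, DistanceMatrix) else patristic_matrix(tree)
    members, weights = _prepare(table, dist, abundance_weighted)
    labels = list(table.index.astype(str))
    n = len(members)
    if n < 2:
        raise ValueError("need at least 2 samples")
    d = dist.data
    n_tips = dist.shape[0]

    def all_pairs(member_idx: list[np.ndarray]) -> np.ndarray:
        out = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                out[a, b] = out[b, a] = _beta_mntd_pair(
                    d, member_idx[a], member_idx[b], weights[a], weights[b]
                )
        return out

    observed = all_pairs(members)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    null_values = np.empty((n_null, n, n))
    for r in range(n_null):
        perm = _null_indexer(rng, n_tips)
        null_values[r] = all_pairs([perm[idx] for idx in members])
    mu = null_values.mean(axis=0)
    sd = null_values.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        index = (observed - mu) / sd
    undefined = sd <= 1e-12 * np.maximum(1.0, np.abs(mu))
    index[undefined] = np.nan
    np.fill_diagonal(index, np.nan)
    np.fill_diagonal(undefined, False)

    def frame(arr):
        return pd.DataFrame(arr, index=labels, columns=labels)

    return BetaNtiResult(
        observed=frame(observed),
        index=frame(index),
        null_mean=frame(mu),
        null_sd=frame(sd),
        undefined=frame(undefined),
        null_values=null_values,
    )


def index_t_test(
    indices: np.ndarray, null_indices: np.ndarray, equal_var: bool = False
) -> tuple[float, float]:
    """Welch two-sample t-test of observed indices against null indices.

    Returns (t, two-sided p).  ``equal_var=True`` switches to the pooled
    variance (Student) form.
    """
    a = np.asarray(indices, dtype=float)
    b = np.asarray(null_indices, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 finite values per sample")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def classify_structure(
    index: float, threshold: float = SES_THRESHOLD, between: bool = False
) -> str:
    """Map an NTI-type index onto the conventional +-2 categories.

    Within communities (alphaNTI): > +2 clustered, < -2 overdispersed.
    Between communities (betaNTI, ``between=True``): < -2 means more related
    than chance (labelled clustered), > +2 less related (overdispersed).
    Boundaries are strict; NaN propagates as "undefined".
    """
    if index is None or not np.isfinite(index):
        return "undefined"
    hi = index > threshold
    lo = index < -threshold
    if between:
        hi, lo = lo, hi
    if hi:
        return "clustered"
    if lo:
        return "overdispersed"
    return "random"
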