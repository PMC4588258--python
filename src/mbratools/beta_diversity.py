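"""Pairwise community dissimilarity, ordination, and permutation tests.

Two dissimilarity measures are used throughout: Bray-Curtis (abundance
weighted, computed on untransformed counts) and Sorenson (its
presence/absence analog, i.e. Bray-Curtis on binarized vectors).  Both are
computed after a single rarefaction of all samples to a common depth.
Group differences are tested with ANOSIM (rank-based R statistic) and
PERMANOVA (pseudo-F partitioning squared dissimilarities), each with
permutation p-values; ordination is non-metric multidimensional scaling
minimizing Kruskal stress-1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.manifold import MDS

from .errors import InsufficientDataError
from .otu_io import OtuTable, subsample

METRICS = ("bray_curtis", "sorenson")


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x_i - y_i| / sum(x_i + y_i)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and the same length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative abundances")
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("zero-sum abundance vector")
    return float(np.abs(x - y).sum() / (x + y).sum())


def sorenson(x, y) -> float:
    """Sorenson dissimilarity 1 - 2C/(S_x + S_y) on presence/absence.

    C is the number of OTUs present (count >= 1) in both samples; equals
    Bray-Curtis on the binarized vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and the same length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative abundances")
    sx = np.count_nonzero(x > 0)
    sy = np.count_nonzero(y > 0)
    if sx == 0 or sy == 0:
        raise ValueError("zero-sum abundance vector")
    shared = int(np.count_nonzero((x > 0) & (y > 0)))
    return 1.0 - 2.0 * shared / (sx + sy)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with sample labels."""

    ids: list[str]
    data: np.ndarray
    metric: str
    depth: int | None = None
    seed: object = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.data, self.data.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.data < -1e-12).any() or (self.data > 1 + 1e-12).any():
            raise ValueError("dissimilarities must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.ids)}

    def between(self, a: str, b: str) -> float:
        return float(self.data[self._index[a], self._index[b]])

    def submatrix(self, sample_ids) -> "DistanceMatrix":
        idx = [self._index[s] for s in sample_ids]
        return DistanceMatrix(
            list(sample_ids), self.data[np.ix_(idx, idx)], self.metric,
            self.depth, self.seed,
        )

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        """Square-matrix TSV with a header row and label column."""
        self.to_dataframe().to_csv(
            path, sep="\t", float_format="%.6g", index_label="sample",
            lineterminator="\n",
        )

    @classmethod
    def read_tsv(cls, path, metric: str = "bray_curtis") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(), metric)


def distance_matrix(
    table: OtuTable, metric: str = "bray_curtis", depth: int = 10_000, seed=None
) -> DistanceMatrix:
    """All pairwise dissimilarities after a single rarefaction to ``depth``."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    sub = subsample(table, depth, seed)
    if sub.n_samples < 2:
        raise InsufficientDataError(
            f"need >= 2 samples at depth {depth}, got {sub.n_samples}"
        )
    x = sub.counts.to_numpy(dtype=float)
    if metric == "sorenson":
        x = (x > 0).astype(float)
    data = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(sub.sample_ids, data, metric, depth=depth, seed=seed)


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame  # index = sample, columns axis1..axisK
    stress: float  # Kruskal stress-1 of the best restart

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# stress\t{self.stress:.6g}\n")
            self.coordinates.to_csv(
                fh, sep="\t", float_format="%.6g", index_label="sample",
                lineterminator="\n",
            )


def nmds(
    dm: DistanceMatrix, dimensions: int = 2, restarts: int = 20, seed=None
) -> NmdsResult:
    """Non-metric MDS of a dissimilarity matrix (best of ``restarts`` starts).

    Minimizes Kruskal stress-1 via SMACOF with isotonic regression of
    configuration distances on the dissimilarity ranks.
    """
    if dimensions < 1:
        raise ValueError("dimensions must be >= 1")
    if not dm.data.any():
        raise ValueError("degenerate distance matrix (all zeros)")
    rs = np.random.default_rng(seed).integers(0, 2**31 - 1)
    model = MDS(
        n_components=dimensions,
        metric="precomputed",
        metric_mds=False,
        init="random",
        n_init=restarts,
        max_iter=300,
        eps=1e-6,
        random_state=int(rs),
        normalized_stress=True,
    )
    coords = model.fit_transform(dm.data)
    cols = [f"axis{k + 1}" for k in range(dimensions)]
    return NmdsResult(
        pd.DataFrame(coords, index=dm.ids, columns=cols), float(model.stress_)
    )


@dataclass
class PermutationTestResult:
    statistic_name: str  # "ANOSIM_R" or "PERMANOVA_F"
    statistic: float
    p_value: float
    permutations: int
    r_squared: float | None = None
    seed: object = None


def _group_codes(groups) -> np.ndarray:
    g = np.asarray(groups)
    _, codes = np.unique(g, return_inverse=True)
    counts = np.bincount(codes)
    if len(counts) < 2:
        raise InsufficientDataError("need >= 2 groups")
    if (counts < 2).any():
        raise InsufficientDataError("every group needs >= 2 samples")
    return codes


def _iter_permutations(codes: np.ndarray, permutations, rng):
    """Yield permuted group-code arrays.

    ``permutations="exhaustive"`` enumerates every distinct assignment of the
    label multiset to positions (the observed assignment included);
    otherwise yields ``permutations`` uniform random shuffles.
    """
    if permutations == "exhaustive":
        seen = set()
        for perm in itertools.permutations(codes.tolist()):
            if perm not in seen:
                seen.add(perm)
                yield np.asarray(perm)
    else:
        for _ in range(int(permutations)):
            yield rng.permutation(codes)


def _anosim_r(rank_sq: np.ndarray, codes: np.ndarray, iu) -> float:
    within = (codes[:, None] == codes[None, :])[iu]
    ranks = rank_sq[iu]
    m = ranks.size
    return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2.0))


def anosim(
    dm: DistanceMatrix, groups, permutations=999, seed=None
) -> PermutationTestResult:
    """ANOSIM: rank-based test of between- vs within-group dissimilarity.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 and mid-ranks for ties; R near 1 means groups are well
    separated, near 0 means no structure.  The p-value is the fraction of
    label permutations with R at least as large as observed, using the
    (1+b)/(1+m) estimator in random mode (never reports p = 0) and the
    exact enumeration fraction with ``permutations="exhaustive"``.
    """
    codes = _group_codes(groups)
    n = len(dm.ids)
    if len(codes) != n:
        raise ValueError("groups length does not match distance matrix")
    iu = np.triu_indices(n, k=1)
    rank_sq = squareform(rankdata(dm.condensed(), method="average"), checks=False)
    observed = _anosim_r(rank_sq, codes, iu)
    rng = np.random.default_rng(seed)
    hits = 0
    total = 0
    for perm in _iter_permutations(codes, permutations, rng):
        total += 1
        if _anosim_r(rank_sq, perm, iu) >= observed - 1e-12:
            hits += 1
    if permutations == "exhaustive":
        p = hits / total
    else:
        p = (1 + hits) / (1 + total)
    return PermutationTestResult("ANOSIM_R", observed, p, total, seed=seed)


def _permanova_f(d2_pairs: np.ndarray, pi, pj, codes: np.ndarray, n: int, a: int):
    ss_total = d2_pairs.sum() / n
    group_counts = np.bincount(codes, minlength=a)
    gi, gj = codes[pi], codes[pj]
    same = gi == gj
    ss_within = 0.0
    for g in range(a):
        ss_within += d2_pairs[same & (gi == g)].sum() / group_counts[g]
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return float(f), float(ss_between / ss_total)


def permanova(
    dm: DistanceMatrix, groups, permutations=999, seed=None
) -> PermutationTestResult:
    """PERMANOVA: pseudo-F test on squared dissimilarities.

    Uses the distance (Gower) formulation — SS_total = (1/N) sum_{i<j} d_ij^2,
    SS_within summed per group with its own 1/n_g — which is exact for
    non-Euclidean dissimilarities and avoids explicit centroids.  R^2 =
    SS_between / SS_total; p-values as in :func:`anosim`.
    """
    codes = _group_codes(groups)
    n = len(dm.ids)
    if len(codes) != n:
        raise ValueError("groups length does not match distance matrix")
    a = int(codes.max()) + 1
    pi, pj = np.triu_indices(n, k=1)
    d2_pairs = (dm.data**2)[pi, pj]
    observed, r2 = _permanova_f(d2_pairs, pi, pj, codes, n, a)
    rng = np.random.default_rng(seed)
    hits = 0
    total = 0
    for perm in _iter_permutations(codes, permutations, rng):
        total += 1
        f_perm, _ = _permanova_f(d2_pairs, pi, pj, perm, n, a)
        if f_perm >= observed - 1e-12:
            hits += 1
    if permutations == "exhaustive":
        p = hits / total
    else:
        p = (1 + hits) / (1 + total)
    return PermutationTestResult(
        "PERMANOVA_F", observed, p, total, r_squared=r2, seed=seed
    )


def similarity_partition(
    dm: DistanceMatrix, metadata: pd.DataFrame, day_range=range(8, 22)
) -> pd.DataFrame:
    """Partition pairwise similarities by relationship between the samples.

    For reactor samples within ``day_range``, every pair is classed as
    ``within_vessel`` (same vessel, different days), ``between_replicates``
    (same donor, different vessels), or ``between_types`` (different
    donors).  Returns mean +/- SD similarity (1 - dissimilarity) per donor
    and comparison class — the replicate-variation summary of the analysis.
    """
    days = set(day_range)
    keep = [
        s
        for s in dm.ids
        if metadata.loc[s, "sample_class"] == "reactor"
        and int(metadata.loc[s, "day"]) in days
    ]
    sub = dm.submatrix(keep)
    donors = metadata.loc[keep, "donor"].to_numpy()
    vessels = metadata.loc[keep, "vessel"].to_numpy()
    sims: dict[tuple, list[float]] = {}
    n = len(keep)
    for i in range(n):
        for j in range(i + 1, n):
            s = 1.0 - sub.data[i, j]
            if vessels[i] == vessels[j]:
                key = (donors[i], "within_vessel", donors[i])
                sims.setdefault(key, []).append(s)
            elif donors[i] == donors[j]:
                key = (donors[i], "between_replicates", donors[i])
                sims.setdefault(key, []).append(s)
            else:
                a, b = sorted((str(donors[i]), str(donors[j])))
                sims.setdefault((a, "between_types", b), []).append(s)
                sims.setdefault((b, "between_types", a), []).append(s)
    records = []
    for (donor, comparison, other), values in sorted(sims.items()):
        v = np.asarray(values)
        records.append(
            {
                "reactor_type": donor,
                "comparison": comparison,
                "other_type": other,
                "mean_similarity": float(v.mean()),
                "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                "n_pairs": len(v),
            }
        )
    return pd.DataFrame(records)
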