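"""Alpha/beta diversity, rarefaction, UPGMA zoning and PCoA for OTU tables.

The estimators follow the mothur conventions used throughout the 16S
literature: Good's coverage 1 - n1/N, bias-corrected Chao1, Shannon with
natural logarithms, the unbiased (without-replacement) inverse Simpson,
incidence-based Jaccard ("jclass") and the abundance-based Yue-Clayton
theta dissimilarity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class SampleInfo:
    """Site and depth interval (cm) of one core section."""

    site: str
    depth_top_cm: float
    depth_bottom_cm: float

    @property
    def depth_mid_cm(self) -> float:
        return 0.5 * (self.depth_top_cm + self.depth_bottom_cm)


@dataclass
class OtuTable:
    """Samples x OTUs count matrix with taxonomy lineages and sample metadata."""

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] = field(default_factory=dict)
    metadata: dict[str, SampleInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise InvalidInputError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise InvalidInputError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise InvalidInputError("counts must be non-negative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InvalidInputError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise InvalidInputError("duplicate OTU ids")
        unknown = set(self.taxonomy) - set(self.otu_ids)
        if unknown:
            raise InvalidInputError(f"taxonomy for unknown OTUs: {sorted(unknown)[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_ids.index(sample_id)]

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)


@dataclass(frozen=True)
class DiversityRecord:
    """Alpha-diversity summary of one sample at a fixed rarefaction depth.

    Point estimates are means over repeated rarefactions; ``ci95`` maps each
    index name to its 2.5/97.5 percentile interval across rarefactions.
    """

    sample_id: str
    depth_used: int
    goods_coverage: float
    chao1: float
    shannon: float
    inv_simpson: float
    evenness: float
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix in [0, 1] with zero diagonal."""

    labels: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if self.data.shape != (n, n):
            raise InvalidInputError("distance matrix shape does not match labels")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise InvalidInputError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise InvalidInputError("distance matrix diagonal not zero")
        if (self.data < -1e-12).any() or (self.data > 1 + 1e-12).any():
            raise InvalidInputError("distances outside [0, 1]")

    def get(self, a: str, b: str) -> float:
        return float(self.data[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# rarefaction

def _rarefy_vector(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample one sample's counts to ``depth`` reads without replacement."""
    total = int(counts.sum())
    if total == depth:
        return counts.copy()
    reads = np.repeat(np.arange(counts.size), counts)
    keep = rng.choice(reads, size=depth, replace=False)
    return np.bincount(keep, minlength=counts.size)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Rarefy every sample to exactly ``depth`` reads (without replacement).

    Samples with fewer than ``depth`` reads are dropped with a logged
    warning.  Deterministic for a fixed seed.
    """
    if depth <= 0:
        raise InvalidInputError("rarefaction depth must be > 0")
    rng = np.random.default_rng(seed)
    keep_rows, new_counts = [], []
    for i, sid in enumerate(table.sample_ids):
        total = int(table.counts[i].sum())
        if total < depth:
            logger.warning("dropping sample %s: %d reads < depth %d", sid, total, depth)
            continue
        keep_rows.append(sid)
        new_counts.append(_rarefy_vector(table.counts[i], depth, rng))
    counts = np.array(new_counts, dtype=np.int64) if new_counts else np.zeros((0, len(table.otu_ids)), dtype=np.int64)
    return OtuTable(
        sample_ids=keep_rows,
        otu_ids=list(table.otu_ids),
        counts=counts,
        taxonomy=dict(table.taxonomy),
        metadata={s: table.metadata[s] for s in keep_rows if s in table.metadata},
    )


# ---------------------------------------------------------------------------
# alpha diversity

def _clean(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.ndim != 1:
        raise InvalidInputError("expected a 1-d count vector")
    return c[c > 0]


def goods_coverage(counts) -> float:
    """Good's coverage 1 - n1/N: estimated fraction of the community sampled."""
    c = _clean(counts)
    n = c.sum()
    if n == 0:
        raise InvalidInputError("empty sample")
    return 1.0 - (c == 1).sum() / n


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + n1(n1-1) / (2(n2+1))."""
    c = _clean(counts)
    if c.sum() == 0:
        raise InvalidInputError("empty sample")
    s_obs = c.size
    n1 = int((c == 1).sum())
    n2 = int((c == 2).sum())
    return s_obs + n1 * (n1 - 1) / (2.0 * (n2 + 1))


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log)."""
    c = _clean(counts)
    if c.sum() == 0:
        raise InvalidInputError("empty sample")
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def inv_simpson(counts) -> float:
    """Unbiased inverse Simpson 1 / [sum n_i(n_i-1) / (N(N-1))].

    Undefined (NaN) when every OTU is a singleton: no two reads can then
    share an OTU and the estimator's denominator vanishes.
    """
    c = _clean(counts)
    n = int(c.sum())
    if n == 0:
        raise InvalidInputError("empty sample")
    num = (c * (c - 1)).sum()
    if num == 0:
        return float("nan")
    return float(n * (n - 1) / num)


def simpson_evenness(counts) -> float:
    """Simpson evenness (1 / sum p_i^2) / S_obs, plug-in estimator, in (0, 1]."""
    c = _clean(counts)
    n = c.sum()
    if n == 0:
        raise InvalidInputError("empty sample")
    p = c / n
    return float((1.0 / (p * p).sum()) / c.size)


_ALPHA_FUNCS = {
    "goods_coverage": goods_coverage,
    "chao1": chao1,
    "shannon": shannon,
    "inv_simpson": inv_simpson,
    "evenness": simpson_evenness,
}


def alpha_with_ci(
    table: OtuTable,
    depth: int,
    n_iter: int = 1000,
    seed: int = 0,
) -> list[DiversityRecord]:
    """Alpha indices with 95% CIs over ``n_iter`` independent rarefactions.

    Point estimates are means across rarefactions; CIs are the 2.5th/97.5th
    percentiles.  NaN draws of the inverse Simpson (all-singleton draws) are
    excluded from its mean and CI.
    """
    if depth <= 0 or n_iter <= 0:
        raise InvalidInputError("depth and n_iter must be > 0")
    rng = np.random.default_rng(seed)
    records = []
    for i, sid in enumerate(table.sample_ids):
        total = int(table.counts[i].sum())
        if total < depth:
            logger.warning("dropping sample %s: %d reads < depth %d", sid, total, depth)
            continue
        draws: dict[str, list[float]] = {k: [] for k in _ALPHA_FUNCS}
        for _ in range(n_iter):
            vec = _rarefy_vector(table.counts[i], depth, rng)
            for name, func in _ALPHA_FUNCS.items():
                draws[name].append(func(vec))
        point, ci = {}, {}
        for name, values in draws.items():
            arr = np.asarray(values, dtype=float)
            arr = arr[~np.isnan(arr)]
            if arr.size == 0:
                point[name], ci[name] = float("nan"), (float("nan"), float("nan"))
            else:
                point[name] = float(arr.mean())
                ci[name] = (
                    float(np.percentile(arr, 2.5)),
                    float(np.percentile(arr, 97.5)),
                )
        records.append(
            DiversityRecord(
                sample_id=sid,
                depth_used=depth,
                goods_coverage=point["goods_coverage"],
                chao1=point["chao1"],
                shannon=point["shannon"],
                inv_simpson=point["inv_simpson"],
                evenness=point["evenness"],
                ci95=ci,
            )
        )
    return records


def diversity_frame(records: list[DiversityRecord]) -> pd.DataFrame:
    """Tidy DataFrame of diversity records, one row per sample."""
    rows = []
    for r in records:
        row = {
            "sample": r.sample_id,
            "depth_used": r.depth_used,
            "goods_coverage": r.goods_coverage,
            "chao1": r.chao1,
            "shannon": r.shannon,
            "inv_simpson": r.inv_simpson,
            "evenness": r.evenness,
        }
        for name, (lo, hi) in r.ci95.items():
            row[f"{name}_ci_low"] = lo
            row[f"{name}_ci_high"] = hi
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# beta diversity

def jaccard_distance(a, b) -> float:
    """Incidence-based Jaccard dissimilarity 1 - |shared| / |either|."""
    pa = np.asarray(a) > 0
    pb = np.asarray(b) > 0
    either = (pa | pb).sum()
    if either == 0:
        return 0.0
    return 1.0 - (pa & pb).sum() / either


def yue_clayton_distance(a, b) -> float:
    """Yue-Clayton dissimilarity 1 - theta on relative abundances.

    theta = sum(p q) / (sum p^2 + sum q^2 - sum(p q)); theta is 1 for
    identical compositions and 0 for disjoint ones.
    """
    p = np.asarray(a, dtype=float)
    q = np.asarray(b, dtype=float)
    if p.sum() == 0 or q.sum() == 0:
        raise InvalidInputError("empty sample in distance computation")
    p = p / p.sum()
    q = q / q.sum()
    cross = (p * q).sum()
    denom = (p * p).sum() + (q * q).sum() - cross
    return 1.0 - cross / denom


_BETA_FUNCS = {"jaccard": jaccard_distance, "yue_clayton": yue_clayton_distance}


def distance_matrix(table: OtuTable, metric: str = "jaccard") -> DistanceMatrix:
    """All-pairs dissimilarity matrix for the samples of an OTU table."""
    try:
        func = _BETA_FUNCS[metric]
    except KeyError:
        raise InvalidInputError(f"unknown beta-diversity metric {metric!r}") from None
    n = table.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = func(table.counts[i], table.counts[j])
    return DistanceMatrix(labels=list(table.sample_ids), data=d)


# ---------------------------------------------------------------------------
# UPGMA

@dataclass(frozen=True)
class ClusterNode:
    """Node of a rooted ultrametric (UPGMA) tree; height is half the merge distance."""

    height: float
    leaves: tuple[str, ...]
    children: tuple["ClusterNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def to_newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf:
            return self.leaves[0]
        parts = [
            f"{c._newick_inner()}:{self.height - c.height:.10g}" for c in self.children
        ]
        return "(" + ",".join(parts) + ")"

    def cophenetic(self, a: str, b: str) -> float:
        """Tree distance between two leaves: twice the height of their LCA."""
        if a == b:
            return 0.0
        node = self
        while True:
            child = next((c for c in node.children if a in c.leaves and b in c.leaves), None)
            if child is None:
                return 2.0 * node.height
            node = child


def upgma(dist: DistanceMatrix) -> ClusterNode:
    """Average-linkage (UPGMA) agglomeration of a dissimilarity matrix.

    Cluster-to-cluster distance is the unweighted mean over all cross-cluster
    leaf pairs; node heights are half the merge distance, so the tree is
    ultrametric.  Ties are broken by the lexicographically smallest pair of
    (sorted) leaf-label tuples, making the merge order deterministic.
    """
    if len(dist.labels) == 0:
        raise InvalidInputError("empty distance matrix")
    idx = {lab: i for i, lab in enumerate(dist.labels)}
    active: list[ClusterNode] = [
        ClusterNode(height=0.0, leaves=(lab,)) for lab in sorted(dist.labels)
    ]

    def mean_dist(x: ClusterNode, y: ClusterNode) -> float:
        rows = [idx[a] for a in x.leaves]
        cols = [idx[b] for b in y.leaves]
        return float(dist.data[np.ix_(rows, cols)].mean())

    while len(active) > 1:
        best = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                a, b = active[i], active[j]
                key = (mean_dist(a, b), *sorted((a.leaves, b.leaves)))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, *_), i, j = best
        a, b = active[j], active[i]  # pop j first (j > i)
        active.pop(j)
        active.pop(i)
        children = tuple(sorted((a, b), key=lambda n: n.leaves))
        merged = ClusterNode(
            height=d / 2.0,
            leaves=tuple(sorted(a.leaves + b.leaves)),
            children=children,
        )
        active.append(merged)
    return active[0]


def cut_tree(root: ClusterNode, k: int) -> list[tuple[str, ...]]:
    """Cut an ultrametric tree into exactly ``k`` clusters of leaf labels.

    Splits the highest internal node repeatedly; equivalent to cutting at the
    height between the (n-k)th and (n-k+1)th merges.
    """
    n_leaves = len(root.leaves)
    if not 1 <= k <= n_leaves:
        raise InvalidInputError(f"k must be in [1, {n_leaves}]")
    clusters = [root]
    while len(clusters) < k:
        splittable = [c for c in clusters if not c.is_leaf]
        top = max(splittable, key=lambda c: (c.height, c.leaves))
        clusters.remove(top)
        clusters.extend(top.children)
    return sorted(c.leaves for c in clusters)


def zone_cut(
    root: ClusterNode,
    k: int,
    depths: dict[str, float] | None = None,
) -> dict[str, str]:
    """Assign each sample to one of ``k`` zones cut from a UPGMA tree.

    Zone labels ("Zone 1" ... "Zone k") are assigned in order of each
    cluster's mean sample depth (``depths`` maps sample id to depth, cm);
    without depths, clusters are ordered by their smallest leaf label.
    """
    clusters = cut_tree(root, k)
    if depths is not None:
        order = sorted(clusters, key=lambda c: (np.mean([depths[s] for s in c]), c))
    else:
        order = clusters
    assignment: dict[str, str] = {}
    for zone_i, cluster in enumerate(order, start=1):
        for sample_id in cluster:
            assignment[sample_id] = f"Zone {zone_i}"
    return assignment


# ---------------------------------------------------------------------------
# PCoA

@dataclass
class PCoAResult:
    """Principal-coordinates embedding of a dissimilarity matrix.

    ``eigenvalues`` carries the full spectrum including negative values
    (non-Euclidean dissimilarities); coordinates span the positive axes only.
    ``proportion_explained`` is lambda_i over the sum of positive lambdas.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dist: DistanceMatrix) -> PCoAResult:
    """Classical metric MDS: Gower double-centering + eigendecomposition.

    B = -1/2 J D^2 J with J the centering matrix; axes are ordered by
    eigenvalue, coordinates are sqrt(lambda)-scaled eigenvectors for the
    positive eigenvalues, and each axis is oriented so its first nonzero
    loading is positive.
    """
    d = dist.data
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tiny = np.abs(eigvals).max() * 1e-12 if n else 0.0
    pos = eigvals > tiny
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    for ax in range(coords.shape[1]):
        col = coords[:, ax]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, ax] = -col
    pos_sum = eigvals[pos].sum()
    explained = eigvals / pos_sum if pos_sum > 0 else np.zeros_like(eigvals)
    frame = pd.DataFrame(
        coords,
        index=dist.labels,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return PCoAResult(coordinates=frame, eigenvalues=eigvals, proportion_explained=explained)


# ---------------------------------------------------------------------------
# ANOVA

def anova_oneway(groups: list[list[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA across groups; returns (F, p).

    p comes from the F distribution with (k-1, N-k) degrees of freedom.
    Equal group means give F = 0, p = 1.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise InvalidInputError("need >= 2 non-empty groups")
    f, p = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(f), float(p)
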