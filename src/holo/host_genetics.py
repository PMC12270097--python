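"""Host genetic structure: IBS distances, clone pruning, cluster
assignment, pairwise Weir-Cockerham FST, and UPGMA trees."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from holo.distance import DistanceMatrix


class GenotypeMatrix:
    """Individuals x biallelic-SNP dosage matrix (0/1/2, NaN = missing).

    Parameters
    ----------
    dosages : DataFrame, individuals x SNPs
        Integer dosages 0/1/2 stored as float; NaN marks missing calls.
    clusters : Series, optional
        Cluster label per individual (index must match ``dosages``).
    """

    def __init__(self, dosages: pd.DataFrame, clusters: pd.Series | None = None):
        values = dosages.to_numpy(dtype=float)
        observed = values[~np.isnan(values)]
        if observed.size and not np.all(np.isin(observed, (0.0, 1.0, 2.0))):
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if np.all(np.isnan(values), axis=0).any():
            raise ValueError("every SNP needs at least one non-missing call")
        if dosages.index.has_duplicates:
            raise ValueError("duplicate individual ids")
        self.dosages = dosages.astype(float)
        if clusters is not None:
            clusters = clusters.reindex(dosages.index)
            if clusters.isna().any():
                raise ValueError("cluster labels missing for some individuals")
        self.clusters = clusters

    @property
    def individual_ids(self) -> list[str]:
        return [str(x) for x in self.dosages.index]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def call_rate(self) -> pd.Series:
        """Fraction of non-missing calls per individual."""
        return self.dosages.notna().mean(axis=1)

    def subset(self, ids: Sequence[str]) -> "GenotypeMatrix":
        clusters = self.clusters.loc[list(ids)] if self.clusters is not None else None
        return GenotypeMatrix(self.dosages.loc[list(ids)], clusters=clusters)

    def to_tsv(self, path) -> None:
        df = self.dosages.copy()
        df.to_csv(path, sep="\t", index_label="id", na_rep="NA")

    @classmethod
    def from_tsv(cls, path, clusters: pd.Series | None = None) -> "GenotypeMatrix":
        df = pd.read_csv(Path(path), sep="\t", index_col=0, na_values=["NA"])
        return cls(df, clusters=clusters)


def ibs_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Expected single-allele-resampling mismatch between individuals.

    At a site with dosages ``g_i`` and ``g_j`` the probability that one
    allele drawn from each individual differs is ``p(1-q) + (1-p)q`` with
    ``p = g_i/2`` and ``q = g_j/2``; the pairwise distance is the mean
    over sites non-missing in both. This is the analytic expectation of
    the stochastic single-read-resampling IBS distance.
    """
    if g.n_individuals < 2:
        raise ValueError("need at least two individuals")
    p = g.dosages.to_numpy(dtype=float) / 2.0
    mask = ~np.isnan(p)
    p0 = np.where(mask, p, 0.0)

    # mean over shared sites of p(1-q) + q(1-p) = p + q - 2pq
    shared = mask.astype(float) @ mask.T.astype(float)
    if np.any(shared[~np.eye(len(shared), dtype=bool)] == 0):
        ii, jj = np.nonzero((shared == 0) & ~np.eye(len(shared), dtype=bool))
        pair = (g.individual_ids[ii[0]], g.individual_ids[jj[0]])
        raise ValueError(f"no jointly genotyped sites for pair {pair}")
    sum_p = p0 @ mask.T.astype(float)  # sum of p_i over sites shared with j
    cross = p0 @ p0.T
    mismatch = sum_p + sum_p.T - 2.0 * cross
    with np.errstate(invalid="ignore"):
        dist = mismatch / shared
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return DistanceMatrix(dist, g.individual_ids)


def default_clone_threshold(d: DistanceMatrix) -> float:
    """Midpoint of the largest gap in the sorted pairwise-distance vector.

    A heuristic cut separating the clone mode (near zero) from the
    between-genotype mode when no externally calibrated threshold exists.
    """
    vec = np.sort(squareform(d.values, checks=False))
    if vec.size < 2:
        return float(vec[0] / 2.0) if vec.size else 0.0
    gaps = np.diff(vec)
    i = int(np.argmax(gaps))
    return float((vec[i] + vec[i + 1]) / 2.0)


def prune_clones(
    d: DistanceMatrix,
    clone_threshold: float | None = None,
    quality: pd.Series | None = None,
) -> tuple[list[str], dict[str, list[str]]]:
    """Collapse clone/replicate groups to one representative each.

    Average-linkage clustering on ``d`` cut at ``clone_threshold`` (default:
    :func:`default_clone_threshold`); within each group the sample with the
    highest ``quality`` (call rate) is retained, ties broken by
    lexicographically smallest id.

    Returns the retained ids (input order) and a map
    ``representative -> group members``.
    """
    if len(d) == 0:
        raise ValueError("empty distance matrix")
    if clone_threshold is None:
        clone_threshold = default_clone_threshold(d)
    if clone_threshold < 0:
        raise ValueError("clone_threshold must be >= 0")
    if len(d) == 1:
        return list(d.labels), {d.labels[0]: list(d.labels)}

    z = hierarchy.linkage(squareform(d.values, checks=False), method="average")
    flat = hierarchy.fcluster(z, t=clone_threshold, criterion="distance")

    if quality is None:
        quality = pd.Series(0.0, index=d.labels)
    groups: dict[int, list[str]] = {}
    for label, cl in zip(d.labels, flat):
        groups.setdefault(int(cl), []).append(label)

    retained = []
    group_map: dict[str, list[str]] = {}
    for members in groups.values():
        best = sorted(members, key=lambda m: (-float(quality.get(m, 0.0)), m))[0]
        retained.append(best)
        group_map[best] = sorted(members)
    retained = [lab for lab in d.labels if lab in set(retained)]
    return retained, group_map


def assign_clusters(d: DistanceMatrix, k: int) -> pd.Series:
    """Cut an average-linkage tree into ``k`` groups.

    Deterministic labeling: groups are numbered 1..k by order of first
    member in the input label order.
    """
    n = len(d)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    if k == n:
        flat = np.arange(1, n + 1)
    else:
        z = hierarchy.linkage(squareform(d.values, checks=False), method="average")
        flat = hierarchy.fcluster(z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    out = []
    for cl in flat:
        if int(cl) not in relabel:
            relabel[int(cl)] = len(relabel) + 1
        out.append(relabel[int(cl)])
    return pd.Series(out, index=d.labels, name="cluster")


def silhouette_scan(d: DistanceMatrix, k_range: Sequence[int]) -> pd.Series:
    """Mean silhouette width of `assign_clusters` cuts over a k range."""
    from sklearn.metrics import silhouette_score

    scores = {}
    for k in k_range:
        if not 2 <= k < len(d):
            continue
        labels = assign_clusters(d, k).to_numpy()
        scores[k] = float(silhouette_score(d.values, labels, metric="precomputed"))
    return pd.Series(scores, name="silhouette")


@dataclass
class FstMatrix:
    """Pairwise weighted FST between clusters; clamped negatives flagged."""

    matrix: DistanceMatrix
    clamped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return self.matrix.labels

    @property
    def values(self) -> np.ndarray:
        return self.matrix.values


def _wc_pair(d1: np.ndarray, d2: np.ndarray) -> tuple[float, float]:
    """Weir-Cockerham (1984) numerator/denominator sums for two samples.

    ``d1``/``d2`` are dosage vectors over loci (NaN = missing); returns
    (sum_a, sum_{a+b+c}) over usable polymorphic loci.
    """
    r = 2.0
    n1 = np.sum(~np.isnan(d1), axis=0).astype(float)
    n2 = np.sum(~np.isnan(d2), axis=0).astype(float)
    p1 = np.nanmean(d1, axis=0) / 2.0
    p2 = np.nanmean(d2, axis=0) / 2.0
    h1 = np.nanmean(d1 == 1.0, axis=0)
    h2 = np.nanmean(d2 == 1.0, axis=0)

    nbar = (n1 + n2) / r
    usable = (n1 >= 2) & (n2 >= 2) & (nbar > 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    usable &= (pbar > 0) & (pbar < 1)  # skip loci monomorphic across the pair
    if not usable.any():
        raise ValueError("no usable polymorphic loci for this cluster pair")

    n1, n2, p1, p2, h1, h2 = (x[usable] for x in (n1, n2, p1, p2, h1, h2))
    nbar = nbar[usable]
    pbar = pbar[usable]
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    return float(np.sum(a)), float(np.sum(a + b + c))


def pairwise_fst(g: GenotypeMatrix, labels: pd.Series | None = None) -> FstMatrix:
    """Weighted Weir-Cockerham FST between every pair of clusters.

    Per-locus components are combined ratio-of-sums style (sum of
    numerators over sum of denominators); loci monomorphic across a pair
    are skipped; negative totals are clamped to 0 and flagged.
    """
    if labels is None:
        labels = g.clusters
    if labels is None:
        raise ValueError("no cluster labels provided")
    labels = labels.reindex(g.dosages.index)
    counts = labels.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"clusters with <2 individuals: {sorted(small.index)}")

    names = sorted(counts.index)
    dosage_by_cluster = {
        c: g.dosages.loc[labels[labels == c].index].to_numpy(dtype=float) for c in names
    }
    k = len(names)
    fst = np.zeros((k, k))
    clamped = []
    for i in range(k):
        for j in range(i + 1, k):
            num, den = _wc_pair(dosage_by_cluster[names[i]], dosage_by_cluster[names[j]])
            val = num / den if den != 0 else 0.0
            if val < 0:
                val = 0.0
                clamped.append((names[i], names[j]))
            fst[i, j] = fst[j, i] = min(val, 1.0)
    return FstMatrix(DistanceMatrix(fst, [str(c) for c in names]), clamped=clamped)


@dataclass
class UpgmaTree:
    """Ultrametric average-linkage tree with a newick serialization."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]
    newick: str

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path length per leaf, summed over branch lengths."""
        n = len(self.labels)
        node_height = {i: 0.0 for i in range(n)}
        children: dict[int, tuple[int, int]] = {}
        for idx, (a, b, dist, _) in enumerate(self.linkage):
            node_height[n + idx] = dist / 2.0
            children[n + idx] = (int(a), int(b))
        root = n + len(self.linkage) - 1 if len(self.linkage) else 0
        depths: dict[str, float] = {}
        stack = [(root, 0.0)]
        while stack:
            node, acc = stack.pop()
            if node < n:
                depths[self.labels[node]] = acc
            else:
                for child in children[node]:
                    stack.append((child, acc + node_height[node] - node_height[child]))
        return depths


def _newick(z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for idx, (a, b, dist, _) in enumerate(z):
        a, b = int(a), int(b)
        if sizes[b] > sizes[a]:  # larger subtree written first
            a, b = b, a
        h = dist / 2.0
        left = f"{nodes[a]}:{h - heights[a]:g}"
        right = f"{nodes[b]}:{h - heights[b]:g}"
        node = n + idx
        nodes[node] = f"({left},{right})"
        heights[node] = h
        sizes[node] = sizes[a] + sizes[b]
    return nodes[n * 2 - 2] + ";" if n > 1 else labels[0] + ";"


def upgma(m: FstMatrix | DistanceMatrix) -> UpgmaTree:
    """UPGMA (size-weighted average linkage) tree of a distance matrix.

    Leaves sit at height 0, a merge of clusters at average distance ``h``
    sits at height ``h/2``, and branch lengths are height differences —
    so the tree is ultrametric by construction.
    """
    d = m.matrix if isinstance(m, FstMatrix) else m
    if len(d) < 2:
        raise ValueError("need at least two labels")
    z = hierarchy.linkage(squareform(d.values, checks=False), method="average")
    return UpgmaTree(linkage=z, labels=list(d.labels), newick=_newick(z, list(d.labels)))
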