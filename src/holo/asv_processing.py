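"""ASV count-table processing: replicate aggregation, correlated-ASV
grouping, prevalence/read filters, Hellinger standardization and
Bray-Curtis distances.

Fixed pipeline order (applied once each by :func:`process_community`):
group (symbiont mode only) -> aggregate -> filter_asvs -> filter_colonies
-> join_with_genotyped -> hellinger -> bray_curtis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from holo.distance import DistanceMatrix

logger = logging.getLogger(__name__)


class AsvTable:
    """Samples x ASVs nonnegative integer count table.

    Parameters
    ----------
    counts : DataFrame
        Rows are samples (or colonies), columns are ASVs; values are
        nonnegative integers.
    colony_map : Series, optional
        sample id -> colony id. Defaults to identity (each row already a
        colony).
    """

    def __init__(self, counts: pd.DataFrame, colony_map: pd.Series | None = None):
        values = counts.to_numpy()
        if np.any(values < 0):
            raise ValueError("counts must be nonnegative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integral")
        if counts.index.has_duplicates or counts.columns.has_duplicates:
            raise ValueError("duplicate sample or ASV ids")
        self.counts = counts.astype(np.int64)
        if colony_map is None:
            colony_map = pd.Series(counts.index, index=counts.index)
        else:
            missing = counts.index.difference(colony_map.index)
            if len(missing):
                raise KeyError(f"samples with no colony mapping: {list(missing)[:5]}")
            colony_map = colony_map.reindex(counts.index).astype(str)
        self.colony_map = colony_map

    @property
    def sample_ids(self) -> list[str]:
        return [str(x) for x in self.counts.index]

    @property
    def asv_ids(self) -> list[str]:
        return [str(x) for x in self.counts.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path, colony_map: pd.Series | None = None) -> "AsvTable":
        df = pd.read_csv(Path(path), sep="\t", index_col=0)
        return cls(df, colony_map=colony_map)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for ASV/colony retention and ASV grouping.

    ``min_colonies_per_asv`` is inclusive (>=); the read thresholds and
    ``min_nonzero_asvs_per_colony`` are strict (>), as is
    ``correlation_threshold``.
    """

    min_colonies_per_asv: int = 3
    min_reads_per_asv: int = 100
    min_reads_per_colony: int = 1000
    min_nonzero_asvs_per_colony: int = 3
    correlation_threshold: float = 0.8

    def __post_init__(self):
        for name in (
            "min_colonies_per_asv",
            "min_reads_per_asv",
            "min_reads_per_colony",
            "min_nonzero_asvs_per_colony",
            "correlation_threshold",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def aggregate_replicates(t: AsvTable) -> AsvTable:
    """Sum counts across samples of the same colony; rows become colonies."""
    agg = t.counts.groupby(t.colony_map, sort=True).sum()
    agg.index.name = None
    return AsvTable(agg)


@dataclass
class AsvGroupMap:
    """Partition of ASVs into co-occurrence groups."""

    asv_to_group: dict[str, str]
    group_members: dict[str, list[str]]

    def __post_init__(self):
        seen: set[str] = set()
        for members in self.group_members.values():
            for m in members:
                if m in seen:
                    raise ValueError(f"ASV {m!r} appears in multiple groups")
                seen.add(m)
        if seen != set(self.asv_to_group):
            raise ValueError("group map is not a partition of the ASV set")


def group_correlated_asvs(
    t: AsvTable, cfg: FilterConfig | None = None
) -> tuple[AsvGroupMap, AsvTable]:
    """Merge ASVs whose presence/absence vectors are strongly correlated.

    Presence = count > 0. Pairs with Pearson correlation of presence (the
    phi coefficient) strictly above ``cfg.correlation_threshold`` are
    linked, and connected components become groups, so chains merge
    transitively. Constant presence vectors (all-present / all-absent
    ASVs) have no defined correlation: they are merged only with ASVs
    whose presence vector is identical, never through a correlation edge.

    Grouped counts are the per-sample sum over members; the group id is
    the lexicographically smallest member id.
    """
    if cfg is None:
        cfg = FilterConfig()
    if t.shape[0] < 2:
        raise ValueError("need at least two samples to correlate presences")
    presence = (t.counts.to_numpy() > 0).astype(float)
    n_asv = presence.shape[1]
    sd = presence.std(axis=0)
    variable = sd > 0

    adj = np.zeros((n_asv, n_asv), dtype=bool)
    if variable.sum() >= 2:
        sub = presence[:, variable]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        edge = corr > cfg.correlation_threshold
        np.fill_diagonal(edge, False)
        idx = np.flatnonzero(variable)
        adj[np.ix_(idx, idx)] = edge

    # constant vectors: exact-duplicate merging only
    const_idx = np.flatnonzero(~variable)
    for pos, i in enumerate(const_idx):
        for j in const_idx[pos + 1 :]:
            if np.array_equal(presence[:, i], presence[:, j]):
                adj[i, j] = adj[j, i] = True

    n_comp, comp = connected_components(adj, directed=False)
    asv_ids = t.asv_ids
    members_by_comp: dict[int, list[str]] = {}
    for asv, c in zip(asv_ids, comp):
        members_by_comp.setdefault(int(c), []).append(asv)

    group_members = {min(m): sorted(m) for m in members_by_comp.values()}
    asv_to_group = {m: g for g, ms in group_members.items() for m in ms}

    grouped = t.counts.T.groupby(pd.Series(asv_to_group)).sum().T
    grouped = grouped[sorted(grouped.columns)]
    return AsvGroupMap(asv_to_group, group_members), AsvTable(grouped, t.colony_map)


def filter_asvs(t: AsvTable, cfg: FilterConfig | None = None) -> AsvTable:
    """Keep ASVs present in >= ``min_colonies_per_asv`` colonies (count>0)
    with total reads strictly above ``min_reads_per_asv``."""
    if cfg is None:
        cfg = FilterConfig()
    presence = (t.counts > 0).sum(axis=0)
    totals = t.counts.sum(axis=0)
    keep = (presence >= cfg.min_colonies_per_asv) & (totals > cfg.min_reads_per_asv)
    dropped = (~keep).sum()
    if dropped:
        logger.info("filter_asvs: dropped %d of %d ASVs", dropped, t.shape[1])
    return AsvTable(t.counts.loc[:, keep], t.colony_map)


def filter_colonies(t: AsvTable, cfg: FilterConfig | None = None) -> AsvTable:
    """Keep colonies with total reads > ``min_reads_per_colony`` and
    strictly more than ``min_nonzero_asvs_per_colony`` nonzero ASVs."""
    if cfg is None:
        cfg = FilterConfig()
    totals = t.counts.sum(axis=1)
    nonzero = (t.counts > 0).sum(axis=1)
    keep = (totals > cfg.min_reads_per_colony) & (nonzero > cfg.min_nonzero_asvs_per_colony)
    if not keep.any():
        raise ValueError(
            "all colonies removed by filter_colonies; review min_reads_per_colony "
            "and min_nonzero_asvs_per_colony"
        )
    dropped = (~keep).sum()
    if dropped:
        logger.info("filter_colonies: dropped %d of %d colonies", dropped, t.shape[0])
    return AsvTable(
        t.counts.loc[keep], t.colony_map.loc[t.counts.index[keep.to_numpy()]]
    )


def join_with_genotyped(t: AsvTable, genotyped: Iterable[str]) -> AsvTable:
    """Restrict the table to colonies that also have genotype data."""
    genotyped = {str(g) for g in genotyped}
    keep = [s for s in t.counts.index if str(t.colony_map[s]) in genotyped]
    if not keep:
        raise ValueError("no overlap between count table colonies and genotyped ids")
    dropped = t.counts.index.difference(keep)
    if len(dropped):
        logger.info("join_with_genotyped: dropped %d colonies: %s", len(dropped), list(dropped))
    return AsvTable(t.counts.loc[keep], t.colony_map.loc[keep])


def hellinger(t: AsvTable | pd.DataFrame) -> pd.DataFrame:
    """Hellinger standardization: sqrt of row-wise relative abundance."""
    counts = t.counts if isinstance(t, AsvTable) else t
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = list(counts.index[totals == 0])[:5]
        raise ValueError(f"rows with zero total reads: {bad}")
    return np.sqrt(counts.div(totals, axis=0))


def bray_curtis(m: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between rows of an abundance matrix."""
    values = m.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("abundances must be nonnegative")
    if np.any(values.sum(axis=1) == 0):
        raise ValueError("all-zero rows have undefined Bray-Curtis distance")
    d = squareform(pdist(values, metric="braycurtis"))
    return DistanceMatrix(d, [str(x) for x in m.index])


@dataclass
class ProcessResult:
    """Outputs of the full community-processing pipeline."""

    group_map: AsvGroupMap | None
    colony_table: AsvTable
    hellinger: pd.DataFrame
    distances: DistanceMatrix
    log: list[str]


def process_community(
    t: AsvTable,
    mode: str = "16s",
    cfg: FilterConfig | None = None,
    genotyped: Sequence[str] | None = None,
) -> ProcessResult:
    """Run the fixed pipeline: [group] -> aggregate -> filter ASVs ->
    filter colonies -> [join] -> Hellinger -> Bray-Curtis.

    ``mode='its2'`` enables correlated-ASV grouping (intragenomic-variant
    collapsing), ``mode='16s'`` skips it.
    """
    if mode not in ("its2", "16s"):
        raise ValueError(f"mode must be 'its2' or '16s', got {mode!r}")
    if cfg is None:
        cfg = FilterConfig()
    log: list[str] = []
    group_map = None
    if mode == "its2":
        group_map, t = group_correlated_asvs(t, cfg)
        log.append(
            f"grouped {len(group_map.asv_to_group)} ASVs into "
            f"{len(group_map.group_members)} groups at r>{cfg.correlation_threshold}"
        )
    t = aggregate_replicates(t)
    log.append(f"aggregated to {t.shape[0]} colonies")
    t = filter_asvs(t, cfg)
    log.append(f"retained {t.shape[1]} ASVs after filter_asvs")
    t = filter_colonies(t, cfg)
    log.append(f"retained {t.shape[0]} colonies after filter_colonies")
    if genotyped is not None:
        t = join_with_genotyped(t, genotyped)
        log.append(f"retained {t.shape[0]} genotyped colonies")
    h = hellinger(t)
    d = bray_curtis(h)
    return ProcessResult(group_map, t, h, d, log)
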