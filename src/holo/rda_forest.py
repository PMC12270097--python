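"""Random-forest variable importance for ordination structure.

Forests of bootstrapped regression trees predict each PCoA axis from
dummy-coded predictors. Per axis, out-of-bag permutation importance is
normalized and weighted by the axis's out-of-bag R^2 times its share of
the retained eigenvalue mass; a categorical predictor's importance is the
sum over its dummy levels, and shares are importances over the model
total.

This is a documented analog of gradient-forest-style importance, not a
numerical clone of any particular implementation: orderings and share
arithmetic are the supported surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from holo.community_stats import PcoaResult


@dataclass
class PredictorMatrix:
    """One 0/1 column per categorical level plus raw quantitative columns.

    ``level_map`` sends each column to its parent predictor; every
    categorical parent's columns sum to exactly 1 in each row (full
    one-hot, no dropped reference level).
    """

    data: pd.DataFrame
    level_map: dict[str, str]

    def __post_init__(self):
        unmapped = set(self.data.columns) - set(self.level_map)
        if unmapped:
            raise ValueError(f"columns without a parent predictor: {sorted(unmapped)}")

    @property
    def parents(self) -> list[str]:
        seen: list[str] = []
        for col in self.data.columns:
            p = self.level_map[col]
            if p not in seen:
                seen.append(p)
        return seen


def dummy_code(metadata: pd.DataFrame, predictors: list[str]) -> PredictorMatrix:
    """Full one-hot coding of categorical predictors (one column per
    level); quantitative predictors pass through unchanged."""
    columns: dict[str, np.ndarray] = {}
    level_map: dict[str, str] = {}
    for pred in predictors:
        if pred not in metadata.columns:
            raise KeyError(f"predictor {pred!r} not in metadata")
        col = metadata[pred]
        if pd.api.types.is_numeric_dtype(col):
            if col.nunique() < 2:
                raise ValueError(f"predictor {pred!r} is constant")
            columns[pred] = col.to_numpy(dtype=float)
            level_map[pred] = pred
            continue
        levels = sorted(col.astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"predictor {pred!r} is constant")
        for lev in levels:
            name = f"{pred}={lev}"
            columns[name] = (col.astype(str) == lev).to_numpy(dtype=float)
            level_map[name] = pred
    return PredictorMatrix(pd.DataFrame(columns, index=metadata.index), level_map)


def compute_max_level(n_individuals: int) -> int:
    """floor(log2(n * 0.368 / 2)) — depth cap for conditional permutation."""
    arg = n_individuals * 0.368 / 2.0
    if arg <= 1.0:
        raise ValueError(f"too few individuals ({n_individuals}) for a permutation level")
    return int(math.floor(math.log2(arg)))


@dataclass(frozen=True)
class RdaForestConfig:
    """Forest settings; ``max_level`` defaults to the sample-size rule of
    :func:`compute_max_level` and only matters with conditional importance."""

    n_axes: int = 15
    n_trees: int = 1500
    max_level: int | None = None
    seed: int = 0
    conditional_importance: bool = False
    min_samples_leaf: int = 5

    def __post_init__(self):
        if self.n_axes < 1 or self.n_trees < 1:
            raise ValueError("n_axes and n_trees must be >= 1")


@dataclass
class ImportanceReport:
    """Weighted importance per predictor (column- or parent-level).

    ``importance`` entries are nonnegative; ``axis_r2`` is the
    out-of-bag R^2 per fitted axis (floored at 0 in the weights);
    ``total_importance`` is the sum over all entries.
    """

    importance: pd.Series
    axis_r2: pd.Series
    axis_weights: pd.Series
    level_map: dict[str, str] = field(default_factory=dict)
    aggregated: bool = False

    @property
    def total_importance(self) -> float:
        return float(self.importance.sum())


def _fit_axis(
    y: np.ndarray,
    x: np.ndarray,
    cfg: RdaForestConfig,
    rng: np.random.Generator,
    strata: list[np.ndarray | None],
) -> tuple[float, np.ndarray]:
    """One forest: returns (OOB R^2, per-column mean OOB importance)."""
    n, p = x.shape
    mtry = max(1, p // 3)
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n, dtype=np.int64)
    imp = np.zeros(p)

    for _ in range(cfg.n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.ones(n, dtype=bool)
        oob[boot] = False
        if not oob.any():
            continue
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_leaf=cfg.min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(x[boot], y[boot])
        xo, yo = x[oob], y[oob]
        m = len(yo)

        # stack baseline + one permuted copy per column: a single predict call
        stacked = np.tile(xo, (p + 1, 1))
        for c in range(p):
            block = stacked[(c + 1) * m : (c + 2) * m]
            col = xo[:, c]
            strat = strata[c]
            if strat is None:
                block[:, c] = rng.permutation(col)
            else:
                permuted = col.copy()
                for s in np.unique(strat[oob]):
                    members = np.flatnonzero(strat[oob] == s)
                    permuted[members] = col[members[rng.permutation(len(members))]]
                block[:, c] = permuted
        preds = tree.predict(stacked)
        base = preds[:m]
        oob_sum[oob] += base
        oob_cnt[oob] += 1
        base_mse = float(np.mean((base - yo) ** 2))
        for c in range(p):
            mse_c = float(np.mean((preds[(c + 1) * m : (c + 2) * m] - yo) ** 2))
            imp[c] += mse_c - base_mse

    covered = oob_cnt > 0
    var_y = float(np.var(y[covered])) if covered.any() else 0.0
    if var_y <= 0 or not covered.any():
        r2 = 0.0
    else:
        resid = oob_sum[covered] / oob_cnt[covered] - y[covered]
        r2 = 1.0 - float(np.mean(resid**2)) / var_y
    return r2, imp / cfg.n_trees


def _conditional_strata(
    x: np.ndarray, cfg: RdaForestConfig
) -> list[np.ndarray | None]:
    """Permutation strata per column: joint levels of correlated columns.

    Columns correlated (|r| > 0.5) with the permuted one define the
    strata; if they split the samples into more than 2^max_level cells,
    plain permutation is used instead. Experimental.
    """
    n, p = x.shape
    max_cells = 2 ** (cfg.max_level if cfg.max_level is not None else compute_max_level(n))
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(corr)
    out: list[np.ndarray | None] = []
    for c in range(p):
        partners = [j for j in range(p) if j != c and abs(corr[c, j]) > 0.5]
        if not partners:
            out.append(None)
            continue
        _, codes = np.unique(x[:, partners], axis=0, return_inverse=True)
        out.append(codes if codes.max() + 1 <= max_cells else None)
    return out


def fit_rda_forest(
    p: PcoaResult, x: PredictorMatrix, cfg: RdaForestConfig | None = None
) -> ImportanceReport:
    """Forest-based weighted importance of predictors for PCoA structure.

    For each of the first ``min(cfg.n_axes, #positive axes)`` axes, a
    forest of ``cfg.n_trees`` bootstrapped trees is fitted; the axis
    contributes its normalized, nonnegative OOB permutation importances
    weighted by ``max(OOB R^2, 0) * eigenvalue share``. Column-level
    importances are returned; use :func:`aggregate_importance` for
    parent-level sums.
    """
    if cfg is None:
        cfg = RdaForestConfig()
    if p.n_axes < 1:
        raise ValueError("PCoA has no positive axes")
    data = x.data.loc[p.coordinates.index]
    xmat = data.to_numpy(dtype=float)
    m = min(cfg.n_axes, p.n_axes)
    eig = p.eigenvalues[:m]
    eig_share = eig / eig.sum()

    rng = np.random.default_rng(cfg.seed)
    strata = (
        _conditional_strata(xmat, cfg)
        if cfg.conditional_importance
        else [None] * xmat.shape[1]
    )

    weighted = np.zeros(xmat.shape[1])
    r2s = np.zeros(m)
    weights = np.zeros(m)
    for k in range(m):
        r2, imp = _fit_axis(p.coordinates.iloc[:, k].to_numpy(), xmat, cfg, rng, strata)
        r2s[k] = r2
        imp = np.clip(imp, 0.0, None)
        total = imp.sum()
        if total > 0:
            imp = imp / total
        weights[k] = max(r2, 0.0) * eig_share[k]
        weighted += weights[k] * imp

    axes = [f"PC{i + 1}" for i in range(m)]
    return ImportanceReport(
        importance=pd.Series(weighted, index=data.columns, name="weighted_importance"),
        axis_r2=pd.Series(r2s, index=axes, name="oob_r2"),
        axis_weights=pd.Series(weights, index=axes, name="axis_weight"),
        level_map=dict(x.level_map),
    )


def aggregate_importance(
    report: ImportanceReport, level_map: dict[str, str] | None = None
) -> ImportanceReport:
    """Sum dummy-column importances into parent-predictor importances."""
    level_map = level_map or report.level_map
    unmapped = [c for c in report.importance.index if c not in level_map]
    if unmapped:
        raise KeyError(f"columns with no parent mapping: {unmapped}")
    parents: list[str] = []
    for col in report.importance.index:
        if level_map[col] not in parents:
            parents.append(level_map[col])
    agg = report.importance.groupby(report.importance.index.map(level_map)).sum()
    agg = agg.reindex(parents)
    return ImportanceReport(
        importance=agg.rename("weighted_importance"),
        axis_r2=report.axis_r2,
        axis_weights=report.axis_weights,
        level_map={p: p for p in parents},
        aggregated=True,
    )


@dataclass
class RelativeImportance:
    """Importance shares as fractions (sum exactly 1) and rounded percents."""

    fractions: pd.Series
    percents: pd.Series
    total: float


def relative_importance(
    importances: pd.Series | dict[str, float], total: float | None = None
) -> RelativeImportance:
    """Share of each predictor in the total model importance.

    ``total`` defaults to the sum of the given importances; pass it
    explicitly to reproduce shares quoted against a separately reported
    model total. Percent values are shares x 100 rounded to integers.
    """
    imp = pd.Series(importances, dtype=float)
    if (imp < 0).any():
        raise ValueError("importances must be nonnegative")
    if total is None:
        total = float(imp.sum())
    if total <= 0:
        raise ValueError("total importance must be positive")
    fractions = imp / total
    percents = (fractions * 100).round().astype(int)
    return RelativeImportance(fractions=fractions, percents=percents, total=float(total))
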