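"""Distance-matrix statistics: principal coordinates analysis,
marginal-term PERMANOVA, and a group-dispersion permutation test.

All three operate directly on a labeled :class:`~holo.distance.DistanceMatrix`
via the Gower-centered inner-product matrix G = -1/2 J D^2 J, so sums of
squares partition exactly as in distance-based ANOVA.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from holo.distance import DistanceMatrix

_EIG_TOL = 1e-10


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


@dataclass
class PcoaResult:
    """Classical-scaling embedding of a distance matrix.

    ``coordinates`` holds only positive-eigenvalue axes, each scaled by
    the square root of its eigenvalue; ``eigenvalues`` lists all
    eigenvalues in descending order (negatives reported, not corrected).
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa(d: DistanceMatrix) -> PcoaResult:
    """Principal coordinates analysis via Gower double-centering.

    Eigendecompose ``-1/2 J D^2 J``; axes with eigenvalue > 1e-10 are
    kept and scaled so that Euclidean distances among coordinates
    reproduce the input distances when the input is Euclidean-embeddable.
    """
    n = len(d)
    if n < 2:
        raise ValueError("need at least two samples")
    g = _gower_center(d.values)
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    keep = eigval > _EIG_TOL
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])
    pos_sum = eigval[keep].sum()
    prop = eigval[keep] / pos_sum if pos_sum > 0 else np.zeros(keep.sum())
    frame = pd.DataFrame(
        coords, index=d.labels, columns=[f"PC{i + 1}" for i in range(coords.shape[1])]
    )
    return PcoaResult(coordinates=frame, eigenvalues=eigval, proportion_explained=prop)


# ---------------------------------------------------------------------------
# PERMANOVA


def parse_model(model: str | list[str]) -> list[str]:
    """Expand an R-style model string into an ordered term list.

    ``"a + b + a:b"`` passes through; ``"a * b"`` expands to
    ``[a, b, a:b]``. Duplicate terms are dropped, keeping first position.
    """
    if isinstance(model, str):
        tokens = [t.strip() for t in model.split("+") if t.strip()]
    else:
        tokens = [str(t).strip() for t in model]
    terms: list[str] = []
    for tok in tokens:
        if "*" in tok:
            parts = [p.strip() for p in tok.split("*")]
            expanded = list(parts) + [":".join(parts)]
        else:
            expanded = [tok]
        for term in expanded:
            if term not in terms:
                terms.append(term)
    return terms


def _factor_columns(metadata: pd.DataFrame, name: str) -> np.ndarray:
    """Treatment-coded columns for one variable (reference level dropped)."""
    if name not in metadata.columns:
        raise KeyError(f"model term {name!r} not in metadata columns")
    col = metadata[name]
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float).reshape(-1, 1)
    levels = sorted(col.astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"term {name!r} has a single level")
    return np.column_stack(
        [(col.astype(str) == lev).to_numpy(dtype=float) for lev in levels[1:]]
    )


def _design(metadata: pd.DataFrame, terms: list[str]) -> dict[str, np.ndarray]:
    """Columns per term; interactions are elementwise products of mains."""
    blocks: dict[str, np.ndarray] = {}
    for term in terms:
        if ":" in term:
            parts = term.split(":")
            cols = _factor_columns(metadata, parts[0])
            for p in parts[1:]:
                other = _factor_columns(metadata, p)
                cols = np.column_stack(
                    [cols[:, i] * other[:, j] for i in range(cols.shape[1]) for j in range(other.shape[1])]
                )
            blocks[term] = cols
        else:
            blocks[term] = _factor_columns(metadata, term)
    return blocks


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of x, plus its rank."""
    rank = int(np.linalg.matrix_rank(x))
    return x @ np.linalg.pinv(x), rank


@dataclass
class PermanovaTable:
    """Marginal-term PERMANOVA results.

    ``table`` rows: one per term, then Residual and Total; columns
    df, SS, R2, F, p.
    """

    table: pd.DataFrame
    n_permutations: int | str
    seed: int | None
    clamped_terms: list[str] = field(default_factory=list)


def permanova_marginal(
    d: DistanceMatrix,
    metadata: pd.DataFrame,
    model: str | list[str],
    n_perm: int | str = 999,
    seed: int | None = None,
) -> PermanovaTable:
    """PERMANOVA with marginal (type-III-style) sums of squares.

    Each term's SS is the drop in explained trace when its columns are
    removed from the full design; pseudo-F tests it against the full-model
    residual. P-values come from free permutation of sample labels (rows
    and columns of D jointly), all terms recomputed per permutation:
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``. Pass
    ``n_perm="exhaustive"`` to enumerate every relabeling exactly
    (``p = #{F_perm >= F_obs} / n!``, identity included).

    Confounded terms (no rank change when removed) are reported with df 0
    and NA statistics.
    """
    metadata = metadata.loc[d.labels]
    terms = parse_model(model)
    if isinstance(n_perm, int) and n_perm < 99:
        raise ValueError("n_perm must be >= 99 (or 'exhaustive')")

    n = len(d)
    g = _gower_center(d.values)
    ss_total = float(np.trace(g))

    blocks = _design(metadata, terms)
    intercept = np.ones((n, 1))
    x_full = np.column_stack([intercept] + [blocks[t] for t in terms])
    h_full, rank_full = _hat(x_full)

    h_reduced: dict[str, np.ndarray] = {}
    df_term: dict[str, int] = {}
    for t in terms:
        x_red = np.column_stack([intercept] + [blocks[u] for u in terms if u != t])
        h_red, rank_red = _hat(x_red)
        h_reduced[t] = h_red
        df_term[t] = rank_full - rank_red

    df_res = n - rank_full
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def stats(g_mat: np.ndarray) -> dict[str, float]:
        ss_model = float(np.sum(h_full * g_mat))
        ss_res = float(np.trace(g_mat)) - ss_model
        out = {}
        for t in terms:
            if df_term[t] == 0:
                out[t] = np.nan
                continue
            ss_t = ss_model - float(np.sum(h_reduced[t] * g_mat))
            out[t] = (ss_t / df_term[t]) / (ss_res / df_res)
        return out

    ss_model = float(np.sum(h_full * g))
    ss_res = ss_total - ss_model
    ss_terms = {
        t: ss_model - float(np.sum(h_reduced[t] * g)) if df_term[t] > 0 else np.nan
        for t in terms
    }
    f_obs = stats(g)

    clamped = [t for t in terms if df_term[t] > 0 and ss_terms[t] < -1e-9]
    for t in terms:
        if df_term[t] > 0 and ss_terms[t] < 0:
            ss_terms[t] = 0.0

    counts = {t: 0 for t in terms}
    if n_perm == "exhaustive":
        n_done = 0
        for perm in itertools.permutations(range(n)):
            idx = np.asarray(perm)
            f_perm = stats(g[np.ix_(idx, idx)])
            for t in terms:
                if not np.isnan(f_obs[t]) and f_perm[t] >= f_obs[t] - 1e-12:
                    counts[t] += 1
            n_done += 1
        pvals = {
            t: counts[t] / n_done if not np.isnan(f_obs[t]) else np.nan for t in terms
        }
    else:
        rng = np.random.default_rng(seed)
        for _ in range(int(n_perm)):
            idx = rng.permutation(n)
            f_perm = stats(g[np.ix_(idx, idx)])
            for t in terms:
                if not np.isnan(f_obs[t]) and f_perm[t] >= f_obs[t]:
                    counts[t] += 1
        pvals = {
            t: (1 + counts[t]) / (1 + int(n_perm)) if not np.isnan(f_obs[t]) else np.nan
            for t in terms
        }

    rows = []
    for t in terms:
        rows.append(
            {
                "term": t,
                "df": df_term[t],
                "SS": ss_terms[t],
                "R2": ss_terms[t] / ss_total if df_term[t] > 0 else np.nan,
                "F": f_obs[t],
                "p": pvals[t],
            }
        )
    rows.append(
        {"term": "Residual", "df": df_res, "SS": ss_res, "R2": ss_res / ss_total,
         "F": np.nan, "p": np.nan}
    )
    rows.append(
        {"term": "Total", "df": n - 1, "SS": ss_total, "R2": 1.0, "F": np.nan, "p": np.nan}
    )
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaTable(table, n_perm, seed, clamped_terms=clamped)


# ---------------------------------------------------------------------------
# dispersion


@dataclass
class DispersionResult:
    """Group dispersion (distance-to-centroid) comparison."""

    group_dispersion: pd.Series
    f_statistic: float
    p_value: float
    n_permutations: int


def _centroid_distances(coords: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    out = np.empty(coords.shape[0])
    for gi in range(n_groups):
        members = codes == gi
        centroid = coords[members].mean(axis=0)
        out[members] = np.sqrt(((coords[members] - centroid) ** 2).sum(axis=1))
    return out


def _anova_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for gi in range(n_groups):
        v = values[codes == gi]
        ss_between += len(v) * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    df_b = n_groups - 1
    df_w = len(values) - n_groups
    if ss_within == 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / df_b) / (ss_within / df_w)


def dispersion_test(
    d: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> DispersionResult:
    """Test homogeneity of multivariate dispersion across groups.

    Samples are embedded by positive-axis PCoA; each sample's distance to
    its group centroid is the dispersion measure; the observed statistic
    is the one-way ANOVA F across groups, and the p-value permutes group
    labels (centroids recomputed per permutation).
    """
    groups = groups.loc[d.labels].astype(str)
    sizes = groups.value_counts()
    if (sizes >= 2).sum() < 2:
        raise ValueError("need at least two groups with at least two members")
    if (sizes < 2).any():
        keep = groups[groups.isin(sizes[sizes >= 2].index)].index
        d = d.subset(list(keep))
        groups = groups.loc[d.labels]

    coords = pcoa(d).coordinates.to_numpy()
    levels = sorted(groups.unique())
    codes = groups.map({g: i for i, g in enumerate(levels)}).to_numpy()
    n_groups = len(levels)

    obs_dist = _centroid_distances(coords, codes, n_groups)
    f_obs = _anova_f(obs_dist, codes, n_groups)
    disp = pd.Series(
        [obs_dist[codes == i].mean() for i in range(n_groups)], index=levels,
        name="mean_distance_to_centroid",
    )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm_codes = rng.permutation(codes)
        if len(np.unique(perm_codes)) < n_groups:
            continue
        f_perm = _anova_f(
            _centroid_distances(coords, perm_codes, n_groups), perm_codes, n_groups
        )
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return DispersionResult(disp, float(f_obs), float(p), n_perm)
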