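"""Weighted co-expression network analysis, implemented from first principles.

The chain follows the classic weighted correlation-network recipe:

1. Pearson correlation between feature profiles, with a two-sided p-value
   from ``t = r * sqrt(n - 2) / sqrt(1 - r^2)`` on ``n - 2`` df.
2. Unsigned adjacency ``a_ij = |r_ij|^beta`` (zero diagonal), with the soft
   power ``beta`` chosen by the scale-free topology criterion.
3. Topological overlap ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
   where ``l_ij = sum_u a_iu a_uj`` and ``k_i`` is node connectivity.
4. Average-linkage hierarchical clustering of ``1 - TOM`` with a static cut
   at ``cut_height x (maximum merge height)``; clusters below
   ``min_module_size`` are left unassigned ("grey").
5. Module eigengenes: first principal component of the z-scored module
   submatrix, unit variance, sign-oriented to correlate positively with the
   module mean profile.

Module labels follow the conventional colour sequence (turquoise, blue,
brown, ...) in decreasing module-size order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .matrix import CartxError, ExpressionMatrix

#: Conventional module colour sequence, assigned by decreasing module size.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)

GREY = "grey"


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Sample Pearson correlation with a two-sided t-test p-value.

    ``|r| = 1`` maps to ``p = 0``; constant vectors and n < 3 are errors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CartxError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise CartxError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CartxError("constant vector passed to pearson_with_p")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    p = _p_from_r(r, n)
    return CorrelationResult(r, p, n)


def _p_from_r(r: float | np.ndarray, n: int) -> float | np.ndarray:
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return float(p) if p.ndim == 0 else p


def correlation_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Feature-feature Pearson correlation across samples."""
    if expr.n_samples < 3:
        raise CartxError("need at least 3 samples for correlations")
    X = expr.data.values
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = [f for f, s in zip(expr.feature_ids, sd) if s == 0]
        raise CartxError(f"constant feature profile(s): {bad[:5]}")
    R = np.corrcoef(X)
    np.clip(R, -1.0, 1.0, out=R)
    return pd.DataFrame(R, index=expr.feature_ids, columns=expr.feature_ids)


@dataclass
class SoftPowerDiagnostics:
    power: int
    fit_reached_target: bool
    table: pd.DataFrame  # columns: power, fit_r2, mean_k, median_k, max_k


def pick_soft_power(
    expr: ExpressionMatrix,
    candidate_powers: tuple[int, ...] = tuple(range(1, 21)),
    target_r2: float = 0.8,
    n_bins: int = 10,
) -> SoftPowerDiagnostics:
    """Scale-free topology criterion for the soft-thresholding power.

    For each candidate power the connectivity distribution is binned into
    equal-count bins of log10(k) and log10(frequency) is regressed on the
    bin means; the signed fit is ``sign(-slope) * R^2``. The smallest power
    reaching ``target_r2`` wins; if none does, the best-fitting power is
    returned with ``fit_reached_target=False``.
    """
    if not candidate_powers:
        raise CartxError("candidate_powers must be non-empty")
    if expr.n_samples < 4:
        raise CartxError("need at least 4 samples for soft-power selection")
    R = np.abs(correlation_matrix(expr).values)
    np.fill_diagonal(R, 0.0)

    rows = []
    for beta in candidate_powers:
        A = R**beta
        k = A.sum(axis=1)
        fit = _scale_free_fit(k, n_bins)
        rows.append(
            {
                "power": beta,
                "fit_r2": fit,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    table = pd.DataFrame(rows)
    defined = table.dropna(subset=["fit_r2"])
    if defined.empty:
        # degenerate connectivity everywhere: flagged fallback
        return SoftPowerDiagnostics(int(table["power"].iloc[0]), False, table)
    passing = defined[defined["fit_r2"] >= target_r2]
    if len(passing):
        power = int(passing["power"].iloc[0])
        return SoftPowerDiagnostics(power, True, table)
    best = defined.loc[defined["fit_r2"].idxmax()]
    return SoftPowerDiagnostics(int(best["power"]), False, table)


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float | None:
    """Signed R^2 of log10(freq) ~ log10(mean k) over equal-count bins."""
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        return None
    n_bins = min(n_bins, k.size)
    order = np.sort(np.log10(k))
    edges = np.array_split(order, n_bins)
    xs, ys = [], []
    for chunk in edges:
        if chunk.size == 0:
            continue
        xs.append(chunk.mean())
        ys.append(np.log10(chunk.size / k.size))
    xs = np.array(xs)
    ys = np.array(ys)
    if xs.size < 2 or np.ptp(xs) == 0:
        return None
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * xs + intercept
    ss_res = float(((ys - pred) ** 2).sum())
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    if ss_tot == 0:
        return None
    r2 = 1.0 - ss_res / ss_tot
    return float(np.sign(-slope) * r2)


def adjacency(expr: ExpressionMatrix, power: float) -> pd.DataFrame:
    """Unsigned adjacency ``|r|^power`` with zero diagonal."""
    if power < 1:
        raise CartxError("power must be >= 1")
    R = correlation_matrix(expr)
    A = np.abs(R.values) ** power
    np.fill_diagonal(A, 0.0)
    return pd.DataFrame(A, index=R.index, columns=R.columns)


def topological_overlap(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency with zero diagonal.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` for ``i != j``,
    ``TOM_ii = 1``, where ``l_ij = sum_u a_iu a_uj``.
    """
    index = adj.index if isinstance(adj, pd.DataFrame) else None
    A = np.asarray(adj, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise CartxError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise CartxError("adjacency must be symmetric")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    if (A < 0).any() or (A > 1).any():
        raise CartxError("adjacency entries must lie in [0, 1]")
    k = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    if index is not None:
        return pd.DataFrame(tom, index=index, columns=index)
    return pd.DataFrame(tom)


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.99,
) -> pd.Series:
    """Static-cut average-linkage module detection on ``1 - TOM``.

    The dendrogram is cut at ``cut_height x (maximum merge height)``;
    clusters smaller than ``min_module_size`` are labelled ``grey``, the
    rest take colours from :data:`MODULE_COLORS` by decreasing size (ties
    broken by the lexicographically smallest member id).
    """
    if min_module_size < 2:
        raise CartxError("min_module_size must be >= 2")
    if not 0 < cut_height <= 1:
        raise CartxError("cut_height must be in (0, 1]")
    features = list(tom.index)
    n = len(features)
    if n == 1:
        return pd.Series([GREY], index=features, name="module")

    D = 1.0 - tom.values
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = linkage(squareform(D, checks=False), method="average")
    max_height = Z[:, 2].max() if len(Z) else 0.0
    if max_height == 0:
        clusters = np.ones(n, dtype=int)
    else:
        clusters = fcluster(Z, t=cut_height * max_height, criterion="distance")

    labels = _label_clusters(features, clusters, min_module_size)
    return pd.Series(labels, index=features, name="module")


def _label_clusters(
    features: list[str], clusters: np.ndarray, min_module_size: int
) -> list[str]:
    members: dict[int, list[str]] = {}
    for f, c in zip(features, clusters):
        members.setdefault(int(c), []).append(f)
    surviving = [
        (len(m), min(m), c) for c, m in members.items() if len(m) >= min_module_size
    ]
    # size descending, then smallest member id ascending
    surviving.sort(key=lambda t: (-t[0], t[1]))
    color_of: dict[int, str] = {}
    for rank, (_, _, c) in enumerate(surviving):
        color_of[c] = (
            MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        )
    return [color_of.get(int(c), GREY) for c in clusters]


def module_eigengene(expr: ExpressionMatrix, assignment: pd.Series) -> pd.DataFrame:
    """First-PC summary profile per module (modules x samples).

    Each module's submatrix is z-scored per feature; the eigengene is the
    leading right singular vector across samples, rescaled to unit variance
    and oriented so it correlates non-negatively with the module's mean
    z-scored profile.
    """
    profiles = {}
    for label in sorted(set(assignment) - {GREY}):
        members = list(assignment.index[assignment == label])
        if len(members) < 2:
            raise CartxError(f"module {label!r} has fewer than 2 members")
        sub = expr.data.loc[members].values
        sd = sub.std(axis=1, ddof=1)
        if (sd == 0).all():
            raise CartxError(f"module {label!r} contains only constant features")
        keep = sd > 0
        sub = sub[keep]
        Z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=1, keepdims=True)
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        pc = vt[0]
        pc = pc - pc.mean()
        pc_sd = pc.std(ddof=1)
        if pc_sd > 0:
            pc = pc / pc_sd
        if np.dot(pc, Z.mean(axis=0)) < 0:
            pc = -pc
        profiles[label] = pc
    out = pd.DataFrame(profiles, index=expr.sample_ids).T
    out.index.name = "module"
    return out


def pathway_activity(expr: ExpressionMatrix, gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Per-sample pathway scores: mean z-score of member features (sets x samples)."""
    X = expr.data
    sd = X.std(axis=1, ddof=1)
    usable = sd > 0
    Z = X.loc[usable].sub(X.loc[usable].mean(axis=1), axis=0).div(sd[usable], axis=0)
    rows = {}
    for name, members in gene_sets.items():
        present = [g for g in members if g in Z.index]
        if not present:
            continue
        rows[name] = Z.loc[present].mean(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "set"
    return out


def module_feature_correlation(
    eigengenes: pd.DataFrame,
    feature_profiles: pd.DataFrame,
    r_min: float = 0.9,
    p_max: float = 1e-6,
) -> pd.DataFrame:
    """Correlate module eigengenes with external per-sample profiles.

    ``feature_profiles`` is profiles x samples (pathway activity scores,
    traits, ...). Rows are flagged significant when ``r > r_min`` and
    ``p < p_max``.
    """
    if list(eigengenes.columns) != list(feature_profiles.columns):
        raise CartxError("eigengenes and feature profiles must share sample ordering")
    rows = []
    for module in eigengenes.index:
        e = eigengenes.loc[module].values
        for prof in feature_profiles.index:
            y = feature_profiles.loc[prof].values
            res = pearson_with_p(e, y)
            rows.append(
                {
                    "module": module,
                    "profile": prof,
                    "r": res.r,
                    "p": res.p,
                    "significant": bool(res.r > r_min and res.p < p_max),
                }
            )
    return pd.DataFrame(rows)


def top_corr_pairs(
    set_a: list[str],
    set_b: list[str],
    expr: ExpressionMatrix,
    n_top: int = 200,
    r_min: float = 0.9,
    p_max: float = 1e-6,
) -> pd.DataFrame:
    """Top cross-set correlated pairs (e.g. coding gene vs lncRNA).

    All (a, b) pairs with ``r > r_min`` and ``p < p_max``, ranked by |r|
    descending (ties: smaller p, then lexicographic pair), truncated to
    ``n_top``. The ``truncated`` attribute on the result records whether
    fewer pairs passed than requested.
    """
    if n_top < 1:
        raise CartxError("n_top must be >= 1")
    if set(set_a) & set(set_b):
        raise CartxError("feature sets must be disjoint")
    if not set_a or not set_b:
        return pd.DataFrame(columns=["feature_a", "feature_b", "r", "p"])
    sub = expr.subset_features(list(set_a) + list(set_b))
    n = sub.n_samples
    X = sub.data.values
    Xa = X[: len(set_a)]
    Xb = X[len(set_a) :]
    Za = _rowwise_standardize(Xa)
    Zb = _rowwise_standardize(Xb)
    R = np.clip(Za @ Zb.T / (n - 1), -1.0, 1.0)
    P = _p_from_r(R, n)
    rows = []
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            r, p = float(R[i, j]), float(P[i, j])
            if r > r_min and p < p_max:
                rows.append({"feature_a": a, "feature_b": b, "r": r, "p": p})
    table = pd.DataFrame(rows, columns=["feature_a", "feature_b", "r", "p"])
    if len(table):
        table["abs_r"] = table["r"].abs()
        table = table.sort_values(
            ["abs_r", "p", "feature_a", "feature_b"], ascending=[False, True, True, True]
        ).drop(columns="abs_r")
    n_passing = len(table)
    table = table.head(n_top).reset_index(drop=True)
    table.attrs["n_passing"] = n_passing
    table.attrs["truncated"] = n_passing > n_top
    return table


def _rowwise_standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = np.inf  # constant rows correlate with nothing
    return (X - mu) / sd
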