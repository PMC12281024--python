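"""Multivariate association statistics and path-effect decomposition.

Implements, from first principles on numpy primitives:

- Bray-Curtis dissimilarities between abundance profiles;
- the Mantel permutation test of correlation between two distance
  matrices (Pearson or Spearman);
- sequential-term PERMANOVA (added-in-order sums of squares on the
  Gower-centred inner-product matrix, significance by free permutation
  of sample labels);
- standardised ordinary least squares with partial correlations;
- the piecewise path decomposition separating the direct effect of a
  diet component on body mass from the indirect effect mediated by gut
  microbiome diversity (indirect = a*b, total = c' + a*b).

Permutation p-values use the (b + 1) / (m + 1) estimator with the
observed statistic counted, so a p-value of exactly zero is impossible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DistanceMatrix",
    "PermutationTestResult",
    "PathModelResult",
    "bray_curtis",
    "mantel_test",
    "permanova_sequential",
    "standardized_ols",
    "path_decomposition",
]


class AssociationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal dissimilarities between samples."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise AssociationError("duplicate sample ids")
        if self.values.shape != (n, n):
            raise AssociationError(
                f"distance matrix shape {self.values.shape} != ({n}, {n})"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise AssociationError("distance matrix not symmetric")
        if np.abs(np.diag(self.values)).max(initial=0.0) != 0.0:
            raise AssociationError("distance matrix diagonal not zero")
        if (self.values < 0).any():
            raise AssociationError("negative dissimilarities")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries (row-major, i > j)."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def reorder(self, ids: list[str]) -> "DistanceMatrix":
        pos = {s: k for k, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise AssociationError(f"ids not in distance matrix: {missing[:5]}")
        idx = np.array([pos[s] for s in ids])
        return DistanceMatrix(ids=list(ids), values=self.values[np.ix_(idx, idx)])


def bray_curtis(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarity ``sum|x - y| / sum(x + y)`` per sample pair.

    Accepts a samples-by-taxa DataFrame, a
    :class:`~dietlink.curation.SampleCompositionTable` (rows = samples),
    or a :class:`~dietlink.diversity.MicrobiomeCountTable`
    (columns = samples).
    """
    if hasattr(table, "rra"):            # SampleCompositionTable
        frame = table.rra
    elif hasattr(table, "counts") and hasattr(table, "asv_ids"):
        frame = table.counts.T           # MicrobiomeCountTable: samples x ASVs
    else:
        frame = pd.DataFrame(table)
    x = frame.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise AssociationError("need >= 2 samples")
    if (x < 0).any():
        raise AssociationError("negative abundances")
    row_tot = x.sum(axis=1)
    if (row_tot == 0).any():
        bad = frame.index[row_tot == 0][0]
        raise AssociationError(f"sample {bad!r} has all-zero abundances")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = row_tot[:, None] + row_tot[None, :]
    d = num / den
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)                  # kill fp asymmetry
    return DistanceMatrix(ids=list(frame.index), values=d)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class PermutationTestResult:
    statistic: float
    n_permutations: int
    p_value: float
    seed: int
    null_statistics: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise AssociationError(f"p-value {self.p_value} outside (0, 1]")


def _rank(a: np.ndarray) -> np.ndarray:
    """Average ranks along the last axis (tie-aware, vectorised)."""
    order = np.argsort(a, axis=-1, kind="stable")
    inv = np.argsort(order, axis=-1, kind="stable")
    s = np.take_along_axis(a, order, axis=-1)
    # average rank for ties: cumulative means over tied runs
    ranks_sorted = np.empty_like(s)
    base = np.arange(1, a.shape[-1] + 1, dtype=float)
    if a.ndim == 1:
        ranks_sorted = _average_ties(s, base)
        return ranks_sorted[inv]
    out = np.empty_like(a, dtype=float)
    for k in range(a.shape[0]):
        out[k] = _average_ties(s[k], base)[inv[k]]
    return out


def _average_ties(sorted_vals: np.ndarray, base: np.ndarray) -> np.ndarray:
    ranks = base.copy()
    n = len(sorted_vals)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        if j > i:
            ranks[i:j + 1] = ranks[i:j + 1].mean()
        i = j + 1
    return ranks


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector ``a`` with each row of ``b``."""
    a = a - a.mean()
    b = b - b.mean(axis=-1, keepdims=True)
    denom = np.sqrt((a @ a) * (b * b).sum(axis=-1))
    return (b @ a) / denom


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 10_000,
    seed: int = 0,
    store_null: bool = False,
) -> PermutationTestResult:
    """Mantel test of matrix correlation between ``d1`` and ``d2``.

    The statistic is the (Pearson or Spearman) correlation of the
    lower-triangle entries; the null distribution is built by jointly
    permuting rows and columns of ``d2``; the p-value is one-sided
    (upper tail).
    """
    if method not in ("pearson", "spearman"):
        raise AssociationError(f"unknown method {method!r}")
    if d1.ids != d2.ids:
        only1 = set(d1.ids) - set(d2.ids)
        only2 = set(d2.ids) - set(d1.ids)
        if only1 or only2:
            raise AssociationError(
                f"sample id mismatch; only in first: {sorted(only1)[:5]}, "
                f"only in second: {sorted(only2)[:5]}"
            )
        d2 = d2.reorder(d1.ids)
    n = d1.n
    tri = np.tril_indices(n, k=-1)
    v1 = d1.values[tri]
    if method == "spearman":
        v1 = _rank(v1)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    m2 = d2.values
    v2_obs = m2[tri]
    # permuted lower triangles, gathered in one shot: (n_perm, n(n-1)/2)
    v2_perm = m2[perms[:, tri[0]], perms[:, tri[1]]]
    if method == "spearman":
        v2_obs = _rank(v2_obs)
        v2_perm = _rank(v2_perm)
    stat = float(_pearson_rows(v1, v2_obs[None, :])[0])
    null = _pearson_rows(v1, v2_perm)
    p = (int(np.sum(null >= stat)) + 1) / (n_perm + 1)
    return PermutationTestResult(
        statistic=stat, n_permutations=n_perm, p_value=p, seed=seed,
        null_statistics=null if store_null else None,
    )


# ---------------------------------------------------------------------------
# sequential PERMANOVA
# ---------------------------------------------------------------------------

def _design_columns(design: pd.DataFrame, term: str) -> np.ndarray:
    """Model-matrix columns for one term (dummies for categoricals)."""
    col = design[term]
    if (col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype)
            or col.dtype == bool):
        dummies = pd.get_dummies(col, drop_first=True, dtype=float)
        return dummies.to_numpy()
    return col.to_numpy(dtype=float)[:, None]


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T


def permanova_sequential(
    d: DistanceMatrix,
    design: pd.DataFrame,
    terms: list[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sequential (added-in-order) PERMANOVA of ``d`` on ``terms``.

    The squared distances are Gower-centred,
    ``G = -1/2 J (D o D) J`` with ``J = I - 11'/n``; each term's sum of
    squares is ``tr((H_k - H_{k-1}) G)`` for the hat matrices of the
    cumulative design (intercept first), pseudo-F is
    ``(SS_term/df_term) / (SS_resid/df_resid)``, and R-squared is
    ``SS_term / SS_total``. Significance comes from free permutation of
    the sample labels of ``d``, recomputing the whole sequential table
    each time. Term order matters and is the caller's model statement
    (e.g. valley, then year, then dietary Salix).

    Returns a DataFrame indexed by term (+ ``Residual``, ``Total``) with
    columns ``df``, ``ss``, ``pseudo_f``, ``r2``, ``p_value``.
    """
    if list(design.index) != list(d.ids):
        design = design.loc[list(d.ids)]
    n = d.n
    missing = [t for t in terms if t not in design.columns]
    if missing:
        raise AssociationError(f"terms not in design: {missing}")

    g = _gower_center(d.values)
    ss_total = float(np.trace(g))

    # cumulative hat matrices and per-term projector increments
    ones = np.ones((n, 1))
    x = ones
    hats = [_hat(x)]
    dfs: list[int] = []
    for term in terms:
        cols = _design_columns(design, term)
        x = np.hstack([x, cols])
        rank_prev = int(np.round(np.trace(hats[-1])))
        h = _hat(x)
        rank_now = int(np.round(np.trace(h)))
        df_term = rank_now - rank_prev
        if df_term < cols.shape[1]:
            raise AssociationError(
                f"term {term!r} is rank-deficient given the preceding terms"
            )
        dfs.append(df_term)
        hats.append(h)
    deltas = [hats[k + 1] - hats[k] for k in range(len(terms))]
    resid_proj = np.eye(n) - hats[-1]
    df_resid = n - 1 - sum(dfs)
    if df_resid <= 0:
        raise AssociationError("no residual degrees of freedom")

    def table_for(gmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ss = np.array([float(np.sum(dl * gmat)) for dl in deltas])
        ss_res = float(np.sum(resid_proj * gmat))
        f = (ss / np.array(dfs)) / (ss_res / df_resid)
        return ss, f

    ss_obs, f_obs = table_for(g)
    ss_resid = ss_total - ss_obs.sum()

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms), dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        _, f_perm = table_for(gp)
        exceed += f_perm >= f_obs
    p = (exceed + 1) / (n_perm + 1)

    rows = []
    for k, term in enumerate(terms):
        rows.append({"df": dfs[k], "ss": ss_obs[k], "pseudo_f": f_obs[k],
                     "r2": ss_obs[k] / ss_total, "p_value": p[k]})
    rows.append({"df": df_resid, "ss": ss_resid, "pseudo_f": np.nan,
                 "r2": ss_resid / ss_total, "p_value": np.nan})
    rows.append({"df": n - 1, "ss": ss_total, "pseudo_f": np.nan,
                 "r2": 1.0, "p_value": np.nan})
    return pd.DataFrame(rows, index=[*terms, "Residual", "Total"])


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d * d
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


# ---------------------------------------------------------------------------
# standardised OLS and path decomposition
# ---------------------------------------------------------------------------

def _zscore(v: np.ndarray, name: str) -> np.ndarray:
    sd = np.std(v, ddof=1)
    if sd < 1e-12:
        raise AssociationError(f"variable {name!r} is constant; cannot z-score")
    return (v - v.mean()) / sd


def standardized_ols(
    response: np.ndarray | pd.Series,
    predictors: pd.DataFrame,
    cond_threshold: float = 1e8,
) -> pd.DataFrame:
    """OLS on z-scored variables, with t-based partial correlations.

    Continuous variables (response and numeric predictors) are z-scored
    with the n-1 denominator; boolean/categorical predictors enter as
    0/1 dummies (first level as reference). The partial correlation of
    each predictor is derived from its t statistic,
    ``r = t / sqrt(t^2 + df_resid)``, which carries the coefficient's
    sign.

    Returns a DataFrame indexed by predictor with columns ``coef``,
    ``se``, ``t``, ``partial_r``.
    """
    y = np.asarray(response, dtype=float).ravel()
    n = len(y)
    cols: list[np.ndarray] = []
    names: list[str] = []
    for name in predictors.columns:
        col = predictors[name]
        if (col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype)):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True,
                                     dtype=float)
            for dcol in dummies.columns:
                cols.append(dummies[dcol].to_numpy())
                names.append(dcol)
        elif col.dtype == bool:
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
        else:
            cols.append(_zscore(col.to_numpy(dtype=float), name))
            names.append(name)
    x = np.column_stack(cols)
    if n <= x.shape[1] + 1:
        raise AssociationError(
            f"n={n} too small for {x.shape[1]} predictors"
        )
    if np.linalg.cond(np.column_stack([np.ones(n), x])) > cond_threshold:
        raise AssociationError("predictors are (near-)collinear")
    zy = _zscore(y, "response")
    fit = sm.OLS(zy, sm.add_constant(x, has_constant="add")).fit()
    coefs = fit.params[1:]
    ses = fit.bse[1:]
    tvals = fit.tvalues[1:]
    partial = tvals / np.sqrt(tvals ** 2 + fit.df_resid)
    return pd.DataFrame(
        {"coef": coefs, "se": ses, "t": tvals, "partial_r": partial},
        index=names,
    )


@dataclass
class PathModelResult:
    """Direct vs microbiome-mediated effect of a diet component on mass.

    ``a`` — diet component -> diversity; ``b`` — diversity -> mass given
    the diet component; ``c_direct`` — diet component -> mass given
    diversity. ``indirect = a * b`` and ``total = c_direct + a * b`` by
    construction.
    """

    a: float
    b: float
    c_direct: float
    diversity_metric: str = "shannon"
    a_partial_r: float | None = None
    b_partial_r: float | None = None
    c_partial_r: float | None = None
    indirect: float = field(init=False)
    total: float = field(init=False)
    direct_exceeds_indirect: bool = field(init=False)

    def __post_init__(self) -> None:
        self.indirect = self.a * self.b
        self.total = self.c_direct + self.indirect
        self.direct_exceeds_indirect = abs(self.c_direct) > abs(self.indirect)


def path_decomposition(
    salix: np.ndarray | pd.Series,
    diversity: np.ndarray | pd.Series,
    mass: np.ndarray | pd.Series,
    adjusters: pd.DataFrame | None = None,
    metric: str = "shannon",
) -> PathModelResult:
    """Piecewise path model: diet component -> diversity -> body mass.

    Two standardised OLS equations are fitted:
    ``diversity ~ salix [+ adjusters]`` (giving ``a``) and
    ``mass ~ salix + diversity [+ adjusters]`` (giving ``c_direct`` and
    ``b``). The indirect (microbiome-mediated) effect is the product
    ``a * b``; the total effect is ``c_direct + a * b``.
    """
    salix = np.asarray(salix, dtype=float).ravel()
    diversity = np.asarray(diversity, dtype=float).ravel()
    mass = np.asarray(mass, dtype=float).ravel()
    if not (len(salix) == len(diversity) == len(mass)):
        raise AssociationError("salix, diversity and mass lengths differ")
    if adjusters is not None and len(adjusters) != len(salix):
        raise AssociationError("adjusters length mismatch")

    x1 = pd.DataFrame({"salix": salix})
    x2 = pd.DataFrame({"salix": salix, "diversity": diversity})
    if adjusters is not None:
        x1 = pd.concat([x1, adjusters.reset_index(drop=True)], axis=1)
        x2 = pd.concat([x2, adjusters.reset_index(drop=True)], axis=1)
    eq1 = standardized_ols(diversity, x1)
    eq2 = standardized_ols(mass, x2)
    return PathModelResult(
        a=float(eq1.loc["salix", "coef"]),
        b=float(eq2.loc["diversity", "coef"]),
        c_direct=float(eq2.loc["salix", "coef"]),
        diversity_metric=metric,
        a_partial_r=float(eq1.loc["salix", "partial_r"]),
        b_partial_r=float(eq2.loc["diversity", "partial_r"]),
        c_partial_r=float(eq2.loc["salix", "partial_r"]),
    )
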