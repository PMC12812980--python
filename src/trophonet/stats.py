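"""Correlation and permutation-test machinery.

Tie-aware Spearman correlation (matrix form over all taxon pairs with
Benjamini–Hochberg FDR control), Mantel and partial Mantel permutation
tests on distance matrices, and a distance-based permutation correlation
between a single environmental variable and a community distance matrix.

All permutation procedures are reproducible given (inputs, n_perm, seed)
and use the add-one p-value formula p = (1 + #{r_perm ≥ r_obs}) / (1 + B),
one-tailed "greater" by default, so p has resolution 1/(B + 1) and is never
exactly zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps

__all__ = [
    "CorrelationResult",
    "MantelResult",
    "spearman_rho",
    "spearman_pvalue",
    "correlation_matrix",
    "bh_fdr",
    "mantel_test",
    "partial_mantel",
    "env_community_correlation",
]

# Exact permutation null for Spearman p below this sample size; the
# t-distribution approximation above it.
EXACT_P_MAX_N = 10


@dataclass(frozen=True)
class CorrelationResult:
    """One unordered taxon pair's Spearman correlation with raw and FDR p."""

    taxon_i: str
    taxon_j: str
    rho: float
    p_raw: float
    q: float


@dataclass(frozen=True)
class MantelResult:
    """Result of a (partial) Mantel permutation test."""

    r: float
    p: float
    n_perm: int
    seed: int | None
    method: str
    n: int
    defined: bool = True
    note: str = ""


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Ties receive average ranks.  A constant input vector makes the
    correlation undefined; NaN is returned as the flagged missing value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 4:
        raise ValueError(f"need at least 4 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    rx, ry = _rank(x), _rank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


def _t_sf_two_sided(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation t = r sqrt((n−2)/(1−r²))."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(rho) >= 1.0, 0.0, np.clip(p, 0.0, 1.0))


def _exact_perm_pvalue(rx: np.ndarray, ry: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman rho at small n.

    Enumerates all n! orderings of the y ranks; the identity permutation is
    part of the reference set, so p > 0.
    """
    n = rx.size
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = math.sqrt((cx @ cx) * (cy @ cy))
    obs = abs(cx @ cy) / denom
    perms = np.array(list(itertools.permutations(range(n))))
    stats = np.abs(cy[perms] @ cx) / denom
    return float(np.mean(stats >= obs - 1e-12))


def spearman_pvalue(x, y) -> tuple[float, float]:
    """(rho, two-sided p).  Exact permutation null for n < 10, t otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = spearman_rho(x, y)
    if math.isnan(rho):
        return rho, math.nan
    n = x.size
    if n < EXACT_P_MAX_N:
        p = _exact_perm_pvalue(_rank(x), _rank(y))
    else:
        p = float(_t_sf_two_sided(np.array([rho]), n)[0])
    return rho, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in the input order.

    q_(i) = min_{j ≥ i} m p_(j) / j, clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def correlation_matrix(matrix, *, taxa=None) -> pd.DataFrame:
    """All-pairs Spearman correlations with BH-FDR over the full pair set.

    Parameters
    ----------
    matrix:
        Taxa × samples numeric array or DataFrame (rows are variables).
    taxa:
        Row labels; taken from the DataFrame index when available.

    Returns
    -------
    DataFrame with one row per unordered pair: columns ``taxon_i``,
    ``taxon_j``, ``rho``, ``p_raw``, ``q``.  Pairs involving a constant
    vector get NaN rho/p and are excluded from the BH family.
    """
    if isinstance(matrix, pd.DataFrame):
        if taxa is None:
            taxa = list(matrix.index)
        matrix = matrix.to_numpy(dtype=float)
    else:
        matrix = np.asarray(matrix, dtype=float)
        if taxa is None:
            taxa = [f"v{i}" for i in range(matrix.shape[0])]
    t, n = matrix.shape
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    ranks = np.apply_along_axis(_rank, 1, matrix)
    constant = np.ptp(matrix, axis=1) == 0
    with np.errstate(invalid="ignore"):
        rho_mat = np.corrcoef(ranks)
    iu, ju = np.triu_indices(t, k=1)
    rho = rho_mat[iu, ju]
    undef = constant[iu] | constant[ju]
    rho = np.where(undef, np.nan, rho)
    if n < EXACT_P_MAX_N:
        p = np.array(
            [
                math.nan if undef[k] else _exact_perm_pvalue(ranks[iu[k]], ranks[ju[k]])
                for k in range(rho.size)
            ]
        )
    else:
        p = np.where(undef, np.nan, _t_sf_two_sided(rho, n))
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = bh_fdr(p[ok])
    taxa = list(taxa)
    return pd.DataFrame(
        {
            "taxon_i": [taxa[i] for i in iu],
            "taxon_j": [taxa[j] for j in ju],
            "rho": rho,
            "p_raw": p,
            "q": q,
        }
    )


def _check_distance_matrix(d, name: str) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if d.shape[0] < 4:
        raise ValueError(f"{name} must have dimension >= 4")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError(f"{name} must have a zero diagonal")
    return d


def _upper(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def _vec_corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "spearman":
        a, b = _rank(a), _rank(b)
    a = a - a.mean()
    b = b - b.mean()
    den = math.sqrt((a @ a) * (b @ b))
    if den == 0:
        return math.nan
    return float((a @ b) / den)


def mantel_test(
    d1,
    d2,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "spearman",
    exact: bool = False,
) -> MantelResult:
    """Mantel permutation test of association between two distance matrices.

    The statistic is the (Spearman by default, Pearson optional)
    correlation of the upper-triangle entries; the null is generated by
    jointly permuting the rows and columns of ``d2``.  One-tailed
    ("greater") with the add-one formula.  ``exact=True`` enumerates all
    n! label permutations (n ≤ 8) and reports p = #{r_perm ≥ r_obs} / n!.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    d1 = _check_distance_matrix(d1, "d1")
    d2 = _check_distance_matrix(d2, "d2")
    if d1.shape != d2.shape:
        raise ValueError("distance matrices must have the same dimension")
    n = d1.shape[0]
    v1 = _upper(d1)
    r_obs = _vec_corr(v1, _upper(d2), method)
    if math.isnan(r_obs):
        return MantelResult(math.nan, math.nan, 0, seed, method, n,
                            defined=False, note="constant distances")
    if exact:
        if n > 8:
            raise ValueError("exact enumeration supported only for n <= 8")
        perms = list(itertools.permutations(range(n)))
        count = 0
        for perm in perms:
            idx = np.asarray(perm)
            r_p = _vec_corr(v1, _upper(d2[np.ix_(idx, idx)]), method)
            if r_p >= r_obs - 1e-12:
                count += 1
        return MantelResult(r_obs, count / len(perms), len(perms), seed, method, n)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        r_p = _vec_corr(v1, _upper(d2[np.ix_(idx, idx)]), method)
        if r_p >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r_obs, p, n_perm, seed, method, n)


def _residualize(v: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Residuals of v after least-squares removal of [1, c]."""
    X = np.column_stack([np.ones_like(c), c])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_mantel(
    d1,
    d2,
    d_control,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "spearman",
) -> MantelResult:
    """Partial Mantel test of d1 vs d2 controlling for d_control.

    The upper triangles (rank-transformed under the Spearman method) of d1
    and d2 are residualized on d_control by least squares; the statistic is
    the Pearson correlation of the residuals.  The null permutes d2's
    labels as in :func:`mantel_test`.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    d1 = _check_distance_matrix(d1, "d1")
    d2 = _check_distance_matrix(d2, "d2")
    dc = _check_distance_matrix(d_control, "d_control")
    if not (d1.shape == d2.shape == dc.shape):
        raise ValueError("all three matrices must have the same dimension")
    n = d1.shape[0]

    def prep(v):
        return _rank(v) if method == "spearman" else v

    vc = prep(_upper(dc))
    r1 = _residualize(prep(_upper(d1)), vc)

    def stat(mat2):
        r2 = _residualize(prep(_upper(mat2)), vc)
        return _vec_corr(r1, r2, "pearson")

    r_obs = stat(d2)
    if math.isnan(r_obs):
        return MantelResult(math.nan, math.nan, 0, seed, method, n,
                            defined=False, note="constant residuals")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        r_p = stat(d2[np.ix_(idx, idx)])
        if r_p >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r_obs, p, n_perm, seed, method, n)


def env_community_correlation(
    env,
    community_dist,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "spearman",
) -> MantelResult:
    """Permutation correlation between one environmental variable and a
    community distance matrix.

    The variable is standardized and turned into a Euclidean distance
    matrix, then tested against the community distances with
    :func:`mantel_test`.  This is a distance-based approximation of the
    envfit-style Monte Carlo vector test; it shares the sign and
    significance logic but not the fitted coefficients.
    """
    env = np.asarray(env, dtype=float)
    d = _check_distance_matrix(community_dist, "community_dist")
    if env.ndim != 1 or env.size != d.shape[0]:
        raise ValueError("env length must match the distance matrix dimension")
    if np.ptp(env) == 0:
        return MantelResult(math.nan, math.nan, 0, seed, method, env.size,
                            defined=False, note="constant environmental variable")
    z = (env - env.mean()) / env.std()
    d_env = np.abs(z[:, None] - z[None, :])
    return mantel_test(d_env, d, n_perm=n_perm, seed=seed, method=method)
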