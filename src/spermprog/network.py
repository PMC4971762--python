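"""Genes x features matrix assembly and partial-correlation networks.

Features (promoter histone-mark levels, nucleosome occupancy, DNA
methylation, embryo expression) are inner-joined on gene id and z-scored
per column. The partial-correlation matrix comes from the inverse of a
shrunk correlation matrix, S* = (1 - lambda) R + lambda I, with the
closed-form shrinkage intensity of Schafer & Strimmer toward the
identity-correlation target ("auto"), or any fixed lambda in [0, 1].
Edges are tested analytically: t = pcor * sqrt((n - k) / (1 - pcor^2))
on n - k degrees of freedom, BH-adjusted over the k(k-1)/2 edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .multtest import bh_adjust

logger = logging.getLogger("spermprog")


def build_feature_matrix(
    features: dict[str, pd.Series], gene_set, min_coverage: float = 0.8
) -> pd.DataFrame:
    """Assemble and z-score the genes x features matrix.

    ``features`` maps feature name -> per-gene values (indexed by
    gene_id). Genes of ``gene_set`` missing any feature are dropped with
    a logged count; each feature must cover at least ``min_coverage`` of
    the set. A constant column is an error.
    """
    genes = sorted(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    cols = {}
    for name, series in features.items():
        covered = sum(g in series.index for g in genes)
        if covered < min_coverage * len(genes):
            raise ValueError(
                f"feature {name!r} covers only {covered}/{len(genes)} genes "
                f"(need >= {min_coverage:.0%})"
            )
        cols[name] = series
    df = pd.DataFrame(cols).reindex(genes).dropna()
    n_dropped = len(genes) - len(df)
    if n_dropped:
        logger.info("feature matrix: dropped %d genes lacking a feature", n_dropped)
    for name in df.columns:
        if np.isclose(df[name].std(ddof=1), 0):
            raise ValueError(f"constant feature column {name!r}")
    z = (df - df.mean()) / df.std(ddof=1)
    return z


def shrinkage_intensity(X: np.ndarray) -> float:
    """Closed-form optimal shrinkage toward the identity-correlation
    target (Schafer-Strimmer): lambda* = sum Var(r_ij) / sum r_ij^2 over
    off-diagonal entries, clipped to [0, 1]."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    r = (Xs.T @ Xs) / (n - 1)
    w_bar = r * (n - 1) / n
    var_r = np.zeros((k, k))
    for i in range(k):
        wi = Xs[:, i][:, None] * Xs
        var_r[i] = n / (n - 1) ** 3 * ((wi - w_bar[i]) ** 2).sum(axis=0)
    off = ~np.eye(k, dtype=bool)
    denom = (r[off] ** 2).sum()
    if denom <= 0:
        return 1.0
    return float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))


def partial_correlation_matrix(
    X: pd.DataFrame | np.ndarray, shrinkage: float | str = "auto"
) -> tuple[np.ndarray, float]:
    """Partial correlations from the shrunk correlation matrix.

    Returns (pcor, lambda_used); pcor has unit diagonal and
    pcor_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj) off the diagonal,
    Omega = inv((1 - lambda) R + lambda I).
    """
    arr = np.asarray(X, dtype=float)
    n, k = arr.shape
    if n <= k:
        logger.warning("partial correlation with n = %d rows <= k = %d features", n, k)
    if shrinkage == "auto":
        lam = shrinkage_intensity(arr)
    else:
        lam = float(shrinkage)
        if not (0 <= lam <= 1):
            raise ValueError("shrinkage must lie in [0, 1] or be 'auto'")
    r = np.corrcoef(arr, rowvar=False)
    s_star = (1 - lam) * r + lam * np.eye(k)
    try:
        omega = np.linalg.inv(s_star)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "shrunk correlation matrix is singular; use shrinkage > 0"
        ) from exc
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = np.clip((pcor + pcor.T) / 2, -1.0, 1.0)
    np.fill_diagonal(pcor, 1.0)
    return pcor, lam


def edge_significance(pcor: np.ndarray, n: int, names=None) -> pd.DataFrame:
    """Analytic two-sided edge test for every feature pair.

    t = pcor * sqrt((n - k) / (1 - pcor^2)) on n - k degrees of freedom
    (k - 2 controlled variables plus the pair); BH over all edges.
    """
    pcor = np.asarray(pcor)
    k = pcor.shape[0]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 rows (n = {n}, k = {k})")
    if names is None:
        names = [f"f{i}" for i in range(k)]
    dof = n - k
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            r = pcor[i, j]
            if abs(r) >= 1.0:
                logger.warning("edge %s-%s: |pcor| = 1, p = 0", names[i], names[j])
                p = 0.0
            else:
                t = r * np.sqrt(dof / (1 - r**2))
                p = 2 * stats.t.sf(abs(t), dof)
            rows.append((names[i], names[j], r, p))
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "pcor", "p"])
    edges["q"] = bh_adjust(edges["p"])
    return edges


@dataclass
class PcorNetwork:
    nodes: list[str]
    edges: pd.DataFrame  # node_a, node_b, pcor, p, q, kept, sign, weight
    shrinkage: float = field(default=np.nan)

    def kept_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["kept"]]

    def edge(self, a: str, b: str) -> pd.Series:
        e = self.edges
        m = ((e["node_a"] == a) & (e["node_b"] == b)) | (
            (e["node_a"] == b) & (e["node_b"] == a)
        )
        if not m.any():
            raise KeyError(f"no edge {a} - {b}")
        return e[m].iloc[0]


def build_network(
    edges: pd.DataFrame, q_threshold: float = 0.05, nodes=None, shrinkage: float = np.nan
) -> PcorNetwork:
    """Threshold the edge table into a signed weighted network; isolated
    nodes are retained."""
    if not (0 < q_threshold < 1):
        raise ValueError("q_threshold must be in (0, 1)")
    e = edges.copy()
    e["kept"] = e["q"] < q_threshold
    e["sign"] = np.where(e["pcor"] > 0, "positive", np.where(e["pcor"] < 0, "negative", "none"))
    e["weight"] = e["pcor"].abs()
    if nodes is None:
        nodes = sorted(set(e["node_a"]) | set(e["node_b"]))
    return PcorNetwork(nodes=list(nodes), edges=e, shrinkage=shrinkage)


def infer_network(
    X: pd.DataFrame, shrinkage: float | str = "auto", q_threshold: float = 0.05
) -> PcorNetwork:
    """Feature matrix -> thresholded partial-correlation network.

    Edge weights (the reported pcor) come from the shrunk estimator;
    p-values from the t-test on the sample (lambda = 0) partial
    correlation, whose sampling distribution the test actually
    describes — the shrunk estimate is biased toward zero by design and
    would make the analytic test arbitrarily conservative as lambda
    grows. If the sample correlation matrix is singular the shrunk
    values are tested instead (with a warning).
    """
    pcor, lam = partial_correlation_matrix(X, shrinkage)
    try:
        pcor_test, _ = partial_correlation_matrix(X, 0.0)
    except np.linalg.LinAlgError:
        logger.warning("sample correlation singular; testing shrunk pcor values")
        pcor_test = pcor
    edges = edge_significance(pcor_test, n=len(X), names=list(X.columns))
    edges["pcor"] = [
        pcor[list(X.columns).index(a), list(X.columns).index(b)]
        for a, b in zip(edges["node_a"], edges["node_b"])
    ]
    return build_network(edges, q_threshold, nodes=list(X.columns), shrinkage=lam)


def permutation_edge_pvalue(
    X: pd.DataFrame,
    node_a: str,
    node_b: str,
    n_perm: int = 1000,
    shrinkage: float | str = "auto",
    rng: np.random.Generator | None = None,
) -> float:
    """Seeded permutation cross-check for one edge: the column of
    ``node_b`` is randomly rotated and the |pcor| of the pair is
    re-measured; p is the fraction of permutations at least as extreme
    (with the +1 correction)."""
    if rng is None:
        rng = np.random.default_rng(0)
    cols = list(X.columns)
    ia, ib = cols.index(node_a), cols.index(node_b)
    arr = np.asarray(X, dtype=float)
    obs = abs(partial_correlation_matrix(arr, shrinkage)[0][ia, ib])
    n = len(arr)
    hits = 0
    for _ in range(n_perm):
        perm = arr.copy()
        shift = int(rng.integers(1, n))
        perm[:, ib] = np.roll(perm[:, ib], shift)
        if abs(partial_correlation_matrix(perm, shrinkage)[0][ia, ib]) >= obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)
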