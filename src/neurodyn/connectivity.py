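"""Gaussian-copula information-theoretic connectivity and weighted graph
metrics.

ROI time series are rank-normalized to standard-normal margins (the
Gaussian copula transform), after which information quantities have closed
Gaussian forms in nats:

* pairwise mutual information  MI = -1/2 ln(1 - rho^2);
* conditional mutual information, conditioning on all remaining ROIs,
  through partial correlations from the inverse of the (shrinkage-
  regularized) correlation matrix;
* the O-information  Omega = (d-2) H(X) + sum_i [H(X_i) - H(X_{-i})],
  with entropies from log-determinants of correlation submatrices —
  positive when redundancy dominates, negative when synergy dominates.

Graph metrics (global efficiency, weighted transitivity, density,
small-worldness) are computed on the max-rescaled weight matrices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import networkx as nx
from scipy import stats
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "copula_transform", "mi_matrix", "cmi_matrix", "o_information",
    "o_information_matrix", "graph_metrics", "ConnectivityGraph",
    "GraphMetrics", "connectivity_graph",
]

#: cap applied when a pair is numerically perfectly correlated
MI_MAX = -0.5 * np.log(1e-12)


def copula_transform(series: np.ndarray) -> np.ndarray:
    """Per-row rank-normalization to standard-normal margins.

    Each row's ranks r (average rank for ties) map to
    ``Phi^{-1}((r - 0.5) / n)``.  Invariant to monotone transforms of a
    row.  Rows with heavy ties (> 50% duplicate samples) still transform
    but a warning is issued, since tied ranks distort the normal margins.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be 2-D (ROIs x samples)")
    n = series.shape[1]
    n_distinct = [len(np.unique(row)) for row in series]
    if min(n_distinct) < 16:
        raise ValueError("each row needs at least 16 distinct values")
    if any(nd < 0.5 * n for nd in n_distinct):
        import warnings

        warnings.warn("heavy ties in copula transform (>50% duplicates)",
                      stacklevel=2)
    ranks = np.apply_along_axis(stats.rankdata, 1, series)
    return stats.norm.ppf((ranks - 0.5) / n)


def _gaussian_mi(rho: np.ndarray) -> np.ndarray:
    r2 = np.clip(rho ** 2, 0.0, 1.0 - 1e-12)
    return -0.5 * np.log(1.0 - r2)


def mi_matrix(z: np.ndarray) -> np.ndarray:
    """Pairwise Gaussian-copula mutual information, nats.  Symmetric, zero
    diagonal; numerically perfect correlations are capped at
    ``-1/2 ln(1e-12)``."""
    rho = np.corrcoef(z)
    w = _gaussian_mi(rho)
    np.fill_diagonal(w, 0.0)
    return np.minimum(w, MI_MAX)


def _shrunk_correlation(z: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf-style shrinkage of the sample correlation toward the
    identity, keeping the matrix well conditioned at modest sample sizes."""
    from sklearn.covariance import LedoitWolf

    lw = LedoitWolf(assume_centered=False).fit(z.T)
    cov = lw.covariance_
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def cmi_matrix(z: np.ndarray) -> np.ndarray:
    """Pairwise conditional mutual information, conditioning each pair on
    all remaining ROIs, nats.

    Partial correlations come from the inverse of the shrinkage-regularized
    correlation matrix; for two ROIs the conditioning set is empty and the
    result equals the mutual information exactly.
    """
    p, n = z.shape
    if n <= 5 * p:
        raise ValueError("need n samples > 5 x n ROIs for full partialization")
    if p == 2:
        return mi_matrix(z)
    corr = _shrunk_correlation(z)
    try:
        prec = np.linalg.inv(corr)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "correlation matrix singular even after shrinkage") from exc
    d = np.sqrt(np.diag(prec))
    partial = -prec / np.outer(d, d)
    np.fill_diagonal(partial, 0.0)
    w = _gaussian_mi(partial)
    np.fill_diagonal(w, 0.0)
    return np.minimum(w, MI_MAX)


def _gaussian_entropy(corr: np.ndarray) -> float:
    """Differential entropy of a multivariate Gaussian with correlation
    matrix `corr`, nats."""
    d = corr.shape[0]
    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0:
        raise np.linalg.LinAlgError("correlation matrix not positive definite")
    return 0.5 * (d * np.log(2.0 * np.pi * np.e) + logdet)


def o_information(z_or_corr: np.ndarray, subset=None, *, is_correlation: bool = False) -> float:
    """Gaussian O-information of a set of >= 3 variables, nats.

    Omega = (d - 2) H(X) + sum_i [H(X_i) - H(X_{-i})].  Positive values
    indicate redundancy-dominated interaction, negative values synergy.
    Accepts normal-scores data (ROIs x samples) or, with
    ``is_correlation=True``, a correlation matrix directly.
    """
    if is_correlation:
        corr = np.asarray(z_or_corr, dtype=float)
    else:
        z = np.asarray(z_or_corr, dtype=float)
        if subset is not None:
            z = z[np.asarray(subset)]
        corr = np.corrcoef(z)
    d = corr.shape[0]
    if d < 3:
        raise ValueError("O-information needs at least 3 variables")
    h_all = _gaussian_entropy(corr)
    h1 = 0.5 * np.log(2.0 * np.pi * np.e)  # unit-variance margins
    omega = (d - 2.0) * h_all
    for i in range(d):
        rest = [j for j in range(d) if j != i]
        omega += h1 - _gaussian_entropy(corr[np.ix_(rest, rest)])
    return float(omega)


def o_information_matrix(z: np.ndarray) -> tuple[float, np.ndarray]:
    """System-wide O-information plus a per-edge matrix where entry (i, j)
    is the mean O-information over all ROI triplets containing the pair."""
    p = z.shape[0]
    corr = np.corrcoef(z)
    total = o_information(corr, is_correlation=True) if p >= 3 else np.nan
    edge = np.zeros((p, p))
    counts = np.zeros((p, p))
    for trip in itertools.combinations(range(p), 3):
        omega = o_information(corr[np.ix_(trip, trip)], is_correlation=True)
        for a, b in itertools.combinations(trip, 2):
            edge[a, b] += omega
            edge[b, a] += omega
            counts[a, b] += 1
            counts[b, a] += 1
    with np.errstate(invalid="ignore"):
        edge = np.where(counts > 0, edge / np.maximum(counts, 1), 0.0)
    return total, edge


# ---------------------------------------------------------------------------
# Graph metrics
# ---------------------------------------------------------------------------

@dataclass
class GraphMetrics:
    global_efficiency: float
    transitivity: float
    density: float
    small_worldness: float
    provenance: str = ""


@dataclass
class ConnectivityGraph:
    """Connectivity matrices for one recording, all in nats."""

    labels: list[str]
    w_mi: np.ndarray
    w_cmi: np.ndarray
    o_info_total: float
    w_oinfo: np.ndarray
    negative_oinfo_clipped: bool = False


def _global_efficiency(w: np.ndarray) -> float:
    """Mean over node pairs of 1/d_ij, with edge lengths 1/w (Dijkstra)."""
    n = w.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    d = dijkstra(lengths, directed=False)
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d[iu]) & (d[iu] > 0), 1.0 / d[iu], 0.0)
    return float(inv.mean()) if n > 1 else 0.0


def _weighted_transitivity(w: np.ndarray) -> float:
    """Geometric-mean triangle form: sum over nodes of cube-root triangle
    intensity divided by the number of connected triples."""
    wc = np.cbrt(w)
    num = float(np.trace(wc @ wc @ wc))
    k = (w > 0).sum(axis=1)
    den = float((k * (k - 1)).sum())
    return num / den if den > 0 else 0.0


def _binarize_proportional(w: np.ndarray, density: float) -> np.ndarray:
    """Keep the strongest `density` fraction of off-diagonal edges."""
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = w[iu]
    k = max(1, int(round(density * len(vals))))
    thresh = np.sort(vals)[::-1][k - 1]
    b = (w >= thresh) & (w > 0)
    np.fill_diagonal(b, False)
    return (b | b.T).astype(int)


def _small_worldness(w: np.ndarray, density: float, n_null: int, seed: int) -> float:
    """sigma = (C/C_rand) / (L/L_rand) on the binarized graph, null model =
    degree-preserving rewired graphs."""
    b = _binarize_proportional(w, density)
    g = nx.from_numpy_array(b)
    if g.number_of_edges() < 2:
        return np.nan
    comp = max(nx.connected_components(g), key=len)
    gc = g.subgraph(comp).copy()
    c_obs = nx.transitivity(g)
    l_obs = nx.average_shortest_path_length(gc)
    rng_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_null)
    c_null, l_null = [], []
    for s in rng_seeds:
        gr = g.copy()
        try:
            nx.double_edge_swap(gr, nswap=4 * gr.number_of_edges(),
                                max_tries=200 * gr.number_of_edges(), seed=int(s))
        except (nx.NetworkXError, nx.NetworkXAlgorithmError):
            pass  # partially rewired graph still serves as a null sample
        c_null.append(nx.transitivity(gr))
        compr = max(nx.connected_components(gr), key=len)
        l_null.append(nx.average_shortest_path_length(gr.subgraph(compr)))
    c_rand, l_rand = np.mean(c_null), np.mean(l_null)
    if c_rand == 0 or l_rand == 0 or l_obs == 0:
        return np.nan
    return float((c_obs / c_rand) / (l_obs / l_rand))


def graph_metrics(w: np.ndarray, sw_density: float = 0.3, n_null: int = 10,
                  seed: int = 0, provenance: str = "") -> GraphMetrics:
    """Weighted graph metrics of a symmetric non-negative matrix.

    Weights are rescaled to [0, 1] by their maximum.  Efficiency,
    transitivity and density use the fully weighted graph; small-worldness
    is computed on the graph binarized at `sw_density` proportional density
    (its null model is defined for binary graphs).
    """
    w = np.asarray(w, dtype=float)
    if w.shape[0] != w.shape[1] or not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("weight matrix must be square and symmetric")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    wmax = w.max()
    if wmax == 0:
        raise ValueError("all-zero weight matrix is degenerate")
    w = w / wmax
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    return GraphMetrics(
        global_efficiency=_global_efficiency(w),
        transitivity=_weighted_transitivity(w),
        density=float(w[iu].mean()),
        small_worldness=_small_worldness(w, sw_density, n_null, seed),
        provenance=provenance,
    )


def connectivity_graph(data: np.ndarray, labels: list[str]) -> ConnectivityGraph:
    """Full connectivity stack for one ROI-level recording: copula
    transform, MI/CMI matrices, and the O-information (system scalar plus
    triplet-averaged edge matrix with negative edges clipped to zero)."""
    z = copula_transform(data)
    w_mi = mi_matrix(z)
    w_cmi = cmi_matrix(z)
    total, w_oinfo = o_information_matrix(z)
    clipped = bool(np.any(w_oinfo < 0))
    w_oinfo = np.clip(w_oinfo, 0.0, None)
    return ConnectivityGraph(labels=list(labels), w_mi=w_mi, w_cmi=w_cmi,
                             o_info_total=total, w_oinfo=w_oinfo,
                             negative_oinfo_clipped=clipped)
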