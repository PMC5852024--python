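"""Phi-correlation similarity, hard-threshold adjacency, scale-free fit.

For diseases i and j in a fixed year, with C_ij patients having both, P_i
and P_j patients having each, and N patients in total, the phi-correlation

    s_ij = (C_ij * N - P_i * P_j) / sqrt(P_i * P_j * (N - P_i) * (N - P_j))

is the Pearson correlation of the two binary indicator vectors.  The
adjacency keeps |s_ij| for pairs passing a hard threshold tau and zeroes the
rest; tau is chosen by the scale-free topology criterion (linear fit of the
log-log binned connectivity distribution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from comorbnet.records import YearlyOccurrence

logger = logging.getLogger(__name__)

#: Default hard-threshold candidates: 0.005 to 0.10 in steps of 0.005.
DEFAULT_TAU_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.005, 0.1001, 0.005), 4))


def phi_correlation(C_ij: float, P_i: float, P_j: float, N: float) -> float:
    """Phi-correlation of two binary disease indicators from their counts.

    Returns NaN when either marginal is 0 or N (zero denominator); such
    pairs are excluded downstream.
    """
    if P_i in (0, N) or P_j in (0, N):
        return float("nan")
    num = C_ij * N - P_i * P_j
    den = np.sqrt(float(P_i) * P_j * (N - P_i) * (N - P_j))
    return float(num / den)


@dataclass
class SimilarityMatrix:
    """Symmetric phi-correlation matrix for one year; diagonal set to 0."""

    diseases: list[str]
    S: np.ndarray
    year: int

    @property
    def n(self) -> int:
        return len(self.diseases)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.diseases, columns=self.diseases)


@dataclass
class AdjacencyMatrix:
    """Hard-thresholded adjacency: entries in {0} | [tau, 1], zero diagonal."""

    diseases: list[str]
    A: np.ndarray
    tau: float
    year: int

    @property
    def n(self) -> int:
        return len(self.diseases)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.A, k=1)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.diseases, columns=self.diseases)


@dataclass
class ScaleFreeFit:
    """Per-candidate scale-free topology diagnostics and the chosen tau."""

    tau_grid: list[float]
    r_squared: list[float]
    slope: list[float]
    n_edges: list[int]
    chosen_tau: float
    fallback: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tau": self.tau_grid,
                "r_squared": self.r_squared,
                "slope": self.slope,
                "n_edges": self.n_edges,
            }
        )


def similarity_matrix(occ: YearlyOccurrence) -> SimilarityMatrix:
    """Phi-correlation for every disease pair of a yearly occurrence.

    Vectorised evaluation of the count formula; pairs with a degenerate
    marginal (P in {0, N}) are NaN-flagged.
    """
    P = occ.P.to_numpy(dtype=float)
    N = float(occ.N)
    C = occ.C.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = C * N - np.outer(P, P)
        den = np.sqrt(np.outer(P * (N - P), P * (N - P)))
        S = num / den
    S[~np.isfinite(S)] = np.nan
    np.fill_diagonal(S, 0.0)
    return SimilarityMatrix(list(occ.diseases), S, occ.year)


def build_adjacency(sim: SimilarityMatrix, tau: float, *, mode: str = "magnitude") -> AdjacencyMatrix:
    """Hard-threshold the similarity matrix at tau.

    ``mode="magnitude"`` (default) keeps |s_ij| when |s_ij| >= tau, treating
    positive and negative correlations alike; ``mode="literal"`` applies the
    predicate s_ij >= tau to the signed value (zeroing all negative
    correlations) while still storing |s_ij|.  The boundary s = tau is
    included.
    """
    if not (0 < tau < 1):
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    if mode not in {"magnitude", "literal"}:
        raise ValueError(f"mode must be magnitude|literal, got {mode!r}")
    S = sim.S
    n_missing = int(np.isnan(S).sum())
    if n_missing:
        logger.warning("build_adjacency: %d undefined similarities treated as 0", n_missing)
    S = np.nan_to_num(S, nan=0.0)
    keep = (np.abs(S) >= tau) if mode == "magnitude" else (S >= tau)
    A = np.where(keep, np.abs(S), 0.0)
    np.fill_diagonal(A, 0.0)
    A = np.minimum(A, 1.0)
    return AdjacencyMatrix(list(sim.diseases), A, float(tau), sim.year)


def scale_free_r2(K: np.ndarray, *, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of the log-log binned connectivity-distribution fit.

    Nodes with zero connectivity are excluded; the remainder is split into
    ``n_bins`` equal-count bins and the log10 frequency density
    (count / bin width, normalised) is regressed on log10 mean connectivity
    per bin.  Returns (nan, nan) when fewer than three usable bins remain.
    """
    K = np.asarray(K, dtype=float)
    K = K[K > 0]
    if K.size < 3:
        return float("nan"), float("nan")
    n_bins = min(n_bins, K.size)
    try:
        binned = pd.qcut(K, q=n_bins, duplicates="drop")
    except ValueError:
        return float("nan"), float("nan")
    df = (
        pd.DataFrame({"K": K, "bin": binned})
        .groupby("bin", observed=True)["K"]
        .agg(["mean", "count"])
    )
    widths = np.array([iv.right - iv.left for iv in df.index])
    keep = (df["count"].to_numpy() > 0) & (df["mean"].to_numpy() > 0) & (widths > 0)
    df, widths = df[keep], widths[keep]
    if len(df) < 3:
        return float("nan"), float("nan")
    x = np.log10(df["mean"].to_numpy())
    y = np.log10(df["count"].to_numpy() / (K.size * widths))
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return float("nan"), float("nan")
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2), float(fit.slope)


def select_threshold(
    sim: SimilarityMatrix,
    *,
    grid: tuple[float, ...] = DEFAULT_TAU_GRID,
    r2_target: float = 0.80,
    n_bins: int = 10,
    mode: str = "magnitude",
) -> ScaleFreeFit:
    """Choose tau by the scale-free topology criterion.

    The chosen tau is the smallest candidate whose binned log-log degree
    regression reaches R^2 >= ``r2_target`` with a negative slope; when no
    candidate qualifies, the candidate with maximal R^2 is used (logged as a
    fallback).  Candidates leaving fewer than three connected nodes are
    skipped.
    """
    grid = tuple(grid)
    if not grid:
        raise ValueError("tau grid is empty")
    if list(grid) != sorted(grid):
        raise ValueError("tau grid must be ascending")
    r2s: list[float] = []
    slopes: list[float] = []
    edges: list[int] = []
    for tau in grid:
        adj = build_adjacency(sim, tau, mode=mode)
        K = adj.A.sum(axis=1)
        if np.count_nonzero(K) < 3:
            logger.warning("select_threshold: tau=%.3f leaves <3 connected nodes; skipped", tau)
            r2, slope = float("nan"), float("nan")
        else:
            r2, slope = scale_free_r2(K, n_bins=n_bins)
        r2s.append(r2)
        slopes.append(slope)
        edges.append(adj.n_edges)
    chosen = None
    for tau, r2, slope in zip(grid, r2s, slopes):
        if np.isfinite(r2) and r2 >= r2_target and slope < 0:
            chosen = tau
            break
    fallback = chosen is None
    if fallback:
        finite = [(r2, tau) for tau, r2 in zip(grid, r2s) if np.isfinite(r2)]
        if finite:
            chosen = max(finite)[1]
            logger.warning(
                "select_threshold: no candidate reached R^2 >= %.2f; falling back to tau=%.3f (max R^2)",
                r2_target,
                chosen,
            )
        else:
            chosen = grid[0]
            logger.warning("select_threshold: no candidate produced a usable fit; using smallest tau")
    return ScaleFreeFit(list(grid), r2s, slopes, edges, float(chosen), fallback)


def export_edge_list(adj: AdjacencyMatrix, path: str | Path) -> Path:
    """Weighted edge list CSV (disease_i, disease_j, a_ij), upper triangle."""
    path = Path(path)
    i_idx, j_idx = np.nonzero(np.triu(adj.A, k=1))
    pd.DataFrame(
        {
            "disease_i": [adj.diseases[i] for i in i_idx],
            "disease_j": [adj.diseases[j] for j in j_idx],
            "weight": adj.A[i_idx, j_idx],
        }
    ).to_csv(path, index=False)
    return path


def to_networkx(adj: AdjacencyMatrix):
    """Weighted undirected graph over all diseases (isolates included)."""
    import networkx as nx

    G = nx.Graph(year=adj.year, tau=adj.tau)
    G.add_nodes_from(adj.diseases)
    i_idx, j_idx = np.nonzero(np.triu(adj.A, k=1))
    G.add_weighted_edges_from(
        (adj.diseases[i], adj.diseases[j], float(adj.A[i, j])) for i, j in zip(i_idx, j_idx)
    )
    return G


def export_graphml(adj: AdjacencyMatrix, path: str | Path) -> Path:
    """GraphML export for network viewers (e.g. Gephi)."""
    import networkx as nx

    path = Path(path)
    nx.write_graphml(to_networkx(adj), path)
    return path
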