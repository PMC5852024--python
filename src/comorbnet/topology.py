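"""Connectivity, topological overlap, modules, eigen-diseases and hubs.

The topological overlap of diseases i and j,

    TOM_ij = (l_ij + a_ij) / (min(K_i, K_j) + 1 - a_ij),   l_ij = sum_u a_iu a_uj,

(u ranging over the other nodes) measures how much of the network
neighbourhood two diseases share; dissTOM = 1 - TOM is the clustering
dissimilarity.  Modules are branches of the average-linkage dendrogram of
dissTOM kept by a dynamic tree cut; each module is summarised by its
eigen-disease (first principal component of the standardised patient x
member incidence submatrix) and its hub (the member most correlated with
the eigen-disease).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from comorbnet.network import AdjacencyMatrix
from comorbnet.records import YearlyOccurrence
from comorbnet.treecut import CutParams, cut_tree_dynamic

logger = logging.getLogger(__name__)

GREY = "grey"

#: Size-ordered module colour vocabulary (largest module first).
MODULE_COLOURS: tuple[str, ...] = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)


@dataclass
class TOMMatrix:
    """Topological overlap matrix; entries in [0, 1], unit diagonal."""

    diseases: list[str]
    TOM: np.ndarray

    @property
    def dissTOM(self) -> np.ndarray:
        d = 1.0 - self.TOM
        np.fill_diagonal(d, 0.0)
        return d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.TOM, index=self.diseases, columns=self.diseases)


@dataclass
class EigenDisease:
    """First principal component of a module's standardised incidence."""

    scores: np.ndarray  # over patients
    explained_variance_ratio: np.ndarray
    dropped_columns: list[str] = field(default_factory=list)


@dataclass
class ModulePartition:
    """Disease -> module colour labels plus per-module summaries."""

    labels: pd.Series  # index: disease codes, values: colour strings
    eigen: dict[str, EigenDisease] = field(default_factory=dict)
    hubs: dict[str, str] = field(default_factory=dict)
    membership: pd.Series | None = None  # per-disease corr with own eigen-disease

    @property
    def diseases(self) -> list[str]:
        return list(self.labels.index)

    @property
    def colours(self) -> list[str]:
        """Module colours ordered by decreasing size (grey excluded)."""
        sizes = self.sizes()
        return [c for c in sizes.index if c != GREY]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def members(self, colour: str) -> list[str]:
        return list(self.labels.index[self.labels == colour])

    def n_modules(self) -> int:
        return len(self.colours)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"module": self.labels})
        if self.membership is not None:
            df["membership"] = self.membership
        df["is_hub"] = [self.hubs.get(m) == d for d, m in self.labels.items()]
        return df


@dataclass
class EigenDendrogram:
    """Average-linkage merge tree over module eigen-diseases."""

    colours: list[str]
    linkage: np.ndarray  # scipy linkage over 1 - correlation

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.colours)
        return str(tree).strip()


def connectivity(adj: AdjacencyMatrix) -> pd.Series:
    """Whole-network connectivity K_i = sum_{j != i} a_ij."""
    A = adj.A.copy()
    np.fill_diagonal(A, 0.0)
    return pd.Series(A.sum(axis=1), index=adj.diseases, name="K")


def tom(adj: AdjacencyMatrix) -> TOMMatrix:
    """Topological overlap matrix of a hard-thresholded adjacency.

    l_ij sums shared-neighbour weight products over u not in {i, j}; with a
    zero diagonal this is exactly (A @ A)_ij.  The diagonal is set to 1 by
    convention.
    """
    A = adj.A.astype(float).copy()
    np.fill_diagonal(A, 0.0)
    K = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(K, K) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        T = (L + A) / denom
    T = np.nan_to_num(T, nan=0.0)
    np.fill_diagonal(T, 1.0)
    return TOMMatrix(list(adj.diseases), T)


def tom_connectivity(T: TOMMatrix) -> pd.Series:
    """TOM-weighted connectivity k_i = sum_{j != i} TOM_ij."""
    M = T.TOM.copy()
    np.fill_diagonal(M, 0.0)
    return pd.Series(M.sum(axis=1), index=T.diseases, name="k")


def detect_modules(
    T: TOMMatrix,
    *,
    min_module_size: int = 20,
    cut_params: CutParams | None = None,
    similarity: np.ndarray | None = None,
) -> ModulePartition:
    """Cluster dissTOM (average linkage) and cut dynamically into modules.

    Modules are named by decreasing size following the conventional colour
    vocabulary; diseases in no module are labelled grey.  ``similarity``
    optionally provides the signed phi-correlation matrix for the
    membership refinement pass of the cut.
    """
    ids = cut_tree_dynamic(
        T.dissTOM,
        min_module_size=min_module_size,
        params=cut_params,
        refine_similarity=similarity,
    )
    colours = np.array([GREY] * len(T.diseases), dtype=object)
    for k in range(1, ids.max() + 1):
        colours[ids == k] = MODULE_COLOURS[(k - 1) % len(MODULE_COLOURS)]
    labels = pd.Series(colours, index=T.diseases, name="module")
    if (labels == GREY).all():
        logger.warning("detect_modules: no modules found; all diseases grey")
    return ModulePartition(labels=labels)


def _standardised_submatrix(occ: YearlyOccurrence, members: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    idx = {d: i for i, d in enumerate(occ.diseases)}
    X = occ.incidence[:, [idx[m] for m in members]].astype(float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [m for m, k in zip(members, keep) if not k]
    if dropped:
        logger.warning("eigen_disease: dropping constant column(s) %s", dropped)
    X = X[:, keep]
    kept = [m for m, k in zip(members, keep) if k]
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return X, kept, dropped


def eigen_disease(occ: YearlyOccurrence, members: list[str]) -> EigenDisease:
    """First principal component of the module's patient scores.

    Columns are standardised indicators of the member diseases; the score
    vector is oriented so that its mean correlation with the member columns
    is positive.  Constant columns are dropped.
    """
    if len(members) < 2:
        raise ValueError("eigen_disease needs at least two member diseases")
    X, kept, dropped = _standardised_submatrix(occ, members)
    if X.shape[1] == 0:
        raise ValueError("all member columns constant; eigen-disease undefined")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, 0] * s[0]
    var = s**2
    evr = var / var.sum()
    mean_corr = np.mean([np.corrcoef(scores, X[:, j])[0, 1] for j in range(X.shape[1])])
    if mean_corr < 0:
        scores = -scores
    return EigenDisease(scores=scores, explained_variance_ratio=evr, dropped_columns=dropped)


def compute_eigen_diseases(partition: ModulePartition, occ: YearlyOccurrence) -> dict[str, EigenDisease]:
    """Eigen-disease per non-grey module (singleton modules skipped)."""
    out: dict[str, EigenDisease] = {}
    for colour in partition.colours:
        members = partition.members(colour)
        if len(members) >= 2:
            out[colour] = eigen_disease(occ, members)
    return out


def _column_correlations(occ: YearlyOccurrence, members: list[str], scores: np.ndarray) -> pd.Series:
    idx = {d: i for i, d in enumerate(occ.diseases)}
    vals = {}
    for m in members:
        col = occ.incidence[:, idx[m]].astype(float)
        vals[m] = np.corrcoef(scores, col)[0, 1] if col.std() > 0 else np.nan
    return pd.Series(vals)


def identify_hubs(
    partition: ModulePartition,
    occ: YearlyOccurrence,
    *,
    adj: AdjacencyMatrix | None = None,
) -> dict[str, str]:
    """Per module, the member most correlated with the module eigen-disease.

    Ties (within 1e-12) break by higher intramodular connectivity when an
    adjacency is supplied, then by lexicographic code.  Also fills the
    partition's eigen, membership and hub tables.  A module reduced to one
    disease has that disease as hub.
    """
    if not partition.eigen:
        partition.eigen = compute_eigen_diseases(partition, occ)
    intra = intramodular_connectivity(adj, partition) if adj is not None else None
    hubs: dict[str, str] = {}
    membership: dict[str, float] = {}
    for colour in partition.colours:
        members = partition.members(colour)
        if len(members) == 1:
            hubs[colour] = members[0]
            membership[members[0]] = 1.0
            continue
        corr = _column_correlations(occ, members, partition.eigen[colour].scores)
        membership.update(corr.to_dict())
        best = corr.max()
        tied = sorted(corr.index[np.isclose(corr, best, atol=1e-12)])
        if len(tied) > 1 and intra is not None:
            best_k = intra.loc[tied].max()
            tied = sorted(intra.loc[tied].index[np.isclose(intra.loc[tied], best_k, atol=1e-12)])
        hubs[colour] = tied[0]
    partition.hubs = hubs
    partition.membership = pd.Series(membership).reindex(partition.labels.index)
    return hubs


def intramodular_connectivity(adj: AdjacencyMatrix, partition: ModulePartition) -> pd.Series:
    """Within-module connectivity; NaN for grey (unassigned) diseases."""
    labels = partition.labels.reindex(adj.diseases)
    A = adj.A.copy()
    np.fill_diagonal(A, 0.0)
    lab = labels.to_numpy()
    out = np.full(len(adj.diseases), np.nan)
    for colour in labels.dropna().unique():
        if colour == GREY:
            continue
        mask = lab == colour
        out[mask] = A[np.ix_(mask, mask)].sum(axis=1)
    return pd.Series(out, index=adj.diseases, name="intramodular_K")


def cluster_eigen_diseases(eigen: dict[str, EigenDisease]) -> EigenDendrogram:
    """Average-linkage tree on 1 - correlation between eigen-disease scores."""
    colours = list(eigen)
    if len(colours) < 2:
        raise ValueError("need at least two modules to cluster eigen-diseases")
    M = np.column_stack([eigen[c].scores for c in colours])
    corr = np.corrcoef(M, rowvar=False)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    return EigenDendrogram(colours=colours, linkage=Z)


def connectivity_table(
    adj: AdjacencyMatrix,
    T: TOMMatrix,
    partition: ModulePartition,
) -> pd.DataFrame:
    """Per-disease K, k, intramodular K, module label and membership corr."""
    df = pd.DataFrame(
        {
            "module": partition.labels.reindex(adj.diseases),
            "K": connectivity(adj),
            "k": tom_connectivity(T),
            "intramodular_K": intramodular_connectivity(adj, partition),
        }
    )
    if partition.membership is not None:
        df["membership"] = partition.membership.reindex(adj.diseases)
    df["is_hub"] = [partition.hubs.get(m) == d for d, m in df["module"].items()]
    return df
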