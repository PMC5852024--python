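"""Adaptive branch harvesting ("dynamic tree cut") for module detection.

Modules are branches of the average-linkage dendrogram of a dissimilarity
matrix (dissTOM) that *detach* from the rest of the tree: a branch of at
least the minimum size is harvested when the gap between its own top merge
height and the height at which it attaches to the remainder is a large
fraction of the dendrogram's total height range.  Harvested branches are
trimmed of tiny late-attaching stragglers and recursively split wherever
their internal merge structure shows gaps of the same magnitude.  Because a
module can be masked by unrelated leaves chaining onto its branch, the
procedure is iterated: harvested leaves are removed, the remainder is
re-clustered, and harvesting repeats until nothing new is found.  A final
refinement pass reassigns every leaf to the module with which its mean
similarity is highest, provided that similarity clearly exceeds the
background level; all other leaves stay unassigned (label 0, "grey").

dissTOM dendrograms occupy a narrow band below 1, so all height parameters
are fractions of the observed merge-height range, not absolute values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import ClusterNode, average, to_tree
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CutParams:
    """Tunable parameters of the dynamic cut.

    gap_frac: minimum attach/split gap as a fraction of the merge-height
        range; branches detaching by less are treated as continuum.
    straggler_size: maximal size of a late-attaching side branch trimmed
        from a harvested branch when it attaches a full gap above the core.
    max_rounds: harvest-and-peel iterations.
    refine_beta: a leaf joins a module in the refinement pass only if its
        mean similarity to the module exceeds ``refine_beta`` times the
        median off-diagonal similarity (the background level).
    refine_member_frac: additionally, the leaf's mean similarity must reach
        this fraction of the median such similarity among the module's
        current members (an adaptive per-module floor).
    refine_iters: refinement passes (0 disables refinement).
    """

    gap_frac: float = 0.10
    straggler_size: int = 2
    max_rounds: int = 10
    refine_beta: float = 3.0
    refine_member_frac: float = 0.4
    refine_iters: int = 2


def _harvest_tree(Z: np.ndarray, min_size: int, params: CutParams) -> np.ndarray:
    """One harvesting pass over a linkage matrix: labels, 0 = unassigned."""
    n = Z.shape[0] + 1
    labels = np.zeros(n, dtype=int)
    heights = Z[:, 2]
    h_range = float(heights.max() - heights.min())
    if h_range <= 0:
        return labels
    thr = params.gap_frac * h_range
    root = to_tree(Z)
    modules: list[list[int]] = []

    def strip(node: ClusterNode) -> ClusterNode:
        while not node.is_leaf():
            left, right = node.left, node.right
            small, big = (left, right) if left.get_count() <= right.get_count() else (right, left)
            if (
                small.get_count() <= params.straggler_size
                and big.get_count() >= min_size
                and node.dist - big.dist >= thr
            ):
                node = big
            else:
                break
        return node

    def accept(node: ClusterNode) -> None:
        node = strip(node)
        left, right = node.left, node.right
        if (
            left.get_count() >= min_size
            and right.get_count() >= min_size
            and node.dist - left.dist >= thr
            and node.dist - right.dist >= thr
        ):
            accept(left)
            accept(right)
        else:
            modules.append(node.pre_order(lambda leaf: leaf.id))

    def descend(node: ClusterNode, eff_attach: float) -> None:
        # eff_attach: height at which this branch joins the nearest
        # substantial (> straggler_size) branch above it, so that a module
        # whose detachment is diluted across a chain of tiny late
        # attachments is still seen to detach.
        if node.is_leaf() or node.get_count() < min_size:
            return
        if eff_attach - node.dist >= thr:
            accept(node)
            return
        for child, sibling in ((node.left, node.right), (node.right, node.left)):
            child_eff = node.dist if sibling.get_count() > params.straggler_size else eff_attach
            descend(child, child_eff)

    descend(root, root.dist)  # the root itself always descends
    for k, leaves in enumerate(modules, start=1):
        labels[leaves] = k
    return labels


def _refine(
    S: np.ndarray, labels: np.ndarray, min_size: int, params: CutParams
) -> np.ndarray:
    """Similarity-based membership refinement (PAM-like reassignment)."""
    n = len(labels)
    off = S[~np.eye(n, dtype=bool)]
    background = float(np.median(off))
    lab = labels.copy()
    for _ in range(params.refine_iters):
        mods = [k for k in np.unique(lab) if k > 0]
        if not mods:
            return lab
        scores = np.empty((n, len(mods)))
        for mi, k in enumerate(mods):
            mask = lab == k
            size = int(mask.sum())
            sums = S[:, mask].sum(axis=1)
            # a current member's own (diagonal) similarity is excluded
            sums[mask] -= np.diag(S)[mask]
            counts = np.where(mask, max(size - 1, 1), size)
            scores[:, mi] = sums / counts
        thresholds = np.empty(len(mods))
        for mi, k in enumerate(mods):
            member_med = float(np.median(scores[lab == k, mi]))
            thresholds[mi] = max(
                params.refine_beta * background, params.refine_member_frac * member_med
            )
        best = scores.argmax(axis=1)
        new = np.zeros(n, dtype=int)
        for i in range(n):
            s = scores[i, best[i]]
            if s > 0 and s >= thresholds[best[i]]:
                new[i] = mods[best[i]]
        for k in mods:  # minimum size still enforced after reassignment
            if 0 < (new == k).sum() < min_size:
                new[new == k] = 0
        lab = new
    return lab


def cut_tree_dynamic(
    D: np.ndarray,
    *,
    min_module_size: int = 20,
    params: CutParams | None = None,
    refine_similarity: np.ndarray | None = None,
) -> np.ndarray:
    """Module labels from a square dissimilarity matrix in [0, 1].

    Returns an integer label per leaf: 1..k for modules ordered by
    decreasing size (ties by lowest leaf index), 0 for unassigned.

    ``refine_similarity`` optionally supplies the similarity used by the
    refinement pass (e.g. the signed phi-correlation matrix, whose
    background level centres on zero); by default ``1 - D`` is used.
    """
    params = params or CutParams()
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    labels = np.zeros(n, dtype=int)
    if n < 2 or n < min_module_size:
        return labels
    active = np.arange(n)
    next_id = 1
    for _ in range(params.max_rounds):
        if len(active) < min_module_size:
            break
        Z = average(squareform(D[np.ix_(active, active)], checks=False))
        sub = _harvest_tree(Z, min_module_size, params)
        if sub.max() == 0:
            break
        for k in range(1, sub.max() + 1):
            labels[active[sub == k]] = next_id
            next_id += 1
        active = active[sub == 0]
    if params.refine_iters > 0:
        S = refine_similarity if refine_similarity is not None else 1.0 - D
        labels = _refine(S, labels, min_module_size, params)
    # renumber by decreasing size, ties by lowest leaf index
    mods = [k for k in np.unique(labels) if k > 0]
    mods.sort(key=lambda k: (-(labels == k).sum(), int(np.nonzero(labels == k)[0][0])))
    out = np.zeros(n, dtype=int)
    for new_k, k in enumerate(mods, start=1):
        out[labels == k] = new_k
    if not mods:
        logger.warning("cut_tree_dynamic: no module met the criteria; all leaves unassigned")
    return out
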