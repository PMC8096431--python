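"""Chemical-dissimilarity clustering and tanglegram comparison.

A blank-filtered LC-MS feature table is binarized (peak intensity
strictly above 1e6 counts as present), strains are compared by Jaccard
distance on their presence/absence profiles, and the distance matrix is
clustered by UPGMA (average linkage).  The resulting chemotype dendrogram
is compared with a phylogeny in a tanglegram: leaf orders of both trees
are optimized by alternating one-sided rotation ("step2side") and the
residual leaf-order mismatch is summarized by the entanglement score.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import Node


@dataclass
class ChemProfile:
    """Strains-by-items presence/absence matrix."""

    strain_ids: list[str]
    item_ids: list[str]
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=np.int8)
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise ValueError("duplicate strain ids")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError("duplicate item ids")
        if self.presence.shape != (len(self.strain_ids), len(self.item_ids)):
            raise ValueError("presence matrix shape does not match id lists")
        if not np.isin(self.presence, (0, 1)).all():
            raise ValueError("presence entries must be 0 or 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence, index=self.strain_ids,
                            columns=self.item_ids)


def filter_blanks(
    features: pd.DataFrame,
    blank_sample_ids: list[str],
    detection_threshold: float = 0.0,
) -> pd.DataFrame:
    """Drop every feature detected in any blank sample.

    A feature is considered detected in a blank when its intensity there
    exceeds ``detection_threshold``.  Remaining rows are returned
    unchanged (including the blank columns themselves).
    """
    unknown = [b for b in blank_sample_ids if b not in features.columns]
    if unknown:
        raise ValueError(f"unknown blank sample ids: {unknown}")
    if not blank_sample_ids:
        return features.copy()
    in_blank = (features[blank_sample_ids] > detection_threshold).any(axis=1)
    return features.loc[~in_blank].copy()


def to_presence_absence(
    features: pd.DataFrame,
    sample_ids: list[str] | None = None,
    intensity_threshold: float = 1e6,
    allow_empty: bool = False,
) -> ChemProfile:
    """Binarize a feature table: present iff intensity > threshold (strict)."""
    if intensity_threshold <= 0:
        raise ValueError("intensity_threshold must be > 0")
    if sample_ids is None:
        sample_ids = [
            c for c in features.columns
            if c not in ("feature_id", "mz", "rt") and
            pd.api.types.is_numeric_dtype(features[c])
        ]
    items = (
        features["feature_id"].astype(str).tolist()
        if "feature_id" in features.columns
        else [str(i) for i in features.index]
    )
    mat = (features[sample_ids].to_numpy(dtype=float) > intensity_threshold)
    profile = ChemProfile(list(sample_ids), items, mat.T.astype(np.int8))
    if not allow_empty and profile.presence.size and (
        profile.presence.sum(axis=1) == 0
    ).any():
        empty = [s for s, row in zip(profile.strain_ids, profile.presence)
                 if row.sum() == 0]
        warnings.warn(f"strains with all-blank profiles: {empty}")
    return profile


def jaccard_distance(row_a: np.ndarray, row_b: np.ndarray) -> float:
    """1 - |A∩B| / |A∪B| on binary vectors; 0 when both are empty."""
    a = np.asarray(row_a, dtype=bool)
    b = np.asarray(row_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = (a | b).sum()
    if union == 0:
        warnings.warn("Jaccard distance of two empty profiles defined as 0")
        return 0.0
    return 1.0 - (a & b).sum() / union


def distance_matrix(profile: ChemProfile) -> pd.DataFrame:
    """Pairwise Jaccard distance matrix of strains."""
    n = len(profile.strain_ids)
    d = np.zeros((n, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = jaccard_distance(
                    profile.presence[i], profile.presence[j]
                )
    return pd.DataFrame(d, index=profile.strain_ids, columns=profile.strain_ids)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(
    dist: pd.DataFrame | np.ndarray,
    labels: list[str] | None = None,
    height_is_distance: bool = True,
) -> Node:
    """Average-linkage agglomerative clustering of a distance matrix.

    At each step the pair of clusters at minimal distance merges; the
    distance from the new cluster to any other is the size-weighted
    arithmetic mean of its members' distances.  Node height defaults to
    the merging distance itself (set ``height_is_distance=False`` for the
    d/2 convention).  Ties are broken by the lexicographically smallest
    pair of cluster labels, where a cluster is labelled by its smallest
    leaf name, so the output is fully deterministic.
    """
    if isinstance(dist, pd.DataFrame):
        labels = [str(l) for l in dist.index]
        D = dist.to_numpy(dtype=float)
    else:
        D = np.asarray(dist, dtype=float)
        if labels is None:
            labels = [f"L{i}" for i in range(D.shape[0])]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if (D < 0).any():
        raise ValueError("distances must be nonnegative")
    if len(labels) != D.shape[0]:
        raise ValueError("labels length does not match matrix size")
    if len(labels) == 1:
        return Node.leaf(labels[0])

    nodes: dict[str, Node] = {l: Node.leaf(l) for l in labels}
    sizes: dict[str, int] = {l: 1 for l in labels}
    dists: dict[frozenset, float] = {
        frozenset((labels[i], labels[j])): D[i, j]
        for i in range(len(labels)) for j in range(i + 1, len(labels))
    }

    while len(nodes) > 1:
        best = min(
            dists.items(), key=lambda kv: (kv[1], tuple(sorted(kv[0])))
        )
        pair, dmin = best
        la, lb = sorted(pair)
        height = dmin if height_is_distance else dmin / 2.0
        merged = Node.merge(nodes[la], nodes[lb], height)
        sa, sb = sizes[la], sizes[lb]
        for lc in nodes:
            if lc in (la, lb):
                continue
            dac = dists.pop(frozenset((la, lc)))
            dbc = dists.pop(frozenset((lb, lc)))
            dists[frozenset((la, lc))] = (sa * dac + sb * dbc) / (sa + sb)
        dists.pop(frozenset((la, lb)))
        del nodes[lb], sizes[lb]
        nodes[la] = merged
        sizes[la] = sa + sb
    return next(iter(nodes.values()))


def cophenetic_matrix(root: Node) -> pd.DataFrame:
    """Pairwise merge heights (heights of lowest common ancestors)."""
    names = sorted(root.leaf_names())
    idx = {n: i for i, n in enumerate(names)}
    M = np.zeros((len(names), len(names)))

    def rec(node: Node) -> list[str]:
        if node.is_leaf:
            return [node.name]
        groups = [rec(c) for c in node.children]
        for ga, gb in itertools.combinations(groups, 2):
            for a in ga:
                for b in gb:
                    M[idx[a], idx[b]] = M[idx[b], idx[a]] = node.height
        return [n for g in groups for n in g]

    rec(root)
    return pd.DataFrame(M, index=names, columns=names)


# ---------------------------------------------------------------------------
# tanglegram
# ---------------------------------------------------------------------------

@dataclass
class TanglegramResult:
    """Optimized leaf orderings of the two trees and their entanglement."""

    ordering_left: list[str]
    ordering_right: list[str]
    entanglement: float
    exponent_L: float
    tree_left: Node | None = None
    tree_right: Node | None = None

    def to_dict(self) -> dict:
        return {
            "entanglement": self.entanglement,
            "exponent_L": self.exponent_L,
            "ordering_left": self.ordering_left,
            "ordering_right": self.ordering_right,
        }


def entanglement(
    ordering_left: list[str], ordering_right: list[str], L: float = 1.5
) -> float:
    """Normalized leaf-order mismatch between two orderings of one label set.

    Sum of |posL(i) - posR(i)|^L over labels, divided by its value when
    one ordering is the exact reversal of the other; 0 for identical
    orderings, 1 for a reversal.
    """
    if set(ordering_left) != set(ordering_right):
        raise ValueError("orderings must be permutations of the same label set")
    n = len(ordering_left)
    if n < 2:
        raise ValueError("need at least 2 labels")
    pos_r = {lab: i for i, lab in enumerate(ordering_right)}
    num = sum(abs(i - pos_r[lab]) ** L for i, lab in enumerate(ordering_left))
    denom = sum(abs(i - (n - 1 - i)) ** L for i in range(n))
    return num / denom


def _optimal_rotation(free: Node, target_pos: dict[str, int], L: float) -> Node:
    """Best rotation of ``free`` against fixed target leaf positions.

    Child blocks of a node occupy contiguous position intervals whose
    sizes are fixed, so the optimal flip at each node decomposes over
    subtrees; dynamic programming over (node, start offset) yields the
    global one-sided optimum.
    """
    sizes: dict[int, int] = {}

    def size(node: Node) -> int:
        if id(node) not in sizes:
            sizes[id(node)] = 1 if node.is_leaf else sum(size(c) for c in node.children)
        return sizes[id(node)]

    memo: dict[tuple[int, int], tuple[float, Node]] = {}

    def opt(node: Node, start: int) -> tuple[float, Node]:
        key = (id(node), start)
        if key in memo:
            return memo[key]
        if node.is_leaf:
            res = (abs(start - target_pos[node.name]) ** L, node)
        else:
            x, y = node.children
            cx1, nx1 = opt(x, start)
            cy1, ny1 = opt(y, start + size(x))
            cy2, ny2 = opt(y, start)
            cx2, nx2 = opt(x, start + size(y))
            if cx1 + cy1 <= cy2 + cx2:
                res = (cx1 + cy1, Node(node.name, node.height, (nx1, ny1)))
            else:
                res = (cy2 + cx2, Node(node.name, node.height, (ny2, nx2)))
        memo[key] = res
        return res

    return opt(free, 0)[1]


def _enum_rotations(node: Node) -> list[Node]:
    """All rotation variants of a tree (2^(#internal nodes) of them)."""
    if node.is_leaf:
        return [node]
    x, y = node.children
    out = []
    for nx in _enum_rotations(x):
        for ny in _enum_rotations(y):
            out.append(Node(node.name, node.height, (nx, ny)))
            out.append(Node(node.name, node.height, (ny, nx)))
    return out


def untangle_step2side(
    dend_left: Node,
    dend_right: Node,
    L: float = 1.5,
    max_rounds: int = 25,
    exact_leaf_limit: int = 10,
) -> TanglegramResult:
    """Alternating one-sided rotation optimization of a tanglegram.

    Both trees start ladderized; rounds alternate between fixing one
    tree's leaf order and rotating the other's internal nodes to the
    one-sided optimum, until a round brings no improvement.  The
    procedure is run from both starting sides and the better result is
    returned, so the final entanglement never exceeds the initial one.

    Alternating one-sided optimization can stall in a local optimum of
    the joint rotation space, so instances with at most
    ``exact_leaf_limit`` leaves are instead solved exactly by enumerating
    one tree's rotations and optimizing the other by dynamic programming
    (the enumeration grows as 2^(n-1); the default limit keeps it cheap).
    """
    if set(dend_left.leaf_names()) != set(dend_right.leaf_names()):
        raise ValueError("trees must share an identical leaf set")

    n = dend_left.size
    if n <= exact_leaf_limit:
        best: tuple[float, Node, Node] | None = None
        for lv in _enum_rotations(dend_left.ladderize()):
            tp = {lab: i for i, lab in enumerate(lv.leaf_names())}
            rv = _optimal_rotation(dend_right.ladderize(), tp, L)
            e = entanglement(lv.leaf_names(), rv.leaf_names(), L)
            if best is None or e < best[0] - 1e-15:
                best = (e, lv, rv)
        e, left, right = best
        return TanglegramResult(
            ordering_left=left.leaf_names(), ordering_right=right.leaf_names(),
            entanglement=e, exponent_L=L, tree_left=left, tree_right=right,
        )

    def run(left: Node, right: Node, right_first: bool):
        e = entanglement(left.leaf_names(), right.leaf_names(), L)
        for _ in range(max_rounds):
            improved = False
            order = ("right", "left") if right_first else ("left", "right")
            for side in order:
                if side == "right":
                    tp = {lab: i for i, lab in enumerate(left.leaf_names())}
                    right = _optimal_rotation(right, tp, L)
                else:
                    tp = {lab: i for i, lab in enumerate(right.leaf_names())}
                    left = _optimal_rotation(left, tp, L)
                e_new = entanglement(left.leaf_names(), right.leaf_names(), L)
                if e_new < e - 1e-15:
                    e, improved = e_new, True
            if not improved:
                break
        return e, left, right

    l0, r0 = dend_left.ladderize(), dend_right.ladderize()
    e1, la, ra = run(l0, r0, right_first=True)
    e2, lb, rb = run(l0, r0, right_first=False)
    e, left, right = (e1, la, ra) if e1 <= e2 else (e2, lb, rb)
    return TanglegramResult(
        ordering_left=left.leaf_names(), ordering_right=right.leaf_names(),
        entanglement=e, exponent_L=L, tree_left=left, tree_right=right,
    )
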