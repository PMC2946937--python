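"""Reading, validating and summarizing ultrametric phylogenies.

The likelihood machinery consumes only the ordered coalescent times of a tree:
the depths (time before present) of its internal nodes and the waiting times
between successive nodes. This module extracts those from Newick input,
validates ultrametricity, and resolves polytomies by inserting arbitrarily
small internode distances, preserving all tip-to-root depths.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "CoalescentTimes",
    "NotUltrametricError",
    "read_newick",
    "tree_from_string",
    "write_newick",
    "resolve_polytomies",
    "coalescent_times",
]

#: default relative tolerance on root-to-tip depth agreement; empirical trees
#: carry rounding noise from their original publications
DEFAULT_ULTRAMETRIC_TOL = 1e-4


class NotUltrametricError(ValueError):
    """Raised when root-to-tip path lengths disagree beyond tolerance."""


@dataclass
class PhyloTree:
    """A rooted ultrametric phylogeny plus per-tree metadata.

    Wraps a :class:`dendropy.Tree`. ``n0`` is the present-day clade richness
    (may exceed the tip count when the tree is incompletely sampled) and
    ``sampling_fraction`` is n/N0 when known.
    """

    tree: dendropy.Tree
    n0: Optional[float] = None
    sampling_fraction: Optional[float] = None
    is_binary: bool = True
    depth_discrepancy: float = 0.0

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    @property
    def depth(self) -> float:
        """Maximum root-to-tip path length (the root age)."""
        return max(
            leaf.distance_from_root() for leaf in self.tree.leaf_node_iter()
        )

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class CoalescentTimes:
    """Ordered node depths and internode distances of an ultrametric tree.

    Nodes are numbered from the root to the tips: ``node_depths[0]`` is the
    root age t_1 and ``node_depths[-1]`` the depth t_{n-1} of the most recent
    node. ``internode_distances[j-2] = t_{j-1} - t_j`` for j = 2..n-1; during
    that interval exactly j lineages exist. The terminal interval (most recent
    node to present) is stored but excluded from the likelihood.
    """

    n: int
    node_depths: np.ndarray
    internode_distances: np.ndarray = field(init=False)
    terminal_interval: float = field(init=False)

    def __post_init__(self) -> None:
        self.node_depths = np.asarray(self.node_depths, dtype=float)
        if self.n < 3:
            raise ValueError("need n >= 3 tips for a usable internode distance")
        if len(self.node_depths) != self.n - 1:
            raise ValueError(
                f"expected {self.n - 1} node depths, got {len(self.node_depths)}"
            )
        if np.any(np.diff(self.node_depths) > 0):
            raise ValueError("node depths must be sorted from root to tips")
        if np.any(self.node_depths < 0):
            raise ValueError("node depths must be nonnegative")
        self.internode_distances = -np.diff(self.node_depths)
        self.terminal_interval = float(self.node_depths[-1])

    @property
    def root_age(self) -> float:
        return float(self.node_depths[0])


def _validate_branch_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # root edge may legitimately be absent
        if edge.length is None:
            raise ValueError("tree has missing branch lengths")
        if edge.length < 0:
            raise ValueError("tree has negative branch lengths")


def _wrap(tree: dendropy.Tree, ultrametric_tolerance: float) -> PhyloTree:
    _validate_branch_lengths(tree)
    depths = np.array([lf.distance_from_root() for lf in tree.leaf_node_iter()])
    depth = float(depths.max())
    discrepancy = float(depths.max() - depths.min())
    if depth > 0 and discrepancy > ultrametric_tolerance * depth:
        raise NotUltrametricError(
            f"tree is not ultrametric: root-to-tip depths differ by "
            f"{discrepancy:g} (> {ultrametric_tolerance:g} of depth {depth:g})"
        )
    is_binary = all(
        len(nd.child_nodes()) == 2 for nd in tree.preorder_internal_node_iter()
    )
    return PhyloTree(
        tree=tree,
        is_binary=is_binary,
        depth_discrepancy=discrepancy,
    )


def read_newick(
    path, ultrametric_tolerance: float = DEFAULT_ULTRAMETRIC_TOL
) -> PhyloTree:
    """Read the first Newick tree in *path* and validate ultrametricity.

    Raises :class:`NotUltrametricError` if root-to-tip depths disagree by more
    than ``ultrametric_tolerance`` (relative to tree depth), and ValueError on
    unparseable input or missing branch lengths.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parser error types
        raise ValueError(f"could not parse Newick file {path}: {exc}") from exc
    return _wrap(tree, ultrametric_tolerance)


def tree_from_string(
    newick: str, ultrametric_tolerance: float = DEFAULT_ULTRAMETRIC_TOL
) -> PhyloTree:
    """Parse a Newick string (same validation as :func:`read_newick`)."""
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:
        raise ValueError(f"could not parse Newick string: {exc}") from exc
    return _wrap(tree, ultrametric_tolerance)


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


def resolve_polytomies(
    tree: PhyloTree, epsilon: float = 1e-6, seed: Optional[int] = None
) -> PhyloTree:
    """Resolve multifurcations into random bifurcations spaced by *epsilon*.

    Each polytomy of degree d is replaced by d-2 random bifurcations whose
    depths sit epsilon, 2*epsilon, ... below the original node; all original
    node depths (in particular every tip-to-root depth) are preserved exactly,
    so the only new internode distances are of size epsilon. Because the
    likelihood depends on internode distances alone, the random order of
    resolution does not affect downstream analyses.

    An already-binary tree is returned unchanged (as a copy).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    rng = random.Random(seed)
    work = tree.tree.clone(depth=1)

    # original depths, to be preserved
    depth_of = {}
    for nd in work.preorder_node_iter():
        parent = nd.parent_node
        base = depth_of[parent] if parent is not None else 0.0
        depth_of[nd] = base + (nd.edge.length or 0.0)

    origin_of = {}  # created node -> the polytomy node it resolves
    for nd in list(work.preorder_internal_node_iter()):
        children = list(nd.child_nodes())
        while len(children) > 2:
            a, b = rng.sample(children, 2)
            nd.remove_child(a)
            nd.remove_child(b)
            new = dendropy.Node()
            new.add_child(a)
            new.add_child(b)
            nd.add_child(new)
            origin_of[new] = nd
            children = list(nd.child_nodes())

    if not origin_of:
        return PhyloTree(
            tree=work,
            n0=tree.n0,
            sampling_fraction=tree.sampling_fraction,
            is_binary=tree.is_binary,
            depth_discrepancy=tree.depth_discrepancy,
        )

    # assign strictly increasing depths (epsilon, 2*epsilon, ... below the
    # original polytomy node) to the new nodes, regardless of how they happen
    # to nest, so every random resolution yields the same multiset of
    # internode distances; then recompute every edge length from depths.
    # Preorder guarantees a created ancestor receives a smaller offset than
    # any created descendant from the same polytomy.
    counter: dict = {}
    for nd in work.preorder_node_iter():
        origin = origin_of.get(nd)
        if origin is not None:
            k = counter.get(id(origin), 0) + 1
            counter[id(origin)] = k
            depth_of[nd] = depth_of[origin] + k * epsilon
    for nd in work.preorder_node_iter():
        if nd.parent_node is not None:
            length = depth_of[nd] - depth_of[nd.parent_node]
            if length < 0:
                raise ValueError(
                    "epsilon too large: polytomy resolution would create a "
                    "negative branch length"
                )
            nd.edge.length = length

    return PhyloTree(
        tree=work,
        n0=tree.n0,
        sampling_fraction=tree.sampling_fraction,
        is_binary=True,
        depth_discrepancy=tree.depth_discrepancy,
    )


def coalescent_times(tree: PhyloTree) -> CoalescentTimes:
    """Extract the ordered coalescent times of a binary ultrametric tree.

    Node depths are measured backwards from the present (the deepest tip).
    Tied node depths are kept as-is; resolve polytomies upstream if exact
    zeros would be a problem.
    """
    n = tree.n_tips
    if n < 3:
        raise ValueError("need at least 3 tips (no usable internode distance)")
    if not tree.is_binary:
        raise ValueError(
            "tree is not binary; call resolve_polytomies() first"
        )
    total_depth = tree.depth
    depths_before_present = [
        total_depth - nd.distance_from_root()
        for nd in tree.tree.preorder_internal_node_iter()
    ]
    depths = np.sort(np.asarray(depths_before_present))[::-1]
    # guard tiny negative values from float noise on the deepest node
    depths = np.clip(depths, 0.0, None)
    return CoalescentTimes(n=n, node_depths=depths)
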