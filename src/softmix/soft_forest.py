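"""Soft decision trees and their ensemble.

A soft tree routes an input through every branch with a logistic probability
instead of a hard indicator: the child satisfying ``z[j] <= C`` receives the
gate ``psi((C - z[j]) / tau)`` with ``psi`` the standard logistic function,
and the other child the complement.  A leaf's weight is the product of the
gates along its path, so the leaf weights of any tree form a partition of
unity and the classic hard (CART/BART) tree is recovered as the bandwidth
``tau -> 0``.

The ensemble ``h(z) = sum_t Tree_t(z)`` carries a simplex ``s`` of
split-variable probabilities with a Dirichlet(a/M, ..., a/M) prior, which is
what gives the model its sparse variable selection.

Evaluation here walks the node objects directly (clear, and an independent
cross-check of the flat-array numba path used by the sampler);
:func:`basis_matrix` delegates to the compiled kernel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from ._kernels import NMAX, _basis


# ---------------------------------------------------------------------------
# types

@dataclass
class SoftTreeNode:
    """Branch (split_index/cutpoint + two children) or leaf (mu)."""

    split_index: int = -1
    cutpoint: float = 0.0
    left: "SoftTreeNode | None" = None
    right: "SoftTreeNode | None" = None
    mu: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def kind(self) -> str:
        return "leaf" if self.is_leaf else "branch"

    def validate(self) -> None:
        if self.is_leaf:
            if self.right is not None:
                raise ValueError("leaf node must have no children")
        else:
            if self.right is None:
                raise ValueError("branch node must have two children")
            if self.split_index < 0:
                raise ValueError("branch node needs a split index")
            self.left.validate()
            self.right.validate()


@dataclass
class SoftTree:
    """A soft tree: root node plus its own positive bandwidth ``tau``."""

    root: SoftTreeNode
    tau: float = 0.1

    def __post_init__(self) -> None:
        if not (self.tau > 0):
            raise ValueError(f"tau must be positive, got {self.tau}")
        self.root.validate()

    def leaves(self) -> list[SoftTreeNode]:
        out: list[SoftTreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.append(node.right)
                stack.append(node.left)
        return out

    def branches(self) -> list[SoftTreeNode]:
        out: list[SoftTreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.append(node.right)
                stack.append(node.left)
        return out

    def n_leaves(self) -> int:
        return len(self.leaves())


@dataclass
class ForestState:
    """T soft trees plus the shared split-probability simplex and scales."""

    trees: list[SoftTree]
    split_probs: np.ndarray
    dirichlet_mass: float = 1.0
    sigma_mu: float = 0.05
    depth_gamma: float = 0.3
    depth_beta: float = 2.0

    def __post_init__(self) -> None:
        self.split_probs = np.asarray(self.split_probs, dtype=float)
        if self.split_probs.ndim != 1:
            raise ValueError("split_probs must be a vector")
        if np.any(self.split_probs < 0) or not np.isclose(
                self.split_probs.sum(), 1.0):
            raise ValueError("split_probs must be a probability simplex")
        if not (self.dirichlet_mass > 0 and self.sigma_mu > 0):
            raise ValueError("dirichlet_mass and sigma_mu must be positive")

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_variables(self) -> int:
        return self.split_probs.size


# ---------------------------------------------------------------------------
# evaluation

def _psi(x: float) -> float:
    """Overflow-safe logistic function."""
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _check_z(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("exposure vector contains non-finite entries")
    return z


def leaf_weight(z: np.ndarray, tree: SoftTree, leaf: SoftTreeNode) -> float:
    """Gating weight of ``leaf`` at exposure vector ``z``.

    Product over the leaf's ancestors b of ``psi((C_b - z[j_b]) / tau)`` when
    the path goes to the <=-child and the complement otherwise.  Weights over
    all leaves of a tree sum to one.
    """
    z = _check_z(z)
    if not (tree.tau > 0):
        raise ValueError("tau must be positive")

    def descend(node: SoftTreeNode, w: float) -> float | None:
        if node is leaf:
            return w
        if node.is_leaf:
            return None
        g = _psi((node.cutpoint - z[node.split_index]) / tree.tau)
        found = descend(node.left, w * g)
        if found is not None:
            return found
        return descend(node.right, w * (1.0 - g))

    w = descend(tree.root, 1.0)
    if w is None:
        raise ValueError("node is not a leaf of this tree")
    return w


def tree_evaluate(z: np.ndarray, tree: SoftTree) -> float:
    """Soft-tree output: sum over leaves of mu_l * leaf_weight."""
    z = _check_z(z)
    total = 0.0
    stack: list[tuple[SoftTreeNode, float]] = [(tree.root, 1.0)]
    while stack:
        node, w = stack.pop()
        if node.is_leaf:
            total += node.mu * w
        else:
            g = _psi((node.cutpoint - z[node.split_index]) / tree.tau)
            stack.append((node.left, w * g))
            stack.append((node.right, w * (1.0 - g)))
    return total


def forest_evaluate(z: np.ndarray, forest: ForestState) -> float:
    """Ensemble output: sum of tree_evaluate over all trees."""
    return float(sum(tree_evaluate(z, tree) for tree in forest.trees))


def basis_matrix(Z: np.ndarray, tree: SoftTree) -> np.ndarray:
    """n x L matrix of leaf weights for each row of Z; rows sum to one.

    Leaf order matches ``tree.leaves()``.  This is the basis-function view
    ``Tree(z) = Phi(z) @ mu`` the sampler's marginalized updates use.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if not np.all(np.isfinite(Z)):
        raise ValueError("exposure matrix contains non-finite entries")
    maxj = max((b.split_index for b in tree.branches()), default=-1)
    if maxj >= Z.shape[1]:
        raise ValueError(
            f"tree splits on column {maxj} but Z has {Z.shape[1]} columns")
    arrs = tree_to_arrays(tree)
    return _basis(arrs["var"], arrs["cut"], arrs["left"], arrs["right"],
                  arrs["nnode"], tree.tau, Z)


# ---------------------------------------------------------------------------
# flat-array conversion (sampler interop)

def tree_to_arrays(tree: SoftTree, nmax: int = NMAX) -> dict:
    """Flatten a node tree into the slot arrays the kernels use.

    Slot 0 is the root; children always occupy higher slots; leaves keep the
    same left-to-right order as ``tree.leaves()``.
    """
    nodes: list[SoftTreeNode] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        nodes.append(node)
        if not node.is_leaf:
            stack.append(node.right)
            stack.append(node.left)
    n = len(nodes)
    if n > nmax:
        raise ValueError(f"tree has {n} nodes, exceeding capacity {nmax}")
    index = {id(node): k for k, node in enumerate(nodes)}
    var = np.full(nmax, -1, dtype=np.int64)
    cut = np.zeros(nmax)
    left = np.full(nmax, -1, dtype=np.int64)
    right = np.full(nmax, -1, dtype=np.int64)
    parent = np.full(nmax, -1, dtype=np.int64)
    depth = np.zeros(nmax, dtype=np.int64)
    mu = np.zeros(nmax)
    for k, node in enumerate(nodes):
        if node.is_leaf:
            mu[k] = node.mu
        else:
            var[k] = node.split_index
            cut[k] = node.cutpoint
            left[k] = index[id(node.left)]
            right[k] = index[id(node.right)]
            parent[left[k]] = k
            parent[right[k]] = k
            depth[left[k]] = depth[k] + 1
            depth[right[k]] = depth[k] + 1
    return {"var": var, "cut": cut, "left": left, "right": right,
            "parent": parent, "depth": depth, "mu": mu, "nnode": n}


def arrays_to_tree(var, cut, left, right, mu, nnode: int,
                   tau: float) -> SoftTree:
    """Rebuild a node tree from flat slot arrays (inverse of tree_to_arrays)."""

    def build(k: int) -> SoftTreeNode:
        if var[k] < 0:
            return SoftTreeNode(mu=float(mu[k]))
        return SoftTreeNode(split_index=int(var[k]), cutpoint=float(cut[k]),
                            left=build(int(left[k])), right=build(int(right[k])))

    if nnode < 1:
        raise ValueError("empty tree")
    return SoftTree(root=build(0), tau=float(tau))


# ---------------------------------------------------------------------------
# JSON serialization

def _node_to_dict(node: SoftTreeNode) -> dict:
    if node.is_leaf:
        return {"kind": "leaf", "mu": node.mu}
    return {"kind": "branch", "split_index": node.split_index,
            "cutpoint": node.cutpoint,
            "left": _node_to_dict(node.left),
            "right": _node_to_dict(node.right)}


def _node_from_dict(d: dict) -> SoftTreeNode:
    if d["kind"] == "leaf":
        return SoftTreeNode(mu=float(d["mu"]))
    return SoftTreeNode(split_index=int(d["split_index"]),
                        cutpoint=float(d["cutpoint"]),
                        left=_node_from_dict(d["left"]),
                        right=_node_from_dict(d["right"]))


def tree_to_json(tree: SoftTree) -> str:
    return json.dumps({"tau": tree.tau, "root": _node_to_dict(tree.root)})


def tree_from_json(text: str) -> SoftTree:
    d = json.loads(text)
    return SoftTree(root=_node_from_dict(d["root"]), tau=float(d["tau"]))


def forest_to_json(forest: ForestState) -> str:
    return json.dumps({
        "trees": [{"tau": t.tau, "root": _node_to_dict(t.root)}
                  for t in forest.trees],
        "split_probs": forest.split_probs.tolist(),
        "dirichlet_mass": forest.dirichlet_mass,
        "sigma_mu": forest.sigma_mu,
        "depth_gamma": forest.depth_gamma,
        "depth_beta": forest.depth_beta,
    })


def forest_from_json(text: str) -> ForestState:
    d = json.loads(text)
    trees = [SoftTree(root=_node_from_dict(td["root"]), tau=float(td["tau"]))
             for td in d["trees"]]
    return ForestState(trees=trees,
                       split_probs=np.asarray(d["split_probs"], dtype=float),
                       dirichlet_mass=float(d["dirichlet_mass"]),
                       sigma_mu=float(d["sigma_mu"]),
                       depth_gamma=float(d["depth_gamma"]),
                       depth_beta=float(d["depth_beta"]))
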