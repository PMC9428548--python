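"""Shared fixtures and independent oracles.

The enumeration oracle materializes the full joint tensor over internal-node
states (root prior x per-edge transition factors x leaf messages) and sums
it explicitly; it never uses the pruning recursion it is checking.
"""

from __future__ import annotations

import numpy as np
import pytest

from depolkit.model import build_wag, transition_matrix
from depolkit.seqio import PhyloTree, TreeNode


@pytest.fixture(scope="session")
def wag():
    return build_wag()


@pytest.fixture(scope="session")
def blosum62():
    from depolkit.seqio import load_blosum62

    return load_blosum62()


def joint_tensor(tree: PhyloTree, P: dict[int, np.ndarray], pi: np.ndarray,
                 leaf_partials: dict[str, np.ndarray]) -> tuple[np.ndarray, dict[int, int]]:
    """Full joint over internal-node states for one column.

    Returns the tensor (one axis per internal node, root first in postorder
    ordering) and the node-uid -> axis map.
    """
    internal = [n for n in tree.postorder() if not n.is_leaf]
    axes = {n.uid: i for i, n in enumerate(internal)}
    k = pi.shape[0]
    shape = tuple([k] * len(internal))
    J = np.ones(shape)

    def expand(vec_or_mat, ax_rows, ax_cols=None):
        """Broadcast a per-state factor onto the joint tensor's axes."""
        if ax_cols is None:
            sh = [1] * len(internal)
            sh[ax_rows] = k
            return vec_or_mat.reshape(sh)
        sh = [1] * len(internal)
        sh[ax_rows] = k
        sh[ax_cols] = k
        out = np.ones((k, k)).reshape(sh).copy()
        idx_rows = np.arange(k).reshape([k if i == ax_rows else 1 for i in range(len(internal))])
        idx_cols = np.arange(k).reshape([k if i == ax_cols else 1 for i in range(len(internal))])
        return vec_or_mat[idx_rows, idx_cols]

    root = tree.root
    J = J * expand(pi, axes[root.uid])
    for node in tree.postorder():
        if node is root:
            continue
        if node.is_leaf:
            msg = P[node.uid] @ leaf_partials[node.label]
            J = J * expand(msg, axes[node.parent.uid])
        else:
            J = J * expand(P[node.uid], axes[node.parent.uid], axes[node.uid])
    return J, axes


def enum_log_likelihood(tree, P, pi, leaf_partials) -> float:
    J, _ = joint_tensor(tree, P, pi, leaf_partials)
    return float(np.log(J.sum()))


def enum_marginal(tree, P, pi, leaf_partials, node_uid) -> np.ndarray:
    J, axes = joint_tensor(tree, P, pi, leaf_partials)
    other = tuple(i for i in range(J.ndim) if i != axes[node_uid])
    m = J.sum(axis=other)
    return m / m.sum()


def random_tree(rng: np.random.Generator, n_leaves: int,
                allow_polytomy: bool = True, max_bl: float = 1.5) -> PhyloTree:
    """Random rooted topology (possibly multifurcating) with random lengths."""
    nodes = [TreeNode(label=f"L{i}", length=float(rng.uniform(0.01, max_bl)))
             for i in range(n_leaves)]
    while len(nodes) > 1:
        k = 2
        if allow_polytomy and len(nodes) > 2 and rng.random() < 0.3:
            k = 3
        picks = rng.choice(len(nodes), size=min(k, len(nodes)), replace=False)
        parent = TreeNode(length=float(rng.uniform(0.01, max_bl)))
        for i in sorted(picks, reverse=True):
            parent.add_child(nodes.pop(i))
        nodes.append(parent)
    nodes[0].length = 0.0
    return PhyloTree(nodes[0])


def branch_P(tree: PhyloTree, model) -> dict[int, np.ndarray]:
    return {n.uid: transition_matrix(model, n.length)
            for n in tree.postorder() if n.parent is not None}


def two_state_branch_P(tree: PhyloTree, pi1: float, rate: float) -> dict[int, np.ndarray]:
    pi = np.array([1 - pi1, pi1])
    out = {}
    for n in tree.postorder():
        if n.parent is None:
            continue
        e = np.exp(-rate * n.length)
        out[n.uid] = np.tile(pi, (2, 1)) * (1 - e) + np.eye(2) * e
    return out
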