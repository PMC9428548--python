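"""Maximum-likelihood marginal ancestral reconstruction.

Two layers share one pruning engine that is generic over the state count:

* residue layer — 20-state WAG likelihood with gaps treated as missing data
  (all-ones partials) and ambiguity codes expanded to their residue sets;
* indel layer — alignment columns grouped into maximal blocks of identical
  leaf gap patterns, each block a binary presence/absence character under a
  two-state reversible model whose single exchange rate is fitted by ML.

Marginal posteriors come from the standard inside/outside (up-down) pass;
per-column scaling keeps 75-taxon likelihoods out of underflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DataError, TreeError
from .model import SubstitutionModel, discrete_gamma_rates, transition_matrix
from .seqio import (
    AA_ALPHABET,
    AA_INDEX,
    AMBIGUITY,
    GAP,
    PhyloTree,
    ProteinAlignment,
    TreeNode,
)

DEFAULT_PRESENCE_THRESHOLD = 0.5


def _char_partial(c: str, n_states: int = 20) -> np.ndarray:
    v = np.zeros(n_states)
    if c == GAP or c == "X":
        v[:] = 1.0
    elif c in AMBIGUITY:
        for r in AMBIGUITY[c]:
            v[AA_INDEX[r]] = 1.0
    elif c in AA_INDEX:
        v[AA_INDEX[c]] = 1.0
    else:
        raise DataError(f"invalid residue character {c!r}")
    return v


def leaf_partials(aln: ProteinAlignment) -> dict[str, np.ndarray]:
    """Per-leaf (ncol, 20) partial-likelihood arrays."""
    out = {}
    for name, row in zip(aln.names, aln.rows):
        out[name] = np.stack([_char_partial(c) for c in row])
    return out


# ---------------------------------------------------------------------------
# Generic pruning engine
# ---------------------------------------------------------------------------


def _branch_matrices(
    tree: PhyloTree, p_of_t: Callable[[float], np.ndarray]
) -> dict[int, np.ndarray]:
    return {
        node.uid: p_of_t(node.length)
        for node in tree.postorder()
        if node.parent is not None
    }


def _inside_pass(
    tree: PhyloTree,
    partials: Mapping[str, np.ndarray],
    P: Mapping[int, np.ndarray],
) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Post-order partials with per-column log scaling factors."""
    inside: dict[int, np.ndarray] = {}
    log_scale: np.ndarray | None = None
    for node in tree.postorder():
        if node.is_leaf:
            if node.label not in partials:
                raise DataError(f"leaf {node.label!r} has no observed states")
            inside[node.uid] = partials[node.label]
            continue
        acc = None
        for child in node.children:
            msg = inside[child.uid] @ P[child.uid].T
            acc = msg if acc is None else acc * msg
        scale = acc.max(axis=1)
        scale[scale == 0.0] = 1.0  # impossible column; keep finite
        acc = acc / scale[:, None]
        log_scale = (
            np.log(scale) if log_scale is None else log_scale + np.log(scale)
        )
        inside[node.uid] = acc
    if log_scale is None:  # single-leaf tree
        log_scale = np.zeros(next(iter(inside.values())).shape[0])
    return inside, log_scale


def _outside_pass(
    tree: PhyloTree,
    inside: Mapping[int, np.ndarray],
    P: Mapping[int, np.ndarray],
    pi: np.ndarray,
) -> dict[int, np.ndarray]:
    """Messages from the rest of the tree, root prior included; normalized."""
    ncol = next(iter(inside.values())).shape[0]
    outside: dict[int, np.ndarray] = {
        tree.root.uid: np.tile(pi, (ncol, 1))
    }
    for node in tree.preorder():
        if node.is_leaf:
            continue
        msgs = [inside[c.uid] @ P[c.uid].T for c in node.children]
        for i, child in enumerate(node.children):
            sib = outside[node.uid].copy()
            for j, m in enumerate(msgs):
                if j != i:
                    sib = sib * m
            o = sib @ P[child.uid]
            norm = o.sum(axis=1, keepdims=True)
            norm[norm == 0.0] = 1.0
            outside[child.uid] = o / norm
        del msgs
    return outside


def _site_log_likelihoods(
    tree: PhyloTree,
    inside: Mapping[int, np.ndarray],
    log_scale: np.ndarray,
    pi: np.ndarray,
) -> np.ndarray:
    lik = inside[tree.root.uid] @ pi
    with np.errstate(divide="ignore"):
        return np.log(lik) + log_scale


# ---------------------------------------------------------------------------
# Residue layer
# ---------------------------------------------------------------------------


def column_likelihood(
    tree: PhyloTree,
    model: SubstitutionModel,
    column: Mapping[str, str],
) -> float:
    """Log-likelihood of a single alignment column (leaf label -> char)."""
    for label in tree.leaf_labels():
        if label not in column:
            raise DataError(f"leaf {label!r} missing from column")
    partials = {lab: _char_partial(c)[None, :] for lab, c in column.items()}
    P = _branch_matrices(tree, lambda t: transition_matrix(model, t))
    inside, log_scale = _inside_pass(tree, partials, P)
    return float(_site_log_likelihoods(tree, inside, log_scale, model.pi)[0])


def alignment_log_likelihood(
    tree: PhyloTree, model: SubstitutionModel, aln: ProteinAlignment
) -> float:
    P = _branch_matrices(tree, lambda t: transition_matrix(model, t))
    inside, log_scale = _inside_pass(tree, leaf_partials(aln), P)
    return float(_site_log_likelihoods(tree, inside, log_scale, model.pi).sum())


def marginal_posterior(
    tree: PhyloTree,
    model: SubstitutionModel,
    aln: ProteinAlignment,
    node: TreeNode | str,
) -> np.ndarray:
    """(ncol, 20) marginal residue posteriors at an internal node."""
    target = tree.find(node) if isinstance(node, str) else node
    if target.is_leaf:
        raise DataError("marginal posteriors are defined for internal nodes")
    P = _branch_matrices(tree, lambda t: transition_matrix(model, t))
    inside, _ = _inside_pass(tree, leaf_partials(aln), P)
    outside = _outside_pass(tree, inside, P, model.pi)
    post = inside[target.uid] * outside[target.uid]
    return post / post.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Indel layer
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndelBlock:
    """Maximal run of columns sharing one leaf presence pattern."""

    start: int  # inclusive column index
    stop: int  # exclusive
    presence: tuple[bool, ...]  # by alignment row order


@dataclass(frozen=True)
class IndelCharacterSet:
    names: tuple[str, ...]
    blocks: tuple[IndelBlock, ...]
    ncol: int


def build_indel_blocks(aln: ProteinAlignment) -> IndelCharacterSet:
    patterns = []
    for j in range(aln.ncol):
        pat = tuple(row[j] != GAP for row in aln.rows)
        if not any(pat):
            raise DataError(f"column {j + 1} is entirely gaps")
        patterns.append(pat)
    blocks: list[IndelBlock] = []
    start = 0
    for j in range(1, aln.ncol + 1):
        if j == aln.ncol or patterns[j] != patterns[start]:
            blocks.append(IndelBlock(start, j, patterns[start]))
            start = j
    return IndelCharacterSet(tuple(aln.names), tuple(blocks), aln.ncol)


def _two_state_p_factory(pi1: float, rate: float) -> Callable[[float], np.ndarray]:
    pi = np.array([1.0 - pi1, pi1])

    def p_of_t(t: float) -> np.ndarray:
        e = np.exp(-rate * t)
        P = np.tile(pi, (2, 1)) * (1.0 - e) + np.eye(2) * e
        return P

    return p_of_t


@dataclass
class IndelReconstruction:
    rate: float
    pi_present: float
    log_likelihood: float
    #: per node uid: (n_blocks,) presence posterior
    block_presence: dict[int, np.ndarray]
    characters: IndelCharacterSet

    def column_presence(self, node_uid: int) -> np.ndarray:
        out = np.empty(self.characters.ncol)
        for k, b in enumerate(self.characters.blocks):
            out[b.start : b.stop] = self.block_presence[node_uid][k]
        return out


def reconstruct_indels(
    tree: PhyloTree,
    characters: IndelCharacterSet,
    rate: float | None = None,
    pseudocount: float = 1.0,
) -> IndelReconstruction:
    """ML presence/absence reconstruction of indel blocks at every node."""
    names = list(characters.names)
    nblocks = len(characters.blocks)
    states = np.array([b.presence for b in characters.blocks], dtype=float)
    n_present = states.sum() + pseudocount
    n_total = states.size + 2 * pseudocount
    pi1 = float(n_present / n_total)
    pi = np.array([1.0 - pi1, pi1])

    partials = {}
    for i, name in enumerate(names):
        arr = np.zeros((nblocks, 2))
        arr[np.arange(nblocks), states[:, i].astype(int)] = 1.0
        partials[name] = arr

    def neg_loglik(log_r: float) -> float:
        P = _branch_matrices(tree, _two_state_p_factory(pi1, np.exp(log_r)))
        inside, log_scale = _inside_pass(tree, partials, P)
        return -float(_site_log_likelihoods(tree, inside, log_scale, pi).sum())

    if rate is None:
        res = minimize_scalar(
            neg_loglik, bounds=(np.log(1e-3), np.log(1e3)), method="bounded",
            options={"xatol": 1e-6},
        )
        rate = float(np.exp(res.x))
    P = _branch_matrices(tree, _two_state_p_factory(pi1, rate))
    inside, log_scale = _inside_pass(tree, partials, P)
    loglik = float(_site_log_likelihoods(tree, inside, log_scale, pi).sum())
    outside = _outside_pass(tree, inside, P, pi)
    block_presence: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        post = inside[node.uid] * outside[node.uid]
        post = post / post.sum(axis=1, keepdims=True)
        block_presence[node.uid] = post[:, 1]
    return IndelReconstruction(rate, pi1, loglik, block_presence, characters)


# ---------------------------------------------------------------------------
# Full reconstruction
# ---------------------------------------------------------------------------


@dataclass
class AncestralReconstruction:
    """Residue and presence posteriors for every internal node."""

    tree: PhyloTree
    model: SubstitutionModel
    #: node uid -> (ncol, 20) residue posterior
    residue_posteriors: dict[int, np.ndarray]
    #: node uid -> (ncol,) presence posterior
    presence_posteriors: dict[int, np.ndarray]
    log_likelihood: float
    indels: IndelReconstruction | None = None

    def node_uid(self, node: TreeNode | str) -> int:
        if isinstance(node, str):
            if node == "root":
                return self.tree.root.uid
            node = self.tree.find(node)
        return node.uid

    def map_sequence(
        self,
        node: TreeNode | str = "root",
        presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    ) -> str:
        return ancestral_sequence(self, node, presence_threshold)


def reconstruct(
    tree: PhyloTree,
    model: SubstitutionModel,
    aln: ProteinAlignment,
    gamma_classes: int | None = None,
    gamma_alpha: float = 1.0,
    indel_reconstruction: bool = True,
) -> AncestralReconstruction:
    """Run both layers and collect posteriors for every internal node.

    With ``gamma_classes`` set, the likelihood is an equal-weight mixture over
    discrete-gamma rate classes and node posteriors are mixed with per-column
    class weights proportional to the class likelihoods.
    """
    missing = set(tree.leaf_labels()) - set(aln.names)
    if missing:
        raise DataError(f"tree leaves missing from alignment: {sorted(missing)}")
    partials = leaf_partials(aln)
    rates = (
        discrete_gamma_rates(gamma_alpha, gamma_classes)
        if gamma_classes
        else np.array([1.0])
    )
    internal = [n for n in tree.postorder() if not n.is_leaf]
    ncol = aln.ncol
    post_acc = {n.uid: np.zeros((ncol, 20)) for n in internal}
    site_lik_acc = np.zeros(ncol)
    max_log = None
    per_class = []
    for r in rates:
        P = _branch_matrices(tree, lambda t, r=r: transition_matrix(model, t * r))
        inside, log_scale = _inside_pass(tree, partials, P)
        site_ll = _site_log_likelihoods(tree, inside, log_scale, model.pi)
        outside = _outside_pass(tree, inside, P, model.pi)
        posts = {}
        for n in internal:
            p = inside[n.uid] * outside[n.uid]
            posts[n.uid] = p / p.sum(axis=1, keepdims=True)
        per_class.append((site_ll, posts))
        max_log = site_ll if max_log is None else np.maximum(max_log, site_ll)
    for site_ll, posts in per_class:
        w = np.exp(site_ll - max_log) / len(rates)
        site_lik_acc += w
        for uid, p in posts.items():
            post_acc[uid] += w[:, None] * p
    loglik = float(np.sum(np.log(site_lik_acc) + max_log))
    residue_posteriors = {
        uid: p / site_lik_acc[:, None] for uid, p in post_acc.items()
    }

    indels = None
    presence = {n.uid: np.ones(ncol) for n in internal}
    if indel_reconstruction and any(GAP in row for row in aln.rows):
        indels = reconstruct_indels(tree, build_indel_blocks(aln))
        presence = {n.uid: indels.column_presence(n.uid) for n in internal}
    return AncestralReconstruction(
        tree, model, residue_posteriors, presence, loglik, indels
    )


def ancestral_sequence(
    recon: AncestralReconstruction,
    node: TreeNode | str = "root",
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> str:
    """MAP sequence at a node: argmax residue, absent columns dropped.

    Ties are broken by higher equilibrium frequency, then alphabetically.
    """
    uid = recon.node_uid(node)
    post = recon.residue_posteriors[uid]
    presence = recon.presence_posteriors[uid]
    pi = recon.model.pi
    out = []
    for j in range(post.shape[0]):
        if presence[j] < presence_threshold:
            continue
        p = post[j]
        top = p.max()
        cand = [i for i in range(20) if p[i] >= top - 1e-12]
        cand.sort(key=lambda i: (-pi[i], AA_ALPHABET[i]))
        out.append(AA_ALPHABET[cand[0]])
    return "".join(out)


def resolve_polytomy(
    tree: PhyloTree,
    node: TreeNode | str,
    guide: Sequence[Iterable[str]],
) -> PhyloTree:
    """Binary-resolve a multifurcation with zero-length internal branches.

    ``guide`` partitions the node's children by their descendant leaf labels;
    each group of two or more children is gathered under a new zero-length
    node, leaving the likelihood unchanged.
    """
    new_tree = tree.copy()
    label = node if isinstance(node, str) else node.label
    if label is None:
        raise TreeError("target polytomy must be identified by label")
    target = new_tree.find(label)
    if len(target.children) < 3:
        raise TreeError(f"node {label!r} is not a multifurcation")

    def leafset(n: TreeNode) -> frozenset[str]:
        if n.is_leaf:
            return frozenset([n.label])
        return frozenset().union(*(leafset(c) for c in n.children))

    groups = [frozenset(g) for g in guide]
    all_leaves = frozenset().union(*(leafset(c) for c in target.children))
    if frozenset().union(*groups) != all_leaves:
        raise TreeError("guide does not cover exactly the polytomy's leaves")
    assignment: list[list[TreeNode]] = [[] for _ in groups]
    for child in target.children:
        ls = leafset(child)
        hits = [k for k, g in enumerate(groups) if ls <= g]
        if not hits:
            raise TreeError(
                f"child with leaves {sorted(ls)} straddles guide groups"
            )
        assignment[hits[0]].append(child)
    new_children: list[TreeNode] = []
    for members in assignment:
        if not members:
            raise TreeError("guide group matches no child of the polytomy")
        if len(members) == 1:
            new_children.append(members[0])
        else:
            hub = TreeNode(length=0.0)
            for m in members:
                hub.add_child(m)
            new_children.append(hub)
    target.children = []
    for c in new_children:
        target.add_child(c)
    return PhyloTree(new_tree.root)
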