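"""Containers and readers/writers for alignments, trees and scoring matrices.

Alignment IO is delegated to Biopython's FASTA parser; Newick IO to dendropy.
The containers themselves are deliberately small: a gapped protein alignment
with column access, a rooted tree with parent links and non-negative branch
lengths, and an integer substitution scoring matrix (BLOSUM62 ships as a
packaged NCBI-format text file).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Sequence

import dendropy
from Bio import SeqIO

from .errors import AlignmentError, DataError, ParseError, TreeError

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
GAP = "-"
#: ambiguity codes expanded to candidate residue sets
AMBIGUITY = {"B": "ND", "Z": "QE", "X": AA_ALPHABET}
VALID_CHARS = set(AA_ALPHABET) | set(AMBIGUITY) | {GAP}


@dataclass
class ProteinAlignment:
    """A gapped amino-acid alignment: unique names, equal-length rows."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise AlignmentError("names and rows differ in length")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise AlignmentError(f"duplicate sequence names: {dupes}")
        if self.rows:
            ncol = len(self.rows[0])
            for name, row in zip(self.names, self.rows):
                if len(row) != ncol:
                    raise AlignmentError(
                        f"row {name!r} has length {len(row)}, expected {ncol}"
                    )
        for name, row in zip(self.names, self.rows):
            for j, c in enumerate(row):
                if c not in VALID_CHARS:
                    raise ParseError(
                        f"invalid residue {c!r} in row {name!r} at column {j + 1}"
                    )

    @property
    def nrow(self) -> int:
        return len(self.rows)

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        """Characters of column ``j`` (0-based), top to bottom."""
        return "".join(row[j] for row in self.rows)

    def columns(self) -> Iterator[str]:
        for j in range(self.ncol):
            yield self.column(j)

    def row(self, name: str) -> str:
        try:
            return self.rows[self.names.index(name)]
        except ValueError:
            raise KeyError(name) from None

    def subset(self, keep: Iterable[str]) -> "ProteinAlignment":
        keep = list(keep)
        missing = [n for n in keep if n not in self.names]
        if missing:
            raise AlignmentError(f"unknown sequence names: {missing}")
        return ProteinAlignment(keep, [self.row(n) for n in keep])


def read_alignment(path) -> ProteinAlignment:
    """Read an aligned FASTA file; '.' gaps are normalized to '-'."""
    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        rows.append(str(rec.seq).upper().replace(".", GAP))
    if not names:
        raise ParseError(f"no FASTA records found in {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise AlignmentError(
            f"unequal sequence lengths in {path}: {sorted(lengths)}"
        )
    return ProteinAlignment(names, rows)


def write_alignment(aln: ProteinAlignment, path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(aln.names, aln.rows):
            fh.write(f">{name}\n{row}\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

_node_counter = [0]


@dataclass
class TreeNode:
    """One node of a rooted tree; ``length`` is the edge to the parent."""

    label: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None
    uid: int = field(default_factory=lambda: _node_counter.__setitem__(0, _node_counter[0] + 1) or _node_counter[0])

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted phylogeny; multifurcations permitted; branch lengths >= 0."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        seen: set[int] = set()
        for node in self.postorder():
            if node.uid in seen:
                raise TreeError("cycle detected in tree")
            seen.add(node.uid)
            if node.length < 0:
                raise TreeError(
                    f"negative branch length {node.length} at node "
                    f"{node.label or node.uid}"
                )
        labels = [n.label for n in self.leaves()]
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate leaf labels")

    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.postorder() if not n.is_leaf]

    def find(self, label: str) -> TreeNode:
        for n in self.postorder():
            if n.label == label:
                return n
        raise TreeError(f"no node labelled {label!r}")

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(label=node.label, length=node.length)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return PhyloTree(clone(self.root))

    def patristic_distances(self) -> dict[tuple[str, str], float]:
        """All-pairs leaf path lengths by brute-force root paths."""

        def path_to_root(node: TreeNode) -> list[TreeNode]:
            out = []
            while node is not None:
                out.append(node)
                node = node.parent
            return out

        leaves = self.leaves()
        dists: dict[tuple[str, str], float] = {}
        for i, a in enumerate(leaves):
            pa = path_to_root(a)
            pa_set = {n.uid: k for k, n in enumerate(pa)}
            for b in leaves[i + 1 :]:
                d = 0.0
                node = b
                while node.uid not in pa_set:
                    d += node.length
                    node = node.parent
                for anc in pa[: pa_set[node.uid]]:
                    d += anc.length
                key = tuple(sorted((a.label, b.label)))
                dists[key] = d
        return dists

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                core = node.label or ""
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    core += node.label
            if node.parent is not None:
                core += f":{node.length:.12g}"
            return core

        return fmt(self.root) + ";"


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def convert(dnode) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        node = TreeNode(label=label, length=float(length))
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return PhyloTree(convert(dtree.seed_node))


def read_tree(path) -> PhyloTree:
    """Read a rooted Newick tree; a missing root edge length becomes 0."""
    try:
        dtree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ParseError(f"failed to parse Newick file {path}: {exc}") from exc
    return _from_dendropy(dtree)


def read_tree_string(newick: str) -> PhyloTree:
    try:
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ParseError(f"failed to parse Newick string: {exc}") from exc
    return _from_dendropy(dtree)


def write_tree(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def prune_to_taxa(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Induced subtree on ``keep``; degree-2 nodes suppressed, lengths summed."""
    keep = set(keep)
    if not keep:
        raise TreeError("keep set is empty")
    labels = set(tree.leaf_labels())
    unknown = sorted(keep - labels)
    if unknown:
        raise TreeError(f"unknown leaf labels: {unknown}")

    def build(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            if node.label in keep:
                return TreeNode(label=node.label, length=node.length)
            return None
        kept_children = [c for c in map(build, node.children) if c is not None]
        if not kept_children:
            return None
        if len(kept_children) == 1:
            # suppress this degree-2 node: absorb its length into the child
            child = kept_children[0]
            child.length += node.length
            return child
        new = TreeNode(label=node.label, length=node.length)
        for c in kept_children:
            new.add_child(c)
        return new

    new_root = build(tree.root)
    assert new_root is not None
    # a pruned root chain leaves the absorbed root-edge length on the new
    # root; zero it (it is above every kept leaf and carries no information)
    if new_root.is_leaf and len(keep) == 1:
        new_root.length = 0.0
    new_root.parent = None
    new_root.length = 0.0 if new_root.parent is None else new_root.length
    return PhyloTree(new_root)


def sequence_identity(a: str, b: str) -> float:
    """Fraction of identical residues over aligned, mutually non-gap sites.

    For unaligned equal-length sequences this is plain per-position identity;
    used for soft comparisons of inferred sequences against references.
    """
    if len(a) != len(b):
        raise DataError(
            f"identity requires equal-length sequences ({len(a)} vs {len(b)})"
        )
    pairs = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
    if not pairs:
        raise DataError("no mutually ungapped positions")
    return sum(x == y for x, y in pairs) / len(pairs)


# ---------------------------------------------------------------------------
# Scoring matrices
# ---------------------------------------------------------------------------


class ScoringMatrix:
    """Symmetric integer substitution scores over the 20-residue alphabet."""

    def __init__(self, scores: dict[tuple[str, str], int]):
        self._scores = dict(scores)
        for (a, b), s in scores.items():
            if self._scores.get((b, a), s) != s:
                raise DataError(f"asymmetric scoring matrix at pair ({a},{b})")

    def __getitem__(self, pair: tuple[str, str]) -> int:
        a, b = pair
        try:
            return self._scores[(a, b)]
        except KeyError:
            return self._scores[(b, a)]

    def score_against(self, residue: str, column: Sequence[str]) -> int:
        """Summed score of ``residue`` against every non-gap char in column."""
        return sum(self[residue, c] for c in column if c != GAP)


def load_scoring_matrix(text: str) -> ScoringMatrix:
    """Parse an NCBI-format matrix (header row of letters, labelled rows)."""
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split()
    scores: dict[tuple[str, str], int] = {}
    for ln in lines[1:]:
        parts = ln.split()
        row = parts[0]
        for col, val in zip(header, parts[1:]):
            scores[(row, col)] = int(val)
    return ScoringMatrix(scores)


def load_blosum62() -> ScoringMatrix:
    """The packaged BLOSUM62 matrix."""
    text = resources.files("depolkit.data").joinpath("blosum62.mat").read_text()
    return load_scoring_matrix(text)
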