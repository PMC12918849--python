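"""Rooted phylogenetic trees: Newick I/O, clades, pruning, and phylogenetic covariance.

The tree type here is deliberately small. Newick parsing is delegated to
dendropy (which handles quoting, comments and dialect quirks); the parsed
tree is converted into a lightweight node structure that the simulators and
concordance machinery can traverse and build cheaply.

Conventions
-----------
* Internal-node labels are interpreted as branch support on the 0-100 scale
  (ultrafast-bootstrap style). ``support_scale="unit"`` rescales 0-1 input
  on read.
* Branch lengths are non-negative; their unit (coalescent units,
  substitutions/site, Myr) is context-dependent and not tracked.
* Clades are rooted tip-label sets. Unrooted bipartitions are available
  separately for gene trees whose rooting is arbitrary.
"""

from __future__ import annotations

import io

from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

__all__ = [
    "Node",
    "PhyloTree",
    "PhyloCov",
    "parse_newick",
    "write_newick",
    "rooted_clades",
    "is_monophyletic",
    "phylo_vcv",
    "prune",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class Node:
    """A node in a rooted tree.

    ``length`` is the length of the branch subtending this node (``None``
    for the root); ``support`` is an optional value in [0, 100] attached to
    internal nodes.
    """

    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
    ) -> None:
        self.label = label
        self.length = length
        self.support = support
        self.children: List["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, len={self.length}, sup={self.support})"


class PhyloTree:
    """Rooted tree with labeled tips and non-negative branch lengths."""

    def __init__(self, root: Node, rooted: bool = True) -> None:
        self.root = root
        self.rooted = rooted
        self._validate()

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, text: str, support_scale: str = "percent") -> "PhyloTree":
        return parse_newick(text, support_scale=support_scale)

    def to_newick(self, include_support: bool = True) -> str:
        out = io.StringIO()

        def fmt_len(x: Optional[float]) -> str:
            return "" if x is None else f":{x:.12g}"

        def walk(n: Node) -> None:
            if n.is_leaf:
                out.write(n.label or "")
            else:
                out.write("(")
                for i, c in enumerate(n.children):
                    if i:
                        out.write(",")
                    walk(c)
                out.write(")")
                if include_support and n.support is not None and n.parent is not None:
                    out.write(f"{n.support:g}")
                elif n.label:
                    out.write(n.label)
            out.write(fmt_len(n.length))

        walk(self.root)
        out.write(";")
        return out.getvalue()

    # ------------------------------------------------------------ traversal
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def postorder(self) -> Iterator[Node]:
        out: List[Node] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return iter(reversed(out))

    def leaves(self) -> List[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def tip_labels(self) -> List[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self, exclude_root: bool = False) -> List[Node]:
        out = [n for n in self.preorder() if not n.is_leaf]
        if exclude_root:
            out = [n for n in out if n is not self.root]
        return out

    def __len__(self) -> int:
        return len(self.leaves())

    # ----------------------------------------------------------- validation
    def _validate(self) -> None:
        labels = self.tip_labels
        if any(lbl is None for lbl in labels):
            raise ValueError("every tip must carry a label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for n in self.preorder():
            if n.parent is not None and n.length is not None and n.length < 0:
                raise ValueError(f"negative branch length on node {n.label!r}")
            if n.support is not None and not (0 <= n.support <= 100):
                raise ValueError(f"support {n.support} outside [0, 100]")

    # ------------------------------------------------------------- queries
    def copy(self) -> "PhyloTree":
        def dup(n: Node) -> Node:
            m = Node(n.label, n.length, n.support)
            for c in n.children:
                m.add_child(dup(c))
            return m

        return PhyloTree(dup(self.root), rooted=self.rooted)

    def tip_sets(self) -> Dict[Node, FrozenSet[str]]:
        """Tip-label set under each node, computed in one postorder pass."""
        sets: Dict[Node, FrozenSet[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                sets[n] = frozenset([n.label])
            else:
                acc: set = set()
                for c in n.children:
                    acc |= sets[c]
                sets[n] = frozenset(acc)
        return sets

    def clades(self) -> List[FrozenSet[str]]:
        """Rooted clades: tip sets of internal non-root nodes."""
        sets = self.tip_sets()
        return [sets[n] for n in self.internal_nodes(exclude_root=True)]

    def bipartitions(self) -> List[FrozenSet[str]]:
        """Non-trivial unrooted bipartitions, each as the smaller/canonical side.

        Each bipartition is represented by the side not containing the
        alphabetically first tip label, so representations are comparable
        across trees on the same taxon set.
        """
        all_tips = frozenset(self.tip_labels)
        anchor = min(all_tips)
        seen = set()
        out: List[FrozenSet[str]] = []
        for s in self.clades():
            side = all_tips - s if anchor in s else s
            if len(side) < 2 or len(all_tips) - len(side) < 2:
                continue
            if side not in seen:
                seen.add(side)
                out.append(side)
        return out

    def mrca(self, taxa: Iterable[str]) -> Node:
        taxa = set(taxa)
        if not taxa:
            raise ValueError("taxa must be non-empty")
        known = set(self.tip_labels)
        unknown = sorted(taxa - known)
        if unknown:
            raise KeyError(f"unknown taxa: {unknown}")
        sets = self.tip_sets()
        best: Optional[Node] = None
        for n in self.postorder():
            if taxa <= sets[n]:
                best = n
                break
        assert best is not None
        return best

    def is_monophyletic(self, taxa: Iterable[str]) -> bool:
        taxa = set(taxa)
        node = self.mrca(taxa)
        return self.tip_sets()[node] == frozenset(taxa)

    def depths(self) -> Dict[Node, float]:
        """Root-to-node path lengths; missing branch lengths raise."""
        d: Dict[Node, float] = {self.root: 0.0}
        for n in self.preorder():
            if n is self.root:
                continue
            if n.length is None:
                raise ValueError(f"missing branch length above node {n.label!r}")
            d[n] = d[n.parent] + n.length
        return d

    def height(self) -> float:
        d = self.depths()
        return max(d[t] for t in self.leaves())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.depths()
        tip_d = [d[t] for t in self.leaves()]
        h = max(tip_d)
        if h == 0:
            return True
        return (h - min(tip_d)) <= rel_tol * h

    def distance_matrix(self) -> Tuple[List[str], np.ndarray]:
        """Pairwise patristic distances between tips (taxa sorted)."""
        taxa = sorted(self.tip_labels)
        C = self.vcv().matrix
        d = self.depths()
        leaf = {t.label: t for t in self.leaves()}
        depth = np.array([d[leaf[t]] for t in taxa])
        D = depth[:, None] + depth[None, :] - 2 * C
        np.fill_diagonal(D, 0.0)
        return taxa, D

    def vcv(self) -> "PhyloCov":
        return phylo_vcv(self)

    def prune(self, keep: Iterable[str]) -> "PhyloTree":
        return prune(self, keep)

    def topology_id(self) -> str:
        """Canonical string identifying the rooted topology (lengths ignored)."""

        def canon(n: Node) -> str:
            if n.is_leaf:
                return n.label
            return "(" + ",".join(sorted(canon(c) for c in n.children)) + ")"

        return canon(self.root)

    def reroot_at_tip(self, tip_label: str) -> "PhyloTree":
        """Return a copy rooted on the pendant edge of ``tip_label``.

        The new root has the outgroup tip as one child and the re-hung
        remainder of the tree as the other. Branch lengths along the
        re-hung path are preserved (the outgroup pendant edge is split in
        half); supports travel with the child node of each original edge.
        """
        t = self.copy()
        leaf = next((n for n in t.preorder() if n.is_leaf and n.label == tip_label), None)
        if leaf is None:
            raise KeyError(f"unknown taxon: {tip_label}")
        if leaf.parent is t.root and len(t.root.children) == 2:
            return t  # already rooted on that edge
        half = (leaf.length / 2.0) if leaf.length is not None else None
        new_root = Node()
        # Detach leaf from its parent; re-hang the path from old parent to old root.
        old_parent = leaf.parent
        old_parent.children.remove(leaf)
        leaf.parent = None
        leaf.length = half
        new_root.add_child(leaf)

        def rehang(n: Node, came_from_length: Optional[float]) -> Node:
            """Reverse the parent pointer chain starting at n."""
            p = n.parent
            plen, psup = n.length, n.support
            n.length = came_from_length
            if p is not None:
                p.children.remove(n)
                n.children.append(rehang(p, plen))
                n.children[-1].parent = n
                n.support = psup
            else:
                # old root: if it becomes degree-2 passthrough, splice it out later
                n.support = psup
            return n

        hung = rehang(old_parent, half)
        new_root.add_child(hung)
        tree = PhyloTree(new_root, rooted=True)
        _suppress_unifurcations(tree)
        return tree


def _suppress_unifurcations(tree: PhyloTree) -> None:
    changed = True
    while changed:
        changed = False
        for n in list(tree.preorder()):
            if not n.is_leaf and len(n.children) == 1 and n is not tree.root:
                child = n.children[0]
                if child.length is not None or n.length is not None:
                    child.length = (child.length or 0.0) + (n.length or 0.0)
                child.parent = n.parent
                idx = n.parent.children.index(n)
                n.parent.children[idx] = child
                changed = True
            elif n is tree.root and not n.is_leaf and len(n.children) == 1:
                tree.root = n.children[0]
                tree.root.parent = None
                tree.root.length = None
                changed = True


class PhyloCov:
    """Phylogenetic covariance: shared root-to-MRCA path lengths.

    ``matrix[i, j]`` is the depth of MRCA(taxa[i], taxa[j]) from the root,
    so diagonals are root-to-tip distances. Taxa are kept sorted so matrices
    from different trees on the same taxon set are comparable.
    """

    def __init__(self, taxa: Sequence[str], matrix: np.ndarray) -> None:
        self.taxa = list(taxa)
        self.matrix = np.asarray(matrix, dtype=float)
        if self.matrix.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")

    def scaled(self) -> "PhyloCov":
        """Copy rescaled so the largest diagonal entry is 1."""
        m = float(np.max(np.diag(self.matrix)))
        if m <= 0:
            raise ValueError("cannot scale a zero-height tree covariance")
        return PhyloCov(self.taxa, self.matrix / m)

    def reorder(self, taxa: Sequence[str]) -> "PhyloCov":
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCov(list(taxa), self.matrix[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------


def parse_newick(text: str, support_scale: str = "percent") -> PhyloTree:
    """Parse a single Newick tree.

    Internal-node labels that parse as numbers are interpreted as branch
    support, on the 0-100 scale by default (``support_scale="unit"`` for
    0-1-scaled input, rescaled to 0-100 on read).
    """
    if support_scale not in ("percent", "unit"):
        raise ValueError("support_scale must be 'percent' or 'unit'")
    text = text.strip()
    if not text:
        raise NewickParseError("empty Newick string")
    _check_parens(text)
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    scale = 100.0 if support_scale == "unit" else 1.0

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            return Node(label=label, length=dnode.edge.length)
        n = Node(length=dnode.edge.length)
        raw = dnode.label
        if raw is not None:
            try:
                n.support = float(raw) * scale
            except ValueError:
                n.label = raw
        for c in dnode.child_nodes():
            n.add_child(convert(c))
        return n

    return PhyloTree(convert(dt.seed_node), rooted=True)


def _check_parens(text: str) -> None:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(f"unbalanced ')' at character offset {i}")
    if depth != 0:
        raise NewickParseError(f"unclosed '(' — {depth} open at end of string")


def parse_newick_list(text: str, support_scale: str = "percent") -> List[PhyloTree]:
    """Parse a multi-tree Newick string (one tree per ';')."""
    trees = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if chunk:
            trees.append(parse_newick(chunk + ";", support_scale=support_scale))
    return trees


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


def rooted_clades(tree: PhyloTree, with_counts: bool = False):
    """Rooted clades of a tree: one frozen tip-set per internal non-root node."""
    if not tree.rooted:
        raise ValueError("tree is unrooted; root it (e.g. on an outgroup) first")
    clades = tree.clades()
    if with_counts:
        counts: Dict[FrozenSet[str], int] = {}
        for c in clades:
            counts[c] = counts.get(c, 0) + 1
        return counts
    return clades


def is_monophyletic(tree: PhyloTree, taxa: Iterable[str]) -> bool:
    return tree.is_monophyletic(taxa)


def phylo_vcv(tree: PhyloTree) -> PhyloCov:
    """Covariance matrix C with C[i,j] = depth of MRCA(i, j) from the root."""
    depths = tree.depths()
    taxa = sorted(tree.tip_labels)
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    C = np.zeros((n, n))
    sets = tree.tip_sets()
    # For every node, its depth is the MRCA depth for pairs split between
    # different child subtrees (and for leaf self-pairs, the tip depth).
    for node in tree.postorder():
        if node.is_leaf:
            i = index[node.label]
            C[i, i] = depths[node]
            continue
        kids = node.children
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                ia = [index[t] for t in sets[kids[a]]]
                ib = [index[t] for t in sets[kids[b]]]
                C[np.ix_(ia, ib)] = depths[node]
                C[np.ix_(ib, ia)] = depths[node]
    return PhyloCov(taxa, C)


def prune(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Induced tree on ``keep``; suppressed degree-2 nodes sum branch lengths."""
    keep = set(keep)
    present = set(tree.tip_labels)
    if not keep & present:
        raise ValueError("keep set is disjoint from the tree's tips")
    t = tree.copy()

    def rec(n: Node) -> Optional[Node]:
        if n.is_leaf:
            return n if n.label in keep else None
        new_children = [c for c in (rec(c) for c in n.children) if c is not None]
        if not new_children:
            return None
        if len(new_children) == 1:
            child = new_children[0]
            if n.length is not None or child.length is not None:
                child.length = (child.length or 0.0) + (n.length or 0.0)
            # support of the suppressed node is dropped; the surviving
            # child keeps its own support
            return child
        n.children = new_children
        for c in new_children:
            c.parent = n
        return n

    new_root = rec(t.root)
    assert new_root is not None
    new_root.parent = None
    if not new_root.is_leaf:
        new_root.length = None
    return PhyloTree(new_root, rooted=tree.rooted)
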