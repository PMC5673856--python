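"""Rooted, support-annotated phylogenies and the tree-metric primitives.

Trees are read from newick strings in which branch lengths follow ``:`` and
numeric internal-node labels are interpreted as nodal support (bootstrap
percentages or posterior probabilities; which scale applies is a per-tree
attribute set by the caller, never auto-detected).  Trees are used exactly as
rooted; no re-rooting is ever performed.  Polytomies and zero-length branches
are allowed, negative branch lengths are rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NewickError",
    "TreeNode",
    "RootedTree",
    "SupportCategory",
    "parse_newick",
    "write_newick",
    "patristic_matrix",
    "mrca",
    "clade_tips",
    "is_monophyletic",
    "support_category",
]


class NewickError(ValueError):
    """Malformed newick input or invalid tree structure."""


@dataclass(eq=False)
class TreeNode:
    """One node of a rooted tree; ``length`` is the edge to the parent."""

    label: Optional[str] = None
    length: float = 0.0
    support: Optional[float] = None
    parent: Optional["TreeNode"] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def ancestors(self) -> Iterator["TreeNode"]:
        """Yield parent, grandparent, ... up to and including the root."""
        node = self.parent
        while node is not None:
            yield node
            node = node.parent

    def depth(self) -> float:
        """Sum of branch lengths from the root down to this node."""
        d = 0.0
        node = self
        while node.parent is not None:
            d += node.length
            node = node.parent
        return d


class RootedTree:
    """A rooted, branch-length-weighted tree with optional nodal support.

    Parameters
    ----------
    root:
        Root node of an already-linked node structure.
    support_kind:
        ``"bootstrap"`` or ``"posterior"``; informational, set by the caller.
    """

    def __init__(self, root: TreeNode, support_kind: Optional[str] = None):
        if root.parent is not None:
            raise NewickError("root node must not have a parent")
        self.root = root
        self.support_kind = support_kind
        self._index_tips()

    def _index_tips(self) -> None:
        tips = [n for n in self.postorder() if n.is_leaf]
        labels = [t.label for t in tips]
        if any(not lab for lab in labels):
            raise NewickError("every tip must carry a non-empty label")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise NewickError(f"duplicate tip labels: {sorted(dupes)}")
        self._tips = tips
        self._tip_index = {t.label: t for t in tips}

    @property
    def tips(self) -> list[TreeNode]:
        return list(self._tips)

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self._tips]

    def tip(self, label: str) -> TreeNode:
        try:
            return self._tip_index[label]
        except KeyError:
            raise KeyError(f"unknown tip label: {label!r}") from None

    def __len__(self) -> int:
        return len(self._tips)

    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


class SupportCategory(str, Enum):
    STRONG = "strong"
    MODERATE = "moderate"
    NEGLIGIBLE = "negligible"
    SIGNIFICANT = "significant"


_TOKEN = re.compile(r"\s*([(),;:]|[^\s(),;:]+)")


def parse_newick(
    text: str,
    support_kind: Optional[str] = None,
    default_branch_length: Optional[float] = None,
) -> RootedTree:
    """Parse a newick string into a :class:`RootedTree`.

    Numeric internal-node labels become support values.  Branch lengths are
    mandatory on non-root nodes unless ``default_branch_length`` is given
    (lenient mode; ``0.0`` is the documented choice).  Negative branch
    lengths, duplicate tip labels and unbalanced parentheses raise
    :class:`NewickError` naming the offending token.
    """
    tokens = _TOKEN.findall(text)
    if not tokens:
        raise NewickError("empty newick string")
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise NewickError("unbalanced parentheses: unexpected end of input")
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_clade() -> TreeNode:
        node = TreeNode()
        if peek() == "(":
            take()
            node.add_child(parse_clade())
            while peek() == ",":
                take()
                node.add_child(parse_clade())
            if peek() != ")":
                raise NewickError(
                    f"unbalanced parentheses near token {peek()!r}"
                )
            take()
            if peek() not in ("(", ")", ",", ":", ";", None):
                label = take()
                try:
                    node.support = float(label)
                except ValueError:
                    node.label = label
        else:
            if peek() in (")", ",", ":", ";", None):
                raise NewickError(f"expected a tip label, got {peek()!r}")
            node.label = take()
        if peek() == ":":
            take()
            tok = take()
            try:
                node.length = float(tok)
            except ValueError:
                raise NewickError(f"invalid branch length token {tok!r}")
            if node.length < 0:
                raise NewickError(f"negative branch length: {tok}")
        else:
            node.length = 0.0
            node._had_length = False  # type: ignore[attr-defined]
        return node

    root = parse_clade()
    if peek() != ";":
        raise NewickError(f"expected ';' at end, got {peek()!r}")
    take()
    if peek() is not None:
        raise NewickError(f"trailing content after ';': {peek()!r}")

    # missing-length policy: the root edge may legitimately lack a length
    tree = RootedTree(root, support_kind=support_kind)
    for node in tree.preorder():
        if node.is_root:
            continue
        if getattr(node, "_had_length", True) is False:
            if default_branch_length is None:
                name = node.label or "(internal node)"
                raise NewickError(
                    f"missing branch length on {name}; pass "
                    "default_branch_length=0.0 to accept"
                )
            node.length = default_branch_length
    return tree


def _fmt(x: float) -> str:
    return repr(float(x))


def write_newick(tree: RootedTree) -> str:
    """Serialize; supports become internal-node labels, round-trip stable."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            body = node.label or ""
        else:
            inner = ",".join(render(c) for c in node.children)
            label = ""
            if node.support is not None:
                label = _fmt(node.support)
            elif node.label:
                label = node.label
            body = f"({inner}){label}"
        if node.is_root:
            return body
        return f"{body}:{_fmt(node.length)}"

    return render(tree.root) + ";"


def patristic_matrix(tree: RootedTree) -> pd.DataFrame:
    """All tip-pair path-length distances, as a symmetric labelled matrix.

    Computed by a single post-order sweep combining, at every internal node,
    the tip lists of its child subtrees; O(n^2) overall.
    """
    labels = tree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    dmat = np.zeros((n, n))
    below: dict[int, list[tuple[int, float]]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = [(index[node.label], 0.0)]
            continue
        merged: list[tuple[int, float]] = []
        for child in node.children:
            clist = [(i, d + child.length) for i, d in below.pop(id(child))]
            for i, di in clist:
                for j, dj in merged:
                    dmat[i, j] = dmat[j, i] = di + dj
            merged.extend(clist)
        below[id(node)] = merged
    return pd.DataFrame(dmat, index=labels, columns=labels)


def mrca(tree: RootedTree, tips: Sequence[str]) -> TreeNode:
    """Most recent common ancestor of a set of tip labels.

    ``mrca([t])`` is the tip itself.
    """
    labels = list(tips)
    if not labels:
        raise ValueError("mrca requires at least one tip label")
    nodes = [tree.tip(lab) for lab in labels]
    common = nodes[0]
    path = {id(common)}
    path.update(id(a) for a in common.ancestors())
    for node in nodes[1:]:
        walker: Optional[TreeNode] = node
        while walker is not None and id(walker) not in path:
            walker = walker.parent
        if walker is None:  # pragma: no cover - single root guarantees a hit
            raise ValueError("tips do not share a common ancestor")
        common = walker
        path = {id(common)}
        path.update(id(a) for a in common.ancestors())
    return common


def clade_tips(node: TreeNode) -> set[str]:
    """Labels of all tips at or below ``node``."""
    out: set[str] = set()
    stack = [node]
    while stack:
        cur = stack.pop()
        if cur.is_leaf:
            out.add(cur.label)
        else:
            stack.extend(cur.children)
    return out


def is_monophyletic(
    tree: RootedTree, tips: Sequence[str]
) -> tuple[bool, frozenset[str]]:
    """Whether the tips form a complete clade.

    Returns ``(flag, intruders)`` where intruders are the extra tips found
    under the group's MRCA.  Singleton groups are monophyletic by definition.
    """
    group = set(tips)
    if not group:
        raise ValueError("empty tip set")
    node = mrca(tree, sorted(group))
    intruders = clade_tips(node) - group
    return (not intruders, frozenset(intruders))


def support_category(value: float, kind: str) -> SupportCategory:
    """Categorize a nodal support value.

    Bootstrap (percent scale): >=75 strong, >50 and <75 moderate,
    <=50 negligible.  Posterior: >=0.95 significant, else negligible.
    """
    if kind == "bootstrap":
        if not 0 <= value <= 100:
            raise ValueError(f"bootstrap support out of [0, 100]: {value}")
        if value >= 75:
            return SupportCategory.STRONG
        if value > 50:
            return SupportCategory.MODERATE
        return SupportCategory.NEGLIGIBLE
    if kind == "posterior":
        if not 0 <= value <= 1:
            raise ValueError(f"posterior probability out of [0, 1]: {value}")
        if value >= 0.95:
            return SupportCategory.SIGNIFICANT
        return SupportCategory.NEGLIGIBLE
    raise ValueError(f"unknown support kind: {kind!r}")
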