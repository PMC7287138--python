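"""Lightweight rooted phylogeny container shared by the whole pipeline.

Newick parsing and serialization are delegated to dendropy; the in-memory
representation is a plain node/pointer tree carrying, as needed, branch
lengths (expected substitutions/site), branch class labels (``typeI`` /
``typeII``), node ages (My) and per-branch rates.
"""

from __future__ import annotations

import io
from typing import Callable, Iterator, Optional

import dendropy

__all__ = ["Node", "Tree", "TreeError"]


class TreeError(ValueError):
    pass


class Node:
    __slots__ = (
        "name", "length", "parent", "children", "klass", "age", "rate",
        "index", "ti", "tv",
    )

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = float(length)  # substitutions/site on the branch above
        self.parent: Optional["Node"] = None
        self.children: list["Node"] = []
        self.klass: Optional[str] = None  # branch class label
        self.age: Optional[float] = None  # node age, My
        self.rate: Optional[float] = None  # substitutions/site/My on branch above
        self.index: int = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else "node"
        return f"<{kind} {self.name!r} t={self.length:.4g}>"


class Tree:
    """A rooted tree; every non-root node owns the branch above it."""

    def __init__(self, root: Node):
        self.root = root
        self.reindex()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        return cls._from_dendropy(dt)

    @classmethod
    def read(cls, path: str) -> "Tree":
        dt = dendropy.Tree.get(path=path, schema="newick")
        return cls._from_dendropy(dt)

    @classmethod
    def _from_dendropy(cls, dt: dendropy.Tree) -> "Tree":
        def build(dnode) -> Node:
            name = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(name=name, length=dnode.edge.length or 0.0)
            for child in dnode.child_nodes():
                node.add_child(build(child))
            return node

        return cls(build(dt.seed_node))

    # -- traversal ----------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def branches(self) -> list[Node]:
        """All nodes except the root; each identifies the branch above it."""
        return [n for n in self.postorder() if not n.is_root]

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        return [
            n
            for n in self.postorder()
            if not n.is_leaf and (include_root or not n.is_root)
        ]

    def reindex(self) -> None:
        for i, node in enumerate(self.postorder()):
            node.index = i

    # -- identification ----------------------------------------------

    def clade_key(self, node: Node) -> frozenset:
        """Branch identity as the set of descendant tip names (topology-stable)."""
        return frozenset(n.name for n in _subtree_leaves(node))

    def clade_map(self) -> dict[frozenset, Node]:
        keys: dict[int, frozenset] = {}
        out: dict[frozenset, Node] = {}
        for node in self.postorder():
            if node.is_leaf:
                key = frozenset([node.name])
            else:
                key = frozenset().union(*(keys[id(c)] for c in node.children))
            keys[id(node)] = key
            out[key] = node
        return out

    def total_length(self) -> float:
        return sum(n.length for n in self.branches())

    # -- editing ------------------------------------------------------

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(name=node.name, length=node.length)
            new.klass, new.age, new.rate = node.klass, node.age, node.rate
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Tree(clone(self.root))

    def set_ages_from_lengths(self) -> None:
        """Interpret branch lengths as durations; tips at age 0 (clock trees)."""
        depth: dict[int, float] = {id(self.root): 0.0}
        for node in self.preorder():
            if not node.is_root:
                depth[id(node)] = depth[id(node.parent)] + node.length
        height = max(depth[id(leaf)] for leaf in self.leaves())
        for node in self.postorder():
            node.age = height - depth[id(node)]

    def set_lengths_from_ages(self) -> None:
        for node in self.branches():
            node.length = node.parent.age - node.age

    def rerooted(self, tip_name: str, fraction: float = 0.5) -> "Tree":
        """Reroot on the branch above the named tip (or internal node).

        The branch is split ``fraction``/(1-``fraction``); unifurcations left
        behind by the old root are suppressed.  For reversible models the
        likelihood is invariant under this operation.
        """
        work = self.copy()
        target = next(
            (n for n in work.postorder() if n.name == tip_name and not n.is_root),
            None,
        )
        if target is None:
            raise TreeError(f"no non-root node named {tip_name!r}")
        old_parent = target.parent
        L = target.length
        old_parent.children.remove(target)
        target.parent = None
        new_root = Node()
        new_root.add_child(target)
        target.length = fraction * L
        prev, prev_len = new_root, (1.0 - fraction) * L
        cur = old_parent
        while cur is not None:
            parent = cur.parent
            cur_len = cur.length
            if parent is not None:
                parent.children.remove(cur)
            cur.parent = None
            prev.add_child(cur)
            cur.length = prev_len
            prev, prev_len, cur = cur, cur_len, parent
        # suppress the unifurcation left by the old root
        for node in list(Tree(new_root).postorder()):
            if not node.is_root and len(node.children) == 1:
                child = node.children[0]
                child.length += node.length
                node.parent.children[node.parent.children.index(node)] = child
                child.parent = node.parent
        return Tree(new_root)

    # -- output -------------------------------------------------------

    def to_newick(
        self,
        lengths: bool = True,
        length_of: Optional[Callable[[Node], float]] = None,
        ages: bool = False,
    ) -> str:
        length_of = length_of or (lambda n: n.length)
        buf = io.StringIO()

        def write(node: Node) -> None:
            if node.children:
                buf.write("(")
                for i, child in enumerate(node.children):
                    if i:
                        buf.write(",")
                    write(child)
                buf.write(")")
            if node.is_leaf or node.name:
                buf.write(_quote(node.name))
            if ages and node.age is not None:
                buf.write(f"[&age={node.age:.6g}]")
            if lengths and not node.is_root:
                buf.write(f":{length_of(node):.10g}")

        write(self.root)
        buf.write(";")
        return buf.getvalue()

    def write(self, path: str, **kwargs) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kwargs) + "\n")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree {len(self.leaves())} tips>"


def _subtree_leaves(node: Node) -> Iterator[Node]:
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        else:
            stack.extend(n.children)


def _quote(name: Optional[str]) -> str:
    if name is None:
        return ""
    if any(c in name for c in " ()[]:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name
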