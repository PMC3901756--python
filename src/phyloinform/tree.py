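"""Rooted time trees: Newick I/O and path-length geometry.

Branch lengths are interpreted throughout the package as absolute time
(millions of years, Ma), so a tree whose root-to-tip depths all agree is a
chronogram and its depth is the root age T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhyloTree",
    "NewickParseError",
    "parse_newick",
    "patristic_distance",
    "root_age",
    "check_ultrametric",
]

#: relative tolerance used by default when testing ultrametricity
ULTRAMETRIC_RTOL = 1e-6


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be interpreted as a rooted tree."""


def _check_balanced(text: str) -> None:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced parentheses: unmatched ')' at offset {i}"
                )
    if depth != 0:
        raise NewickParseError(
            f"unbalanced parentheses: {depth} '(' left open at offset {len(text)}"
        )


@dataclass
class PhyloTree:
    """A rooted tree stored as flat parent/child arrays in preorder.

    Node 0 is the root. ``labels[i]`` is the tip label for leaf nodes and
    ``None`` for internal nodes. ``blen[i]`` is the length of the branch
    above node *i* (0 for the root).
    """

    parent: np.ndarray  # int, -1 for root
    blen: np.ndarray  # float, Ma
    labels: list  # str | None per node
    children: list = field(repr=False)  # list[list[int]]
    root_blen: float = 0.0  # only meaningful for a single-node tree

    def __post_init__(self):
        if np.any(self.blen < 0):
            raise ValueError("branch lengths must be non-negative")
        tips = [l for l in self.labels if l is not None]
        if len(set(tips)) != len(tips):
            dup = sorted({t for t in tips if tips.count(t) > 1})
            raise NewickParseError(f"duplicate tip labels: {dup}")
        self._tip_index = {
            lab: i for i, lab in enumerate(self.labels) if lab is not None
        }

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree) -> "PhyloTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        blen = np.zeros(len(nodes))
        labels: list = [None] * len(nodes)
        children: list = [[] for _ in nodes]
        root_blen = 0.0
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                if nd.edge.length is None:
                    raise NewickParseError(
                        f"missing branch length above node {i}"
                    )
                blen[i] = float(nd.edge.length)
            elif nd.edge.length is not None:
                root_blen = float(nd.edge.length)
            if nd.is_leaf():
                if nd.taxon is not None:
                    labels[i] = nd.taxon.label
                elif nd.label is not None:
                    labels[i] = nd.label
                else:
                    raise NewickParseError(f"unlabeled tip (node {i})")
        return cls(parent, blen, labels, children, root_blen)

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        import dendropy

        _check_balanced(text)
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"newick parse failed: {exc}") from exc
        tree = cls.from_dendropy(dtree)
        if len(tree.children[0]) > 2:
            warnings.warn(
                "root is a multifurcation (unrooted-style Newick); "
                "treating it as the root",
                stacklevel=2,
            )
        return tree

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    # -- basic queries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def tip_ids(self) -> list:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tip_ids]

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    def postorder(self) -> list:
        order: list = []
        stack = [0]
        while stack:
            nd = stack.pop()
            order.append(nd)
            stack.extend(self.children[nd])
        order.reverse()
        return order

    def _node_of(self, label: str) -> int:
        try:
            return self._tip_index[label]
        except KeyError:
            raise KeyError(f"unknown tip label: {label!r}") from None

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node (preorder fill)."""
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            d[i] = d[self.parent[i]] + self.blen[i]
        if self.n_nodes == 1:
            d[0] = self.root_blen
        return d

    @property
    def root_age(self) -> float:
        d = self.depths()
        return float(max(d[i] for i in self.tip_ids))

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = self.depths()
        tip_d = np.array([d[i] for i in self.tip_ids])
        T = tip_d.max()
        if T == 0:
            return True
        return bool(tip_d.max() - tip_d.min() <= rtol * T)

    # -- distances ---------------------------------------------------------

    def _ancestor_path(self, node: int) -> dict:
        """Map ancestor node id -> cumulative distance from *node*."""
        path = {node: 0.0}
        dist = 0.0
        while self.parent[node] != -1:
            dist += self.blen[node]
            node = self.parent[node]
            path[node] = dist
        return path

    def patristic_distance(self, a: str, b: str) -> float:
        na, nb = self._node_of(a), self._node_of(b)
        if na == nb:
            return 0.0
        pa = self._ancestor_path(na)
        node, dist = nb, 0.0
        while True:
            if node in pa:
                return pa[node] + dist
            dist += self.blen[node]
            node = self.parent[node]

    def tip_distance_matrix(self):
        """(labels, symmetric ndarray) of pairwise patristic distances."""
        tips = self.tip_ids
        labels = [self.labels[i] for i in tips]
        paths = [self._ancestor_path(i) for i in tips]
        n = len(tips)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                pa = paths[i]
                node, dist = tips[j], 0.0
                while node not in pa:
                    dist += self.blen[node]
                    node = self.parent[node]
                mat[i, j] = mat[j, i] = pa[node] + dist
        return labels, mat

    def mrca_depth(self, a: str, b: str) -> float:
        """Root-to-MRCA path length for two tips."""
        pa = self._ancestor_path(self._node_of(a))
        node = self._node_of(b)
        while node not in pa:
            node = self.parent[node]
        d = self.depths()
        return float(d[node])

    # -- transforms and output ---------------------------------------------

    def scaled(self, factor: float) -> "PhyloTree":
        """Return a copy with every branch length multiplied by *factor*."""
        return PhyloTree(
            self.parent.copy(),
            self.blen * factor,
            list(self.labels),
            [list(c) for c in self.children],
            self.root_blen * factor,
        )

    def to_newick(self) -> str:
        def fmt(x: float) -> str:
            return format(x, ".17g")

        def render(node: int) -> str:
            if not self.children[node]:
                lab = self.labels[node]
                quoted = f"'{lab}'" if any(c in lab for c in "(),:;[] ") else lab
                if node == 0:
                    bl = f":{fmt(self.root_blen)}" if self.root_blen else ""
                    return quoted + bl
                return f"{quoted}:{fmt(self.blen[node])}"
            inner = ",".join(render(c) for c in self.children[node])
            if node == 0:
                return f"({inner})"
            return f"({inner}):{fmt(self.blen[node])}"

        return render(0) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


# -- functional wrappers (module-level API) ---------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string with branch lengths into a :class:`PhyloTree`."""
    return PhyloTree.from_newick(text)


def patristic_distance(tree: PhyloTree, a: str, b: str) -> float:
    """Sum of branch lengths on the tree path between tips *a* and *b*."""
    return tree.patristic_distance(a, b)


def root_age(tree: PhyloTree) -> float:
    """Maximum root-to-tip path length (the age T of the root, in Ma)."""
    return tree.root_age


def check_ultrametric(tree: PhyloTree, rtol: float = ULTRAMETRIC_RTOL) -> bool:
    """True iff all root-to-tip depths agree within ``rtol * root_age``."""
    return tree.is_ultrametric(rtol)
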