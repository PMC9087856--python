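"""Tree construction and comparison.

Implements Saitou–Nei neighbour joining over a labelled distance matrix,
outgroup rooting, species-aware collapsing of isolate clades, and the
normalized Robinson–Foulds distance RF = |split symmetric difference| / 2(N−3).

Trees are lightweight rooted structures of :class:`Node`; unrooted trees are
represented with a trifurcating root. Newick parsing is delegated to dendropy;
writing is a direct recursive emit.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from kmerphylo.io_formats import ParseError, ValidationError


class Node:
    __slots__ = ("name", "length", "children")

    def __init__(self, name: str | None = None, length: float | None = None,
                 children: list["Node"] | None = None):
        self.name = name
        self.length = length
        self.children = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        return Node(self.name, self.length, [c.copy() for c in self.children])

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, n_children={len(self.children)})"


class PhyloTree:
    """A labelled (un)rooted tree with optional branch lengths.

    A tree whose root has exactly two children is treated as rooted; a
    trifurcating (or higher-degree) root represents an unrooted tree.
    """

    def __init__(self, root: Node):
        self.root = root
        labels = self.leaf_names()
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate leaf labels: {dupes}")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(data=text, schema="newick",
                                      preserve_underscores=True,
                                      suppress_internal_node_taxa=True)
        except Exception as exc:
            raise ParseError(f"invalid Newick: {exc}") from exc

        def convert(dnode) -> Node:
            name = None
            if dnode.taxon is not None:
                name = dnode.taxon.label
            elif dnode.label:
                name = dnode.label
            return Node(name, dnode.edge.length, [convert(c) for c in dnode.child_nodes()])

        return cls(convert(dtree.seed_node))

    def to_newick(self, precision: int | None = None) -> str:
        def fmt_len(length: float | None) -> str:
            if length is None:
                return ""
            if precision is not None:
                return f":{length:.{precision}g}"
            return f":{length!r}"

        def emit(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}{fmt_len(node.length)}"
            inner = ",".join(emit(c) for c in node.children)
            label = node.name if node.name is not None else ""
            return f"({inner}){label}{fmt_len(node.length)}"

        return emit(self.root) + ";"

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy())

    # -- basic queries ------------------------------------------------------

    @property
    def rooted(self) -> bool:
        return len(self.root.children) == 2

    def leaves(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            else:
                stack.extend(reversed(n.children))
        return out

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def postorder(self) -> Iterable[Node]:
        def walk(n: Node):
            for c in n.children:
                yield from walk(c)
            yield n
        return walk(self.root)

    def node_leafsets(self) -> dict[int, frozenset]:
        """id(node) -> frozenset of leaf names below it."""
        sets: dict[int, frozenset] = {}
        for n in self.postorder():
            if n.is_leaf:
                sets[id(n)] = frozenset([n.name])
            else:
                acc: set = set()
                for c in n.children:
                    acc |= sets[id(c)]
                sets[id(n)] = frozenset(acc)
        return sets

    def clade_leafsets(self) -> set[frozenset]:
        """The leafsets of all non-root nodes (rooted-sense clades)."""
        sets = self.node_leafsets()
        return {sets[id(n)] for n in self.postorder() if n is not self.root}

    # -- bipartitions & RF --------------------------------------------------

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits of the unrooted topology.

        Each split is canonicalised as the side *not* containing the
        lexicographically smallest leaf; trivial splits (one leaf against the
        rest) are excluded.
        """
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        n = len(all_leaves)
        splits: set[frozenset] = set()
        sets = self.node_leafsets()
        for node in self.postorder():
            if node is self.root:
                continue
            side = sets[id(node)]
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= n - 2:
                splits.add(side)
        return splits


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

def _check_matrix(labels: Sequence[str], values: np.ndarray) -> None:
    values = np.asarray(values, dtype=float)
    n = len(labels)
    if values.shape != (n, n):
        raise ValidationError(f"matrix shape {values.shape} does not match {n} labels")
    if not np.allclose(values, values.T, atol=0, rtol=0):
        raise ValidationError("distance matrix is not symmetric")
    if np.any(np.diag(values) != 0):
        raise ValidationError("distance matrix diagonal is not zero")


def neighbor_joining(matrix) -> PhyloTree:
    """Saitou–Nei neighbour joining.

    ``matrix`` is any object with ``labels`` and ``values`` attributes (e.g.
    :class:`kmerphylo.d2s_distance.DistanceMatrix`). Returns an unrooted binary tree
    (trifurcating root). On an additive matrix the leaf-to-leaf path lengths
    reproduce the input exactly. Ties in the Q-criterion are broken by joining
    the lexicographically smallest label pair, so results are deterministic
    across platforms. Negative branch lengths are retained.
    """
    labels = list(matrix.labels)
    D = np.array(matrix.values, dtype=float)
    _check_matrix(labels, D)
    n = len(labels)
    if n < 3:
        raise ValidationError("neighbour joining requires at least 3 taxa")

    nodes: list[Node] = [Node(lab) for lab in labels]
    keys: list[str] = list(labels)  # sort key: smallest leaf label in subtree
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        tol = 1e-12 * (1.0 + abs(qmin))
        candidates = np.argwhere(Q <= qmin + tol)
        best = None
        for ai, aj in candidates:
            if ai >= aj:
                continue
            i, j = active[ai], active[aj]
            key = tuple(sorted((keys[i], keys[j])))
            if best is None or key < best[0]:
                best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = float(li), float(lj)
        parent = Node(children=[ni, nj] if keys[i] <= keys[j] else [nj, ni])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(len(D) + 1)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    for idx, ln in zip((a, b, c), (la, lb, lc)):
        nodes[idx].length = float(ln)
    children = sorted((a, b, c), key=lambda idx: keys[idx])
    root = Node(children=[nodes[idx] for idx in children])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def _adjacency(tree: PhyloTree):
    """Undirected adjacency of the unrooted topology.

    A degree-2 root is suppressed (its two incident edges are fused). Returns
    (vertices, neighbours) where neighbours maps id(v) -> list of
    (neighbour_node, edge_length).
    """
    nbrs: dict[int, list] = {}
    obj: dict[int, Node] = {}

    def add_edge(u: Node, v: Node, length):
        nbrs.setdefault(id(u), []).append((v, length))
        nbrs.setdefault(id(v), []).append((u, length))
        obj[id(u)] = u
        obj[id(v)] = v

    def walk(n: Node):
        for c in n.children:
            add_edge(n, c, c.length)
            walk(c)

    root = tree.root
    if len(root.children) == 2:
        a, b = root.children
        fused = None
        if a.length is not None or b.length is not None:
            fused = (a.length or 0.0) + (b.length or 0.0)
        add_edge(a, b, fused)
        for c in root.children:
            walk(c)
    else:
        walk(root)
    return obj, nbrs


def root_with_outgroup(tree: PhyloTree, outgroup_labels: Iterable[str]) -> PhyloTree:
    """Root on the edge separating the outgroup clade from the rest.

    The outgroup must form a clade in the unrooted topology; the root edge
    length is split evenly between the two sides.
    """
    og = frozenset(outgroup_labels)
    all_leaves = frozenset(tree.leaf_names())
    missing = og - all_leaves
    if missing:
        raise ValidationError(f"outgroup labels not in tree: {sorted(missing)}")
    if og == all_leaves:
        raise ValidationError("outgroup cannot contain every leaf")

    work = tree.copy()
    _, nbrs = _adjacency(work)

    # find the directed edge (u -> v) such that leaves on v's side == outgroup
    def side_leaves(v: Node, u: Node) -> frozenset:
        acc = set()
        stack = [(v, u)]
        while stack:
            node, parent = stack.pop()
            if node.is_leaf:
                acc.add(node.name)
            for (w, _l) in nbrs[id(node)]:
                if w is not parent:
                    stack.append((w, node))
        return frozenset(acc)

    target = None
    seen = set()
    # iterate edges once
    edges = []
    for uid, lst in nbrs.items():
        for (v, length) in lst:
            key = tuple(sorted((uid, id(v))))
            if key in seen:
                continue
            seen.add(key)
            edges.append((uid, v, length))
    id2node = {}
    for uid, lst in nbrs.items():
        for (v, _l) in lst:
            id2node[id(v)] = v
    for uid, v, length in edges:
        u = id2node[uid]
        if side_leaves(v, u) == og:
            target = (u, v, length)
            break
        if side_leaves(u, v) == og:
            target = (v, u, length)
            break
    if target is None:
        raise ValidationError(
            f"outgroup {sorted(og)} is not monophyletic in the unrooted topology")

    u, v, length = target  # v's side is the outgroup
    half = None if length is None else length / 2.0

    def rebuild(at: Node, parent: Node) -> Node:
        children = []
        for (w, elen) in nbrs[id(at)]:
            if w is parent:
                continue
            c = rebuild(w, at)
            c.length = elen
            children.append(c)
        if at.is_leaf:
            return Node(at.name, None, [])
        return Node(None, None, children)

    og_side = rebuild(v, u)
    og_side.length = half
    in_side = rebuild(u, v)
    in_side.length = half
    return PhyloTree(Node(children=[og_side, in_side]))


def unroot(tree: PhyloTree) -> PhyloTree:
    """Collapse a degree-2 root into a trifurcation."""
    if len(tree.root.children) != 2:
        return tree.copy()
    work = tree.copy()
    a, b = work.root.children
    if a.is_leaf and b.is_leaf:
        return work  # 2-leaf tree cannot be unrooted further
    keep, fold = (a, b) if not a.is_leaf else (b, a)
    if keep.length is not None or fold.length is not None:
        fold.length = (keep.length or 0.0) + (fold.length or 0.0)
    root = Node(children=list(keep.children) + [fold])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# species collapsing and normalized RF
# ---------------------------------------------------------------------------

def _monophyletic_species(tree: PhyloTree, species_map: Mapping[str, str]) -> set[str]:
    """Species whose full isolate set forms a clade of the unrooted topology."""
    leaves = tree.leaf_names()
    by_species: dict[str, set] = {}
    for leaf in leaves:
        by_species.setdefault(species_map.get(leaf, leaf), set()).add(leaf)
    all_leaves = frozenset(leaves)
    clades = tree.clade_leafsets() | {all_leaves}
    mono = set()
    for sp, members in by_species.items():
        fs = frozenset(members)
        if len(fs) == 1 or fs in clades or (all_leaves - fs) in clades:
            mono.add(sp)
    return mono


def collapse_species(tree: PhyloTree, species_map: Mapping[str, str],
                     only: set[str] | None = None) -> PhyloTree:
    """Collapse each monophyletic same-species isolate clade into one leaf.

    Collapsed leaves are labelled with the species name; single-isolate
    species are simply relabelled. Species whose isolates are non-monophyletic
    (or not listed in ``only``, when given) keep their isolate leaves with
    their original labels. Leaves absent from ``species_map`` map to
    themselves, which makes the operation idempotent.
    """
    mono = _monophyletic_species(tree, species_map)
    allowed = mono if only is None else (mono & set(only))

    by_species: dict[str, frozenset] = {}
    for leaf in tree.leaf_names():
        sp = species_map.get(leaf, leaf)
        by_species[sp] = by_species.get(sp, frozenset()) | frozenset([leaf])

    work = tree.copy()
    # a multi-isolate clade can sit "across" the root of the rooted
    # representation; reroot so every allowed species is a rooted clade
    sets = work.node_leafsets()
    clades = {sets[id(n)] for n in work.postorder()}
    for sp in sorted(allowed):
        members = by_species[sp]
        if len(members) > 1 and members not in clades:
            work = root_with_outgroup(work, members)
            sets = work.node_leafsets()
            clades = {sets[id(n)] for n in work.postorder()}

    sets = work.node_leafsets()

    def transform(node: Node) -> Node:
        leafset = sets[id(node)]
        if len(leafset) >= 1:
            species = {species_map.get(l, l) for l in leafset}
            if len(species) == 1:
                sp = next(iter(species))
                if sp in allowed and leafset == by_species[sp]:
                    return Node(sp, node.length, [])
        if node.is_leaf:
            return Node(node.name, node.length, [])
        return Node(node.name, node.length, [transform(c) for c in node.children])

    return PhyloTree(transform(work.root))


def normalized_rf(tree1: PhyloTree, tree2: PhyloTree,
                  species_map: Mapping[str, str] | None = None) -> float:
    """Robinson–Foulds distance normalised by 2(N−3), in [0, 1].

    With a ``species_map``, isolate clades of each species that is
    monophyletic in *both* trees are collapsed to a single species leaf in
    both before comparison, so the branching order of same-species isolates
    does not contribute. N is the post-collapse leaf count.
    """
    t1, t2 = tree1, tree2
    if species_map is not None:
        joint = (_monophyletic_species(t1, species_map)
                 & _monophyletic_species(t2, species_map))
        t1 = collapse_species(t1, species_map, only=joint)
        t2 = collapse_species(t2, species_map, only=joint)

    s1, s2 = set(t1.leaf_names()), set(t2.leaf_names())
    if s1 != s2:
        raise ValidationError(
            f"leaf sets differ after collapsing: only-in-first={sorted(s1 - s2)}, "
            f"only-in-second={sorted(s2 - s1)}")
    n = len(s1)
    raw = len(t1.bipartitions() ^ t2.bipartitions())
    denom = 2 * (n - 3)
    if denom <= 0:
        return 0.0
    return raw / denom
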