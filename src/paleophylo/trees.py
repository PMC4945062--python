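"""Rooted phylogenetic trees: Newick I/O, bipartitions, consensus, RF distance.

The tree structure is deliberately small: mutable nodes with parent/child
links, optional branch lengths (interpreted as expected changes or Ma
depending on context) and a free-form annotation dict per node.  Newick
parsing is delegated to dendropy; serialization is canonical (taxa sorted
within each node's children by smallest descendant label) so that identical
topologies always print identically.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

import dendropy


class Node:
    __slots__ = ("name", "length", "parent", "children", "annotations")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None):
        self.name = name
        self.length = length
        self.parent: Optional["Node"] = None
        self.children: list["Node"] = []
        self.annotations: dict = {}

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.name or '*'} k={len(self.children)}>"


class PhyloTree:
    """A rooted tree over named leaves (taxa).

    Polytomies are allowed (consensus trees).  Leaf names must be unique.
    """

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ #
    # construction
    # ------------------------------------------------------------------ #
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        return cls._from_dendropy(dt)

    @classmethod
    def read_newick(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @classmethod
    def _from_dendropy(cls, dt: dendropy.Tree) -> "PhyloTree":
        def convert(dnode) -> Node:
            name = dnode.taxon.label if dnode.taxon is not None else dnode.label
            if name is not None:
                name = name.replace(" ", "_")
            node = Node(name=name, length=dnode.edge.length)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(dt.seed_node))

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        tns = taxon_namespace if taxon_namespace is not None else dendropy.TaxonNamespace()
        dt = dendropy.Tree(taxon_namespace=tns)

        def convert(node: Node, dnode):
            if node.is_leaf:
                dnode.taxon = tns.require_taxon(label=node.name)
            dnode.edge.length = node.length
            for child in node.children:
                convert(child, dnode.new_child())

        convert(self.root, dt.seed_node)
        return dt

    # ------------------------------------------------------------------ #
    # traversal & queries
    # ------------------------------------------------------------------ #
    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

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

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def find_leaf(self, name: str) -> Node:
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(f"leaf {name!r} not in tree")

    def mrca(self, names: Iterable[str]) -> Node:
        """Most recent common ancestor of the named leaves."""
        names = set(names)
        missing = names - set(self.leaf_names())
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        node_sets: dict[int, set] = {}
        for node in self.postorder():
            if node.is_leaf:
                s = {node.name} if node.name in names else set()
            else:
                s = set()
                for child in node.children:
                    s |= node_sets.pop(id(child))
            if s == names:
                return node
            node_sets[id(node)] = s
        raise KeyError("mrca not found")  # pragma: no cover

    def clade_node(self, names: Iterable[str]) -> Node:
        """Node whose leaf set is exactly `names`; KeyError if no such clade."""
        names = set(names)
        node = self.mrca(names) if len(names) > 1 else self.find_leaf(next(iter(names)))
        if {l.name for l in subtree_leaves(node)} != names:
            raise KeyError(f"{sorted(names)} is not a clade in this tree")
        return node

    def has_clade(self, names: Iterable[str]) -> bool:
        try:
            self.clade_node(names)
            return True
        except KeyError:
            return False

    # ------------------------------------------------------------------ #
    # copying / editing
    # ------------------------------------------------------------------ #
    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length)
            new.annotations = dict(node.annotations)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root))

    def prune_taxa(self, names: Iterable[str]) -> "PhyloTree":
        """Return a copy with the named leaves removed and degree-2 nodes suppressed."""
        drop = set(names)
        tree = self.copy()

        def prune(node: Node) -> Optional[Node]:
            if node.is_leaf:
                return None if node.name in drop else node
            kept = [c for c in (prune(ch) for ch in node.children) if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                child = kept[0]
                if node.length is not None and child.length is not None:
                    child.length += node.length
                child.parent = node.parent
                return child
            node.children = kept
            for c in kept:
                c.parent = node
            return node

        new_root = prune(tree.root)
        if new_root is None:
            raise ValueError("pruning removed every leaf")
        new_root.parent = None
        return PhyloTree(new_root)

    # ------------------------------------------------------------------ #
    # serialization
    # ------------------------------------------------------------------ #
    def to_newick(self, lengths: bool = True, annotations: Optional[str] = None) -> str:
        def fmt(node: Node) -> tuple[str, str]:
            # returns (sort key, newick string)
            if node.is_leaf:
                key = node.name
                s = node.name
            else:
                parts = sorted(fmt(c) for c in node.children)
                key = parts[0][0]
                s = "(" + ",".join(p[1] for p in parts) + ")"
                if node.name:
                    s += node.name
            if annotations is not None and annotations in node.annotations:
                s += f"[&{annotations}={node.annotations[annotations]:g}]"
            if lengths and node.length is not None:
                s += f":{node.length:g}"
            return key, s

        return fmt(self.root)[1] + ";"

    def write_newick(self, path, **kw) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kw) + "\n")

    def __repr__(self):  # pragma: no cover
        return f"<PhyloTree {len(self.leaves())} leaves>"


def subtree_leaves(node: Node) -> list[Node]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        else:
            stack.extend(n.children)
    return out


# ---------------------------------------------------------------------- #
# bipartitions, RF distance, strict consensus
# ---------------------------------------------------------------------- #
def bipartitions(tree: PhyloTree) -> set[frozenset]:
    """Non-trivial unrooted bipartitions, each encoded as its smaller side
    (ties broken by sorted tuple) over the full leaf set."""
    all_taxa = frozenset(tree.leaf_names())
    out = set()
    sets: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            sets[id(node)] = frozenset([node.name])
        else:
            s = frozenset().union(*(sets.pop(id(c)) for c in node.children))
            sets[id(node)] = s
            if node is tree.root:
                continue
            if 1 < len(s) < len(all_taxa) - 1:
                out.add(_canonical_split(s, all_taxa))
    return out


def _canonical_split(side: frozenset, all_taxa: frozenset) -> frozenset:
    other = all_taxa - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return min(side, other, key=lambda s: tuple(sorted(s)))


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds symmetric difference (count of non-shared bipartitions)."""
    if set(t1.leaf_names()) != set(t2.leaf_names()):
        raise ValueError("trees have different leaf sets")
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)


def strict_consensus(trees: list[PhyloTree]) -> PhyloTree:
    """Strict consensus: exactly the bipartitions present in every input tree.

    The output is rooted at the first tree's root split only in the trivial
    sense that a rooted star is refined by the shared clades; inputs are
    compared as unrooted trees.
    """
    if not trees:
        raise ValueError("no trees given")
    leaf_sets = {frozenset(t.leaf_names()) for t in trees}
    if len(leaf_sets) != 1:
        raise ValueError("trees have mismatched leaf sets")
    taxa = sorted(leaf_sets.pop())
    all_taxa = frozenset(taxa)
    shared = bipartitions(trees[0])
    for t in trees[1:]:
        shared &= bipartitions(t)
        if not shared:
            break
    # Anchor clades on an arbitrary outgroup taxon so nested sets form a tree.
    anchor = taxa[0]
    clades = sorted(
        (split if anchor not in split else all_taxa - split for split in shared),
        key=len,
    )
    root = Node()
    leaf_node = {name: Node(name) for name in taxa}
    # O(n^2) construction: attach smallest-first
    node_of: dict[frozenset, Node] = {}
    for clade in clades:
        cn = Node()
        remaining = set(clade)
        for sub in sorted((c for c in node_of if c <= clade), key=len, reverse=True):
            sn = node_of[sub]
            if sn.parent is None and sub <= remaining:
                cn.add_child(sn)
                remaining -= sub
        for name in sorted(remaining):
            leaf = leaf_node[name]
            if leaf.parent is None:
                cn.add_child(leaf)
        node_of[clade] = cn
    top_remaining = set(taxa)
    for clade in sorted(node_of, key=len, reverse=True):
        sn = node_of[clade]
        if sn.parent is None and clade <= top_remaining:
            root.add_child(sn)
            top_remaining -= clade
    for name in sorted(top_remaining):
        root.add_child(leaf_node[name])
    return PhyloTree(root)


def insert_leaf_on_edge(target: Node, name: str) -> Node:
    """Split the edge above `target`, attach a new leaf; returns the new leaf."""
    parent = target.parent
    mid = Node()
    parent.children[parent.children.index(target)] = mid
    mid.parent = parent
    mid.add_child(target)
    return mid.add_child(Node(name))


def random_topology(taxa: list[str], rng) -> PhyloTree:
    """Random rooted binary topology by sequential random edge attachment."""
    taxa = list(taxa)
    if len(taxa) < 2:
        raise ValueError("need >= 2 taxa")
    rng.shuffle(taxa)
    root = Node()
    root.add_child(Node(taxa[0]))
    root.add_child(Node(taxa[1]))
    tree = PhyloTree(root)
    for name in taxa[2:]:
        edges = [n for n in tree.postorder() if n.parent is not None]
        insert_leaf_on_edge(edges[int(rng.integers(len(edges)))], name)
    return tree


def _clone_node(node: Node) -> Node:
    new = Node(node.name, node.length)
    for c in node.children:
        new.add_child(_clone_node(c))
    return new


def all_rooted_binary_topologies(taxa: list[str]) -> Iterator[PhyloTree]:
    """Enumerate all (2n-3)!! rooted binary topologies (oracle use; n <= 8)."""
    taxa = list(taxa)

    def grow(root: Node, remaining: list[str]) -> Iterator[Node]:
        if not remaining:
            yield root
            return
        name, rest = remaining[0], remaining[1:]
        # insert on every edge
        edges = [n for n in _postorder_nodes(root) if n.parent is not None]
        for i in range(len(edges)):
            clone = _clone_node(root)
            cedges = [n for n in _postorder_nodes(clone) if n.parent is not None]
            insert_leaf_on_edge(cedges[i], name)
            yield from grow(clone, rest)
        # or above the root
        clone = _clone_node(root)
        new_root = Node()
        new_root.add_child(clone)
        new_root.add_child(Node(name))
        yield from grow(new_root, rest)

    if len(taxa) == 1:
        yield PhyloTree(Node(taxa[0]))
        return
    for root in grow(Node(taxa[0]), taxa[1:]):
        yield PhyloTree(root)


def _postorder_nodes(root: Node) -> list[Node]:
    out, stack = [], [root]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out[::-1]


def all_unrooted_topologies(taxa: list[str]) -> Iterator[PhyloTree]:
    """All (2n-5)!! distinct unrooted binary topologies, rooted at taxa[0]'s edge.

    Counts: 4 taxa -> 3, 5 -> 15, 6 -> 105, 7 -> 945, 8 -> 10395.
    """
    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")
    for sub in all_rooted_binary_topologies(taxa[1:]):
        root = Node()
        root.add_child(Node(taxa[0]))
        root.add_child(sub.root)
        yield PhyloTree(root)
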