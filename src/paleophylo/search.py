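"""Heuristic maximum-parsimony tree search.

Searches operate on rooted binary trees scored as unrooted (Fitch length is
root-invariant).  Stepwise random addition and branch swapping (NNI/SPR/TBR)
both use an exact O(1)-per-move scoring trick: for a pruned component with
Fitch root set R and a target edge whose "point set" (states assignable to a
point on that edge in some most-parsimonious reconstruction) is P, the
reconnected tree's length is

    L(core) + L(pruned) + [R and P disjoint]

because a single junction edge can absorb at most one extra step per
character.  Point sets for every edge come from one down-pass plus one
up-pass of Fitch set operations, so a full swap neighborhood costs a handful
of vectorized operations per prune site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .matrix import CharacterMatrix
from .parsimony import fitch_lengths, optimize_character
from .trees import (
    Node,
    PhyloTree,
    bipartitions,
    insert_leaf_on_edge,
    subtree_leaves,
)


@dataclass
class SearchConfig:
    """Heuristic search settings.

    Desk-scale defaults (100 addition replicates, TBR truncated to SPR above
    `tbr_max_taxa` taxa); published cluster-scale settings (1e5 replicates)
    remain expressible.
    """

    replicates: int = 100
    swap: str = "tbr"  # nni | spr | tbr
    seed: int = 0
    keep: int = 50
    collapse_rule: Optional[str] = "min"
    ratchet_iterations: int = 0
    tbr_max_taxa: int = 40

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.swap not in ("nni", "spr", "tbr"):
            raise ValueError(f"unknown swap mode {self.swap!r}")


@dataclass
class SearchResult:
    trees: list[PhyloTree]
    length: int
    replicate_lengths: list[int] = field(default_factory=list)

    def __iter__(self):
        return iter(self.trees)


def tree_key(tree: PhyloTree) -> frozenset:
    """Unrooted-topology identity."""
    return frozenset(bipartitions(tree))


# ---------------------------------------------------------------------- #
# mask machinery
# ---------------------------------------------------------------------- #
def _combine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    inter = a & b
    return np.where(inter == 0, a | b, inter)


def _down_masks(tree: PhyloTree, M: np.ndarray, row_of: dict[str, int]):
    """Fitch down-pass over a binary tree.

    Returns (order, idx, F, length) with F the per-node state-set masks.
    """
    order = list(tree.postorder())
    idx = {id(n): i for i, n in enumerate(order)}
    nchar = M.shape[1]
    F = np.zeros((len(order), nchar), dtype=np.uint64)
    steps = np.zeros(nchar, dtype=np.int64)
    for i, node in enumerate(order):
        if node.is_leaf:
            F[i] = M[row_of[node.name]]
            continue
        acc = None
        for c in node.children:
            fc = F[idx[id(c)]]
            if acc is None:
                acc = fc
                continue
            inter = acc & fc
            empty = inter == 0
            steps += empty
            acc = np.where(empty, acc | fc, inter)
        F[i] = acc
    return order, idx, F, int(steps.sum())


def _point_masks(tree: PhyloTree, order, idx, F: np.ndarray) -> np.ndarray:
    """Per-edge point sets P (indexed by the edge's child node).

    P[i] is the set of states assignable, in some minimum-length labeling,
    to a new point subdividing the edge above node i.  Rows for the root are
    unused (all-ones placeholder).
    """
    U = np.zeros_like(F)
    P = np.full_like(F, np.uint64(~np.uint64(0)))
    for node in tree.preorder():
        if node.parent is None:
            continue
        i = idx[id(node)]
        u = node.parent
        sibs = [c for c in u.children if c is not node]
        if u.parent is None:
            m = F[idx[id(sibs[0])]]
            for s in sibs[1:]:
                m = _combine(m, F[idx[id(s)]])
        else:
            m = U[idx[id(u)]]
            for s in sibs:
                m = _combine(m, F[idx[id(s)]])
        U[i] = m
        P[i] = _combine(F[i], m)
    return P


# ---------------------------------------------------------------------- #
# tree surgery
# ---------------------------------------------------------------------- #
def _clone_with_map(tree: PhyloTree) -> tuple[PhyloTree, list[Node]]:
    """Clone; returns clone plus its postorder node list (aligned with the
    original's postorder)."""
    clone = tree.copy()
    return clone, list(clone.postorder())


def _detach(tree: PhyloTree, node: Node) -> tuple[PhyloTree, PhyloTree]:
    """Remove `node`'s subtree (mutating); returns (core, subtree).

    The suppressed degree-2 parent is spliced out.
    """
    parent = node.parent
    parent.children.remove(node)
    node.parent = None
    sub = PhyloTree(node)
    if len(parent.children) != 1:
        return tree, sub
    only = parent.children[0]
    if parent.parent is None:
        only.parent = None
        only.length = None
        return PhyloTree(only), sub
    gp = parent.parent
    gp.children[gp.children.index(parent)] = only
    only.parent = gp
    return tree, sub


def _attach(core: PhyloTree, target: Node, sub_root: Node) -> PhyloTree:
    """Regraft `sub_root` onto the edge above `target` (mutating core)."""
    parent = target.parent
    mid = Node()
    parent.children[parent.children.index(target)] = mid
    mid.parent = parent
    mid.add_child(target)
    mid.add_child(sub_root)
    return core


def _reroot_at_edge(sub: PhyloTree, target: Node) -> PhyloTree:
    """Reroot a (sub)tree so the root subdivides the edge above `target`."""
    if target.parent is None:
        return sub
    # reverse parent pointers from target's parent up to the old root
    path = []
    n = target.parent
    while n is not None:
        path.append(n)
        n = n.parent
    new_root = Node()
    target.parent.children.remove(target)
    new_root.add_child(target)
    prev = new_root
    for n in path:
        parent = n.parent
        if parent is not None:
            parent.children.remove(n)
        n.parent = None
        prev.add_child(n)
        prev = n
    # suppress any degree-1 internal nodes created on the reversed path
    _suppress_unary(new_root)
    return PhyloTree(new_root)


def _suppress_unary(root: Node) -> None:
    stack = [root]
    while stack:
        n = stack.pop()
        changed = True
        while changed:
            changed = False
            for i, c in enumerate(list(n.children)):
                if not c.is_leaf and len(c.children) == 1:
                    gc = c.children[0]
                    gc.parent = n
                    n.children[i] = gc
                    changed = True
        stack.extend(n.children)


# ---------------------------------------------------------------------- #
# stepwise addition
# ---------------------------------------------------------------------- #
def random_addition_tree(
    matrix: CharacterMatrix,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> PhyloTree:
    """Stepwise addition with a seeded random taxon order; each taxon goes to
    an attachment minimizing Fitch length (ties broken by the RNG)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if matrix.n_taxa < 3:
        raise ValueError("need >= 3 taxa")
    M = matrix.bitmasks()
    row_of = {t: i for i, t in enumerate(matrix.taxa)}
    taxa = list(matrix.taxa)
    perm = rng.permutation(len(taxa))
    taxa = [taxa[i] for i in perm]
    root = Node()
    root.add_child(Node(taxa[0]))
    root.add_child(Node(taxa[1]))
    tree = PhyloTree(root)
    for name in taxa[2:]:
        order, idx, F, _ = _down_masks(tree, M, row_of)
        P = _point_masks(tree, order, idx, F)
        R = M[row_of[name]]
        extra = ((P & R) == 0).sum(axis=1)
        candidates = [i for i, n in enumerate(order) if n.parent is not None]
        costs = extra[candidates]
        best = costs.min()
        pool = [candidates[j] for j in np.nonzero(costs == best)[0]]
        choice = pool[int(rng.integers(len(pool)))]
        insert_leaf_on_edge(order[choice], name)
    return tree


# ---------------------------------------------------------------------- #
# swapping
# ---------------------------------------------------------------------- #
def _iter_moves(
    tree: PhyloTree,
    M: np.ndarray,
    row_of: dict[str, int],
    mode: str,
) -> Iterator[tuple[int, int, int, int]]:
    """Yield (length, prune_index, target_index, sub_edge_index) for every
    swap move; indices refer to the tree's postorder.  sub_edge_index = -1
    keeps the pruned component's original rooting (SPR)."""
    order = list(tree.postorder())
    nchar = M.shape[1]
    n = len(order)
    for pi in range(n - 1):  # skip root
        node = order[pi]
        prune_leaves = {id(l) for l in subtree_leaves(node)}
        n_core_leaves = sum(1 for o in order if o.is_leaf) - len(prune_leaves)
        if n_core_leaves < 2:
            continue
        work, work_order = _clone_with_map(tree)
        core, sub = _detach(work, work_order[pi])
        corder, cidx, CF, c_len = _down_masks(core, M, row_of)
        CP = _point_masks(core, corder, cidx, CF)
        sorder, sidx, SF, s_len = _down_masks(sub, M, row_of) if not sub.root.is_leaf \
            else ([sub.root], {id(sub.root): 0},
                  M[row_of[sub.root.name]][None, :].astype(np.uint64), 0)
        base = c_len + s_len
        core_targets = [i for i, cn in enumerate(corder) if cn.parent is not None]
        # original-rooting reconnection (SPR)
        R = SF[len(sorder) - 1]
        extra = ((CP & R) == 0).sum(axis=1)
        for ti in core_targets:
            yield base + int(extra[ti]), pi, ti, -1
        if mode == "tbr" and not sub.root.is_leaf:
            SP = _point_masks(sub, sorder, sidx, SF)
            for si, sn in enumerate(sorder):
                if sn.parent is None or sn.parent is sub.root:
                    continue  # root-adjacent reroots duplicate the original rooting
                extra = ((CP & SP[si]) == 0).sum(axis=1)
                for ti in core_targets:
                    yield base + int(extra[ti]), pi, ti, si


def _nni_moves(tree: PhyloTree) -> Iterator[PhyloTree]:
    """Materialized NNI neighbors (used when swap='nni')."""
    order = list(tree.postorder())
    for i, node in enumerate(order):
        if node.is_leaf or node.parent is None:
            continue
        parent = node.parent
        sibs = [c for c in parent.children if c is not node]
        for child in node.children:
            for sib in sibs:
                work, worder = _clone_with_map(tree)
                wnode = worder[i]
                wparent = wnode.parent
                wchild = worder[order.index(child)]
                wsib = worder[order.index(sib)]
                wnode.children[wnode.children.index(wchild)] = wsib
                wparent.children[wparent.children.index(wsib)] = wchild
                wchild.parent, wsib.parent = wparent, wnode
                yield work


def _apply_move(tree: PhyloTree, move: tuple[int, int, int, int]) -> PhyloTree:
    _, pi, ti, si = move
    work, worder = _clone_with_map(tree)
    core, sub = _detach(work, worder[pi])
    corder = list(core.postorder())
    if si >= 0:
        sorder = list(sub.postorder())
        sub = _reroot_at_edge(sub, sorder[si])
    _attach(core, corder[ti], sub.root)
    return core


def _tree_length(tree: PhyloTree, M: np.ndarray, row_of: dict[str, int]) -> int:
    rows = [row_of[l.name] for l in tree.leaves()]
    return fitch_lengths(tree, M[rows])


def _swap_to_optimum(
    tree: PhyloTree,
    M: np.ndarray,
    row_of: dict[str, int],
    rng: np.random.Generator,
    mode: str,
) -> tuple[PhyloTree, int]:
    """Steepest-descent branch swapping until no neighbor is shorter."""
    length = _tree_length(tree, M, row_of)
    while True:
        best_len, best_moves = length, []
        if mode == "nni":
            neighbors = []
            for nb in _nni_moves(tree):
                l = _tree_length(nb, M, row_of)
                if l < best_len:
                    best_len, neighbors = l, [nb]
                elif l == best_len and l < length:
                    neighbors.append(nb)
            if best_len >= length:
                return tree, length
            tree = neighbors[int(rng.integers(len(neighbors)))]
            length = best_len
            continue
        for move in _iter_moves(tree, M, row_of, mode):
            if move[0] < best_len:
                best_len, best_moves = move[0], [move]
            elif move[0] == best_len and best_len < length:
                best_moves.append(move)
        if best_len >= length:
            return tree, length
        move = best_moves[int(rng.integers(len(best_moves)))]
        tree = _apply_move(tree, move)
        length = best_len


def heuristic_search(matrix: CharacterMatrix, config: SearchConfig) -> SearchResult:
    """Random-addition + branch-swapping search; returns all distinct shortest
    trees found (after the collapse rule), deterministically for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    M = matrix.bitmasks()
    row_of = {t: i for i, t in enumerate(matrix.taxa)}
    mode = config.swap
    if mode == "tbr" and matrix.n_taxa > config.tbr_max_taxa:
        mode = "spr"
    best_len: Optional[int] = None
    best: dict[frozenset, PhyloTree] = {}
    rep_lengths = []
    for rep in range(config.replicates):
        tree = random_addition_tree(matrix, rng=rng)
        tree, length = _swap_to_optimum(tree, M, row_of, rng, mode)
        for _ in range(config.ratchet_iterations):
            tree2, l2 = _ratchet_cycle(tree, matrix, M, row_of, rng, mode)
            if l2 <= length:
                tree, length = tree2, l2
        rep_lengths.append(length)
        if best_len is None or length < best_len:
            best_len = length
            best = {tree_key(tree): tree}
        elif length == best_len:
            best.setdefault(tree_key(tree), tree)
    # plateau sweep: collect equal-length neighbors of the best trees
    frontier = list(best.values())
    while frontier and len(best) < config.keep:
        tree = frontier.pop()
        for move in _iter_moves(tree, M, row_of, mode if mode != "nni" else "spr"):
            if move[0] != best_len or len(best) >= config.keep:
                continue
            nb = _apply_move(tree, move)
            k = tree_key(nb)
            if k not in best:
                best[k] = nb
                frontier.append(nb)
    trees = [best[k] for k in sorted(best, key=lambda k: sorted(map(sorted, k)))]
    if config.collapse_rule == "min":
        collapsed: dict[frozenset, PhyloTree] = {}
        for t in trees:
            ct = collapse_min_branches(t, matrix)
            collapsed.setdefault(tree_key(ct), ct)
        trees = list(collapsed.values())
    return SearchResult(trees=trees, length=int(best_len), replicate_lengths=rep_lengths)


def _ratchet_cycle(tree, matrix, M, row_of, rng, mode):
    """One parsimony-ratchet perturbation: upweight a random ~25% of characters
    (by column duplication), swap, then swap again under original weights."""
    nchar = M.shape[1]
    chosen = rng.random(nchar) < 0.25
    M2 = np.concatenate([M, M[:, chosen]], axis=1)
    t2, _ = _swap_to_optimum(tree, M2, row_of, rng, mode)
    return _swap_to_optimum(t2, M, row_of, rng, mode)


# ---------------------------------------------------------------------- #
# collapse rule and suboptimal sweep
# ---------------------------------------------------------------------- #
def collapse_min_branches(tree: PhyloTree, matrix: CharacterMatrix) -> PhyloTree:
    """PAUP-style 'min' collapse: drop every internal branch whose minimum
    length over all most-parsimonious reconstructions is zero for every
    character (i.e. no character forces a change there)."""
    from .matrix import classify_characters

    order = list(tree.postorder())
    idx = {id(n): i for i, n in enumerate(order)}
    forced = np.zeros(len(order), dtype=bool)
    root2 = tree.root.children if len(tree.root.children) == 2 else None
    # Only parsimony-informative characters can force a change on an internal
    # branch; characters with partial-uncertainty cells are kept too, since
    # determinate-cell classification does not bound their behavior.
    classes = classify_characters(matrix)
    candidates = [
        j for j in range(matrix.n_characters)
        if classes[j] == "parsimony_informative"
        or any(row[j].kind in ("polymorphic", "uncertain") for row in matrix.cells)
    ]
    for j in candidates:
        down, _, changes, best = optimize_character(tree, matrix, j)
        for ch in changes:
            if ch.flag == "unambiguous":
                forced[ch.child_index] = True
        if root2 is not None:
            # a degree-2 root's two edges form one unrooted edge: forced iff
            # no minimum labeling lets both root children share a state
            a, b = (idx[id(c)] for c in root2)
            if int((down[a] + down[b]).min()) > best:
                forced[a] = forced[b] = True
    if root2 is not None:
        a, b = (idx[id(c)] for c in root2)
        joint = forced[a] or forced[b]
        forced[a] = forced[b] = joint
    out, oorder = _clone_with_map(tree)
    for i, node in enumerate(order):
        onode = oorder[i]
        if node.is_leaf or node.parent is None or forced[i]:
            continue
        parent = onode.parent
        pos = parent.children.index(onode)
        parent.children[pos:pos + 1] = onode.children
        for c in onode.children:
            c.parent = parent
    return out


def sweep_suboptimal(
    matrix: CharacterMatrix,
    start_trees: list[PhyloTree],
    cap: int,
    max_trees: int = 5000,
) -> dict[frozenset, int]:
    """Breadth-first SPR closure over trees within `cap` extra steps of the
    shortest start tree.  Returns {topology key: length} for every tree kept
    (used by Bremer decay analysis)."""
    import heapq

    M = matrix.bitmasks()
    row_of = {t: i for i, t in enumerate(matrix.taxa)}
    best = min(_tree_length(t, M, row_of) for t in start_trees)
    limit = best + cap
    mode = "tbr" if matrix.n_taxa <= 8 else "spr"
    seen: dict[frozenset, int] = {}
    frontier: list = []
    counter = 0
    for t in start_trees:
        k = tree_key(t)
        if k not in seen:
            seen[k] = _tree_length(t, M, row_of)
            heapq.heappush(frontier, (seen[k], counter, t))
            counter += 1
    # shortest-first expansion: trees nearest the optimum are swept before the
    # tree budget runs out
    while frontier and len(seen) < max_trees:
        _, _, tree = heapq.heappop(frontier)
        for move in _iter_moves(tree, M, row_of, mode):
            if move[0] > limit or len(seen) >= max_trees:
                continue
            nb = _apply_move(tree, move)
            k = tree_key(nb)
            if k not in seen:
                seen[k] = move[0]
                heapq.heappush(frontier, (move[0], counter, nb))
                counter += 1
    return seen
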