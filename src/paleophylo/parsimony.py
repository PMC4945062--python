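"""Unordered (Fitch) parsimony: scoring, MPR ancestral sets, synapomorphies,
and ensemble fit indices (CI / RI / HI).

Scoring is vectorized over characters using bitmask state sets, with the
Hartigan generalization at polytomies (exact minimum for unordered characters
on multifurcating trees).  MPR sets use a two-sided dynamic program (0/1-cost
Sankoff down-pass plus an out-of-subtree pass), which is exact on arbitrary
trees and agrees with exhaustive labeling enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .matrix import CharacterMatrix
from .trees import PhyloTree, subtree_leaves

_POPCOUNT = np.array([bin(i).count("1") for i in range(65536)], dtype=np.uint8)


def _popcount(x: np.ndarray) -> np.ndarray:
    x = x.astype(np.uint64)
    out = _POPCOUNT[(x & np.uint64(0xFFFF)).astype(np.intp)].astype(np.int64)
    for shift in (16, 32, 48):
        out += _POPCOUNT[((x >> np.uint64(shift)) & np.uint64(0xFFFF)).astype(np.intp)]
    return out


class TreeIndex:
    """Postorder-indexed view of a tree against a matrix's taxa.

    Rows 0..n_leaves-1 are leaves (in the tree's own leaf order); internal
    nodes follow in postorder.  Reused across many Fitch evaluations.
    """

    def __init__(self, tree: PhyloTree, matrix: CharacterMatrix):
        self.tree = tree
        order = list(tree.postorder())
        self.nodes = order
        self.index = {id(n): i for i, n in enumerate(order)}
        missing = [n.name for n in order if n.is_leaf and n.name not in matrix.taxa]
        if missing:
            raise KeyError(f"leaf without matrix row: {missing[0]}")
        self.leaf_rows = {
            i: matrix.taxon_index(n.name) for i, n in enumerate(order) if n.is_leaf
        }


def leaf_masks(tree: PhyloTree, matrix: CharacterMatrix) -> np.ndarray:
    """Bitmask matrix aligned to the tree's leaf order."""
    names = tree.leaf_names()
    return matrix.bitmasks(taxa_order=names)


def _fitch_pass(tree: PhyloTree, masks: np.ndarray) -> np.ndarray:
    """Per-character minimum step counts (Fitch; Hartigan at polytomies)."""
    nchar = masks.shape[1]
    down: dict[int, np.ndarray] = {}
    steps = np.zeros(nchar, dtype=np.int64)
    leaf_i = 0
    for node in tree.postorder():
        if node.is_leaf:
            down[id(node)] = masks[leaf_i]
            leaf_i += 1
            continue
        children = [down.pop(id(c)) for c in node.children]
        if len(children) == 2:
            a, b = children
            inter = a & b
            empty = inter == 0
            steps += empty
            cur = np.where(empty, a | b, inter)
        else:
            # Hartigan: per state, count children whose set contains it;
            # down-set = states at max count; added steps = #children - max
            k_bits = max(int(masks.max()).bit_length(), 1)
            counts = np.zeros((k_bits, nchar), dtype=np.int16)
            for ch in children:
                for s in range(k_bits):
                    counts[s] += ((ch >> np.uint64(s)) & np.uint64(1)).astype(np.int16)
            cmax = counts.max(axis=0)
            steps += len(children) - cmax
            cur = np.zeros(nchar, dtype=np.uint64)
            for s in range(k_bits):
                cur |= (counts[s] == cmax).astype(np.uint64) << np.uint64(s)
        down[id(node)] = cur
    return steps


def fitch_lengths(
    tree: PhyloTree,
    masks: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> int:
    """Total Fitch length over all characters.

    `masks` is the (n_leaves, n_char) bitmask matrix in the tree's leaf order
    (see `leaf_masks`).  `weights` optionally weights characters (jackknife).
    """
    steps = _fitch_pass(tree, masks)
    if weights is None:
        return int(steps.sum())
    return int((steps * weights).sum())


def fitch_steps_per_character(tree: PhyloTree, matrix: CharacterMatrix) -> np.ndarray:
    return _fitch_pass(tree, leaf_masks(tree, matrix))


@dataclass
class BranchChange:
    """Per-branch optimization outcome for one character."""

    child_index: int  # postorder index of the branch's child node
    flag: str  # none | unambiguous | ambiguous
    from_states: frozenset
    to_states: frozenset


@dataclass
class OptimizationResult:
    """Per-character ancestral optimization on a fixed tree."""

    tree: PhyloTree
    steps: np.ndarray  # per character
    downpass: list[dict[int, frozenset]]  # per character: node index -> state set
    mpr: list[dict[int, frozenset]]  # per character: node index -> MPR set
    changes: list[list[BranchChange]]  # per character

    @property
    def total_length(self) -> int:
        return int(self.steps.sum())


def _column_states(matrix: CharacterMatrix, tree: PhyloTree, char: int) -> list[frozenset]:
    """Observed state sets for one character, in tree leaf order (blank = full)."""
    k = matrix.characters[char].state_count
    full = frozenset(range(k))
    out = []
    for leaf in tree.leaves():
        cell = matrix.cell(leaf.name, char)
        out.append(full if cell.is_blank else cell.states)
    return out


def _sankoff_down(tree: PhyloTree, leaf_sets: list[frozenset], k: int):
    """0/1-cost Sankoff down-pass.

    Returns (order, down) where down[node index] is a length-k int array:
    minimal subtree cost given the node has each state (big for disallowed).
    """
    BIG = 10**6
    order = list(tree.postorder())
    idx = {id(n): i for i, n in enumerate(order)}
    down = np.zeros((len(order), k), dtype=np.int64)
    leaf_i = 0
    for i, node in enumerate(order):
        if node.is_leaf:
            allowed = leaf_sets[leaf_i]
            leaf_i += 1
            down[i] = BIG
            for s in allowed:
                down[i, s] = 0
        else:
            total = np.zeros(k, dtype=np.int64)
            for c in node.children:
                child = down[idx[id(c)]]
                # cost(t,s): child cost with change (+1) or without
                total += np.minimum(child, child.min() + 1)
            down[i] = total
    return order, down


def optimize_character(
    tree: PhyloTree, matrix: CharacterMatrix, char: int
) -> tuple[np.ndarray, dict[int, frozenset], list[BranchChange], int]:
    """Exact MPR analysis of one character.

    Returns (down table, MPR sets keyed by postorder node index, branch change
    records, minimal steps).
    """
    k = matrix.characters[char].state_count
    leaf_sets = _column_states(matrix, tree, char)
    order, down = _sankoff_down(tree, leaf_sets, k)
    idx = {id(n): i for i, n in enumerate(order)}
    n = len(order)
    # up[i][s]: minimal cost of everything outside subtree(i), including the
    # edge into i, given node i has state s.  up[root] = 0.
    up = np.zeros((n, k), dtype=np.int64)
    for node in tree.preorder():
        i = idx[id(node)]
        if node.parent is None:
            up[i] = 0
            continue
        u = idx[id(node.parent)]
        # partial[t] = up[u][t] + sum over siblings of min_r (down[sib][r] + [r != t])
        partial = up[u].copy()
        for sib in node.parent.children:
            if sib is node:
                continue
            si = idx[id(sib)]
            partial += np.minimum(down[si], down[si].min() + 1)
        # up[i][s] = min_t (partial[t] + [t != s]); t == s term is partial[s]
        up[i] = np.minimum(partial, partial.min() + 1)
    total = down + up
    best = int(total[idx[id(tree.root)]].min())
    mpr = {
        i: frozenset(int(s) for s in np.nonzero(total[i] == total[i].min())[0])
        for i in range(n)
    }
    # leaves report their observed sets (full when blank), the standard
    # terminal-set convention, rather than achievable-in-minimum subsets
    leaf_i = 0
    for i, nd in enumerate(order):
        if nd.is_leaf:
            mpr[i] = frozenset(leaf_sets[leaf_i])
            leaf_i += 1
    changes: list[BranchChange] = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        i, u = idx[id(node)], idx[id(node.parent)]
        partial = up[u].copy()
        for sib in node.parent.children:
            if sib is node:
                continue
            si = idx[id(sib)]
            partial += np.minimum(down[si], down[si].min() + 1)
        # can the edge carry zero changes in some MPR?  min_s down[i][s] + partial[s]
        same_cost = int((down[i] + partial).min())
        # can it carry a change?  min_{s != t} down[i][s] + partial[t] + 1
        diff_cost = _min_diff_cost(down[i], partial) + 1
        can_same = same_cost == best
        can_diff = diff_cost == best
        if not can_same and can_diff:
            flag = "unambiguous"
        elif can_same and can_diff:
            flag = "ambiguous"
        else:
            flag = "none"
        changes.append(BranchChange(i, flag, mpr[u], mpr[i]))
    return down, mpr, changes, best


def _min_diff_cost(a: np.ndarray, b: np.ndarray) -> int:
    """min over s != t of a[s] + b[t]; large for k = 1 (no change possible)."""
    if len(a) < 2:
        return 10**6
    best = None
    for s in np.argsort(a)[:2]:
        for t in np.argsort(b)[:2]:
            if s != t:
                v = int(a[s] + b[t])
                best = v if best is None or v < best else best
    return best


def fitch_score(tree: PhyloTree, matrix: CharacterMatrix) -> OptimizationResult:
    """Full per-character optimization: steps, down-pass sets, MPR sets, changes."""
    steps = []
    downs, mprs, all_changes = [], [], []
    for j in range(matrix.n_characters):
        down, mpr, changes, best = optimize_character(tree, matrix, j)
        steps.append(best)
        order = list(tree.postorder())
        down_sets = {
            i: frozenset(int(s) for s in np.nonzero(down[i] == down[i].min())[0])
            for i in range(len(order))
        }
        downs.append(down_sets)
        mprs.append(mpr)
        all_changes.append(changes)
    return OptimizationResult(
        tree=tree,
        steps=np.array(steps, dtype=np.int64),
        downpass=downs,
        mpr=mprs,
        changes=all_changes,
    )


def mpr_sets(tree: PhyloTree, matrix: CharacterMatrix, char: int) -> dict[int, frozenset]:
    """MPR state set per postorder node index for one character."""
    _, mpr, _, _ = optimize_character(tree, matrix, char)
    return mpr


@dataclass
class SynapomorphyRecord:
    clade: frozenset  # leaf names below the branch's child
    character: int
    from_states: frozenset
    to_states: frozenset
    unambiguous: bool


def find_synapomorphies(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    clade: Sequence[str],
    characters: Optional[Sequence[int]] = None,
) -> list[SynapomorphyRecord]:
    """Character changes on the branch subtending `clade`.

    Unambiguous records have disjoint parent/child MPR sets (every minimum
    labeling places a change there); ambiguous records overlap but change in
    at least one MPR.
    """
    node = tree.clade_node(set(clade))
    if node.parent is None:
        raise KeyError("clade is the whole tree; no subtending branch")
    order = list(tree.postorder())
    node_i = order.index(node)
    leafset = frozenset(l.name for l in subtree_leaves(node))
    records = []
    for j in characters if characters is not None else range(matrix.n_characters):
        _, mpr, changes, _ = optimize_character(tree, matrix, j)
        for ch in changes:
            if ch.child_index != node_i or ch.flag == "none":
                continue
            records.append(
                SynapomorphyRecord(
                    clade=leafset,
                    character=j,
                    from_states=ch.from_states,
                    to_states=ch.to_states,
                    unambiguous=ch.flag == "unambiguous",
                )
            )
    return records


def all_branch_changes(tree: PhyloTree, matrix: CharacterMatrix):
    """One row per (branch, character) change across the whole tree: the
    synapomorphy table mirrored by per-clade reports."""
    import pandas as pd

    order = list(tree.postorder())
    clade_of = {
        i: "|".join(sorted(l.name for l in subtree_leaves(n)))
        for i, n in enumerate(order)
    }
    rows = []
    for j in range(matrix.n_characters):
        _, _, changes, _ = optimize_character(tree, matrix, j)
        for ch in changes:
            if ch.flag == "none":
                continue
            rows.append({
                "clade": clade_of[ch.child_index],
                "character": matrix.characters[j].label,
                "from": "/".join(map(str, sorted(ch.from_states))),
                "to": "/".join(map(str, sorted(ch.to_states))),
                "unambiguous": ch.flag == "unambiguous",
            })
    return pd.DataFrame(rows, columns=["clade", "character", "from", "to", "unambiguous"])


@dataclass
class TreeStats:
    length: int
    min_length: int
    max_length: int

    @property
    def ci(self) -> float:
        return self.min_length / self.length if self.length else 1.0

    @property
    def hi(self) -> float:
        return 1.0 - self.ci

    @property
    def ri(self) -> float:
        g, m, l = self.max_length, self.min_length, self.length
        if g == m:
            return float("nan")
        return (g - l) / (g - m)


def character_bounds(matrix: CharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-character (min steps over trees, max steps over trees).

    Determinate cells only: min = (#observed states - 1, floored at 0);
    max = N_determinate - largest state count (steps on the worst topology).
    """
    mins, maxs = [], []
    for j in range(matrix.n_characters):
        counts: dict[int, int] = {}
        for row in matrix.cells:
            cell = row[j]
            if cell.kind == "determinate":
                (s,) = cell.states
                counts[s] = counts.get(s, 0) + 1
        if not counts:
            mins.append(0)
            maxs.append(0)
        else:
            mins.append(len(counts) - 1)
            maxs.append(sum(counts.values()) - max(counts.values()))
    return np.array(mins, dtype=np.int64), np.array(maxs, dtype=np.int64)


def tree_stats(tree: PhyloTree, matrix: CharacterMatrix) -> TreeStats:
    steps = fitch_steps_per_character(tree, matrix)
    mins, maxs = character_bounds(matrix)
    return TreeStats(
        length=int(steps.sum()),
        min_length=int(mins.sum()),
        max_length=int(maxs.sum()),
    )


# ---------------------------------------------------------------------- #
# exhaustive oracles (used by the test suite; kept here so they are shared
# and clearly separated from the production two-pass implementation)
# ---------------------------------------------------------------------- #
def brute_force_character(
    tree: PhyloTree, leaf_sets: list[frozenset], k: int
) -> tuple[int, dict[int, frozenset]]:
    """Minimum steps and MPR sets by enumerating every internal labeling.

    Exponential; use only for <= 7 leaves / small k.
    """
    import itertools

    order = list(tree.postorder())
    internal = [i for i, n in enumerate(order) if not n.is_leaf]
    leaves = [i for i, n in enumerate(order) if n.is_leaf]
    parent_of = {}
    idx = {id(n): i for i, n in enumerate(order)}
    for n in order:
        for c in n.children:
            parent_of[idx[id(c)]] = idx[id(n)]
    best = None
    best_labelings = []
    leaf_choices = [sorted(s) for s in leaf_sets]
    for internal_lab in itertools.product(range(k), repeat=len(internal)):
        assign = dict(zip(internal, internal_lab))
        # leaves with uncertainty pick the cheapest option given parents
        cost = 0
        for li, choices in zip(leaves, leaf_choices):
            p = assign[parent_of[li]]
            cost += 0 if p in choices else 1
        for ii in internal:
            if ii in parent_of:
                cost += assign[ii] != assign[parent_of[ii]]
        if best is None or cost < best:
            best = cost
            best_labelings = [assign]
        elif cost == best:
            best_labelings.append(assign)
    mpr = {ii: frozenset(a[ii] for a in best_labelings) for ii in internal}
    return best, mpr
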