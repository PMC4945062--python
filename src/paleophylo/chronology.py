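"""Ghost-lineage minimum clade ages from fossil first-appearance data.

A fossil's first appearance datum (FAD) is the median of the narrowest
stratigraphic interval assigned to it; extant taxa have FAD 0.  A clade's
minimum age is the oldest FAD among its members, propagated root-ward: every
node is at least as old as its oldest descendant, and the gap between a
node's age and a child lineage's own record is the child's ghost-lineage
range extension.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .trees import Node, PhyloTree, subtree_leaves

EXTANT = "extant"
FOSSIL = "fossil"


def fad_from_intervals(intervals: Sequence[tuple[float, float]]) -> float:
    """Median (midpoint) of the narrowest (older, younger) interval, in Ma.

    Width ties go to the younger interval.
    """
    if not intervals:
        raise ValueError("no age intervals given")
    for older, younger in intervals:
        if older < younger or younger < 0:
            raise ValueError(f"bad interval ({older}, {younger}): need older >= younger >= 0")
    best = min(intervals, key=lambda iv: (iv[0] - iv[1], iv[1]))
    return (best[0] + best[1]) / 2.0


@dataclass
class TaxonAgeRecord:
    taxon: str
    status: str  # extant | fossil
    intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        if self.status not in (EXTANT, FOSSIL):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == FOSSIL and not self.intervals:
            raise ValueError(f"fossil {self.taxon} needs >= 1 age interval")

    @property
    def fad(self) -> float:
        """First appearance datum in Ma (0 for extant taxa)."""
        if self.status == EXTANT:
            return 0.0
        return fad_from_intervals(self.intervals)


def read_age_table(path) -> dict[str, TaxonAgeRecord]:
    """CSV with columns taxon, status, older_Ma, younger_Ma (blank for extant)."""
    out: dict[str, TaxonAgeRecord] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            taxon = row["taxon"]
            status = row["status"]
            if taxon in out:
                out[taxon].intervals.append((float(row["older_Ma"]), float(row["younger_Ma"])))
            else:
                ivs = []
                if status == FOSSIL:
                    ivs = [(float(row["older_Ma"]), float(row["younger_Ma"]))]
                out[taxon] = TaxonAgeRecord(taxon, status, ivs)
    return out


def write_age_table(records: Iterable[TaxonAgeRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["taxon", "status", "older_Ma", "younger_Ma"])
        for rec in records:
            if rec.status == EXTANT:
                w.writerow([rec.taxon, rec.status, "", ""])
            else:
                for older, younger in rec.intervals:
                    w.writerow([rec.taxon, rec.status, older, younger])


class AgeAnnotatedTree:
    """A tree whose nodes carry minimum ages (Ma) and whose branches carry
    ghost-lineage extensions (My)."""

    MIN_AGE = "min_age"
    GHOST = "ghost_extension"

    def __init__(self, tree: PhyloTree):
        self.tree = tree

    def min_age(self, node: Node) -> float:
        return node.annotations[self.MIN_AGE]

    def ghost_extension(self, node: Node) -> float:
        """Ghost range of the lineage subtending `node` (parent age - node age)."""
        return node.annotations.get(self.GHOST, 0.0)

    def to_newick(self) -> str:
        return self.tree.to_newick(lengths=False, annotations=self.MIN_AGE)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for node in self.tree.postorder():
            leaves = sorted(l.name for l in subtree_leaves(node))
            rows.append({
                "clade": "|".join(leaves),
                "n_taxa": len(leaves),
                "min_age_Ma": self.min_age(node),
                "ghost_extension_My": self.ghost_extension(node),
            })
        return pd.DataFrame(rows)


def propagate_min_ages(
    tree: PhyloTree, age_records: dict[str, TaxonAgeRecord]
) -> AgeAnnotatedTree:
    """Post-order max-propagation of tip FADs; pre-order ghost extensions.

    Every leaf needs an age record.  Node minimum age = max over children;
    a child's ghost extension = parent minimum age - child minimum age.
    """
    out = tree.copy()
    missing = [l.name for l in out.leaves() if l.name not in age_records]
    if missing:
        raise KeyError(f"no age record for taxa: {missing}")
    for node in out.postorder():
        if node.is_leaf:
            node.annotations[AgeAnnotatedTree.MIN_AGE] = age_records[node.name].fad
        else:
            node.annotations[AgeAnnotatedTree.MIN_AGE] = max(
                c.annotations[AgeAnnotatedTree.MIN_AGE] for c in node.children
            )
    for node in out.preorder():
        if node.parent is None:
            node.annotations[AgeAnnotatedTree.GHOST] = 0.0
        else:
            node.annotations[AgeAnnotatedTree.GHOST] = (
                node.parent.annotations[AgeAnnotatedTree.MIN_AGE]
                - node.annotations[AgeAnnotatedTree.MIN_AGE]
            )
    return AgeAnnotatedTree(out)


def clade_min_age(
    annotated: AgeAnnotatedTree, clade: Iterable[str], stem: bool = False
) -> float:
    """Minimum age of a clade's crown node (or, with stem=True, of its stem
    lineage: the parent node's minimum age)."""
    names = set(clade)
    if len(names) == 1:
        node = annotated.tree.find_leaf(next(iter(names)))
    else:
        node = annotated.tree.clade_node(names)
    if stem:
        if node.parent is None:
            raise ValueError("root clade has no stem lineage")
        node = node.parent
    return annotated.min_age(node)
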