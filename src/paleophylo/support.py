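"""Clade support: character-jackknife frequencies and Bremer (decay) values.

The jackknife deletes each character independently with probability p
(default 0.36, approximately 1 - e^-1, the standard parametrization behind
the "36% deletion" setting) and re-searches each pseudo-replicate.  Bremer
support sweeps suboptimal trees: BS(clade) = shortest length among trees
lacking the clade minus the globally shortest length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .matrix import CharacterMatrix
from .search import SearchConfig, SearchResult, heuristic_search, sweep_suboptimal
from .trees import PhyloTree, bipartitions, strict_consensus


@dataclass
class SupportTable:
    """Per-clade support values; clades keyed by their smaller bipartition side."""

    jackknife: dict[frozenset, float] = field(default_factory=dict)  # percent
    bremer: dict[frozenset, float] = field(default_factory=dict)  # steps (may be >= cap)
    replicates: int = 0
    consensus: Optional[PhyloTree] = None

    def to_frame(self) -> pd.DataFrame:
        clades = sorted(set(self.jackknife) | set(self.bremer),
                        key=lambda c: (len(c), sorted(c)))
        rows = []
        for c in clades:
            rows.append({
                "clade": "|".join(sorted(c)),
                "jackknife_pct": self.jackknife.get(c, float("nan")),
                "bremer": self.bremer.get(c, float("nan")),
            })
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _default_search(matrix: CharacterMatrix, seed: int) -> SearchResult:
    return heuristic_search(
        matrix, SearchConfig(replicates=2, swap="spr", seed=seed, keep=8)
    )


def jackknife_support(
    matrix: CharacterMatrix,
    search_fn: Optional[Callable[[CharacterMatrix, int], SearchResult]] = None,
    p_delete: float = 0.36,
    replicates: int = 1000,
    seed: int = 0,
) -> SupportTable:
    """Character jackknife.

    Each replicate deletes each character independently with probability
    `p_delete`, re-searches with `search_fn(matrix, seed)`, and tallies the
    bipartitions of the replicate's strict consensus.  Frequencies are
    percentages over replicates.  Fully deterministic for a fixed seed.
    """
    if not 0 < p_delete < 1:
        raise ValueError("p_delete must be in (0, 1)")
    search_fn = search_fn or _default_search
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    done = 0
    redrawn = 0
    while done < replicates:
        keep = np.nonzero(rng.random(matrix.n_characters) >= p_delete)[0]
        if keep.size == 0:
            redrawn += 1  # all characters deleted: redraw (logged)
            continue
        sub = matrix.subset_characters(list(keep))
        rep_seed = int(rng.integers(2**31 - 1))
        result = search_fn(sub, rep_seed)
        cons = strict_consensus(result.trees) if len(result.trees) > 1 else result.trees[0]
        for split in bipartitions(cons):
            counts[split] = counts.get(split, 0) + 1
        done += 1
    table = SupportTable(
        jackknife={c: 100.0 * n / replicates for c, n in counts.items()},
        replicates=replicates,
    )
    table.redrawn = redrawn  # type: ignore[attr-defined]
    return table


def bremer_support(
    matrix: CharacterMatrix,
    best_trees: list[PhyloTree],
    search_fn: Optional[Callable[[CharacterMatrix, int], SearchResult]] = None,
    max_extra_steps: int = 10,
    max_trees: int = 5000,
) -> SupportTable:
    """Bremer decay by suboptimal-tree sweep.

    For each clade of the strict consensus of `best_trees`, BS = (shortest
    length among swept trees lacking the clade) - (shortest length overall).
    Clades unbroken within the sweep are reported as >= cap (value = cap).
    Clades absent from some most-parsimonious tree get BS = 0 by definition.
    """
    if max_extra_steps < 1:
        raise ValueError("max_extra_steps must be >= 1")
    swept = sweep_suboptimal(matrix, best_trees, cap=max_extra_steps,
                             max_trees=max_trees)
    best_len = min(swept.values())
    mpt_keys = [k for k, l in swept.items() if l == best_len]
    consensus_splits = set.intersection(*(set(k) for k in mpt_keys))
    cons = strict_consensus(best_trees) if len(best_trees) > 1 else best_trees[0]
    support: dict[frozenset, float] = {}
    for clade in bipartitions(cons):
        if clade not in consensus_splits:
            support[clade] = 0.0
            continue
        lacking = [l for k, l in swept.items() if clade not in k]
        if lacking:
            support[clade] = float(min(lacking) - best_len)
        else:
            support[clade] = float(max_extra_steps)
    return SupportTable(bremer=support, consensus=cons)
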