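"""Shared fixtures: small matrices, random trees, and brute-force helpers."""

from __future__ import annotations

import numpy as np
import pytest

from paleophylo.matrix import CharacterMatrix, _read_tsv
from paleophylo.trees import PhyloTree, bipartitions, random_topology


def matrix_from_rows(rows: dict[str, str], partitions: str = "") -> CharacterMatrix:
    """Build a matrix from {taxon: symbol-string} via the TSV dialect."""
    lines = []
    if partitions:
        for part in partitions.split(";"):
            lines.append(f"# partition {part}")
    lines += [f"{t}\t{s}" for t, s in rows.items()]
    return _read_tsv("\n".join(lines) + "\n")


def clean_matrix(tree: PhyloTree, reps: int = 3) -> CharacterMatrix:
    """Homoplasy-free binary matrix: `reps` characters per internal split."""
    taxa = tree.leaf_names()
    cols = []
    for split in sorted(bipartitions(tree), key=lambda s: sorted(s)):
        cols.extend([{t: ("1" if t in split else "0") for t in taxa}] * reps)
    rows = {t: "".join(col[t] for col in cols) for t in taxa}
    return matrix_from_rows(rows)


def random_column(
    rng: np.random.Generator,
    taxa: list[str],
    k: int,
    p_missing: float = 0.15,
    p_set: float = 0.15,
) -> dict[str, str]:
    """Random cell strings for one character (with missing/uncertain cells)."""
    from paleophylo.matrix import SYMBOLS

    out = {}
    for t in taxa:
        r = rng.random()
        if r < p_missing:
            out[t] = "?"
        elif r < p_missing + p_set and k > 2:
            ss = sorted(rng.choice(k, size=2, replace=False))
            out[t] = "{" + "".join(SYMBOLS[int(s)] for s in ss) + "}"
        else:
            out[t] = SYMBOLS[int(rng.integers(k))]
    return out


def random_case(rng: np.random.Generator, n_min=4, n_max=7, k_max=4):
    """(tree, matrix, k) with a single random character, for oracle tests."""
    n = int(rng.integers(n_min, n_max + 1))
    k = int(rng.integers(2, k_max + 1))
    taxa = [f"t{i}" for i in range(n)]
    tree = random_topology(list(taxa), rng)
    col = random_column(rng, taxa, k)
    rows = {t: col[t] for t in taxa}
    m = matrix_from_rows(rows)
    for ch in m.characters:
        ch.state_count = k
    return tree, m, k


def observed_leaf_sets(tree: PhyloTree, m: CharacterMatrix, char: int = 0):
    full = frozenset(range(m.characters[char].state_count))
    sets = []
    for leaf in tree.leaves():
        cell = m.cell(leaf.name, char)
        sets.append(full if cell.is_blank else cell.states)
    return sets


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
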