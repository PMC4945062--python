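"""Combined phenomic + molecular character matrices.

Cells carry an explicit observation kind so that the biologically distinct
situations -- a determinate score, a true polymorphism, scoring uncertainty,
missing data, and inapplicability (e.g. the size of an absent exopod) -- are
preserved through I/O even though parsimony scoring treats the last three
identically (full uncertainty over the character's state space).

Canonical on-disk form is a restricted NEXUS dialect (single MATRIX, symbols
0-9A-Z, MISSING=?, GAP=- for inapplicable, {..} uncertain, (..) polymorphic,
one CHARSET per partition).  A TSV dialect exists for human-readable fixtures.
DNA partitions use the fixed state order A, C, G, T (indices 0-3).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"
DNA_STATES = "ACGT"
# IUPAC ambiguity -> subset of ACGT indices
IUPAC = {
    "A": (0,), "C": (1,), "G": (2,), "T": (3,), "U": (3,),
    "R": (0, 2), "Y": (1, 3), "S": (1, 2), "W": (0, 3),
    "K": (2, 3), "M": (0, 1), "B": (1, 2, 3), "D": (0, 2, 3),
    "H": (0, 1, 3), "V": (0, 1, 2), "N": (0, 1, 2, 3),
}

DETERMINATE = "determinate"
POLYMORPHIC = "polymorphic"
UNCERTAIN = "uncertain"
MISSING = "missing"
INAPPLICABLE = "inapplicable"


@dataclass(frozen=True)
class ObservedStates:
    """One matrix cell: an observation kind plus a set of state indices."""

    kind: str
    states: frozenset = frozenset()

    def __post_init__(self):
        if self.kind == DETERMINATE and len(self.states) != 1:
            raise ValueError("determinate cell must carry exactly one state")
        if self.kind in (POLYMORPHIC, UNCERTAIN) and len(self.states) < 2:
            raise ValueError(f"{self.kind} cell must carry >= 2 states")
        if self.kind in (MISSING, INAPPLICABLE) and self.states:
            raise ValueError(f"{self.kind} cell carries no states")

    @property
    def is_blank(self) -> bool:
        """True for cells scored as full uncertainty (missing or inapplicable)."""
        return self.kind in (MISSING, INAPPLICABLE)

    @classmethod
    def determinate(cls, state: int) -> "ObservedStates":
        return cls(DETERMINATE, frozenset([state]))

    @classmethod
    def missing(cls) -> "ObservedStates":
        return cls(MISSING)

    @classmethod
    def inapplicable(cls) -> "ObservedStates":
        return cls(INAPPLICABLE)

    @classmethod
    def of(cls, states: Iterable[int], polymorphic: bool = False) -> "ObservedStates":
        states = frozenset(states)
        if len(states) == 1:
            return cls(DETERMINATE, states)
        return cls(POLYMORPHIC if polymorphic else UNCERTAIN, states)


@dataclass
class CharacterDef:
    id: int
    label: str
    state_count: int
    partition: str
    ordered: bool = False

    def __post_init__(self):
        if self.state_count < 1:
            raise ValueError("state_count must be >= 1")
        if self.ordered:
            raise ValueError("ordered characters are not supported")


class MatrixError(ValueError):
    pass


class CharacterMatrix:
    """Taxa x characters, with partition bookkeeping.

    cells[i][j] is the ObservedStates of taxon i at character j.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        characters: Sequence[CharacterDef],
        cells: Sequence[Sequence[ObservedStates]],
    ):
        self.taxa = list(taxa)
        self.characters = list(characters)
        self.cells = [list(row) for row in cells]
        self.validate()

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            dup = [t for t in self.taxa if self.taxa.count(t) > 1]
            raise MatrixError(f"duplicate taxon: {dup[0]}")
        if len(self.cells) != len(self.taxa):
            raise MatrixError("row count != taxon count")
        ncol = len(self.characters)
        for taxon, row in zip(self.taxa, self.cells):
            if len(row) != ncol:
                raise MatrixError(f"taxon {taxon}: {len(row)} cells, expected {ncol}")
            for cell, char in zip(row, self.characters):
                if cell.states and max(cell.states) >= char.state_count:
                    raise MatrixError(
                        f"taxon {taxon}, character {char.id}: state out of range"
                    )
        covered = sorted(i for name in self.partition_names()
                         for i in self.partition_indices(name))
        if covered != list(range(ncol)):
            raise MatrixError("partitions must cover all characters exactly once")

    # ------------------------------------------------------------------ #
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def partition_names(self) -> list[str]:
        seen: list[str] = []
        for ch in self.characters:
            if ch.partition not in seen:
                seen.append(ch.partition)
        return seen

    def partition_indices(self, name: str) -> list[int]:
        idx = [j for j, ch in enumerate(self.characters) if ch.partition == name]
        if not idx:
            raise KeyError(f"no partition {name!r}")
        return idx

    def taxon_index(self, taxon: str) -> int:
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in matrix") from None

    def cell(self, taxon: str, char_index: int) -> ObservedStates:
        return self.cells[self.taxon_index(taxon)][char_index]

    def subset_characters(self, indices: Sequence[int]) -> "CharacterMatrix":
        chars = [
            CharacterDef(j, self.characters[i].label, self.characters[i].state_count,
                         self.characters[i].partition)
            for j, i in enumerate(indices)
        ]
        cells = [[row[i] for i in indices] for row in self.cells]
        return CharacterMatrix(self.taxa, chars, cells)

    def drop_taxa(self, names: Iterable[str]) -> "CharacterMatrix":
        drop = set(names)
        keep = [i for i, t in enumerate(self.taxa) if t not in drop]
        return CharacterMatrix(
            [self.taxa[i] for i in keep],
            self.characters,
            [self.cells[i] for i in keep],
        )

    # ------------------------------------------------------------------ #
    def state_counts(self) -> np.ndarray:
        return np.array([ch.state_count for ch in self.characters], dtype=np.int64)

    def bitmasks(self, taxa_order: Optional[Sequence[str]] = None) -> np.ndarray:
        """(n_taxa, n_char) uint64 bitmask encoding for parsimony scoring.

        Missing/inapplicable cells get the full state set of their character;
        polymorphic and uncertain cells get their observed subset.
        """
        order = list(taxa_order) if taxa_order is not None else self.taxa
        full = (np.uint64(1) << self.state_counts().astype(np.uint64)) - np.uint64(1)
        out = np.empty((len(order), self.n_characters), dtype=np.uint64)
        for i, taxon in enumerate(order):
            row = self.cells[self.taxon_index(taxon)]
            for j, cell in enumerate(row):
                if cell.is_blank:
                    out[i, j] = full[j]
                else:
                    m = 0
                    for s in cell.states:
                        m |= 1 << s
                    out[i, j] = m
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and [(c.label, c.state_count, c.partition) for c in self.characters]
            == [(c.label, c.state_count, c.partition) for c in other.characters]
            and self.cells == other.cells
        )

    def __repr__(self):  # pragma: no cover
        return f"<CharacterMatrix {self.n_taxa} taxa x {self.n_characters} characters>"


# ---------------------------------------------------------------------- #
# classification
# ---------------------------------------------------------------------- #
INVARIANT = "invariant"
VARIABLE_UNINFORMATIVE = "variable_uninformative"
PARSIMONY_INFORMATIVE = "parsimony_informative"


def classify_characters(matrix: CharacterMatrix) -> list[str]:
    """Classify each character as invariant / variable-uninformative /
    parsimony-informative.

    Only determinate cells count: a character is invariant when at most one
    state is determinately observed, informative when at least two states are
    each determinately observed in at least two taxa, and otherwise variable
    but uninformative (autapomorphies add the same steps on every topology).
    """
    out = []
    for j in range(matrix.n_characters):
        counts: dict[int, int] = {}
        for row in matrix.cells:
            cell = row[j]
            if cell.kind == DETERMINATE:
                (s,) = cell.states
                counts[s] = counts.get(s, 0) + 1
        if len(counts) <= 1:
            out.append(INVARIANT)
        elif sum(1 for c in counts.values() if c >= 2) >= 2:
            out.append(PARSIMONY_INFORMATIVE)
        else:
            out.append(VARIABLE_UNINFORMATIVE)
    return out


def classification_counts(matrix: CharacterMatrix) -> dict[str, int]:
    classes = classify_characters(matrix)
    return {
        INVARIANT: classes.count(INVARIANT),
        VARIABLE_UNINFORMATIVE: classes.count(VARIABLE_UNINFORMATIVE),
        PARSIMONY_INFORMATIVE: classes.count(PARSIMONY_INFORMATIVE),
    }


# ---------------------------------------------------------------------- #
# combining partitions
# ---------------------------------------------------------------------- #
def combine_partitions(
    phenomic: CharacterMatrix, genes: Sequence[CharacterMatrix]
) -> CharacterMatrix:
    """Concatenate a phenomic matrix with gene matrices into one total-evidence
    matrix.  Taxa absent from an input are padded with all-missing rows (with a
    warning); characters are renumbered sequentially with source partitions kept.
    """
    inputs = [phenomic, *genes]
    if not genes:
        return phenomic
    names_seen: set[str] = set()
    for m in inputs:
        for p in m.partition_names():
            if p in names_seen:
                raise MatrixError(f"conflicting partition/character ids: {p!r}")
            names_seen.add(p)
    taxa: list[str] = []
    for m in inputs:
        for t in m.taxa:
            if t not in taxa:
                taxa.append(t)
    chars: list[CharacterDef] = []
    for m in inputs:
        for ch in m.characters:
            chars.append(CharacterDef(len(chars), ch.label, ch.state_count, ch.partition))
    cells: list[list[ObservedStates]] = [[] for _ in taxa]
    for m in inputs:
        pad = [ObservedStates.missing()] * m.n_characters
        for i, t in enumerate(taxa):
            if t in m.taxa:
                cells[i].extend(m.cells[m.taxon_index(t)])
            else:
                warnings.warn(f"taxon {t!r} absent from one input: padded as all-missing")
                cells[i].extend(pad)
    return CharacterMatrix(taxa, chars, cells)


# ---------------------------------------------------------------------- #
# NEXUS dialect
# ---------------------------------------------------------------------- #
def _parse_cell(token: str, char: CharacterDef, line_no: int) -> ObservedStates:
    if token == "?":
        return ObservedStates.missing()
    if token == "-":
        return ObservedStates.inapplicable()
    poly = token.startswith("(")
    if token[0] in "({":
        body = token[1:-1]
    else:
        body = token
    states = []
    for sym in body:
        idx = SYMBOLS.find(sym)
        if idx < 0:
            raise MatrixError(f"line {line_no}: bad state symbol {sym!r}")
        states.append(idx)
    if not states:
        raise MatrixError(f"line {line_no}: empty state set {token!r}")
    return ObservedStates.of(states, polymorphic=poly)


def _format_cell(cell: ObservedStates) -> str:
    if cell.kind == MISSING:
        return "?"
    if cell.kind == INAPPLICABLE:
        return "-"
    syms = "".join(SYMBOLS[s] for s in sorted(cell.states))
    if cell.kind == DETERMINATE:
        return syms
    return f"({syms})" if cell.kind == POLYMORPHIC else "{" + syms + "}"


_CELL_RE = re.compile(r"\(([^)]*)\)|\{([^}]*)\}|(\S)")


def _split_row(symbols: str, line_no: int) -> list[str]:
    out = []
    pos = 0
    s = symbols.replace(" ", "").replace("\t", "")
    while pos < len(s):
        m = _CELL_RE.match(s, pos)
        if not m:
            raise MatrixError(f"line {line_no}: cannot parse row at ...{s[pos:pos+10]!r}")
        out.append(m.group(0))
        pos = m.end()
    return out


def _infer_state_counts(token_rows: list[list[str]], nchar: int) -> list[int]:
    """Max observed symbol index + 1 per column (floored at 2)."""
    inferred = [2] * nchar
    for tokens in token_rows:
        for j, tok in enumerate(tokens):
            for sym in tok.strip("(){}"):
                if sym in "?-":
                    continue
                idx = SYMBOLS.find(sym)
                if idx >= 0:
                    inferred[j] = max(inferred[j], idx + 1)
    return inferred


def read_matrix(path, format: str = "nexus") -> CharacterMatrix:
    """Read a matrix in the canonical NEXUS dialect or the TSV fixture dialect."""
    with open(path) as fh:
        text = fh.read()
    if format == "nexus":
        return _read_nexus(text)
    if format == "tsv":
        return _read_tsv(text)
    raise ValueError(f"unknown format {format!r}")


def write_matrix(matrix: CharacterMatrix, path, format: str = "nexus") -> None:
    with open(path, "w") as fh:
        if format == "nexus":
            fh.write(to_nexus(matrix))
        elif format == "tsv":
            fh.write(to_tsv(matrix))
        else:
            raise ValueError(f"unknown format {format!r}")


def _read_nexus(text: str) -> CharacterMatrix:
    lines = text.splitlines()
    ntax = nchar = None
    nstates: Optional[list[int]] = None
    in_matrix = False
    rows: list[tuple[str, list[str], int]] = []
    charsets: list[tuple[str, int, int]] = []
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("[") and line.endswith("]"):
            # [STATECOUNTS ...] comment carries per-character state counts
            m = re.match(r"\[STATECOUNTS\s+([\d\s]+)\]", line)
            if m:
                nstates = [int(x) for x in m.group(1).split()]
            continue
        up = line.upper()
        if up.startswith("DIMENSIONS"):
            m = re.search(r"NTAX\s*=\s*(\d+)", up)
            if not m:
                raise MatrixError(f"line {ln}: DIMENSIONS lacks NTAX")
            ntax = int(m.group(1))
            m = re.search(r"NCHAR\s*=\s*(\d+)", up)
            if not m:
                raise MatrixError(f"line {ln}: DIMENSIONS lacks NCHAR")
            nchar = int(m.group(1))
        elif up.startswith("MATRIX"):
            if ntax is None:
                raise MatrixError(f"line {ln}: MATRIX before DIMENSIONS")
            in_matrix = True
        elif in_matrix:
            if line == ";":
                in_matrix = False
                continue
            parts = line.rstrip(";").split(None, 1)
            if len(parts) != 2:
                raise MatrixError(f"line {ln}: malformed matrix row")
            rows.append((parts[0], _split_row(parts[1], ln), ln))
            if line.endswith(";"):
                in_matrix = False
        elif up.startswith("CHARSET"):
            m = re.match(r"CHARSET\s+(\S+)\s*=\s*(\d+)\s*-\s*(\d+)\s*;", line,
                         re.IGNORECASE)
            if not m:
                raise MatrixError(f"line {ln}: malformed CHARSET")
            charsets.append((m.group(1), int(m.group(2)), int(m.group(3))))
    if ntax is None or nchar is None:
        raise MatrixError("no DIMENSIONS line found")
    if len(rows) != ntax:
        raise MatrixError(f"expected {ntax} matrix rows, found {len(rows)}")
    if not charsets:
        charsets = [("all", 1, nchar)]
    for taxon, tokens, ln in rows:
        if len(tokens) != nchar:
            raise MatrixError(f"line {ln}: {len(tokens)} cells, expected {nchar}")
    partition_of: dict[int, str] = {}
    for name, lo, hi in charsets:
        for j in range(lo - 1, hi):
            partition_of[j] = name
    if sorted(partition_of) != list(range(nchar)):
        raise MatrixError("CHARSET ranges do not cover NCHAR characters")
    if nstates is None:
        nstates = _infer_state_counts([tokens for _, tokens, _ in rows], nchar)
    chars = [
        CharacterDef(j, f"char_{j + 1}", nstates[j], partition_of[j])
        for j in range(nchar)
    ]
    taxa = [r[0] for r in rows]
    cells = [
        [_parse_cell(tok, chars[j], ln) for j, tok in enumerate(tokens)]
        for taxon, tokens, ln in rows
    ]
    return CharacterMatrix(taxa, chars, cells)


def to_nexus(matrix: CharacterMatrix) -> str:
    """Canonical NEXUS serialization (byte-stable; round-trips exactly)."""
    name_w = max(len(t) for t in matrix.taxa) + 2
    max_k = max(ch.state_count for ch in matrix.characters)
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        f'FORMAT SYMBOLS="{SYMBOLS[:max_k]}" MISSING=? GAP=-;',
        "[STATECOUNTS " + " ".join(str(c.state_count) for c in matrix.characters) + "]",
        "MATRIX",
    ]
    for taxon, row in zip(matrix.taxa, matrix.cells):
        lines.append(taxon.ljust(name_w) + "".join(_format_cell(c) for c in row))
    lines.append(";")
    lines.append("END;")
    lines.append("BEGIN SETS;")
    for name in matrix.partition_names():
        idx = matrix.partition_indices(name)
        lines.append(f"CHARSET {name} = {min(idx) + 1}-{max(idx) + 1};")
    lines.append("END;")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------- #
# TSV fixture dialect
# ---------------------------------------------------------------------- #
def _read_tsv(text: str) -> CharacterMatrix:
    charsets: list[tuple[str, int, int]] = []
    nstates: Optional[list[int]] = None
    rows: list[tuple[str, list[str], int]] = []
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*partition\s+(\S+)\s+(\d+)\s+(\d+)", line)
            if m:
                charsets.append((m.group(1), int(m.group(2)), int(m.group(3))))
            m = re.match(r"#\s*statecounts\s+([\d\s]+)", line)
            if m:
                nstates = [int(x) for x in m.group(1).split()]
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise MatrixError(f"line {ln}: expected taxon<TAB>symbols")
        rows.append((parts[0], _split_row(parts[1], ln), ln))
    if not rows:
        raise MatrixError("empty TSV matrix")
    nchar = len(rows[0][1])
    for taxon, tokens, ln in rows:
        if len(tokens) != nchar:
            raise MatrixError(f"line {ln}: ragged row ({len(tokens)} != {nchar})")
    if not charsets:
        charsets = [("all", 1, nchar)]
    partition_of: dict[int, str] = {}
    for name, lo, hi in charsets:
        for j in range(lo - 1, hi):
            partition_of[j] = name
    if nstates is None:
        nstates = _infer_state_counts([tokens for _, tokens, _ in rows], nchar)
    chars = [
        CharacterDef(j, f"char_{j + 1}", nstates[j], partition_of[j])
        for j in range(nchar)
    ]
    taxa = [r[0] for r in rows]
    cells = [
        [_parse_cell(tok, chars[j], ln) for j, tok in enumerate(tokens)]
        for taxon, tokens, ln in rows
    ]
    return CharacterMatrix(taxa, chars, cells)


def to_tsv(matrix: CharacterMatrix) -> str:
    lines = []
    for name in matrix.partition_names():
        idx = matrix.partition_indices(name)
        lines.append(f"# partition {name} {min(idx) + 1} {max(idx) + 1}")
    lines.append(
        "# statecounts " + " ".join(str(c.state_count) for c in matrix.characters)
    )
    for taxon, row in zip(matrix.taxa, matrix.cells):
        lines.append(taxon + "\t" + "".join(_format_cell(c) for c in row))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------- #
# molecular input
# ---------------------------------------------------------------------- #
def matrix_from_fasta(
    path, partition: str, ambiguity: str = "subset"
) -> CharacterMatrix:
    """Build a 4-state DNA matrix (A,C,G,T -> 0..3) from an aligned FASTA file.

    IUPAC ambiguity codes become uncertainty cells covering the coded subset
    (ambiguity="subset", the default) or plain missing cells ("full").
    Gaps ('-') and 'N'/'?' become missing.
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MatrixError(f"no sequences in {path}")
    length = len(records[0].seq)
    taxa, cells = [], []
    for rec in records:
        if len(rec.seq) != length:
            raise MatrixError(f"{rec.id}: unaligned length {len(rec.seq)} != {length}")
        taxa.append(rec.id)
        row = []
        for base in str(rec.seq).upper():
            if base in "-?N" or base not in IUPAC:
                row.append(ObservedStates.missing())
            else:
                sub = IUPAC[base]
                if len(sub) == 1:
                    row.append(ObservedStates.determinate(sub[0]))
                elif ambiguity == "subset":
                    row.append(ObservedStates.of(sub))
                else:
                    row.append(ObservedStates.missing())
        cells.append(row)
    chars = [CharacterDef(j, f"{partition}_{j + 1}", 4, partition) for j in range(length)]
    return CharacterMatrix(taxa, chars, cells)
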