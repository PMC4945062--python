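"""Deterministic trait discretization and gill/epipod formula arithmetic.

Body size, maximum inhabited depth, and minimum inhabited water temperature
are coded into small ordered-looking (but analytically unordered) state sets
with fixed, documented thresholds; gill formulas are per-appendage branchial
counts over thoracic segments VII-XIV whose totals summarize a taxon's (or a
reconstructed ancestor's) breathing apparatus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .matrix import CharacterMatrix
from .parsimony import optimize_character
from .trees import PhyloTree, subtree_leaves

# body-size classes (total length, cm)
SMALL, MEDIUM, LARGE = "small", "medium", "large"
SIZE_THRESHOLDS = (5.0, 20.0)
MAX_RECORDED_LENGTH_CM = 35.0  # largest recorded penaeoid (giant tiger shrimp)

# depth zones (positive meters below surface)
SUBLITTORAL, MESOPELAGIC, BATHYAL, ABYSSAL = (
    "sublittoral", "mesopelagic", "bathyal", "abyssal",
)
DEPTH_BOUNDARIES = (200.0, 1000.0, 4000.0)

# minimum water temperature classes (deg C)
VERY_COLD, COLD_TEMPERATE, WARM = "very_cold", "cold_temperate", "warm"
TEMP_BOUNDARIES = (7.0, 15.0)

SIZE_STATES = (SMALL, MEDIUM, LARGE)
DEPTH_STATES = (SUBLITTORAL, MESOPELAGIC, BATHYAL, ABYSSAL)
TEMP_STATES = (VERY_COLD, COLD_TEMPERATE, WARM)


def code_body_size(max_total_length_cm: float) -> str:
    """small: up to 5 cm (inclusive); medium: over 5 and under 20; large: >= 20."""
    if max_total_length_cm <= 0:
        raise ValueError("total length must be positive")
    if max_total_length_cm <= SIZE_THRESHOLDS[0]:
        return SMALL
    if max_total_length_cm < SIZE_THRESHOLDS[1]:
        return MEDIUM
    return LARGE


def code_depth_zone(max_depth_m: float) -> str:
    """Zones by maximum depth: 0-200 sublittoral, 201-1000 mesopelagic,
    1001-4000 bathyal, >4000 abyssal.  Depths are positive magnitudes."""
    if max_depth_m < 0:
        raise ValueError("depth must be a non-negative magnitude in meters")
    if max_depth_m <= DEPTH_BOUNDARIES[0]:
        return SUBLITTORAL
    if max_depth_m <= DEPTH_BOUNDARIES[1]:
        return MESOPELAGIC
    if max_depth_m <= DEPTH_BOUNDARIES[2]:
        return BATHYAL
    return ABYSSAL


def code_min_temperature(t_celsius: float) -> str:
    """very_cold below 7 C; cold_temperate 7-15 C inclusive; warm above 15 C.

    A boundary value joins the lower class ("between 7 and 15" read inclusive).
    """
    if not -2.0 <= t_celsius <= 40.0:
        warnings.warn(f"temperature {t_celsius} C outside plausible marine range")
    if t_celsius < TEMP_BOUNDARIES[0]:
        return VERY_COLD
    if t_celsius <= TEMP_BOUNDARIES[1]:
        return COLD_TEMPERATE
    return WARM


def size_class_representative(size_class: str) -> float:
    """Class midpoint in cm: small 2.5, medium 12.5, large 27.5 (the large
    class is closed at the 35 cm maximum recorded total length)."""
    lo, hi = SIZE_THRESHOLDS
    reps = {
        SMALL: lo / 2.0,
        MEDIUM: (lo + hi) / 2.0,
        LARGE: (hi + MAX_RECORDED_LENGTH_CM) / 2.0,
    }
    if size_class not in reps:
        raise ValueError(f"unknown size class {size_class!r}")
    return reps[size_class]


# ---------------------------------------------------------------------- #
# gill formulas
# ---------------------------------------------------------------------- #
SEGMENTS = ("VII", "VIII", "IX", "X", "XI", "XII", "XIII", "XIV")
APPENDAGES = ("Max1", "Max2", "Max3", "Per1", "Per2", "Per3", "Per4", "Per5")


@dataclass
class GillFormula:
    """Per-appendage gill counts (and optional epipod counts) over thoracic
    segments VII-XIV (maxillipeds 1-3, pereiopods 1-5)."""

    gills: Mapping[str, int]
    epipods: Optional[Mapping[str, int]] = None
    taxon: Optional[str] = None

    def __post_init__(self):
        for counts in (self.gills, self.epipods):
            if counts is None:
                continue
            for seg, n in counts.items():
                if seg not in SEGMENTS:
                    raise ValueError(f"unknown segment {seg!r}; use {SEGMENTS}")
                if n < 0 or int(n) != n:
                    raise ValueError(f"count for {seg} must be a non-negative integer")


def gill_total(formula: GillFormula) -> tuple[int, int]:
    """(total gills, total epipods) summed over segments VII-XIV."""
    missing = [s for s in SEGMENTS if s not in formula.gills]
    if missing:
        raise ValueError(f"gill formula incomplete: missing segment(s) {missing}")
    total_gills = sum(int(formula.gills[s]) for s in SEGMENTS)
    if formula.epipods is None:
        return total_gills, 0
    total_epipods = sum(int(v) for v in formula.epipods.values())
    return total_gills, total_epipods


# ---------------------------------------------------------------------- #
# ancestral summaries
# ---------------------------------------------------------------------- #
def coded_trait_matrix(
    taxa: Sequence[str],
    coded: Mapping[str, Optional[str]],
    states: Sequence[str],
    label: str = "trait",
) -> CharacterMatrix:
    """Wrap a single coded trait (state name per taxon, None = missing) as a
    one-character matrix suitable for parsimony optimization."""
    from .matrix import CharacterDef, ObservedStates

    index = {s: i for i, s in enumerate(states)}
    cells = []
    for t in taxa:
        value = coded.get(t)
        if value is None:
            cells.append([ObservedStates.missing()])
        else:
            cells.append([ObservedStates.determinate(index[value])])
    chars = [CharacterDef(0, label, len(states), "trait")]
    return CharacterMatrix(list(taxa), chars, cells)


def ancestral_trait_summary(
    tree: PhyloTree,
    trait_matrix: CharacterMatrix,
    states: Optional[Sequence[str]] = None,
    char: int = 0,
) -> pd.DataFrame:
    """MPR state set per node for one coded trait, with ambiguity flags.

    Rows are postorder nodes identified by their sorted leaf set.
    """
    _, mpr, _, _ = optimize_character(tree, trait_matrix, char)
    k = trait_matrix.characters[char].state_count
    names = list(states) if states is not None else [str(i) for i in range(k)]
    rows = []
    for i, node in enumerate(tree.postorder()):
        stateset = sorted(mpr[i])
        rows.append({
            "clade": "|".join(sorted(l.name for l in subtree_leaves(node))),
            "is_leaf": node.is_leaf,
            "states": "/".join(names[s] for s in stateset),
            "ambiguous": len(stateset) > 1,
        })
    return pd.DataFrame(rows)
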