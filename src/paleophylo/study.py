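"""Published reference fixtures for the penaeoid shrimp analysis.

A reduced genus-level reference topology of Penaeoidea (rooted on the krill
outgroup Euphausia superba) covering every named clade -- the deep-water
Phorcysida (Solenoceridae + Podobranchida, the latter = Aristeidae +
Benthesicymidae) and the shallow-water Penaeidae (Penaeini incl. the farmed
clade Agripenaeina, Parapenaeini, and Trachypenaeini incl. Sicyonia) -- with
the seven fossil terminals placed as the combined-evidence analysis found
them: the Solnhofen (Late Jurassic, ca. 145 Ma) fossils Antrimpos speciosus
inside Agripenaeina, Acanthochirana smithwoodwardi as its stem taxon, Drobna
deformis as sister to Sicyonia, and Aeger tipularius with Artemesia in
Parapenaeini; the Early Triassic Ifasya madagascariensis in Parapenaeini;
Palaeobenthesicymus libanensis in Benthesicymidae; and Paleomattea deliciosa
among the sergestoid outgroups.

Fossil age intervals: the Solnhofen taxa carry the interval (150, 140) Ma
(first appearance datum 145 Ma).  Ifasya is from the Middle Sakamena Group of
Madagascar; the narrowest stage assignment in the literature is the Induan
(251.9-251.2 Ma, FAD 251.55 Ma).  The remaining two fossils carry approximate
period-level intervals and can be overridden by user-supplied tables.

Also here: the published ancestral gill/epipod formulas for the five major
clades (per side, segments VII-XIV), whose totals are 24, 20, 19, 18, 17
gills and 7, 7, 6, 5, 5 epipods.
"""

from __future__ import annotations

from .chronology import TaxonAgeRecord
from .traits import GillFormula
from .trees import PhyloTree

# clade membership (leaf names) of the reference topology
AGRIPENAEINA = (
    "Penaeus_monodon",
    "Litopenaeus_vannamei",
    "Fenneropenaeus_chinensis",
    "Antrimpos_speciosus",
)
PAN_AGRIPENAEINA = AGRIPENAEINA + ("Acanthochirana_smithwoodwardi",)
PENAEINI = PAN_AGRIPENAEINA + (
    "Heteropenaeus_longimanus",
    "Funchalia_woodwardi",
    "Pelagopenaeus_balboae",
)
PARAPENAEINI = (
    "Parapenaeus_longirostris",
    "Metapenaeopsis_goodei",
    "Artemesia_longinaris",
    "Aeger_tipularius",
    "Ifasya_madagascariensis",
)
SICYONIA = ("Sicyonia_lancifer", "Sicyonia_brevirostris")
PAN_SICYONIA = SICYONIA + ("Drobna_deformis",)
TRACHYPENAEINI = PAN_SICYONIA + ("Metapenaeus_ensis", "Trachypenaeus_constrictus")
PENAEIDAE = PENAEINI + PARAPENAEINI + TRACHYPENAEINI
ARISTEIDAE = ("Aristeus_antennatus", "Aristaeomorpha_foliacea")
BENTHESICYMIDAE = ("Benthesicymus_bartletti", "Gennadas_valens",
                   "Palaeobenthesicymus_libanensis")
PODOBRANCHIDA = ARISTEIDAE + BENTHESICYMIDAE
SOLENOCERIDAE = ("Solenocera_vioscai", "Hymenopenaeus_debilis")
PHORCYSIDA = PODOBRANCHIDA + SOLENOCERIDAE
PENAEOIDEA = PENAEIDAE + PHORCYSIDA
SERGESTOIDEA = ("Sergestes_arcticus", "Acetes_americanus", "Paleomattea_deliciosa")
OUTGROUPS = ("Euphausia_superba", "Palaemon_serratus", "Alpheus_heterochaelis")

FOSSILS = (
    "Antrimpos_speciosus",
    "Acanthochirana_smithwoodwardi",
    "Drobna_deformis",
    "Aeger_tipularius",
    "Ifasya_madagascariensis",
    "Palaeobenthesicymus_libanensis",
    "Paleomattea_deliciosa",
)

CLADES = {
    "Agripenaeina": AGRIPENAEINA,
    "Pan_Agripenaeina": PAN_AGRIPENAEINA,
    "Penaeini": PENAEINI,
    "Parapenaeini": PARAPENAEINI,
    "Sicyonia": SICYONIA,
    "Pan_Sicyonia": PAN_SICYONIA,
    "Trachypenaeini": TRACHYPENAEINI,
    "Penaeidae": PENAEIDAE,
    "Aristeidae": ARISTEIDAE,
    "Benthesicymidae": BENTHESICYMIDAE,
    "Podobranchida": PODOBRANCHIDA,
    "Solenoceridae": SOLENOCERIDAE,
    "Phorcysida": PHORCYSIDA,
    "Penaeoidea": PENAEOIDEA,
}

_REFERENCE_NEWICK = """
(Euphausia_superba,
 ((Palaemon_serratus,Alpheus_heterochaelis),
  (((Sergestes_arcticus,Acetes_americanus),Paleomattea_deliciosa),
   ((((Aristeus_antennatus,Aristaeomorpha_foliacea),
      ((Benthesicymus_bartletti,Gennadas_valens),Palaeobenthesicymus_libanensis)),
     (Solenocera_vioscai,Hymenopenaeus_debilis)),
    (((Funchalia_woodwardi,Pelagopenaeus_balboae),
      (Heteropenaeus_longimanus,
       (Acanthochirana_smithwoodwardi,
        (Antrimpos_speciosus,
         (Penaeus_monodon,(Litopenaeus_vannamei,Fenneropenaeus_chinensis)))))),
     ((Parapenaeus_longirostris,
       (Metapenaeopsis_goodei,
        ((Artemesia_longinaris,Aeger_tipularius),Ifasya_madagascariensis))),
      ((Metapenaeus_ensis,Trachypenaeus_constrictus),
       (Drobna_deformis,(Sicyonia_lancifer,Sicyonia_brevirostris)))))))));
"""


def reference_topology() -> PhyloTree:
    """The reduced reference topology (31 tips, rooted on Euphausia superba)."""
    return PhyloTree.from_newick(_REFERENCE_NEWICK)


# (older, younger) Ma; Solnhofen = 145 Ma FAD, Ifasya = Induan (Middle Sakamena)
_SOLNHOFEN = (150.0, 140.0)
FOSSIL_INTERVALS: dict[str, tuple[float, float]] = {
    "Antrimpos_speciosus": _SOLNHOFEN,
    "Acanthochirana_smithwoodwardi": _SOLNHOFEN,
    "Drobna_deformis": _SOLNHOFEN,
    "Aeger_tipularius": _SOLNHOFEN,
    "Ifasya_madagascariensis": (251.9, 251.2),
    # approximate period-level assignments (user-suppliable):
    "Palaeobenthesicymus_libanensis": (100.5, 93.9),  # Cenomanian, Lebanon
    "Paleomattea_deliciosa": (113.0, 100.5),  # Albian, Brazil (Santana)
}


def reference_age_records() -> dict[str, TaxonAgeRecord]:
    """Age records for every tip of the reference topology."""
    out: dict[str, TaxonAgeRecord] = {}
    for name in reference_topology().leaf_names():
        if name in FOSSIL_INTERVALS:
            out[name] = TaxonAgeRecord(name, "fossil", [FOSSIL_INTERVALS[name]])
        else:
            out[name] = TaxonAgeRecord(name, "extant")
    return out


# Published ancestral gill formulas per side, segments VII-XIV (Max1-3,
# Per1-5), for the five major clades.  Per-segment gill counts are as
# published; the per-segment epipod decomposition is synthetic (only the
# epipod totals 7/7/6/5/5 are published) and kept consistent with them.
ANCESTRAL_GILL_FORMULAS: dict[str, GillFormula] = {
    "Podobranchida": GillFormula(
        gills={"VII": 1, "VIII": 3, "IX": 4, "X": 4, "XI": 4, "XII": 4,
               "XIII": 3, "XIV": 1},
        epipods={"VII": 1, "VIII": 1, "IX": 1, "X": 1, "XI": 1, "XII": 1,
                 "XIII": 1, "XIV": 0},
        taxon="Podobranchida",
    ),
    "Solenoceridae": GillFormula(
        gills={"VII": 1, "VIII": 3, "IX": 3, "X": 3, "XI": 3, "XII": 3,
               "XIII": 3, "XIV": 1},
        epipods={"VII": 1, "VIII": 1, "IX": 1, "X": 1, "XI": 1, "XII": 1,
                 "XIII": 1, "XIV": 0},
        taxon="Solenoceridae",
    ),
    "Penaeini": GillFormula(
        gills={"VII": 1, "VIII": 3, "IX": 3, "X": 3, "XI": 3, "XII": 3,
               "XIII": 2, "XIV": 1},
        epipods={"VII": 1, "VIII": 1, "IX": 1, "X": 1, "XI": 1, "XII": 1,
                 "XIII": 0, "XIV": 0},
        taxon="Penaeini",
    ),
    "Parapenaeini": GillFormula(
        gills={"VII": 1, "VIII": 3, "IX": 3, "X": 3, "XI": 3, "XII": 3,
               "XIII": 2, "XIV": 0},
        epipods={"VII": 1, "VIII": 1, "IX": 1, "X": 1, "XI": 1, "XII": 0,
                 "XIII": 0, "XIV": 0},
        taxon="Parapenaeini",
    ),
    "Trachypenaeini": GillFormula(
        gills={"VII": 1, "VIII": 3, "IX": 3, "X": 3, "XI": 3, "XII": 3,
               "XIII": 1, "XIV": 0},
        epipods={"VII": 1, "VIII": 1, "IX": 1, "X": 1, "XI": 1, "XII": 0,
                 "XIII": 0, "XIV": 0},
        taxon="Trachypenaeini",
    ),
}

# published totals (gills, epipods) for the same five columns
PUBLISHED_TOTALS = {
    "Podobranchida": (24, 7),
    "Solenoceridae": (20, 7),
    "Penaeini": (19, 6),
    "Parapenaeini": (18, 5),
    "Trachypenaeini": (17, 5),
}

# published gene partition aligned lengths (bp)
GENE_LENGTHS = {"H3": 328, "NAK": 582, "PEPCK": 570}
N_PHENOMIC_CHARACTERS = 339
N_TAXA = 63
N_FOSSIL_TAXA = 7
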