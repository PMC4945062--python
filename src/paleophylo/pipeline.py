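"""End-to-end analysis orchestration.

read matrix -> heuristic search -> strict consensus -> support (jackknife +
Bremer) -> synapomorphy table -> trait optimization -> ghost-lineage dating
-> report bundle.  A run is reproducible bit-for-bit from its config plus
inputs: every stochastic stage draws its seed from the master seed through a
named substream, and every output file carries the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .chronology import TaxonAgeRecord, propagate_min_ages, read_age_table
from .matrix import CharacterMatrix, classification_counts, read_matrix
from .parsimony import all_branch_changes, tree_stats
from .search import SearchConfig, heuristic_search
from .support import bremer_support, jackknife_support
from .traits import ancestral_trait_summary
from .trees import PhyloTree, rf_distance, strict_consensus

STAGES = ("search", "jackknife", "bremer", "traits", "dating")


@dataclass
class RunConfig:
    matrix_path: Optional[str] = None
    matrix_format: str = "nexus"
    ages_path: Optional[str] = None
    out_dir: str = "paleophylo_out"
    seed: int = 0
    search: SearchConfig = field(default_factory=lambda: SearchConfig(replicates=10))
    jackknife_replicates: int = 100
    jackknife_p_delete: float = 0.36
    bremer_cap: int = 10
    bremer_max_trees: int = 2000
    trait_characters: Sequence[int] = ()
    fossil_exclusion: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        search = SearchConfig(**raw.pop("search", {}))
        return cls(search=search, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trait_characters"] = list(self.trait_characters)
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def stage_seed(master: int, stage: str) -> int:
    """Named substream seed below 2**31, derived from the master seed."""
    idx = STAGES.index(stage) if stage in STAGES else 97 + len(stage)
    return int(np.random.SeedSequence([master, idx]).generate_state(1)[0] % (2**31 - 1))


@dataclass
class RunReport:
    config: RunConfig
    consensus: PhyloTree
    best_length: int
    n_best_trees: int
    stats: dict
    outputs: dict[str, str]
    fossil_exclusion_rf: Optional[int] = None


def _write_with_hash(path: Path, text: str, config_hash: str, comment: str = "#") -> None:
    """Prefix a config-hash line; '[&' selects a newick-safe bracket comment."""
    if comment == "[&":
        head = f"[config_hash={config_hash}]"
    else:
        head = f"{comment} config_hash={config_hash}"
    path.write_text(f"{head}\n{text}")


def run_full_analysis(
    config: RunConfig,
    matrix: Optional[CharacterMatrix] = None,
    ages: Optional[dict[str, TaxonAgeRecord]] = None,
) -> RunReport:
    """Run every stage and write the report bundle to config.out_dir.

    `matrix` and `ages` may be passed directly (e.g. a simulated bundle)
    instead of being read from the configured paths.
    """
    if matrix is None:
        if config.matrix_path is None:
            raise ValueError("no matrix: set matrix_path or pass one directly")
        matrix = read_matrix(config.matrix_path, format=config.matrix_format)
    if ages is None and config.ages_path:
        ages = read_age_table(config.ages_path)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    log: dict = {
        "config_hash": h,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "n_taxa": matrix.n_taxa,
        "n_characters": matrix.n_characters,
        "classification": classification_counts(matrix),
    }
    outputs: dict[str, str] = {}

    # --- search & consensus ------------------------------------------- #
    scfg = dataclasses.replace(config.search, seed=stage_seed(config.seed, "search"))
    result = heuristic_search(matrix, scfg)
    cons = strict_consensus(result.trees) if len(result.trees) > 1 else result.trees[0]
    stats = tree_stats(result.trees[0], matrix)
    log["search"] = {
        "best_length": result.length,
        "n_best_trees": len(result.trees),
        "replicate_lengths": result.replicate_lengths,
        "ci": round(stats.ci, 4),
        "ri": round(stats.ri, 4) if stats.ri == stats.ri else None,
        "hi": round(stats.hi, 4),
    }
    consensus_path = out / "consensus.nwk"
    _write_with_hash(consensus_path, cons.to_newick(lengths=False) + "\n", h, "[&")
    outputs["consensus"] = str(consensus_path)

    # --- support ------------------------------------------------------- #
    jack = jackknife_support(
        matrix,
        p_delete=config.jackknife_p_delete,
        replicates=config.jackknife_replicates,
        seed=stage_seed(config.seed, "jackknife"),
    )
    brem = bremer_support(matrix, result.trees, max_extra_steps=config.bremer_cap,
                          max_trees=config.bremer_max_trees)
    merged = jack
    merged.bremer = brem.bremer
    support_path = out / "support.tsv"
    _write_with_hash(support_path, merged.to_frame().to_csv(sep="\t", index=False), h)
    outputs["support"] = str(support_path)
    log["support"] = {
        "jackknife_replicates": config.jackknife_replicates,
        "n_clades": len(merged.bremer),
    }

    # --- synapomorphies ------------------------------------------------ #
    syn = all_branch_changes(result.trees[0], matrix)
    syn_path = out / "synapomorphies.tsv"
    _write_with_hash(syn_path, syn.to_csv(sep="\t", index=False), h)
    outputs["synapomorphies"] = str(syn_path)
    log["synapomorphies"] = {"n_changes": int(len(syn))}

    # --- trait optimization -------------------------------------------- #
    trait_chars = list(config.trait_characters)
    if not trait_chars and "phenomic" in matrix.partition_names():
        trait_chars = [matrix.partition_indices("phenomic")[0]]
    frames = []
    for j in trait_chars:
        df = ancestral_trait_summary(result.trees[0], matrix, char=j)
        df.insert(0, "character", matrix.characters[j].label)
        frames.append(df)
    traits_path = out / "trait_optimization.tsv"
    if frames:
        import pandas as pd

        _write_with_hash(traits_path, pd.concat(frames).to_csv(sep="\t", index=False), h)
    else:
        _write_with_hash(traits_path, "character\tclade\tstates\tambiguous\n", h)
    outputs["traits"] = str(traits_path)

    # --- dating --------------------------------------------------------- #
    ages_tsv = out / "clade_ages.tsv"
    ages_nwk = out / "ages.nwk"
    if ages:
        annotated = propagate_min_ages(cons, ages)
        _write_with_hash(ages_nwk, annotated.to_newick() + "\n", h, "[&")
        _write_with_hash(ages_tsv, annotated.to_frame().to_csv(sep="\t", index=False), h)
        log["dating"] = {"n_fossils": sum(1 for a in ages.values() if a.status == "fossil")}
    else:
        _write_with_hash(ages_nwk, ";\n", h, "[&")
        _write_with_hash(ages_tsv, "clade\tn_taxa\tmin_age_Ma\tghost_extension_My\n", h)
        log["dating"] = {"n_fossils": 0}
    outputs["ages_tree"] = str(ages_nwk)
    outputs["ages_table"] = str(ages_tsv)

    # --- fossil exclusion ---------------------------------------------- #
    fossil_rf = None
    if config.fossil_exclusion and ages:
        fossils = [t for t, a in ages.items() if a.status == "fossil" and t in matrix.taxa]
        if fossils:
            sub = matrix.drop_taxa(fossils)
            res2 = heuristic_search(sub, scfg)
            cons2 = strict_consensus(res2.trees) if len(res2.trees) > 1 else res2.trees[0]
            pruned = cons.prune_taxa(fossils)
            fossil_rf = rf_distance(pruned, cons2)
            nofossil_path = out / "consensus_no_fossils.nwk"
            _write_with_hash(nofossil_path, cons2.to_newick(lengths=False) + "\n", h, "[&")
            outputs["consensus_no_fossils"] = str(nofossil_path)
            log["fossil_exclusion"] = {"rf_to_full": fossil_rf,
                                       "best_length": res2.length}

    # --- log ------------------------------------------------------------ #
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    outputs["log"] = str(log_path)
    return RunReport(
        config=config,
        consensus=cons,
        best_length=result.length,
        n_best_trees=len(result.trees),
        stats=log["search"],
        outputs=outputs,
        fossil_exclusion_rf=fossil_rf,
    )


def sensitivity_run(
    config: RunConfig,
    matrix: CharacterMatrix,
    drop_characters: Sequence[int] = (),
    drop_taxa: Sequence[str] = (),
) -> dict:
    """Re-search under character/taxon exclusion; report consensus congruence.

    Returns {"rf": RF distance to baseline consensus (over shared taxa),
    "baseline_length", "excluded_length"}.  Empty drop sets are a warned no-op.
    """
    import warnings

    scfg = dataclasses.replace(config.search, seed=stage_seed(config.seed, "search"))
    base = heuristic_search(matrix, scfg)
    base_cons = strict_consensus(base.trees) if len(base.trees) > 1 else base.trees[0]
    if not drop_characters and not drop_taxa:
        warnings.warn("empty drop set: sensitivity run is a no-op")
        return {"rf": 0, "baseline_length": base.length, "excluded_length": base.length}
    bad_chars = [j for j in drop_characters if not 0 <= j < matrix.n_characters]
    bad_taxa = [t for t in drop_taxa if t not in matrix.taxa]
    if bad_chars or bad_taxa:
        raise KeyError(f"unknown drop ids: characters {bad_chars}, taxa {bad_taxa}")
    sub = matrix
    if drop_characters:
        keep = [j for j in range(matrix.n_characters) if j not in set(drop_characters)]
        sub = sub.subset_characters(keep)
    if drop_taxa:
        sub = sub.drop_taxa(drop_taxa)
    res = heuristic_search(sub, scfg)
    cons = strict_consensus(res.trees) if len(res.trees) > 1 else res.trees[0]
    base_cmp = base_cons.prune_taxa(drop_taxa) if drop_taxa else base_cons
    return {
        "rf": rf_distance(base_cmp, cons),
        "baseline_length": base.length,
        "excluded_length": res.length,
    }
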