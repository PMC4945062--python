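"""Synthetic-data generator: trees, fossils, characters, missingness."""

import numpy as np

from paleophylo.chronology import propagate_min_ages
from paleophylo.matrix import classify_characters
from paleophylo.mk import SubstitutionModel, constant_site_probability
from paleophylo.simulate import (
    GenePartition,
    SimulationConfig,
    inject_missing,
    make_study_like_dataset,
    sample_fossils,
    simulate_characters,
    simulate_tree,
    true_node_ages,
)
from paleophylo.trees import PhyloTree, subtree_leaves


def _pure_birth_cfg(n, seed=0, **kw):
    return SimulationConfig(
        birth_rate=0.05, death_rate=0.0, n_extant=n, sampling_fraction=1.0,
        fossil_rate=0.0, seed=seed, **kw
    )


class TestSimulateTree:
    def test_pure_birth_four_tips(self):
        t = simulate_tree(_pure_birth_cfg(4))
        assert len(t.leaves()) == 4
        assert len(t.internal_nodes()) == 3

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=5, n_extant=10, sampling_fraction=1.0)
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        t1 = simulate_tree(cfg, rng1)
        t2 = simulate_tree(cfg, rng2)
        assert t1.to_newick() == t2.to_newick()

    def test_root_age_respected(self):
        cfg = _pure_birth_cfg(8, seed=3)
        t = simulate_tree(cfg)
        ages = true_node_ages(t, cfg.root_age)
        root_key = frozenset(t.leaf_names())
        assert np.isclose(ages[root_key], cfg.root_age)

    def test_topology_distribution_matches_independent_yule_oracle(self):
        """Mean leaf depth (edges root-to-tip) of the birth-death simulator at
        death 0 matches an independent pick-a-leaf-and-split Yule simulator."""
        n, reps = 12, 150

        def mean_depth(tree):
            total = 0
            for leaf in tree.leaves():
                d, node = 0, leaf
                while node.parent is not None:
                    d += 1
                    node = node.parent
                total += d
            return total / n

        mine = [
            mean_depth(simulate_tree(_pure_birth_cfg(n, seed=s)))
            for s in range(reps)
        ]
        # oracle: grow by splitting a uniformly random current leaf
        rng = np.random.default_rng(123)
        oracle = []
        from paleophylo.trees import Node

        for _ in range(reps):
            root = Node()
            root.add_child(Node("l0"))
            root.add_child(Node("l1"))
            tree = PhyloTree(root)
            for i in range(2, n):
                leaves = tree.leaves()
                leaf = leaves[int(rng.integers(len(leaves)))]
                leaf.add_child(Node(f"l{i}"))
                leaf.add_child(Node(f"l{i}b"))
                leaf.name = None
            oracle.append(mean_depth(tree))
        assert abs(np.mean(mine) - np.mean(oracle)) < 0.25


class TestSampleFossils:
    def test_rate_zero_no_fossils(self):
        cfg = _pure_birth_cfg(6, seed=1)
        t = simulate_tree(cfg)
        t2, recs = sample_fossils(t, cfg)
        assert recs == []

    def test_interval_median_recovers_true_age(self):
        cfg = SimulationConfig(seed=2, n_extant=10, sampling_fraction=1.0,
                               fossil_rate=0.01, interval_width=0.0)
        rng = np.random.default_rng(2)
        t = simulate_tree(cfg, rng)
        t2, recs = sample_fossils(t, cfg, rng)
        assert recs
        leaf_age = {l.name: l.annotations.get("tip_age") for l in t2.leaves()}
        for rec in recs:
            assert np.isclose(rec.fad, leaf_age[rec.taxon])

    def test_wide_intervals_still_center_on_truth(self):
        cfg = SimulationConfig(seed=3, n_extant=10, sampling_fraction=1.0,
                               fossil_rate=0.01, interval_width=20.0)
        rng = np.random.default_rng(3)
        t = simulate_tree(cfg, rng)
        t2, recs = sample_fossils(t, cfg, rng)
        leaf_age = {l.name: l.annotations.get("tip_age") for l in t2.leaves()}
        for rec in recs:
            assert np.isclose(rec.fad, leaf_age[rec.taxon])

    def test_dense_sampling_tightens_clade_ages(self):
        """With a high fossilization rate every deep clade holds fossils, so
        propagated minimum ages approach the true node ages."""
        cfg = SimulationConfig(seed=4, n_extant=12, sampling_fraction=1.0,
                               fossil_rate=0.08, interval_width=0.0)
        rng = np.random.default_rng(4)
        t = simulate_tree(cfg, rng)
        t2, recs = sample_fossils(t, cfg, rng)
        ages = {r.taxon: r for r in recs}
        for l in t2.leaves():
            if l.name not in ages:
                from paleophylo.chronology import TaxonAgeRecord

                ages[l.name] = TaxonAgeRecord(l.name, "extant")
        ann = propagate_min_ages(t2, ages)
        truth = true_node_ages(t2, cfg.root_age)
        ratios = []
        for node in ann.tree.postorder():
            if node.is_leaf:
                continue
            key = frozenset(l.name for l in subtree_leaves(node))
            if truth[key] > 50:
                ratios.append(ann.min_age(node) / truth[key])
        assert ratios and np.mean(ratios) > 0.5
        assert all(r <= 1.0 + 1e-9 for r in ratios)


class TestSimulateCharacters:
    def test_rate_zero_all_invariant(self):
        cfg = _pure_birth_cfg(6, seed=5, n_phenomic=40, phenomic_rate_per_my=0.0,
                              phenomic_p_inv=0.0,
                              genes=(GenePartition("H3", 30, "JC", 0.0, alpha=None),))
        t = simulate_tree(cfg)
        m = simulate_characters(t, cfg)
        assert all(c == "invariant" for c in classify_characters(m))

    def test_long_branches_reach_stationarity(self):
        cfg = _pure_birth_cfg(
            8, seed=6, n_phenomic=600, phenomic_rate_per_my=0.5,
            phenomic_alpha=None, phenomic_p_inv=0.0,
            phenomic_state_counts=(2,), phenomic_state_weights=(1.0,),
            genes=(),
        )
        t = simulate_tree(cfg)
        m = simulate_characters(t, cfg)
        states = [
            next(iter(m.cells[i][j].states))
            for i in range(m.n_taxa) for j in range(m.n_characters)
        ]
        assert abs(np.mean(states) - 0.5) < 0.05

    def test_constant_fraction_matches_closed_form(self):
        tree = PhyloTree.from_newick("((a:30,b:50):20,(c:40,d:25):35);")
        rate = 0.01
        cfg = _pure_birth_cfg(
            4, seed=7, n_phenomic=4000, phenomic_rate_per_my=rate,
            phenomic_alpha=None, phenomic_p_inv=0.0,
            phenomic_state_counts=(2,), phenomic_state_weights=(1.0,), genes=(),
        )
        m = simulate_characters(tree, cfg, np.random.default_rng(7))
        observed = np.mean([c == "invariant" for c in classify_characters(m)])
        scaled = tree.copy()
        for node in scaled.postorder():
            if node.length is not None:
                node.length *= rate
        expected = constant_site_probability(scaled, SubstitutionModel(family="Mk", k=2))
        se = np.sqrt(expected * (1 - expected) / 4000)
        assert abs(observed - expected) < 5 * se

    def test_variable_only_filtering(self):
        cfg = _pure_birth_cfg(6, seed=8, n_phenomic=60, genes=())
        t = simulate_tree(cfg)
        m = simulate_characters(t, cfg, variable_only=True)
        assert all(c != "invariant" for c in classify_characters(m))


class TestInjectMissing:
    def _matrix(self, seed=0):
        cfg = _pure_birth_cfg(5, seed=seed, n_phenomic=339, genes=())
        t = simulate_tree(cfg)
        return simulate_characters(t, cfg)

    def test_fraction_zero_unchanged(self):
        m = self._matrix()
        m2 = inject_missing(m, {t: 0.0 for t in m.taxa}, seed=1)
        assert m2 == m

    def test_binomial_mean_masking(self):
        m = self._matrix()
        masked_counts = []
        for s in range(10):
            m2 = inject_missing(m, {m.taxa[0]: 0.8}, seed=s)
            masked_counts.append(
                sum(m2.cells[0][j].kind == "missing" for j in range(339))
            )
        # expectation 0.8 * 339 = 271.2, sd ~ 7.4; mean of 10 draws is tight
        assert abs(np.mean(masked_counts) - 271.2) < 12

    def test_fossil_molecular_always_missing(self):
        cfg = _pure_birth_cfg(5, seed=3, n_phenomic=10,
                              genes=(GenePartition("H3", 20, "JC", 0.001, alpha=None),))
        t = simulate_tree(cfg)
        m = simulate_characters(t, cfg)
        fossil = m.taxa[2]
        m2 = inject_missing(m, {}, fossil_taxa=[fossil],
                            molecular_partitions=["H3"], seed=0)
        for j in m2.partition_indices("H3"):
            assert m2.cell(fossil, j).kind == "missing"
        assert any(m2.cell(m.taxa[0], j).kind != "missing"
                   for j in m2.partition_indices("H3"))


class TestStudyLikeBundle:
    def test_shape(self):
        b = make_study_like_dataset(seed=11)
        assert b.matrix.n_taxa == 63
        assert b.matrix.n_characters == 1819
        assert len(b.fossils) == 7 and len(b.extant) == 56
        mol = [j for j, ch in enumerate(b.matrix.characters)
               if ch.partition != "phenomic"]
        assert len(mol) == 1480
        assert set(b.matrix.partition_names()) == {"phenomic", "H3", "NAK", "PEPCK"}

    def test_determinism(self):
        b1 = make_study_like_dataset(seed=11)
        b2 = make_study_like_dataset(seed=11)
        assert b1.tree.to_newick() == b2.tree.to_newick()
        assert b1.matrix == b2.matrix
        assert {t: r.fad for t, r in b1.ages.items()} == \
            {t: r.fad for t, r in b2.ages.items()}

    def test_fossils_morphology_only(self):
        b = make_study_like_dataset(seed=11)
        mol = [j for j, ch in enumerate(b.matrix.characters)
               if ch.partition != "phenomic"]
        for f in b.fossils:
            assert all(b.matrix.cell(f, j).kind == "missing" for j in mol)

    def test_ghost_lineage_soundness(self):
        b = make_study_like_dataset(seed=11)
        ann = propagate_min_ages(b.tree, b.ages)
        for node in ann.tree.postorder():
            if node.is_leaf:
                continue
            key = "|".join(sorted(l.name for l in subtree_leaves(node)))
            assert ann.min_age(node) <= b.node_ages[key] + 1e-6


def test_true_params_beat_perturbed_on_average(rng):
    """Average log-likelihood advantage of the generating rate over a 2x
    perturbed rate across simulated datasets (scaled down: 20 seeds, 300
    sites, 4 taxa)."""
    from paleophylo.mk import variable_coding_loglik
    from paleophylo.simulate import _evolve_block
    from paleophylo.matrix import CharacterDef, CharacterMatrix, ObservedStates

    tree = PhyloTree.from_newick("((a:0.2,b:0.35):0.15,(c:0.25,d:0.4):0.1);")
    model_true = SubstitutionModel(family="Mk", k=2)
    diffs = []
    for seed in range(20):
        r = np.random.default_rng(seed)
        data = _evolve_block(tree, model_true, 1.0, 300, r)
        taxa = [l.name for l in tree.leaves()]
        chars = [CharacterDef(j, f"c{j}", 2, "phenomic") for j in range(300)]
        cells = [[ObservedStates.determinate(int(s)) for s in row] for row in data]
        m = CharacterMatrix(taxa, chars, cells)
        scaled = tree.copy()
        for node in scaled.postorder():
            if node.length is not None:
                node.length *= 2.0
        ll_true = variable_coding_loglik(tree, m, model_true)
        ll_pert = variable_coding_loglik(scaled, m, model_true)
        diffs.append(ll_true - ll_pert)
    assert np.mean(diffs) > 0
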