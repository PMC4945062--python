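"""Mk/GTR-family likelihood: closed forms, discretization, pruning, and the
variable-coding ascertainment correction."""

import itertools

import numpy as np
import pytest
from scipy import integrate
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from paleophylo.matrix import CharacterDef, CharacterMatrix, ObservedStates
from paleophylo.mk import (
    SubstitutionModel,
    constant_site_probability,
    discretize_gamma,
    enumerate_site_likelihood,
    mk_transition_prob,
    site_likelihood,
    site_log_likelihood,
    variable_coding_loglik,
)
from paleophylo.trees import PhyloTree, random_topology

from conftest import matrix_from_rows


def _random_lengths(tree, rng, scale=0.5):
    for node in tree.postorder():
        if node.parent is not None:
            node.length = float(rng.uniform(0.05, scale))
    return tree


class TestMkTransition:
    def test_t0_identity(self):
        assert np.allclose(mk_transition_prob(3, 0.0), np.eye(3))

    def test_stationary_limit(self):
        P = mk_transition_prob(4, 1e4)
        assert np.allclose(P, 0.25)

    @pytest.mark.parametrize("k,t", [(2, 0.5), (3, 0.1), (5, 2.0)])
    def test_matches_matrix_exponential(self, k, t):
        m = SubstitutionModel(family="Mk", k=k)
        assert np.allclose(mk_transition_prob(k, t), expm(m.rate_matrix() * t))

    def test_rows_sum_to_one(self):
        assert np.allclose(mk_transition_prob(4, 0.3).sum(axis=1), 1.0)

    def test_k1_rejected(self):
        with pytest.raises(ValueError):
            mk_transition_prob(1, 0.1)


class TestRateMatrices:
    @pytest.mark.parametrize("family,kw", [
        ("HKY", dict(kappa=3.0, freqs=[0.4, 0.3, 0.2, 0.1])),
        ("GTR", dict(exchangeabilities=[1, 2, 3, 4, 5, 6],
                     freqs=[0.1, 0.2, 0.3, 0.4])),
        ("SYM", dict(exchangeabilities=[1, 2, 3, 4, 5, 6])),
    ])
    def test_normalized_and_balanced(self, family, kw):
        q = SubstitutionModel(family=family, **kw).rate_matrix()
        assert np.allclose(q.sum(axis=1), 0.0)
        pi = np.asarray(SubstitutionModel(family=family, **kw).freqs)
        assert np.isclose(-(pi * np.diag(q)).sum(), 1.0)
        # detailed balance (reversibility)
        assert np.allclose(pi[:, None] * q, (pi[:, None] * q).T)


class TestGammaDiscretization:
    def test_single_category(self):
        assert discretize_gamma(0.7, 1).tolist() == [1.0]

    def test_large_alpha_limit(self):
        assert np.allclose(discretize_gamma(1e4, 4), 1.0, atol=0.05)

    def test_mean_one(self):
        for a in (0.2, 0.5, 1.0, 5.0):
            assert np.isclose(discretize_gamma(a, 4).mean(), 1.0)

    def test_matches_quadrature(self):
        a, n = 0.5, 4
        rates = discretize_gamma(a, n)
        qs = gamma_dist.ppf(np.arange(n + 1) / n, a=a, scale=1 / a)
        qs[-1] = np.inf
        for i in range(n):
            val, _ = integrate.quad(
                lambda x: x * gamma_dist.pdf(x, a=a, scale=1 / a),
                qs[i], min(qs[i + 1], 1e3),
            )
            assert np.isclose(rates[i], val * n, atol=1e-5)


class TestSiteLikelihood:
    def test_single_leaf(self):
        t = PhyloTree.from_newick("a;")
        model = SubstitutionModel(family="Mk", k=3)
        assert np.isclose(site_log_likelihood(t, [frozenset([1])], model),
                          np.log(1 / 3))

    def test_all_missing_marginalizes_to_one(self):
        t = PhyloTree.from_newick("((a:0.1,b:0.2):0.1,c:0.3);")
        model = SubstitutionModel(family="Mk", k=2)
        assert np.isclose(site_log_likelihood(t, [None, None, None], model), 0.0)

    def test_negative_branch_rejected(self):
        t = PhyloTree.from_newick("((a:0.1,b:-0.2):0.1,c:0.3);")
        model = SubstitutionModel(family="Mk", k=2)
        with pytest.raises(ValueError):
            site_likelihood(t, [frozenset([0])] * 3, model)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 6))
            tree = _random_lengths(
                random_topology([f"t{i}" for i in range(n)], rng), rng
            )
            fam = ["Mk", "HKY", "GTR"][int(rng.integers(3))]
            kw = {}
            if fam == "Mk":
                kw["k"] = int(rng.integers(2, 4))
            if rng.random() < 0.5:
                kw["alpha"] = float(rng.uniform(0.3, 2.0))
            if fam != "Mk" and rng.random() < 0.5:
                kw["p_inv"] = 0.2
            model = SubstitutionModel(family=fam, **kw)
            col = [
                None if rng.random() < 0.2 else frozenset([int(rng.integers(model.k))])
                for _ in range(n)
            ]
            assert np.isclose(
                site_likelihood(tree, col, model),
                enumerate_site_likelihood(tree, col, model),
                rtol=1e-10,
            )

    def test_sums_to_one_over_all_columns(self, rng):
        for k, L in [(2, 4), (3, 3)]:
            tree = _random_lengths(
                random_topology([f"t{i}" for i in range(L)], rng), rng
            )
            model = SubstitutionModel(family="Mk", k=k, alpha=0.8)
            total = sum(
                site_likelihood(tree, [frozenset([s]) for s in combo], model)
                for combo in itertools.product(range(k), repeat=L)
            )
            assert np.isclose(total, 1.0)

    def test_reroot_invariance(self, rng):
        tree = _random_lengths(random_topology(list("abcde"), rng), rng)
        model = SubstitutionModel(family="Mk", k=2, alpha=0.5)
        col = [frozenset([int(rng.integers(2))]) for _ in range(5)]
        base = site_likelihood(tree, col, model)
        dt = tree.to_dendropy()
        edges = [e for e in dt.preorder_edge_iter()
                 if e.head_node.parent_node not in (None, dt.seed_node)]
        dt.reroot_at_edge(edges[2], length1=edges[2].length / 2,
                          length2=edges[2].length / 2)
        t2 = PhyloTree._from_dendropy(dt)
        col2 = [col[tree.leaf_names().index(n)] for n in t2.leaf_names()]
        assert np.isclose(site_likelihood(t2, col2, model), base)


class TestVariableCoding:
    def _star(self, lengths):
        nwk = "(" + ",".join(f"t{i}:{b}" for i, b in enumerate(lengths)) + ");"
        return PhyloTree.from_newick(nwk)

    def test_star_tree_closed_form(self):
        """On a star tree, P(constant) = sum_s sum_root pi_root prod_l P(root->s)."""
        lengths = [0.2, 0.4, 0.3, 0.6]
        tree = self._star(lengths)
        model = SubstitutionModel(family="Mk", k=3)
        P = [mk_transition_prob(3, b) for b in lengths]
        closed = sum(
            sum((1 / 3) * np.prod([p[r, s] for p in P]) for r in range(3))
            for s in range(3)
        )
        assert np.isclose(constant_site_probability(tree, model), closed)

    def test_zero_branches_send_variable_loglik_to_minus_inf(self):
        tree = self._star([1e-9, 1e-9, 1e-9])
        m = matrix_from_rows({"t0": "0", "t1": "1", "t2": "2"})
        m.characters[0].state_count = 3
        model = SubstitutionModel(family="Mk", k=3, conditioning="variable")
        ll = variable_coding_loglik(tree, m, model)
        assert ll < -10

    def test_conditioning_raises_per_site_loglik(self):
        tree = self._star([0.3, 0.5, 0.4])
        m = matrix_from_rows({"t0": "01", "t1": "10", "t2": "11"})
        plain = variable_coding_loglik(
            tree, m, SubstitutionModel(family="Mk", k=2, conditioning="none")
        )
        cond = variable_coding_loglik(
            tree, m, SubstitutionModel(family="Mk", k=2, conditioning="variable")
        )
        assert cond > plain

    def test_invariant_characters_rejected_under_variable(self):
        tree = self._star([0.3, 0.5, 0.4])
        m = matrix_from_rows({"t0": "00", "t1": "10", "t2": "10"})
        model = SubstitutionModel(family="Mk", k=2, conditioning="variable")
        with pytest.raises(ValueError, match="invariant"):
            variable_coding_loglik(tree, m, model)


def test_ml_branch_length_recovery(rng):
    """MLE of a single branch length on 2,000 simulated Mk characters lands
    within 15% of the truth."""
    from scipy.optimize import minimize_scalar

    from paleophylo.simulate import _evolve_block

    true_t = 0.3
    tree = PhyloTree.from_newick(f"(a:{true_t / 2},b:{true_t / 2});")
    model = SubstitutionModel(family="Mk", k=2)
    data = _evolve_block(tree, model, 1.0, 2000, rng)
    n_diff = int((data[0] != data[1]).sum())

    def nll(t):
        if t <= 0:
            return 1e9
        p_diff = mk_transition_prob(2, t)[0, 1]
        return -(n_diff * np.log(p_diff) + (2000 - n_diff) * np.log(1 - p_diff))

    res = minimize_scalar(nll, bounds=(1e-4, 5), method="bounded")
    assert abs(res.x - true_t) / true_t < 0.15
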