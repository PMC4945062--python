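"""Likelihood evaluation for discrete characters on fixed trees.

Supports the Mk family (k states, equal rates and frequencies; closed-form
transition probabilities) for morphology and the usual reversible DNA
families (JC, HKY, SYM, GTR) for gene partitions, each optionally with a
proportion of invariable sites (+I) and discrete-gamma rate variation (+G).
The "variable" conditioning divides each site likelihood by the probability
that a site is non-constant, the ascertainment correction appropriate for
matrices from which invariant characters were never recorded.

No tree or parameter optimization lives here (out of scope); the module
exists so the models used alongside parsimony are evaluable and testable,
and to back the synthetic-data generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .matrix import CharacterMatrix
from .trees import Node, PhyloTree

FAMILIES = ("Mk", "JC", "HKY", "SYM", "GTR")


@dataclass
class SubstitutionModel:
    """A reversible substitution model with optional +I and +G mixtures.

    exchangeabilities: upper-triangle rates in the order (AC, AG, AT, CG,
    CT, GT) for k = 4; ignored for Mk/JC.  kappa: HKY transition/transversion
    ratio.  The rate matrix is normalized to one expected substitution per
    unit branch length at stationarity.
    """

    family: str = "Mk"
    k: int = 2
    freqs: Optional[Sequence[float]] = None
    exchangeabilities: Optional[Sequence[float]] = None
    kappa: float = 2.0
    p_inv: float = 0.0
    alpha: Optional[float] = None  # gamma shape; None = no rate variation
    n_cat: int = 4
    conditioning: str = "none"  # none | variable

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in ("JC", "HKY", "SYM", "GTR"):
            self.k = 4
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0 <= self.p_inv < 1:
            raise ValueError("p_inv must be in [0, 1)")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("gamma shape must be positive")
        if self.conditioning not in ("none", "variable"):
            raise ValueError(f"unknown conditioning {self.conditioning!r}")
        if self.freqs is None or self.family in ("Mk", "JC", "SYM"):
            self.freqs = [1.0 / self.k] * self.k
        total = float(sum(self.freqs))
        self.freqs = [f / total for f in self.freqs]

    # ------------------------------------------------------------------ #
    def rate_matrix(self) -> np.ndarray:
        """Normalized instantaneous rate matrix Q (rows sum to 0, mean rate 1)."""
        k = self.k
        pi = np.asarray(self.freqs, dtype=float)
        if self.family in ("Mk", "JC"):
            s = np.ones((k, k))
        elif self.family in ("SYM", "GTR"):
            s = np.ones((k, k))
            if self.exchangeabilities is not None:
                vals = list(self.exchangeabilities)
                if len(vals) != k * (k - 1) // 2:
                    raise ValueError("need k(k-1)/2 exchangeabilities")
                iu = np.triu_indices(k, 1)
                s[iu] = vals
                s[(iu[1], iu[0])] = vals
        elif self.family == "HKY":
            s = np.ones((4, 4))
            # transitions: A<->G (0,2), C<->T (1,3)
            s[0, 2] = s[2, 0] = self.kappa
            s[1, 3] = s[3, 1] = self.kappa
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_rate = -(pi * np.diag(q)).sum()
        return q / mean_rate

    def transition_probs(self, t: float) -> np.ndarray:
        """P(t) for one unit-rate branch of length t."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        if self.family in ("Mk", "JC"):
            return mk_transition_prob(self.k, t)
        from scipy.linalg import expm

        return expm(self.rate_matrix() * t)

    def rate_categories(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the across-site rate mixture (+G and +I)."""
        if self.alpha is None:
            rates = np.array([1.0])
            weights = np.array([1.0])
        else:
            rates = discretize_gamma(self.alpha, self.n_cat)
            weights = np.full(self.n_cat, 1.0 / self.n_cat)
        if self.p_inv > 0:
            rates = np.concatenate([[0.0], rates])
            weights = np.concatenate([[self.p_inv], (1 - self.p_inv) * weights])
        return rates, weights


def mk_transition_prob(k: int, t: float) -> np.ndarray:
    """Closed-form Mk transition matrix for a unit-mean-rate branch of length t.

    P_ii = 1/k + (k-1)/k * exp(-k t / (k-1));  P_ij = 1/k - 1/k * exp(-k t / (k-1)).
    """
    if k < 2:
        raise ValueError("Mk requires k >= 2")
    if t < 0:
        raise ValueError("branch length must be non-negative")
    e = np.exp(-k * t / (k - 1))
    p = np.full((k, k), (1.0 - e) / k)
    np.fill_diagonal(p, 1.0 / k + (k - 1) / k * e)
    return p


def discretize_gamma(alpha: float, n_cat: int) -> np.ndarray:
    """Mean-of-equal-probability-bins discretization of a mean-1 gamma.

    Category i's rate is the mean of the gamma(alpha, 1/alpha) distribution
    between quantiles i/n and (i+1)/n; the rates average exactly 1.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if n_cat < 1:
        raise ValueError("n_cat must be >= 1")
    if n_cat == 1:
        return np.array([1.0])
    probs = np.arange(1, n_cat) / n_cat
    cuts = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    # E[X | bin] via the incomplete-gamma identity with shape alpha + 1
    upper = np.concatenate([gammainc(alpha + 1, cuts * alpha), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1, cuts * alpha)])
    return (upper - lower) * n_cat


# ---------------------------------------------------------------------- #
# pruning
# ---------------------------------------------------------------------- #
def _column_partials(column: Sequence[Optional[frozenset]], k: int) -> list[np.ndarray]:
    """Leaf partial vectors from a column of observed state sets (None = missing)."""
    out = []
    for obs in column:
        v = np.zeros(k)
        if obs is None:
            v[:] = 1.0
        else:
            for s in obs:
                v[s] = 1.0
        out.append(v)
    return out


def _prune(tree: PhyloTree, leaf_partials: list[np.ndarray], P_of) -> np.ndarray:
    """One pruning pass; returns the root partial vector.

    P_of(node) must give the transition matrix for the branch above `node`.
    """
    partial: dict[int, np.ndarray] = {}
    leaf_i = 0
    for node in tree.postorder():
        if node.is_leaf:
            p = leaf_partials[leaf_i]
            leaf_i += 1
        else:
            p = np.ones(len(leaf_partials[0]))
            for c in node.children:
                child_partial = partial.pop(id(c))
                p = p * (P_of(c) @ child_partial)
        partial[id(node)] = p
    return partial[id(tree.root)]


def site_likelihood(
    tree: PhyloTree,
    column: Sequence[Optional[frozenset]],
    model: SubstitutionModel,
) -> float:
    """Likelihood of one site column (leaf order = tree leaf order).

    Column entries are observed state sets; None marginalizes over all states.
    The +G/+I rate mixture is averaged; branch lengths are expected
    substitutions per site at rate 1.
    """
    for node in tree.postorder():
        if node.parent is not None and (node.length is None or node.length < 0):
            raise ValueError("every non-root branch needs a non-negative length")
    leaf_partials = _column_partials(column, model.k)
    pi = np.asarray(model.freqs)
    rates, weights = model.rate_categories()
    total = 0.0
    for rate, w in zip(rates, weights):
        cache: dict[float, np.ndarray] = {}

        def P_of(node: Node, _rate=rate, _cache=cache):
            t = node.length * _rate
            if t not in _cache:
                _cache[t] = model.transition_probs(t)
            return _cache[t]

        root_partial = _prune(tree, leaf_partials, P_of)
        total += w * float(pi @ root_partial)
    return total


def site_log_likelihood(tree, column, model) -> float:
    return float(np.log(site_likelihood(tree, column, model)))


def constant_site_probability(tree: PhyloTree, model: SubstitutionModel) -> float:
    """Probability that a site is constant: sum over states s of the
    likelihood of the all-s column."""
    n = len(tree.leaves())
    total = 0.0
    for s in range(model.k):
        col = [frozenset([s])] * n
        total += site_likelihood(tree, col, model)
    return total


def variable_coding_loglik(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    model: SubstitutionModel,
    characters: Optional[Sequence[int]] = None,
) -> float:
    """Total log-likelihood of a partition.

    With conditioning = "variable", each site's likelihood is divided by
    (1 - P(constant)), the ascertainment correction for matrices that record
    only variable characters; such partitions must not contain invariant-coded
    characters.
    """
    from .matrix import classify_characters

    chars = list(characters) if characters is not None else list(range(matrix.n_characters))
    if model.conditioning == "variable":
        classes = classify_characters(matrix)
        bad = [j for j in chars if classes[j] == "invariant"]
        if bad:
            raise ValueError(
                f"conditioning='variable' forbids invariant-coded characters: {bad[:5]}"
            )
    total = 0.0
    leaves = tree.leaves()
    correction_cache: dict[int, float] = {}
    for j in chars:
        k = matrix.characters[j].state_count
        if k != model.k:
            raise ValueError(
                f"character {j} has {k} states but the model has {model.k}"
            )
        column = []
        for leaf in leaves:
            cell = matrix.cell(leaf.name, j)
            column.append(None if cell.is_blank else cell.states)
        lik = site_likelihood(tree, column, model)
        if model.conditioning == "variable":
            if k not in correction_cache:
                correction_cache[k] = constant_site_probability(tree, model)
            denom = 1.0 - correction_cache[k]
            if denom <= 0:
                raise FloatingPointError(
                    f"variable-coding correction denominator <= 0 "
                    f"(P(constant) = {correction_cache[k]:.6g}); branch lengths "
                    f"may be degenerate for this {model.family} model"
                )
            lik = lik / denom
        if lik <= 0:
            return float("-inf")
        total += float(np.log(lik))
    return total


# ---------------------------------------------------------------------- #
# brute-force oracle (shared with the test suite)
# ---------------------------------------------------------------------- #
def enumerate_site_likelihood(
    tree: PhyloTree,
    column: Sequence[Optional[frozenset]],
    model: SubstitutionModel,
) -> float:
    """Site likelihood by summing over all internal-node labelings (tiny trees)."""
    import itertools

    order = list(tree.postorder())
    internal = [n for n in order if not n.is_leaf]
    leaves = [n for n in order if n.is_leaf]
    pi = np.asarray(model.freqs)
    rates, weights = model.rate_categories()
    total = 0.0
    for rate, w in zip(rates, weights):
        Ps = {id(n): model.transition_probs(n.length * rate) for n in order
              if n.parent is not None}
        rate_total = 0.0
        for lab in itertools.product(range(model.k), repeat=len(internal)):
            assign = {id(n): s for n, s in zip(internal, lab)}
            p = pi[assign[id(tree.root)]]
            for n in internal:
                if n.parent is not None:
                    p *= Ps[id(n)][assign[id(n.parent)], assign[id(n)]]
            for leaf, obs in zip(leaves, column):
                states = range(model.k) if obs is None else obs
                p *= sum(Ps[id(leaf)][assign[id(leaf.parent)], s] for s in states)
            rate_total += p
        total += w * rate_total
    return total
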