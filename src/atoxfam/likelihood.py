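"""Equal-rates 20-state substitution model and Felsenstein pruning.

The model is the amino-acid analogue of Jukes–Cantor: all exchanges occur
at equal rates and the stationary distribution is uniform (1/20).  With
branch length t in expected substitutions per site,

    P(same)      = 1/20 + (19/20) exp(-(20/19) t)
    P(different) = 1/20 - (1/20)  exp(-(20/19) t)   (per target state)

which is exactly the model under which the Poisson-corrected distance
d = -ln(1 - p) is the expected-substitution estimator: the expected
fraction of differing sites between two sequences separated by d is
(19/20)(1 - exp(-(20/19) d)).

The log-likelihood of an alignment on a tree is computed by Felsenstein's
pruning algorithm with uniform root frequencies; gaps and X are missing
data (all-ones partial likelihood).  Under this time-reversible model the
likelihood is invariant under re-rooting (the pulley principle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .tree import PhyloTree, TreeError

N_STATES = 20


@dataclass(frozen=True)
class PoissonAminoAcidModel:
    """Equal-rates, uniform-frequency 20-state model."""

    n_states: int = N_STATES

    @property
    def frequencies(self) -> np.ndarray:
        return np.full(self.n_states, 1.0 / self.n_states)

    def p_same(self, t: float) -> float:
        k = self.n_states
        return 1.0 / k + (k - 1) / k * math.exp(-k / (k - 1) * t)

    def expected_difference(self, d: float) -> float:
        """Expected differing-site fraction at distance d (closed form)."""
        k = self.n_states
        return (k - 1) / k * (1.0 - math.exp(-k / (k - 1) * d))

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be non-negative")
        k = self.n_states
        e = math.exp(-k / (k - 1) * t)
        off = (1.0 - e) / k
        mat = np.full((k, k), off)
        np.fill_diagonal(mat, 1.0 / k + (k - 1) / k * e)
        return mat


def pruning_log_likelihood(
    tree: PhyloTree, aln: Alignment, model: PoissonAminoAcidModel | None = None
) -> float:
    """Column-wise log-likelihood by Felsenstein's pruning algorithm.

    Tree leaves must match the alignment ids exactly; every non-root node
    needs a branch length.  Gap and X columns contribute all-ones partials
    (missing data).
    """
    model = model or PoissonAminoAcidModel()
    leaf_names = set(tree.leaf_names())
    if leaf_names != set(aln.ids):
        raise TreeError("tree leaves do not match alignment ids")
    mat = aln.to_matrix()
    ncols = aln.ncols
    row_of = {seq_id: k for k, seq_id in enumerate(aln.ids)}

    def partial(node) -> np.ndarray:
        if node.is_leaf:
            states = mat[row_of[node.name]]
            out = np.zeros((ncols, model.n_states))
            known = states < model.n_states
            out[~known, :] = 1.0
            out[known, states[known].astype(int)] = 1.0
            return out
        prod = np.ones((ncols, model.n_states))
        for child in node.children:
            if child.length is None:
                raise TreeError("branch length missing on an internal edge")
            p = model.transition_matrix(child.length)
            prod *= partial(child) @ p.T
        return prod

    root_partial = partial(tree.root)
    site_likelihoods = root_partial @ model.frequencies
    if np.any(site_likelihoods <= 0):
        raise FloatingPointError("zero site likelihood (underflow)")
    return float(np.sum(np.log(site_likelihoods)))
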