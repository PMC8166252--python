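"""Felsenstein pruning for codon alignments and the branch-site (Model A) likelihood.

Two computational routes are provided:

* :func:`site_log_likelihood` — textbook pruning for a single column with
  arbitrary per-branch transition matrices; the reference route used by the
  exhaustive-enumeration tests.
* :class:`PruningEngine` — the production route: site patterns are compressed,
  partials are propagated for all sites at once, and the likelihood is
  factorized around the foreground branch.  One "edge pass" with a background
  model yields the root-side (outside) and tip-side (inside) partial vectors at
  the foreground edge, after which the likelihood under *any* foreground omega
  is a cheap bilinear form.  All branch-site fits exploit this factorization.

Model A has four site classes: class 0 (omega0 <= 1 everywhere), class 1
(neutral everywhere), and classes 2a/2b where the foreground branch switches
to omega2 while the background keeps omega0 (2a) or 1 (2b).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from primsel.codons import MISSING, N_CODONS
from primsel.msa import CodonAlignment
from primsel.ratematrix import CodonSubstitutionModel
from primsel.trees import PhyloTree


@dataclass
class SiteClassMixture:
    """Branch-site Model A parameters.

    ``p0`` and ``p1`` are the proportions of the purifying and neutral classes;
    the positively selected classes have derived proportions
    ``p2a = (1 - p0 - p1) p0 / (p0 + p1)`` and
    ``p2b = (1 - p0 - p1) p1 / (p0 + p1)``.  ``omega1`` is fixed at 1;
    ``omega2 == 1`` gives the null model.
    """

    p0: float
    p1: float
    omega0: float
    omega2: float
    kappa: float
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if not (0 <= self.p0 <= 1 and 0 <= self.p1 <= 1 and self.p0 + self.p1 <= 1 + 1e-12):
            raise ValueError("p0, p1 must lie in [0, 1] with p0 + p1 <= 1")
        if self.p0 + self.p1 <= 0:
            raise ValueError("p0 + p1 must be positive (classes 2a/2b are derived from them)")
        if not 0 <= self.omega0 <= 1:
            raise ValueError("omega0 must lie in [0, 1]")
        if self.omega2 < 1:
            raise ValueError("omega2 must be >= 1 (equal to 1 in the null model)")

    @property
    def p2a(self) -> float:
        return (1 - self.p0 - self.p1) * self.p0 / (self.p0 + self.p1)

    @property
    def p2b(self) -> float:
        return (1 - self.p0 - self.p1) * self.p1 / (self.p0 + self.p1)

    @property
    def proportions(self) -> np.ndarray:
        """Class proportions (p0, p1, p2a, p2b); sums to 1."""
        return np.array([self.p0, self.p1, self.p2a, self.p2b])

    def background_omegas(self) -> tuple[float, float, float, float]:
        """omega per class on background branches."""
        return (self.omega0, 1.0, self.omega0, 1.0)

    def foreground_omegas(self) -> tuple[float, float, float, float]:
        """omega per class on the foreground branch."""
        return (self.omega0, 1.0, self.omega2, self.omega2)


# ---------------------------------------------------------------------------
# reference single-column pruning


def site_log_likelihood(
    tree: PhyloTree,
    column: Sequence[str],
    P_by_taxon_or_node: Mapping,
    pi: np.ndarray,
    taxa: Optional[Sequence[str]] = None,
) -> float:
    """Log-likelihood of one codon column by plain pruning.

    ``column`` holds one codon string per taxon (ordered as ``taxa``, or as
    ``tree.leaf_labels`` when ``taxa`` is omitted); gaps/N/stop codons are
    missing data and contribute all-ones partials.  ``P_by_taxon_or_node``
    maps each non-root node (keyed by ``id(node)``) or leaf label to its
    transition matrix.  A column of entirely missing states has probability 1.
    """
    from primsel.codons import codon_index

    labels = list(taxa) if taxa is not None else tree.leaf_labels
    if len(column) != len(labels):
        raise ValueError("column width does not match the number of taxa")
    states = {lab: codon_index(c) for lab, c in zip(labels, column)}

    def partial(node) -> np.ndarray:
        if node.is_leaf():
            s = states[node.taxon.label]
            vec = np.ones(N_CODONS)
            if s != MISSING:
                vec = np.zeros(N_CODONS)
                vec[s] = 1.0
            return vec
        out = np.ones(N_CODONS)
        for child in node.child_nodes():
            P = _lookup_P(P_by_taxon_or_node, child)
            out = out * (P @ partial(child))
        return out

    root_partial = partial(tree.tree.seed_node)
    return float(np.log(pi @ root_partial))


def _lookup_P(mapping: Mapping, node) -> np.ndarray:
    if id(node) in mapping:
        return mapping[id(node)]
    if node.is_leaf() and node.taxon.label in mapping:
        return mapping[node.taxon.label]
    raise KeyError(f"no transition matrix for node {node}")


# ---------------------------------------------------------------------------
# production engine


@dataclass
class EdgeDecomposition:
    """Likelihood factorized around the foreground edge.

    For each site pattern, ``outside[n, i]`` is the likelihood of all data
    outside the foreground subtree given state ``i`` at the foreground edge's
    parent (root prior folded in), ``inside[n, j]`` the likelihood of the
    foreground subtree given state ``j`` at its head node, and ``log_scale[n]``
    the accumulated scaling.  The per-pattern log-likelihood under a foreground
    transition matrix ``P`` is ``log(outside @ P * inside summed) + log_scale``.
    """

    outside: np.ndarray
    inside: np.ndarray
    log_scale: np.ndarray
    fg_length: float


class PruningEngine:
    """Vectorized pruning over all alignment columns of one gene.

    Site patterns are deduplicated; per-site quantities are expanded back to
    alignment coordinates on return.
    """

    def __init__(self, aln: CodonAlignment, tree: PhyloTree):
        self.tree = tree
        missing = set(tree.leaf_labels) - set(aln.taxa)
        if missing:
            raise ValueError(f"alignment lacks rows for tree leaves: {sorted(missing)}")

        codes = aln.codes()
        row_of = {t: i for i, t in enumerate(aln.taxa)}

        # postorder node arrays
        self.nodes = list(tree.tree.postorder_node_iter())
        self.index = {id(nd): k for k, nd in enumerate(self.nodes)}
        n = len(self.nodes)
        self.parent = np.full(n, -1)
        self.length = np.zeros(n)
        self.children: list[list[int]] = [[] for _ in range(n)]
        leaf_rows: dict[int, int] = {}
        for k, nd in enumerate(self.nodes):
            if nd.parent_node is not None:
                p = self.index[id(nd.parent_node)]
                self.parent[k] = p
                self.children[p].append(k)
                self.length[k] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                leaf_rows[k] = row_of[nd.taxon.label]
        self.leaf_rows = leaf_rows
        self.root = n - 1

        # foreground edge
        self.fg_node: Optional[int] = None
        if tree.foreground is not None:
            fg = tree.foreground_node()
            self.fg_node = self.index[id(fg)]
            if self.fg_node == self.root:
                raise ValueError("foreground branch coincides with the root")

        # pattern compression
        leaf_order = sorted(leaf_rows)
        mat = codes[[leaf_rows[k] for k in leaf_order], :]
        patterns, inverse = np.unique(mat, axis=1, return_inverse=True)
        self.pattern_states = {k: patterns[i] for i, k in enumerate(leaf_order)}
        self.site_to_pattern = np.asarray(inverse).ravel()
        self.n_patterns = patterns.shape[1]
        self.n_sites = mat.shape[1]
        self.weights = np.bincount(self.site_to_pattern, minlength=self.n_patterns).astype(float)

    # -- helpers -----------------------------------------------------------
    def _leaf_contrib(self, P: np.ndarray, node: int) -> np.ndarray:
        """(n_patterns, 61) parent-side contribution of a leaf edge."""
        states = self.pattern_states[node]
        contrib = np.ones((self.n_patterns, N_CODONS))
        obs = states != MISSING
        contrib[obs] = P[:, states[obs]].T
        return contrib

    def _inside_pass(self, P_of, skip: Optional[int] = None):
        """Tipward partials for every internal node, with per-node cumulative scaling.

        ``P_of(node_index)`` returns the transition matrix of the edge above
        that node.  The child ``skip`` (the foreground node) is left out of its
        parent's product when given.  Returns ``(partials, cum_scale)`` where
        ``cum_scale[k]`` is the summed log-scaling of node ``k``'s subtree.
        """
        partials: dict[int, np.ndarray] = {}
        cum_scale: dict[int, np.ndarray] = {}
        for k in range(len(self.nodes)):
            if not self.children[k]:
                continue
            acc = np.ones((self.n_patterns, N_CODONS))
            scale = np.zeros(self.n_patterns)
            for c in self.children[k]:
                if c == skip:
                    continue
                P = P_of(c)
                if c in self.leaf_rows:
                    acc *= self._leaf_contrib(P, c)
                else:
                    acc *= partials[c] @ P.T
                    scale += cum_scale[c]
            mx = acc.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            acc /= mx[:, None]
            partials[k] = acc
            cum_scale[k] = scale + np.log(mx)
        return partials, cum_scale

    def _leaf_indicator(self, node: int) -> np.ndarray:
        states = self.pattern_states[node]
        vec = np.ones((self.n_patterns, N_CODONS))
        obs = states != MISSING
        vec[obs] = 0.0
        vec[obs, states[obs]] = 1.0
        return vec

    def _P_cache(self, model: CodonSubstitutionModel):
        cache = {t: model.P(t) for t in np.unique(self.length)}
        return lambda c: cache[self.length[c]]

    # -- public API --------------------------------------------------------
    def site_logliks(self, model: CodonSubstitutionModel, P_of=None) -> np.ndarray:
        """Per-site log-likelihoods under a single model on every branch."""
        if P_of is None:
            P_of = self._P_cache(model)
        partials, cum_scale = self._inside_pass(P_of)
        lik = partials[self.root] @ model.pi
        per_pattern = np.log(np.maximum(lik, 1e-300)) + cum_scale[self.root]
        return per_pattern[self.site_to_pattern]

    def total_loglik(self, model: CodonSubstitutionModel) -> float:
        return float(self.site_logliks(model).sum())

    def edge_pass(self, bg_model: CodonSubstitutionModel) -> EdgeDecomposition:
        """Factorize the likelihood around the foreground edge.

        All branches except the foreground edge use ``bg_model``.  An outside
        recursion walks from the root down to the foreground edge's parent;
        the foreground subtree's inside vector is computed once.
        """
        if self.fg_node is None:
            raise ValueError("tree has no foreground branch marked")
        P_of = self._P_cache(bg_model)
        partials, cum_scale = self._inside_pass(P_of, skip=self.fg_node)

        # path from root down to the foreground edge's parent
        path = []
        k = int(self.parent[self.fg_node])
        while k != -1:
            path.append(k)
            k = int(self.parent[k])
        path = path[::-1]

        outside = np.tile(bg_model.pi, (self.n_patterns, 1))
        scale_out = np.zeros(self.n_patterns)
        for u, v in zip(path[:-1], path[1:]):
            acc = outside
            for c in self.children[u]:
                if c == v:
                    continue
                P = P_of(c)
                if c in self.leaf_rows:
                    acc = acc * self._leaf_contrib(P, c)
                else:
                    acc = acc * (partials[c] @ P.T)
                    scale_out += cum_scale[c]
            outside = acc @ P_of(v)
            mx = outside.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            outside = outside / mx[:, None]
            scale_out += np.log(mx)

        # siblings of the foreground node: the skip-pass partial of its parent
        # is exactly the normalized product of the non-foreground children
        pf = path[-1]
        outside = outside * partials[pf]
        scale_out += cum_scale[pf]

        # inside vector at the foreground node
        if self.fg_node in self.leaf_rows:
            inside = self._leaf_indicator(self.fg_node)
            scale_in = np.zeros(self.n_patterns)
        else:
            # the skip only affects the fg parent, so this partial is intact
            inside = partials[self.fg_node]
            scale_in = cum_scale[self.fg_node]

        return EdgeDecomposition(outside, inside, scale_out + scale_in, float(self.length[self.fg_node]))

    def fg_site_logliks(self, decomp: EdgeDecomposition, fg_model: CodonSubstitutionModel) -> np.ndarray:
        """Per-site log-likelihoods with an arbitrary model on the foreground edge."""
        P = fg_model.P(decomp.fg_length)
        lik = np.einsum("ni,ij,nj->n", decomp.outside, P, decomp.inside)
        per_pattern = np.log(np.maximum(lik, 1e-300)) + decomp.log_scale
        return per_pattern[self.site_to_pattern]


# ---------------------------------------------------------------------------
# Model A


def model_A_site_components(engine: PruningEngine, mix: SiteClassMixture) -> np.ndarray:
    """Per-site log-likelihood of each Model A class; shape (4, n_sites).

    Classes are ordered (0, 1, 2a, 2b).  Two edge passes (background omega0
    and background 1) supply the components for every foreground omega.
    """
    m0 = CodonSubstitutionModel(mix.kappa, mix.omega0, mix.pi)
    m1 = CodonSubstitutionModel(mix.kappa, 1.0, mix.pi)
    m2 = m1 if mix.omega2 == 1.0 else CodonSubstitutionModel(mix.kappa, mix.omega2, mix.pi)
    pass0 = engine.edge_pass(m0)
    pass1 = engine.edge_pass(m1)
    return np.vstack(
        [
            engine.fg_site_logliks(pass0, m0),
            engine.fg_site_logliks(pass1, m1),
            engine.fg_site_logliks(pass0, m2),
            engine.fg_site_logliks(pass1, m2),
        ]
    )


def model_A_loglik(aln: CodonAlignment, tree: PhyloTree, mix: SiteClassMixture) -> float:
    """Total branch-site Model A log-likelihood on a foreground-marked tree."""
    if tree.foreground is None:
        raise ValueError("Model A requires a foreground-marked tree")
    engine = PruningEngine(aln, tree)
    comps = model_A_site_components(engine, mix)
    return float(mixture_loglik(comps, mix.proportions))


def mixture_loglik(class_logliks: np.ndarray, proportions: np.ndarray) -> float:
    """Sum over sites of log sum_k p_k exp(l_k); zero-proportion classes drop out."""
    props = np.asarray(proportions, dtype=float)
    keep = props > 0
    lse = logsumexp(class_logliks[keep], axis=0, b=props[keep, None])
    return float(lse.sum())
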