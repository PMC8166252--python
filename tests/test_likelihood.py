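"""Pruning likelihoods against exhaustive ancestral-state enumeration."""

import itertools

import numpy as np
import pytest

from primsel.codons import SENSE_CODONS, codon_index
from primsel.likelihood import (
    PruningEngine,
    SiteClassMixture,
    mixture_loglik,
    model_A_loglik,
    model_A_site_components,
    site_log_likelihood,
)
from primsel.msa import CodonAlignment
from primsel.ratematrix import CodonSubstitutionModel
from primsel.simulate import SimulationConfig, simulate_codon_alignment
from primsel.trees import PhyloTree


def _brute_force_column(tree, column, taxa, models_by_node, pi):
    """Sum the joint probability over every internal-state assignment."""
    nodes = list(tree.tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    lab2state = {lab: codon_index(c) for lab, c in zip(taxa, column)}
    total = 0.0
    for assign in itertools.product(range(61), repeat=len(internal)):
        amap = {id(n): s for n, s in zip(internal, assign)}
        p = pi[amap[id(tree.tree.seed_node)]]
        for n in nodes:
            if n.parent_node is None:
                continue
            P = models_by_node[id(n)]
            ps = amap[id(n.parent_node)]
            if n.is_leaf():
                s = lab2state[n.taxon.label]
                p *= 1.0 if s < 0 else P[ps, s]
            else:
                p *= P[ps, amap[id(n)]]
        total += p
    return total


def _P_maps(tree, bg_model, fg_model=None):
    fg = tree.foreground_node() if fg_model is not None else None
    out = {}
    for n in tree.tree.preorder_node_iter():
        if n.parent_node is None:
            continue
        m = fg_model if n is fg else bg_model
        out[id(n)] = m.P(n.edge.length)
    return out


def test_single_leaf_tree_likelihood_is_log_pi(dirichlet_pi):
    tree = PhyloTree.from_newick("A:0.5;")
    ll = site_log_likelihood(tree, ["AAA"], {}, dirichlet_pi)
    assert ll == pytest.approx(np.log(dirichlet_pi[codon_index("AAA")]))


def test_all_missing_column_has_probability_one(toy4_tree, dirichlet_pi):
    m = CodonSubstitutionModel(2.0, 0.5, dirichlet_pi)
    Pmap = _P_maps(toy4_tree, m)
    ll = site_log_likelihood(toy4_tree, ["---", "NNN", "---", "TAA"], Pmap, dirichlet_pi, taxa=list("ABCD"))
    assert ll == pytest.approx(0.0, abs=1e-12)


def test_pruning_matches_exhaustive_enumeration(toy4_tree, dirichlet_pi):
    """Engine and reference pruning agree with brute-force state enumeration."""
    mix = SiteClassMixture(0.5, 0.3, 0.3, 4.0, 2.0, dirichlet_pi)
    aln, _ = simulate_codon_alignment(SimulationConfig(toy4_tree, 3, mix, seed=5))
    m = CodonSubstitutionModel(2.0, 0.7, dirichlet_pi)
    Pmap = _P_maps(toy4_tree, m)
    engine = PruningEngine(aln, toy4_tree)
    ll_engine = engine.site_logliks(m)
    for k in range(aln.width):
        col = aln.column(k + 1)
        ll_ref = site_log_likelihood(toy4_tree, col, Pmap, dirichlet_pi, taxa=aln.taxa)
        ll_brute = np.log(_brute_force_column(toy4_tree, col, aln.taxa, Pmap, dirichlet_pi))
        assert ll_ref == pytest.approx(ll_brute, abs=1e-10)
        assert ll_engine[k] == pytest.approx(ll_brute, abs=1e-10)


def test_model_A_matches_exhaustive_enumeration(toy3_tree, dirichlet_pi):
    """Branch-site mixture log-likelihood vs classes x ancestral-state sums."""
    mix = SiteClassMixture(0.45, 0.35, 0.25, 5.0, 2.0, dirichlet_pi)
    aln, _ = simulate_codon_alignment(SimulationConfig(toy3_tree, 4, mix, seed=9))
    models = {w: CodonSubstitutionModel(2.0, w, dirichlet_pi) for w in (0.25, 1.0, 5.0)}
    omaps = [(0.25, 0.25), (1.0, 1.0), (0.25, 5.0), (1.0, 5.0)]
    ll_brute = 0.0
    for k in range(aln.width):
        col = aln.column(k + 1)
        per_class = [
            _brute_force_column(toy3_tree, col, aln.taxa, _P_maps(toy3_tree, models[bw], models[fw]), dirichlet_pi)
            for bw, fw in omaps
        ]
        ll_brute += np.log(float(np.dot(mix.proportions, per_class)))
    assert model_A_loglik(aln, toy3_tree, mix) == pytest.approx(ll_brute, abs=1e-8)


def test_degenerate_mixture_reduces_to_two_classes(toy3_tree, dirichlet_pi):
    """p2 = 0: Model A equals the plain neutral/purifying two-class mixture."""
    mix = SiteClassMixture(0.6, 0.4 - 1e-12, 0.3, 7.0, 2.0, dirichlet_pi)
    aln, _ = simulate_codon_alignment(SimulationConfig(toy3_tree, 5, mix, seed=3))
    engine = PruningEngine(aln, toy3_tree)
    m0 = CodonSubstitutionModel(2.0, 0.3, dirichlet_pi)
    m1 = CodonSubstitutionModel(2.0, 1.0, dirichlet_pi)
    direct = np.logaddexp(
        np.log(0.6) + engine.site_logliks(m0), np.log(0.4) + engine.site_logliks(m1)
    ).sum()
    assert model_A_loglik(aln, toy3_tree, mix) == pytest.approx(direct, abs=1e-6)


def test_omega2_equal_one_nests_null_inside_alternative(toy3_tree, dirichlet_pi):
    mix_null = SiteClassMixture(0.5, 0.3, 0.4, 1.0, 2.0, dirichlet_pi)
    aln, _ = simulate_codon_alignment(SimulationConfig(toy3_tree, 5, mix_null, seed=4))
    ll = model_A_loglik(aln, toy3_tree, mix_null)
    # identical parameters, omega2 formally free but equal to 1
    comps = model_A_site_components(PruningEngine(aln, toy3_tree), mix_null)
    assert mixture_loglik(comps, mix_null.proportions) == pytest.approx(ll, abs=1e-12)


def test_edge_decomposition_equals_full_pruning(primate_tree, selected_alignment, uniform_pi):
    """Factorizing around the foreground edge leaves the likelihood unchanged."""
    aln, _, _ = selected_alignment
    engine = PruningEngine(aln, primate_tree)
    m = CodonSubstitutionModel(2.0, 0.4, uniform_pi)
    dec = engine.edge_pass(m)
    assert np.abs(engine.fg_site_logliks(dec, m) - engine.site_logliks(m)).max() < 1e-9


def test_likelihood_invariant_to_root_placement(dirichlet_pi):
    """Reversibility: rerooting an unrooted 4-taxon tree preserves lnL."""
    t1 = PhyloTree.from_newick("((A:0.3,B:0.2):0.1,C:0.4,D:0.25);")
    t2 = PhyloTree.from_newick("((C:0.4,D:0.25):0.1,A:0.3,B:0.2);")
    mix = SiteClassMixture(0.5, 0.3, 0.3, 4.0, 2.0, dirichlet_pi)
    aln, _ = simulate_codon_alignment(SimulationConfig(PhyloTree(t1.tree, "A"), 6, mix, seed=12))
    m = CodonSubstitutionModel(2.0, 0.6, dirichlet_pi)
    ll1 = PruningEngine(aln, t1).site_logliks(m).sum()
    ll2 = PruningEngine(aln, t2).site_logliks(m).sum()
    assert ll1 == pytest.approx(ll2, abs=1e-9)


def test_scaling_matches_unscaled_computation_on_short_alignments(toy4_tree, dirichlet_pi):
    """Per-node rescaling never changes lnL beyond round-off."""
    mix = SiteClassMixture(0.5, 0.3, 0.3, 4.0, 2.0, dirichlet_pi)
    aln, _ = simulate_codon_alignment(SimulationConfig(toy4_tree, 8, mix, seed=6))
    m = CodonSubstitutionModel(2.0, 0.5, dirichlet_pi)
    Pmap = _P_maps(toy4_tree, m)
    lls = PruningEngine(aln, toy4_tree).site_logliks(m)
    for k in range(aln.width):
        unscaled = site_log_likelihood(toy4_tree, aln.column(k + 1), Pmap, dirichlet_pi, taxa=aln.taxa)
        assert abs(lls[k] - unscaled) < 1e-9
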