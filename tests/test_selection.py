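"""Gene-level LRTs, BH adjustment, site detection, and the two-method consensus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from primsel.fixtures import site_support_table
from primsel.likelihood import PruningEngine, SiteClassMixture
from primsel.msa import CodonAlignment
from primsel.optimize import fit_branch_site, fit_m0
from primsel.selection import (
    LRTResult,
    absrel_like_branch_test,
    beb_posteriors,
    bh_adjust,
    branch_site_lrt,
    consensus,
    lrt_pvalue,
    meme_like_site_test,
)
from primsel.simulate import SimulationConfig, simulate_codon_alignment
from primsel.trees import PhyloTree


class TestBhAdjust:
    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        # step-up: q_(i) = min_{j>=i} p_(j) * m / j -> all 0.04 here
        qs = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(qs, [0.04, 0.04, 0.04, 0.04])

    def test_sorted_inputs_give_nondecreasing_q(self):
        p = np.sort(np.random.default_rng(0).uniform(size=25))
        qs = bh_adjust(p)
        assert (np.diff(qs) >= -1e-12).all()

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms())
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_permutation_invariance(self, pvals, rnd):
        base = bh_adjust(pvals)
        idx = list(range(len(pvals)))
        rnd.shuffle(idx)
        perm = bh_adjust([pvals[i] for i in idx])
        assert np.allclose([base[i] for i in idx], perm)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestGeneLevelTests:
    def test_null_data_statistic_nonnegative_and_p_valid(self, primate_tree, uniform_pi):
        mix = SiteClassMixture(0.45, 0.45, 0.2, 1.0, 2.0, uniform_pi)
        aln, _ = simulate_codon_alignment(SimulationConfig(primate_tree, 150, mix, seed=41))
        r = branch_site_lrt(aln, primate_tree, gene="g")
        assert r.statistic >= 0.0
        assert 0.0 <= r.p <= 1.0
        assert r.lnL1 >= r.lnL0

    def test_strong_selection_detected_by_both_tests(self, primate_tree, selected_alignment):
        aln, _, _ = selected_alignment
        ra = branch_site_lrt(aln, primate_tree, gene="g")
        rb = absrel_like_branch_test(aln, primate_tree, gene="g", kappa=ra.params["kappa"])
        assert ra.p < 0.05 and rb.p < 0.05
        assert ra.params["omega2"] > 1.0 and rb.params["omega_plus"] > 1.0

    def test_mle_respects_parameter_bounds(self, primate_tree, selected_alignment):
        aln, _, _ = selected_alignment
        r = branch_site_lrt(aln, primate_tree, gene="g")
        p = r.params
        assert 0.0 <= p["omega0"] <= 1.0
        assert p["omega2"] >= 1.0
        assert 0 <= p["p0"] <= 1 and 0 <= p["p1"] <= 1 and p["p0"] + p["p1"] <= 1

    def test_refit_at_truth_never_beats_the_mle(self, primate_tree, selected_alignment, uniform_pi):
        from primsel.likelihood import mixture_loglik, model_A_site_components

        aln, _, mix = selected_alignment
        engine = PruningEngine(aln, primate_tree)
        ll_truth = mixture_loglik(model_A_site_components(engine, mix), mix.proportions)
        fit = fit_branch_site(engine, mix.kappa, uniform_pi)
        assert fit.lnL1 >= ll_truth - 1e-6

    def test_mixture_half_null_distribution_is_conservative(self):
        assert lrt_pvalue(0.0, 1, "mixture_half") == 1.0
        assert lrt_pvalue(3.0, 1, "mixture_half") == pytest.approx(0.5 * lrt_pvalue(3.0, 1, "chi2_1"))


class TestBebPosteriors:
    def test_grid_posterior_matches_direct_summation(self, toy3_tree, dirichlet_pi):
        """Vectorized grid BEB vs an explicit loop over all grid cells (1e-10)."""
        mix = SiteClassMixture(0.5, 0.3, 0.3, 5.0, 2.0, dirichlet_pi)
        aln, _ = simulate_codon_alignment(SimulationConfig(toy3_tree, 6, mix, seed=13))
        n_grid = 4
        beb = beb_posteriors(aln, toy3_tree, mle=mix, n_grid=n_grid)

        # independent direct summation
        from primsel.optimize import _ModelAProfiler

        engine = PruningEngine(aln, toy3_tree)
        prof = _ModelAProfiler(engine, mix.kappa, dirichlet_pi)
        mid = (np.arange(n_grid) + 0.5) / n_grid
        cells = []
        for s in mid:
            for a in mid:
                for w0 in mid:
                    for w2 in 1.0 + 10.0 * mid:
                        w = np.array([s * a, s * (1 - a), (1 - s) * a, (1 - s) * (1 - a)])
                        comp = np.exp(prof.class_components(w0, w2))
                        site_lik = w @ comp
                        pos_lik = w[2:] @ comp[2:]
                        cells.append((np.log(site_lik).sum(), pos_lik / site_lik))
        logliks = np.array([c[0] for c in cells])
        weights = np.exp(logliks - logliks.max())
        weights /= weights.sum()
        direct = np.sum(weights[:, None] * np.array([c[1] for c in cells]), axis=0)
        assert np.abs(beb["beb_posterior"].to_numpy() - direct).max() < 1e-10

    def test_posteriors_separate_true_classes(self, primate_tree, selected_alignment):
        """Mean posterior over simulated class-2 sites exceeds class-0 sites."""
        aln, classes, mix = selected_alignment
        beb = beb_posteriors(aln, primate_tree, mle=mix)
        post = beb["beb_posterior"].to_numpy()
        assert post[classes >= 2].mean() > post[classes == 0].mean()
        assert np.all((post >= 0) & (post <= 1))

    def test_degenerate_grid_rejected(self, toy3_tree, dirichlet_pi):
        mix = SiteClassMixture(0.5, 0.3, 0.3, 5.0, 2.0, dirichlet_pi)
        aln, _ = simulate_codon_alignment(SimulationConfig(toy3_tree, 3, mix, seed=1))
        with pytest.raises(ValueError):
            beb_posteriors(aln, toy3_tree, mle=mix, n_grid=1)


class TestMemeSiteTest:
    def test_invariant_sites_get_p_one(self, primate_tree):
        rows = ["ATGAAAGAT" * 3] * 27
        aln = CodonAlignment(list(primate_tree.leaf_labels), rows)
        res = meme_like_site_test(aln, primate_tree, kappa=2.0)
        assert (res["meme_p"] == 1.0).all()
        assert (res["statistic"] == 0.0).all()

    def test_all_missing_site_noted(self, primate_tree, uniform_pi):
        mix = SiteClassMixture(0.5, 0.4, 0.3, 2.0, 2.0, uniform_pi)
        aln, _ = simulate_codon_alignment(SimulationConfig(primate_tree, 10, mix, seed=15))
        rows = [r[:15] + "---" + r[18:] for r in aln.rows]  # blank column 6
        res = meme_like_site_test(CodonAlignment(aln.taxa, rows), primate_tree, kappa=2.0)
        row = res[res["column"] == 6].iloc[0]
        assert row["meme_p"] == 1.0 and row["note"] == "no data"

    def test_episodic_site_ranks_highly(self, primate_tree, selected_alignment):
        """Simulated class-2 sites are enriched among the smallest p-values."""
        aln, classes, mix = selected_alignment
        res = meme_like_site_test(aln, primate_tree, kappa=mix.kappa)
        p = res["meme_p"].to_numpy()
        top = np.argsort(p)[: max(1, len(p) // 20)]
        assert (classes[top] >= 2).mean() > (classes >= 2).mean()


@pytest.fixture(scope="module")
def small_tree(primate_tree):
    from primsel.trees import prune_tree

    keep = ["Hsap", "Ptro", "Ppan", "Ggor", "Ppyg", "Nleu", "Mmul", "Panu", "Csab", "Cjac", "Anan", "Tsyr"]
    return prune_tree(primate_tree, keep)


class TestBranchReTestCalibration:
    """Size and power of the per-branch random-effects test at reduced scale."""

    def test_empirical_size_under_foreground_neutral_simulation(self, small_tree, uniform_pi):
        mix = SiteClassMixture(0.45, 0.45, 0.2, 1.0, 2.0, uniform_pi)
        rejections = 0
        n = 200
        for i in range(n):
            aln, _ = simulate_codon_alignment(SimulationConfig(small_tree, 150, mix, seed=50_000 + i))
            r = absrel_like_branch_test(aln, small_tree, gene=f"n{i}")
            rejections += r.p < 0.05
        assert rejections / n <= 0.08

    def test_power_under_strong_foreground_selection(self, small_tree, uniform_pi):
        # foreground two-class {omega+ = 10 at weight ~0.2}: simulate with the
        # branch-site generator at matching intensity
        mix = SiteClassMixture(0.55, 0.25, 0.2, 10.0, 2.0, uniform_pi)  # p2 = 0.2
        detected = 0
        n = 20
        for i in range(n):
            aln, _ = simulate_codon_alignment(SimulationConfig(small_tree, 300, mix, seed=60_000 + i))
            r = absrel_like_branch_test(aln, small_tree, gene=f"a{i}")
            detected += r.p < 0.05
        assert detected / n >= 0.5


class TestConsensus:
    def _genes(self, ps):
        return [LRTResult(g, 0.0, 0.0, 0.0, 1, p) for g, p in ps.items()]

    def test_empty_side_gives_empty_consensus(self):
        a = self._genes({"g1": 0.01})
        b = self._genes({"g1": 0.5})
        res = consensus(a, b, {"g1": [3]}, {"g1": [3]})
        assert res.candidate_genes == [] and res.candidate_sites == {}

    def test_consensus_is_an_intersection(self):
        a = self._genes({"g1": 0.001, "g2": 0.01, "g3": 0.2})
        b = self._genes({"g1": 0.02, "g2": 0.3, "g3": 0.01})
        res = consensus(a, b, {"g1": [1, 2, 5]}, {"g1": [2, 5, 9]})
        assert res.candidate_genes == ["g1"]
        assert res.candidate_sites == {"g1": [2, 5]}

    def test_commutative_and_idempotent(self):
        a = self._genes({"g1": 0.001, "g2": 0.2})
        b = self._genes({"g1": 0.01, "g2": 0.01})
        sa, sb = {"g1": [1, 4]}, {"g1": [4, 8]}
        r1 = consensus(a, b, sa, sb)
        r2 = consensus(b, a, sb, sa)
        assert r1.candidate_genes == r2.candidate_genes
        assert r1.candidate_sites == r2.candidate_sites
        r3 = consensus(a, a, sa, sa)
        assert r3.candidate_sites == {"g1": [1, 4]}

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError):
            consensus(self._genes({"g1": 0.01}), self._genes({"g2": 0.01}), {}, {})

    def test_curated_support_table_yields_twelve_sites_in_three_genes(self):
        """Both-method candidate sites from the packaged support table."""
        tab = site_support_table()
        both = tab[tab["beb"] & tab["meme"]]
        assert len(both) == 12
        assert set(both["gene"]) == {"MAMLD1", "PRDM9", "ZNF860"}
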