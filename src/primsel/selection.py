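"""Gene- and site-level tests for episodic positive selection, and their consensus.

Two gene-level tests mirror the two field-standard routes:

* :func:`branch_site_lrt` — the branch-site Model A likelihood-ratio test
  (alternative: omega2 >= 1 free on the foreground branch; null: omega2 = 1),
  p-value from chi-squared with df = 1 by default (a 50:50 mixture of a point
  mass at zero and chi2_1 is available as the conservative boundary option).
* :func:`absrel_like_branch_test` — a simplified per-branch random-effects
  test: the foreground branch carries a two-class omega distribution
  {omega- <= 1 with prob 1-w, omega+ with prob w}, background branches share a
  single free (uncapped) omega; the null caps omega+ at 1.

Site-level evidence comes from Bayes empirical Bayes posteriors under the
alternative branch-site model and from a per-site episodic test; candidate
genes and sites are those supported by both methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from primsel.codons import MISSING
from primsel.likelihood import PruningEngine, SiteClassMixture
from primsel.msa import CodonAlignment
from primsel.optimize import (
    _ModelAProfiler,
    _grid_bracket,
    _refine_1d,
    fit_branch_site,
    fit_m0,
)
from primsel.ratematrix import codon_frequencies
from primsel.trees import PhyloTree


@dataclass
class LRTResult:
    """Outcome of one gene-level likelihood-ratio test."""

    gene: str
    lnL0: float
    lnL1: float
    statistic: float
    df: float
    p: float
    q: Optional[float] = None
    params: Optional[dict] = None

    @classmethod
    def from_lnl(cls, gene: str, lnL0: float, lnL1: float, df: float, null_dist: str, params=None) -> "LRTResult":
        stat = 2.0 * (lnL1 - lnL0)
        if stat < -1e-6:
            raise ValueError(f"negative LRT statistic {stat} for {gene}")
        stat = max(stat, 0.0)
        return cls(gene, lnL0, lnL1, stat, df, lrt_pvalue(stat, df, null_dist), params=params)


@dataclass
class SiteScore:
    """Per-codon evidence for positive selection on the foreground branch."""

    codon_index: int  # 1-based, in the human representative sequence
    beb_posterior: float = np.nan
    meme_p: float = np.nan
    beb_flag: bool = False
    meme_flag: bool = False


def lrt_pvalue(stat: float, df: float, null_dist: str = "chi2_1") -> float:
    """P-value of a (possibly boundary-corrected) likelihood-ratio statistic.

    ``chi2_1`` / ``chi2_2``: plain chi-squared.  ``mixture_half``: 50:50 mix of
    a point mass at 0 and chi2_1 (boundary null for a single constrained
    parameter).  ``chi2_mix_1_2``: equal-weight mix of chi2_1 and chi2_2, the
    approximation used for the per-site episodic test.
    """
    if stat < 0:
        raise ValueError("statistic must be >= 0")
    if null_dist == "chi2_1":
        return float(scipy.stats.chi2.sf(stat, 1))
    if null_dist == "chi2_2":
        return float(scipy.stats.chi2.sf(stat, 2))
    if null_dist == "mixture_half":
        return 1.0 if stat == 0 else float(0.5 * scipy.stats.chi2.sf(stat, 1))
    if null_dist == "chi2_mix_1_2":
        return float(0.5 * scipy.stats.chi2.sf(stat, 1) + 0.5 * scipy.stats.chi2.sf(stat, 2))
    raise ValueError(f"unknown null distribution: {null_dist!r}")


def _prepare(aln: CodonAlignment, tree: PhyloTree, foreground: Optional[str], freqs: str, kappa: Optional[float], fit_scale: bool):
    if foreground is not None:
        tree = PhyloTree(tree.tree, foreground)
    if tree.foreground is None:
        raise ValueError("no foreground branch specified")
    pi = codon_frequencies(aln.codes(), freqs)
    engine = PruningEngine(aln, tree)
    if kappa is None or fit_scale:
        m0 = fit_m0(engine, pi=pi, fit_scale=fit_scale)
        kappa = kappa if kappa is not None else m0.kappa
        if fit_scale and abs(m0.scale - 1.0) > 1e-9:
            engine = PruningEngine(aln, tree.scale_lengths(m0.scale))
    return engine, tree, pi, kappa


def branch_site_lrt(
    aln: CodonAlignment,
    tree: PhyloTree,
    foreground: Optional[str] = None,
    *,
    gene: str = "gene",
    freqs: str = "f3x4",
    null_dist: str = "chi2_1",
    kappa: Optional[float] = None,
    fit_scale: bool = False,
    refine: bool = True,
    refine_kappa: bool = False,
) -> LRTResult:
    """Branch-site LRT for positive selection on the foreground branch."""
    engine, tree, pi, kappa = _prepare(aln, tree, foreground, freqs, kappa, fit_scale)
    fit = fit_branch_site(engine, kappa, pi, refine=refine, refine_kappa=refine_kappa)
    params = {
        "kappa": fit.alt.kappa,
        "p0": fit.alt.p0,
        "p1": fit.alt.p1,
        "omega0": fit.alt.omega0,
        "omega2": fit.alt.omega2,
    }
    return LRTResult.from_lnl(gene, fit.lnL0, fit.lnL1, 1, null_dist, params=params)


# ---------------------------------------------------------------------------
# simplified per-branch random-effects test

_BG_GRID = (0.05, 0.12, 0.25, 0.45, 0.7, 1.0, 1.8)
_WMINUS_GRID = (0.0, 0.1, 0.25, 0.45, 0.7, 1.0)
_WPLUS_GRID = (2.0, 4.0, 8.0, 16.0, 40.0, 120.0)


def _em_two_class(la: np.ndarray, lb: np.ndarray, tol: float = 1e-9, max_iter: int = 200) -> tuple[float, float]:
    """Maximize sum_site log((1-w) e^la + w e^lb) over w in [0, 1].

    The per-site likelihood is linear in w, so the objective is concave and EM
    reaches the global maximum.
    """
    ll, w = _em_two_class_batch(la[None, :], lb[None, :], tol=tol, max_iter=max_iter)
    return float(ll[0]), float(w[0])


def _em_two_class_batch(la: np.ndarray, lb: np.ndarray, tol: float = 1e-6, max_iter: int = 150):
    """Vectorized two-class weight EM over a batch of component pairs.

    ``la``, ``lb`` have shape (batch, n_sites); returns (loglik, w) arrays of
    length batch.
    """
    w = np.full(la.shape[0], 0.3)
    prev = np.full(la.shape[0], -np.inf)
    ll = prev
    for _ in range(max_iter):
        za = la + np.log(np.maximum(1 - w, 1e-300))[:, None]
        zb = lb + np.log(np.maximum(w, 1e-300))[:, None]
        lse = np.logaddexp(za, zb)
        ll = lse.sum(axis=1)
        w = np.exp(zb - lse).mean(axis=1)
        if np.all(ll - prev < tol):
            break
        prev = ll
    return ll, w


def absrel_like_branch_test(
    aln: CodonAlignment,
    tree: PhyloTree,
    foreground: Optional[str] = None,
    *,
    gene: str = "gene",
    freqs: str = "f3x4",
    null_dist: str = "mixture_half",
    kappa: Optional[float] = None,
    fit_scale: bool = False,
    refine: bool = True,
) -> LRTResult:
    """Simplified aBSREL-style test: branch-specific selection pressure.

    Background branches share one free omega (uncapped, allowing pressure to
    differ between foreground and background); the foreground branch carries a
    two-class omega distribution.  The alternative frees omega+ above 1; the
    null caps it at 1.  With w = 0 the alternative collapses to the null and
    the statistic is 0.
    """
    engine, tree, pi, kappa = _prepare(aln, tree, foreground, freqs, kappa, fit_scale)
    prof = _ModelAProfiler(engine, kappa, pi)

    def profile(bg: float, wm: float, wp: float) -> tuple[float, float]:
        return _em_two_class(prof.component(bg, wm), prof.component(bg, wp))

    # one sweep over (bg, omega-, omega+); the null (omega+ <= 1) is the
    # capped subset of the same grid, so both optima come from shared EMs
    wp_all = list(_WMINUS_GRID) + list(_WPLUS_GRID)
    combos = [(wm, wp) for wm in _WMINUS_GRID for wp in wp_all]
    best_alt = (-np.inf, (None, None, None, None))
    best_null = (-np.inf, (None, None, None, None))
    for bg in _BG_GRID:
        la = np.stack([prof.component(bg, wm) for wm, _ in combos])
        lb = np.stack([prof.component(bg, wp) for _, wp in combos])
        ll, w = _em_two_class_batch(la, lb)
        for i, (wm, wp) in enumerate(combos):
            entry = (float(ll[i]), (bg, wm, wp, float(w[i])))
            if entry[0] > best_alt[0]:
                best_alt = entry
            if wp <= 1.0 and entry[0] > best_null[0]:
                best_null = entry
    ll0, (bg0, wm0, wp0, w0) = best_null
    ll1, (bg1, wm1, wp1, w1) = best_alt
    if refine:
        lo, hi = _grid_bracket(_WPLUS_GRID, wp1, wm1, 500.0)
        wp1, ll1 = _refine_1d(lambda w: profile(bg1, wm1, w)[0], wp1, max(lo, 1e-4), hi, 1e-2)
        lo, hi = _grid_bracket(_BG_GRID, bg1, 0.0, 10.0)
        bg1, ll1 = _refine_1d(lambda b: profile(b, wm1, wp1)[0], bg1, max(lo, 1e-4), hi, 1e-3)
        lo, hi = _grid_bracket(_BG_GRID, bg0, 0.0, 10.0)
        bg0, ll0 = _refine_1d(lambda b: profile(b, wm0, wp0)[0], bg0, max(lo, 1e-4), hi, 1e-3)
    ll1 = max(ll1, ll0)
    _, w1 = profile(bg1, wm1, wp1)
    params = {"kappa": kappa, "omega_bg": bg1, "omega_minus": wm1, "omega_plus": wp1, "weight_plus": w1}
    return LRTResult.from_lnl(gene, ll0, ll1, 1, null_dist, params=params)


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# site-level detection


def beb_posteriors(
    aln: CodonAlignment,
    tree: PhyloTree,
    foreground: Optional[str] = None,
    mle: Optional[SiteClassMixture] = None,
    *,
    n_grid: int = 10,
    threshold: float = 0.95,
    freqs: str = "f3x4",
) -> pd.DataFrame:
    """Bayes empirical Bayes posterior that each site is positively selected.

    The mixture parameters are integrated over a uniform grid with equal prior
    mass per cell: ``n_grid`` midpoints per dimension for s = p0 + p1 and
    a = p0 / (p0 + p1) (both on (0, 1)), omega0 on (0, 1) and omega2 on
    (1, 11).  kappa and codon frequencies are fixed at their MLE (from ``mle``
    when given, else an M0 fit).  Returns a per-alignment-column table with the
    posterior of classes 2a+2b and a flag at ``threshold``.
    """
    if n_grid < 2:
        raise ValueError("degenerate grid: n_grid must be >= 2")
    if foreground is not None:
        tree = PhyloTree(tree.tree, foreground)
    pi = mle.pi if mle is not None else codon_frequencies(aln.codes(), freqs)
    engine = PruningEngine(aln, tree)
    if mle is not None:
        kappa = mle.kappa
    else:
        kappa = fit_m0(engine, pi=pi).kappa
    prof = _ModelAProfiler(engine, kappa, pi)

    mid = (np.arange(n_grid) + 0.5) / n_grid
    s_grid, a_grid, w0_grid = mid, mid, mid
    w2_grid = 1.0 + 10.0 * mid

    n = engine.n_sites
    l1 = prof.component(1.0, 1.0)
    f = np.stack([prof.component(w0, w0) for w0 in w0_grid])  # (G, n)
    k = np.stack([prof.component(1.0, w2) for w2 in w2_grid])  # (G, n)
    h = np.stack([[prof.component(w0, w2) for w2 in w2_grid] for w0 in w0_grid])  # (G, G, n)

    s = s_grid[:, None, None, None, None]
    a = a_grid[None, :, None, None, None]
    w = np.stack(
        [
            np.broadcast_to(s * a, (n_grid,) * 4 + (1,)),
            np.broadcast_to(s * (1 - a), (n_grid,) * 4 + (1,)),
            np.broadcast_to((1 - s) * a, (n_grid,) * 4 + (1,)),
            np.broadcast_to((1 - s) * (1 - a), (n_grid,) * 4 + (1,)),
        ]
    )  # (4, S, A, W0, W2, 1)
    comps = np.stack(
        [
            np.broadcast_to(f[None, None, :, None, :], (n_grid,) * 4 + (n,)),
            np.broadcast_to(l1[None, None, None, None, :], (n_grid,) * 4 + (n,)),
            np.broadcast_to(h[None, None, :, :, :], (n_grid,) * 4 + (n,)),
            np.broadcast_to(k[None, None, None, :, :], (n_grid,) * 4 + (n,)),
        ]
    )  # (4, S, A, W0, W2, n)

    logw = np.log(np.maximum(w, 1e-300))
    site_ll = logsumexp(comps + logw, axis=0)  # (S, A, W0, W2, n)
    cell_ll = site_ll.sum(axis=-1)
    cell_logpost = cell_ll - logsumexp(cell_ll)
    pos_ll = logsumexp(comps[2:] + logw[2:], axis=0)  # classes 2a + 2b
    site_pos = np.exp(pos_ll - site_ll)  # P(class 2 | cell, site)
    posterior = np.einsum("sawx,sawxn->n", np.exp(cell_logpost), site_pos)
    posterior = np.clip(posterior, 0.0, 1.0)
    return pd.DataFrame(
        {
            "column": np.arange(1, n + 1),
            "beb_posterior": posterior,
            "flagged": posterior >= threshold,
        }
    )


def meme_like_site_test(
    aln: CodonAlignment,
    tree: PhyloTree,
    foreground: Optional[str] = None,
    *,
    alpha: float = 0.05,
    kappa: Optional[float] = None,
    freqs: str = "f3x4",
    null_dist: str = "chi2_mix_1_2",
    fit_scale: bool = False,
) -> pd.DataFrame:
    """Per-site episodic-selection test on the foreground branch.

    Each site is fit with a shared background/foreground omega- <= 1 and a
    free foreground omega+; the null caps omega+ at 1.  Both omegas are
    profiled on grids (the per-site likelihood under any foreground omega is a
    cheap bilinear form once the background pass is done).  P-values use an
    equal-weight mixture of chi2_1 and chi2_2 as the approximate null.
    Sites with no data get p = 1 and a note.
    """
    engine, tree, pi, kappa = _prepare(aln, tree, foreground, freqs, kappa, fit_scale)
    prof = _ModelAProfiler(engine, kappa, pi)

    wm_grid = np.array([0.0, 0.05, 0.1, 0.2, 0.3, 0.45, 0.6, 0.8, 1.0])
    wp_grid = np.array([1.5, 2.5, 4.0, 7.0, 12.0, 20.0, 40.0, 90.0])
    fg_all = np.concatenate([wm_grid, wp_grid])

    # L[i, j, site]: background omega- = wm_grid[i], foreground omega = fg_all[j]
    L = np.stack([np.stack([prof.component(wm, fg) for fg in fg_all]) for wm in wm_grid])
    null_ll = L[:, : len(wm_grid), :].max(axis=(0, 1))
    alt_ll = L.max(axis=(0, 1))
    stat = np.maximum(2.0 * (alt_ll - null_ll), 0.0)

    mat = np.vstack([engine.pattern_states[k] for k in sorted(engine.leaf_rows)])[:, engine.site_to_pattern]
    no_data = (mat == MISSING).all(axis=0)
    pvals = np.array([lrt_pvalue(s, 1, null_dist) for s in stat])
    pvals[no_data] = 1.0
    stat[no_data] = 0.0
    return pd.DataFrame(
        {
            "column": np.arange(1, engine.n_sites + 1),
            "statistic": stat,
            "meme_p": pvals,
            "flagged": (pvals < alpha) & ~no_data,
            "note": np.where(no_data, "no data", ""),
        }
    )


# ---------------------------------------------------------------------------
# consensus


@dataclass
class ConsensusResult:
    """Genes and sites supported by both detection routes."""

    candidate_genes: list[str]
    candidate_sites: dict[str, list[int]]
    gene_table: pd.DataFrame


def consensus(
    genes_a: Sequence[LRTResult],
    genes_b: Sequence[LRTResult],
    sites_a: Mapping[str, Sequence[int]],
    sites_b: Mapping[str, Sequence[int]],
    alpha: float = 0.05,
) -> ConsensusResult:
    """Intersect the two methods' candidate genes and flagged sites.

    Candidate genes have raw p < alpha in *both* methods (BH-adjusted values,
    when present, are carried along in the gene table); candidate sites are
    the per-gene intersection of BEB-flagged and per-site-test-flagged codons
    within candidate genes.
    """
    ua = {r.gene for r in genes_a}
    ub = {r.gene for r in genes_b}
    if ua != ub:
        raise ValueError(f"gene universes differ between methods: {sorted(ua ^ ub)}")
    a_by_gene = {r.gene: r for r in genes_a}
    b_by_gene = {r.gene: r for r in genes_b}
    rows = []
    genes = []
    for g in sorted(ua):
        ra, rb = a_by_gene[g], b_by_gene[g]
        both = ra.p < alpha and rb.p < alpha
        rows.append(
            {
                "gene": g,
                "p_a": ra.p,
                "q_a": ra.q,
                "p_b": rb.p,
                "q_b": rb.q,
                "consensus": both,
            }
        )
        if both:
            genes.append(g)
    sites = {}
    for g in genes:
        inter = sorted(set(sites_a.get(g, ())) & set(sites_b.get(g, ())))
        if inter:
            sites[g] = inter
    return ConsensusResult(genes, sites, pd.DataFrame(rows))
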