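"""Maximum-likelihood fitting of the codon models.

The one-ratio (M0) model is fit by bounded quasi-Newton optimization over
(log kappa, log omega[, log branch-scale]).  The branch-site Model A fit
exploits the foreground-edge factorization: for a candidate background omega0
a single edge pass yields the likelihood under *every* foreground omega2, and
the mixture proportions (p0, p1) have a closed-form EM because the Model A
proportions factorize as p = (s, 1-s) x (a, 1-a) with s = p0 + p1 and
a = p0 / (p0 + p1).  omega0 is profiled on a grid with a bounded 1-D
refinement, omega2 refined continuously; the null (omega2 = 1) and
alternative fits share all expensive passes, which guarantees
lnL(alt) >= lnL(null) up to the refinement tolerance (enforced exactly by a
final clamp of the shared candidates).

kappa is estimated under M0 and held fixed for the branch-site fit by
default; ``refine_kappa=True`` adds a coordinate-ascent Brent refinement of
kappa under the alternative model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import scipy.optimize

from primsel.likelihood import PruningEngine, SiteClassMixture, EdgeDecomposition
from primsel.msa import CodonAlignment
from primsel.ratematrix import CodonSubstitutionModel, codon_frequencies
from primsel.trees import PhyloTree

OMEGA0_GRID = (0.02, 0.08, 0.2, 0.35, 0.55, 0.8, 1.0)
OMEGA2_GRID = (1.0, 2.0, 4.0, 8.0, 16.0, 40.0, 120.0)
OMEGA2_MAX = 500.0


class FitError(RuntimeError):
    """Optimizer failed to produce a usable fit."""


@dataclass
class M0Result:
    kappa: float
    omega: float
    scale: float
    lnL: float


@dataclass
class BranchSiteFit:
    lnL0: float
    lnL1: float
    null: SiteClassMixture
    alt: SiteClassMixture


def fit_m0(
    aln_or_engine,
    tree: Optional[PhyloTree] = None,
    pi: Optional[np.ndarray] = None,
    *,
    fit_scale: bool = False,
    freqs: str = "f3x4",
) -> M0Result:
    """Fit the one-ratio GY94 model (shared kappa and omega on every branch).

    With ``fit_scale=True`` a global multiplier of all branch lengths is
    estimated jointly (the desk-scale stand-in for per-branch length
    estimation; relative lengths come from the species tree).
    """
    engine = aln_or_engine if isinstance(aln_or_engine, PruningEngine) else PruningEngine(aln_or_engine, tree)
    if pi is None:
        mat = np.vstack([engine.pattern_states[k] for k in sorted(engine.leaf_rows)])
        pi = codon_frequencies(mat[:, engine.site_to_pattern], freqs)

    lengths = np.unique(engine.length)

    def negloglik(x) -> float:
        kappa, omega = np.exp(x[0]), np.exp(x[1])
        s = np.exp(x[2]) if fit_scale else 1.0
        model = CodonSubstitutionModel(kappa, omega, pi)
        cache = {t: model.P(t * s) for t in lengths}
        ll = engine.site_logliks(model, P_of=lambda c: cache[engine.length[c]])
        return -float(ll.sum())

    x0 = [np.log(2.0), np.log(0.3)] + ([0.0] if fit_scale else [])
    bounds = [(np.log(0.05), np.log(50.0)), (np.log(1e-4), np.log(20.0))] + (
        [(np.log(0.01), np.log(100.0))] if fit_scale else []
    )
    res = scipy.optimize.minimize(
        negloglik, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": 200, "ftol": 1e-10}
    )
    if not np.all(np.isfinite(res.x)):
        raise FitError("M0 optimization diverged")
    kappa, omega = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    scale = float(np.exp(res.x[2])) if fit_scale else 1.0
    return M0Result(kappa, omega, scale, -float(res.fun))


# ---------------------------------------------------------------------------
# Model A machinery


def _em_proportions_batch(comps: np.ndarray, starts=((0.85, 0.6), (0.5, 0.9)), tol: float = 1e-6, max_iter: int = 200):
    """Maximize the Model A mixture log-likelihood over (p0, p1) by EM, batched.

    ``comps`` holds per-site class log-likelihoods, shape (C, 4, n_sites) in
    class order (0, 1, 2a, 2b) for C parameter combinations.  The proportions
    factorize as (s*a, s*(1-a), (1-s)*a, (1-s)*(1-a)); the M-step is closed
    form.  Returns (loglik, s, a) arrays of length C, best over starts.
    """
    C, _, n = comps.shape
    best_ll = np.full(C, -np.inf)
    best_s = np.full(C, 0.5)
    best_a = np.full(C, 0.5)
    lo, hi = 1e-9, 1 - 1e-9
    for s0, a0 in starts:
        s = np.full(C, s0)
        a = np.full(C, a0)
        prev = np.full(C, -np.inf)
        ll = prev
        for _ in range(max_iter):
            w = np.stack([s * a, s * (1 - a), (1 - s) * a, (1 - s) * (1 - a)], axis=1)
            z = comps + np.log(np.maximum(w, 1e-300))[:, :, None]
            zmax = z.max(axis=1)
            r = np.exp(z - zmax[:, None, :])
            tot = r.sum(axis=1)
            ll = (zmax + np.log(tot)).sum(axis=1)
            R = (r / tot[:, None, :]).sum(axis=2)
            s = np.clip((R[:, 0] + R[:, 1]) / n, lo, hi)
            a = np.clip((R[:, 0] + R[:, 2]) / n, lo, hi)
            if np.all(ll - prev < tol):
                break
            prev = ll
        better = ll > best_ll
        best_ll = np.where(better, ll, best_ll)
        best_s = np.where(better, s, best_s)
        best_a = np.where(better, a, best_a)
    return best_ll, best_s, best_a


def _em_proportions(comps: np.ndarray, starts=((0.85, 0.6), (0.5, 0.9)), tol: float = 1e-7, max_iter: int = 300):
    """Single-combination Model A proportion EM; returns (loglik, p0, p1)."""
    ll, s, a = _em_proportions_batch(comps[None], starts=starts, tol=tol, max_iter=max_iter)
    return float(ll[0]), float(s[0] * a[0]), float(s[0] * (1 - a[0]))


class _ModelAProfiler:
    """Shared expensive state for Model A fits on one gene.

    Caches one edge pass per background omega and one substitution model per
    omega, so the profile likelihood over (omega0, omega2, p0, p1) costs a
    pass only when omega0 changes.
    """

    def __init__(self, engine: PruningEngine, kappa: float, pi: np.ndarray):
        self.engine = engine
        self.kappa = kappa
        self.pi = pi
        self._models: dict[float, CodonSubstitutionModel] = {}
        self._passes: dict[float, EdgeDecomposition] = {}
        self._fg_logliks: dict[tuple[float, float], np.ndarray] = {}

    def model(self, omega: float) -> CodonSubstitutionModel:
        key = round(float(omega), 12)
        if key not in self._models:
            self._models[key] = CodonSubstitutionModel(self.kappa, key, self.pi)
        return self._models[key]

    def edge_pass(self, bg_omega: float) -> EdgeDecomposition:
        key = round(float(bg_omega), 12)
        if key not in self._passes:
            self._passes[key] = self.engine.edge_pass(self.model(key))
        return self._passes[key]

    def component(self, bg_omega: float, fg_omega: float) -> np.ndarray:
        """Per-site log-likelihood with bg_omega off the foreground branch, fg_omega on it."""
        key = (round(float(bg_omega), 12), round(float(fg_omega), 12))
        if key not in self._fg_logliks:
            self._fg_logliks[key] = self.engine.fg_site_logliks(self.edge_pass(key[0]), self.model(key[1]))
        return self._fg_logliks[key]

    def class_components(self, omega0: float, omega2: float) -> np.ndarray:
        """(4, n_sites) per-site class log-likelihoods at fixed (omega0, omega2)."""
        return np.vstack(
            [
                self.component(omega0, omega0),
                self.component(1.0, 1.0),
                self.component(omega0, omega2),
                self.component(1.0, omega2),
            ]
        )

    def profile(self, omega0: float, omega2: float, start=None):
        """(loglik, p0, p1) maximized over proportions at fixed (omega0, omega2).

        ``start`` optionally warm-starts the EM from a previous (s, a) pair.
        """
        starts = ((0.85, 0.6), (0.5, 0.9)) if start is None else (start,)
        return _em_proportions(self.class_components(omega0, omega2), starts=starts)


def _refine_1d(fun: Callable[[float], float], x0: float, lo: float, hi: float, tol: float) -> tuple[float, float]:
    """Bounded maximization around x0; returns (x*, f(x*)). fun is maximized."""
    res = scipy.optimize.minimize_scalar(
        lambda x: -fun(x), bounds=(lo, hi), method="bounded", options={"xatol": tol, "maxiter": 12}
    )
    fx = -float(res.fun)
    f0 = fun(x0)
    return (float(res.x), fx) if fx > f0 else (x0, f0)


def fit_branch_site(
    engine: PruningEngine,
    kappa: float,
    pi: np.ndarray,
    *,
    omega0_grid=OMEGA0_GRID,
    omega2_grid=OMEGA2_GRID,
    refine: bool = True,
    refine_kappa: bool = False,
) -> BranchSiteFit:
    """Fit null (omega2 = 1) and alternative branch-site models jointly.

    Both models are profiled on the same omega0 grid (with bounded continuous
    refinement), so the alternative search space contains the null optimum and
    the LRT statistic is non-negative by construction.
    """
    prof = _ModelAProfiler(engine, kappa, pi)

    # --- one batched EM over the full (omega0, omega2) grid; the null
    # (omega2 = 1) lives on the same grid, so both optima come from one sweep
    grid2 = [1.0] + [w for w in omega2_grid if w != 1.0]
    combos = [(w0, w2) for w0 in omega0_grid for w2 in grid2]
    comps = np.stack([prof.class_components(w0, w2) for w0, w2 in combos])
    ll, s, a = _em_proportions_batch(comps)

    null_idx = [i for i, (_, w2) in enumerate(combos) if w2 == 1.0]
    i0 = max(null_idx, key=lambda i: ll[i])
    w0_0, _ = combos[i0]
    ll0, start0 = float(ll[i0]), (float(s[i0]), float(a[i0]))
    i1 = int(np.argmax(ll))
    w0_1, w2_1 = combos[i1]
    ll1, start1 = float(ll[i1]), (float(s[i1]), float(a[i1]))

    if refine:
        lo, hi = _grid_bracket(omega0_grid, w0_0, 0.0, 1.0)
        w0_0, ll0 = _refine_1d(lambda w: prof.profile(w, 1.0, start=start0)[0], w0_0, lo, hi, 5e-3)
        lo, hi = _grid_bracket(omega2_grid, w2_1, 1.0, OMEGA2_MAX)
        w2_1, ll1 = _refine_1d(lambda w: prof.profile(w0_1, w, start=start1)[0], w2_1, max(lo, 1.0), hi, 1e-2)
        lo, hi = _grid_bracket(omega0_grid, w0_1, 0.0, 1.0)
        w0_1, ll1 = _refine_1d(lambda w: prof.profile(w, w2_1, start=start1)[0], w0_1, lo, hi, 5e-3)
    _, p0_0, p1_0 = prof.profile(w0_0, 1.0, start=start0)
    _, p0_1, p1_1 = prof.profile(w0_1, w2_1, start=start1)

    if refine_kappa:
        kappa, ll1, (p0_1, p1_1, w0_1, w2_1) = _refine_kappa_alt(engine, pi, kappa, (p0_1, p1_1, w0_1, w2_1))
        prof = _ModelAProfiler(engine, kappa, pi)
        cand0 = [(prof.profile(w0, 1.0), w0) for w0 in omega0_grid]
        (ll0, p0_0, p1_0), w0_0 = max(cand0, key=lambda t: t[0][0])
        if refine:
            lo, hi = _grid_bracket(omega0_grid, w0_0, 0.0, 1.0)
            w0_0, ll0 = _refine_1d(lambda w: prof.profile(w, 1.0)[0], w0_0, lo, hi, 5e-3)
            _, p0_0, p1_0 = prof.profile(w0_0, 1.0)

    ll1 = max(ll1, ll0)  # nested models: clamp away refinement round-off
    null = SiteClassMixture(p0_0, p1_0, w0_0, 1.0, kappa, pi)
    alt = SiteClassMixture(p0_1, p1_1, w0_1, max(w2_1, 1.0), kappa, pi)
    return BranchSiteFit(ll0, ll1, null, alt)


def _grid_bracket(grid, x: float, lo: float, hi: float) -> tuple[float, float]:
    """Neighbors of x on the grid, clipped to [lo, hi]."""
    g = sorted(set(list(grid) + [lo, hi]))
    i = int(np.argmin([abs(v - x) for v in g]))
    return g[max(i - 1, 0)], g[min(i + 1, len(g) - 1)]


def _refine_kappa_alt(engine, pi, kappa, params):
    """One round of coordinate ascent on kappa under the alternative model."""
    p0, p1, w0, w2 = params

    def ll_at(kap: float):
        prof = _ModelAProfiler(engine, kap, pi)
        ll, q0, q1 = prof.profile(w0, w2)
        return ll, (q0, q1)

    res = scipy.optimize.minimize_scalar(
        lambda k: -ll_at(k)[0], bounds=(kappa * 0.4, kappa * 2.5), method="bounded",
        options={"xatol": kappa * 0.01, "maxiter": 15},
    )
    kap = float(res.x)
    ll, (p0, p1) = ll_at(kap)
    # re-refine omega2 at the new kappa
    prof = _ModelAProfiler(engine, kap, pi)
    lo, hi = _grid_bracket(OMEGA2_GRID, w2, 1.0, OMEGA2_MAX)
    w2, ll = _refine_1d(lambda w: prof.profile(w0, w)[0], w2, lo, hi, 1e-2)
    _, p0, p1 = prof.profile(w0, w2)
    return kap, ll, (p0, p1, w0, w2)


def fit_model(
    aln: CodonAlignment,
    tree: PhyloTree,
    model: str = "alternative",
    options: Optional[dict] = None,
) -> tuple[SiteClassMixture, float]:
    """Fit the null or alternative branch-site model and return (MLE, lnL).

    Options: ``freqs`` ("f3x4" | "f1x4" | "equal"), ``kappa`` (skip the M0
    pre-fit), ``refine`` and ``refine_kappa`` (see :func:`fit_branch_site`),
    ``fit_scale`` (estimate a global branch-length multiplier under M0 and
    keep it for the branch-site fit).
    """
    opts = dict(options or {})
    if model not in ("null", "alternative"):
        raise ValueError("model must be 'null' or 'alternative'")
    freqs = opts.pop("freqs", "f3x4")
    pi = codon_frequencies(aln.codes(), freqs)
    fit_scale = opts.pop("fit_scale", False)
    kappa = opts.pop("kappa", None)
    engine = PruningEngine(aln, tree)
    if kappa is None or fit_scale:
        m0 = fit_m0(engine, pi=pi, fit_scale=fit_scale)
        kappa = kappa if kappa is not None else m0.kappa
        if fit_scale and abs(m0.scale - 1.0) > 1e-9:
            engine = PruningEngine(aln, tree.scale_lengths(m0.scale))
    fit = fit_branch_site(engine, kappa, pi, **opts)
    if model == "null":
        return fit.null, fit.lnL0
    return fit.alt, fit.lnL1
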