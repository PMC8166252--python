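"""GY94-style codon rate matrices and transition probabilities.

The substitution model is the Goldman–Yang codon model: instantaneous rates
between codons differing at a single nucleotide position, proportional to the
target codon frequency, multiplied by the transition/transversion ratio kappa
for transitions and by omega (dN/dS) for non-synonymous changes.  Each matrix
is scaled so the expected number of substitutions per codon per unit time is
one, so branch lengths are in expected substitutions per codon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from primsel.codons import MISSING, N_CODONS, SENSE_CODONS, SINGLE_STEP, SYNONYMOUS, TRANSITION


@dataclass
class CodonModelParams:
    """Parameters of a single-class GY94 codon model."""

    kappa: float
    omega: float
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if not np.isfinite(self.kappa) or self.kappa <= 0:
            raise ValueError("kappa must be positive and finite")
        if not np.isfinite(self.omega) or self.omega < 0:
            raise ValueError("omega must be >= 0 and finite")
        if self.pi.shape != (N_CODONS,):
            raise ValueError(f"pi must have {N_CODONS} entries")
        if np.any(self.pi <= 0) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be strictly positive and sum to 1")


def build_rate_matrix(params: CodonModelParams, normalization: str = "own") -> np.ndarray:
    """Build the normalized GY94 rate matrix Q (61 x 61).

    ``q[i, j]`` is zero for codon pairs differing at more than one position;
    otherwise proportional to ``pi[j]``, times kappa for transitions and omega
    for non-synonymous changes.  The diagonal makes rows sum to zero.

    ``normalization="own"`` scales so that ``-sum_i pi_i q_ii == 1`` (one
    expected substitution per codon per unit time under *this* omega; the
    single-ratio convention).  ``normalization="neutral"`` divides by the rate
    the same (kappa, pi) would have at omega = 1, so matrices of different
    site classes share one clock and omega > 1 accelerates non-synonymous
    substitutions instead of merely recomposing them; branch lengths are then
    in neutral-equivalent substitutions per codon.
    """
    pi = params.pi
    base = np.where(SINGLE_STEP, pi[None, :], 0.0)
    base = np.where(TRANSITION, base * params.kappa, base)
    nonsyn = SINGLE_STEP & ~SYNONYMOUS
    Q = np.where(nonsyn, base * params.omega, base)
    np.fill_diagonal(Q, 0.0)
    syn_rate = float(pi @ np.where(SINGLE_STEP & SYNONYMOUS, base, 0.0).sum(axis=1))
    nonsyn_rate_neutral = float(pi @ np.where(nonsyn, base, 0.0).sum(axis=1))
    if normalization == "own":
        rate = syn_rate + params.omega * nonsyn_rate_neutral
    elif normalization == "neutral":
        rate = syn_rate + nonsyn_rate_neutral
    else:
        raise ValueError(f"unknown normalization: {normalization!r}")
    if rate <= 0:
        raise ValueError("degenerate rate matrix (zero expected rate)")
    Q = Q / rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t) by scaling-and-squaring; rows sum to one.

    This is the reference route; :class:`CodonSubstitutionModel` uses the
    symmetrized eigendecomposition and the two agree to ~1e-10.
    """
    if t < 0:
        raise ValueError("branch length t must be >= 0")
    if t == 0:
        return np.eye(Q.shape[0])
    return scipy.linalg.expm(Q * t)


class CodonSubstitutionModel:
    """A GY94 model with a cached symmetric eigendecomposition for fast P(t).

    Time reversibility (``pi_i q_ij == pi_j q_ji``) makes
    ``diag(sqrt(pi)) Q diag(1/sqrt(pi))`` symmetric, so
    ``P(t) = U exp(L t) V`` with real eigenvalues ``L`` and precomputed
    ``U = diag(1/sqrt(pi)) W`` and ``V = W' diag(sqrt(pi))``.
    """

    def __init__(self, kappa: float, omega: float, pi: np.ndarray, normalization: str = "neutral"):
        self.params = CodonModelParams(kappa, omega, np.asarray(pi, dtype=float))
        self.normalization = normalization
        self.Q = build_rate_matrix(self.params, normalization)
        sqrt_pi = np.sqrt(self.params.pi)
        B = (self.Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        B = 0.5 * (B + B.T)  # enforce exact symmetry against round-off
        eigval, W = scipy.linalg.eigh(B)
        self.eigval = eigval
        self._U = W / sqrt_pi[:, None]
        self._V = W.T * sqrt_pi[None, :]

    @property
    def pi(self) -> np.ndarray:
        return self.params.pi

    def P(self, t: float) -> np.ndarray:
        """Transition probability matrix over a branch of length ``t``."""
        if t < 0:
            raise ValueError("branch length t must be >= 0")
        P = (self._U * np.exp(self.eigval * t)[None, :]) @ self._V
        np.clip(P, 0.0, None, out=P)
        return P

    def propagate(self, partial: np.ndarray, t: float) -> np.ndarray:
        """Apply P(t) to partial-likelihood vectors without forming P.

        ``partial`` has shape (..., 61); returns ``partial @ P(t).T``, i.e. the
        parent-side contribution ``sum_j P_ij L_j``.
        """
        return ((partial @ self._V.T) * np.exp(self.eigval * t)) @ self._U.T


def codon_frequencies(codes: np.ndarray, method: str = "f3x4") -> np.ndarray:
    """Estimate equilibrium sense-codon frequencies from an alignment.

    Parameters
    ----------
    codes:
        Integer codon-state matrix (taxa x sites), ``-1`` for missing.
    method:
        ``"f3x4"`` (position-specific nucleotide frequencies), ``"f1x4"``
        (pooled nucleotide frequencies) or ``"equal"``.

    A small pseudo-count keeps every sense-codon frequency strictly positive.
    """
    if method == "equal":
        return np.full(N_CODONS, 1.0 / N_CODONS)
    observed = codes[codes != MISSING]
    counts = np.zeros((3, 4))  # position x nucleotide (T, C, A, G)
    nuc_idx = {"T": 0, "C": 1, "A": 2, "G": 3}
    codon_nucs = np.array([[nuc_idx[c[k]] for k in range(3)] for c in SENSE_CODONS])
    for k in range(3):
        counts[k] += np.bincount(codon_nucs[observed, k], minlength=4)
    counts += 0.5  # pseudo-count
    if method == "f1x4":
        pooled = counts.sum(axis=0)
        counts = np.tile(pooled, (3, 1))
    elif method != "f3x4":
        raise ValueError(f"unknown codon frequency method: {method!r}")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array([freqs[0, codon_nucs[i, 0]] * freqs[1, codon_nucs[i, 1]] * freqs[2, codon_nucs[i, 2]] for i in range(N_CODONS)])
    return pi / pi.sum()
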