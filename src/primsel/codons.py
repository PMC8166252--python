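"""Universal genetic code tables and codon indexing.

The likelihood engine works on the 61 sense codons of the universal code;
stop codons are excluded from the state space.  Codons are referenced by an
integer index into :data:`SENSE_CODONS`; ``-1`` denotes missing data (gap or
ambiguous codon).
"""

from __future__ import annotations

import itertools

import numpy as np

NUCLEOTIDES = "TCAG"

#: Universal-code translation table, codon string -> one-letter amino acid
#: ("*" for stop).
GENETIC_CODE: dict[str, str] = {}
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, (_a, _b, _c) in enumerate(itertools.product(NUCLEOTIDES, repeat=3)):
    GENETIC_CODE[_a + _b + _c] = _AA[_i]

STOP_CODONS = tuple(c for c, aa in GENETIC_CODE.items() if aa == "*")

#: The 61 sense codons, in a fixed deterministic order.
SENSE_CODONS: tuple[str, ...] = tuple(c for c in GENETIC_CODE if GENETIC_CODE[c] != "*")

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

N_CODONS = len(SENSE_CODONS)  # 61

MISSING = -1

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def codon_index(codon: str) -> int:
    """Return the state index of a sense codon, or ``MISSING`` for anything else.

    Gaps ("---"), codons containing N or other ambiguity characters, and stop
    codons all map to missing data.
    """
    return CODON_INDEX.get(codon.upper(), MISSING)


def translate_codon(codon: str) -> str:
    """Translate one codon; codons containing N (or any non-ACGT) become 'X'."""
    codon = codon.upper()
    aa = GENETIC_CODE.get(codon)
    if aa is None:
        return "X"
    return aa


def is_transition(a: str, b: str) -> bool:
    """True when the single-nucleotide change a->b is a transition (A<->G, C<->T)."""
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def _pair_structure() -> tuple[np.ndarray, np.ndarray]:
    """Precompute the single-step substitution structure among sense codons.

    Returns (single, ts, syn): boolean (61, 61) arrays marking, for pairs of codons
    differing at exactly one position, whether the change is a transition and
    whether it is synonymous.  Pairs differing at 0 or >1 positions are False
    in both (their rate is zero; the diagonal is handled separately).
    """
    ts = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    syn = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            k = diffs[0]
            ts[i, j] = is_transition(ci[k], cj[k])
            syn[i, j] = GENETIC_CODE[ci] == GENETIC_CODE[cj]
    return single, ts, syn


SINGLE_STEP, TRANSITION, SYNONYMOUS = _pair_structure()
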