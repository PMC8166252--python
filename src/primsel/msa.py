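"""Codon and protein alignments: translation, progressive alignment, back-translation.

The screen aligns at the protein level and back-translates to codons, so the
codon alignment is always in frame.  Manual alignment curation is replaced by
explicit, logged column masks: user-supplied masks plus a gap-fraction
auto-mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from primsel.codons import GENETIC_CODE, MISSING, codon_index
from primsel.trees import PhyloTree, prune_tree

GAP_CODON = "---"


class TranslationError(ValueError):
    """CDS cannot be translated cleanly (length or internal stop)."""


def translate_cds(cds: str, code: str = "universal") -> str:
    """Translate a CDS to protein under the universal genetic code.

    A terminal stop codon is trimmed silently.  Codons containing ``N`` (or any
    other non-ACGT character) translate to ``X``.  An internal stop codon
    raises :class:`TranslationError` naming the codon position: in-frame stops
    signal a mis-annotated sequence and the gene should be flagged upstream,
    never silently repaired.
    """
    if code != "universal":
        raise ValueError(f"unsupported genetic code: {code!r}")
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise TranslationError(f"CDS length {len(cds)} not divisible by 3")
    bad = set(cds) - set("ACGTN")
    if bad:
        raise TranslationError(f"invalid characters in CDS: {sorted(bad)}")
    n = len(cds) // 3
    out = []
    for k in range(n):
        codon = cds[3 * k : 3 * k + 3]
        aa = GENETIC_CODE.get(codon, "X")
        if aa == "*":
            if k == n - 1:
                break  # trailing stop trimmed
            raise TranslationError(f"internal stop at codon {k + 1}")
        out.append(aa)
    return "".join(out)


@dataclass
class ProteinMSA:
    """Protein multiple alignment: equal-length gapped rows keyed by taxon."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


@dataclass
class CodonAlignment:
    """In-frame codon alignment; rows are nucleotide strings with ``---`` gaps."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("alignment rows differ in length")
        if self.rows and len(self.rows[0]) % 3 != 0:
            raise ValueError("row length not divisible by 3")

    @property
    def width(self) -> int:
        """Number of codon columns."""
        return len(self.rows[0]) // 3 if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def codes(self) -> np.ndarray:
        """Integer state matrix (n_taxa, n_codon_columns); missing/gap/stop = -1."""
        w = self.width
        out = np.full((len(self.taxa), w), MISSING, dtype=np.int16)
        for i, row in enumerate(self.rows):
            out[i] = [codon_index(row[3 * k : 3 * k + 3]) for k in range(w)]
        return out

    def column(self, k: int) -> list[str]:
        """Codon column ``k`` (1-based) as a list of codon strings."""
        j = 3 * (k - 1)
        return [r[j : j + 3] for r in self.rows]

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path) -> "CodonAlignment":
        recs = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in recs], [str(r.seq).upper() for r in recs])

    def to_fasta(self, path) -> None:
        recs = [SeqRecord(Seq(row), id=tax, description="") for tax, row in zip(self.taxa, self.rows)]
        SeqIO.write(recs, str(path), "fasta")


@dataclass
class ColumnMask:
    """Codon columns to drop (1-based indices), each with a logged reason."""

    drop_columns: set[int] = field(default_factory=set)
    reasons: dict[int, str] = field(default_factory=dict)

    def validate(self, width: int) -> None:
        bad = [c for c in self.drop_columns if not (1 <= c <= width)]
        if bad:
            raise ValueError(f"mask columns out of range 1..{width}: {sorted(bad)}")


# ---------------------------------------------------------------------------
# Progressive protein alignment (Gotoh profile-profile, BLOSUM62).

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_AA_ORDER = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_IDX = {a: i for i, a in enumerate(_AA_ORDER)}
_SUBST = np.zeros((len(_AA_ORDER), len(_AA_ORDER)))
for _a in _AA_ORDER:
    for _b in _AA_ORDER:
        _SUBST[_AA_IDX[_a], _AA_IDX[_b]] = _BLOSUM62[_a][_b]

GAP_OPEN = -10.0
GAP_EXTEND = -0.5


def _profile_counts(rows: list[str]) -> np.ndarray:
    """(width, n_symbols) residue counts per column, gaps excluded."""
    w = len(rows[0])
    counts = np.zeros((w, len(_AA_ORDER)))
    for row in rows:
        for j, ch in enumerate(row):
            if ch != "-":
                counts[j, _AA_IDX.get(ch, _AA_IDX["X"])] += 1
    return counts


def _profile_scores(c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
    """Mean pairwise substitution score between profile columns."""
    n1 = c1.sum(axis=1)
    n2 = c2.sum(axis=1)
    raw = c1 @ _SUBST @ c2.T
    denom = np.outer(np.maximum(n1, 1.0), np.maximum(n2, 1.0))
    return raw / denom


def _gotoh_align(rows1: list[str], rows2: list[str]) -> tuple[list[str], list[str], float]:
    """Global affine-gap alignment of two profiles.

    A gap of length L costs ``GAP_OPEN + (L - 1) * GAP_EXTEND``.  Tie-break is
    deterministic: match > gap-in-profile-2 > gap-in-profile-1 during
    traceback.
    """
    S = _profile_scores(_profile_counts(rows1), _profile_counts(rows2))
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in profile 2 (consume profile 1)
    Y = np.full((n + 1, m + 1), NEG)  # gap in profile 1 (consume profile 2)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = GAP_OPEN + (i - 1) * GAP_EXTEND
    for j in range(1, m + 1):
        Y[0, j] = GAP_OPEN + (j - 1) * GAP_EXTEND
    j_idx = np.arange(1, m + 1)
    for i in range(1, n + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        M[i, 1:] = np.maximum(np.maximum(Mi1[:-1], Xi1[:-1]), Yi1[:-1]) + S[i - 1]
        X[i, 1:] = np.maximum(
            np.maximum(Mi1[1:] + GAP_OPEN, Yi1[1:] + GAP_OPEN), Xi1[1:] + GAP_EXTEND
        )
        # Y[i, j] = max_{k<=j} (max(M[i,k-1], X[i,k-1]) + OPEN + (j-k)*EXTEND):
        # a running-maximum scan after subtracting the EXTEND ramp.
        base = np.maximum(M[i, :-1], X[i, :-1]) + GAP_OPEN
        Y[i, 1:] = np.maximum.accumulate(base - GAP_EXTEND * j_idx) + GAP_EXTEND * j_idx
    score = max(M[n, m], X[n, m], Y[n, m])
    # traceback
    out1: list[str] = []
    out2: list[str] = []
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            out1.append("C")
            out2.append("C")
            prev = [M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1 or (state == 0 and j == 0):
            out1.append("C")
            out2.append("-")
            cand = [M[i - 1][j] + GAP_OPEN, X[i - 1][j] + GAP_EXTEND, Y[i - 1][j] + GAP_OPEN]
            i -= 1
            state = int(np.argmax(cand)) if i > 0 or j > 0 else 0
        else:
            out1.append("-")
            out2.append("C")
            cand = [M[i][j - 1] + GAP_OPEN, Y[i][j - 1] + GAP_EXTEND, X[i][j - 1] + GAP_OPEN]
            j -= 1
            state = [0, 2, 1][int(np.argmax(cand))] if i > 0 or j > 0 else 0
    path1 = out1[::-1]
    path2 = out2[::-1]

    def expand(rows: list[str], path: list[str]) -> list[str]:
        res = []
        for row in rows:
            buf = []
            k = 0
            for step in path:
                if step == "C":
                    buf.append(row[k])
                    k += 1
                else:
                    buf.append("-")
            res.append("".join(buf))
        return res

    return expand(rows1, path1), expand(rows2, path2), float(score)


def pairwise_affine_score(a: str, b: str) -> float:
    """Optimal global affine-gap alignment score of two protein sequences."""
    return _gotoh_align([a], [b])[2]


def align_proteins(seqs: Mapping[str, str], guide: PhyloTree) -> ProteinMSA:
    """Progressive multiple alignment following the guide tree.

    Profiles are merged at each internal node of the guide tree (pruned to the
    sequence labels) with affine-gap Gotoh dynamic programming on BLOSUM62
    column scores.  Deterministic for fixed inputs.  For two sequences this is
    exactly the optimal pairwise affine-gap alignment.
    """
    labels = list(seqs)
    if len(labels) < 2:
        raise ValueError("need at least two sequences to align")
    for lab, s in seqs.items():
        if len(s) == 0:
            raise ValueError(f"empty sequence for {lab!r}")
    missing = set(labels) - set(guide.leaf_labels)
    if missing:
        raise ValueError(f"sequences without guide-tree leaves: {sorted(missing)}")
    pruned = prune_tree(PhyloTree(guide.tree.clone(depth=1), None), labels)

    def merge(node) -> tuple[list[str], list[str]]:
        if node.is_leaf():
            lab = node.taxon.label
            return [lab], [seqs[lab]]
        parts = [merge(ch) for ch in node.child_nodes()]
        taxa, rows = parts[0]
        for t2, r2 in parts[1:]:
            rows, rows2, _ = _gotoh_align(rows, r2)
            taxa = taxa + t2
            rows = rows + rows2
        return taxa, rows

    taxa, rows = merge(pruned.tree.seed_node)
    return ProteinMSA(taxa, rows)


def back_translate(msa: ProteinMSA, cds_by_taxon: Mapping[str, str]) -> CodonAlignment:
    """Replace each aligned amino acid by its source codon (PAL2NAL behaviour).

    Every protein gap becomes ``---``.  The ungapped translation of each row
    must equal the translation of its CDS; a mismatch reports the taxon and the
    first discordant position.
    """
    rows = []
    for taxon, prot_row in zip(msa.taxa, msa.rows):
        cds = cds_by_taxon[taxon].upper()
        protein = translate_cds(cds)
        ungapped = prot_row.replace("-", "")
        if ungapped != protein:
            pos = next(
                (k + 1 for k, (x, y) in enumerate(zip(ungapped, protein)) if x != y),
                min(len(ungapped), len(protein)) + 1,
            )
            raise ValueError(f"translation mismatch for {taxon!r} at protein position {pos}")
        buf = []
        k = 0
        for ch in prot_row:
            if ch == "-":
                buf.append(GAP_CODON)
            else:
                buf.append(cds[3 * k : 3 * k + 3])
                k += 1
        rows.append("".join(buf))
    return CodonAlignment(list(msa.taxa), rows)


def apply_mask(aln: CodonAlignment, mask: ColumnMask) -> CodonAlignment:
    """Drop the masked codon columns from every row."""
    mask.validate(aln.width)
    if not mask.drop_columns:
        return CodonAlignment(list(aln.taxa), list(aln.rows))
    keep = [k for k in range(1, aln.width + 1) if k not in mask.drop_columns]
    rows = ["".join(r[3 * (k - 1) : 3 * (k - 1) + 3] for k in keep) for r in aln.rows]
    return CodonAlignment(list(aln.taxa), rows)


def auto_mask(aln: CodonAlignment, min_nongap_fraction: float = 0.5) -> ColumnMask:
    """Flag codon columns where fewer than ``min_nongap_fraction`` of taxa have a non-gap codon."""
    mask = ColumnMask()
    n = len(aln.taxa)
    for k in range(1, aln.width + 1):
        nongap = sum(1 for c in aln.column(k) if c != GAP_CODON)
        if nongap / n < min_nongap_fraction:
            mask.drop_columns.add(k)
            mask.reasons[k] = f"non-gap fraction {nongap}/{n} below {min_nongap_fraction}"
    return mask
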