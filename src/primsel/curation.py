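"""Gene- and sequence-level curation of the ortholog sets.

Mirrors the screen's conservative input filtering: read-through transcripts
and genes duplicated on the human lineage after the Homo-Pan split are
excluded outright (no reliable orthology); for the survivors the human
representative (MANE) isoform anchors a greedy identity clustering of all
non-human isoforms, and only the human-containing cluster is analyzed, one
isoform per species.  Very divergent orthologs therefore drop out, which
protects the downstream branch-site tests from saturation artifacts.

Identity is computed on protein sequences by global alignment (match +1,
mismatch 0, affine gaps): identical positions over aligned columns, dual-gap
columns excluded.  Whether the published 80% threshold was nucleotide- or
protein-level is not stated; protein identity is used here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from Bio import Align

from primsel.msa import TranslationError, translate_cds


@dataclass
class GeneRecord:
    """All isoforms of one gene in one species, with curation flags."""

    gene_id: str
    species: str
    sequences: dict[str, str]  # isoform id -> CDS
    read_through: bool = False
    human_lineage_duplicate: bool = False
    mane_isoform_id: Optional[str] = None  # human records only


@dataclass
class ClusterConfig:
    min_identity: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must lie in (0, 1]")


def filter_gene_set(records: Sequence[GeneRecord]) -> tuple[list[GeneRecord], pd.DataFrame]:
    """Drop read-through and recent human-lineage-duplicate genes.

    Filtering never adds records: survivors plus exclusions partition the
    input.  Returns (survivors, exclusion log with one reason row per
    excluded record).
    """
    kept, log_rows = [], []
    for rec in records:
        reasons = []
        if rec.read_through:
            reasons.append("read-through transcript")
        if rec.human_lineage_duplicate:
            reasons.append("recent human-lineage duplication")
        if reasons:
            log_rows.append({"gene": rec.gene_id, "species": rec.species, "reason": "; ".join(reasons)})
        else:
            kept.append(rec)
    return kept, pd.DataFrame(log_rows, columns=["gene", "species", "reason"])


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = 0.0
_aligner.open_gap_score = -1.0
_aligner.extend_gap_score = -0.1


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical positions over aligned columns (global alignment).

    Symmetric and in [0, 1]; 1.0 for identical sequences.  Dual-gap columns
    cannot occur in an optimal pairwise alignment, so the denominator is the
    alignment length.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _aligner.align(a, b)[0]
    identical = 0
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        identical += sum(1 for x, y in zip(a[s1:e1], b[s2:e2]) if x == y)
    return identical / aln.length


@dataclass
class SelectedSequence:
    species: str
    isoform_id: str
    cds: str
    protein: str
    identity_to_human: float


@dataclass
class ClusterSelection:
    """Outcome of the human-anchored isoform clustering for one gene."""

    selected: dict[str, SelectedSequence]  # species -> chosen sequence
    excluded: pd.DataFrame  # species, isoform, reason


def select_isoform_cluster(
    human: GeneRecord,
    orthologs: Sequence[GeneRecord],
    cfg: Optional[ClusterConfig] = None,
) -> ClusterSelection:
    """Cluster isoforms around the human MANE sequence; keep the human cluster.

    Greedy centroid clustering, deterministic: the human MANE protein is the
    first centroid; remaining isoforms are visited longest-first (ties by
    species then isoform id) and join the first centroid at
    >= ``min_identity`` protein identity, else found a new centroid.  From the
    human-containing cluster one isoform is kept per species: highest identity
    to human, then longest, then lexicographically smallest id.  Species with
    no isoform in the human cluster are absent from the result.
    """
    cfg = cfg or ClusterConfig()
    if human.mane_isoform_id is None:
        raise ValueError(f"human record for {human.gene_id} lacks a MANE isoform id")
    if human.mane_isoform_id not in human.sequences:
        raise ValueError(f"MANE isoform {human.mane_isoform_id} not among human sequences")
    human_cds = human.sequences[human.mane_isoform_id]
    human_prot = translate_cds(human_cds)  # raises on mis-annotation

    entries = []  # (species, isoform, cds, protein)
    excluded_rows = []
    for rec in orthologs:
        for iso, cds in sorted(rec.sequences.items()):
            try:
                prot = translate_cds(cds)
            except TranslationError as exc:
                excluded_rows.append({"species": rec.species, "isoform": iso, "reason": f"untranslatable: {exc}"})
                continue
            entries.append((rec.species, iso, cds, prot))
    entries.sort(key=lambda e: (-len(e[3]), e[0], e[1]))

    centroids = [(human.species, human.mane_isoform_id, human_cds, human_prot)]
    membership = {0: [("__human__", human.mane_isoform_id, human_cds, human_prot, 1.0)]}
    for species, iso, cds, prot in entries:
        assigned = False
        for ci, (_, _, _, cprot) in enumerate(centroids):
            ident = pairwise_identity(prot, cprot)
            if ident >= cfg.min_identity:
                ident_h = ident if ci == 0 else pairwise_identity(prot, human_prot)
                membership.setdefault(ci, []).append((species, iso, cds, prot, ident_h))
                assigned = True
                break
        if not assigned:
            centroids.append((species, iso, cds, prot))
            membership.setdefault(len(centroids) - 1, []).append((species, iso, cds, prot, pairwise_identity(prot, human_prot)))

    human_members = membership[0]
    by_species: dict[str, list] = {}
    for species, iso, cds, prot, ident_h in human_members[1:]:
        by_species.setdefault(species, []).append((species, iso, cds, prot, ident_h))

    selected = {
        human.species: SelectedSequence(human.species, human.mane_isoform_id, human_cds, human_prot, 1.0)
    }
    for species, cands in by_species.items():
        cands.sort(key=lambda c: (-c[4], -len(c[3]), c[1]))
        s, iso, cds, prot, ident = cands[0]
        selected[species] = SelectedSequence(s, iso, cds, prot, ident)

    in_cluster = {(m[0], m[1]) for m in human_members[1:]}
    for species, iso, cds, prot in entries:
        if (species, iso) not in in_cluster:
            excluded_rows.append(
                {"species": species, "isoform": iso, "reason": f"outside the human cluster (<{cfg.min_identity:.0%} identity)"}
            )
    return ClusterSelection(selected, pd.DataFrame(excluded_rows, columns=["species", "isoform", "reason"]))
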