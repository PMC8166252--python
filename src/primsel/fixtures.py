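"""Packaged worked example: the twelve both-method candidate codons.

The screen's published worked example comprises 12 candidate positively
selected codons in three genes (MAMLD1, PRDM9, ZNF860) on the human branch,
together with the population evidence used to classify each of them: dbSNP
identifiers and ancestral-allele frequencies where a modern-human polymorphism
is recorded, the intragenic ZNF860 haplotype block (codons 348-464-609, r2
between 0.5 and 1), archaic-human genotypes, and great-ape panel variation.

Ancestral frequencies quoted in the source results: PRDM9 573 -> 0.02
(Gambian), 591 -> 0.06 (Korean), 681 -> ~0.75 overall; ZNF860 348/464 -> up
to 0.80/0.90 in African populations.  PRDM9 629 and 657 are described as rare
without a printed number; the fixture uses a representative 0.01 (synthetic
placeholder, below every rare-variant threshold of interest).  The ZNF626
BEB-only rows in :func:`site_support_table` carry synthetic codon indices
(their positions are not part of the worked example) and never enter the
two-method consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from primsel.simulate import simulate_archaic_and_ape_genotypes
from primsel.verification import VariantRecord


@dataclass
class CandidateSiteFixture:
    """One candidate codon with its verification evidence."""

    gene: str
    codon_index: int  # 1-based, human representative isoform
    ancestral_codons: tuple[str, ...]
    derived_codon: str
    snp_id: Optional[str] = None
    ancestral_freq: Optional[float] = None
    freq_population: Optional[str] = None
    ld_partners: tuple[int, ...] = ()
    archaic_state: str = "derived"  # derived | ancestral | heterozygous | missing
    ape_variation: str = "none"  # none | variable | missing

    def __post_init__(self) -> None:
        for c in self.ancestral_codons + (self.derived_codon,):
            if len(c) != 3 or set(c) - set("ACGT"):
                raise ValueError(f"invalid codon {c!r}")


def table2_fixture() -> list[CandidateSiteFixture]:
    """The 12 both-method candidate codons in MAMLD1, PRDM9 and ZNF860."""
    recs = [
        CandidateSiteFixture("MAMLD1", 726, ("AGT",), "AGA"),
        CandidateSiteFixture("MAMLD1", 728, ("GGC",), "GAC"),
        CandidateSiteFixture("PRDM9", 155, ("CCT",), "TCT", ape_variation="variable"),
        CandidateSiteFixture(
            "PRDM9", 573, ("ACA",), "ATA", snp_id="rs199686868",
            ancestral_freq=0.02, freq_population="Gambian", ape_variation="variable",
        ),
        CandidateSiteFixture(
            "PRDM9", 591, ("CGG", "CAG", "GTT"), "TGG", snp_id="rs200381384",
            ancestral_freq=0.06, freq_population="Korean", ape_variation="variable",
        ),
        CandidateSiteFixture(
            "PRDM9", 629, ("ACA",), "AGA", snp_id="rs112192848",
            ancestral_freq=0.01, freq_population="ALL", ape_variation="variable",
        ),
        CandidateSiteFixture(
            "PRDM9", 657, ("ACA",), "AGA", snp_id="rs112679149",
            ancestral_freq=0.01, freq_population="ALL", ape_variation="variable",
        ),
        CandidateSiteFixture(
            "PRDM9", 681, ("AGA", "AGT"), "ACT", snp_id="rs6875787",
            ancestral_freq=0.75, freq_population="ALL", archaic_state="missing",
            ape_variation="variable",
        ),
        CandidateSiteFixture("PRDM9", 737, ("TGT", "ATT"), "AGA", ape_variation="variable"),
        CandidateSiteFixture("ZNF860", 219, ("CAA",), "CTA"),
        CandidateSiteFixture(
            "ZNF860", 348, ("GAC",), "GAA", snp_id="rs13064905",
            ancestral_freq=0.80, freq_population="African", ld_partners=(464, 609),
            archaic_state="heterozygous", ape_variation="missing",
        ),
        CandidateSiteFixture(
            "ZNF860", 464, ("AGT", "CGT"), "CAT", snp_id="rs1808125",
            ancestral_freq=0.90, freq_population="African", ld_partners=(348, 609),
            archaic_state="heterozygous", ape_variation="missing",
        ),
    ]
    assert len(recs) == 12 and len({r.gene for r in recs}) == 3
    return recs


def table2_inputs():
    """Classifier-ready inputs reconstructed from the fixture.

    Returns ``(sites, variants, ld, archaic, ape)``: the candidate site keys,
    the modern-human variant records (absent where no polymorphism is
    recorded), the intragenic candidate-pair r2 map, and the archaic / ape
    genotype tables.
    """
    recs = table2_fixture()
    sites = [(r.gene, r.codon_index) for r in recs]

    variants = {}
    for r in recs:
        if r.snp_id is None:
            continue
        variants[(r.gene, r.codon_index)] = VariantRecord(
            gene=r.gene,
            codon_index=r.codon_index,
            ancestral_allele="|".join(r.ancestral_codons),
            derived_allele=r.derived_codon,
            freq_by_population={r.freq_population: 1.0 - r.ancestral_freq},
            snp_id=r.snp_id,
        )

    # ZNF860 codons 348-464-609 form one haplotype block (r2 within [0.5, 1]);
    # 609 is a single-method candidate but anchors the block.
    ld = {
        (("ZNF860", 348), ("ZNF860", 464)): 0.8,
        (("ZNF860", 348), ("ZNF860", 609)): 0.7,
        (("ZNF860", 464), ("ZNF860", 609)): 0.6,
    }

    archaic, ape = simulate_archaic_and_ape_genotypes(
        sites,
        spec={
            "archaic_state": {(r.gene, r.codon_index): r.archaic_state for r in recs},
            "ape_variation": {(r.gene, r.codon_index): r.ape_variation for r in recs},
        },
        seed=0,
    )
    return sites, variants, ld, archaic, ape


def candidate_gene_table() -> pd.DataFrame:
    """The five human-branch candidate genes with their family annotation."""
    return pd.DataFrame(
        [
            {"gene": "MAMLD1", "family": "mastermind-like", "krab_znf": False},
            {"gene": "PRDM9", "family": "KRAB-ZNF", "krab_znf": True},
            {"gene": "ZNF626", "family": "KRAB-ZNF", "krab_znf": True},
            {"gene": "ZNF806", "family": "KRAB-ZNF", "krab_znf": True},
            {"gene": "ZNF860", "family": "KRAB-ZNF", "krab_znf": True},
        ]
    )


def site_support_table() -> pd.DataFrame:
    """Per-site method support across the human-branch candidate genes.

    The 12 fixture codons are supported by both detection routes; ZNF860 609
    by the per-site test only; the seven ZNF626 BEB-only rows use synthetic
    codon indices (real positions are not part of the worked example).
    """
    rows = [
        {"gene": r.gene, "codon_index": r.codon_index, "beb": True, "meme": True}
        for r in table2_fixture()
    ]
    rows.append({"gene": "ZNF860", "codon_index": 609, "beb": False, "meme": True})
    for idx in range(101, 108):  # synthetic ZNF626 positions
        rows.append({"gene": "ZNF626", "codon_index": idx, "beb": True, "meme": False})
    return pd.DataFrame(rows)
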