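"""Verification of candidate positively selected sites against population variation.

A codon that looks positively selected in a species-level comparison can be an
artifact of standing variation in modern humans: if the "ancestral" (great-ape)
state still segregates at appreciable frequency, or if several candidate codons
travel together on one haplotype block, the signal more likely reflects the
reference-genome allele choice or ancient polymorphism than fixation by
selection.  The classifier applies, in order:

1. no recorded modern-human polymorphism at the codon -> TRUE_PSS;
2. ancestral allele present but rare everywhere (max population frequency <=
   ``rare_backvariant_max``) and no LD with other candidates -> TRUE_PSS
   ("rare independent back-variant");
3. the derived (selected) allele is the minor allele overall (ancestral
   frequency >= ``minor_allele_min_ancestral``) without LD-block evidence ->
   MINOR_ALLELE (reference-allele artifact / unfixed variant);
4. ancestral allele common in at least one population and/or membership in an
   LD block of candidates -> FALSE_POSITIVE.

Sites surviving as TRUE_PSS are dated against archaic genomes (Vindija and
Altai Neanderthals, Denisovan): if every non-missing archaic genotype carries
the derived state the selective episode predates the archaic/modern split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd


class Call(str, Enum):
    TRUE_PSS = "TRUE_PSS"
    MINOR_ALLELE = "MINOR_ALLELE"
    FALSE_POSITIVE = "FALSE_POSITIVE"
    UNRESOLVED = "UNRESOLVED"


class Dating(str, Enum):
    PRE_ARCHAIC_SPLIT = "PRE_ARCHAIC_SPLIT"
    POST_ARCHAIC_SPLIT = "POST_ARCHAIC_SPLIT"
    UNDATED = "UNDATED"


@dataclass
class VariantRecord:
    """Modern-human population variation at one candidate codon.

    ``freq_by_population`` stores the *derived* (putatively selected) allele
    fraction per population; the ancestral fraction is its complement.  The
    population key ``"ALL"``, when present, is the overall frequency.
    """

    gene: str
    codon_index: int
    ancestral_allele: str
    derived_allele: str
    freq_by_population: dict[str, float] = field(default_factory=dict)
    snp_id: Optional[str] = None
    haplotypes: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.ancestral_allele == self.derived_allele:
            raise ValueError("ancestral and derived states must differ")
        for pop, f in self.freq_by_population.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency out of [0,1] for {pop}")

    @property
    def site(self) -> tuple[str, int]:
        return (self.gene, self.codon_index)

    def ancestral_freqs(self) -> dict[str, float]:
        return {pop: 1.0 - f for pop, f in self.freq_by_population.items()}

    def overall_ancestral_freq(self) -> float:
        anc = self.ancestral_freqs()
        if "ALL" in anc:
            return anc["ALL"]
        return float(np.mean(list(anc.values())))


@dataclass
class VerificationThresholds:
    """Frequency and LD cut-offs of the verification cascade (all in [0, 1])."""

    rare_backvariant_max: float = 0.10
    minor_allele_min_ancestral: float = 0.50
    common_ancestral_min: float = 0.50
    ld_r2_min: float = 0.5

    def __post_init__(self) -> None:
        for name in ("rare_backvariant_max", "minor_allele_min_ancestral", "common_ancestral_min", "ld_r2_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class PSSDecision:
    """Classification of one candidate site, with machine-readable reasons."""

    site: tuple[str, int]
    call: Call
    rationale: list[str]
    dating: Dating = Dating.UNDATED


def compute_r2(site_a: Sequence[int], site_b: Sequence[int]) -> float:
    """Squared allelic correlation r2 between two phased haplotype columns.

    ``r2 = D**2 / (pA pa pB pb)`` with ``D = f(AB) - pA pB``.  Columns must be
    equal-length 0/1 (biallelic) vectors.  Returns 0.0 when either site is
    monomorphic in the panel (r2 undefined; noted as no LD evidence).
    """
    a = np.asarray(site_a, dtype=float)
    b = np.asarray(site_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("haplotype columns must be equal-length vectors")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("haplotype columns must be biallelic 0/1")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return 0.0
    D = (a * b).mean() - pa * pb
    return float(D * D / (pa * (1 - pa) * pb * (1 - pb)))


def _in_ld_block(site: tuple[str, int], ld: Optional[Mapping], r2_min: float) -> bool:
    """Whether the site shows r2 >= r2_min with any other candidate in its gene."""
    if ld is None:
        return False
    for (sa, sb), r2 in ld.items():
        if site in (sa, sb) and r2 >= r2_min:
            return True
    return False


def classify_pss(
    site: tuple[str, int],
    variants: Mapping[tuple[str, int], VariantRecord],
    ld: Optional[Mapping[tuple, float]] = None,
    thresholds: Optional[VerificationThresholds] = None,
) -> PSSDecision:
    """Classify one consensus candidate site; see the module docstring for rules.

    ``variants`` maps (gene, codon_index) to the modern-human polymorphism
    record, absent when none is recorded; ``ld`` maps unordered candidate-site
    pairs to r2 (intragenic pairs only).  A site with a SNP id but no
    frequency data is UNRESOLVED, never guessed.
    """
    th = thresholds or VerificationThresholds()
    rec = variants.get(site)
    if rec is None:
        return PSSDecision(site, Call.TRUE_PSS, ["no modern-human polymorphism recorded"])
    if not rec.freq_by_population:
        return PSSDecision(site, Call.UNRESOLVED, [f"SNP {rec.snp_id or '?'} recorded without frequency data"])

    anc = rec.ancestral_freqs()
    max_anc = max(anc.values())
    in_block = _in_ld_block(site, ld, th.ld_r2_min)

    if max_anc <= th.rare_backvariant_max and not in_block:
        return PSSDecision(
            site,
            Call.TRUE_PSS,
            [f"rare independent back-variant (max ancestral freq {max_anc:.3g})"],
        )
    if rec.overall_ancestral_freq() >= th.minor_allele_min_ancestral and not in_block:
        return PSSDecision(
            site,
            Call.MINOR_ALLELE,
            [
                "derived allele is the minor allele overall "
                f"(ancestral freq {rec.overall_ancestral_freq():.3g}); reference-allele artifact / unfixed variant"
            ],
        )
    reasons = []
    if max_anc >= th.common_ancestral_min:
        reasons.append(f"ancestral allele common in >=1 population (max {max_anc:.3g})")
    if in_block:
        reasons.append(f"member of a candidate haplo-block (r2 >= {th.ld_r2_min})")
    if not reasons:
        reasons.append(
            f"intermediate-frequency polymorphism (max ancestral freq {max_anc:.3g}); conservative exclusion"
        )
    return PSSDecision(site, Call.FALSE_POSITIVE, reasons)


def archaic_dating(
    decisions: Sequence[PSSDecision],
    archaic: Optional[pd.DataFrame],
) -> list[PSSDecision]:
    """Date TRUE_PSS calls against archaic genotypes (long table: site, individual, state).

    All non-missing archaic genotypes derived -> PRE_ARCHAIC_SPLIT; any
    ancestral or heterozygous genotype -> POST_ARCHAIC_SPLIT candidate flag;
    no data -> UNDATED.  Missing archaic data never blocks a TRUE_PSS call.
    Non-TRUE_PSS decisions keep dating UNDATED.
    """
    out = []
    for d in decisions:
        dating = Dating.UNDATED
        if d.call == Call.TRUE_PSS and archaic is not None and len(archaic):
            states = archaic.loc[archaic["site"].apply(lambda s: tuple(s) == d.site if isinstance(s, (tuple, list)) else s == d.site), "state"]
            observed = [s for s in states if s != "missing"]
            if observed:
                dating = Dating.PRE_ARCHAIC_SPLIT if all(s == "derived" for s in observed) else Dating.POST_ARCHAIC_SPLIT
        out.append(PSSDecision(d.site, d.call, list(d.rationale), dating))
    return out


def ape_panel_summary(site, ape: Optional[pd.DataFrame]) -> dict[str, str]:
    """Summarize great-ape panel variation at one site, per taxon.

    Returns taxon -> ``monomorphic-ancestral`` | ``polymorphic`` |
    ``monomorphic-other`` | ``missing``; the special key ``"note"`` is set to
    ``"no incomplete lineage sorting signal"`` when every covered taxon is
    monomorphic ancestral.
    """
    if ape is None or not len(ape):
        return {"note": "site missing from the ape panel"}
    sub = ape.loc[ape["site"].apply(lambda s: tuple(s) == tuple(site) if isinstance(s, (tuple, list)) else s == site)]
    if not len(sub):
        return {"note": "site missing from the ape panel"}
    out: dict[str, str] = {}
    all_anc = True
    for taxon, grp in sub.groupby("taxon"):
        genos = set(grp["genotype"]) - {"missing"}
        if not genos:
            out[taxon] = "missing"
        elif len(genos) > 1:
            out[taxon] = "polymorphic"
            all_anc = False
        elif genos == {"ancestral"}:
            out[taxon] = "monomorphic-ancestral"
        else:
            out[taxon] = "monomorphic-other"
            all_anc = False
    if all_anc and any(v != "missing" for v in out.values()):
        out["note"] = "no incomplete lineage sorting signal"
    return out
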