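"""LD computation and the candidate-site verification cascade."""

import numpy as np
import pandas as pd
import pytest

from primsel.fixtures import table2_fixture, table2_inputs
from primsel.verification import (
    Call,
    Dating,
    PSSDecision,
    VariantRecord,
    VerificationThresholds,
    ape_panel_summary,
    archaic_dating,
    classify_pss,
    compute_r2,
)


class TestComputeR2:
    def test_identical_columns_give_one(self):
        col = np.array([0, 1, 1, 0, 1])
        assert compute_r2(col, col) == pytest.approx(1.0)

    def test_hand_computed_haplotype_counts(self):
        """AB=40, ab=40, Ab=10, aB=10: D = 0.15, r2 = 0.36."""
        a = np.array([1] * 40 + [0] * 40 + [1] * 10 + [0] * 10)
        b = np.array([1] * 40 + [0] * 40 + [0] * 10 + [1] * 10)
        assert compute_r2(a, b) == pytest.approx(0.36)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(11)
        a = (rng.random(10000) < 0.3).astype(int)
        b = (rng.random(10000) < 0.6).astype(int)
        assert compute_r2(a, b) < 0.05

    def test_monomorphic_column_returns_zero(self):
        assert compute_r2(np.zeros(10), np.array([0, 1] * 5)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_r2(np.array([0, 1]), np.array([0, 1, 1]))


def _variant(gene, codon, freqs, snp="rs1"):
    return VariantRecord(gene, codon, "AAA", "AAG", freqs, snp_id=snp)


class TestClassifyPss:
    def test_no_polymorphism_is_true_pss(self):
        d = classify_pss(("MAMLD1", 726), {})
        assert d.call == Call.TRUE_PSS

    def test_rare_back_variant_kept(self):
        # ancestral allele at 0.02 (derived 0.98), no LD: still a true PSS
        variants = {("PRDM9", 573): _variant("PRDM9", 573, {"Gambian": 0.98})}
        d = classify_pss(("PRDM9", 573), variants)
        assert d.call == Call.TRUE_PSS
        assert "back-variant" in d.rationale[0]

    def test_majority_ancestral_is_minor_allele_artifact(self):
        variants = {("PRDM9", 681): _variant("PRDM9", 681, {"ALL": 0.25})}
        d = classify_pss(("PRDM9", 681), variants)
        assert d.call == Call.MINOR_ALLELE

    def test_common_ancestral_with_ld_block_is_false_positive(self):
        variants = {("ZNF860", 348): _variant("ZNF860", 348, {"African": 0.20})}
        ld = {(("ZNF860", 348), ("ZNF860", 464)): 0.8}
        d = classify_pss(("ZNF860", 348), variants, ld)
        assert d.call == Call.FALSE_POSITIVE
        assert any("haplo-block" in r for r in d.rationale)

    def test_snp_without_frequencies_is_unresolved(self):
        variants = {("X", 1): VariantRecord("X", 1, "AAA", "AAG", {}, snp_id="rs9")}
        d = classify_pss(("X", 1), variants)
        assert d.call == Call.UNRESOLVED

    def test_intermediate_frequency_defaults_to_false_positive(self):
        variants = {("X", 1): _variant("X", 1, {"ALL": 0.7})}  # ancestral 0.3
        d = classify_pss(("X", 1), variants)
        assert d.call == Call.FALSE_POSITIVE

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            VerificationThresholds(rare_backvariant_max=1.2)

    def test_partition_and_order_invariance(self):
        """Every candidate gets exactly one call; input order never matters."""
        sites, variants, ld, _, _ = table2_inputs()
        calls = {s: classify_pss(s, variants, ld).call for s in sites}
        assert len(calls) == len(sites)
        rng = np.random.default_rng(0)
        for _ in range(3):
            shuffled = list(sites)
            rng.shuffle(shuffled)
            assert {s: classify_pss(s, variants, ld).call for s in shuffled} == calls


class TestArchaicDating:
    def test_empty_input_gives_empty_output(self):
        assert archaic_dating([], None) == []

    def test_all_derived_dates_before_the_split(self):
        d = [PSSDecision(("G", 1), Call.TRUE_PSS, [])]
        archaic = pd.DataFrame({"site": [("G", 1)] * 3, "individual": list("abc"), "state": ["derived"] * 3})
        out = archaic_dating(d, archaic)
        assert out[0].dating == Dating.PRE_ARCHAIC_SPLIT

    def test_heterozygous_archaic_flags_post_split(self):
        d = [PSSDecision(("G", 1), Call.TRUE_PSS, [])]
        archaic = pd.DataFrame(
            {"site": [("G", 1)] * 2, "individual": ["a", "b"], "state": ["derived", "heterozygous"]}
        )
        assert archaic_dating(d, archaic)[0].dating == Dating.POST_ARCHAIC_SPLIT

    def test_missing_data_leaves_sites_undated_but_called(self):
        d = [PSSDecision(("G", 1), Call.TRUE_PSS, [])]
        archaic = pd.DataFrame({"site": [("G", 1)], "individual": ["a"], "state": ["missing"]})
        out = archaic_dating(d, archaic)
        assert out[0].call == Call.TRUE_PSS and out[0].dating == Dating.UNDATED

    def test_non_true_pss_never_dated(self):
        d = [PSSDecision(("G", 1), Call.MINOR_ALLELE, [])]
        archaic = pd.DataFrame({"site": [("G", 1)], "individual": ["a"], "state": ["derived"]})
        assert archaic_dating(d, archaic)[0].dating == Dating.UNDATED


class TestApePanelSummary:
    def _table(self, genos_by_taxon, site=("G", 1)):
        rows = []
        for taxon, genos in genos_by_taxon.items():
            for i, g in enumerate(genos):
                rows.append({"site": site, "taxon": taxon, "individual": f"{taxon}{i}", "genotype": g})
        return pd.DataFrame(rows)

    def test_monomorphic_ancestral_panel_notes_no_ils(self):
        tab = self._table({"chimpanzee": ["ancestral"] * 5, "gorilla": ["ancestral"] * 3})
        out = ape_panel_summary(("G", 1), tab)
        assert out["chimpanzee"] == "monomorphic-ancestral"
        assert out["note"] == "no incomplete lineage sorting signal"

    def test_two_alleles_in_one_taxon_is_polymorphic(self):
        tab = self._table({"chimpanzee": ["ancestral", "derived"]})
        assert ape_panel_summary(("G", 1), tab)["chimpanzee"] == "polymorphic"

    def test_site_absent_from_table_is_missing(self):
        tab = self._table({"chimpanzee": ["ancestral"]})
        assert "missing" in ape_panel_summary(("G", 2), tab)["note"]


class TestTable2Fixture:
    def test_twelve_records_in_three_genes(self):
        recs = table2_fixture()
        assert len(recs) == 12
        assert {r.gene for r in recs} == {"MAMLD1", "PRDM9", "ZNF860"}

    def test_mamld1_726_codon_change(self):
        rec = next(r for r in table2_fixture() if (r.gene, r.codon_index) == ("MAMLD1", 726))
        assert rec.ancestral_codons == ("AGT",) and rec.derived_codon == "AGA"
        assert rec.snp_id is None

    def test_prdm9_681_minor_allele_evidence(self):
        rec = next(r for r in table2_fixture() if (r.gene, r.codon_index) == ("PRDM9", 681))
        assert rec.snp_id == "rs6875787"
        assert rec.ancestral_freq == pytest.approx(0.75)
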