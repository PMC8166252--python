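"""Gene filtering, protein identity, and human-anchored isoform clustering."""

import numpy as np
import pytest

from primsel.curation import (
    ClusterConfig,
    GeneRecord,
    SelectedSequence,
    filter_gene_set,
    pairwise_identity,
    select_isoform_cluster,
)

AAS = "ARNDCQEGHILKMFPSTWYV"
CODON_OF = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}


def _cds(protein: str) -> str:
    return "".join(CODON_OF[a] for a in protein)


def _mutate(protein: str, n: int, rng) -> str:
    s = list(protein)
    for i in rng.choice(len(s), size=min(n, len(s)), replace=False):
        s[i] = rng.choice([a for a in AAS if a != s[i]])
    return "".join(s)


class TestFilterGeneSet:
    def test_flagged_genes_are_dropped_with_reasons(self):
        recs = [GeneRecord(f"g{i}", "Hsap", {}) for i in range(7)]
        recs += [GeneRecord("rt1", "Hsap", {}, read_through=True),
                 GeneRecord("rt2", "Hsap", {}, read_through=True),
                 GeneRecord("dup", "Hsap", {}, human_lineage_duplicate=True)]
        kept, log = filter_gene_set(recs)
        assert len(kept) == 7
        assert len(log) == 3
        assert set(log["gene"]) == {"rt1", "rt2", "dup"}

    def test_unflagged_input_returned_unchanged(self):
        recs = [GeneRecord("a", "Hsap", {}), GeneRecord("b", "Hsap", {})]
        kept, log = filter_gene_set(recs)
        assert kept == recs and len(log) == 0

    def test_partition_invariant(self):
        rng = np.random.default_rng(0)
        recs = [
            GeneRecord(f"g{i}", "Hsap", {}, read_through=bool(rng.integers(2)),
                       human_lineage_duplicate=bool(rng.integers(2)))
            for i in range(30)
        ]
        kept, log = filter_gene_set(recs)
        assert len(kept) + len(log) == len(recs)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("MKDLV", "MKDLV") == 1.0

    def test_single_mismatch_over_six(self):
        assert pairwise_identity("ACDEFG", "ACDEYG") == pytest.approx(5 / 6)

    def test_symmetry_and_recomputation_from_alignment(self):
        """Identity equals recounting identical positions over alignment columns."""
        from primsel.curation import _aligner

        rng = np.random.default_rng(3)
        for _ in range(8):
            a = "".join(rng.choice(list(AAS), size=rng.integers(6, 25)))
            b = "".join(rng.choice(list(AAS), size=rng.integers(6, 25)))
            ident = pairwise_identity(a, b)
            assert ident == pytest.approx(pairwise_identity(b, a))
            aln = _aligner.align(a, b)[0]
            s1, s2 = aln[0], aln[1]
            cols = [(x, y) for x, y in zip(s1, s2) if not (x == "-" and y == "-")]
            oracle = sum(1 for x, y in cols if x == y and x != "-") / len(cols)
            assert ident == pytest.approx(oracle)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "MK")


class TestSelectIsoformCluster:
    def _human(self, protein):
        return GeneRecord("G", "Hsap", {"mane": _cds(protein)}, mane_isoform_id="mane")

    def test_all_close_orthologs_keep_every_species(self):
        rng = np.random.default_rng(1)
        base = "".join(rng.choice(list(AAS), size=60))
        orthologs = [
            GeneRecord("G", sp, {"i1": _cds(_mutate(base, 2, rng))})
            for sp in ("Ptro", "Ggor", "Mmul")
        ]
        sel = select_isoform_cluster(self._human(base), orthologs)
        assert set(sel.selected) == {"Hsap", "Ptro", "Ggor", "Mmul"}
        assert all(isinstance(v, SelectedSequence) for v in sel.selected.values())

    def test_divergent_species_excluded(self):
        rng = np.random.default_rng(2)
        base = "".join(rng.choice(list(AAS), size=60))
        far = "".join(rng.choice(list(AAS), size=60))
        orthologs = [
            GeneRecord("G", "Ptro", {"i1": _cds(_mutate(base, 1, rng))}),
            GeneRecord("G", "Mmul", {"i1": _cds(far)}),  # ~5% expected identity
        ]
        sel = select_isoform_cluster(self._human(base), orthologs)
        assert "Mmul" not in sel.selected
        assert "Ptro" in sel.selected
        assert (sel.excluded["species"] == "Mmul").any()

    def test_missing_mane_id_rejected(self):
        human = GeneRecord("G", "Hsap", {"i1": "ATGAAA"})
        with pytest.raises(ValueError):
            select_isoform_cluster(human, [])

    def test_human_cluster_equals_connected_components_for_bimodal_data(self):
        """Brute-force oracle: with bimodal identities (close variants of the
        human protein vs unrelated sequences) the greedy human cluster is the
        connected component of the >=0.8-identity graph seeded at human."""
        rng = np.random.default_rng(4)
        base = "".join(rng.choice(list(AAS), size=80))
        unrelated = "".join(rng.choice(list(AAS), size=80))
        seqs = {
            ("Ptro", "i1"): _mutate(base, 3, rng),
            ("Ggor", "i1"): _mutate(base, 5, rng),
            ("Mmul", "i1"): _mutate(unrelated, 3, rng),
            ("Cjac", "i1"): _mutate(unrelated, 5, rng),
            ("Ppan", "i1"): _mutate(base, 2, rng),
        }
        orthologs = [GeneRecord("G", sp, {iso: _cds(p)}) for (sp, iso), p in seqs.items()]
        sel = select_isoform_cluster(self._human(base), orthologs)

        # oracle: connected components over all-pairs identity
        labels = ["Hsap"] + [sp for sp, _ in seqs]
        prots = {"Hsap": base, **{sp: p for (sp, _), p in seqs.items()}}
        adj = {l: set() for l in labels}
        for i, x in enumerate(labels):
            for y in labels[i + 1 :]:
                if pairwise_identity(prots[x], prots[y]) >= 0.8:
                    adj[x].add(y)
                    adj[y].add(x)
        comp, todo = set(), ["Hsap"]
        while todo:
            n = todo.pop()
            if n not in comp:
                comp.add(n)
                todo.extend(adj[n])
        assert set(sel.selected) == comp

    def test_isoform_tiebreak_prefers_identity_then_length_then_id(self):
        rng = np.random.default_rng(6)
        base = "".join(rng.choice(list(AAS), size=60))
        close = _mutate(base, 1, rng)
        closer = base
        orthologs = [GeneRecord("G", "Ptro", {"b_iso": _cds(close), "a_iso": _cds(closer)})]
        sel = select_isoform_cluster(self._human(base), orthologs)
        assert sel.selected["Ptro"].isoform_id == "a_iso"
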