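"""End-to-end orchestration: curation -> alignment -> tests -> consensus -> verification.

The pipeline operates on a dataset directory (normally written by
:func:`generate_screen_dataset` or ``primsel simulate``):

``tree.nwk``
    species tree with branch lengths (Newick).
``genes.tsv``
    gene, read_through, human_duplicate, mane_isoform.
``genes/<gene>.fasta``
    unaligned CDS, headers ``species|gene|isoform``.
``variants.tsv`` (optional)
    gene, codon_index, snp_id, ancestral, derived, population, derived_freq.
``haplotypes.tsv`` (optional)
    gene, codon_index, hap_id, allele (0/1 phased haplotypes, pooled panel).
``archaic.tsv`` / ``ape.tsv`` (optional)
    archaic-human and great-ape genotypes per codon.

Every stage writes its outputs under the run directory and can be re-run from
those files; gene-level failures are logged and do not stop the run.  All
coordinates in reports are 1-based codon indices in the human representative
isoform.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

import primsel
from primsel.curation import ClusterConfig, GeneRecord, filter_gene_set, select_isoform_cluster
from primsel.likelihood import SiteClassMixture
from primsel.msa import CodonAlignment, align_proteins, apply_mask, auto_mask, back_translate
from primsel.selection import (
    LRTResult,
    absrel_like_branch_test,
    beb_posteriors,
    bh_adjust,
    branch_site_lrt,
    consensus,
    meme_like_site_test,
)
from primsel.simulate import SimulationConfig, simulate_archaic_and_ape_genotypes, simulate_codon_alignment
from primsel.trees import PhyloTree, build_default_tree, prune_tree
from primsel.verification import (
    Call,
    VariantRecord,
    VerificationThresholds,
    archaic_dating,
    ape_panel_summary,
    classify_pss,
    compute_r2,
)

log = logging.getLogger("primsel")

HUMAN = "Hsap"


@dataclass
class PipelineConfig:
    dataset_dir: Path
    out_dir: Path
    foreground: str = "Hominina"
    alpha: float = 0.05
    beb_threshold: float = 0.95
    null_dist: str = "chi2_1"
    absrel_null_dist: str = "mixture_half"
    freqs: str = "f3x4"
    fit_scale: bool = False
    min_identity: float = 0.80
    min_species: int = 3
    auto_mask_min_nongap: float = 0.5
    thresholds: VerificationThresholds = field(default_factory=VerificationThresholds)
    seed: int = 0

    def __post_init__(self) -> None:
        self.dataset_dir = Path(self.dataset_dir)
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        th = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if th:
            cfg.thresholds = VerificationThresholds(**th)
        return cfg

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("dataset_dir", None)  # paths are environment-specific, not parameters
        d.pop("out_dir", None)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Reconciled per-stage counts plus the result tables of one run."""

    counts: dict
    gene_results: pd.DataFrame
    site_results: pd.DataFrame
    decisions: pd.DataFrame
    exclusions: pd.DataFrame
    failures: pd.DataFrame
    provenance: dict

    def reconcile(self) -> None:
        c = self.counts
        if c["genes_in"] != c["genes_excluded"] + c["genes_curated"] + c["genes_failed"]:
            raise AssertionError("stage counts do not reconcile")
        if c["pss_decisions"] != len(self.decisions):
            raise AssertionError("decision counts do not reconcile")


# ---------------------------------------------------------------------------
# dataset I/O


def _read_gene_records(cfg: PipelineConfig, gene: str) -> dict[str, GeneRecord]:
    path = cfg.dataset_dir / "genes" / f"{gene}.fasta"
    by_species: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        species, g, iso = rec.id.split("|")
        by_species.setdefault(species, {})[iso] = str(rec.seq).upper()
    meta = _gene_meta(cfg).loc[gene]
    out = {}
    for species, seqs in by_species.items():
        out[species] = GeneRecord(
            gene_id=gene,
            species=species,
            sequences=seqs,
            read_through=bool(meta["read_through"]),
            human_lineage_duplicate=bool(meta["human_duplicate"]),
            mane_isoform_id=str(meta["mane_isoform"]) if species == HUMAN else None,
        )
    return out


def _gene_meta(cfg: PipelineConfig) -> pd.DataFrame:
    return pd.read_csv(cfg.dataset_dir / "genes.tsv", sep="\t", index_col="gene")


def _load_tree(cfg: PipelineConfig) -> PhyloTree:
    return PhyloTree.from_newick((cfg.dataset_dir / "tree.nwk").read_text(), cfg.foreground)


# ---------------------------------------------------------------------------
# stages


def stage_curate(cfg: PipelineConfig) -> dict:
    """Filter flagged genes, select the human-cluster isoforms, prune the tree."""
    meta = _gene_meta(cfg)
    tree = _load_tree(cfg)
    genes = list(meta.index)
    human_flagged = [
        GeneRecord(g, HUMAN, {}, bool(meta.loc[g, "read_through"]), bool(meta.loc[g, "human_duplicate"]), None)
        for g in genes
    ]
    kept, exclusion_log = filter_gene_set(human_flagged)
    survivors = [r.gene_id for r in kept]

    out = cfg.out_dir / "curated"
    out.mkdir(parents=True, exist_ok=True)
    curated, failures = [], []
    extra_rows = []
    for gene in survivors:
        try:
            records = _read_gene_records(cfg, gene)
            human = records.pop(HUMAN)
            selection = select_isoform_cluster(human, list(records.values()), ClusterConfig(cfg.min_identity))
            if len(selection.selected) < cfg.min_species:
                extra_rows.append({"gene": gene, "species": "", "reason": f"<{cfg.min_species} species in the human cluster"})
                continue
            pruned = prune_tree(tree, list(selection.selected))
            with open(out / f"{gene}.fasta", "w") as fh:
                for sp, sel in sorted(selection.selected.items()):
                    fh.write(f">{sp}|{gene}|{sel.isoform_id}\n{sel.cds}\n")
            (out / f"{gene}.nwk").write_text(pruned.to_newick() + "\n")
            curated.append(gene)
        except Exception as exc:  # gene-level failure: log and continue
            log.warning("curation failed for %s: %s", gene, exc)
            failures.append({"gene": gene, "stage": "curate", "error": str(exc)})
    exclusions = pd.concat([exclusion_log, pd.DataFrame(extra_rows, columns=exclusion_log.columns)], ignore_index=True)
    exclusions.to_csv(out / "exclusions.tsv", sep="\t", index=False)
    return {"genes_in": genes, "curated": curated, "exclusions": exclusions, "failures": failures}


def stage_align(cfg: PipelineConfig, curated: Optional[list[str]] = None) -> dict:
    """Translate, align progressively on the pruned tree, back-translate, auto-mask."""
    cur_dir = cfg.out_dir / "curated"
    out = cfg.out_dir / "aligned"
    out.mkdir(parents=True, exist_ok=True)
    if curated is None:
        curated = sorted(p.stem for p in cur_dir.glob("*.fasta"))
    aligned, failures, mask_rows = [], [], []
    for gene in curated:
        try:
            cds_by_taxon = {}
            for rec in SeqIO.parse(str(cur_dir / f"{gene}.fasta"), "fasta"):
                cds_by_taxon[rec.id.split("|")[0]] = str(rec.seq).upper()
            guide = PhyloTree.from_newick((cur_dir / f"{gene}.nwk").read_text())
            prots = {sp: _translate_for_align(cds) for sp, cds in cds_by_taxon.items()}
            msa = align_proteins(prots, guide)
            codon_aln = back_translate(msa, cds_by_taxon)
            mask = auto_mask(codon_aln, cfg.auto_mask_min_nongap)
            for col, reason in sorted(mask.reasons.items()):
                mask_rows.append({"gene": gene, "column": col, "reason": reason})
            codon_aln = apply_mask(codon_aln, mask)
            codon_aln.to_fasta(out / f"{gene}.codon.fasta")
            (out / f"{gene}.nwk").write_text(guide.to_newick() + "\n")
            aligned.append(gene)
        except Exception as exc:
            log.warning("alignment failed for %s: %s", gene, exc)
            failures.append({"gene": gene, "stage": "align", "error": str(exc)})
    pd.DataFrame(mask_rows, columns=["gene", "column", "reason"]).to_csv(out / "masks.tsv", sep="\t", index=False)
    return {"aligned": aligned, "failures": failures}


def _translate_for_align(cds: str) -> str:
    from primsel.msa import translate_cds

    return translate_cds(cds)


def stage_test(cfg: PipelineConfig, aligned: Optional[list[str]] = None) -> dict:
    """Run both gene-level tests, BH correction, and site-level detection."""
    aln_dir = cfg.out_dir / "aligned"
    out = cfg.out_dir / "tests"
    out.mkdir(parents=True, exist_ok=True)
    if aligned is None:
        aligned = sorted(p.name.removesuffix(".codon.fasta") for p in aln_dir.glob("*.codon.fasta"))
    res_a, res_b, failures = [], [], []
    site_rows = []
    for gene in aligned:
        try:
            aln = CodonAlignment.from_fasta(aln_dir / f"{gene}.codon.fasta")
            tree = PhyloTree.from_newick((aln_dir / f"{gene}.nwk").read_text(), cfg.foreground)
            ra = branch_site_lrt(
                aln, tree, gene=gene, freqs=cfg.freqs, null_dist=cfg.null_dist, fit_scale=cfg.fit_scale
            )
            rb = absrel_like_branch_test(
                aln, tree, gene=gene, freqs=cfg.freqs, null_dist=cfg.absrel_null_dist,
                kappa=ra.params["kappa"], fit_scale=cfg.fit_scale,
            )
            res_a.append(ra)
            res_b.append(rb)
            codon_of = _human_codon_indices(aln)
            if ra.p < cfg.alpha:
                mix = SiteClassMixture(
                    ra.params["p0"], ra.params["p1"], ra.params["omega0"],
                    max(ra.params["omega2"], 1.0), ra.params["kappa"],
                    _pi_for(aln, cfg.freqs),
                )
                beb = beb_posteriors(aln, tree, mle=mix, threshold=cfg.beb_threshold)
                for _, row in beb.iterrows():
                    ci = codon_of.get(int(row["column"]))
                    if ci is not None:
                        site_rows.append(
                            {"gene": gene, "codon_index": ci, "method": "beb",
                             "score": float(row["beb_posterior"]), "flagged": bool(row["flagged"])}
                        )
            if rb.p < cfg.alpha:
                meme = meme_like_site_test(aln, tree, alpha=cfg.alpha, kappa=rb.params["kappa"], freqs=cfg.freqs)
                for _, row in meme.iterrows():
                    ci = codon_of.get(int(row["column"]))
                    if ci is not None:
                        site_rows.append(
                            {"gene": gene, "codon_index": ci, "method": "meme",
                             "score": float(row["meme_p"]), "flagged": bool(row["flagged"])}
                        )
        except Exception as exc:
            log.warning("tests failed for %s: %s", gene, exc)
            failures.append({"gene": gene, "stage": "test", "error": str(exc)})

    for res in (res_a, res_b):
        if res:
            qs = bh_adjust([r.p for r in res])
            for r, q in zip(res, qs):
                r.q = float(q)
    gene_rows = []
    for ra, rb in zip(res_a, res_b):
        gene_rows.append(
            {
                "gene": ra.gene,
                "lnL0_bs": ra.lnL0, "lnL1_bs": ra.lnL1, "stat_bs": ra.statistic, "p_bs": ra.p, "q_bs": ra.q,
                "omega2": ra.params["omega2"], "kappa": ra.params["kappa"],
                "lnL0_br": rb.lnL0, "lnL1_br": rb.lnL1, "stat_br": rb.statistic, "p_br": rb.p, "q_br": rb.q,
                "omega_plus": rb.params["omega_plus"],
            }
        )
    gene_table = pd.DataFrame(gene_rows)
    site_table = pd.DataFrame(site_rows, columns=["gene", "codon_index", "method", "score", "flagged"])
    gene_table.to_csv(out / "gene_results.tsv", sep="\t", index=False)
    site_table.to_csv(out / "site_results.tsv", sep="\t", index=False)
    return {"genes_a": res_a, "genes_b": res_b, "gene_table": gene_table, "site_table": site_table, "failures": failures}


def _pi_for(aln: CodonAlignment, freqs: str) -> np.ndarray:
    from primsel.ratematrix import codon_frequencies

    return codon_frequencies(aln.codes(), freqs)


def _human_codon_indices(aln: CodonAlignment) -> dict[int, int]:
    """Alignment column (1-based) -> codon index in the ungapped human row."""
    row = aln.row(HUMAN)
    out = {}
    idx = 0
    for col in range(1, aln.width + 1):
        codon = row[3 * (col - 1) : 3 * (col - 1) + 3]
        if codon != "---":
            idx += 1
            out[col] = idx
    return out


def stage_verify(cfg: PipelineConfig, cons=None, gene_table=None, site_table=None) -> dict:
    """Classify consensus candidate sites and date the surviving true PSS."""
    out = cfg.out_dir / "verification"
    out.mkdir(parents=True, exist_ok=True)
    tests_dir = cfg.out_dir / "tests"
    if cons is None:
        gene_table = pd.read_csv(tests_dir / "gene_results.tsv", sep="\t")
        site_table = pd.read_csv(tests_dir / "site_results.tsv", sep="\t")
        res_a = [LRTResult(r.gene, r.lnL0_bs, r.lnL1_bs, r.stat_bs, 1, r.p_bs, r.q_bs) for r in gene_table.itertuples()]
        res_b = [LRTResult(r.gene, r.lnL0_br, r.lnL1_br, r.stat_br, 1, r.p_br, r.q_br) for r in gene_table.itertuples()]
        cons = consensus(res_a, res_b, *_site_flags(site_table), alpha=cfg.alpha)

    variants = _load_variants(cfg)
    haplo = _load_haplotypes(cfg)
    archaic = _load_site_table(cfg, "archaic.tsv")
    ape = _load_site_table(cfg, "ape.tsv")

    decisions = []
    for gene, codons in cons.candidate_sites.items():
        sites = [(gene, c) for c in codons]
        ld = {}
        if haplo is not None:
            for i, sa in enumerate(sites):
                for sb in sites[i + 1 :]:
                    cols = _haplo_columns(haplo, sa, sb)
                    if cols is not None:
                        ld[(sa, sb)] = compute_r2(*cols)
        for site in sites:
            decisions.append(classify_pss(site, variants, ld, cfg.thresholds))
    decisions = archaic_dating(decisions, archaic)

    rows = []
    for d in decisions:
        ape_note = ape_panel_summary(d.site, ape).get("note", "")
        rows.append(
            {
                "gene": d.site[0],
                "codon_index": d.site[1],
                "call": d.call.value,
                "dating": d.dating.value,
                "rationale": "; ".join(d.rationale),
                "ape_note": ape_note,
            }
        )
    table = pd.DataFrame(rows, columns=["gene", "codon_index", "call", "dating", "rationale", "ape_note"])
    table.to_csv(out / "decisions.tsv", sep="\t", index=False)
    return {"consensus": cons, "decisions": table}


def _site_flags(site_table: pd.DataFrame):
    sites_a: dict[str, set[int]] = {}
    sites_b: dict[str, set[int]] = {}
    for r in site_table.itertuples():
        if r.flagged:
            target = sites_a if r.method == "beb" else sites_b
            target.setdefault(r.gene, set()).add(int(r.codon_index))
    return sites_a, sites_b


def _load_variants(cfg: PipelineConfig) -> dict:
    path = cfg.dataset_dir / "variants.tsv"
    if not path.exists():
        return {}
    df = pd.read_csv(path, sep="\t")
    out: dict[tuple[str, int], VariantRecord] = {}
    for (gene, codon), grp in df.groupby(["gene", "codon_index"]):
        first = grp.iloc[0]
        out[(gene, int(codon))] = VariantRecord(
            gene=gene,
            codon_index=int(codon),
            ancestral_allele=str(first["ancestral"]),
            derived_allele=str(first["derived"]),
            freq_by_population={str(r["population"]): float(r["derived_freq"]) for _, r in grp.iterrows()},
            snp_id=None if pd.isna(first["snp_id"]) else str(first["snp_id"]),
        )
    return out


def _load_haplotypes(cfg: PipelineConfig) -> Optional[pd.DataFrame]:
    path = cfg.dataset_dir / "haplotypes.tsv"
    return pd.read_csv(path, sep="\t") if path.exists() else None


def _haplo_columns(haplo: pd.DataFrame, sa, sb):
    a = haplo[(haplo["gene"] == sa[0]) & (haplo["codon_index"] == sa[1])].sort_values("hap_id")["allele"]
    b = haplo[(haplo["gene"] == sb[0]) & (haplo["codon_index"] == sb[1])].sort_values("hap_id")["allele"]
    if not len(a) or len(a) != len(b):
        return None
    return a.to_numpy(), b.to_numpy()


def _load_site_table(cfg: PipelineConfig, name: str) -> Optional[pd.DataFrame]:
    path = cfg.dataset_dir / name
    if not path.exists():
        return None
    df = pd.read_csv(path, sep="\t")
    df["site"] = list(zip(df["gene"], df["codon_index"].astype(int)))
    return df


# ---------------------------------------------------------------------------
# the full run


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and assemble the reconciled run report."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    cur = stage_curate(config)
    ali = stage_align(config, cur["curated"])
    tst = stage_test(config, ali["aligned"])
    cons = consensus(tst["genes_a"], tst["genes_b"], *_site_flags(tst["site_table"]), alpha=config.alpha) if len(tst["gene_table"]) else None
    if cons is not None:
        ver = stage_verify(config, cons, tst["gene_table"], tst["site_table"])
        decisions = ver["decisions"]
    else:
        from primsel.selection import ConsensusResult

        cons = ConsensusResult([], {}, pd.DataFrame())
        decisions = pd.DataFrame(columns=["gene", "codon_index", "call", "dating", "rationale", "ape_note"])

    failures = pd.DataFrame(
        cur["failures"] + ali["failures"] + tst["failures"], columns=["gene", "stage", "error"]
    )
    counts = {
        "genes_in": len(cur["genes_in"]),
        "genes_excluded": len(cur["genes_in"]) - len(cur["curated"]) - len(cur["failures"]),
        "genes_curated": len(cur["curated"]),
        "genes_failed": len(cur["failures"]),
        "genes_tested": len(tst["gene_table"]),
        "candidates_branch_site": int((tst["gene_table"]["p_bs"] < config.alpha).sum()) if len(tst["gene_table"]) else 0,
        "candidates_branch_re": int((tst["gene_table"]["p_br"] < config.alpha).sum()) if len(tst["gene_table"]) else 0,
        "consensus_genes": len(cons.candidate_genes),
        "consensus_sites": sum(len(v) for v in cons.candidate_sites.values()),
        "pss_decisions": sum(len(v) for v in cons.candidate_sites.values()),
        "true_pss": int((decisions["call"] == Call.TRUE_PSS.value).sum()) if len(decisions) else 0,
    }
    report = RunReport(
        counts=counts,
        gene_results=tst["gene_table"],
        site_results=tst["site_table"],
        decisions=decisions,
        exclusions=cur["exclusions"],
        failures=failures,
        provenance={"config_digest": config.digest(), "seed": config.seed, "version": primsel.__version__},
    )
    report.reconcile()
    return report


def write_report(report: RunReport, out_dir, fmt: str = "tsv+json") -> list[Path]:
    """Write the report tables (TSV) and the JSON summary; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    if "tsv" in fmt:
        for name in ("gene_results", "site_results", "decisions", "exclusions", "failures"):
            p = out / f"{name}.tsv"
            getattr(report, name).to_csv(p, sep="\t", index=False)
            paths.append(p)
    if "json" in fmt:
        p = out / "report.json"
        p.write_text(json.dumps({"counts": report.counts, "provenance": report.provenance}, indent=2, sort_keys=True) + "\n")
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# synthetic dataset generation


def generate_screen_dataset(
    out_dir,
    *,
    n_genes: int = 6,
    n_selected: int = 1,
    n_codons: int = 300,
    seed: int = 1,
    foreground: str = "Hominina",
    branch_length_scale: float = 0.05,
    kappa: float = 2.0,
    omega0: float = 0.2,
    p0: float = 0.45,
    p1: float = 0.45,
    omega2: float = 8.0,
    p0_selected: float = 0.5,
    p1_selected: float = 0.35,
    n_read_through: int = 0,
    n_human_dup: int = 0,
    minor_allele_codon: Optional[int] = None,
) -> Path:
    """Write a complete synthetic dataset directory for the pipeline.

    The first ``n_selected`` genes evolve under the alternative branch-site
    model (omega2 on the foreground branch); the rest under the null
    (omega2 = 1).  Flagged decoy genes exercise the curation filters.  Archaic
    genotypes are all-derived and the ape panel monomorphic-ancestral for the
    selected genes, so surviving candidate sites classify as pre-split true
    PSS; ``minor_allele_codon`` optionally injects a modern-human polymorphism
    with the derived allele at 25% (a reference-allele artifact) at that codon
    of the first selected gene.  True simulation parameters are recorded in
    ``truth.json``.
    """
    from primsel.ratematrix import codon_frequencies  # noqa: F401  (doc pointer)

    out = Path(out_dir)
    (out / "genes").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    tree = build_default_tree(branch_length_scale, foreground)
    (out / "tree.nwk").write_text(tree.to_newick() + "\n")

    pi = np.full(61, 1.0 / 61)
    meta_rows, truth = [], {}
    gene_names = [f"gene{str(i + 1).zfill(2)}" for i in range(n_genes)]
    for i, gene in enumerate(gene_names):
        selected = i < n_selected
        mix = SiteClassMixture(
            p0_selected if selected else p0,
            p1_selected if selected else p1,
            omega0,
            omega2 if selected else 1.0,
            kappa,
            pi,
        )
        sim = SimulationConfig(tree, n_codons, mix, seed=int(rng.integers(2**31 - 1)))
        aln, classes = simulate_codon_alignment(sim)
        with open(out / "genes" / f"{gene}.fasta", "w") as fh:
            for sp, row in zip(aln.taxa, aln.rows):
                fh.write(f">{sp}|{gene}|iso1\n{row}\n")
        meta_rows.append({"gene": gene, "read_through": 0, "human_duplicate": 0, "mane_isoform": "iso1"})
        truth[gene] = {
            "selected": selected,
            "omega2": mix.omega2,
            "p2": mix.p2a + mix.p2b,
            "kappa": kappa,
            "class2_sites": [int(c + 1) for c in np.nonzero(classes >= 2)[0]],
        }

    for j in range(n_read_through + n_human_dup):
        gene = f"decoy{str(j + 1).zfill(2)}"
        mix = SiteClassMixture(p0, p1, omega0, 1.0, kappa, pi)
        sim = SimulationConfig(tree, n_codons, mix, seed=int(rng.integers(2**31 - 1)))
        aln, _ = simulate_codon_alignment(sim)
        with open(out / "genes" / f"{gene}.fasta", "w") as fh:
            for sp, row in zip(aln.taxa, aln.rows):
                fh.write(f">{sp}|{gene}|iso1\n{row}\n")
        meta_rows.append(
            {
                "gene": gene,
                "read_through": int(j < n_read_through),
                "human_duplicate": int(j >= n_read_through),
                "mane_isoform": "iso1",
            }
        )
    pd.DataFrame(meta_rows).to_csv(out / "genes.tsv", sep="\t", index=False)

    # archaic and ape tables for the genes simulated under selection
    sel_sites = [(g, c) for g in gene_names[:n_selected] for c in range(1, n_codons + 1)]
    if sel_sites:
        archaic, ape = simulate_archaic_and_ape_genotypes(sel_sites, {"archaic_state": "derived"}, seed=seed)
        for df, name in ((archaic, "archaic.tsv"), (ape, "ape.tsv")):
            df = df.copy()
            df["gene"] = [s[0] for s in df["site"]]
            df["codon_index"] = [s[1] for s in df["site"]]
            df.drop(columns=["site"]).to_csv(out / name, sep="\t", index=False)

    if minor_allele_codon is not None and n_selected > 0:
        gene = gene_names[0]
        pd.DataFrame(
            [
                {
                    "gene": gene, "codon_index": minor_allele_codon, "snp_id": "rs_synthetic_1",
                    "ancestral": "ANC", "derived": "DER", "population": "ALL", "derived_freq": 0.25,
                }
            ]
        ).to_csv(out / "variants.tsv", sep="\t", index=False)

    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return out
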