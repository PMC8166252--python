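# primsel

Detection and verification of episodic positive selection in primate
protein-coding genes.

Comparative screens ask whether a gene accumulated an excess of amino-acid
changing substitutions on one branch of the species tree — here the human
terminal branch (Hominina) or the great-ape stem (Hominidae) of a fixed
27-species primate phylogeny. The statistic is ω = dN/dS under a GY94 codon
model: a fraction of sites with ω > 1 restricted to the foreground branch is
the signature of an episodic selective sweep. Because every such test also
fires on alignment artifacts and on standing variation (an "ancestral" allele
that still segregates in modern humans is not a fixed human-specific change),
the screen combines:

1. **curation** — read-through/recent-duplicate filters, clustering of
   orthologous isoforms around the human MANE sequence at ≥ 80% protein
   identity, species-tree pruning;
2. **codon alignment** — protein alignment along the guide tree,
   back-translation, explicit logged column masks;
3. **two independent gene-level tests** — the branch-site likelihood-ratio
   test (mixture Model A: classes with ω0 ≤ 1, ω = 1, and ω2 ≥ 1 on the
   foreground only; LRT of ω2 = 1 against χ²₁) and a per-branch
   random-effects test (foreground two-class ω distribution against a free
   background ω), with Benjamini–Hochberg correction;
4. **two site-level detectors** — Bayes empirical Bayes posteriors over a
   parameter grid, and a per-site episodic LRT — intersected so only
   codons supported by both methods survive;
5. **verification** — candidate codons are screened against modern-human
   allele frequencies and linkage-disequilibrium blocks
   (r² = D²/(p_A p_a p_B p_b)), classified as true PSS / minor-allele
   artifact / false positive, dated against Neanderthal and Denisovan
   genotypes, and checked for incomplete lineage sorting in a 180-individual
   great-ape panel.

A synthetic-data module generates every input the pipeline consumes (codon
alignments evolved under the branch-site mixture on the primate tree,
population variant tables with controlled frequencies and LD, archaic/ape
genotypes), so the whole screen is testable end to end. See
`docs/methods.md` for models, fitting strategy and limitations.

## Worked example

The packaged worked example is the screen's verification step on twelve
candidate positively selected codons in three genes (MAMLD1, PRDM9, ZNF860):

```bash
python analysis/03_verify_worked_example.py
```

prints (abridged):

```
  gene  codon           call            dating                              rationale
MAMLD1    726       TRUE_PSS PRE_ARCHAIC_SPLIT  no modern-human polymorphism recorded
 PRDM9    573       TRUE_PSS PRE_ARCHAIC_SPLIT  rare independent back-variant (max ancestral freq 0.02)
 PRDM9    681   MINOR_ALLELE           UNDATED  derived allele is the minor allele overall (ancestral freq 0.75); ...
ZNF860    348 FALSE_POSITIVE           UNDATED  ancestral allele common in >=1 population (max 0.8); member of a candidate haplo-block (r2 >= 0.5)
...
9 true PSS, 1 minor-allele, 2 false-positive; 9 true PSS predate the archaic split
```

Reading: a codon with no recorded human polymorphism, or whose ancestral
state survives only as a rare independent back-variant (frequency ≤ 0.10, no
LD), is a true positively selected site; PRDM9 681, where the "ancestral"
allele is the 75% majority, is an artifact of the reference-genome allele
choice; the ZNF860 pair travels on one haplotype block (r² ≥ 0.5) of common
ancestral variation and is discarded. All nine surviving sites carry the
derived state in the archaic genomes, dating the selection before the
Neanderthal/Denisovan split.

A full synthetic screen — six genes on the 27-primate tree, one evolved with
a strong selective episode on the human branch, plus two flagged decoys:

```bash
python analysis/01_simulate_screen.py --seed 1
python analysis/02_run_screen.py --seed 1
```

With seed 1 the selected gene is recovered by both tests (branch-site LRT
statistic 42.8, p ≈ 6e-11; branch test statistic 42.4) and is the only
consensus gene; its six both-method consensus sites all classify as true PSS
predating the archaic split. The two decoys are removed by the curation
filters, and the five null genes stay non-significant.

The same stages are scriptable via the CLI
(`primsel simulate | curate | align | test | verify | report | run-all`).

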