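# Methods

`primsel` re-implements, at desk scale, a comparative screen for episodic
positive selection in primate protein-coding genes, together with the
population-genetic verification step that separates genuinely fixed,
human-specific substitutions from standing variation. This note records the
models, the numerical strategy, and the design decisions that were genuinely
open.

## Substitution model

Codon evolution follows the Goldman–Yang (GY94) parameterization over the 61
sense codons of the universal code. Instantaneous rates between codons
differing at one nucleotide position are proportional to the target codon
frequency π_j, multiplied by κ for transitions and by ω = dN/dS for
non-synonymous changes; multi-step changes have rate zero. Codon frequencies
default to F3x4 (position-specific nucleotide frequencies estimated from the
alignment, with a 0.5 pseudo-count so every sense codon keeps positive
frequency); F1x4 and equal frequencies are options. Stop codons are excluded
from the state space, and alignments containing in-frame stops are rejected
upstream rather than silently repaired. Ambiguous codons (N, gaps) are
missing data and contribute all-ones partial likelihoods.

**Rate normalization.** A single-ratio matrix is scaled so that
−Σ π_i q_ii = 1 (branch lengths in expected substitutions per codon, the
usual M0 convention). Matrices belonging to different site classes of a
mixture are instead all divided by the rate the same (κ, π) would have at
ω = 1. This keeps one clock across classes: a class with ω > 1 substitutes
*faster* than a neutral class, rather than merely recomposing the same number
of substitutions, and branch lengths are in neutral-equivalent substitutions
per codon. Without a shared clock the branch-site test loses essentially all
its power (elevated ω2 would change only the synonymous/non-synonymous
composition of a fixed number of events on one short branch). The common
alternative — normalizing by the proportion-weighted mixture rate — ties the
per-site class likelihoods to the mixture proportions and would preclude the
profile-likelihood strategy below; the neutral normalization is
proportion-free and self-consistent between the simulator and the fitted
model, which share one likelihood engine.

## Branch-site mixture (Model A)

Sites fall into four latent classes: class 0 (ω0 ≤ 1 on every branch), class
1 (ω = 1 everywhere), and classes 2a/2b, which behave like classes 0 and 1 on
background branches but switch to ω2 ≥ 1 on the designated foreground branch
(the human terminal branch, Hominina, or the great-ape stem, Hominidae).
Proportions are (p0, p1, p2a, p2b) with p2a = (1−p0−p1)·p0/(p0+p1) and p2b
defined analogously. The null model fixes ω2 = 1; the likelihood-ratio
statistic 2ΔlnL is referred to χ²₁ by default (a 50:50 mixture of a point
mass at zero and χ²₁ — the boundary null — is selectable and is the default
for the per-branch random-effects test).

## Likelihood computation

Per-site likelihoods come from Felsenstein pruning with per-node rescaling
and site-pattern compression. Transition matrices use the symmetric
eigendecomposition available for reversible models
(P(t) = Π^{-1/2} W e^{Λt} W' Π^{1/2}); a scaling-and-squaring matrix
exponential is kept as the reference route, and the two agree to ~1e-10.

The fits exploit a factorization around the foreground edge: one "edge pass"
with a background model produces, for every site pattern, the tip-side
partial vector of the foreground subtree and the root-side (outside) vector
of everything else, after which the site likelihood under *any* foreground ω
is a 61×61 bilinear form. One pass per candidate background ω therefore
serves every candidate foreground ω — the property all model fits here are
built on.

## Fitting strategy

κ is estimated under the one-ratio model (bounded L-BFGS-B over log κ, log ω,
optionally a log global branch-length multiplier) and held fixed for the
branch-site fit; an optional coordinate-ascent refinement re-estimates κ
under the alternative model (used for parameter-recovery experiments).
Relative branch lengths always come from the species tree; when requested, a
single global scale factor is fit under M0 — per-branch re-estimation is out
of scope at desk scale.

The Model A fit profiles ω0 (grid 0.02–1.0 with bounded Brent refinement) and
ω2 (grid 1–120, refined continuously up to 500), maximizing over (p0, p1) at
each grid point by EM. The EM is closed-form because the Model A proportions
factor as (s·a, s(1−a), (1−s)a, (1−s)(1−a)) with s = p0+p1 and a = p0/(p0+p1):
the M-step updates s and a from summed responsibilities. The likelihood is
not jointly concave in (s, a), so the EM runs from two starts; grid points
act as the multi-start mechanism for the ω parameters. Null (ω2 = 1) and
alternative optima come from a single shared grid sweep, so the alternative
search space contains the null optimum and the LRT statistic is non-negative
by construction (a final clamp removes refinement round-off). Tolerances: EM
stops at an absolute log-likelihood gain below 1e-6 (1e-7 single-combination),
1-D refinements use bounded Brent with ≤ 12 iterations.

The per-branch random-effects test gives the foreground branch a two-class ω
distribution {ω− ≤ 1 with probability 1−w, ω+ with probability w} and the
background branches one shared free, uncapped ω; the null caps ω+ at 1. The
weight w has a concave one-dimensional likelihood and is fit by EM, batched
across the (ω−, ω+) grid. A per-branch free background ω (the full
random-effects construction) would add ~50 parameters at 27 taxa and is out
of scope; the shared background ω preserves the test's distinguishing
feature — selection pressure differing between foreground and background.

**Site-level detection.** Bayes empirical Bayes posteriors integrate
(p0+p1, p0/(p0+p1), ω0, ω2) over a uniform 10-point-per-dimension grid with
equal prior mass per cell (ω0 on (0,1), ω2 on (1,11)), κ and π fixed at their
MLE; sites with posterior ≥ 0.95 (configurable) are flagged. The per-site
episodic test fits each site with a shared background/foreground ω− ≤ 1 plus
a free foreground ω+ (null: ω+ ≤ 1), profiling both on grids; with a single
foreground branch the within-site mixture weight maximizes at a boundary, so
the grid profile is exact up to grid resolution. P-values use an equal-weight
χ²₁/χ²₂ mixture as an approximate null, validated by the size simulation in
the test suite (empirical site-level false-positive rate ≤ 0.08 at α = 0.05).

**Consensus.** Candidate genes must reach raw p < α (default 0.05) under
*both* gene-level tests (Benjamini–Hochberg q-values are reported alongside);
candidate sites within candidate genes must be flagged by both BEB and the
per-site test. Coordinates are 1-based codon indices in the human
representative isoform everywhere.

## Curation and alignment

Read-through transcripts and genes duplicated on the human lineage after the
Homo–Pan split are excluded outright. For each surviving gene the human MANE
isoform anchors a deterministic greedy centroid clustering of all non-human
isoforms (human protein is the first centroid; candidates visited
longest-first; join threshold 80% protein identity by global alignment,
identical positions over aligned columns). Only the human-containing cluster
is analyzed, one isoform per species (tie-break: identity to human, then
length, then id). Whether the published threshold was nucleotide- or
protein-level identity is not recorded; protein identity is used. Genes with
fewer than three species after selection are dropped — a two-taxon tree
cannot support a branch-site test.

Proteins are aligned progressively along the species tree with affine-gap
Gotoh profile alignment (BLOSUM62, gap open −10, extend −0.5; deterministic
tie-breaks), then back-translated so each amino acid is replaced by its
source codon and each gap by `---`. Manual alignment curation is replaced by
two explicit, logged mechanisms: user-supplied column masks and a
gap-fraction auto-mask (columns with < 50% non-gap taxa dropped by default).

## Verification of candidate sites

Candidate codons are screened against modern-human population variation.
With derived-allele frequencies per population and phased haplotypes for LD
(r² = D²/(p_A p_a p_B p_b), zero and noted when a site is monomorphic), the
classifier applies, in order: (1) no recorded polymorphism → true PSS;
(2) ancestral allele everywhere rare (≤ 0.10) and no LD with other candidates
→ true PSS, rare independent back-variant; (3) ancestral allele the overall
majority (≥ 0.50) without LD evidence → minor-allele artifact of the
reference genome; (4) ancestral allele common in some population and/or
membership in a candidate haplo-block (r² ≥ 0.5) → false positive.
Polymorphic sites falling between rules (ancestral frequency in (0.10, 0.50),
no LD) are conservatively called false positives. The published account
gives exemplar frequencies, not cut-offs; the defaults reproduce every
decision of the worked example and are exposed in configuration. LD is
computed only among candidate sites within the same gene.

True PSS are dated against archaic genomes (Vindija and Altai Neanderthals,
Denisovan): all non-missing archaic genotypes derived → the selective episode
predates the archaic/modern split; any ancestral or heterozygous archaic
genotype flags a post-split candidate; missing data leave the site undated
but never revoke the call. A great-ape panel (defaults 111 chimpanzees, 17
bonobos, 42 gorillas, 10 orangutans) is summarized per taxon; sites
monomorphic-ancestral across all covered taxa receive a note that no
incomplete-lineage-sorting signal is present.

## Synthetic data

The generator emulates the screen's inputs rather than any particular genome:

* **Codon alignments** evolve by sampling from the exact transition matrices
  of the likelihood engine along the fixed 27-taxon primate topology, site
  classes drawn from the Model A mixture, ancestral codons from π. Simulator
  and model are the same stochastic process, so fits are exactly specified.
* **Branch lengths** are uniform and scalable; the default 0.05 expected
  substitutions per codon per branch gives a root-to-tip depth near 0.4,
  matching typical primate codon-tree depth. A uniform tree cannot
  simultaneously match the short human terminal branch (~0.02) and the deep
  strepsirrhine branches; this is a known limitation — power estimates on the
  uniform tree are optimistic for the human branch relative to real data.
* **Variant tables** draw phased haplotypes per population; LD blocks use a
  latent two-background mixture (each haplotype samples a Bernoulli(θ)
  background; site i is derived with probability a_i or b_i given the
  background, with a_i − b_i ∝ σ_i so every within-block pair hits the target
  r² in closed form; θ is searched for feasibility, and unattainable targets
  raise an error).
* **Archaic and ape genotypes** are generated per site from explicit state
  specifications with an optional missing rate.

What the generator does **not** emulate: indels and frameshifts, alignment
error, recombination within genes, non-equilibrium codon usage, assembly and
annotation artifacts, and gene-tree/species-tree discordance (incomplete
lineage sorting enters only through the verification tables, not the
sequences). Passing tests therefore demonstrate correctness and calibration
of the *methods* under their own model, not robustness of the screen to real
data pathologies — the screen's published workflow addresses those with
manual curation, which is here replaced by explicit masks.

Default generating conditions for experiments: κ = 2, ω0 = 0.2, null
proportions p0 = p1 = 0.45 (10% of sites in the fg-neutral classes), selected
genes p0 = 0.5, p1 = 0.35 (p2 ≈ 0.15) with ω2 = 8, uniform π. Problem sizes
used by the test suite: 200 null replicates of 300 codons (type-I error),
20 replicates of 500 codons (power), 100 replicates of 100 codons (site-level
size), 10 replicates of 2,000 codons (parameter recovery, ω2 = 5), chosen so
each experiment answers its question at single-workstation scale.

## Known limitations

* The ω0/ω2 grids make the gene-level LRTs mildly conservative (a grid
  optimum can only undershoot the continuous one); the size simulations
  bound the effect.
* κ fixed at its M0 estimate during the branch-site fit can bias κ̂ slightly
  under strong selection; the refinement option removes this for recovery
  experiments.
* The per-branch random-effects test is a two-class, shared-background
  simplification; it is not the adaptive-complexity construction, and its
  p-values (boundary mixture) are approximate.
* Verification thresholds are calibrated to the worked example only; real
  applications should treat them as tunable analysis parameters.
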