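"""Synthetic inputs for the selection screen.

Three generators stand in for the real data the screen consumes:

* codon alignments evolved on the primate species tree under the branch-site
  mixture, by sampling from the exact transition matrices of the likelihood
  engine (simulator and model are the same process by construction);
* population variant tables with controlled per-population derived-allele
  frequencies and haplotype linkage-disequilibrium blocks hitting a target
  r-squared through a two-haplotype-background mixture with closed-form r2;
* archaic-human and great-ape panel genotype tables (default panel sizes:
  111 chimpanzees, 17 bonobos, 42 gorillas, 10 orangutans).

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from primsel.codons import N_CODONS, SENSE_CODONS
from primsel.likelihood import SiteClassMixture
from primsel.msa import CodonAlignment
from primsel.ratematrix import CodonSubstitutionModel
from primsel.trees import PhyloTree

APE_PANEL_SIZES = {"chimpanzee": 111, "bonobo": 17, "gorilla": 42, "orangutan": 10}
ARCHAIC_INDIVIDUALS = ("Vindija", "Altai", "Denisova")


@dataclass
class SimulationConfig:
    """Configuration of one simulated codon alignment."""

    tree: PhyloTree
    n_codons: int
    mixture: SiteClassMixture
    seed: int
    foreground_branch: Optional[str] = None  # overrides the tree's marking

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.foreground_branch is not None:
            self.tree = PhyloTree(self.tree.tree, self.foreground_branch)
        if self.tree.foreground is None:
            raise ValueError("simulation requires a foreground-marked tree")
        if len(self.tree) < 2:
            raise ValueError("tree must have at least two leaves")
        props = self.mixture.proportions
        if np.any(props < -1e-12) or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("mixture proportions must lie in [0,1] and sum to 1")


def simulate_codon_alignment(config: SimulationConfig) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve codons along the tree under the branch-site mixture.

    Each site draws a latent class (0, 1, 2a, 2b) from the mixture; the
    ancestral codon is drawn from pi, and each branch applies the exact
    transition matrix of its class-specific omega (foreground omega on the
    marked branch, background omega elsewhere).  Returns the leaf alignment
    and the latent class label per site.
    """
    mix = config.mixture
    rng = np.random.default_rng(config.seed)
    tree = config.tree
    fg = tree.foreground_node()

    models = {}
    for w in {mix.omega0, 1.0, mix.omega2}:
        models[w] = CodonSubstitutionModel(mix.kappa, w, mix.pi)
    bg_omega = mix.background_omegas()
    fg_omega = mix.foreground_omegas()

    n = config.n_codons
    props = np.clip(mix.proportions, 0.0, None)
    classes = rng.choice(4, size=n, p=props / props.sum())
    root_states = rng.choice(N_CODONS, size=n, p=mix.pi / mix.pi.sum())

    states = {id(tree.tree.seed_node): root_states}
    leaf_states: dict[str, np.ndarray] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_states = states[id(node.parent_node)]
        t = node.edge.length if node.edge.length is not None else 0.0
        omega_by_class = fg_omega if node is fg else bg_omega
        child = np.empty(n, dtype=np.int64)
        for cls in range(4):
            idx = np.nonzero(classes == cls)[0]
            if idx.size == 0:
                continue
            P = models[omega_by_class[cls]].P(t)
            cum = np.cumsum(P, axis=1)
            cum[:, -1] = 1.0
            u = rng.random(idx.size)
            rows = cum[parent_states[idx]]
            child[idx] = (rows < u[:, None]).sum(axis=1)
        states[id(node)] = child
        if node.is_leaf():
            leaf_states[node.taxon.label] = child

    taxa = tree.leaf_labels
    rows = ["".join(SENSE_CODONS[s] for s in leaf_states[t]) for t in taxa]
    return CodonAlignment(taxa, rows), classes


# ---------------------------------------------------------------------------
# population variant tables with LD blocks


@dataclass
class LDBlock:
    """Sites sharing one haplotype background with a common target r-squared."""

    sites: list
    r2: float


@dataclass
class VariantSimConfig:
    """Configuration of a simulated population variant table.

    ``freqs`` maps site -> population -> target derived-allele frequency.
    ``panel_sizes`` gives phased haplotype counts per population.  Sites in an
    LD block share haplotype structure; each site may belong to at most one
    block.
    """

    freqs: Mapping[object, Mapping[str, float]]
    panel_sizes: Mapping[str, int]
    ld_blocks: Sequence[LDBlock] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for site, by_pop in self.freqs.items():
            for pop, f in by_pop.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"frequency out of [0,1] at {site}/{pop}")
        for pop, nh in self.panel_sizes.items():
            if nh <= 0:
                raise ValueError(f"panel size must be positive for {pop}")
        seen = set()
        for block in self.ld_blocks:
            if not 0.0 <= block.r2 <= 1.0:
                raise ValueError("target r2 must lie in [0,1]")
            for s in block.sites:
                if s in seen:
                    raise ValueError(f"site {s} appears in more than one LD block")
                seen.add(s)
                if s not in self.freqs:
                    raise ValueError(f"LD block site {s} has no frequency entry")


@dataclass
class VariantTable:
    """Simulated population variation: realized frequencies plus haplotypes."""

    frequencies: pd.DataFrame  # site, population, target_freq, realized_freq, monomorphic
    haplotypes: dict[str, pd.DataFrame]  # population -> (haplotype x site) 0/1 matrix


def _ld_block_params(p: np.ndarray, r2: float) -> tuple[float, np.ndarray, np.ndarray]:
    """Find a two-background mixture hitting pairwise r2 for sites with freqs p.

    Haplotypes draw a latent background U ~ Bernoulli(theta); site i is derived
    with probability a_i when U = 1 and b_i when U = 0, independently given U.
    Choosing a_i - b_i = k * sigma_i with theta * (1 - theta) * k**2 = r (the
    signed correlation, here +sqrt(r2)) gives corr(i, j) = r for every pair,
    hence r-squared r2, in closed form.  theta is searched for feasibility
    (all a_i, b_i within [0, 1]).
    """
    r = float(np.sqrt(r2))
    sigma = np.sqrt(p * (1 - p))
    if r == 0.0:
        return 0.5, p.copy(), p.copy()
    if r2 >= 1.0:
        # perfect LD forces identical columns, attainable only at equal freqs
        if np.ptp(p) > 1e-12:
            raise ValueError(f"r2=1 unattainable for unequal frequencies {p.tolist()}")
        return float(p[0]), np.ones_like(p), np.zeros_like(p)
    for theta in np.linspace(0.5, 0.99, 50):
        for th in (theta, 1 - theta):
            k = np.sqrt(r / (th * (1 - th)))
            a = p + (1 - th) * k * sigma
            b = p - th * k * sigma
            if np.all((a >= -1e-12) & (a <= 1 + 1e-12) & (b >= -1e-12) & (b <= 1 + 1e-12)):
                return th, np.clip(a, 0, 1), np.clip(b, 0, 1)
    raise ValueError(f"target r2={r2} unattainable for site frequencies {p.tolist()} (configuration error)")


def simulate_variant_table(config: VariantSimConfig) -> VariantTable:
    """Sample phased haplotype panels with target frequencies and LD structure."""
    rng = np.random.default_rng(config.seed)
    sites = list(config.freqs)
    in_block = {s: blk for blk in config.ld_blocks for s in blk.sites}

    haplotypes: dict[str, pd.DataFrame] = {}
    rows = []
    for pop, n_hap in config.panel_sizes.items():
        mat = np.zeros((n_hap, len(sites)), dtype=np.int8)
        col = {s: i for i, s in enumerate(sites)}
        done = set()
        for blk in config.ld_blocks:
            p = np.array([config.freqs[s].get(pop, 0.0) for s in blk.sites])
            theta, a, b = _ld_block_params(p, blk.r2)
            u = rng.random(n_hap) < theta
            for j, s in enumerate(blk.sites):
                prob = np.where(u, a[j], b[j])
                mat[:, col[s]] = rng.random(n_hap) < prob
                done.add(s)
        for s in sites:
            if s in done:
                continue
            f = config.freqs[s].get(pop, 0.0)
            mat[:, col[s]] = rng.random(n_hap) < f
        hap = pd.DataFrame(mat, columns=[str(s) for s in sites])
        haplotypes[pop] = hap
        for s in sites:
            realized = float(mat[:, col[s]].mean())
            rows.append(
                {
                    "site": s,
                    "population": pop,
                    "target_freq": config.freqs[s].get(pop, 0.0),
                    "realized_freq": realized,
                    "monomorphic": realized in (0.0, 1.0),
                }
            )
    return VariantTable(pd.DataFrame(rows), haplotypes)


# ---------------------------------------------------------------------------
# archaic and great-ape genotypes


def simulate_archaic_and_ape_genotypes(
    sites: Sequence,
    spec: Optional[Mapping] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype tables for archaic humans and the great-ape panel.

    ``spec`` keys (all optional):

    * ``archaic_state`` — ``"derived"`` / ``"ancestral"`` / ``"heterozygous"``
      applied to every site, or a mapping site -> state;
    * ``missing_rate`` — probability an archaic genotype is missing;
    * ``ape_variation`` — ``"none"`` (panel monomorphic ancestral) or a
      mapping site -> ``"none"`` | ``"variable"``;
    * ``panel_sizes`` — mapping taxon -> individual count (defaults to
      111/17/42/10 for chimpanzee/bonobo/gorilla/orangutan).

    The archaic table is long format (site, individual, state); the ape table
    is long format (site, taxon, individual, genotype) with genotypes
    ``"ancestral"`` or ``"derived"``.
    """
    if len(sites) == 0:
        raise ValueError("sites must be non-empty")
    spec = dict(spec or {})
    rng = np.random.default_rng(seed)
    archaic_state = spec.get("archaic_state", "derived")
    missing_rate = float(spec.get("missing_rate", 0.0))
    ape_variation = spec.get("ape_variation", "none")
    panel_sizes = dict(spec.get("panel_sizes", APE_PANEL_SIZES))

    arch_rows = []
    for s in sites:
        state = archaic_state.get(s, "derived") if isinstance(archaic_state, Mapping) else archaic_state
        for ind in ARCHAIC_INDIVIDUALS:
            st = "missing" if rng.random() < missing_rate else state
            arch_rows.append({"site": s, "individual": ind, "state": st})
    archaic = pd.DataFrame(arch_rows)

    ape_rows = []
    for s in sites:
        var = ape_variation.get(s, "none") if isinstance(ape_variation, Mapping) else ape_variation
        for taxon, count in panel_sizes.items():
            if var == "variable":
                genos = np.where(rng.random(count) < 0.2, "derived", "ancestral")
            elif var == "missing":
                genos = np.full(count, "missing", dtype=object)
            else:
                genos = np.full(count, "ancestral", dtype=object)
            for i, g in enumerate(genos):
                ape_rows.append({"site": s, "taxon": taxon, "individual": f"{taxon}_{i + 1}", "genotype": g})
    ape = pd.DataFrame(ape_rows)
    return archaic, ape
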