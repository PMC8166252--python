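"""Primate species tree handling: default topology, foreground marking, pruning.

The screen uses a single fixed species-tree topology for all genes.  Two
foreground branches are of interest: the terminal human branch (subtribe
Hominina) and the stem branch of the great apes (family Hominidae).  Genes
with missing species use a pruned copy of the tree; pruning collapses unary
nodes and sums their branch lengths, so path lengths among surviving taxa are
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import dendropy

#: Leaf-name abbreviations of the 27 primate assemblies used by the screen.
DEFAULT_TAXA = (
    "Ogar Psim Pcoq Mmur Tsyr Cjac Ccap Sbbo Anan Nleu Ppyg Ggor Hsap Ptro "
    "Ppan Ptep Capa Rbie Rrox Csab Mmul Mfas Mnem Panu Tgel Mleu Caty"
).split()

GREAT_APES = frozenset({"Ppyg", "Ggor", "Hsap", "Ptro", "Ppan"})

HOMININA = "Hominina"
HOMINIDAE = "Hominidae"

# Fixed 27-taxon topology: strepsirrhines, tarsier, New World monkeys,
# apes (gibbon + great apes) and Old World monkeys.
_DEFAULT_TOPOLOGY = (
    "((Ogar,((Psim,Pcoq),Mmur)),(Tsyr,(((Cjac,(Ccap,Sbbo)),Anan),"
    "((Nleu,(Ppyg,(Ggor,(Hsap,(Ptro,Ppan))))),"
    "(((Ptep,Capa),(Rbie,Rrox)),(Csab,(((Mmul,Mfas),Mnem),"
    "((Panu,Tgel),(Mleu,Caty)))))))));"
)


class ForegroundError(ValueError):
    """Raised when the requested foreground branch cannot be resolved."""


@dataclass
class PhyloTree:
    """A rooted species tree with an optional foreground-branch marking.

    The foreground is stored as a *label* (``"Hominina"``, ``"Hominidae"`` or
    an explicit leaf/internal-node label) and resolved lazily against the
    current leaf set, so that pruning re-attaches the marking to the surviving
    stem automatically.
    """

    tree: dendropy.Tree
    foreground: Optional[str] = None

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, foreground: Optional[str] = None) -> "PhyloTree":
        t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        t.is_rooted = True
        return cls(t, foreground)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.tree.clone(depth=1), self.foreground)

    # -- basic queries -----------------------------------------------------
    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def __len__(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def total_length(self) -> float:
        return sum(e.length or 0.0 for e in self.tree.edges() if e.head_node is not self.tree.seed_node)

    def scale_lengths(self, factor: float) -> "PhyloTree":
        out = self.copy()
        for e in out.tree.edges():
            if e.length is not None:
                e.length = e.length * factor
        return out

    # -- foreground --------------------------------------------------------
    def foreground_node(self) -> dendropy.Node:
        """Resolve the foreground label to the node below the marked branch."""
        if self.foreground is None:
            raise ForegroundError("no foreground branch marked on this tree")
        labels = set(self.leaf_labels)
        if self.foreground == HOMININA:
            if "Hsap" not in labels:
                raise ForegroundError("Hominina foreground requires the Hsap leaf")
            return self._leaf("Hsap")
        if self.foreground == HOMINIDAE:
            present = sorted(GREAT_APES & labels)
            if not present:
                raise ForegroundError("Hominidae foreground requires at least one great-ape leaf")
            if len(present) == 1:
                return self._leaf(present[0])
            node = self.tree.mrca(taxon_labels=present)
            if node is self.tree.seed_node:
                raise ForegroundError("great-ape stem coincides with the root; foreground undefined")
            return node
        # explicit label: leaf first, then internal node label
        if self.foreground in labels:
            return self._leaf(self.foreground)
        for nd in self.tree.preorder_node_iter():
            if nd.label == self.foreground:
                return nd
        raise ForegroundError(f"unknown foreground label: {self.foreground!r}")

    def _leaf(self, label: str) -> dendropy.Node:
        for lf in self.tree.leaf_node_iter():
            if lf.taxon.label == label:
                return lf
        raise ForegroundError(f"leaf {label!r} not found")


def build_default_tree(
    branch_length_scale: float = 0.05,
    foreground: Optional[str] = None,
) -> PhyloTree:
    """Build the fixed 27-taxon primate species tree.

    Branch lengths are not part of the published topology, so every branch is
    given the uniform length ``branch_length_scale`` (expected substitutions
    per codon).  Supply a full Newick with lengths via
    :meth:`PhyloTree.from_newick` when real lengths are available.

    Parameters
    ----------
    branch_length_scale:
        Uniform branch length, > 0.
    foreground:
        Optional foreground marking: ``"Hominina"`` (terminal human branch),
        ``"Hominidae"`` (great-ape stem) or an explicit leaf label.  Resolved
        eagerly to validate the label.
    """
    if branch_length_scale <= 0:
        raise ValueError("branch_length_scale must be > 0")
    t = PhyloTree.from_newick(_DEFAULT_TOPOLOGY, foreground)
    for e in t.tree.edges():
        if e.head_node is not t.tree.seed_node:
            e.length = branch_length_scale
    if foreground is not None:
        t.foreground_node()  # validate
    return t


def prune_tree(tree: PhyloTree, present_taxa: Iterable[str]) -> PhyloTree:
    """Restrict the tree to ``present_taxa``, collapsing unary nodes.

    Branch lengths of collapsed unary nodes are summed, so pairwise path
    lengths among surviving leaves are unchanged.  The foreground marking is
    preserved (it re-resolves against the surviving leaves); an error is
    raised if it becomes undefinable.
    """
    present = set(present_taxa)
    leaves = set(tree.leaf_labels)
    unknown = present - leaves
    if unknown:
        raise ValueError(f"taxa not in the tree: {sorted(unknown)}")
    if len(present) < 2:
        raise ValueError("at least two taxa must remain after pruning")
    out = tree.copy()
    # the clone initially shares the source namespace; detach it so pruning
    # (and the purge below) cannot mutate the original tree's namespace
    out.tree.migrate_taxon_namespace(dendropy.TaxonNamespace())
    out.tree.retain_taxa_with_labels(sorted(present))
    # removing a whole cherry can leave a taxonless leaf behind
    out.tree.prune_leaves_without_taxa(suppress_unifurcations=True)
    out.tree.purge_taxon_namespace()
    # collapse a degree-one root left behind by pruning
    root = out.tree.seed_node
    while len(root.child_nodes()) == 1:
        child = root.child_nodes()[0]
        out.tree.seed_node = child
        child.parent_node = None
        child.edge.length = None
        root = child
    if out.foreground is not None:
        out.foreground_node()  # raises ForegroundError if no longer definable
    return out
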