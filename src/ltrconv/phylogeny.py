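"""Variant polarization and mutational-event counting on a fixed rooted tree.

The tree is a known scaffold (e.g. the human Y-chromosome haplogroup
phylogeny) and is never re-estimated.  Each biallelic variant is polarized by
Fitch small parsimony: the ancestral allele is the root state under the
most-parsimonious assignment, with ties broken by a designated outgroup tip
or, failing that, by the major allele.  Every state change along an edge is
one mutational event on the branch named after that edge's child node;
variants with more than one event are homoplasic (recurrent or back
mutations).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

from .clusters import fisher_exact_two_sided
from .io_formats import MISSING, Variant, VariantTable

__all__ = [
    "PhyloTree",
    "BranchAssignment",
    "read_newick_tree",
    "polarize_and_assign",
    "count_events",
    "compare_homoplasy_rates",
]


@dataclass(frozen=True)
class _Node:
    name: str  # branch name of the edge above this node ("" for the root)
    children: tuple["_Node", ...]

    @property
    def is_tip(self) -> bool:
        return not self.children


class PhyloTree:
    """A rooted tree with uniquely named branches.

    Every non-root node names the branch (edge) above it; the root carries no
    branch.  Tip names must match the sample columns of the genotype table.
    """

    def __init__(self, root: _Node):
        self.root = root
        self.tips: list[str] = []
        self.branches: list[str] = []
        self._collect(root, at_root=True)
        dup = [b for b, c in Counter(self.branches).items() if c > 1]
        if dup:
            raise ValueError(f"duplicate branch names: {dup}")
        dup = [t for t, c in Counter(self.tips).items() if c > 1]
        if dup:
            raise ValueError(f"duplicate tip names: {dup}")

    def _collect(self, node: _Node, at_root: bool = False) -> None:
        if not at_root:
            self.branches.append(node.name)
        if node.is_tip:
            self.tips.append(node.name)
        for child in node.children:
            self._collect(child)

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick", suppress_internal_node_taxa=True)
        counter = 0

        def build(node: dendropy.Node, at_root: bool) -> _Node:
            nonlocal counter
            label = None
            if node.taxon is not None and node.taxon.label:
                label = node.taxon.label
            elif node.label:
                label = node.label
            if label is None:
                if at_root:
                    label = "root"  # the root carries no branch; name is cosmetic
                else:
                    # unlabeled branches are auto-named b1..bk in preorder so
                    # branch assignments are reproducible
                    counter += 1
                    label = f"b{counter}"
            children = tuple(build(c, False) for c in node.child_nodes())
            return _Node(name=str(label).replace(" ", "_"), children=children)

        root = build(tree.seed_node, True)
        return cls(root)


def read_newick_tree(path: str | Path) -> PhyloTree:
    """Parse a single rooted Newick tree; unlabeled branches are auto-named
    "b1…bk" in preorder so branch assignments are reproducible."""
    text = Path(path).read_text().strip()
    if text.count("(") != text.count(")"):
        raise ValueError(f"{path}: unbalanced parentheses in Newick string")
    return PhyloTree.from_newick(text)


@dataclass
class BranchAssignment:
    """Polarized placement of one variant's mutational events on the tree."""

    variant: str
    ancestral_allele: str
    derived_allele: str
    events: list[tuple[str, str]]  # (branch, direction in {forward, back})
    placement_ambiguous: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def homoplasic(self) -> bool:
        return self.n_events > 1

    @property
    def forward_branches(self) -> list[str]:
        return [b for b, d in self.events if d == "forward"]


def _fitch_down(node: _Node, genotypes: dict[str, str], alleles: set[str], sets: dict) -> set[str]:
    if node.is_tip:
        allele = genotypes.get(node.name, MISSING)
        s = alleles.copy() if allele == MISSING else {allele}
    else:
        child_sets = [_fitch_down(c, genotypes, alleles, sets) for c in node.children]
        inter = set.intersection(*child_sets)
        s = inter if inter else set.union(*child_sets)
    sets[id(node)] = s
    return s


def _fitch_up(node: _Node, parent_state: str, sets: dict, states: dict) -> None:
    s = sets[id(node)]
    states[id(node)] = parent_state if parent_state in s else min(s)
    for child in node.children:
        _fitch_up(child, states[id(node)], sets, states)


def polarize_variant(
    variant: Variant, tree: PhyloTree, outgroup: str | None = None
) -> BranchAssignment | None:
    """Fitch-polarize one biallelic variant; returns None if non-segregating
    or all genotypes are missing."""
    genotypes = variant.genotypes
    for sample in genotypes:
        if sample not in tree.tips:
            raise ValueError(f"sample {sample!r} is not a tip of the tree")
    observed = {a for a in genotypes.values() if a != MISSING}
    if len(observed) > 2:
        raise ValueError(f"variant {variant.name!r} is multi-allelic: {sorted(observed)}")
    if len(observed) < 2:
        return None  # non-segregating (or all-missing): nothing to place

    alleles = set(variant.alleles)
    sets: dict = {}
    internal_ids: list[int] = []

    def collect_internal(node: _Node) -> None:
        if not node.is_tip:
            internal_ids.append(id(node))
            for c in node.children:
                collect_internal(c)

    collect_internal(tree.root)
    root_set = _fitch_down(tree.root, genotypes, alleles, sets)

    if len(root_set) == 1:
        (ancestral,) = root_set
    elif outgroup is not None and genotypes.get(outgroup, MISSING) != MISSING:
        ancestral = genotypes[outgroup]
    else:
        counts = Counter(a for a in genotypes.values() if a != MISSING)
        ancestral = max(sorted(counts), key=lambda a: counts[a])
    derived = next(a for a in sorted(alleles) if a != ancestral)

    states: dict = {}
    states[id(tree.root)] = ancestral
    for child in tree.root.children:
        _fitch_up(child, ancestral, sets, states)

    # multiple equally parsimonious labelings exist only if some internal
    # node's down-pass set is non-singleton (missing tips are unconstrained
    # by design and do not count as ambiguity)
    ambiguous = any(len(sets[k]) > 1 for k in internal_ids)

    events: list[tuple[str, str]] = []

    def walk(node: _Node) -> None:
        parent_state = states[id(node)]
        for child in node.children:
            child_state = states[id(child)]
            if child_state != parent_state:
                direction = "forward" if child_state == derived else "back"
                events.append((child.name, direction))
            walk(child)

    walk(tree.root)
    return BranchAssignment(
        variant=variant.name,
        ancestral_allele=ancestral,
        derived_allele=derived,
        events=events,
        placement_ambiguous=ambiguous,
        flags=list(variant.flags),
    )


def polarize_and_assign(
    variants: VariantTable | Iterable[Variant],
    tree: PhyloTree,
    outgroup: str | None = None,
) -> list[BranchAssignment]:
    """Polarize every variant on the tree and assign events to branches.

    Variants whose genotypes are all missing are skipped (with a flag in the
    returned list omitted entirely); the variant table is also updated in
    place with the inferred ancestral/derived alleles.
    """
    assignments = []
    for variant in variants:
        assignment = polarize_variant(variant, tree, outgroup=outgroup)
        if assignment is None:
            continue
        variant.ancestral_allele = assignment.ancestral_allele
        variant.derived_allele = assignment.derived_allele
        assignments.append(assignment)
    return assignments


@dataclass(frozen=True)
class EventSummary:
    total_events: int
    n_variants: int
    n_homoplasic: int
    recurrent_events: int
    per_variant: dict[str, int]


def count_events(assignments: Sequence[BranchAssignment]) -> EventSummary:
    """Summarize mutational events: totals, homoplasy counts, and the extra
    (recurrent) events beyond one per variant.

    Satisfies the identity total_events = n_variants + recurrent_events for
    biallelic variants.
    """
    per_variant = {a.variant: a.n_events for a in assignments}
    total = sum(per_variant.values())
    homoplasic = sum(1 for a in assignments if a.homoplasic)
    recurrent = sum(a.n_events - 1 for a in assignments if a.homoplasic)
    return EventSummary(
        total_events=total,
        n_variants=len(assignments),
        n_homoplasic=homoplasic,
        recurrent_events=recurrent,
        per_variant=per_variant,
    )


def compare_homoplasy_rates(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact test comparing homoplasic fractions k1/n1 vs
    k2/n2 between two datasets."""
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n):
            raise ValueError("need 0 <= k <= n")
    return fisher_exact_two_sided(k1, n1 - k1, k2, n2 - k2)
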