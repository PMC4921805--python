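import itertools

import pytest

from ltrconv.io_formats import Variant
from ltrconv.phylogeny import PhyloTree


@pytest.fixture
def quartet_tree() -> PhyloTree:
    return PhyloTree.from_newick("((A,B)ab,(C,D)cd)root;")


def make_snp(name, pos, genotypes, alleles=None):
    """Build a SNP variant from a sample->base mapping."""
    if alleles is None:
        obs = sorted({a for a in genotypes.values() if a != "N"})
        alleles = tuple(obs) if len(obs) == 2 else (obs[0], "T" if obs[0] != "T" else "C")
    return Variant(name=name, chrom="chrY", pos=pos, type="SNP", indel_length=0,
                   alleles=tuple(alleles), genotypes=dict(genotypes))


def brute_force_parsimony(tree: PhyloTree, genotypes: dict, alleles) -> int:
    """Minimum number of state changes over ALL labelings of internal nodes
    (and of missing tips), by exhaustive enumeration.  Oracle for Fitch."""
    nodes = []

    def collect(node):
        nodes.append(node)
        for c in node.children:
            collect(c)

    collect(tree.root)
    free = [n for n in nodes
            if not n.is_tip or genotypes.get(n.name, "N") == "N"]
    fixed = {id(n): genotypes[n.name] for n in nodes
             if n.is_tip and genotypes.get(n.name, "N") != "N"}
    best = len(nodes)
    for combo in itertools.product(alleles, repeat=len(free)):
        states = dict(fixed)
        states.update({id(n): s for n, s in zip(free, combo)})
        changes = 0

        def walk(node):
            nonlocal changes
            for c in node.children:
                if states[id(c)] != states[id(node)]:
                    changes += 1
                walk(c)

        walk(tree.root)
        best = min(best, changes)
    return best


def brute_force_clusters(events, max_gap):
    """Independent chaining oracle: same-branch transitive closure of the
    'within max_gap' relation, components of size >= 2, as member-name sets."""
    out = []
    branches = {b for _, _, b in events}
    for branch in branches:
        items = sorted((p, n) for n, p, b in events if b == branch)
        n = len(items)
        # adjacency: consecutive-in-position within max_gap, then closure
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                between = [p for p, _ in items[i + 1 : j]]
                chain = [items[i][0]] + between + [items[j][0]]
                if all(b - a <= max_gap for a, b in zip(chain, chain[1:])):
                    parent[find(i)] = find(j)
        comps = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(items[i][1])
        out.extend(frozenset(m) for m in comps.values() if len(m) >= 2)
    return set(out)
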