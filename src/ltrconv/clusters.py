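"""Clustered-variant detection and its significance machinery.

A cluster is two or more variants that arose on the same branch of the fixed
phylogeny with every adjacent pair no more than ``max_gap`` bp apart
(single-linkage chaining; the default gap is 50 bp).  Such clusters are the
signature of a single ectopic gene-conversion event copying a tract that
contains several paralogous sequence variants.

The excess of clustered variants over chance is quantified by a permutation
null — variant positions uniform without replacement over the sequenced
length, branch labels uniform over the branches — whose mean clustered count
λ feeds a Poisson upper-tail probability, computed in log space so values far
below the double-precision floor survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import fisher_exact

__all__ = [
    "SNPCluster",
    "PermutationNull",
    "detect_clusters",
    "cluster_span",
    "permutation_null",
    "poisson_tail_p",
    "poisson_tail_log10_p",
    "fisher_exact_two_sided",
    "clustered_proportion",
]

DEFAULT_MAX_GAP = 50


@dataclass(frozen=True)
class SNPCluster:
    """A maximal chain of same-branch variants with adjacent gaps ≤ max_gap."""

    id: int
    branch: str
    members: tuple[str, ...]  # variant names, in position order
    positions: tuple[int, ...]
    region: str = ""

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster needs at least two members")
        if list(self.positions) != sorted(self.positions):
            raise ValueError("cluster positions must be sorted")

    @property
    def start(self) -> int:
        return self.positions[0]

    @property
    def end(self) -> int:
        return self.positions[-1]

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def degenerate(self) -> bool:
        return self.start == self.end


def cluster_span(start: int, end: int) -> int:
    """Inclusive span in bp between the outermost member positions."""
    if end < start:
        raise ValueError("end < start")
    return end - start + 1


def detect_clusters(
    events: Iterable[tuple[str, int, str]],
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[SNPCluster]:
    """Chain same-branch variant events into clusters.

    Parameters
    ----------
    events : iterable of (variant_name, position, branch).  A homoplasic
        variant contributes one entry per branch event, so it can belong to
        one cluster per branch.
    max_gap : maximum distance in bp between adjacent members.

    Clusters are maximal chains of size ≥ 2, ordered by (start position,
    branch) and numbered from 1.
    """
    by_branch: dict[str, list[tuple[int, str]]] = {}
    for name, pos, branch in events:
        by_branch.setdefault(branch, []).append((pos, name))

    raw: list[tuple[int, str, list[tuple[int, str]]]] = []
    for branch, items in by_branch.items():
        items.sort()
        chain: list[tuple[int, str]] = []
        for item in items:
            if chain and item[0] - chain[-1][0] > max_gap:
                if len(chain) >= 2:
                    raw.append((chain[0][0], branch, chain))
                chain = []
            chain.append(item)
        if len(chain) >= 2:
            raw.append((chain[0][0], branch, chain))

    raw.sort(key=lambda r: (r[0], r[1]))
    clusters = []
    for cid, (_, branch, chain) in enumerate(raw, 1):
        clusters.append(
            SNPCluster(
                id=cid,
                branch=branch,
                members=tuple(name for _, name in chain),
                positions=tuple(pos for pos, _ in chain),
            )
        )
    return clusters


@dataclass
class PermutationNull:
    """Null distribution of the clustered-variant count under randomization."""

    n_variants: int
    L: int
    n_branches: int
    max_gap: int
    reps: int
    seed: int
    null_clustered_counts: np.ndarray = field(repr=False)

    @property
    def lam(self) -> float:
        return float(np.mean(self.null_clustered_counts))


def _count_clustered(positions: np.ndarray, branches: np.ndarray, max_gap: int) -> int:
    """Number of variants that belong to some same-branch cluster."""
    order = np.lexsort((positions, branches))
    pos = positions[order]
    br = branches[order]
    same = np.zeros(len(pos), dtype=bool)
    if len(pos) > 1:
        near = (np.diff(pos) <= max_gap) & (br[:-1] == br[1:])
        same[:-1] |= near
        same[1:] |= near
    return int(same.sum())


def permutation_null(
    n_variants: int,
    L: int,
    n_branches: int,
    reps: int = 1000,
    max_gap: int = DEFAULT_MAX_GAP,
    seed: int = 0,
    replace_positions: bool = False,
) -> PermutationNull:
    """Randomize variant positions and branch labels; count clustered variants.

    Positions are drawn uniformly from 1..L without replacement (distinct
    sites) by default; branch labels are independent uniform over
    ``n_branches``.  Reproducible given ``seed``.
    """
    if n_variants < 2:
        raise ValueError("need at least two variants")
    if n_variants > L and not replace_positions:
        raise ValueError("more variants than sites")
    if L <= max_gap:
        raise ValueError("L must exceed max_gap")
    if n_branches < 1:
        raise ValueError("need at least one branch")
    rng = np.random.default_rng(seed)
    counts = np.empty(reps, dtype=int)
    for r in range(reps):
        if replace_positions:
            positions = rng.integers(1, L + 1, size=n_variants)
        else:
            positions = rng.choice(L, size=n_variants, replace=False) + 1
        branches = rng.integers(0, n_branches, size=n_variants)
        counts[r] = _count_clustered(positions, branches, max_gap)
    return PermutationNull(
        n_variants=n_variants,
        L=L,
        n_branches=n_branches,
        max_gap=max_gap,
        reps=reps,
        seed=seed,
        null_clustered_counts=counts,
    )


def poisson_tail_log10_p(observed: int, lam: float, terms: int = 400) -> float:
    """log10 P(X ≥ observed) for X ~ Poisson(lam), stable for tiny tails."""
    if observed < 0:
        raise ValueError("observed must be non-negative")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if observed == 0:
        return 0.0
    ks = np.arange(observed, observed + terms)
    log_terms = ks * np.log(lam) - lam - gammaln(ks + 1)
    return float(logsumexp(log_terms) / np.log(10.0))


def poisson_tail_p(observed: int, lam: float) -> float:
    """P(X ≥ observed) for X ~ Poisson(lam).

    Computed in log space; may underflow to 0.0 below ~1e-308 — use
    :func:`poisson_tail_log10_p` when the magnitude itself is needed.
    """
    return float(10.0 ** poisson_tail_log10_p(observed, lam))


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p for the 2×2 table [[a, b], [c, d]].

    Two-sidedness by the point-probability method: sum hypergeometric point
    probabilities no larger than that of the observed table.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if (a + b == 0 and c + d == 0) or (a + c == 0 and b + d == 0):
        raise ValueError("a margin of the table is all zero")
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def clustered_proportion(
    n_total: int, clusters: Sequence[SNPCluster]
) -> tuple[int, int, float]:
    """(k, n, percent): distinct variants belonging to ≥1 cluster out of n."""
    members: set[str] = set()
    for cl in clusters:
        members.update(cl.members)
    k = len(members)
    percent = 100.0 * k / n_total if n_total else 0.0
    return k, n_total, percent
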