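"""Nucleotide diversity (Nei's π) for panels of aligned haploid haplotypes.

π is the average number of pairwise differences per site,

    π = [ Σ_{i<j} d_ij / C(n,2) ] / L ,

without small-sample correction, and its standard deviation is the square
root of Nei's (1987) sampling variance:

    V(π) = (n+1)·π / (3(n−1)·L) + 2(n²+n+3)·π² / (9n(n−1)) .

Sites where either member of a pair is missing (N) are excluded from that
pair's difference count; L is not reduced (region lengths are fixed).  A run
of alignment columns where either sequence is gapped counts as a single
difference if the two sequences differ over the run (an indel is one
mutational event regardless of length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import GAP, MISSING, SequenceRecord

__all__ = ["DiversityEstimate", "pairwise_differences", "nucleotide_diversity"]


@dataclass(frozen=True)
class DiversityEstimate:
    region: str
    n: int
    L: int
    pi: float
    sd: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.pi <= 1.0 and self.sd >= 0.0


def _seq_of(h) -> str:
    return h.seq if isinstance(h, SequenceRecord) else str(h).upper()


def _pair_differences(a: str, b: str) -> int:
    """Differences between two aligned haplotypes: SNP sites plus one per
    differing gap run; N-bearing sites are skipped pairwise-complete."""
    d = 0
    i, n = 0, len(a)
    while i < n:
        if a[i] == GAP or b[i] == GAP:
            j = i
            while j < n and (a[j] == GAP or b[j] == GAP):
                j += 1
            seg_a, seg_b = a[i:j], b[i:j]
            if MISSING not in seg_a and MISSING not in seg_b and seg_a != seg_b:
                d += 1
            i = j
        else:
            if a[i] != MISSING and b[i] != MISSING and a[i] != b[i]:
                d += 1
            i += 1
    return d


def pairwise_differences(haplotypes: Sequence) -> np.ndarray:
    """Symmetric matrix of pairwise difference counts between haplotypes."""
    seqs = [_seq_of(h) for h in haplotypes]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"haplotypes have unequal lengths: {sorted(lengths)}")
    n = len(seqs)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pair_differences(seqs[i], seqs[j])
    return d


def nucleotide_diversity(
    haplotypes: Sequence,
    L: int | None = None,
    region: str = "",
    variance: str = "nei",
) -> DiversityEstimate:
    """Estimate π and its standard deviation for one region.

    Parameters
    ----------
    haplotypes : aligned haploid sequences (n ≥ 2)
    L : sites compared, in bp; defaults to the alignment length
    variance : "nei" for Nei's (1987) sampling variance, "none" for sd = 0
    """
    seqs = [_seq_of(h) for h in haplotypes]
    n = len(seqs)
    if n < 2:
        raise ValueError("nucleotide diversity needs at least two haplotypes")
    if L is None:
        L = len(seqs[0])
    if L <= 0:
        raise ValueError("L must be positive")
    d = pairwise_differences(seqs)
    n_pairs = n * (n - 1) // 2
    mean_d = d[np.triu_indices(n, k=1)].sum() / n_pairs
    pi = mean_d / L
    if variance == "nei":
        var = (n + 1) * pi / (3 * (n - 1) * L) + 2 * (n * n + n + 3) * pi * pi / (
            9 * n * (n - 1)
        )
        sd = math.sqrt(var)
    elif variance == "none":
        sd = 0.0
    else:
        raise ValueError(f"unknown variance formula {variance!r}")
    return DiversityEstimate(region=region, n=n, L=L, pi=pi, sd=sd)
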