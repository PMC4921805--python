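"""Donor identification and conversion-tract bounds for SNP clusters.

A cluster of same-branch variants is explained by a gene-conversion event if
some paralogous "donor" sequence is 100% identical to the derived state of
the cluster over its span.  The minimum tract is the cluster span itself; the
maximum tract is bounded by the nearest flanking paralogous sequence variants
(PSVs) at which the converted chromosome still carries the acceptor base —
the conversion tract cannot have crossed those sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .clusters import SNPCluster
from .io_formats import GAP, MISSING, Region, SequenceRecord
from .phylogeny import BranchAssignment

__all__ = [
    "PSV",
    "PSVSet",
    "DonorHit",
    "identify_psvs",
    "align_donor_ungapped",
    "filter_clusters_for_donor_search",
    "build_derived_tract",
    "match_donors",
    "tract_bounds",
    "classify_conversion",
]


@dataclass(frozen=True)
class PSV:
    """A fixed difference between acceptor and donor at an acceptor position."""

    acceptor_pos: int  # 1-based chromosome position on the acceptor
    acceptor_base: str
    donor_base: str

    def __post_init__(self) -> None:
        if self.acceptor_base == self.donor_base:
            raise ValueError("a PSV requires differing acceptor and donor bases")


@dataclass(frozen=True)
class PSVSet:
    """All PSVs between one donor and the acceptor reference, sorted."""

    donor_id: str
    psvs: tuple[PSV, ...]

    def __post_init__(self) -> None:
        positions = [p.acceptor_pos for p in self.psvs]
        if positions != sorted(positions):
            raise ValueError("PSVs must be sorted by acceptor position")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p.acceptor_pos for p in self.psvs)


@dataclass
class DonorHit:
    """A donor region whose sequence matches a cluster's derived tract."""

    cluster_id: int
    donor_id: str
    identity: bool
    conversion_class: str | None = None
    shared_variants: list[str] = field(default_factory=list)


def identify_psvs(
    acceptor_ref: SequenceRecord, donor: SequenceRecord, donor_offset: int = 0
) -> PSVSet:
    """PSVs between the acceptor reference and a donor aligned to it.

    The donor sequence is compared position by position against the acceptor
    reference starting at acceptor coordinate ``acceptor_ref.start +
    donor_offset``; gap or N sites are skipped.
    """
    if not acceptor_ref.has_coords:
        raise ValueError("acceptor reference needs coordinates")
    psvs = []
    for i, (a, d) in enumerate(zip(acceptor_ref.seq[donor_offset:], donor.seq)):
        if a in (GAP, MISSING) or d in (GAP, MISSING):
            continue
        if a != d:
            psvs.append(
                PSV(
                    acceptor_pos=acceptor_ref.start + donor_offset + i,  # type: ignore[operator]
                    acceptor_base=a,
                    donor_base=d,
                )
            )
    return PSVSet(donor_id=donor.id, psvs=tuple(psvs))


def align_donor_ungapped(acceptor_seq: str, donor_seq: str) -> int:
    """Best ungapped offset of the donor along the acceptor (fewest mismatches).

    A deliberately simple exact sliding aligner for equal-scale paralogs; ties
    go to the leftmost offset.  Gapped alignment is out of scope — donors are
    normally supplied pre-aligned.
    """
    if len(donor_seq) > len(acceptor_seq):
        raise ValueError("donor longer than acceptor; supply pre-aligned donors")
    best_offset, best_mm = 0, len(donor_seq) + 1
    for offset in range(len(acceptor_seq) - len(donor_seq) + 1):
        mm = sum(
            1
            for a, d in zip(acceptor_seq[offset : offset + len(donor_seq)], donor_seq)
            if a != d and a not in (GAP, MISSING) and d not in (GAP, MISSING)
        )
        if mm < best_mm:
            best_offset, best_mm = offset, mm
    return best_offset


def filter_clusters_for_donor_search(
    clusters: Sequence[SNPCluster], min_span: int = 3
) -> list[SNPCluster]:
    """Drop clusters spanning fewer than ``min_span`` bp.

    Very short clusters (e.g. two contiguous variants, span 2) are excluded
    from the donor search because a matching region is too likely by chance.
    """
    return [c for c in clusters if c.span >= min_span]


def build_derived_tract(
    acceptor_ref: SequenceRecord,
    cluster: SNPCluster,
    assignments: Mapping[str, BranchAssignment],
) -> str:
    """Acceptor reference bases over the cluster span with derived alleles
    substituted at every member position."""
    if not acceptor_ref.has_coords:
        raise ValueError("acceptor reference needs coordinates")
    start, end = cluster.start, cluster.end
    if start < acceptor_ref.start or end > acceptor_ref.end:  # type: ignore[operator]
        raise ValueError("cluster lies outside the acceptor reference")
    tract = list(acceptor_ref.seq[start - acceptor_ref.start : end - acceptor_ref.start + 1])  # type: ignore[operator]
    for name, pos in zip(cluster.members, cluster.positions):
        a = assignments.get(name)
        if a is None:
            raise ValueError(f"cluster member {name!r} has no polarity assignment")
        if a.derived_allele == a.ancestral_allele:
            raise ValueError(f"variant {name!r}: derived equals ancestral")
        tract[pos - start] = a.derived_allele
    return "".join(tract)


def match_donors(
    derived_tract: str,
    cluster: SNPCluster,
    donor_library: Sequence[SequenceRecord],
    acceptor_ref: SequenceRecord,
    donor_offsets: Mapping[str, int] | None = None,
) -> list[DonorHit]:
    """Donors whose aligned bases over the cluster span equal the derived
    tract exactly (100% identity; one mismatch destroys the hit).

    ``donor_offsets`` maps donor id to the 0-based offset of the donor's
    first base on the acceptor alignment; donors absent from the map are
    assumed to start at offset 0 (pre-aligned, equal length).  Donors not
    covering the span are skipped.
    """
    offsets = donor_offsets or {}
    start_idx = cluster.start - acceptor_ref.start  # type: ignore[operator]
    hits = []
    for donor in donor_library:
        off = offsets.get(donor.id, 0)
        lo = start_idx - off
        hi = lo + cluster.span
        if lo < 0 or hi > len(donor.seq):
            continue  # donor does not cover the span
        if donor.seq[lo:hi] == derived_tract:
            hits.append(DonorHit(cluster_id=cluster.id, donor_id=donor.id, identity=True))
    return hits


def tract_bounds(
    cluster: SNPCluster,
    psvs: PSVSet,
    converted_haplotype: SequenceRecord | str,
    acceptor_start: int = 1,
    mode: str = "between",
) -> tuple[int, int | None]:
    """Minimum and maximum conversion-tract bounds for a cluster.

    min_tract is the cluster span.  max_tract is bounded by the nearest PSV
    on each side at which the converted chromosome retains the ACCEPTOR base
    (proving conversion did not reach it): with flanking non-converted PSVs
    at L and R, max = R − L − 1 bases strictly between them (``mode=
    "between"``), or R − L + 1 including the PSV positions (``mode=
    "inclusive"``).  If either side has no such PSV inside the locus,
    max_tract is None (unbounded within the data).
    """
    if mode not in ("between", "inclusive"):
        raise ValueError(f"unknown tract-bound mode {mode!r}")
    seq = converted_haplotype.seq if isinstance(converted_haplotype, SequenceRecord) else converted_haplotype
    min_tract = cluster.span

    def retains_acceptor(psv: PSV) -> bool:
        idx = psv.acceptor_pos - acceptor_start
        if idx < 0 or idx >= len(seq):
            return False
        return seq[idx] == psv.acceptor_base

    left = [p for p in psvs.psvs if p.acceptor_pos < cluster.start and retains_acceptor(p)]
    right = [p for p in psvs.psvs if p.acceptor_pos > cluster.end and retains_acceptor(p)]
    if not left or not right:
        return min_tract, None
    L = left[-1].acceptor_pos
    R = right[0].acceptor_pos
    max_tract = (R - L - 1) if mode == "between" else (R - L + 1)
    return min_tract, max_tract


_AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}


def _norm_chrom(chrom: str) -> str:
    return chrom.lower().removeprefix("chr")


def classify_conversion(
    donor_chrom: str,
    donor_start: int,
    donor_end: int,
    acceptor_chrom: str,
    acceptor_element: Region | None = None,
) -> str:
    """Classify a conversion event by donor location.

    intra-LTR if the donor interval lies within the acceptor element itself
    (a duplicated sub-region of one element); else Y-to-Y, X-to-Y,
    autosome-to-Y, or generic inter-chromosomal when the acceptor is not on Y.
    """
    dch = _norm_chrom(donor_chrom)
    ach = _norm_chrom(acceptor_chrom)
    if (
        acceptor_element is not None
        and _norm_chrom(acceptor_element.chrom) == dch
        and donor_start >= acceptor_element.start
        and donor_end <= acceptor_element.end
    ):
        return "intra-LTR"
    known = {"y", "x"} | {str(i) for i in range(1, 23)}
    if dch not in known:
        raise ValueError(f"unknown chromosome label {donor_chrom!r}")
    if ach == "y":
        if dch == "y":
            return "Y-to-Y"
        if dch == "x":
            return "X-to-Y"
        return "autosome-to-Y"
    return "intra-chromosomal" if dch == ach else "inter-chromosomal"
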