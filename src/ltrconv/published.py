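"""Reference values from the published Y-chromosome LTR re-sequencing survey
this pipeline re-implements, used as fixed inputs for consistency checks.

The survey re-sequenced 52 LTR elements (61,165 bp of the MSY) in 16 men,
then two hotspot elements (LTR 2, 1550 bp, 111 men; LTR 24, 1828 bp, 51 men),
and printed a table of 16 SNP clusters with their outermost coordinates,
lengths and conversion-tract bounds.  Those printed coordinates and counts
are inputs here — the pipeline's arithmetic is checked against them, never
the other way around.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ClusterRow",
    "CLUSTER_TABLE",
    "SURVEY",
    "CONTINGENCY_VS_NGS",
    "HOMOPLASY_COMPARISONS",
]


@dataclass(frozen=True)
class ClusterRow:
    """One printed cluster: outermost coordinates, printed span and tract bounds."""

    id: int
    element: str
    n_snps: int
    branch: str
    chrom: str
    start: int
    end: int
    printed_span: int
    min_tract: int | None  # None where printed N.A.
    max_tract: int | None
    conversion_class: str


# The published cluster table (coordinates 1-based inclusive).  Cluster 12
# (two contiguous variants, span 2) was excluded from the donor search and
# carries no tract bounds; cluster 6 had several putative donors and no
# resolvable bounds.
CLUSTER_TABLE: tuple[ClusterRow, ...] = (
    ClusterRow(1, "LTR-2", 6, "E-V257*", "chrY", 2866271, 2866356, 86, 86, 246, "Y-to-Y"),
    ClusterRow(2, "LTR-2", 2, "E-V12*", "chrY", 2866347, 2866356, 10, 10, 57, "multi"),
    ClusterRow(3, "LTR-2", 3, "Homoplasic", "chrY", 2866480, 2866496, 17, 3, 14, "Y-to-Y"),
    ClusterRow(4, "LTR-2", 3, "B1", "chrY", 2866490, 2866505, 16, 16, 69, "autosome-to-Y"),
    ClusterRow(5, "LTR-2", 4, "A3-M28", "chrY", 2866617, 2866630, 14, 14, 41, "Y-to-Y"),
    ClusterRow(6, "LTR-2", 2, "A1-M31", "chrY", 2866786, 2866791, 6, None, None, "unresolved"),
    ClusterRow(7, "LTR-2", 5, "B2-P6", "chrY", 2866724, 2866733, 10, 10, 89, "Y-to-Y"),
    ClusterRow(8, "LTR-2", 2, "E-M33", "chrY", 2866871, 2866880, 10, 10, 74, "Y-to-Y"),
    ClusterRow(9, "LTR-2", 2, "E-V22*", "chrY", 2866630, 2866640, 11, 11, 54, "autosome-to-Y"),
    ClusterRow(10, "LTR-2", 5, "C-M217", "chrY", 2866880, 2866931, 52, 24, 450, "Y-to-Y"),
    ClusterRow(11, "LTR-2", 3, "O-M117", "chrY", 2866881, 2866903, 23, 23, 34, "multi"),
    ClusterRow(12, "LTR-2", 2, "Homoplasic", "chrY", 2866613, 2866613, 2, None, None, "excluded"),
    ClusterRow(13, "LTR-2", 5, "J-M67*", "chrY", 2866398, 2866421, 24, 24, 83, "Y-to-Y"),
    ClusterRow(14, "LTR-24", 9, "I-M170*", "chrY", 16709731, 16709794, 63, 63, 96, "intra-LTR"),
    ClusterRow(15, "LTR-24", 2, "A3-M51", "chrY", 16710137, 16710139, 3, 3, 26, "Y-to-Y"),
    ClusterRow(16, "LTR-24", 2, "B2-M182", "chrY", 16710593, 16710595, 3, 3, 49, "Y-to-Y"),
)

# Clusters whose printed span disagrees with inclusive arithmetic on the
# printed outermost coordinates (documented anomalies in the source table):
# cluster 14 prints 63 where chrY:16709731-16709794 spans 64; cluster 12
# prints a degenerate start==end coordinate pair alongside span 2.
SPAN_EXCEPTIONS: frozenset[int] = frozenset({12, 14})

# Survey-level counts and parameters used by the excess test.
SURVEY = {
    "sequenced_bp": 61165,
    "n_branches": 30,
    "n_tips": 16,
    "n_variants": 134,  # 131 SNPs + 3 indels; a companion figure of 136 also circulates
    "n_variants_alt": 136,
    "n_clustered": 25,
    "n_clusters_survey": 9,
    "max_gap_bp": 50,
    "permutation_reps": 1000,
    "poisson_excess_p": 2.3e-20,
    "ltr2": {"length_bp": 1550, "n_samples": 111, "n_variants": 51,
             "n_clustered": 36, "n_homoplasic": 14, "recurrent_events": 34,
             "total_events": 85},
    "ltr24": {"length_bp": 1828, "n_samples": 51, "n_variants": 23,
              "n_clustered": 13},
    "pi_ltr": (3.6e-4, 0.4e-4),
    "pi_flanking": (2.2e-4, 0.4e-4),
}

# 2x2 tables: clustered vs conventional SNPs, this survey against three NGS
# callsets (all printed as P < 1e-16, two-sided Fisher).
CONTINGENCY_VS_NGS = {
    "ngs_all": ((25, 109), (350, 42035)),
    "ngs_filtered": ((25, 109), (256, 33072)),
    "unique_msy": ((25, 109), (28, 3362)),
}

# Homoplasic-site fractions compared against two earlier surveys
# (k homoplasic out of n variants); both printed as P < 1e-4.
HOMOPLASY_COMPARISONS = {
    "vs_xdeg_resequencing": ((14, 51), (4, 2386)),
    "vs_ngs_mutations": ((14, 51), (172, 5865)),
}
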