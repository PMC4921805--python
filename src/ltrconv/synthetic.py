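"""Synthetic haploid datasets with point mutation and ectopic gene conversion.

The generator emulates the data regime the analysis targets: a panel of
haploid haplotypes (a male-specific Y region, so no crossover) evolving down
a fixed rooted tree, with per-branch Poisson point mutations and Poisson
gene-conversion events that overwrite a geometric-length tract with the
sequence of a diverged donor paralog.  Donors differ from the ancestral
acceptor at binomially sampled PSV positions (~1–3 % density in real LTR
paralogs), so a conversion tract covering two or more PSVs plants the
clustered, phylogenetically equivalent variants the detector looks for.

To keep every segregating site biallelic (the analysis rejects multi-allelic
sites, and Sanger-scale Y data is overwhelmingly biallelic), each site is
assigned a single alternate base up front: point mutations toggle a lineage
between the ancestral and alternate base (giving natural back mutations), and
donor PSVs carry the same alternate base at their positions.  Full ground
truth (every event, branch, tract and donor) is recorded for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .clusters import SNPCluster
from .donors import PSVSet, identify_psvs
from .io_formats import SequenceRecord, VariantTable, call_variants, write_fasta
from .phylogeny import PhyloTree, _Node

__all__ = [
    "SimConfig",
    "SimEvent",
    "SimTruth",
    "SimResult",
    "caterpillar_tree",
    "generate_donor_library",
    "simulate_dataset",
    "truth_report",
    "RecoveryMetrics",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
SIM_CHROM = "chrYsim"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated dataset.

    Defaults match the study regime: 16 haplotypes on a 30-branch tree, a
    1550 bp locus, donors at 2 % PSV divergence, one expected point mutation
    and 0.3 expected conversions per branch, 100 bp mean tracts.
    """

    seed: int = 0
    n_tips: int = 16
    newick: str | None = None  # overrides n_tips when given
    locus_length: int = 1550
    n_donors: int = 4
    psv_rate: float = 0.02
    mut_rate: float = 1.0
    conv_rate: float = 0.3
    tract_mean: float = 100.0
    error_rate: float = 0.0  # optional per-base miscall rate at the tips

    def __post_init__(self) -> None:
        if min(self.psv_rate, self.mut_rate, self.conv_rate, self.error_rate) < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.psv_rate <= 0.2:
            raise ValueError("psv_rate must lie in [0, 0.2]")
        if self.tract_mean < 1:
            raise ValueError("tract_mean must be >= 1")
        if self.locus_length <= self.tract_mean:
            raise ValueError("locus_length must exceed tract_mean")


@dataclass(frozen=True)
class SimEvent:
    branch: str
    kind: str  # {"mutation", "conversion"}
    start: int  # 1-based; == end for a mutation
    end: int
    donor_id: str | None = None
    n_changed: int = 0  # bases actually changed by the event
    n_psvs_covered: int = 0  # donor PSVs inside the tract (conversions)


@dataclass
class SimTruth:
    events: list[SimEvent] = field(default_factory=list)

    @property
    def conversions(self) -> list[SimEvent]:
        return [e for e in self.events if e.kind == "conversion"]

    @property
    def mutations(self) -> list[SimEvent]:
        return [e for e in self.events if e.kind == "mutation"]


@dataclass
class SimResult:
    config: SimConfig
    tree: PhyloTree
    ancestor: SequenceRecord
    tips: list[SequenceRecord]
    donors: list[SequenceRecord]
    psv_sets: dict[str, PSVSet]
    variants: VariantTable
    truth: SimTruth

    def write(self, outdir: str | Path) -> None:
        """Emit FASTA (tips + ancestor + donors), variant TSV, truth TSV and
        the exact config as YAML, for provenance."""
        from .io_formats import write_variant_table
        import pandas as pd

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta([self.ancestor, *self.tips, *self.donors], out / "sequences.fasta")
        write_variant_table(self.variants, out / "variants.tsv")
        rows = [
            {
                "branch": e.branch,
                "kind": e.kind,
                "start": e.start,
                "end": e.end,
                "donor_id": e.donor_id or "",
                "n_changed": e.n_changed,
                "n_psvs_covered": e.n_psvs_covered,
            }
            for e in self.truth.events
        ]
        pd.DataFrame(rows).to_csv(out / "truth.tsv", sep="\t", index=False)
        with open(out / "sim_config.yaml", "w") as fh:
            yaml.safe_dump(self.config.__dict__, fh, sort_keys=True)


def caterpillar_tree(n_tips: int = 16) -> str:
    """Newick for a labeled asymmetric (caterpillar) rooted binary tree.

    A rooted binary tree with n tips has 2n − 2 edges, so 16 tips give the
    30 branches of the study's fixed Y phylogeny.
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    names = [f"S{i:02d}" for i in range(1, n_tips + 1)]
    node = f"({names[0]},{names[1]})i1"
    for k in range(2, n_tips - 1):
        node = f"({node},{names[k]})i{k}"
    return f"({node},{names[-1]})root;"


def generate_donor_library(
    ancestral_seq: str,
    n_donors: int,
    psv_rate: float,
    seed: int | np.random.Generator = 0,
    alt_alleles: np.ndarray | None = None,
) -> tuple[list[SequenceRecord], dict[str, PSVSet]]:
    """Donor paralogs diverged from the ancestral acceptor at Binomial(L,
    psv_rate) positions, with the emitted PSVSet matching by construction.

    ``alt_alleles`` optionally fixes the substitute base per position (used
    by the simulator to keep all variation biallelic); otherwise substitutes
    are drawn uniformly from the three non-ancestral bases.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(ancestral_seq)
    anc = np.frombuffer(ancestral_seq.encode(), dtype="S1").copy()
    if alt_alleles is None:
        alt_alleles = _draw_alt_alleles(anc, rng)
    donors: list[SequenceRecord] = []
    psv_sets: dict[str, PSVSet] = {}
    # donor coordinates live on their own pseudo-chromosome so conversion
    # classification and header parsing stay exercised
    for d in range(n_donors):
        mask = rng.random(L) < psv_rate
        seq = anc.copy()
        seq[mask] = alt_alleles[mask]
        donor_id = f"donor{d + 1}:1-{L}"
        rec = SequenceRecord(
            id=donor_id, seq=seq.tobytes().decode(), chrom=f"donor{d + 1}", start=1, end=L
        )
        donors.append(rec)
        psv_sets[rec.id] = PSVSet(
            donor_id=rec.id,
            psvs=tuple(
                _psv(i + 1, anc[i], seq[i]) for i in np.flatnonzero(mask)
            ),
        )
    return donors, psv_sets


def _psv(pos: int, a: bytes, d: bytes):
    from .donors import PSV

    return PSV(acceptor_pos=int(pos), acceptor_base=a.decode(), donor_base=d.decode())


def _draw_alt_alleles(anc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One fixed alternate base per position, never equal to the ancestral."""
    L = len(anc)
    alt = _BASES[rng.integers(0, 4, size=L)]
    clash = alt == anc
    while clash.any():
        alt[clash] = _BASES[rng.integers(0, 4, size=int(clash.sum()))]
        clash = alt == anc
    return alt


def simulate_dataset(config: SimConfig) -> SimResult:
    """Evolve the ancestral locus down the tree and call variants at the tips.

    On each branch: Poisson(mut_rate) point mutations at uniform positions
    (toggling ancestral ↔ alternate base) and Poisson(conv_rate) conversions
    (uniform start, geometric length with mean tract_mean truncated at the
    locus end, donor uniform from the library; tract bases overwritten with
    the donor's bases).  Byte-identical outputs for identical configs.
    """
    rng = np.random.default_rng(config.seed)
    L = config.locus_length
    anc = _BASES[rng.integers(0, 4, size=L)]
    alt = _draw_alt_alleles(anc, rng)
    donors, psv_sets = generate_donor_library(
        anc.tobytes().decode(), config.n_donors, config.psv_rate, rng, alt_alleles=alt
    )
    donor_arrays = {
        rec.id: np.frombuffer(rec.seq.encode(), dtype="S1") for rec in donors
    }
    donor_psv_positions = {
        rec.id: np.array(psv_sets[rec.id].positions, dtype=int) for rec in donors
    }

    newick = config.newick or caterpillar_tree(config.n_tips)
    tree = PhyloTree.from_newick(newick)

    truth = SimTruth()
    tip_seqs: dict[str, np.ndarray] = {}

    def evolve(node: _Node, seq: np.ndarray, at_root: bool) -> None:
        if not at_root:
            seq = seq.copy()
            n_mut = rng.poisson(config.mut_rate)
            for _ in range(n_mut):
                pos = int(rng.integers(0, L))
                new = alt[pos] if seq[pos] == anc[pos] else anc[pos]
                changed = int(seq[pos] != new)
                seq[pos] = new
                truth.events.append(
                    SimEvent(
                        branch=node.name,
                        kind="mutation",
                        start=pos + 1,
                        end=pos + 1,
                        n_changed=changed,
                    )
                )
            n_conv = rng.poisson(config.conv_rate)
            for _ in range(n_conv):
                start = int(rng.integers(0, L))
                length = int(rng.geometric(1.0 / config.tract_mean))
                end = min(start + length - 1, L - 1)
                donor = donors[int(rng.integers(0, len(donors)))]
                dseq = donor_arrays[donor.id]
                tract = slice(start, end + 1)
                changed = int((seq[tract] != dseq[tract]).sum())
                seq[tract] = dseq[tract]
                pos1 = donor_psv_positions[donor.id]
                covered = int(((pos1 >= start + 1) & (pos1 <= end + 1)).sum())
                truth.events.append(
                    SimEvent(
                        branch=node.name,
                        kind="conversion",
                        start=start + 1,
                        end=end + 1,
                        donor_id=donor.id,
                        n_changed=changed,
                        n_psvs_covered=covered,
                    )
                )
        if node.is_tip and not at_root:
            if config.error_rate > 0:
                seq = seq.copy()
                errs = rng.random(L) < config.error_rate
                seq[errs] = _draw_alt_alleles(seq, rng)[errs]
            tip_seqs[node.name] = seq
        for child in node.children:
            evolve(child, seq, at_root=False)

    evolve(tree.root, anc, at_root=True)

    ancestor = SequenceRecord(
        id=f"{SIM_CHROM}:1-{L}", seq=anc.tobytes().decode(), chrom=SIM_CHROM, start=1, end=L
    )
    tips = [
        SequenceRecord(id=name, seq=tip_seqs[name].tobytes().decode()) for name in tree.tips
    ]
    variants, _ = call_variants(tips, ancestor)
    return SimResult(
        config=config,
        tree=tree,
        ancestor=ancestor,
        tips=tips,
        donors=donors,
        psv_sets=psv_sets,
        variants=variants,
        truth=truth,
    )


@dataclass(frozen=True)
class RecoveryMetrics:
    recall: float | None
    precision: float | None
    tract_coverage: float | None  # true tracts within [min_tract, max_tract]
    n_detectable: int
    n_detected: int


def truth_report(
    truth: SimTruth,
    detected: Sequence[SNPCluster],
    min_psvs: int = 2,
    bounds: dict[int, tuple[int, int | None]] | None = None,
) -> RecoveryMetrics:
    """Score detected clusters against the simulation ledger.

    A detected cluster is a true positive if its span overlaps a true
    conversion tract on the same branch.  Conversions whose tract covers
    fewer than ``min_psvs`` donor PSVs are excluded from the recall
    denominator: they cannot produce a cluster of that size even in
    principle.  Precision is computed over detected clusters with at least
    ``min_psvs`` members, the size class conversions of that strength
    produce — pair clusters also arise from chance point mutations at the
    rate the permutation null itself quantifies, so they are not evidence
    against the detector.  When cluster tract bounds are supplied, the
    fraction of matched true tracts lying within [min_tract, max_tract] is
    reported too.
    """
    detectable = [c for c in truth.conversions if c.n_psvs_covered >= min_psvs]

    def overlaps(cluster: SNPCluster, event: SimEvent) -> bool:
        return (
            cluster.branch == event.branch
            and cluster.start <= event.end
            and event.start <= cluster.end
        )

    matched_events = [
        e for e in detectable if any(overlaps(c, e) for c in detected)
    ]
    strong = [c for c in detected if len(c.members) >= min_psvs]
    true_positive_clusters = [
        c for c in strong if any(overlaps(c, e) for e in truth.conversions)
    ]
    recall = len(matched_events) / len(detectable) if detectable else None
    precision = len(true_positive_clusters) / len(strong) if strong else None

    coverage = None
    if bounds:
        pairs = []
        for c in detected:
            for e in detectable:
                if overlaps(c, e) and c.id in bounds:
                    lo, hi = bounds[c.id]
                    tract_len = e.end - e.start + 1
                    ok = tract_len >= lo and (hi is None or tract_len <= hi)
                    pairs.append(ok)
        if pairs:
            coverage = sum(pairs) / len(pairs)
    return RecoveryMetrics(
        recall=recall,
        precision=precision,
        tract_coverage=coverage,
        n_detectable=len(detectable),
        n_detected=len(detected),
    )
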