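"""End-to-end orchestration: alignment → variants → polarization → diversity
→ cluster detection → permutation/Poisson excess → donor search → report.

Defaults reproduce the declared analysis parameters: a 50 bp cluster gap,
1,000 permutation replicates, and a 3 bp minimum cluster span for the donor
search.  All convention switches (variance formula, null sampling mode,
tract-bound mode, the variant-count override) are logged in the report
metadata so reproductions are auditable.  No multiple-testing correction is
applied; the handful of p values is reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import clusters as cl
from . import diversity as dv
from . import donors as dn
from . import io_formats as iof
from . import phylogeny as ph
from . import published

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending record."""


@dataclass
class RunConfig:
    # inputs
    fasta: str | None = None  # aligned haplotypes; reference = first record with coords
    tree: str | None = None
    variants: str | None = None  # pre-called variant TSV (alternative to fasta)
    regions: str | None = None
    donor_library: str | None = None
    outdir: str = "ltrconv_report"
    # analysis parameters (defaults reproduce the declared study parameters)
    max_gap: int = 50
    reps: int = 1000
    seed: int = 0
    min_cluster_span: int = 3
    outgroup: str | None = None
    # convention switches
    variance: str = "nei"  # {nei, none}
    null_replace_positions: bool = False
    tract_mode: str = "between"  # {between, inclusive}
    n_variants_override: int | None = None  # e.g. 136 instead of the table's count
    float_format: str = "%.6g"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage {name!r}: {exc}") from exc

        return wrapped

    return deco


@_stage("variants")
def _load_variants(config: RunConfig):
    if config.variants:
        table = iof.read_variant_table(config.variants)
        return table, [], None, []
    if not config.fasta:
        raise PipelineError("stage 'variants': need --fasta or --variants input")
    records = iof.read_fasta(config.fasta)
    refs = [r for r in records if r.has_coords]
    if not refs:
        raise PipelineError("stage 'variants': no coordinate-bearing reference record in FASTA")
    reference = refs[0]
    samples = [r for r in records if r is not reference]
    table, ref_specific = iof.call_variants(samples, reference)
    return table, ref_specific, reference, samples


@_stage("diversity")
def _diversity(samples, reference, regions, variance) -> pd.DataFrame:
    rows = []
    if samples:
        whole = dv.nucleotide_diversity(samples, region="all", variance=variance)
        rows.append(whole)
        if reference is not None and regions:
            positions = iof.column_positions(reference)
            pooled: dict[str, list[int]] = {}
            for region in regions:
                cols = [i for i, p in enumerate(positions) if region.contains(p)]
                if not cols:
                    continue
                sliced = ["".join(s.seq[c] for c in cols) for s in samples]
                rows.append(
                    dv.nucleotide_diversity(sliced, L=region.length, region=region.name,
                                            variance=variance)
                )
                pooled.setdefault(region.kind, []).extend(cols)
            # pooled rows per kind (concatenated columns over pooled length)
            for kind, cols in sorted(pooled.items()):
                sliced = ["".join(s.seq[c] for c in cols) for s in samples]
                rows.append(
                    dv.nucleotide_diversity(sliced, L=len(cols), region=f"pooled:{kind}",
                                            variance=variance)
                )
    return pd.DataFrame(
        [{"region": r.region, "n": r.n, "L": r.L, "pi": r.pi, "sd": r.sd} for r in rows]
    )


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every stage and write the report TSVs; returns the tables."""
    table, ref_specific, reference, samples = _load_variants(config)

    if not config.tree:
        raise PipelineError("stage 'phylogeny': a Newick tree is required")
    tree = ph.read_newick_tree(config.tree)

    try:
        assignments = ph.polarize_and_assign(table, tree, outgroup=config.outgroup)
    except Exception as exc:
        raise PipelineError(f"stage 'phylogeny': {exc}") from exc
    summary = ph.count_events(assignments)

    regions = iof.read_regions(config.regions) if config.regions else []
    diversity_df = _diversity(samples, reference, regions, config.variance)

    # cluster detection over per-branch events (homoplasic variants enter
    # once per branch event)
    pos_of = {v.name: v.pos for v in table}
    events = [
        (a.variant, pos_of[a.variant], branch)
        for a in assignments
        for branch, _ in a.events
    ]
    found = cl.detect_clusters(events, max_gap=config.max_gap)

    n_variants = config.n_variants_override or len(table)
    L = (reference.end - reference.start + 1) if reference is not None else (
        max(pos_of.values()) - min(pos_of.values()) + 1
    )
    k, n, percent = cl.clustered_proportion(len(table), found)

    null = excess_p = log10_p = None
    if len(table) >= 2 and L > config.max_gap:
        null = cl.permutation_null(
            n_variants, L, tree.n_branches, reps=config.reps,
            max_gap=config.max_gap, seed=config.seed,
            replace_positions=config.null_replace_positions,
        )
        lam = null.lam
        if lam == 0.0:
            if k == 0:
                excess_p, log10_p = 1.0, 0.0
            else:
                lam = 1.0 / (2 * config.reps)  # continuity guard; flagged in metadata
        if excess_p is None:
            log10_p = cl.poisson_tail_log10_p(k, lam)
            excess_p = 10.0 ** log10_p

    fisher_rows = []
    for name, ((_, _), (c2, d2)) in published.CONTINGENCY_VS_NGS.items():
        fisher_rows.append(
            {
                "comparison": name,
                "k_this": k,
                "n_this": len(table),
                "k_other": c2,
                "n_other": c2 + d2,
                "p_two_sided": cl.fisher_exact_two_sided(k, len(table) - k, c2, d2),
            }
        )

    # donor search with tract bounds
    donor_rows = []
    if config.donor_library and reference is not None:
        library = iof.read_fasta(config.donor_library)
        assignment_map = {a.variant: a for a in assignments}
        searchable = dn.filter_clusters_for_donor_search(found, config.min_cluster_span)
        for cluster in searchable:
            try:
                tract = dn.build_derived_tract(reference, cluster, assignment_map)
                hits = dn.match_donors(tract, cluster, library, reference)
            except Exception as exc:
                raise PipelineError(
                    f"stage 'donors': cluster {cluster.id}: {exc}"
                ) from exc
            carrier = _derived_carrier(cluster, table, samples)
            for hit in hits:
                donor = next(r for r in library if r.id == hit.donor_id)
                psvs = dn.identify_psvs(reference, donor)
                min_t, max_t = (
                    dn.tract_bounds(cluster, psvs, carrier,
                                    acceptor_start=reference.start,
                                    mode=config.tract_mode)
                    if carrier is not None
                    else (cluster.span, None)
                )
                if donor.has_coords:
                    try:
                        klass = dn.classify_conversion(donor.chrom, donor.start,
                                                       donor.end, reference.chrom)
                    except ValueError:
                        klass = "unplaced"  # donor library on non-genomic labels
                else:
                    klass = "unplaced"
                donor_rows.append(
                    {
                        "cluster": cluster.id,
                        "branch": cluster.branch,
                        "members": ",".join(cluster.members),
                        "start": cluster.start,
                        "end": cluster.end,
                        "span": cluster.span,
                        "donor": hit.donor_id,
                        "min_tract": min_t,
                        "max_tract": "N.A." if max_t is None else max_t,
                        "class": klass,
                        "multi_donor": len(hits) > 1,
                    }
                )

    tables: dict[str, pd.DataFrame] = {
        "variants": table.to_frame(),
        "assignments": pd.DataFrame(
            [
                {
                    "variant": a.variant,
                    "ancestral": a.ancestral_allele,
                    "derived": a.derived_allele,
                    "branches": ";".join(f"{b}:{d}" for b, d in a.events),
                    "n_events": a.n_events,
                    "homoplasic": a.homoplasic,
                    "placement_ambiguous": a.placement_ambiguous,
                }
                for a in assignments
            ]
        ),
        "diversity": diversity_df,
        "clusters": pd.DataFrame(
            [
                {
                    "cluster": c.id,
                    "branch": c.branch,
                    "members": ",".join(c.members),
                    "start": c.start,
                    "end": c.end,
                    "span": c.span,
                    "degenerate": c.degenerate,
                }
                for c in found
            ],
            columns=["cluster", "branch", "members", "start", "end", "span", "degenerate"],
        ),
        "null_summary": pd.DataFrame(
            [
                {
                    "n_variants_permuted": n_variants,
                    "L": L,
                    "n_branches": tree.n_branches,
                    "max_gap": config.max_gap,
                    "reps": config.reps,
                    "seed": config.seed,
                    "lambda": null.lam if null else float("nan"),
                    "observed_clustered": k,
                    "poisson_tail_p": excess_p if excess_p is not None else float("nan"),
                    "log10_p": log10_p if log10_p is not None else float("nan"),
                }
            ]
        ),
        "proportions": pd.DataFrame(
            [
                {
                    "clustered": k,
                    "total": n,
                    "percent": percent,
                    "total_events": summary.total_events,
                    "n_homoplasic": summary.n_homoplasic,
                    "recurrent_events": summary.recurrent_events,
                }
            ]
        ),
        "fisher": pd.DataFrame(fisher_rows),
        "donor_hits": pd.DataFrame(
            donor_rows,
            columns=["cluster", "branch", "members", "start", "end", "span", "donor",
                     "min_tract", "max_tract", "class", "multi_donor"],
        ),
        "reference_specific": pd.DataFrame({"pos": ref_specific}),
    }
    metadata = {
        "seed": config.seed,
        "max_gap": config.max_gap,
        "reps": config.reps,
        "min_cluster_span": config.min_cluster_span,
        "variance": config.variance,
        "null_replace_positions": config.null_replace_positions,
        "tract_mode": config.tract_mode,
        "n_variants_permuted": n_variants,
        "n_variants_called": len(table),
        "outgroup": config.outgroup or "",
    }
    iof.write_report(tables, config.outdir, metadata=metadata,
                     float_format=config.float_format)
    return tables


def _derived_carrier(cluster, table, samples):
    """A haplotype carrying the derived allele at every cluster member (the
    converted chromosome), used to test which flanking PSVs it retains."""
    if not samples:
        return None
    names = set(cluster.members)
    for sample in samples:
        ok = True
        for v in table:
            if v.name in names and v.genotypes.get(sample.id) != v.derived_allele:
                ok = False
                break
        if ok:
            return sample
    return None
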