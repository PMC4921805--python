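"""Input/output for the formats the pipeline touches.

Defines the coordinate dialect used throughout: 1-based, inclusive on both
ends, so a region chrY:10-19 spans 10 bp.  FASTA headers of the form
``chrom:start-end`` (hyphen or en-dash) carry coordinates; everything else is
a bare identifier.  Variant tables are a minimal TSV dialect (the data this
pipeline targets is Sanger-scale, so VCF machinery is deliberately avoided).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SequenceRecord",
    "Region",
    "Variant",
    "VariantTable",
    "FormatError",
    "AlignmentError",
    "read_fasta",
    "write_fasta",
    "read_regions",
    "call_variants",
    "read_variant_table",
    "write_variant_table",
    "write_report",
]

VALID_BASES = set("ACGTN-")
MISSING = "N"
GAP = "-"

_COORD_HEADER = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>\d+)[–—-](?P<end>\d+)$")


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class AlignmentError(ValueError):
    """Sequences expected to be aligned have inconsistent lengths."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence, optionally anchored to chromosome coordinates.

    Coordinates are 1-based inclusive; when present and the sequence is
    ungapped, ``end - start + 1 == len(seq)``.
    """

    id: str
    seq: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid characters {sorted(bad)} "
                "(only A,C,G,T,N,- accepted; IUPAC ambiguity codes are rejected)"
            )
        object.__setattr__(self, "seq", seq)
        if self.has_coords:
            if self.end < self.start:  # type: ignore[operator]
                raise FormatError(f"record {self.id!r}: end < start")
            ungapped = len(seq) - seq.count(GAP)
            span = self.end - self.start + 1  # type: ignore[operator]
            if GAP not in seq and ungapped != span:
                raise FormatError(
                    f"record {self.id!r}: length {ungapped} != coordinate span {span}"
                )

    @property
    def has_coords(self) -> bool:
        return self.chrom is not None and self.start is not None and self.end is not None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Region:
    """A named locus, 1-based inclusive (e.g. an LTR element or its flank)."""

    name: str
    chrom: str
    start: int
    end: int
    family: str | None = None
    kind: str = "other"  # {acceptor-LTR, flanking, other}

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"region {self.name!r}: end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class Variant:
    """One segregating site: a SNP or an indel anchored at its leftmost base.

    ``alleles`` holds the two observed states (single bases for SNPs; for
    indels the present segment and "-").  ``genotypes`` maps sample name to
    its haploid allele, with "N" meaning missing.  Polarity fields are filled
    by the phylogeny stage.
    """

    name: str
    chrom: str
    pos: int
    type: str  # {"SNP", "indel"}
    indel_length: int
    alleles: tuple[str, str]
    genotypes: dict[str, str]
    ancestral_allele: str | None = None
    derived_allele: str | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.type not in ("SNP", "indel"):
            raise ValueError(f"variant {self.name!r}: unknown type {self.type!r}")
        if self.type == "SNP" and not all(len(a) == 1 for a in self.alleles):
            raise ValueError(f"variant {self.name!r}: SNP alleles must be single bases")
        allowed = set(self.alleles) | {MISSING}
        for sample, allele in self.genotypes.items():
            if allele not in allowed:
                raise ValueError(
                    f"variant {self.name!r}: genotype {allele!r} of {sample!r} "
                    f"not in alleles {self.alleles}"
                )
        n = len(self.genotypes)
        if n and sum(a == MISSING for a in self.genotypes.values()) > 0.2 * n:
            if "high-missingness" not in self.flags:
                self.flags.append("high-missingness")


class VariantTable:
    """An ordered collection of variants on one chromosome.

    Variants are kept sorted by position; positions must be unique.
    """

    def __init__(self, variants: Iterable[Variant]):
        self.variants: list[Variant] = sorted(variants, key=lambda v: (v.chrom, v.pos))
        seen: set[tuple[str, int]] = set()
        for v in self.variants:
            key = (v.chrom, v.pos)
            if key in seen:
                raise ValueError(f"duplicate variant position {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def __getitem__(self, i: int) -> Variant:
        return self.variants[i]

    @property
    def samples(self) -> list[str]:
        names: list[str] = []
        for v in self.variants:
            for s in v.genotypes:
                if s not in names:
                    names.append(s)
        return names

    def by_name(self, name: str) -> Variant:
        for v in self.variants:
            if v.name == name:
                return v
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        samples = self.samples
        rows = []
        for v in self.variants:
            row = {
                "name": v.name,
                "chrom": v.chrom,
                "pos": v.pos,
                "type": v.type,
                "indel_length": v.indel_length,
                "ref_allele_state": v.alleles[0],
                "alt_allele_state": v.alleles[1],
            }
            for s in samples:
                row[s] = v.genotypes.get(s, MISSING)
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Headers matching ``chrom:start-end`` (hyphen or en-dash) populate the
    record's coordinates.  Sequences are uppercased.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}: header at line {header_line} has no sequence")
        m = _COORD_HEADER.match(header)
        if m:
            records.append(
                SequenceRecord(
                    id=header,
                    seq=seq,
                    chrom=m.group("chrom"),
                    start=int(m.group("start")),
                    end=int(m.group("end")),
                )
            )
        else:
            records.append(SequenceRecord(id=header, seq=seq))
        header, chunks = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FormatError(f"{path}: empty header at line {lineno}")
                header_line = lineno
            else:
                if header is None:
                    raise FormatError(f"{path}: sequence before any header at line {lineno}")
                chunks.append(line)
    flush()
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_regions(path: str | Path) -> list[Region]:
    """Read region definitions from TSV (name, chrom, start, end[, family, kind]).

    A header row is required.  A ``coords`` column value of ``bed`` switches
    start to 0-based half-open and converts on read; default is 1-based
    inclusive.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"name", "chrom", "start", "end"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: region table needs columns {sorted(required)}")
    regions = []
    names = set()
    for _, row in df.iterrows():
        start, end = int(row["start"]), int(row["end"])
        if str(row.get("coords", "")).lower() == "bed":
            start, end = start + 1, end
        name = str(row["name"])
        if name in names:
            raise FormatError(f"{path}: duplicate region name {name!r}")
        names.add(name)
        regions.append(
            Region(
                name=name,
                chrom=str(row["chrom"]),
                start=start,
                end=end,
                family=str(row["family"]) if "family" in df.columns and pd.notna(row.get("family")) else None,
                kind=str(row["kind"]) if "kind" in df.columns and pd.notna(row.get("kind")) else "other",
            )
        )
    return regions


# ---------------------------------------------------------------------------
# Variant calling from an alignment


def column_positions(reference: SequenceRecord) -> list[int]:
    """Chromosome position of each alignment column, following the reference row.

    Gap columns in the reference inherit the position of the preceding
    reference base (leftmost-anchor convention for insertions).
    """
    if not reference.has_coords:
        raise ValueError("reference record needs coordinates to map alignment columns")
    positions = []
    pos = reference.start - 1  # type: ignore[operator]
    for base in reference.seq:
        if base != GAP:
            pos += 1
        positions.append(max(pos, reference.start))  # type: ignore[arg-type]
    return positions


def call_variants(
    alignment: Sequence[SequenceRecord],
    reference: SequenceRecord,
    name_prefix: str = "V",
    name_offset: int = 1,
) -> tuple[VariantTable, list[int]]:
    """Call segregating sites from an aligned haploid sample panel.

    Each column where at least two distinct non-missing sample alleles occur
    yields one variant.  Runs of consecutive gap-bearing columns are collapsed
    into a single indel variant anchored at the leftmost affected base, with
    ``indel_length`` equal to the run length.  Columns invariant among the
    samples but different from the reference are returned separately as
    reference-specific positions, not as variants.
    """
    L = len(reference.seq)
    for rec in alignment:
        if len(rec.seq) != L:
            raise AlignmentError(
                f"sample {rec.id!r} length {len(rec.seq)} != reference length {L}"
            )
    positions = column_positions(reference)
    samples = [rec.id for rec in alignment]
    seqs = [rec.seq for rec in alignment]

    variants: list[Variant] = []
    ref_specific: list[int] = []
    counter = name_offset

    def snp_at(col: int) -> None:
        nonlocal counter
        col_alleles = {s[col] for s in seqs if s[col] != MISSING}
        ref_base = reference.seq[col]
        if len(col_alleles) >= 2:
            ordered = sorted(col_alleles, key=lambda a: (a != ref_base, a))
            if len(ordered) > 2:
                raise ValueError(
                    f"column {col}: more than two alleles {sorted(col_alleles)}; "
                    "multi-allelic sites are not supported"
                )
            genotypes = {name: seq[col] for name, seq in zip(samples, seqs)}
            variants.append(
                Variant(
                    name=f"{name_prefix}{counter}",
                    chrom=reference.chrom or "?",
                    pos=positions[col],
                    type="SNP",
                    indel_length=0,
                    alleles=(ordered[0], ordered[1]),
                    genotypes=genotypes,
                )
            )
            counter += 1
        elif len(col_alleles) == 1 and ref_base != GAP:
            (allele,) = col_alleles
            if allele != ref_base:
                ref_specific.append(positions[col])

    col = 0
    while col < L:
        has_gap = any(s[col] == GAP for s in seqs) or reference.seq[col] == GAP
        if not has_gap:
            snp_at(col)
            col += 1
            continue
        # collapse the maximal run of gap-bearing columns into one indel
        run_start = col
        while col < L and (any(s[col] == GAP for s in seqs) or reference.seq[col] == GAP):
            col += 1
        run = slice(run_start, col)
        run_len = col - run_start
        segments = {seq[run] for seq in seqs if MISSING not in seq[run]}
        if len(segments) >= 2:
            present = sorted(s for s in segments if s != GAP * run_len)
            absent = GAP * run_len
            if not present or len(present) > 1:
                raise ValueError(
                    f"columns {run_start}-{col - 1}: indel with more than two states"
                )
            genotypes = {}
            for name, seq in zip(samples, seqs):
                seg = seq[run]
                genotypes[name] = (
                    MISSING if MISSING in seg else (present[0] if seg == present[0] else absent)
                )
            variants.append(
                Variant(
                    name=f"{name_prefix}{counter}",
                    chrom=reference.chrom or "?",
                    pos=positions[run_start],
                    type="indel",
                    indel_length=run_len,
                    alleles=(present[0], absent),
                    genotypes=genotypes,
                )
            )
            counter += 1
    return VariantTable(variants), ref_specific


# ---------------------------------------------------------------------------
# Variant TSV dialect


_FIXED_COLUMNS = ["name", "chrom", "pos", "type", "indel_length", "ref_allele_state", "alt_allele_state"]


def write_variant_table(table: VariantTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> VariantTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_FIXED_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: variant TSV missing columns {sorted(missing)}")
    samples = [c for c in df.columns if c not in _FIXED_COLUMNS]
    variants = []
    for _, row in df.iterrows():
        variants.append(
            Variant(
                name=row["name"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                type=row["type"],
                indel_length=int(row["indel_length"]),
                alleles=(row["ref_allele_state"], row["alt_allele_state"]),
                genotypes={s: row[s] for s in samples},
            )
        )
    return VariantTable(variants)


# ---------------------------------------------------------------------------
# Reports


def write_report(
    tables: Mapping[str, pd.DataFrame],
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
    float_format: str = "%.6g",
) -> list[Path]:
    """Write named result tables as TSV files under ``path``.

    Row order is made deterministic (sorted by the first column); a
    ``run_metadata.tsv`` block records the seed and parameters so runs are
    auditable.  Same inputs and config produce byte-identical files.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in sorted(tables.items()):
        target = out / f"{name}.tsv"
        frame = df.copy()
        if len(frame.columns) and len(frame):
            frame = frame.sort_values(list(frame.columns[:1]), kind="mergesort")
        frame.to_csv(target, sep="\t", index=False, float_format=float_format)
        written.append(target)
    if metadata is not None:
        meta = pd.DataFrame(
            sorted((str(k), str(v)) for k, v in metadata.items()), columns=["key", "value"]
        )
        target = out / "run_metadata.tsv"
        meta.to_csv(target, sep="\t", index=False)
        written.append(target)
    return written
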