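"""Readers and writers for the external representations the pipeline touches.

Formats: FASTA (reference coding sequences), SAM/BAM (optional count
ingestion), fixed-header tab-separated tables, and Newick trees with branch
lengths. Gene length and GC fraction are derived from sequence here, so the
rest of the pipeline never needs to look at nucleotides again.

Conventions used throughout the package:

* GC content is stored as a fraction in [0, 1] (the GC-bias slope ``b`` is
  defined on this scale).
* SNP positions are 1-based and fully closed.
* Alignment counting uses primary records only; multi-mapper resolution is
  the upstream mapper's job.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
import pysam
from Bio import SeqIO


class FormatError(ValueError):
    """Raised when an input file violates its documented schema."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """One CDS reference entry.

    ``length_bp`` and ``gc_fraction`` are the gene length L and GC content x
    entering the length-normalized rate model c/L = a + b*x.
    """

    gene_id: str
    family_id: str
    length_bp: int
    gc_fraction: float

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"{self.gene_id}: length_bp must be >= 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"{self.gene_id}: gc_fraction outside [0, 1]")


@dataclass
class CountTable:
    """Observed read counts per gene for one sample.

    ``total_reads`` is the library size N used as the number of binomial
    trials; it may exceed the sum of counts (reads can map nowhere) but must
    be at least the largest single count.
    """

    sample_id: str
    counts: dict[str, int]
    total_reads: int

    def __post_init__(self) -> None:
        if self.total_reads < 1:
            raise ValueError("total_reads must be positive")
        for gid, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {gid}")
            if c > self.total_reads:
                raise ValueError(
                    f"count for {gid} ({c}) exceeds total_reads "
                    f"({self.total_reads})"
                )


@dataclass(frozen=True)
class SampleMeta:
    """Sequencing metadata for one accession."""

    sample_id: str
    read_pairs: int
    read_length_bp: int
    genome_size_2cx_gb: float | None = None
    ploidy: int | None = None

    def __post_init__(self) -> None:
        if self.read_pairs < 1 or self.read_length_bp < 1:
            raise ValueError("read_pairs and read_length_bp must be positive")
        if self.genome_size_2cx_gb is not None and self.genome_size_2cx_gb <= 0:
            raise ValueError("genome_size_2cx_gb must be positive when present")


@dataclass(frozen=True)
class SNPDepthRecord:
    """Read depths of the two variant bases at one biallelic site, in the
    genome and the transcriptome data set of the same individual."""

    gene_id: str
    position: int
    base_a: str
    base_b: str
    genome_depth_a: int
    genome_depth_b: int
    transcriptome_depth_a: int
    transcriptome_depth_b: int

    def __post_init__(self) -> None:
        if self.base_a == self.base_b:
            raise ValueError(
                f"{self.gene_id}:{self.position}: base_a equals base_b"
            )
        if self.position < 1:
            raise ValueError("positions are 1-based; got < 1")
        for d in (self.genome_depth_a, self.genome_depth_b,
                  self.transcriptome_depth_a, self.transcriptome_depth_b):
            if d < 0:
                raise ValueError("negative depth")


@dataclass(frozen=True)
class ExpressionRecord:
    """Transcript abundance (RPKM) of one gene in one accession."""

    accession_id: str
    gene_id: str
    rpkm: float

    def __post_init__(self) -> None:
        if self.rpkm < 0:
            raise ValueError("rpkm must be non-negative")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_GC_BASES = frozenset("GCS")
_COUNTED_BASES = frozenset("ACGTS")


def gc_fraction_of(sequence: str) -> float:
    """GC fraction of a nucleotide sequence.

    S (G or C) counts as GC; ambiguity codes other than S are excluded from
    both numerator and denominator, which is unbiased under symmetric
    ambiguity. Case-insensitive.
    """
    seq = sequence.upper()
    denom = sum(1 for ch in seq if ch in _COUNTED_BASES)
    if denom == 0:
        raise ValueError("sequence has no unambiguous A/C/G/T/S base")
    num = sum(1 for ch in seq if ch in _GC_BASES)
    return num / denom


def read_reference_fasta(
    path: str | Path,
    family_map: Mapping[str, str] | None = None,
) -> list[GeneRecord]:
    """Read a CDS reference FASTA into :class:`GeneRecord` entries.

    ``family_id`` is looked up in ``family_map`` when given; otherwise a
    ``family=NAME`` token in the FASTA description is used, falling back to
    the gene id itself (singleton family).
    """
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        gid = entry.id
        if gid in seen:
            raise FormatError(f"duplicate FASTA identifier: {gid}")
        seen.add(gid)
        seq = str(entry.seq)
        if not seq:
            raise FormatError(f"empty sequence for {gid}")
        family = None
        if family_map is not None:
            family = family_map.get(gid)
        if family is None:
            for token in entry.description.split():
                if token.startswith("family="):
                    family = token[len("family="):]
                    break
        records.append(
            GeneRecord(
                gene_id=gid,
                family_id=family if family is not None else gid,
                length_bp=len(seq),
                gc_fraction=gc_fraction_of(seq),
            )
        )
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


# ---------------------------------------------------------------------------
# SAM/BAM counting
# ---------------------------------------------------------------------------

def counts_from_alignment(
    path: str | Path,
    reference: Sequence[GeneRecord],
    sample_id: str | None = None,
) -> CountTable:
    """Count mapped primary records per reference gene from a SAM/BAM file.

    ``total_reads`` is the number of primary records in the file, mapped or
    not; unmapped records contribute to the library size only. Secondary and
    supplementary records are ignored entirely.
    """
    known = {g.gene_id for g in reference}
    counts: dict[str, int] = {g.gene_id: 0 for g in reference}
    total = 0
    unknown: set[str] = set()
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af:
            if rec.is_secondary or rec.is_supplementary:
                continue
            total += 1
            if rec.is_unmapped:
                continue
            target = rec.reference_name
            if target not in known:
                unknown.add(target)
                continue
            counts[target] += 1
    if unknown:
        raise FormatError(
            "alignment targets not in reference: " + ", ".join(sorted(unknown))
        )
    if total == 0:
        raise FormatError(f"empty library: no records in {path}")
    if sample_id is None:
        sample_id = Path(str(path)).stem
    return CountTable(sample_id=sample_id, counts=counts, total_reads=total)


# ---------------------------------------------------------------------------
# Tab-separated tables
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    """Read a fixed-header TSV, validating header and per-row field counts."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""] or [""]
    header = lines[0].split("\t")
    for col in required:
        if col not in header:
            raise FormatError(f"{path.name}: missing column '{col}'")
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path.name}: line {lineno}: expected {len(header)} fields, "
                f"found {len(fields)}"
            )
        rows.append(fields)
    return pd.DataFrame(rows, columns=header)


def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


GENES_COLUMNS = ["gene_id", "family_id", "length_bp", "gc_fraction"]


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    df = _read_tsv(path, GENES_COLUMNS)
    out = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        if row.gene_id in seen:
            raise FormatError(f"duplicate gene_id: {row.gene_id}")
        seen.add(row.gene_id)
        out.append(GeneRecord(row.gene_id, row.family_id,
                              int(row.length_bp), float(row.gc_fraction)))
    return out


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.family_id, g.length_bp, repr(g.gc_fraction))
         for g in genes],
        columns=GENES_COLUMNS,
    )
    _write_tsv(df, path)


COUNTS_COLUMNS = ["sample_id", "gene_id", "count"]
SAMPLES_COLUMNS = ["sample_id", "total_reads", "read_pairs",
                   "read_length_bp", "genome_size_2cx_gb", "ploidy"]


def read_count_table(
    counts_path: str | Path, samples_path: str | Path
) -> dict[str, CountTable]:
    """Read per-gene counts (long format) plus the per-sample library sizes."""
    cdf = _read_tsv(counts_path, COUNTS_COLUMNS)
    sdf = _read_tsv(samples_path, SAMPLES_COLUMNS)
    totals = {row.sample_id: int(row.total_reads) for _, row in sdf.iterrows()}
    tables: dict[str, CountTable] = {}
    for sid, grp in cdf.groupby("sample_id", sort=False):
        if sid not in totals:
            raise FormatError(f"sample '{sid}' absent from sample table")
        tables[sid] = CountTable(
            sample_id=sid,
            counts={r.gene_id: int(r["count"]) for _, r in grp.iterrows()},
            total_reads=totals[sid],
        )
    return tables


def write_count_table(
    tables: Iterable[CountTable],
    counts_path: str | Path,
    samples_path: str | Path,
    meta: Mapping[str, SampleMeta] | None = None,
) -> None:
    tables = list(tables)
    rows = [(t.sample_id, gid, c)
            for t in tables for gid, c in t.counts.items()]
    _write_tsv(pd.DataFrame(rows, columns=COUNTS_COLUMNS), counts_path)
    srows = []
    for t in tables:
        m = meta.get(t.sample_id) if meta else None
        srows.append((
            t.sample_id, t.total_reads,
            m.read_pairs if m else t.total_reads // 2 or 1,
            m.read_length_bp if m else 100,
            "" if m is None or m.genome_size_2cx_gb is None
            else repr(m.genome_size_2cx_gb),
            "" if m is None or m.ploidy is None else m.ploidy,
        ))
    _write_tsv(pd.DataFrame(srows, columns=SAMPLES_COLUMNS), samples_path)


def read_sample_table(path: str | Path) -> dict[str, SampleMeta]:
    df = _read_tsv(path, SAMPLES_COLUMNS)
    out: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        size = row.genome_size_2cx_gb
        ploidy = row.ploidy
        out[row.sample_id] = SampleMeta(
            sample_id=row.sample_id,
            read_pairs=int(row.read_pairs),
            read_length_bp=int(row.read_length_bp),
            genome_size_2cx_gb=float(size) if str(size).strip() else None,
            ploidy=int(ploidy) if str(ploidy).strip() else None,
        )
    return out


def write_sample_table(meta: Iterable[SampleMeta], path: str | Path) -> None:
    rows = []
    for m in meta:
        # total_reads column kept for schema compatibility: 2 x pairs
        rows.append((m.sample_id, 2 * m.read_pairs, m.read_pairs,
                     m.read_length_bp,
                     "" if m.genome_size_2cx_gb is None
                     else repr(m.genome_size_2cx_gb),
                     "" if m.ploidy is None else m.ploidy))
    _write_tsv(pd.DataFrame(rows, columns=SAMPLES_COLUMNS), path)


SNP_COLUMNS = ["gene_id", "position", "base_a", "base_b",
               "g_depth_a", "g_depth_b", "t_depth_a", "t_depth_b"]


def read_snp_table(path: str | Path) -> list[SNPDepthRecord]:
    df = _read_tsv(path, SNP_COLUMNS)
    return [
        SNPDepthRecord(
            gene_id=r.gene_id, position=int(r.position),
            base_a=r.base_a, base_b=r.base_b,
            genome_depth_a=int(r.g_depth_a), genome_depth_b=int(r.g_depth_b),
            transcriptome_depth_a=int(r.t_depth_a),
            transcriptome_depth_b=int(r.t_depth_b),
        )
        for _, r in df.iterrows()
    ]


def write_snp_table(records: Iterable[SNPDepthRecord],
                    path: str | Path) -> None:
    rows = [(r.gene_id, r.position, r.base_a, r.base_b,
             r.genome_depth_a, r.genome_depth_b,
             r.transcriptome_depth_a, r.transcriptome_depth_b)
            for r in records]
    _write_tsv(pd.DataFrame(rows, columns=SNP_COLUMNS), path)


EXPR_COLUMNS = ["accession_id", "gene_id", "rpkm"]


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    df = _read_tsv(path, EXPR_COLUMNS)
    return [ExpressionRecord(r.accession_id, r.gene_id, float(r.rpkm))
            for _, r in df.iterrows()]


def write_expression_table(records: Iterable[ExpressionRecord],
                           path: str | Path) -> None:
    rows = [(r.accession_id, r.gene_id, repr(r.rpkm)) for r in records]
    _write_tsv(pd.DataFrame(rows, columns=EXPR_COLUMNS), path)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse a Newick tree, requiring a branch length on every non-root edge.

    Branch lengths carry the Brownian-motion covariance downstream, so a
    lengthless edge is a hard error rather than an implicit zero.
    """
    text = str(source)
    if "(" in text and ";" in text:
        tree = dendropy.Tree.get(data=text, schema="newick")
    else:
        tree = dendropy.Tree.get(path=text, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise FormatError(
                "Newick edge without a branch length (lengths are required "
                "for phylogenetic covariance)"
            )
        if edge.length < 0:
            raise FormatError("negative branch length in Newick tree")
    return tree
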