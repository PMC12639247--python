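"""Read-to-gene assignment from aligned SAM/BAM with tagged read names.

Genome mode assigns each primary alignment to a gene through its exon
model (exon / intron / ambiguous / intergenic / unmapped); probe mode
treats each reference sequence name as a gene identifier, as used for
probe-based chemistries where reads align to a per-gene probe reference.
Assigned reads aggregate into the molecular-info table of
(barcode, UMI, gene, read count) rows that feeds UMI deduplication.

Coordinates are 0-based half-open internally; GTF/GFF3 1-based inclusive
coordinates are converted at load time.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .demultiplex import BarcodeAllowList, DemuxStats, match_barcode
from .read_structure import split_header

__all__ = [
    "GeneModel",
    "GeneIndex",
    "load_annotation",
    "assign_alignment",
    "count_molecules",
    "CountResult",
    "write_molecular_table",
    "read_molecular_table",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("exon", "intron", "ambiguous", "intergenic", "unmapped")


@dataclass(frozen=True)
class GeneModel:
    """One gene: span plus merged, sorted exon intervals (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for s, e in self.exons:
            if not (self.span[0] <= s < e <= self.span[1]):
                raise ValueError(f"exon [{s},{e}) outside span {self.span} ({self.gene_id})")


def merge_intervals(intervals: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Merge overlapping/adjacent half-open intervals."""
    if not intervals:
        return ()
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def load_annotation(path: str | Path, format: str | None = None) -> list[GeneModel]:
    """Parse a GTF or GFF3 file into gene models.

    Exons are attached to genes via the ``gene_id`` attribute (GTF) or by
    walking ``Parent`` chains up to a ``gene`` feature (GFF3); exons with no
    resolvable gene are skipped with a logged warning count.
    """
    path = Path(path)
    if format is None:
        format = "gtf" if path.suffix.lower() in (".gtf",) else "gff3"
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    gene_spans: dict[str, tuple[str, str, int, int]] = {}
    for gene in db.features_of_type("gene"):
        gid = gene.attributes.get("gene_id", [gene.id])[0]
        gene_spans[gid] = (gene.seqid, gene.strand, gene.start - 1, gene.end)

    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    exon_meta: dict[str, tuple[str, str]] = {}
    n_orphans = 0
    for exon in db.features_of_type("exon"):
        gid = None
        if "gene_id" in exon.attributes:
            gid = exon.attributes["gene_id"][0]
        else:
            for parent_gene in db.parents(exon, featuretype="gene"):
                gid = parent_gene.attributes.get("gene_id", [parent_gene.id])[0]
                break
        if gid is None:
            n_orphans += 1
            continue
        exons_by_gene.setdefault(gid, []).append((exon.start - 1, exon.end))
        exon_meta.setdefault(gid, (exon.seqid, exon.strand))
    if n_orphans:
        logger.warning("skipped %d exons with no resolvable gene", n_orphans)

    models: list[GeneModel] = []
    for gid in sorted(set(gene_spans) | set(exons_by_gene)):
        exons = merge_intervals(exons_by_gene.get(gid, []))
        if gid in gene_spans:
            chrom, strand, start, end = gene_spans[gid]
        else:
            chrom, strand = exon_meta[gid]
            start, end = exons[0][0], exons[-1][1]
        models.append(GeneModel(gid, chrom, strand, (start, end), exons))
    return models


class GeneIndex:
    """Interval index over gene spans for fast alignment-block queries."""

    def __init__(self, models: list[GeneModel]) -> None:
        self.models = {m.gene_id: m for m in models}
        self._trees: dict[str, IntervalTree] = {}
        for m in models:
            tree = self._trees.setdefault(m.chrom, IntervalTree())
            tree.addi(m.span[0], m.span[1], m.gene_id)

    def overlapping_genes(self, chrom: str, blocks: list[tuple[int, int]]) -> set[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        hits: set[str] = set()
        for s, e in blocks:
            hits.update(iv.data for iv in tree.overlap(s, e))
        return hits


def _exon_overlap(model: GeneModel, blocks: list[tuple[int, int]]) -> int:
    total = 0
    for bs, be in blocks:
        for es, ee in model.exons:
            lo, hi = max(bs, es), min(be, ee)
            if lo < hi:
                total += hi - lo
    return total


def assign_alignment(
    aln: pysam.AlignedSegment,
    index: GeneIndex,
    stranded: bool = True,
    min_overlap_frac: float = 0.5,
) -> tuple[str, str | None]:
    """Categorize one primary alignment and name its gene when unique.

    Rule order: exon-uniqueness first (total exon overlap of exactly one
    gene >= ``min_overlap_frac`` of the aligned length), then gene-span
    membership (one span -> intron, several -> ambiguous), else intergenic.
    Sense-strand agreement is required when ``stranded``.
    """
    if aln.is_unmapped:
        return "unmapped", None
    blocks = aln.get_blocks()
    aligned_len = sum(e - s for s, e in blocks)
    read_strand = "-" if aln.is_reverse else "+"
    candidates = index.overlapping_genes(aln.reference_name, blocks)
    if stranded:
        candidates = {g for g in candidates if index.models[g].strand == read_strand}

    exon_hits = [
        g
        for g in candidates
        if _exon_overlap(index.models[g], blocks) >= min_overlap_frac * aligned_len
    ]
    if len(exon_hits) == 1:
        return "exon", exon_hits[0]
    if len(exon_hits) >= 2:
        return "ambiguous", None
    if len(candidates) == 1:
        return "intron", None
    if len(candidates) >= 2:
        return "ambiguous", None
    return "intergenic", None


@dataclass
class CountResult:
    """Molecular-info table plus the per-stage tallies collected alongside."""

    records: pd.DataFrame  # columns: barcode, umi, gene_id, reads
    category_totals: dict[str, int]
    demux_stats: DemuxStats | None
    badname: int = 0


def count_molecules(
    aln_path: str | Path,
    annotation: list[GeneModel] | GeneIndex | None = None,
    mode: str = "genome",
    allow: BarcodeAllowList | None = None,
    max_dist: int = 1,
    stranded: bool = True,
    min_overlap_frac: float = 0.5,
    max_reads: int | None = None,
) -> CountResult:
    """Aggregate gene-assigned reads into the molecular-info table.

    Read names must follow ``<barcode>_<umi>#<id>``; malformed names are
    tallied under ``badname`` and skipped.  Secondary and supplementary
    alignments are ignored.  When an allow list is given, barcodes are
    demultiplexed against it (bounded-distance correction) and only assigned
    reads contribute molecules; demultiplexing tallies are returned.
    """
    if mode not in ("genome", "probe"):
        raise ValueError(f"mode must be 'genome' or 'probe', got {mode!r}")
    index: GeneIndex | None = None
    if mode == "genome":
        if annotation is None:
            raise ValueError("genome mode requires an annotation")
        index = annotation if isinstance(annotation, GeneIndex) else GeneIndex(annotation)

    categories: Counter = Counter({c: 0 for c in CATEGORIES})
    demux = DemuxStats() if allow is not None else None
    molecule_reads: Counter = Counter()
    badname = 0

    n_seen = 0
    with pysam.AlignmentFile(str(aln_path), check_sq=False) as af:
        for aln in af:
            if aln.is_secondary or aln.is_supplementary:
                continue
            if max_reads is not None and n_seen >= max_reads:
                break
            n_seen += 1
            barcode, umi, _ = split_header(aln.query_name or "")
            if not barcode or not umi:
                badname += 1
                continue
            if mode == "probe":
                if aln.is_unmapped:
                    categories["unmapped"] += 1
                    continue
                category, gene = "exon", aln.reference_name
            else:
                category, gene = assign_alignment(
                    aln, index, stranded=stranded, min_overlap_frac=min_overlap_frac
                )
            categories[category] += 1
            if gene is None:
                continue
            if demux is not None:
                assigned, match_cat = match_barcode(barcode, allow, max_dist=max_dist)
                demux.record(match_cat)
                if assigned is None:
                    continue
                barcode = assigned
            molecule_reads[(barcode, umi, gene)] += 1

    records = pd.DataFrame(
        [(b, u, g, n) for (b, u, g), n in sorted(molecule_reads.items())],
        columns=["barcode", "umi", "gene_id", "reads"],
    )
    return CountResult(records, dict(categories), demux, badname)


def write_molecular_table(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_molecular_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"barcode": str, "umi": str, "gene_id": str})
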