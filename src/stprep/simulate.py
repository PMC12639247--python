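"""Synthetic spatial transcriptomics data with known ground truth.

The generator produces everything the pipeline consumes — a chip layout
with Visium-like hexagonal geometry (55 um spots, 100 um horizontal
center-to-center spacing), a toy one-chromosome transcriptome with GFF3
annotation, paired FASTQ reads with the platform read-1 layout, and a
truth alignment (SAM) that places each read 2 at its true locus with the
reformatted header already applied, so the whole pipeline is testable
without an external aligner.

Error model: per tissue location the molecule count is
Poisson(mean_molecules_per_location), split over genes by a per-location
Dirichlet profile; empty locations draw Poisson(mean * ambient_fraction)
molecules from one shared ambient profile.  Each molecule receives a UMI
unique within its (location, gene) group and 1 + Geometric extra PCR
copies; duplicate copies mutate one UMI base with probability
``umi_error_rate`` and every read's barcode mutates one base with
probability ``barcode_error_rate``.  All randomness flows from the config
seed; outputs are byte-identical across reruns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from ._util import open_text_write, revcomp
from .dedup import CountMatrix
from .features import GeneModel
from .locations import ChipLayout
from .read_structure import ReadStructure, SegmentRole, get_preset, make_header
from .stereo import location_token

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Transcriptome",
    "SimulatedSample",
    "generate_layout",
    "generate_transcriptome",
    "simulate_reads",
    "write_fasta",
    "write_gff3",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    platform: str = "visium"
    n_tissue_locations: int = 50
    n_empty_locations: int = 50
    n_genes: int = 100
    mean_molecules_per_location: float = 100.0
    pcr_duplication_rate: float = 0.5
    barcode_error_rate: float = 0.01
    umi_error_rate: float = 0.02
    ambient_fraction: float = 0.05
    read2_len: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pcr_duplication_rate", "barcode_error_rate", "umi_error_rate",
                     "ambient_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.n_tissue_locations, self.n_genes) < 1:
            raise ValueError("counts must be positive")


@dataclass
class GroundTruth:
    molecules: pd.DataFrame  # barcode, gene_id, umi, reads
    matrix: CountMatrix  # true distinct-molecule counts, genes x barcodes
    tissue_barcodes: set[str]
    empty_barcodes: set[str]
    layout: ChipLayout


@dataclass
class Transcriptome:
    chrom: str
    sequence: str
    models: list[GeneModel]
    truth: pd.DataFrame = field(default=None)  # gene_id, strand, span, n_exons


@dataclass
class SimulatedSample:
    r1_path: Path
    r2_path: Path
    sam_path: Path
    truth: GroundTruth
    coordinate_map_path: Path | None = None
    layout_path: Path | None = None


def _random_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """n distinct random nucleotide strings of the given length."""
    if 4**length < n:
        raise ValueError(f"cannot draw {n} distinct {length}-mers")
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        seq = "".join(rng.choice(_BASES, size=length))
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def generate_layout(
    platform: str = "visium",
    n_rows: int = 10,
    n_cols: int = 10,
    spacing_um: float = 100.0,
    diameter_um: float = 55.0,
    barcode_len: int = 16,
    seed: int = 0,
) -> ChipLayout:
    """Offset-row (hexagonal) grid with exact horizontal spacing.

    Odd rows are shifted by half the spacing; the vertical row pitch is
    spacing * sqrt(3)/2, the close-packed choice.  Barcodes are drawn
    without replacement.
    """
    if barcode_len < 8:
        raise ValueError("barcode_len must be >= 8")
    n_spots = n_rows * n_cols
    rng = np.random.default_rng(seed)
    barcodes = _random_seqs(rng, n_spots, barcode_len)
    rows = []
    v_pitch = spacing_um * math.sqrt(3.0) / 2.0
    k = 0
    for r in range(n_rows):
        for c in range(n_cols):
            rows.append(
                {
                    "barcode": barcodes[k],
                    "array_row": r,
                    "array_col": c,
                    "x": c * spacing_um + (spacing_um / 2.0 if r % 2 else 0.0),
                    "y": r * v_pitch,
                }
            )
            k += 1
    table = pd.DataFrame(rows)
    return ChipLayout(
        table,
        geometry={
            "spot_diameter_um": diameter_um,
            "center_spacing_um": spacing_um,
            "platform": platform,
        },
    )


def generate_transcriptome(
    n_genes: int = 100,
    exons_per_gene: int = 2,
    exon_len: int = 100,
    intron_len: int = 50,
    intergenic_gap: int = 50,
    seed: int = 0,
) -> Transcriptome:
    """One chromosome of non-overlapping genes on alternating strands.

    Gene i is on '+' when i is even, '-' when odd; each gene has
    ``exons_per_gene`` exons of ``exon_len`` separated by introns.
    """
    rng = np.random.default_rng(seed)
    chrom = "chrT"
    pos = intergenic_gap
    models: list[GeneModel] = []
    rows = []
    for i in range(n_genes):
        exons = []
        start = pos
        for _ in range(exons_per_gene):
            exons.append((pos, pos + exon_len))
            pos += exon_len + intron_len
        pos -= intron_len  # no trailing intron
        strand = "+" if i % 2 == 0 else "-"
        gid = f"G{i + 1:04d}"
        models.append(GeneModel(gid, chrom, strand, (start, pos), tuple(exons)))
        rows.append({"gene_id": gid, "strand": strand, "start": start, "end": pos,
                     "n_exons": exons_per_gene})
        pos += intergenic_gap
    sequence = "".join(rng.choice(_BASES, size=pos))
    return Transcriptome(chrom, sequence, models, pd.DataFrame(rows))


def write_fasta(tx: Transcriptome, path: str | Path) -> Path:
    path = Path(path)
    with open_text_write(path) as fh:
        fh.write(f">{tx.chrom}\n")
        for i in range(0, len(tx.sequence), 70):
            fh.write(tx.sequence[i : i + 70] + "\n")
    return path


def write_gff3(tx: Transcriptome, path: str | Path) -> Path:
    path = Path(path)
    with open_text_write(path) as fh:
        fh.write("##gff-version 3\n")
        for m in tx.models:
            fh.write(
                f"{m.chrom}\tstprep_sim\tgene\t{m.span[0] + 1}\t{m.span[1]}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id};gene_id={m.gene_id}\n"
            )
            for k, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.chrom}\tstprep_sim\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.gene_id}.e{k};Parent={m.gene_id};gene_id={m.gene_id}\n"
                )
    return path


def _mutate_one_base(seq: str, rng: np.random.Generator) -> str:
    i = int(rng.integers(len(seq)))
    alternatives = [b for b in "ACGT" if b != seq[i]]
    return seq[:i] + alternatives[int(rng.integers(3))] + seq[i + 1 :]


def _build_read1(structure: ReadStructure, barcode: str, umi: str) -> str:
    parts, b, u = [], 0, 0
    for seg in structure.segments:
        if seg.role is SegmentRole.BARCODE:
            parts.append(barcode[b : b + seg.length])
            b += seg.length
        elif seg.role is SegmentRole.UMI:
            parts.append(umi[u : u + seg.length])
            u += seg.length
        elif seg.role is SegmentRole.LINKER:
            parts.append(seg.expected_sequence)
        else:
            parts.append("A" * seg.length)
    return "".join(parts)


def simulate_reads(
    config: SimulationConfig,
    layout: ChipLayout | None = None,
    transcriptome: Transcriptome | None = None,
    out_dir: str | Path = ".",
    structure: ReadStructure | None = None,
) -> SimulatedSample:
    """Simulate one sample: FASTQ pair, truth SAM, and ground truth tables.

    The truth SAM emulates the aligner's output on the reformatted FASTQ:
    read names carry the observed (error-injected) barcode and UMI, and
    each read 2 is placed at its true locus within one exon of its source
    gene.  For Stereo-seq the read name carries the true location token
    (deconvolution ground truth) and a coordinate-map TSV is also written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stereo = config.platform == "stereo_seq"
    if structure is None:
        structure = get_preset(config.platform)
    if transcriptome is None:
        transcriptome = generate_transcriptome(
            config.n_genes, seed=int(rng.integers(2**31))
        )
    n_loc = config.n_tissue_locations + config.n_empty_locations
    if layout is None:
        side = math.ceil(math.sqrt(n_loc))
        layout = generate_layout(
            config.platform,
            n_rows=side,
            n_cols=side,
            barcode_len=structure.barcode_total_len,
            seed=int(rng.integers(2**31)),
        )
    if len(layout) < n_loc:
        raise ValueError("layout too small for requested location counts")

    lay = layout.table
    spot_barcodes = lay["barcode"].tolist()
    tissue = spot_barcodes[: config.n_tissue_locations]
    empty = spot_barcodes[config.n_tissue_locations : n_loc]
    if stereo:
        tokens = {
            bc: location_token(int(row.x), int(row.y))
            for bc, row in zip(lay["barcode"], lay.itertuples())
        }

    genes = [m.gene_id for m in transcriptome.models]
    model_by_gene = {m.gene_id: m for m in transcriptome.models}
    n_genes = len(genes)
    ambient_profile = rng.dirichlet(np.full(n_genes, 5.0))
    umi_len = structure.umi_total_len

    truth_rows = []
    fastq1, fastq2, sam_records = [], [], []
    serial = 0
    for bc in tissue + empty:
        if bc in set(tissue):
            profile = rng.dirichlet(np.full(n_genes, 0.1))
            n_mol = rng.poisson(config.mean_molecules_per_location)
        else:
            profile = ambient_profile
            n_mol = rng.poisson(
                config.mean_molecules_per_location * config.ambient_fraction
            )
        if n_mol == 0:
            continue
        gene_draws = rng.multinomial(n_mol, profile)
        loc_key = tokens[bc] if stereo else bc
        for gi in np.flatnonzero(gene_draws):
            gene = genes[gi]
            model = model_by_gene[gene]
            used_umis: set[str] = set()
            for _ in range(int(gene_draws[gi])):
                while True:
                    umi = "".join(rng.choice(_BASES, size=umi_len))
                    if umi not in used_umis:
                        used_umis.add(umi)
                        break
                extra = (
                    0
                    if config.pcr_duplication_rate == 0
                    else int(rng.geometric(1.0 - config.pcr_duplication_rate)) - 1
                )
                n_reads = 1 + extra
                truth_rows.append((loc_key, gene, umi, n_reads))
                # pick one exon long enough for the read, then a start within it
                eligible = [e for e in model.exons if e[1] - e[0] >= config.read2_len]
                es, ee = eligible[int(rng.integers(len(eligible)))]
                start = int(rng.integers(es, ee - config.read2_len + 1))
                ref_seq = transcriptome.sequence[start : start + config.read2_len]
                for copy in range(n_reads):
                    obs_umi = umi
                    if copy > 0 and rng.random() < config.umi_error_rate:
                        obs_umi = _mutate_one_base(umi, rng)
                    obs_bc = bc
                    if rng.random() < config.barcode_error_rate:
                        obs_bc = _mutate_one_base(bc, rng)
                    serial += 1
                    rid = f"r{serial:08d}"
                    r1 = _build_read1(structure, obs_bc, obs_umi)
                    r2 = ref_seq if model.strand == "+" else revcomp(ref_seq)
                    fastq1.append((rid, r1))
                    fastq2.append((rid, r2))
                    if stereo:
                        # truth token: deconvolution ground truth for this read
                        qname = make_header(tokens[bc], obs_umi, rid)
                    else:
                        qname = make_header(obs_bc, obs_umi, rid)
                    sam_records.append(
                        (qname, start, ref_seq, model.strand == "-")
                    )

    r1_path = out_dir / "sample_R1.fastq.gz"
    r2_path = out_dir / "sample_R2.fastq.gz"
    for path, records in ((r1_path, fastq1), (r2_path, fastq2)):
        with open_text_write(path) as fh:
            for rid, seq in records:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")

    sam_path = out_dir / "sample.sam"
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": transcriptome.chrom, "LN": len(transcriptome.sequence)}],
    }
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as sam:
        for qname, start, ref_seq, is_reverse in sam_records:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = qname
            a.query_sequence = ref_seq  # SEQ is stored on the forward strand
            a.flag = 16 if is_reverse else 0
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{len(ref_seq)}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * len(ref_seq))
            sam.write(a)

    molecules = pd.DataFrame(
        truth_rows, columns=["barcode", "gene_id", "umi", "reads"]
    )
    cell_counts = molecules.groupby(["gene_id", "barcode"]).size()
    true_genes = sorted(molecules["gene_id"].unique())
    true_bcs = sorted(molecules["barcode"].unique())
    import scipy.sparse as sp

    gi = {g: i for i, g in enumerate(true_genes)}
    bi = {b: i for i, b in enumerate(true_bcs)}
    mat = sp.csr_matrix(
        (
            cell_counts.values,
            (
                [gi[g] for g, _ in cell_counts.index],
                [bi[b] for _, b in cell_counts.index],
            ),
        ),
        shape=(len(true_genes), len(true_bcs)),
        dtype=np.int64,
    )
    tissue_keys = {tokens[b] for b in tissue} if stereo else set(tissue)
    empty_keys = {tokens[b] for b in empty} if stereo else set(empty)
    truth = GroundTruth(
        molecules, CountMatrix(mat, true_genes, true_bcs), tissue_keys, empty_keys, layout
    )

    cmap_path = None
    if stereo:
        cmap_path = out_dir / "coordinate_map.tsv"
        with open_text_write(cmap_path) as fh:
            fh.write("barcode\tx\ty\n")
            for bc, row in zip(lay["barcode"], lay.itertuples()):
                fh.write(f"{bc}\t{int(row.x)}\t{int(row.y)}\n")
    layout_path = out_dir / "layout.csv"
    lay.to_csv(layout_path, index=False)
    return SimulatedSample(r1_path, r2_path, sam_path, truth, cmap_path, layout_path)
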