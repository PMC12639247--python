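"""Annotation loading and read-to-gene assignment."""

import pysam
import pytest

from stprep.demultiplex import BarcodeAllowList
from stprep.features import (
    GeneIndex,
    GeneModel,
    assign_alignment,
    count_molecules,
    load_annotation,
    merge_intervals,
    read_molecular_table,
    write_molecular_table,
)
from stprep.simulate import write_gff3


def _write_gtf(path, lines):
    path.write_text("".join(lines))


def _make_aln(header, name, start, length=50, reverse=False, unmapped=False, chrom="chr1"):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = "A" * length
    if unmapped:
        a.flag = 4
        return a
    a.flag = 16 if reverse else 0
    a.reference_id = header.references.index(chrom)
    a.reference_start = start
    a.cigarstring = f"{length}M"
    a.mapping_quality = 60
    return a


HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100000}]}
)


class TestLoadAnnotation:
    def test_gtf_coordinate_conversion(self, tmp_path):
        """GTF 1-based inclusive 100-200 becomes internal [99, 200)."""
        gtf = tmp_path / "toy.gtf"
        _write_gtf(gtf, [
            'chr1\tsrc\tgene\t100\t200\t.\t+\t.\tgene_id "G1";\n',
            'chr1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "G1";\n',
        ])
        (model,) = load_annotation(gtf, format="gtf")
        assert model.span == (99, 200)
        assert model.exons == ((99, 200),)

    def test_overlapping_exons_merged(self, tmp_path):
        gtf = tmp_path / "toy.gtf"
        _write_gtf(gtf, [
            'chr1\tsrc\tgene\t1\t150\t.\t+\t.\tgene_id "G1";\n',
            'chr1\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "G1";\n',
            'chr1\tsrc\texon\t51\t150\t.\t+\t.\tgene_id "G1";\n',
        ])
        (model,) = load_annotation(gtf, format="gtf")
        assert model.exons == ((0, 150),)

    def test_generator_gff3_round_trip(self, tmp_path, toy_transcriptome):
        gff = write_gff3(toy_transcriptome, tmp_path / "toy.gff3")
        models = {m.gene_id: m for m in load_annotation(gff)}
        assert len(models) == len(toy_transcriptome.models)
        for truth in toy_transcriptome.models:
            loaded = models[truth.gene_id]
            assert loaded.span == truth.span
            assert loaded.exons == truth.exons
            assert loaded.strand == truth.strand

    def test_merge_intervals_rule(self):
        assert merge_intervals([(0, 100), (50, 150)]) == ((0, 150),)
        assert merge_intervals([(0, 10), (20, 30)]) == ((0, 10), (20, 30))


class TestAssignAlignment:
    @pytest.fixture
    def two_gene_index(self):
        g1 = GeneModel("G1", "chr1", "+", (1000, 2000), ((1000, 1500),))
        g2 = GeneModel("G2", "chr1", "+", (1400, 2400), ((1400, 1900),))
        g3 = GeneModel("G3", "chr1", "-", (5000, 6000), ((5000, 5500),))
        return GeneIndex([g1, g2, g3])

    def test_exonic_read(self, two_gene_index):
        aln = _make_aln(HEADER, "b_u#1", 1050)
        idx = GeneIndex([GeneModel("G1", "chr1", "+", (1000, 2000), ((1000, 1500),))])
        assert assign_alignment(aln, idx) == ("exon", "G1")

    def test_intronic_read(self):
        idx = GeneIndex([GeneModel("G1", "chr1", "+", (1000, 2000), ((1000, 1100),))])
        aln = _make_aln(HEADER, "b_u#1", 1500)
        assert assign_alignment(aln, idx) == ("intron", None)

    def test_two_gene_exon_overlap_is_ambiguous(self, two_gene_index):
        """Brute-force interval check: [1420,1470) lies inside the exons of
        both G1 and G2, so full overlap on both -> ambiguous."""
        aln = _make_aln(HEADER, "b_u#1", 1420)
        for g in ("G1", "G2"):
            es, ee = two_gene_index.models[g].exons[0]
            assert es <= 1420 and 1470 <= ee
        assert assign_alignment(aln, two_gene_index) == ("ambiguous", None)

    def test_intergenic_read(self, two_gene_index):
        aln = _make_aln(HEADER, "b_u#1", 90000)
        assert assign_alignment(aln, two_gene_index) == ("intergenic", None)

    def test_unmapped(self, two_gene_index):
        aln = _make_aln(HEADER, "b_u#1", 0, unmapped=True)
        assert assign_alignment(aln, two_gene_index) == ("unmapped", None)

    def test_strand_mismatch_not_assigned_when_stranded(self, two_gene_index):
        aln = _make_aln(HEADER, "b_u#1", 5100)  # forward read over '-' gene G3
        assert assign_alignment(aln, two_gene_index, stranded=True)[0] == "intergenic"
        assert assign_alignment(aln, two_gene_index, stranded=False) == ("exon", "G3")

    def test_overlap_fraction_threshold(self):
        idx = GeneIndex([GeneModel("G1", "chr1", "+", (1000, 2000), ((1000, 1020),))])
        aln = _make_aln(HEADER, "b_u#1", 1010, length=50)
        # only 10/50 bases exonic < 0.5 -> intron, but passes at frac 0.2
        assert assign_alignment(aln, idx, min_overlap_frac=0.5) == ("intron", None)
        assert assign_alignment(aln, idx, min_overlap_frac=0.2) == ("exon", "G1")


class TestCountMolecules:
    def _write_sam(self, path, alignments):
        with pysam.AlignmentFile(str(path), "wh", header=HEADER) as out:
            for a in alignments:
                out.write(a)

    def test_read_aggregation(self, tmp_path):
        idx = [GeneModel("G1", "chr1", "+", (1000, 2000), ((1000, 1500),))]
        sam = tmp_path / "t.sam"
        self._write_sam(sam, [_make_aln(HEADER, "BC_UMI#%d" % i, 1100) for i in range(3)])
        result = count_molecules(sam, idx, mode="genome")
        assert len(result.records) == 1
        row = result.records.iloc[0]
        assert (row["barcode"], row["umi"], row["gene_id"], row["reads"]) == (
            "BC", "UMI", "G1", 3,
        )

    def test_probe_mode_uses_reference_name(self, tmp_path):
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": "GeneX", "LN": 1000}]}
        )
        sam = tmp_path / "p.sam"
        with pysam.AlignmentFile(str(sam), "wh", header=header) as out:
            out.write(_make_aln(header, "BC_UMI#1", 10, chrom="GeneX"))
        result = count_molecules(sam, mode="probe")
        assert result.records.iloc[0]["gene_id"] == "GeneX"

    def test_malformed_name_tallied_and_skipped(self, tmp_path):
        idx = [GeneModel("G1", "chr1", "+", (1000, 2000), ((1000, 1500),))]
        sam = tmp_path / "t.sam"
        self._write_sam(sam, [_make_aln(HEADER, "nounderscore", 1100)])
        result = count_molecules(sam, idx, mode="genome")
        assert result.badname == 1
        assert len(result.records) == 0

    def test_category_totals_match_truth_and_conserve(self, clean_count_result, clean_sample):
        sample, _, _ = clean_sample
        totals = clean_count_result.category_totals
        n_reads = int(sample.truth.molecules["reads"].sum())
        assert sum(totals.values()) == n_reads
        assert totals["exon"] == n_reads  # error-free exonic simulation

    def test_genome_and_probe_modes_agree_on_molecules(self, tmp_path, clean_sample,
                                                       toy_transcriptome, clean_count_result):
        """A probe reference built one-reference-per-gene from the same
        transcriptome yields the same molecular table as genome mode."""
        sample, _, _ = clean_sample
        gene_lens = {m.gene_id: m.span[1] - m.span[0] for m in toy_transcriptome.models}
        header = pysam.AlignmentHeader.from_dict({
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": g, "LN": L} for g, L in sorted(gene_lens.items())],
        })
        probe_sam = tmp_path / "probe.sam"
        models = {m.gene_id: m for m in toy_transcriptome.models}
        with pysam.AlignmentFile(str(probe_sam), "wh", header=header) as out, \
                pysam.AlignmentFile(str(sample.sam_path), check_sq=False) as src:
            for aln in src:
                # recover the gene from the truth locus, remap onto its probe ref
                for gid, m in models.items():
                    if m.span[0] <= aln.reference_start < m.span[1]:
                        out.write(_make_aln(header, aln.query_name,
                                            aln.reference_start - m.span[0],
                                            length=aln.query_length, chrom=gid))
                        break
        probe = count_molecules(probe_sam, mode="probe")
        genome_records = clean_count_result.records.drop(columns=[]).reset_index(drop=True)
        # genome mode demultiplexes; rebuild bare records for comparison
        assert sorted(map(tuple, probe.records.values.tolist())) == sorted(
            map(tuple, genome_records.values.tolist())
        )

    def test_table_round_trip(self, tmp_path, clean_count_result):
        path = tmp_path / "mol.tsv"
        write_molecular_table(clean_count_result.records, path)
        loaded = read_molecular_table(path)
        assert loaded.equals(clean_count_result.records)
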