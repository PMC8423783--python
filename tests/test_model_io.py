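"""Format readers/writers and the shared coordinate convention."""

import json

import pytest

from t2taudit.model import (AuditReport, Assembly, FormatError, GenomeInterval,
                            SequenceRecord, read_alignments, read_fasta,
                            read_genes, read_intervals, read_markers,
                            read_report, read_similarity_hits, write_bed,
                            write_fasta, write_markers, write_report)
from t2taudit.model import MarkerObservation


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestFasta:
    def test_identity_load_uppercases(self, tmp_path):
        asm = read_fasta(_write(tmp_path, "a.fa", ">c1\nacgt\n"))
        assert asm.names == ["c1"]
        assert asm["c1"].residues == "ACGT"
        assert asm["c1"].length == 4

    def test_non_acgtn_coerced_to_n(self, tmp_path, caplog):
        with caplog.at_level("WARNING"):
            asm = read_fasta(_write(tmp_path, "a.fa", ">c1\nACRT\n"))
        assert asm["c1"].residues == "ACNT"
        assert "1 non-ACGTN" in caplog.text

    def test_duplicate_header_is_hard_error(self, tmp_path):
        path = _write(tmp_path, "a.fa", ">c1\nACGT\n>c1\nTTTT\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_fasta(path)

    def test_empty_file_is_hard_error(self, tmp_path):
        with pytest.raises(FormatError, match="no FASTA"):
            read_fasta(_write(tmp_path, "a.fa", ""))

    def test_round_trip(self, tmp_path):
        asm = Assembly([SequenceRecord("s1", "ACGT" * 50),
                        SequenceRecord("s2", "GGCC")])
        write_fasta(asm, tmp_path / "out.fa")
        back = read_fasta(tmp_path / "out.fa")
        assert [(r.name, r.residues) for r in back] == \
               [(r.name, r.residues) for r in asm]


class TestIntervalDialects:
    def test_bed_is_already_half_open(self, tmp_path):
        ivs = read_intervals(_write(tmp_path, "a.bed", "c1\t10\t20\tNanica\n"), "bed")
        assert ivs == [GenomeInterval("c1", 10, 20, ".", "Nanica")]

    def test_gff3_converts_one_based_inclusive(self, tmp_path):
        row = "c1\tsrc\trepeat\t11\t20\t.\t+\t.\tName=Nanica\n"
        ivs = read_intervals(_write(tmp_path, "a.gff3", row), "gff3")
        assert ivs == [GenomeInterval("c1", 10, 20, "+", "Nanica")]

    def test_bed_and_gff3_agree(self, tmp_path):
        """The same annotation in both dialects loads identically."""
        bed = _write(tmp_path, "a.bed", "c1\t99\t250\tCRM\t0\t-\n")
        gff = _write(tmp_path, "a.gff3",
                     "c1\tsrc\trepeat\t100\t250\t.\t-\t.\tName=CRM\n")
        assert read_intervals(bed, "bed") == read_intervals(gff, "gff3")

    def test_blast_reversed_subject_means_minus_strand(self, tmp_path):
        row = "q1\ts1\t95.0\t60\t3\t0\t1\t60\t120\t61\t1e-30\t100\n"
        ivs = read_intervals(_write(tmp_path, "a.tsv", row), "blast_tab")
        assert ivs[0].strand == "-"
        assert (ivs[0].start, ivs[0].end) == (0, 60)
        hits = read_similarity_hits(tmp_path / "a.tsv")
        assert hits[0].s_start < hits[0].s_end == 120
        assert hits[0].strand == "-"

    def test_repeatmasker_out_with_header(self, tmp_path):
        text = ("   SW   perc perc\nscore   div. del.\n\n"
                "  239 27.4 5.4 3.2 c1 101 200 (0) + Nanica LINE 1 100 (0) 1\n")
        ivs = read_intervals(_write(tmp_path, "a.out", text), "repeatmasker_out")
        assert ivs == [GenomeInterval("c1", 100, 200, "+", "Nanica")]

    def test_degenerate_row_rejected_with_log(self, tmp_path, caplog):
        with caplog.at_level("WARNING"):
            ivs = read_intervals(
                _write(tmp_path, "a.bed", "c1\t20\t20\tx\nc1\t5\t9\ty\n"), "bed")
        assert [iv.feature_class for iv in ivs] == ["y"]
        assert ":1: rejected" in caplog.text

    def test_unknown_dialect(self, tmp_path):
        with pytest.raises(ValueError, match="unknown dialect"):
            read_intervals(_write(tmp_path, "a", ""), "vcf")

    def test_bed_round_trip(self, tmp_path):
        ivs = [GenomeInterval("c2", 5, 9, "+", "Gypsy"),
               GenomeInterval("c1", 0, 7, "-", "Copia")]
        write_bed(ivs, tmp_path / "t.bed")
        back = read_intervals(tmp_path / "t.bed", "bed")
        assert back == sorted(ivs, key=lambda iv: (iv.seq_name, iv.start))


class TestAlignmentsAndMarkers:
    def test_paf_block(self, tmp_path):
        row = "new1\t1000\t100\t300\t-\told1\t900\t0\t200\t180\t200\t60\n"
        blocks = read_alignments(_write(tmp_path, "a.paf", row), "paf")
        b = blocks[0]
        assert (b.query.seq_name, b.query.start, b.query.end) == ("new1", 100, 300)
        assert (b.target.seq_name, b.target.start, b.target.end) == ("old1", 0, 200)
        assert b.strand == "-" and b.identity == pytest.approx(0.9)

    def test_coords_block_reversed_query(self, tmp_path):
        row = "101\t300\t500\t301\t200\t200\t98.5\told1\tnew1\n"
        b = read_alignments(_write(tmp_path, "a.coords", row), "coords")[0]
        assert (b.query.seq_name, b.query.start, b.query.end) == ("new1", 300, 500)
        assert (b.target.start, b.target.end) == (100, 300)
        assert b.strand == "-"

    def test_paf_and_coords_reduce_to_same_block(self, tmp_path):
        paf = _write(tmp_path, "a.paf",
                     "new1\t1000\t100\t300\t+\told1\t900\t50\t250\t200\t200\t60\n")
        coords = _write(tmp_path, "a.coords",
                        "51\t250\t101\t300\t200\t200\t100.0\told1\tnew1\n")
        bp, bc = read_alignments(paf, "paf")[0], read_alignments(coords, "coords")[0]
        assert (bp.query, bp.target, bp.strand) == (bc.query, bc.target, bc.strand)

    def test_marker_tsv_round_trip(self, tmp_path):
        markers = [MarkerObservation("m1", "chr1", 12.5, "ctg7", 4096)]
        write_markers(markers, tmp_path / "m.tsv")
        assert read_markers(tmp_path / "m.tsv") == markers

    def test_genes_from_gff3(self, tmp_path):
        text = ("##gff-version 3\n"
                "c1\tsim\tgene\t1\t900\t.\t+\t.\tID=gA\n"
                "c1\tsim\tmRNA\t1\t900\t.\t+\t.\tID=gA.1;Parent=gA\n")
        genes = read_genes(_write(tmp_path, "g.gff3", text))
        assert genes == [("gA", GenomeInterval("c1", 0, 900, "+", "gene"))]


class TestReport:
    def _report(self):
        return AuditReport(
            assembly_label="sim",
            metrics={"sim": {"cumulative_size": 100}},
            chromosomes=[{"seq_name": "c1", "status": "gapless_T2T", "n_gaps": 0}],
            tracks={"telomeres": [GenomeInterval("c1", 0, 70, "+", "telomere")]},
            tables={"gaps": []},
            provenance={"seed": 1})

    def test_json_round_trip_lossless(self, tmp_path):
        report = self._report()
        write_report(report, tmp_path)
        assert read_report(tmp_path / "report.json") == report

    def test_empty_report_serialises(self, tmp_path):
        write_report(AuditReport(), tmp_path)
        assert json.loads((tmp_path / "report.json").read_text())["tracks"] == {}

    def test_bed_tracks_sorted(self, tmp_path):
        report = self._report()
        report.tracks["telomeres"].insert(
            0, GenomeInterval("c9", 5, 9, ".", "telomere"))
        report.tracks["telomeres"].insert(
            0, GenomeInterval("c1", 80, 95, ".", "telomere"))
        write_report(report, tmp_path)
        rows = (tmp_path / "telomeres.bed").read_text().splitlines()
        keys = [(r.split("\t")[0], int(r.split("\t")[1])) for r in rows]
        assert keys == sorted(keys)

    def test_validate_rejects_out_of_bounds(self):
        report = self._report()
        asm = Assembly([SequenceRecord("c1", "A" * 50)])
        with pytest.raises(ValueError, match="exceeds"):
            report.validate(asm)
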