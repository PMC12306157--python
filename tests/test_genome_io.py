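import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pefinder as pf
from pefinder.genome_io import GFFParseError, normalize_sequence


class TestReadFasta:
    def test_case_and_u_normalization(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1\nacgt\n>c2\nACGU\n")
        recs = pf.read_fasta(p)
        assert [(r.seq_id, r.sequence, r.length) for r in recs] == [
            ("c1", "ACGT", 4),
            ("c2", "ACGT", 4),
        ]

    def test_ambiguity_codes_become_n(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1\nARYG\n")
        assert pf.read_fasta(p)[0].sequence == "ANNG"

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(ValueError, match="no records"):
            pf.read_fasta(p)

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            pf.read_fasta(tmp_path / "nope.fa")

    def test_wrapped_multiline_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1\nACGT\nACGT\n")
        assert pf.read_fasta(p)[0].sequence == "ACGTACGT"


class TestReadGff:
    def test_coordinate_convention_and_id(self, tmp_path):
        p = tmp_path / "a.gff"
        p.write_text("c1\t.\tgene\t101\t200\t.\t+\t.\tID=g1\n")
        (g,) = pf.read_gff(p)
        assert (g.start, g.end, g.strand, g.gene_id) == (100, 200, "+", "g1")

    def test_type_filter_and_locus_tag_fallback(self, tmp_path):
        p = tmp_path / "a.gff"
        p.write_text(
            "##gff-version 3\n"
            "c1\t.\texon\t1\t50\t.\t+\t.\tID=e1\n"
            "c1\t.\tgene\t10\t90\t.\t-\t.\tlocus_tag=b0001\n"
        )
        feats = pf.read_gff(p, feature_classes={"gene"})
        assert len(feats) == 1 and feats[0].gene_id == "b0001"

    @pytest.mark.parametrize(
        "row,msg",
        [
            ("c1\t.\tgene\t200\t100\t.\t+\t.\tID=g1", "end"),
            ("c1\t.\tgene\t1\t9\t.\t?\t.\tID=g1", "strand"),
            ("c1\tgene\t1\t9\t+\tID=g1", "columns"),
        ],
    )
    def test_malformed_rows_name_the_line(self, tmp_path, row, msg):
        p = tmp_path / "bad.gff"
        p.write_text("# header\n" + row + "\n")
        with pytest.raises(GFFParseError, match=r"line 2.*" + msg):
            pf.read_gff(p)


class TestRevcomp:
    def test_known_values(self):
        assert pf.revcomp("ACGT") == "ACGT"
        assert pf.revcomp("AAA") == "TTT"
        assert pf.revcomp("GCN") == "NGC"

    def test_rejects_non_dna(self):
        with pytest.raises(ValueError):
            pf.revcomp("ACGX")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.text(alphabet="ACGTN", max_size=100))
    def test_involution(self, s):
        assert pf.revcomp(pf.revcomp(s)) == s


def _cand(start, end, seq_id="c1", strand="+", type_="REP", energy=-7.2):
    return pf.PECandidate(
        seq_id=seq_id,
        start=start,
        end=end,
        strand=strand,
        type=type_,
        sequence="A" * (end - start),
        stem_len=5,
        loop_len=4,
        hairpin_energy=energy,
        tail_score=-1.0,
    )


class TestWriteOutputs:
    def test_coordinate_conventions(self, tmp_path):
        paths = pf.write_outputs([_cand(99, 120)], tmp_path / "out")
        tsv = paths["tsv"].read_text().splitlines()
        row = dict(zip(tsv[0].split("\t"), tsv[1].split("\t")))
        assert (row["start"], row["end"], row["length"]) == ("100", "120", "21")
        bed = paths["bed"].read_text().split("\t")
        assert (bed[1], bed[2]) == ("99", "120")

    def test_bed_score_and_name(self, tmp_path):
        paths = pf.write_outputs(
            [_cand(0, 10, energy=-7.2), _cand(50, 60, energy=5.0)], tmp_path / "out"
        )
        lines = [l.split("\t") for l in paths["bed"].read_text().splitlines()]
        assert [l[3] for l in lines] == ["REP_1", "REP_2"]
        assert [l[4] for l in lines] == ["72", "0"]

    def test_empty_candidate_list(self, tmp_path):
        paths = pf.write_outputs([], tmp_path / "out")
        assert len(paths["tsv"].read_text().splitlines()) == 1
        assert paths["bed"].read_text() == ""
        assert paths["fasta"].read_text() == ""

    def test_sorted_across_records_and_fasta_roundtrip(self, tmp_path):
        cands = [_cand(5, 20, seq_id="c2"), _cand(50, 70, seq_id="c1"), _cand(0, 15, seq_id="c1")]
        paths = pf.write_outputs(cands, tmp_path / "out")
        rows = [l.split("\t") for l in paths["tsv"].read_text().splitlines()[1:]]
        assert [(r[0], r[1]) for r in rows] == [("c1", "1"), ("c1", "51"), ("c2", "6")]
        recs = pf.read_fasta(paths["fasta"])
        assert [r.sequence for r in recs] == [c.sequence for c in sorted(
            cands, key=lambda c: (c.seq_id, c.start))]


def test_normalize_sequence_maps_everything_outside_acgt():
    assert normalize_sequence("acgu r.y-n") == "ACGTNNNNNN"
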