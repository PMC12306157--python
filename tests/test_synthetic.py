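import pytest

import pefinder as pf
from conftest import build_clean_fixture


class TestMakeGenome:
    def test_deterministic_under_seed(self):
        a = pf.make_genome(2000, 0.5, seed=7)
        b = pf.make_genome(2000, 0.5, seed=7)
        assert a.sequence == b.sequence
        assert a.sequence != pf.make_genome(2000, 0.5, seed=8).sequence

    def test_gc_content_concentrates(self):
        g = pf.make_genome(100_000, 0.7, seed=1)
        gc = sum(1 for b in g.sequence if b in "GC") / g.length
        assert gc == pytest.approx(0.7, abs=0.02)

    def test_gc_zero_has_no_gc(self):
        g = pf.make_genome(1000, 0.0, seed=1)
        assert set(g.sequence) <= {"A", "T"}

    def test_rejects_tiny_genomes(self):
        with pytest.raises(ValueError):
            pf.make_genome(100, 0.5, seed=1)


class TestImplant:
    def test_truth_bookkeeping(self, clean_fixture):
        assert len(clean_fixture.truth) == 30
        kinds = [t.kind for t in clean_fixture.truth]
        assert kinds.count("REP") == 20 and kinds.count("RIT") == 10

    def test_same_seed_identical_files(self, tmp_path):
        d1 = build_clean_fixture(tmp_path / "a", seed=77)
        d2 = build_clean_fixture(tmp_path / "b", seed=77)
        assert d1.record.sequence == d2.record.sequence
        assert d1.paths["fasta"].read_text() == d2.paths["fasta"].read_text()
        assert d1.paths["truth_bed"].read_text() == d2.paths["truth_bed"].read_text()

    def test_implanted_sequence_is_perfect_palindrome(self, clean_fixture):
        seq = clean_fixture.record.sequence
        for t in clean_fixture.truth:
            elem = seq[t.start : t.end]
            arm = elem[:8]  # default arm length
            assert elem[-8:] == pf.revcomp(arm)

    def test_rit_tails_written(self, clean_fixture):
        seq = clean_fixture.record.sequence
        for t in clean_fixture.truth:
            if t.kind == "RIT":
                assert seq[t.end : t.end + 12] == "T" * 12

    def test_implants_avoid_genes(self, clean_fixture):
        for t in clean_fixture.truth:
            for g in clean_fixture.genes:
                assert t.end <= g.start or t.start >= g.end

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="tail"):
            pf.ImplantSpec(kind="RIT")
        with pytest.raises(ValueError):
            pf.ImplantSpec(kind="REP", tail="TTT")

    def test_too_many_implants_errors(self):
        genome = pf.make_genome(5000, 0.5, seed=1)
        genes = pf.make_gene_layout(5000, 3)
        with pytest.raises(ValueError, match="gaps"):
            pf.implant(genome, genes, [pf.ImplantSpec(kind="REP", count=10)], seed=2)


class TestEvaluateRecovery:
    def _pred(self, t, type_=None):
        return pf.PECandidate(
            seq_id=t.seq_id, start=t.start, end=t.end, strand="+",
            type=type_ or t.kind, sequence="A" * (t.end - t.start),
            stem_len=8, loop_len=4, hairpin_energy=-10.0, tail_score=-1.0,
        )

    def test_perfect_predictions(self, clean_fixture):
        preds = [self._pred(t) for t in clean_fixture.truth]
        rep = pf.evaluate_recovery(preds, clean_fixture.truth)
        assert rep.precision == 1.0
        assert all(v == 1.0 for v in rep.recall.values())

    def test_empty_predictions(self, clean_fixture):
        rep = pf.evaluate_recovery([], clean_fixture.truth)
        assert rep.precision is None
        assert all(v == 0.0 for v in rep.recall.values())

    def test_kind_confusion_not_counted_as_recall(self, clean_fixture):
        truth = clean_fixture.truth
        preds = [self._pred(t, type_="RIT" if t.kind == "REP" else t.kind) for t in truth]
        rep = pf.evaluate_recovery(preds, truth)
        assert rep.recall["REP"] == 0.0 and rep.recall["RIT"] == 1.0
        assert rep.confusion[("REP", "RIT")] == 20

    def test_truth_bed_roundtrip(self, clean_fixture):
        loaded = pf.synthetic.read_truth_bed(clean_fixture.paths["truth_bed"])
        assert [(t.start, t.end, t.kind) for t in loaded] == [
            (t.start, t.end, t.kind) for t in clean_fixture.truth
        ]

    def test_tsv_predictions_accepted(self, clean_fixture, clean_result, tmp_path):
        paths = pf.write_outputs(clean_result.candidates, tmp_path / "o")
        rep = pf.evaluate_recovery(paths["tsv"], clean_fixture.paths["truth_bed"])
        assert rep.recall["REP"] >= 0.95 and rep.recall["RIT"] >= 0.9
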