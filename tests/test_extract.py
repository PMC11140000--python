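import numpy as np
import pytest

from ticktx.align import HomologyHit
from ticktx.extract import (call_cds_by_homology, extract_cds,
                            flag_contaminants, refine_start, CdsRecord)
from ticktx.orfs import find_orfs
from ticktx.params import PipelineParams
from ticktx.simulate import SimParams, simulate


def _hit(subject_length, subject_span, score=200.0, taxon="tick",
         query_span=(0, 70)):
    return HomologyHit("q", "s", "desc", subject_length, subject_span,
                       query_span, score, 0.95, 1, taxon)


def _planted_orf(seq, min_len_nt):
    """The forward frame-0 ORF starting at 0, where these fixtures plant CDS."""
    (orf,) = [o for o in find_orfs("t", seq, min_len_nt=min_len_nt)
              if o.strand == "+" and o.frame == 0 and o.start == 0]
    return orf


class TestHomologyRoute:
    def setup_method(self):
        self.params = PipelineParams()
        rng = np.random.default_rng(0)
        # 120-codon ORF: ATG + 118 aa + stop
        from ticktx.simulate import _back_translate, _random_protein

        self.protein = _random_protein(rng, 119)
        self.seq = _back_translate(rng, self.protein) + "TAA"
        self.orf = _planted_orf(self.seq, self.params.min_orf_nt)

    def test_seventy_percent_coverage_boundary_accepted(self):
        hits = [_hit(100, (30, 100), query_span=(0, 70))]
        rec = call_cds_by_homology(self.orf, hits, self.params, self.seq)
        assert rec is not None and rec.evidence == "homology"

    def test_below_coverage_rejected(self):
        hits = [_hit(100, (65, 100), query_span=(0, 35))]
        assert call_cds_by_homology(self.orf, hits, self.params, self.seq) is None

    def test_no_hits_no_record(self):
        assert call_cds_by_homology(self.orf, [], self.params, self.seq) is None

    def test_short_orf_rejected_even_with_good_hit(self):
        seq = "ATGAAAAAAGAAGAAGAATAA"  # 21 nt < 100
        params = self.params
        orf = _planted_orf(seq, min_len_nt=9)
        hits = [_hit(6, (0, 6), query_span=(0, 6))]
        assert call_cds_by_homology(orf, hits, params, seq) is None

    def test_start_extended_to_met_at_or_before_query_span(self):
        # query span starts 2 residues into the protein; the Met at 0 is the
        # nearest at-or-upstream Met, so the CDS starts at the planted ATG
        hits = [_hit(110, (0, 110), query_span=(2, 112))]
        rec = call_cds_by_homology(self.orf, hits, self.params, self.seq)
        assert rec.start == 0 and rec.end == len(self.seq)
        assert rec.protein == self.protein


class TestSignalRoute:
    def setup_method(self):
        self.params = PipelineParams()

    def _seq_for(self, protein):
        from ticktx.simulate import _back_translate

        rng = np.random.default_rng(1)
        return _back_translate(rng, protein) + "TAA"

    def test_most_5prime_positive_met_selected(self):
        signal = "MKKLLLLLLLLLASA"
        protein = signal + "E" * 10 + signal + "E" * 40
        seq = self._seq_for(protein)
        orf = _planted_orf(seq, min_len_nt=100)
        rec = refine_start(orf, self.params, seq)
        assert rec is not None and rec.evidence == "signal"
        assert rec.start == 0  # the first Met wins, not the later one
        assert rec.protein == protein

    def test_no_positive_sub_orf_gives_none(self):
        protein = "M" + "D" * 60
        seq = self._seq_for(protein)
        orf = _planted_orf(seq, min_len_nt=100)
        assert refine_start(orf, self.params, seq) is None

    def test_min_length_enforced(self):
        # positive pattern but sub-ORF shorter than 40 aa
        protein = "MKKLLLLLLLLLASA" + "E" * 20  # 35 aa
        seq = self._seq_for(protein)
        orf = _planted_orf(seq, min_len_nt=60)
        assert refine_start(orf, self.params, seq) is None

    def test_external_signal_table_bypasses_heuristic(self):
        from ticktx.signalpep import SignalCall

        protein = "M" + "D" * 60  # heuristic-negative
        seq = self._seq_for(protein)
        orf = _planted_orf(seq, min_len_nt=100)
        table = {protein: SignalCall(True, 15, 1.0)}
        rec = refine_start(orf, self.params, seq, signal_table=table)
        assert rec is not None and rec.signal.cleavage_index == 15


class TestContaminantFlag:
    def _rec(self):
        return CdsRecord("c1", "t1", 0, 30, "+", "M" * 10, "ATG" * 10,
                         "homology", orf_id="o1")

    def test_sole_vertebrate_hit_flagged(self):
        rec = self._rec()
        hits = {"o1": [_hit(100, (0, 100), score=200, taxon="vertebrate")]}
        flag_contaminants([rec], hits, PipelineParams())
        assert rec.contaminant

    def test_close_tick_hit_rescues(self):
        rec = self._rec()
        hits = {"o1": [_hit(100, (0, 100), score=200, taxon="vertebrate"),
                       _hit(100, (0, 100), score=195, taxon="tick")]}
        flag_contaminants([rec], hits, PipelineParams())
        assert not rec.contaminant

    def test_distant_tick_hit_does_not_rescue(self):
        rec = self._rec()
        hits = {"o1": [_hit(100, (0, 100), score=200, taxon="bacteria"),
                       _hit(100, (0, 100), score=150, taxon="tick")]}
        flag_contaminants([rec], hits, PipelineParams())
        assert rec.contaminant

    def test_no_hits_kept(self):
        rec = self._rec()
        flag_contaminants([rec], {"o1": []}, PipelineParams())
        assert not rec.contaminant


class TestEmittedRecordInvariants:
    def test_records_translate_cleanly_and_meet_length_bounds(self, default_run):
        params = default_run.params
        for rec in default_run.records:
            assert "*" not in rec.protein
            assert rec.end - rec.start >= min(params.min_orf_nt,
                                              3 * params.min_signal_orf_aa)
            if rec.evidence in ("signal", "both"):
                assert rec.protein.startswith("M")
                assert len(rec.protein) >= params.min_signal_orf_aa

    def test_start_recovery_with_no_mutations_and_all_signals(self, clean_signal_sim,
                                                              clean_signal_run):
        truth = {t.transcript_id: t for t in clean_signal_sim.truth}
        n = n_exact = 0
        for rec in clean_signal_run.records:
            t = truth[rec.transcript_id]
            if t.contaminant:
                continue
            n += 1
            n_exact += (rec.strand == t.strand and rec.start == t.cds_start
                        and rec.end == t.cds_end)
        assert n > 0 and n_exact / n >= 0.95

    def test_mutation_free_best_hit_is_source_protein(self, clean_signal_sim,
                                                      clean_signal_run):
        truth = {t.transcript_id: t for t in clean_signal_sim.truth}
        for rec in clean_signal_run.records:
            t = truth[rec.transcript_id]
            if not t.source_subject:
                continue
            assert rec.best_hit is not None
            assert rec.best_hit.subject_id == t.source_subject
            assert rec.best_hit.identity_fraction == 1.0
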