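import numpy as np
import pandas as pd
import pytest

from ticktx.classify import default_vocabulary, RULE_CLASSES
from ticktx.design import build_design
from ticktx.orfs import revcomp
from ticktx.simulate import (SimParams, Simulation, generate_counts,
                             generate_reference_proteome, generate_transcripts,
                             group_multipliers, planted_log2fc, simulate)
from ticktx.signalpep import predict_signal_peptide

from Bio.Seq import Seq

SMALL = dict(transcripts_per_class=2, proteins_per_class=1,
             fraction_contaminant=0.0)


class TestProteome:
    def test_informative_descriptions_match_exactly_their_class(self):
        vocab = default_vocabulary()
        sim = SimParams(**SMALL, rng_seed=2)
        entries, class_proteins, hyp, cont = generate_reference_proteome(sim, vocab)
        for label, ids in class_proteins.items():
            for pid in ids:
                (entry,) = [e for e in entries if e.id == pid]
                found = vocab.match(entry.description)
                assert found is not None and found[3] == label

    def test_hypothetical_pool_is_keyword_free(self):
        vocab = default_vocabulary()
        sim = SimParams(**SMALL, rng_seed=2)
        entries, _, hyp, _ = generate_reference_proteome(sim, vocab)
        for e in entries:
            if e.id in set(hyp):
                assert vocab.match(e.description) is None
                assert "hypothetical" in e.description

    def test_deterministic_for_fixed_seed(self):
        sim = SimParams(**SMALL, rng_seed=5)
        a = generate_reference_proteome(sim)[0]
        b = generate_reference_proteome(sim)[0]
        assert a == b

    def test_too_many_classes_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            generate_reference_proteome(SimParams(n_classes=40))


@pytest.fixture(scope="module")
def small_sim():
    return simulate(SimParams(**SMALL, rng_seed=3))


class TestTranscripts:
    def test_planted_interval_translates_to_recorded_protein(self, small_sim):
        seq_by_id = {t.id: t.seq for t in small_sim.transcripts}
        for t in small_sim.truth:
            region = seq_by_id[t.transcript_id][t.cds_start:t.cds_end]
            if t.strand == "-":
                region = revcomp(region)
            assert str(Seq(region[:-3]).translate()) == t.protein
            assert region[-3:] in ("TAA", "TAG", "TGA")

    def test_signal_transcripts_accepted_by_predictor(self):
        sim = SimParams(**SMALL, fraction_signal_peptide=1.0, rng_seed=4)
        s = simulate(sim)
        planted = [t for t in s.truth if not t.contaminant]
        calls = [predict_signal_peptide(t.protein) for t in planted
                 if t.signal_peptide]
        assert len(calls) > 0
        assert np.mean([c.is_positive for c in calls]) >= 0.9
        assert all(c.cleavage_index == 20 for c in calls if c.is_positive)

    def test_no_hypothetical_descriptions_when_fraction_zero(self):
        sim = SimParams(**SMALL, fraction_unknown_conserved=0.0, rng_seed=5)
        s = simulate(sim)
        assert not any(t.class_label == "unknown conserved" for t in s.truth)

    def test_every_transcript_appears_once_in_truth(self, small_sim):
        ids = [t.transcript_id for t in small_sim.truth]
        assert len(ids) == len(set(ids)) == len(small_sim.transcripts)


class TestCounts:
    def _truth_and_design(self, seed=6, **kw):
        s = simulate(SimParams(**SMALL, rng_seed=seed, **kw))
        return s.truth, s.design

    def test_flat_transcripts_have_zero_planted_lfc(self):
        truth, _ = self._truth_and_design()
        for t in truth:
            if t.shape == "flat":
                assert all(v == 0.0 for v in t.log2fc.values())

    def test_fixed_seed_reproduces_table(self):
        truth, design = self._truth_and_design()
        sim = SimParams(**SMALL, rng_seed=6)
        rng1 = np.random.default_rng(99)
        rng2 = np.random.default_rng(99)
        a = generate_counts(truth, design, sim, rng1)
        b = generate_counts(truth, design, sim, rng2)
        pd.testing.assert_frame_equal(a, b)

    def test_poisson_limit_group_means_within_3se(self):
        # phi = 0 and unit size factors: counts are Poisson; each transcript's
        # per-group mean must sit within 3 standard errors of its planted mean
        sim = SimParams(**SMALL, dispersion=0.0, size_factor_range=(1.0, 1.0),
                        rng_seed=7)
        design = build_design(["s"], ["UF", "FED6h", "FED12h", "FED24h", "FED5d"],
                              30)  # many replicates to make SE meaningful
        s_truth = simulate(sim).truth[:40]
        counts = generate_counts(s_truth, design, sim, np.random.default_rng(8))
        bad = 0
        total = 0
        for t in s_truth:
            mult = group_multipliers(t.shape, list(design.groups), 16.0, 64.0)
            for g in design.groups:
                libs = design.cell("s", g)
                mu = t.baseline * mult[g]
                se = np.sqrt(mu / len(libs))
                total += 1
                if abs(counts.loc[t.transcript_id, libs].mean() - mu) > 3 * se:
                    bad += 1
        assert bad / total < 0.05  # 3-SE exceedances are rare under Poisson

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            SimParams(dispersion=-0.5)


class TestProfiles:
    def test_multiplier_shapes(self):
        groups = ["UF", "FED6h", "FED12h", "FED24h", "FED5d"]
        u = group_multipliers("u_shape", groups, 16, 64)
        assert u["UF"] == 1 and u["FED6h"] == 1 / 16 and u["FED5d"] == 1
        ind = group_multipliers("induced", groups, 16, 64)
        assert ind["FED6h"] == 16 and ind["FED5d"] == 1
        late = group_multipliers("late_switch", groups, 16, 64)
        assert late["UF"] == 1 and late["FED5d"] == 64

    def test_planted_lfc_matches_multipliers(self):
        groups = ["UF", "FED6h", "FED12h", "FED24h", "FED5d"]
        lfc = planted_log2fc("u_shape", groups, 16, 64)
        assert lfc[("UF", "FED6h")] == -4.0
        assert lfc[("FED24h", "FED5d")] == 4.0
        assert lfc[("UF", "FED5d")] == 0.0


def test_default_simulation_is_deterministic_and_sized(default_sim):
    s2 = simulate(SimParams(rng_seed=1))
    assert [t.seq for t in s2.transcripts] == [t.seq for t in default_sim.transcripts]
    pd.testing.assert_frame_equal(s2.counts, default_sim.counts)
    assert len(default_sim.transcripts) == 540  # 500 planted + 8% contaminants
    assert len(default_sim.design.libraries) == 45
    labels = {t.class_label for t in default_sim.truth if t.class_label}
    assert len(labels) == 25
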