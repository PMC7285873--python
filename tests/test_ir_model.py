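"""Intron-retention detection, chain fitting, sampling and templates."""

import numpy as np
import pytest

from ont_txsim.io_formats import AlignmentRecord, Transcript, TranscriptAnnotation, revcomp
from ont_txsim.ir_model import (
    IRModel,
    IRObservation,
    build_template,
    classify_read_introns,
    detect_ir,
    fit_ir_model,
    sample_ir_pattern,
    transcripts_with_retention,
)

# one gene: exons (0,100) and (600,700), 500 nt intron
TX = Transcript("t1", "g1", "c1", "+", [(0, 100), (600, 700)])


def _genome_aln(walk, tstart=0):
    q = sum(n for op, n in walk if op in "MXI")
    t = sum(n for op, n in walk if op in "MXDN")
    return AlignmentRecord("r1", q, "c1", "genome", "+", 0, q, tstart,
                           tstart + t, walk)


class TestClassification:
    def test_spliced_read_n_op(self):
        obs = classify_read_introns(_genome_aln([("M", 100), ("N", 500), ("M", 100)]), TX)
        assert obs.intron_states == [False]
        assert obs.introns_covered == [0]

    def test_retained_read_contiguous_match(self):
        obs = classify_read_introns(_genome_aln([("M", 700)]), TX)
        assert obs.intron_states == [True]

    def test_intron_outside_span_uncovered(self):
        # read covers only the first exon: intron not informative
        obs = classify_read_introns(_genome_aln([("M", 100)]), TX)
        assert obs is None

    def test_poor_coverage_no_n_uninformative(self):
        # read enters 200/500 intron bases without splicing: below the 90%
        # retention threshold and no N op -> uncovered
        walk = [("M", 300), ("I", 5), ("M", 400)]
        aln = AlignmentRecord("r1", 705, "c1", "genome", "+", 0, 705, 0, 700, walk)
        obs = classify_read_introns(aln, TX)
        assert obs.intron_states[0] is True  # fully aligned through: retained
        short = _genome_aln([("M", 300)])
        assert classify_read_introns(short, TX) is None


class TestFitIRModel:
    def test_all_spliced(self):
        obs = [
            IRObservation(f"r{i}", "t1", [False, False], [0, 1]) for i in range(200)
        ]
        model = fit_ir_model(obs)
        assert model.p_first == 0.0
        assert model.p_retain_given_spliced == 0.0

    def test_smoothing_small_counts(self):
        # a single observation: conditioning counts < 5 -> add-one smoothing
        obs = [IRObservation("r0", "t1", [True, True], [0, 1])]
        model = fit_ir_model(obs)
        assert model.p_first == 1.0
        assert model.p_retain_given_retained == pytest.approx(2 / 3)  # (1+1)/(1+2)

    def test_no_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_ir_model([])

    def test_conditional_enrichment_shape(self):
        """With first-intron retention rare but strong retained->retained
        transition (0.41% -> 17.12%), conditional retention is elevated
        ~42-fold over the first-intron rate."""
        model = IRModel(p_first=0.0041, p_retain_given_spliced=0.0041,
                        p_retain_given_retained=0.1712)
        assert model.p_retain_given_retained / model.p_first == pytest.approx(41.76, rel=1e-3)
        marg = model.marginal_retention(6)
        assert marg[0] == pytest.approx(0.0041)
        assert np.all(np.diff(marg) >= 0)  # retention compounds along the chain

    def test_recovery_from_fixture_chain(self, ir_corpus):
        spec, ref, corpus = ir_corpus
        obs, report = detect_ir(
            corpus.genome_alignments, corpus.transcriptome_alignments, ref.annotation
        )
        model = fit_ir_model(obs)
        truth = spec.ir_chain
        c = model.counts
        for est, tru, (k, n) in [
            (model.p_first, truth[0], c["first"]),
            (model.p_retain_given_spliced, truth[1], c["from_spliced"]),
            (model.p_retain_given_retained, truth[2], c["from_retained"]),
        ]:
            se = np.sqrt(tru * (1 - tru) / n)
            assert abs(est - tru) <= 3 * se

    def test_exact_call_accuracy(self, ir_corpus):
        """With exact alignments every covered intron call equals the
        generating pattern."""
        _, ref, corpus = ir_corpus
        obs, _ = detect_ir(
            corpus.genome_alignments, corpus.transcriptome_alignments, ref.annotation
        )
        by_id = {o.read_id: o for o in obs}
        checked = 0
        for rid, pattern in corpus.ir_patterns.items():
            o = by_id.get(rid)
            if o is None:
                continue
            for i in o.introns_covered:
                assert o.intron_states[i] == pattern[i]
                checked += 1
        assert checked > 10000

    def test_report_consistency(self, ir_corpus):
        _, ref, corpus = ir_corpus
        obs, report = detect_ir(
            corpus.genome_alignments, corpus.transcriptome_alignments, ref.annotation
        )
        from_obs = len(
            {o.transcript_id for o in obs
             if any(o.intron_states[i] for i in o.introns_covered)}
        )
        assert transcripts_with_retention(report) == from_obs


class TestSampleIRPattern:
    def test_all_zero_model(self):
        model = IRModel(0.0, 0.0, 0.0)
        rng = np.random.default_rng(0)
        assert sample_ir_pattern(model, 5, rng) == [False] * 5

    def test_zero_introns_empty(self):
        assert sample_ir_pattern(IRModel(0.5, 0.5, 0.5), 0,
                                 np.random.default_rng(0)) == []

    def test_marginals_match_forward_oracle(self):
        model = IRModel(0.05, 0.02, 0.6)
        rng = np.random.default_rng(11)
        n, k = 30000, 5
        counts = np.zeros(k)
        for _ in range(n):
            counts += sample_ir_pattern(model, k, rng)
        # independent forward computation
        expected = []
        p = 0.05
        for _ in range(k):
            expected.append(p)
            p = p * 0.6 + (1 - p) * 0.02
        for i in range(k):
            se = np.sqrt(expected[i] * (1 - expected[i]) / n)
            assert abs(counts[i] / n - expected[i]) <= 3 * se


@pytest.fixture(scope="module")
def mini_ref():
    rng = np.random.default_rng(12)
    bases = np.array(list("ACGT"))
    chrom = "".join(rng.choice(bases, size=1000))
    genome = {"c1": chrom}
    plus = Transcript("tp", "g1", "c1", "+", [(0, 100), (600, 700), (850, 900)])
    minus = Transcript("tm", "g2", "c1", "-", [(0, 100), (600, 700), (850, 900)])
    return genome, plus, minus


class TestBuildTemplate:

    def test_all_spliced_equals_transcript(self, mini_ref):
        genome, plus, _ = mini_ref
        spliced = genome["c1"][0:100] + genome["c1"][600:700] + genome["c1"][850:900]
        template, records = build_template(plus, genome, [False, False], spliced)
        assert template == spliced and records == []

    def test_retained_intron_length_arithmetic(self, mini_ref):
        genome, plus, _ = mini_ref
        template, records = build_template(plus, genome, [True, False])
        assert len(template) == 250 + 500
        assert records[0].ref_pos == 0 and records[0].length == 500

    def test_minus_strand_revcomp(self, mini_ref):
        genome, _, minus = mini_ref
        # transcript intron index 0 is the genomically-last gap (700, 850)
        template, records = build_template(minus, genome, [True, False])
        expected = revcomp(
            genome["c1"][0:100] + genome["c1"][600:850] + genome["c1"][850:900]
        )
        assert template == expected
        assert records[0].length == 150

    def test_missing_chromosome_rejected(self, mini_ref):
        _, plus, _ = mini_ref
        with pytest.raises(KeyError, match="c1"):
            build_template(plus, {"other": "ACGT"}, [False, False])

    def test_fixture_molecule_cross_check(self, ir_corpus):
        """build_template reproduces the generator's independently-built
        molecule for random retained patterns."""
        from ont_txsim.fixtures import _molecule_for

        _, ref, _ = ir_corpus
        rng = np.random.default_rng(13)
        tids = sorted(ref.annotation.transcripts)
        for tid in tids[:10]:
            tx = ref.annotation[tid]
            if not tx.introns:
                continue
            pattern = [bool(rng.random() < 0.5) for _ in tx.introns]
            template, records = build_template(tx, ref.genome, pattern,
                                               ref.transcriptome[tid])
            molecule, _ = _molecule_for(ref, tid, pattern)
            assert template == molecule
            retained_len = sum(
                e - s for (s, e), keep in zip(tx.introns, pattern) if keep
            )
            assert len(template) == tx.length + retained_len
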