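"""Error-mode extraction, mixture/Markov fitting, layout sampling, replay."""

import numpy as np
import pytest

from ont_txsim.error_model import (
    ERROR_TYPES,
    ErrorEventTable,
    ErrorModel,
    apply_errors,
    extract_error_events,
    fit_error_model,
    fit_length_mixture,
    layout_ref_consumption,
    measure_segment_lengths,
    mixture_mean,
    sample_error_layout,
)
from ont_txsim.io_formats import AlignmentRecord


def _aln(walk, qlen=None, tlen=None):
    q = sum(n for op, n in walk if op in "MXI")
    t = sum(n for op, n in walk if op in "MXDN")
    return AlignmentRecord("r0", q, "t0", "transcriptome", "+", 0, q, 0, t, walk)


class TestExtractErrorEvents:
    def test_perfect_walk(self):
        table = extract_error_events([_aln([("M", 10)])])
        assert table.per_read_events == [[]]
        assert table.match_lengths == [10]
        assert table.rates == (0.0, 0.0, 0.0)

    def test_arithmetic_example(self):
        walk = [("M", 5), ("X", 2), ("M", 3), ("D", 1), ("M", 4)]
        table = extract_error_events([_aln(walk)])
        assert table.per_read_events == [[("mis", 2), ("del", 1)]]
        assert table.match_lengths == [5, 3, 4]
        assert table.rates == pytest.approx((2 / 15, 0.0, 1 / 15))

    def test_abutting_errors_zero_match(self):
        walk = [("M", 5), ("X", 1), ("D", 2), ("M", 3)]
        table = extract_error_events([_aln(walk)])
        assert table.match_lengths == [5, 0, 3]

    def test_closed_loop_rate_recovery(self, error_corpus):
        """Rates recovered from ~6e6 fixture-aligned bases are within 0.3
        percentage points of the generating 5/3/3%."""
        spec, _, corpus = error_corpus
        table = extract_error_events(corpus.transcriptome_alignments)
        assert table.aligned_ref_bases > 1_000_000
        for rate, truth in zip(table.rates, spec.error_rates):
            assert abs(rate - truth) < 0.003


class TestMixtureFits:
    def test_pure_geometric_recovery(self):
        rng = np.random.default_rng(0)
        lengths = rng.geometric(0.4, size=20000)
        mix = fit_length_mixture(lengths, "weibull")
        assert abs(mixture_mean(mix) - 2.5) / 2.5 < 0.05

    def test_degenerate_all_ones(self):
        with pytest.warns(UserWarning, match="degenerate"):
            mix = fit_length_mixture([1] * 100, "poisson")
        assert mix == {"w": 0.0, "lam": 1.0, "p": 1.0}

    def test_few_events_geometric_fallback(self):
        mix = fit_length_mixture([1, 2, 3], "weibull")
        assert mix["w"] == 0.0 and mix["p"] == pytest.approx(0.5)

    def test_generating_mixture_mean_recovery(self, error_corpus, trained_bundle):
        spec, _, _ = error_corpus
        fitted = {
            "mis": trained_bundle.error_model.mismatch_mixture,
            "ins": trained_bundle.error_model.ins_mixture,
            "del": trained_bundle.error_model.del_mixture,
        }
        truth = {"mis": spec.mis_mixture, "ins": spec.ins_mixture,
                 "del": spec.del_mixture}
        for t in ERROR_TYPES:
            m_fit, m_true = mixture_mean(fitted[t]), mixture_mean(truth[t])
            assert abs(m_fit - m_true) / m_true < 0.05, t


class TestMarkovFit:
    def test_known_chain_recovery(self):
        chain = np.array([[0.5, 0.3, 0.2], [0.2, 0.5, 0.3], [0.3, 0.2, 0.5]])
        rng = np.random.default_rng(3)
        per_read = []
        for _ in range(500):
            state = int(rng.integers(3))
            events = [(ERROR_TYPES[state], 2)]
            for _ in range(20):
                state = int(np.searchsorted(np.cumsum(chain[state]), rng.random()))
                events.append((ERROR_TYPES[state], 2))
            per_read.append(events)
        table = ErrorEventTable(
            per_read_events=per_read,
            match_lengths=[5] * 11000,
            aligned_ref_bases=1_000_000,
            type_bases={t: 10000 for t in ERROR_TYPES},
            type_counts={t: sum(len(e) for e in per_read) // 3 for t in ERROR_TYPES},
        )
        model = fit_error_model(table)
        n_per_row = 500 * 20 / 3  # ~transitions per conditioning state
        for i in range(3):
            for j in range(3):
                p = chain[i, j]
                se = np.sqrt(p * (1 - p) / n_per_row)
                assert abs(model.markov[i, j] - p) < 3 * se

    def test_single_type_rows_smoothed_uniform(self):
        per_read = [[("mis", 1)] * 10 for _ in range(100)]
        table = ErrorEventTable(per_read, [3] * 1100, 100000,
                                {"mis": 1000, "ins": 0, "del": 0},
                                {"mis": 1000, "ins": 0, "del": 0})
        with pytest.warns(UserWarning):
            model = fit_error_model(table)
        # never-seen conditioning states get uniform rows after smoothing
        np.testing.assert_allclose(model.markov[1], [1 / 3] * 3)
        np.testing.assert_allclose(model.markov[2], [1 / 3] * 3)

    def test_stationary_distribution_matches_eigen_oracle(self, trained_bundle):
        model = trained_bundle.error_model
        rng = np.random.default_rng(5)
        state = model.sample_first_type(rng)
        counts = dict.fromkeys(ERROR_TYPES, 0)
        n = 100_000
        for _ in range(n):
            counts[state] += 1
            state = model.sample_next_type(state, rng)
        vals, vecs = np.linalg.eig(model.markov.T)
        stat = np.real(vecs[:, np.argmax(np.real(vals))])
        stat = stat / stat.sum()
        for i, t in enumerate(ERROR_TYPES):
            se = np.sqrt(stat[i] * (1 - stat[i]) / n)
            # correlated draws: allow 6 nominal SE
            assert abs(counts[t] / n - stat[i]) < 6 * se


class TestLayoutSampling:
    def test_zero_rate_model_single_match(self):
        model = ErrorModel(
            rates=(0.0, 0.0, 0.0),
            mismatch_mixture={"w": 0.0, "lam": 1.0, "p": 1.0},
            ins_mixture={"w": 0.0, "shape": 1.0, "scale": 1.0, "p": 1.0},
            del_mixture={"w": 0.0, "shape": 1.0, "scale": 1.0, "p": 1.0},
            match_points=np.array([np.log1p(10.0)]), match_bandwidth=0.1,
            markov=np.full((3, 3), 1 / 3), pi=np.full(3, 1 / 3),
        )
        assert sample_error_layout(model, 500, np.random.default_rng(0)) == [
            ("match", 500, 0)
        ]

    def test_reference_consumption_exact(self, trained_bundle):
        model = trained_bundle.error_model
        rng = np.random.default_rng(6)
        for _ in range(300):
            n = int(rng.integers(1, 3000))
            layout = sample_error_layout(model, n, rng)
            assert layout_ref_consumption(layout) == n

    def test_masked_intervals_receive_no_errors(self, trained_bundle):
        model = trained_bundle.error_model
        rng = np.random.default_rng(7)
        masked = [(100, 150), (300, 420)]
        for _ in range(50):
            layout = sample_error_layout(model, 500, rng, masked)
            for typ, n, off in layout:
                if typ == "match":
                    continue
                hi = off + n if typ in ("mis", "del") else off
                for s, e in masked:
                    assert hi <= s or off >= e

    def test_aggregate_rates_match_model(self, trained_bundle):
        model = trained_bundle.error_model
        rng = np.random.default_rng(8)
        totals = dict.fromkeys(("mis", "ins", "del"), 0)
        ref = 0
        for _ in range(3000):
            layout = sample_error_layout(model, 1000, rng)
            ref += 1000
            for typ, n, _ in layout:
                if typ in totals:
                    totals[typ] += n
        for t, rate in zip(ERROR_TYPES, model.rates):
            assert abs(totals[t] / ref - rate) < 0.003, t


class TestApplyErrors:
    def test_all_match_identity(self):
        rng = np.random.default_rng(0)
        seq, events = apply_errors("ACGTAC", [("match", 6, 0)], rng)
        assert seq == "ACGTAC" and events == []

    def test_deletion_example(self):
        rng = np.random.default_rng(0)
        seq, events = apply_errors(
            "AAAA", [("match", 1, 0), ("del", 2, 1), ("match", 1, 3)], rng
        )
        assert seq == "AA"
        assert len(events) == 1
        assert (events[0].event, events[0].ref_pos, events[0].length) == ("del", 1, 2)

    def test_empty_layout_rejected(self):
        with pytest.raises(ValueError, match="layout consumes"):
            apply_errors("ACGT", [], np.random.default_rng(0))

    def test_mismatch_always_changes_base(self):
        rng = np.random.default_rng(1)
        seq, events = apply_errors("AAAAAAAA", [("mis", 8, 0)], rng)
        assert all(b != "A" for b in seq)

    def test_replay_reconstruction(self, trained_bundle):
        """Applying recorded events back to the template reproduces the read."""
        model = trained_bundle.error_model
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            n = int(rng.integers(20, 500))
            template = "".join(rng.choice(bases, size=n))
            layout = sample_error_layout(model, n, rng)
            read, events = apply_errors(template, layout, rng)
            # independent pointer replay
            out, ti = [], 0
            for e in events:
                out.append(template[ti : e.ref_pos])
                ti = e.ref_pos
                if e.event == "mis":
                    out.append(e.bases)
                    ti += e.length
                elif e.event == "del":
                    ti += e.length
                else:
                    out.append(e.bases)
            out.append(template[ti:])
            assert "".join(out) == read


class TestMeasureSegmentLengths:
    def test_perfect_alignments_no_errors(self):
        hist = measure_segment_lengths([_aln([("M", 50)])])
        assert sum(hist["mis"].values()) == 0
        assert hist["match"] == {50: 1}

    def test_totals_conserved(self, error_corpus):
        _, _, corpus = error_corpus
        alns = corpus.transcriptome_alignments[:500]
        hist = measure_segment_lengths(alns)
        table = extract_error_events(alns)
        for t in ERROR_TYPES:
            assert sum(hist[t].values()) == table.type_counts[t]
        assert sum(hist["match"].values()) == len(table.match_lengths)

    def test_simulated_vs_training_distribution(self, trained_bundle, error_corpus):
        """Chi-squared over pooled mismatch-length bins: simulated layouts vs
        the empirical training distribution."""
        from collections import Counter
        from scipy import stats

        _, _, corpus = error_corpus
        table = extract_error_events(corpus.transcriptome_alignments)
        emp = Counter(n for ev in table.per_read_events for t, n in ev if t == "mis")
        model = trained_bundle.error_model
        rng = np.random.default_rng(10)
        sim = Counter()
        for _ in range(2000):
            for typ, n, _ in sample_error_layout(model, 600, rng):
                if typ == "mis":
                    sim[n] += 1
        bins = [1, 2, 3, 4]  # pooled tail
        def pooled(c):
            v = [c.get(b, 0) for b in bins]
            v.append(sum(n for k, n in c.items() if k > bins[-1]))
            return np.array(v, dtype=float)
        e, s = pooled(emp), pooled(sim)
        e = e / e.sum() * s.sum()
        chi2 = ((s - e) ** 2 / np.maximum(e, 1)).sum()
        p = 1 - stats.chi2.cdf(chi2, df=len(bins))
        assert p > 0.01
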