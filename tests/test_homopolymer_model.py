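"""Homopolymer run finding, measurement, regression fits and simulation."""

from itertools import groupby

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ont_txsim.homopolymer_model import (
    HomopolymerModel,
    HomopolymerObservation,
    _BaseFit,
    apply_homopolymer_effects,
    extract_homopolymer_observations,
    find_homopolymers,
    fit_homopolymer_model,
)
from ont_txsim.io_formats import AlignmentRecord


class TestFindHomopolymers:
    def test_no_runs(self):
        assert find_homopolymers("ACGT", 5) == []

    def test_adjacent_runs(self):
        assert find_homopolymers("AAAAACCCCCC", 5) == [("A", 0, 5), ("C", 5, 6)]

    def test_planted_runs_recovered(self, hp_corpus):
        _, ref, _ = hp_corpus
        n_planted = sum(len(v) for v in ref.planted_runs.values())
        assert n_planted > 50
        for tid, runs in ref.planted_runs.items():
            assert find_homopolymers(ref.transcriptome[tid], 5) == runs

    @given(st.text(alphabet="ACGT", min_size=0, max_size=80), st.integers(2, 6))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_matches_groupby_oracle(self, seq, min_len):
        oracle = []
        pos = 0
        for base, grp in groupby(seq):
            n = len(list(grp))
            if n >= min_len:
                oracle.append((base, pos, n))
            pos += n
        assert find_homopolymers(seq, min_len) == oracle


def _aln_over(tid, walk, tstart=0):
    q = sum(n for op, n in walk if op in "MXI")
    t = sum(n for op, n in walk if op in "MXDN")
    return AlignmentRecord("r1", q, tid, "transcriptome", "+", 0, q, tstart,
                           tstart + t, walk)


class TestExtractObservations:
    REF = {"t1": "CG" + "A" * 10 + "GC" + "T" * 3 + "G"}  # run (A, 2, 10)

    def test_perfect_alignment(self):
        obs = extract_homopolymer_observations(
            [_aln_over("t1", [("M", 18)])], self.REF, 5
        )
        assert obs == [HomopolymerObservation("A", 10, 10)]

    def test_deletion_inside_run(self):
        walk = [("M", 5), ("D", 3), ("M", 10)]
        obs = extract_homopolymer_observations([_aln_over("t1", walk)], self.REF, 5)
        assert obs == [HomopolymerObservation("A", 10, 7)]

    def test_truncated_run_skipped(self):
        # alignment ends mid-run
        obs = extract_homopolymer_observations(
            [_aln_over("t1", [("M", 8)])], self.REF, 5
        )
        assert obs == []

    def test_matching_insertion_extends(self):
        walk = [("M", 5), ("I", 2), ("M", 13)]
        reads = {"r1": self.REF["t1"][:5] + "AA" + self.REF["t1"][5:]}
        obs = extract_homopolymer_observations(
            [_aln_over("t1", walk)], self.REF, 5, reads
        )
        assert obs == [HomopolymerObservation("A", 10, 12)]
        # non-matching inserted bases are ignored for the measurement
        reads2 = {"r1": self.REF["t1"][:5] + "GG" + self.REF["t1"][5:]}
        obs2 = extract_homopolymer_observations(
            [_aln_over("t1", walk)], self.REF, 5, reads2
        )
        assert obs2 == [HomopolymerObservation("A", 10, 10)]

    def test_fixture_mean_recovery(self, hp_corpus, hp_model):
        """Mean read length per reference length tracks 0.9*L within 3 SE."""
        spec, _, _ = hp_corpus
        _, obs = hp_model
        by_len = {}
        for o in obs:
            by_len.setdefault(o.ref_len, []).append(o.read_len)
        checked = 0
        for L, vals in by_len.items():
            if len(vals) < 30:
                continue
            sd = spec.hp_sd_slope * L + spec.hp_sd_intercept
            se = np.sqrt(sd**2 / len(vals) + 0.25 / len(vals))  # + rounding var
            assert abs(np.mean(vals) - spec.hp_mean_slope * L) <= 4 * se
            checked += 1
        assert checked >= 5


class TestFitModel:
    def test_regression_recovery(self, hp_corpus, hp_model):
        spec, _, _ = hp_corpus
        model, _ = hp_model
        for b in "ACGT":
            fit = model.per_base[b]
            assert not fit.identity
            for L in range(spec.hp_min_len, 21):
                pred = fit.mean(L)
                assert abs(pred - 0.9 * L) / (0.9 * L) < 0.05, (b, L)
            # SD line: slope 0.05, intercept 0.3
            assert model.sd(b, 15) == pytest.approx(0.05 * 15 + 0.3, rel=0.35)

    def test_identity_fit_when_unchanged(self):
        obs = [HomopolymerObservation("A", L, L) for L in (5, 8, 12) for _ in range(20)]
        with pytest.warns(UserWarning):  # C/G/T fall back
            model = fit_homopolymer_model(obs, 5)
        fit = model.per_base["A"]
        for L in (5, 8, 12):
            assert fit.mean(L) == pytest.approx(L, abs=1e-6)
        assert fit.sd(10) == pytest.approx(0.1)  # clamped floor

    def test_insufficient_observations_fallback(self):
        obs = [HomopolymerObservation("A", 6, 5)] * 10
        with pytest.warns(UserWarning, match="identity"):
            model = fit_homopolymer_model(obs, 5)
        assert model.per_base["A"].identity
        assert model.mean("A", 12) == 12.0

    def test_per_base_differences_recovered(self):
        """A/T runs generated with a different contraction law than C/G fit
        to visibly different mean models."""
        from ont_txsim.fixtures import FixtureSpec, make_reads_with_truth, make_reference

        rng = np.random.default_rng(21)
        per_base = {b: {"mean_slope": 0.95, "mean_intercept": 0.0,
                        "sd_slope": 0.02, "sd_intercept": 0.3} for b in "AT"}
        per_base.update({b: {"mean_slope": 0.75, "mean_intercept": 0.0,
                             "sd_slope": 0.02, "sd_intercept": 0.3} for b in "CG"})
        spec = FixtureSpec(n_genes=30, with_errors=False, with_homopolymers=True,
                           full_length=True, hp_per_base=per_base)
        ref = make_reference(spec, rng)
        corpus = make_reads_with_truth(spec, ref, 1200, rng)
        reads = {r.id: r.sequence for r in corpus.reads}
        obs = extract_homopolymer_observations(
            corpus.transcriptome_alignments, ref.transcriptome, 5, reads
        )
        model = fit_homopolymer_model(obs, 5)
        assert model.mean("A", 15) > model.mean("C", 15) + 1.5
        assert model.mean("T", 15) > model.mean("G", 15) + 1.5


class TestApplyEffects:
    def test_identity_low_sd_unchanged(self):
        model = HomopolymerModel.identity_model(5)
        for b in "ACGT":
            model.per_base[b] = _BaseFit(0, 0, 1.0, 1.0, 0.0, 0.0, 100)
        seq = "CG" + "A" * 12 + "TTTTTT" + "GC"
        out, records, masked = apply_homopolymer_effects(
            seq, model, np.random.default_rng(0)
        )
        assert out == seq
        assert [r.new_length for r in records] == [12, 6]

    def test_deterministic_contraction(self):
        model = HomopolymerModel.identity_model(5)
        model.per_base["A"] = _BaseFit(
            breakpoint=0, intercept=-2.0, slope1=1.0, slope2=1.0,
            sd_intercept=0.0, sd_slope=0.0, n_observations=100,
        )  # mean(L) = L - 2, sd clamped to 0.1
        seq = "C" + "A" * 20 + "G"
        rng = np.random.default_rng(1)
        for _ in range(100):
            out, records, _ = apply_homopolymer_effects(seq, model, rng)
            assert out == "C" + "A" * 18 + "G"
            assert records[0].new_length == 18

    def test_length_arithmetic_and_untouched_bytes(self, hp_model):
        model, _ = hp_model
        rng = np.random.default_rng(2)
        bases = np.array(list("ACGT"))
        for _ in range(100):
            parts = []
            for _ in range(4):
                parts.append("".join(rng.choice(bases, size=int(rng.integers(5, 30)))))
                b = "ACGT"[rng.integers(4)]
                parts.append(b * int(rng.integers(5, 22)))
            parts.append("".join(rng.choice(bases, size=10)))
            seq = "".join(parts)
            out, records, masked = apply_homopolymer_effects(seq, model, rng)
            delta = sum(r.new_length - r.length for r in records)
            assert len(out) == len(seq) + delta
            for (s0, e0), (s1, e1) in zip(masked, masked[1:]):
                assert e0 <= s1  # reported runs never overlap
            # bytes outside modified runs are identical
            rebuilt = []
            cursor = 0
            for r in sorted(records, key=lambda r: r.ref_pos):
                rebuilt.append(seq[cursor : r.ref_pos])
                rebuilt.append(r.bases * r.new_length)
                cursor = r.ref_pos + r.length
            rebuilt.append(seq[cursor:])
            assert "".join(rebuilt) == out

    def test_sampled_moments_match_model(self, hp_model):
        model, _ = hp_model
        rng = np.random.default_rng(3)
        L = 15
        seq = "C" + "A" * L + "G"
        draws = []
        for _ in range(5000):
            _, records, _ = apply_homopolymer_effects(seq, model, rng)
            draws.append(records[0].new_length)
        mu, sd = model.mean("A", L), model.sd("A", L)
        sd_round = np.sqrt(sd**2 + 1 / 12)  # integer rounding variance
        assert abs(np.mean(draws) - mu) <= 3 * sd_round / np.sqrt(len(draws))
        assert abs(np.std(draws) - sd_round) / sd_round < 0.1
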