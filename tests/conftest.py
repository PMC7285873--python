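"""Shared synthetic corpora (session-scoped: several tests recover parameters
from the same generated data)."""

from __future__ import annotations

import numpy as np
import pytest

from ont_txsim.characterize import characterize
from ont_txsim.fixtures import FixtureSpec, make_reads_with_truth, make_reference


@pytest.fixture(scope="session")
def error_corpus():
    """10k reads with known error process (5/3/3%), strand 0.85, 5% unaligned."""
    rng = np.random.default_rng(101)
    spec = FixtureSpec(n_genes=50, unaligned_fraction=0.05)
    ref = make_reference(spec, rng)
    corpus = make_reads_with_truth(spec, ref, 10000, rng)
    return spec, ref, corpus


@pytest.fixture(scope="session")
def trained_bundle(error_corpus):
    """ModelBundle characterized from the error corpus."""
    _, ref, corpus = error_corpus
    return characterize(
        corpus.transcriptome_alignments,
        ref.transcriptome,
        read_lengths=corpus.read_lengths,
    )


@pytest.fixture(scope="session")
def ir_corpus():
    """20k full-length error-free reads from IR chain (0.05, 0.02, 0.6)."""
    rng = np.random.default_rng(202)
    spec = FixtureSpec(
        n_genes=40, with_errors=False, with_ir=True, full_length=True,
        unaligned_fraction=0.0,
    )
    ref = make_reference(spec, rng)
    corpus = make_reads_with_truth(spec, ref, 20000, rng)
    return spec, ref, corpus


@pytest.fixture(scope="session")
def hp_corpus():
    """3k full-length reads whose only changes are homopolymer resampling
    with mean 0.9*L and SD 0.05*L + 0.3."""
    rng = np.random.default_rng(303)
    spec = FixtureSpec(
        n_genes=40, with_errors=False, with_homopolymers=True,
        full_length=True, unaligned_fraction=0.0,
    )
    ref = make_reference(spec, rng)
    corpus = make_reads_with_truth(spec, ref, 3000, rng)
    return spec, ref, corpus


@pytest.fixture(scope="session")
def hp_model(hp_corpus):
    from ont_txsim.homopolymer_model import (
        extract_homopolymer_observations,
        fit_homopolymer_model,
    )

    spec, ref, corpus = hp_corpus
    reads = {r.id: r.sequence for r in corpus.reads}
    obs = extract_homopolymer_observations(
        corpus.transcriptome_alignments, ref.transcriptome,
        spec.hp_min_len, reads,
    )
    return fit_homopolymer_model(obs, spec.hp_min_len), obs


@pytest.fixture(scope="session")
def full_bundle(trained_bundle, hp_corpus, hp_model):
    """Bundle with every component active, targeting the homopolymer
    reference (which has planted runs and multi-exon genes)."""
    import copy

    from ont_txsim.ir_model import IRModel

    _, ref, _ = hp_corpus
    bundle = copy.deepcopy(trained_bundle)
    bundle.expression = ref.expression
    bundle.ir_model = IRModel(0.05, 0.02, 0.6)
    bundle.homopolymer_model = hp_model[0]
    return bundle


@pytest.fixture(scope="session")
def full_sim_reads(full_bundle, hp_corpus):
    """10k fully-featured simulated reads (IR + homopolymers + errors +
    flanks + unaligned), used by the replay and conservation checks."""
    from ont_txsim.simulator import simulate

    _, ref, _ = hp_corpus
    return simulate(
        full_bundle, ref.transcriptome, 10000, seed=42,
        genome=ref.genome, annotation=ref.annotation,
    )


@pytest.fixture(scope="session")
def expression_loop():
    """Quantify a 500-transcript training corpus, simulate 50k reads from
    that estimated profile, re-quantify the simulated reads, and compare the
    two estimates (training-side vs simulated-side expression)."""
    from ont_txsim.simulator import alignments_from_truth, simulate
    from ont_txsim.quantify import quantify_alignments

    rng = np.random.default_rng(404)
    spec = FixtureSpec(n_genes=500)
    ref = make_reference(spec, rng)
    corpus = make_reads_with_truth(spec, ref, 4000, rng)
    bundle = characterize(
        corpus.transcriptome_alignments, ref.transcriptome,
        read_lengths=corpus.read_lengths,
    )
    training_profile = bundle.expression
    reads = simulate(bundle, ref.transcriptome, 50000, seed=55)
    est = quantify_alignments(alignments_from_truth(reads))
    return training_profile, est, reads
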