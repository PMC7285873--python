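"""Stage-one orchestration: fit every model from training alignments.

Ties the per-model fitting functions together into a :class:`ModelBundle`
ready for :func:`ont_txsim.simulator.simulate` or :func:`save_profile`.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from . import __version__
from .error_model import extract_error_events, fit_error_model
from .homopolymer_model import (
    DEFAULT_MIN_LEN,
    extract_homopolymer_observations,
    fit_homopolymer_model,
)
from .io_formats import AlignmentRecord, ModelBundle, TranscriptAnnotation
from .ir_model import detect_ir, fit_ir_model
from .length_strand_model import fit_length_model, infer_strand_stats
from .quantify import DEFAULT_MIN_SCORE_FRAC, quantify_alignments


def characterize(
    transcriptome_alignments: Sequence[AlignmentRecord],
    transcripts: Mapping[str, str],
    read_lengths: Mapping[str, int] | None = None,
    genome_alignments: Sequence[AlignmentRecord] | None = None,
    annotation: TranscriptAnnotation | None = None,
    with_homopolymers: bool = False,
    hp_min_len: int = DEFAULT_MIN_LEN,
    read_sequences: Mapping[str, str] | None = None,
    min_score_frac: float = DEFAULT_MIN_SCORE_FRAC,
    unaligned_error_rate: float = 0.9,
    metadata: dict | None = None,
) -> ModelBundle:
    """Learn all statistical models from training alignments.

    ``read_lengths`` (all training reads, aligned or not) enables the
    unaligned-read fraction and length model; IR modelling runs when both
    ``genome_alignments`` and ``annotation`` are given; homopolymer
    modelling when ``with_homopolymers`` is set.
    """
    transcriptome_alignments = list(transcriptome_alignments)
    primaries = [a for a in transcriptome_alignments if a.is_primary]
    if not primaries:
        raise ValueError("no primary transcriptome alignments to train on")
    transcript_lengths = {tid: len(seq) for tid, seq in transcripts.items()}

    unaligned_lengths: list[int] = []
    unaligned_fraction = 0.0
    if read_lengths:
        aligned_ids = {a.query_id for a in transcriptome_alignments}
        unaligned_lengths = [
            n for rid, n in read_lengths.items() if rid not in aligned_ids
        ]
        unaligned_fraction = len(unaligned_lengths) / len(read_lengths)

    length_model = fit_length_model(primaries, transcript_lengths, unaligned_lengths)
    strand = infer_strand_stats(primaries)
    error_model = fit_error_model(extract_error_events(primaries))
    expression = quantify_alignments(transcriptome_alignments, min_score_frac)

    ir_model = None
    if genome_alignments is not None and annotation is not None:
        observations, _report = detect_ir(
            genome_alignments, transcriptome_alignments, annotation
        )
        if observations:
            ir_model = fit_ir_model(observations)

    hp_model = None
    if with_homopolymers:
        obs = extract_homopolymer_observations(
            primaries, dict(transcripts), hp_min_len, read_sequences
        )
        hp_model = fit_homopolymer_model(obs, hp_min_len)

    meta = {
        "tool": "ont-txsim",
        "version": __version__,
        "n_training_alignments": len(transcriptome_alignments),
        "n_primary": len(primaries),
    }
    if metadata:
        meta.update(metadata)
    return ModelBundle(
        length_model=length_model,
        error_model=error_model,
        expression=expression,
        strand_ratio=strand.strand_ratio,
        unaligned_fraction=unaligned_fraction,
        ir_model=ir_model,
        homopolymer_model=hp_model,
        unaligned_error_rate=unaligned_error_rate,
        metadata=meta,
    )
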