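"""Read generation: the second stage of the pipeline.

Each simulated read is produced by: select a source transcript from the
expression profile -> draw an intron-retention pattern and expand the
template -> sample read anatomy (aligned span + flanks) from the length
model -> resample homopolymer runs -> lay out and apply base-call errors
(homopolymer runs masked) -> attach random-base flanks -> orient the read by
the strand ratio. A fixed fraction of reads is emitted as "unaligned":
transcript slices at lengths from the unaligned-length KDE, mutated at an
arbitrarily high per-base error rate (default 90%) with single-base events.

Determinism: read ``serial`` maps to an independent RNG substream derived
from the master seed, so output is byte-identical for a given seed
regardless of worker count.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .error_model import apply_errors, sample_error_layout
from .homopolymer_model import apply_homopolymer_effects
from .io_formats import (
    AlignmentRecord,
    ModelBundle,
    ReadEvent,
    SimulatedRead,
    TranscriptAnnotation,
    make_read_id,
    merge_walk,
)
from .ir_model import build_template, sample_ir_pattern
from .length_strand_model import sample_read_anatomy, sample_unaligned_length
from .quantify import ExpressionProfile

_BASES = "ACGT"


def select_transcript(expression: ExpressionProfile, rng: np.random.Generator) -> str:
    """Categorical draw of a transcript with p_i = tpm_i / 1e6."""
    tids, cum = _expression_tables(expression)
    return tids[int(np.searchsorted(cum, rng.random() * cum[-1]))]


def _expression_tables(expression: ExpressionProfile) -> tuple[list[str], np.ndarray]:
    tids = sorted(t for t, (_, v) in expression.abundances.items() if v > 0)
    if not tids:
        raise ValueError("expression profile is empty")
    probs = np.array([expression.tpm(t) for t in tids])
    return tids, np.cumsum(probs)


@dataclass
class SimOptions:
    perfect: bool = False
    with_ir: bool = True
    with_homopolymers: bool = True
    uniform_start: bool = False
    sense_only: bool = False
    no_flanks: bool = False


@dataclass
class _SimContext:
    bundle: ModelBundle
    transcriptome: dict[str, str]
    genome: dict[str, str] | None
    annotation: TranscriptAnnotation | None
    options: SimOptions
    tids: list[str]
    cum: np.ndarray
    n_unaligned: int
    seed: int


def _read_rng(seed: int, serial: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(serial,)))


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(4, size=n)) if n else ""


def _pick_transcript(ctx: _SimContext, rng: np.random.Generator) -> str:
    i = int(np.searchsorted(ctx.cum, rng.random() * ctx.cum[-1]))
    return ctx.tids[min(i, len(ctx.tids) - 1)]


def _simulate_unaligned(ctx: _SimContext, serial: int,
                        rng: np.random.Generator) -> SimulatedRead:
    bundle = ctx.bundle
    tid = _pick_transcript(ctx, rng)
    seq = ctx.transcriptome[tid]
    if bundle.length_model.unaligned_log_length.size:
        length = sample_unaligned_length(bundle.length_model, rng)
    else:
        length = min(300, len(seq))
    length = max(1, min(length, len(seq)))
    tstart = int(rng.integers(0, len(seq) - length + 1))
    template = seq[tstart : tstart + length]

    # single-base events at the unaligned error rate, split evenly by type
    e = bundle.unaligned_error_rate
    layout: list[tuple[str, int, int]] = []
    for i in range(length):
        u = rng.random()
        if u < e / 3:
            layout.append(("mis", 1, i))
        elif u < 2 * e / 3:
            layout.append(("del", 1, i))
        elif u < e:
            layout.append(("ins", 1, i))
            layout.append(("match", 1, i))
        else:
            layout.append(("match", 1, i))
    body, events = apply_errors(template, layout, rng)

    sense = ctx.options.sense_only or rng.random() < bundle.strand_ratio
    orientation = "sense" if sense else "antisense"
    read_id = make_read_id(tid, orientation, tstart, length, 0, 0, serial, "unaligned")
    sequence = body if sense else _revcomp(body)
    return SimulatedRead(
        read_id=read_id,
        sequence=sequence,
        category="unaligned",
        transcript_id=tid,
        template_start=tstart,
        template_end=tstart + length,
        orientation=orientation,
        ir_pattern=(),
        head_len=0,
        tail_len=0,
        events=events,
    )


def _revcomp(seq: str) -> str:
    from .io_formats import revcomp

    return revcomp(seq)


def simulate_one(ctx: _SimContext, serial: int) -> SimulatedRead:
    """Simulate the read with the given serial number (deterministic)."""
    rng = _read_rng(ctx.seed, serial)
    if serial < ctx.n_unaligned:
        return _simulate_unaligned(ctx, serial, rng)
    bundle = ctx.bundle
    opts = ctx.options

    tid = _pick_transcript(ctx, rng)
    tx_seq = ctx.transcriptome[tid]
    pattern: list[bool] = []
    ir_records: list[ReadEvent] = []
    template = tx_seq
    if (
        opts.with_ir
        and not opts.perfect
        and bundle.ir_model is not None
        and ctx.annotation is not None
        and tid in ctx.annotation
    ):
        tx = ctx.annotation[tid]
        if tx.introns:
            pattern = sample_ir_pattern(bundle.ir_model, len(tx.introns), rng)
            if any(pattern):
                if ctx.genome is None:
                    raise ValueError("IR simulation requires the genome FASTA")
                template, ir_records = build_template(tx, ctx.genome, pattern, tx_seq)

    head, aligned, tail = sample_read_anatomy(bundle.length_model, len(template), rng)
    if opts.no_flanks:
        head = tail = 0
    if opts.uniform_start:
        tstart = int(rng.integers(0, len(template) - aligned + 1))
    else:
        tstart = len(template) - aligned  # 3'-anchored (direct RNA chemistry)
    body_template = template[tstart : tstart + aligned]

    hp_records: list[ReadEvent] = []
    masked: list[tuple[int, int]] = []
    if opts.with_homopolymers and not opts.perfect and bundle.homopolymer_model is not None:
        body_template, hp_records, masked = apply_homopolymer_effects(
            body_template, bundle.homopolymer_model, rng
        )

    if opts.perfect:
        body, error_events = body_template, []
    else:
        layout = sample_error_layout(
            bundle.error_model, max(1, len(body_template)), rng, masked
        )
        body, error_events = apply_errors(body_template, layout, rng)

    head_seq = _random_bases(rng, head)
    tail_seq = _random_bases(rng, tail)
    events = list(ir_records) + list(hp_records) + list(error_events)
    if head_seq:
        events.append(ReadEvent("head", 0, -1, head, bases=head_seq))
    if tail_seq:
        events.append(ReadEvent("tail", -1, -1, tail, bases=tail_seq))

    sense = opts.sense_only or rng.random() < bundle.strand_ratio
    orientation = "sense" if sense else "antisense"
    sequence = head_seq + body + tail_seq
    if not sense:
        sequence = _revcomp(sequence)
    read_id = make_read_id(tid, orientation, tstart, aligned, head, tail,
                           serial, "aligned")
    return SimulatedRead(
        read_id=read_id,
        sequence=sequence,
        category="aligned",
        transcript_id=tid,
        template_start=tstart,
        template_end=tstart + aligned,
        orientation=orientation,
        ir_pattern=tuple(pattern),
        head_len=head,
        tail_len=tail,
        events=events,
    )


def _make_context(bundle, transcriptome, genome, annotation, n_reads, seed,
                  options) -> _SimContext:
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    tids, cum = _expression_tables(bundle.expression)
    missing = [t for t in tids if t not in transcriptome]
    if missing:
        raise KeyError(f"expressed transcripts missing from the reference: {missing[:3]}")
    n_unaligned = int(round(n_reads * bundle.unaligned_fraction))
    if bundle.unaligned_fraction > 0 and not bundle.length_model.unaligned_log_length.size:
        n_unaligned = 0
    return _SimContext(
        bundle=bundle,
        transcriptome=transcriptome,
        genome=genome,
        annotation=annotation,
        options=options or SimOptions(),
        tids=tids,
        cum=cum,
        n_unaligned=n_unaligned,
        seed=int(seed),
    )


def simulate(
    bundle: ModelBundle,
    transcriptome: dict[str, str],
    n_reads: int,
    seed: int,
    genome: dict[str, str] | None = None,
    annotation: TranscriptAnnotation | None = None,
    options: SimOptions | None = None,
) -> list[SimulatedRead]:
    """Simulate ``n_reads`` reads; single-process reference implementation."""
    ctx = _make_context(bundle, transcriptome, genome, annotation, n_reads,
                        seed, options)
    return [simulate_one(ctx, i) for i in range(n_reads)]


_WORKER_CTX: _SimContext | None = None


def _init_worker(ctx: _SimContext) -> None:
    global _WORKER_CTX
    _WORKER_CTX = ctx


def _run_range(bounds: tuple[int, int]) -> list[SimulatedRead]:
    lo, hi = bounds
    return [simulate_one(_WORKER_CTX, i) for i in range(lo, hi)]


def run_multiprocess(
    bundle: ModelBundle,
    transcriptome: dict[str, str],
    n_reads: int,
    seed: int,
    n_workers: int,
    genome: dict[str, str] | None = None,
    annotation: TranscriptAnnotation | None = None,
    options: SimOptions | None = None,
) -> list[SimulatedRead]:
    """Simulate in parallel; output identical to the single-process run.

    Read serials are split into contiguous ranges; every read's RNG substream
    depends only on (seed, serial), so the merged output is byte-identical to
    ``simulate`` with the same seed.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    ctx = _make_context(bundle, transcriptome, genome, annotation, n_reads,
                        seed, options)
    if n_workers == 1:
        return [simulate_one(ctx, i) for i in range(n_reads)]
    bounds = []
    step = -(-n_reads // n_workers)
    for lo in range(0, n_reads, step):
        bounds.append((lo, min(lo + step, n_reads)))
    out: list[SimulatedRead] = []
    with ProcessPoolExecutor(max_workers=n_workers, initializer=_init_worker,
                             initargs=(ctx,)) as pool:
        for chunk in pool.map(_run_range, bounds):
            out.extend(chunk)
    return out


# ---------------------------------------------------------------------------
# Truth-derived alignments (for hermetic closed-loop characterization)
# ---------------------------------------------------------------------------


def alignments_from_truth(reads: Iterable[SimulatedRead]) -> list[AlignmentRecord]:
    """Exact transcriptome alignments reconstructed from simulation truth.

    Only valid for aligned-category reads without IR or homopolymer events
    (those change the template away from the annotated transcript); such
    reads are skipped. Lets closed-loop tests re-characterize simulator
    output without invoking an aligner.
    """
    out = []
    for read in reads:
        if read.category != "aligned":
            continue
        if any(e.event in ("ir", "homopolymer") for e in read.events):
            continue
        aligned_len = read.template_end - read.template_start
        walk: list[tuple[str, int]] = []
        ti = 0
        body_len = 0
        for e in read.events:
            if e.event not in ("mis", "ins", "del"):
                continue
            if e.ref_pos > ti:
                walk.append(("M", e.ref_pos - ti))
                body_len += e.ref_pos - ti
                ti = e.ref_pos
            if e.event == "mis":
                walk.append(("X", e.length))
                ti += e.length
                body_len += e.length
            elif e.event == "del":
                walk.append(("D", e.length))
                ti += e.length
            else:
                walk.append(("I", e.length))
                body_len += e.length
        if aligned_len > ti:
            walk.append(("M", aligned_len - ti))
            body_len += aligned_len - ti
        qlen = read.head_len + body_len + read.tail_len
        if read.orientation == "sense":
            qs, qe = read.head_len, read.head_len + body_len
            strand = "+"
        else:
            qs, qe = read.tail_len, read.tail_len + body_len
            strand = "-"
        out.append(
            AlignmentRecord(
                query_id=read.read_id,
                query_length=qlen,
                target_id=read.transcript_id,
                target_kind="transcriptome",
                strand=strand,
                query_start=qs,
                query_end=qe,
                target_start=read.template_start,
                target_end=read.template_end,
                edit_walk=merge_walk(walk),
                is_primary=True,
            )
        )
    return out
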