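"""Deterministic synthetic corpora with fully known generating parameters.

Everything the characterization stage learns from real data can be tested by
parameter recovery against corpora built here: synthetic genomes with
multi-exon genes and planted homopolymer runs, spliced transcriptomes,
log-normal expression profiles, and reads drawn directly from the stated
generating laws together with their *exact* alignments (no aligner runs).

The read generator here is implementationally independent of the simulator
module — it shares no sampling code — so closed-loop tests
(characterize(generate(params)) ~= params) are genuine cross-checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .error_model import mixture_mean, mixture_pmf
from .io_formats import (
    AlignmentRecord,
    SequenceRecord,
    Transcript,
    TranscriptAnnotation,
    revcomp,
)
from .quantify import ExpressionProfile

_BASES = "ACGT"


@dataclass
class FixtureSpec:
    """Generating parameters of one synthetic corpus (same spec + seed ->
    identical corpus)."""

    # gene structure
    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_length: tuple[int, int] = (120, 400)
    intron_length: tuple[int, int] = (80, 400)
    spacer: int = 150
    minus_strand_fraction: float = 0.3
    # expression: log-normal TPM, natural-log sigma
    expression_sigma: float = 1.5
    # read anatomy
    ratio_beta: tuple[float, float] = (5.0, 2.0)
    full_length: bool = False  # ratio 1.0, no flanks
    head_mean: float = 30.0
    tail_mean: float = 15.0
    strand_ratio: float = 0.85
    unaligned_fraction: float = 0.0
    unaligned_log10_mean: float = 2.4
    unaligned_log10_sd: float = 0.2
    # base-call errors (per aligned reference base)
    with_errors: bool = True
    error_rates: tuple[float, float, float] = (0.05, 0.03, 0.03)
    mis_mixture: dict = field(default_factory=lambda: {"w": 0.5, "lam": 0.9, "p": 0.65})
    ins_mixture: dict = field(
        default_factory=lambda: {"w": 0.5, "shape": 1.3, "scale": 1.6, "p": 0.6}
    )
    del_mixture: dict = field(
        default_factory=lambda: {"w": 0.5, "shape": 1.3, "scale": 1.6, "p": 0.6}
    )
    # intron retention chain (p_first, p_retain|spliced, p_retain|retained)
    with_ir: bool = False
    ir_chain: tuple[float, float, float] = (0.05, 0.02, 0.6)
    # homopolymers
    with_homopolymers: bool = False
    hp_min_len: int = 5
    hp_run_length: tuple[int, int] = (5, 20)
    hp_runs_per_exon: float = 1.0
    hp_mean_slope: float = 0.9
    hp_mean_intercept: float = 0.0
    hp_sd_slope: float = 0.05
    hp_sd_intercept: float = 0.3
    hp_per_base: dict = field(default_factory=dict)  # base -> 4 coefficient overrides

    @classmethod
    def from_json(cls, path) -> "FixtureSpec":
        data = json.loads(open(path).read())
        spec = cls(**data)
        return spec

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def hp_coefficients(self, base: str) -> tuple[float, float, float, float]:
        d = self.hp_per_base.get(base)
        if d:
            return (d["mean_slope"], d["mean_intercept"], d["sd_slope"], d["sd_intercept"])
        return (self.hp_mean_slope, self.hp_mean_intercept,
                self.hp_sd_slope, self.hp_sd_intercept)


@dataclass
class Reference:
    genome: dict[str, str]
    transcriptome: dict[str, str]
    annotation: TranscriptAnnotation
    planted_runs: dict[str, list[tuple[str, int, int]]]  # tid -> (base, tx pos, len)
    true_tpm: dict[str, float]

    @property
    def expression(self) -> ExpressionProfile:
        return ExpressionProfile.from_tpm(self.true_tpm)


@dataclass
class FixtureCorpus:
    reads: list[SequenceRecord]
    transcriptome_alignments: list[AlignmentRecord]
    genome_alignments: list[AlignmentRecord]
    read_lengths: dict[str, int]
    ir_patterns: dict[str, list[bool]]
    true_ratios: list[float]
    true_heads: list[int]
    true_tails: list[int]
    unaligned_lengths: list[int]


def _dna_no_runs(rng: np.random.Generator, n: int, max_run: int = 2) -> list[str]:
    """Random DNA with no homopolymer run longer than ``max_run`` (so planted
    runs are the only ones a run finder can report)."""
    out: list[str] = []
    run = 0
    for _ in range(n):
        if run >= max_run:
            prev = out[-1]
            choices = [b for b in _BASES if b != prev]
            b = choices[rng.integers(3)]
        else:
            b = _BASES[rng.integers(4)]
        if out and b == out[-1]:
            run += 1
        else:
            run = 1
        out.append(b)
    return out


def make_reference(spec: FixtureSpec, rng: np.random.Generator) -> Reference:
    """Build genome + spliced transcriptome + GTF-consistent annotation.

    One gene per contig; transcripts are named t0000..; homopolymer runs of
    known base/position/length are planted inside exons when enabled.
    """
    genome: dict[str, str] = {}
    transcripts: dict[str, Transcript] = {}
    transcriptome: dict[str, str] = {}
    planted: dict[str, list[tuple[str, int, int]]] = {}

    for g in range(spec.n_genes):
        chrom = f"ctg{g:04d}"
        tid = f"t{g:04d}"
        gid = f"g{g:04d}"
        strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
        k = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        exon_lens = [int(rng.integers(spec.exon_length[0], spec.exon_length[1] + 1))
                     for _ in range(k)]
        intron_lens = [int(rng.integers(spec.intron_length[0], spec.intron_length[1] + 1))
                       for _ in range(k - 1)]

        chrom_seq = _dna_no_runs(rng, spec.spacer)
        exons: list[tuple[int, int]] = []
        for i, el in enumerate(exon_lens):
            start = len(chrom_seq)
            exon = _dna_no_runs(rng, el)
            if spec.with_homopolymers and rng.random() < spec.hp_runs_per_exon:
                run_len = int(rng.integers(spec.hp_run_length[0],
                                           spec.hp_run_length[1] + 1))
                if el >= run_len + 6:
                    pos = int(rng.integers(3, el - run_len - 3))
                    base = _BASES[rng.integers(4)]
                    exon[pos : pos + run_len] = [base] * run_len
                    # break any accidental extension at the boundaries
                    for edge in (pos - 1, pos + run_len):
                        if exon[edge] == base:
                            exon[edge] = _BASES[(base == "A")]  # any other base
            chrom_seq.extend(exon)
            exons.append((start, start + el))
            if i < k - 1:
                chrom_seq.extend(_dna_no_runs(rng, intron_lens[i]))
        chrom_seq.extend(_dna_no_runs(rng, spec.spacer))
        genome[chrom] = "".join(chrom_seq)

        tx = Transcript(tid, gid, chrom, strand, exons)
        transcripts[tid] = tx
        spliced = "".join(genome[chrom][s:e] for s, e in exons)
        if strand == "-":
            spliced = revcomp(spliced)
        transcriptome[tid] = spliced
        if spec.with_homopolymers:
            from .homopolymer_model import find_homopolymers

            planted[tid] = find_homopolymers(spliced, spec.hp_min_len)

    tpm_raw = np.exp(rng.normal(0.0, spec.expression_sigma, size=spec.n_genes))
    tpm = {f"t{g:04d}": float(1e6 * tpm_raw[g] / tpm_raw.sum())
           for g in range(spec.n_genes)}
    return Reference(
        genome=genome,
        transcriptome=transcriptome,
        annotation=TranscriptAnnotation(transcripts),
        planted_runs=planted,
        true_tpm=tpm,
    )


# ---------------------------------------------------------------------------
# Error process (independent of the simulator's sampling code)
# ---------------------------------------------------------------------------


class _ErrorProcess:
    """Alternating match/error generator with the exact target per-base rates.

    Error types are i.i.d. with probabilities s_t proportional to
    rate_t / E[length_t] (a rank-one Markov chain); match stretches are
    geometric (support >= 0) with mean solved so that per-reference-base
    rates equal ``spec.error_rates`` exactly in expectation. Event lengths
    are drawn by inverse-CDF lookup from the mixture pmf tables.
    """

    def __init__(self, spec: FixtureSpec):
        mixes = (spec.mis_mixture, spec.ins_mixture, spec.del_mixture)
        means = np.array([mixture_mean(m) for m in mixes])
        rates = np.array(spec.error_rates, dtype=float)
        s = rates / means
        self.type_probs = s / s.sum()
        c = self.type_probs[0] * means[0] + self.type_probs[2] * means[2]
        r_ref = rates[0] + rates[2]
        # match stretches: geometric on {1,2,...} so that error events never
        # abut (alignment merging would make the chain unidentifiable)
        self.match_mean = c * (1.0 - r_ref) / r_ref
        self.match_p = min(1.0, 1.0 / self.match_mean)
        support = np.arange(1, 501)
        self.length_cdfs = [np.cumsum(mixture_pmf(m, support)) for m in mixes]

    def sample_type(self, rng) -> int:
        return int(np.searchsorted(np.cumsum(self.type_probs), rng.random()))

    def sample_length(self, typ: int, rng) -> int:
        cdf = self.length_cdfs[typ]
        return 1 + int(np.searchsorted(cdf, rng.random() * cdf[-1]))

    def walk(self, ref_len: int, rng) -> list[tuple[str, int]]:
        ops: list[tuple[str, int]] = []
        consumed = 0
        syms = ("X", "I", "D")
        while consumed < ref_len:
            m = min(int(rng.geometric(self.match_p)), ref_len - consumed)
            ops.append(("M", m))
            consumed += m
            if consumed >= ref_len:
                break
            t = self.sample_type(rng)
            n = self.sample_length(t, rng)
            if syms[t] == "I":
                ops.append(("I", n))
            else:
                n = min(n, ref_len - consumed)
                ops.append((syms[t], n))
                consumed += n
        return ops


def _apply_walk(template: str, ops: Sequence[tuple[str, int]],
                rng: np.random.Generator) -> str:
    out: list[str] = []
    ti = 0
    for op, n in ops:
        if op == "M":
            out.append(template[ti : ti + n])
            ti += n
        elif op == "X":
            for b in template[ti : ti + n]:
                alts = [c for c in _BASES if c != b]
                out.append(alts[rng.integers(3)])
            ti += n
        elif op == "D":
            ti += n
        elif op == "I":
            out.append("".join(_BASES[i] for i in rng.integers(4, size=n)))
    return "".join(out)


def _hp_walk(template: str, spec: FixtureSpec, rng: np.random.Generator
             ) -> tuple[list[tuple[str, int]], str]:
    """Walk + read sequence with only homopolymer contractions/expansions.

    A shrink of d bases is a D op inside the run; a growth of d bases is an
    I op of the run base placed after the run's first base.
    """
    from .homopolymer_model import find_homopolymers

    ops: list[tuple[str, int]] = []
    read: list[str] = []
    cursor = 0
    for base, start, length in find_homopolymers(template, spec.hp_min_len):
        ms, mi, ss, si = spec.hp_coefficients(base)
        new_len = max(0, int(round(rng.normal(ms * length + mi, ss * length + si))))
        if start > cursor:
            ops.append(("M", start - cursor))
            read.append(template[cursor:start])
        d = new_len - length
        if d == 0:
            ops.append(("M", length))
        elif d < 0:
            keep_left = (length + d) // 2
            keep_right = length + d - keep_left
            if keep_left:
                ops.append(("M", keep_left))
            ops.append(("D", -d))
            if keep_right:
                ops.append(("M", keep_right))
        else:
            ops.append(("M", 1))
            ops.append(("I", d))
            ops.append(("M", length - 1))
        read.append(base * new_len)
        cursor = start + length
    if cursor < len(template):
        ops.append(("M", len(template) - cursor))
        read.append(template[cursor:])
    return ops, "".join(read)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def _sample_ir_pattern(chain: tuple[float, float, float], n: int,
                       rng: np.random.Generator) -> list[bool]:
    p_first, p_rs, p_rr = chain
    pattern = []
    p = p_first
    for _ in range(n):
        state = bool(rng.random() < p)
        pattern.append(state)
        p = p_rr if state else p_rs
    return pattern


def _molecule_for(ref: Reference, tid: str, pattern: Sequence[bool]
                  ) -> tuple[str, list[int]]:
    """Molecule sequence with retained introns; returns transcript-order
    exon/intron segment lengths for walk construction (exon, [intron], ...)."""
    tx = ref.annotation[tid]
    chrom = ref.genome[tx.chrom]
    genomic_pattern = list(pattern) if tx.strand == "+" else list(pattern)[::-1]
    pieces = []
    for i, (s, e) in enumerate(tx.exons):
        pieces.append(chrom[s:e])
        if i < len(tx.introns_genomic) and genomic_pattern[i]:
            gs, ge = tx.introns_genomic[i]
            pieces.append(chrom[gs:ge])
    mol = "".join(pieces)
    if tx.strand == "-":
        mol = revcomp(mol)
    return mol, []


def make_reads_with_truth(spec: FixtureSpec, ref: Reference, n_reads: int,
                          rng: np.random.Generator) -> FixtureCorpus:
    """Generate reads directly from the spec's true parameters with exact
    alignments (the independent oracle for characterization tests)."""
    tids = sorted(ref.true_tpm)
    cum = np.cumsum([ref.true_tpm[t] for t in tids])
    err = _ErrorProcess(spec) if spec.with_errors else None

    reads: list[SequenceRecord] = []
    tx_alns: list[AlignmentRecord] = []
    g_alns: list[AlignmentRecord] = []
    read_lengths: dict[str, int] = {}
    ir_patterns: dict[str, list[bool]] = {}
    ratios: list[float] = []
    heads: list[int] = []
    tails: list[int] = []
    unaligned_lengths: list[int] = []

    n_unaligned = int(round(n_reads * spec.unaligned_fraction))
    for i in range(n_reads):
        rid = f"read{i:06d}"
        tid = tids[min(int(np.searchsorted(cum, rng.random() * cum[-1])), len(tids) - 1)]
        tx_seq = ref.transcriptome[tid]

        if i < n_unaligned:
            length = int(round(10 ** rng.normal(spec.unaligned_log10_mean,
                                                spec.unaligned_log10_sd)))
            length = max(30, min(length, len(tx_seq)))
            start = int(rng.integers(0, len(tx_seq) - length + 1))
            seq = _apply_walk(
                tx_seq[start : start + length],
                [("X", length)],  # fully scrambled; never aligns
                rng,
            )
            reads.append(SequenceRecord(rid, seq))
            read_lengths[rid] = len(seq)
            unaligned_lengths.append(len(seq))
            continue

        pattern: list[bool] = []
        tx = ref.annotation[tid]
        if spec.with_ir and tx.introns:
            pattern = _sample_ir_pattern(spec.ir_chain, len(tx.introns), rng)
            ir_patterns[rid] = pattern
        molecule, _ = (_molecule_for(ref, tid, pattern)
                       if any(pattern) else (tx_seq, []))

        if spec.full_length:
            ratio, aligned_len, tstart, head, tail = 1.0, len(molecule), 0, 0, 0
        else:
            ratio = float(rng.beta(*spec.ratio_beta))
            aligned_len = max(1, int(round(ratio * len(molecule))))
            tstart = len(molecule) - aligned_len
            head = int(rng.geometric(1.0 / (1.0 + spec.head_mean))) - 1
            tail = int(rng.geometric(1.0 / (1.0 + spec.tail_mean))) - 1
        template = molecule[tstart : tstart + aligned_len]
        ratios.append(aligned_len / len(molecule))
        heads.append(head)
        tails.append(tail)

        if spec.with_homopolymers:
            ops, body = _hp_walk(template, spec, rng)
        elif err is not None:
            ops = err.walk(aligned_len, rng)
            body = _apply_walk(template, ops, rng)
        else:
            ops, body = [("M", aligned_len)], template

        head_seq = "".join(_BASES[j] for j in rng.integers(4, size=head))
        tail_seq = "".join(_BASES[j] for j in rng.integers(4, size=tail))
        sense = bool(rng.random() < spec.strand_ratio)
        full = head_seq + body + tail_seq
        read_seq = full if sense else revcomp(full)
        reads.append(SequenceRecord(rid, read_seq))
        read_lengths[rid] = len(read_seq)

        qlen = len(full)
        body_len = len(body)
        if sense:
            qs, qe, strand = head, head + body_len, "+"
        else:
            qs, qe, strand = tail, tail + body_len, "-"

        if any(pattern):
            # transcriptome walk: exon blocks match, retained introns insert
            walk = _ir_transcript_walk(tx, pattern)
            t_start, t_end = 0, tx.length
        else:
            walk, t_start, t_end = ops, tstart, tstart + aligned_len
        tx_alns.append(
            AlignmentRecord(
                query_id=rid, query_length=qlen, target_id=tid,
                target_kind="transcriptome", strand=strand,
                query_start=qs, query_end=qe,
                target_start=t_start, target_end=t_end,
                edit_walk=walk, is_primary=True,
            )
        )
        if spec.with_ir and tx.introns:
            g_alns.append(_genome_alignment(ref, rid, tid, pattern, qlen, qs, qe, sense))
    return FixtureCorpus(
        reads=reads,
        transcriptome_alignments=tx_alns,
        genome_alignments=g_alns,
        read_lengths=read_lengths,
        ir_patterns=ir_patterns,
        true_ratios=ratios,
        true_heads=heads,
        true_tails=tails,
        unaligned_lengths=unaligned_lengths,
    )


def _ir_transcript_walk(tx: Transcript, pattern: Sequence[bool]
                        ) -> list[tuple[str, int]]:
    exon_lens = [e - s for s, e in tx.exons]
    intron_lens = [e - s for s, e in tx.introns_genomic]
    if tx.strand == "-":
        exon_lens = exon_lens[::-1]
        intron_lens = intron_lens[::-1]
    walk: list[tuple[str, int]] = []
    for i, el in enumerate(exon_lens):
        walk.append(("M", el))
        if i < len(intron_lens) and pattern[i]:
            walk.append(("I", intron_lens[i]))
    return walk


def _genome_alignment(ref: Reference, rid: str, tid: str,
                      pattern: Sequence[bool], qlen: int, qs: int, qe: int,
                      sense: bool) -> AlignmentRecord:
    """Idealized full-span genomic alignment: M through exons and retained
    introns, N through spliced introns."""
    tx = ref.annotation[tid]
    genomic_pattern = list(pattern) if tx.strand == "+" else list(pattern)[::-1]
    walk: list[tuple[str, int]] = []
    for i, (s, e) in enumerate(tx.exons):
        walk.append(("M", e - s))
        if i < len(tx.introns_genomic):
            gs, ge = tx.introns_genomic[i]
            walk.append(("M" if genomic_pattern[i] else "N", ge - gs))
    read_sense_on_genome = sense if tx.strand == "+" else not sense
    return AlignmentRecord(
        query_id=rid, query_length=qlen, target_id=tx.chrom,
        target_kind="genome", strand="+" if read_sense_on_genome else "-",
        query_start=qs, query_end=qe,
        target_start=tx.exons[0][0], target_end=tx.exons[-1][1],
        edit_walk=walk, is_primary=True,
    )
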