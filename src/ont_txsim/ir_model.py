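"""Intron-retention (IR) detection, modelling and template expansion.

Retention is called per read and per intron from the read's genomic
alignment: an intron is retained when aligned (M/X) blocks cover at least
90% of its span and no splice (N) op traverses it; an N op spanning the
intron marks it spliced; introns outside the read's genomic span are
uncovered and uninformative. Retention along a transcript is modelled as a
first-order Markov chain over the ordered introns with states
{spliced, retained}.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import (
    AlignmentRecord,
    ReadEvent,
    Transcript,
    TranscriptAnnotation,
    revcomp,
)

RETENTION_COVERAGE = 0.90


@dataclass
class IRObservation:
    """Per-read intron states, 5'->3' in transcript orientation.

    ``intron_states[i]`` is only meaningful when ``i in introns_covered``.
    """

    read_id: str
    transcript_id: str
    intron_states: list[bool]
    introns_covered: list[int]


@dataclass
class IRModel:
    """First-order Markov chain over per-intron {spliced, retained} states."""

    p_first: float
    p_retain_given_spliced: float
    p_retain_given_retained: float
    counts: dict | None = None

    def __post_init__(self):
        for name in ("p_first", "p_retain_given_spliced", "p_retain_given_retained"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")

    def __eq__(self, other):
        if not isinstance(other, IRModel):
            return NotImplemented
        return (
            self.p_first == other.p_first
            and self.p_retain_given_spliced == other.p_retain_given_spliced
            and self.p_retain_given_retained == other.p_retain_given_retained
        )

    def to_dict(self) -> dict:
        d = {
            "p_first": self.p_first,
            "p_retain_given_spliced": self.p_retain_given_spliced,
            "p_retain_given_retained": self.p_retain_given_retained,
        }
        if self.counts is not None:
            d["counts"] = self.counts
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "IRModel":
        return cls(
            p_first=d["p_first"],
            p_retain_given_spliced=d["p_retain_given_spliced"],
            p_retain_given_retained=d["p_retain_given_retained"],
            counts=d.get("counts"),
        )

    def marginal_retention(self, n_introns: int) -> np.ndarray:
        """Forward marginal P(intron i retained) under the chain."""
        out = np.zeros(n_introns)
        p = self.p_first
        for i in range(n_introns):
            out[i] = p
            p = p * self.p_retain_given_retained + (1 - p) * self.p_retain_given_spliced
        return out


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def _aligned_and_skip_blocks(a: AlignmentRecord) -> tuple[list, list]:
    """Genomic intervals of aligned (M/X) blocks and of N (splice) skips."""
    aligned, skips = [], []
    pos = a.target_start
    for op, n in a.edit_walk:
        if op in ("M", "X"):
            aligned.append((pos, pos + n))
            pos += n
        elif op == "N":
            skips.append((pos, pos + n))
            pos += n
        elif op == "D":
            pos += n  # neither aligned coverage nor a splice
        # I consumes no target
    return aligned, skips


def _overlap(blocks: Sequence[tuple[int, int]], s: int, e: int) -> int:
    return sum(max(0, min(be, e) - max(bs, s)) for bs, be in blocks)


def classify_read_introns(genome_aln: AlignmentRecord, tx: Transcript
                          ) -> IRObservation | None:
    """Call per-intron retention states for one read from its genomic alignment."""
    introns = tx.introns  # transcript 5'->3' order, genomic intervals
    if not introns:
        return None
    aligned, skips = _aligned_and_skip_blocks(genome_aln)
    span = (genome_aln.target_start, genome_aln.target_end)
    states: list[bool] = [False] * len(introns)
    covered: list[int] = []
    for i, (s, e) in enumerate(introns):
        if s < span[0] or e > span[1]:
            continue  # outside the read's genomic span: uncovered
        if _overlap(skips, s, e) > 0:
            states[i] = False  # an N op traverses the intron: spliced
            covered.append(i)
        elif _overlap(aligned, s, e) >= RETENTION_COVERAGE * (e - s):
            states[i] = True
            covered.append(i)
        # else: inside span but poorly covered -> uninformative
    if not covered:
        return None
    return IRObservation(
        read_id=genome_aln.query_id,
        transcript_id=tx.transcript_id,
        intron_states=states,
        introns_covered=covered,
    )


@dataclass
class IRReportRow:
    transcript_id: str
    intron_index: int
    chrom: str
    start: int
    end: int
    reads_covering: int
    reads_retaining: int

    @property
    def frequency(self) -> float:
        return self.reads_retaining / self.reads_covering if self.reads_covering else 0.0


def detect_ir(
    genome_alignments: Iterable[AlignmentRecord],
    transcriptome_alignments: Iterable[AlignmentRecord],
    annotation: TranscriptAnnotation,
) -> tuple[list[IRObservation], list[IRReportRow]]:
    """Detect IR events: per-read observations plus a per-intron report.

    Each read's transcript is assigned by its best (most matched bases)
    primary transcriptome alignment; retention is then called from the read's
    genomic alignment against that transcript's introns.
    """
    best_tx: dict[str, tuple[int, str]] = {}
    for a in transcriptome_alignments:
        if not a.is_primary:
            continue
        score = a.matched_bases
        if a.query_id not in best_tx or score > best_tx[a.query_id][0]:
            best_tx[a.query_id] = (score, a.target_id)

    observations: list[IRObservation] = []
    missing_tx: set[str] = set()
    for g in genome_alignments:
        if not g.is_primary:
            continue
        assigned = best_tx.get(g.query_id)
        if assigned is None:
            continue
        tid = assigned[1]
        if tid not in annotation:
            if tid not in missing_tx:
                warnings.warn(f"transcript {tid} absent from annotation; skipped")
                missing_tx.add(tid)
            continue
        tx = annotation[tid]
        if not tx.introns:
            continue  # intron-less transcript: nothing to call
        obs = classify_read_introns(g, tx)
        if obs is not None:
            observations.append(obs)

    cover: dict[tuple[str, int], int] = defaultdict(int)
    retain: dict[tuple[str, int], int] = defaultdict(int)
    for obs in observations:
        for i in obs.introns_covered:
            cover[(obs.transcript_id, i)] += 1
            if obs.intron_states[i]:
                retain[(obs.transcript_id, i)] += 1
    report = []
    for (tid, i), n_cov in sorted(cover.items()):
        tx = annotation[tid]
        s, e = tx.introns[i]
        report.append(
            IRReportRow(
                transcript_id=tid,
                intron_index=i,
                chrom=tx.chrom,
                start=s,
                end=e,
                reads_covering=n_cov,
                reads_retaining=retain[(tid, i)],
            )
        )
    return observations, report


def transcripts_with_retention(report: Sequence[IRReportRow]) -> int:
    """Number of transcripts with at least one retained intron observed."""
    return len({r.transcript_id for r in report if r.reads_retaining > 0})


def write_ir_report(report: Sequence[IRReportRow], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "transcript_id\tintron_index\tchrom\tstart\tend\t"
            "reads_covering\treads_retaining\tfrequency\n"
        )
        for r in report:
            fh.write(
                f"{r.transcript_id}\t{r.intron_index}\t{r.chrom}\t{r.start}\t"
                f"{r.end}\t{r.reads_covering}\t{r.reads_retaining}\t"
                f"{r.frequency:.6g}\n"
            )


# ---------------------------------------------------------------------------
# Fitting and sampling
# ---------------------------------------------------------------------------

_SMOOTH_MIN_COUNT = 5


def fit_ir_model(observations: Sequence[IRObservation]) -> IRModel:
    """Fit the retention chain from per-read intron-state observations.

    ``p_first`` is the retained fraction among covered first introns;
    transition probabilities are counted over consecutive covered intron
    pairs, with add-one smoothing when a conditioning state has < 5 counts.
    Uncovered introns break transition chains rather than being imputed.
    """
    n_first = k_first = 0
    trans = {False: [0, 0], True: [0, 0]}  # state -> [n, retained_next]
    any_covered = False
    for obs in observations:
        covered = set(obs.introns_covered)
        if covered:
            any_covered = True
        if 0 in covered:
            n_first += 1
            k_first += obs.intron_states[0]
        for i in sorted(covered):
            if i + 1 in covered:
                prev = obs.intron_states[i]
                trans[prev][0] += 1
                trans[prev][1] += obs.intron_states[i + 1]
    if not any_covered:
        raise ValueError("no covered introns in observations")

    def estimate(k: int, n: int) -> float:
        if n < _SMOOTH_MIN_COUNT:
            return (k + 1) / (n + 2)
        return k / n

    p_first = k_first / n_first if n_first else estimate(0, 0)
    return IRModel(
        p_first=p_first,
        p_retain_given_spliced=estimate(trans[False][1], trans[False][0]),
        p_retain_given_retained=estimate(trans[True][1], trans[True][0]),
        counts={
            "first": [k_first, n_first],
            "from_spliced": [trans[False][1], trans[False][0]],
            "from_retained": [trans[True][1], trans[True][0]],
        },
    )


def sample_ir_pattern(model: IRModel, n_introns: int,
                      rng: np.random.Generator) -> list[bool]:
    """Draw one retention pattern (length ``n_introns``) from the chain."""
    if n_introns < 0:
        raise ValueError("n_introns must be >= 0")
    pattern: list[bool] = []
    p = model.p_first
    for _ in range(n_introns):
        state = rng.random() < p
        pattern.append(bool(state))
        p = model.p_retain_given_retained if state else model.p_retain_given_spliced
    return pattern


# ---------------------------------------------------------------------------
# Template expansion
# ---------------------------------------------------------------------------


def build_template(
    tx: Transcript,
    genome: dict[str, str],
    pattern: Sequence[bool],
    transcript_seq: str | None = None,
) -> tuple[str, list[ReadEvent]]:
    """Expand a transcript with its retained introns into a read template.

    ``pattern`` is in transcript 5'->3' intron order. The template is the
    exon sequence with each retained intron's genomic sequence inserted at
    its junction (reverse-complemented for minus-strand transcripts). With an
    all-spliced pattern the template equals the transcript sequence. Returns
    the template and one ``ir`` truth record per retained intron (ref_pos =
    intron index, length = intron genomic length).
    """
    if len(pattern) != len(tx.introns):
        raise ValueError(
            f"pattern length {len(pattern)} != intron count {len(tx.introns)}"
        )
    if tx.chrom not in genome:
        raise KeyError(f"chromosome {tx.chrom} missing from genome")
    chrom_seq = genome[tx.chrom]

    # genomic-order pattern: transcript order is reversed on the minus strand
    if tx.strand == "+":
        genomic_pattern = list(pattern)
    else:
        genomic_pattern = list(pattern)[::-1]

    pieces = []
    introns_genomic = tx.introns_genomic
    for i, (s, e) in enumerate(tx.exons):
        pieces.append(chrom_seq[s:e])
        if i < len(introns_genomic) and genomic_pattern[i]:
            gs, ge = introns_genomic[i]
            pieces.append(chrom_seq[gs:ge])
    template = "".join(pieces)
    if tx.strand == "-":
        template = revcomp(template)

    if not any(pattern) and transcript_seq is not None:
        if template != transcript_seq:
            raise ValueError(
                f"{tx.transcript_id}: spliced template disagrees with the "
                "provided transcript sequence; annotation and references are "
                "inconsistent"
            )

    records = [
        ReadEvent("ir", read_pos=-1, ref_pos=i,
                  length=tx.introns[i][1] - tx.introns[i][0])
        for i, retained in enumerate(pattern) if retained
    ]
    return template, records
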