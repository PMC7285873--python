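"""Readers and writers for the standard formats the tool touches.

Covers FASTA/FASTQ input (gzip ok), GTF/GFF3 transcript annotation,
PAF/SAM/BAM alignments resolved to explicit edit walks, the on-disk model
profile directory, and simulated-read output (FASTA + ground-truth TSV).

All internal coordinates are 0-based half-open; conversion happens only at
file boundaries.
"""

from __future__ import annotations

import gzip
import json
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

PROFILE_VERSION = "1.0"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

_NORMALIZE = str.maketrans("acgtunU", "ACGTTNT")
_VALID_BASES = frozenset("ACGTN")


@dataclass
class SequenceRecord:
    """One reference or read sequence.

    ``sequence`` is uppercase DNA over {A,C,G,T,N}; U (direct RNA references)
    is mapped to T at parse time.
    """

    id: str
    sequence: str
    description: str = ""


def _open_text(path):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA or FASTQ file (auto-detected, gzip ok).

    Lowercase is uppercased and U is mapped to T. Raises ``ValueError`` on
    malformed records or duplicate ids.
    """
    seen: set[str] = set()
    with _open_text(path) as fh:
        first = fh.read(1)
        if first == "":
            return
        fh.seek(0)
        if first == ">":
            parser = _iter_fasta(fh)
        elif first == "@":
            parser = _iter_fastq(fh)
        else:
            raise ValueError(
                f"{path}: not FASTA/FASTQ (first character {first!r})"
            )
        for rec in parser:
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            yield rec


def _normalize_seq(raw: str, name: str, lineno: int) -> str:
    seq = raw.translate(_NORMALIZE)
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(
            f"invalid characters {sorted(bad)} in sequence {name!r} near line {lineno}"
        )
    return seq


def _iter_fasta(fh) -> Iterator[SequenceRecord]:
    name = None
    desc = ""
    chunks: list[str] = []
    start_line = 0
    for lineno, line in enumerate(fh, 1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                if not chunks:
                    raise ValueError(f"empty sequence for {name!r} at line {start_line}")
                yield SequenceRecord(name, "".join(chunks), desc)
            headers = line[1:].split(maxsplit=1)
            if not headers:
                raise ValueError(f"empty FASTA header at line {lineno}")
            name = headers[0]
            desc = headers[1] if len(headers) > 1 else ""
            chunks = []
            start_line = lineno
        else:
            if name is None:
                raise ValueError(f"sequence data before first header at line {lineno}")
            chunks.append(_normalize_seq(line, name, lineno))
    if name is not None:
        if not chunks:
            raise ValueError(f"empty sequence for {name!r} at line {start_line}")
        yield SequenceRecord(name, "".join(chunks), desc)


def _iter_fastq(fh) -> Iterator[SequenceRecord]:
    while True:
        header = fh.readline()
        if not header:
            return
        header = header.rstrip("\n")
        if not header:
            continue
        if not header.startswith("@"):
            raise ValueError(f"malformed FASTQ header: {header!r}")
        seq = fh.readline().rstrip("\n")
        plus = fh.readline()
        qual = fh.readline()
        if not qual:
            raise ValueError(f"truncated FASTQ record for {header!r}")
        parts = header[1:].split(maxsplit=1)
        yield SequenceRecord(
            parts[0], _normalize_seq(seq, parts[0], 0), parts[1] if len(parts) > 1 else ""
        )


def load_sequences(path) -> dict[str, str]:
    """Read a FASTA/FASTQ file fully into an id -> sequence dict."""
    return {rec.id: rec.sequence for rec in read_fasta(path)}


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


@dataclass
class Transcript:
    """One annotated transcript: sorted genomic exons plus derived introns.

    ``exons`` are 0-based half-open genomic intervals sorted by coordinate.
    ``introns`` are the gaps between consecutive exons, ordered 5'->3' in
    *transcript* orientation (reversed for minus-strand transcripts so index
    0 is always the transcript's 5'-most intron).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.transcript_id}")
        exons = sorted(self.exons)
        if exons != self.exons:
            warnings.warn(f"unsorted exons for {self.transcript_id}; sorting")
            self.exons = exons
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if e0 > s1:
                raise ValueError(f"overlapping exons in {self.transcript_id}")

    @property
    def introns_genomic(self) -> list[tuple[int, int]]:
        """Introns in genomic coordinate order."""
        return [
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        ]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Introns ordered 5'->3' along the transcript."""
        ig = self.introns_genomic
        return ig if self.strand == "+" else ig[::-1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class TranscriptAnnotation:
    transcripts: dict[str, Transcript]

    def __getitem__(self, tid: str) -> Transcript:
        return self.transcripts[tid]

    def __contains__(self, tid: str) -> bool:
        return tid in self.transcripts

    def __iter__(self):
        return iter(self.transcripts.values())

    def __len__(self):
        return len(self.transcripts)


def parse_annotation(path) -> TranscriptAnnotation:
    """Parse a GTF or GFF3 file into per-transcript exon structures.

    File coordinates (1-based inclusive) are converted to 0-based half-open.
    Transcripts with zero exon features are skipped with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        os.fspath(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    groups: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tids = feat.attributes.get("transcript_id") or feat.attributes.get("Parent")
        if not tids:
            warnings.warn(f"exon without transcript_id/Parent at {feat.seqid}:{feat.start}")
            continue
        gene = (feat.attributes.get("gene_id") or [tids[0]])[0]
        for tid in tids:
            g = groups.setdefault(
                tid, {"gene": gene, "chrom": feat.seqid, "strand": feat.strand, "exons": []}
            )
            # GTF/GFF are 1-based inclusive; feat.start-1 .. feat.end half-open
            g["exons"].append((feat.start - 1, feat.end))
    transcripts = {}
    for tid, g in groups.items():
        if not g["exons"]:
            warnings.warn(f"transcript {tid} has no exons; skipped")
            continue
        transcripts[tid] = Transcript(
            transcript_id=tid,
            gene_id=g["gene"],
            chrom=g["chrom"],
            strand=g["strand"] if g["strand"] in "+-" else "+",
            exons=sorted(g["exons"]),
        )
    return TranscriptAnnotation(transcripts)


def write_gtf(annotation: TranscriptAnnotation, path, source: str = "ont_txsim") -> None:
    """Write exon features in GTF2.2, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        for tx in annotation:
            for i, (s, e) in enumerate(tx.exons, 1):
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'exon_number "{i}";'
                )
                fh.write(
                    f"{tx.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

QUERY_OPS = frozenset("MXI")
TARGET_OPS = frozenset("MXDN")


@dataclass
class AlignmentRecord:
    """One read<->reference alignment with an explicit edit-operation walk.

    ``edit_walk`` ops: M exact match, X mismatch, I insertion to the read,
    D deletion from the read, N skipped target region (splice). Adjacent ops
    of identical type are merged; plain CIGAR M must be resolved to M/X
    before construction.
    """

    query_id: str
    query_length: int
    target_id: str
    target_kind: str  # "transcriptome" | "genome"
    strand: str  # "+" | "-"
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    edit_walk: list[tuple[str, int]]
    is_primary: bool = True

    def __post_init__(self):
        self.edit_walk = merge_walk(self.edit_walk)
        self.validate()

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        q = sum(n for op, n in self.edit_walk if op in QUERY_OPS)
        t = sum(n for op, n in self.edit_walk if op in TARGET_OPS)
        if q != self.query_end - self.query_start:
            raise ValueError(
                f"{self.query_id}: walk consumes {q} query bases, span is "
                f"{self.query_end - self.query_start}"
            )
        if t != self.target_end - self.target_start:
            raise ValueError(
                f"{self.query_id}: walk consumes {t} target bases, span is "
                f"{self.target_end - self.target_start}"
            )
        for op, n in self.edit_walk:
            if op not in "MXIDN":
                raise ValueError(f"unknown edit op {op!r}")
            if n < 1:
                raise ValueError(f"non-positive op length in {self.query_id}")

    @property
    def matched_bases(self) -> int:
        """Exactly matched bases; the score proxy for compatibility filtering."""
        return sum(n for op, n in self.edit_walk if op == "M")

    @property
    def aligned_target_span(self) -> int:
        return self.target_end - self.target_start


def merge_walk(walk: Sequence[tuple[str, int]]) -> list[tuple[str, int]]:
    merged: list[tuple[str, int]] = []
    for op, n in walk:
        if n == 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return merged


_CIGAR_OPS = "MIDNSHP=X"


def _split_cigar(cg: str) -> list[tuple[str, int]]:
    out = []
    num = ""
    for ch in cg:
        if ch.isdigit():
            num += ch
        elif ch in _CIGAR_OPS:
            out.append((ch, int(num)))
            num = ""
        else:
            raise ValueError(f"bad CIGAR character {ch!r} in {cg!r}")
    if num:
        raise ValueError(f"trailing number in CIGAR {cg!r}")
    return out


def _walk_from_cs(cs: str) -> list[tuple[str, int]]:
    """Edit walk from a minimap2 short-form cs tag."""
    walk: list[tuple[str, int]] = []
    i = 0
    n = len(cs)
    while i < n:
        ch = cs[i]
        if ch == ":":
            j = i + 1
            while j < n and cs[j].isdigit():
                j += 1
            walk.append(("M", int(cs[i + 1 : j])))
            i = j
        elif ch == "*":
            walk.append(("X", 1))
            i += 3
        elif ch in "+-":
            j = i + 1
            while j < n and cs[j].isalpha():
                j += 1
            walk.append(("I" if ch == "+" else "D", j - i - 1))
            i = j
        elif ch == "~":
            # ~gt123ag -> intron of 123 target bases
            j = i + 3
            k = j
            while k < n and cs[k].isdigit():
                k += 1
            walk.append(("N", int(cs[j:k])))
            i = k + 2
        else:
            raise ValueError(f"unsupported cs token at {cs[i:i+8]!r}")
    return walk


def parse_paf(path, target_kind: str) -> Iterator[AlignmentRecord]:
    """Parse PAF alignments; the cs tag is preferred, cg accepted if M-free."""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: PAF needs >=12 columns")
            tags = {}
            for tag in cols[12:]:
                name, typ, val = tag.split(":", 2)
                tags[name] = val
            if "cs" in tags:
                walk = _walk_from_cs(tags["cs"])
            elif "cg" in tags:
                ops = _split_cigar(tags["cg"])
                if any(op == "M" for op, _ in ops):
                    raise ValueError(
                        f"{path}:{lineno}: CIGAR contains plain M and no cs tag; "
                        "re-align with --eqx/--cs or provide a cs tag"
                    )
                walk = [("M" if op == "=" else op, n) for op, n in ops if op not in "SH"]
            else:
                raise ValueError(f"{path}:{lineno}: PAF line lacks both cs and cg tags")
            yield AlignmentRecord(
                query_id=cols[0],
                query_length=int(cols[1]),
                target_id=cols[5],
                target_kind=target_kind,
                strand=cols[4],
                query_start=int(cols[2]),
                query_end=int(cols[3]),
                target_start=int(cols[7]),
                target_end=int(cols[8]),
                edit_walk=walk,
                is_primary=tags.get("tp", "P") == "P",
            )


def write_paf(alignments: Iterable[AlignmentRecord], path) -> None:
    """Write alignments as PAF with an eqx cg tag (=/X, never plain M)."""
    with open(path, "w") as fh:
        for a in alignments:
            cg = "".join(
                f"{n}{'=' if op == 'M' else op}" for op, n in a.edit_walk
            )
            nmatch = a.matched_bases
            block = sum(n for op, n in a.edit_walk if op != "N")
            tp = "P" if a.is_primary else "S"
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        a.query_id, a.query_length, a.query_start, a.query_end,
                        a.strand, a.target_id, 0, a.target_start, a.target_end,
                        nmatch, block, 60, f"tp:A:{tp}", f"cg:Z:{cg}",
                    )
                )
                + "\n"
            )


def parse_sam(path, target_kind: str, reference: dict[str, str] | None = None
              ) -> Iterator[AlignmentRecord]:
    """Parse SAM/BAM via pysam; plain-M CIGARs resolved via MD or reference."""
    import pysam

    mode = "rb" if os.fspath(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(os.fspath(path), mode, check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped:
                continue
            walk = _walk_from_sam(read, reference)
            qlen = read.infer_read_length() or read.query_length
            lead = 0
            trail = 0
            ct = read.cigartuples or []
            if ct and ct[0][0] in (4, 5):
                lead = ct[0][1]
            if ct and ct[-1][0] in (4, 5):
                trail = ct[-1][1]
            yield AlignmentRecord(
                query_id=read.query_name,
                query_length=qlen,
                target_id=read.reference_name,
                target_kind=target_kind,
                strand="-" if read.is_reverse else "+",
                query_start=lead,
                query_end=qlen - trail,
                target_start=read.reference_start,
                target_end=read.reference_end,
                edit_walk=walk,
                is_primary=not (read.is_secondary or read.is_supplementary),
            )


def _walk_from_sam(read, reference) -> list[tuple[str, int]]:
    code = {0: "M?", 1: "I", 2: "D", 3: "N", 7: "M", 8: "X"}
    ct = read.cigartuples or []
    has_plain_m = any(op == 0 for op, _ in ct)
    refseq = None
    if has_plain_m:
        if read.has_tag("MD"):
            refseq = read.get_reference_sequence().upper()
        elif reference is not None and read.reference_name in reference:
            refseq = reference[read.reference_name][
                read.reference_start : read.reference_end
            ]
        else:
            raise ValueError(
                f"{read.query_name}: CIGAR contains plain M but no MD tag and no "
                "reference was provided; re-align with --eqx or pass the reference"
            )
    walk: list[tuple[str, int]] = []
    qpos = read.query_alignment_start
    rpos = 0  # within refseq
    qseq = read.query_sequence or ""
    for op, n in ct:
        if op in (4, 5):
            continue
        sym = code.get(op)
        if sym is None:
            raise ValueError(f"unsupported CIGAR op code {op}")
        if sym == "M?":
            for k in range(n):
                same = qseq[qpos + k] == refseq[rpos + k]
                walk.append(("M" if same else "X", 1))
            qpos += n
            rpos += n
        else:
            walk.append((sym, n))
            if sym in ("I", "X"):
                qpos += n
            if sym in ("D", "N", "X"):
                rpos += n
            if sym == "M":
                qpos += n
                rpos += n
    return merge_walk(walk)


def parse_alignments(path, target_kind: str, reference: dict[str, str] | None = None
                     ) -> Iterator[AlignmentRecord]:
    """Parse PAF (by extension .paf/.paf.gz) or SAM/BAM alignments."""
    name = os.fspath(path)
    if name.endswith((".paf", ".paf.gz")):
        yield from parse_paf(path, target_kind)
    else:
        yield from parse_sam(path, target_kind, reference)


# ---------------------------------------------------------------------------
# Simulated reads + ground truth
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = (
    "read_id", "event", "read_pos", "ref_pos", "length", "new_length", "bases",
)


@dataclass
class ReadEvent:
    """One introduced change, sufficient (with the read id) for byte-exact replay.

    Coordinate frames: ``ir`` rows index introns; ``homopolymer`` rows use the
    pre-modification template-slice frame; error rows (mis/ins/del) use the
    post-homopolymer template frame for ``ref_pos`` and the growing read for
    ``read_pos``; ``head``/``tail`` rows carry the flank bases.
    """

    event: str
    read_pos: int
    ref_pos: int
    length: int
    new_length: int = -1
    bases: str = ""


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    category: str  # "aligned" | "unaligned"
    transcript_id: str
    template_start: int
    template_end: int
    orientation: str  # "sense" | "antisense"
    ir_pattern: tuple[bool, ...]
    head_len: int
    tail_len: int
    events: list[ReadEvent] = field(default_factory=list)


def make_read_id(tid: str, orientation: str, tstart: int, aligned_len: int,
                 head: int, tail: int, serial: int, category: str) -> str:
    strand = "+" if orientation == "sense" else "-"
    return f"{tid}!{strand}!{tstart}!{aligned_len}!{head}!{tail}!{serial}!{category}"


def parse_read_id(read_id: str) -> dict:
    tid, strand, tstart, alen, head, tail, serial, category = read_id.rsplit("!", 7)
    return {
        "transcript_id": tid,
        "orientation": "sense" if strand == "+" else "antisense",
        "template_start": int(tstart),
        "aligned_len": int(alen),
        "head_len": int(head),
        "tail_len": int(tail),
        "serial": int(serial),
        "category": category,
    }


def write_simulated_reads(reads: Iterable[SimulatedRead], fasta_path, truth_path) -> None:
    """Write read FASTA plus the per-event ground-truth TSV."""
    seen: set[str] = set()
    with open(fasta_path, "w") as ff, open(truth_path, "w") as tf:
        tf.write("\t".join(TRUTH_COLUMNS) + "\n")
        for read in reads:
            if read.read_id in seen:
                raise ValueError(f"duplicate simulated read id {read.read_id}")
            seen.add(read.read_id)
            ff.write(f">{read.read_id}\n")
            for i in range(0, len(read.sequence), 80):
                ff.write(read.sequence[i : i + 80] + "\n")
            for ev in read.events:
                tf.write(
                    f"{read.read_id}\t{ev.event}\t{ev.read_pos}\t{ev.ref_pos}\t"
                    f"{ev.length}\t{ev.new_length}\t{ev.bases}\n"
                )


def read_truth(truth_path) -> dict[str, list[ReadEvent]]:
    """Load the truth TSV back, preserving per-read event order."""
    out: dict[str, list[ReadEvent]] = {}
    with _open_text(truth_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TRUTH_COLUMNS:
            raise ValueError(f"unexpected truth header {header}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rid = parts[0]
            out.setdefault(rid, []).append(
                ReadEvent(
                    event=parts[1],
                    read_pos=int(parts[2]),
                    ref_pos=int(parts[3]),
                    length=int(parts[4]),
                    new_length=int(parts[5]),
                    bases=parts[6],
                )
            )
    return out


def reconstruct_read(read_id: str, events: Sequence[ReadEvent],
                     transcriptome: dict[str, str],
                     genome: dict[str, str] | None = None,
                     annotation: TranscriptAnnotation | None = None) -> str:
    """Rebuild a simulated read byte-exactly from its id, truth rows and refs.

    This is the replay oracle: reference interval + truth rows deterministically
    reconstruct the emitted sequence.
    """
    info = parse_read_id(read_id)
    tid = info["transcript_id"]
    ir_rows = [e for e in events if e.event == "ir"]
    if ir_rows:
        if genome is None or annotation is None:
            raise ValueError("IR events present but genome/annotation not given")
        from .ir_model import build_template  # local import avoids a cycle

        tx = annotation[tid]
        pattern = [False] * len(tx.introns)
        for e in ir_rows:
            pattern[e.ref_pos] = True
        template, _ = build_template(tx, genome, pattern, transcriptome.get(tid))
    else:
        template = transcriptome[tid]
    start = info["template_start"]
    body = template[start : start + info["aligned_len"]]

    # homopolymer rows: coordinates on the unmodified slice, applied in order
    hp_rows = [e for e in events if e.event == "homopolymer"]
    if hp_rows:
        pieces = []
        cursor = 0
        for e in sorted(hp_rows, key=lambda r: r.ref_pos):
            pieces.append(body[cursor : e.ref_pos])
            pieces.append(e.bases * e.new_length)
            cursor = e.ref_pos + e.length
        pieces.append(body[cursor:])
        body = "".join(pieces)

    # error rows: ref_pos on the homopolymer-modified slice, in emission order
    out = []
    ti = 0
    for e in events:
        if e.event not in ("mis", "ins", "del"):
            continue
        out.append(body[ti : e.ref_pos])
        ti = e.ref_pos
        if e.event == "mis":
            out.append(e.bases)
            ti += e.length
        elif e.event == "del":
            ti += e.length
        else:  # ins
            out.append(e.bases)
    out.append(body[ti:])
    seq = "".join(out)

    head = next((e.bases for e in events if e.event == "head"), "")
    tail = next((e.bases for e in events if e.event == "tail"), "")
    seq = head + seq + tail
    if info["orientation"] == "antisense":
        seq = revcomp(seq)
    return seq


# ---------------------------------------------------------------------------
# Model profile directory
# ---------------------------------------------------------------------------


@dataclass
class ModelBundle:
    """Everything characterization learned; the input of the simulation stage."""

    length_model: "object"
    error_model: "object"
    expression: "object"
    strand_ratio: float
    unaligned_fraction: float
    ir_model: "object | None" = None
    homopolymer_model: "object | None" = None
    unaligned_error_rate: float = 0.9
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("strand_ratio", "unaligned_fraction", "unaligned_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")

    def __eq__(self, other):
        if not isinstance(other, ModelBundle):
            return NotImplemented
        return (
            self.length_model == other.length_model
            and self.error_model == other.error_model
            and self.expression == other.expression
            and self.ir_model == other.ir_model
            and self.homopolymer_model == other.homopolymer_model
            and self.strand_ratio == other.strand_ratio
            and self.unaligned_fraction == other.unaligned_fraction
            and self.unaligned_error_rate == other.unaligned_error_rate
        )


def _write_tsv(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    repr(float(x)) if isinstance(x, (float, np.floating)) else str(x)
                    for x in row
                )
                + "\n"
            )


def save_profile(bundle: ModelBundle, directory) -> None:
    """Serialize a ModelBundle to a human-readable profile directory.

    Scalars and regression coefficients go to JSON; KDE training points,
    matrices and expression go to TSV at full float precision, so that
    ``load_profile(save_profile(b)) == b``.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    lm = bundle.length_model
    em = bundle.error_model

    model = {
        "version": PROFILE_VERSION,
        "strand_ratio": bundle.strand_ratio,
        "unaligned_fraction": bundle.unaligned_fraction,
        "unaligned_error_rate": bundle.unaligned_error_rate,
        "metadata": {**bundle.metadata, "total_reads": bundle.expression.total_reads},
        "length_model": {
            "joint_bandwidth": list(map(float, lm.joint_bandwidth)),
            "flank_bandwidth": list(map(float, lm.flank_bandwidth)),
            "n_training": lm.n_training,
        },
        "has_ir_model": bundle.ir_model is not None,
        "has_homopolymer_model": bundle.homopolymer_model is not None,
    }
    (d / "model.json").write_text(json.dumps(model, indent=2))

    rows = [("joint", x, y) for x, y in zip(lm.joint_log_length, lm.joint_ratio)]
    rows += [("flank", x, y) for x, y in zip(lm.flank_head, lm.flank_tail)]
    _write_tsv(d / "length_kde.tsv", ("kind", "x", "y"), rows)
    (d / "unaligned.json").write_text(
        json.dumps(
            {
                "points": [float(x) for x in lm.unaligned_log_length],
                "bandwidth": float(lm.unaligned_bandwidth),
            }
        )
    )

    (d / "error_mixtures.json").write_text(json.dumps(em.mixtures_dict(), indent=2))
    _write_tsv(
        d / "error_markov.tsv",
        ("from", "mis", "ins", "del"),
        [
            (state, *[float(v) for v in row])
            for state, row in zip(("mis", "ins", "del"), em.markov)
        ],
    )
    _write_tsv(d / "match_lengths.tsv", ("log1p_length",), [(float(x),) for x in em.match_points])

    if bundle.ir_model is not None:
        (d / "ir_markov.json").write_text(json.dumps(bundle.ir_model.to_dict(), indent=2))
    if bundle.homopolymer_model is not None:
        (d / "homopolymer.json").write_text(
            json.dumps(bundle.homopolymer_model.to_dict(), indent=2)
        )

    _write_tsv(
        d / "expression.tsv",
        ("target_id", "est_count", "tpm"),
        [
            (tid, float(c), float(t))
            for tid, (c, t) in sorted(bundle.expression.abundances.items())
        ],
    )


def load_profile(directory) -> ModelBundle:
    """Load a profile directory saved by :func:`save_profile`."""
    from .error_model import ErrorModel
    from .homopolymer_model import HomopolymerModel
    from .ir_model import IRModel
    from .length_strand_model import LengthModel
    from .quantify import ExpressionProfile

    d = Path(directory)
    for mandatory in ("model.json", "length_kde.tsv", "unaligned.json",
                      "error_mixtures.json", "error_markov.tsv",
                      "match_lengths.tsv", "expression.tsv"):
        if not (d / mandatory).exists():
            raise FileNotFoundError(f"profile is missing mandatory file {mandatory}")
    model = json.loads((d / "model.json").read_text())
    if model.get("version") != PROFILE_VERSION:
        warnings.warn(
            f"profile version {model.get('version')} != {PROFILE_VERSION}; loading anyway"
        )

    jx, jy, fx, fy = [], [], [], []
    with open(d / "length_kde.tsv") as fh:
        fh.readline()
        for line in fh:
            kind, x, y = line.rstrip("\n").split("\t")
            if kind == "joint":
                jx.append(float(x))
                jy.append(float(y))
            else:
                fx.append(float(x))
                fy.append(float(y))
    un = json.loads((d / "unaligned.json").read_text())
    lmj = model["length_model"]
    lm = LengthModel(
        joint_log_length=np.array(jx),
        joint_ratio=np.array(jy),
        joint_bandwidth=tuple(lmj["joint_bandwidth"]),
        flank_head=np.array(fx),
        flank_tail=np.array(fy),
        flank_bandwidth=tuple(lmj["flank_bandwidth"]),
        unaligned_log_length=np.array(un["points"]),
        unaligned_bandwidth=un["bandwidth"],
        n_training=lmj["n_training"],
    )

    mix = json.loads((d / "error_mixtures.json").read_text())
    markov = []
    with open(d / "error_markov.tsv") as fh:
        fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            markov.append([float(v) for v in parts[1:4]])
    match_pts = []
    with open(d / "match_lengths.tsv") as fh:
        fh.readline()
        for line in fh:
            match_pts.append(float(line.strip()))
    em = ErrorModel.from_dicts(mix, np.array(markov), np.array(match_pts))

    ir = None
    if model.get("has_ir_model") and (d / "ir_markov.json").exists():
        ir = IRModel.from_dict(json.loads((d / "ir_markov.json").read_text()))
    elif model.get("has_ir_model"):
        raise FileNotFoundError("profile declares an IR model but ir_markov.json is missing")
    hp = None
    if model.get("has_homopolymer_model") and (d / "homopolymer.json").exists():
        hp = HomopolymerModel.from_dict(json.loads((d / "homopolymer.json").read_text()))
    elif model.get("has_homopolymer_model"):
        raise FileNotFoundError("profile declares a homopolymer model but homopolymer.json is missing")

    abundances = {}
    with open(d / "expression.tsv") as fh:
        fh.readline()
        for line in fh:
            tid, c, t = line.rstrip("\n").split("\t")
            abundances[tid] = (float(c), float(t))
    expr = ExpressionProfile(abundances=abundances,
                             total_reads=model["metadata"].get("total_reads", 0))

    return ModelBundle(
        length_model=lm,
        error_model=em,
        expression=expr,
        strand_ratio=model["strand_ratio"],
        unaligned_fraction=model["unaligned_fraction"],
        ir_model=ir,
        homopolymer_model=hp,
        unaligned_error_rate=model["unaligned_error_rate"],
        metadata=model["metadata"],
    )
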