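"""Transcript abundance estimation from multi-mapping long-read alignments.

Reads are assigned to transcripts by expectation maximization over a
read-by-transcript compatibility matrix (RSEM-style, but count-based: one
long read evidences one molecule, so TPM is proportional to the expected
read count with no effective-length divisor by default; a length-normalized
mode is available).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import AlignmentRecord

DEFAULT_MIN_SCORE_FRAC = 0.8
TPM_SCALE = 1e6


@dataclass
class CompatibilityMatrix:
    """Per-read compatible transcript sets after the score filter."""

    reads: dict[str, list[str]]
    n_dropped: int = 0

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @property
    def transcripts(self) -> list[str]:
        seen = set()
        for tids in self.reads.values():
            seen.update(tids)
        return sorted(seen)


@dataclass
class ExpressionProfile:
    """transcript_id -> (est_count, tpm); TPM sums to 1e6."""

    abundances: dict[str, tuple[float, float]]
    total_reads: int = 0
    n_iterations: int = 0
    log_likelihood: float = float("nan")

    def __eq__(self, other):
        if not isinstance(other, ExpressionProfile):
            return NotImplemented
        return (
            self.abundances == other.abundances
            and self.total_reads == other.total_reads
        )

    def tpm(self, tid: str) -> float:
        return self.abundances.get(tid, (0.0, 0.0))[1]

    def est_count(self, tid: str) -> float:
        return self.abundances.get(tid, (0.0, 0.0))[0]

    @property
    def tpm_total(self) -> float:
        return sum(t for _, t in self.abundances.values())

    @classmethod
    def from_tpm(cls, tpm: Mapping[str, float], total_reads: int = 0
                 ) -> "ExpressionProfile":
        total = sum(tpm.values())
        if total <= 0:
            raise ValueError("expression profile sums to zero")
        return cls(
            abundances={
                tid: (total_reads * v / total, TPM_SCALE * v / total)
                for tid, v in tpm.items()
            },
            total_reads=total_reads,
        )


def build_compatibility(
    alignments: Iterable[AlignmentRecord],
    min_score_frac: float = DEFAULT_MIN_SCORE_FRAC,
) -> CompatibilityMatrix:
    """Keep, per read, alignments scoring >= min_score_frac x the read's best.

    The score is the exactly-matched base count of the edit walk (the PAF
    residue-match column for eqx alignments). Secondary alignments are
    retained so multi-mapping reads stay ambiguous; unaligned reads simply
    never appear.
    """
    per_read: dict[str, list[tuple[int, str]]] = {}
    for a in alignments:
        per_read.setdefault(a.query_id, []).append((a.matched_bases, a.target_id))
    reads: dict[str, list[str]] = {}
    n_dropped = 0
    for rid, hits in per_read.items():
        best = max(s for s, _ in hits)
        keep = sorted({tid for s, tid in hits if s >= min_score_frac * best})
        if keep:
            reads[rid] = keep
        else:
            n_dropped += 1
    return CompatibilityMatrix(reads=reads, n_dropped=n_dropped)


def em_quantify(matrix: CompatibilityMatrix, max_iter: int = 100,
                tol: float = 1e-6) -> ExpressionProfile:
    """RSEM-style EM over the compatibility matrix; deterministic.

    E-step: z_{r,i} = tau_i / sum_{j in compat(r)} tau_j.
    M-step: tau_i = sum_r z_{r,i} / N. Iterates until the max absolute change
    in tau falls below ``tol`` or ``max_iter``; est_count = N*tau,
    tpm = tau * 1e6.
    """
    if matrix.n_reads == 0:
        raise ValueError("empty compatibility matrix")
    transcripts = matrix.transcripts
    index = {tid: i for i, tid in enumerate(transcripts)}
    k = len(transcripts)

    # identical compatibility classes collapse into weighted rows
    classes = Counter(tuple(tids) for tids in matrix.reads.values())
    class_members = [np.array([index[t] for t in tids]) for tids in classes]
    class_counts = np.array(list(classes.values()), dtype=float)
    n = class_counts.sum()

    tau = np.full(k, 1.0 / k)
    it = 0
    for it in range(1, max_iter + 1):
        new = np.zeros(k)
        for members, cnt in zip(class_members, class_counts):
            w = tau[members]
            s = w.sum()
            if s <= 0:
                w = np.full(len(members), 1.0 / len(members))
                s = 1.0
            new[members] += cnt * w / s
        new /= n
        delta = np.abs(new - tau).max()
        tau = new
        if delta < tol:
            break
    ll = float(
        sum(
            cnt * np.log(max(tau[members].sum(), 1e-300))
            for members, cnt in zip(class_members, class_counts)
        )
    )
    return ExpressionProfile(
        abundances={
            tid: (float(n * tau[i]), float(TPM_SCALE * tau[i]))
            for tid, i in index.items()
        },
        total_reads=int(n),
        n_iterations=it,
        log_likelihood=ll,
    )


def quantify_alignments(alignments: Iterable[AlignmentRecord],
                        min_score_frac: float = DEFAULT_MIN_SCORE_FRAC,
                        tpm_mode: str = "count",
                        transcript_lengths: Mapping[str, int] | None = None,
                        ) -> ExpressionProfile:
    """Convenience pipeline: compatibility filter then EM.

    ``tpm_mode="length"`` divides expected counts by transcript length before
    rescaling to 1e6 (short-read-style TPM); the default ``"count"`` treats
    one read as one molecule.
    """
    profile = em_quantify(build_compatibility(alignments, min_score_frac))
    if tpm_mode == "count":
        return profile
    if tpm_mode != "length":
        raise ValueError(f"unknown tpm_mode {tpm_mode!r}")
    if transcript_lengths is None:
        raise ValueError("length mode needs transcript_lengths")
    dens = {
        tid: c / max(1, transcript_lengths.get(tid, 1))
        for tid, (c, _) in profile.abundances.items()
    }
    total = sum(dens.values())
    return ExpressionProfile(
        abundances={
            tid: (profile.abundances[tid][0], TPM_SCALE * d / total)
            for tid, d in dens.items()
        },
        total_reads=profile.total_reads,
        n_iterations=profile.n_iterations,
        log_likelihood=profile.log_likelihood,
    )


def expression_r2(profile_a: ExpressionProfile, profile_b: ExpressionProfile) -> float:
    """Coefficient of determination between two profiles on log10(TPM+1).

    Least-squares fit of b's values on a's over the union of transcripts
    where either TPM > 0 (missing = 0). Requires >= 3 shared transcripts.
    """
    universe = sorted(
        {t for t, (_, v) in profile_a.abundances.items() if v > 0}
        | {t for t, (_, v) in profile_b.abundances.items() if v > 0}
    )
    if len(universe) < 3:
        raise ValueError("need >= 3 expressed transcripts to compute R^2")
    x = np.log10(np.array([profile_a.tpm(t) for t in universe]) + 1.0)
    y = np.log10(np.array([profile_b.tpm(t) for t in universe]) + 1.0)
    if np.allclose(x.std(), 0.0):
        raise ValueError("profile_a has no variance on the shared universe")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def load_user_expression(path, known_transcripts: Sequence[str] | None = None
                         ) -> ExpressionProfile:
    """Load a user TSV (transcript_id + tpm or est_count) and renormalize.

    Transcripts absent from ``known_transcripts`` (when given) are dropped
    with a warning; negative or empty input is an error.
    """
    import csv

    values: dict[str, float] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty expression file")
        cols = {c.lower(): c for c in reader.fieldnames}
        id_col = cols.get("transcript_id") or cols.get("target_id")
        val_col = cols.get("tpm") or cols.get("est_count")
        if not id_col or not val_col:
            raise ValueError(
                f"{path}: need transcript_id/target_id and tpm/est_count columns"
            )
        for row in reader:
            v = float(row[val_col])
            if v < 0:
                raise ValueError(f"{path}: negative abundance for {row[id_col]}")
            values[row[id_col]] = values.get(row[id_col], 0.0) + v
    if known_transcripts is not None:
        known = set(known_transcripts)
        unknown = sorted(set(values) - known)
        if unknown:
            warnings.warn(
                f"{len(unknown)} transcripts absent from the reference dropped "
                f"(e.g. {unknown[:3]})"
            )
            values = {t: v for t, v in values.items() if t in known}
    if not values or sum(values.values()) <= 0:
        raise ValueError(f"{path}: no usable expression rows")
    return ExpressionProfile.from_tpm(values)


def write_expression(profile: ExpressionProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("target_id\test_count\ttpm\n")
        for tid, (c, t) in sorted(profile.abundances.items()):
            fh.write(f"{tid}\t{c:.6f}\t{t:.6f}\n")
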