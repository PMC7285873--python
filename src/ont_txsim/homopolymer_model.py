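"""Homopolymer expansion/contraction characterization and simulation.

Nanopore base callers systematically mis-estimate homopolymer run lengths
(mostly contractions). For each base, the read-side run length given a
reference run of length L is modelled as Normal(mean(L), sd(L)) where
mean(L) is a continuous two-segment linear regression (integer breakpoint
chosen by SSE grid search) and sd(L) an ordinary least-squares line, with
the predicted SD clamped at >= 0.1. During simulation each reference run of
length >= min_len is replaced by a rounded, non-negative draw from that
normal; modified runs are masked from generic error placement so the
elevated indel rate inside homopolymers is carried by this model alone.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import AlignmentRecord, ReadEvent
from .io_formats import revcomp as _rc

DEFAULT_MIN_LEN = 5
MIN_OBS_PER_BASE = 30
SD_FLOOR = 0.1
BASES = "ACGT"


@dataclass
class HomopolymerObservation:
    base: str
    ref_len: int
    read_len: int


@dataclass
class _BaseFit:
    """Per-base regression coefficients.

    mean(L) = intercept + slope1*min(L, breakpoint) + slope2*max(L-breakpoint, 0)
    sd(L)   = max(sd_intercept + sd_slope*L, 0.1)
    """

    breakpoint: float
    intercept: float
    slope1: float
    slope2: float
    sd_intercept: float
    sd_slope: float
    n_observations: int
    identity: bool = False  # fallback: mean(L) = L, sd = 0.5

    def mean(self, ref_len: float) -> float:
        if self.identity:
            return float(ref_len)
        return (
            self.intercept
            + self.slope1 * min(ref_len, self.breakpoint)
            + self.slope2 * max(ref_len - self.breakpoint, 0.0)
        )

    def sd(self, ref_len: float) -> float:
        if self.identity:
            return 0.5
        return max(self.sd_intercept + self.sd_slope * ref_len, SD_FLOOR)


@dataclass
class HomopolymerModel:
    min_len: int
    per_base: dict[str, _BaseFit]

    def __eq__(self, other):
        if not isinstance(other, HomopolymerModel):
            return NotImplemented
        return self.min_len == other.min_len and self.per_base == other.per_base

    def mean(self, base: str, ref_len: int) -> float:
        return self.per_base[base].mean(ref_len)

    def sd(self, base: str, ref_len: int) -> float:
        return self.per_base[base].sd(ref_len)

    def to_dict(self) -> dict:
        return {
            "min_len": self.min_len,
            "per_base": {
                b: {
                    "breakpoint": f.breakpoint,
                    "intercept": f.intercept,
                    "slope1": f.slope1,
                    "slope2": f.slope2,
                    "sd_intercept": f.sd_intercept,
                    "sd_slope": f.sd_slope,
                    "n_observations": f.n_observations,
                    "identity": f.identity,
                }
                for b, f in self.per_base.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HomopolymerModel":
        return cls(
            min_len=d["min_len"],
            per_base={b: _BaseFit(**f) for b, f in d["per_base"].items()},
        )

    @classmethod
    def identity_model(cls, min_len: int = DEFAULT_MIN_LEN) -> "HomopolymerModel":
        return cls(
            min_len=min_len,
            per_base={
                b: _BaseFit(0, 0, 0, 0, 0, 0, 0, identity=True) for b in BASES
            },
        )


# ---------------------------------------------------------------------------
# Characterization
# ---------------------------------------------------------------------------


def find_homopolymers(sequence: str, min_len: int = DEFAULT_MIN_LEN
                      ) -> list[tuple[str, int, int]]:
    """Maximal runs of identical A/C/G/T bases with length >= min_len."""
    runs = []
    i = 0
    n = len(sequence)
    while i < n:
        j = i + 1
        while j < n and sequence[j] == sequence[i]:
            j += 1
        if j - i >= min_len and sequence[i] in BASES:
            runs.append((sequence[i], i, j - i))
        i = j
    return runs


def extract_homopolymer_observations(
    alignments: Iterable[AlignmentRecord],
    reference_sequences: dict[str, str],
    min_len: int = DEFAULT_MIN_LEN,
    read_sequences: dict[str, str] | None = None,
) -> list[HomopolymerObservation]:
    """Measure read-side run lengths for reference runs covered by alignments.

    For each reference homopolymer fully inside an alignment's target span,
    read_len = run length - deleted bases within the run + inserted bases
    strictly inside the run (when read sequences are available, only
    insertions consisting of the run base count; without them all interior
    insertions count). Runs truncated by an alignment boundary are skipped.
    """
    runs_by_target: dict[str, list[tuple[str, int, int]]] = {}
    obs: list[HomopolymerObservation] = []
    for a in alignments:
        if not a.is_primary:
            continue
        if a.target_id not in reference_sequences:
            continue
        runs = runs_by_target.get(a.target_id)
        if runs is None:
            runs = find_homopolymers(reference_sequences[a.target_id], min_len)
            runs_by_target[a.target_id] = runs
        inner = [
            (b, s, l)
            for b, s, l in runs
            if s >= a.target_start and s + l <= a.target_end
        ]
        if not inner:
            continue
        read_seq = None
        if read_sequences is not None:
            read_seq = read_sequences.get(a.query_id)
        obs.extend(_measure_runs(a, inner, read_seq))
    return obs


def _measure_runs(a: AlignmentRecord, runs, read_seq
                  ) -> list[HomopolymerObservation]:
    events = []  # (target_pos, kind, n, query_pos) for D and I ops
    tpos = a.target_start
    qpos = a.query_start
    for op, n in a.edit_walk:
        if op in ("M", "X"):
            tpos += n
            qpos += n
        elif op == "D":
            events.append((tpos, "D", n, qpos))
            tpos += n
        elif op == "N":
            tpos += n
        elif op == "I":
            events.append((tpos, "I", n, qpos))
            qpos += n
    out = []
    for base, start, length in runs:
        end = start + length
        read_len = length
        for pos, kind, n, q in events:
            if kind == "D":
                read_len -= max(0, min(pos + n, end) - max(pos, start))
            else:  # insertion at target position pos, strictly inside the run
                if start < pos < end:
                    if read_seq is not None:
                        if a.strand == "+":
                            ins = read_seq[q : q + n]
                        else:
                            # query coords run target-forward; on the stored
                            # (reverse-complemented) read the segment sits
                            # mirrored at the other end of the aligned span
                            off = q - a.query_start
                            lo = a.query_end - off - n
                            ins = _rc(read_seq[lo : lo + n])
                        read_len += sum(1 for c in ins if c == base)
                    else:
                        read_len += n
        out.append(HomopolymerObservation(base, length, max(0, read_len)))
    return out


def _two_segment_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray
                     ) -> tuple[float, float, float, float]:
    """Weighted continuous two-segment least squares with grid-searched break.

    Returns (breakpoint, intercept, slope1, slope2).
    """
    xs = np.unique(x)
    sw = np.sqrt(w)

    def sse_for(bp: float):
        d = np.column_stack([np.ones_like(x), np.minimum(x, bp),
                             np.maximum(x - bp, 0.0)])
        coef, *_ = np.linalg.lstsq(d * sw[:, None], y * sw, rcond=None)
        resid = y - d @ coef
        return float((w * resid ** 2).sum()), coef

    if xs.size < 3:
        # degenerate: at most one distinct slope is identifiable
        d = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(d * sw[:, None], y * sw, rcond=None)
        return float(xs[-1]), float(coef[0]), float(coef[1]), float(coef[1])

    best = None
    for bp in xs[1:-1]:
        sse, coef = sse_for(float(bp))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, float(bp), coef)
    # also allow a single straight line (breakpoint at the right edge)
    sse, coef = sse_for(float(xs[-1]))
    if sse < best[0] - 1e-12:
        best = (sse, float(xs[-1]), coef)
    _, bp, coef = best
    return bp, float(coef[0]), float(coef[1]), float(coef[2])


def fit_homopolymer_model(
    observations: Sequence[HomopolymerObservation],
    min_len: int = DEFAULT_MIN_LEN,
) -> HomopolymerModel:
    """Fit per-base mean (segmented) and SD (linear) regressions.

    Observations are grouped by reference length; the mean model is fit on
    per-group means weighted by group size, the SD model on per-group sample
    SDs (groups of >= 2). Bases with < 30 observations fall back to an
    identity mean with SD 0.5, with a warning.
    """
    by_base: dict[str, dict[int, list[int]]] = {b: defaultdict(list) for b in BASES}
    for o in observations:
        if o.ref_len < min_len:
            raise ValueError(f"observation ref_len {o.ref_len} < min_len {min_len}")
        by_base[o.base][o.ref_len].append(o.read_len)

    per_base = {}
    for b in BASES:
        groups = by_base[b]
        n_obs = sum(len(v) for v in groups.values())
        if n_obs < MIN_OBS_PER_BASE:
            warnings.warn(
                f"only {n_obs} homopolymer observations for base {b}; "
                "falling back to identity mean / SD 0.5"
            )
            per_base[b] = _BaseFit(0, 0, 0, 0, 0, 0, n_obs, identity=True)
            continue
        xs = np.array(sorted(groups), dtype=float)
        means = np.array([np.mean(groups[int(x)]) for x in xs])
        weights = np.array([len(groups[int(x)]) for x in xs], dtype=float)
        bp, b0, b1, b2 = _two_segment_fit(xs, means, weights)

        sd_x, sd_y, sd_w = [], [], []
        for x in xs:
            vals = groups[int(x)]
            if len(vals) >= 2:
                sd_x.append(x)
                sd_y.append(np.std(vals, ddof=1))
                sd_w.append(len(vals))
        if len(sd_x) >= 2:
            sw = np.sqrt(np.asarray(sd_w, dtype=float))
            d = np.column_stack([np.ones(len(sd_x)), np.asarray(sd_x)])
            coef, *_ = np.linalg.lstsq(d * sw[:, None], np.asarray(sd_y) * sw,
                                       rcond=None)
            sd_int, sd_slope = float(coef[0]), float(coef[1])
        elif len(sd_x) == 1:
            sd_int, sd_slope = float(sd_y[0]), 0.0
        else:
            sd_int, sd_slope = SD_FLOOR, 0.0
        per_base[b] = _BaseFit(bp, b0, b1, b2, sd_int, sd_slope, n_obs)
    return HomopolymerModel(min_len=min_len, per_base=per_base)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def apply_homopolymer_effects(
    template_seq: str,
    model: HomopolymerModel,
    rng: np.random.Generator,
) -> tuple[str, list[ReadEvent], list[tuple[int, int]]]:
    """Resample every reference run >= min_len to its modelled read length.

    Returns the modified sequence, one ``homopolymer`` truth record per run
    (ref_pos/length on the input sequence, new_length after modification),
    and the modified run intervals in the *new* sequence, for masking from
    generic error placement.
    """
    runs = find_homopolymers(template_seq, model.min_len)
    if not runs:
        return template_seq, [], []
    pieces = []
    records: list[ReadEvent] = []
    masked: list[tuple[int, int]] = []
    cursor = 0
    out_len = 0
    for base, start, length in runs:
        fit = model.per_base.get(base)
        if fit is None:
            continue
        new_len = max(0, int(round(rng.normal(fit.mean(length), fit.sd(length)))))
        pieces.append(template_seq[cursor:start])
        out_len += start - cursor
        pieces.append(base * new_len)
        records.append(
            ReadEvent("homopolymer", read_pos=out_len, ref_pos=start,
                      length=length, new_length=new_len, bases=base)
        )
        masked.append((out_len, out_len + new_len))
        out_len += new_len
        cursor = start + length
    pieces.append(template_seq[cursor:])
    return "".join(pieces), records, masked
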