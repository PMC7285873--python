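"""Read-length anatomy and strand-ratio characterization.

Nanopore transcriptome reads are usually shorter than their source molecule,
so read length is modelled *relative* to the source transcript: a 2-D Gaussian
KDE over (log10 transcript length, aligned ratio), plus a 2-D KDE over the
unaligned head/tail flank lengths (log1p scale) and a 1-D KDE over the lengths
of reads that fail to align at all (log10 scale). Sampling conditions the
joint KDE on the transcript length by kernel-weighted resampling of training
points in the length dimension followed by Gaussian jitter in the ratio
dimension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import AlignmentRecord

MIN_TRAINING_READS = 30
_BW_FLOOR = 1e-3
_MAX_REJECTIONS = 1000


def _moments(x: np.ndarray) -> tuple[float, float]:
    if x.size < 2:
        return (float(x.mean()) if x.size else 0.0, 0.0)
    return float(x.mean()), float(x.std(ddof=1))


def smoothed_draw(value: float, mean: float, std: float, bw: float,
                  rng: np.random.Generator) -> float:
    """One variance-corrected smoothed-bootstrap draw.

    Resampling a training point and adding kernel noise inflates the variance
    by bw^2; rescaling about the training mean restores it, so simulated
    samples match the training distribution in both moments.
    """
    eps = rng.normal(0.0, bw)
    if std <= 0:
        return value + eps
    return mean + (value - mean + eps) / np.sqrt(1.0 + (bw / std) ** 2)


def scott_bandwidth(points: np.ndarray, n_dims: int) -> np.ndarray:
    """Scott's-rule per-dimension bandwidths for an (n, d) point array.

    Degenerate (zero-variance) dimensions get a small positive floor so the
    KDE remains a proper density.
    """
    pts = np.atleast_2d(points)
    n = pts.shape[0]
    factor = n ** (-1.0 / (n_dims + 4))
    std = pts.std(axis=0, ddof=1) if n > 1 else np.zeros(pts.shape[1])
    return np.maximum(factor * std, _BW_FLOOR)


def cdf_bandwidth(points: np.ndarray) -> float:
    """Smoothed-bootstrap bandwidth (sigma * n^-1/3) for sampled dimensions.

    Dimensions the simulator *samples* from are judged by distribution-
    function distance, not density error; the n^-1/3 rate keeps the smoothed
    empirical CDF within sampling noise of the training CDF, where Scott's
    density-optimal n^-1/5 rate would visibly displace it.
    """
    x = np.asarray(points, dtype=float)
    if x.size < 2:
        return _BW_FLOOR
    return float(max(x.std(ddof=1) * x.size ** (-1.0 / 3.0), _BW_FLOOR))


@dataclass(eq=False)
class LengthModel:
    """KDE training points + bandwidths for read anatomy sampling."""

    joint_log_length: np.ndarray   # log10 source-transcript length
    joint_ratio: np.ndarray        # aligned span / transcript length, in (0,1]
    joint_bandwidth: tuple[float, float]
    flank_head: np.ndarray         # log1p head flank length
    flank_tail: np.ndarray         # log1p tail flank length
    flank_bandwidth: tuple[float, float]
    unaligned_log_length: np.ndarray  # log10 length of fully unaligned reads
    unaligned_bandwidth: float
    n_training: int

    def __post_init__(self):
        self.joint_log_length = np.asarray(self.joint_log_length, dtype=float)
        self.joint_ratio = np.asarray(self.joint_ratio, dtype=float)
        self.flank_head = np.asarray(self.flank_head, dtype=float)
        self.flank_tail = np.asarray(self.flank_tail, dtype=float)
        self.unaligned_log_length = np.asarray(self.unaligned_log_length, dtype=float)
        if self.joint_ratio.size and not (
            (self.joint_ratio > 0).all() and (self.joint_ratio <= 1).all()
        ):
            raise ValueError("aligned ratios must lie in (0, 1]")
        if min(self.joint_bandwidth) <= 0 or min(self.flank_bandwidth) <= 0:
            raise ValueError("bandwidths must be positive")
        # moments for variance-corrected smoothed-bootstrap sampling
        self._flank_moments = (
            _moments(self.flank_head), _moments(self.flank_tail),
        )
        self._unaligned_moments = _moments(self.unaligned_log_length)

    def __eq__(self, other):
        if not isinstance(other, LengthModel):
            return NotImplemented
        return (
            np.array_equal(self.joint_log_length, other.joint_log_length)
            and np.array_equal(self.joint_ratio, other.joint_ratio)
            and tuple(self.joint_bandwidth) == tuple(other.joint_bandwidth)
            and np.array_equal(self.flank_head, other.flank_head)
            and np.array_equal(self.flank_tail, other.flank_tail)
            and tuple(self.flank_bandwidth) == tuple(other.flank_bandwidth)
            and np.array_equal(self.unaligned_log_length, other.unaligned_log_length)
            and self.unaligned_bandwidth == other.unaligned_bandwidth
            and self.n_training == other.n_training
        )


@dataclass
class StrandStats:
    strand_ratio: float
    n: int

    def __post_init__(self):
        if not (0.0 <= self.strand_ratio <= 1.0):
            raise ValueError("strand_ratio must be in [0,1]")


def fit_length_model(
    alignments: Iterable[AlignmentRecord],
    transcript_lengths: dict[str, int],
    unaligned_lengths: Sequence[int] = (),
    max_points: int = 20000,
) -> LengthModel:
    """Fit the joint, flank and unaligned-length KDEs from primary alignments.

    ``unaligned_lengths`` are the raw lengths of training reads with no
    alignment (may be empty). Refuses with fewer than 30 aligned reads.
    Observed ratios > 1 (alignment artefacts) are clipped to 1 with a warning.
    """
    log_lt, ratios, heads, tails = [], [], [], []
    n_clipped = 0
    for a in alignments:
        if not a.is_primary:
            continue
        lt = transcript_lengths.get(a.target_id)
        if lt is None:
            raise KeyError(f"no transcript length for {a.target_id}")
        if lt <= 0:
            raise ValueError(f"transcript {a.target_id} has length {lt}")
        ratio = a.aligned_target_span / lt
        if ratio > 1.0:
            ratio = 1.0
            n_clipped += 1
        if ratio <= 0:
            continue
        log_lt.append(np.log10(lt))
        ratios.append(ratio)
        # flanks in the transcript-sense frame: for '-' alignments the stored
        # read's prefix is the sense-frame tail and vice versa
        if a.strand == "+":
            head, tail = a.query_start, a.query_length - a.query_end
        else:
            head, tail = a.query_length - a.query_end, a.query_start
        heads.append(np.log1p(head))
        tails.append(np.log1p(tail))
    if n_clipped:
        warnings.warn(f"clipped {n_clipped} aligned ratios > 1 to 1.0")
    n = len(ratios)
    if n < MIN_TRAINING_READS:
        raise ValueError(
            f"need >= {MIN_TRAINING_READS} aligned training reads, got {n}"
        )

    log_lt = np.array(log_lt)
    ratios = np.array(ratios)
    heads = np.array(heads)
    tails = np.array(tails)
    if n > max_points:  # cap stored points; deterministic subsample
        idx = np.random.default_rng(0).choice(n, size=max_points, replace=False)
        idx.sort()
        log_lt, ratios, heads, tails = (
            log_lt[idx], ratios[idx], heads[idx], tails[idx],
        )

    # conditioning dimension (transcript length): Scott's rule; sampled
    # dimensions (ratio, flanks, unaligned): CDF-consistent bootstrap rate
    joint_bw_x = float(scott_bandwidth(log_lt[:, None], 1)[0])
    ua = np.log10(np.asarray([max(1, x) for x in unaligned_lengths], dtype=float)) \
        if len(unaligned_lengths) else np.empty(0)
    ua_bw = cdf_bandwidth(ua) if ua.size else _BW_FLOOR

    return LengthModel(
        joint_log_length=log_lt,
        joint_ratio=ratios,
        joint_bandwidth=(joint_bw_x, cdf_bandwidth(ratios)),
        flank_head=heads,
        flank_tail=tails,
        flank_bandwidth=(cdf_bandwidth(heads), cdf_bandwidth(tails)),
        unaligned_log_length=ua,
        unaligned_bandwidth=ua_bw,
        n_training=int(len(ratios)),
    )


def _conditional_weights(model: LengthModel, log_lt: float) -> np.ndarray:
    hx = model.joint_bandwidth[0]
    z = (log_lt - model.joint_log_length) / hx
    w = np.exp(-0.5 * z * z)
    s = w.sum()
    if s <= 1e-300:
        # query far outside the training range: fall back to the nearest points
        order = np.argsort(np.abs(z))[: min(50, z.size)]
        w = np.zeros_like(w)
        w[order] = 1.0
        s = w.sum()
    return w / s


def sample_aligned_ratio(model: LengthModel, transcript_length: int,
                         rng: np.random.Generator) -> float:
    """Draw an aligned ratio from the joint KDE conditional on the length."""
    if transcript_length < 1:
        raise ValueError("transcript_length must be >= 1")
    w = _conditional_weights(model, np.log10(transcript_length))
    hy = model.joint_bandwidth[1]
    cdf = np.cumsum(w)
    for _ in range(_MAX_REJECTIONS):
        i = int(np.searchsorted(cdf, rng.random()))
        i = min(i, model.joint_ratio.size - 1)
        ratio = model.joint_ratio[i] + rng.normal(0.0, hy)
        if 0.0 < ratio <= 1.0 and round(ratio * transcript_length) >= 1:
            return float(ratio)
    warnings.warn("KDE ratio rejection limit reached; resampling empirically")
    i = int(np.searchsorted(cdf, rng.random()))
    return float(np.clip(model.joint_ratio[min(i, model.joint_ratio.size - 1)],
                         1.0 / transcript_length, 1.0))


def sample_read_anatomy(model: LengthModel, transcript_length: int,
                        rng: np.random.Generator) -> tuple[int, int, int]:
    """Sample (head_len, aligned_len, tail_len) for one read.

    ``aligned_len = round(ratio * transcript_length)`` with the ratio drawn
    conditionally on log10 transcript length; head/tail drawn jointly from
    the flank KDE and rounded to non-negative integers.
    """
    ratio = sample_aligned_ratio(model, transcript_length, rng)
    aligned = max(1, int(round(ratio * transcript_length)))
    aligned = min(aligned, transcript_length)
    if model.flank_head.size:
        i = rng.integers(model.flank_head.size)
        (mh, sh), (mt, st) = model._flank_moments
        h = np.expm1(smoothed_draw(model.flank_head[i], mh, sh,
                                   model.flank_bandwidth[0], rng))
        t = np.expm1(smoothed_draw(model.flank_tail[i], mt, st,
                                   model.flank_bandwidth[1], rng))
        head = max(0, int(round(h)))
        tail = max(0, int(round(t)))
    else:
        head = tail = 0
    return head, aligned, tail


def sample_unaligned_length(model: LengthModel, rng: np.random.Generator) -> int:
    """Draw a fully-unaligned read length from its 1-D KDE."""
    if not model.unaligned_log_length.size:
        raise ValueError("model has no unaligned-length training points")
    i = rng.integers(model.unaligned_log_length.size)
    m, s = model._unaligned_moments
    x = smoothed_draw(model.unaligned_log_length[i], m, s,
                      model.unaligned_bandwidth, rng)
    return max(1, int(round(10.0 ** x)))


def infer_strand_stats(alignments: Iterable[AlignmentRecord]) -> StrandStats:
    """Fraction of primary alignments in the annotated sense direction.

    Transcriptome alignment strand '+' means the read ran in the same
    direction as the annotated transcript.
    """
    n = 0
    sense = 0
    for a in alignments:
        if not a.is_primary:
            continue
        n += 1
        if a.strand == "+":
            sense += 1
    if n == 0:
        raise ValueError("no primary alignments; cannot infer strand ratio")
    return StrandStats(strand_ratio=sense / n, n=n)
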