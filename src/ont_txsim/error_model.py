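"""Base-call error characterization and simulation.

Aligned reads are decomposed into an alternating walk of match stretches and
error events (mismatch / insertion / deletion). The model learns:

* per-type error rates per aligned reference base,
* event-length distributions — a Poisson/Geometric mixture for mismatches and
  Weibull/Geometric mixtures for insertions and deletions, fit by EM on
  integer lengths >= 1 (continuous densities discretized via CDF differences),
* a first-order Markov chain over consecutive error types, and
* a KDE over inter-error match-stretch lengths.

Unaligned reads are excluded from error-rate analysis.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .io_formats import AlignmentRecord, ReadEvent
from .length_strand_model import cdf_bandwidth

ERROR_TYPES = ("mis", "ins", "del")
_OP_TO_TYPE = {"X": "mis", "I": "ins", "D": "del"}
MIN_EVENTS_TOTAL = 500
MIN_EVENTS_PER_TYPE = 10
_EM_RESTARTS = 5
_EM_MAX_ITER = 300
_EM_TOL = 1e-9
_LEN_CAP = 10000  # support cap for mixture moments

_BASES = "ACGT"
_ALTERNATIVES = {
    b: "".join(c for c in _BASES if c != b) for b in _BASES
}
_ALTERNATIVES["N"] = _BASES


# ---------------------------------------------------------------------------
# Event extraction
# ---------------------------------------------------------------------------


@dataclass
class ErrorEventTable:
    """Per-read error events and match stretches plus aggregate counts."""

    per_read_events: list[list[tuple[str, int]]]
    match_lengths: list[int]
    aligned_ref_bases: int
    type_bases: dict[str, int]
    type_counts: dict[str, int]

    @property
    def rates(self) -> tuple[float, float, float]:
        if self.aligned_ref_bases == 0:
            return (0.0, 0.0, 0.0)
        return tuple(
            self.type_bases[t] / self.aligned_ref_bases for t in ERROR_TYPES
        )

    @property
    def n_events(self) -> int:
        return sum(self.type_counts.values())


def extract_error_events(alignments: Iterable[AlignmentRecord]) -> ErrorEventTable:
    """Decompose primary aligned reads into error events and match stretches.

    X runs become mismatches, I insertions, D deletions; M runs are match
    stretches (0-length stretches are recorded between abutting errors); N
    (splice) ops close the current segment without emitting an error.
    Rates are per aligned reference base (M+X+D).
    """
    per_read: list[list[tuple[str, int]]] = []
    matches: list[int] = []
    type_bases = {t: 0 for t in ERROR_TYPES}
    type_counts = {t: 0 for t in ERROR_TYPES}
    ref_bases = 0
    for a in alignments:
        if not a.is_primary:
            continue
        events: list[tuple[str, int]] = []
        last_was_error = True  # a leading error implies an empty leading match
        for op, n in a.edit_walk:
            if op == "M":
                matches.append(n)
                ref_bases += n
                last_was_error = False
            elif op == "N":
                last_was_error = True
            elif op in _OP_TO_TYPE:
                if last_was_error and events:
                    matches.append(0)
                t = _OP_TO_TYPE[op]
                events.append((t, n))
                type_bases[t] += n
                type_counts[t] += 1
                if op in ("X", "D"):
                    ref_bases += n
                last_was_error = True
            else:
                raise ValueError(f"unresolved edit op {op!r} in {a.query_id}")
        per_read.append(events)
    return ErrorEventTable(
        per_read_events=per_read,
        match_lengths=matches,
        aligned_ref_bases=ref_bases,
        type_bases=type_bases,
        type_counts=type_counts,
    )


def measure_segment_lengths(alignments: Iterable[AlignmentRecord]) -> dict[str, Counter]:
    """Histograms of consecutive match/error base-stretch lengths.

    Evaluation utility for comparing empirical vs simulated alignments;
    histogram totals equal the event counts of :func:`extract_error_events`.
    """
    table = extract_error_events(alignments)
    out = {"match": Counter(table.match_lengths)}
    for t in ERROR_TYPES:
        out[t] = Counter()
    for events in table.per_read_events:
        for t, n in events:
            out[t][n] += 1
    return out


# ---------------------------------------------------------------------------
# Length mixtures
# ---------------------------------------------------------------------------


def _geom_logpmf(lengths: np.ndarray, p: float) -> np.ndarray:
    # support {1, 2, ...}
    p = min(max(p, 1e-12), 1 - 1e-12)
    return np.log(p) + (lengths - 1) * np.log1p(-p)


def _pois_trunc_logpmf(lengths: np.ndarray, lam: float) -> np.ndarray:
    # Poisson conditioned on >= 1
    lam = max(lam, 1e-12)
    base = stats.poisson.logpmf(lengths, lam)
    return base - np.log1p(-math.exp(-lam)) if lam > 1e-10 else base

def _weib_sf(x, shape: float, scale: float):
    return np.exp(-np.power(x / scale, shape))


def _weib_disc_logpmf(lengths: np.ndarray, shape: float, scale: float) -> np.ndarray:
    # continuous Weibull discretized by CDF differences on [l-0.5, l+0.5),
    # renormalized to support >= 1
    shape = min(max(shape, 1e-6), 50.0)
    scale = max(scale, 1e-6)
    pm = _weib_sf(lengths - 0.5, shape, scale) - _weib_sf(lengths + 0.5, shape, scale)
    z = _weib_sf(0.5, shape, scale)
    pm = np.maximum(pm / max(z, 1e-300), 1e-300)
    return np.log(pm)


def _geom_mle(lengths: np.ndarray, weights: np.ndarray) -> float:
    tot = weights.sum()
    if tot <= 0:
        return 0.5
    mean = (weights * lengths).sum() / tot
    return float(min(max(1.0 / mean, 1e-9), 1.0))


def _pois_trunc_mle(lengths: np.ndarray, weights: np.ndarray) -> float:
    tot = weights.sum()
    if tot <= 0:
        return 1.0
    m = (weights * lengths).sum() / tot
    if m <= 1.0 + 1e-12:
        return 1e-6
    f = lambda lam: lam / (1.0 - math.exp(-lam)) - m
    return float(optimize.brentq(f, 1e-9, max(m * 2, 1.0)))


def _weib_disc_mle(lengths: np.ndarray, weights: np.ndarray,
                   init: tuple[float, float]) -> tuple[float, float]:
    def nll(logparams):
        k, lam = np.exp(logparams)
        return -(weights * _weib_disc_logpmf(lengths, k, lam)).sum()

    # warm-started from the previous EM iteration, so few steps are needed
    res = optimize.minimize(
        nll, np.log(np.asarray(init)), method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 60},
    )
    k, lam = np.exp(res.x)
    return float(k), float(lam)


def _em_mixture(lengths: np.ndarray, counts: np.ndarray, kind: str,
                rng: np.random.Generator) -> dict:
    """EM fit of a 2-component mixture (Poisson|Weibull + Geometric) with restarts."""
    n = counts.sum()
    mean = (counts * lengths).sum() / n

    def logpmf_a(params):
        if kind == "poisson":
            return _pois_trunc_logpmf(lengths, params[0])
        return _weib_disc_logpmf(lengths, params[0], params[1])

    best = None
    for _ in range(_EM_RESTARTS):
        w = rng.uniform(0.2, 0.8)
        if kind == "poisson":
            params_a = [max(mean * rng.uniform(0.5, 1.5), 0.05)]
        else:
            params_a = [rng.uniform(0.7, 2.0), max(mean * rng.uniform(0.5, 1.5), 0.1)]
        p_geom = min(max((1.0 / mean) * rng.uniform(0.5, 1.5), 1e-6), 1 - 1e-6)
        ll_prev = -np.inf
        for _it in range(_EM_MAX_ITER):
            la = logpmf_a(params_a) + np.log(max(w, 1e-300))
            lb = _geom_logpmf(lengths, p_geom) + np.log(max(1 - w, 1e-300))
            m = np.maximum(la, lb)
            lse = m + np.log(np.exp(la - m) + np.exp(lb - m))
            ll = (counts * lse).sum()
            r = np.exp(la - lse)  # responsibility of component A
            wa = counts * r
            wb = counts * (1 - r)
            w = wa.sum() / n
            if wa.sum() > 1e-9:
                if kind == "poisson":
                    params_a = [_pois_trunc_mle(lengths, wa)]
                else:
                    params_a = list(_weib_disc_mle(lengths, wa, tuple(params_a)))
            if wb.sum() > 1e-9:
                p_geom = _geom_mle(lengths, wb)
            if ll - ll_prev < _EM_TOL * (abs(ll_prev) + 1):
                break
            ll_prev = ll
        if best is None or ll > best[0]:
            best = (ll, w, list(params_a), p_geom)

    _, w, params_a, p_geom = best
    if kind == "poisson":
        return {"w": float(w), "lam": float(params_a[0]), "p": float(p_geom)}
    return {"w": float(w), "shape": float(params_a[0]),
            "scale": float(params_a[1]), "p": float(p_geom)}


def fit_length_mixture(lengths: Sequence[int], kind: str,
                       rng: np.random.Generator | None = None) -> dict:
    """Fit one event-length mixture. ``kind`` is "poisson" or "weibull".

    Fewer than 10 events -> pure Geometric MLE fallback; all lengths equal 1
    -> degenerate pure Geometric with p = 1 (with a warning).
    """
    counter = Counter(int(x) for x in lengths)
    if any(l < 1 for l in counter):
        raise ValueError("event lengths must be >= 1")
    ls = np.array(sorted(counter), dtype=float)
    cs = np.array([counter[int(l)] for l in ls], dtype=float)
    n = int(cs.sum())
    base = {"w": 0.0, "lam": 1.0} if kind == "poisson" else \
        {"w": 0.0, "shape": 1.0, "scale": 1.0}
    if n == 0:
        return {**base, "p": 1.0}
    if ls.size == 1 and ls[0] == 1.0:
        warnings.warn("all event lengths equal 1; degenerate Geometric(p=1) fit")
        return {**base, "p": 1.0}
    if n < MIN_EVENTS_PER_TYPE:
        return {**base, "p": _geom_mle(ls, cs)}
    if rng is None:
        rng = np.random.default_rng(12345)
    return _em_mixture(ls, cs, kind, rng)


def mixture_pmf(mix: dict, lengths: np.ndarray) -> np.ndarray:
    """Mixture pmf over integer lengths >= 1."""
    lengths = np.asarray(lengths, dtype=float)
    pb = np.exp(_geom_logpmf(lengths, mix["p"]))
    if mix["w"] == 0.0:
        return pb
    if "lam" in mix:
        pa = np.exp(_pois_trunc_logpmf(lengths, mix["lam"]))
    else:
        pa = np.exp(_weib_disc_logpmf(lengths, mix["shape"], mix["scale"]))
    return mix["w"] * pa + (1.0 - mix["w"]) * pb


def mixture_mean(mix: dict) -> float:
    ls = np.arange(1, _LEN_CAP + 1, dtype=float)
    pm = mixture_pmf(mix, ls)
    return float((pm * ls).sum() / pm.sum())


def sample_mixture_length(mix: dict, rng: np.random.Generator) -> int:
    if rng.random() >= mix["w"]:
        return int(rng.geometric(min(max(mix["p"], 1e-12), 1.0)))
    if "lam" in mix:
        for _ in range(1000):
            x = rng.poisson(mix["lam"])
            if x >= 1:
                return int(x)
        return 1
    for _ in range(1000):
        x = int(round(mix["scale"] * rng.weibull(mix["shape"])))
        if x >= 1:
            return x
    return 1


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class ErrorModel:
    """Fitted error-mode model; see the module docstring for components."""

    rates: tuple[float, float, float]  # (mis, ins, del) per aligned ref base
    mismatch_mixture: dict
    ins_mixture: dict
    del_mixture: dict
    match_points: np.ndarray  # log1p match-stretch lengths (KDE training)
    match_bandwidth: float
    markov: np.ndarray  # 3x3 row-stochastic, order (mis, ins, del)
    pi: np.ndarray  # initial error-type distribution
    n_events: dict = field(default_factory=dict)

    def __post_init__(self):
        self.markov = np.asarray(self.markov, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.match_points = np.asarray(self.match_points, dtype=float)
        if self.markov.shape != (3, 3):
            raise ValueError("markov must be 3x3")
        if not np.allclose(self.markov.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("markov rows must sum to 1")
        if not math.isclose(self.pi.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("pi must sum to 1")
        mis, ins, dele = self.rates
        if not all(0.0 <= r < 1.0 for r in self.rates) or mis + dele > 1.0:
            raise ValueError(f"invalid rates {self.rates}")
        from .length_strand_model import _moments

        self._match_moments = _moments(self.match_points)

    def __eq__(self, other):
        if not isinstance(other, ErrorModel):
            return NotImplemented
        return (
            tuple(self.rates) == tuple(other.rates)
            and self.mismatch_mixture == other.mismatch_mixture
            and self.ins_mixture == other.ins_mixture
            and self.del_mixture == other.del_mixture
            and np.array_equal(self.match_points, other.match_points)
            and self.match_bandwidth == other.match_bandwidth
            and np.array_equal(self.markov, other.markov)
            and np.array_equal(self.pi, other.pi)
        )

    # -- serialization ------------------------------------------------------

    def mixtures_dict(self) -> dict:
        return {
            "rates": [float(r) for r in self.rates],
            "mismatch": self.mismatch_mixture,
            "ins": self.ins_mixture,
            "del": self.del_mixture,
            "pi": [float(x) for x in self.pi],
            "match_bandwidth": float(self.match_bandwidth),
            "n_events": {k: int(v) for k, v in self.n_events.items()},
        }

    @classmethod
    def from_dicts(cls, mix: dict, markov: np.ndarray, match_points: np.ndarray
                   ) -> "ErrorModel":
        return cls(
            rates=tuple(mix["rates"]),
            mismatch_mixture=mix["mismatch"],
            ins_mixture=mix["ins"],
            del_mixture=mix["del"],
            match_points=match_points,
            match_bandwidth=mix["match_bandwidth"],
            markov=markov,
            pi=np.array(mix["pi"]),
            n_events=mix.get("n_events", {}),
        )

    # -- sampling -----------------------------------------------------------

    def _mixture(self, typ: str) -> dict:
        return {
            "mis": self.mismatch_mixture,
            "ins": self.ins_mixture,
            "del": self.del_mixture,
        }[typ]

    def sample_length(self, typ: str, rng: np.random.Generator) -> int:
        return sample_mixture_length(self._mixture(typ), rng)

    def sample_match(self, rng: np.random.Generator) -> int:
        if not self.match_points.size:
            return 0
        from .length_strand_model import smoothed_draw

        i = rng.integers(self.match_points.size)
        m, s = self._match_moments
        x = np.expm1(smoothed_draw(self.match_points[i], m, s,
                                   self.match_bandwidth, rng))
        return max(0, int(round(x)))

    def sample_first_type(self, rng: np.random.Generator) -> str:
        return ERROR_TYPES[int(np.searchsorted(np.cumsum(self.pi), rng.random()))]

    def sample_next_type(self, current: str, rng: np.random.Generator) -> str:
        row = self.markov[ERROR_TYPES.index(current)]
        return ERROR_TYPES[int(np.searchsorted(np.cumsum(row), rng.random()))]


def fit_error_model(table: ErrorEventTable, max_match_points: int = 50000) -> ErrorModel:
    """Fit the full error model from an extracted event table.

    Mixtures by EM with 5 random restarts (best log-likelihood kept); the
    Markov transition matrix by row-normalized bigram counts with add-one
    smoothing; pi as the empirical first-error distribution; the match-stretch
    KDE on log1p scale with Scott's-rule bandwidth.
    """
    if table.n_events < MIN_EVENTS_TOTAL:
        raise ValueError(
            f"need >= {MIN_EVENTS_TOTAL} error events to fit, got {table.n_events}"
        )
    lengths_by_type: dict[str, list[int]] = {t: [] for t in ERROR_TYPES}
    for events in table.per_read_events:
        for t, n in events:
            lengths_by_type[t].append(n)

    rng = np.random.default_rng(12345)  # fitting is deterministic given data
    mis_mix = fit_length_mixture(lengths_by_type["mis"], "poisson", rng)
    ins_mix = fit_length_mixture(lengths_by_type["ins"], "weibull", rng)
    del_mix = fit_length_mixture(lengths_by_type["del"], "weibull", rng)

    bigrams = np.ones((3, 3))  # add-one smoothing
    firsts = np.zeros(3)
    for events in table.per_read_events:
        if events:
            firsts[ERROR_TYPES.index(events[0][0])] += 1
        for (t0, _), (t1, _) in zip(events, events[1:]):
            bigrams[ERROR_TYPES.index(t0), ERROR_TYPES.index(t1)] += 1
    markov = bigrams / bigrams.sum(axis=1, keepdims=True)
    pi = firsts / firsts.sum() if firsts.sum() else np.full(3, 1 / 3)

    pts = np.log1p(np.asarray(table.match_lengths, dtype=float))
    if pts.size > max_match_points:
        idx = np.random.default_rng(0).choice(pts.size, max_match_points, replace=False)
        idx.sort()
        pts = pts[idx]
    bw = cdf_bandwidth(pts)

    return ErrorModel(
        rates=table.rates,
        mismatch_mixture=mis_mix,
        ins_mixture=ins_mix,
        del_mixture=del_mix,
        match_points=pts,
        match_bandwidth=bw,
        markov=markov,
        pi=pi,
        n_events=dict(table.type_counts),
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def sample_error_layout(
    model: ErrorModel,
    aligned_ref_len: int,
    rng: np.random.Generator,
    masked_intervals: Sequence[tuple[int, int]] = (),
) -> list[tuple[str, int, int]]:
    """Sample an ordered error layout over ``aligned_ref_len`` reference bases.

    Alternates match stretches (from the match KDE) with error events (type
    from the Markov chain, length from that type's mixture) until the
    reference is consumed; the final event is truncated to fit. Insertions
    consume no reference; a match of >= 1 base is forced after an insertion
    so the process always progresses. ``masked_intervals`` (e.g. modified
    homopolymer runs, in template coordinates) receive plain match stretches
    and no errors.

    Returns (type, length, ref_offset) tuples, type in
    {"match", "mis", "ins", "del"}.
    """
    if aligned_ref_len < 1:
        raise ValueError("aligned_ref_len must be >= 1")
    if model.rates == (0.0, 0.0, 0.0):
        return [("match", aligned_ref_len, 0)]

    segments: list[tuple[int, int, bool]] = []
    cursor = 0
    for s, e in sorted(masked_intervals):
        s, e = max(0, s), min(aligned_ref_len, e)
        if s > cursor:
            segments.append((cursor, s, False))
        if e > s:
            segments.append((s, e, True))
        cursor = max(cursor, e)
    if cursor < aligned_ref_len:
        segments.append((cursor, aligned_ref_len, False))

    layout: list[tuple[str, int, int]] = []
    prev_type: str | None = None
    for seg_start, seg_end, masked in segments:
        if masked:
            layout.append(("match", seg_end - seg_start, seg_start))
            continue
        s_len = seg_end - seg_start
        consumed = 0
        force_match = False
        while consumed < s_len:
            m = model.sample_match(rng)
            if force_match:
                m = max(1, m)
            m = min(m, s_len - consumed)
            if m > 0:
                layout.append(("match", m, seg_start + consumed))
                consumed += m
            force_match = False
            if consumed >= s_len:
                break
            if prev_type is None:
                typ = model.sample_first_type(rng)
            else:
                typ = model.sample_next_type(prev_type, rng)
            prev_type = typ
            n = model.sample_length(typ, rng)
            if typ == "ins":
                if layout and layout[-1][0] == "ins":  # merge consecutive insertions
                    t, n0, off = layout[-1]
                    layout[-1] = (t, n0 + n, off)
                else:
                    layout.append(("ins", n, seg_start + consumed))
                force_match = True
            else:
                n = min(n, s_len - consumed)
                layout.append((typ, n, seg_start + consumed))
                consumed += n
    # merge adjacent matches across segment boundaries
    merged: list[tuple[str, int, int]] = []
    for typ, n, off in layout:
        if merged and typ == "match" and merged[-1][0] == "match" \
                and merged[-1][2] + merged[-1][1] == off:
            merged[-1] = ("match", merged[-1][1] + n, merged[-1][2])
        else:
            merged.append((typ, n, off))
    return merged


def layout_ref_consumption(layout: Sequence[tuple[str, int, int]]) -> int:
    return sum(n for typ, n, _ in layout if typ in ("match", "mis", "del"))


def apply_errors(template_seq: str, layout: Sequence[tuple[str, int, int]],
                 rng: np.random.Generator) -> tuple[str, list[ReadEvent]]:
    """Apply an error layout to a template sequence.

    Mismatched bases are substituted uniformly among the 3 alternatives
    (independently per base); inserted bases are uniform over ACGT. Returns
    the read sequence and replayable event records (ref offsets on the
    template, read positions on the growing read).
    """
    if layout_ref_consumption(layout) != len(template_seq):
        raise ValueError(
            f"layout consumes {layout_ref_consumption(layout)} bases, "
            f"template has {len(template_seq)}"
        )
    out: list[str] = []
    events: list[ReadEvent] = []
    ti = 0
    read_pos = 0
    for typ, n, _off in layout:
        if typ == "match":
            out.append(template_seq[ti : ti + n])
            ti += n
            read_pos += n
        elif typ == "mis":
            new = "".join(
                _ALTERNATIVES[b][rng.integers(len(_ALTERNATIVES[b]))]
                for b in template_seq[ti : ti + n]
            )
            events.append(ReadEvent("mis", read_pos, ti, n, bases=new))
            out.append(new)
            ti += n
            read_pos += n
        elif typ == "del":
            events.append(
                ReadEvent("del", read_pos, ti, n, bases=template_seq[ti : ti + n])
            )
            ti += n
        elif typ == "ins":
            new = "".join(_BASES[i] for i in rng.integers(4, size=n))
            events.append(ReadEvent("ins", read_pos, ti, n, bases=new))
            out.append(new)
            read_pos += n
        else:
            raise ValueError(f"unknown layout op {typ!r}")
    return "".join(out), events
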