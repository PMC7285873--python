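# Methods

`ont-txsim` models an ONT transcriptome sequencing experiment as a
composition of independent stochastic layers applied to a reference
molecule. This note documents each layer, the estimation procedure, the
defaults and why, what the synthetic corpora do and do not emulate, and the
numerical choices that matter for reproducibility.

## Read anatomy

A nanopore read usually covers only part of its source molecule, and the
attainable aligned length depends on the molecule's length. We therefore
model the *aligned ratio* r = (aligned reference span) / (molecule length)
jointly with log₁₀ molecule length as a 2-D Gaussian KDE over training
pairs, and sample r conditionally on the molecule length by kernel-weighted
resampling of training points in the length dimension followed by Gaussian
jitter in the ratio dimension, rejecting until r ∈ (0, 1]. Ratios observed
above 1 in training (alignment artefacts) are clipped to 1 with a warning: a
read cannot be longer than its (IR-expanded) source molecule.

Unaligned head/tail flanks are modelled as a 2-D KDE on log1p scale
(strictly positive, heavy-tailed quantities), and the lengths of reads with
no alignment at all as a 1-D KDE on log₁₀ scale. Flanks are defined in the
*transcript-sense frame*: for a minus-strand alignment the stored read's
prefix is the sense-frame tail. The simulator attaches flanks in the sense
frame before reverse-complementing antisense reads, so characterization and
simulation use one consistent frame.

Bandwidths: the conditioning dimension (log length) uses Scott's rule.
Dimensions that are *sampled from* (ratio, flanks, unaligned lengths, match
stretches) use σ·n^(−1/3): sampling fidelity is judged by CDF distance, and
the density-optimal Scott rate visibly displaces the smoothed CDF at the
training sizes involved (10³–10⁵ points). Sampling uses a variance-corrected
smoothed bootstrap (resample a training point, add kernel noise, rescale
about the training mean) so the simulated distribution matches the training
distribution in location and spread, not just shape. Zero-variance
dimensions get a 10⁻³ bandwidth floor.

The aligned span is 3′-anchored on the molecule by default (direct RNA
library chemistry sequences from the 3′ end); `--uniform-start` switches to
a uniform start position (cDNA). This anchoring choice is an assumption, not
something the alignments themselves pin down, which is why it is a flag.

The strand ratio is the fraction of primary transcriptome alignments in the
annotated sense orientation; each simulated read is antisense with
probability 1 − strand_ratio, implemented as a reverse complement of the
finished sense read so that truth coordinates live in a single frame.

## Base-call errors

Aligned reads are decomposed into an alternating walk: match stretch, error
event, match stretch, ... where an error event is a maximal run of
mismatches (X), insertions (I) or deletions (D). Splice (N) operations close
the current segment without emitting an event. Rates are per aligned
reference base (M+X+D). Unaligned reads are excluded from error analysis
(their source is untraceable); they are simulated separately at a flat 90%
per-base error rate, split evenly between single-base mismatches,
insertions and deletions. The 90% default is deliberately extreme — these
reads exist to exercise downstream filters, not to be alignable.

Event lengths ≥ 1 follow two-component mixtures: Poisson+Geometric for
mismatches, Weibull+Geometric for insertions and deletions. Continuous
densities are discretized by CDF differences on [ℓ−0.5, ℓ+0.5), renormalized
to support ≥ 1; the Poisson is truncated at ≥ 1. Mixtures are fit by EM on
(length, count) pairs with 5 random restarts (internal fixed seed, so the
fit is a deterministic function of the data), keeping the best
log-likelihood. M-steps: closed form for the Geometric; 1-D root-finding for
the truncated-Poisson mean equation; Nelder-Mead (warm-started, 60
iterations) for the discretized Weibull. Degenerate inputs: all lengths
equal 1 collapses to Geometric(p=1) with a warning; fewer than 10 events of
a type falls back to the Geometric MLE. Mixture *parameters* are weakly
identified when the components overlap; the mixture *mean and shape* are
what recovery tests assert.

Consecutive error types follow a first-order Markov chain: row-normalized
bigram counts with add-one smoothing (so never-observed conditioning states
yield uniform rows), with the initial distribution π taken from first errors
per read. Simulation alternates: match length from the match KDE, type from
the chain, length from that type's mixture, until the aligned span is
consumed; the final event is truncated to fit. After an insertion a match of
at least one base is forced, which guarantees termination and prevents
adjacent insertions from merging.

Substituted bases are uniform over the 3 alternatives, independently per
base within a multi-base mismatch; inserted bases are uniform over ACGT. No
sequence-context dependence is modelled.

## Intron retention

For each read, the best (most matched bases) primary transcriptome
alignment assigns its transcript; the genomic alignment then informs the
transcript's introns (ordered 5′→3′ in transcript orientation, i.e.
reversed relative to genomic order for minus-strand transcripts). An intron
is called *retained* when M/X blocks cover ≥ 90% of its span and no N
operation overlaps it; an overlapping N calls it *spliced*; introns outside
the read's genomic span, or inside the span but below the coverage
threshold without an N, are *uncovered* and uninformative. The 90%
threshold tolerates alignment edge wobble while excluding splice-junction
overhangs; it is a constant in `ir_model.py`.

The chain has three parameters: p_first (retention of the transcript's
first intron), and retention probabilities conditional on the previous
intron's state. Transitions are counted over consecutive *covered* pairs
only — uncovered introns break chains rather than being imputed — with
add-one smoothing when a conditioning state has fewer than 5 counts.

Template expansion inserts each retained intron's genomic sequence at its
junction (reverse-complemented for minus-strand transcripts), so template
length always equals transcript length plus the summed retained intron
lengths. IR expansion happens *before* anatomy sampling: retained introns
physically lengthen the molecule, so the aligned ratio applies to the
expanded template.

## Homopolymers

Base callers systematically contract (and occasionally expand) homopolymer
runs. For each reference run of length L ≥ min_len (default 5, flag
`--hp-min-len`), the read-side run length is measured from the alignment as
L minus deletions inside the run plus insertions strictly inside the run
(only insertions of the run's own base when read sequences are available —
a foreign inserted base interrupts rather than extends a run). Runs
truncated by alignment boundaries are skipped.

Per base, the mean read length is a continuous two-segment linear
regression of per-L group means (weighted by group size), with the integer
breakpoint chosen by SSE grid search over observed lengths and a plain line
allowed as the degenerate case; the SD is an ordinary least-squares line on
per-group sample SDs, clamped at ≥ 0.1. Bases with fewer than 30
observations fall back to an identity mean with SD 0.5, with a warning.

In simulation each run ≥ min_len is replaced by round(N(mean(L), sd(L)))
clamped at 0 (0 = run fully deleted); the modified run intervals are masked
from generic error placement, so the elevated indel rate inside
homopolymers is carried by this model alone and never double-counted. Error
layouts are generated per unmasked segment (the chain restarts at segment
boundaries — a deliberate simplification; segments are long relative to
typical inter-error distances).

## Expression

Transcript abundance is estimated by EM over a read-transcript
compatibility matrix: per read, alignments scoring ≥ 0.8 × the read's best
(matched-base count) are kept, secondaries included. E-step spreads each
read over its compatible transcripts ∝ τ; M-step re-estimates τ; iteration
stops when max|Δτ| < 10⁻⁶ or at 100 iterations. The EM is deterministic and
collapses identical compatibility classes, so cost scales with the number
of distinct classes, not reads.

TPM is *count-based* by default: one long read evidences one molecule, so
tpm_i = τ_i·10⁶ with no effective-length divisor. A `length` mode (divide
expected counts by transcript length before rescaling) is available for
comparison with short-read conventions. User-supplied profiles
(tab-delimited transcript_id/tpm) are renormalized to 10⁶ and filtered
against the reference with warnings.

## Simulation determinism and parallelism

Read *serial number* s under master seed S uses the RNG substream
`SeedSequence(entropy=S, spawn_key=(s,))`. Output is therefore a pure
function of (seed, inputs) and is byte-identical regardless of worker
count: multiprocessing partitions serial ranges across workers and
concatenates in order. The first ⌊n·unaligned_fraction⌉ serials are the
unaligned reads.

Each read's name encodes its provenance
(`transcript!strand!start!aligned_len!head!tail!serial!category`) and the
truth TSV carries one row per introduced event, including the flank bases
(`head`/`tail` rows) — the read-name convention alone cannot carry
byte-exact replay, and replaying truth rows over the recorded template
interval must reconstruct every read exactly. `reconstruct_read` implements
that replay and is tested exhaustively.

## Synthetic corpora

The fixture generator builds one gene per contig (2–5 exons of 120–400 nt,
introns 80–400 nt, ~30% minus-strand), log-normal TPM (σ = 1.5 natural log
— a realistic bulk RNA-seq spread of ~3 orders of magnitude), Beta(5, 2)
aligned ratios, geometric flanks (means 30/15 nt), strand ratio 0.85, and
an error process whose rank-one error-type chain and geometric match
stretches are solved analytically so the per-base rates hit their 5/3/3%
targets exactly in expectation. Background sequence is generated run-free
(no homopolymer longer than 2), so planted runs are provably the only runs
a finder can report; the known contraction law is mean 0.9·L, SD
0.05·L + 0.3. Match stretches are ≥ 1 so that error events never abut —
abutting same-type events merge in any alignment representation, which
would make the generating chain unidentifiable from data.

The generator emits reads together with their *exact* alignments by
construction, so recovery tests are hermetic and free of aligner noise, and
it shares no sampling code with the simulator — closed-loop tests
(characterize(generate(θ)) ≈ θ, and simulate → re-characterize) are genuine
cross-checks. What the corpora do **not** emulate: aligner errors and
mapping ambiguity between paralogs, sequence-context-dependent error rates,
expression-dependent length biases, poly(A) tails, adapters and barcodes.
Passing recovery tests therefore demonstrates the estimators are correct
and self-consistent, not that real ONT data obeys these parametric forms.

Problem sizes used by the test suite and acceptance script — 10⁴ reads
(~6×10⁶ aligned bases) for error/length/strand recovery, 2×10⁴ full-length
reads for IR, 3×10³ reads for homopolymers, 5×10⁴ reads over 500
transcripts for the expression loop, 10⁴ fully-featured reads for replay —
were chosen so that every recovery tolerance corresponds to ≥ 3 standard
errors at that scale while the whole suite stays desk-sized.

## Known limitations

- FASTA output only: no quality strings, signal-level (FAST5/POD5) output,
  or adapter/barcode simulation.
- Retention probabilities are shared across introns (chain-position only),
  not intron-identity-specific.
- The mismatch block substitutes independently per base; real miscalls at a
  given locus are correlated.
- Homopolymer agreement degrades for very long runs (> ~20 nt), which are
  rare in transcripts; the segmented mean model extrapolates its last
  segment linearly there.
- `detect_ir` trusts the aligner's splice (N) operations; spurious
  junctions in low-quality alignments propagate into retention calls.
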