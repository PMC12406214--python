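# Methods

## Signal model and simulator

A simulated direct RNA read is a piecewise process in raw sample space.
Four regions appear in signal order (the molecule threads 3'→5'):
sequencing adapter, RTA, poly(A) tail, transcript body. Region boundaries
are recorded 0-based, half-open, and tile every read exactly.

Current levels are Gaussian around per-region means in arbitrary pA-like
units (defaults: adapter 70 ± 4, RTA 88 ± 3.5, poly(A) 108 ± 2.2). The
transcript body is a sequence of per-nucleotide levels resampled from a
stationary distribution (mean 100, between-level SD 12, within-level SD
2.5), so it has the high level-to-level variance that distinguishes it
from the flat poly(A) plateau. The translocation rate *r* (samples/nt) is
drawn once per read from a truncated normal floored at 1 sample/nt; two
presets fix the mean to the motor speeds of the two current chemistries,
`rna002_config` (r = sampling_rate/70 ≈ 43 samples/nt at 3012 Hz) and
`rna004_config` (r = sampling_rate/130 ≈ 31 samples/nt at 4 kHz). The
poly(A) span is round(L·r) samples for a tail of L nt; the RTA span is
10·r samples, matching its 10 poly(T) positions, which is also why tails
under ~10 nt are at the method detection floor.

Artifact processes, each applied with a configurable per-read probability
(at most one truncating artifact per molecule):

- **degradation** — the tail is shortened by a geometric draw
  (mean `degradation_scale`, default 40 nt) capped at the tail length;
  the read's 3' end still maps to the reference 3' end (offset 0);
- **fragmentation** — the tail is removed and the body 3'-truncated at a
  random position, leaving a mapped-end offset > 20 nt;
- **mispriming** — the read starts at an internal A-rich site (every
  reference carries one planted six-adenine run at 40% of its length), so
  the apparent tail is 0–10 nt and the mapped end sits at that site;
- **split reads** — the molecule's samples are written as two consecutive
  reads on the same channel separated by a 0.2 s gap; the two parts
  conserve the parent's sample count.

No quantitative degradation/mispriming model is established for real
libraries, so these rates are exposed in `SimConfig` and default to 0;
study conditions set them explicitly. Reads carry an `AlignmentStub`
(reference id, mapped-end offset, mean qscore) instead of a real
alignment; what the simulator does **not** emulate is sequence-dependent
pore current (k-mer models), basecalling, RNA modifications, or
non-Gaussian noise such as stalls. Tests passing on this generator
therefore demonstrate algorithmic correctness of segmentation and
statistics, not end-to-end accuracy on real flowcell data.

Default problem sizes used by the test suite and the acceptance script —
500 reads per known length for recovery, 200 small reads for the decoder
oracle, 100 replicates for distributional claims, transcripts of 150 nt —
were chosen as the smallest sets at which the statistics of interest are
stable, and are all configurable.

## Standardization

All segmenters standardize each read to z = (x − median) / SD. The SD
scale (rather than a rank-based spread such as the MAD) is deliberate: a
150 nt tail at RNA002 rates puts nearly half the read's samples at one
constant level, which collapses the MAD toward the poly(A) noise floor
and explodes the z-scale, while the SD varies only mildly with
composition. Because read composition (tail length, truncation) still
shifts the per-read median, methods optionally re-anchor the z-scores so
that the median of the first samples — always sequencing adapter —
matches the adapter's expected level. Residual scale mismatch of ~0.3 z
remains, which is why the HMM's narrow states are widened (SD floors of
0.30–0.35 z). All methods are exactly invariant to multiplying a read's
current values by a constant.

`*_params_from_config` helpers convert a simulator config's raw-unit
levels to z-units using a deterministic "typical read" profile (expected
tail length, transcript levels at stationary-distribution quantiles), so
segmentation parameters are reproducible functions of the config.

## Segmentation

**HMM (`hmm_segment`).** Four states in a linear chain with no skips,
Gaussian emissions, per-state self-transition probability p, and minimum
durations enforced by expanding each state into duration copies
(transitions inside the minimum are deterministic). The decoded path must
start in the adapter and end in the transcript, so every read yields a
poly(A) span. Log-probability of a segmentation with durations d_s:

    Σ_t log N(x_t; μ_state(t), σ_state(t))
      + Σ_s (d_s − min_s) log p_s + Σ_{s<4} log(1 − p_s)

Viterbi decoding runs in a numba kernel, O(T·Σ min_s) per read; ties
break toward the earlier transition for determinism. `oracle_segment`
scores every admissible boundary triple directly (reads ≤ 300 samples)
and is used to verify that Viterbi attains the same maximum — the two
agree on all tested seeded reads.

**Sliding window (`window_segment`).** Pass 1 thresholds a 25-sample
moving average into a band (±0.5 z) around the expected poly(A) level and
keeps the longest surviving run. Pass 2 averages 25-sample bins inside
the clipped region (run ± one smoothing window) and shrinks the
boundaries while edge bins are out-of-band or the bin-to-bin slope
exceeds 0.15 z; a region whose interior slopes are mostly above the limit
is structureless noise and reported undetected. Finally the partial bins
lost to quantization (at most one per side) are recovered at sample
resolution under a tighter half-band criterion. Boundaries are accurate
to about one bin.

**Anchor-and-grow (`anchor_segment`).** The adapter end is detected as
the first trailing window whose mean enters the poly(A) band with
variance under the ceiling; the region is refined backward and grown
forward while the trailing-window mean tracks the running region mean
(±0.35 z), windowed variance stays under 0.25 z², and no sample jumps
more than max(0.3 z, 4.5× the robust in-region noise). Regions shorter
than 300 samples (≈ 7 nt at RNA002 rates) are reported undetected — this
method is deliberately the most conservative and discards short-tail
reads the HMM keeps, which is why cross-tool comparisons must first
intersect detected read sets.

## Tail length and QC

L = span / r, reported unrounded. The rate comes from the decoded
transcript region and the known covered transcript length (benchmark
mode); methods that do not segment the transcript fall back to the
simulator's annotated rate. QC is `pass`, `no_tail` (undetected), or
`rate_unavailable` (empty transcript region or nonpositive rate). With
true boundaries and rate, the error is bounded by the 1-sample rounding
of the span, i.e. 1/r nt.

## Evaluation statistics

**Density summaries.** Gaussian KDE with the Silverman/rule-of-thumb
bandwidth 0.9·min(SD, IQR/1.34)·n^(−1/5) (overridable), evaluated on a
fixed 513-point grid spanning the data range ± 4 bandwidths. The odd
point count places a grid point exactly at the value of a degenerate
sample, and the 4-bandwidth margin keeps the trapezoid integral within
10⁻³ of 1. `maxpeak` is the grid argmax (ties → smallest value);
read sets under 10 reads are rejected rather than summarized. The peak SD
is FWHM / 2√(2 ln 2), with the two half-height crossings found by walking
outward from the highest peak and interpolating linearly — distant minor
modes therefore cannot widen it. If the density never falls below
half-maximum inside the grid the width is undefined and an error is
raised.

**Windowed MAE.** Reads are partitioned in input order into
non-overlapping windows of N (incomplete trailing window dropped; maxpeak
windows require N ≥ 10); MAE is the mean over windows of
|statistic − known length|. Confidence intervals are percentile bootstrap:
reads are resampled with replacement within the known-length category and
re-windowed on each of B = 1000 resamples (resample-then-window; whether
windowing precedes resampling was an open choice and this order is the
one implemented). The reported interval is clipped to include the point
estimate. The two-tool test is two-sided on the bootstrap distribution of
the MAE difference centered at its mean; with B resamples the smallest
nonzero p is 1/B and a zero count is flagged as "< 1/B" rather than 0.

## Short-tail diagnostics

Reads with passing calls under 10 nt are classified exactly once:
`full_length` if the mapped 3' end is within 20 nt (inclusive — the
boundary convention chosen here) of the reference 3' end, else
`truncated`. Truncated reads are screened in the 10 reference nt
downstream of the mapped end (10 nt matching the RTA's poly(T) length):
flagged as mispriming-consistent when the longest adenine run is ≥ 4 or
the A fraction exceeds 0.5. Both thresholds are configurable (a stricter
0.6 content threshold is also in circulation); the flag is monotone in
both. Split pairs are consecutive reads on one channel with an inter-read
gap below `max_gap_seconds` (default 1 s, above the simulator's 0.2 s
emission gap and below its ≥ 2 s between-molecule gap), paired greedily
earliest-first with each read used once. Tail-quality association uses
Spearman rank correlation (average ranks for ties); constant inputs are
reported as not-applicable rather than a number.

## Known limitations

- Emission parameters are Gaussian per state; real pore noise is heavier
  tailed and autocorrelated.
- The anchor method's overestimation correction used by production
  basecallers is unspecified publicly and not implemented; its calls here
  are uncorrected.
- The window method's threshold and slope limits were calibrated on the
  simulator and are exposed in `WindowParams`; on real data they would
  need re-tuning.
- Rate estimation relies on a known transcript length (benchmark mode);
  there is no basecalling here to supply read lengths.
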