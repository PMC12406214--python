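# tailbench

Poly(A) tail length inference from nanopore-style raw current signal, with
the benchmarking machinery needed to evaluate it against known ground
truth.

mRNA poly(A) tail length regulates transcript stability and translation,
and direct RNA nanopore sequencing is the main high-throughput way to
measure it per molecule. A direct RNA read threads 3'→5' through the pore,
so its raw current trace consists of four regions in order: sequencing
adapter, reverse-transcription adapter (RTA, carrying 10 poly(T) bases),
the poly(A) tail, and the transcript body. Estimating a tail length means
(1) locating the poly(A) region in sample space and (2) converting its
span to nucleotides with the read-specific translocation rate *r* (raw
samples per nucleotide): **L = (end − start) / r**.

`tailbench` is aimed at developers and evaluators of poly(A) callers. It
provides:

- a **squiggle simulator** that emits four-region reads with known tails
  (10–150 nt), plus the artifact processes that contaminate real
  libraries with spuriously short tails: tail degradation, fragmentation,
  internal-site mispriming, and split reads;
- three **segmentation strategies** spanning the design space of published
  tools: a 4-state linear-chain HMM decoded by Viterbi (with an
  exhaustive-enumeration oracle to prove the decoder exact), a two-pass
  sliding-window/slope method, and a conservative anchor-and-grow method;
- the **evaluation statistics** used to benchmark callers: kernel-density
  summaries of a read set — the density mode ("maxpeak"), the median, and
  a main-peak SD from the full width at half-maximum
  (σ = FWHM / 2√(2 ln 2)) — and the windowed mean absolute error

  MAE = (1/W) Σ over windows |statistic(window of N reads) − known length|

  with percentile bootstrap confidence intervals and two-sided bootstrap
  tests (B = 1000 resamples, so the smallest reportable nonzero p is
  0.001);
- **short-tail diagnostics**: classify each sub-10 nt call as 3'-intact
  (degradation-consistent) or truncated, screen the 10 reference
  nucleotides downstream of a truncated read's mapped end for adenine runs
  or >50% A content (the mispriming signature), detect split reads from
  channel/start-time adjacency, and correlate tail length with read
  quality.

The maxpeak statistic exists because tail-length distributions from real
libraries are multimodal: a main peak near the true length plus a
short-tail contaminant peak. The contaminant drags medians and means; the
density mode is robust to it as long as the main peak holds a plurality of
the mass.

## Worked example

Simulate 300 reads with a known 60 nt tail where 45% of molecules carry a
degraded or fragmented (short) tail, call tails with the HMM, and compare
group-level averaging strategies:

```python
from dataclasses import replace
from tailbench.simulate import rna002_config, simulate_dataset
from tailbench.pipeline import estimate_dataset
from tailbench.evaluation import density_estimate, windowed_mae

cfg = replace(rna002_config(),
              tail_population=[(60.0, 1.0)],
              degradation_prob=0.3,
              fragmentation_prob=0.15)
ds = simulate_dataset(cfg, 300, seed=42)
est = estimate_dataset(ds, cfg, methods=("hmm",))
ok = est[est.qc == "pass"]

summary = density_estimate(ok.tail_nt)
print(f"median  = {summary.median:.1f} nt")
print(f"maxpeak = {summary.maxpeak:.1f} nt")
print(f"peak SD (FWHM) = {summary.fwhm_sd:.1f} nt")
print(f"MAE, median windows of 100:  {windowed_mae(ok.tail_nt, 60, 100, 'median').mae:.2f} nt")
print(f"MAE, maxpeak windows of 100: {windowed_mae(ok.tail_nt, 60, 100, 'maxpeak').mae:.2f} nt")
```

Output:

```
median  = 60.0 nt
maxpeak = 60.1 nt
peak SD (FWHM) = 8.2 nt
MAE, median windows of 100:  1.50 nt
MAE, maxpeak windows of 100: 0.39 nt
```

Both group-level averages sit at the true 60 nt, but the short-tail
contamination widens the peak (SD 8.2 nt) and biases the *windowed* median
(MAE 1.50 nt per window of 100 reads) four-fold relative to the windowed
maxpeak (0.39 nt) — the reason mode-based averaging is preferred for read
sets of ≥100 reads.

There is also a CLI that chains the stages on one dataset and writes TSV
artifacts plus a run log:

```bash
tailbench all --seed 5 --out-dir out/     # simulate→segment→estimate→evaluate→diagnose
tailbench simulate --n-reads 500 --seed 1 --out-dir out/
```

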