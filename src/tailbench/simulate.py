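"""Synthetic direct-RNA squiggle simulator with known poly(A) ground truth.

Direct RNA sequencing threads the molecule 3'->5', so the raw current trace
of a read consists of four regions in signal order: sequencing adapter,
reverse-transcription adapter (RTA, which carries 10 poly(T) bases), the
poly(A) tail, and finally the transcript body. The simulator emits reads
with exactly this structure, records exact region boundaries and the
per-read translocation rate (raw samples per nucleotide), and optionally
applies the artifact processes that produce spuriously short tail calls in
real libraries:

* degradation  - the tail is shortened by a geometric draw (3' end intact),
* fragmentation - the tail is lost and the read body is 3'-truncated,
* mispriming  - the RTA anneals to an internal A-rich site, so the read
  starts inside the transcript with a near-zero tail,
* split reads - one molecule's signal is written as two consecutive reads
  on the same channel.

Because no aligner runs here, each read carries an ``AlignmentStub`` giving
the distance from its mapped 3' end to the reference 3' end, which is what
the short-tail diagnostics consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigError

__all__ = [
    "SimConfig",
    "Squiggle",
    "SegmentAnnotation",
    "AlignmentStub",
    "RefTranscript",
    "SimulatedDataset",
    "rna002_config",
    "rna004_config",
    "simulate_references",
    "simulate_read",
    "simulate_dataset",
]

REGIONS = ("adapter", "rta", "polya", "transcript")

# internal A-run planted in every reference so mispriming has a target site
_MISPRIME_RUN = "AAAAAA"


@dataclass
class SimConfig:
    """Parameters of the squiggle generator.

    Current levels are in arbitrary pA-like units; durations in raw samples;
    the translocation rate in samples per nucleotide is drawn once per read
    from a truncated normal (floored at 1).
    """

    sampling_rate: float = 3012.0
    rate_mean: float = 3012.0 / 70.0  # samples per nt (RNA002-like, 70 nt/s)
    rate_sd: float = 4.0

    adapter_mean: float = 70.0
    adapter_sd: float = 4.0
    rta_mean: float = 88.0
    rta_sd: float = 3.5
    polya_mean: float = 108.0
    polya_sd: float = 2.2
    transcript_mean: float = 100.0
    transcript_sd: float = 2.5  # within-level noise
    transcript_level_sd: float = 12.0  # between-level spread (> polya_sd)

    adapter_samples_mean: float = 400.0
    adapter_samples_sd: float = 40.0
    rta_nt: int = 10  # the RTA's 10 poly(T) positions
    transcript_len_nt: int = 150
    n_refs: int = 4

    tail_population: Sequence[tuple[float, float]] = field(
        default_factory=lambda: [(60.0, 1.0)]
    )

    degradation_prob: float = 0.0
    degradation_scale: float = 40.0  # mean nt removed by degradation
    fragmentation_prob: float = 0.0
    mispriming_prob: float = 0.0
    split_prob: float = 0.0

    qscore_mean: float = 22.0
    qscore_sd: float = 2.5
    split_gap_seconds: float = 0.2
    n_channels: int = 126
    noise_seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate", "must be > 0")
        if self.rate_mean <= 0:
            raise ConfigError("rate_mean", "must be > 0")
        for name in ("rate_sd", "adapter_sd", "rta_sd", "polya_sd",
                     "transcript_sd", "transcript_level_sd",
                     "adapter_samples_sd", "qscore_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be >= 0")
        for name in ("degradation_prob", "fragmentation_prob",
                     "mispriming_prob", "split_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(name, "must be in [0, 1]")
        if self.degradation_scale <= 0:
            raise ConfigError("degradation_scale", "must be > 0")
        if self.transcript_len_nt <= 0:
            raise ConfigError("transcript_len_nt", "must be > 0")
        if self.n_refs <= 0:
            raise ConfigError("n_refs", "must be > 0")
        if not self.tail_population:
            raise ConfigError("tail_population", "must be nonempty")
        weights = np.array([w for _, w in self.tail_population], dtype=float)
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ConfigError(
                "tail_population",
                "weights must be nonnegative with positive sum",
            )
        if any(length < 0 for length, _ in self.tail_population):
            raise ConfigError("tail_population", "tail lengths must be >= 0")

    def normalized_weights(self) -> np.ndarray:
        w = np.array([w for _, w in self.tail_population], dtype=float)
        return w / w.sum()


def rna002_config(**overrides) -> SimConfig:
    """RNA002-like preset: ~70 nt/s motor, rate = sampling_rate / 70."""
    cfg = SimConfig(sampling_rate=3012.0, rate_mean=3012.0 / 70.0, rate_sd=4.0)
    return replace(cfg, **overrides)


def rna004_config(**overrides) -> SimConfig:
    """RNA004-like preset: ~130 nt/s motor, rate = sampling_rate / 130."""
    cfg = SimConfig(sampling_rate=4000.0, rate_mean=4000.0 / 130.0, rate_sd=3.0)
    return replace(cfg, **overrides)


@dataclass
class Squiggle:
    """One read's raw current trace plus acquisition metadata."""

    read_id: str
    samples: np.ndarray  # float64, arbitrary current units
    sampling_rate: float
    channel: int
    start_time: float  # seconds

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("samples must be nonempty")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class SegmentAnnotation:
    """Ground-truth region boundaries of a read (0-based, half-open)."""

    read_id: str
    adapter: tuple[int, int]
    rta: tuple[int, int]
    polya: tuple[int, int]
    transcript: tuple[int, int]
    true_tail_nt: float
    rate: float
    artifact_labels: frozenset[str] = frozenset()

    def region(self, name: str) -> tuple[int, int]:
        return getattr(self, name)

    def tiles(self, n_samples: int) -> bool:
        """Regions are contiguous, ordered, and cover the read exactly."""
        spans = [self.adapter, self.rta, self.polya, self.transcript]
        if spans[0][0] != 0 or spans[-1][1] != n_samples:
            return False
        return all(a[1] == b[0] and a[0] <= a[1] for a, b in zip(spans, spans[1:])) \
            and spans[-1][0] <= spans[-1][1]


@dataclass
class AlignmentStub:
    """Stand-in for an alignment record: where the read's 3' end maps."""

    read_id: str
    ref_id: str
    ref_end_offset_nt: int  # distance from mapped 3' end to reference 3' end
    mean_qscore: float

    def __post_init__(self):
        if self.ref_end_offset_nt < 0:
            raise ValueError("ref_end_offset_nt must be >= 0")


@dataclass
class RefTranscript:
    ref_id: str
    sequence: str
    misprime_pos: int  # 0-based start of the planted internal A-run


@dataclass
class SimulatedDataset:
    squiggles: list[Squiggle]
    annotations: list[SegmentAnnotation]
    stubs: list[AlignmentStub]
    truth: "object"  # pandas.DataFrame, see truth_table()
    references: list[RefTranscript]


def simulate_references(config: SimConfig, rng: np.random.Generator) -> list[RefTranscript]:
    """Random reference transcripts, each with one internal A-rich site.

    The site is planted at ~40% of the length from the 5' end so that a
    misprimed read's mapped 3' end sits well inside the body (offset > 20 nt).
    """
    refs = []
    bases = np.array(list("ACGT"))
    for i in range(config.n_refs):
        L = config.transcript_len_nt
        seq = list(rng.choice(bases, size=L))
        pos = max(1, int(0.4 * L))
        run = _MISPRIME_RUN[: max(0, L - pos)]
        seq[pos:pos + len(run)] = list(run)
        refs.append(RefTranscript(f"ref_{i:03d}", "".join(seq), pos))
    return refs


def _nt_dwell_spans(n_nt: int, rate: float) -> np.ndarray:
    """Per-nucleotide dwell times (samples) whose sum is round(n_nt * rate)."""
    edges = np.round(np.arange(n_nt + 1) * rate).astype(int)
    return np.diff(edges)


def _draw_tail(config: SimConfig, rng: np.random.Generator) -> float:
    lengths = np.array([length for length, _ in config.tail_population])
    idx = rng.choice(len(lengths), p=config.normalized_weights())
    return float(lengths[idx])


def simulate_read(
    config: SimConfig,
    rng: np.random.Generator,
    references: list[RefTranscript] | None = None,
    read_id: str = "read_0",
    channel: int = 1,
    start_time: float = 0.0,
) -> tuple[Squiggle, SegmentAnnotation, AlignmentStub]:
    """Simulate one molecule's squiggle (never split; see simulate_dataset).

    Artifact processes are applied with the configured probabilities; at
    most one of degradation / fragmentation / mispriming is applied to a
    molecule. The annotation records the realized tail length and rate.
    """
    config.validate()
    if references is None:
        references = simulate_references(config, rng)

    rate = max(1.0, rng.normal(config.rate_mean, config.rate_sd))
    tail_nt = _draw_tail(config, rng)
    ref = references[rng.integers(len(references))]
    ref_len = len(ref.sequence)

    labels: set[str] = set()
    offset_nt = 0
    u = rng.random()
    if u < config.degradation_prob:
        labels.add("degraded")
        removed = min(int(rng.geometric(1.0 / config.degradation_scale)), int(tail_nt))
        tail_nt = float(int(tail_nt) - removed)
    elif u < config.degradation_prob + config.fragmentation_prob:
        labels.add("fragmented")
        tail_nt = 0.0
        hi = max(22, ref_len - 10)
        offset_nt = int(rng.integers(21, hi)) if hi > 21 else 21
    elif u < (config.degradation_prob + config.fragmentation_prob
              + config.mispriming_prob):
        labels.add("misprimed")
        tail_nt = float(rng.integers(0, 11))
        offset_nt = ref_len - ref.misprime_pos

    covered_nt = max(1, ref_len - offset_nt)

    adapter_n = max(1, int(round(rng.normal(config.adapter_samples_mean,
                                            config.adapter_samples_sd))))
    rta_n = max(1, int(round(config.rta_nt * rate)))
    polya_n = int(round(tail_nt * rate))
    dwells = _nt_dwell_spans(covered_nt, rate)
    transcript_n = int(dwells.sum())

    # per-region mean profile, then additive Gaussian noise per region
    levels = rng.normal(config.transcript_mean, config.transcript_level_sd,
                        size=covered_nt)
    mean_profile = np.concatenate([
        np.full(adapter_n, config.adapter_mean),
        np.full(rta_n, config.rta_mean),
        np.full(polya_n, config.polya_mean),
        np.repeat(levels, dwells),
    ])
    noise_sd = np.concatenate([
        np.full(adapter_n, config.adapter_sd),
        np.full(rta_n, config.rta_sd),
        np.full(polya_n, config.polya_sd),
        np.full(transcript_n, config.transcript_sd),
    ])
    samples = mean_profile + rng.standard_normal(mean_profile.size) * noise_sd

    a0, a1 = 0, adapter_n
    r1 = a1 + rta_n
    p1 = r1 + polya_n
    t1 = p1 + transcript_n
    ann = SegmentAnnotation(
        read_id=read_id,
        adapter=(a0, a1),
        rta=(a1, r1),
        polya=(r1, p1),
        transcript=(p1, t1),
        true_tail_nt=tail_nt,
        rate=rate,
        artifact_labels=frozenset(labels),
    )
    sq = Squiggle(read_id, samples, config.sampling_rate, channel, start_time)
    qscore = float(np.clip(rng.normal(config.qscore_mean, config.qscore_sd), 1, 40))
    stub = AlignmentStub(read_id, ref.ref_id, offset_nt, qscore)
    return sq, ann, stub


def _clip_annotation(ann: SegmentAnnotation, lo: int, hi: int,
                     read_id: str, label: str) -> SegmentAnnotation:
    """Intersect an annotation with [lo, hi) and shift to part-local indices."""

    def clip(span):
        s = min(max(span[0], lo), hi) - lo
        e = min(max(span[1], lo), hi) - lo
        return (s, e)

    return SegmentAnnotation(
        read_id=read_id,
        adapter=clip(ann.adapter),
        rta=clip(ann.rta),
        polya=clip(ann.polya),
        transcript=clip(ann.transcript),
        true_tail_nt=ann.true_tail_nt,
        rate=ann.rate,
        artifact_labels=ann.artifact_labels | {label},
    )


def simulate_dataset(config: SimConfig, n_reads: int,
                     seed: int | None = None) -> SimulatedDataset:
    """Simulate ``n_reads`` molecules; split glitches may emit extra reads.

    A molecule hit by a split glitch is written as two consecutive reads on
    the same channel whose sample counts sum to the parent molecule's.
    Identical seeds give bit-identical output.
    """
    import pandas as pd

    config.validate()
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if seed is None:
        seed = config.noise_seed
    ss = np.random.SeedSequence(seed)
    ref_rng, read_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    references = simulate_references(config, ref_rng)

    squiggles: list[Squiggle] = []
    annotations: list[SegmentAnnotation] = []
    stubs: list[AlignmentStub] = []
    channel_clock = np.zeros(config.n_channels)

    for i in range(n_reads):
        rid = f"read_{i:06d}"
        channel = int(read_rng.integers(1, config.n_channels + 1))
        gap = read_rng.uniform(2.0, 10.0)
        start = channel_clock[channel - 1] + gap
        sq, ann, stub = simulate_read(config, read_rng, references,
                                      read_id=rid, channel=channel,
                                      start_time=start)
        if read_rng.random() < config.split_prob and sq.samples.size >= 4:
            k = int(read_rng.integers(sq.samples.size // 4,
                                      3 * sq.samples.size // 4))
            id1, id2 = rid + "a", rid + "b"
            sq1 = Squiggle(id1, sq.samples[:k], sq.sampling_rate, channel, start)
            t2 = start + sq1.duration + config.split_gap_seconds
            sq2 = Squiggle(id2, sq.samples[k:], sq.sampling_rate, channel, t2)
            squiggles += [sq1, sq2]
            annotations += [
                _clip_annotation(ann, 0, k, id1, "split_first"),
                _clip_annotation(ann, k, sq.samples.size, id2, "split_second"),
            ]
            stubs += [
                AlignmentStub(id1, stub.ref_id, stub.ref_end_offset_nt,
                              stub.mean_qscore),
                AlignmentStub(id2, stub.ref_id, stub.ref_end_offset_nt,
                              stub.mean_qscore),
            ]
            channel_clock[channel - 1] = t2 + sq2.duration
        else:
            squiggles.append(sq)
            annotations.append(ann)
            stubs.append(stub)
            channel_clock[channel - 1] = start + sq.duration

    rows = []
    for ann, stub in zip(annotations, stubs):
        rows.append({
            "read_id": ann.read_id,
            "true_tail_nt": ann.true_tail_nt,
            "rate": ann.rate,
            "artifact_labels": ",".join(sorted(ann.artifact_labels)),
            "ref_id": stub.ref_id,
            "ref_end_offset_nt": stub.ref_end_offset_nt,
            "mean_qscore": stub.mean_qscore,
        })
    truth = pd.DataFrame(
        rows,
        columns=["read_id", "true_tail_nt", "rate", "artifact_labels",
                 "ref_id", "ref_end_offset_nt", "mean_qscore"],
    )
    return SimulatedDataset(squiggles, annotations, stubs, truth, references)
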