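"""Locate the poly(A) region in a raw-signal read.

Three strategies are implemented, modelled on the families of published
poly(A) callers:

* ``hmm_segment``    - a 4-state linear-chain hidden Markov model (adapter,
  RTA, poly(A), transcript) with Gaussian emissions and minimum state
  durations, decoded by Viterbi (nanopolish-style).
* ``window_segment`` - two passes: threshold a smoothed signal for rough
  boundaries, then average 25-sample bins inside the clipped region and
  shrink the boundaries until the bin-to-bin slope is flat
  (tailfindr-style).
* ``anchor_segment`` - detect the adapter, place an anchor at its end, and
  grow a low-variance, stable-mean region forward from it; reads whose
  grown region is too short are reported as undetected (Dorado-style, and
  deliberately the most conservative of the three).

``oracle_segment`` is an exhaustive-enumeration maximum-likelihood
segmenter for small reads, used to validate the Viterbi implementation.

All methods standardize the signal per read (median-centered, SD-scaled)
and can additionally recenter on the adapter that starts every read, so
parameters are expressed in z-units and every method is invariant to the
arbitrary current scale of a read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from ._viterbi import _viterbi_kernel
from .errors import ConfigError, SignalTooShortError
from .simulate import SimConfig, Squiggle

__all__ = [
    "HmmParams",
    "WindowParams",
    "AnchorParams",
    "Boundaries",
    "HmmSegmentation",
    "standardize",
    "hmm_segment",
    "window_segment",
    "anchor_segment",
    "oracle_segment",
    "hmm_params_from_config",
    "window_params_from_config",
    "anchor_params_from_config",
]

_STATES = ("adapter", "rta", "polya", "transcript")
_MIN_SD = 1e-3


def standardize(x: np.ndarray) -> np.ndarray:
    """Per-read z-scores: (x - median) / std.

    A median center with a standard-deviation scale: the SD stays stable
    across read compositions (a long tail can put half the read at one
    level, which collapses rank-based spread measures like the MAD), and
    the transform keeps every segmenter invariant to the arbitrary current
    scale of a read.
    """
    x = np.asarray(x, dtype=float)
    scale = x.std()
    if scale <= 0:
        scale = 1.0
    return (x - np.median(x)) / scale


def _typical_profile(config: SimConfig) -> np.ndarray:
    """Deterministic noise-free mean profile of a typical read.

    Used to convert a simulator config's raw-unit levels into the robust
    z-units the segmenters operate in. Transcript levels are represented by
    quantiles of their stationary distribution rather than random draws.
    """
    rate = config.rate_mean
    w = config.normalized_weights()
    tail = float(np.dot([length for length, _ in config.tail_population], w))
    n_nt = config.transcript_len_nt
    q = (np.arange(n_nt) + 0.5) / n_nt
    levels = config.transcript_mean + config.transcript_level_sd * norm.ppf(q)
    return np.concatenate([
        np.full(int(config.adapter_samples_mean), config.adapter_mean),
        np.full(int(round(config.rta_nt * rate)), config.rta_mean),
        np.full(int(round(tail * rate)), config.polya_mean),
        np.repeat(levels, int(round(rate))),
    ])


def _z_stats(config: SimConfig) -> tuple[float, float]:
    prof = _typical_profile(config)
    med = float(np.median(prof))
    scale = float(prof.std()) or 1.0
    return med, scale


@dataclass
class HmmParams:
    """4-state linear-chain model parameters, in robust z-units.

    ``adapter_anchor_n`` > 0 recenters each standardized read so the median
    of its first samples (which are always sequencing adapter) matches the
    adapter state mean; this removes the shift that different read
    compositions (tail length, truncation) induce in per-read z-scores.
    """

    means: np.ndarray  # (4,) adapter, rta, polya, transcript
    sds: np.ndarray  # (4,)
    self_p: np.ndarray = field(default_factory=lambda: np.full(4, 0.999))
    min_dur: np.ndarray = field(
        default_factory=lambda: np.array([24, 8, 8, 24], dtype=int))
    adapter_anchor_n: int = 150

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.maximum(np.asarray(self.sds, dtype=float), _MIN_SD)
        self.self_p = np.asarray(self.self_p, dtype=float)
        self.min_dur = np.asarray(self.min_dur, dtype=int)
        if self.means.shape != (4,) or self.sds.shape != (4,):
            raise ConfigError("means", "HMM has exactly 4 states")
        if np.any(self.sds <= 0):
            raise ConfigError("sds", "must be > 0")
        if np.any((self.self_p <= 0) | (self.self_p >= 1)):
            raise ConfigError("self_p", "must be in (0, 1)")
        if np.any(self.min_dur < 1):
            raise ConfigError("min_dur", "must be >= 1")


@dataclass
class WindowParams:
    """Sliding-window (tailfindr-style) segmentation parameters (z-units)."""

    polya_level: float
    adapter_level: float | None = None  # enables adapter-anchored recentering
    anchor_n: int = 150
    level_band: float = 0.5
    smoothing_window: int = 25
    bin_size: int = 25  # second-pass averaging bin
    slope_limit: float = 0.15  # max |bin-to-bin mean change| inside the tail
    min_run: int = 50  # shortest acceptable rough region, samples

    def __post_init__(self):
        if self.smoothing_window < 1:
            raise ConfigError("smoothing_window", "must be >= 1")
        if self.bin_size < 1:
            raise ConfigError("bin_size", "must be >= 1")
        if self.level_band <= 0:
            raise ConfigError("level_band", "must be > 0")


@dataclass
class AnchorParams:
    """Anchor-and-grow (Dorado-style) segmentation parameters (z-units)."""

    polya_level: float
    adapter_level: float | None = None  # enables adapter-anchored recentering
    anchor_n: int = 150
    detect_window: int = 25  # trailing window for adapter-end detection
    search_radius: int = 200  # max backward refinement from the anchor
    var_ceiling: float = 0.25  # windowed variance ceiling inside the region
    mean_tol: float = 0.35  # window-mean similarity to the polya level
    # minimum per-sample jump treated as a region boundary; scaled up to
    # 4.5x the running noise level when the region is noisy
    grow_tol: float = 0.3
    min_region_len: int = 300  # samples; shorter regions -> undetected

    def __post_init__(self):
        if self.search_radius <= 0:
            raise ConfigError("search_radius", "must be > 0")
        if self.var_ceiling <= 0:
            raise ConfigError("var_ceiling", "must be > 0")
        if self.detect_window < 2:
            raise ConfigError("detect_window", "must be >= 2")


@dataclass
class Boundaries:
    """A method's poly(A) call for one read (0-based, half-open samples)."""

    read_id: str
    polya_start: int
    polya_end: int
    detected: bool
    method: str
    score: float = float("nan")

    def __post_init__(self):
        if self.detected and not 0 <= self.polya_start < self.polya_end:
            raise ValueError("detected requires 0 <= start < end")

    @property
    def span(self) -> int:
        return self.polya_end - self.polya_start if self.detected else 0


@dataclass
class HmmSegmentation:
    boundaries: Boundaries
    path: np.ndarray  # per-sample state index 0..3
    log_prob: float
    regions: dict[str, tuple[int, int]]


def hmm_params_from_config(config: SimConfig) -> HmmParams:
    """Derive z-unit HMM emission parameters from a simulator config."""
    med, scale = _z_stats(config)
    means = (np.array([config.adapter_mean, config.rta_mean,
                       config.polya_mean, config.transcript_mean]) - med) / scale
    transcript_marginal = np.hypot(config.transcript_sd,
                                   config.transcript_level_sd)
    sds = np.array([config.adapter_sd, config.rta_sd, config.polya_sd,
                    transcript_marginal]) / scale
    # widen narrow states: per-read standardization leaves a residual
    # shift/scale mismatch (composition- and rate-dependent) of ~0.3 z that
    # razor-thin emission sds would otherwise turn into segmentation flips
    sds = np.maximum(sds, [0.30, 0.30, 0.35, 0.0])
    rate = config.rate_mean
    expected = np.array([
        config.adapter_samples_mean,
        config.rta_nt * rate,
        60.0 * rate,
        config.transcript_len_nt * rate,
    ])
    self_p = 1.0 - 1.0 / np.maximum(expected, 2.0)
    anchor_n = min(150, max(8, int(0.4 * config.adapter_samples_mean)))
    return HmmParams(means=means, sds=np.maximum(sds, _MIN_SD),
                     self_p=self_p, adapter_anchor_n=anchor_n)


def window_params_from_config(config: SimConfig) -> WindowParams:
    med, scale = _z_stats(config)
    anchor_n = min(150, max(8, int(0.4 * config.adapter_samples_mean)))
    return WindowParams(polya_level=(config.polya_mean - med) / scale,
                        adapter_level=(config.adapter_mean - med) / scale,
                        anchor_n=anchor_n)


def anchor_params_from_config(config: SimConfig) -> AnchorParams:
    med, scale = _z_stats(config)
    anchor_n = min(150, max(8, int(0.4 * config.adapter_samples_mean)))
    return AnchorParams(polya_level=(config.polya_mean - med) / scale,
                        adapter_level=(config.adapter_mean - med) / scale,
                        anchor_n=anchor_n)


def _recenter(z: np.ndarray, adapter_level: float | None,
              n: int) -> np.ndarray:
    """Shift z so the first samples (always adapter) sit at adapter_level."""
    if adapter_level is not None and n > 0 and z.size >= n:
        return z - (np.median(z[:n]) - adapter_level)
    return z


def _emission_loglik(z: np.ndarray, params: HmmParams) -> np.ndarray:
    """(4, T) per-state Gaussian log-likelihoods."""
    mu = params.means[:, None]
    sd = params.sds[:, None]
    return (-0.5 * ((z[None, :] - mu) / sd) ** 2
            - np.log(sd) - 0.5 * np.log(2 * np.pi))


def hmm_segment(squiggle: Squiggle, params: HmmParams) -> HmmSegmentation:
    """Viterbi decoding of the 4-region model; poly(A) is the third state."""
    z = _recenter(standardize(squiggle.samples), float(params.means[0]),
                  params.adapter_anchor_n)
    if z.size < int(params.min_dur.sum()):
        raise SignalTooShortError(
            f"signal too short: {z.size} samples < "
            f"{int(params.min_dur.sum())} minimum")
    logp, path = _viterbi_kernel(
        z, params.means, params.sds,
        np.log(params.self_p), np.log1p(-params.self_p),
        params.min_dur.astype(np.int64))
    regions = {}
    for s, name in enumerate(_STATES):
        idx = np.flatnonzero(path == s)
        regions[name] = (int(idx[0]), int(idx[-1]) + 1)
    start, end = regions["polya"]
    bnd = Boundaries(squiggle.read_id, start, end, True, "hmm", float(logp))
    return HmmSegmentation(bnd, path, float(logp), regions)


def _moving_mean(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average, same length as x (edges use partial windows)."""
    c = np.cumsum(np.concatenate([[0.0], x]))
    half = w // 2
    idx = np.arange(x.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + w - half, x.size)
    return (c[hi] - c[lo]) / (hi - lo)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as [start, end) pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def window_segment(squiggle: Squiggle, params: WindowParams) -> Boundaries:
    """Two-pass sliding-window segmentation (threshold, then bin-shrink)."""
    z = _recenter(standardize(squiggle.samples), params.adapter_level,
                  params.anchor_n)
    undetected = Boundaries(squiggle.read_id, 0, 0, False, "window")

    # pass 1: threshold the smoothed signal around the poly(A) level
    s = _moving_mean(z, params.smoothing_window)
    mask = np.abs(s - params.polya_level) <= params.level_band
    runs = [r for r in _runs(mask) if r[1] - r[0] >= params.min_run]
    if not runs:
        return undetected
    rough_start, rough_end = max(runs, key=lambda r: r[1] - r[0])

    # pass 2: bin means inside the clipped region, shrink by slope
    clip_lo = max(0, rough_start - params.smoothing_window)
    clip_hi = min(z.size, rough_end + params.smoothing_window)
    clipped = z[clip_lo:clip_hi]
    n_bins = clipped.size // params.bin_size
    if n_bins < 1:
        return undetected
    binned = clipped[: n_bins * params.bin_size].reshape(
        n_bins, params.bin_size).mean(axis=1)
    in_level = np.abs(binned - params.polya_level) <= params.level_band
    lo, hi = 0, n_bins  # half-open bin range
    while lo < hi and (
            not in_level[lo]
            or (lo + 1 < hi and abs(binned[lo + 1] - binned[lo]) > params.slope_limit)):
        lo += 1
    while hi > lo and (
            not in_level[hi - 1]
            or (hi - 2 >= lo and abs(binned[hi - 1] - binned[hi - 2]) > params.slope_limit)):
        hi -= 1
    if hi <= lo:
        return undetected
    # a real tail is flat bin-to-bin almost everywhere; structureless noise
    # whose bin means wander is rejected here
    if hi - lo >= 3:
        slopes = np.abs(np.diff(binned[lo:hi]))
        if np.mean(slopes <= params.slope_limit) < 0.8:
            return undetected
    start = clip_lo + lo * params.bin_size
    end = clip_lo + hi * params.bin_size
    # recover the partial bins the quantization dropped (at most one bin
    # per side) at sample resolution; the running mean of the recovered
    # samples must track the poly(A) level tightly, so a neighbouring
    # transcript level that merely falls inside the coarse band is not
    # swallowed
    half_band = params.level_band / 2.0
    limit = max(0, start - params.bin_size)
    total, k = 0.0, 0
    while start > limit:
        total += z[start - 1]
        k += 1
        if abs(total / k - params.polya_level) > half_band:
            break
        start -= 1
    limit = min(z.size, end + params.bin_size)
    total, k = 0.0, 0
    while end < limit:
        total += z[end]
        k += 1
        if abs(total / k - params.polya_level) > half_band:
            break
        end += 1
    if end - start < params.min_run:
        return undetected
    return Boundaries(squiggle.read_id, start, end, True, "window",
                      float(np.abs(binned[lo:hi] - params.polya_level).mean()))


def anchor_segment(squiggle: Squiggle, params: AnchorParams) -> Boundaries:
    """Anchor at the detected adapter end, grow a low-variance region."""
    z = _recenter(standardize(squiggle.samples), params.adapter_level,
                  params.anchor_n)
    undetected = Boundaries(squiggle.read_id, 0, 0, False, "anchor")
    w = params.detect_window
    if z.size <= w:
        return undetected

    # adapter end: first trailing window whose mean sits in the poly(A)
    # band with variance under the ceiling
    c1 = np.cumsum(np.concatenate([[0.0], z]))
    c2 = np.cumsum(np.concatenate([[0.0], z * z]))
    t = np.arange(w, z.size + 1)
    mean_w = (c1[t] - c1[t - w]) / w
    var_w = np.maximum((c2[t] - c2[t - w]) / w - mean_w ** 2, 0.0)
    ok = (np.abs(mean_w - params.polya_level) <= params.mean_tol) \
        & (var_w <= params.var_ceiling)
    hits = np.flatnonzero(ok)
    if hits.size == 0:
        return undetected
    anchor = int(hits[0]) + w  # end index of the first qualifying window

    # noise level inside the anchoring window scales the jump guard; a
    # robust (MAD-based) estimate so a stray boundary sample in the window
    # cannot inflate it
    win0 = z[anchor - w:anchor]
    sd0 = 1.4826 * float(np.median(np.abs(win0 - np.median(win0))))
    jump = max(params.grow_tol, 4.5 * sd0)

    # backward refinement: the region starts where samples stop matching
    start = anchor
    limit = max(0, anchor - w - params.search_radius)
    while start > limit and abs(z[start - 1] - params.polya_level) <= jump:
        start -= 1

    # forward growth while the trailing-window mean tracks the running
    # region mean, its variance stays under the ceiling, and no sample
    # jumps away from the region level
    end = anchor
    total = float(z[start:end].sum())
    count = end - start
    while end < z.size:
        running_mean = total / count
        if abs(z[end] - running_mean) > jump:
            break
        if end - start >= w:
            win = z[end - w + 1:end + 1]
            if abs(win.mean() - running_mean) > params.mean_tol:
                break
            if np.var(win) > params.var_ceiling:
                break
        total += float(z[end])
        count += 1
        end += 1

    if end - start < params.min_region_len:
        return undetected
    return Boundaries(squiggle.read_id, start, end, True, "anchor",
                      float(np.var(z[start:end])))


def oracle_segment(squiggle: Squiggle, params: HmmParams,
                   max_len: int = 300) -> HmmSegmentation:
    """Exact ML 4-region tiling by exhaustive enumeration of boundary triples.

    Scores every admissible (adapter_end, polya_start, transcript_start)
    triple directly under the same linear-chain duration model as
    ``hmm_segment``; intended for validating the Viterbi decoder on small
    reads only.
    """
    z = _recenter(standardize(squiggle.samples), float(params.means[0]),
                  params.adapter_anchor_n)
    T = z.size
    if T > max_len:
        raise ValueError(f"oracle refuses reads longer than {max_len} samples")
    d = params.min_dur
    if T < int(d.sum()):
        raise SignalTooShortError("signal too short")
    E = _emission_loglik(z, params)
    C = np.concatenate([np.zeros((4, 1)), np.cumsum(E, axis=1)], axis=1)
    ls = np.log(params.self_p)
    la = np.log1p(-params.self_p)
    const = (float(la[:3].sum())
             - float(np.dot(d, ls)))

    best = -np.inf
    best_abc = None
    c_all = np.arange(T + 1)
    for a in range(d[0], T - d[1] - d[2] - d[3] + 1):
        sc_a = C[0, a] + a * ls[0]
        for b in range(a + d[1], T - d[2] - d[3] + 1):
            sc_b = sc_a + (C[1, b] - C[1, a]) + (b - a) * ls[1]
            cs = c_all[b + d[2]: T - d[3] + 1]
            scores = (sc_b
                      + (C[2, cs] - C[2, b]) + (cs - b) * ls[2]
                      + (C[3, T] - C[3, cs]) + (T - cs) * ls[3]
                      + const)
            k = int(np.argmax(scores))
            if scores[k] > best:
                best = float(scores[k])
                best_abc = (a, b, int(cs[k]))
    a, b, c = best_abc
    path = np.empty(T, dtype=np.int64)
    path[:a] = 0
    path[a:b] = 1
    path[b:c] = 2
    path[c:] = 3
    regions = {"adapter": (0, a), "rta": (a, b), "polya": (b, c),
               "transcript": (c, T)}
    bnd = Boundaries(squiggle.read_id, b, c, True, "hmm", best)
    return HmmSegmentation(bnd, path, best, regions)
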