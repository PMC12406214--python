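"""Benchmarking statistics for per-read tail-length estimates.

Read-set summaries
    A Gaussian kernel density over the per-read tail lengths gives
    "maxpeak" (the length maximizing the density, the preferred group-level
    average for the multimodal distributions real libraries produce), the
    median, and an SD of the main peak derived from its full width at
    half-maximum (FWHM / 2*sqrt(2*ln 2)).

Accuracy
    Reads are partitioned in input order into non-overlapping windows of N
    reads; the windowed MAE is the mean over windows of |statistic(window) -
    known length|, with percentile bootstrap confidence intervals and a
    two-sided bootstrap test for the MAE difference between two tools
    (B resamples, so the smallest reportable nonzero p is 1/B).

Detection
    ``common_reads`` intersects the reads every tool calls successfully, so
    cross-tool comparisons use identical read sets, and reports per-tool
    detection counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientReadsError, UnboundedPeakError

__all__ = [
    "DensitySummary",
    "BenchmarkResult",
    "BootstrapTest",
    "CommonReads",
    "density_estimate",
    "maxpeak",
    "fwhm_sd",
    "windowed_mae",
    "bootstrap_ci",
    "bootstrap_test",
    "common_reads",
    "bw_nrd0",
]

_FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...
_MIN_READS = 10
_GRID_POINTS = 513  # odd, so a degenerate sample's value is a grid point
_GRID_CUT = 4.0  # grid extends this many bandwidths past the data range


def bw_nrd0(x: np.ndarray) -> float:
    """Silverman rule-of-thumb bandwidth (R's bw.nrd0)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return 1.0
    sd = x.std(ddof=1)
    q25, q75 = np.percentile(x, [25, 75])
    lo = min(sd, (q75 - q25) / 1.34)
    if lo == 0:
        lo = sd or abs(float(x[0])) or 1.0
    return 0.9 * lo * n ** (-0.2)


@dataclass
class DensitySummary:
    """KDE of a read set's tail lengths plus its scalar summaries."""

    grid: np.ndarray  # nt, ascending
    density: np.ndarray
    bandwidth: float
    n: int
    maxpeak: float
    median: float
    fwhm_sd: float  # nan if the peak never drops below half-maximum


@dataclass
class BenchmarkResult:
    """Windowed MAE of one tool at one known length."""

    tool: str
    known_length_nt: float
    window_n: int
    statistic: str  # median | maxpeak
    mae: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_windows: int = 0
    detection_count: int = 0


@dataclass
class BootstrapTest:
    """Two-sided bootstrap test of an MAE difference between two tools."""

    observed_diff: float
    p_value: float  # floored at 1/B
    n_extreme: int
    B: int
    floored: bool  # True means "p < 1/B"


@dataclass
class CommonReads:
    read_ids: set[str]
    tables: dict[str, pd.DataFrame]
    detection_counts: dict[str, int]
    empty_intersection: bool = False


def density_estimate(tails, bandwidth: float | None = None,
                     grid_points: int = _GRID_POINTS) -> DensitySummary:
    """Gaussian KDE on a fixed grid spanning the data range plus margins.

    Requires 10 or more reads; below that, group-level summaries such as
    maxpeak are not considered meaningful and an error is raised.
    """
    x = np.asarray(list(tails), dtype=float)
    if x.size < _MIN_READS:
        raise InsufficientReadsError(
            f"insufficient reads: {x.size} < {_MIN_READS}")
    h = bw_nrd0(x) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be > 0")
    grid = np.linspace(x.min() - _GRID_CUT * h, x.max() + _GRID_CUT * h,
                       grid_points)
    z = (grid[:, None] - x[None, :]) / h
    density = np.exp(-0.5 * z * z).sum(axis=1) / (x.size * h * np.sqrt(2 * np.pi))
    peak = float(grid[int(np.argmax(density))])
    summary = DensitySummary(grid=grid, density=density, bandwidth=h,
                             n=int(x.size), maxpeak=peak,
                             median=float(np.median(x)), fwhm_sd=float("nan"))
    try:
        summary.fwhm_sd = fwhm_sd(summary)
    except UnboundedPeakError:
        pass
    return summary


def maxpeak(summary: DensitySummary) -> float:
    """Grid point maximizing the density (ties -> smallest value)."""
    return float(summary.grid[int(np.argmax(summary.density))])


def fwhm_sd(summary: DensitySummary) -> float:
    """SD of the main density peak from its full width at half-maximum.

    Walks outward from the highest peak to the nearest half-height
    crossings (linear interpolation between grid points), so well-separated
    minor modes do not influence the width.
    """
    d = summary.density
    g = summary.grid
    i = int(np.argmax(d))
    half = d[i] / 2.0

    def cross(direction: int) -> float:
        j = i
        while 0 <= j + direction < d.size and d[j + direction] >= half:
            j += direction
        if not 0 <= j + direction < d.size:
            raise UnboundedPeakError(
                "unbounded peak: density never drops below half-maximum")
        j2 = j + direction
        frac = (d[j] - half) / (d[j] - d[j2])
        return float(g[j] + frac * (g[j2] - g[j]))

    left = cross(-1)
    right = cross(+1)
    return (right - left) / _FWHM_TO_SD


def _window_statistics(values: np.ndarray, window_n: int,
                       statistic: str) -> np.ndarray:
    n_windows = values.size // window_n
    if n_windows < 1:
        raise ValueError("no complete window of size "
                         f"{window_n} in {values.size} reads")
    windows = values[: n_windows * window_n].reshape(n_windows, window_n)
    if statistic == "median":
        return np.median(windows, axis=1)
    if statistic == "maxpeak":
        if window_n < _MIN_READS:
            raise ValueError("maxpeak windows require window_n >= 10")
        return np.array([density_estimate(w).maxpeak for w in windows])
    raise ValueError(f"unknown statistic {statistic!r}")


def windowed_mae(estimates, truth: float, window_n: int,
                 statistic: str = "median", tool: str = "") -> BenchmarkResult:
    """MAE of the windowed statistic against the known tail length.

    Reads are windowed in input order; an incomplete trailing window is
    dropped.
    """
    values = np.asarray(list(estimates), dtype=float)
    stats = _window_statistics(values, window_n, statistic)
    return BenchmarkResult(
        tool=tool, known_length_nt=float(truth), window_n=window_n,
        statistic=statistic, mae=float(np.abs(stats - truth).mean()),
        n_windows=stats.size, detection_count=values.size)


def _bootstrap_maes(values: np.ndarray, truth: float, window_n: int,
                    statistic: str, B: int,
                    rng: np.random.Generator) -> np.ndarray:
    """MAE recomputed on B with-replacement resamples of the read set."""
    n = values.size
    n_windows = n // window_n
    idx = rng.integers(0, n, size=(B, n_windows * window_n))
    resampled = values[idx]
    if statistic == "median":
        stats = np.median(resampled.reshape(B, n_windows, window_n), axis=2)
        return np.abs(stats - truth).mean(axis=1)
    maes = np.empty(B)
    for b in range(B):
        stats = _window_statistics(resampled[b], window_n, statistic)
        maes[b] = np.abs(stats - truth).mean()
    return maes


def bootstrap_ci(estimates, truth: float, window_n: int,
                 statistic: str = "median", B: int = 1000,
                 seed: int | None = None, tool: str = "") -> BenchmarkResult:
    """Windowed MAE with a 95% percentile bootstrap confidence interval.

    Reads are resampled with replacement within the known-length category
    and re-windowed on each of the B resamples.
    """
    values = np.asarray(list(estimates), dtype=float)
    result = windowed_mae(values, truth, window_n, statistic, tool)
    rng = np.random.default_rng(seed)
    maes = _bootstrap_maes(values, truth, window_n, statistic, B, rng)
    lo, hi = np.percentile(maes, [2.5, 97.5])
    # the interval always includes the point estimate
    result.ci_low = float(min(lo, result.mae))
    result.ci_high = float(max(hi, result.mae))
    return result


def bootstrap_test(estimates_a, estimates_b, truth: float, window_n: int,
                   statistic: str = "median", B: int = 1000,
                   seed: int | None = None) -> BootstrapTest:
    """Two-sided bootstrap test for the MAE difference between two tools.

    Both groups are resampled with replacement B times; the p-value is the
    fraction of the bootstrap MAE differences (centered at their mean) at
    least as extreme as the observed difference. With B resamples the
    smallest reportable nonzero p is 1/B; ``floored=True`` marks results
    that should be read as "p < 1/B".
    """
    a = np.asarray(list(estimates_a), dtype=float)
    b = np.asarray(list(estimates_b), dtype=float)
    observed = (windowed_mae(a, truth, window_n, statistic).mae
                - windowed_mae(b, truth, window_n, statistic).mae)
    rng = np.random.default_rng(seed)
    maes_a = _bootstrap_maes(a, truth, window_n, statistic, B, rng)
    maes_b = _bootstrap_maes(b, truth, window_n, statistic, B, rng)
    diffs = maes_a - maes_b
    centered = diffs - diffs.mean()
    n_extreme = int(np.sum(np.abs(centered) >= abs(observed)))
    floored = n_extreme == 0
    p = max(n_extreme, 1) / B
    return BootstrapTest(observed_diff=float(observed), p_value=float(p),
                         n_extreme=n_extreme, B=B, floored=floored)


def common_reads(tables: dict[str, pd.DataFrame]) -> CommonReads:
    """Reads with qc=pass in every tool's table; tables filtered to them."""
    if len(tables) < 2:
        raise ValueError("need at least 2 estimate tables")
    passing = {}
    for tool, df in tables.items():
        if "qc" not in df.columns or "read_id" not in df.columns:
            raise ValueError(f"table {tool!r} lacks read_id/qc columns")
        passing[tool] = set(df.loc[df["qc"] == "pass", "read_id"])
    ids = set.intersection(*passing.values())
    filtered = {tool: df[df["read_id"].isin(ids)].reset_index(drop=True)
                for tool, df in tables.items()}
    return CommonReads(
        read_ids=ids,
        tables=filtered,
        detection_counts={tool: len(s) for tool, s in passing.items()},
        empty_intersection=len(ids) == 0,
    )
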