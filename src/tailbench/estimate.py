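"""Convert poly(A) boundaries from sample space to nucleotide lengths.

A read's tail length in nucleotides is its poly(A) span in raw samples
divided by the read-specific translocation rate r (samples per nucleotide).
Here r is derived from the transcript region: r = transcript-region sample
count / transcript length in nucleotides, the benchmark-mode stand-in for
the basecall-derived rates real tools use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import Boundaries

__all__ = ["TailEstimate", "estimate_rate", "estimate_tail", "RateUnavailable"]


class RateUnavailable(Exception):
    """No translocation rate can be derived for this read."""


@dataclass
class TailEstimate:
    """One method's per-read tail call."""

    read_id: str
    method: str
    qc: str  # pass | no_tail | rate_unavailable
    tail_nt: float = float("nan")
    polya_start: int = -1
    polya_end: int = -1
    rate: float = float("nan")

    def __post_init__(self):
        if self.qc not in ("pass", "no_tail", "rate_unavailable"):
            raise ValueError(f"unknown qc status {self.qc!r}")
        if self.qc == "pass" and not self.tail_nt >= 0:
            raise ValueError("qc=pass requires tail_nt >= 0")


def estimate_rate(transcript_region: tuple[int, int],
                  transcript_len_nt: float) -> float:
    """Translocation rate in samples/nt from the transcript region span."""
    n_samples = transcript_region[1] - transcript_region[0]
    if n_samples <= 0:
        raise RateUnavailable("empty transcript region")
    if transcript_len_nt <= 0:
        raise RateUnavailable("transcript length must be > 0")
    return n_samples / transcript_len_nt


def estimate_tail(boundaries: Boundaries, rate: float) -> TailEstimate:
    """Tail length = poly(A) span / rate, with QC status.

    Undetected boundaries give qc="no_tail"; a nonpositive or missing rate
    gives qc="rate_unavailable". The length is reported unrounded.
    """
    if not boundaries.detected:
        return TailEstimate(boundaries.read_id, boundaries.method, "no_tail")
    if rate is None or not np.isfinite(rate) or rate <= 0:
        return TailEstimate(boundaries.read_id, boundaries.method,
                            "rate_unavailable",
                            polya_start=boundaries.polya_start,
                            polya_end=boundaries.polya_end)
    span = boundaries.polya_end - boundaries.polya_start
    return TailEstimate(boundaries.read_id, boundaries.method, "pass",
                        tail_nt=span / rate,
                        polya_start=boundaries.polya_start,
                        polya_end=boundaries.polya_end, rate=rate)
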