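"""Why does a read get a short poly(A) call?

Reads called with tails under ~10 nt (the nominal detection floor set by
the RTA's 10 poly(T) bases) can arise from several distinct processes, and
this module implements the screens that separate them:

* ``classify_end``    - a read whose mapped 3' end lies within 20 nt of the
  reference 3' end is "full_length" (consistent with tail degradation);
  farther than that it is "truncated" (fragmentation or mispriming).
* ``mispriming_screen`` - inspects the 10 reference nucleotides immediately
  3' of the mapped end for an adenine run or high A content, the signature
  of the poly(T) adapter annealing internally.
* ``find_split_pairs``  - consecutive reads on the same channel separated
  by a short gap, the signature of one molecule written as two reads.
* ``quality_length_correlation`` - Spearman correlation between tail
  lengths and mean read quality.
* ``short_tail_report`` - ties these together for every read under a tail
  cutoff and reports the class proportions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import InsufficientReadsError
from .simulate import AlignmentStub

__all__ = [
    "DiagnosticRecord",
    "SpearmanResult",
    "classify_end",
    "mispriming_screen",
    "find_split_pairs",
    "quality_length_correlation",
    "split_read_percentage",
    "short_tail_report",
    "ShortTailSummary",
]

log = logging.getLogger(__name__)

DOWNSTREAM_WINDOW_NT = 10  # matches the RTA's 10 poly(T) bases


@dataclass
class DiagnosticRecord:
    read_id: str
    tail_nt: float
    end_class: str  # full_length | truncated
    downstream_10mer: str | None
    longest_a_run: int
    a_fraction: float
    mispriming_flag: bool
    split_partner: str | None
    mean_qscore: float


@dataclass
class SpearmanResult:
    r: float
    p_value: float
    status: str  # ok | not_applicable


@dataclass
class ShortTailSummary:
    n_short: int
    fraction_full_length: float
    fraction_truncated: float
    fraction_truncated_misprimed: float
    fraction_qscore_gt20: float
    status: str = "ok"  # or not_applicable when no short-tail reads exist


def classify_end(stub: AlignmentStub, threshold_nt: int = 20) -> str:
    """full_length iff the mapped 3' end is within ``threshold_nt``
    (inclusive) of the reference 3' end."""
    return "full_length" if stub.ref_end_offset_nt <= threshold_nt else "truncated"


def mispriming_screen(reference_seq: str, mapped_end_pos: int,
                      run_threshold: int = 4,
                      content_threshold: float = 0.5,
                      ) -> tuple[int, float, bool]:
    """Screen the 10 nt downstream of a mapped 3' end for an A-rich context.

    Returns (longest adenine run, adenine fraction, flag) where the flag is
    set when the run reaches ``run_threshold`` or the A fraction exceeds
    ``content_threshold``. If fewer than 10 nt remain before the reference
    end, whatever exists is used. Coordinates are 0-based.
    """
    if not 0 <= mapped_end_pos <= len(reference_seq):
        raise IndexError(
            f"mapped_end_pos {mapped_end_pos} outside reference of length "
            f"{len(reference_seq)}")
    window = reference_seq[mapped_end_pos:mapped_end_pos + DOWNSTREAM_WINDOW_NT]
    if not window:
        return 0, 0.0, False
    upper = window.upper()
    runs = [len(m) for m in re.findall(r"A+", upper)]
    longest = max(runs, default=0)
    a_fraction = upper.count("A") / len(window)
    flag = longest >= run_threshold or a_fraction > content_threshold
    return longest, a_fraction, flag


def find_split_pairs(metadata: pd.DataFrame,
                     max_gap_seconds: float = 1.0) -> list[tuple[str, str]]:
    """Pair consecutive reads on one channel separated by a short gap.

    ``metadata`` needs columns read_id, channel, start_time, duration.
    Pairing is greedy earliest-first and each read joins at most one pair.
    """
    required = {"read_id", "channel", "start_time", "duration"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata lacks columns: {sorted(missing)}")
    pairs: list[tuple[str, str]] = []
    for _, group in metadata.sort_values(["channel", "start_time"]).groupby(
            "channel", sort=False):
        rows = group.itertuples(index=False)
        prev = next(rows, None)
        for row in rows:
            if prev is not None:
                gap = row.start_time - (prev.start_time + prev.duration)
                if gap <= max_gap_seconds:
                    pairs.append((prev.read_id, row.read_id))
                    prev = None  # greedy: each read in at most one pair
                    continue
            prev = row
    return pairs


def split_read_percentage(n_pairs: int, n_reads: int) -> float:
    """Percentage of reads that belong to a split pair (2 reads per pair)."""
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    return 100.0 * 2 * n_pairs / n_reads


def quality_length_correlation(tails, qscores) -> SpearmanResult:
    """Spearman rank correlation between tail lengths and mean qscores."""
    tails = np.asarray(list(tails), dtype=float)
    qscores = np.asarray(list(qscores), dtype=float)
    if tails.size != qscores.size:
        raise ValueError("tails and qscores must have equal length")
    if tails.size < 10:
        raise InsufficientReadsError(
            f"insufficient reads: {tails.size} < 10")
    if np.unique(tails).size < 2 or np.unique(qscores).size < 2:
        return SpearmanResult(float("nan"), float("nan"), "not_applicable")
    r, p = spearmanr(tails, qscores)
    return SpearmanResult(float(r), float(p), "ok")


def short_tail_report(
    estimates: pd.DataFrame,
    stubs: dict[str, AlignmentStub],
    references: dict[str, str],
    tail_cutoff: float = 10.0,
    end_threshold_nt: int = 20,
    run_threshold: int = 4,
    content_threshold: float = 0.5,
    split_partners: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, ShortTailSummary]:
    """Per-read diagnostics and class proportions for short-tail calls.

    Restricts ``estimates`` (read_id, qc, tail_nt, ...) to passing reads
    with tail_nt < ``tail_cutoff`` and classifies each exactly once as
    full_length (3'-intact, degradation-consistent) or truncated; truncated
    reads are additionally screened for mispriming. Reads whose reference
    is missing are skipped with a logged warning.
    """
    split_partners = split_partners or {}
    short = estimates[(estimates["qc"] == "pass")
                      & (estimates["tail_nt"] < tail_cutoff)]
    records = []
    for row in short.itertuples(index=False):
        stub = stubs.get(row.read_id)
        if stub is None:
            log.warning("no alignment stub for %s; skipped", row.read_id)
            continue
        seq = references.get(stub.ref_id)
        if seq is None:
            log.warning("no reference sequence for %s (read %s); skipped",
                        stub.ref_id, row.read_id)
            continue
        end_class = classify_end(stub, end_threshold_nt)
        end_pos = len(seq) - stub.ref_end_offset_nt
        longest, frac, flag = mispriming_screen(
            seq, end_pos, run_threshold, content_threshold)
        tenmer = seq[end_pos:end_pos + DOWNSTREAM_WINDOW_NT] or None
        records.append(DiagnosticRecord(
            read_id=row.read_id, tail_nt=float(row.tail_nt),
            end_class=end_class, downstream_10mer=tenmer,
            longest_a_run=longest, a_fraction=frac, mispriming_flag=flag,
            split_partner=split_partners.get(row.read_id),
            mean_qscore=float(stub.mean_qscore)))

    table = pd.DataFrame(
        [r.__dict__ for r in records],
        columns=["read_id", "tail_nt", "end_class", "downstream_10mer",
                 "longest_a_run", "a_fraction", "mispriming_flag",
                 "split_partner", "mean_qscore"])
    if not records:
        summary = ShortTailSummary(0, float("nan"), float("nan"),
                                   float("nan"), float("nan"),
                                   status="not_applicable")
        return table, summary

    n = len(records)
    truncated = table["end_class"] == "truncated"
    n_trunc = int(truncated.sum())
    summary = ShortTailSummary(
        n_short=n,
        fraction_full_length=float((~truncated).mean()),
        fraction_truncated=float(truncated.mean()),
        fraction_truncated_misprimed=(
            float(table.loc[truncated, "mispriming_flag"].mean())
            if n_trunc else float("nan")),
        fraction_qscore_gt20=float((table["mean_qscore"] > 20).mean()),
    )
    return table, summary
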