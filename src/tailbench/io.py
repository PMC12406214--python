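"""File round-tripping: TSV tables, the signal container, FASTA references.

All tabular exchange uses TSV with fixed headers (diffable, and matching
the per-read output tables the published tools emit). The signal container
is a self-describing JSON-lines file: a header line followed by one record
per read holding the raw samples and the acquisition metadata. Floats
survive a write/read cycle exactly (shortest-repr serialization).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import SchemaError
from .estimate import TailEstimate
from .segmentation import Boundaries
from .simulate import AlignmentStub, RefTranscript, Squiggle

__all__ = [
    "ESTIMATE_COLUMNS", "TRUTH_COLUMNS", "BOUNDARY_COLUMNS", "STUB_COLUMNS",
    "write_estimates", "read_estimates", "write_truth", "read_truth",
    "write_boundaries", "read_boundaries", "write_stubs", "read_stubs",
    "write_signals", "read_signals",
    "write_reference_fasta", "read_reference_fasta",
]

ESTIMATE_COLUMNS = ["read_id", "method", "qc", "tail_nt",
                    "polya_start", "polya_end", "rate"]
TRUTH_COLUMNS = ["read_id", "true_tail_nt", "rate", "artifact_labels",
                 "ref_id", "ref_end_offset_nt", "mean_qscore"]
BOUNDARY_COLUMNS = ["read_id", "method", "detected",
                    "polya_start", "polya_end", "score"]
STUB_COLUMNS = ["read_id", "ref_id", "ref_end_offset_nt", "mean_qscore"]

_SIGNAL_MAGIC = "tailbench-signals"


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"read_id": str})
    except pd.errors.ParserError as exc:  # pandas reports the line number
        raise SchemaError(f"{path}: malformed TSV: {exc}") from exc
    _check_columns(df, required, path)
    return df


def write_estimates(estimates, path) -> None:
    if isinstance(estimates, pd.DataFrame):
        df = estimates
        _check_columns(df, ESTIMATE_COLUMNS, path)
    else:
        df = pd.DataFrame([{
            "read_id": e.read_id, "method": e.method, "qc": e.qc,
            "tail_nt": e.tail_nt, "polya_start": e.polya_start,
            "polya_end": e.polya_end, "rate": e.rate,
        } for e in estimates], columns=ESTIMATE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_estimates(path) -> pd.DataFrame:
    return _read_tsv(path, ESTIMATE_COLUMNS)


def estimates_to_objects(df: pd.DataFrame) -> list[TailEstimate]:
    return [TailEstimate(str(r.read_id), r.method, r.qc,
                         tail_nt=float(r.tail_nt),
                         polya_start=int(r.polya_start),
                         polya_end=int(r.polya_end), rate=float(r.rate))
            for r in df.itertuples(index=False)]


def write_truth(truth: pd.DataFrame, path) -> None:
    _check_columns(truth, TRUTH_COLUMNS, path)
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = _read_tsv(path, TRUTH_COLUMNS)
    df["artifact_labels"] = df["artifact_labels"].fillna("")
    return df


def write_boundaries(boundaries, path) -> None:
    df = pd.DataFrame([{
        "read_id": b.read_id, "method": b.method, "detected": b.detected,
        "polya_start": b.polya_start, "polya_end": b.polya_end,
        "score": b.score,
    } for b in boundaries], columns=BOUNDARY_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_boundaries(path) -> list[Boundaries]:
    df = _read_tsv(path, BOUNDARY_COLUMNS)
    return [Boundaries(str(r.read_id), int(r.polya_start), int(r.polya_end),
                       bool(r.detected), r.method, float(r.score))
            for r in df.itertuples(index=False)]


def write_stubs(stubs, path) -> None:
    df = pd.DataFrame([{
        "read_id": s.read_id, "ref_id": s.ref_id,
        "ref_end_offset_nt": s.ref_end_offset_nt,
        "mean_qscore": s.mean_qscore,
    } for s in stubs], columns=STUB_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_stubs(path) -> list[AlignmentStub]:
    df = _read_tsv(path, STUB_COLUMNS)
    return [AlignmentStub(str(r.read_id), str(r.ref_id),
                          int(r.ref_end_offset_nt), float(r.mean_qscore))
            for r in df.itertuples(index=False)]


def write_signals(squiggles, path) -> None:
    """Self-describing JSON-lines signal container, one record per read."""
    squiggles = list(squiggles)
    with open(path, "w") as fh:
        fh.write(json.dumps({"format": _SIGNAL_MAGIC, "version": 1,
                             "n_reads": len(squiggles)}) + "\n")
        for sq in squiggles:
            fh.write(json.dumps({
                "read_id": sq.read_id,
                "sampling_rate": sq.sampling_rate,
                "channel": sq.channel,
                "start_time": sq.start_time,
                "samples": sq.samples.tolist(),
            }) + "\n")


def read_signals(path) -> list[Squiggle]:
    squiggles = []
    with open(path) as fh:
        header_line = fh.readline()
        try:
            header = json.loads(header_line)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: line 1: not a signal container") from exc
        if header.get("format") != _SIGNAL_MAGIC:
            raise SchemaError(f"{path}: line 1: not a signal container")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                squiggles.append(Squiggle(
                    rec["read_id"], np.array(rec["samples"], dtype=float),
                    rec["sampling_rate"], rec["channel"], rec["start_time"]))
            except (json.JSONDecodeError, KeyError) as exc:
                raise SchemaError(
                    f"{path}: line {lineno}: malformed record ({exc})") from exc
    n = header.get("n_reads")
    if n is not None and n != len(squiggles):
        raise SchemaError(
            f"{path}: header declares {n} reads, found {len(squiggles)}")
    return squiggles


def write_reference_fasta(references, path) -> None:
    records = [SeqRecord(Seq(r.sequence), id=r.ref_id,
                         description=f"misprime_pos={r.misprime_pos}")
               for r in references]
    SeqIO.write(records, path, "fasta")


def read_reference_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def signal_metadata(squiggles) -> pd.DataFrame:
    """Per-read acquisition metadata table (for split-pair detection)."""
    return pd.DataFrame([{
        "read_id": sq.read_id, "channel": sq.channel,
        "start_time": sq.start_time, "duration": sq.duration,
    } for sq in squiggles])
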