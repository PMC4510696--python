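"""Adapter trimming and minimum-length filtering.

The 3' adapter is located by unit-cost edit-distance search (substitutions,
insertions, deletions), allowing at most ``floor(max_error_rate x matched
adapter length)`` edits — the error-rate semantics of standard small-RNA
trimmers. Both full internal occurrences and 3'-terminal suffix overlaps of
at least 3 nt are considered. Among admissible occurrences the one with the
smallest edit count wins, ties broken by the leftmost start, and everything
from the match start to the read end is removed.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import edlib

MIN_OVERLAP = 3


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    pass_filter: bool = True

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TrimReport:
    reads_in: int = 0
    reads_trimmed: int = 0
    reads_removed_short: int = 0
    warnings: int = 0

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def find_adapter(seq: str, adapter: str, max_error_rate: float = 0.1) -> tuple[int, int] | None:
    """Best admissible adapter occurrence as ``(start, edits)``, or None.

    Candidate placements are (a) the full adapter aligned starting at any
    read position (budget ``floor(rate x m)``) and (b) a proper adapter
    prefix of length ``alen`` in [3, m) aligned to the read's 3' tail
    (budget ``floor(rate x alen)``). Exact occurrences short-circuit; the
    general case scores placements by edit distance (edlib).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not 0 <= max_error_rate < 1:
        raise ValueError("max_error_rate must lie in [0, 1)")
    n, m = len(seq), len(adapter)
    # fast path: leftmost exact full occurrence beats every other candidate
    s0 = seq.find(adapter)
    if s0 != -1:
        return s0, 0
    # fast path: longest exact suffix overlap (leftmost 0-edit candidate left)
    for alen in range(min(m - 1, n), MIN_OVERLAP - 1, -1):
        if seq.endswith(adapter[:alen]):
            return n - alen, 0
    best: tuple[int, int] | None = None  # (edits, start)
    full_budget = int(max_error_rate * m)
    if full_budget > 0:
        for s in range(n - (m - full_budget) + 1):
            r = edlib.align(adapter, seq[s:], mode="SHW", k=full_budget)
            ed = r["editDistance"]
            if ed != -1 and (best is None or (ed, s) < best):
                best = (ed, s)
    max_ov_budget = int(max_error_rate * (m - 1))
    if max_ov_budget > 0:
        for s in range(max(0, n - (m - 1) - max_ov_budget), n - MIN_OVERLAP + 1):
            rest = seq[s:]
            for alen in range(MIN_OVERLAP, m):
                budget = int(max_error_rate * alen)
                if abs(alen - len(rest)) > budget:
                    continue
                ed = edlib.align(rest, adapter[:alen], mode="NW", k=budget)["editDistance"]
                if ed != -1 and (best is None or (ed, s) < best):
                    best = (ed, s)
    if best is None:
        return None
    return best[1], best[0]


def trim_adapter(
    read: ReadRecord | str,
    adapter: str,
    max_error_rate: float = 0.1,
    report: TrimReport | None = None,
) -> ReadRecord:
    """Remove the best-scoring 3' adapter occurrence; unchanged if none."""
    rec = read if isinstance(read, ReadRecord) else ReadRecord("read", read)
    if report is not None:
        report.reads_in += 1
    if not rec.sequence:
        if report is not None:
            report.warnings += 1
        return rec
    hit = find_adapter(rec.sequence, adapter, max_error_rate)
    if hit is None:
        return rec
    if report is not None:
        report.reads_trimmed += 1
    return ReadRecord(rec.read_id, rec.sequence[: hit[0]])


def filter_min_length(
    reads: list[ReadRecord], min_length: int = 15
) -> tuple[list[ReadRecord], int]:
    """Keep reads of at least ``min_length`` nt; return (kept, n_removed)."""
    kept = [r for r in reads if r.length >= min_length]
    return kept, len(reads) - len(kept)


def process_reads(
    reads: list[tuple[str, str, str]] | list[ReadRecord],
    adapter: str,
    max_error_rate: float = 0.1,
    min_length: int = 15,
) -> tuple[list[ReadRecord], TrimReport]:
    """Adapter-trim then length-filter a library; returns kept reads + report."""
    report = TrimReport()
    recs = []
    for r in reads:
        rec = r if isinstance(r, ReadRecord) else ReadRecord(r[0], r[1])
        recs.append(trim_adapter(rec, adapter, max_error_rate, report))
    kept, removed = filter_min_length(recs, min_length)
    report.reads_removed_short = removed
    return kept, report


def process_fastq(
    fastq_in: str | Path,
    fastq_out: str | Path,
    adapter: str,
    max_error_rate: float = 0.1,
    min_length: int = 15,
) -> TrimReport:
    from .simulate import read_fastq, write_fastq

    reads = read_fastq(fastq_in)
    kept, report = process_reads(reads, adapter, max_error_rate, min_length)
    write_fastq([(r.read_id, r.sequence, "I" * r.length) for r in kept], fastq_out)
    return report
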