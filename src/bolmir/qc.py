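"""Raw-read cleaning for small RNA libraries.

A read survives iff it has no N base, at most 4 bases below Q10 and at most
6 below Q13, a detectable 3' adapter whose removal leaves an insert of at
least 18 nt, and the insert is neither a 5'-adapter contaminant nor a
poly-A fragment.  Rules are applied in a fixed order and each rejected read
increments exactly one counter, so the report is an exact partition of the
input.

Quality rules are evaluated on the untrimmed read.  Adapter-dimer reads
(insert length 0) fall under the short-insert counter.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass, fields

from .core import PipelineConfig, SmallRNARead, rna

__all__ = ["QcReport", "qc_filter", "find_adapter3"]


@dataclass
class QcReport:
    input_reads: int = 0
    removed_n: int = 0
    removed_q10: int = 0
    removed_q13: int = 0
    removed_short: int = 0
    removed_5prime_adapter: int = 0
    removed_polyA: int = 0
    removed_no_3prime_adapter: int = 0
    clean_reads: int = 0

    def check(self) -> None:
        removed = sum(
            getattr(self, f.name)
            for f in fields(self)
            if f.name.startswith("removed_")
        )
        if self.clean_reads + removed != self.input_reads:
            raise AssertionError("QC accounting does not partition the input")

    def to_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def find_adapter3(seq: str, adapter3: str, min_overlap: int = 6, max_mismatch: int = 1) -> int:
    """Return the insert length (adapter start) or -1 if no adapter found.

    Detects the longest prefix of *adapter3* that aligns at the read's 3'
    end: either the full adapter somewhere inside the read, or a prefix of
    it running off the end.  At least *min_overlap* aligned bases and at
    most *max_mismatch* mismatches are required; the earliest (longest
    prefix) hit wins so trimming is maximal.
    """
    seq = rna(seq)
    adapter3 = rna(adapter3)
    n, m = len(seq), len(adapter3)
    for start in range(0, n - min_overlap + 1):
        span = min(m, n - start)
        mism = sum(1 for a, b in zip(seq[start : start + span], adapter3[:span]) if a != b)
        if mism <= max_mismatch:
            return start
    return -1


def _is_5prime_contaminant(insert: str, adapter5: str, probe: int = 8, max_mismatch: int = 1) -> bool:
    """Insert whose first *probe* nt match the 5' adapter with <=1 mismatch."""
    if len(insert) < probe or len(adapter5) < probe:
        return False
    mism = sum(1 for a, b in zip(rna(insert[:probe]), rna(adapter5[:probe])) if a != b)
    return mism <= max_mismatch


def _is_polya(insert: str, frac: float = 0.8, run: int = 8) -> bool:
    if not insert:
        return False
    if insert.count("A") / len(insert) >= frac:
        return True
    return insert.endswith("A" * run)


def qc_filter(
    reads: Iterable[SmallRNARead],
    adapter3: str,
    adapter5: str,
    cfg: PipelineConfig | None = None,
    require_adapter3: bool = True,
) -> tuple[list[str], QcReport]:
    """Apply the cleaning rules; return (clean inserts, report).

    With ``require_adapter3=False`` (already-trimmed input) the adapter
    search is skipped and each read is its own insert; this makes the filter
    idempotent on its own output.
    """
    cfg = cfg or PipelineConfig()
    if require_adapter3 and not adapter3:
        raise ValueError("adapter3 must be non-empty")
    report = QcReport()
    clean: list[str] = []
    for read in reads:
        report.input_reads += 1
        seq = rna(read.seq)
        if "N" in seq:
            report.removed_n += 1
            continue
        if sum(1 for q in read.qual if q < 10) > cfg.max_bases_below_q10:
            report.removed_q10 += 1
            continue
        if sum(1 for q in read.qual if q < 13) > cfg.max_bases_below_q13:
            report.removed_q13 += 1
            continue
        if require_adapter3:
            pos = find_adapter3(seq, adapter3)
            if pos < 0:
                report.removed_no_3prime_adapter += 1
                continue
            insert = seq[:pos]
        else:
            insert = seq
        if len(insert) < cfg.min_read_len:
            report.removed_short += 1
            continue
        if _is_5prime_contaminant(insert, adapter5):
            report.removed_5prime_adapter += 1
            continue
        if _is_polya(insert):
            report.removed_polyA += 1
            continue
        clean.append(insert)
        report.clean_reads += 1
    report.check()
    return clean, report
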