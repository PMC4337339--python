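"""Raw-read quality control: drop adapter, N-rich and low-quality reads.

Three whole-read filters, applied in fixed order with the first failure
winning:

1. adapter   — the read contains any configured adapter sequence as an
               exact substring;
2. unknown   — more than 5% of bases are 'N';
3. lowqual   — more than 30% of bases have Phred quality <= 10.

The fraction thresholds are strict (>), the Phred cutoff inclusive (<=).
Reads are kept or dropped whole; no trimming.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO

import pandas as pd

from .io import FastqRecord, MalformedRecordError, iter_fastq, write_fastq

__all__ = ["QcThresholds", "QcReport", "classify_read", "filter_records",
           "filter_fastq", "REASONS"]

REASONS = ("adapter", "unknown", "lowqual")


@dataclass(frozen=True)
class QcThresholds:
    max_unknown_fraction: float = 0.05
    max_lowqual_fraction: float = 0.30
    lowqual_phred_cutoff: int = 10
    adapter_sequences: tuple[str, ...] = ()
    phred_offset: int = 33

    def __post_init__(self):
        for name in ("max_unknown_fraction", "max_lowqual_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.lowqual_phred_cutoff < 0:
            raise ValueError("lowqual_phred_cutoff must be >= 0")
        if self.phred_offset not in (33, 64):
            raise ValueError(f"phred_offset must be 33 or 64, got {self.phred_offset}")
        object.__setattr__(self, "adapter_sequences",
                           tuple(a.upper() for a in self.adapter_sequences))


@dataclass
class QcReport:
    input_reads: int = 0
    removed_adapter: int = 0
    removed_unknown: int = 0
    removed_lowqual: int = 0
    clean_reads: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def classify_read(read_id: str, bases: str, qualities: str,
                  thresholds: QcThresholds) -> str | None:
    """Return None for a clean read, else the first-matching failure reason.

    Reasons are checked in the fixed order adapter -> unknown -> lowqual.
    """
    if len(bases) != len(qualities):
        raise MalformedRecordError(
            f"read {read_id!r}: sequence length {len(bases)} != "
            f"quality length {len(qualities)}")
    if not bases:
        raise MalformedRecordError(f"read {read_id!r}: empty sequence")
    length = len(bases)
    upper = bases.upper()

    for adapter in thresholds.adapter_sequences:
        if adapter and adapter in upper:
            return "adapter"

    if upper.count("N") / length > thresholds.max_unknown_fraction:
        return "unknown"

    offset = thresholds.phred_offset
    cutoff = thresholds.lowqual_phred_cutoff
    n_low = 0
    for ch in qualities:
        q = ord(ch) - offset
        if q < 0:
            raise MalformedRecordError(
                f"read {read_id!r}: quality char {ch!r} not decodable "
                f"with Phred+{offset}")
        if q <= cutoff:
            n_low += 1
    if n_low / length > thresholds.max_lowqual_fraction:
        return "lowqual"
    return None


def filter_records(records: Iterable[FastqRecord], thresholds: QcThresholds,
                   report: QcReport) -> Iterator[FastqRecord]:
    """Yield clean records in input order, tallying removals into `report`."""
    for title, bases, quals in records:
        report.input_reads += 1
        verdict = classify_read(title.split()[0] if title else "", bases, quals,
                                thresholds)
        if verdict is None:
            report.clean_reads += 1
            yield title, bases, quals
        else:
            setattr(report, f"removed_{verdict}",
                    getattr(report, f"removed_{verdict}") + 1)


def filter_fastq(in_handle: TextIO, out_handle: TextIO,
                 thresholds: QcThresholds | None = None) -> QcReport:
    """Filter a FASTQ stream; write clean reads; return the removal report."""
    thresholds = thresholds or QcThresholds()
    report = QcReport()
    write_fastq(filter_records(iter_fastq(in_handle), thresholds, report),
                out_handle)
    return report
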