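"""Readers and writers shared by all pipeline stages.

All tabular artifacts are TSV with a single header line, optionally preceded
by ``#``-prefixed comment lines carrying provenance (tool version, config
hash). Annotation maps use the GMT-like layout: one category per line,
``category_id <TAB> description <TAB> gene1 <TAB> gene2 ...``.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, Mapping, Sequence, TextIO, Tuple

import pandas as pd

COUNT_INDEX = "gene_id"
LENGTH_COL = "length_nt"
PROFILE_COLS = ["library_id", "stage", "total_reads"]

FastqRecord = Tuple[str, str, str]  # (id line sans '@', bases, quality string)


class MalformedRecordError(ValueError):
    """A sequencing record that cannot be parsed or is internally inconsistent."""


def write_table(frame: pd.DataFrame, path: str | os.PathLike,
                comments: Sequence[str] = (), index: bool = False,
                float_format: str = "%.6g") -> None:
    """Write a TSV table with optional leading ``#`` comment lines."""
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=index, float_format=float_format)


def read_table(path: str | os.PathLike, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a count table: gene_id, length_nt, then one count column per library."""
    frame = read_table(path, index_col=COUNT_INDEX)
    if LENGTH_COL not in frame.columns:
        raise ValueError(f"count table {path} lacks a '{LENGTH_COL}' column")
    return frame


def write_counts(frame: pd.DataFrame, path: str | os.PathLike,
                 comments: Sequence[str] = ()) -> None:
    write_table(frame.reset_index() if frame.index.name == COUNT_INDEX else frame,
                path, comments=comments)


def read_profiles(path: str | os.PathLike) -> pd.DataFrame:
    """Read library profiles: library_id, stage, total uniquely mapped reads."""
    frame = read_table(path)
    missing = [c for c in PROFILE_COLS if c not in frame.columns]
    if missing:
        raise ValueError(f"profile table {path} lacks columns {missing}")
    return frame.set_index("library_id", drop=False)


def write_profiles(frame: pd.DataFrame, path: str | os.PathLike,
                   comments: Sequence[str] = ()) -> None:
    write_table(frame[PROFILE_COLS], path, comments=comments)


def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    """Parse a GMT-like annotation map into ``{category_id: {gene ids}}``."""
    categories: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs id, description and >=1 gene")
            categories[fields[0]] = set(g for g in fields[2:] if g)
    return categories


def write_gmt(categories: Mapping[str, Iterable[str]], path: str | os.PathLike,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for cat_id in sorted(categories):
            desc = (descriptions or {}).get(cat_id, cat_id)
            genes = "\t".join(sorted(categories[cat_id]))
            fh.write(f"{cat_id}\t{desc}\t{genes}\n")


def iter_fastq(handle: TextIO) -> Iterator[FastqRecord]:
    """Yield ``(title, bases, qualities)`` from a FASTQ stream.

    Thin wrapper over Biopython's FastqGeneralIterator that converts its
    parse failures into :class:`MalformedRecordError` naming the index of
    the record on which parsing stopped.
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    parser = FastqGeneralIterator(handle)
    index = 0
    while True:
        try:
            record = next(parser)
        except StopIteration:
            return
        except ValueError as exc:
            raise MalformedRecordError(f"record {index}: {exc}") from exc
        yield record
        index += 1


def write_fastq(records: Iterable[FastqRecord], handle: TextIO) -> int:
    n = 0
    for title, bases, quals in records:
        handle.write(f"@{title}\n{bases}\n+\n{quals}\n")
        n += 1
    return n
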