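"""Expression quantification: RPKM and normalized log2 expression ratios.

RPKM (reads per kilobase of transcript per million mapped reads) for a gene
with C uniquely aligned reads, transcript length L nt, in a library with N
total uniquely mapped reads:

    RPKM = 1e9 * C / (N * L)

Fold changes between two libraries are computed from library-size-normalized
counts with a pseudocount so genes observed in only one library stay finite:

    log2 ratio = log2( ((y + c) / N2) / ((x + c) / N1) )
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["compute_rpkm", "log2_ratio", "rpkm_matrix"]


def compute_rpkm(counts, library_total, length_nt):
    """RPKM for scalar or array counts.

    Parameters
    ----------
    counts : int or array-like
        Uniquely aligned reads C for the gene(s); non-negative.
    library_total : float
        Total uniquely mapped reads N of the library; must be positive.
    length_nt : float or array-like
        Transcript length L in nucleotides; must be positive.
    """
    counts = np.asarray(counts, dtype=float)
    length_nt = np.asarray(length_nt, dtype=float)
    if library_total <= 0:
        raise ValueError(f"library_total must be positive, got {library_total}")
    if np.any(length_nt <= 0):
        raise ValueError("length_nt must be positive for every gene")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    out = 1e9 * counts / (library_total * length_nt)
    return out.item() if out.ndim == 0 else out


def log2_ratio(count_test, count_ctrl, total_test, total_ctrl, pseudocount=1.0):
    """Normalized log2 fold change of the test library over the control.

    ``log2(((y + c)/N_test) / ((x + c)/N_ctrl))`` — finite for all
    non-negative counts, antisymmetric under swapping the two libraries.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    if total_test <= 0 or total_ctrl <= 0:
        raise ValueError("library totals must be positive")
    y = np.asarray(count_test, dtype=float)
    x = np.asarray(count_ctrl, dtype=float)
    out = np.log2((y + pseudocount) / total_test) - np.log2((x + pseudocount) / total_ctrl)
    return out.item() if out.ndim == 0 else out


def rpkm_matrix(counts: pd.DataFrame, profiles: pd.DataFrame,
                length_col: str = "length_nt") -> pd.DataFrame:
    """Per-gene RPKM for every library in `profiles`.

    `counts` is indexed by gene id with a length column plus one count column
    per library id; `profiles` is indexed by library id with a `total_reads`
    column. Returns a gene x library RPKM DataFrame.
    """
    lengths = counts[length_col]
    cols = {}
    for lib_id, row in profiles.iterrows():
        if lib_id not in counts.columns:
            raise KeyError(f"library {lib_id!r} has no count column")
        cols[lib_id] = compute_rpkm(counts[lib_id].to_numpy(),
                                    float(row["total_reads"]),
                                    lengths.to_numpy())
    return pd.DataFrame(cols, index=counts.index)
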