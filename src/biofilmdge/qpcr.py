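"""Relative qPCR quantification (2^-ddCt) and RNA-seq concordance.

The Livak 2^-ddCt method normalizes a target gene's threshold cycle (Ct) to
a reference gene (here 18S rRNA) in each condition, then compares the two
conditions:

    ddCt = (Ct_target,test - Ct_ref,test) - (Ct_target,ctrl - Ct_ref,ctrl)
    fold change = 2^-ddCt

Technical replicates are averaged (arithmetic mean of Ct) before
differencing. Concordance with sequencing-based estimates is the Pearson
product-moment correlation of the two log2 fold-change vectors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["delta_delta_ct", "fold_changes_from_ct_table", "concordance",
           "DEFAULT_REFERENCE_GENE", "CT_COLUMNS"]

DEFAULT_REFERENCE_GENE = "18S"
CT_COLUMNS = ["sample_id", "condition", "gene_id", "replicate", "ct"]


def _mean_ct(value) -> float:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 0 or np.any(~np.isfinite(arr)):
        raise ValueError("Ct values must be non-empty and finite")
    return float(arr.mean())


def delta_delta_ct(ct_target_test, ct_ref_test, ct_target_ctrl, ct_ref_ctrl) -> float:
    """2^-ddCt fold change of the target in test vs control.

    Each argument is a scalar mean Ct or a sequence of replicate Ct values
    (averaged before differencing). Invariant to any constant added to all
    four Ct values.
    """
    ddct = ((_mean_ct(ct_target_test) - _mean_ct(ct_ref_test))
            - (_mean_ct(ct_target_ctrl) - _mean_ct(ct_ref_ctrl)))
    return float(2.0 ** (-ddct))


def fold_changes_from_ct_table(ct_table: pd.DataFrame,
                               reference_gene: str = DEFAULT_REFERENCE_GENE) -> pd.DataFrame:
    """Per-gene 2^-ddCt fold changes from a long-format Ct table.

    Expects columns sample_id, condition (control/test), gene_id, replicate,
    ct. Returns a table with fold_change and log2_fold_change per target gene.
    """
    missing = [c for c in CT_COLUMNS if c not in ct_table.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns {missing}")
    means = ct_table.groupby(["condition", "gene_id"])["ct"].mean()

    def ref_ct(condition: str) -> float:
        try:
            return means[(condition, reference_gene)]
        except KeyError:
            raise ValueError(
                f"missing reference-gene ({reference_gene!r}) Ct for condition {condition!r}")

    ref = {cond: ref_ct(cond) for cond in ("control", "test")}
    rows = []
    for gene in sorted(ct_table["gene_id"].unique()):
        if gene == reference_gene:
            continue
        try:
            fc = delta_delta_ct(means[("test", gene)], ref["test"],
                                means[("control", gene)], ref["control"])
        except KeyError:
            raise ValueError(f"gene {gene!r} lacks Ct in one of the conditions")
        rows.append({"gene_id": gene, "fold_change": fc,
                     "log2_fold_change": float(np.log2(fc))})
    return pd.DataFrame(rows, columns=["gene_id", "fold_change", "log2_fold_change"])


def concordance(rnaseq_lfc: pd.Series | dict, qpcr_lfc: pd.Series | dict):
    """Pearson r between sequencing and qPCR log2 fold changes.

    Computed over the genes shared by the two inputs (at least 3 required).
    Returns ``(r, paired_table)`` where the table lists both values per gene.
    """
    a = pd.Series(rnaseq_lfc, dtype=float)
    b = pd.Series(qpcr_lfc, dtype=float)
    shared = sorted(set(a.index) & set(b.index))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes for a correlation, got {len(shared)}")
    paired = pd.DataFrame({"gene_id": shared,
                           "rnaseq_log2fc": a[shared].to_numpy(),
                           "qpcr_log2fc": b[shared].to_numpy()})
    r = stats.pearsonr(paired["rnaseq_log2fc"], paired["qpcr_log2fc"]).statistic
    return float(r), paired
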