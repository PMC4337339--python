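"""Category over-representation testing of DEG sets against an annotated universe.

Categories are flat gene sets (KEGG-pathway- or GO-term-like) supplied as a
GMT-like map. For a category with K genes in a universe of N genes, and a
DEG set that (after intersection with the universe) has n genes of which k
fall in the category, the enrichment p-value is the hypergeometric upper
tail P(X >= k). The tail is summed in log-space so that p-values far below
the double-precision underflow threshold of a naive product (e.g. 1e-50)
remain accurate. Q-values are Benjamini-Hochberg across the categories
tested in one run; categories with Q <= 0.05 are called enriched.

Only over-representation is tested; depletion is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import special

from .dge import adjust_fdr

__all__ = ["AnnotationSet", "hypergeom_upper_tail", "log_hypergeom_upper_tail",
           "enrich_categories", "ENRICHMENT_COLUMNS"]

ENRICHMENT_COLUMNS = ["category_id", "k", "K", "n", "N_univ",
                      "p_value", "q_value", "significant"]


@dataclass
class AnnotationSet:
    """category_id -> gene set map plus the annotated universe (their union)."""

    categories: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not self.universe:
            self.universe = set().union(*self.categories.values()) if self.categories else set()
        for cat_id, genes in self.categories.items():
            if not genes <= self.universe:
                raise ValueError(f"category {cat_id!r} is not a subset of the universe")

    @classmethod
    def from_gmt(cls, path) -> "AnnotationSet":
        from .io import read_gmt
        return cls(categories=read_gmt(path))

    def __len__(self) -> int:
        return len(self.categories)


def _check_counts(k: int, K: int, n: int, n_univ: int) -> None:
    if n_univ <= 0:
        raise ValueError("universe size must be positive")
    if not (0 <= K <= n_univ and 0 <= n <= n_univ):
        raise ValueError(f"need 0 <= K={K}, n={n} <= N_univ={n_univ}")
    if k < 0 or k > K or k > n:
        raise ValueError(f"inconsistent counts: k={k} must satisfy 0 <= k <= min(K={K}, n={n})")


def log_hypergeom_upper_tail(k: int, K: int, n: int, n_univ: int) -> float:
    """log P(X >= k) for X ~ Hypergeometric(N_univ, K, n).

    Summed as logsumexp over log-gamma terms, so extreme tails (p ~ 1e-50
    and below) keep full relative precision.
    """
    _check_counts(k, K, n, n_univ)
    if k == 0:
        return 0.0
    i = np.arange(k, min(K, n) + 1)
    if i.size == 0:
        return -np.inf
    log_terms = (special.gammaln(K + 1) - special.gammaln(i + 1)
                 - special.gammaln(K - i + 1)
                 + special.gammaln(n_univ - K + 1) - special.gammaln(n - i + 1)
                 - special.gammaln(n_univ - K - (n - i) + 1)
                 - (special.gammaln(n_univ + 1) - special.gammaln(n + 1)
                    - special.gammaln(n_univ - n + 1)))
    return float(min(0.0, special.logsumexp(log_terms)))


def hypergeom_upper_tail(k: int, K: int, n: int, n_univ: int) -> float:
    """Enrichment p-value P(X >= k); 1 when k = 0."""
    return float(np.exp(log_hypergeom_upper_tail(k, K, n, n_univ)))


def enrich_categories(deg_genes: Iterable[str], annotation: AnnotationSet,
                      q_method: str = "BH", q_cutoff: float = 0.05) -> pd.DataFrame:
    """Test every annotated category for DEG over-representation.

    The DEG set is intersected with the annotated universe before testing
    (the background n counts only DEGs that carry annotation); empty
    categories are skipped. Rows are sorted by p ascending; q-values are
    computed across exactly the categories tested.
    """
    if not annotation.universe:
        raise ValueError("annotation universe is empty")
    deg_in_universe = set(deg_genes) & annotation.universe
    n = len(deg_in_universe)
    n_univ = len(annotation.universe)

    rows = []
    for cat_id in sorted(annotation.categories):  # order-independent tie-breaks
        genes = annotation.categories[cat_id]
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & deg_in_universe)
        rows.append({"category_id": cat_id, "k": k, "K": K, "n": n,
                     "N_univ": n_univ,
                     "p_value": hypergeom_upper_tail(k, K, n, n_univ)})
    table = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-2])
    if len(table):
        table["q_value"] = adjust_fdr(table["p_value"].to_numpy(), method=q_method)
        table["significant"] = table["q_value"] <= q_cutoff
        table = table.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        table["q_value"] = []
        table["significant"] = []
    return table[ENRICHMENT_COLUMNS]
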