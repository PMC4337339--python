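"""Two-library differential expression by the Audic-Claverie exact test.

For a gene with x tags in library 1 (N1 total tags) and y tags in library 2
(N2 total), the Audic-Claverie model places a flat prior on the unknown
Poisson rate and marginalizes it, giving the conditional law of the second
count given the first:

    p(y | x) = (N2/N1)^y * (x+y)! / (x! y!) * (1 + N2/N1)^-(x+y+1)

which is the negative-binomial distribution with size x+1 and success
probability N1/(N1+N2). The two-sided p-value doubles the smaller tail:
with S = sum_{i<=y} p(i|x),

    p = min(1, 2*S)                     if S <= 1/2
    p = min(1, 2*(1 - S + p(y|x)))      otherwise,

the upper branch retaining p(y|x) so both branches include the observed
point and agree near S = 1/2.

`AudicClaverieDGE` wraps the per-gene test over a count table; its `fit()`
returns a `DGEResults` carrying normalized log2 ratios, raw and FDR-adjusted
p-values, significance calls, a `summary()` table and a volcano plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .quant import compute_rpkm, log2_ratio

__all__ = [
    "ac_pmf", "ac_logpmf", "ac_two_sided_p", "adjust_fdr", "call_degs",
    "summarize_stage_counts", "AudicClaverieDGE", "DGEResults",
    "DEFAULT_FDR_CUTOFF", "DEFAULT_LFC_CUTOFF",
]

DEFAULT_FDR_CUTOFF = 0.001
DEFAULT_LFC_CUTOFF = 1.0

RESULT_COLUMNS = ["gene_id", "x", "y", "log2_ratio", "rpkm_x", "rpkm_y",
                  "rpkm_log2_ratio", "p_raw", "p_adjusted", "significant",
                  "direction"]


def _validate(x, y, n1, n2):
    x = np.asarray(x)
    y = np.asarray(y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("tag counts x and y must be non-negative")
    if not np.all(np.equal(np.mod(x, 1), 0)) or not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("tag counts x and y must be integral")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes N1 and N2 must be positive")
    return x.astype(np.int64), y.astype(np.int64)


def ac_logpmf(y, x, n1, n2):
    """log p(y|x), evaluated through log-gamma; stable for counts to 1e6+."""
    x, y = _validate(x, y, n1, n2)
    log_r = np.log(n2) - np.log(n1)
    # log1p(r) computed from logaddexp(0, log r) to survive extreme N2/N1
    return (y * log_r
            + special.gammaln(x + y + 1)
            - special.gammaln(x + 1) - special.gammaln(y + 1)
            - (x + y + 1) * np.logaddexp(0.0, log_r))


def ac_pmf(y, x, n1, n2):
    """Audic-Claverie conditional probability p(y|x); in (0, 1]."""
    out = np.exp(ac_logpmf(y, x, n1, n2))
    return out.item() if np.ndim(out) == 0 else out


def ac_two_sided_p(x, y, n1, n2):
    """Two-sided Audic-Claverie p-value; vectorized; always in (0, 1].

    The lower-tail sum S is evaluated through the negative-binomial CDF
    identity (a regularized incomplete beta), so the cost per gene is O(1)
    rather than O(y).
    """
    x, y = _validate(x, y, n1, n2)
    p_success = n1 / (n1 + n2)  # NB success prob for the size-(x+1) law
    s = stats.nbinom.cdf(y, x + 1, p_success)
    pmf = np.exp(ac_logpmf(y, x, n1, n2))
    two_sided = np.where(s <= 0.5, 2.0 * s, 2.0 * (1.0 - s + pmf))
    out = np.minimum(1.0, two_sided)
    return out.item() if np.ndim(out) == 0 else out


def adjust_fdr(p_values, method: str = "BY"):
    """Step-up FDR adjustment (Benjamini-Hochberg or Benjamini-Yekutieli).

    Returns adjusted p-values in the input order, monotone in rank and
    clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "BY": "fdr_by"}.get(method.upper())
    if key is None:
        raise ValueError(f"unknown FDR method {method!r}; use 'BH' or 'BY'")
    return multipletests(p, method=key)[1]


def call_degs(results: pd.DataFrame, fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
              lfc_cutoff: float = DEFAULT_LFC_CUTOFF) -> pd.DataFrame:
    """Flag differentially expressed genes.

    Both gates are inclusive: significant iff p_adjusted <= fdr_cutoff and
    |log2_ratio| >= lfc_cutoff; direction follows the sign of the ratio.
    """
    out = results.copy()
    sig = (out["p_adjusted"] <= fdr_cutoff) & (out["log2_ratio"].abs() >= lfc_cutoff)
    out["significant"] = sig
    direction = np.where(out["log2_ratio"] > 0, "up", "down")
    out["direction"] = np.where(sig, direction, "none")
    return out


def summarize_stage_counts(deg_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Up/down/total DEG counts per stage comparison (Figure-3-style summary)."""
    rows = []
    for comparison, table in deg_tables.items():
        up = int(((table["direction"] == "up") & table["significant"]).sum())
        down = int(((table["direction"] == "down") & table["significant"]).sum())
        rows.append({"comparison": comparison, "up": up, "down": down,
                     "total": up + down})
    return pd.DataFrame(rows, columns=["comparison", "up", "down", "total"])


@dataclass
class AudicClaverieDGE:
    """Audic-Claverie two-library DGE model over a count table.

    Parameters
    ----------
    counts : DataFrame
        Indexed by gene id; must contain a ``length_nt`` column and one
        integer count column per library.
    profiles : DataFrame
        Indexed by library id with columns ``stage`` and ``total_reads``
        (total uniquely mapped reads N; a supplied constant, not the column
        sum).
    comparison : (str, str)
        ``(control_library, test_library)``; the log2 ratio is
        test over control.
    pseudocount : float
        Added to both counts in the normalized ratio; default 1.
    """

    counts: pd.DataFrame
    profiles: pd.DataFrame
    comparison: tuple[str, str]
    pseudocount: float = 1.0

    def __post_init__(self):
        ctrl, test = self.comparison
        for lib in (ctrl, test):
            if lib not in self.profiles.index:
                raise KeyError(f"library {lib!r} not declared in profiles")
            if lib not in self.counts.columns:
                raise KeyError(f"library {lib!r} has no count column")
        if "length_nt" not in self.counts.columns:
            raise ValueError("count table lacks a 'length_nt' column")
        if self.pseudocount <= 0:
            raise ValueError(f"pseudocount must be positive, got {self.pseudocount}")

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, profiles: pd.DataFrame,
                       control: str, test: str, **kwargs) -> "AudicClaverieDGE":
        return cls(counts=counts, profiles=profiles, comparison=(control, test),
                   **kwargs)

    @property
    def library_totals(self) -> tuple[float, float]:
        ctrl, test = self.comparison
        return (float(self.profiles.loc[ctrl, "total_reads"]),
                float(self.profiles.loc[test, "total_reads"]))

    def fit(self, fdr_method: str = "BY",
            fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
            lfc_cutoff: float = DEFAULT_LFC_CUTOFF) -> "DGEResults":
        ctrl, test = self.comparison
        n1, n2 = self.library_totals
        x = self.counts[ctrl].to_numpy()
        y = self.counts[test].to_numpy()
        lengths = self.counts["length_nt"].to_numpy()

        lfc = log2_ratio(y, x, n2, n1, pseudocount=self.pseudocount)
        rpkm_x = compute_rpkm(x, n1, lengths)
        rpkm_y = compute_rpkm(y, n2, lengths)
        with np.errstate(divide="ignore", invalid="ignore"):
            rpkm_lfc = np.log2(rpkm_y) - np.log2(rpkm_x)
        p_raw = ac_two_sided_p(x, y, n1, n2)
        p_adj = adjust_fdr(p_raw, method=fdr_method)

        frame = pd.DataFrame({
            "gene_id": self.counts.index,
            "x": x, "y": y,
            "log2_ratio": lfc,
            "rpkm_x": rpkm_x, "rpkm_y": rpkm_y,
            "rpkm_log2_ratio": rpkm_lfc,
            "p_raw": p_raw, "p_adjusted": p_adj,
        })
        frame = call_degs(frame, fdr_cutoff=fdr_cutoff, lfc_cutoff=lfc_cutoff)
        return DGEResults(model=self, frame=frame[RESULT_COLUMNS],
                          fdr_method=fdr_method, fdr_cutoff=fdr_cutoff,
                          lfc_cutoff=lfc_cutoff)


@dataclass
class DGEResults:
    """Fit results of :class:`AudicClaverieDGE` for one stage comparison."""

    model: AudicClaverieDGE
    frame: pd.DataFrame
    fdr_method: str
    fdr_cutoff: float
    lfc_cutoff: float
    _degs: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_genes(self) -> int:
        return len(self.frame)

    @property
    def n_up(self) -> int:
        return int((self.frame["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.frame["direction"] == "down").sum())

    @property
    def degs(self) -> pd.DataFrame:
        if self._degs is None:
            self._degs = self.frame[self.frame["significant"]]
        return self._degs

    @property
    def deg_genes(self) -> set[str]:
        return set(self.degs["gene_id"])

    def call_degs(self, fdr_cutoff: float | None = None,
                  lfc_cutoff: float | None = None) -> pd.DataFrame:
        """Re-call DEGs at different cutoffs without refitting."""
        return call_degs(self.frame,
                         fdr_cutoff=self.fdr_cutoff if fdr_cutoff is None else fdr_cutoff,
                         lfc_cutoff=self.lfc_cutoff if lfc_cutoff is None else lfc_cutoff)

    def summary(self) -> str:
        ctrl, test = self.model.comparison
        n1, n2 = self.model.library_totals
        lines = [
            "Audic-Claverie two-library DGE",
            "=" * 46,
            f"comparison:      {ctrl} (N1={n1:.6g}) vs {test} (N2={n2:.6g})",
            f"genes tested:    {self.n_genes}",
            f"FDR method:      {self.fdr_method}  (cutoff <= {self.fdr_cutoff:g})",
            f"|log2| cutoff:   >= {self.lfc_cutoff:g}",
            f"DEGs:            {self.n_up + self.n_down} "
            f"({self.n_up} up, {self.n_down} down)",
        ]
        top = self.degs.nsmallest(10, "p_adjusted")
        if len(top):
            lines.append("-" * 46)
            lines.append(f"{'gene':<12}{'x':>8}{'y':>8}{'log2':>8}  p_adj")
            for _, r in top.iterrows():
                lines.append(f"{r.gene_id:<12}{r.x:>8d}{r.y:>8d}"
                             f"{r.log2_ratio:>8.2f}  {r.p_adjusted:.3e}")
        return "\n".join(lines)

    def plot_volcano(self, ax=None):
        """log2 ratio vs -log10 adjusted p, DEGs highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f = self.frame
        logp = -np.log10(np.maximum(f["p_adjusted"], 1e-300))
        sig = f["significant"]
        ax.scatter(f.loc[~sig, "log2_ratio"], logp[~sig], s=4, c="grey", alpha=0.4)
        ax.scatter(f.loc[sig, "log2_ratio"], logp[sig], s=6, c="firebrick")
        ax.axhline(-np.log10(self.fdr_cutoff), ls="--", lw=0.8, c="k")
        for v in (-self.lfc_cutoff, self.lfc_cutoff):
            ax.axvline(v, ls="--", lw=0.8, c="k")
        ax.set_xlabel("log2 ratio (test / control)")
        ax.set_ylabel("-log10 adjusted p")
        ctrl, test = self.model.comparison
        ax.set_title(f"{ctrl} vs {test}")
        return ax
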