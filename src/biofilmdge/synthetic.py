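"""Synthetic data generators for every input the pipeline consumes.

The generators emulate the data model of a two-library digital
gene-expression experiment on staged *S. cerevisiae* biofilms: one pooled
tag library per developmental stage (free-cell period FCP, attachment
period AP, sessile-growth period SGP, biofilm-maturation period BMP), no
biological replicates, counts Poisson around length-weighted expected tags,
with an optional gamma-mixed (negative-binomial-like) overdispersion knob
for deliberately violating the Poisson assumption of the downstream test.

`simulate_biofilm_scenario` plants the published biofilm fold changes as
named sentinel genes (Flo11 6.8/5.0/18.4-fold up across the three stages,
Fbp1 239-fold and Pck1 555-fold up at attachment, Hsp12 181/49/13-fold up,
Gut1 6.6/1.4/2.3-fold up, Bsc1 42/4/3-fold down, Mig1 26-fold down at
attachment, Tec1 2-fold up, Kss1 3-fold down) and builds a 2143-gene
annotation universe whose special categories carry exact planted DEG
contingencies (26 of 32, 37 of 55, 69 of 183, 9 of 12, 120 of 183,
19 of 55, 8 of 12), so enrichment results are checkable against known
truth.

All outputs are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .enrichment import AnnotationSet

__all__ = [
    "SyntheticConfig", "SyntheticTruth", "ScenarioData",
    "simulate_de_experiment", "simulate_biofilm_scenario",
    "simulate_fastq", "simulate_qpcr",
    "STAGES", "SENTINEL_FOLDS", "DEFAULT_ADAPTER", "QPCR_VALIDATION_GENES",
]

STAGES = ("FCP", "AP", "SGP", "BMP")

# Published fold changes planted as ground truth, keyed gene -> stage -> fold
# (relative to the free-cell period; folds < 1 are down-regulation).
SENTINEL_FOLDS: dict[str, dict[str, float]] = {
    "Flo11": {"AP": 6.8, "SGP": 5.0, "BMP": 18.4},
    "Fbp1": {"AP": 239.0},
    "Pck1": {"AP": 555.0},
    "Hsp12": {"AP": 181.0, "SGP": 49.0, "BMP": 13.0},
    "Gut1": {"AP": 6.6, "SGP": 1.4, "BMP": 2.3},
    "Bsc1": {"AP": 1 / 42.0, "SGP": 1 / 4.0, "BMP": 1 / 3.0},
    "Mig1": {"AP": 1 / 26.0},
    "Tec1": {"AP": 2.0},
    "Kss1": {"AP": 1 / 3.0},
}

# Six-gene validation panel with printed planted folds (cf. the published
# six-gene RT-PCR check).
QPCR_VALIDATION_GENES = ("Flo11", "Fbp1", "Pck1", "Hsp12", "Mig1", "Bsc1")

# Planted DE-set sizes per stage comparison: total up/down regulated genes,
# how many of the DE genes are pathway-annotated, and exact planted counts
# inside the special categories.
_SCENARIO_DE_PLAN = {
    "AP": {"up": 522, "down": 1576, "annotated": 648,
           "special": {"ko00020": 26, "ko00010": 37}},
    "SGP": {"up": 511, "down": 1045, "annotated": 518,
            "special": {"ko03010": 69, "ko00640": 9}},
    "BMP": {"up": 472, "down": 455, "annotated": 376,
            "special": {"ko03010": 120, "ko00640": 8, "ko00010": 19}},
}

_SPECIAL_CATEGORIES = {  # category id -> (size, description)
    "ko00020": (32, "Citrate cycle (TCA cycle)"),
    "ko00010": (55, "Glycolysis / Gluconeogenesis"),
    "ko03010": (183, "Ribosome"),
    "ko00640": (12, "Propanoate metabolism"),
}

_PLANTED_ENRICHED = {
    "FCP_vs_AP": {"ko00020", "ko00010"},
    "FCP_vs_SGP": {"ko03010", "ko00640"},
    "FCP_vs_BMP": {"ko03010", "ko00640", "ko00010"},
}

DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"

_ANNOTATED_UNIVERSE_SIZE = 2143
_SCENARIO_N_GENES = 6000
_SCENARIO_LIBRARY_SIZES = {"FCP": 10_000_000, "AP": 11_000_000,
                           "SGP": 9_000_000, "BMP": 10_500_000}
# Non-sentinel planted effect magnitudes (|log2 fold change|).
_SCENARIO_EFFECT_MAGNITUDES = (1.5, 2.0, 2.5, 3.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions for a generic two-library DE simulation.

    gene_length_law: lognormal in nt, parameters ``mean_log``/``sd_log``
    with a hard floor ``min_nt`` (default 100). baseline_expression_law:
    lognormal relative abundance with parameter ``sd_log`` (long-tailed, so
    a realistic RPKM dynamic range arises). dispersion is the gamma-mixing
    variance of a gamma-Poisson draw; 0 means pure Poisson.
    """

    n_genes: int
    library_sizes: Mapping[str, int]
    gene_length_law: Mapping[str, float] = field(
        default_factory=lambda: {"mean_log": math.log(1400.0), "sd_log": 0.45,
                                 "min_nt": 100})
    baseline_expression_law: Mapping[str, float] = field(
        default_factory=lambda: {"sd_log": 1.2})
    de_fraction: float = 0.0
    effect_sizes: Sequence[float] = (-2.0, 2.0)
    dispersion: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 10:
            raise ValueError(f"n_genes must be >= 10, got {self.n_genes}")
        if len(self.library_sizes) != 2:
            raise ValueError("library_sizes must declare exactly two libraries")
        for lib, n in self.library_sizes.items():
            if n < 10_000:
                raise ValueError(f"library_sizes[{lib!r}] must be >= 1e4, got {n}")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError(f"de_fraction must lie in [0, 1], got {self.de_fraction}")
        if self.de_fraction > 0 and not self.effect_sizes:
            raise ValueError("effect_sizes must be non-empty when de_fraction > 0")
        if self.dispersion < 0:
            raise ValueError(f"dispersion must be >= 0, got {self.dispersion}")


@dataclass
class SyntheticTruth:
    """Planted ground truth, keyed by stage comparison ("A_vs_B").

    log2_fold_changes maps each comparison to a per-gene Series (zero for
    non-DE genes); enriched_categories maps each comparison to the planted
    enriched category ids.
    """

    log2_fold_changes: dict[str, pd.Series]
    enriched_categories: dict[str, set[str]] = field(default_factory=dict)

    def planted_de_genes(self, comparison: str) -> set[str]:
        lfc = self.log2_fold_changes[comparison]
        return set(lfc.index[lfc != 0.0])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.log2_fold_changes).rename_axis("gene_id")


class ScenarioData(NamedTuple):
    counts: pd.DataFrame
    profiles: pd.DataFrame
    annotation: AnnotationSet
    truth: SyntheticTruth


def _gene_lengths(rng: np.random.Generator, n: int, law: Mapping[str, float]) -> np.ndarray:
    lengths = rng.lognormal(law.get("mean_log", math.log(1400.0)),
                            law.get("sd_log", 0.45), size=n)
    return np.maximum(np.round(lengths), law.get("min_nt", 100)).astype(np.int64)


def _draw_counts(rng: np.random.Generator, expected: np.ndarray,
                 dispersion: float) -> np.ndarray:
    if dispersion > 0:
        shape = 1.0 / dispersion
        expected = expected * rng.gamma(shape, dispersion, size=expected.shape)
    return rng.poisson(expected)


def _library_counts(rng, weights: np.ndarray, lfc: np.ndarray, total: int,
                    dispersion: float) -> np.ndarray:
    """Poisson (or gamma-Poisson) tag counts around length-weighted expectations.

    Expected tags are normalized against the *baseline* transcriptome mass,
    so a planted log2 fold change is recovered exactly (up to sampling
    noise) by N-normalized count ratios: the nominal depth `total` is the
    normalizing constant reported in the library profile, while the
    realized column sum may drift with the net planted mass change (the
    profile's N is a supplied constant, not the column sum).
    """
    expr = weights * np.exp2(lfc)
    mu = total * expr / weights.sum()
    # per-library relative abundances mu / mu.sum() sum to 1 by construction
    return _draw_counts(rng, mu, dispersion)


def simulate_de_experiment(config: SyntheticConfig):
    """Two-library count simulation with planted log2 fold changes.

    Returns ``(counts, profiles, truth)``: a gene x library count table with
    lengths, a library-profile table, and the planted truth. The second
    library carries the planted effects; the first is the baseline.
    """
    rng = np.random.default_rng(config.seed)
    genes = pd.Index([f"g{i + 1:05d}" for i in range(config.n_genes)],
                     name="gene_id")
    lengths = _gene_lengths(rng, config.n_genes, config.gene_length_law)
    abundance = rng.lognormal(0.0, config.baseline_expression_law.get("sd_log", 1.2),
                              size=config.n_genes)
    weights = abundance * lengths / 1000.0  # expected tags scale with length

    lfc = np.zeros(config.n_genes)
    n_de = int(round(config.de_fraction * config.n_genes))
    if n_de > 0:
        de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
        lfc[de_idx] = rng.choice(np.asarray(config.effect_sizes, dtype=float),
                                 size=n_de)

    (lib_a, n_a), (lib_b, n_b) = config.library_sizes.items()
    counts = pd.DataFrame({"length_nt": lengths}, index=genes)
    counts[lib_a] = _library_counts(rng, weights, np.zeros(config.n_genes),
                                    n_a, config.dispersion)
    counts[lib_b] = _library_counts(rng, weights, lfc, n_b, config.dispersion)

    profiles = pd.DataFrame({
        "library_id": [lib_a, lib_b], "stage": [lib_a, lib_b],
        "total_reads": [n_a, n_b],
    }).set_index("library_id", drop=False)

    comparison = f"{lib_a}_vs_{lib_b}"
    truth = SyntheticTruth({comparison: pd.Series(lfc, index=genes)})
    return counts, profiles, truth


def _build_annotation(rng: np.random.Generator,
                      universe: list[str]) -> tuple[AnnotationSet, dict[str, str],
                                                    dict[str, list[str]]]:
    """Partition the annotated universe into special + filler categories."""
    order = list(universe)
    rng.shuffle(order)
    categories: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    special_members: dict[str, list[str]] = {}
    pos = 0
    for cat_id, (size, desc) in _SPECIAL_CATEGORIES.items():
        members = order[pos:pos + size]
        categories[cat_id] = set(members)
        special_members[cat_id] = members
        descriptions[cat_id] = desc
        pos += size
    i = 0
    while pos < len(order):
        size = int(rng.integers(10, 101))
        members = order[pos:pos + size]
        pos += size
        i += 1
        cat_id = f"koF{i:04d}"
        categories[cat_id] = set(members)
        descriptions[cat_id] = f"filler pathway {i}"
    return AnnotationSet(categories=categories), descriptions, special_members


def simulate_biofilm_scenario(seed: int = 0) -> ScenarioData:
    """The staged-biofilm study conditions with planted published truth.

    6000 genes, one pooled library per stage (~1e7 uniquely mapped tags),
    sentinel genes carrying the published fold changes, planted DE sets
    sized to the published per-comparison up/down and annotated-DEG counts,
    and an annotation universe of 2143 genes whose special categories hold
    the published contingency counts exactly.
    """
    rng = np.random.default_rng(seed)
    sentinels = list(SENTINEL_FOLDS)
    n_other = _SCENARIO_N_GENES - len(sentinels)
    other = [f"g{i + 1:05d}" for i in range(n_other)]
    genes = pd.Index(sentinels + other, name="gene_id")

    # Annotated universe: 2143 non-sentinel genes (sentinels stay outside so
    # per-category planted contingencies are exact by construction).
    universe = list(rng.choice(other, size=_ANNOTATED_UNIVERSE_SIZE, replace=False))
    annotation, descriptions, special_members = _build_annotation(rng, universe)
    universe_set = set(universe)
    special_all = set().union(*special_members.values())
    plain_annotated = sorted(universe_set - special_all)
    unannotated = sorted(set(other) - universe_set)

    lfc = {f"FCP_vs_{stage}": pd.Series(0.0, index=genes)
           for stage in ("AP", "SGP", "BMP")}
    for gene, folds in SENTINEL_FOLDS.items():
        for stage, fold in folds.items():
            lfc[f"FCP_vs_{stage}"][gene] = math.log2(fold)

    for stage, plan in _SCENARIO_DE_PLAN.items():
        comparison = f"FCP_vs_{stage}"
        chosen: list[str] = []
        for cat_id, n_req in plan["special"].items():
            chosen += list(rng.choice(special_members[cat_id], size=n_req,
                                      replace=False))
        n_plain = plan["annotated"] - len(chosen)
        chosen += list(rng.choice(plain_annotated, size=n_plain, replace=False))
        sentinel_up = sum(1 for g in sentinels if lfc[comparison][g] >= 1.0)
        sentinel_down = sum(1 for g in sentinels if lfc[comparison][g] <= -1.0)
        n_unannot = (plan["up"] + plan["down"] - sentinel_up - sentinel_down
                     - plan["annotated"])
        chosen += list(rng.choice(unannotated, size=n_unannot, replace=False))

        rng.shuffle(chosen)
        n_up = plan["up"] - sentinel_up
        magnitudes = rng.choice(_SCENARIO_EFFECT_MAGNITUDES, size=len(chosen))
        signs = np.where(np.arange(len(chosen)) < n_up, 1.0, -1.0)
        lfc[comparison][chosen] = signs * magnitudes

    lengths = _gene_lengths(rng, _SCENARIO_N_GENES, SyntheticConfig(
        n_genes=10, library_sizes={"a": 10_000, "b": 10_000}).gene_length_law)
    abundance = rng.lognormal(0.0, 1.2, size=_SCENARIO_N_GENES)
    # Give very-high-fold sentinels a solid baseline so their free-cell
    # counts are non-trivial and down-regulation stays detectable.
    abundance[:len(sentinels)] = rng.lognormal(1.0, 0.4, size=len(sentinels))
    weights = abundance * lengths / 1000.0

    counts = pd.DataFrame({"length_nt": lengths}, index=genes)
    for stage in STAGES:
        stage_lfc = (np.zeros(_SCENARIO_N_GENES) if stage == "FCP"
                     else lfc[f"FCP_vs_{stage}"].to_numpy())
        counts[stage] = _library_counts(rng, weights, stage_lfc,
                                        _SCENARIO_LIBRARY_SIZES[stage], 0.0)

    profiles = pd.DataFrame({
        "library_id": list(STAGES), "stage": list(STAGES),
        "total_reads": [_SCENARIO_LIBRARY_SIZES[s] for s in STAGES],
    }).set_index("library_id", drop=False)

    truth = SyntheticTruth(log2_fold_changes=lfc,
                           enriched_categories={k: set(v) for k, v in
                                                _PLANTED_ENRICHED.items()})
    annotation_descriptions = descriptions  # kept for GMT export
    annotation = AnnotationSet(categories=annotation.categories,
                               universe=annotation.universe)
    annotation.descriptions = annotation_descriptions  # type: ignore[attr-defined]
    return ScenarioData(counts=counts, profiles=profiles,
                        annotation=annotation, truth=truth)


# ---------------------------------------------------------------------------
# FASTQ fixture generator


def _random_bases(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _quality_string(qualities: np.ndarray, offset: int) -> str:
    return "".join(chr(int(q) + offset) for q in qualities)


def simulate_fastq(n_reads: int, read_length: int = 90,
                   contamination: Mapping[str, float] | None = None,
                   seed: int = 0, phred_offset: int = 33,
                   adapters: Sequence[str] = (DEFAULT_ADAPTER,)):
    """FASTQ fixture with planted contamination classes.

    contamination maps class names (``adapter``, ``unknown``, ``lowqual``)
    to fractions summing to <= 1; the remainder is clean by construction
    (no adapter substring, no N, every base above the low-quality cutoff).
    Returns ``(records, labels)`` where records are ``(title, bases, qual)``
    tuples in shuffled order and labels give each read's planted class.
    """
    contamination = dict(contamination or {})
    unknown_classes = set(contamination) - {"adapter", "unknown", "lowqual"}
    if unknown_classes:
        raise ValueError(f"unknown contamination classes: {sorted(unknown_classes)}")
    frac_sum = sum(contamination.values())
    if any(v < 0 for v in contamination.values()) or frac_sum > 1.0 + 1e-9:
        raise ValueError(f"contamination fractions must be >= 0 and sum <= 1, "
                         f"got sum {frac_sum}")
    if read_length < 20:
        raise ValueError(f"read_length must be >= 20, got {read_length}")

    rng = np.random.default_rng(seed)
    adapters = tuple(a.upper()[:read_length] for a in adapters if a)

    n_by_class = {cls: int(round(contamination.get(cls, 0.0) * n_reads))
                  for cls in ("adapter", "unknown", "lowqual")}
    labels = (["adapter"] * n_by_class["adapter"]
              + ["unknown"] * n_by_class["unknown"]
              + ["lowqual"] * n_by_class["lowqual"])
    labels += ["clean"] * (n_reads - len(labels))
    labels = list(np.array(labels)[rng.permutation(n_reads)]) if n_reads else []

    n_n_bases = math.ceil(0.06 * read_length)  # >5% unknown by construction
    if n_n_bases <= 0.05 * read_length:
        n_n_bases += 1
    n_low_bases = math.ceil(0.35 * read_length)  # >30% low-quality

    def adapter_free(seq: str) -> bool:
        return not any(a in seq for a in adapters)

    records = []
    for i, label in enumerate(labels):
        bases = _random_bases(rng, read_length)
        while not adapter_free(bases):
            bases = _random_bases(rng, read_length)
        quals = rng.integers(30, 41, size=read_length)
        if label == "adapter":
            a = adapters[int(rng.integers(len(adapters)))] if adapters else ""
            if not a:
                raise ValueError("adapter contamination requested with no adapters")
            pos = int(rng.integers(0, read_length - len(a) + 1))
            bases = bases[:pos] + a + bases[pos + len(a):]
        elif label == "unknown":
            sites = rng.choice(read_length, size=n_n_bases, replace=False)
            arr = list(bases)
            for s in sites:
                arr[s] = "N"
            bases = "".join(arr)
        elif label == "lowqual":
            sites = rng.choice(read_length, size=n_low_bases, replace=False)
            quals[sites] = rng.integers(2, 11, size=n_low_bases)
        records.append((f"read{i:07d} planted={label}", bases,
                        _quality_string(quals, phred_offset)))
    return records, labels


# ---------------------------------------------------------------------------
# qPCR Ct table generator


def simulate_qpcr(truth: SyntheticTruth, genes: Sequence[str],
                  noise_sd: float = 0.1, seed: int = 0,
                  comparison: str = "FCP_vs_AP",
                  reference_gene: str = "18S",
                  n_replicates: int = 3) -> pd.DataFrame:
    """Long-format Ct table consistent with the planted fold changes.

    The target's mean Ct drops by the planted log2 fold change from control
    to test (one PCR cycle per doubling); the reference gene's Ct is
    constant across conditions; every replicate Ct carries independent
    Gaussian noise of `noise_sd` cycles.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if comparison not in truth.log2_fold_changes:
        raise KeyError(f"comparison {comparison!r} not in truth "
                       f"(have {sorted(truth.log2_fold_changes)})")
    lfc = truth.log2_fold_changes[comparison]
    missing = [g for g in genes if g not in lfc.index]
    if missing:
        raise KeyError(f"genes not present in truth: {missing}")

    rng = np.random.default_rng(seed)
    rows = []
    ref_base = 12.0

    def emit(condition: str, gene: str, base_ct: float) -> None:
        for rep in range(1, n_replicates + 1):
            ct = base_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"sample_id": f"{condition}_pool", "condition": condition,
                         "gene_id": gene, "replicate": rep, "ct": float(ct)})

    for condition in ("control", "test"):
        emit(condition, reference_gene, ref_base)
    for gene in genes:
        base_ctrl = float(rng.uniform(18.0, 28.0))
        emit("control", gene, base_ctrl)
        emit("test", gene, base_ctrl - float(lfc[gene]))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "gene_id",
                                       "replicate", "ct"])
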