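"""End-to-end pipeline: qc -> quantify -> dge -> enrich -> qpcr validation.

One configured, seeded run produces a fixed artifact set under the output
directory:

    qc_report.tsv            read-removal counts by reason
    rpkm_matrix.tsv          gene x library RPKM
    dge_<A>_vs_<B>.tsv       per-gene DGE table per comparison
    deg_summary.tsv          up/down/total DEGs per comparison
    enrichment_<A>_vs_<B>.tsv  category enrichment per comparison
    qpcr_concordance.tsv     paired qPCR / RNA-seq log2 fold changes
    run.log                  INFO-level per-stage counts

Every table carries a ``#`` header line with the package version and a hash
of the configuration, so reruns are attributable; with a fixed seed the
tables are byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .dge import (AudicClaverieDGE, DEFAULT_FDR_CUTOFF, DEFAULT_LFC_CUTOFF,
                  summarize_stage_counts)
from .enrichment import AnnotationSet, enrich_categories
from .io import write_fastq, write_gmt, write_table
from .qc import QcThresholds, filter_fastq
from .qpcr import concordance, fold_changes_from_ct_table
from .quant import rpkm_matrix
from .synthetic import (QPCR_VALIDATION_GENES, simulate_biofilm_scenario,
                        simulate_fastq, simulate_qpcr)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("biofilmdge")

DEFAULT_COMPARISONS = (("FCP", "AP"), ("FCP", "SGP"), ("FCP", "BMP"),
                       ("AP", "SGP"), ("AP", "BMP"), ("SGP", "BMP"))


class PipelineError(RuntimeError):
    """A configuration or input problem detected before/during a run."""


@dataclass
class PipelineConfig:
    """Declarative run configuration (YAML-serializable)."""

    outdir: str
    seed: int = 0
    comparisons: Sequence[tuple[str, str]] = DEFAULT_COMPARISONS
    pseudocount: float = 1.0
    fdr_method: str = "BY"
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF
    lfc_cutoff: float = DEFAULT_LFC_CUTOFF
    q_cutoff: float = 0.05
    qc: QcThresholds = field(default_factory=QcThresholds)
    reference_gene: str = "18S"
    qpcr_noise_sd: float = 0.1
    n_fastq_reads: int = 20000
    fastq_contamination: Mapping[str, float] = field(
        default_factory=lambda: {"adapter": 0.05, "unknown": 0.10,
                                 "lowqual": 0.15})

    def as_dict(self) -> dict:
        d = asdict(self)
        d["comparisons"] = [list(c) for c in self.comparisons]
        d["fastq_contamination"] = dict(self.fastq_contamination)
        return d

    @property
    def config_hash(self) -> str:
        # hash the analysis parameters only: the same run written to a
        # different directory is the same run
        params = {k: v for k, v in self.as_dict().items() if k != "outdir"}
        blob = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "comparisons" in raw:
            raw["comparisons"] = [tuple(c) for c in raw["comparisons"]]
        if "qc" in raw:
            raw["qc"] = QcThresholds(**{
                **raw["qc"],
                "adapter_sequences": tuple(raw["qc"].get("adapter_sequences", ())),
            })
        return cls(**raw)


def _header(config: PipelineConfig) -> list[str]:
    return [f"biofilmdge v{__version__} config={config.config_hash} "
            f"seed={config.seed}"]


def _validate(config: PipelineConfig, declared: set[str]) -> None:
    for ctrl, test in config.comparisons:
        for lib in (ctrl, test):
            if lib not in declared:
                raise PipelineError(
                    f"comparison {ctrl} vs {test} references undeclared "
                    f"library {lib!r} (declared: {sorted(declared)})")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full synthetic-scenario pipeline; return artifact paths.

    Deterministic given ``config.seed``: rerunning with the same config
    yields byte-identical tables.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    artifacts: dict[str, Path] = {"log": log_path}
    header = _header(config)

    try:
        logger.info("run start: config=%s seed=%d", config.config_hash, config.seed)
        scenario = simulate_biofilm_scenario(seed=config.seed)
        counts, profiles, annotation, truth = scenario
        _validate(config, set(profiles.index))

        # --- QC stage (synthetic FASTQ fixture) ---
        qc_thresholds = config.qc
        if not qc_thresholds.adapter_sequences:
            from .synthetic import DEFAULT_ADAPTER
            qc_thresholds = QcThresholds(
                max_unknown_fraction=qc_thresholds.max_unknown_fraction,
                max_lowqual_fraction=qc_thresholds.max_lowqual_fraction,
                lowqual_phred_cutoff=qc_thresholds.lowqual_phred_cutoff,
                adapter_sequences=(DEFAULT_ADAPTER,),
                phred_offset=qc_thresholds.phred_offset)
        records, _labels = simulate_fastq(
            config.n_fastq_reads, contamination=config.fastq_contamination,
            seed=config.seed, phred_offset=qc_thresholds.phred_offset,
            adapters=qc_thresholds.adapter_sequences)
        raw_fastq = outdir / "reads_raw.fastq"
        clean_fastq = outdir / "reads_clean.fastq"
        with open(raw_fastq, "w") as fh:
            write_fastq(records, fh)
        with open(raw_fastq) as src, open(clean_fastq, "w") as dst:
            report = filter_fastq(src, dst, qc_thresholds)
        logger.info("qc: %d reads in, %d clean, removed adapter=%d unknown=%d "
                    "lowqual=%d", report.input_reads, report.clean_reads,
                    report.removed_adapter, report.removed_unknown,
                    report.removed_lowqual)
        write_table(report.as_frame(), outdir / "qc_report.tsv", comments=header)
        artifacts["qc_report"] = outdir / "qc_report.tsv"

        # --- inputs as on-disk artifacts ---
        write_table(counts.reset_index(), outdir / "counts.tsv", comments=header)
        write_table(profiles.reset_index(drop=True), outdir / "profiles.tsv",
                    comments=header)
        write_gmt(annotation.categories, outdir / "annotation.gmt",
                  descriptions=getattr(annotation, "descriptions", None))
        write_table(truth.as_frame().reset_index(), outdir / "truth.tsv",
                    comments=header)

        # --- quantification ---
        rpkm = rpkm_matrix(counts, profiles)
        write_table(rpkm.reset_index(), outdir / "rpkm_matrix.tsv",
                    comments=header)
        artifacts["rpkm_matrix"] = outdir / "rpkm_matrix.tsv"
        logger.info("quantify: %d genes x %d libraries", *rpkm.shape)

        # --- differential expression per comparison ---
        deg_tables: dict[str, pd.DataFrame] = {}
        results_by_comparison = {}
        for ctrl, test in config.comparisons:
            name = f"{ctrl}_vs_{test}"
            model = AudicClaverieDGE(counts=counts, profiles=profiles,
                                     comparison=(ctrl, test),
                                     pseudocount=config.pseudocount)
            res = model.fit(fdr_method=config.fdr_method,
                            fdr_cutoff=config.fdr_cutoff,
                            lfc_cutoff=config.lfc_cutoff)
            results_by_comparison[name] = res
            deg_tables[name] = res.frame
            path = outdir / f"dge_{name}.tsv"
            _write_dge_table(res.frame, path, header)
            artifacts[f"dge_{name}"] = path
            logger.info("dge %s: %d genes tested, %d DEGs (%d up, %d down)",
                        name, res.n_genes, res.n_up + res.n_down, res.n_up,
                        res.n_down)

        summary = summarize_stage_counts(deg_tables)
        write_table(summary, outdir / "deg_summary.tsv", comments=header)
        artifacts["deg_summary"] = outdir / "deg_summary.tsv"

        # --- enrichment per comparison ---
        for name, res in results_by_comparison.items():
            enrich = enrich_categories(res.deg_genes, annotation,
                                       q_cutoff=config.q_cutoff)
            path = outdir / f"enrichment_{name}.tsv"
            _write_enrichment_table(enrich, path, header)
            artifacts[f"enrichment_{name}"] = path
            logger.info("enrich %s: %d categories tested, %d significant",
                        name, len(enrich), int(enrich["significant"].sum()))

        # --- qPCR concordance (attachment-period comparison) ---
        ct_table = simulate_qpcr(truth, QPCR_VALIDATION_GENES,
                                 noise_sd=config.qpcr_noise_sd,
                                 seed=config.seed,
                                 reference_gene=config.reference_gene)
        write_table(ct_table, outdir / "qpcr_ct.tsv", comments=header)
        qpcr_fc = fold_changes_from_ct_table(ct_table,
                                             reference_gene=config.reference_gene)
        rnaseq = results_by_comparison.get("FCP_vs_AP")
        if rnaseq is not None:
            rnaseq_lfc = rnaseq.frame.set_index("gene_id")["log2_ratio"]
            r, paired = concordance(rnaseq_lfc,
                                    qpcr_fc.set_index("gene_id")["log2_fold_change"])
            paired["pearson_r"] = r
            write_table(paired, outdir / "qpcr_concordance.tsv", comments=header)
            artifacts["qpcr_concordance"] = outdir / "qpcr_concordance.tsv"
            logger.info("qpcr: %d genes, Pearson r = %.4f", len(paired), r)

        logger.info("run complete")
    except Exception as exc:
        logger.error("run failed: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return artifacts


def _format_table(frame: pd.DataFrame, p_cols: Sequence[str]) -> pd.DataFrame:
    out = frame.copy()
    for col in p_cols:
        out[col] = out[col].map(lambda v: f"{v:.6e}")
    return out


def _write_dge_table(frame: pd.DataFrame, path: Path,
                     comments: Sequence[str]) -> None:
    write_table(_format_table(frame, ["p_raw", "p_adjusted"]), path,
                comments=comments)


def _write_enrichment_table(frame: pd.DataFrame, path: Path,
                            comments: Sequence[str]) -> None:
    write_table(_format_table(frame, ["p_value", "q_value"]), path,
                comments=comments)
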