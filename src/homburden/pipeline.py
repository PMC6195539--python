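"""End-to-end screen: exclusion → QC → classification → burden → null.

:func:`run_pipeline` wires the stages together for a single cohort and
gene set, producing a report bundle on disk: the QC summary, the
classified-variants table, a burden report shaped like the screen's
category table (per-category homozygote counts, percentages, one-tailed
Fisher p, simulation p), the per-category null distributions, the
genome-complement control test, and a machine-readable run manifest with
the fully resolved configuration and seed.  Reruns with the same inputs
and seed produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from .burden import BurdenResult, GeneSet, burden_test, complement_burden
from .matrix import CohortMatrix
from .nullsim import NullDistribution, simulate_null
from .qc import QCParams, QCSummary, run_qc
from .vcfio import read_gene_list, read_subject_list, read_vcf

logger = logging.getLogger("homburden")

__all__ = ["RunConfig", "apply_subject_exclusion", "run_pipeline", "PipelineReport"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Defaults are the screen's standard thresholds: GQ ≥ 20, ≤10% group
    missingness, ≤5% hom-call ref-read fraction, dataset MAF < 0.001,
    population MAF < 0.01 / < 0.001, CADD > 20, 5,000 random sets of 120
    genes.
    """

    vcf: str = ""
    gene_set: str = ""
    exclusion_list: str | None = None
    out_dir: str = "homburden_out"
    # QC
    gq_threshold: int = 20
    max_missing_fraction: float = 0.10
    max_ref_fraction: float = 0.05
    drop_indels: bool = True
    # classification
    dataset_maf_threshold: float = 1e-3
    pop_rare_threshold: float = 1e-2
    pop_ultrarare_threshold: float = 1e-3
    cadd_threshold: float = 20.0
    splice_needs_cadd: bool = False
    # simulation null
    n_sims: int = 5000
    set_size: int | None = None  # None → size of the supplied gene set
    seed: int = 0
    categories: tuple = ("A", "B", "C", "D")
    run_null: bool = True
    run_complement: bool = True

    def validate(self) -> None:
        if self.gq_threshold < 0:
            raise ValueError("gq_threshold must be non-negative")
        for name in ("max_missing_fraction", "max_ref_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in (
            "dataset_maf_threshold",
            "pop_rare_threshold",
            "pop_ultrarare_threshold",
        ):
            v = getattr(self, name)
            if not 0 < v <= 0.5:
                raise ValueError(f"{name} must lie in (0, 0.5]")
        if self.n_sims < 1:
            raise ValueError("n_sims must be positive")
        unknown = set(self.categories) - set(_classify.CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown configuration keys: {sorted(extra)}")
        if "categories" in data:
            data["categories"] = tuple(data["categories"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["categories"] = list(d["categories"])
        return d


def apply_subject_exclusion(matrix: CohortMatrix, exclusion_ids) -> CohortMatrix:
    """Drop listed subjects (e.g. a precomputed ancestry-outlier list).

    IDs absent from the matrix are warned about but not fatal.  Group
    totals update automatically.
    """
    exclusion = set(exclusion_ids)
    if not exclusion:
        return matrix
    present = set(matrix.subject_ids)
    unknown = exclusion - present
    if unknown:
        warnings.warn(
            f"{len(unknown)} exclusion-list ID(s) not present in the cohort",
            stacklevel=2,
        )
    keep = np.array([s not in exclusion for s in matrix.subject_ids])
    return matrix.take_subjects(np.flatnonzero(keep))


@dataclass
class PipelineReport:
    """In-memory result bundle of one pipeline run."""

    config: RunConfig
    qc_summary: pd.DataFrame
    classified: pd.DataFrame
    burden: pd.DataFrame
    null_distributions: dict = field(default_factory=dict)
    complement: pd.DataFrame | None = None
    n_cases: int = 0
    n_controls: int = 0

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.qc_summary.to_csv(out / "qc_summary.tsv", sep="\t", index=False)
        self.classified.to_csv(
            out / "classified_variants.tsv", sep="\t", index=False
        )
        self.burden.to_csv(
            out / "burden_report.tsv", sep="\t", index=False, float_format="%.6g"
        )
        if self.complement is not None:
            self.complement.to_csv(
                out / "complement_report.tsv",
                sep="\t",
                index=False,
                float_format="%.6g",
            )
        null_summaries = {}
        for cat, dist in self.null_distributions.items():
            dist.to_frame().to_csv(
                out / f"null_distribution_{cat}.tsv", sep="\t", index=False
            )
            null_summaries[cat] = dist.summary()
        manifest = {
            "config": self.config.to_dict(),
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "null_summaries": null_summaries,
        }
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _burden_row(category: str, res: BurdenResult, sim_p) -> dict:
    c = res.counts
    return {
        "category": category,
        "n_case_hom": c.case_hom,
        "pct_case": c.case_pct,
        "n_control_hom": c.control_hom,
        "pct_control": c.control_pct,
        "fisher_p": res.fisher_p,
        "simulation_p": sim_p,
    }


def run_pipeline(
    config: RunConfig,
    matrix: CohortMatrix | None = None,
    gene_set: GeneSet | None = None,
    write: bool = True,
) -> PipelineReport:
    """Execute the full screen and (optionally) write the report bundle.

    ``matrix`` and ``gene_set`` may be passed in-memory; otherwise they
    are loaded from the paths in ``config``.  Stages: subject exclusion →
    QC → classification → per-category burden tests → per-category
    random-gene-set null → genome-complement control.
    """
    config.validate()
    if matrix is None:
        logger.info("reading VCF %s", config.vcf)
        matrix = read_vcf(config.vcf)
    if gene_set is None:
        genes = read_gene_list(config.gene_set)
        gene_set = GeneSet(Path(config.gene_set).stem, genes)

    if config.exclusion_list:
        excl = read_subject_list(config.exclusion_list)
        logger.info("excluding %d listed subjects", len(excl))
        matrix = apply_subject_exclusion(matrix, excl)

    qc_summary = QCSummary()
    params = QCParams(
        gq_threshold=config.gq_threshold,
        max_missing_fraction=config.max_missing_fraction,
        max_ref_fraction=config.max_ref_fraction,
        drop_indels=config.drop_indels,
    )
    logger.info(
        "QC on %d variants × %d subjects", matrix.n_variants, matrix.n_subjects
    )
    clean = run_qc(matrix, params, qc_summary)

    classified = _classify.classify_variants(
        clean,
        dataset_maf_threshold=config.dataset_maf_threshold,
        pop_rare_threshold=config.pop_rare_threshold,
        pop_ultrarare_threshold=config.pop_ultrarare_threshold,
        cadd_threshold=config.cadd_threshold,
        splice_needs_cadd=config.splice_needs_cadd,
    )

    missing_symbols = gene_set.genes - set(clean.variants["gene"])
    if missing_symbols:
        logger.warning(
            "%d gene-set symbol(s) carry no variant in the matrix",
            len(missing_symbols),
        )

    set_size = config.set_size or len(gene_set)
    rows = []
    nulls: dict[str, NullDistribution] = {}
    comp_rows = []
    for ci, cat in enumerate(config.categories):
        res = burden_test(clean, classified, gene_set, cat)
        sim_p = float("nan")
        if config.run_null:
            dist = simulate_null(
                clean,
                classified,
                cat,
                target_genes=gene_set.genes,
                set_size=min(set_size, len(set(clean.variants["gene"]))),
                n_sims=config.n_sims,
                seed=config.seed + ci,  # distinct stream per category
            )
            nulls[cat] = dist
            sim_p = dist.empirical_p
        rows.append(_burden_row(cat, res, sim_p))
        if config.run_complement:
            comp = complement_burden(clean, classified, gene_set, cat)
            comp_rows.append(_burden_row(cat, comp, float("nan")))

    report = PipelineReport(
        config=config,
        qc_summary=qc_summary.to_frame(),
        classified=classified,
        burden=pd.DataFrame(rows),
        null_distributions=nulls,
        complement=pd.DataFrame(comp_rows) if comp_rows else None,
        n_cases=clean.n_cases,
        n_controls=clean.n_controls,
    )
    if write:
        report.write(config.out_dir)
    return report
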