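"""End-to-end orchestration: merge → correction → estimation → QC →
nested ANOVA → summaries.

The pipeline mirrors the stepwise pooled-GWAS workflow: marker pre-filters
(rs names, autosomes), heterozygote-based correction factors, pooled
frequency estimation under the requested method tracks (with per-replicate
channel normalisation for N), per-track QC, per-track nested ANOVA, and the
cross-track significance / frequency / accuracy summaries.  Every stage
writes its table into the output directory and appends marker counts to a
run log, so each stage can also be re-run in isolation from intermediates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import association, frequency, ingest, qc, reporting
from .design import PoolDesign
from .errors import ConfigError
from .qc import QCThresholds

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run."""

    pool_intensities: Path
    genotypes: Path
    design: Path
    output_dir: Path
    individual_intensities: Path | None = None
    annotation: Path | None = None
    sample_groups: Path | None = None
    methods: tuple[str, ...] = frequency.METHODS
    min_het: int = frequency.DEFAULT_MIN_HET
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    significance_threshold: float = reporting.DEFAULT_SIGNIFICANCE_THRESHOLD
    transform: str | None = None

    def validate(self) -> None:
        if not self.methods:
            raise ConfigError("no estimation methods requested")
        bad = set(self.methods) - set(frequency.METHODS)
        if bad:
            raise ConfigError(f"unknown method(s) {sorted(bad)}; choose from {frequency.METHODS}")
        needs_factors = set(self.methods) & {"H", "M", "N"}
        if needs_factors and self.individual_intensities is None:
            raise ConfigError(
                f"methods {sorted(needs_factors)} require individual-sample "
                "intensities (individual_intensities) for correction factors"
            )
        for name in ("pool_intensities", "genotypes", "design"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise ConfigError(f"input file for {name!r} not found: {path}")
        for name in ("individual_intensities", "annotation", "sample_groups"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"input file for {name!r} not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        inputs = raw.get("inputs", {})
        kwargs = {}
        for name in ("pool_intensities", "genotypes", "design",
                     "individual_intensities", "annotation", "sample_groups"):
            if inputs.get(name) is not None:
                kwargs[name] = Path(inputs[name])
        if "output_dir" in raw:
            kwargs["output_dir"] = Path(raw["output_dir"])
        if "methods" in raw:
            kwargs["methods"] = tuple(raw["methods"])
        if "min_het" in raw:
            kwargs["min_het"] = int(raw["min_het"])
        if "qc" in raw:
            kwargs["thresholds"] = QCThresholds(**raw["qc"])
        if "significance_threshold" in raw:
            kwargs["significance_threshold"] = float(raw["significance_threshold"])
        if raw.get("transform"):
            kwargs["transform"] = str(raw["transform"])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(f"incomplete pipeline config {path}: {exc}") from None


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    factors: pd.DataFrame | None
    freqs: dict[str, pd.DataFrame]
    survivors: dict[str, set[str]]
    qc_reports: dict[str, qc.QCReport]
    anova: dict[str, pd.DataFrame]
    significant: pd.DataFrame
    accuracy: dict[str, pd.DataFrame]
    counts: dict[str, int]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the output bundle.

    Raises on the first failing stage; downstream stages are not run.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    counts: dict[str, int] = {}

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    # ---- ingest ----------------------------------------------------------
    pool_int = ingest.parse_intensity_table(config.pool_intensities)
    genotypes = ingest.parse_genotype_table(config.genotypes)
    design = ingest.parse_design_table(config.design)
    counts["markers_raw"] = pool_int["marker_id"].nunique()
    log(f"ingest: {counts['markers_raw']} markers, "
        f"{pool_int['sample_id'].nunique()} pool replicates, "
        f"{genotypes['sample_id'].nunique()} genotyped samples")

    # ---- marker pre-filters (rs names, autosomes) ------------------------
    if config.annotation is not None:
        ann = ingest.parse_annotation_table(config.annotation)
        rs = ingest.filter_markers_rs(ann)
        keep = rs & ingest.filter_autosomal(ann)
        counts["markers_rs"] = len(rs & set(pool_int["marker_id"]))
        pool_int = pool_int[pool_int["marker_id"].isin(keep)].reset_index(drop=True)
        genotypes = genotypes[genotypes["marker_id"].isin(keep)].reset_index(drop=True)
        counts["markers_prefiltered"] = pool_int["marker_id"].nunique()
        log(f"pre-filter: {counts['markers_rs']} rs-named markers, "
            f"{counts['markers_prefiltered']} autosomal rs markers kept")
    marker_pool = set(pool_int["marker_id"])

    # ---- correction factors ---------------------------------------------
    factors = None
    if set(config.methods) & {"H", "M", "N"}:
        ind_int = ingest.parse_intensity_table(config.individual_intensities)
        ind_int = ind_int[ind_int["marker_id"].isin(marker_pool)]
        het, join_report = ingest.merge_genotype_intensity(genotypes, ind_int, het_only=True)
        log(f"merge: {join_report}")
        factors = frequency.estimate_correction_factors(het, min_het=config.min_het)
        frequency.write_correction_factor_table(factors, out / "correction_factors.tsv")
        counts["markers_usable_factors"] = int(factors["usable"].sum())
        log(f"correction factors: {counts['markers_usable_factors']} of "
            f"{len(factors)} markers usable (min_het={config.min_het})")

    scales = None
    if "N" in config.methods:
        scales = frequency.fit_normalization(pool_int)
        scales.reset_index().to_csv(
            out / "normalization_scales.tsv", sep="\t", index=False,
            float_format="%.10g", lineterminator="\n",
        )

    # ---- per-method estimation, QC, ANOVA --------------------------------
    freqs: dict[str, pd.DataFrame] = {}
    survivors: dict[str, set[str]] = {}
    qc_reports: dict[str, qc.QCReport] = {}
    anova_results: dict[str, pd.DataFrame] = {}
    sample_count = int(genotypes["sample_id"].nunique())
    for method in config.methods:
        f = frequency.estimate_pool_frequencies(
            pool_int, design, method, factors=factors, scales=scales
        )
        frequency.write_frequency_table(f, out / f"freq_{method}.tsv")
        freqs[method] = f
        surv, report = qc.filter_qc(
            f, genotypes, design, thresholds=config.thresholds,
            method=method, sample_count=sample_count,
        )
        survivors[method] = surv
        qc_reports[method] = report
        log(f"qc: {report}")
        with open(out / f"qc_survivors_{method}.txt", "w") as fh:
            fh.write("\n".join(sorted(surv)) + ("\n" if surv else ""))
        filtered = f[f["marker_id"].isin(surv)]
        frequency.write_frequency_table(filtered, out / f"freq_{method}_qc.tsv")
        res = association.nested_anova_all(
            filtered, design, method=method, transform=config.transform
        )
        association.write_anova_table(res, out / f"anova_{method}.tsv")
        anova_results[method] = res
        counts[f"markers_tested_{method}"] = len(res)
        stats = reporting.mean_freq_statistics(f, design, method=method)
        reporting.write_mean_freq_table(stats, out / f"mean_freq_{method}.tsv")

    with open(out / "qc_report.txt", "w") as fh:
        fh.write("\n".join(str(r) for r in qc_reports.values()) + "\n")

    # ---- cross-method summaries ------------------------------------------
    significant = reporting.summarize_significant(
        anova_results, threshold=config.significance_threshold
    )
    reporting.write_significance_table(significant, out / "significant.tsv")
    counts["markers_significant_union"] = len(significant)
    log(f"summary: {len(significant)} marker(s) with p < "
        f"{config.significance_threshold:g} in at least one method")

    accuracy: dict[str, pd.DataFrame] = {}
    if config.sample_groups is not None:
        groups_df = pd.read_csv(config.sample_groups, sep="\t", dtype=str)
        assignment = dict(zip(groups_df["Sample"], groups_df["Group"]))
        ref = reporting.individual_allele_frequency(genotypes, assignment)
        for method in config.methods:
            stats = reporting.mean_freq_statistics(freqs[method], design, method=method)
            accuracy[method] = reporting.accuracy_evaluation(stats, ref, design, method=method)
            reporting.write_accuracy_table(accuracy[method], out / f"accuracy_{method}.tsv")
        with open(out / "accuracy_report.txt", "w") as fh:
            fh.write(reporting.format_accuracy_table(accuracy) + "\n")

    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")

    return PipelineResult(
        factors=factors,
        freqs=freqs,
        survivors=survivors,
        qc_reports=qc_reports,
        anova=anova_results,
        significant=significant,
        accuracy=accuracy,
        counts=counts,
    )
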