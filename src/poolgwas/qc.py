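"""Marker quality control for the pooled-frequency tracks.

Markers failing a minor-allele-frequency floor, an individual-sample call
rate floor, or a limit on invalid replicate estimates are removed per
estimation-method track before association testing.  Defaults (MAF 0.01,
call rate 0.80) follow common pooled-GWAS practice; a marker exactly at a
threshold survives (only markers *below* a threshold are removed).

MAF is computed from the pooled estimates of each method track, so the
survivor sets of the four tracks can differ; the call rate comes from the
individual-DNA genotype table and is method-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .design import PoolDesign
from .errors import ValidationError


@dataclass(frozen=True)
class QCThresholds:
    """Survival thresholds; a marker passes on >= for both rate criteria."""

    maf_min: float = 0.01
    call_rate_min: float = 0.80
    max_invalid_replicates: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValidationError(f"maf_min must be in [0, 0.5], got {self.maf_min}")
        if not 0.0 <= self.call_rate_min <= 1.0:
            raise ValidationError(
                f"call_rate_min must be in [0, 1], got {self.call_rate_min}"
            )
        if self.max_invalid_replicates < 0:
            raise ValidationError("max_invalid_replicates must be >= 0")


@dataclass(frozen=True)
class QCReport:
    """Failure partition for one method track.

    A marker may be counted in several ``failed_*`` tallies; ``markers_out``
    subtracts the union of failing markers once.
    """

    method: str
    markers_in: int
    failed_maf: int
    failed_call_rate: int
    failed_validity: int
    markers_out: int

    def __str__(self) -> str:  # pragma: no cover - formatting
        return (
            f"[{self.method}] {self.markers_in} markers in; "
            f"failed MAF: {self.failed_maf}, call rate: {self.failed_call_rate}, "
            f"validity: {self.failed_validity}; {self.markers_out} markers out"
        )


def compute_call_rate(
    genotypes: pd.DataFrame, sample_count: int, markers=None
) -> pd.Series:
    """Fraction of individual samples with a non-missing call, per marker.

    The denominator is the declared ``sample_count`` (the genotyped cohort
    size), not the number of observed rows; markers absent from the table
    get call rate 0.
    """
    if sample_count < 1:
        raise ValidationError("sample_count must be >= 1")
    called = (
        genotypes.loc[genotypes["call"] != "NoCall"].groupby("marker_id").size()
    )
    if markers is not None:
        called = called.reindex(sorted(set(markers)), fill_value=0)
    rate = called / float(sample_count)
    rate.name = "call_rate"
    return rate


def compute_pool_maf(freqs: pd.DataFrame, method: str | None = None) -> pd.Series:
    """Minor allele frequency per marker from pooled estimates.

    The per-marker mean f̄ is taken over all *valid* replicate estimates of
    both groups; MAF = min(f̄, 1 − f̄).  Markers with no valid estimate are
    NaN (they fail QC through the validity rule anyway).
    """
    df = freqs
    if method is not None and "method" in df.columns:
        df = df[df["method"] == method]
    mean = df.loc[df["valid"], "freq"].groupby(df.loc[df["valid"], "marker_id"]).mean()
    mean = mean.reindex(sorted(df["marker_id"].unique()))
    maf = pd.concat([mean, 1.0 - mean], axis=1).min(axis=1)
    maf.name = "maf"
    return maf


def filter_qc(
    freqs: pd.DataFrame,
    genotypes: pd.DataFrame,
    design: PoolDesign,
    thresholds: QCThresholds = QCThresholds(),
    method: str | None = None,
    sample_count: int | None = None,
) -> tuple[set[str], QCReport]:
    """Apply MAF / call-rate / validity filters to one method track.

    Parameters
    ----------
    freqs:
        Pooled frequency table (long format with ``valid`` flags) for one
        method, or a multi-method table plus ``method=``.
    sample_count:
        Genotyped-cohort size for the call-rate denominator; defaults to
        the number of distinct samples in the genotype table.

    Returns the surviving marker-id set and a :class:`QCReport`.
    """
    df = freqs
    if method is not None and "method" in df.columns:
        df = df[df["method"] == method]
    track = method if method is not None else str(df["method"].iloc[0]) if len(df) else "?"
    markers = sorted(df["marker_id"].unique())
    if sample_count is None:
        sample_count = int(genotypes["sample_id"].nunique())

    maf = compute_pool_maf(df)
    call_rate = compute_call_rate(genotypes, sample_count, markers=markers)
    n_invalid = (~df["valid"]).groupby(df["marker_id"]).sum().reindex(markers, fill_value=0)

    # an undefined MAF (no valid estimate) fails through the validity rule only
    failed_maf = set(maf.index[maf < thresholds.maf_min])
    failed_cr = set(call_rate.index[call_rate < thresholds.call_rate_min])
    failed_val = set(n_invalid.index[n_invalid > thresholds.max_invalid_replicates])
    failed_val |= set(maf.index[maf.isna()])  # no valid estimate at all

    failing = failed_maf | failed_cr | failed_val
    survivors = set(markers) - failing
    report = QCReport(
        method=track,
        markers_in=len(markers),
        failed_maf=len(failed_maf),
        failed_call_rate=len(failed_cr),
        failed_validity=len(failed_val),
        markers_out=len(survivors),
    )
    return survivors, report
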