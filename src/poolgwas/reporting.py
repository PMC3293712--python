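"""Cross-method summaries: significant markers, per-group frequency
statistics, and pool-vs-reference accuracy evaluation.

The four estimation tracks (H, M, N, U) are analysed in parallel; a marker
is called suggestive when its nested-ANOVA p-value falls below the screening
threshold (default 1e-4, a deliberately lenient level since hits are meant
to be confirmed by individual genotyping) in *at least one* track.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .design import PoolDesign
from .errors import ValidationError

DEFAULT_SIGNIFICANCE_THRESHOLD = 1e-4


# ---------------------------------------------------------------------------
# significance summary (union rule)


def summarize_significant(
    results: Mapping[str, pd.DataFrame],
    threshold: float = DEFAULT_SIGNIFICANCE_THRESHOLD,
    include_degenerate: bool = False,
) -> pd.DataFrame:
    """Markers with p < threshold in at least one method track.

    Parameters
    ----------
    results:
        Mapping method -> nested-ANOVA result frame.
    include_degenerate:
        When False (default), results carrying a degeneracy flag do not
        count toward the union (their p-values of exactly 0 or 1 reflect a
        pathology, not evidence).

    Returns a wide frame with one row per union-significant marker: the
    per-method p-values (``p_<method>``), per-method significance flags
    (``sig_<method>``), the best p-value, and the union flag; sorted by
    best p ascending, ties broken by marker id.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError(f"significance threshold must be in (0, 1), got {threshold}")
    pieces = []
    for meth, res in results.items():
        if res.empty:
            continue
        r = res[["marker_id", "p_value", "flags"]].copy()
        if not include_degenerate:
            r.loc[r["flags"] != "", "p_value"] = np.nan
        pieces.append(r.assign(method=meth))
    if not pieces:
        return pd.DataFrame(columns=["marker_id", "best_p", "union_significant"])
    long = pd.concat(pieces, ignore_index=True)
    wide = long.pivot(index="marker_id", columns="method", values="p_value")
    wide = wide.rename(columns={m: f"p_{m}" for m in wide.columns})
    for meth in results:
        col = f"p_{meth}"
        if col not in wide.columns:
            wide[col] = np.nan
        wide[f"sig_{meth}"] = wide[col] < threshold
    sig_cols = [c for c in wide.columns if c.startswith("sig_")]
    wide["union_significant"] = wide[sig_cols].any(axis=1)
    wide["best_p"] = wide[[c for c in wide.columns if c.startswith("p_")]].min(axis=1)
    out = (
        wide.loc[wide["union_significant"]]
        .reset_index()
        .sort_values(["best_p", "marker_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


# ---------------------------------------------------------------------------
# per-group frequency statistics


def mean_freq_statistics(
    freqs: pd.DataFrame, design: PoolDesign, method: str | None = None
) -> pd.DataFrame:
    """Per-marker, per-group mean and sample SD of the replicate estimates.

    Only valid estimates contribute; the SD uses the n−1 denominator and is
    NaN when a single replicate remains.  Groups with no valid estimate for
    a marker are absent from the output (missing entry).
    """
    df = freqs
    if method is not None and "method" in df.columns:
        df = df[df["method"] == method]
    if "valid" in df.columns:
        df = df[df["valid"]]
    d = df.merge(design.to_frame(), on="replicate_id", how="left")
    if d["group"].isna().any():
        bad = sorted(set(d.loc[d["group"].isna(), "replicate_id"]))
        raise ValidationError(f"replicate id(s) not in the pool design: {bad[:5]}")
    out = (
        d.groupby(["marker_id", "group"], sort=True)["freq"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="size")
        .reset_index()
    )
    return out


def individual_allele_frequency(
    genotypes: pd.DataFrame, group_assignment: Mapping[str, str]
) -> pd.DataFrame:
    """Allele-A frequency per marker and group from individual genotypes.

    freq = (2·#AA + #AB) / (2·#called); NoCall rows are excluded from both
    numerator and denominator.  Markers with zero called samples in a group
    are absent from the output.
    """
    df = genotypes.copy()
    df["group"] = df["sample_id"].map(dict(group_assignment))
    if df["group"].isna().any():
        bad = sorted(set(df.loc[df["group"].isna(), "sample_id"]))
        raise ValidationError(f"sample(s) without a group assignment: {bad[:5]}")
    df = df[df["call"] != "NoCall"]
    if df.empty:
        return pd.DataFrame(columns=["marker_id", "group", "freq", "n_called"])
    dose = df["call"].map({"AA": 2, "AB": 1, "BB": 0}).astype(int)
    g = df.assign(dose=dose).groupby(["marker_id", "group"], sort=True)
    out = g.agg(n_called=("dose", "size"), a_count=("dose", "sum")).reset_index()
    out["freq"] = out["a_count"] / (2.0 * out["n_called"])
    return out[["marker_id", "group", "freq", "n_called"]]


# ---------------------------------------------------------------------------
# accuracy evaluation (pool estimates vs a reference)


@dataclass(frozen=True)
class AccuracyRow:
    """One comparison row: method x (case | control | case-control)."""

    method: str
    comparison: str
    n_markers: int
    mean_diff: float
    sd_diff: float
    mean_abs_diff: float
    sd_abs_diff: float
    pct_over: float


def accuracy_evaluation(
    pool_group_means: pd.DataFrame,
    reference_freqs: pd.DataFrame,
    design: PoolDesign,
    method: str = "",
) -> pd.DataFrame:
    """Accuracy of pooled estimates against a per-group reference.

    Parameters
    ----------
    pool_group_means:
        Output of :func:`mean_freq_statistics` (``marker_id, group, mean``).
    reference_freqs:
        Reference table ``marker_id, group, freq`` — typically
        :func:`individual_allele_frequency` of the individually genotyped
        samples, or the generator's truth table in simulations.

    For each comparison the per-marker signed difference is
    d = pooled − reference (for case−control, d = Δpooled − Δreference).
    Reported per comparison: mean(d), sample SD(d), mean(|d|), SD(|d|),
    and the percentage of markers with d strictly > 0 (over-estimated;
    exact ties count as not over-estimated).  Markers present in both
    sources for both groups are used; an empty intersection is an error.
    """
    pools = pool_group_means.pivot(index="marker_id", columns="group", values="mean")
    ref = reference_freqs.pivot(index="marker_id", columns="group", values="freq")
    case, ctrl = design.case_group, design.control_group
    for frame, what in ((pools, "pooled"), (ref, "reference")):
        for grp in (case, ctrl):
            if grp not in frame.columns:
                raise ValidationError(f"{what} table has no group {grp!r}")
    common = pools.dropna().index.intersection(ref.dropna().index)
    if len(common) == 0:
        raise ValidationError("no markers shared between pooled and reference tables")
    pools, ref = pools.loc[common], ref.loc[common]

    diffs = {
        "case": pools[case] - ref[case],
        "control": pools[ctrl] - ref[ctrl],
        "case-control": (pools[case] - pools[ctrl]) - (ref[case] - ref[ctrl]),
    }
    rows = []
    for comparison, d in diffs.items():
        d = d.to_numpy(dtype=float)
        rows.append(
            AccuracyRow(
                method=method,
                comparison=comparison,
                n_markers=len(d),
                mean_diff=float(np.mean(d)),
                sd_diff=float(np.std(d, ddof=1)) if len(d) > 1 else float("nan"),
                mean_abs_diff=float(np.mean(np.abs(d))),
                sd_abs_diff=float(np.std(np.abs(d), ddof=1)) if len(d) > 1 else float("nan"),
                pct_over=float(100.0 * np.mean(d > 0)),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def format_accuracy_table(summaries: Mapping[str, pd.DataFrame]) -> str:
    """Human-readable accuracy report, one row per method x comparison.

    Layout: signed-difference mean and SD, absolute-difference mean and SD,
    and the percentage of markers with over-estimated frequency.
    """
    header = (
        f"{'Method':<8}{'Comparison':<14}{'N':>6}"
        f"{'MeanDiff':>10}{'SD':>9}{'Mean|Diff|':>12}{'SD':>9}{'%Over':>8}"
    )
    lines = [header, "-" * len(header)]
    for meth, table in summaries.items():
        for _, r in table.iterrows():
            lines.append(
                f"{meth:<8}{r['comparison']:<14}{int(r['n_markers']):>6}"
                f"{r['mean_diff']:>10.4f}{r['sd_diff']:>9.4f}"
                f"{r['mean_abs_diff']:>12.4f}{r['sd_abs_diff']:>9.4f}"
                f"{r['pct_over']:>8.1f}"
            )
    return "\n".join(lines)


def write_significance_table(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def write_mean_freq_table(stats: pd.DataFrame, path) -> None:
    out = stats.rename(
        columns={"marker_id": "Marker", "group": "Group", "mean": "Mean", "sd": "SD", "n": "N"}
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def write_accuracy_table(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
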