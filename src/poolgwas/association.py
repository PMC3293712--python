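"""Nested ANOVA for case-control association on pooled frequencies.

Replicate arrays are nested within physical pools, pools within the two
phenotype groups.  Pools are treated as a random effect, so the group
effect is tested against pool-within-group variation:

    F = MS_group / MS_pool,   df = (g − 1, Σ_i (b_i − 1))

with g groups and b_i pools in group i.  Sums of squares use actual counts
(so validity-filtered, unbalanced data are handled; in the unbalanced case
the ratio is the usual approximation to the random-effects F):

    SS_group = Σ_i N_i (ȳ_i·· − ȳ···)²
    SS_pool  = Σ_ij n_ij (ȳ_ij· − ȳ_i··)²
    SS_error = Σ_ijk (y_ijk − ȳ_ij·)²

The replicate-level MS_error is computed and reported but is *not* the
denominator of the group test.  Frequencies are tested untransformed (the
group contrast is on mean pooled allele frequency); an optional arcsine
square-root variance-stabilising transform can be applied first.

Degenerate markers are flagged, not dropped: an all-constant response
gives p = 1 (no evidence); zero pool-within-group variance with a nonzero
group contrast gives p = 0.  No multiple-testing correction is applied —
downstream screening uses a lenient raw-p threshold with confirmation by
individual genotyping in mind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import PoolDesign
from .errors import DesignError, ValidationError

#: absolute floor (per unit sum-of-squares scale) below which a mean square
#: is considered exactly zero; far above double rounding, far below any
#: real replicate noise
_TINY = 1e-18

FLAG_CONSTANT = "constant"
FLAG_ZERO_POOL_MS = "zero_pool_ms"
FLAG_INSUFFICIENT = "insufficient_pools"

RESULT_COLUMNS = [
    "marker_id",
    "method",
    "f_stat",
    "df_num",
    "df_den",
    "p_value",
    "mean_case",
    "mean_control",
    "ms_group",
    "ms_pool",
    "ms_error",
    "flags",
]


@dataclass(frozen=True)
class AnovaResult:
    """Nested-ANOVA outcome for a single marker."""

    marker_id: str
    method: str
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    mean_case: float
    mean_control: float
    ms_group: float
    ms_pool: float
    ms_error: float
    flags: str = ""


def _arcsine(y: np.ndarray) -> np.ndarray:
    return np.arcsin(np.sqrt(np.clip(y, 0.0, 1.0)))


def nested_anova_all(
    freqs: pd.DataFrame,
    design: PoolDesign,
    method: str | None = None,
    transform: str | None = None,
) -> pd.DataFrame:
    """Nested ANOVA for every marker of one (QC-filtered) frequency track.

    Parameters
    ----------
    freqs:
        Long frequency table ``marker_id, replicate_id, freq`` (+ optional
        ``valid``/``method`` columns; invalid rows are dropped, and when
        ``method`` is given only that track is used).
    transform:
        ``None`` (default, test raw frequencies) or ``"arcsine"`` for the
        arcsin-sqrt variance-stabilising transform.

    Returns a frame with one row per marker (``RESULT_COLUMNS``), sorted by
    ``marker_id``.  Markers with fewer than two data-bearing pools in
    either group are flagged ``insufficient_pools`` with NaN statistics.
    """
    df = freqs
    if method is not None and "method" in df.columns:
        df = df[df["method"] == method]
    track = method if method is not None else (str(df["method"].iloc[0]) if "method" in df.columns and len(df) else "")
    if "valid" in df.columns:
        df = df[df["valid"]]
    if df.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS)

    rep = design.to_frame()
    d = df.merge(rep, on="replicate_id", how="left")
    if d["pool_id"].isna().any():
        bad = sorted(set(d.loc[d["pool_id"].isna(), "replicate_id"]))
        raise ValidationError(f"replicate id(s) not in the pool design: {bad[:5]}")
    y = d["freq"].to_numpy(dtype=float)
    if transform == "arcsine":
        y = _arcsine(y)
    elif transform is not None:
        raise ValidationError(f"unknown transform {transform!r}")
    d = d.assign(y=y)

    # hierarchical means with actual counts
    pool = (
        d.groupby(["marker_id", "group", "pool_id"], sort=True)["y"]
        .agg(n="size", mean="mean")
        .reset_index()
    )
    grp = (
        d.groupby(["marker_id", "group"], sort=True)["y"]
        .agg(N="size", mean="mean")
        .reset_index()
    )
    grand = d.groupby("marker_id", sort=True)["y"].agg(n_total="size", grand_mean="mean")

    t = grp.merge(grand, on="marker_id")
    ss_group = (
        (t["N"] * (t["mean"] - t["grand_mean"]) ** 2).groupby(t["marker_id"]).sum()
    )
    n_groups = grp.groupby("marker_id").size()

    t2 = pool.merge(grp, on=["marker_id", "group"], suffixes=("", "_grp"))
    ss_pool = (
        (t2["n"] * (t2["mean"] - t2["mean_grp"]) ** 2).groupby(t2["marker_id"]).sum()
    )
    pools_per_group = pool.groupby(["marker_id", "group"]).size()
    df_pool = (pools_per_group - 1).groupby("marker_id").sum()
    min_pools = pools_per_group.groupby("marker_id").min()

    d2 = d.merge(
        pool.rename(columns={"mean": "pool_mean"})[
            ["marker_id", "pool_id", "pool_mean"]
        ],
        on=["marker_id", "pool_id"],
    )
    ss_error = ((d2["y"] - d2["pool_mean"]) ** 2).groupby(d2["marker_id"]).sum()
    df_error = (pool["n"] - 1).groupby(pool["marker_id"]).sum()

    markers = grand.index
    res = pd.DataFrame(index=markers)
    res["ss_group"] = ss_group
    res["ss_pool"] = ss_pool.reindex(markers, fill_value=0.0)
    res["ss_error"] = ss_error.reindex(markers, fill_value=0.0)
    res["df_num"] = (n_groups - 1).reindex(markers)
    res["df_den"] = df_pool.reindex(markers)
    res["df_error"] = df_error.reindex(markers)

    ok = (n_groups.reindex(markers) == 2) & (min_pools.reindex(markers) >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        res["ms_group"] = res["ss_group"] / res["df_num"]
        res["ms_pool"] = res["ss_pool"] / res["df_den"]
        res["ms_error"] = np.where(
            res["df_error"] > 0, res["ss_error"] / res["df_error"], np.nan
        )

    tiny = _TINY * grand["n_total"].reindex(markers) * (1.0 + grand["grand_mean"] ** 2)
    sst = res["ss_group"] + res["ss_pool"] + res["ss_error"]
    constant = ok & (sst <= tiny)
    zero_pool = ok & ~constant & (res["ms_pool"] <= tiny) & (res["ms_group"] > tiny)
    pool_and_group_flat = ok & ~constant & (res["ms_pool"] <= tiny) & (res["ms_group"] <= tiny)
    regular = ok & ~constant & ~zero_pool & ~pool_and_group_flat

    f = np.full(len(markers), np.nan)
    p = np.full(len(markers), np.nan)
    reg = regular.to_numpy()
    f[reg] = (res["ms_group"] / res["ms_pool"]).to_numpy()[reg]
    p[reg] = stats.f.sf(
        f[reg], res["df_num"].to_numpy()[reg], res["df_den"].to_numpy()[reg]
    )
    p[constant.to_numpy()] = 1.0
    p[pool_and_group_flat.to_numpy()] = 1.0
    zp = zero_pool.to_numpy()
    f[zp] = np.inf
    p[zp] = 0.0

    flags = np.full(len(markers), "", dtype=object)
    flags[~ok.to_numpy()] = FLAG_INSUFFICIENT
    flags[constant.to_numpy() | pool_and_group_flat.to_numpy()] = FLAG_CONSTANT
    flags[zp] = FLAG_ZERO_POOL_MS

    means = grp.pivot(index="marker_id", columns="group", values="mean")
    out = pd.DataFrame(
        {
            "marker_id": markers,
            "method": track,
            "f_stat": f,
            "df_num": res["df_num"].to_numpy(),
            "df_den": res["df_den"].to_numpy(),
            "p_value": p,
            "mean_case": means.get(design.case_group, pd.Series(index=markers, dtype=float)).reindex(markers).to_numpy(),
            "mean_control": means.get(design.control_group, pd.Series(index=markers, dtype=float)).reindex(markers).to_numpy(),
            "ms_group": res["ms_group"].to_numpy(),
            "ms_pool": res["ms_pool"].to_numpy(),
            "ms_error": res["ms_error"].to_numpy(),
            "flags": flags,
        }
    ).sort_values("marker_id", kind="mergesort").reset_index(drop=True)
    return out


def nested_anova_marker(
    values: pd.DataFrame, design: PoolDesign, transform: str | None = None
) -> AnovaResult:
    """Nested ANOVA for one marker.

    ``values`` holds one row per replicate measurement with columns
    ``replicate_id, freq``.  Raises :class:`DesignError` when either group
    has fewer than two data-bearing pools.
    """
    df = values[["replicate_id", "freq"]].copy()
    df["marker_id"] = "_single_"
    res = nested_anova_all(df, design, transform=transform)
    row = res.iloc[0]
    if row["flags"] == FLAG_INSUFFICIENT:
        raise DesignError("nested ANOVA needs at least 2 pools with data per group")
    return AnovaResult(
        marker_id=str(values["marker_id"].iloc[0]) if "marker_id" in values else "_single_",
        method=row["method"],
        f_stat=float(row["f_stat"]),
        df_num=int(row["df_num"]),
        df_den=int(row["df_den"]),
        p_value=float(row["p_value"]),
        mean_case=float(row["mean_case"]),
        mean_control=float(row["mean_control"]),
        ms_group=float(row["ms_group"]),
        ms_pool=float(row["ms_pool"]),
        ms_error=float(row["ms_error"]),
        flags=str(row["flags"]),
    )


def read_anova_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_anova_table`."""
    raw = pd.read_csv(path, sep="\t", dtype={"Marker": str, "Method": str}, keep_default_na=False)
    return pd.DataFrame(
        {
            "marker_id": raw["Marker"],
            "method": raw["Method"],
            "f_stat": pd.to_numeric(raw["F"], errors="coerce"),
            "df_num": raw["DF1"].astype(int),
            "df_den": raw["DF2"].astype(int),
            "p_value": pd.to_numeric(raw["P"], errors="coerce"),
            "mean_case": pd.to_numeric(raw["MeanCase"], errors="coerce"),
            "mean_control": pd.to_numeric(raw["MeanControl"], errors="coerce"),
            "ms_group": pd.to_numeric(raw["MSGroup"], errors="coerce"),
            "ms_pool": pd.to_numeric(raw["MSPool"], errors="coerce"),
            "ms_error": pd.to_numeric(raw["MSError"], errors="coerce"),
            "flags": raw["Flags"].astype(str),
        }
    )


def write_anova_table(results: pd.DataFrame, path) -> None:
    """Tab-delimited result table (Marker, Method, F, DF1, DF2, P, ...)."""
    out = pd.DataFrame(
        {
            "Marker": results["marker_id"],
            "Method": results["method"],
            "F": results["f_stat"],
            "DF1": results["df_num"],
            "DF2": results["df_den"],
            "P": results["p_value"],
            "MeanCase": results["mean_case"],
            "MeanControl": results["mean_control"],
            "MSGroup": results["ms_group"],
            "MSPool": results["ms_pool"],
            "MSError": results["ms_error"],
            "Flags": results["flags"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
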