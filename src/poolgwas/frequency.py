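"""Pooled allele-frequency estimation with allelic-amplification correction.

On two-channel SNP arrays the two alleles of a heterozygote do not fluoresce
equally despite equal dosage (allelic preferential amplification /
hybridisation).  The raw relative allele signal RAS = a/(a+b) of a DNA pool
is therefore a biased estimate of the pool's allele-A frequency.  This
module estimates a per-marker correction from individually genotyped
heterozygotes and applies it to pooled intensities under four parallel
methods:

``U`` (unadjusted)
    p = a / (a + b), the raw RAS.
``H`` (heterozygote ratio correction)
    k is the arithmetic mean over heterozygotes of the per-sample signal
    ratio a/b; p = a / (a + k·b).
``M`` (heterozygote RAS correction)
    With R = a/(a+b) and the mean heterozygote RAS r̄, define
    κ = r̄/(1−r̄); p = R / (R + κ·(1−R)).  Algebraically this equals
    a / (a + κ·b), so M differs from H only through how the heterozygote
    summary is averaged (mean of ratios vs ratio of the mean RAS).
``N`` (per-replicate channel normalisation, then M)
    Each replicate array's A and B channels are rescaled so that every
    array has the same mean channel intensity, then the M formula is
    applied.  This removes array-to-array differences in overall channel
    brightness before correction.

All estimators are vectorised over numpy arrays; invalid estimates
(unusable correction factor, zero denominator, out-of-range result) are
returned as NaN and flagged, never silently replaced.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .design import PoolDesign
from .errors import ValidationError

METHODS = ("H", "M", "N", "U")

#: default minimum usable heterozygotes per marker; with common variants
#: (MAF >= 5%) one expects 2-3 heterozygotes among 20-30 genotyped samples.
DEFAULT_MIN_HET = 2


# ---------------------------------------------------------------------------
# correction factors


def estimate_correction_factors(
    het_records: pd.DataFrame, min_het: int = DEFAULT_MIN_HET
) -> pd.DataFrame:
    """Per-marker amplification correction from heterozygous individuals.

    Parameters
    ----------
    het_records:
        Merged heterozygote table with columns ``marker_id, signal_a,
        signal_b`` (every row a confirmed AB call).
    min_het:
        Markers with fewer usable heterozygotes are flagged unusable.

    Returns
    -------
    DataFrame indexed by ``marker_id`` with columns:

    ``k_h``
        arithmetic mean of per-heterozygote signal ratios a/b (rows with
        b == 0 are excluded and counted in ``n_excluded``);
    ``ras_het_mean``
        arithmetic mean of per-heterozygote RAS a/(a+b) (rows with
        a + b == 0 excluded);
    ``n_het``
        heterozygotes usable for ``k_h`` (b > 0);
    ``n_excluded``
        heterozygote rows dropped from the ratio mean because b == 0;
    ``usable``
        ``n_het >= min_het`` and both summaries finite and in range.
    """
    if min_het < 1:
        raise ValidationError(f"min_het must be >= 1, got {min_het}")
    if "call" in het_records.columns and (het_records["call"] != "AB").any():
        raise ValidationError("estimate_correction_factors expects only AB records")
    df = het_records[["marker_id", "signal_a", "signal_b"]].copy()
    df["ratio_ok"] = df["signal_b"] > 0
    df["ras_ok"] = (df["signal_a"] + df["signal_b"]) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        df["ratio"] = np.where(df["ratio_ok"], df["signal_a"] / df["signal_b"], np.nan)
        df["ras"] = np.where(
            df["ras_ok"], df["signal_a"] / (df["signal_a"] + df["signal_b"]), np.nan
        )
    g = df.groupby("marker_id", sort=True)
    out = pd.DataFrame(
        {
            "k_h": g["ratio"].mean(),
            "ras_het_mean": g["ras"].mean(),
            "n_het": g["ratio_ok"].sum().astype(int),
            "n_excluded": (g["ratio_ok"].count() - g["ratio_ok"].sum()).astype(int),
        }
    )
    out["usable"] = (
        (out["n_het"] >= min_het)
        & np.isfinite(out["k_h"])
        & (out["k_h"] > 0)
        & np.isfinite(out["ras_het_mean"])
        & (out["ras_het_mean"] > 0)
        & (out["ras_het_mean"] < 1)
    )
    out.index.name = "marker_id"
    return out


# ---------------------------------------------------------------------------
# the four per-measurement estimators (array-valued; NaN marks invalid)


def estimate_unadjusted(signal_a, signal_b):
    """Raw relative allele signal p = a/(a+b); NaN when a + b == 0."""
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    total = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, a / total, np.nan)
    return p if p.ndim else float(p)


def estimate_hoogendoorn(signal_a, signal_b, k):
    """Ratio-corrected frequency p = a/(a + k·b).

    With k = 1 this reduces bit-for-bit to :func:`estimate_unadjusted`.
    NaN when k is non-positive/non-finite or the denominator is zero.
    """
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    k = np.asarray(k, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = a + k * b
        p = np.where((k > 0) & np.isfinite(k) & (denom > 0), a / denom, np.nan)
    return p if p.ndim else float(p)


def estimate_meaburn(signal_a, signal_b, ras_het_mean):
    """RAS-corrected frequency.

    With pool RAS R = a/(a+b) and mean heterozygote RAS r̄, the corrected
    frequency is R / (R + κ·(1−R)) where κ = r̄/(1−r̄).  Computed through
    the RAS form (not the algebraically equal a/(a+κ·b)) so the identity
    between the two corrections is a genuine cross-check, not a tautology.
    NaN when r̄ is outside (0, 1) or a + b == 0.
    """
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    r_het = np.asarray(ras_het_mean, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        total = a + b
        R = np.where(total > 0, a / total, np.nan)
        kappa = r_het / (1.0 - r_het)
        ok = (r_het > 0) & (r_het < 1) & np.isfinite(r_het) & (total > 0)
        denom = R + kappa * (1.0 - R)
        p = np.where(ok & (denom > 0), R / denom, np.nan)
    return p if p.ndim else float(p)


# ---------------------------------------------------------------------------
# normalisation (method N)


def fit_normalization(
    pool_intensities: pd.DataFrame, marker_set: Iterable[str] | None = None
) -> pd.DataFrame:
    """Per-replicate, per-channel scale factors equalising mean intensity.

    For replicate r let ā(r), b̄(r) be the mean A- and B-channel signals
    over ``marker_set`` (all markers when None), and T_a, T_b the grand
    means of those channel means across replicates.  The scales are
    c_a(r) = T_a/ā(r) and c_b(r) = T_b/b̄(r); after rescaling every
    replicate has identical per-channel means, and already-homogeneous
    replicates get unit scales.  Scaling the channels separately can
    change the RAS of a replicate — that is the point: it removes
    per-array channel-brightness differences that a total-intensity
    scaling could not, while leaving the cohort-average channel balance
    (hence the amplification correction) intact.

    Returns a frame indexed by ``replicate_id`` with columns ``c_a, c_b``.
    """
    df = pool_intensities
    if marker_set is not None:
        df = df[df["marker_id"].isin(set(marker_set))]
    if df.empty:
        raise ValidationError("no intensity rows available to fit normalisation scales")
    means = df.groupby("sample_id", sort=True)[["signal_a", "signal_b"]].mean()
    zero = means[(means["signal_a"] <= 0) | (means["signal_b"] <= 0)]
    if len(zero):
        raise ValidationError(
            f"replicate(s) with a non-positive mean channel intensity: {list(zero.index)}"
        )
    out = pd.DataFrame(
        {
            "c_a": float(means["signal_a"].mean()) / means["signal_a"],
            "c_b": float(means["signal_b"].mean()) / means["signal_b"],
        }
    )
    out.index.name = "replicate_id"
    return out


# ---------------------------------------------------------------------------
# pooled frequency table


def estimate_pool_frequencies(
    pool_intensities: pd.DataFrame,
    design: PoolDesign,
    method: str,
    factors: pd.DataFrame | None = None,
    scales: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One allele-A frequency estimate per (marker, replicate) under one method.

    Parameters
    ----------
    pool_intensities:
        Intensity table for pooled replicates; ``sample_id`` is the
        replicate id and must appear in ``design``.
    method:
        One of ``H``, ``M``, ``N``, ``U``.
    factors:
        Correction-factor table (required for H/M/N); markers that are
        missing or flagged unusable get invalid estimates — they are never
        silently swapped to the unadjusted value.
    scales:
        Per-replicate normalisation scales (required for N).

    Returns
    -------
    Long frame ``marker_id, replicate_id, method, freq, valid``; invalid
    estimates carry ``freq = NaN``.  Estimates landing outside [0, 1]
    (impossible for H/M/U with non-negative signals, checked anyway) are
    marked invalid rather than clamped.
    """
    if method not in METHODS:
        raise ValidationError(f"unknown estimation method {method!r}; expected one of {METHODS}")
    unknown = set(pool_intensities["sample_id"]) - set(design.replicate_to_pool)
    if unknown:
        raise ValidationError(
            f"replicate id(s) not in the pool design: {sorted(unknown)[:5]}"
        )
    df = pool_intensities[["marker_id", "sample_id", "signal_a", "signal_b"]].rename(
        columns={"sample_id": "replicate_id"}
    )
    a = df["signal_a"].to_numpy(dtype=float)
    b = df["signal_b"].to_numpy(dtype=float)

    if method == "U":
        freq = estimate_unadjusted(a, b)
    else:
        if factors is None:
            raise ValidationError(f"method {method} requires a correction-factor table")
        fac = factors.reindex(df["marker_id"])
        usable = fac["usable"].fillna(False).to_numpy(dtype=bool)
        if method == "N":
            if scales is None:
                raise ValidationError("method N requires per-replicate normalisation scales")
            sc = scales.reindex(df["replicate_id"])
            if sc["c_a"].isna().any():
                missing = sorted(set(df.loc[sc["c_a"].isna().to_numpy(), "replicate_id"]))
                raise ValidationError(f"no normalisation scale for replicate(s): {missing[:5]}")
            a = a * sc["c_a"].to_numpy(dtype=float)
            b = b * sc["c_b"].to_numpy(dtype=float)
        if method == "H":
            freq = estimate_hoogendoorn(a, b, fac["k_h"].to_numpy(dtype=float))
        else:  # M or N (N applies the M formula to rescaled channels)
            freq = estimate_meaburn(a, b, fac["ras_het_mean"].to_numpy(dtype=float))
        freq = np.where(usable, freq, np.nan)

    valid = np.isfinite(freq) & (freq >= 0.0) & (freq <= 1.0)
    freq = np.where(valid, freq, np.nan)
    return pd.DataFrame(
        {
            "marker_id": df["marker_id"].to_numpy(),
            "replicate_id": df["replicate_id"].to_numpy(),
            "method": method,
            "freq": freq,
            "valid": valid,
        }
    )


def write_frequency_table(frame: pd.DataFrame, path) -> None:
    """Write a long-format frequency table (Marker, Replicate, Method, Freq, Valid)."""
    out = pd.DataFrame(
        {
            "Marker": frame["marker_id"],
            "Replicate": frame["replicate_id"],
            "Method": frame["method"],
            "Freq": frame["freq"],
            "Valid": frame["valid"].astype(int),
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def read_frequency_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_frequency_table`."""
    raw = pd.read_csv(path, sep="\t", dtype={"Marker": str, "Replicate": str, "Method": str})
    return pd.DataFrame(
        {
            "marker_id": raw["Marker"],
            "replicate_id": raw["Replicate"],
            "method": raw["Method"],
            "freq": raw["Freq"].astype(float),
            "valid": raw["Valid"].astype(bool),
        }
    )


def write_correction_factor_table(factors: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "Marker": factors.index,
            "K_H": factors["k_h"],
            "RAS_het": factors["ras_het_mean"],
            "N_het": factors["n_het"],
            "Usable": factors["usable"].astype(int),
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
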