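"""Parsing, validation, merging and pre-filtering of the four input tables.

All inputs are tab-delimited UTF-8 text with a header row, the convention of
BeadStudio-style exports after shell extraction:

========================  =======================================
table                     default columns
========================  =======================================
intensities               Marker, Sample, SignalA, SignalB
genotype calls            Marker, Sample, Call
marker annotation         Marker, Chr, Pos
pool design               Replicate, Pool, Group
========================  =======================================

Column names (and the genotype-call vocabulary) are remappable through the
dialect dataclasses, since vendor exports differ.  Internally every table
becomes a :class:`pandas.DataFrame` with canonical snake_case columns.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Literal, Mapping

import numpy as np
import pandas as pd

from .design import PoolDesign
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

RS_PATTERN = re.compile(r"^rs[0-9]+$", re.IGNORECASE)
AUTOSOMES = {str(c) for c in range(1, 23)}
KNOWN_CHROMOSOMES = AUTOSOMES | {"X", "Y", "XY", "MT"}

ClampPolicy = Literal["clamp", "drop", "error"]


# ---------------------------------------------------------------------------
# dialects


@dataclass(frozen=True)
class IntensityDialect:
    """Column names and negative-signal policy for intensity tables.

    Negative raw signals can occur after vendor background subtraction;
    ``negative_policy`` decides whether they are clamped to zero (default),
    dropped row-wise, or treated as a hard error.
    """

    marker: str = "Marker"
    sample: str = "Sample"
    signal_a: str = "SignalA"
    signal_b: str = "SignalB"
    negative_policy: ClampPolicy = "clamp"


def _default_call_map() -> dict[str, str]:
    return {
        "AA": "AA",
        "AB": "AB",
        "BA": "AB",  # unordered het codes normalised
        "BB": "BB",
        "NC": "NoCall",
        "NoCall": "NoCall",
    }


@dataclass(frozen=True)
class GenotypeDialect:
    marker: str = "Marker"
    sample: str = "Sample"
    call: str = "Call"
    #: raw call string -> canonical {AA, AB, BB, NoCall}
    call_map: Mapping[str, str] = field(default_factory=_default_call_map)


@dataclass(frozen=True)
class AnnotationDialect:
    marker: str = "Marker"
    chromosome: str = "Chr"
    position: str = "Pos"


@dataclass(frozen=True)
class DesignDialect:
    replicate: str = "Replicate"
    pool: str = "Pool"
    group: str = "Group"


# ---------------------------------------------------------------------------
# low-level helpers


def _read_tsv(source: str | Path | IO[str]) -> pd.DataFrame:
    if isinstance(source, (str, Path)):
        return pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    return pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)


def _require_columns(frame: pd.DataFrame, needed: Mapping[str, str], what: str) -> None:
    for role, name in needed.items():
        if name not in frame.columns:
            raise FormatError(f"{what} table is missing required column {name!r} ({role})")


def _numeric(frame: pd.DataFrame, column: str, what: str) -> pd.Series:
    """Convert a string column to float, reporting 1-based data line numbers."""
    values = pd.to_numeric(frame[column], errors="coerce")
    bad = values.isna()
    if bad.any():
        lines = [int(i) + 2 for i in frame.index[bad][:5]]  # +2: header + 1-based
        raise ValidationError(
            f"non-numeric value(s) in column {column!r} of {what} table at "
            f"line(s) {lines}"
        )
    values = values.astype(float)
    if not np.isfinite(values.to_numpy()).all():
        raise ValidationError(f"non-finite value(s) in column {column!r} of {what} table")
    return values


def _check_unique(frame: pd.DataFrame, what: str) -> None:
    dup = frame.duplicated(["marker_id", "sample_id"])
    if dup.any():
        pairs = frame.loc[dup, ["marker_id", "sample_id"]].head(5).itertuples(index=False)
        raise ValidationError(
            f"duplicate (marker, sample) pair(s) in {what} table: "
            + ", ".join(f"({m}, {s})" for m, s in pairs)
        )


# ---------------------------------------------------------------------------
# parsers


def parse_intensity_table(
    source: str | Path | IO[str], dialect: IntensityDialect = IntensityDialect()
) -> pd.DataFrame:
    """Parse a two-channel intensity table.

    Returns a frame with columns ``marker_id, sample_id, signal_a, signal_b``
    (floats, finite, >= 0), one row per input row, in input order.  Negative
    signals are handled per ``dialect.negative_policy``.
    """
    raw = _read_tsv(source)
    d = dialect
    _require_columns(
        raw,
        {"marker": d.marker, "sample": d.sample, "signal_a": d.signal_a, "signal_b": d.signal_b},
        "intensity",
    )
    out = pd.DataFrame(
        {
            "marker_id": raw[d.marker].astype(str),
            "sample_id": raw[d.sample].astype(str),
            "signal_a": _numeric(raw, d.signal_a, "intensity"),
            "signal_b": _numeric(raw, d.signal_b, "intensity"),
        }
    )
    neg = (out["signal_a"] < 0) | (out["signal_b"] < 0)
    if neg.any():
        n = int(neg.sum())
        if d.negative_policy == "error":
            raise ValidationError(f"{n} row(s) with negative signal in intensity table")
        if d.negative_policy == "drop":
            logger.warning("dropping %d row(s) with negative signal", n)
            out = out.loc[~neg].reset_index(drop=True)
        else:  # clamp
            logger.warning("clamping %d negative signal value(s) to 0", n)
            out[["signal_a", "signal_b"]] = out[["signal_a", "signal_b"]].clip(lower=0.0)
    _check_unique(out, "intensity")
    return out


def parse_genotype_table(
    source: str | Path | IO[str], dialect: GenotypeDialect = GenotypeDialect()
) -> pd.DataFrame:
    """Parse an individual-sample genotype-call table.

    Calls are normalised to ``{AA, AB, BB, NoCall}`` through the dialect's
    call map; a call string absent from the map is a validation error.
    """
    raw = _read_tsv(source)
    d = dialect
    _require_columns(raw, {"marker": d.marker, "sample": d.sample, "call": d.call}, "genotype")
    calls = raw[d.call].astype(str).map(dict(d.call_map))
    if calls.isna().any():
        bad = sorted(set(raw.loc[calls.isna(), d.call].astype(str)))[:5]
        raise ValidationError(f"unknown genotype call value(s): {bad}")
    out = pd.DataFrame(
        {
            "marker_id": raw[d.marker].astype(str),
            "sample_id": raw[d.sample].astype(str),
            "call": calls,
        }
    )
    _check_unique(out, "genotype")
    return out


def normalize_chromosome(label: str) -> str:
    """Canonicalise a chromosome label: strip a ``chr`` prefix, upper-case
    sex/mito labels; anything outside 1-22/X/Y/XY/MT becomes ``unknown``."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    if s in KNOWN_CHROMOSOMES:
        return s
    return "unknown"


def parse_annotation_table(
    source: str | Path | IO[str], dialect: AnnotationDialect = AnnotationDialect()
) -> pd.DataFrame:
    """Parse a marker annotation table into
    ``marker_id, chromosome, position, is_rs``.

    Positions are 1-based base pairs, carried through but never used in any
    computation.  ``is_rs`` is true iff the marker name matches the NCBI
    refSNP pattern ``rs<digits>`` (case-insensitive).
    """
    raw = _read_tsv(source)
    d = dialect
    _require_columns(
        raw, {"marker": d.marker, "chromosome": d.chromosome, "position": d.position}, "annotation"
    )
    markers = raw[d.marker].astype(str)
    if markers.duplicated().any():
        dups = sorted(set(markers[markers.duplicated()]))[:5]
        raise ValidationError(f"duplicate marker id(s) in annotation table: {dups}")
    pos = _numeric(raw, d.position, "annotation")
    if (pos < 0).any():
        raise ValidationError("negative position(s) in annotation table")
    return pd.DataFrame(
        {
            "marker_id": markers,
            "chromosome": raw[d.chromosome].map(normalize_chromosome),
            "position": pos.astype(int),
            "is_rs": markers.str.match(RS_PATTERN).astype(bool),
        }
    )


def parse_design_table(
    source: str | Path | IO[str],
    dialect: DesignDialect = DesignDialect(),
    groups: tuple[str, str] | None = None,
) -> PoolDesign:
    """Parse the pool-design table into a :class:`PoolDesign`."""
    raw = _read_tsv(source)
    d = dialect
    _require_columns(raw, {"replicate": d.replicate, "pool": d.pool, "group": d.group}, "design")
    frame = pd.DataFrame(
        {
            "replicate_id": raw[d.replicate].astype(str),
            "pool_id": raw[d.pool].astype(str),
            "group": raw[d.group].astype(str),
        }
    )
    return PoolDesign.from_frame(frame, groups=groups)


# ---------------------------------------------------------------------------
# merging and marker filters


@dataclass(frozen=True)
class JoinReport:
    """Bookkeeping of a genotype x intensity merge."""

    n_genotypes: int
    n_intensities: int
    n_matched: int
    n_unmatched_genotypes: int
    n_unmatched_intensities: int
    n_output: int

    def __str__(self) -> str:  # pragma: no cover - formatting
        return (
            f"merge: {self.n_matched} matched pairs "
            f"({self.n_unmatched_genotypes} genotype rows and "
            f"{self.n_unmatched_intensities} intensity rows unmatched), "
            f"{self.n_output} rows kept"
        )


def merge_genotype_intensity(
    genotypes: pd.DataFrame,
    intensities: pd.DataFrame,
    het_only: bool = True,
) -> tuple[pd.DataFrame, JoinReport]:
    """Inner-join genotype calls with intensity measurements on
    ``(marker_id, sample_id)``.

    With ``het_only`` (the default) only heterozygous (AB) rows are kept —
    these calibrate the per-marker allelic-amplification correction.
    Unmatched rows on either side are dropped and counted; an empty overlap
    is reported with a warning, not raised.
    """
    merged = genotypes.merge(
        intensities, on=["marker_id", "sample_id"], how="inner", sort=False
    )
    n_matched = len(merged)
    if het_only:
        merged = merged.loc[merged["call"] == "AB"].reset_index(drop=True)
    report = JoinReport(
        n_genotypes=len(genotypes),
        n_intensities=len(intensities),
        n_matched=n_matched,
        n_unmatched_genotypes=len(genotypes) - n_matched,
        n_unmatched_intensities=len(intensities) - n_matched,
        n_output=len(merged),
    )
    if n_matched == 0:
        logger.warning("genotype/intensity merge found no overlapping (marker, sample) pairs")
    return merged, report


def filter_markers_rs(annotations: pd.DataFrame) -> set[str]:
    """Markers whose names are NCBI refSNP (``rs<digits>``) identifiers."""
    return set(annotations.loc[annotations["is_rs"], "marker_id"])


def filter_autosomal(annotations: pd.DataFrame) -> set[str]:
    """Markers on autosomes 1-22; unknown chromosome labels are excluded
    (and counted in the log)."""
    on_auto = annotations["chromosome"].isin(AUTOSOMES)
    n_unknown = int((annotations["chromosome"] == "unknown").sum())
    if n_unknown:
        logger.info("%d marker(s) with unrecognised chromosome excluded", n_unknown)
    return set(annotations.loc[on_auto, "marker_id"])


# ---------------------------------------------------------------------------
# writers (round-trip partners of the parsers)

_FLOAT_FMT = "%.10g"


def _write(frame: pd.DataFrame, path: str | Path | IO[str]) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def write_intensity_table(
    frame: pd.DataFrame, path: str | Path | IO[str], dialect: IntensityDialect = IntensityDialect()
) -> None:
    d = dialect
    out = frame.rename(
        columns={
            "marker_id": d.marker,
            "sample_id": d.sample,
            "signal_a": d.signal_a,
            "signal_b": d.signal_b,
        }
    )[[d.marker, d.sample, d.signal_a, d.signal_b]]
    _write(out, path)


def write_genotype_table(
    frame: pd.DataFrame, path: str | Path | IO[str], dialect: GenotypeDialect = GenotypeDialect()
) -> None:
    d = dialect
    # write the canonical NoCall back as the dialect's first alias for it
    reverse = {"NoCall": "NC", "AA": "AA", "AB": "AB", "BB": "BB"}
    for raw_code, canonical in d.call_map.items():
        if canonical == "NoCall":
            reverse["NoCall"] = raw_code
            break
    out = pd.DataFrame(
        {
            d.marker: frame["marker_id"],
            d.sample: frame["sample_id"],
            d.call: frame["call"].map(reverse),
        }
    )
    _write(out, path)


def write_annotation_table(
    frame: pd.DataFrame, path: str | Path | IO[str], dialect: AnnotationDialect = AnnotationDialect()
) -> None:
    d = dialect
    out = pd.DataFrame(
        {
            d.marker: frame["marker_id"],
            d.chromosome: frame["chromosome"],
            d.position: frame["position"],
        }
    )
    _write(out, path)


def write_design_table(
    design: PoolDesign, path: str | Path | IO[str], dialect: DesignDialect = DesignDialect()
) -> None:
    d = dialect
    frame = design.to_frame().rename(
        columns={"replicate_id": d.replicate, "pool_id": d.pool, "group": d.group}
    )
    _write(frame, path)
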