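"""Reading and writing fragment-analysis peak tables and sample sheets.

The pipeline starts from the tab-delimited "genotypes table" export of
capillary-electrophoresis software: one row per sample x marker with the
amplicon size (bp), peak height (RFU) and peak area.  A :class:`MarkerPanel`
declares which markers target the transgene construct and which single-copy
native gene serves as the internal amplification control.

A missing row and a zero-height row both mean "no product detected" and are
represented identically as absent (NaN) in trait matrices; capillary software
simply omits undetected peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, ValidationError

logger = logging.getLogger(__name__)

#: Traits measured for every PCR product peak.
TRAITS = ("height", "area", "size")

#: Recognised sample generations; anything else maps to "other".
GENERATIONS = ("parent", "F1", "BC1S1", "BC1S2", "other")

_PEAK_COLUMNS = {
    "sample": "sample_id",
    "marker": "marker",
    "size": "size_bp",
    "height": "height",
    "area": "area",
}

_SHEET_COLUMNS = {
    "sample": "sample_id",
    "population": "population_id",
    "generation": "generation",
    "family": "family_id",
    "parentprediction": "parent_prediction",
}


@dataclass(frozen=True)
class MarkerPanel:
    """Declared marker set: transgene targets plus the single-copy reference.

    The default panel targets three conserved T-DNA elements (35S promoter,
    OCS terminator, NPTII selectable marker) and normalizes against the
    single-copy cotton gene GhUBC1.
    """

    transgene_markers: tuple[str, ...] = ("35S_S", "OCS_S", "NPTII-3")
    reference_marker: str = "GhUBC1"
    expected_size_bp: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.transgene_markers:
            raise ValidationError("panel needs at least one transgene marker")
        names = (*self.transgene_markers, self.reference_marker)
        if len(set(names)) != len(names):
            raise ValidationError("marker names must be unique and the "
                                  "reference must not be a transgene marker")
        for m, s in dict(self.expected_size_bp).items():
            if m not in names:
                raise ValidationError(f"expected size given for unknown marker {m!r}")
            if not s > 0:
                raise ValidationError(f"expected size for {m!r} must be positive")
        object.__setattr__(self, "transgene_markers", tuple(self.transgene_markers))

    @property
    def all_markers(self) -> tuple[str, ...]:
        return (*self.transgene_markers, self.reference_marker)


DEFAULT_PANEL = MarkerPanel()


@dataclass
class PeakTable:
    """Collection of peak records over a marker panel.

    ``records`` has columns sample_id, marker, size_bp, height, area with at
    most one row per (sample_id, marker).
    """

    records: pd.DataFrame
    panel: MarkerPanel

    @property
    def samples(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    def __len__(self) -> int:
        return len(self.records)


def _normalise_header(df: pd.DataFrame, mapping: Mapping[str, str],
                      required: tuple[str, ...]) -> pd.DataFrame:
    renames = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in mapping:
            renames[col] = mapping[key]
    df = df.rename(columns=renames)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    return df


def read_peak_table(source: str | IO[str], panel: MarkerPanel = DEFAULT_PANEL) -> PeakTable:
    """Read a tab-delimited peak table (Sample, Marker, Size, Height, Area).

    Rows for markers outside the panel are skipped with a logged warning.
    Duplicate (sample, marker) rows raise :class:`IntegrityError`.
    """
    try:
        df = pd.read_csv(source, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:  # pragma: no cover - delegated parsing
        raise FormatError(f"could not parse peak table: {exc}") from exc
    df = _normalise_header(df, _PEAK_COLUMNS,
                           ("sample_id", "marker", "size_bp", "height", "area"))
    df = df[["sample_id", "marker", "size_bp", "height", "area"]].copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["marker"] = df["marker"].astype(str)
    for col in ("size_bp", "height", "area"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-numeric value in column {col!r}: {exc}") from exc

    known = set(panel.all_markers)
    foreign = df.loc[~df["marker"].isin(known), "marker"].unique()
    if len(foreign):
        logger.warning("skipping %d record(s) for marker(s) outside the panel: %s",
                       (~df["marker"].isin(known)).sum(), ", ".join(sorted(foreign)))
        df = df[df["marker"].isin(known)].reset_index(drop=True)

    if (df["height"] < 0).any() or (df["area"] < 0).any():
        raise ValidationError("negative peak height or area")
    bad_size = (df["height"] > 0) & ~(df["size_bp"] > 0)
    if bad_size.any():
        raise ValidationError("size_bp must be positive for detected peaks")

    dup = df.duplicated(subset=["sample_id", "marker"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["sample_id", "marker"]].drop_duplicates()
        listing = "; ".join(f"({r.sample_id}, {r.marker})" for r in pairs.itertuples())
        raise IntegrityError(f"duplicate (sample, marker) rows: {listing}")

    return PeakTable(records=df.reset_index(drop=True), panel=panel)


def write_peak_table(table: PeakTable, dest: str | IO[str]) -> None:
    """Write a peak table in the same TSV dialect accepted by :func:`read_peak_table`."""
    out = table.records.rename(columns={
        "sample_id": "Sample", "marker": "Marker", "size_bp": "Size",
        "height": "Height", "area": "Area"})
    out.to_csv(dest, sep="\t", index=False)


def read_sample_sheet(source: str | IO[str]) -> pd.DataFrame:
    """Read a sample sheet (Sample, Population, Generation[, Family, ParentPrediction]).

    Unknown generation labels map to ``"other"`` with a logged warning.
    Returns a DataFrame with columns sample_id, population_id, generation,
    family_id, parent_prediction (missing optional values are empty strings).
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    df = _normalise_header(df, _SHEET_COLUMNS,
                           ("sample_id", "population_id", "generation"))
    for opt in ("family_id", "parent_prediction"):
        if opt not in df.columns:
            df[opt] = ""
    df = df[["sample_id", "population_id", "generation", "family_id",
             "parent_prediction"]].fillna("")
    df["sample_id"] = df["sample_id"].astype(str)

    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
        raise IntegrityError(f"duplicate sample id(s): {', '.join(dups)}")

    canon = {g.lower(): g for g in GENERATIONS}
    gen = df["generation"].str.strip().str.lower().map(canon)
    unknown = df.loc[gen.isna(), "generation"].unique()
    if len(unknown):
        logger.warning("unknown generation label(s) mapped to 'other': %s",
                       ", ".join(sorted(map(str, unknown))))
    df["generation"] = gen.fillna("other")

    bad_pred = ~df["parent_prediction"].isin(["", "homozygous", "hemizygous"])
    if bad_pred.any():
        raise ValidationError("parent_prediction must be 'homozygous', "
                              "'hemizygous' or empty")
    no_family = (df["generation"] == "BC1S2") & (df["family_id"] == "")
    if no_family.any():
        missing = sorted(df.loc[no_family, "sample_id"])
        raise ValidationError(
            f"BC1S2 samples require a family id: {', '.join(missing[:5])}")
    return df.reset_index(drop=True)


def build_trait_matrix(table: PeakTable, trait: str) -> pd.DataFrame:
    """Per-sample trait values over the panel, with absent markers as NaN.

    A marker is absent for a sample when it has no record or a zero-height
    record.  Columns follow panel order; every sample appearing in the table
    gets a row.
    """
    if trait not in TRAITS:
        raise ValidationError(f"unknown trait {trait!r}; expected one of {TRAITS}")
    col = {"height": "height", "area": "area", "size": "size_bp"}[trait]
    rec = table.records.copy()
    # undetected peaks carry no trait value at all
    rec.loc[rec["height"] <= 0, ["height", "area", "size_bp"]] = np.nan
    matrix = rec.pivot(index="sample_id", columns="marker", values=col)
    matrix = matrix.reindex(columns=list(table.panel.all_markers))
    matrix.index.name = "sample_id"
    matrix.columns.name = "marker"
    return matrix.sort_index()


def write_calls(calls, dest: str | IO[str]) -> None:
    """Write a zygosity call set as a deterministic, sample-sorted TSV."""
    df = calls.calls if hasattr(calls, "calls") else calls
    if df is None or len(df) == 0:
        raise ValidationError("cannot write an empty call set")
    out = pd.DataFrame({
        "Sample": df["sample_id"],
        "Population": df["population_id"],
        "PresenceCall": df["presence"],
        "PitCall": df["pit_call"].fillna(""),
        "KMeansCall": df["kmeans_call"].fillna(""),
        "FinalCall": df["final_call"],
        "NormalizedHeight": df["normalized_height"],
        "NormalizedArea": df["normalized_area"],
    }).sort_values("Sample", kind="mergesort")
    out.to_csv(dest, sep="\t", index=False)


def read_calls(source: str | IO[str]) -> pd.DataFrame:
    """Read a calls TSV written by :func:`write_calls` back into a DataFrame."""
    df = pd.read_csv(source, sep="\t", dtype={"Sample": str, "Population": str},
                     keep_default_na=False,
                     na_values={"NormalizedHeight": [""], "NormalizedArea": [""]})
    df = df.rename(columns={
        "Sample": "sample_id", "Population": "population_id",
        "PresenceCall": "presence", "PitCall": "pit_call",
        "KMeansCall": "kmeans_call", "FinalCall": "final_call",
        "NormalizedHeight": "normalized_height", "NormalizedArea": "normalized_area"})
    for col in ("pit_call", "kmeans_call"):
        df[col] = df[col].replace("", np.nan)
    return df
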