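"""Reading, QC filtering and aggregation of per-cell feature tables.

The package works on CellProfiler-style tabular exports: one row per
segmented object (cell) with a few hundred numeric morphology features,
keyed by plate barcode, well, image (field) and object. This module reads
those tables into canonical column names, removes low-quality images by
saturation/focus thresholds, and collapses objects -> image medians ->
well medians. A plate map assigns each well a compound, concentration,
role (treatment / negative control / positive control), cell line and
replicate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, LayoutError

log = logging.getLogger("thetascreen")

# canonical identifier / metadata column names used throughout the package
PLATE = "plate"
WELL = "well"
IMAGE = "image_id"
OBJECT = "object_id"
QC_SATURATION = "qc_saturation"
QC_FOCUS = "qc_focus"

ID_COLUMNS = (PLATE, WELL, IMAGE, OBJECT)
QC_COLUMNS = (QC_SATURATION, QC_FOCUS)
LAYOUT_COLUMNS = ("compound", "conc", "role", "cell_line", "replicate")
ROLES = ("treatment", "negctrl", "posctrl")

#: columns that are never treated as morphological features
RESERVED_COLUMNS = frozenset(
    ID_COLUMNS + QC_COLUMNS + LAYOUT_COLUMNS + ("n_objects", "n_images")
)


def feature_columns(df: pd.DataFrame) -> list[str]:
    """Morphological feature columns of ``df`` in alphabetical order."""
    return sorted(c for c in df.columns if c not in RESERVED_COLUMNS)


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping from a source CSV to the canonical schema."""

    plate: str = PLATE
    well: str = WELL
    image: str = IMAGE
    object: str = OBJECT
    saturation: str | None = QC_SATURATION
    focus: str | None = QC_FOCUS

    def id_mapping(self) -> dict[str, str]:
        return {self.plate: PLATE, self.well: WELL, self.image: IMAGE, self.object: OBJECT}


DIALECTS: dict[str, Dialect] = {
    "generic": Dialect(),
    "cellprofiler": Dialect(
        plate="Metadata_Plate",
        well="Metadata_Well",
        image="ImageNumber",
        object="ObjectNumber",
        saturation="ImageQuality_PercentSaturation",
        focus="ImageQuality_FocusScore",
    ),
}


def get_dialect(name_or_dialect: str | Dialect) -> Dialect:
    if isinstance(name_or_dialect, Dialect):
        return name_or_dialect
    try:
        return DIALECTS[name_or_dialect]
    except KeyError:
        raise ConfigError(
            f"unknown dialect {name_or_dialect!r}; known: {sorted(DIALECTS)}"
        ) from None


def read_feature_table(path: str | Path, dialect: str | Dialect = "generic") -> pd.DataFrame:
    """Read a per-object feature CSV into the canonical schema.

    Identifier columns are renamed per the dialect; every remaining column
    is coerced to numeric (non-numeric cells become missing). Rows with a
    missing identifier are dropped and their count logged. Raises
    :class:`FormatError` if the file is empty, lacks an identifier column,
    or contains duplicated (plate, well, image, object) keys.
    """
    d = get_dialect(dialect)
    path = Path(path)
    try:
        df = pd.read_csv(path, engine="pyarrow")
    except (pd.errors.EmptyDataError, pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse feature table ({exc})") from exc
    if df.empty:
        raise FormatError(f"{path}: empty feature table")

    for src in (d.plate, d.well, d.image, d.object):
        if src not in df.columns:
            raise FormatError(f"{path}: missing identifier column {src!r}")
    rename = d.id_mapping()
    if d.saturation and d.saturation in df.columns:
        rename[d.saturation] = QC_SATURATION
    if d.focus and d.focus in df.columns:
        rename[d.focus] = QC_FOCUS
    df = df.rename(columns=rename)

    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise FormatError(f"{path}: duplicated column names {dups}")

    for col in df.columns:
        if col in (PLATE, WELL):
            df[col] = df[col].astype(str)
        else:
            df[col] = pd.to_numeric(df[col], errors="coerce")

    bad_keys = df[list(ID_COLUMNS)].isna().any(axis=1)
    if bad_keys.any():
        log.warning("%s: dropped %d rows with missing identifiers", path, int(bad_keys.sum()))
        df = df.loc[~bad_keys]
    df.attrs["n_rejected"] = int(bad_keys.sum())

    if df.duplicated(subset=list(ID_COLUMNS)).any():
        raise FormatError(f"{path}: duplicated (plate, well, image, object) keys")
    return df.reset_index(drop=True)


def read_plate_map(path: str | Path) -> pd.DataFrame:
    """Read a plate map CSV (plate, well, compound, conc, role, cell_line, replicate)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty plate map") from exc
    needed = (PLATE, WELL) + LAYOUT_COLUMNS
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: plate map missing columns {missing}")
    df[PLATE] = df[PLATE].astype(str)
    df[WELL] = df[WELL].astype(str)
    validate_layout(df)
    return df


def validate_layout(layout: pd.DataFrame) -> None:
    bad_roles = set(layout["role"].unique()) - set(ROLES)
    if bad_roles:
        raise LayoutError(f"unknown roles {sorted(bad_roles)}; expected {ROLES}")
    if layout.duplicated(subset=[PLATE, WELL]).any():
        raise LayoutError("plate map assigns some (plate, well) more than once")
    counts = layout.groupby(PLATE)["role"].value_counts().unstack(fill_value=0)
    for role in ("negctrl", "posctrl"):
        n = counts[role] if role in counts else pd.Series(0, index=counts.index)
        low = n[n < 2]
        if len(low):
            raise LayoutError(
                f"plates with fewer than 2 {role} wells: {sorted(low.index)}"
            )


@dataclass
class QCThresholds:
    """Image-level QC cutoffs.

    ``sat_max`` removes images with saturated-pixel fraction above the cutoff.
    ``focus_min`` removes images whose focus score (higher = sharper) falls
    below it; when None the cutoff is self-calibrated per plate as the 1st
    percentile of negative-control image focus scores (requires a layout).
    """

    sat_max: float = 0.2
    focus_min: float | None = None


@dataclass
class QCReport:
    removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=[PLATE, WELL, IMAGE, "reason"])
    )
    focus_cutoffs: dict[str, float] = field(default_factory=dict)

    @property
    def n_removed_images(self) -> int:
        return len(self.removed)


def qc_filter_images(
    table: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    layout: pd.DataFrame | None = None,
    enabled: bool = True,
) -> tuple[pd.DataFrame, QCReport]:
    """Drop all objects from images failing saturation/focus QC.

    Returns the filtered table plus a report listing removed image ids with
    a reason ("saturation" or "focus"). With ``enabled=False`` the table
    passes through untouched. Raises :class:`ConfigError` if QC is enabled
    but the QC metric columns are absent.
    """
    if not enabled:
        return table, QCReport()
    thresholds = thresholds or QCThresholds()
    for col in QC_COLUMNS:
        if col not in table.columns:
            raise ConfigError(
                f"QC enabled but column {col!r} missing; pass enabled=False to skip QC"
            )

    images = (
        table[[PLATE, WELL, IMAGE, QC_SATURATION, QC_FOCUS]]
        .drop_duplicates(subset=[PLATE, WELL, IMAGE])
        .sort_values([PLATE, WELL, IMAGE], kind="stable")
        .reset_index(drop=True)
    )

    sat_fail = images[QC_SATURATION] > thresholds.sat_max

    focus_cutoffs: dict[str, float] = {}
    if thresholds.focus_min is not None:
        focus_fail = images[QC_FOCUS] < thresholds.focus_min
        focus_cutoffs = {p: float(thresholds.focus_min) for p in images[PLATE].unique()}
    elif layout is not None:
        neg = layout.loc[layout["role"] == "negctrl", [PLATE, WELL]]
        neg_images = images.merge(neg, on=[PLATE, WELL])
        cut = neg_images.groupby(PLATE)[QC_FOCUS].quantile(0.01)
        focus_cutoffs = {str(k): float(v) for k, v in cut.items()}
        per_image_cut = images[PLATE].map(cut)
        focus_fail = images[QC_FOCUS] < per_image_cut.fillna(-np.inf)
    else:
        # no explicit cutoff and no layout to calibrate one from
        focus_fail = pd.Series(False, index=images.index)

    removed = images.loc[sat_fail | focus_fail, [PLATE, WELL, IMAGE]].copy()
    removed["reason"] = np.where(sat_fail[sat_fail | focus_fail], "saturation", "focus")
    report = QCReport(removed=removed.reset_index(drop=True), focus_cutoffs=focus_cutoffs)

    if len(removed):
        key = pd.MultiIndex.from_frame(table[[PLATE, WELL, IMAGE]])
        bad = pd.MultiIndex.from_frame(removed[[PLATE, WELL, IMAGE]])
        table = table.loc[~key.isin(bad)].reset_index(drop=True)
    return table, report


def aggregate_to_image_median(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse objects to one row per image: per-feature median + n_objects.

    Missing values are ignored within each median; a feature that is missing
    for every object of an image stays missing (logged as a warning).
    """
    feats = feature_columns(table)
    grouped = table.groupby([PLATE, WELL, IMAGE], sort=True)
    out = grouped[feats].median()
    out["n_objects"] = grouped.size()
    n_allnan = int(out[feats].isna().any(axis=None) and out[feats].isna().sum().sum())
    if n_allnan:
        log.warning("image aggregation: %d image-level feature values are all-missing", n_allnan)
    return out.reset_index()


def aggregate_to_well(image_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse image medians to one row per well (median of image medians)."""
    feats = feature_columns(image_table)
    grouped = image_table.groupby([PLATE, WELL], sort=True)
    out = grouped[feats].median()
    out["n_images"] = grouped.size()
    return out.reset_index()


def join_layout(profiles: pd.DataFrame, layout: pd.DataFrame) -> pd.DataFrame:
    """Annotate profile rows with compound/role/cell-line metadata.

    The join must be total: any profile well absent from the layout raises
    :class:`LayoutError`.
    """
    merged = profiles.merge(
        layout[[PLATE, WELL] + list(LAYOUT_COLUMNS)], on=[PLATE, WELL], how="left"
    )
    orphan = merged["role"].isna()
    if orphan.any():
        missing = merged.loc[orphan, [PLATE, WELL]].drop_duplicates()
        raise LayoutError(
            f"{len(missing)} wells in the feature data have no plate-map entry, "
            f"e.g. {missing.iloc[0].tolist()}"
        )
    return merged
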