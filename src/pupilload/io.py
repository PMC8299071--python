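"""Readers and writers for the delimited-text formats the pipeline touches.

Samples and segments arrive as comma- or tab-separated text (delimiter is
sniffed from the header line); vendor column names are mapped onto the
canonical schema through a :class:`Dialect`.  All timestamps are normalised
to seconds internally.  Writers emit a fixed column order with fixed decimal
formatting so outputs are deterministic and round-trip through the readers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError, FormatError
from .model import (LABELS, SAMPLE_COLUMNS, SEGMENT_COLUMNS, Segment)

logger = logging.getLogger(__name__)

_TIME_SCALE = {"s": 1.0, "ms": 1e-3, "us": 1e-6}

#: Physiological pupil-diameter bounds in mm; values outside are marked invalid.
PUPIL_MIN_MM = 0.5
PUPIL_MAX_MM = 10.0

# Fixed decimal formatting (declared output precision per column).
_SAMPLE_FORMATS = {"t": "%.6f", "pupil_left": "%.4f", "pupil_right": "%.4f",
                   "gaze_x": "%.2f", "gaze_y": "%.2f"}
_SEGMENT_FORMATS = {"t_start": "%.6f", "t_end": "%.6f"}
_INDICATOR_FORMATS = {"value": "%.6f"}
_COMPARISON_FORMATS = {"t_stat": "%.4f", "bf10": "%.6g", "es_mean": "%.4f",
                       "es_lo": "%.4f", "es_hi": "%.4f"}

INDICATOR_COLUMNS = ("participant_id", "label", "segment_id", "channel",
                     "standardized", "value")
AGGREGATE_COLUMNS = ("participant_id", "label", "channel", "standardized",
                     "value", "n_segments")
COMPARISON_COLUMNS = ("pair_a", "pair_b", "channel", "standardized",
                      "direction", "n", "t_stat", "bf10", "es_mean",
                      "es_lo", "es_hi", "evidence")


@dataclass(frozen=True)
class Dialect:
    """Column-name map and unit declaration for a vendor export.

    ``columns`` maps canonical names (see :data:`~pupilload.model.SAMPLE_COLUMNS`)
    to the names used in the file.  ``time_unit`` declares the unit of the
    timestamp column; pupil diameters are always millimetres (no unit
    auto-detection — silent guessing corrupts thresholds downstream).
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    time_unit: str = "s"
    delimiter: str | None = None

    def __post_init__(self) -> None:
        if self.time_unit not in _TIME_SCALE:
            raise ValueError(f"time_unit must be one of {sorted(_TIME_SCALE)}")

    def file_column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


DEFAULT_DIALECT = Dialect()


def _sniff_delimiter(path, dialect: Dialect) -> str:
    if dialect.delimiter is not None:
        return dialect.delimiter
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _require_columns(df: pd.DataFrame, canonical: Iterable[str],
                     dialect: Dialect, path) -> None:
    for name in canonical:
        col = dialect.file_column(name)
        if col not in df.columns:
            raise FormatError(
                f"{path}: missing required column '{col}' (for '{name}')")


def read_samples(path, dialect: Dialect = DEFAULT_DIALECT,
                 pupil_min_mm: float = PUPIL_MIN_MM,
                 pupil_max_mm: float = PUPIL_MAX_MM) -> pd.DataFrame:
    """Read a binocular samples file into the canonical frame.

    Samples are returned sorted by time within participant (stable, so file
    order is preserved among ties).  An eye's sample is usable iff its
    validity flag is set *and* the diameter is finite and inside the
    physiological bounds; out-of-range diameters are flagged invalid, never
    dropped.  Timestamps must be non-decreasing per participant in file
    order; a decrease raises :class:`DataError` naming the first offending
    data row (0-based).
    """
    sep = _sniff_delimiter(path, dialect)
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, SAMPLE_COLUMNS, dialect, path)
    rename = {dialect.file_column(c): c for c in SAMPLE_COLUMNS}
    extra = [c for c in df.columns if c not in rename]
    if extra:
        logger.info("read_samples(%s): ignoring extra columns %s", path, extra)
    df = df.rename(columns=rename)[list(SAMPLE_COLUMNS)]

    df["t"] = pd.to_numeric(df["t"], errors="raise").astype(float) \
        * _TIME_SCALE[dialect.time_unit]
    for c in ("pupil_left", "pupil_right", "gaze_x", "gaze_y"):
        df[c] = pd.to_numeric(df[c], errors="raise").astype(float)
    df["participant_id"] = df["participant_id"].astype(str)

    # monotone-timestamp check per participant, in file order
    for pid, grp in df.groupby("participant_id", sort=False):
        t = grp["t"].to_numpy()
        bad = np.nonzero(np.diff(t) < 0)[0]
        if bad.size:
            row = int(grp.index[bad[0] + 1])
            raise DataError(
                f"{path}: non-monotone timestamps for participant {pid} "
                f"at data row {row}")

    for eye in ("left", "right"):
        d = df[f"pupil_{eye}"].to_numpy()
        flag = df[f"valid_{eye}"].astype(bool).to_numpy()
        usable = flag & np.isfinite(d) & (d > pupil_min_mm) & (d < pupil_max_mm)
        df[f"valid_{eye}"] = usable

    # stable sort by t within participant, participants in order of appearance
    order = {pid: i for i, pid in enumerate(
        df["participant_id"].drop_duplicates())}
    df = df.assign(_p=df["participant_id"].map(order)) \
        .sort_values(["_p", "t"], kind="mergesort") \
        .drop(columns="_p").reset_index(drop=True)
    return df


def read_segments(path, dialect: Dialect = DEFAULT_DIALECT) -> pd.DataFrame:
    """Read a segment table; validates labels and rejects overlapping spans."""
    sep = _sniff_delimiter(path, dialect)
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, SEGMENT_COLUMNS, dialect, path)
    rename = {dialect.file_column(c): c for c in SEGMENT_COLUMNS}
    df = df.rename(columns=rename)[list(SEGMENT_COLUMNS)]
    for c in ("participant_id", "segment_id", "label", "item_type"):
        df[c] = df[c].astype(str)
    df["response_correct"] = pd.to_numeric(df["response_correct"],
                                           errors="coerce").astype(float)
    for c in ("t_start", "t_end"):
        df[c] = pd.to_numeric(df[c], errors="raise").astype(float)

    unknown = sorted(set(df["label"]) - set(LABELS))
    if unknown:
        raise FormatError(f"{path}: unknown segment label(s) {unknown}")

    df = _sort_segments(df)
    _check_overlap(df, path)
    return df.reset_index(drop=True)


def _sort_segments(df: pd.DataFrame) -> pd.DataFrame:
    order = {pid: i for i, pid in enumerate(
        df["participant_id"].drop_duplicates())}
    return df.assign(_p=df["participant_id"].map(order)) \
        .sort_values(["_p", "t_start"], kind="mergesort").drop(columns="_p")


def _check_overlap(df: pd.DataFrame, path) -> None:
    for pid, grp in df.groupby("participant_id", sort=False):
        t0 = grp["t_start"].to_numpy()
        t1 = grp["t_end"].to_numpy()
        sid = grp["segment_id"].to_numpy()
        bad = np.nonzero(t0[1:] < t1[:-1] - 1e-12)[0]
        if bad.size:
            i = bad[0]
            raise DataError(
                f"{path}: overlapping segments for participant {pid}: "
                f"'{sid[i]}' ([{t0[i]:g}, {t1[i]:g})) and "
                f"'{sid[i + 1]}' ([{t0[i + 1]:g}, {t1[i + 1]:g}))")


def iter_segments(segments: pd.DataFrame):
    """Yield :class:`~pupilload.model.Segment` objects from a segment frame."""
    for row in segments.itertuples(index=False):
        yield Segment(participant_id=row.participant_id,
                      segment_id=row.segment_id, label=row.label,
                      item_type=row.item_type,
                      response_correct=float(row.response_correct)
                      if row.response_correct == row.response_correct
                      else float("nan"),
                      t_start=float(row.t_start), t_end=float(row.t_end))


# -- writers ---------------------------------------------------------------

def _write_frame(df: pd.DataFrame, path, columns, formats: Mapping[str, str],
                 what: str) -> None:
    if len(df) == 0:
        warnings.warn(f"writing empty {what} table to {path} (header only)")
        out = pd.DataFrame(columns=list(columns))
    else:
        out = df.loc[:, list(columns)].copy()
        for col, fmt in formats.items():
            vals = out[col].astype(float)
            out[col] = [fmt % v if np.isfinite(v) else "nan" for v in vals]
        for col in out.columns:
            if out[col].dtype == bool:
                out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def write_samples(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for c in ("valid_left", "valid_right"):
        out[c] = out[c].astype(bool).astype(int)
    _write_frame(out, path, SAMPLE_COLUMNS, _SAMPLE_FORMATS, "samples")


def write_segments(df: pd.DataFrame, path) -> None:
    _write_frame(df, path, SEGMENT_COLUMNS, _SEGMENT_FORMATS, "segments")


def write_indicators(df: pd.DataFrame, path) -> None:
    """Write indicator records; raw and z-standardized rows share one table."""
    _write_frame(df, path, INDICATOR_COLUMNS, _INDICATOR_FORMATS, "indicator")


def read_indicators(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["standardized"] = df["standardized"].astype(bool)
    return df


def write_aggregates(df: pd.DataFrame, path) -> None:
    _write_frame(df, path, AGGREGATE_COLUMNS, _INDICATOR_FORMATS, "aggregate")


def read_aggregates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["standardized"] = df["standardized"].astype(bool)
    return df


def write_comparisons(df: pd.DataFrame, path) -> None:
    _write_frame(df, path, COMPARISON_COLUMNS, _COMPARISON_FORMATS,
                 "comparison")


def read_comparisons(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if len(df):
        df["standardized"] = df["standardized"].astype(bool)
    return df
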