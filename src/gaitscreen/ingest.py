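"""Readers for per-timepoint gait exports and the master lookup table.

CatWalk XT exports one wide table per acquisition session: one row per
animal (or per run), one column per gait variable.  Blinding practice keeps
group identity out of those exports, so a separate "master lookup table"
maps each animal id to its group/genotype/treatment metadata.  This module
reads both, joins them, combines timepoints into one long dataset and
eliminates variables that carry no usable signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import ID_COL, TIME_COL, VALUE_COL, VAR_COL, StudyDataset
from .errors import DegenerateDataError, FormatError, IntegrityError

#: Strings treated as missing values in exports, on top of genuine blanks.
DEFAULT_SENTINELS = ("", "-", "NaN", "NA")


@dataclass
class GaitTable:
    """Wide per-animal measurements for a single timepoint."""

    data: pd.DataFrame  # animal_id column + one numeric column per variable
    timepoint: str

    @property
    def variables(self) -> list[str]:
        return [c for c in self.data.columns if c != ID_COL]

    @property
    def animals(self) -> list[str]:
        return list(self.data[ID_COL])


@dataclass
class LookupTable:
    """Master table mapping each animal id to its metadata."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if ID_COL not in self.data.columns:
            raise FormatError(f"lookup table must have an '{ID_COL}' column")
        if self.data[ID_COL].isna().any():
            raise IntegrityError("lookup table contains missing animal ids")
        if self.data[ID_COL].duplicated().any():
            dupes = self.data.loc[self.data[ID_COL].duplicated(), ID_COL].tolist()
            raise IntegrityError(f"duplicate animal ids in lookup table: {dupes}")
        self.data = self.data.assign(**{ID_COL: self.data[ID_COL].astype(str)})

    @property
    def metadata_cols(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c != ID_COL)


def _read_table(path: str | Path, sheet: str | int | None = None) -> pd.DataFrame:
    """Read a delimited text file (separator autodetected) or a spreadsheet."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path, sheet_name=sheet or 0, dtype=object)
    # sep=None triggers csv.Sniffer-based comma/tab autodetection
    return pd.read_csv(path, sep=None, engine="python", dtype=object,
                       skipinitialspace=True)


def _find_id_column(df: pd.DataFrame) -> str:
    candidates = [c for c in df.columns
                  if str(c).strip().lower() in {"animal_id", "animal", "id", "subject"}]
    if not candidates:
        raise FormatError(
            f"no animal-id column found (looked for animal_id/animal/id/subject "
            f"among {list(df.columns)})"
        )
    return candidates[0]


def read_gait_export(
    path: str | Path,
    timepoint_label: str,
    sentinels: Sequence[str] = DEFAULT_SENTINELS,
    sheet: str | int | None = None,
) -> GaitTable:
    """Read one CatWalk-style export and tag it with its timepoint.

    Blank cells and sentinel strings become missing values; every other cell
    must parse as a number.  Variable-name whitespace is trimmed (internal
    spaces are preserved — names later feed tag fragmentation).  Column order
    is preserved.
    """
    df = _read_table(path, sheet=sheet)
    id_col = _find_id_column(df)
    df = df.rename(columns={id_col: ID_COL})
    df.columns = [ID_COL if c == ID_COL else str(c).strip() for c in df.columns]
    df[ID_COL] = df[ID_COL].astype(str).str.strip()
    if df[ID_COL].duplicated().any():
        dupes = sorted(df.loc[df[ID_COL].duplicated(), ID_COL].unique())
        raise IntegrityError(
            f"duplicate animal ids in {path} (use average_runs on run-level "
            f"exports first): {dupes}"
        )
    var_cols = [c for c in df.columns if c != ID_COL]
    sentinel_set = {s.strip() for s in sentinels}
    for c in var_cols:
        col = df[c].astype(object)
        col = col.where(~col.astype(str).str.strip().isin(sentinel_set), other=np.nan)
        try:
            df[c] = pd.to_numeric(col)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-numeric value in column {c!r} of {path}: {exc}")
    return GaitTable(df[[ID_COL, *var_cols]], str(timepoint_label))


def read_lookup(path: str | Path) -> LookupTable:
    """Read the master lookup table from delimited text."""
    df = _read_table(path)
    id_col = _find_id_column(df)
    df = df.rename(columns={id_col: ID_COL})
    df.columns = [str(c).strip() for c in df.columns]
    df[ID_COL] = df[ID_COL].astype(str).str.strip()
    return LookupTable(df)


def average_runs(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse multiple runs per animal to one row of per-animal means.

    CatWalk typically records several crossings per session; the screening
    models expect one observation per animal per timepoint, so runs are
    averaged (missing run values ignored) before analysis.
    """
    if ID_COL not in df.columns:
        raise FormatError(f"run table must have an '{ID_COL}' column")
    return df.groupby(ID_COL, as_index=False, sort=False).mean(numeric_only=True)


def join_metadata(
    tables: Iterable[GaitTable],
    lookup: LookupTable,
    strict: bool = True,
) -> StudyDataset:
    """Combine per-timepoint tables into one long dataset with metadata.

    Every animal id must appear in the lookup table; under ``strict=False``
    unmatched animals are dropped with a logged warning instead.  Animals
    absent at some timepoints are allowed.
    """
    tables = list(tables)
    if not tables:
        raise DegenerateDataError("no gait tables supplied")
    timepoints = []
    for t in tables:
        if t.timepoint not in timepoints:
            timepoints.append(t.timepoint)
    known = set(lookup.data[ID_COL])
    log: list[dict] = []
    long_parts = []
    for t in tables:
        unmatched = sorted(set(t.data[ID_COL]) - known)
        data = t.data
        if unmatched:
            if strict:
                raise IntegrityError(
                    f"animals at timepoint {t.timepoint!r} missing from lookup "
                    f"table: {unmatched}"
                )
            log.append({"action": "drop_unmatched_animals",
                        "detail": f"timepoint {t.timepoint}: {unmatched}"})
            data = data[~data[ID_COL].isin(unmatched)]
        melted = data.melt(id_vars=[ID_COL], var_name=VAR_COL, value_name=VALUE_COL)
        melted.insert(1, TIME_COL, t.timepoint)
        long_parts.append(melted)
    rec = pd.concat(long_parts, ignore_index=True)
    rec = rec.merge(lookup.data, on=ID_COL, how="left")
    cols = [ID_COL, TIME_COL, *lookup.metadata_cols, VAR_COL, VALUE_COL]
    ds = StudyDataset(rec[cols], tuple(timepoints), lookup.metadata_cols)
    ds.log.extend(log)
    return ds


def drop_unusable_variables(ds: StudyDataset) -> StudyDataset:
    """Remove variables with all-missing or all-zero values, with a log.

    The rule is evaluated over the combined dataset (all timepoints pooled):
    a variable observed at any timepoint with any nonzero value survives.
    """
    if ds.records.empty:
        raise DegenerateDataError("empty dataset")
    vals = ds.records.groupby(VAR_COL, sort=False)[VALUE_COL]
    n_obs = vals.count()
    n_nonzero = vals.apply(lambda s: int((s.dropna() != 0).sum()))
    all_missing = n_obs == 0
    all_zero = (~all_missing) & (n_nonzero == 0)
    dropped = n_obs.index[all_missing | all_zero]
    if len(dropped) == len(n_obs):
        raise DegenerateDataError("every variable is all-missing or all-zero")
    out = ds.subset_variables(set(n_obs.index) - set(dropped))
    for v in dropped:
        reason = "all values missing" if all_missing[v] else "all non-missing values zero"
        out.log_event("drop_variable", reason, variable=v)
    return out
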