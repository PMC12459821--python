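"""Long-format study container shared by every pipeline stage.

A :class:`StudyDataset` holds one record per (animal, timepoint, variable)
triple together with the animal-level metadata joined from the master lookup
table, the declared ordered timepoint list, and a provenance log of every
variable or subject dropped along the way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import IntegrityError

#: Fixed leading columns of the long format; metadata columns sit between
#: ``timepoint`` and ``variable`` when written to disk.
ID_COL = "animal_id"
TIME_COL = "timepoint"
VAR_COL = "variable"
VALUE_COL = "value"


@dataclass
class StudyDataset:
    """Combined, metadata-annotated longitudinal gait dataset.

    Parameters
    ----------
    records
        Long-format frame with columns ``animal_id``, ``timepoint``,
        metadata columns, ``variable``, ``value``.
    timepoints
        Ordered study timepoints (chronological); the first is typically the
        pre-injury baseline.
    metadata_cols
        Names of the lookup-table metadata columns carried on each record.
    baseline
        Baseline timepoint label, set once normalization has been configured.
    log
        Provenance log: one entry per dropped variable / excluded subject /
        imputation, each a dict with at least ``action`` and ``detail``.
    """

    records: pd.DataFrame
    timepoints: tuple[str, ...]
    metadata_cols: tuple[str, ...] = ()
    baseline: str | None = None
    log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timepoints = tuple(str(t) for t in self.timepoints)
        self.metadata_cols = tuple(self.metadata_cols)
        required = [ID_COL, TIME_COL, *self.metadata_cols, VAR_COL, VALUE_COL]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise IntegrityError(f"records missing columns: {missing}")
        self.records = self.records.loc[:, required].reset_index(drop=True)
        dupes = self.records.duplicated([ID_COL, TIME_COL, VAR_COL])
        if dupes.any():
            bad = self.records.loc[dupes, [ID_COL, TIME_COL, VAR_COL]].head()
            raise IntegrityError(
                f"duplicate (animal, timepoint, variable) records, e.g.\n{bad}"
            )
        unknown = set(self.records[TIME_COL].astype(str)) - set(self.timepoints)
        if unknown:
            raise IntegrityError(f"records at undeclared timepoints: {sorted(unknown)}")

    # ------------------------------------------------------------------ views
    @property
    def variables(self) -> list[str]:
        """Variable names in first-appearance order."""
        return list(pd.unique(self.records[VAR_COL]))

    @property
    def animals(self) -> list[str]:
        return list(pd.unique(self.records[ID_COL]))

    def to_wide(self) -> pd.DataFrame:
        """One row per (animal, timepoint), one column per variable.

        Metadata columns are carried along; row order follows timepoint
        order then animal id, column order follows variable order.
        """
        idx_cols = [ID_COL, TIME_COL]
        pivoted = (
            self.records.pivot(index=idx_cols, columns=VAR_COL, values=VALUE_COL)
            .reindex(columns=self.variables)
            .reset_index()
        )
        pivoted.columns.name = None
        meta = self.records[[*idx_cols, *self.metadata_cols]].drop_duplicates(idx_cols)
        wide = meta.merge(pivoted, on=idx_cols)
        order = {t: i for i, t in enumerate(self.timepoints)}
        wide = wide.sort_values(
            [TIME_COL, ID_COL], key=lambda s: s.map(order) if s.name == TIME_COL else s
        )
        return wide.reset_index(drop=True)

    def subset_variables(self, keep: Iterable[str]) -> "StudyDataset":
        keep = set(keep)
        rec = self.records[self.records[VAR_COL].isin(keep)].reset_index(drop=True)
        return StudyDataset(rec, self.timepoints, self.metadata_cols,
                            self.baseline, list(self.log))

    def log_event(self, action: str, detail: str, **extra) -> None:
        self.log.append({"action": action, "detail": detail, **extra})

    # ------------------------------------------------------------------- I/O
    def write(self, path: str | Path) -> None:
        """Write the long format as delimited text (tab-separated)."""
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(
        cls,
        path: str | Path,
        timepoints: Sequence[str],
        metadata_cols: Sequence[str] = (),
        baseline: str | None = None,
    ) -> "StudyDataset":
        rec = pd.read_csv(path, sep="\t", dtype={ID_COL: str, TIME_COL: str, VAR_COL: str})
        return cls(rec, tuple(timepoints), tuple(metadata_cols), baseline)
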