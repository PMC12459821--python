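"""End-to-end orchestration: ingest → clean → normalize → screen.

`run_pipeline` wires the stage modules together the way the analyses in
this package's two worked case studies use them; each stage remains
individually importable for bespoke workflows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .dataset import StudyDataset
from .ingest import (GaitTable, LookupTable, drop_unusable_variables,
                     join_metadata, read_gait_export, read_lookup)
from .normalize import NormalizationPolicy, normalize_to_baseline
from .screen import ModelSpec, ScreenResult, screen


@dataclass
class PipelineResult:
    raw: StudyDataset
    normalized: StudyDataset | None
    result: ScreenResult

    def hit_counts(self) -> dict[str, int]:
        return self.result.hit_counts()


def ingest(data: Sequence[tuple[str | Path, str]], lookup: str | Path,
           strict: bool = True) -> StudyDataset:
    """Read (path, timepoint) exports plus the lookup table and combine."""
    tables = [read_gait_export(p, tp) for p, tp in data]
    ds = join_metadata(tables, read_lookup(lookup), strict=strict)
    return drop_unusable_variables(ds)

def run_pipeline(
    data: Sequence[tuple[str | Path, str]] | list[GaitTable],
    lookup: str | Path | LookupTable,
    spec: ModelSpec,
    policy: NormalizationPolicy | None = None,
    strict: bool = True,
) -> PipelineResult:
    """Full forward screen from raw exports (paths or in-memory tables).

    When ``policy`` is None no baseline normalization is applied (single
    timepoint studies); otherwise the data is normalized and the baseline
    timepoint excluded before screening.
    """
    if isinstance(lookup, LookupTable):
        tables = [t if isinstance(t, GaitTable) else read_gait_export(*t)
                  for t in data]
        ds = join_metadata(tables, lookup, strict=strict)
        ds = drop_unusable_variables(ds)
    else:
        ds = ingest(data, lookup, strict=strict)
    normalized = normalize_to_baseline(ds, policy) if policy else None
    result = screen(normalized if normalized is not None else ds, spec)
    return PipelineResult(ds, normalized, result)


def case_one_spec(group_col: str = "group", alpha: float = 0.05) -> ModelSpec:
    """Repeated-measures screen: genotype (between) × timepoint (within).

    The design of the package's first worked case: two genotypes, a
    pre-injury baseline plus two post-injury timepoints, ratio-normalized,
    terms group, timepoint and their interaction at alpha 0.05 with no
    multiplicity adjustment.
    """
    return ModelSpec(between_factors=(group_col,), within_factor="timepoint",
                     alpha=alpha)


def case_two_spec(factors: Sequence[str] = ("cells", "bridge"),
                  alpha: float = 0.05) -> ModelSpec:
    """Single-timepoint factorial screen over binary treatment factors.

    The second worked case: a terminal-timepoint study with binary
    treatment indicators (e.g. biomaterial bridge, cell transplant) crossed
    factorially; two-way ANOVA per variable with main effects and their
    interaction.  The factor list is configurable because combinatorial
    studies differ in which factors enter each model.
    """
    return ModelSpec(between_factors=tuple(factors), within_factor=None,
                     alpha=alpha)
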