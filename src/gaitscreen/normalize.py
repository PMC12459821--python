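"""Baseline normalization of longitudinal gait data.

Each animal's post-baseline values are expressed relative to its own value
at a declared baseline timepoint (usually pre-injury), either as a ratio
(fold of baseline, the default — it puts heterogeneous-unit variables on a
common scale) or as a difference.  The baseline timepoint itself is then
removed from the dataset so it cannot distort downstream screening.

Animals lacking a baseline measurement for a variable are handled by
policy: exclude the subject entirely, or stand in the mean of its group's
baseline values and normalize the animal's own post values against that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ID_COL, TIME_COL, VALUE_COL, VAR_COL, StudyDataset
from .errors import NormalizationError


@dataclass(frozen=True)
class NormalizationPolicy:
    """How to normalize to baseline.

    Parameters
    ----------
    baseline_timepoint
        Label of the reference timepoint; must be one of the study's
        declared timepoints.
    transform
        ``"ratio"`` → value / baseline; ``"difference"`` → value − baseline.
    missing_baseline
        ``"exclude_subject"`` drops every record of an animal that has no
        baseline for a variable (for that variable); ``"impute_group_mean"``
        uses the mean of the animal's group's baseline values instead.
    zero_baseline
        Under the ratio transform a zero baseline is undefined:
        ``"set_missing"`` (default) marks the normalized values missing;
        ``"epsilon_offset"`` divides by ``epsilon`` instead (for count-like
        variables).
    group_col
        Metadata column defining the groups used for imputation.
    """

    baseline_timepoint: str
    transform: str = "ratio"
    missing_baseline: str = "exclude_subject"
    zero_baseline: str = "set_missing"
    epsilon: float = 1e-6
    group_col: str = "group"

    def __post_init__(self) -> None:
        if self.transform not in {"ratio", "difference"}:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.missing_baseline not in {"exclude_subject", "impute_group_mean"}:
            raise ValueError(f"unknown missing_baseline {self.missing_baseline!r}")
        if self.zero_baseline not in {"set_missing", "epsilon_offset"}:
            raise ValueError(f"unknown zero_baseline {self.zero_baseline!r}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def normalize_to_baseline(ds: StudyDataset, policy: NormalizationPolicy) -> StudyDataset:
    """Normalize every post-baseline record to the animal's baseline.

    Returns a new dataset containing only post-baseline timepoints, with a
    provenance log of excluded subjects and imputations.
    """
    base_tp = str(policy.baseline_timepoint)
    if base_tp not in ds.timepoints:
        raise NormalizationError(
            f"baseline timepoint {base_tp!r} not among study timepoints {ds.timepoints}"
        )
    rec = ds.records
    is_base = rec[TIME_COL].astype(str) == base_tp
    if not is_base.any():
        raise NormalizationError(f"no records at baseline timepoint {base_tp!r}")

    base = (
        rec[is_base]
        .dropna(subset=[VALUE_COL])
        .set_index([ID_COL, VAR_COL])[VALUE_COL]
    )
    post = rec[~is_base].copy()
    key = pd.MultiIndex.from_frame(post[[ID_COL, VAR_COL]])
    baseline_vals = pd.Series(base.reindex(key).to_numpy(), index=post.index)

    out = StudyDataset(
        post.iloc[0:0], tuple(t for t in ds.timepoints if t != base_tp),
        ds.metadata_cols, baseline=base_tp, log=list(ds.log),
    )

    missing_base = baseline_vals.isna()
    if missing_base.any():
        if policy.missing_baseline == "exclude_subject":
            # Exclude animals with no usable baseline session at all; a
            # missing baseline for an individual variable only voids that
            # variable's normalized values.
            with_base = set(base.index.get_level_values(ID_COL))
            excluded = sorted(set(post[ID_COL]) - with_base)
            if excluded:
                keep = ~post[ID_COL].isin(excluded)
                post = post[keep]
                baseline_vals = baseline_vals[keep.to_numpy()]
                for a in excluded:
                    out.log_event("exclude_subject", "no baseline measurement",
                                  animal_id=a)
            still = baseline_vals.isna() & post[VALUE_COL].notna()
            for a, v in post.loc[still.to_numpy(), [ID_COL, VAR_COL]].drop_duplicates().itertuples(index=False):
                out.log_event("missing_baseline_cell",
                              "baseline missing for this variable; "
                              "normalized values set missing",
                              animal_id=a, variable=v)
        else:  # impute_group_mean
            affected = post.loc[missing_base, [ID_COL, VAR_COL]].drop_duplicates()
            if policy.group_col not in ds.metadata_cols:
                raise NormalizationError(
                    f"group column {policy.group_col!r} not in metadata "
                    f"{ds.metadata_cols}; needed for imputation"
                )
            grp_of = (
                rec[[ID_COL, policy.group_col]]
                .drop_duplicates(ID_COL)
                .set_index(ID_COL)[policy.group_col]
            )
            group_means = (
                rec[is_base]
                .groupby([policy.group_col, VAR_COL])[VALUE_COL]
                .mean()
            )
            mkey = pd.MultiIndex.from_arrays(
                [post[ID_COL].map(grp_of), post[VAR_COL]]
            )
            imputed = pd.Series(group_means.reindex(mkey).to_numpy(), index=post.index)
            need = missing_base.loc[post.index]
            still = need & imputed.isna()
            if still.any():
                bad = post.loc[still, [policy.group_col, VAR_COL]].drop_duplicates()
                pairs = [f"{g}/{v}" for g, v in bad.itertuples(index=False)]
                raise NormalizationError(
                    "no baseline observations to impute from for "
                    f"(group/variable): {pairs}"
                )
            baseline_vals = baseline_vals.where(~need, imputed)
            for a, v in affected.itertuples(index=False):
                out.log_event("impute_baseline",
                              "group-mean baseline used", animal_id=a, variable=v)

    b = baseline_vals.to_numpy(dtype=float)
    y = post[VALUE_COL].to_numpy(dtype=float)
    if policy.transform == "ratio":
        zero = b == 0
        if policy.zero_baseline == "epsilon_offset":
            b = np.where(zero, policy.epsilon, b)
        with np.errstate(divide="ignore", invalid="ignore"):
            norm = y / b
        if policy.zero_baseline == "set_missing":
            norm = np.where(zero, np.nan, norm)
            for a, v in post.loc[zero & ~np.isnan(y), [ID_COL, VAR_COL]].itertuples(index=False):
                out.log_event("zero_baseline_set_missing",
                              "ratio to zero baseline undefined",
                              animal_id=a, variable=v)
    else:
        norm = y - b

    post = post.assign(**{VALUE_COL: norm})
    out.records = StudyDataset(
        post, out.timepoints, ds.metadata_cols, base_tp
    ).records
    return out


def baseline_summary(ds: StudyDataset, group_col: str = "group",
                     baseline: str | None = None) -> pd.DataFrame:
    """Per-group per-variable descriptive summary of raw baseline values.

    Useful for checking the non-normalized data for group differences at
    baseline (expected e.g. across genotypes).  Returns a table with
    columns (group, variable, mean, sd, n); groups with no observations for
    a variable yield missing cells rather than errors.
    """
    base_tp = str(baseline if baseline is not None else
                  (ds.baseline or ds.timepoints[0]))
    rec = ds.records
    base = rec[rec[TIME_COL].astype(str) == base_tp]
    if base.empty:
        raise NormalizationError(f"no records at baseline timepoint {base_tp!r}")
    grouped = base.groupby([group_col, VAR_COL], sort=False, dropna=False)[VALUE_COL]
    summ = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    return summ.rename(columns={group_col: "group", VAR_COL: "variable"})
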