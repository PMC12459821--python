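"""Mass-univariate forward screen over normalized gait variables.

Rather than pre-selecting a handful of "gold standard" gait variables, the
forward screen fits the user's ANOVA model to *every* variable that
survived cleaning and normalization, and collects per-effect-term p-values.
The variables significant for each term form that term's "hit set" — the
screen's primary output, feeding enrichment analysis and visualization.

Multiple-comparison adjustment defaults to none: gait variables are highly
inter-correlated and the screen is exploratory/descriptive, so a per-test
alpha is used; Bonferroni and Benjamini–Hochberg are available as options.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .anova import Term, anova_decompose, parse_terms, term_name
from .dataset import ID_COL, TIME_COL, StudyDataset
from .errors import DegenerateDataError


@dataclass(frozen=True)
class ModelSpec:
    """The user's ANOVA design for the screen.

    Parameters
    ----------
    between_factors
        Metadata columns used as between-subject factors, in entry order
        (sequential sums of squares follow this order).
    within_factor
        Set to ``"timepoint"`` (or another column) for repeated measures;
        terms containing it are tested against the subject-by-within
        residual stratum, the rest against the subject stratum.
    terms
        Effect terms to test.  Default: full factorial over all declared
        factors (e.g. ``group``, ``timepoint``, ``group:timepoint``).
    alpha
        Per-test significance threshold; a variable is a hit when its
        (adjusted) p-value is strictly below alpha.
    adjustment
        ``"none"`` (default), ``"bonferroni"``, or ``"bh_fdr"``; applied
        per term across variables.
    sphericity
        ``"none"`` (default, matching classical ``aov`` output) or ``"gg"``
        for Greenhouse–Geisser-corrected within-term p-values.
    """

    between_factors: tuple[str, ...]
    within_factor: str | None = None
    terms: tuple[str, ...] | None = None
    alpha: float = 0.05
    adjustment: str = "none"
    sphericity: str = "none"

    def __post_init__(self) -> None:
        object.__setattr__(self, "between_factors", tuple(self.between_factors))
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.adjustment not in {"none", "bonferroni", "bh_fdr"}:
            raise ValueError(f"unknown adjustment {self.adjustment!r}")
        if self.sphericity not in {"none", "gg"}:
            raise ValueError(f"unknown sphericity option {self.sphericity!r}")
        if self.terms is not None:
            object.__setattr__(self, "terms", tuple(self.terms))

    @property
    def factor_names(self) -> tuple[str, ...]:
        extra = (self.within_factor,) if self.within_factor else ()
        return self.between_factors + extra

    def effect_terms(self) -> list[Term]:
        if self.terms is not None:
            return parse_terms(list(self.terms))
        return parse_terms("*".join(self.factor_names))

    @property
    def term_names(self) -> list[str]:
        return [term_name(t) for t in self.effect_terms()]


@dataclass
class ScreenResult:
    """Per-variable, per-term screen output.

    ``table`` has one row per (variable, term) with columns F, df1, df2,
    p, p_adj and hit; ``skipped`` maps unscreenable variables to reasons.
    """

    table: pd.DataFrame
    alpha: float
    adjustment: str
    term_names: list[str]
    skipped: dict[str, str] = field(default_factory=dict)

    @property
    def n_tested(self) -> int:
        return self.table["variable"].nunique()

    @property
    def variables(self) -> list[str]:
        return list(pd.unique(self.table["variable"]))

    def hit_sets(self) -> dict[str, set[str]]:
        """Significant-variable set per term (strict p < alpha)."""
        out: dict[str, set[str]] = {}
        for term in self.term_names:
            sub = self.table[self.table["term"] == term]
            out[term] = set(sub.loc[sub["hit"], "variable"])
        return out

    def hit_counts(self) -> dict[str, int]:
        return {t: len(s) for t, s in self.hit_sets().items()}

    def summary_json(self) -> str:
        return json.dumps({
            "n_tested": self.n_tested,
            "alpha": self.alpha,
            "adjustment": self.adjustment,
            "hit_counts": self.hit_counts(),
            "skipped": self.skipped,
        }, indent=2, sort_keys=True)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def fit_anova_one(records: pd.DataFrame, spec: ModelSpec,
                  value_col: str = "value") -> pd.DataFrame:
    """Fit the declared model to one variable's records.

    ``records`` holds one observation per row with the factor columns and
    the response in ``value_col``; rows with a missing response are dropped.
    Returns a per-term table with F, df1, df2 and p.
    """
    rec = records.dropna(subset=[value_col])
    rec = _complete_cases(rec, spec)
    _check_design(rec, spec)
    dec = anova_decompose(
        rec, rec[value_col].to_numpy(dtype=float), spec.effect_terms(),
        within_factor=spec.within_factor,
    )
    tab = dec.f_table().drop(columns="response")
    if spec.sphericity == "gg" and spec.within_factor is not None:
        tab = _apply_gg(tab, rec, spec, value_col)
    return tab


def screen(ds: StudyDataset, spec: ModelSpec) -> ScreenResult:
    """Apply the model to every variable and derive per-term hit sets.

    Missing responses are deleted casewise per variable; in a
    repeated-measures design, subjects without a complete within-factor
    profile for a variable are dropped for that variable.  Variables whose
    design degenerates (a factor collapsing to one level, or no residual
    degrees of freedom) are skipped with a logged reason.  Output is
    deterministic given input ordering.
    """
    wide = ds.to_wide()
    variables = ds.variables
    skipped: dict[str, str] = {}
    # Batch variables sharing a missingness pattern: the projection basis
    # depends only on which rows survive, so each pattern is decomposed once.
    masks: dict[tuple, list[str]] = {}
    for v in variables:
        mask = wide[v].notna().to_numpy()
        if spec.within_factor is not None:
            mask &= _complete_profile_mask(wide, mask, spec)
        masks.setdefault(tuple(mask), []).append(v)

    parts = []
    for mask_key, vs in masks.items():
        mask = np.asarray(mask_key)
        sub = wide.loc[mask].reset_index(drop=True)
        try:
            _check_design(sub, spec)
            dec = anova_decompose(
                sub, sub[vs].to_numpy(dtype=float), spec.effect_terms(),
                within_factor=spec.within_factor,
            )
        except DegenerateDataError as e:
            for v in vs:
                skipped[v] = str(e)
            continue
        tab = dec.f_table()
        tab["variable"] = tab.pop("response").map(dict(enumerate(vs)))
        if spec.sphericity == "gg" and spec.within_factor is not None:
            tab = pd.concat([
                _apply_gg(g.drop(columns="variable"), sub, spec, v).assign(variable=v)
                for v, g in tab.groupby("variable", sort=False)
            ], ignore_index=True)
        parts.append(tab)

    if not parts:
        raise DegenerateDataError("no variable could be screened")
    table = pd.concat(parts, ignore_index=True)
    # restore input variable order, then term order
    var_order = {v: i for i, v in enumerate(variables)}
    term_order = {t: i for i, t in enumerate(spec.term_names)}
    table = table.sort_values(
        ["variable", "term"],
        key=lambda s: s.map(var_order if s.name == "variable" else term_order),
        kind="stable",
    ).reset_index(drop=True)
    table = table[["variable", "term", "F", "df1", "df2", "p"]]
    table["p_adj"] = table["p"]
    if spec.adjustment != "none":
        method = {"bonferroni": "bonferroni", "bh_fdr": "fdr_bh"}[spec.adjustment]
        for term in spec.term_names:
            idx = table.index[table["term"] == term]
            table.loc[idx, "p_adj"] = multipletests(
                table.loc[idx, "p"], method=method)[1]
    table["hit"] = table["p_adj"] < spec.alpha
    return ScreenResult(table, spec.alpha, spec.adjustment, spec.term_names, skipped)


def hit_matrix(result: ScreenResult, cap: float = 4.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(variable × term) display matrices: −log10 p (capped) and 0/1 hits.

    Rows are ordered by each variable's minimum p-value across terms, most
    significant first, so heatmaps lead with the strongest signals.
    """
    if result.table.empty:
        raise DegenerateDataError("empty screen result")
    pmat = result.table.pivot(index="variable", columns="term", values="p")
    pmat = pmat.loc[:, result.term_names]
    order = pmat.min(axis=1).sort_values(kind="stable").index
    pmat = pmat.loc[order]
    hits = result.table.pivot(index="variable", columns="term", values="hit")
    hits = hits.loc[order, result.term_names].astype(int)
    with np.errstate(divide="ignore"):
        neglog = np.minimum(-np.log10(pmat), cap)
    return neglog, hits


# --------------------------------------------------------------------- helpers

def _complete_cases(rec: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    if spec.within_factor is None:
        return rec
    counts = rec.groupby(ID_COL, sort=False)[spec.within_factor].nunique()
    n_levels = rec[spec.within_factor].nunique()
    complete = set(counts.index[counts == n_levels])
    return rec[rec[ID_COL].isin(complete)]


def _complete_profile_mask(wide: pd.DataFrame, obs_mask: np.ndarray,
                           spec: ModelSpec) -> np.ndarray:
    """Rows belonging to subjects observed at every within-factor level."""
    sub = wide.loc[obs_mask]
    n_levels = wide[spec.within_factor].nunique()
    counts = sub.groupby(ID_COL, sort=False)[spec.within_factor].nunique()
    complete = set(counts.index[counts == n_levels])
    return wide[ID_COL].isin(complete).to_numpy()


def _check_design(rec: pd.DataFrame, spec: ModelSpec) -> None:
    if rec.empty:
        raise DegenerateDataError("no observations after missing-data removal")
    for f in spec.factor_names:
        if f not in rec.columns:
            raise DegenerateDataError(f"factor column {f!r} not present")
        if rec[f].nunique() < 2:
            raise DegenerateDataError(
                f"factor {f!r} has fewer than 2 levels after missing-data removal")


def _gg_epsilon(rec: pd.DataFrame, spec: ModelSpec, value_col: str) -> float:
    """Greenhouse–Geisser epsilon from the within-subject covariance."""
    piv = rec.pivot_table(index=ID_COL, columns=spec.within_factor,
                          values=value_col, aggfunc="first")
    piv = piv.dropna()
    grp_cols = list(spec.between_factors)
    meta = rec[[ID_COL, *grp_cols]].drop_duplicates(ID_COL).set_index(ID_COL)
    centered = piv.copy()
    if grp_cols:
        cells = meta.loc[piv.index, grp_cols].astype(str).agg("|".join, axis=1)
        centered = piv.groupby(cells.values).transform(lambda g: g - g.mean())
    else:
        centered = piv - piv.mean()
    S = np.cov(centered.to_numpy(), rowvar=False, ddof=1)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    grand = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(row_means**2) + k**2 * grand**2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def _apply_gg(tab: pd.DataFrame, rec: pd.DataFrame, spec: ModelSpec,
              value_col: str) -> pd.DataFrame:
    from scipy import stats

    eps = _gg_epsilon(rec, spec, value_col)
    tab = tab.copy()
    within = [term_name(t) for t in spec.effect_terms()
              if spec.within_factor in t]
    for i, row in tab.iterrows():
        if row["term"] in within:
            tab.loc[i, "p"] = float(stats.f.sf(
                row["F"], row["df1"] * eps, row["df2"] * eps))
    return tab
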