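"""Sequential sums-of-squares ANOVA with optional subject error stratum.

This is the statistical engine behind the forward screen.  It implements
classical fixed-effects factorial ANOVA with sequential (Type I) sums of
squares, factors entered in the user's declared order, matching the
behavior of base R's ``aov``.  When a within-subject factor is declared the
engine performs repeated-measures ANOVA with two error strata:
between-subject terms are tested against the subject stratum, and
within-subject terms (the within factor and its interactions) against the
subject-by-within residual stratum.

The decomposition works by projection: for each term, the corresponding
dummy-coded design block is residualized against everything entered before
it and orthonormalized; the term's sum of squares is the squared norm of
the response's projection onto the new directions.  Because the projections
are shared across responses, many variables measured on the same design can
be decomposed in one pass (the response may be an ``n × m`` matrix).

On balanced designs sequential, Type II and Type III sums of squares
coincide, which bounds the sensitivity of the screen to entry order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError

#: Relative singular-value cutoff for detecting rank when orthonormalizing.
_RANK_TOL = 1e-9

Term = tuple[str, ...]


def parse_terms(spec: str | list) -> list[Term]:
    """Expand a model description into an ordered list of effect terms.

    Accepts either a list of term strings (``["group", "time",
    "group:time"]``) or a single formula-like string where ``a*b`` expands
    to ``a``, ``b``, ``a:b`` and ``+`` separates terms.  Each term is a
    tuple of factor names; interaction order is as written.
    """
    if isinstance(spec, str):
        parts = [p.strip() for p in spec.split("+") if p.strip()]
    else:
        parts = [str(p).strip() for p in spec]
    terms: list[Term] = []

    def add(t: Term) -> None:
        if t not in terms:
            terms.append(t)

    for part in parts:
        if "*" in part:
            factors = [f.strip() for f in part.split("*")]
            # full factorial expansion: mains, then pairs, then triples, ...
            from itertools import combinations

            for k in range(1, len(factors) + 1):
                for combo in combinations(factors, k):
                    add(tuple(combo))
        else:
            add(tuple(f.strip() for f in part.split(":")))
    return terms


def term_name(term: Term) -> str:
    return ":".join(term)


def _dummy_block(values: np.ndarray) -> np.ndarray:
    """Full-rank treatment coding (first level dropped), levels sorted."""
    levels = np.unique(values)
    return (values[:, None] == levels[None, 1:]).astype(float)


def _term_block(df: pd.DataFrame, term: Term) -> np.ndarray:
    block = None
    for f in term:
        d = _dummy_block(df[f].to_numpy(dtype=str))
        block = d if block is None else (block[:, :, None] * d[:, None, :]).reshape(len(df), -1)
    return block


def _orthonormal_complement(block: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Orthonormal basis of block's column space orthogonal to span(Q)."""
    r = block - Q @ (Q.T @ block)
    r = r - Q @ (Q.T @ r)  # second pass for numerical stability
    if r.shape[1] == 0:
        return r
    u, s, _ = np.linalg.svd(r, full_matrices=False)
    scale = max(np.linalg.norm(block), 1.0)
    rank = int(np.sum(s > _RANK_TOL * scale))
    return u[:, :rank]


@dataclass
class TermResult:
    term: Term
    ss: np.ndarray  # per-response sum of squares, shape (m,)
    df: int
    stratum: str  # "between" or "within"


@dataclass
class AnovaDecomposition:
    """Per-term SS/df plus error strata for a shared design.

    ``f_table()`` converts to F statistics and upper-tail p-values, testing
    each term against its stratum's error mean square.
    """

    terms: list[TermResult]
    error_ss: dict[str, np.ndarray]  # stratum -> per-response SS
    error_df: dict[str, int]
    n_obs: int

    def f_table(self) -> pd.DataFrame:
        rows = []
        m = len(self.terms[0].ss) if self.terms else 0
        for t in self.terms:
            ess, edf = self.error_ss[t.stratum], self.error_df[t.stratum]
            with np.errstate(divide="ignore", invalid="ignore"):
                f = (t.ss / t.df) / (ess / edf)
            p = stats.f.sf(f, t.df, edf)
            for j in range(m):
                rows.append({
                    "term": term_name(t.term), "response": j,
                    "F": float(f[j]), "df1": t.df, "df2": edf,
                    "p": float(p[j]),
                })
        return pd.DataFrame(rows)


def anova_decompose(
    data: pd.DataFrame,
    y: np.ndarray,
    terms: list[Term],
    within_factor: str | None = None,
    subject: str = "animal_id",
) -> AnovaDecomposition:
    """Sequentially decompose responses ``y`` over the declared terms.

    Parameters
    ----------
    data
        One row per observation; holds the factor columns (and the subject
        id column when ``within_factor`` is set).  All factors are treated
        as categorical.
    y
        Response vector ``(n,)`` or matrix ``(n, m)`` aligned with ``data``
        rows; no missing values (casewise deletion happens upstream).
    terms
        Ordered effect terms.  With a within factor, between-subject terms
        must all precede within-subject terms (terms containing the within
        factor); the subject stratum is inserted between the two groups.
    within_factor
        Name of the repeated-measures factor, or None for a purely
        between-subjects design.
    subject
        Column identifying the experimental unit for the error stratum.

    Raises
    ------
    DegenerateDataError
        If a term contributes no estimable contrast (factor collapsed to
        one level) or an error stratum has no residual degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = len(data)
    if y.shape[0] != n:
        raise ValueError("response length does not match design rows")

    if within_factor is not None:
        between_terms = [t for t in terms if within_factor not in t]
        within_terms = [t for t in terms if within_factor in t]
        ordered = between_terms + within_terms
    else:
        between_terms, within_terms, ordered = list(terms), [], list(terms)

    Q = np.ones((n, 1)) / np.sqrt(n)  # intercept
    results: list[TermResult] = []
    total_rank = 1

    def project(block: np.ndarray) -> tuple[np.ndarray, int]:
        nonlocal Q, total_rank
        basis = _orthonormal_complement(block, Q)
        rank = basis.shape[1]
        if rank:
            Q = np.hstack([Q, basis])
            total_rank += rank
        ss = np.sum((basis.T @ y) ** 2, axis=0)
        return ss, rank

    for t in between_terms:
        ss, rank = project(_term_block(data, t))
        if rank == 0:
            raise DegenerateDataError(
                f"term {term_name(t)} is not estimable (factor collapsed "
                "or aliased with earlier terms)")
        results.append(TermResult(t, ss, rank, "between"))

    error_ss: dict[str, np.ndarray] = {}
    error_df: dict[str, int] = {}
    tot = np.sum(y**2, axis=0)

    if within_factor is None:
        explained = sum((r.ss for r in results), np.zeros(y.shape[1]))
        mean_ss = np.sum((Q[:, :1].T @ y) ** 2, axis=0)
        resid_df = n - total_rank
        if resid_df < 1:
            raise DegenerateDataError("no residual degrees of freedom")
        error_ss["between"] = tot - mean_ss - explained
        error_df["between"] = resid_df
        return AnovaDecomposition(results, error_ss, error_df, n)

    # subject stratum: subject indicators entered after between terms
    subj_ss, subj_rank = project(_dummy_block(data[subject].to_numpy(dtype=str)))
    if subj_rank < 1:
        raise DegenerateDataError("subject error stratum has no degrees of freedom")
    error_ss["between"] = subj_ss
    error_df["between"] = subj_rank

    for t in within_terms:
        ss, rank = project(_term_block(data, t))
        if rank == 0:
            raise DegenerateDataError(
                f"term {term_name(t)} is not estimable (factor collapsed "
                "or aliased with earlier terms)")
        results.append(TermResult(t, ss, rank, "within"))

    mean_ss = np.sum((Q[:, :1].T @ y) ** 2, axis=0)
    explained = sum((r.ss for r in results), np.zeros(y.shape[1])) + subj_ss
    resid_df = n - total_rank
    if resid_df < 1:
        raise DegenerateDataError("no residual degrees of freedom in the "
                                  "within-subject stratum")
    error_ss["within"] = tot - mean_ss - explained
    error_df["within"] = resid_df
    # keep declared term order in the output
    order = {t: i for i, t in enumerate(terms)}
    results.sort(key=lambda r: order[r.term])
    return AnovaDecomposition(results, error_ss, error_df, n)
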