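"""Hit-set visualizations and their underlying data tables.

Every figure is driven by a plain table computed here (region counts, word
weights, trajectory summaries, embedding coordinates), so any plot can be
re-derived outside matplotlib.  The figure renderers are thin.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import ID_COL, TIME_COL, VALUE_COL, VAR_COL, StudyDataset
from .errors import DegenerateDataError


# ------------------------------------------------------------------ Venn

def venn_counts(hit_sets: Mapping[str, set]) -> dict[frozenset, int]:
    """Exact disjoint-region cardinalities for 2 or 3 hit sets.

    Keys are frozensets of term names: ``{A}`` is the A-only region,
    ``{A, B}`` the A∩B-only region, and so on.  Region counts sum to the
    size of the union.
    """
    names = list(hit_sets)
    if len(names) not in (2, 3):
        raise ValueError(
            f"venn_counts supports 2 or 3 sets, got {len(names)}; "
            "use pairwise_overlap_table for more")
    counts: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            region = set.intersection(*(set(hit_sets[t]) for t in inside))
            for t in names:
                if t not in inside:
                    region -= set(hit_sets[t])
            counts[frozenset(inside)] = len(region)
    return counts


def pairwise_overlap_table(hit_sets: Mapping[str, set]) -> pd.DataFrame:
    """|A∩B| for every pair of terms (fallback when >3 sets)."""
    names = list(hit_sets)
    rows = [{"term_a": a, "term_b": b,
             "n_a": len(hit_sets[a]), "n_b": len(hit_sets[b]),
             "overlap": len(set(hit_sets[a]) & set(hit_sets[b]))}
            for a, b in combinations(names, 2)]
    return pd.DataFrame(rows)


# ------------------------------------------------------------- word cloud

def wordcloud_weights(enrichment: pd.DataFrame, cap: float = 4.0) -> pd.DataFrame:
    """Per-tag display weights: size ∝ hit frequency, color ∝ enrichment.

    ``size`` is k (the tag's frequency among hits; tags with k = 0 are
    omitted) and ``color_score`` is −log10 p_enrich clipped to ``cap``, so
    redder tags are those disproportionately hit relative to the universe.
    """
    if enrichment.empty:
        raise DegenerateDataError("empty enrichment table")
    out = enrichment.loc[enrichment["k"] > 0, ["tag", "k", "p_enrich"]].copy()
    out["size"] = out["k"].astype(float)
    with np.errstate(divide="ignore"):
        out["color_score"] = np.minimum(-np.log10(out["p_enrich"]), cap)
    return out[["tag", "size", "color_score"]].reset_index(drop=True)


# ------------------------------------------------------------ trajectories

def trajectory_plot_data(ds: StudyDataset, variable: str,
                         group_by: str = "group") -> pd.DataFrame:
    """Per-group per-timepoint mean ± sem for one variable's line plot."""
    rec = ds.records
    sub = rec[rec[VAR_COL] == variable]
    if sub.empty:
        raise KeyError(f"unknown variable {variable!r}")
    g = sub.groupby([group_by, TIME_COL], sort=False)[VALUE_COL]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    order = {t: i for i, t in enumerate(ds.timepoints)}
    out = out.sort_values([group_by, TIME_COL],
                          key=lambda s: s.map(order) if s.name == TIME_COL else s,
                          kind="stable")
    return out.rename(columns={group_by: "group"}).reset_index(drop=True)


# -------------------------------------------------------------- embedding

def embed_animals(ds: StudyDataset, seed: int = 0, imputation: str = "median",
                  n_neighbors: int = 15, aggregate: bool = False,
                  ) -> pd.DataFrame:
    """2-D UMAP embedding of animal(-timepoint) rows.

    Rows are (animal, timepoint) profiles of the normalized variables
    (or per-animal means across timepoints when ``aggregate``); each
    variable is z-scored, missing values are imputed per policy (variable
    median by default), and the embedding is fitted with a fixed random
    seed so identical input reproduces identical coordinates.
    """
    wide = ds.to_wide()
    variables = ds.variables
    meta_cols = [ID_COL, TIME_COL, *ds.metadata_cols]
    if aggregate:
        wide = wide.groupby([ID_COL, *ds.metadata_cols], as_index=False,
                            sort=False)[variables].mean()
        meta_cols = [ID_COL, *ds.metadata_cols]
    X = wide[variables].to_numpy(dtype=float)
    keep = ~np.all(np.isnan(X), axis=0)
    X = X[:, keep]
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    if imputation == "median":
        med = np.nanmedian(X, axis=0)
        X = np.where(np.isnan(X), med, X)
    elif imputation == "zero":
        X = np.where(np.isnan(X), 0.0, X)
    else:
        raise ValueError(f"unknown imputation {imputation!r}")
    n_neighbors = min(n_neighbors, X.shape[0] - 1)
    if X.shape[0] < 4 or n_neighbors < 2:
        raise DegenerateDataError(
            f"too few rows ({X.shape[0]}) for a meaningful embedding")
    import umap  # heavy import kept local

    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        random_state=int(seed))
    coords = reducer.fit_transform(X)
    out = wide[meta_cols].copy()
    out["umap1"] = coords[:, 0]
    out["umap2"] = coords[:, 1]
    return out


# ------------------------------------------------------------------ figures

def plot_heatmap(neglog: pd.DataFrame, ax=None):
    """Heatmap of −log10 p per (variable, term)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4 + 0.4 * neglog.shape[1],
                                      max(3, 0.14 * len(neglog))))
    im = ax.imshow(neglog.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(neglog.shape[1]), neglog.columns, rotation=45,
                  ha="right")
    ax.set_yticks(range(len(neglog)), neglog.index, fontsize=5)
    ax.figure.colorbar(im, ax=ax, label="−log10 p")
    return ax


def plot_venn(counts: dict[frozenset, int], ax=None):
    """2- or 3-circle Venn diagram annotated with region counts."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    names = sorted({t for key in counts for t in key})
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    centers = {2: [(-0.5, 0), (0.5, 0)],
               3: [(-0.5, -0.29), (0.5, -0.29), (0, 0.58)]}[len(names)]
    label_pos = {
        frozenset([names[0]]): (-0.9, 0) if len(names) == 2 else (-0.9, -0.5),
        frozenset([names[1]]): (0.9, 0) if len(names) == 2 else (0.9, -0.5),
        frozenset(names[:2]): (0, -0.29 if len(names) == 3 else 0),
    }
    if len(names) == 3:
        label_pos.update({
            frozenset([names[2]]): (0, 1.0),
            frozenset([names[0], names[2]]): (-0.5, 0.3),
            frozenset([names[1], names[2]]): (0.5, 0.3),
            frozenset(names): (0, 0.0),
        })
    for (x, y), name in zip(centers, names):
        ax.add_patch(Circle((x, y), 1.0, alpha=0.25, lw=1.5, ec="k"))
        ax.annotate(name, (x, y + 1.05), ha="center")
    for region, cnt in counts.items():
        x, y = label_pos[region]
        ax.annotate(str(cnt), (x, y), ha="center", va="center")
    ax.set_xlim(-2.2, 2.2)
    ax.set_ylim(-2.2, 2.2)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax


def plot_wordcloud(weights: pd.DataFrame, seed: int = 0, ax=None):
    """Seeded scatter of tags sized by hit frequency, colored by enrichment."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    rng = np.random.default_rng(seed)
    cmap = plt.get_cmap("Reds")
    top = weights.sort_values("size", ascending=False).head(30)
    for _, row in top.iterrows():
        x, y = rng.uniform(0.05, 0.95, 2)
        ax.text(x, y, row["tag"], fontsize=8 + 3 * row["size"],
                color=cmap(0.2 + 0.8 * row["color_score"] / 4.0),
                ha="center", va="center", transform=ax.transAxes)
    ax.axis("off")
    return ax


def plot_trajectory(traj: pd.DataFrame, variable: str = "", ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for grp, sub in traj.groupby("group", sort=False):
        x = np.arange(len(sub))
        ax.errorbar(x, sub["mean"], yerr=sub["sem"], label=str(grp),
                    marker="o", capsize=3)
        ax.set_xticks(x, sub[TIME_COL])
    ax.set_xlabel("timepoint")
    ax.set_ylabel(variable or "value")
    ax.legend()
    return ax


def plot_embedding(embedding: pd.DataFrame, color_by: str = "group", ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for grp, sub in embedding.groupby(color_by, sort=False):
        ax.scatter(sub["umap1"], sub["umap2"], label=str(grp), s=25)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.legend()
    return ax
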