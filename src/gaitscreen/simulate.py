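"""Synthetic CatWalk-like studies with known ground truth.

The generator emulates the statistical structure the screening models
assume: multiple groups of animals, an ordered series of timepoints with a
pre-injury baseline, dozens of correlated-scale gait variables spanning
orders of magnitude, group/time/interaction effects injected on known
variable subsets, missing values, and all-zero junk columns.

Each animal draws a positive per-variable baseline (a per-variable scale
spanning orders of magnitude times per-animal heterogeneity and session
noise); every post-baseline value is that same baseline times
``(1 + effect + noise)``, so ratio normalization recovers ``1 + effect``
plus noise and the animal-level heterogeneity cancels.

Effect sizes are standardized: an effect of size ``d`` shifts the
normalized response by ``d`` times ``noise_sd``, the per-observation noise
standard deviation on the normalized scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import StudyDataset
from .ingest import GaitTable, LookupTable, join_metadata

#: Fragment templates cycled by the default variable namer; each pairs a paw
#: code with a measurement category so default names carry controlled tags.
_PAW_CODES = ("RF", "LF", "RH", "LH")
_CATEGORIES = ("Stand", "Swing", "Stride", "Support", "Couplings",
               "Cadence", "Speed", "Duty")


def variable_namer(n_variables: int,
                   tag_structure: list[tuple[tuple[str, ...], int]] | None = None,
                   ) -> list[str]:
    """Generate CatWalk-style variable names with controlled tag content.

    ``tag_structure`` assigns fragment tuples to consecutive index ranges:
    ``[(("RF", "Stand"), 5), (("LF", "Swing"), 3)]`` yields five names
    beginning ``"RF Stand"`` then three beginning ``"LF Swing"``.  Remaining
    indices (or all of them, when the structure is empty) get untaggable
    ``"Var NN"`` names.  With ``tag_structure=None`` a default structure
    cycling paw codes × measurement categories is used.
    """
    if tag_structure is None:
        tag_structure = []
        blocks = [(p, c) for c in _CATEGORIES for p in _PAW_CODES]
        per = n_variables // len(blocks)
        rem = n_variables % len(blocks)
        for i, frag in enumerate(blocks):
            cnt = per + (1 if i < rem else 0)
            if cnt:
                tag_structure.append((frag, cnt))
    names: list[str] = []
    for frags, count in tag_structure:
        for _ in range(count):
            i = len(names)
            if i >= n_variables:
                break
            prefix = " ".join(frags) if frags else "Var"
            names.append(f"{prefix} Mean {i:02d}" if frags else f"Var {i:02d}")
    while len(names) < n_variables:
        names.append(f"Var {len(names):02d}")
    return names


@dataclass(frozen=True)
class EffectSpec:
    """Variables affected by one model term, with a standardized size."""

    indices: tuple[int, ...]
    size: float


@dataclass(frozen=True)
class SimConfig:
    """Study-generator configuration (defaults emulate a two-genotype,
    three-timepoint unilateral-injury design).

    ``effects`` maps term names (``"group"``, ``"timepoint"``,
    ``"group:timepoint"``) to the affected variable indices and the
    standardized effect size on the normalized scale.
    """

    groups: tuple[str, ...] = ("WT", "KO")
    n_per_group: int = 10
    timepoints: tuple[str, ...] = ("pre", "14dpi", "28dpi")
    baseline: str = "pre"
    n_variables: int = 60
    effects: dict = field(default_factory=dict)
    noise_sd: float = 0.15
    baseline_noise_sd: float = 0.15
    animal_sd: float = 0.2
    missing_rate: float = 0.0
    n_all_zero: int = 0
    effect_mode: str = "multiplicative"
    tag_structure: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline not in self.timepoints:
            raise ValueError(f"baseline {self.baseline!r} not in timepoints")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_per_group < 2 or not self.groups:
            raise ValueError("need at least 2 animals per group")
        if self.effect_mode not in {"multiplicative", "additive"}:
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")
        for term, eff in self.effects.items():
            if any(i >= self.n_variables or i < 0 for i in eff.indices):
                raise ValueError(
                    f"effect indices for {term!r} out of range "
                    f"[0, {self.n_variables})")

    @property
    def sigma_obs(self) -> float:
        """Per-observation noise sd of the ratio-normalized response."""
        return float(self.noise_sd)


@dataclass
class SimStudy:
    """Generated study: per-timepoint tables, lookup, and ground truth."""

    tables: list[GaitTable]
    lookup: LookupTable
    truth: dict[str, set]  # term -> affected variable names
    config: SimConfig

    def to_dataset(self) -> StudyDataset:
        return join_metadata(self.tables, self.lookup)

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for t in self.tables:
            p = outdir / f"gait_{t.timepoint}.csv"
            t.data.to_csv(p, index=False)
            written.append(p)
        p = outdir / "lookup.csv"
        self.lookup.data.to_csv(p, index=False)
        written.append(p)
        return written


def simulate_study(cfg: SimConfig) -> SimStudy:
    """Generate one synthetic study; same config (incl. seed) → same output."""
    rng = np.random.default_rng(cfg.seed)
    names = variable_namer(cfg.n_variables, list(cfg.tag_structure)
                           if cfg.tag_structure is not None else None)
    groups = np.repeat(cfg.groups, cfg.n_per_group)
    n_animals = len(groups)
    animals = [f"A{i + 1:03d}" for i in range(n_animals)]

    # realized baseline: per-variable scale (orders of magnitude apart, like
    # real gait variables) x per-animal heterogeneity x session noise; the
    # same realized value multiplies every post-baseline measurement, so it
    # cancels under ratio normalization
    scale_v = 10.0 ** rng.uniform(-1, 2, cfg.n_variables)
    baseline = (scale_v[None, :]
                * rng.lognormal(0.0, cfg.animal_sd, (n_animals, cfg.n_variables))
                * (1.0 + cfg.baseline_noise_sd
                   * rng.standard_normal((n_animals, cfg.n_variables))))

    beta = {}
    for term, eff in cfg.effects.items():
        shift = np.zeros(cfg.n_variables)
        shift[list(eff.indices)] = eff.size * cfg.sigma_obs
        beta[term] = shift
    zero_shift = np.zeros(cfg.n_variables)
    is_ref_group = groups == cfg.groups[0]
    post_tps = [t for t in cfg.timepoints if t != cfg.baseline]

    tables = []
    for tp in cfg.timepoints:
        if tp == cfg.baseline:
            vals = baseline
        else:
            t_frac = (post_tps.index(tp) + 1) / len(post_tps)
            mu = np.zeros(baseline.shape)
            mu += beta.get("timepoint", zero_shift)[None, :] * t_frac
            grp_shift = beta.get("group", zero_shift)[None, :] * (~is_ref_group)[:, None]
            mu += grp_shift
            if tp == post_tps[-1]:
                mu += (beta.get("group:timepoint", zero_shift)[None, :]
                       * (~is_ref_group)[:, None])
            eps = cfg.noise_sd * rng.standard_normal(baseline.shape)
            if cfg.effect_mode == "multiplicative":
                vals = baseline * (1.0 + mu + eps)
            else:
                vals = baseline + scale_v[None, :] * (mu + eps)
        if cfg.missing_rate > 0:
            holes = rng.random(vals.shape) < cfg.missing_rate
            vals = np.where(holes, np.nan, vals)
        df = pd.DataFrame(vals, columns=names)
        for z in range(cfg.n_all_zero):
            df[f"Zero Var {z:02d}"] = 0.0
        df.insert(0, "animal_id", animals)
        tables.append(GaitTable(df, tp))

    lookup = LookupTable(pd.DataFrame({"animal_id": animals, "group": groups}))
    truth = {term: {names[i] for i in eff.indices}
             for term, eff in cfg.effects.items()}
    return SimStudy(tables, lookup, truth, cfg)


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """Convenience: a no-effect configuration for type-I-error studies."""
    return replace(SimConfig(seed=seed), effects={}, **overrides)
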