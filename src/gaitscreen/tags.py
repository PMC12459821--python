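"""Semantic tagging of gait-variable names and hypergeometric enrichment.

CatWalk variable names are compositional — ``"RF Stand Mean"`` is the mean
stand duration of the right forepaw — so a hit set can be characterized by
fragmenting each name into semantic *tags* (paw identity, measurement
category) and asking whether any tag is over-represented among the hits
relative to the screened universe.  Over-representation is tested with the
exact upper-tail hypergeometric probability P(X ≥ k) of drawing k tagged
variables in a hit set of size n from a universe of N variables of which K
carry the tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from scipy.stats import hypergeom

from .errors import DegenerateDataError
from .screen import ScreenResult

#: Characters/sequences that separate tokens in CatWalk variable names.
DEFAULT_DELIMITERS = (" ", "_", "->", "-", "(", ")", "/")

#: Default fragment → tag rules following CatWalk XT naming conventions.
#: Multi-token fragments are matched before single tokens.
DEFAULT_RULES: tuple[tuple[str, str], ...] = (
    ("Right Front", "right forepaw"),
    ("Right Forepaw", "right forepaw"),
    ("Left Front", "left forepaw"),
    ("Left Forepaw", "left forepaw"),
    ("Right Hind", "right hindpaw"),
    ("Right Hindpaw", "right hindpaw"),
    ("Left Hind", "left hindpaw"),
    ("Left Hindpaw", "left hindpaw"),
    ("Step Cycle", "step cycle"),
    ("Base of Support", "base of support"),
    ("Print Area", "print area"),
    ("Max Contact", "max contact"),
    ("RF", "right forepaw"),
    ("LF", "left forepaw"),
    ("RH", "right hindpaw"),
    ("LH", "left hindpaw"),
    ("Stand", "stand"),
    ("Swing", "swing"),
    ("Stride", "stride"),
    ("StepCycle", "step cycle"),
    ("Support", "support"),
    ("Couplings", "couplings"),
    ("Duty", "duty cycle"),
    ("Cadence", "cadence"),
    ("BOS", "base of support"),
    ("PrintArea", "print area"),
    ("MaxContact", "max contact"),
    ("Speed", "speed"),
)

#: Laterality/girdle tags derived from paw tags.
_PAW_DERIVED = {
    "right forepaw": ("right paws", "forepaws"),
    "left forepaw": ("left paws", "forepaws"),
    "right hindpaw": ("right paws", "hindpaws"),
    "left hindpaw": ("left paws", "hindpaws"),
}


@dataclass
class TagDictionary:
    """Ordered fragment → tag rules plus tokenization delimiters.

    Matching is case-insensitive and longest-fragment-first: tokens consumed
    by a multi-token fragment (e.g. ``"Right Front"``) are not re-matched by
    shorter fragments.  A variable may carry several tags; unmatched tokens
    simply yield none.  When ``derive_laterality`` is set, each paw tag also
    contributes its side (``left paws``/``right paws``) and girdle
    (``forepaws``/``hindpaws``) tags.
    """

    rules: tuple[tuple[str, str], ...] = DEFAULT_RULES
    delimiters: tuple[str, ...] = DEFAULT_DELIMITERS
    derive_laterality: bool = True
    _compiled: list[tuple[tuple[str, ...], str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for frag, tag in self.rules:
            if not str(tag).strip():
                raise ValueError(f"empty tag for fragment {frag!r}")
        compiled = [(tuple(self._tokenize(frag)), tag) for frag, tag in self.rules]
        # longest fragment first; original order breaks ties (deterministic)
        self._compiled = sorted(
            compiled, key=lambda ft: -len(ft[0]))

    def _tokenize(self, name: str) -> list[str]:
        s = str(name)
        for d in self.delimiters:
            s = s.replace(d, "\x00")
        return [t.lower() for t in s.split("\x00") if t]

    def tags_for(self, name: str) -> set[str]:
        tokens = self._tokenize(name)
        consumed = [False] * len(tokens)
        tags: set[str] = set()
        for frag, tag in self._compiled:
            L = len(frag)
            for i in range(len(tokens) - L + 1):
                if any(consumed[i:i + L]):
                    continue
                if tuple(tokens[i:i + L]) == frag:
                    consumed[i:i + L] = [True] * L
                    tags.add(tag)
        if self.derive_laterality:
            for t in list(tags):
                tags.update(_PAW_DERIVED.get(t, ()))
        return tags

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TagDictionary":
        """Load a user dictionary: ``rules: [{fragment, tag}, ...]`` etc."""
        cfg = yaml.safe_load(Path(path).read_text())
        rules = tuple((r["fragment"], r["tag"]) for r in cfg.get("rules", []))
        return cls(
            rules=rules or DEFAULT_RULES,
            delimiters=tuple(cfg.get("delimiters", DEFAULT_DELIMITERS)),
            derive_laterality=bool(cfg.get("derive_laterality", True)),
        )


def tag_variables(names: list[str], dictionary: TagDictionary | None = None
                  ) -> dict[str, set[str]]:
    """Map each variable name to its tag set (possibly empty)."""
    dictionary = dictionary or TagDictionary()
    if not dictionary.rules:
        raise ValueError("tag dictionary has no rules")
    return {name: dictionary.tags_for(name) for name in names}


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact P(X ≥ k) for X ~ Hypergeometric(N, K, n).

    N: universe size; K: tagged variables in the universe; n: hit-set size;
    k: tagged variables among the hits.
    """
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(
            f"invalid hypergeometric parameters N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_tags(result: ScreenResult, term: str,
                dictionary: TagDictionary | None = None) -> pd.DataFrame:
    """Hypergeometric tag enrichment of a term's hit set.

    The universe is the set of variables that survived cleaning and were
    screened.  Returns one row per tag present in the universe, sorted by
    enrichment p ascending (ties by tag name), with columns
    (tag, K, k, N, n, p_enrich).
    """
    if term not in result.term_names:
        raise KeyError(f"term {term!r} not in screen result {result.term_names}")
    universe = result.variables
    if not universe:
        raise DegenerateDataError("empty screening universe")
    hits = result.hit_sets()[term]
    tag_map = tag_variables(universe, dictionary)
    all_tags = sorted({t for ts in tag_map.values() for t in ts})
    N, n = len(universe), len(hits)
    rows = []
    for tag in all_tags:
        carriers = {v for v, ts in tag_map.items() if tag in ts}
        K = len(carriers)
        k = len(carriers & hits)
        rows.append({"tag": tag, "K": K, "k": k, "N": N, "n": n,
                     "p_enrich": hypergeom_upper_tail(N, K, n, k)})
    out = pd.DataFrame(rows, columns=["tag", "K", "k", "N", "n", "p_enrich"])
    return out.sort_values(["p_enrich", "tag"], kind="stable").reset_index(drop=True)
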