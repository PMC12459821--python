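"""Engine checks against independent oracles.

The brute-force oracle computes sequential sums of squares from explicit
least-squares fits of nested design matrices (numpy lstsq), a different
code path from the engine's incremental orthonormal projections.  Further
cross-checks: statsmodels Type-I ANOVA, pingouin's mixed ANOVA, and values
frozen from base R's aov on deterministic fixtures.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gaitscreen import DegenerateDataError, ModelSpec, fit_anova_one
from gaitscreen.anova import anova_decompose, parse_terms


# ------------------------------------------------------------------ oracle

def _full_dummies(values):
    levels = sorted(set(values))
    return np.array([[float(v == lv) for lv in levels] for v in values])


def oracle_sequential_ss(df, y, terms):
    """Sequential SS via nested lstsq fits; returns [(term, ss, df), ...]."""
    n = len(df)
    X = np.ones((n, 1))
    rss_prev = float(np.sum((y - y.mean()) ** 2))
    rank_prev = 1
    out = []
    for term in terms:
        block = None
        for f in term:
            d = _full_dummies(df[f])
            block = d if block is None else np.hstack(
                [block[:, [i]] * d for i in range(block.shape[1])])
        X = np.hstack([X, block])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        out.append((term, rss_prev - rss, rank - rank_prev))
        rss_prev, rank_prev = rss, rank
    return out, rss_prev, n - rank_prev


def _random_balanced_2x2(rng, n_cell=5, m=1):
    rows = []
    for a in "pq":
        for b in "uv":
            for _ in range(n_cell):
                rows.append((a, b))
    df = pd.DataFrame(rows, columns=["A", "B"])
    y = rng.normal(size=(len(df), m))
    return df, y


def test_engine_matches_projection_oracle_on_random_designs():
    """Engine F and p equal the nested-lstsq oracle on balanced 2x2 designs."""
    rng = np.random.default_rng(42)
    terms = parse_terms("A*B")
    for _ in range(20):
        df, y = _random_balanced_2x2(rng)
        dec = anova_decompose(df, y[:, 0], terms)
        oracle, rss, dfe = oracle_sequential_ss(df, y[:, 0], terms)
        tab = dec.f_table().set_index("term")
        for term, ss, df1 in oracle:
            f_expected = (ss / df1) / (rss / dfe)
            name = ":".join(term)
            assert tab.loc[name, "F"] == pytest.approx(f_expected, abs=1e-8)
            assert tab.loc[name, "p"] == pytest.approx(
                stats.f.sf(f_expected, df1, dfe), abs=1e-10)


def test_f_equals_squared_t_on_two_groups():
    """One between factor, two balanced groups: F = t^2 exactly."""
    rng = np.random.default_rng(1)
    for _ in range(25):
        y = rng.normal(size=16)
        df = pd.DataFrame({"g": ["a"] * 8 + ["b"] * 8})
        dec = anova_decompose(df, y, [("g",)])
        t, p_t = stats.ttest_ind(y[:8], y[8:])
        tab = dec.f_table()
        assert tab.loc[0, "F"] == pytest.approx(t**2, abs=1e-10)
        assert tab.loc[0, "p"] == pytest.approx(p_t, abs=1e-12)


def test_p_is_upper_tail_of_f_distribution():
    rng = np.random.default_rng(2)
    df = pd.DataFrame({"g": list("aabbcc")})
    dec = anova_decompose(df, rng.normal(size=6), [("g",)])
    tab = dec.f_table()
    assert tab.loc[0, "p"] == pytest.approx(
        stats.f.sf(tab.loc[0, "F"], tab.loc[0, "df1"], tab.loc[0, "df2"]))


def test_engine_matches_statsmodels_type1_unbalanced():
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    rng = np.random.default_rng(3)
    rows = []
    for a in range(2):
        for b in range(3):
            for _ in range(int(rng.integers(2, 6))):
                rows.append((f"a{a}", f"b{b}", rng.normal()))
    df = pd.DataFrame(rows, columns=["A", "B", "y"])
    dec = anova_decompose(df, df["y"].to_numpy(), parse_terms("A*B"))
    mine = dec.f_table().set_index("term")
    ref = anova_lm(smf.ols("y ~ C(A)*C(B)", df).fit(), typ=1)
    for term, rname in [("A", "C(A)"), ("B", "C(B)"), ("A:B", "C(A):C(B)")]:
        assert mine.loc[term, "F"] == pytest.approx(ref.loc[rname, "F"], rel=1e-9)
        assert mine.loc[term, "p"] == pytest.approx(ref.loc[rname, "PR(>F)"], abs=1e-12)


def test_mixed_design_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(4)
    rows = []
    for g in "AB":
        for s in range(6):
            for t in ["t1", "t2", "t3"]:
                rows.append((f"{g}{s}", g, t, rng.normal()))
    df = pd.DataFrame(rows, columns=["animal_id", "group", "timepoint", "y"])
    dec = anova_decompose(df, df["y"].to_numpy(), parse_terms("group*timepoint"),
                          within_factor="timepoint")
    mine = dec.f_table().set_index("term")
    ref = pg.mixed_anova(data=df, dv="y", within="timepoint", between="group",
                         subject="animal_id").set_index("Source")
    for term, rname in [("group", "group"), ("timepoint", "timepoint"),
                        ("group:timepoint", "Interaction")]:
        assert mine.loc[term, "F"] == pytest.approx(ref.loc[rname, "F"], rel=1e-8)
        assert mine.loc[term, "p"] == pytest.approx(ref.loc[rname, "p_unc"], abs=1e-10)


class TestFrozenAovReferences:
    """Deterministic fixtures with F/p values frozen from base R's aov."""

    def _rm_fixture(self):
        rng = np.random.default_rng(11)
        rows = []
        for gi, g in enumerate("AB"):
            for s in range(4):
                for ti, t in enumerate(["t1", "t2", "t3"]):
                    rows.append((f"{g}{s}", g, t,
                                 float(rng.integers(0, 20)) + gi * 3 + ti))
        return pd.DataFrame(rows, columns=["animal_id", "group", "timepoint", "y"])

    def test_repeated_measures_strata(self):
        df = self._rm_fixture()
        dec = anova_decompose(df, df["y"].to_numpy(),
                              parse_terms("group*timepoint"),
                              within_factor="timepoint")
        tab = dec.f_table().set_index("term")
        # aov(y ~ group*timepoint + Error(animal_id)):
        #   group      F=3.77352  p=0.10009   (subject stratum, df 1,6)
        #   timepoint  F=5.40000  p=0.021256  (within stratum, df 2,12)
        #   group:time F=0.11351  p=0.893639
        assert tab.loc["group", ["df1", "df2"]].tolist() == [1, 6]
        assert tab.loc["group", "F"] == pytest.approx(3.77352, abs=2e-5)
        assert tab.loc["group", "p"] == pytest.approx(0.10009, abs=1e-5)
        assert tab.loc["timepoint", ["df1", "df2"]].tolist() == [2, 12]
        assert tab.loc["timepoint", "F"] == pytest.approx(5.40000, abs=2e-5)
        assert tab.loc["timepoint", "p"] == pytest.approx(0.021256, abs=1e-5)
        assert tab.loc["group:timepoint", "F"] == pytest.approx(0.11351, abs=2e-5)
        assert tab.loc["group:timepoint", "p"] == pytest.approx(0.893639, abs=1e-5)

    def _bw_fixture(self):
        rng = np.random.default_rng(11)
        rng.integers(0, 20, size=24)  # skip the RM fixture's draws
        rows = []
        sizes = {"px": 3, "py": 4, "pz": 2, "qx": 5, "qy": 3, "qz": 4}
        for a in "pq":
            for b in "xyz":
                for _ in range(sizes[a + b]):
                    rows.append((a, b, float(rng.integers(0, 30))))
        return pd.DataFrame(rows, columns=["A", "B", "y"])

    def test_sequential_ss_entry_order_matches_aov(self):
        df = self._bw_fixture()
        # aov(y ~ A*B): A F=0.53754 p=0.47476; B F=1.17502 p=0.33568;
        #               A:B F=1.27001 p=0.30936
        dec = anova_decompose(df, df["y"].to_numpy(), parse_terms("A*B"))
        tab = dec.f_table().set_index("term")
        assert tab.loc["A", "F"] == pytest.approx(0.53754, abs=2e-5)
        assert tab.loc["B", "F"] == pytest.approx(1.17502, abs=2e-5)
        assert tab.loc["A:B", "F"] == pytest.approx(1.27001, abs=2e-5)
        assert tab.loc["A", "p"] == pytest.approx(0.47476, abs=1e-5)
        # reversed entry order changes the sequential main-effect SS
        # aov(y ~ B*A): B F=1.13695; A F=0.61367
        dec2 = anova_decompose(df, df["y"].to_numpy(), parse_terms("B*A"))
        tab2 = dec2.f_table().set_index("term")
        assert tab2.loc["B", "F"] == pytest.approx(1.13695, abs=2e-5)
        assert tab2.loc["A", "F"] == pytest.approx(0.61367, abs=2e-5)


def test_balanced_design_is_order_invariant():
    """On balanced designs sequential SS coincide across entry orders."""
    rng = np.random.default_rng(9)
    df, y = _random_balanced_2x2(rng, n_cell=4)
    t1 = anova_decompose(df, y[:, 0], parse_terms("A*B")).f_table().set_index("term")
    t2 = anova_decompose(df, y[:, 0], parse_terms("B*A")).f_table().set_index("term")
    assert t1.loc["A", "F"] == pytest.approx(t2.loc["A", "F"], rel=1e-10)
    assert t1.loc["B", "F"] == pytest.approx(t2.loc["B", "F"], rel=1e-10)


def test_batched_responses_equal_individual_fits():
    rng = np.random.default_rng(10)
    df, Y = _random_balanced_2x2(rng, m=7)
    terms = parse_terms("A*B")
    batched = anova_decompose(df, Y, terms).f_table()
    for j in range(7):
        single = anova_decompose(df, Y[:, j], terms).f_table()
        got = batched[batched["response"] == j].reset_index(drop=True)
        pd.testing.assert_frame_equal(
            got.drop(columns="response").reset_index(drop=True),
            single.drop(columns="response"))


def test_degenerate_single_level_factor_raises():
    df = pd.DataFrame({"g": ["a"] * 6})
    with pytest.raises(DegenerateDataError):
        anova_decompose(df, np.arange(6.0), [("g",)])


def test_no_residual_df_raises():
    df = pd.DataFrame({"g": ["a", "b"]})
    with pytest.raises(DegenerateDataError):
        anova_decompose(df, np.array([1.0, 2.0]), [("g",)])


def test_fit_anova_one_drops_missing_casewise():
    rng = np.random.default_rng(12)
    rec = pd.DataFrame({
        "animal_id": [f"s{i}" for i in range(12)],
        "group": ["a"] * 6 + ["b"] * 6,
        "value": rng.normal(size=12),
    })
    rec.loc[0, "value"] = np.nan
    spec = ModelSpec(between_factors=("group",))
    tab = fit_anova_one(rec, spec)
    complete = rec.dropna(subset=["value"])
    ref = anova_decompose(complete, complete["value"].to_numpy(),
                          [("group",)]).f_table()
    assert tab.loc[0, "F"] == pytest.approx(ref.loc[0, "F"])
    assert tab.loc[0, "df2"] == 9  # 11 obs - 2 params


def test_greenhouse_geisser_correction():
    pg = pytest.importorskip("pingouin")
    from gaitscreen.screen import _gg_epsilon

    rng = np.random.default_rng(13)
    rows = []
    for g in "AB":
        for s in range(5):
            for t in ["t1", "t2", "t3", "t4"]:
                rows.append((f"{g}{s}", g, t, rng.normal()))
    rec = pd.DataFrame(rows, columns=["animal_id", "group", "timepoint", "value"])
    spec = ModelSpec(("group",), within_factor="timepoint", sphericity="gg")
    eps = _gg_epsilon(rec, spec, "value")
    assert 1 / 3 <= eps <= 1  # k = 4 levels -> lower bound 1/(k-1)
    plain = fit_anova_one(rec, ModelSpec(("group",), within_factor="timepoint"))
    gg = fit_anova_one(rec, spec)
    for term in ["timepoint", "group:timepoint"]:
        row = plain.set_index("term").loc[term]
        expected = stats.f.sf(row["F"], row["df1"] * eps, row["df2"] * eps)
        assert gg.set_index("term").loc[term, "p"] == pytest.approx(expected)
    # between-subject term untouched by the correction
    assert gg.set_index("term").loc["group", "p"] == pytest.approx(
        plain.set_index("term").loc["group", "p"])
    # with a single group, epsilon reduces to the classical estimate on the
    # subject x timepoint matrix (cross-checked against pingouin)
    one = rec[rec.group == "A"]
    eps1 = _gg_epsilon(one, ModelSpec((), within_factor="timepoint"), "value")
    piv = one.pivot(index="animal_id", columns="timepoint", values="value")
    assert eps1 == pytest.approx(float(pg.epsilon(piv, correction="gg")), abs=1e-10)
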