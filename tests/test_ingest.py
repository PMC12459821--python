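import numpy as np
import pandas as pd
import pytest

from gaitscreen import (DegenerateDataError, FormatError, IntegrityError,
                        StudyDataset, average_runs, drop_unusable_variables,
                        join_metadata, read_gait_export, read_lookup)

from conftest import make_lookup, make_study, make_table


def test_read_gait_export_round_trip(tmp_path):
    p = tmp_path / "pre.csv"
    p.write_text(
        "Animal,RF Stand,LF Stand,Cadence,Speed\n"
        "M01,1.5,2.0,10,0.5\n"
        "M02,1.6,2.1,11,0.6\n"
        "M03,1.7,2.2,12,0.7\n")
    t = read_gait_export(p, "pre")
    assert t.timepoint == "pre"
    assert t.animals == ["M01", "M02", "M03"]
    assert t.variables == ["RF Stand", "LF Stand", "Cadence", "Speed"]
    assert t.data.loc[1, "Cadence"] == 11


def test_read_gait_export_tab_delimited_autodetect(tmp_path):
    p = tmp_path / "pre.tsv"
    p.write_text("animal_id\tv1\tv2\nM01\t1\t2\nM02\t3\t4\n")
    t = read_gait_export(p, "pre")
    assert t.data.loc[0, "v1"] == 1


@pytest.mark.parametrize("sentinel", ["-", "NaN", "NA", ""])
def test_sentinel_strings_become_missing(tmp_path, sentinel):
    p = tmp_path / "x.csv"
    p.write_text(f"animal_id,v1,v2\nM01,{sentinel},2\nM02,1,3\n")
    t = read_gait_export(p, "pre")
    assert np.isnan(t.data.loc[0, "v1"])
    assert t.data.loc[1, "v1"] == 1


def test_missing_id_column_is_format_error(tmp_path):
    p = tmp_path / "x.csv"
    p.write_text("mouse,v1\nM01,1\n")
    with pytest.raises(FormatError):
        read_gait_export(p, "pre")


def test_duplicate_animals_is_integrity_error(tmp_path):
    p = tmp_path / "x.csv"
    p.write_text("animal_id,v1\nM01,1\nM01,2\n")
    with pytest.raises(IntegrityError, match="M01"):
        read_gait_export(p, "pre")


def test_variable_names_trimmed_but_internal_spaces_kept(tmp_path):
    p = tmp_path / "x.csv"
    p.write_text("animal_id, RF Stand Mean ,v2\nM01,1,2\n")
    t = read_gait_export(p, "pre")
    assert "RF Stand Mean" in t.variables


def test_average_runs_collapses_to_one_row_per_animal():
    runs = pd.DataFrame({"animal_id": ["M01", "M01", "M02"],
                         "v1": [1.0, 3.0, 5.0], "v2": [np.nan, 4.0, 6.0]})
    out = average_runs(runs)
    assert list(out["animal_id"]) == ["M01", "M02"]
    assert out.loc[0, "v1"] == 2.0
    assert out.loc[0, "v2"] == 4.0  # missing run value ignored


def test_join_metadata_attaches_group(two_timepoint_study):
    ds = two_timepoint_study
    assert set(ds.records["group"]) == {"ctrl", "trt"}
    assert ds.metadata_cols == ("group",)
    assert sorted(ds.timepoints) == ["post", "pre"]
    # 4 animals x 2 timepoints x 3 variables
    assert len(ds.records) == 24


def test_join_metadata_strict_names_missing_animal():
    t = make_table("pre", ["M01", "M07"], [[1.0], [2.0]])
    lookup = make_lookup(["M01"], ["ctrl"])
    with pytest.raises(IntegrityError, match="M07"):
        join_metadata([t], lookup)


def test_join_metadata_lenient_drops_and_logs():
    t = make_table("pre", ["M01", "M07"], [[1.0], [2.0]])
    lookup = make_lookup(["M01"], ["ctrl"])
    ds = join_metadata([t], lookup, strict=False)
    assert ds.animals == ["M01"]
    assert any("M07" in e["detail"] for e in ds.log)


def test_animal_present_at_one_timepoint_only():
    pre = make_table("pre", ["M01", "M02"], [[1.0], [2.0]])
    post = make_table("post", ["M01"], [[3.0]])
    ds = make_study([pre, post], make_lookup(["M01", "M02"], ["a", "b"]))
    m02 = ds.records[ds.records["animal_id"] == "M02"]
    assert set(m02["timepoint"]) == {"pre"}


def test_join_metadata_preserves_values_bitwise():
    vals = np.random.default_rng(0).lognormal(size=(3, 4))
    t = make_table("pre", ["a", "b", "c"], vals)
    ds = make_study([t], make_lookup(["a", "b", "c"], ["g1", "g1", "g2"]))
    got = ds.to_wide()[ds.variables].to_numpy()
    assert np.array_equal(got, vals)


def test_duplicate_lookup_ids_rejected():
    with pytest.raises(IntegrityError):
        make_lookup(["M01", "M01"], ["a", "b"])


class TestDropUnusable:
    def _study(self, values):
        t = make_table("pre", ["a", "b", "c"], values,
                       variables=["keep", "zero", "gone"])
        return make_study([t], make_lookup(["a", "b", "c"], ["g", "g", "h"]))

    def test_all_zero_removed_all_missing_removed(self):
        ds = self._study([[1.0, 0.0, np.nan],
                          [2.0, 0.0, np.nan],
                          [3.0, 0.0, np.nan]])
        out = drop_unusable_variables(ds)
        assert out.variables == ["keep"]
        reasons = {e["variable"]: e["detail"] for e in out.log
                   if e["action"] == "drop_variable"}
        assert "zero" in reasons["zero"] or "zero" in reasons  # logged
        assert set(reasons) == {"zero", "gone"}

    def test_not_all_zero_retained(self):
        ds = self._study([[1.0, 0.0, 1.0],
                          [2.0, 0.0, 1.0],
                          [3.0, 1.0, 1.0]])
        assert set(drop_unusable_variables(ds).variables) == {"keep", "zero", "gone"}

    def test_rule_applies_over_combined_dataset(self):
        # all-missing at one timepoint but observed at another -> retained
        pre = make_table("pre", ["a", "b"], [[np.nan], [np.nan]], ["v"])
        post = make_table("post", ["a", "b"], [[1.0], [2.0]], ["v"])
        ds = make_study([pre, post], make_lookup(["a", "b"], ["g", "h"]))
        out = drop_unusable_variables(ds)
        assert out.variables == ["v"]
        # whereas missing everywhere -> dropped
        pre2 = make_table("pre", ["a", "b"], [[np.nan, 1.0], [np.nan, 2.0]],
                          ["v", "w"])
        ds2 = make_study([pre2], make_lookup(["a", "b"], ["g", "h"]))
        assert drop_unusable_variables(ds2).variables == ["w"]

    def test_idempotent(self):
        ds = self._study([[1.0, 0.0, np.nan],
                          [2.0, 0.0, np.nan],
                          [3.0, 0.0, np.nan]])
        once = drop_unusable_variables(ds)
        twice = drop_unusable_variables(once)
        pd.testing.assert_frame_equal(once.records, twice.records)

    def test_dropped_plus_retained_equals_input(self):
        ds = self._study([[1.0, 0.0, np.nan],
                          [2.0, 0.0, np.nan],
                          [3.0, 0.0, np.nan]])
        out = drop_unusable_variables(ds)
        dropped = {e["variable"] for e in out.log if e["action"] == "drop_variable"}
        assert dropped | set(out.variables) == set(ds.variables)

    def test_all_variables_dropped_is_degenerate(self):
        t = make_table("pre", ["a", "b"], [[0.0], [0.0]], ["v"])
        ds = make_study([t], make_lookup(["a", "b"], ["g", "h"]))
        with pytest.raises(DegenerateDataError):
            drop_unusable_variables(ds)


def test_long_format_write_read_round_trip(tmp_path, two_timepoint_study):
    ds = two_timepoint_study
    p = tmp_path / "ds.tsv"
    ds.write(p)
    back = StudyDataset.read(p, ds.timepoints, ds.metadata_cols)
    pd.testing.assert_frame_equal(ds.records, back.records)


def test_read_lookup_and_exports_from_disk(tmp_path):
    (tmp_path / "lk.csv").write_text("id,group,sex\nM01,ctrl,F\nM02,trt,M\n")
    lk = read_lookup(tmp_path / "lk.csv")
    assert lk.metadata_cols == ("group", "sex")
    (tmp_path / "pre.csv").write_text("animal_id,v1\nM01,1\nM02,2\n")
    ds = join_metadata([read_gait_export(tmp_path / "pre.csv", "pre")], lk)
    assert set(ds.records["sex"]) == {"F", "M"}
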