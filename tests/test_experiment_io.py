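"""Control files, data files, trial minimums, parameter tables, outputs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fastdm import (ControlFileError, DataFileError, Dataset, ParameterSet,
                    TrialMinimumError, build_parameter_table,
                    check_trial_minimums, expand_wildcards,
                    parse_control_file, read_data_file)
from fastdm.experiment_io import (format_log_table, resolve_save_name)
from fastdm.optimizer import FitResult
from fastdm.fit_criteria import FitIndex

FACTORIAL_CTL = """
# model definition
method ml
precision 2.5
set d 0
set zr 0.5
set szr 0
set sv 0
depends v stimulus difficulty
format RESPONSE TIME stimulus difficulty
load data_*.dat
save parameters_*.dat
log all.log
"""


def factorial_dataset(n_per_cell=5):
    """2 x 2 design: stimulus in {0,1}, difficulty in {easy, hard}."""
    rows = []
    for stim in ("0", "1"):
        for diff in ("easy", "hard"):
            for i in range(n_per_cell):
                rows.append((i % 2, 0.4 + 0.01 * i, stim, diff))
    resp, rts, stim, diff = zip(*rows)
    return Dataset(np.array(resp), np.array(rts),
                   np.array([stim, diff], dtype=object).T,
                   labels=("stimulus", "difficulty"))


class TestControlFileParsing:
    def test_factorial_specification(self):
        spec = parse_control_file(FACTORIAL_CTL)
        assert spec.method == "ml"
        assert spec.precision == 2.5
        assert spec.fixed == {"d": 0.0, "zr": 0.5, "szr": 0.0, "sv": 0.0}
        assert spec.depends == {"v": ("stimulus", "difficulty")}
        assert spec.format == ("RESPONSE", "TIME", "stimulus", "difficulty")

    def test_defaults(self):
        spec = parse_control_file(
            "format RESPONSE TIME\nload a.dat\nlog out.log\n")
        assert spec.method == "ks"
        assert spec.precision == 3.0

    def test_empty_file_rejected(self):
        with pytest.raises(ControlFileError):
            parse_control_file("")

    def test_missing_load_rejected(self):
        with pytest.raises(ControlFileError, match="load"):
            parse_control_file("format RESPONSE TIME\nlog out.log\n")

    def test_missing_save_and_log_rejected(self):
        with pytest.raises(ControlFileError):
            parse_control_file("format RESPONSE TIME\nload a.dat\n")

    def test_depends_label_missing_from_format(self):
        with pytest.raises(ControlFileError, match="block"):
            parse_control_file(
                "depends t0 block\nformat RESPONSE TIME\n"
                "load a.dat\nlog out.log\n")

    def test_unknown_command(self):
        with pytest.raises(ControlFileError, match="frobnicate"):
            parse_control_file("frobnicate 3\nformat RESPONSE TIME\n"
                               "load a.dat\nlog out.log\n")

    def test_set_after_format_rejected(self):
        with pytest.raises(ControlFileError):
            parse_control_file("format RESPONSE TIME\nset d 0\n"
                               "load a.dat\nlog out.log\n")

    def test_param_both_set_and_depends(self):
        with pytest.raises(ControlFileError):
            parse_control_file("set v 1\ndepends v cond\n"
                               "format RESPONSE TIME cond\n"
                               "load a.dat\nlog out.log\n")

    def test_wildcard_load_needs_wildcard_save(self):
        with pytest.raises(ControlFileError, match="asterisk"):
            parse_control_file("format RESPONSE TIME\nload p_*.dat\n"
                               "save out.dat\n")

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(method=st.sampled_from(["ml", "ks", "cs"]),
           precision=st.floats(1.0, 6.0),
           fix_d=st.booleans(), fix_zr=st.booleans(),
           dep_v=st.booleans(), dep_t0=st.booleans())
    def test_round_trip(self, method, precision, fix_d, fix_zr, dep_v, dep_t0):
        lines = [f"method {method}", f"precision {precision!r}"]
        fixed = {}
        if fix_d:
            lines.append("set d 0")
            fixed["d"] = 0.0
        if fix_zr:
            lines.append("set zr 0.5")
            fixed["zr"] = 0.5
        depends = {}
        if dep_v:
            lines.append("depends v cond")
            depends["v"] = ("cond",)
        if dep_t0:
            lines.append("depends t0 cond")
            depends["t0"] = ("cond",)
        lines += ["format RESPONSE TIME cond", "load a.dat", "log out.log"]
        spec = parse_control_file("\n".join(lines))
        assert spec.method == method
        assert spec.precision == pytest.approx(precision)
        assert spec.fixed == fixed
        assert spec.depends == depends


class TestDataFiles:
    def test_four_column_file(self, tmp_path):
        path = tmp_path / "p1.dat"
        path.write_text("# a comment line\n"
                        "1 0.523 0 easy\n"
                        "0 0.961 1 hard\n"
                        "\n"
                        "1 0.410 0 easy\n")
        data = read_data_file(str(path),
                              ("RESPONSE", "TIME", "stimulus", "difficulty"))
        assert data.n == 3
        np.testing.assert_array_equal(data.responses, [1, 0, 1])
        assert data.rts[1] == pytest.approx(0.961)
        assert tuple(data.conditions[1]) == ("1", "hard")

    def test_comments_only_yields_empty_dataset(self, tmp_path):
        path = tmp_path / "empty.dat"
        path.write_text("# nothing\n# here\n")
        data = read_data_file(str(path), ("RESPONSE", "TIME"))
        assert data.n == 0

    def test_ignored_star_column(self, tmp_path):
        path = tmp_path / "star.dat"
        path.write_text("99 1 0.5\nxx 0 0.6\n")
        data = read_data_file(str(path), ("*", "RESPONSE", "TIME"))
        assert data.n == 2
        assert data.labels == ()

    def test_bad_response_named_with_line_number(self, tmp_path):
        path = tmp_path / "bad.dat"
        path.write_text("1 0.5\n2 0.6\n")
        with pytest.raises(DataFileError, match=":2"):
            read_data_file(str(path), ("RESPONSE", "TIME"))

    def test_non_numeric_time(self, tmp_path):
        path = tmp_path / "bad.dat"
        path.write_text("1 fast\n")
        with pytest.raises(DataFileError, match="TIME"):
            read_data_file(str(path), ("RESPONSE", "TIME"))

    def test_wrong_column_count(self, tmp_path):
        path = tmp_path / "bad.dat"
        path.write_text("1 0.5 extra\n")
        with pytest.raises(DataFileError, match="columns"):
            read_data_file(str(path), ("RESPONSE", "TIME"))

    def test_whitespace_dialects_equivalent(self, tmp_path):
        a = tmp_path / "tabs.dat"
        a.write_text("1\t0.5\t x\n0\t\t0.6\ty\n")
        b = tmp_path / "blanks.dat"
        b.write_text("1 0.5    x\n0   0.6 y\n")
        da = read_data_file(str(a), ("RESPONSE", "TIME", "cond"))
        db = read_data_file(str(b), ("RESPONSE", "TIME", "cond"))
        np.testing.assert_array_equal(da.responses, db.responses)
        np.testing.assert_array_equal(da.rts, db.rts)
        assert [tuple(r) for r in da.conditions] == \
            [tuple(r) for r in db.conditions]


class TestWildcards:
    def test_expansion_is_ordered(self, tmp_path, monkeypatch):
        for name in ("participant_2.dat", "participant_1.dat"):
            (tmp_path / name).write_text("")
        monkeypatch.chdir(tmp_path)
        assert expand_wildcards("participant_*.dat") == \
            ["participant_1.dat", "participant_2.dat"]

    def test_literal_name(self, tmp_path, monkeypatch):
        (tmp_path / "one.dat").write_text("")
        monkeypatch.chdir(tmp_path)
        assert expand_wildcards("one.dat") == ["one.dat"]

    def test_no_match_is_error(self, tmp_path, monkeypatch):
        monkeypatch.chdir(tmp_path)
        with pytest.raises(DataFileError):
            expand_wildcards("nothing_*.dat")

    def test_save_name_substitution(self):
        assert resolve_save_name("out_*.dat", "p_*.dat", "p_7.dat") == "out_7.dat"
        assert resolve_save_name("out.dat", "p.dat", "p.dat") == "out.dat"


class TestTrialMinimums:
    def test_nine_trials_abort_for_ks(self):
        data = Dataset(np.ones(9, int), np.linspace(0.3, 0.9, 9))
        with pytest.raises(TrialMinimumError):
            check_trial_minimums(data, "ks")
        check_trial_minimums(Dataset(np.ones(10, int),
                                     np.linspace(0.3, 0.9, 10)), "ks")

    def test_even_split_of_twenty_aborts_for_cs(self):
        data = Dataset(np.tile([0, 1], 10), np.linspace(0.3, 1.0, 20))
        with pytest.raises(TrialMinimumError):
            check_trial_minimums(data, "cs")

    def test_twelve_same_response_ok_for_cs(self):
        data = Dataset(np.ones(12, int), np.linspace(0.3, 0.9, 12))
        check_trial_minimums(data, "cs")

    def test_per_condition_check(self):
        # one condition rich, the other starved
        resp = np.concatenate([np.ones(20, int), np.ones(5, int)])
        rts = np.linspace(0.3, 1.2, 25)
        cond = np.array([["A"]] * 20 + [["B"]] * 5, dtype=object)
        data = Dataset(resp, rts, cond, labels=("c",))
        with pytest.raises(TrialMinimumError, match="B"):
            check_trial_minimums(data, "ml", ("c",))


class TestParameterTable:
    def test_factorial_design_has_seven_free_parameters(self):
        spec = parse_control_file(FACTORIAL_CTL)
        table = build_parameter_table(spec, factorial_dataset())
        v_slots = [s for s in table.slots if s.param == "v"]
        assert len(v_slots) == 4
        assert table.n_free == 7  # 4 drifts + shared a, t0, st0

    def test_no_depends_single_cell(self):
        spec = parse_control_file("set d 0\nformat RESPONSE TIME\n"
                                  "load a.dat\nlog out.log\n")
        table = build_parameter_table(
            spec, Dataset(np.array([1]), np.array([0.5])))
        assert table.cells == [()]
        assert table.n_free == 7  # 8 parameters - 1 fixed

    def test_three_level_depends_adds_two_slots(self):
        spec = parse_control_file("depends v cond\nformat RESPONSE TIME cond\n"
                                  "load a.dat\nlog out.log\n")
        cond = np.array([["lo"], ["mid"], ["hi"]], dtype=object)
        data = Dataset(np.array([1, 0, 1]), np.array([0.5, 0.6, 0.7]),
                       cond, labels=("cond",))
        table = build_parameter_table(spec, data)
        assert table.n_free == 8 + 2

    def test_expand_resolves_every_cell(self):
        spec = parse_control_file(FACTORIAL_CTL)
        table = build_parameter_table(spec, factorial_dataset())
        x = np.arange(1.0, table.n_free + 1)
        cells = table.expand(x)
        assert len(cells) == 4
        for cell, p in cells.items():
            assert isinstance(p, ParameterSet)
            assert p.d == 0.0 and p.zr == 0.5
        # drift slots differ between cells, shared slots do not
        drifts = {p.v for p in cells.values()}
        assert len(drifts) == 4
        assert len({p.a for p in cells.values()}) == 1


class TestOutputs:
    def _result(self, name, slots, fitval):
        return FitResult(
            dataset=name, method="ml", precision=3.0,
            estimates={s: 0.5 for s in slots}, params_by_cell={},
            fit_index=FitIndex("ml", fitval), run_values=[fitval] * 3,
            penalized=False, penalty=0.0, n_free=len(slots), n_eval=100)

    def test_log_table_shape(self):
        spec = parse_control_file(FACTORIAL_CTL)
        slots = ["a", "v_0_easy", "v_0_hard", "v_1_easy", "v_1_hard",
                 "t0", "st0"]
        results = [self._result(f"p{i}.dat", slots, 10.0 + i) for i in range(3)]
        text = format_log_table(results, spec)
        lines = text.strip().split("\n")
        assert len(lines) == 4  # header + 3 datasets
        header = lines[0].split("\t")
        assert header == ["dataset"] + slots + ["fit", "penalized"]
        for line in lines[1:]:
            assert len(line.split("\t")) == len(header)

    def test_depends_columns_indexed_by_level(self):
        spec = parse_control_file(
            "depends v stimulus\nformat RESPONSE TIME stimulus\n"
            "load a.dat\nlog out.log\n")
        cond = np.array([["0"], ["1"]], dtype=object)
        data = Dataset(np.array([1, 0]), np.array([0.5, 0.6]), cond,
                       labels=("stimulus",))
        table = build_parameter_table(spec, data)
        assert "v_0" in table.slot_names and "v_1" in table.slot_names

    def test_penalized_result_reports_penalty(self):
        spec = parse_control_file("format RESPONSE TIME\nload a.dat\nlog o.log\n")
        res = FitResult(
            dataset="p.dat", method="ks", precision=3.0,
            estimates={"a": 1.0}, params_by_cell={},
            fit_index=FitIndex("ks", float("nan"), penalized=True, penalty=2.5),
            run_values=[2.5] * 3, penalized=True, penalty=2.5,
            n_free=1, n_eval=10)
        text = format_log_table([res], spec)
        row = text.strip().split("\n")[1].split("\t")
        assert row[-1] == "1"
        assert row[-2] == "2.5"
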