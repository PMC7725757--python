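"""Statistics tests: long-table shaping, the test matrix, arity policing,
CSV export, power under an injected effect and type-I error under the null."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from gazekit.experiment import ExperimentConfig
from gazekit.parameters import PARAMETER_NAMES, ParameterSet
from gazekit.stats import build_long_table, export_parameters_csv, run_statistical_test


def make_config(subjects_by_group, stimuli_by_group):
    return ExperimentConfig(
        name="t",
        subjects={
            g: {s: {"Age": 25, "Eyesight": "normal"} for s in subs}
            for g, subs in subjects_by_group.items()
        },
        stimuli=stimuli_by_group,
        control=[],
        sampling_freq=1000.0,
        screen=(1280, 1024),
    )


def make_sets(subjects_by_group, stimuli_by_group, value_fn):
    sets = []
    for g, subs in subjects_by_group.items():
        for s in subs:
            for tg, stims in stimuli_by_group.items():
                for stim in stims:
                    v = value_fn(g, s, tg, stim)
                    sets.append(
                        ParameterSet(
                            subject=s,
                            stimulus=stim,
                            **{n: v for n in PARAMETER_NAMES},
                        )
                    )
    return sets


SUBJ = {"g1": ["s1", "s2", "s3"], "g2": ["s4", "s5", "s6"]}
STIM = {"ta": ["a1", "a2", "a3"], "tb": ["b1", "b2", "b3"]}


class TestLongTable:
    def test_row_count_all_parameters(self):
        cfg = make_config(SUBJ, STIM)
        sets = make_sets(SUBJ, STIM, lambda *a: 1.0)
        table = build_long_table(sets, cfg)
        assert len(table) == 6 * 6 * 21

    def test_single_parameter_restriction(self):
        cfg = make_config(SUBJ, STIM)
        sets = make_sets(SUBJ, STIM, lambda *a: 1.0)
        table = build_long_table(sets, cfg, ["saccade_count"])
        assert len(table) == 36
        assert set(table["parameter"]) == {"saccade_count"}

    def test_factor_columns_match_config(self):
        cfg = make_config(SUBJ, STIM)
        sets = make_sets(SUBJ, STIM, lambda *a: 1.0)
        table = build_long_table(sets, cfg, ["pupil_mean"])
        assert set(table["subject_group"]) == {"g1", "g2"}
        assert set(table["stimulus_group"]) == {"ta", "tb"}
        assert (table.loc[table.subject == "s4", "subject_group"] == "g2").all()
        assert "Age" in table.columns

    def test_unknown_parameter_lists_valid_names(self):
        cfg = make_config(SUBJ, STIM)
        sets = make_sets(SUBJ, STIM, lambda *a: 1.0)
        with pytest.raises(ValueError, match="pupil_mean"):
            build_long_table(sets, cfg, ["bogus"])


class TestTestMatrix:
    @staticmethod
    def table_from_values(values_by_group):
        rows = []
        for g, vals in values_by_group.items():
            for i, v in enumerate(vals):
                rows.append(
                    {
                        "subject": f"{g}_s{i}",
                        "subject_group": g,
                        "stimulus": "x",
                        "stimulus_group": "t",
                        "parameter": "pupil_mean",
                        "value": v,
                    }
                )
        return pd.DataFrame(rows)

    def test_welch_hand_computed(self):
        table = self.table_from_values({"g1": [1.0, 2, 3], "g2": [4.0, 5, 6]})
        res = run_statistical_test(table, "welch_t", between=["subject_group"])
        assert res.loc[0, "statistic"] == pytest.approx(-3.674, abs=0.001)
        assert res.loc[0, "df"] == pytest.approx(4.0, abs=0.01)

    def test_identical_groups_null(self):
        table = self.table_from_values({"g1": [1.0, 2, 3], "g2": [1.001, 2, 3]})
        res = run_statistical_test(table, "welch_t", between=["subject_group"])
        assert abs(res.loc[0, "statistic"]) < 0.01
        assert res.loc[0, "p"] > 0.9

    def test_zero_variance_cell_skipped_with_warning(self):
        table = self.table_from_values({"g1": [2.0, 2.0, 2.0], "g2": [4.0, 5, 6]})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = run_statistical_test(table, "welch_t", between=["subject_group"])
        assert res.empty

    @pytest.mark.parametrize(
        "test,between,within",
        [
            ("mixed_anova", ["a", "b"], ["w"]),
            ("rm_anova", ["a"], ["w"]),
            ("rm_anova", [], ["w1", "w2", "w3"]),
            ("welch_t", ["a", "b"], []),
            ("nway_anova", ["a"], ["w"]),
        ],
    )
    def test_arity_violations_rejected(self, test, between, within):
        table = self.table_from_values({"g1": [1.0, 2], "g2": [3.0, 4]})
        with pytest.raises(ValueError):
            run_statistical_test(table, test, between=between, within=within)

    def test_mixed_anova_on_full_design(self):
        cfg = make_config(SUBJ, STIM)
        rng = np.random.default_rng(0)
        sets = make_sets(
            SUBJ, STIM, lambda g, s, tg, stim: rng.normal(5.0 if g == "g2" else 0.0)
        )
        table = build_long_table(sets, cfg, ["pupil_mean"])
        res = run_statistical_test(
            table, "mixed_anova", between=["subject_group"], within=["stimulus_group"]
        )
        row = res[res["effect"] == "subject_group"].iloc[0]
        assert row["p"] < 0.05

    def test_results_written_to_csv(self, tmp_path):
        table = self.table_from_values({"g1": [1.0, 2, 3], "g2": [4.0, 5, 6]})
        run_statistical_test(
            table, "welch_t", between=["subject_group"], out_dir=tmp_path
        )
        out = pd.read_csv(tmp_path / "welch_t_results.csv")
        assert list(out.columns) == ["parameter", "effect", "df", "statistic", "p"]


class TestSimulationCalibration:
    def test_injected_group_effect_detected_in_most_replicates(self):
        # 3-SD between-group shift, 6 subjects per group, 2 within levels
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            rows = []
            for g, delta in (("g1", 0.0), ("g2", 3.0)):
                for i in range(6):
                    subj_effect = rng.normal(0, 0.5)
                    for w in ("ta", "tb"):
                        rows.append(
                            {
                                "subject": f"{g}_s{i}",
                                "subject_group": g,
                                "stimulus": w,
                                "stimulus_group": w,
                                "parameter": "pupil_mean",
                                "value": delta + subj_effect + rng.normal(0, 1.0),
                            }
                        )
            res = run_statistical_test(
                pd.DataFrame(rows),
                "mixed_anova",
                between=["subject_group"],
                within=["stimulus_group"],
            )
            if res[res["effect"] == "subject_group"].iloc[0]["p"] < 0.05:
                hits += 1
        assert hits >= 95

    def test_type_i_error_near_alpha_under_null(self):
        # 500 seeded replicates per test; binomial test must not reject 0.05
        n_rep = 500
        rejections = {"welch_t": 0, "mixed_anova": 0}
        for rep in range(n_rep):
            rng = np.random.default_rng(5000 + rep)
            rows = []
            for g in ("g1", "g2"):
                for i in range(6):
                    subj_effect = rng.normal(0, 0.5)
                    for w in ("ta", "tb"):
                        rows.append(
                            {
                                "subject": f"{g}_s{i}",
                                "subject_group": g,
                                "stimulus": w,
                                "stimulus_group": w,
                                "parameter": "pupil_mean",
                                "value": subj_effect + rng.normal(0, 1.0),
                            }
                        )
            table = pd.DataFrame(rows)
            res = run_statistical_test(table, "welch_t", between=["subject_group"])
            if res.iloc[0]["p"] < 0.05:
                rejections["welch_t"] += 1
            res = run_statistical_test(
                table,
                "mixed_anova",
                between=["subject_group"],
                within=["stimulus_group"],
            )
            if res[res["effect"] == "subject_group"].iloc[0]["p"] < 0.05:
                rejections["mixed_anova"] += 1
        for test, k in rejections.items():
            assert binomtest(k, n_rep, 0.05).pvalue > 0.01, (test, k / n_rep)


class TestExport:
    def test_rows_and_round_trip(self, tmp_path):
        sets = make_sets(SUBJ, STIM, lambda g, s, tg, stim: hash((s, stim)) % 97 / 7)
        path = export_parameters_csv(sets, tmp_path / "params.csv")
        back = pd.read_csv(path)
        assert len(back) == 36
        assert list(back.columns) == ["subject", "stimulus"] + PARAMETER_NAMES
        lookup = {(r.subject, r.stimulus): r.pupil_mean for r in back.itertuples()}
        for s in sets:
            assert lookup[(s.subject, s.stimulus)] == pytest.approx(s.pupil_mean)

    def test_empty_set_header_only(self, tmp_path):
        with pytest.warns(UserWarning):
            path = export_parameters_csv([], tmp_path / "params.csv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("subject,stimulus,pupil_mean")
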