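"""Schema, I/O, worst-case recoding and per-day summaries."""

from __future__ import annotations

import pytest

import acceptmap as am
from acceptmap.schema import time_band

from conftest import TABLE2_N


def make_obs(pid="P01", day="D1", **kw) -> am.RawObservation:
    reported = {
        "result_intake": "fully_taken",
        "reaction": "positive",
        "prep_admin_time": "medium",
        **{m: "not_used" for m in
           ("divided_dose", "food_drink", "alteration", "extra_device", "reward", "restraint")},
    }
    reported.update(kw.pop("reported", {}))
    return am.RawObservation(pid, day, reported, **kw)


class TestCodebook:
    def test_default_dimensions(self, codebook):
        assert len(codebook.variables) == 9
        assert codebook.n_categories == 21
        assert len(codebook.positive_categories()) == 9

    def test_worst_of_prefers_less_acceptable(self, codebook):
        assert codebook.worst_of("result_intake", ["fully_taken", "not_taken"]) == "not_taken"
        assert codebook.worst_of("food_drink", ["used", "not_used"]) == "used"


class TestReadWrite:
    def test_round_trip_cell_for_cell(self, tmp_path, study_dataset):
        path = tmp_path / "study.csv"
        am.write_study(study_dataset.raw_observations, study_dataset.patients, path)
        observations, patients = am.read_study(path)
        assert observations == study_dataset.raw_observations
        assert patients == study_dataset.patients

    def test_evaluations_round_trip_preserves_missing(self, tmp_path, table2_evaluations):
        path = tmp_path / "evals.csv"
        am.write_evaluations(table2_evaluations, path)
        assert am.read_evaluations(path) == table2_evaluations

    def test_unknown_category_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,day,result_intake\nP01,D1,swallowed\n")
        with pytest.raises(am.SchemaError, match="swallowed"):
            am.read_study(path)

    def test_duplicate_patient_day_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("patient_id,day,result_intake\nP01,D1,fully_taken\nP01,D1,not_taken\n")
        with pytest.raises(am.IntegrityError):
            am.read_study(path)

    def test_header_only_file_yields_empty_lists(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("patient_id,day,result_intake\n")
        observations, patients = am.read_study(path)
        assert observations == [] and patients == []


class TestWorstCaseRecoding:
    def test_fast_administration_downgrades_full_intake(self):
        # reported fully taken but administered in <60 s: cannot have been
        # kept under the tongue long enough
        obs = make_obs(admin_time_seconds=45.0, reported={"prep_admin_time": None})
        evaluations, log = am.apply_worst_case_recoding([obs])
        assert evaluations[0].measures["result_intake"] == "partly_taken"
        assert len(log.entries) == 1 and log.entries[0].rule_id == "R3"

    def test_very_fast_partial_intake_implies_alteration(self):
        obs = make_obs(
            reported={"result_intake": "partly_taken", "prep_admin_time": None},
            admin_time_seconds=20.0,
        )
        evaluations, log = am.apply_worst_case_recoding([obs])
        assert evaluations[0].measures["alteration"] == "used"
        assert [e.rule_id for e in log.entries] == ["R4"]

    def test_tablet_gone_at_one_minute(self):
        obs = make_obs(under_tongue_1min=False)
        evaluations, log = am.apply_worst_case_recoding([obs])
        assert evaluations[0].measures["result_intake"] == "partly_taken"
        assert [e.rule_id for e in log.entries] == ["R1"]

    def test_tablet_gone_at_thirty_seconds_means_swallowed(self):
        obs = make_obs(under_tongue_30s=False, under_tongue_1min=False)
        evaluations, log = am.apply_worst_case_recoding([obs])
        assert evaluations[0].measures["alteration"] == "used"
        assert {e.rule_id for e in log.entries} == {"R1", "R2"}

    def test_keyword_in_text_field_ticks_method(self):
        obs = make_obs(method_texts={"other": "Drank some Water after intake"})
        evaluations, log = am.apply_worst_case_recoding([obs])
        assert evaluations[0].measures["food_drink"] == "used"
        assert [e.rule_id for e in log.entries] == ["R5"]

    def test_seconds_override_reported_time_category(self):
        obs = make_obs(admin_time_seconds=200.0)  # reported medium
        evaluations, log = am.apply_worst_case_recoding([obs])
        assert evaluations[0].measures["prep_admin_time"] == "long"
        assert [e.rule_id for e in log.entries] == ["R6"]

    def test_seconds_never_fill_missing_time(self):
        obs = make_obs(admin_time_seconds=100.0, reported={"prep_admin_time": None})
        evaluations, log = am.apply_worst_case_recoding([obs])
        assert evaluations[0].measures["prep_admin_time"] is None
        assert log.entries == []

    def test_compliant_record_untouched(self):
        obs = make_obs(under_tongue_30s=True, under_tongue_1min=True,
                       admin_time_seconds=90.0)
        evaluations, log = am.apply_worst_case_recoding([obs])
        assert evaluations[0].measures == obs.reported
        assert log.entries == [] and log.n_cells_total == 9

    def test_contradictory_raw_fields_warn_but_apply_worst_case(self):
        obs = make_obs(under_tongue_1min=True, admin_time_seconds=25.0,
                       reported={"result_intake": "partly_taken", "prep_admin_time": None})
        with pytest.warns(UserWarning, match="worst case"):
            evaluations, _ = am.apply_worst_case_recoding([obs])
        assert evaluations[0].measures["alteration"] == "used"

    def test_recoding_is_idempotent(self, study_dataset):
        once, log1 = am.apply_worst_case_recoding(study_dataset.raw_observations)
        # feed the recoded categories back in with the same raw fields
        again = [
            am.RawObservation(o.patient_id, o.day, dict(e.measures),
                              o.under_tongue_30s, o.under_tongue_1min,
                              o.admin_time_seconds, o.method_texts)
            for o, e in zip(study_dataset.raw_observations, once)
        ]
        twice, log2 = am.apply_worst_case_recoding(again)
        assert [e.measures for e in twice] == [e.measures for e in once]
        assert log2.entries == []

    def test_recoding_never_improves_result_or_methods(self, codebook, study_dataset):
        evaluations, _ = am.apply_worst_case_recoding(study_dataset.raw_observations)
        for obs, ev in zip(study_dataset.raw_observations, evaluations):
            for var in ("result_intake", *am.schema.METHOD_VARIABLES):
                old, new = obs.reported.get(var), ev.measures[var]
                if old is None or old == new:
                    continue
                order = codebook.acceptability_order[var]
                assert order.index(new) > order.index(old)

    def test_recoded_fraction_reproducible_from_entries(self, study_dataset):
        _, log = am.apply_worst_case_recoding(study_dataset.raw_observations)
        assert log.n_cells_total == 9 * len(study_dataset.raw_observations)
        assert log.recoded_fraction == len(log.entries) / log.n_cells_total


@pytest.mark.parametrize(
    "seconds, band",
    [(30, "short"), (60, "short"), (61, "medium"), (150, "medium"), (151, "long")],
)
def test_time_bands_closed_on_the_better_side(seconds, band):
    assert time_band(seconds) == band


class TestSummarizeByDay:
    def test_counts_match_published_table(self, table2_evaluations):
        summary = am.summarize_by_day(table2_evaluations)
        assert list(summary.counts.xs("reaction", level="variable")["D10"]) == [15, 15, 2]
        assert summary.missing.loc["reaction", "D10"] == 3
        assert summary.missing.loc["prep_admin_time", "D2"] == 3
        assert dict(summary.n_by_day()) == TABLE2_N

    def test_percentages_use_nonmissing_denominator(self, table2_evaluations):
        summary = am.summarize_by_day(table2_evaluations)
        neutral_or_positive = (
            summary.percent.loc[("reaction", "positive"), "D10"]
            + summary.percent.loc[("reaction", "neutral"), "D10"]
        )
        assert round(neutral_or_positive) == 94  # 30 of 32 non-missing
        assert round(summary.percent.loc[("reaction", "negative"), "D1"]) == 30

    def test_single_evaluation(self, codebook):
        ev = am.Evaluation("P01", "D1", {v: codebook.categories[v][0] for v in codebook.variables})
        summary = am.summarize_by_day([ev])
        assert summary.counts["D1"].sum() == 9
        assert (summary.missing == 0).all().all()
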