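"""Discretization of continuous-time follow-up into person-period format."""

import datetime

import numpy as np
import pandas as pd
import pytest

import ccistate as cs
from ccistate.cohort import iter_person_steps

D0 = datetime.date(2010, 1, 1)


def subj(sid="A", events=(), end=60, status="censored", treatment="AS", cci0=0, **kw):
    return cs.SubjectRecord(
        subject_id=sid,
        treatment=treatment,
        entry_date=D0,
        age_at_entry=65.0,
        baseline_cci=cci0,
        cci_events=tuple((D0 + datetime.timedelta(days=d), w) for d, w in events),
        end_date=D0 + datetime.timedelta(days=end),
        end_status=status,
        **kw,
    )


class TestSubjectRecord:
    def test_rejects_bad_weight(self):
        with pytest.raises(ValueError, match="weight"):
            subj(events=[(5, 4)])

    def test_rejects_event_outside_window(self):
        with pytest.raises(ValueError, match="outside follow-up"):
            subj(events=[(70, 1)], end=60)

    def test_rejects_unknown_treatment(self):
        with pytest.raises(ValueError, match="treatment"):
            subj(treatment="XX")

    def test_rejects_end_before_entry(self):
        with pytest.raises(ValueError, match="end_date"):
            subj(end=-1)


class TestClockAndCciCategories:
    @pytest.mark.parametrize(
        "since,expected",
        [(1, "1"), (2, "2-3"), (3, "2-3"), (4, "4-6"), (5, "4-6"), (6, "4-6"),
         (7, ">6/none"), (100, ">6/none"), (None, ">6/none")],
    )
    def test_clock_categories(self, since, expected):
        assert cs.categorize_clock(since) == expected

    @pytest.mark.parametrize("bad", [0, -1])
    def test_clock_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            cs.categorize_clock(bad)

    @pytest.mark.parametrize(
        "cci,expected", [(0, "0"), (1, "1"), (2, "2"), (3, "3"), (4, "4+"), (11, "4+")]
    )
    def test_cci_category(self, cci, expected):
        assert cs.cci_category(cci) == expected

    def test_cci_category_rejects_negative(self):
        with pytest.raises(ValueError):
            cs.cci_category(-1)


class TestDiscretize:
    def test_death_day50_gives_two_rows(self):
        steps, _ = cs.discretize_followup([subj(end=50, status="died")])
        rows = list(iter_person_steps(steps))
        assert len(rows) == 2
        assert (rows[0].died, rows[0].changed) == (False, False)
        assert rows[1].died and not rows[1].changed

    def test_same_interval_events_pooled(self):
        steps, report = cs.discretize_followup(
            [subj(events=[(3, 1), (10, 2)], end=60)]
        )
        rows = list(iter_person_steps(steps))
        assert len(rows) == 3
        assert rows[0].changed and rows[0].change_size == 3
        assert rows[0].transformed_size == 2 and rows[0].ge6 is False
        assert [r.cci for r in rows] == [0, 3, 3]
        assert report.n_events_pooled == 2 and report.n_changes == 1

    def test_death_interval_change_discarded(self):
        steps, report = cs.discretize_followup(
            [subj(events=[(45, 2)], end=50, status="died")]
        )
        rows = list(iter_person_steps(steps))
        assert rows[1].died and not rows[1].changed
        assert report.n_events_discarded_death_interval == 1
        assert report.n_events_kept == 0

    def test_censored_terminal_interval_keeps_change(self):
        steps, _ = cs.discretize_followup([subj(events=[(58, 1)], end=60)])
        rows = list(iter_person_steps(steps))
        assert rows[2].changed and rows[2].change_size == 1

    def test_change_clock_sequence(self):
        # change in step 1 (day 30): clock none,none,1,2-3,2-3,4-6...
        steps, _ = cs.discretize_followup([subj(events=[(30, 1)], end=250)])
        cats = [r.t_since_change_cat for r in iter_person_steps(steps)]
        assert cats[:6] == [">6/none", ">6/none", "1", "2-3", "2-3", "4-6"]
        assert cats[8] == ">6/none"  # step 8: 7 steps since the change

    def test_rp_clock_from_entry(self):
        rec = cs.SubjectRecord(
            subject_id="B", treatment="RP", entry_date=D0, age_at_entry=60.0,
            baseline_cci=0, rp_date=D0, end_date=D0 + datetime.timedelta(days=250),
        )
        steps, _ = cs.discretize_followup([rec])
        cats = [r.t_since_rp_cat for r in iter_person_steps(steps)]
        # procedure at entry: not yet qualifying in step 0, then 1, 2-3, ...
        assert cats[:4] == [">6/none", "1", "2-3", "2-3"]
        assert all(c == ">6/none" for c in
                   [r.t_since_rt_cat for r in iter_person_steps(steps)])

    def test_age_advances_per_step(self):
        steps, _ = cs.discretize_followup([subj(end=90)])
        ages = steps["age"].to_numpy()
        assert np.allclose(np.diff(ages), 28 / 365.25)

    def test_rejects_bad_rows_with_diagnostics(self):
        subs = pd.DataFrame(
            {
                "subject_id": ["ok", "badtrt", "badev"],
                "treatment": ["AS", "XX", "AS"],
                "entry_date": ["2010-01-01"] * 3,
                "age_at_entry": [65.0] * 3,
                "baseline_cci": [0] * 3,
                "rp_date": [None] * 3,
                "rt_date": [None] * 3,
                "end_date": ["2010-03-01"] * 3,
                "end_status": ["censored"] * 3,
            }
        )
        events = pd.DataFrame(
            {"subject_id": ["badev"], "event_date": ["2010-06-01"], "weight": [1]}
        )
        steps, report = cs.discretize_followup(cs.Cohort(subs, events))
        assert report.n_rejected == 2
        reasons = dict(report.rejected)
        assert "treatment" in reasons["badtrt"]
        assert "outside follow-up" in reasons["badev"]
        assert set(steps["subject_id"].unique()) == {"ok"}


class TestInvariantsOnGenerated:
    def test_person_step_conservation(self, truth_small):
        cohort = cs.generate_cohort(truth_small, 500, seed=3)
        steps, _ = cs.discretize_followup(cohort)
        span = (cohort.subjects["end_date"] - cohort.subjects["entry_date"]).dt.days
        expected = (span // 28 + 1).set_axis(cohort.subjects["subject_id"])
        got = steps.groupby("subject_id", observed=True).size()
        assert got.sort_index().equals(expected.sort_index())

    def test_cci_monotone_and_roundtrip(self, truth_small):
        cohort = cs.generate_cohort(truth_small, 500, seed=4)
        steps, _ = cs.discretize_followup(cohort)
        for sid, grp in steps.groupby("subject_id", observed=True):
            cci = grp.sort_values("step_index")["cci"].to_numpy()
            assert (np.diff(cci) >= 0).all()
        # censored subjects: summed change sizes reproduce the event history
        censored = cohort.subjects.loc[
            cohort.subjects["end_status"] == "censored", "subject_id"
        ]
        ev_total = cohort.events.groupby("subject_id")["weight"].sum()
        chg_total = (
            steps[steps["changed"]]
            .groupby("subject_id", observed=True)["change_size"]
            .sum()
        )
        for sid in censored:
            assert ev_total.get(sid, 0) == chg_total.get(sid, 0)

    def test_pooling_report_matches_bruteforce(self, truth_small):
        cohort = cs.generate_cohort(truth_small, 2000, seed=5)
        steps, report = cs.discretize_followup(cohort)
        # independent scan: events sharing a (subject, interval) cell
        ev = cohort.events.merge(
            cohort.subjects[["subject_id", "entry_date"]], on="subject_id"
        )
        ev["step"] = (ev["event_date"] - ev["entry_date"]).dt.days // 28
        counts = ev.groupby(["subject_id", "step"]).size()
        expected_pooled = int(counts[counts >= 2].sum())
        assert report.n_events_pooled == expected_pooled
        assert report.n_events_kept == len(ev)  # no deaths-with-changes here
        assert 0.0 < report.frac_events_pooled < 0.15


class TestCohortIO:
    def test_csv_and_records_roundtrip(self, tmp_path, truth_small):
        cohort = cs.generate_cohort(truth_small, 50, seed=6)
        cohort.to_csv(tmp_path / "subs.csv", tmp_path / "ev.csv")
        back = cs.Cohort.from_csv(tmp_path / "subs.csv", tmp_path / "ev.csv")
        pd.testing.assert_frame_equal(cohort.subjects, back.subjects)
        pd.testing.assert_frame_equal(
            cohort.events.astype({"weight": "int64"}),
            back.events.astype({"weight": "int64"}),
        )
        records = back.to_records()
        again = cs.Cohort.from_records(records)
        steps_a, _ = cs.discretize_followup(back)
        steps_b, _ = cs.discretize_followup(again)
        pd.testing.assert_frame_equal(steps_a, steps_b)
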