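import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raredetect.ehr_model import (
    Analyte,
    Cohort,
    LabResult,
    MedicationOrder,
    Sex,
    age_at,
)
from raredetect.errors import ConfigurationError
from raredetect.fabry_screen import ScreenStatus
from raredetect.fh_screen import (
    RULE_ASCVD_FEMALE,
    RULE_ASCVD_MALE,
    RULE_LDL_ADULT,
    RULE_LDL_CHILD,
    RULE_LDL_STATIN,
    FHConfig,
    FHRules,
    flag_fh,
    is_premature_ascvd,
    on_high_intensity_statin,
    screen_fh_cohort,
)
from raredetect.synthetic_data import (
    FabrySynthConfig,
    FHSynthConfig,
    SyntheticConfig,
    generate_cohort,
)

from conftest import WINDOW, make_patient, make_problem


def ascvd_entry(catalog, pid="PID000001", date=dt.date(2020, 1, 1)):
    system, code = sorted(catalog["ascvd"].codes)[0]
    return make_problem(pid=pid, code=code, system=system,
                        description="myocardial infarction", date=date)


def ldl(value, date=dt.date(2020, 6, 1), pid="PID000001", units="mmol/L"):
    return LabResult(pid, Analyte.LDL_C, value, units, date)


def statin(drug="atorvastatin", dose=80.0, start=dt.date(2020, 1, 1),
           end=dt.date(2021, 1, 1), pid="PID000001"):
    return MedicationOrder(pid, drug, dose, start, end)


def dob_for_age(age, reference):
    """dob giving exactly *age* completed years at *reference*."""
    return dt.date(reference.year - age, reference.month, reference.day)


class TestPrematureAscvd:
    def test_male_event_at_54(self, catalog, window):
        event = dt.date(2020, 1, 1)
        patient = make_patient(sex=Sex.MALE, dob=dob_for_age(54, event))
        ok, rule = is_premature_ascvd(patient, [ascvd_entry(catalog, date=event)],
                                      catalog["ascvd"], window)
        assert (ok, rule) == (True, RULE_ASCVD_MALE)

    def test_male_event_at_55_is_not_premature(self, catalog, window):
        event = dt.date(2020, 1, 1)
        patient = make_patient(sex=Sex.MALE, dob=dob_for_age(55, event))
        assert is_premature_ascvd(patient, [ascvd_entry(catalog, date=event)],
                                  catalog["ascvd"], window) == (False, None)

    def test_female_bound_is_60(self, catalog, window):
        event = dt.date(2020, 1, 1)
        patient = make_patient(sex=Sex.FEMALE, dob=dob_for_age(59, event))
        ok, rule = is_premature_ascvd(patient, [ascvd_entry(catalog, date=event)],
                                      catalog["ascvd"], window)
        assert (ok, rule) == (True, RULE_ASCVD_FEMALE)

    def test_unknown_sex_not_applicable(self, catalog, window):
        patient = make_patient(sex=Sex.UNKNOWN, dob=dt.date(1990, 1, 1))
        assert is_premature_ascvd(patient, [ascvd_entry(catalog)],
                                  catalog["ascvd"], window) == (False, None)

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_earliest_event_matches_brute_force_scan(self, data):
        from raredetect.valuesets import default_catalog

        catalog = default_catalog()
        dob = data.draw(st.dates(dt.date(1950, 1, 1), dt.date(1985, 12, 31)))
        dates = data.draw(st.lists(
            st.dates(WINDOW.start, WINDOW.end), min_size=1, max_size=6))
        sex = data.draw(st.sampled_from([Sex.MALE, Sex.FEMALE]))
        patient = make_patient(sex=sex, dob=dob)
        problems = [ascvd_entry(catalog, date=d) for d in dates]
        ok, _ = is_premature_ascvd(patient, problems, catalog["ascvd"], WINDOW)
        # oracle: minimum age over every matching entry, scanned one by one
        bound = 55 if sex is Sex.MALE else 60
        expected = min(age_at(dob, d) for d in dates) < bound
        assert ok == expected


class TestHighIntensityStatin:
    def test_covering_high_dose(self):
        assert on_high_intensity_statin([statin(dose=80.0)], dt.date(2020, 6, 1))

    def test_min_dose_inclusive(self):
        assert on_high_intensity_statin([statin(dose=40.0)], dt.date(2020, 6, 1))

    def test_below_min_dose(self):
        assert not on_high_intensity_statin([statin(dose=20.0)], dt.date(2020, 6, 1))

    def test_outside_interval(self):
        assert not on_high_intensity_statin([statin()], dt.date(2021, 6, 1))

    def test_non_statin_ignored(self):
        assert not on_high_intensity_statin(
            [statin(drug="metformin", dose=1000.0)], dt.date(2020, 6, 1))

    def test_drug_name_case_insensitive(self):
        assert on_high_intensity_statin([statin(drug="Rosuvastatin", dose=20.0)],
                                        dt.date(2020, 6, 1))

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_interval_containment(self, data):
        rules = FHRules()
        orders = []
        for _ in range(data.draw(st.integers(0, 5))):
            start = data.draw(st.dates(dt.date(2019, 1, 1), dt.date(2021, 1, 1)))
            length = data.draw(st.integers(0, 400))
            open_ended = data.draw(st.booleans())
            drug = data.draw(st.sampled_from(["atorvastatin", "rosuvastatin", "aspirin"]))
            dose = data.draw(st.sampled_from([10.0, 20.0, 40.0, 80.0]))
            orders.append(MedicationOrder(
                "PID000001", drug, dose, start,
                None if open_ended else start + dt.timedelta(days=length)))
        date = data.draw(st.dates(dt.date(2019, 1, 1), dt.date(2022, 3, 1)))
        expected = any(
            o.drug_name in rules.high_intensity_statins
            and o.dose_mg >= rules.high_intensity_statins[o.drug_name]
            and o.start_date <= date
            and (o.end_date is None or date <= o.end_date)
            for o in orders
        )
        assert on_high_intensity_statin(orders, date, rules) == expected


class TestFlagFH:
    def _flag(self, catalog, patient, problems=(), labs=(), meds=(), window=WINDOW):
        return flag_fh(patient, list(problems), list(labs), list(meds), FHRules(),
                       catalog["familial hypercholesterolaemia"], catalog["ascvd"],
                       window)

    def test_adult_at_threshold_is_negative(self, catalog):
        # LDL exactly 4.9 with no statin and no ASCVD: strict > fails
        patient = make_patient(dob=dob_for_age(30, dt.date(2020, 6, 1)))
        result = self._flag(catalog, patient, labs=[ldl(4.9)])
        assert result.status is ScreenStatus.NEGATIVE
        assert result.triggered_rules == frozenset()
        assert result.qualifying_ldl is None

    def test_adult_above_threshold(self, catalog):
        patient = make_patient(dob=dob_for_age(30, dt.date(2020, 6, 1)))
        result = self._flag(catalog, patient, labs=[ldl(5.0)])
        assert result.status is ScreenStatus.SUSPECT
        assert result.triggered_rules == {RULE_LDL_ADULT}
        assert result.qualifying_ldl == 5.0

    def test_child_rule(self, catalog):
        patient = make_patient(dob=dob_for_age(17, dt.date(2020, 6, 1)))
        result = self._flag(catalog, patient, labs=[ldl(4.0)])
        assert result.status is ScreenStatus.SUSPECT
        assert result.triggered_rules == {RULE_LDL_CHILD}

    def test_exactly_18_uses_child_rule_only(self, catalog):
        patient = make_patient(dob=dob_for_age(18, dt.date(2020, 6, 1)))
        # above the adult threshold but evaluated by the child rule
        result = self._flag(catalog, patient, labs=[ldl(5.5)])
        assert result.triggered_rules == {RULE_LDL_CHILD}
        # between child and adult thresholds: child rule fires at 18
        result = self._flag(catalog, patient, labs=[ldl(4.0)])
        assert result.triggered_rules == {RULE_LDL_CHILD}

    def test_age_crossing_18_uses_draw_date(self, catalog):
        # 18 at the early draw, 19 at the late one; only the early LDL 4.0
        # fires (child rule), proving age is taken per result
        birthday19 = dt.date(2020, 6, 1)
        patient = make_patient(dob=dob_for_age(19, birthday19))
        early = ldl(4.0, date=birthday19 - dt.timedelta(days=30))
        late = ldl(4.0, date=birthday19 + dt.timedelta(days=30))
        assert self._flag(catalog, patient, labs=[early]).triggered_rules == {RULE_LDL_CHILD}
        assert self._flag(catalog, patient, labs=[late]).triggered_rules == frozenset()

    def test_statin_rule(self, catalog):
        patient = make_patient(dob=dob_for_age(45, dt.date(2020, 6, 1)))
        result = self._flag(catalog, patient, labs=[ldl(3.0)], meds=[statin(dose=40.0)])
        assert result.triggered_rules == {RULE_LDL_STATIN}
        assert result.qualifying_ldl == 3.0

    def test_statin_below_high_intensity_dose(self, catalog):
        patient = make_patient(dob=dob_for_age(45, dt.date(2020, 6, 1)))
        result = self._flag(catalog, patient, labs=[ldl(3.0)], meds=[statin(dose=20.0)])
        assert result.status is ScreenStatus.NEGATIVE

    def test_qualifying_ldl_is_max_over_firing_results(self, catalog):
        patient = make_patient(dob=dob_for_age(40, dt.date(2020, 6, 1)))
        labs = [ldl(5.1, date=dt.date(2020, 2, 1)),
                ldl(6.3, date=dt.date(2020, 5, 1)),
                ldl(2.0, date=dt.date(2020, 8, 1))]
        result = self._flag(catalog, patient, labs=labs)
        assert result.qualifying_ldl == 6.3

    def test_unconvertible_units_skipped(self, catalog):
        patient = make_patient(dob=dob_for_age(40, dt.date(2020, 6, 1)))
        result = self._flag(catalog, patient, labs=[ldl(500.0, units="ng/mL")])
        assert result.status is ScreenStatus.NEGATIVE

    def test_known_case_preempts(self, catalog):
        patient = make_patient(dob=dob_for_age(40, dt.date(2020, 6, 1)))
        dx_system, dx_code = sorted(
            catalog["familial hypercholesterolaemia"].codes)[0]
        dx = make_problem(code=dx_code, system=dx_system, description="FH dx")
        result = self._flag(catalog, patient, problems=[dx], labs=[ldl(9.0)])
        assert result.status is ScreenStatus.KNOWN_CASE
        assert result.triggered_rules == frozenset()

    def test_out_of_window_lab_ignored(self, catalog):
        patient = make_patient(dob=dob_for_age(40, dt.date(2020, 6, 1)))
        result = self._flag(catalog, patient, labs=[ldl(9.0, date=dt.date(2016, 1, 1))])
        assert result.status is ScreenStatus.NEGATIVE

    @given(st.lists(st.floats(0.5, 10.0), max_size=4), st.floats(0.5, 10.0))
    @settings(max_examples=40, deadline=None)
    def test_adding_a_lab_never_demotes(self, values, extra):
        from raredetect.valuesets import default_catalog

        catalog = default_catalog()
        patient = make_patient(dob=dt.date(1980, 1, 1))
        labs = [ldl(v, date=dt.date(2020, 6, 1)) for v in values]
        base = self._flag(catalog, patient, labs=labs)
        grown = self._flag(catalog, patient, labs=labs + [ldl(extra)])
        if base.status is ScreenStatus.SUSPECT:
            assert grown.status is ScreenStatus.SUSPECT
        assert base.triggered_rules <= grown.triggered_rules
        # suspects carry rules; negatives carry none
        for r in (base, grown):
            assert (r.status is ScreenStatus.SUSPECT) == bool(r.triggered_rules)


class TestRulesConfig:
    def test_from_yaml(self, tmp_path):
        path = tmp_path / "rules.yaml"
        path.write_text(
            "ldl_adult: 5.0\nhigh_intensity_statins:\n  Atorvastatin: 40\n")
        rules = FHRules.from_yaml(path)
        assert rules.ldl_adult == 5.0
        assert rules.high_intensity_statins == {"atorvastatin": 40.0}
        assert rules.ldl_child == 3.9  # untouched default

    def test_unknown_field_rejected(self, tmp_path):
        path = tmp_path / "rules.yaml"
        path.write_text("ldl_grownup: 5.0\n")
        with pytest.raises(ConfigurationError, match="ldl_grownup"):
            FHRules.from_yaml(path)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            FHRules(ldl_adult=-1.0)

    def test_bad_ordering_warns_but_builds(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="raredetect.fh_screen"):
            FHRules(ldl_on_statin=5.0)
        assert any("ordering" in r.message for r in caplog.records)


class TestScreenCohort:
    def test_empty_cohort(self, catalog, window):
        results, summary = screen_fh_cohort(Cohort(), FHConfig(catalog, window))
        assert results == []
        assert (summary.n_known, summary.n_suspect) == (0, 0)

    def test_all_known_cohort_has_no_suspects(self, catalog, window):
        cohort = Cohort()
        dx_system, dx_code = sorted(
            catalog["familial hypercholesterolaemia"].codes)[0]
        for i in range(5):
            pid = f"PID{i + 1:06d}"
            cohort.patients.append(make_patient(pid=pid, dob=dt.date(1980, 1, 1)))
            cohort.problems.append(make_problem(
                pid=pid, code=dx_code, system=dx_system, description="dx"))
            cohort.labs.append(ldl(9.0, pid=pid))
        _, summary = screen_fh_cohort(cohort, FHConfig(catalog, window))
        assert (summary.n_known, summary.n_suspect) == (5, 0)

    def test_161_known_500_suspect_miniature(self, catalog):
        config = SyntheticConfig(
            n_patients=800,
            seed=13,
            fabry=FabrySynthConfig(n_known=0, n_suspect=0),
            fh=FHSynthConfig(n_known=161, n_suspect=500),
            decoys={},
        )
        cohort, truth = generate_cohort(config)
        _, summary = screen_fh_cohort(cohort, FHConfig(catalog, config.window))
        assert (summary.n_known, summary.n_suspect) == (161, 500)
        assert truth.expected_summary("fh") == (161, 500)
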