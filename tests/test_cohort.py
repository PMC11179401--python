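import datetime as dt

import pandas as pd
import pytest

from trialemu.cohort import (
    CHECKABLE_CRITERIA,
    CriterionConfig,
    cohorts_frame,
    eye_view,
    evaluate_eye,
    find_index,
    has_prn_marker,
    is_treatment_naive,
    meets_cadence,
    meets_regimen,
    passes_exclusions,
    run_attrition,
    select_study_eye,
)

from conftest import d, make_registry

CFG = CriterionConfig()
WINDOW = (CFG.window_start, CFG.window_end)


def single_eye_registry(injections=None, encounters=None, diagnoses=None,
                        procedures=None, va=None, iop=None):
    return make_registry(
        patients=[{"patient_id": "P1", "age_at_first_record": 79, "gender": "F", "race": "white"}],
        injections=injections,
        encounters=encounters,
        diagnoses=diagnoses,
        procedures=procedures,
        va=va,
        iop=iop,
    )


def inj(date, drug="bevacizumab", lat="OD", pid="P1"):
    return {"patient_id": pid, "laterality": lat, "date": d(date), "drug": drug}


class TestFindIndex:
    def test_first_injection_wins(self):
        reg = single_eye_registry(injections=[inj("2016-02-10"), inj("2016-01-10")])
        assert find_index(eye_view(reg, "P1", "OD"), WINDOW) == d("2016-01-10")

    def test_pre_window_only_absent(self):
        reg = single_eye_registry(injections=[inj("2015-06-01")])
        assert find_index(eye_view(reg, "P1", "OD"), WINDOW) is None

    def test_window_start_inclusive(self):
        reg = single_eye_registry(injections=[inj("2015-10-01")])
        assert find_index(eye_view(reg, "P1", "OD"), WINDOW) == d("2015-10-01")


class TestTreatmentNaive:
    def test_recent_prior_injection_fails(self):
        reg = single_eye_registry(injections=[inj("2016-06-01"), inj("2016-02-22")])
        view = eye_view(reg, "P1", "OD")
        assert not is_treatment_naive(view, d("2016-06-01"))

    def test_old_prior_injection_passes(self):
        # 400 days earlier is outside the 365-day lookback
        reg = single_eye_registry(injections=[inj("2016-06-01"), inj("2015-04-28")])
        view = eye_view(reg, "P1", "OD")
        assert is_treatment_naive(view, d("2016-06-01"))

    def test_no_priors_passes(self):
        reg = single_eye_registry(injections=[inj("2016-06-01")])
        assert is_treatment_naive(eye_view(reg, "P1", "OD"), d("2016-06-01"))


class TestRegimen:
    def test_single_drug(self):
        rows = [inj(f"2016-{m:02d}-01") for m in range(6, 13)]
        reg = single_eye_registry(injections=rows)
        assert meets_regimen(eye_view(reg, "P1", "OD"), d("2016-06-01")) == "bevacizumab"

    def test_other_agent_disqualifies(self):
        rows = [inj("2016-06-01"), inj("2016-12-18", drug="aflibercept")]
        reg = single_eye_registry(injections=rows)
        assert meets_regimen(eye_view(reg, "P1", "OD"), d("2016-06-01")) is None

    def test_ranibizumab_only(self):
        rows = [inj("2016-06-01", drug="ranibizumab"), inj("2016-08-01", drug="ranibizumab")]
        reg = single_eye_registry(injections=rows)
        assert meets_regimen(eye_view(reg, "P1", "OD"), d("2016-06-01")) == "ranibizumab"


def visits(start, gaps):
    days, acc = [], 0
    rows = [{"patient_id": "P1", "date": d(start), "provider_type": "retina"}]
    for g in gaps:
        acc += g
        rows.append(
            {
                "patient_id": "P1",
                "date": d(start) + dt.timedelta(days=acc),
                "provider_type": "retina",
            }
        )
    return rows


class TestCadence:
    def test_every_35_days_through_year(self):
        reg = single_eye_registry(encounters=visits("2016-06-01", [35] * 10))
        assert meets_cadence(eye_view(reg, "P1", "OD"), d("2016-06-01"), CFG)

    def test_sixty_day_gap_fails(self):
        reg = single_eye_registry(encounters=visits("2016-06-01", [35, 60] + [35] * 8))
        assert not meets_cadence(eye_view(reg, "P1", "OD"), d("2016-06-01"), CFG)

    def test_no_visits_fails(self):
        reg = single_eye_registry()
        assert not meets_cadence(eye_view(reg, "P1", "OD"), d("2016-06-01"), CFG)

    def test_early_stop_fails(self):
        # last visit at day 280 < 323
        reg = single_eye_registry(encounters=visits("2016-06-01", [40] * 7))
        assert not meets_cadence(eye_view(reg, "P1", "OD"), d("2016-06-01"), CFG)

    def test_strict_min_gap_flag(self):
        strict = CriterionConfig(cadence_min_gap_days=28)
        enc = visits("2016-06-01", [35, 10, 25] + [35] * 8)
        reg = single_eye_registry(encounters=enc)
        assert not meets_cadence(eye_view(reg, "P1", "OD"), d("2016-06-01"), strict)
        assert meets_cadence(eye_view(reg, "P1", "OD"), d("2016-06-01"), CFG)


class TestPrnMarker:
    def test_non_injection_visit_present(self):
        reg = single_eye_registry(
            encounters=visits("2016-06-01", [35] * 10),
            injections=[inj("2016-06-01")],
        )
        assert has_prn_marker(eye_view(reg, "P1", "OD"), d("2016-06-01"))

    def test_every_visit_injected(self):
        enc = visits("2016-06-01", [35] * 10)
        rows = [inj(r["date"].isoformat()) for r in enc]
        reg = single_eye_registry(encounters=enc, injections=rows)
        assert not has_prn_marker(eye_view(reg, "P1", "OD"), d("2016-06-01"))

    def test_day_level_join(self):
        enc = visits("2016-06-01", [35])
        rows = [inj(r["date"].isoformat()) for r in enc]
        enc.append({"patient_id": "P1", "date": d("2016-08-20"), "provider_type": "retina"})
        reg = single_eye_registry(encounters=enc, injections=rows)
        assert has_prn_marker(eye_view(reg, "P1", "OD"), d("2016-06-01"))


class TestExclusions:
    def test_two_high_iop_readings_fail(self):
        iop = [
            {"patient_id": "P1", "laterality": "OD", "date": d("2016-05-02"), "mmhg": 26.0},
            {"patient_id": "P1", "laterality": "OD", "date": d("2016-04-02"), "mmhg": 27.0},
        ]
        reg = single_eye_registry(iop=iop)
        ok, label = passes_exclusions(eye_view(reg, "P1", "OD"), d("2016-06-01"), CFG)
        assert not ok and label == "glaucoma"

    def test_single_high_reading_passes(self):
        iop = [{"patient_id": "P1", "laterality": "OD", "date": d("2016-05-02"), "mmhg": 30.0}]
        reg = single_eye_registry(iop=iop)
        ok, _ = passes_exclusions(eye_view(reg, "P1", "OD"), d("2016-06-01"), CFG)
        assert ok

    def test_recent_cataract_surgery_fails(self):
        proc = [{"patient_id": "P1", "laterality": "OD", "date": d("2016-05-02"),
                 "category": "intraocular_surgery"}]
        reg = single_eye_registry(procedures=proc)
        ok, label = passes_exclusions(eye_view(reg, "P1", "OD"), d("2016-06-01"), CFG)
        assert not ok and label == "recent_surgery"

    def test_old_surgery_passes(self):
        proc = [{"patient_id": "P1", "laterality": "OD", "date": d("2016-02-01"),
                 "category": "intraocular_surgery"}]
        reg = single_eye_registry(procedures=proc)
        ok, _ = passes_exclusions(eye_view(reg, "P1", "OD"), d("2016-06-01"), CFG)
        assert ok

    def test_fellow_eye_treatment_fails(self):
        reg = single_eye_registry(injections=[inj("2016-09-01", lat="OS")])
        ok, label = passes_exclusions(eye_view(reg, "P1", "OD"), d("2016-06-01"), CFG)
        assert not ok and label == "fellow_eye"

    def test_bilateral_diagnosis_applies(self):
        dx = [{"patient_id": "P1", "laterality": None, "date": d("2016-01-01"),
               "code_category": "dr_dme"}]
        reg = single_eye_registry(diagnoses=dx)
        ok, label = passes_exclusions(eye_view(reg, "P1", "OD"), d("2016-06-01"), CFG)
        assert not ok and label == "dr_dme"


class TestSelectStudyEye:
    def test_earlier_index_wins(self):
        assert select_study_eye([("OD", d("2016-04-10")), ("OS", d("2016-02-19"))])[0] == "OS"

    def test_single_candidate(self):
        assert select_study_eye([("OS", d("2016-04-10"))])[0] == "OS"

    def test_same_day_tie_prefers_od(self):
        assert select_study_eye([("OS", d("2016-04-10")), ("OD", d("2016-04-10"))])[0] == "OD"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_study_eye([])


def _toy_patient(pid, *, naive_violation=False, cadence_violation=False,
                 fellow_violation=False):
    """One hand-traceable eye: index 2016-06-01, monthly visits, VA 20/40."""
    rows = {"patients": [], "encounters": [], "injections": [], "diagnoses": [], "va": []}
    rows["patients"].append(
        {"patient_id": pid, "age_at_first_record": 78, "gender": "F", "race": "white"}
    )
    index = d("2016-06-01")
    gaps = [30] * 13
    offsets = [0]
    for g in gaps:
        offsets.append(offsets[-1] + g)
    if cadence_violation:
        offsets = [o for o in offsets if not 60 <= o <= 170]
    for o in offsets:
        rows["encounters"].append(
            {"patient_id": pid, "date": index + dt.timedelta(days=o), "provider_type": "retina"}
        )
    rows["encounters"].append(
        {"patient_id": pid, "date": d("2015-01-05"), "provider_type": "other"}
    )
    rows["diagnoses"].append(
        {"patient_id": pid, "laterality": "OD", "date": d("2016-05-01"), "code_category": "namd"}
    )
    for o in offsets[::2]:
        if o <= 365:
            rows["injections"].append(inj((index + dt.timedelta(days=o)).isoformat(), pid=pid))
    if naive_violation:  # pre-window injection 260 days before index
        rows["injections"].append(inj("2015-09-15", pid=pid))
    if fellow_violation:
        rows["injections"].append(inj("2016-09-10", lat="OS", pid=pid))
    rows["va"] = [
        {"patient_id": pid, "laterality": "OD", "date": index, "snellen_num": 20, "snellen_den": 40},
        {"patient_id": pid, "laterality": "OD", "date": index + dt.timedelta(days=360),
         "snellen_num": 20, "snellen_den": 32},
    ]
    return rows


def merge_rows(dicts):
    out = {}
    for k in dicts[0]:
        out[k] = [r for one in dicts for r in one.get(k, [])]
    return out


class TestRunAttrition:
    def test_toy_registry_hand_trace(self):
        # 1 non-naive, 1 cadence-fail, 1 fellow-eye-treated, 2 clean -> 2 survive
        rows = merge_rows(
            [
                _toy_patient("P1"),
                _toy_patient("P2"),
                _toy_patient("P3", naive_violation=True),
                _toy_patient("P4", cadence_violation=True),
                _toy_patient("P5", fellow_violation=True),
            ]
        )
        reg = make_registry(**rows)
        cohorts, table = run_attrition(reg, CFG)
        df = table.to_frame().set_index("criterion")
        # P5's treated fellow eye (OS) also enters the universe and drops
        # at the nAMD row (diagnosis is OD-only)
        assert df.loc["index_injection", "eyes_remaining"] == 6
        assert df.loc["namd_dx", "eyes_remaining"] == 5
        assert df.loc["age", "eyes_remaining"] == 5
        assert df.loc["naive", "eyes_remaining"] == 4      # P3 drops here
        assert df.loc["cadence", "eyes_remaining"] == 3    # P4 drops here
        assert df.loc["other_va_compromising", "eyes_remaining"] == 3
        assert df.loc["fellow_eye", "eyes_remaining"] == 2  # P5 drops here
        assert df.loc["prn_marker", "eyes_remaining"] == 2
        final = sorted(e.patient_id for es in cohorts.values() for e in es)
        assert final == ["P1", "P2"]
        survivor = cohorts["bevacizumab"][0]
        assert survivor.baseline_letters == 70
        assert survivor.year1_letters == 75
        assert survivor.n_injections_year1 == 7

    def test_counts_non_increasing(self, violated_bundle):
        _, registry, _ = violated_bundle
        _, table = run_attrition(registry, CFG)
        eyes = table.to_frame()["eyes_remaining"]
        assert (eyes.diff().dropna() <= 0).all()
        patients = table.to_frame()["patients_remaining"]
        assert (patients.diff().dropna() <= 0).all()

    def test_zero_violations_retains_everything(self, clean_bundle, clean_cohorts):
        _, registry, truth = clean_bundle
        cohorts, table = clean_cohorts[0], clean_cohorts[1]
        n_final = sum(len(v) for v in cohorts.values())
        assert n_final == len(truth)
        assert table.to_frame()["eyes_remaining"].iloc[-1] == len(truth)

    def test_verdicts_match_ground_truth_on_single_violation_eyes(self, violated_bundle):
        from trialemu.cohort import _EyeView, _PatientTables

        _, registry, truth = violated_bundle
        tables = _PatientTables(registry)
        n_viol = sum((truth[f"pass_{c}"] == 0) for c in CHECKABLE_CRITERIA)
        single = truth[n_viol <= 1]
        assert len(single) > 100
        checked = 0
        for row in single.itertuples(index=False):
            view = _EyeView(tables, row.patient_id, row.laterality)
            index = find_index(view, WINDOW)
            verdicts = evaluate_eye(view, index, CFG)
            for c in CHECKABLE_CRITERIA:
                assert verdicts[c] == bool(getattr(row, f"pass_{c}")), (
                    row.patient_id,
                    c,
                )
                checked += 1
        assert checked == len(single) * len(CHECKABLE_CRITERIA)

    def test_row_order_is_presentation_only(self, violated_bundle):
        """The final cohort is the set of all-pass eyes, whatever the order."""
        from trialemu.cohort import _EyeView, _PatientTables

        _, registry, truth = violated_bundle
        cohorts, _ = run_attrition(registry, CFG)
        final = {
            (e.patient_id, e.laterality) for es in cohorts.values() for e in es
        }
        tables = _PatientTables(registry)
        expected = set()
        for row in truth.itertuples(index=False):
            view = _EyeView(tables, row.patient_id, row.laterality)
            index = find_index(view, WINDOW)
            verdicts = evaluate_eye(view, index, CFG)
            if all(verdicts[c] for c in reversed(CHECKABLE_CRITERIA)):
                expected.add((row.patient_id, row.laterality))
        assert final == expected

    def test_one_study_eye_per_patient(self, clean_cohorts):
        df = clean_cohorts[2]
        assert df["patient_id"].is_unique

    def test_eligible_eye_invariants(self, clean_cohorts):
        df = clean_cohorts[2]
        assert set(df["drug"]) <= {"bevacizumab", "ranibizumab"}
        assert (df["n_injections_year1"] >= 1).all()
        assert df["baseline_letters"].between(25, 80).all()

    def test_year1_and_baseline_match_truth(self, clean_bundle, clean_cohorts):
        _, _, truth = clean_bundle
        df = clean_cohorts[2].set_index("patient_id")
        t = truth.set_index("patient_id")
        joined = df.join(t, rsuffix="_t")
        assert (joined["baseline_letters"] == joined["baseline_letters_t"]).all()
        assert (joined["year1_letters"].astype(int) == joined["year1_letters_t"]).all()
        assert (joined["n_injections_year1"] == joined["n_injections"]).all()


class TestCriterionConfig:
    def test_negative_days_rejected(self):
        with pytest.raises(ValueError):
            CriterionConfig(naive_lookback_days=-1)

    def test_unordered_bounds_rejected(self):
        with pytest.raises(ValueError):
            CriterionConfig(va_lower_fraction=0.9, va_upper_fraction=0.1)
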