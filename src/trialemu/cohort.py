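"""Eligibility/attrition engine for the registry *prn* cohorts.

Applies an ordered list of inclusion, treatment-pattern and exclusion
criteria to a longitudinal registry and emits the surviving eyes (split by
drug) together with a cumulative attrition table.

Interval conventions (documented because the source rules state none):
lookbacks are half-open ``(index - N, index]``; follow-up is closed
``[index, index + 365]``.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import vision
from .vision import SnellenAcuity, VAEvent

logger = logging.getLogger(__name__)

__all__ = [
    "ANTI_VEGF_DRUGS",
    "STUDY_DRUGS",
    "CRITERIA",
    "CRITERION_LABELS",
    "Registry",
    "CriterionConfig",
    "EligibleEye",
    "AttritionTable",
    "find_index",
    "is_treatment_naive",
    "meets_regimen",
    "meets_cadence",
    "has_prn_marker",
    "passes_exclusions",
    "select_study_eye",
    "run_attrition",
    "cohorts_frame",
]

#: Recognised anti-VEGF agents.  "other" stands in for any further agent.
ANTI_VEGF_DRUGS = frozenset({"bevacizumab", "ranibizumab", "aflibercept", "other"})
#: The two agents whose monotherapy defines the study cohorts.
STUDY_DRUGS = frozenset({"bevacizumab", "ranibizumab"})

#: Diagnosis code categories the engine understands.
DX_CATEGORIES = frozenset(
    {
        "namd",
        "dr_dme",
        "vitreous_hemorrhage",
        "rrd_macular_hole",
        "fibrosis_ga",
        "cnv_other",
        "other_va_compromising",
        "endophthalmitis",
        "other",
    }
)
#: Procedure categories.
PROC_CATEGORIES = frozenset({"ppv", "intraocular_surgery", "pdt", "other"})

#: Ordered (key, human label) attrition rows.  Row order is fixed: each
#: row's drop counts eyes whose *first* failing criterion is that row.
CRITERIA: tuple[tuple[str, str], ...] = (
    ("index_injection", "Injection of bevacizumab or ranibizumab in study window"),
    ("namd_dx", "Documentation of nAMD within 1 year preindex"),
    ("age", "Age >=50 years at time of index injection"),
    ("naive", "No anti-VEGF injections received up to 365 days preindex"),
    ("preindex", ">=1 year of preindex data"),
    ("va", "Visual acuity between 20/25 and 20/320 in the study eye"),
    ("cadence", "Visit every 4-6 weeks for 365 days by a retina specialist"),
    ("regimen", "Treatment with only bevacizumab or only ranibizumab for 365 days"),
    ("dr_dme", "Diabetic retinopathy or diabetic macular edema in the study eye"),
    ("vitreous_hemorrhage", "Vitreous hemorrhage in the study eye"),
    ("rrd_macular_hole", "History of rhegmatogenous retinal detachment or macular hole"),
    ("ppv", "History of pars plana vitrectomy in the study eye"),
    ("recent_surgery", "Intraocular surgery in the study eye within 2 months"),
    ("glaucoma", "Uncontrolled glaucoma (IOP >=25 mmHg on >=2 readings in prior year)"),
    ("prior_treatment", "Previous PDT, ranibizumab, or bevacizumab in the study eye"),
    ("fibrosis_ga", "Fibrosis or geographic atrophy involving the fovea"),
    ("cnv_other", "CNV in either eye due to other causes"),
    ("other_va_compromising", "Other ocular disease compromising study-eye acuity"),
    ("fellow_eye", "Anti-VEGF treatment in the fellow eye during follow-up"),
    ("prn_marker", ">=1 retina specialist visit without an anti-VEGF injection"),
)
CRITERION_LABELS = dict(CRITERIA)
#: Criteria that can be seeded to fail / checked against ground truth
#: (everything after the universe-defining first row).
CHECKABLE_CRITERIA = tuple(key for key, _ in CRITERIA[1:])


class RegistrySchemaError(ValueError):
    """A registry table is missing columns or holds unparseable values."""


_SCHEMAS = {
    "patients": ["patient_id", "age_at_first_record", "gender", "race"],
    "encounters": ["patient_id", "date", "provider_type"],
    "injections": ["patient_id", "laterality", "date", "drug"],
    "diagnoses": ["patient_id", "laterality", "date", "code_category"],
    "procedures": ["patient_id", "laterality", "date", "category"],
    "va": ["patient_id", "laterality", "date", "snellen_num", "snellen_den"],
    "iop": ["patient_id", "laterality", "date", "mmhg"],
}


@dataclass
class Registry:
    """The seven longitudinal event tables keyed by patient / eye."""

    patients: pd.DataFrame
    encounters: pd.DataFrame
    injections: pd.DataFrame
    diagnoses: pd.DataFrame
    procedures: pd.DataFrame
    va: pd.DataFrame
    iop: pd.DataFrame

    def validate(self) -> "Registry":
        for name, cols in _SCHEMAS.items():
            df = getattr(self, name)
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise RegistrySchemaError(f"{name}: missing columns {missing}")
        bad = set(self.injections["drug"]) - ANTI_VEGF_DRUGS
        if bad:
            raise RegistrySchemaError(f"injections: unknown drug values {sorted(bad)}")
        known_pids = set(self.patients["patient_id"])
        for name in ("injections", "va", "iop"):
            df = getattr(self, name)
            orphans = set(df["patient_id"]) - known_pids
            if orphans:
                raise RegistrySchemaError(
                    f"{name}: patient ids not in patients table: "
                    f"{sorted(orphans)[:5]}"
                )
        return self

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in _SCHEMAS}


@dataclass
class CriterionConfig:
    """Tunable thresholds behind the attrition rows."""

    window_start: _dt.date = _dt.date(2015, 10, 1)
    window_end: _dt.date = _dt.date(2019, 12, 31)
    naive_lookback_days: int = 365
    dx_lookback_days: int = 365
    min_age: int = 50
    min_preindex_days: int = 365
    va_lower_fraction: float = 20 / 320
    va_upper_fraction: float = 20 / 25
    cadence_max_gap_days: int = 42
    cadence_min_gap_days: Optional[int] = None  # strict 4-week floor if set
    cadence_first_visit_max_day: int = 42
    cadence_last_visit_min_day: int = 323
    followup_days: int = 365
    surgery_washout_days: int = 60
    iop_threshold_mmhg: float = 25.0
    iop_min_readings: int = 2
    baseline_lookback_days: int = 14
    year1_window_days: int = 56
    endophthalmitis_attribution_days: int = 42
    exclusion_dx: tuple[str, ...] = (
        "dr_dme",
        "vitreous_hemorrhage",
        "rrd_macular_hole",
        "fibrosis_ga",
        "cnv_other",
        "other_va_compromising",
    )

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name.endswith("_days") and v is not None and v < 0:
                raise ValueError(f"{f.name} must be >= 0")
        if not self.va_lower_fraction <= self.va_upper_fraction:
            raise ValueError("va bounds must be ordered")


@dataclass(frozen=True)
class EligibleEye:
    """A registry eye that survived every attrition row."""

    patient_id: str
    laterality: str
    index_date: _dt.date
    drug: str
    age_at_index: int
    gender: str
    baseline_letters: int
    year1_letters: Optional[int]
    n_injections_year1: int
    endophthalmitis: bool

    @property
    def va_change(self) -> Optional[int]:
        if self.year1_letters is None:
            return None
        return self.year1_letters - self.baseline_letters


@dataclass
class AttritionTable:
    """Ordered cumulative patient/eye counts per criterion row."""

    rows: pd.DataFrame  # criterion, label, patients_remaining, eyes_remaining, pct

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()

    def render(self) -> str:
        df = self.rows.copy()
        df["pct_of_initial_eyes"] = df["pct_of_initial_eyes"].map("{:.1f}%".format)
        return df.to_string(index=False)


# ---------------------------------------------------------------------------
# Per-eye event view


_OTHER_EYE = {"OD": "OS", "OS": "OD"}


class _PatientTables:
    """Per-patient slices of the seven tables, grouped once for speed."""

    def __init__(self, registry: Registry):
        self._groups = {
            name: dict(tuple(df.groupby("patient_id", sort=False)))
            for name, df in registry.tables().items()
        }
        self._empties = {name: df.iloc[0:0] for name, df in registry.tables().items()}
        self._patients = registry.patients.set_index("patient_id")

    def get(self, name: str, patient_id: str) -> pd.DataFrame:
        return self._groups[name].get(patient_id, self._empties[name])

    def patient_row(self, patient_id: str) -> pd.Series:
        return self._patients.loc[patient_id]


class _EyeView:
    """All events relevant to one candidate study eye, as plain arrays."""

    def __init__(self, tables: _PatientTables, patient_id: str, laterality: str):
        self.patient_id = patient_id
        self.laterality = laterality
        pid = patient_id

        inj = tables.get("injections", pid)
        mine = inj["laterality"] == laterality
        self.inj_dates = inj.loc[mine, "date"].tolist()
        self.inj_drugs = inj.loc[mine, "drug"].tolist()
        fellow = inj["laterality"] == _OTHER_EYE.get(laterality, "")
        self.fellow_inj_dates = inj.loc[fellow, "date"].tolist()

        enc = tables.get("encounters", pid)
        self.retina_visit_dates = sorted(
            set(enc.loc[enc["provider_type"] == "retina", "date"])
        )

        dx = tables.get("diagnoses", pid)
        eye_or_na = dx["laterality"].isna() | (dx["laterality"] == laterality)
        self.dx_dates = dx.loc[eye_or_na, "date"].tolist()
        self.dx_cats = dx.loc[eye_or_na, "code_category"].tolist()
        self.dx_any_eye = list(zip(dx["date"], dx["code_category"]))

        proc = tables.get("procedures", pid)
        proc = proc[proc["laterality"] == laterality]
        self.proc_dates = proc["date"].tolist()
        self.proc_cats = proc["category"].tolist()

        va = tables.get("va", pid)
        va = va[va["laterality"] == laterality]
        self.va_events = [
            VAEvent(
                eye=(pid, laterality),
                date=d,
                acuity=SnellenAcuity(n, dd),
            )
            for d, n, dd in zip(va["date"], va["snellen_num"], va["snellen_den"])
        ]

        iop = tables.get("iop", pid)
        iop = iop[iop["laterality"] == laterality]
        self.iop_dates = iop["date"].tolist()
        self.iop_values = iop["mmhg"].tolist()

        row = tables.patient_row(pid)
        self.age_at_first_record = int(row["age_at_first_record"])
        self.gender = row["gender"]

        all_dates = [
            d
            for dates in (
                self.inj_dates,
                self.fellow_inj_dates,
                list(enc["date"]),
                dx["date"].tolist(),
                self.proc_dates,
                [ev.date for ev in self.va_events],
                self.iop_dates,
            )
            for d in dates
        ]
        self.first_record_date: Optional[_dt.date] = (
            min(all_dates) if all_dates else None
        )

    def dx_dates_for(self, category: str, any_eye: bool = False):
        if any_eye:
            return [d for d, c in self.dx_any_eye if c == category]
        return [d for d, c in zip(self.dx_dates, self.dx_cats) if c == category]

    def proc_dates_for(self, category: str):
        return [d for d, c in zip(self.proc_dates, self.proc_cats) if c == category]


def eye_view(registry: Registry, patient_id: str, laterality: str) -> _EyeView:
    """Build a single eye's event view straight from a registry."""
    return _EyeView(_PatientTables(registry), patient_id, laterality)


def _days(a: _dt.date, b: _dt.date) -> int:
    return (a - b).days


# ---------------------------------------------------------------------------
# Individual criteria


def find_index(eye: _EyeView, window: tuple[_dt.date, _dt.date]) -> Optional[_dt.date]:
    """First anti-VEGF injection date for the eye inside the window."""
    start, end = window
    dates = [d for d in eye.inj_dates if start <= d <= end]
    return min(dates) if dates else None


def is_treatment_naive(eye: _EyeView, index: _dt.date, lookback_days: int = 365) -> bool:
    """True iff no anti-VEGF injection in ``(index - lookback, index)``."""
    lo = index - _dt.timedelta(days=lookback_days)
    return not any(lo < d < index for d in eye.inj_dates)


def meets_regimen(
    eye: _EyeView, index: _dt.date, followup_days: int = 365
) -> Optional[str]:
    """The single study drug if all follow-up injections use it, else None."""
    end = index + _dt.timedelta(days=followup_days)
    drugs = {
        drug
        for d, drug in zip(eye.inj_dates, eye.inj_drugs)
        if index <= d <= end
    }
    if len(drugs) == 1:
        (drug,) = drugs
        if drug in STUDY_DRUGS:
            return drug
    return None


def meets_cadence(eye: _EyeView, index: _dt.date, config: CriterionConfig) -> bool:
    """Retina visits every <=42 days covering the follow-up year."""
    end = index + _dt.timedelta(days=config.followup_days)
    visits = [d for d in eye.retina_visit_dates if index <= d <= end]
    if not visits:
        return False
    if _days(visits[0], index) > config.cadence_first_visit_max_day:
        return False
    if _days(visits[-1], index) < config.cadence_last_visit_min_day:
        return False
    gaps = [_days(b, a) for a, b in zip(visits, visits[1:])]
    if any(g > config.cadence_max_gap_days for g in gaps):
        return False
    if config.cadence_min_gap_days is not None and any(
        g < config.cadence_min_gap_days for g in gaps
    ):
        return False
    return True


def has_prn_marker(eye: _EyeView, index: _dt.date, followup_days: int = 365) -> bool:
    """True iff some follow-up retina visit day carries no study-eye injection."""
    end = index + _dt.timedelta(days=followup_days)
    inj_days = {d for d in eye.inj_dates if index <= d <= end}
    return any(
        d not in inj_days for d in eye.retina_visit_dates if index <= d <= end
    )


def _baseline_event(
    eye: _EyeView, index: _dt.date, lookback_days: int
) -> Optional[VAEvent]:
    """The best-documented VA event backing the baseline score."""
    same_day = [ev for ev in eye.va_events if ev.date == index]
    if not same_day:
        lo = index - _dt.timedelta(days=lookback_days)
        prior = [ev for ev in eye.va_events if lo <= ev.date < index]
        if not prior:
            return None
        best_day = max(ev.date for ev in prior)
        same_day = [ev for ev in prior if ev.date == best_day]
    return max(
        same_day,
        key=lambda ev: (vision.snellen_to_letters(ev.acuity), ev.acuity.fraction),
    )


def passes_exclusions(
    eye: _EyeView, index: _dt.date, config: CriterionConfig
) -> tuple[bool, Optional[str]]:
    """Evaluate the exclusion rows in order; return first failing label."""
    verdicts = _exclusion_verdicts(eye, index, config)
    for key, _ in CRITERIA:
        if key in verdicts and not verdicts[key]:
            return False, key
    return True, None


def _exclusion_verdicts(
    eye: _EyeView, index: _dt.date, config: CriterionConfig
) -> dict[str, bool]:
    fu_end = index + _dt.timedelta(days=config.followup_days)
    surgery_lo = index - _dt.timedelta(days=config.surgery_washout_days)
    iop_lo = index - _dt.timedelta(days=config.dx_lookback_days)

    def no_dx(cat: str, any_eye: bool = False) -> bool:
        return not any(d <= index for d in eye.dx_dates_for(cat, any_eye=any_eye))

    high_iop = [
        v
        for d, v in zip(eye.iop_dates, eye.iop_values)
        if iop_lo < d <= index and v >= config.iop_threshold_mmhg
    ]
    # injections inside the naive lookback already fail the naive row; this
    # row catches strictly older study-drug treatment (plus PDT any time)
    naive_lo = index - _dt.timedelta(days=config.naive_lookback_days)
    prior_study_drug = any(
        d <= naive_lo and drug in STUDY_DRUGS
        for d, drug in zip(eye.inj_dates, eye.inj_drugs)
    )
    return {
        "dr_dme": no_dx("dr_dme"),
        "vitreous_hemorrhage": no_dx("vitreous_hemorrhage"),
        "rrd_macular_hole": no_dx("rrd_macular_hole"),
        "ppv": not any(d <= index for d in eye.proc_dates_for("ppv")),
        "recent_surgery": not any(
            surgery_lo < d <= index
            for d in eye.proc_dates_for("intraocular_surgery")
        ),
        "glaucoma": len(high_iop) < config.iop_min_readings,
        "prior_treatment": not (
            any(d < index for d in eye.proc_dates_for("pdt")) or prior_study_drug
        ),
        "fibrosis_ga": no_dx("fibrosis_ga"),
        "cnv_other": no_dx("cnv_other", any_eye=True),
        "other_va_compromising": no_dx("other_va_compromising"),
        "fellow_eye": not any(index <= d <= fu_end for d in eye.fellow_inj_dates),
    }


def evaluate_eye(
    eye: _EyeView, index: _dt.date, config: CriterionConfig
) -> dict[str, bool]:
    """Verdict per checkable criterion key (True = passes)."""
    lo_dx = index - _dt.timedelta(days=config.dx_lookback_days)
    namd = any(lo_dx < d <= index for d in eye.dx_dates_for("namd"))
    age = _age_at_index(eye, index)
    baseline = _baseline_event(eye, index, config.baseline_lookback_days)
    va_ok = baseline is not None and (
        config.va_lower_fraction
        <= baseline.acuity.fraction
        <= config.va_upper_fraction
    )
    verdicts = {
        "namd_dx": namd,
        "age": age >= config.min_age,
        "naive": is_treatment_naive(eye, index, config.naive_lookback_days),
        "preindex": (
            eye.first_record_date is not None
            and _days(index, eye.first_record_date) >= config.min_preindex_days
        ),
        "va": va_ok,
        "cadence": meets_cadence(eye, index, config),
        "regimen": meets_regimen(eye, index, config.followup_days) is not None,
    }
    verdicts.update(_exclusion_verdicts(eye, index, config))
    verdicts["prn_marker"] = has_prn_marker(eye, index, config.followup_days)
    return verdicts


def _age_at_index(eye: _EyeView, index: _dt.date) -> int:
    first = eye.first_record_date or index
    elapsed_years = _days(index, first) // 365
    return min(90, eye.age_at_first_record + elapsed_years)


def select_study_eye(candidates: list[tuple[str, _dt.date]]) -> tuple[str, _dt.date]:
    """Pick one study eye per patient: earlier index date; tie -> OD."""
    if not candidates:
        raise ValueError("no candidate eyes")
    return min(candidates, key=lambda c: (c[1], 0 if c[0] == "OD" else 1))


# ---------------------------------------------------------------------------
# The attrition engine


def run_attrition(
    registry: Registry, config: CriterionConfig | None = None
) -> tuple[dict[str, list[EligibleEye]], AttritionTable]:
    """Apply all criteria cumulatively; return per-drug cohorts + the table."""
    config = config or CriterionConfig()
    registry.validate()
    window = (config.window_start, config.window_end)

    inj = registry.injections
    in_window = inj["date"].between(config.window_start, config.window_end)
    universe = (
        inj.loc[in_window & inj["drug"].isin(STUDY_DRUGS), ["patient_id", "laterality"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    tables = _PatientTables(registry)
    eyes: list[tuple[_EyeView, _dt.date, dict[str, bool]]] = []
    for pid, lat in universe:
        view = _EyeView(tables, pid, lat)
        index = find_index(view, window)
        if index is None:  # pragma: no cover - universe implies an index
            continue
        eyes.append((view, index, evaluate_eye(view, index, config)))

    initial_eyes = len(eyes)
    rows = []
    surviving = eyes
    for key, label in CRITERIA:
        if key != "index_injection":
            surviving = [e for e in surviving if e[2][key]]
        n_eyes = len(surviving)
        n_patients = len({v.patient_id for v, _, _ in surviving})
        pct = 100.0 * n_eyes / initial_eyes if initial_eyes else 0.0
        rows.append(
            {
                "criterion": key,
                "label": label,
                "patients_remaining": n_patients,
                "eyes_remaining": n_eyes,
                "pct_of_initial_eyes": pct,
            }
        )
        logger.info("attrition %-22s patients=%d eyes=%d", key, n_patients, n_eyes)

    table = AttritionTable(rows=pd.DataFrame(rows))

    # one study eye per patient: earlier index date, tie toward OD
    by_patient: dict[str, list[tuple[_EyeView, _dt.date]]] = {}
    for view, index, _ in surviving:
        by_patient.setdefault(view.patient_id, []).append((view, index))
    cohorts: dict[str, list[EligibleEye]] = {d: [] for d in sorted(STUDY_DRUGS)}
    for pid in sorted(by_patient):
        cands = by_patient[pid]
        lat, index = select_study_eye([(v.laterality, idx) for v, idx in cands])
        view = next(v for v, idx in cands if v.laterality == lat and idx == index)
        eligible = _build_eligible(view, index, config)
        cohorts[eligible.drug].append(eligible)
    return cohorts, table


def _build_eligible(
    eye: _EyeView, index: _dt.date, config: CriterionConfig
) -> EligibleEye:
    drug = meets_regimen(eye, index, config.followup_days)
    assert drug is not None
    baseline = _baseline_event(eye, index, config.baseline_lookback_days)
    assert baseline is not None
    key = (eye.patient_id, eye.laterality)
    year1 = vision.select_year1_va(
        eye.va_events, key, index, window_days=config.year1_window_days
    )
    fu_end = index + _dt.timedelta(days=config.followup_days)
    inj_days = sorted(d for d in eye.inj_dates if index <= d <= fu_end)
    endo_dates = eye.dx_dates_for("endophthalmitis")
    attribution = _dt.timedelta(days=config.endophthalmitis_attribution_days)
    endo = any(
        inj_d <= e <= inj_d + attribution for e in endo_dates for inj_d in inj_days
    )
    return EligibleEye(
        patient_id=eye.patient_id,
        laterality=eye.laterality,
        index_date=index,
        drug=drug,
        age_at_index=_age_at_index(eye, index),
        gender=eye.gender,
        baseline_letters=vision.snellen_to_letters(baseline.acuity),
        year1_letters=year1,
        n_injections_year1=len(inj_days),
        endophthalmitis=endo,
    )


def cohorts_frame(cohorts: dict[str, list[EligibleEye]]) -> pd.DataFrame:
    """Flatten per-drug cohorts into one table (CSV-ready)."""
    records = []
    for drug in sorted(cohorts):
        for e in cohorts[drug]:
            records.append(
                {
                    "patient_id": e.patient_id,
                    "laterality": e.laterality,
                    "index_date": e.index_date.isoformat(),
                    "drug": e.drug,
                    "age_at_index": e.age_at_index,
                    "gender": e.gender,
                    "baseline_letters": e.baseline_letters,
                    "year1_letters": "" if e.year1_letters is None else e.year1_letters,
                    "n_injections_year1": e.n_injections_year1,
                    "endophthalmitis": int(e.endophthalmitis),
                }
            )
    cols = [
        "patient_id",
        "laterality",
        "index_date",
        "drug",
        "age_at_index",
        "gender",
        "baseline_letters",
        "year1_letters",
        "n_injections_year1",
        "endophthalmitis",
    ]
    return pd.DataFrame.from_records(records, columns=cols)
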