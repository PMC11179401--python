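"""Synthetic registry and trial-roster generator.

Produces a longitudinal event-table bundle with the statistical structure
the downstream pipeline assumes (chart-valued acuities, visit cadences,
per-arm outcome distributions) plus a ground-truth manifest so recovery
tests can compare engine verdicts against seeded truth.

All randomness flows from one integer seed through named substreams, so
adding a field does not reshuffle the others.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import vision
from .cohort import CHECKABLE_CRITERIA, Registry
from .vision import STANDARD_CHART, SnellenAcuity

__all__ = [
    "SimConfig",
    "TrialArmConfig",
    "TrialParticipant",
    "ConfigurationError",
    "generate_registry",
    "generate_trial_arm",
    "default_trial_roster",
    "trial_frame",
    "write_fixture_bundle",
    "read_fixture_bundle",
]


class ConfigurationError(ValueError):
    """Raised for infeasible or inconsistent simulation settings."""


def _substream(seed: int, name: str, index: Optional[int] = None) -> np.random.Generator:
    """Named, platform-stable child stream of the master seed."""
    tag = int.from_bytes(hashlib.sha256(name.encode()).digest()[:8], "big")
    key = [seed, tag] if index is None else [seed, tag, index]
    return np.random.default_rng(key)


@dataclass
class SimConfig:
    """Knobs for the synthetic registry.

    Per-arm parameters (``va_change_mean`` etc.) map drug name to value.
    ``violation_fractions`` maps a criterion key (see
    :data:`trialemu.cohort.CHECKABLE_CRITERIA`) to the fraction of eyes
    seeded to fail that criterion.
    """

    n_patients: int = 500
    window_start: _dt.date = _dt.date(2015, 10, 1)
    window_end: _dt.date = _dt.date(2019, 12, 31)
    age_mean: float = 81.0
    age_sd: float = 8.0
    age_min: int = 50
    age_topcode: int = 90
    female_fraction: float = 0.63
    race_probs: dict = field(
        default_factory=lambda: {"white": 0.90, "other": 0.03, "unknown": 0.07}
    )
    baseline_letters_mean: float = 60.0
    baseline_letters_sd: float = 13.0
    age_va_correlation: float = 0.0
    chart: Sequence[SnellenAcuity] = STANDARD_CHART
    va_lower_fraction: float = 20 / 320
    va_upper_fraction: float = 20 / 25
    arm_probs: dict = field(
        default_factory=lambda: {"bevacizumab": 0.64, "ranibizumab": 0.36}
    )
    va_change_mean: dict = field(
        default_factory=lambda: {"bevacizumab": 2.1, "ranibizumab": 2.8}
    )
    va_change_sd: dict = field(
        default_factory=lambda: {"bevacizumab": 16.0, "ranibizumab": 15.0}
    )
    injection_count_mean: dict = field(
        default_factory=lambda: {"bevacizumab": 7.7, "ranibizumab": 9.0}
    )
    visit_gap_min_days: int = 28
    visit_gap_max_days: int = 42
    violation_fractions: dict = field(default_factory=dict)
    endophthalmitis_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if self.window_start >= self.window_end:
            raise ConfigurationError("empty date window")
        fractions = dict(self.violation_fractions)
        fractions["female"] = self.female_fraction
        fractions["endo"] = self.endophthalmitis_rate
        for name, f in fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"fraction {name}={f} outside [0, 1]")
        unknown = set(self.violation_fractions) - set(CHECKABLE_CRITERIA)
        if unknown:
            raise ConfigurationError(f"unknown violation criteria: {sorted(unknown)}")
        for d in (self.age_sd, self.baseline_letters_sd):
            if d <= 0:
                raise ConfigurationError("sd values must be > 0")
        if self.visit_gap_min_days > self.visit_gap_max_days:
            raise ConfigurationError("visit gap bounds out of order")


@dataclass
class TrialArmConfig:
    """Marginals for one synthetic trial arm."""

    age_mean: float = 79.5
    age_sd: float = 7.3
    age_min: int = 50
    age_topcode: int = 90
    female_fraction: float = 0.61
    baseline_letters_mean: float = 60.1
    baseline_letters_sd: float = 13.5
    baseline_letters_min: int = 23
    baseline_letters_max: int = 82
    va_change_mean: float = 8.5
    va_change_sd: float = 14.0
    injection_mean: float = 11.7
    injection_sd: float = 1.5
    endophthalmitis_rate: float = 0.007


@dataclass(frozen=True)
class TrialParticipant:
    """One clinical-trial subject with covariates and 1-year outcomes."""

    participant_id: str
    arm: str
    age: int
    gender: str
    baseline_letters: int
    year1_letters: int
    n_injections: int
    endophthalmitis: bool


# ---------------------------------------------------------------------------
# Registry generation


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, lo, hi)


def _chart_range_letters(config: SimConfig) -> tuple[int, int]:
    eligible_lines = [
        line
        for line in config.chart
        if config.va_lower_fraction <= line.fraction <= config.va_upper_fraction
    ]
    letters = [vision.snellen_to_letters(line) for line in eligible_lines]
    return min(letters), max(letters)


def generate_registry(config: SimConfig) -> tuple[Registry, pd.DataFrame]:
    """Generate the seven event tables plus a ground-truth manifest.

    Eyes are eligible by construction; each criterion listed in
    ``violation_fractions`` is independently seeded to fail on roughly that
    fraction of eyes.  Deterministic given ``config.seed``.
    """
    n = config.n_patients
    seed = config.seed
    start = config.window_start
    horizon_days = (config.window_end - start).days

    # --- per-field substreams -------------------------------------------
    lat = np.where(_substream(seed, "laterality").random(n) < 0.5, "OD", "OS")
    gender = np.where(
        _substream(seed, "gender").random(n) < config.female_fraction, "F", "M"
    )
    race = _substream(seed, "race").choice(
        list(config.race_probs), size=n, p=list(config.race_probs.values())
    )
    z = _substream(seed, "age_va").multivariate_normal(
        [0.0, 0.0],
        [[1.0, config.age_va_correlation], [config.age_va_correlation, 1.0]],
        size=n,
    )
    ages = np.clip(
        np.round(config.age_mean + config.age_sd * z[:, 0]),
        config.age_min,
        config.age_topcode,
    ).astype(int)
    lo_letters, hi_letters = _chart_range_letters(config)
    # truncate by resampling (not clipping) so no point mass piles up at
    # the eligibility bounds; the correlated z-score is kept where it fits
    baseline_raw = config.baseline_letters_mean + config.baseline_letters_sd * z[:, 1]
    oob = (baseline_raw < lo_letters) | (baseline_raw > hi_letters)
    if oob.any():
        baseline_raw[oob] = _truncated_normal(
            _substream(seed, "baseline_resample"),
            int(oob.sum()),
            config.baseline_letters_mean,
            config.baseline_letters_sd,
            lo_letters,
            hi_letters,
        )
    arms = _substream(seed, "arm").choice(
        sorted(config.arm_probs), size=n, p=[config.arm_probs[k] for k in sorted(config.arm_probs)]
    )
    change_z = _substream(seed, "va_change").standard_normal(n)
    index_days = _substream(seed, "index_day").integers(0, horizon_days + 1, size=n)
    endo_flags = _substream(seed, "endophthalmitis").random(n) < config.endophthalmitis_rate

    violations: dict[str, np.ndarray] = {}
    for crit in CHECKABLE_CRITERIA:
        f = config.violation_fractions.get(crit, 0.0)
        violations[crit] = (
            _substream(seed, f"violation:{crit}").random(n) < f
            if f > 0
            else np.zeros(n, dtype=bool)
        )
    # a seeded naive violation needs its pre-index injection to fall before
    # the study window, so the index is pinned near the window start
    index_days = np.where(
        violations["naive"], np.minimum(index_days, 180), index_days
    )
    age_viol_ages = _substream(seed, "age_violation").integers(40, 50, size=n)
    ages = np.where(violations["age"], age_viol_ages, ages)

    tables: dict[str, list[dict]] = {
        name: [] for name in ("patients", "encounters", "injections",
                              "diagnoses", "procedures", "va", "iop")
    }
    truth_rows: list[dict] = []

    for i in range(n):
        pid = f"P{i:06d}"
        eye_lat = str(lat[i])
        fellow_lat = "OS" if eye_lat == "OD" else "OD"
        drug = str(arms[i])
        index_date = start + _dt.timedelta(days=int(index_days[i]))
        rng_i = _substream(seed, "schedule", i)
        viol = {c: bool(violations[c][i]) for c in CHECKABLE_CRITERIA}
        patient_dates: list[_dt.date] = []

        def day(offset: int) -> _dt.date:
            d = index_date + _dt.timedelta(days=int(offset))
            patient_dates.append(d)
            return d

        # --- visit schedule (retina encounters) -------------------------
        offsets = [0]
        while offsets[-1] < 380:
            offsets.append(
                offsets[-1]
                + int(rng_i.integers(config.visit_gap_min_days,
                                     config.visit_gap_max_days + 1))
            )
        if viol["cadence"]:
            offsets = [o for o in offsets if not 140 < o < 230]
        for o in offsets:
            tables["encounters"].append(
                {"patient_id": pid, "date": day(o), "provider_type": "retina"}
            )

        # --- pre-index history -----------------------------------------
        if not viol["preindex"]:
            tables["encounters"].append(
                {
                    "patient_id": pid,
                    "date": day(-int(rng_i.integers(380, 441))),
                    "provider_type": "other",
                }
            )
        if viol["naive"]:
            tables["injections"].append(
                {
                    "patient_id": pid,
                    "laterality": eye_lat,
                    "date": day(-int(rng_i.integers(200, 351))),
                    "drug": drug,
                }
            )
        if not viol["namd_dx"]:
            tables["diagnoses"].append(
                {
                    "patient_id": pid,
                    "laterality": eye_lat,
                    "date": day(-int(rng_i.integers(1, 301))),
                    "code_category": "namd",
                }
            )
        else:  # documentation exists but falls outside the lookback window
            tables["diagnoses"].append(
                {
                    "patient_id": pid,
                    "laterality": eye_lat,
                    "date": day(-int(rng_i.integers(400, 600))),
                    "code_category": "namd",
                }
            )

        # --- follow-up injections ---------------------------------------
        year_visits = [o for o in offsets if o <= 365]
        target = 1 + int(rng_i.poisson(max(config.injection_count_mean[drug] - 1, 0)))
        if viol["prn_marker"]:
            inj_offsets = list(year_visits)
        else:
            n_inj = min(target, max(len(year_visits) - 1, 1))
            extra = rng_i.choice(
                year_visits[1:], size=min(n_inj - 1, len(year_visits) - 1),
                replace=False,
            )
            inj_offsets = [0] + sorted(int(o) for o in extra)
        for o in inj_offsets:
            tables["injections"].append(
                {"patient_id": pid, "laterality": eye_lat, "date": day(o), "drug": drug}
            )
        if viol["regimen"]:
            off_drug = day(int(rng_i.choice([o for o in year_visits if o > 0])))
            tables["injections"].append(
                {
                    "patient_id": pid,
                    "laterality": eye_lat,
                    "date": off_drug,
                    "drug": "aflibercept",
                }
            )
        if viol["fellow_eye"]:
            tables["injections"].append(
                {
                    "patient_id": pid,
                    "laterality": fellow_lat,
                    "date": day(int(rng_i.integers(30, 301))),
                    "drug": "bevacizumab",
                }
            )

        # --- visual acuity ----------------------------------------------
        if viol["va"]:
            baseline_line = SnellenAcuity(20, 20)
        else:
            baseline_line = vision.letters_to_nearest_snellen(
                int(round(baseline_raw[i])), config.chart
            )
        baseline_letters = vision.snellen_to_letters(baseline_line)
        delta = (
            config.va_change_mean[drug]
            + config.va_change_sd[drug] * float(change_z[i])
        )
        year1_target = float(np.clip(baseline_letters + delta, 0, 100))
        year1_line = vision.letters_to_nearest_snellen(
            int(round(year1_target)), config.chart
        )
        year1_letters = vision.snellen_to_letters(year1_line)
        endpoint_offset = min(year_visits + offsets[-1:], key=lambda o: abs(o - 365))
        mid_offset = min(
            (o for o in year_visits if o > 0), key=lambda o: abs(o - 180), default=None
        )
        mid_line = vision.letters_to_nearest_snellen(
            int(round(np.clip(baseline_letters + delta / 2, 0, 100))), config.chart
        )
        va_rows = [(0, baseline_line), (endpoint_offset, year1_line)]
        if mid_offset is not None and abs(mid_offset - 365) > 56:
            va_rows.insert(1, (mid_offset, mid_line))
        for o, line in va_rows:
            tables["va"].append(
                {
                    "patient_id": pid,
                    "laterality": eye_lat,
                    "date": day(o),
                    "snellen_num": float(line.numerator),
                    "snellen_den": float(line.denominator),
                }
            )

        # --- exclusion-criterion events ---------------------------------
        dx_viols = {
            "dr_dme": "dr_dme",
            "vitreous_hemorrhage": "vitreous_hemorrhage",
            "rrd_macular_hole": "rrd_macular_hole",
            "fibrosis_ga": "fibrosis_ga",
            "cnv_other": "cnv_other",
            "other_va_compromising": "other_va_compromising",
        }
        for crit, cat in dx_viols.items():
            if viol[crit]:
                tables["diagnoses"].append(
                    {
                        "patient_id": pid,
                        "laterality": eye_lat,
                        "date": day(-int(rng_i.integers(0, 301))),
                        "code_category": cat,
                    }
                )
        if viol["ppv"]:
            tables["procedures"].append(
                {
                    "patient_id": pid,
                    "laterality": eye_lat,
                    "date": day(-int(rng_i.integers(100, 301))),
                    "category": "ppv",
                }
            )
        if viol["recent_surgery"]:
            tables["procedures"].append(
                {
                    "patient_id": pid,
                    "laterality": eye_lat,
                    "date": day(-int(rng_i.integers(1, 60))),
                    "category": "intraocular_surgery",
                }
            )
        if viol["prior_treatment"]:
            tables["procedures"].append(
                {
                    "patient_id": pid,
                    "laterality": eye_lat,
                    "date": day(-int(rng_i.integers(400, 601))),
                    "category": "pdt",
                }
            )
        if viol["glaucoma"]:
            for off in (30, 90):
                tables["iop"].append(
                    {
                        "patient_id": pid,
                        "laterality": eye_lat,
                        "date": day(-off),
                        "mmhg": float(rng_i.integers(26, 36)),
                    }
                )
        else:
            tables["iop"].append(
                {
                    "patient_id": pid,
                    "laterality": eye_lat,
                    "date": day(-60),
                    "mmhg": float(rng_i.integers(10, 21)),
                }
            )

        # --- adverse event ----------------------------------------------
        endo = bool(endo_flags[i])
        if endo:
            inj_o = int(rng_i.choice(inj_offsets))
            tables["diagnoses"].append(
                {
                    "patient_id": pid,
                    "laterality": eye_lat,
                    "date": day(inj_o + int(rng_i.integers(1, 22))),
                    "code_category": "endophthalmitis",
                }
            )

        # --- patient row: age stored relative to first record -----------
        first_day = min(patient_dates)
        elapsed_years = (index_date - first_day).days // 365
        tables["patients"].append(
            {
                "patient_id": pid,
                "age_at_first_record": int(ages[i]) - elapsed_years,
                "gender": str(gender[i]),
                "race": str(race[i]),
            }
        )

        truth = {
            "patient_id": pid,
            "laterality": eye_lat,
            "drug": drug,
            "index_date": index_date.isoformat(),
            "age_at_index": int(ages[i]),
            "gender": str(gender[i]),
            "baseline_letters": baseline_letters,
            "year1_letters": year1_letters,
            "va_change": year1_letters - baseline_letters,
            "n_injections": len(inj_offsets) + (1 if viol["regimen"] else 0),
            "endophthalmitis": int(endo),
            "eligible": int(not any(viol.values())),
        }
        for crit in CHECKABLE_CRITERIA:
            truth[f"pass_{crit}"] = int(not viol[crit])
        truth_rows.append(truth)

    from .cohort import _SCHEMAS

    frames = {}
    for name, rows in tables.items():
        df = pd.DataFrame(rows, columns=_SCHEMAS[name])
        sort_cols = [c for c in ("patient_id", "date") if c in df.columns]
        frames[name] = df.sort_values(sort_cols, kind="stable").reset_index(drop=True)
    frames["diagnoses"]["laterality"] = frames["diagnoses"]["laterality"].astype(object)
    registry = Registry(**frames).validate()
    truth = pd.DataFrame(truth_rows)
    if int(truth["eligible"].sum()) == 0:
        raise ConfigurationError(
            "violation fractions left no eligible eyes; increase n_patients "
            "or lower the fractions"
        )
    return registry, truth


# ---------------------------------------------------------------------------
# Trial roster generation


def generate_trial_arm(
    arm_name: str,
    n: int,
    config: TrialArmConfig | None = None,
    seed: int = 0,
) -> list[TrialParticipant]:
    """Draw one trial arm with configured covariate/outcome marginals."""
    if n <= 0:
        raise ConfigurationError("arm size must be positive")
    cfg = config or TrialArmConfig()
    ages = np.clip(
        np.round(
            _substream(seed, f"trial:{arm_name}:age").normal(
                cfg.age_mean, cfg.age_sd, size=n
            )
        ),
        cfg.age_min,
        cfg.age_topcode,
    ).astype(int)
    female = (
        _substream(seed, f"trial:{arm_name}:gender").random(n) < cfg.female_fraction
    )
    baseline = np.clip(
        np.round(
            _truncated_normal(
                _substream(seed, f"trial:{arm_name}:baseline"),
                n,
                cfg.baseline_letters_mean,
                cfg.baseline_letters_sd,
                cfg.baseline_letters_min,
                cfg.baseline_letters_max,
            )
        ),
        cfg.baseline_letters_min,
        cfg.baseline_letters_max,
    ).astype(int)
    change = np.round(
        _substream(seed, f"trial:{arm_name}:change").normal(
            cfg.va_change_mean, cfg.va_change_sd, size=n
        )
    ).astype(int)
    year1 = np.clip(baseline + change, 0, 100).astype(int)
    n_inj = np.clip(
        np.round(
            _substream(seed, f"trial:{arm_name}:inj").normal(
                cfg.injection_mean, cfg.injection_sd, size=n
            )
        ),
        1,
        26,
    ).astype(int)
    endo = (
        _substream(seed, f"trial:{arm_name}:endo").random(n)
        < cfg.endophthalmitis_rate
    )
    return [
        TrialParticipant(
            participant_id=f"{arm_name}:{i:04d}",
            arm=arm_name,
            age=int(ages[i]),
            gender="F" if female[i] else "M",
            baseline_letters=int(baseline[i]),
            year1_letters=int(year1[i]),
            n_injections=int(n_inj[i]),
            endophthalmitis=bool(endo[i]),
        )
        for i in range(n)
    ]


def default_trial_roster(seed: int = 0) -> list[TrialParticipant]:
    """Two monthly trial arms with roster sizes and marginals like the
    published trial (ranibizumab n=301, bevacizumab n=286)."""
    ran = generate_trial_arm(
        "ranibizumab_monthly",
        301,
        TrialArmConfig(female_fraction=0.608, va_change_mean=8.5,
                       injection_mean=11.7, endophthalmitis_rate=2 / 284),
        seed=seed,
    )
    bev = generate_trial_arm(
        "bevacizumab_monthly",
        286,
        TrialArmConfig(female_fraction=0.629, va_change_mean=8.0,
                       injection_mean=11.9, endophthalmitis_rate=4 / 265),
        seed=seed,
    )
    return ran + bev


def trial_frame(participants: Sequence[TrialParticipant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "arm": p.arm,
                "age": p.age,
                "gender": p.gender,
                "baseline_letters": p.baseline_letters,
                "year1_letters": p.year1_letters,
                "n_injections": p.n_injections,
                "endophthalmitis": int(p.endophthalmitis),
            }
            for p in participants
        ]
    )


# ---------------------------------------------------------------------------
# Fixture bundle I/O


def write_fixture_bundle(
    path: str | Path,
    registry: Registry,
    trial: pd.DataFrame,
    ground_truth: pd.DataFrame,
) -> None:
    """Write the registry tables, trial roster and ground truth as CSVs."""
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {path}")
    for name, df in registry.tables().items():
        df.to_csv(path / f"{name}.csv", index=False)
    trial.to_csv(path / "trial.csv", index=False)
    ground_truth.to_csv(path / "ground_truth.csv", index=False)


def read_fixture_bundle(path: str | Path) -> tuple[Registry, pd.DataFrame, pd.DataFrame]:
    """Round-trip reader for :func:`write_fixture_bundle`."""
    from .io import load_registry

    path = Path(path)
    registry = load_registry(path)
    trial = pd.read_csv(path / "trial.csv")
    truth = pd.read_csv(path / "ground_truth.csv")
    return registry, trial, truth
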