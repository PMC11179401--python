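"""1:1 caliper matching of trial participants to eligible registry eyes.

Compatibility requires equal gender, age within +/-5 years (ages >= 90 are
top-coded and only match each other), and baseline acuity within +/-5
letters.  The default solver returns a maximum-cardinality matching of the
compatibility graph; a greedy solver is kept as a sensitivity baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "MatchRules",
    "MatchPair",
    "MatchSet",
    "compatible",
    "match_max_cardinality",
    "match_greedy",
    "match_rate",
    "pairs_frame",
]


@dataclass(frozen=True)
class MatchRules:
    age_caliper_years: int = 5
    va_caliper_letters: int = 5
    topcode_age: int = 90
    gender_exact: bool = True

    def __post_init__(self) -> None:
        if self.age_caliper_years < 0 or self.va_caliper_letters < 0:
            raise ValueError("calipers must be >= 0")


@dataclass(frozen=True)
class MatchPair:
    participant_id: str
    eye_id: str
    age_diff: int
    letter_diff: int


@dataclass
class MatchSet:
    pairs: list[MatchPair]
    unmatched_participants: list[str]

    def __len__(self) -> int:
        return len(self.pairs)


class MissingCovariateError(ValueError):
    """A unit lacks age, gender, or baseline letters."""


def _field(unit, *names):
    for name in names:
        if isinstance(unit, dict):
            if name in unit:
                return unit[name]
        elif hasattr(unit, name):
            return getattr(unit, name)
    raise MissingCovariateError(f"unit lacks any of {names}: {unit!r}")


def _covariates(unit) -> tuple[int, str, int]:
    age = _field(unit, "age", "age_at_index")
    gender = _field(unit, "gender")
    letters = _field(unit, "baseline_letters")
    if pd.isna(age) or pd.isna(letters) or pd.isna(gender):
        raise MissingCovariateError(f"missing covariate in {unit!r}")
    return int(age), str(gender), int(letters)


def compatible(participant, eye, rules: MatchRules = MatchRules()) -> bool:
    """True iff the pair satisfies every caliper.

    Ages at or above the top-code are a single deidentified category: a
    top-coded participant matches only top-coded eyes, regardless of the
    nominal difference.
    """
    p_age, p_gender, p_letters = _covariates(participant)
    e_age, e_gender, e_letters = _covariates(eye)
    if rules.gender_exact and p_gender != e_gender:
        return False
    p_top = p_age >= rules.topcode_age
    e_top = e_age >= rules.topcode_age
    if p_top != e_top:
        return False
    if not p_top and abs(p_age - e_age) > rules.age_caliper_years:
        return False
    return abs(p_letters - e_letters) <= rules.va_caliper_letters


def _as_records(units) -> list[dict]:
    import dataclasses as _dc

    if isinstance(units, pd.DataFrame):
        return units.to_dict("records")
    out = []
    for u in units:
        out.append(_dc.asdict(u) if _dc.is_dataclass(u) else dict(u))
    return out


def _unit_id(record: dict) -> str:
    if "participant_id" in record:
        return str(record["participant_id"])
    if "eye_id" in record:
        return str(record["eye_id"])
    return f"{record['patient_id']}:{record['laterality']}"


def _diffs(p: dict, e: dict) -> tuple[int, int]:
    p_age, _, p_letters = _covariates(p)
    e_age, _, e_letters = _covariates(e)
    return abs(p_age - e_age), abs(p_letters - e_letters)


def match_max_cardinality(
    participants, eyes, rules: MatchRules = MatchRules()
) -> MatchSet:
    """Maximum-cardinality 1:1 matching of the compatibility graph.

    Among maximum matchings, ties are broken deterministically by
    minimising total letter difference, then total age difference, then
    lexicographic (participant, eye) order.  Solved as a rectangular
    assignment problem whose infeasible-edge cost dominates any feasible
    total, so minimising cost maximises the number of feasible pairs.
    """
    p_recs = _as_records(participants)
    e_recs = _as_records(eyes)
    n, m = len(p_recs), len(e_recs)
    if n == 0 or m == 0:
        return MatchSet(pairs=[], unmatched_participants=[_unit_id(r) for r in p_recs])

    p_recs = sorted(p_recs, key=_unit_id)
    e_recs = sorted(e_recs, key=_unit_id)

    k = min(n, m)
    # lexicographic cost layers packed into one int64:
    #   letter diff >> age diff >> (i, j) rank; the infeasible-edge cost
    #   dominates all of them.  Per-edge age diffs can exceed the caliper
    #   only between top-coded units, so 50 bounds any single diff; sizes
    #   beyond ~2000x2000 would need a wider cost type.
    rank_cap = n * m + 1
    age_cap = 50 * k + 1
    cost = np.empty((n, m), dtype=np.int64)
    for i, p in enumerate(p_recs):
        for j, e in enumerate(e_recs):
            if compatible(p, e, rules):
                age_d, let_d = _diffs(p, e)
                cost[i, j] = (let_d * age_cap + age_d) * rank_cap + (i * m + j)
            else:
                cost[i, j] = -1  # placeholder, filled below
    feasible_cap = (
        np.int64((rules.va_caliper_letters * age_cap + 50) * rank_cap + rank_cap) * k
        + 1
    )
    cost[cost < 0] = feasible_cap
    rows, cols = linear_sum_assignment(cost)

    pairs = []
    matched_p = set()
    for i, j in zip(rows, cols):
        p, e = p_recs[i], e_recs[j]
        if compatible(p, e, rules):
            age_d, let_d = _diffs(p, e)
            pairs.append(
                MatchPair(
                    participant_id=_unit_id(p),
                    eye_id=_unit_id(e),
                    age_diff=age_d,
                    letter_diff=let_d,
                )
            )
            matched_p.add(_unit_id(p))
    unmatched = [_unit_id(p) for p in p_recs if _unit_id(p) not in matched_p]
    result = MatchSet(pairs=pairs, unmatched_participants=unmatched)
    _validate(result, p_recs, e_recs, rules)
    return result


def _validate(ms: MatchSet, p_recs, e_recs, rules: MatchRules) -> None:
    """Invariant check run on every solve: pairs valid, no vertex reused."""
    by_p = {_unit_id(r): r for r in p_recs}
    by_e = {_unit_id(r): r for r in e_recs}
    seen_p: set[str] = set()
    seen_e: set[str] = set()
    for pair in ms.pairs:
        assert pair.participant_id not in seen_p, "participant reused"
        assert pair.eye_id not in seen_e, "eye reused"
        seen_p.add(pair.participant_id)
        seen_e.add(pair.eye_id)
        assert compatible(by_p[pair.participant_id], by_e[pair.eye_id], rules)


def match_greedy(
    participants, eyes, rules: MatchRules = MatchRules(), order: Optional[Sequence[str]] = None
) -> MatchSet:
    """Sequential closest-candidate matching in participant order.

    Baseline comparator: never beats the maximum-cardinality solver on
    size, and shows how much the solve order matters.
    """
    p_recs = _as_records(participants)
    e_recs = _as_records(eyes)
    by_id = {_unit_id(p): p for p in p_recs}
    ids = list(order) if order is not None else sorted(by_id)
    available = {_unit_id(e): e for e in e_recs}
    pairs, unmatched = [], []
    for pid in ids:
        p = by_id[pid]
        best = None
        for eid in sorted(available):
            e = available[eid]
            if compatible(p, e, rules):
                age_d, let_d = _diffs(p, e)
                key = (let_d, age_d, eid)
                if best is None or key < best[0]:
                    best = (key, eid, age_d, let_d)
        if best is None:
            unmatched.append(pid)
        else:
            _, eid, age_d, let_d = best
            del available[eid]
            pairs.append(MatchPair(pid, eid, age_d, let_d))
    result = MatchSet(pairs=pairs, unmatched_participants=unmatched)
    _validate(result, p_recs, e_recs, rules)
    return result


def match_rate(matchset: MatchSet, n_participants: int) -> int:
    """Matched share as an integer percent (half rounds up)."""
    if n_participants <= 0:
        raise ValueError("n_participants must be positive")
    import math

    return int(math.floor(100.0 * len(matchset) / n_participants + 0.5))


def pairs_frame(matchset: MatchSet) -> pd.DataFrame:
    rows = []
    for p in matchset.pairs:
        pid, _, lat = p.eye_id.rpartition(":")
        rows.append(
            {
                "participant_id": p.participant_id,
                "patient_id": pid,
                "laterality": lat,
                "age_diff": p.age_diff,
                "letter_diff": p.letter_diff,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "patient_id", "laterality", "age_diff", "letter_diff"],
    )
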