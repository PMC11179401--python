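"""Per-arm outcome summaries: acuity change, responders, injections, cost,
and endophthalmitis incidence, with an optional weighted path.

Costs are carried in integer cents internally; display rounding happens
only at the report layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .ipsw import weighted_mean_sd, effective_n

__all__ = [
    "CostSchedule",
    "ArmSummary",
    "va_change",
    "responder_flags",
    "drug_cost",
    "summarize_arm",
    "ae_incidence",
    "summaries_frame",
]


@dataclass(frozen=True)
class CostSchedule:
    """Per-dose drug cost in whole dollars (stored as cents)."""

    unit_cost_cents: dict = field(
        default_factory=lambda: {"ranibizumab": 200000, "bevacizumab": 5000}
    )

    def cost_cents(self, drug: str) -> int:
        try:
            c = self.unit_cost_cents[drug]
        except KeyError:
            raise KeyError(f"no unit cost for drug {drug!r}") from None
        if c < 0:
            raise ValueError("costs must be >= 0")
        return c


def va_change(baseline: int, year1: int) -> int:
    """Letter change ``year1 - baseline``."""
    return int(year1) - int(baseline)


def responder_flags(change: int) -> tuple[bool, bool]:
    """(gained >= 15 letters, lost >= 15 letters); boundaries inclusive."""
    return change >= 15, change <= -15


def drug_cost(mean_injections: float, drug: str, schedule: CostSchedule = CostSchedule()) -> float:
    """Mean annual drug cost per patient in dollars, exact to the cent."""
    if mean_injections < 0:
        raise ValueError("mean_injections must be >= 0")
    cents = mean_injections * schedule.cost_cents(drug)
    return round(cents) / 100.0


def ae_incidence(flags, weights=None) -> tuple[float, float]:
    """(count, percent) of flagged units; percent rounded to 2 decimals."""
    f = np.asarray(flags, dtype=float)
    if f.size == 0:
        raise ValueError("empty arm")
    if weights is None:
        count = float(f.sum())
        pct = 100.0 * count / f.size
    else:
        w = np.asarray(weights, dtype=float)
        count = float((w * f).sum())
        pct = 100.0 * count / w.sum()
    return count, round(pct, 2)


@dataclass
class ArmSummary:
    arm: str
    drug: str
    n: float
    n_va: float
    mean_change_letters: Optional[float]
    sd_change_letters: Optional[float]
    pct_gain15: Optional[float]
    pct_loss15: Optional[float]
    mean_injections: float
    cost_per_patient: float  # dollars, exact mean injections x unit cost
    endophthalmitis_n: float
    endophthalmitis_pct: float
    effective_n: Optional[float] = None


def summarize_arm(
    frame: pd.DataFrame,
    arm: str,
    drug: str,
    weights=None,
    schedule: CostSchedule = CostSchedule(),
) -> ArmSummary:
    """Summarise one arm's outcomes, optionally under positive weights.

    ``frame`` needs columns ``baseline_letters``, ``year1_letters`` (may be
    missing/NaN), ``n_injections`` (or ``n_injections_year1``) and
    ``endophthalmitis``.  Eyes lacking a year-1 score stay in the arm for
    injection/cost/safety outcomes but drop out of the VA-change summary;
    ``n_va`` reports that denominator explicitly.
    """
    if len(frame) == 0:
        raise ValueError("empty arm")
    inj_col = "n_injections" if "n_injections" in frame.columns else "n_injections_year1"
    w = None if weights is None else np.asarray(weights, dtype=float)
    if w is not None and len(w) != len(frame):
        raise ValueError("weights length mismatch")

    year1 = pd.to_numeric(frame["year1_letters"], errors="coerce")
    has_va = year1.notna().to_numpy()
    change = (year1 - frame["baseline_letters"]).to_numpy(dtype=float)

    if w is None:
        n = float(len(frame))
        n_va = float(has_va.sum())
        mean_inj = float(frame[inj_col].mean())
        eff_n = None
    else:
        n = float(w.sum())
        n_va = float(w[has_va].sum())
        mean_inj, _ = weighted_mean_sd(frame[inj_col], w)
        eff_n = effective_n(w)

    if has_va.sum() >= 2:
        cv = change[has_va]
        if w is None:
            mean_change = float(cv.mean())
            sd_change = float(cv.std(ddof=1))
            gain = float(np.mean(cv >= 15)) * 100
            loss = float(np.mean(cv <= -15)) * 100
        else:
            wv = w[has_va]
            mean_change, sd_change = weighted_mean_sd(cv, wv)
            gain = 100.0 * float(wv[cv >= 15].sum() / wv.sum())
            loss = 100.0 * float(wv[cv <= -15].sum() / wv.sum())
    else:
        mean_change = sd_change = gain = loss = None

    endo_count, endo_pct = ae_incidence(
        frame["endophthalmitis"].astype(float), weights=w
    )
    return ArmSummary(
        arm=arm,
        drug=drug,
        n=n,
        n_va=n_va,
        mean_change_letters=mean_change,
        sd_change_letters=sd_change,
        pct_gain15=gain,
        pct_loss15=loss,
        mean_injections=mean_inj,
        cost_per_patient=drug_cost(mean_inj, drug, schedule),
        endophthalmitis_n=endo_count,
        endophthalmitis_pct=endo_pct,
        effective_n=eff_n,
    )


def summaries_frame(summaries: list[ArmSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])
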