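"""Visual-acuity representations and selection rules.

Snellen chart fractions are converted to an approximated ETDRS letter score
with ``85 + 50 * log10(fraction)``, rounded half-away-from-zero to the
nearest letter and clamped to [0, 100].  Selection helpers pick the
best-documented score on a day, a baseline score at (or shortly before) an
index date, and a 1-year endpoint score.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "SnellenAcuity",
    "VAEvent",
    "STANDARD_CHART",
    "snellen_to_letters",
    "snellen_letters_array",
    "letters_to_nearest_snellen",
    "best_documented_letters",
    "select_baseline_va",
    "select_year1_va",
]


class InvalidAcuityError(ValueError):
    """Raised for non-positive or out-of-range Snellen fractions."""


@dataclass(frozen=True, order=True)
class SnellenAcuity:
    """A Snellen chart line, e.g. 20/40.

    ``numerator`` is the test distance (conventionally 20 feet) and
    ``denominator`` the distance at which the optotype subtends 5 arcmin.
    The fraction numerator/denominator must lie in (0, 2].
    """

    numerator: float
    denominator: float

    def __post_init__(self) -> None:
        if self.numerator <= 0 or self.denominator <= 0:
            raise InvalidAcuityError(
                f"Snellen values must be positive, got "
                f"{self.numerator}/{self.denominator}"
            )
        if self.fraction > 2:
            raise InvalidAcuityError(
                f"Snellen fraction {self.fraction:g} outside (0, 2]"
            )

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator

    def __str__(self) -> str:  # pragma: no cover - display helper
        return f"{self.numerator:g}/{self.denominator:g}"


#: Chart used by the synthetic generator; denominators are configurable.
#: Includes better-than-20/20 lines (90/95/100 letters) so endpoint scores
#: are not artificially ceilinged at 85.
STANDARD_CHART: tuple[SnellenAcuity, ...] = tuple(
    SnellenAcuity(20, d)
    for d in (10, 12.5, 16, 20, 25, 32, 40, 50, 63, 80,
              100, 125, 160, 200, 250, 320, 400)
)


@dataclass(frozen=True)
class VAEvent:
    """One visual-acuity measurement of one eye on one calendar day."""

    eye: object
    date: _dt.date
    acuity: SnellenAcuity


def _round_half_away(x: float) -> int:
    """Round to nearest integer with ties going away from zero.

    Python's ``round`` uses banker's rounding, which would silently shift
    chart lines that land exactly on .5.
    """
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def snellen_to_letters(acuity: SnellenAcuity) -> int:
    """Convert a Snellen fraction to an approximated ETDRS letter score.

    Returns ``round(85 + 50 * log10(numerator / denominator))`` with
    half-away-from-zero rounding, clamped to [0, 100].
    """
    raw = 85.0 + 50.0 * math.log10(acuity.fraction)
    return max(0, min(100, _round_half_away(raw)))


def snellen_letters_array(numerators, denominators) -> np.ndarray:
    """Vectorised :func:`snellen_to_letters` for table-level conversion.

    Uses the same half-away-from-zero rounding so per-row results match the
    scalar function exactly.
    """
    num = np.asarray(numerators, dtype=float)
    den = np.asarray(denominators, dtype=float)
    if np.any(num <= 0) or np.any(den <= 0):
        raise InvalidAcuityError("Snellen values must be positive")
    raw = 85.0 + 50.0 * np.log10(num / den)
    rounded = np.sign(raw) * np.floor(np.abs(raw) + 0.5)
    return np.clip(rounded, 0, 100).astype(int)


def letters_to_nearest_snellen(
    letters: int, chart: Sequence[SnellenAcuity] = STANDARD_CHART
) -> SnellenAcuity:
    """Return the chart line whose letter score is closest to ``letters``.

    Ties are broken toward the better (higher-letters) line.  Used by the
    synthetic generator to emit chart-valued acuities.
    """
    if not chart:
        raise ValueError("chart must be non-empty")
    return min(
        chart,
        key=lambda line: (abs(snellen_to_letters(line) - letters),
                          -snellen_to_letters(line)),
    )


def best_documented_letters(
    events: Iterable[VAEvent], eye: object, date: _dt.date
) -> Optional[int]:
    """Best (maximum) converted letter score for ``eye`` on ``date``.

    Returns ``None`` when the eye has no measurement that day.
    """
    scores = [
        snellen_to_letters(ev.acuity)
        for ev in events
        if ev.eye == eye and ev.date == date
    ]
    return max(scores) if scores else None


def select_baseline_va(
    events: Iterable[VAEvent],
    eye: object,
    index_date: _dt.date,
    lookback_days: int = 14,
) -> Optional[int]:
    """Baseline letter score: index-day VA, else nearest prior VA in window.

    Prefers a measurement on the index date; otherwise takes the
    best-documented score at the closest earlier date within
    ``lookback_days``.  Returns ``None`` when no measurement qualifies.
    """
    if lookback_days < 0:
        raise ValueError("lookback_days must be >= 0")
    events = [ev for ev in events if ev.eye == eye]
    on_index = best_documented_letters(events, eye, index_date)
    if on_index is not None:
        return on_index
    prior_dates = sorted(
        {
            ev.date
            for ev in events
            if index_date - _dt.timedelta(days=lookback_days)
            <= ev.date
            < index_date
        },
        reverse=True,
    )
    if prior_dates:
        return best_documented_letters(events, eye, prior_dates[0])
    return None


def select_year1_va(
    events: Iterable[VAEvent],
    eye: object,
    index_date: _dt.date,
    target_offset_days: int = 365,
    window_days: int = 56,
) -> Optional[int]:
    """1-year endpoint: best-documented VA at the date nearest index+365.

    Only dates within ``±window_days`` of the target qualify; distance ties
    are broken toward the later date.  Returns ``None`` when no date
    qualifies.
    """
    if window_days < 0:
        raise ValueError("window_days must be >= 0")
    target = index_date + _dt.timedelta(days=target_offset_days)
    events = [ev for ev in events if ev.eye == eye]
    candidates = sorted(
        {
            ev.date
            for ev in events
            if abs((ev.date - target).days) <= window_days
        }
    )
    if not candidates:
        return None
    # max over reversed-sorted dates keeps the later date on a distance tie
    best = min(
        reversed(candidates), key=lambda d: abs((d - target).days)
    )
    return best_documented_letters(events, eye, best)
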