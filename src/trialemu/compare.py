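"""Unpaired two-sample t-tests, from raw samples or summary statistics.

The pooled-variance variant is the default: recomputing the published
comparisons from their printed summary triples reproduces them under
pooling (Welch differs in the second decimal on one of them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ipsw import effective_n, weighted_mean_sd

__all__ = [
    "SummaryStat",
    "TTestResult",
    "t_test_from_summary",
    "t_test_from_samples",
    "comparison_table",
]


@dataclass(frozen=True)
class SummaryStat:
    mean: float
    sd: float
    n: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    method: str


def t_test_from_summary(
    a: SummaryStat, b: SummaryStat, method: str = "pooled"
) -> TTestResult:
    """Two-sided unpaired t-test from two (mean, sd, n) triples."""
    if method == "pooled":
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        se = math.sqrt(sp2 * (1 / a.n + 1 / b.n))
        df = a.n + b.n - 2
    elif method == "welch":
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    else:
        raise ValueError(f"unknown method {method!r}")
    t = (a.mean - b.mean) / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=t, df=float(df), p=min(p, 1.0), method=method)


def t_test_from_samples(
    xs, ys, method: str = "pooled", weights_x=None, weights_y=None
) -> TTestResult:
    """Reduce samples to summary statistics, then test.

    Weighted samples use the weighted mean/SD with the Kish effective
    sample size as n — a documented approximation.
    """
    def reduce(values, weights) -> SummaryStat:
        v = np.asarray(values, dtype=float)
        if len(v) < 2:
            raise ValueError("each sample needs n >= 2")
        if weights is None:
            return SummaryStat(float(v.mean()), float(v.std(ddof=1)), len(v))
        mean, sd = weighted_mean_sd(v, weights)
        return SummaryStat(mean, sd, effective_n(weights))

    return t_test_from_summary(reduce(xs, weights_x), reduce(ys, weights_y), method)


def comparison_table(contrasts, method: str = "pooled"):
    """Run the configured pairwise contrasts.

    ``contrasts`` is an iterable of ``(label, SummaryStat, SummaryStat)``;
    returns one result row per contrast.
    """
    rows = []
    for label, a, b in contrasts:
        res = t_test_from_summary(a, b, method=method)
        rows.append(
            {
                "contrast": label,
                "mean_a": a.mean,
                "mean_b": b.mean,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "method": res.method,
            }
        )
    import pandas as pd

    return pd.DataFrame(rows)
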