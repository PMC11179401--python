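"""Text renderings of the pipeline outputs.

Attrition, baseline-characteristics (with fractional weighted counts on
the weighted arms) and outcome tables, laid out as aligned text.  The CSV
outputs stay full precision; rounding happens only here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["render_attrition", "render_baseline", "render_outcomes"]


def render_attrition(attrition_df: pd.DataFrame) -> str:
    df = attrition_df.copy()
    df["pct_of_initial_eyes"] = df["pct_of_initial_eyes"].map("{:.1f}%".format)
    return df[["label", "patients_remaining", "eyes_remaining", "pct_of_initial_eyes"]].to_string(index=False)


def _arm_block(frame: pd.DataFrame, weights=None) -> dict:
    """Baseline characteristic tallies; fractional under weights."""
    w = np.ones(len(frame)) if weights is None else np.asarray(weights, dtype=float)
    age_col = "age" if "age" in frame.columns else "age_at_index"
    n = w.sum()
    female = w[(frame["gender"] == "F").to_numpy()].sum()
    letters = frame["baseline_letters"].to_numpy(dtype=float)
    mean_age = float((w * frame[age_col].to_numpy(dtype=float)).sum() / n)
    mean_letters = float((w * letters).sum() / n)
    bands = {
        "68-82 letters": (68, 82),
        "53-67 letters": (53, 67),
        "38-52 letters": (38, 52),
        "23-37 letters": (23, 37),
    }
    block = {
        "N": round(float(n), 1),
        "Age mean": round(mean_age, 2),
        "Female n": round(float(female), 1),
        "Female %": round(100.0 * female / n, 1),
        "Mean letters": round(mean_letters, 2),
    }
    for name, (lo, hi) in bands.items():
        in_band = w[(letters >= lo) & (letters <= hi)].sum()
        block[name] = round(float(in_band), 1)
        block[f"{name} %"] = round(100.0 * in_band / n, 1)
    return block


def render_baseline(arm_frames: dict[str, tuple[pd.DataFrame, np.ndarray | None]]) -> str:
    """``arm_frames`` maps arm label -> (frame, optional weights)."""
    blocks = {
        label: _arm_block(frame, weights)
        for label, (frame, weights) in arm_frames.items()
    }
    return pd.DataFrame(blocks).to_string()


def render_outcomes(outcomes_df: pd.DataFrame) -> str:
    if outcomes_df.empty:
        return "(no arms)"
    df = outcomes_df.copy()
    for col in ("mean_change_letters", "sd_change_letters", "mean_injections"):
        df[col] = df[col].map(lambda v: "-" if pd.isna(v) else f"{v:.1f}")
    for col in ("pct_gain15", "pct_loss15"):
        df[col] = df[col].map(lambda v: "-" if pd.isna(v) else f"{v:.1f}%")
    df["cost_per_patient"] = df["cost_per_patient"].map("${:,.2f}".format)
    df["endophthalmitis_pct"] = df["endophthalmitis_pct"].map("{:.2f}%".format)
    cols = [
        "arm",
        "n",
        "n_va",
        "mean_change_letters",
        "sd_change_letters",
        "pct_gain15",
        "pct_loss15",
        "mean_injections",
        "cost_per_patient",
        "endophthalmitis_n",
        "endophthalmitis_pct",
    ]
    return df[cols].to_string(index=False)
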