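"""Outcome coding and participant exclusion rules.

The questionnaire outcome is the number of active (walking) one-way trips to
or from school in a week, an integer 0–10.  Participants reporting 4–10 trips
are coded active (1), 0–3 non-active (0).  Cyclists are excluded outright
(not recoded), as are records with missing outcome or unusable addresses.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["dichotomize_acs", "apply_exclusions", "median_dummy"]

ACTIVE_MIN_TRIPS = 4


def dichotomize_acs(trips: int) -> int:
    """1 if weekly active trips are in [4, 10], 0 if in [0, 3]."""
    t = int(trips)
    if not 0 <= t <= 10:
        raise ValueError(f"trip count {t} outside [0, 10]")
    return int(t >= ACTIVE_MIN_TRIPS)


def apply_exclusions(participants: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove unusable questionnaire records.

    Exclusion reasons, applied in order and logged per participant:

    - ``missing_acs``: no weekly trip count reported;
    - ``bike``: commuted by bicycle (excluded, not recoded to active);
    - ``bad_address``: home coordinates missing or non-finite;
    - ``null``: completely empty record (no age group).

    Returns (retained roster, log with columns ``pid, reason``).  The
    operation is idempotent and retained + excluded = input count.
    """
    df = participants.copy()
    reasons: list[tuple[object, str]] = []
    keep = pd.Series(True, index=df.index)

    def mark(mask: pd.Series, reason: str) -> None:
        for pid in df.loc[mask & keep, "pid"]:
            reasons.append((pid, reason))
        keep.loc[mask & keep] = False

    if "age_group" in df:
        mark(df["age_group"].isna(), "null")
    if "trips" in df:
        mark(df["trips"].isna(), "missing_acs")
    if "mode" in df:
        mark(df["mode"] == "bike", "bike")
    for col in ("home_x", "home_y"):
        if col in df:
            vals = pd.to_numeric(df[col], errors="coerce")
            mark(vals.isna() | ~np.isfinite(vals.fillna(np.nan)), "bad_address")
    retained = df.loc[keep].copy()
    log = pd.DataFrame(reasons, columns=["pid", "reason"])
    return retained, log


def median_dummy(values: Sequence[float]) -> np.ndarray:
    """Median-split dummy coding: 1 where value > median, else 0.

    The median is taken over the participant-level column passed in (each
    participant carrying their school's value), matching the regression's
    unit of analysis; values exactly at the median code to 0 (strict >).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one value")
    med = np.median(x)
    return (x > med).astype(int)
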