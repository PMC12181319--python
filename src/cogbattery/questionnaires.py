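"""Scoring of the four self-report instruments.

PHQ-9 (depressiveness, sum 0–27), PSQ-20 (perceived stress, transformed
0–100 with four subscales), GAD-7 (anxiety, sum 0–21) and WHO-5 (well-being,
sum × 4, 0–100). Severity bands follow the instruments' published cut
points. Missing items are never imputed: an incomplete instrument is
invalid for that participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .data_model import item_columns


@dataclass(frozen=True)
class QuestionnaireResult:
    instrument: str
    total: float
    band: str
    subscales: dict[str, float] = field(default_factory=dict)
    flag: Optional[bool] = None  # clinical / poor-wellbeing flag where defined


def _check_items(items: Sequence[int], n: int, vmax: int, name: str) -> list[int]:
    items = list(items)
    if len(items) != n:
        raise ValueError(f"{name} requires exactly {n} items, got {len(items)}")
    for v in items:
        if not isinstance(v, (int,)) or isinstance(v, bool):
            if not float(v).is_integer():
                raise ValueError(f"{name} items must be integers")
            v = int(v)
        if v < 0 or v > vmax:
            raise ValueError(f"{name} items must be in 0..{vmax}, got {v}")
    return [int(v) for v in items]


def score_phq9(items: Sequence[int]) -> QuestionnaireResult:
    """PHQ-9 total = item sum (0–27); bands minimal/mild/moderate/
    moderately_severe/severe at 0–4 / 5–9 / 10–14 / 15–19 / >=20."""
    items = _check_items(items, 9, 3, "PHQ-9")
    total = sum(items)
    if total <= 4:
        band = "minimal"
    elif total <= 9:
        band = "mild"
    elif total <= 14:
        band = "moderate"
    elif total <= 19:
        band = "moderately_severe"
    else:
        band = "severe"
    return QuestionnaireResult("phq9", float(total), band)


#: Standard PSQ-20 subscale key (1-based item numbers in administration order).
#: The joy subscale is reverse-coded in the total.
PSQ20_SUBSCALES: Mapping[str, tuple[int, ...]] = {
    "worries": (1, 5, 9, 13, 17),
    "tension": (2, 6, 10, 14, 18),
    "joy": (3, 7, 11, 15, 19),
    "demands": (4, 8, 12, 16, 20),
}


def score_psq20(
    items: Sequence[int],
    subscale_map: Mapping[str, tuple[int, ...]] = PSQ20_SUBSCALES,
    joy_subscale: str = "joy",
) -> QuestionnaireResult:
    """PSQ-20: subscale score = mean(items)/3*100 (joy items reverse-coded
    item-wise, x -> 3-x, before averaging); total = mean of the four
    transformed subscales. ``subscale_map`` must partition items 1..20 into
    four sets of five."""
    items = _check_items(items, 20, 3, "PSQ-20")
    covered = sorted(i for idxs in subscale_map.values() for i in idxs)
    if len(subscale_map) != 4 or any(len(v) != 5 for v in subscale_map.values()):
        raise ValueError("subscale_map must contain four subscales of five items")
    if covered != list(range(1, 21)):
        raise ValueError("subscale_map must partition items 1..20")
    if joy_subscale not in subscale_map:
        raise ValueError(f"joy subscale {joy_subscale!r} not in subscale_map")
    subscales = {}
    for name, idxs in subscale_map.items():
        vals = [items[i - 1] for i in idxs]
        if name == joy_subscale:
            vals = [3 - v for v in vals]
        subscales[name] = sum(vals) / 5 / 3 * 100
    total = sum(subscales.values()) / 4
    # No published severity cut points are adopted for the PSQ-20 total.
    return QuestionnaireResult("psq20", total, "na", subscales=subscales)


def score_gad7(items: Sequence[int]) -> QuestionnaireResult:
    """GAD-7 total = item sum (0–21); bands minimal/mild/moderate/severe at
    0–4 / 5–9 / 10–14 / >=15; clinical flag above 10."""
    items = _check_items(items, 7, 3, "GAD-7")
    total = sum(items)
    if total <= 4:
        band = "minimal"
    elif total <= 9:
        band = "mild"
    elif total <= 14:
        band = "moderate"
    else:
        band = "severe"
    return QuestionnaireResult("gad7", float(total), band, flag=total > 10)


def score_who5(items: Sequence[int]) -> QuestionnaireResult:
    """WHO-5 total = item sum × 4 (0–100); totals <= 50 flag poor well-being."""
    items = _check_items(items, 5, 5, "WHO-5")
    total = sum(items) * 4
    flag = total <= 50
    return QuestionnaireResult(
        "who5", float(total), "poor" if flag else "good", flag=flag
    )


_SCORERS = {
    "phq9": score_phq9,
    "psq20": score_psq20,
    "gad7": score_gad7,
    "who5": score_who5,
}


def score_survey_frame(survey: pd.DataFrame) -> pd.DataFrame:
    """Score all four instruments for every survey row.

    Returns one row per participant with totals, the PSQ-20 subscales and
    the severity bands (``questionnaire_scores.csv`` layout).
    """
    out = []
    for _, row in survey.iterrows():
        rec: dict = {"participant_id": row["participant_id"]}
        for prefix in _SCORERS:
            items = [int(row[c]) for c in item_columns(prefix)]
            res = _SCORERS[prefix](items)
            rec[f"{prefix}_total"] = res.total
            rec[f"{prefix}_band"] = res.band
            for sub, val in res.subscales.items():
                rec[f"{prefix}_{sub}"] = val
        out.append(rec)
    return pd.DataFrame(out)
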