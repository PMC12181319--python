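"""Mnemonic-similarity-task (MST) and Corsi block-tapping scoring.

MST test trials present targets (studied objects), lures (similar variants)
and foils (new objects); participants answer old / similar / new. The three
indices are simple conditional response proportions:

* LDI  (lure discrimination)  = P("similar" | lure)  - P("similar" | foil)
* REC  (item recognition)     = P("old" | target)    - P("old" | foil)
* PC bias (pattern completion)= P("old" | lure)      - P("similar" | lure)

Denominators are responded, post-filter trials of the item type; trials
faster than 100 ms are discarded as accidental key presses and nonresponses
never enter a denominator. A participant is included only when every
response key was used at least once and every item category retains at
least 10 analyzable trials.

The Corsi block span is the greatest sequence length reproduced correctly
in at least three of five administered trials; a participant failing that
criterion already at length three is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

MST_FAST_GUESS_MS = 100.0
MST_MIN_TRIALS_PER_CATEGORY = 10
MST_ITEM_TYPES = ("target", "lure", "foil")
MST_RESPONSE_KEYS = ("old", "similar", "new")

CORSI_TRIALS_PER_LENGTH = 5
CORSI_PASS_CRITERION = 3


@dataclass(frozen=True)
class MstFilterStats:
    n_trials_in: int
    n_filtered_fast: int
    n_nonresponse: int


@dataclass(frozen=True)
class MstIndices:
    ldi: float
    rec: float
    pc_bias: float
    counts: pd.DataFrame  # item type x {old, similar, new, none}
    n_filtered_fast: int
    n_nonresponse: int


@dataclass(frozen=True)
class InclusionDecision:
    included: bool
    reason: str = ""  # "", "key_coverage", "min_trials"


def filter_mst_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, MstFilterStats]:
    """Drop mst_test trials with rt < 100 ms; keep (flagged) nonresponses.

    Idempotent: re-filtering the output changes nothing.
    """
    fast = trials["rt_ms"].notna() & (trials["rt_ms"] < MST_FAST_GUESS_MS)
    kept = trials.loc[~fast].reset_index(drop=True)
    stats = MstFilterStats(
        n_trials_in=len(trials),
        n_filtered_fast=int(fast.sum()),
        n_nonresponse=int((kept["response"] == "none").sum()),
    )
    return kept, stats


def mst_count_table(trials: pd.DataFrame) -> pd.DataFrame:
    """3x4 response-count table (item type x {old, similar, new, none})."""
    tab = pd.crosstab(trials["condition"], trials["response"])
    tab = tab.reindex(
        index=list(MST_ITEM_TYPES),
        columns=list(MST_RESPONSE_KEYS) + ["none"],
        fill_value=0,
    )
    tab.index.name = "item_type"
    tab.columns.name = "response"
    return tab


def mst_inclusion_check(trials: pd.DataFrame) -> InclusionDecision:
    """Apply the participant-level MST inclusion rule to filtered test trials.

    Included iff each of the old/similar/new keys was pressed at least once
    and each item category retains >= 10 responded trials.
    """
    counts = mst_count_table(trials)
    keys_used = counts[list(MST_RESPONSE_KEYS)].sum(axis=0)
    if (keys_used < 1).any():
        return InclusionDecision(False, "key_coverage")
    responded = counts[list(MST_RESPONSE_KEYS)].sum(axis=1)
    if (responded < MST_MIN_TRIALS_PER_CATEGORY).any():
        return InclusionDecision(False, "min_trials")
    return InclusionDecision(True)


def indices_from_counts(counts: pd.DataFrame) -> tuple[float, float, float]:
    """LDI, REC, PC bias from a 3x4 count table (brute-force arithmetic)."""
    responded = counts[list(MST_RESPONSE_KEYS)].sum(axis=1)
    if (responded == 0).any():
        empty = responded.index[responded == 0].tolist()
        raise ZeroDivisionError(
            f"no responded trials for item type(s) {empty}; cannot form "
            "conditional probabilities"
        )
    p = counts[list(MST_RESPONSE_KEYS)].div(responded, axis=0)
    ldi = p.loc["lure", "similar"] - p.loc["foil", "similar"]
    rec = p.loc["target", "old"] - p.loc["foil", "old"]
    pc = p.loc["lure", "old"] - p.loc["lure", "similar"]
    return float(ldi), float(rec), float(pc)


def compute_mst_indices(trials: pd.DataFrame) -> MstIndices:
    """Score one participant's mst_test trials (filters, then indices)."""
    filtered, stats = filter_mst_trials(trials)
    counts = mst_count_table(filtered)
    ldi, rec, pc = indices_from_counts(counts)
    return MstIndices(
        ldi=ldi,
        rec=rec,
        pc_bias=pc,
        counts=counts,
        n_filtered_fast=stats.n_filtered_fast,
        n_nonresponse=stats.n_nonresponse,
    )


def speed_check_mean_rt(trials: pd.DataFrame, response_class: str) -> float:
    """Mean rt (ms) of correct responses of one class on responded trials.

    "Correct" means the canonical response for the item type (old|target,
    similar|lure, new|foil). Used for the speed-accuracy control comparisons.
    """
    if response_class not in MST_RESPONSE_KEYS:
        raise ValueError(f"unknown response class {response_class!r}")
    item_type = {"old": "target", "similar": "lure", "new": "foil"}[response_class]
    sel = trials[
        (trials["condition"] == item_type)
        & (trials["response"] == response_class)
        & trials["rt_ms"].notna()
    ]
    if sel.empty:
        raise ValueError(
            f"no correct {response_class!r} responses; mean rt undefined"
        )
    return float(sel["rt_ms"].mean())


# ---------------------------------------------------------------------------
# Corsi block tapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorsiScore:
    span: int | None  # None when excluded
    excluded: bool
    reason: str = ""
    per_length: dict[int, tuple[int, int]] = field(default_factory=dict)
    # per_length[length] = (n correct, n administered)


def corsi_span(trials: pd.DataFrame, phase: str = "forward") -> CorsiScore:
    """Block span for one participant and phase (forward or backward).

    Span = greatest length with >= 3 correct among its 5 administered trials.
    Lengths administered fewer than five times (the single post-failure
    presentations) can never satisfy the criterion. Failing the criterion at
    length three (< 3/5 correct) signals exclusion.
    """
    task = {"forward": "corsi_fwd", "backward": "corsi_bwd"}.get(phase)
    if task is None:
        raise ValueError("phase must be 'forward' or 'backward'")
    sub = trials[trials["task"] == task]
    if sub.empty:
        raise ValueError(f"no {task} trials")
    per_length: dict[int, tuple[int, int]] = {}
    for length_str, grp in sub.groupby("condition"):
        length = int(length_str)
        n_admin = len(grp)
        n_correct = int(grp["correct"].fillna(False).sum())
        per_length[length] = (n_correct, n_admin)
    lengths = sorted(per_length)
    if lengths[0] != 3:
        raise ValueError("malformed design: Corsi must start at length 3")
    # a fully administered pre-failure length has exactly 5 trials
    n3_correct, n3_admin = per_length[3]
    if n3_admin != CORSI_TRIALS_PER_LENGTH:
        raise ValueError("malformed design: length 3 must have 5 trials")
    if n3_correct < CORSI_PASS_CRITERION:
        return CorsiScore(None, True, "initial_level_failed", per_length)
    span = 0
    for length in lengths:
        n_correct, n_admin = per_length[length]
        if n_admin >= CORSI_TRIALS_PER_LENGTH and n_correct >= CORSI_PASS_CRITERION:
            span = max(span, length)
    return CorsiScore(span, False, "", per_length)


def score_mst_table(test_trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant MST scores with inclusion flags (mst_scores.csv layout)."""
    rows = []
    for pid, grp in test_trials.groupby("participant_id", sort=True):
        filtered, stats = filter_mst_trials(grp)
        decision = mst_inclusion_check(filtered)
        row: dict = {
            "participant_id": pid,
            "mst_included": decision.included,
            "mst_exclusion_reason": decision.reason,
            "n_filtered_fast": stats.n_filtered_fast,
            "n_nonresponse": stats.n_nonresponse,
            "ldi": float("nan"),
            "rec": float("nan"),
            "pc_bias": float("nan"),
        }
        if decision.included:
            ldi, rec, pc = indices_from_counts(mst_count_table(filtered))
            row.update(ldi=ldi, rec=rec, pc_bias=pc)
        rows.append(row)
    return pd.DataFrame(rows)


def score_corsi_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant forward/backward spans (corsi_scores.csv layout)."""
    rows: dict[str, dict] = {}
    for phase, key in (("forward", "fwd"), ("backward", "bwd")):
        sub = trials[trials["task"] == f"corsi_{key}"]
        for pid, grp in sub.groupby("participant_id", sort=True):
            score = corsi_span(grp, phase)
            row = rows.setdefault(pid, {"participant_id": pid})
            row[f"corsi_{key}_span"] = (
                float("nan") if score.excluded else score.span
            )
            row[f"corsi_{key}_excluded"] = score.excluded
            row[f"corsi_{key}_reason"] = score.reason
    return pd.DataFrame(sorted(rows.values(), key=lambda r: r["participant_id"]))
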