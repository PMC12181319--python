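"""Scoring of the speeded executive-function tasks.

Covers tonic alertness (simple RT), the 2-back working-memory task and the
go/no-go task (signal-detection d' with the extreme-rate correction), task
switching (specific switch costs and mixing costs in RT and error rate),
and the stop-signal task (integration-method SSRT under the independent
race model, with the consensus eligibility filters).

d' is Phi^-1(hit rate) - Phi^-1(false-alarm rate). Rates of exactly 0 are
replaced by 0.5/n and rates of exactly 1 by (n-0.5)/n, where n is the trial
count of the respective category; interior rates are untouched.

SSRT (integration method): sort all go-trial RTs ascending, with choice
errors included and omitted go trials replaced by the participant's maximum
observed go RT; take the n-th value, n = round(N_go * p(respond|stop));
SSRT = n-th RT - mean SSD over all stop trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

EF_FAST_GUESS_MS = 100.0
TASKSWITCH_N_BUFFER = 4


# ---------------------------------------------------------------------------
# Signal detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalDetectionScore:
    hit_rate: float
    fa_rate: float
    hit_rate_corrected: float
    fa_rate_corrected: float
    dprime: float
    n_signal: int
    n_noise: int


def corrected_rate(count: int, n: int) -> float:
    """count/n with extreme proportions nudged off 0 and 1.

    0 -> 0.5/n and n -> (n-0.5)/n; interior counts are returned exactly.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    if count < 0 or count > n:
        raise ValueError(f"count must be in 0..{n}")
    if count == 0:
        return 0.5 / n
    if count == n:
        return (n - 0.5) / n
    return count / n


def dprime(hits: int, n_signal: int, fas: int, n_noise: int) -> SignalDetectionScore:
    """Sensitivity d' = z(hit rate) - z(false-alarm rate), extreme rates corrected."""
    if n_signal <= 0 or n_noise <= 0:
        raise ValueError("n_signal and n_noise must be >= 1")
    hr = corrected_rate(hits, n_signal)
    fr = corrected_rate(fas, n_noise)
    d = float(sps.norm.ppf(hr) - sps.norm.ppf(fr))
    return SignalDetectionScore(
        hit_rate=hits / n_signal,
        fa_rate=fas / n_noise,
        hit_rate_corrected=hr,
        fa_rate_corrected=fr,
        dprime=d,
        n_signal=n_signal,
        n_noise=n_noise,
    )


# ---------------------------------------------------------------------------
# Alertness
# ---------------------------------------------------------------------------

ALERTNESS_MIN_RESPONSE_RATE = 0.5


@dataclass(frozen=True)
class AlertnessScore:
    mean_rt_ms: float
    accuracy: float
    included: bool
    n_trials: int


def alertness_scores(trials: pd.DataFrame) -> AlertnessScore:
    """Mean RT over responded trials and hit rate; included iff >= 50% responded."""
    responded = trials["rt_ms"].notna()
    n = len(trials)
    if n == 0 or not responded.any():
        raise ValueError("no responded alertness trials; mean RT undefined")
    accuracy = float(responded.mean())
    return AlertnessScore(
        mean_rt_ms=float(trials.loc[responded, "rt_ms"].mean()),
        accuracy=accuracy,
        included=accuracy >= ALERTNESS_MIN_RESPONSE_RATE,
        n_trials=n,
    )


# ---------------------------------------------------------------------------
# N-back
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NbackScore:
    sd: SignalDetectionScore
    mean_hit_rt_ms: float  # NaN when there is no hit


def nback_scores(trials: pd.DataFrame) -> NbackScore:
    """2-back d' (targets = signal, nontargets = noise) and mean hit RT.

    Responses faster than 100 ms are discarded before both the response
    counts and the RT average.
    """
    fast = trials["rt_ms"].notna() & (trials["rt_ms"] < EF_FAST_GUESS_MS)
    t = trials.loc[~fast]
    targets = t[t["condition"] == "target"]
    nontargets = t[t["condition"] == "nontarget"]
    if targets.empty or nontargets.empty:
        raise ValueError("n-back requires both target and nontarget trials")
    hits = int((targets["response"] == "press").sum())
    fas = int((nontargets["response"] == "press").sum())
    sd = dprime(hits, len(targets), fas, len(nontargets))
    hit_rts = targets.loc[targets["response"] == "press", "rt_ms"]
    mean_hit_rt = float(hit_rts.mean()) if len(hit_rts) else float("nan")
    return NbackScore(sd=sd, mean_hit_rt_ms=mean_hit_rt)


# ---------------------------------------------------------------------------
# Task switching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SwitchCosts:
    switch_cost_rt_ms: float
    mixing_cost_rt_ms: float
    switch_cost_err: float
    mixing_cost_err: float
    class_mean_rt_ms: dict[str, float] = field(default_factory=dict)
    class_error_rate: dict[str, float] = field(default_factory=dict)


def drop_taskswitch_buffers(
    trials: pd.DataFrame, n_buffer: int = TASKSWITCH_N_BUFFER
) -> pd.DataFrame:
    """Remove the first ``n_buffer`` trials of each task-switching block."""
    order = trials.sort_values("trial_index").groupby("block").cumcount()
    keep = order.reindex(trials.index) >= n_buffer
    return trials.loc[keep]


def switch_mixing_costs(trials: pd.DataFrame, buffers_dropped: bool = False) -> SwitchCosts:
    """Specific switch and mixing costs in RT and error rate.

    Specific switch cost = switch - repeat (within the heterogeneous block);
    mixing cost = repeat (heterogeneous) - homogeneous. RT costs use correct
    responses with rt >= 100 ms; error rates are the proportion of trials
    per class without a correct response (nonresponses count as errors).
    """
    if not buffers_dropped:
        trials = drop_taskswitch_buffers(trials)
    mean_rt: dict[str, float] = {}
    err: dict[str, float] = {}
    for cls in ("homogeneous", "repeat", "switch"):
        sub = trials[trials["condition"] == cls]
        if sub.empty:
            raise ValueError(f"no analyzable {cls!r} trials")
        ok_rt = (
            sub["correct"].fillna(False)
            & sub["rt_ms"].notna()
            & (sub["rt_ms"] >= EF_FAST_GUESS_MS)
        )
        if not ok_rt.any():
            raise ValueError(f"no correct responses >= 100 ms in class {cls!r}")
        mean_rt[cls] = float(sub.loc[ok_rt, "rt_ms"].mean())
        err[cls] = float(1.0 - sub["correct"].fillna(False).mean())
    return SwitchCosts(
        switch_cost_rt_ms=mean_rt["switch"] - mean_rt["repeat"],
        mixing_cost_rt_ms=mean_rt["repeat"] - mean_rt["homogeneous"],
        switch_cost_err=err["switch"] - err["repeat"],
        mixing_cost_err=err["repeat"] - err["homogeneous"],
        class_mean_rt_ms=mean_rt,
        class_error_rate=err,
    )


# ---------------------------------------------------------------------------
# Go/no-go
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GonogoScore:
    phase1: SignalDetectionScore
    phase2: SignalDetectionScore
    fa_rate: float  # raw false-alarm rate over both phases
    mean_go_rt_ms: float  # correct go responses
    mean_nogo_rt_ms: float  # incorrect no-go responses; NaN if none


def gonogo_scores(trials: pd.DataFrame) -> GonogoScore:
    """Per-phase d' (go = signal, no-go = noise), overall FA rate, RT by type."""
    phases = []
    for block in (0, 1):
        sub = trials[trials["block"] == block]
        go = sub[sub["condition"] == "go"]
        nogo = sub[sub["condition"] == "nogo"]
        if go.empty or nogo.empty:
            raise ValueError(f"phase {block} lacks go or no-go trials")
        hits = int((go["response"] != "none").sum())
        fas = int((nogo["response"] != "none").sum())
        phases.append(dprime(hits, len(go), fas, len(nogo)))
    nogo_all = trials[trials["condition"] == "nogo"]
    fa_rate = float((nogo_all["response"] != "none").mean())
    go_all = trials[trials["condition"] == "go"]
    go_rts = go_all.loc[go_all["response"] != "none", "rt_ms"]
    nogo_rts = nogo_all.loc[nogo_all["response"] != "none", "rt_ms"]
    return GonogoScore(
        phase1=phases[0],
        phase2=phases[1],
        fa_rate=fa_rate,
        mean_go_rt_ms=float(go_rts.mean()) if len(go_rts) else float("nan"),
        mean_nogo_rt_ms=float(nogo_rts.mean()) if len(nogo_rts) else float("nan"),
    )


# ---------------------------------------------------------------------------
# Stop-signal task
# ---------------------------------------------------------------------------

SST_COMMISSION_BOUNDS = (0.25, 0.75)
SST_MAX_OMISSION_RATE = 0.10


@dataclass(frozen=True)
class SstScore:
    eligible: bool
    reasons: tuple[str, ...]
    ssrt_ms: float  # NaN when ineligible
    mean_go_rt_ms: float
    mean_unsuccessful_stop_rt_ms: float
    p_respond_given_stop: float
    mean_ssd_ms: float
    nth_rt_ms: float
    n_used: int


def _sst_summaries(trials: pd.DataFrame):
    go = trials[trials["condition"] == "go"]
    stop = trials[trials["condition"] == "stop"]
    if go.empty or stop.empty:
        raise ValueError("stop-signal record needs both go and stop trials")
    go_responded = go[go["response"] != "none"]
    stop_responded = stop[stop["response"] != "none"]
    p_respond = len(stop_responded) / len(stop)
    omission_rate = 1.0 - len(go_responded) / len(go)
    mean_go_rt = float(go_responded["rt_ms"].mean()) if len(go_responded) else float("nan")
    mean_usrt = (
        float(stop_responded["rt_ms"].mean()) if len(stop_responded) else float("nan")
    )
    return go, stop, go_responded, p_respond, omission_rate, mean_go_rt, mean_usrt


def sst_eligibility(trials: pd.DataFrame) -> tuple[bool, tuple[str, ...]]:
    """Consensus eligibility filters for SSRT estimation.

    Eligible iff p(respond|stop) in [0.25, 0.75], go-omission rate <= 0.10,
    and mean unsuccessful-stop RT below mean go RT. Reasons enumerate every
    violated rule.
    """
    (_, _, go_responded, p_respond, omission_rate,
     mean_go_rt, mean_usrt) = _sst_summaries(trials)
    reasons: list[str] = []
    lo, hi = SST_COMMISSION_BOUNDS
    if not (lo <= p_respond <= hi):
        reasons.append("commission_rate")
    if omission_rate > SST_MAX_OMISSION_RATE:
        reasons.append("omission_rate")
    if len(go_responded) == 0 or not (mean_usrt < mean_go_rt):
        # covers both "no usable go RTs" and slow unsuccessful stops;
        # a stop-respond rate of 0 gives mean_usrt = NaN -> ineligible here
        reasons.append("stop_rt_not_faster")
    return (len(reasons) == 0), tuple(reasons)


def ssrt_integration(trials: pd.DataFrame) -> SstScore:
    """Integration-method SSRT for one participant's stop-signal record."""
    (go, stop, go_responded, p_respond, _omission,
     mean_go_rt, mean_usrt) = _sst_summaries(trials)
    eligible, reasons = sst_eligibility(trials)
    mean_ssd = float(stop["ssd_ms"].mean())
    if not eligible:
        return SstScore(
            eligible=False,
            reasons=reasons,
            ssrt_ms=float("nan"),
            mean_go_rt_ms=mean_go_rt,
            mean_unsuccessful_stop_rt_ms=mean_usrt,
            p_respond_given_stop=p_respond,
            mean_ssd_ms=mean_ssd,
            nth_rt_ms=float("nan"),
            n_used=0,
        )
    rts = go["rt_ms"].to_numpy(dtype=float)
    if len(go_responded) == 0:
        raise ValueError("no responded go trials; SSRT undefined")
    max_rt = float(np.nanmax(rts))
    rts = np.where(np.isnan(rts), max_rt, rts)  # omissions -> max observed RT
    rts.sort(kind="stable")
    n_go = len(rts)
    # half-up rounding, 1-based rank, clamped to the list
    n = int(math.floor(n_go * p_respond + 0.5))
    n = min(max(n, 1), n_go)
    nth_rt = float(rts[n - 1])
    return SstScore(
        eligible=True,
        reasons=(),
        ssrt_ms=nth_rt - mean_ssd,
        mean_go_rt_ms=mean_go_rt,
        mean_unsuccessful_stop_rt_ms=mean_usrt,
        p_respond_given_stop=p_respond,
        mean_ssd_ms=mean_ssd,
        nth_rt_ms=nth_rt,
        n_used=n,
    )


# ---------------------------------------------------------------------------
# Batch scoring
# ---------------------------------------------------------------------------


def score_ef_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant EF measures over all tasks present (ef_scores.csv layout).

    A participant appears once; tasks they did not complete leave NaN columns.
    Participants whose records violate a scorer's preconditions get NaN for
    that task and a reason code.
    """
    rows: dict[str, dict] = {}

    def row(pid: str) -> dict:
        return rows.setdefault(pid, {"participant_id": pid})

    for pid, grp in trials[trials["task"] == "alertness"].groupby("participant_id"):
        r = row(pid)
        try:
            a = alertness_scores(grp)
            r.update(
                alertness_mean_rt_ms=a.mean_rt_ms,
                alertness_accuracy=a.accuracy,
                alertness_included=a.included,
            )
        except ValueError as exc:
            r.update(alertness_included=False, alertness_reason=str(exc))

    for pid, grp in trials[trials["task"] == "nback"].groupby("participant_id"):
        r = row(pid)
        # study rule: at least one key press, otherwise task misunderstood
        if (grp["response"] == "none").all():
            r.update(nback_included=False, nback_reason="no_key_press")
            continue
        nb = nback_scores(grp)
        r.update(
            nback_dprime=nb.sd.dprime,
            nback_hit_rt_ms=nb.mean_hit_rt_ms,
            nback_included=True,
        )

    for pid, grp in trials[trials["task"] == "taskswitch"].groupby("participant_id"):
        r = row(pid)
        try:
            c = switch_mixing_costs(grp)
            r.update(
                switch_cost_rt_ms=c.switch_cost_rt_ms,
                mixing_cost_rt_ms=c.mixing_cost_rt_ms,
                switch_cost_err=c.switch_cost_err,
                mixing_cost_err=c.mixing_cost_err,
                taskswitch_included=True,
            )
        except ValueError as exc:
            r.update(taskswitch_included=False, taskswitch_reason=str(exc))

    for pid, grp in trials[trials["task"] == "gonogo"].groupby("participant_id"):
        r = row(pid)
        try:
            g = gonogo_scores(grp)
            r.update(
                gonogo_dprime_phase1=g.phase1.dprime,
                gonogo_dprime_phase2=g.phase2.dprime,
                gonogo_fa_rate=g.fa_rate,
                gonogo_go_rt_ms=g.mean_go_rt_ms,
                gonogo_included=True,
            )
        except ValueError as exc:
            r.update(gonogo_included=False, gonogo_reason=str(exc))

    for pid, grp in trials[trials["task"] == "sst"].groupby("participant_id"):
        r = row(pid)
        s = ssrt_integration(grp)
        r.update(
            ssrt_ms=s.ssrt_ms,
            sst_eligible=s.eligible,
            sst_reasons=";".join(s.reasons),
            sst_mean_go_rt_ms=s.mean_go_rt_ms,
            sst_p_respond=s.p_respond_given_stop,
            sst_mean_ssd_ms=s.mean_ssd_ms,
        )

    return pd.DataFrame(
        sorted(rows.values(), key=lambda r: r["participant_id"])
    )
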