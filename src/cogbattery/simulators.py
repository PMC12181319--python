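"""Trial-level generators for the eight cognitive tasks and the cohort layer.

Each task generator reproduces the printed trial structure of the battery
(trial counts per condition, block layout, staircase rules) under an
explicit generative model of responding, so every scorer can be exercised
end-to-end against known ground truth:

* MST: per-participant multinomial response propensities by item type; the
  expected scored LDI equals p_lure_similar - p_foil_similar by
  construction.
* Stop-signal: independent race between an ex-Gaussian go process and a
  constant-latency stop process under the 50 ms up/down SSD staircase
  (start 250 ms); a stop trial draws a response iff the sampled go finish
  time is below SSD + true SSRT.
* Go/no-go and n-back: Bernoulli hit / false-alarm responding.
* Task switching: RT = base + mixing effect (heterogeneous block)
  + switch effect (switch trials) + ex-Gaussian noise.
* Corsi: logistic success probability in (capacity - sequence length), with
  the design rule that lengths after a failed level are presented once.
* Alertness: ex-Gaussian simple RT with a miss probability.
* Questionnaires: items are rounded, clipped latent normals with a shared
  participant trait; group shifts are calibrated analytically so a target
  total-score difference is reproduced in expectation.

All randomness flows from numpy Generators; the cohort layer derives one
independent stream per (participant, task) from the master seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from math import log
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .data_model import TRIAL_COLUMNS, item_columns

# ---------------------------------------------------------------------------
# Randomness plumbing
# ---------------------------------------------------------------------------


def _crc(s: str) -> int:
    return zlib.crc32(s.encode("utf8"))


def task_rng(master_seed: int, participant_id: str, task: str) -> np.random.Generator:
    """Independent, reproducible stream for one participant and task."""
    ss = np.random.SeedSequence([int(master_seed), _crc(participant_id), _crc(task)])
    return np.random.Generator(np.random.PCG64(ss))


def _exgauss(rng: np.random.Generator, mu: float, sigma: float, tau: float, size=None):
    return rng.normal(mu, sigma, size=size) + rng.exponential(tau, size=size)


def _cols(pid: str, task: str, n: int) -> dict:
    return {
        "participant_id": [pid] * n,
        "task": [task] * n,
        "block": np.zeros(n, dtype=int),
        "trial_index": np.arange(n, dtype=int),
        "condition": [""] * n,
        "stimulus_id": ["s"] * n,
        "response": ["none"] * n,
        "correct": [None] * n,
        "rt_ms": np.full(n, np.nan),
        "ssd_ms": np.full(n, np.nan),
        "participation_index": np.zeros(n, dtype=int),
    }


def _to_frame(cols: dict) -> pd.DataFrame:
    df = pd.DataFrame(cols, columns=TRIAL_COLUMNS)
    df["correct"] = df["correct"].astype("boolean")
    return df


# ---------------------------------------------------------------------------
# Mnemonic similarity task
# ---------------------------------------------------------------------------

MST_N_STUDY = 128
MST_N_PER_TYPE = 64

#: log-normal RT parameters (meanlog of ms, sdlog) per response key.
MST_RT_LOGPARAMS = {
    "old": (log(1060.0), 0.11),
    "similar": (log(1360.0), 0.11),
    "new": (log(1200.0), 0.12),
}


@dataclass(frozen=True)
class MstResponderParams:
    """Multinomial response propensities of one MST responder.

    Per item type, the probability of each named response; the residual mass
    goes to the remaining response key. ``nonresponse_rate`` is applied
    first; ``fast_guess_rate`` replaces a responded trial's RT by a sub-100
    ms accidental press (the response itself is unchanged, so the scorer's
    100 ms filter removes these trials without biasing the indices).
    """

    p_correct_target: float = 0.84  # P(old | target)
    p_target_similar: float = 0.12
    p_lure_similar: float = 0.42
    p_lure_old: float = 0.30
    p_foil_new: float = 0.87
    p_foil_similar: float = 0.10
    nonresponse_rate: float = 0.055
    fast_guess_rate: float = 0.0
    rt_logparams: dict = field(default_factory=lambda: dict(MST_RT_LOGPARAMS))

    def response_probs(self) -> dict[str, np.ndarray]:
        """Per item type, probabilities over (old, similar, new)."""
        p = {
            "target": np.array(
                [
                    self.p_correct_target,
                    self.p_target_similar,
                    1.0 - self.p_correct_target - self.p_target_similar,
                ]
            ),
            "lure": np.array(
                [
                    self.p_lure_old,
                    self.p_lure_similar,
                    1.0 - self.p_lure_old - self.p_lure_similar,
                ]
            ),
            "foil": np.array(
                [
                    1.0 - self.p_foil_new - self.p_foil_similar,
                    self.p_foil_similar,
                    self.p_foil_new,
                ]
            ),
        }
        return p

    def validate(self) -> None:
        if not 0.0 <= self.nonresponse_rate <= 0.2:
            raise ValueError("nonresponse_rate must be in [0, 0.2]")
        if not 0.0 <= self.fast_guess_rate <= 1.0:
            raise ValueError("fast_guess_rate must be in [0, 1]")
        for item_type, probs in self.response_probs().items():
            if (probs < -1e-12).any() or probs.sum() > 1 + 1e-12:
                raise ValueError(
                    f"response probabilities for {item_type!r} outside [0, 1]: {probs}"
                )


def simulate_mst(
    params: MstResponderParams,
    seed: int | np.random.Generator,
    participant_id: str = "p0",
) -> pd.DataFrame:
    """One participant's MST record: 128 study and 192 test trials.

    The test phase holds exactly 64 targets, 64 lures and 64 foils in random
    order; lure stimuli carry their studied pair's identity as metadata.
    """
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # 192 stimulus pairs; 128 studied, of which 64 return as targets and 64
    # as their similar pair member (lures); 64 unstudied pairs give foils.
    pair_ids = rng.permutation(192)
    studied = pair_ids[:MST_N_STUDY]
    targets, lure_sources = studied[:MST_N_PER_TYPE], studied[MST_N_PER_TYPE:]
    foils = pair_ids[MST_N_STUDY:]

    study = _cols(participant_id, "mst_study", MST_N_STUDY)
    study["condition"] = ["study"] * MST_N_STUDY
    study["stimulus_id"] = [f"pair{p:03d}a" for p in studied]
    study["response"] = list(rng.choice(["indoor", "outdoor"], size=MST_N_STUDY))
    study["rt_ms"] = np.exp(rng.normal(log(900.0), 0.2, size=MST_N_STUDY))

    conditions = np.array(
        ["target"] * MST_N_PER_TYPE + ["lure"] * MST_N_PER_TYPE + ["foil"] * MST_N_PER_TYPE
    )
    stim = np.array(
        [f"pair{p:03d}a" for p in targets]
        + [f"pair{p:03d}b" for p in lure_sources]
        + [f"pair{p:03d}a" for p in foils]
    )
    order = rng.permutation(len(conditions))
    conditions, stim = conditions[order], stim[order]

    probs = params.response_probs()
    keys = np.array(["old", "similar", "new"])
    responses = np.empty(len(conditions), dtype=object)
    for item_type in ("target", "lure", "foil"):
        m = conditions == item_type
        p = np.clip(probs[item_type], 0.0, 1.0)
        p = p / p.sum()
        idx = rng.choice(3, size=int(m.sum()), p=p)
        responses[m] = keys[idx]
    nonresp = rng.random(len(conditions)) < params.nonresponse_rate
    responses[nonresp] = "none"

    rt = np.full(len(conditions), np.nan)
    for key in keys:
        m = responses == key
        mu, sd = params.rt_logparams[key]
        rt[m] = np.exp(rng.normal(mu, sd, size=int(m.sum())))
    fast = (~nonresp) & (rng.random(len(conditions)) < params.fast_guess_rate)
    rt[fast] = rng.uniform(20.0, 99.0, size=int(fast.sum()))

    canonical = {"target": "old", "lure": "similar", "foil": "new"}
    correct = [
        None if r == "none" else (r == canonical[c])
        for r, c in zip(responses, conditions)
    ]

    test = _cols(participant_id, "mst_test", len(conditions))
    test["condition"] = list(conditions)
    test["stimulus_id"] = list(stim)
    test["response"] = list(responses)
    test["correct"] = correct
    test["rt_ms"] = rt
    return pd.concat([_to_frame(study), _to_frame(test)], ignore_index=True)


# ---------------------------------------------------------------------------
# Stop-signal task
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RaceModelParams:
    """Independent-race generative model for the stop-signal task."""

    mu: float = 450.0  # ex-Gaussian go RT (ms)
    sigma: float = 50.0
    tau: float = 160.0
    true_ssrt_ms: float = 280.0
    p_go_omission: float = 0.02
    p_choice_error: float = 0.02
    initial_ssd_ms: float = 250.0
    step_ms: float = 50.0
    floor_ms: float = 0.0
    ceiling_ms: float = 1250.0
    n_blocks: int = 3
    go_per_block: int = 48
    stop_per_block: int = 16

    def validate(self) -> None:
        if min(self.mu, self.sigma, self.tau) <= 0:
            raise ValueError("mu, sigma, tau must be > 0")
        if self.true_ssrt_ms < 0:
            raise ValueError("true_ssrt_ms must be >= 0")
        if not (0 <= self.p_go_omission <= 1 and 0 <= self.p_choice_error <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.floor_ms > self.ceiling_ms:
            raise ValueError("floor above ceiling")


def simulate_sst(
    params: RaceModelParams,
    seed: int | np.random.Generator,
    participant_id: str = "p0",
) -> pd.DataFrame:
    """One participant's stop-signal record under the adaptive SSD staircase.

    Default design: 3 blocks x (48 go + 16 stop) shuffled within block. The
    SSD starts at 250 ms, moves +50 ms after successful inhibition and
    -50 ms after a failed stop, clamped to [floor, ceiling], and carries
    across blocks. A stop trial yields a response iff the sampled go finish
    time beats SSD + true SSRT.
    """
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    blocks, conditions = [], []
    for b in range(params.n_blocks):
        mix = np.array(["go"] * params.go_per_block + ["stop"] * params.stop_per_block)
        rng.shuffle(mix)
        conditions.extend(mix)
        blocks.extend([b] * len(mix))
    n = len(conditions)

    shapes = rng.choice(["circle", "square"], size=n)
    key_for = {"circle": "f", "square": "j"}
    other = {"f": "j", "j": "f"}

    ssd = params.initial_ssd_ms
    responses, rts, ssds, corrects = [], [], [], []
    for i, cond in enumerate(conditions):
        go_finish = _exgauss(rng, params.mu, params.sigma, params.tau)
        go_finish = max(go_finish, 1.0)
        key = key_for[shapes[i]]
        if rng.random() < params.p_choice_error:
            key = other[key]
        if cond == "go":
            if rng.random() < params.p_go_omission:
                responses.append("none"); rts.append(np.nan); corrects.append(None)
            else:
                responses.append(key); rts.append(go_finish)
                corrects.append(key == key_for[shapes[i]])
            ssds.append(np.nan)
        else:
            ssds.append(ssd)
            if go_finish < ssd + params.true_ssrt_ms:  # go wins the race
                responses.append(key); rts.append(go_finish); corrects.append(False)
                ssd = max(params.floor_ms, ssd - params.step_ms)
            else:  # successful inhibition
                responses.append("none"); rts.append(np.nan); corrects.append(True)
                ssd = min(params.ceiling_ms, ssd + params.step_ms)

    cols = _cols(participant_id, "sst", n)
    cols["block"] = np.array(blocks, dtype=int)
    cols["condition"] = conditions
    cols["stimulus_id"] = list(shapes)
    cols["response"] = responses
    cols["correct"] = corrects
    cols["rt_ms"] = np.array(rts)
    cols["ssd_ms"] = np.array(ssds)
    return _to_frame(cols)


# ---------------------------------------------------------------------------
# Go/no-go
# ---------------------------------------------------------------------------

GONOGO_NOGO_LETTERS_P1 = list("EFHKMNTVWY")
GONOGO_GO_LETTERS_P2 = list("AEFHIKMNRTVWYZ")


@dataclass(frozen=True)
class GonogoParams:
    hit_p: tuple[float, float] = (0.97, 0.95)  # per phase
    fa_p: tuple[float, float] = (0.25, 0.33)
    go_rt_logparams: tuple[float, float] = (log(390.0), 0.14)
    nogo_rt_logparams: tuple[float, float] = (log(330.0), 0.16)


def simulate_gonogo(
    params: GonogoParams,
    seed: int | np.random.Generator,
    participant_id: str = "p0",
) -> pd.DataFrame:
    """Two 100-trial phases (80 go / 20 no-go), roles reversed in phase 2."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    all_cols = []
    for phase in (0, 1):
        if phase == 0:
            stims = ["X"] * 80 + [l for l in GONOGO_NOGO_LETTERS_P1 for _ in range(2)]
            conds = ["go"] * 80 + ["nogo"] * 20
        else:
            # 10 letters x 6 + 4 letters x 5 = 80 go trials from the 14-letter set
            go_letters = [l for l in GONOGO_GO_LETTERS_P2[:10] for _ in range(6)] + [
                l for l in GONOGO_GO_LETTERS_P2[10:] for _ in range(5)
            ]
            stims = go_letters + ["X"] * 20
            conds = ["go"] * 80 + ["nogo"] * 20
        order = rng.permutation(100)
        stims = [stims[i] for i in order]
        conds = [conds[i] for i in order]
        p_press = np.where(
            np.array(conds) == "go", params.hit_p[phase], params.fa_p[phase]
        )
        pressed = rng.random(100) < p_press
        rts = np.full(100, np.nan)
        for cond, lp in (("go", params.go_rt_logparams), ("nogo", params.nogo_rt_logparams)):
            m = pressed & (np.array(conds) == cond)
            rts[m] = np.exp(rng.normal(lp[0], lp[1], size=int(m.sum())))
        correct = [
            (p if c == "go" else not p) for p, c in zip(pressed, conds)
        ]
        cols = _cols(participant_id, "gonogo", 100)
        cols["block"] = np.full(100, phase, dtype=int)
        cols["trial_index"] = np.arange(100 * phase, 100 * (phase + 1))
        cols["condition"] = conds
        cols["stimulus_id"] = stims
        cols["response"] = ["press" if p else "none" for p in pressed]
        cols["correct"] = correct
        cols["rt_ms"] = rts
        all_cols.append(_to_frame(cols))
    return pd.concat(all_cols, ignore_index=True)


# ---------------------------------------------------------------------------
# N-back
# ---------------------------------------------------------------------------

NBACK_LETTERS = list("ABCDFGHJKLMNPSTU")
NBACK_N_BLOCKS = 4
NBACK_BLOCK_LEN = 24
NBACK_TARGETS_PER_BLOCK = 6


@dataclass(frozen=True)
class NbackParams:
    hit_p: float = 0.78
    fa_p: float = 0.08
    rt_logparams: tuple[float, float] = (log(520.0), 0.15)


def simulate_nback(
    params: NbackParams,
    seed: int | np.random.Generator,
    participant_id: str = "p0",
) -> pd.DataFrame:
    """96-trial 2-back task: 4 blocks x 24 trials, 6 targets per block."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    for b in range(NBACK_N_BLOCKS):
        target_pos = rng.choice(
            np.arange(2, NBACK_BLOCK_LEN), size=NBACK_TARGETS_PER_BLOCK, replace=False
        )
        letters: list[str] = []
        for i in range(NBACK_BLOCK_LEN):
            if i in target_pos:
                letters.append(letters[i - 2])
            else:
                l = rng.choice(NBACK_LETTERS)
                while i >= 2 and l == letters[i - 2]:
                    l = rng.choice(NBACK_LETTERS)
                letters.append(str(l))
        conds = [
            "target" if i in target_pos else "nontarget" for i in range(NBACK_BLOCK_LEN)
        ]
        p_press = np.where(np.array(conds) == "target", params.hit_p, params.fa_p)
        pressed = rng.random(NBACK_BLOCK_LEN) < p_press
        rts = np.where(
            pressed,
            np.exp(rng.normal(*params.rt_logparams, size=NBACK_BLOCK_LEN)),
            np.nan,
        )
        cols = _cols(participant_id, "nback", NBACK_BLOCK_LEN)
        cols["block"] = np.full(NBACK_BLOCK_LEN, b, dtype=int)
        cols["trial_index"] = np.arange(b * NBACK_BLOCK_LEN, (b + 1) * NBACK_BLOCK_LEN)
        cols["condition"] = conds
        cols["stimulus_id"] = letters
        cols["response"] = ["press" if p else "none" for p in pressed]
        cols["correct"] = [
            (p if c == "target" else not p) for p, c in zip(pressed, conds)
        ]
        cols["rt_ms"] = rts
        frames.append(_to_frame(cols))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Task switching
# ---------------------------------------------------------------------------

TASKSWITCH_N_HOMOGENEOUS = 28  # per homogeneous block, incl. 4 buffer trials
TASKSWITCH_N_HETEROGENEOUS = 52  # incl. 4 buffer trials; 26 switch / 26 repeat


@dataclass(frozen=True)
class TaskSwitchParams:
    base_rt_ms: float = 620.0
    mixing_effect_ms: float = 260.0
    switch_effect_ms: float = 310.0
    sigma: float = 60.0
    tau: float = 110.0
    error_p: dict = field(
        default_factory=lambda: {"homogeneous": 0.03, "repeat": 0.06, "switch": 0.08}
    )
    nonresponse_p: float = 0.015


def simulate_taskswitch(
    params: TaskSwitchParams,
    seed: int | np.random.Generator,
    participant_id: str = "p0",
) -> pd.DataFrame:
    """Two homogeneous 28-trial blocks and one 52-trial heterogeneous block.

    The first four trials of each block are warm-up buffers (removed by the
    scorer), leaving 24 + 24 + 48 valid trials. Heterogeneous trials hold
    exactly 26 switch and 26 repeat trials.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    trial_counter = 0
    for b, n in ((0, TASKSWITCH_N_HOMOGENEOUS), (1, TASKSWITCH_N_HOMOGENEOUS),
                 (2, TASKSWITCH_N_HETEROGENEOUS)):
        if b < 2:
            conds = ["homogeneous"] * n
        else:
            conds = ["switch"] * (n // 2) + ["repeat"] * (n // 2)
            rng.shuffle(conds)
        effect = np.array(
            [
                params.mixing_effect_ms * (c != "homogeneous")
                + params.switch_effect_ms * (c == "switch")
                for c in conds
            ]
        )
        rts = params.base_rt_ms + effect + _exgauss(rng, 0.0, params.sigma, params.tau, n)
        rts = np.maximum(rts, 120.0)
        err = rng.random(n) < np.array([params.error_p[c] for c in conds])
        nonresp = rng.random(n) < params.nonresponse_p
        cols = _cols(participant_id, "taskswitch", n)
        cols["block"] = np.full(n, b, dtype=int)
        cols["trial_index"] = np.arange(trial_counter, trial_counter + n)
        trial_counter += n
        cols["condition"] = conds
        cols["stimulus_id"] = [
            f"{s}{d}" for s, d in zip(
                rng.choice(["square", "diamond"], n), rng.choice(["2", "3"], n)
            )
        ]
        cols["response"] = [
            "none" if nr else ("m" if e else "x") for nr, e in zip(nonresp, err)
        ]
        cols["correct"] = [
            None if nr else (not e) for nr, e in zip(nonresp, err)
        ]
        cols["rt_ms"] = np.where(nonresp, np.nan, rts)
        frames.append(_to_frame(cols))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Corsi block tapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorsiParams:
    theta: float = 5.5  # capacity (blocks)
    slope: float = 2.0  # logistic steepness


def simulate_corsi(
    params: CorsiParams,
    seed: int | np.random.Generator,
    participant_id: str = "p0",
    phase: str = "forward",
) -> pd.DataFrame:
    """One Corsi phase: lengths 3..9, five trials per length until a level is
    failed (< 3/5 correct), after which each later length appears once."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    task = {"forward": "corsi_fwd", "backward": "corsi_bwd"}[phase]
    rows_cond, rows_correct, rows_rt = [], [], []
    failed = False
    for length in range(3, 10):
        n_trials = 5 if not failed else 1
        p = 1.0 / (1.0 + np.exp(-params.slope * (params.theta - length)))
        correct = rng.random(n_trials) < p
        rows_cond.extend([str(length)] * n_trials)
        rows_correct.extend(bool(c) for c in correct)
        rows_rt.extend(
            np.exp(rng.normal(log(1100.0 * length), 0.2, size=n_trials))
        )
        if not failed and correct.sum() < 3:
            failed = True
    n = len(rows_cond)
    cols = _cols(participant_id, task, n)
    cols["condition"] = rows_cond
    cols["stimulus_id"] = [f"seq{i:02d}" for i in range(n)]
    cols["response"] = ["press"] * n
    cols["correct"] = rows_correct
    cols["rt_ms"] = np.array(rows_rt)
    return _to_frame(cols)


# ---------------------------------------------------------------------------
# Alertness
# ---------------------------------------------------------------------------

ALERTNESS_N_BLOCKS = 4
ALERTNESS_BLOCK_LEN = 20
ALERTNESS_JITTERS_MS = tuple(range(700, 3501, 100))


@dataclass(frozen=True)
class AlertnessParams:
    mu: float = 300.0
    sigma: float = 30.0
    tau: float = 55.0
    miss_p: float = 0.007


def simulate_alertness(
    params: AlertnessParams,
    seed: int | np.random.Generator,
    participant_id: str = "p0",
) -> pd.DataFrame:
    """Simple-RT task: 4 blocks x 20 trials, ISI jittered in {700..3500} ms."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = ALERTNESS_N_BLOCKS * ALERTNESS_BLOCK_LEN
    jitter = rng.choice(ALERTNESS_JITTERS_MS, size=n)
    missed = rng.random(n) < params.miss_p
    rts = np.where(missed, np.nan, _exgauss(rng, params.mu, params.sigma, params.tau, n))
    rts = np.where(np.isnan(rts), np.nan, np.maximum(rts, 120.0))
    cols = _cols(participant_id, "alertness", n)
    cols["block"] = np.repeat(np.arange(ALERTNESS_N_BLOCKS), ALERTNESS_BLOCK_LEN)
    cols["condition"] = ["signal"] * n
    cols["stimulus_id"] = [f"isi{j}" for j in jitter]
    cols["response"] = ["none" if m else "press" for m in missed]
    cols["correct"] = [None if m else True for m in missed]
    cols["rt_ms"] = rts
    return _to_frame(cols)


# ---------------------------------------------------------------------------
# Questionnaires
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InstrumentModel:
    """Discretized latent-normal item model of one instrument.

    item = clip(round(item_mean + loading * z + e), 0, vmax) with a shared
    participant trait z ~ N(shift, 1) and item noise e ~ N(0, noise_sd).
    Negative loadings encode reverse-keyed items (PSQ-20 joy).
    """

    prefix: str
    item_means: tuple[float, ...]
    loadings: tuple[float, ...]
    noise_sd: float
    vmax: int


def _default_instruments() -> dict[str, InstrumentModel]:
    psq_means, psq_loads = [], []
    from .questionnaires import PSQ20_SUBSCALES

    joy = set(PSQ20_SUBSCALES["joy"])
    for i in range(1, 21):
        if i in joy:
            psq_means.append(1.8)
            psq_loads.append(-0.6)
        else:
            psq_means.append(1.2)
            psq_loads.append(0.6)
    return {
        "phq9": InstrumentModel("phq9", (0.68,) * 9, (0.5,) * 9, 1.0, 3),
        "psq20": InstrumentModel("psq20", tuple(psq_means), tuple(psq_loads), 1.0, 3),
        "gad7": InstrumentModel("gad7", (0.81,) * 7, (0.5,) * 7, 1.0, 3),
        "who5": InstrumentModel("who5", (2.42,) * 5, (1.1,) * 5, 1.0, 5),
    }


DEFAULT_INSTRUMENTS = _default_instruments()


def expected_item_mean(mean: float, loading: float, noise_sd: float,
                       vmax: int, shift: float = 0.0) -> float:
    """Closed-form expectation of one rounded, clipped latent-normal item."""
    mu = mean + loading * shift
    s = float(np.hypot(loading, noise_sd))
    e = 0.0
    for c in range(vmax + 1):
        lo = -np.inf if c == 0 else (c - 0.5 - mu) / s
        hi = np.inf if c == vmax else (c + 0.5 - mu) / s
        e += c * (sps.norm.cdf(hi) - sps.norm.cdf(lo))
    return float(e)


def expected_total(instrument: str, shift: float = 0.0,
                   models: Optional[dict] = None) -> float:
    """Expected scored total of an instrument at latent shift ``shift``."""
    from .questionnaires import PSQ20_SUBSCALES

    m = (models or DEFAULT_INSTRUMENTS)[instrument]
    means = [
        expected_item_mean(m.item_means[i], m.loadings[i], m.noise_sd, m.vmax, shift)
        for i in range(len(m.item_means))
    ]
    if instrument in ("phq9", "gad7"):
        return float(sum(means))
    if instrument == "who5":
        return float(sum(means) * 4)
    if instrument == "psq20":
        joy = set(PSQ20_SUBSCALES["joy"])
        total = 0.0
        for name, idxs in PSQ20_SUBSCALES.items():
            vals = [means[i - 1] for i in idxs]
            if name == "joy":
                vals = [3 - v for v in vals]
            total += sum(vals) / 5 / 3 * 100
        return total / 4
    raise KeyError(instrument)


def latent_shift_for_points(instrument: str, target_points: float,
                            models: Optional[dict] = None) -> float:
    """Latent shift whose expected total differs from baseline by ``target_points``."""
    base = expected_total(instrument, 0.0, models)

    def f(shift: float) -> float:
        return expected_total(instrument, shift, models) - base - target_points

    return float(optimize.brentq(f, -4.0, 4.0, xtol=1e-10))


def simulate_questionnaires(
    n: int,
    group_shifts: Optional[dict[str, float]] = None,
    seed: int | np.random.Generator = 0,
    models: Optional[dict] = None,
) -> pd.DataFrame:
    """Item responses for ``n`` participants; shifts are in latent units."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    group_shifts = group_shifts or {}
    models = models or DEFAULT_INSTRUMENTS
    out = {}
    for prefix, m in models.items():
        shift = group_shifts.get(prefix, 0.0)
        z = rng.normal(shift, 1.0, size=n)
        for i, col in enumerate(item_columns(prefix)):
            latent = m.item_means[i] + m.loadings[i] * z + rng.normal(
                0.0, m.noise_sd, size=n
            )
            out[col] = np.clip(np.rint(latent), 0, m.vmax).astype(int)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Cohort layer
# ---------------------------------------------------------------------------

#: Study-calibrated participation probabilities (per-task N / overall N).
DEFAULT_PARTICIPATION = {
    "mst": 0.11,
    "alertness": 0.11,
    "corsi_fwd": 0.18,
    "corsi_bwd": 0.16,
    "nback": 0.23,
    "taskswitch": 0.23,
    "gonogo": 0.30,
    "sst": 0.24,
}

DEFAULT_HEALTH_FLAG_P = {flag: 0.01 for flag in (
    "stroke", "cardiac_arrest", "cancer", "brain_surgery", "recent_major_surgery",
    "loss_of_consciousness_gt5min", "psychiatric_or_neurologic_disorder",
    "untreated_hypertension", "cognition_affecting_medication",
)} | {"impaired_vision": 0.02}


@dataclass(frozen=True)
class CohortConfig:
    """Parameterization of the synthetic cohort.

    Defaults reproduce the study's composition: group sizes 910 previously
    infected / 495 never positive, ages ~N(44, 14.5) truncated to 18-90, an
    education imbalance between groups, questionnaire group shifts matched
    to the reported adjusted differences, and an LDI deficit of 0.08
    (subtracted from the infected group's p_lure_similar, so the expected
    scored LDI difference equals the configured value).
    """

    n_infected: int = 910
    n_uninfected: int = 495
    seed: int = 0

    age_mean: float = 44.0
    age_sd: float = 14.5
    age_min: int = 18
    age_max: int = 90
    p_male: float = 0.277
    p_diverse: float = 0.002
    p_postsec_uninfected: float = 0.438
    p_postsec_infected: float = 0.337

    months_since_pcr_mean: float = 11.15
    months_since_pcr_sd: float = 6.97
    months_since_pcr_max: int = 29
    sequelae_rate: float = 2.0  # Poisson mean of symptom counts

    # questionnaire group shifts in scored total points (infected - uninfected)
    questionnaire_point_shifts: dict = field(
        default_factory=lambda: {
            "phq9": 1.06, "psq20": 3.34, "gad7": 0.45, "who5": -3.53,
        }
    )

    mst_base: MstResponderParams = field(
        default_factory=lambda: MstResponderParams(fast_guess_rate=0.05)
    )
    true_ldi_deficit: float = 0.08
    age_ldi_slope: float = -0.0023  # per year on p_lure_similar
    months_ldi_slope: float = -0.010  # per month since PCR, centered
    sequelae_ldi_slope: float = -0.020  # per reported symptom, centered
    mst_concentration: float = 15.0  # Beta concentration of person propensities

    corsi_base: CorsiParams = field(default_factory=CorsiParams)
    corsi_theta_sd: float = 1.1
    corsi_fwd_deficit: float = 0.31  # capacity drop (blocks) when infected
    corsi_bwd_deficit: float = 0.0

    sst_base: RaceModelParams = field(default_factory=RaceModelParams)
    sst_ssrt_sd: float = 50.0
    sst_mu_sd: float = 60.0
    ssrt_deficit_ms: float = 0.0

    nback_base: NbackParams = field(default_factory=NbackParams)
    nback_hit_sd: float = 0.10
    nback_deficit: float = 0.0  # subtracted from hit_p when infected

    gonogo_base: GonogoParams = field(default_factory=GonogoParams)
    gonogo_fa_sd: float = 0.10
    gonogo_deficit: float = 0.0  # added to fa_p when infected

    taskswitch_base: TaskSwitchParams = field(default_factory=TaskSwitchParams)
    taskswitch_base_rt_sd: float = 120.0
    switch_effect_sd: float = 120.0
    mixing_effect_sd: float = 140.0
    switch_cost_deficit_ms: float = 0.0

    alertness_base: AlertnessParams = field(default_factory=AlertnessParams)
    alertness_mu_sd: float = 35.0
    alertness_deficit_ms: float = 0.0

    participation: dict = field(default_factory=lambda: dict(DEFAULT_PARTICIPATION))
    health_flag_p: dict = field(default_factory=lambda: dict(DEFAULT_HEALTH_FLAG_P))
    p_recovered: float = 0.5  # infected self-reporting full recovery
    p_vaccinated: float = 0.4
    p_vaccination_missing: float = 0.25

    def validate(self) -> None:
        if self.n_infected < 1 or self.n_uninfected < 1:
            raise ValueError("group sizes must be >= 1")
        self.mst_base.validate()
        self.sst_base.validate()


@dataclass
class SimulationLog:
    """Bookkeeping of probability clipping during cohort generation."""

    n_prob_draws: int = 0
    n_clipped: int = 0
    warnings: list[str] = field(default_factory=list)

    def clip01(self, x: float, lo: float = 0.0, hi: float = 1.0) -> float:
        self.n_prob_draws += 1
        if x < lo or x > hi:
            self.n_clipped += 1
            return min(max(x, lo), hi)
        return x

    def finish(self) -> None:
        if self.n_prob_draws and self.n_clipped / self.n_prob_draws > 0.01:
            self.warnings.append(
                f"clipped {self.n_clipped}/{self.n_prob_draws} probability draws (> 1%)"
            )


def _person_mst_params(
    cfg: CohortConfig,
    rng: np.random.Generator,
    infected: bool,
    age: int,
    months: Optional[int],
    n_seq: Optional[int],
    log_: SimulationLog,
) -> MstResponderParams:
    base = cfg.mst_base
    p_ls = base.p_lure_similar
    p_ls += cfg.age_ldi_slope * (age - cfg.age_mean)
    if infected:
        p_ls -= cfg.true_ldi_deficit
        if months is not None:
            p_ls += cfg.months_ldi_slope * (months - cfg.months_since_pcr_mean)
        if n_seq is not None:
            p_ls += cfg.sequelae_ldi_slope * (n_seq - cfg.sequelae_rate)
    kappa = cfg.mst_concentration

    def draw(mean: float) -> float:
        mean = log_.clip01(mean, 0.005, 0.995)
        return float(rng.beta(kappa * mean, kappa * (1 - mean)))

    p_ls = draw(p_ls)
    p_fs = draw(base.p_foil_similar)
    p_ct = draw(base.p_correct_target)
    # keep secondary masses proportional to the base split of the remainder
    rem_t = 1 - base.p_correct_target
    p_ts = (1 - p_ct) * (base.p_target_similar / rem_t if rem_t > 0 else 0.0)
    p_lo = log_.clip01(base.p_lure_old + (0.4 * (base.p_lure_similar - p_ls)),
                       0.0, 1.0 - p_ls)
    p_fn = log_.clip01(draw(base.p_foil_new), 0.0, 1.0 - p_fs)
    return replace(
        base,
        p_correct_target=p_ct,
        p_target_similar=p_ts,
        p_lure_similar=p_ls,
        p_lure_old=p_lo,
        p_foil_new=p_fn,
        p_foil_similar=p_fs,
    )


def simulate_cohort(
    config: CohortConfig,
    tasks: Optional[Iterable[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationLog]:
    """Generate the survey table and the trial table of a synthetic cohort.

    ``tasks`` restricts generation to a subset (e.g. ``{"mst"}``) with
    participation forced to 1 for those tasks; by default every task is
    generated with its study-calibrated participation probability.
    Regeneration with the same config is bit-identical.
    """
    config.validate()
    log_ = SimulationLog()
    only = set(tasks) if tasks is not None else None
    n_total = config.n_infected + config.n_uninfected
    width = max(4, len(str(n_total)))

    master = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([config.seed, _crc("cohort")]))
    )
    survey_rows: list[dict] = []
    trial_frames: list[pd.DataFrame] = []

    statuses = ["previously_positive"] * config.n_infected + [
        "never_positive"
    ] * config.n_uninfected

    shifts = {
        k: latent_shift_for_points(k, v)
        for k, v in config.questionnaire_point_shifts.items()
    }

    for i, status in enumerate(statuses):
        pid = f"p{i:0{width}d}"
        prng = task_rng(config.seed, pid, "person")
        infected = status == "previously_positive"
        age = int(np.clip(round(prng.normal(config.age_mean, config.age_sd)),
                          config.age_min, config.age_max))
        u = prng.random()
        gender = (
            "diverse" if u < config.p_diverse
            else "male" if u < config.p_diverse + config.p_male
            else "female"
        )
        p_edu = config.p_postsec_infected if infected else config.p_postsec_uninfected
        education = bool(prng.random() < p_edu)
        months = n_seq = None
        recovered = None
        vaccinated = "missing"
        if infected:
            months = int(np.clip(
                round(prng.normal(config.months_since_pcr_mean,
                                  config.months_since_pcr_sd)),
                0, config.months_since_pcr_max,
            ))
            n_seq = int(prng.poisson(config.sequelae_rate))
            recovered = bool(prng.random() < config.p_recovered)
            if prng.random() >= config.p_vaccination_missing:
                vaccinated = "yes" if prng.random() < config.p_vaccinated else "no"
        flags = sorted(
            f for f, p in config.health_flag_p.items() if prng.random() < p
        )

        qrng = task_rng(config.seed, pid, "questionnaires")
        items = simulate_questionnaires(
            1, group_shifts=(shifts if infected else None), seed=qrng
        ).iloc[0]

        row = {
            "participant_id": pid,
            "participation_index": 0,
            "age_years": age,
            "gender": gender,
            "education_post_secondary": education,
            "infection_status": status,
            "months_since_pcr": months,
            "n_sequelae": n_seq,
            "vaccinated_before_infection": vaccinated,
            "recovered_self_report": recovered,
            "health_exclusion_flags": ";".join(flags),
        }
        row.update(items.to_dict())
        survey_rows.append(row)

        def does(task: str) -> bool:
            if only is not None:
                return task in only
            return prng.random() < config.participation.get(task, 0.0)

        if does("mst"):
            rng = task_rng(config.seed, pid, "mst")
            params = _person_mst_params(
                config, rng, infected, age, months, n_seq, log_
            )
            trial_frames.append(simulate_mst(params, rng, pid))
        if does("alertness"):
            rng = task_rng(config.seed, pid, "alertness")
            mu = max(
                150.0,
                config.alertness_base.mu + rng.normal(0, config.alertness_mu_sd)
                + (config.alertness_deficit_ms if infected else 0.0),
            )
            trial_frames.append(
                simulate_alertness(replace(config.alertness_base, mu=mu), rng, pid)
            )
        for phase, key in (("forward", "corsi_fwd"), ("backward", "corsi_bwd")):
            if does(key):
                rng = task_rng(config.seed, pid, key)
                deficit = (
                    config.corsi_fwd_deficit if key == "corsi_fwd"
                    else config.corsi_bwd_deficit
                )
                theta = (
                    config.corsi_base.theta
                    + rng.normal(0, config.corsi_theta_sd)
                    - (deficit if infected else 0.0)
                )
                trial_frames.append(
                    simulate_corsi(
                        replace(config.corsi_base, theta=theta), rng, pid, phase
                    )
                )
        if does("nback"):
            rng = task_rng(config.seed, pid, "nback")
            hit = log_.clip01(
                config.nback_base.hit_p + rng.normal(0, config.nback_hit_sd)
                - (config.nback_deficit if infected else 0.0),
                0.02, 0.995,
            )
            trial_frames.append(
                simulate_nback(replace(config.nback_base, hit_p=hit), rng, pid)
            )
        if does("taskswitch"):
            rng = task_rng(config.seed, pid, "taskswitch")
            base = replace(
                config.taskswitch_base,
                base_rt_ms=max(
                    200.0,
                    config.taskswitch_base.base_rt_ms
                    + rng.normal(0, config.taskswitch_base_rt_sd),
                ),
                switch_effect_ms=max(
                    0.0,
                    config.taskswitch_base.switch_effect_ms
                    + rng.normal(0, config.switch_effect_sd)
                    + (config.switch_cost_deficit_ms if infected else 0.0),
                ),
                mixing_effect_ms=max(
                    0.0,
                    config.taskswitch_base.mixing_effect_ms
                    + rng.normal(0, config.mixing_effect_sd),
                ),
            )
            trial_frames.append(simulate_taskswitch(base, rng, pid))
        if does("gonogo"):
            rng = task_rng(config.seed, pid, "gonogo")
            fa_shift = rng.normal(0, config.gonogo_fa_sd) + (
                config.gonogo_deficit if infected else 0.0
            )
            fa = tuple(
                log_.clip01(p + fa_shift, 0.005, 0.95)
                for p in config.gonogo_base.fa_p
            )
            trial_frames.append(
                simulate_gonogo(replace(config.gonogo_base, fa_p=fa), rng, pid)
            )
        if does("sst"):
            rng = task_rng(config.seed, pid, "sst")
            params = replace(
                config.sst_base,
                mu=max(200.0, config.sst_base.mu + rng.normal(0, config.sst_mu_sd)),
                true_ssrt_ms=max(
                    80.0,
                    config.sst_base.true_ssrt_ms
                    + rng.normal(0, config.sst_ssrt_sd)
                    + (config.ssrt_deficit_ms if infected else 0.0),
                ),
            )
            trial_frames.append(simulate_sst(params, rng, pid))

    from .data_model import SURVEY_COLUMNS

    survey = pd.DataFrame(survey_rows)[SURVEY_COLUMNS]
    trials = (
        pd.concat(trial_frames, ignore_index=True)
        if trial_frames
        else _to_frame(_cols("none", "mst_test", 0))
    )
    log_.finish()
    return survey, trials, log_
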