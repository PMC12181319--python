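"""End-to-end orchestration: simulate -> score -> analyze, with exclusion
ledgers and a reproducible run manifest.

The analysis battery mirrors the study design: four questionnaire models
(outcome ~ infection + age + gender + education, focal p values
Holm-corrected as a family) and, per cognitive outcome, covariate-adjusted
models with infection status as focal predictor, subsample variants for
previously infected participants (months since PCR, number of sequelae),
the recovered-or-never-infected contrast, and the age-by-infection
interaction. Participant-level exclusions are applied in a fixed,
documented order so ledgers are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import __version__
from .data_model import first_participation_only, read_survey, read_trials, write_survey, write_trials
from .ef import score_ef_table, ssrt_integration
from .inference import (
    ModelSpec,
    fit_linear_model,
    groupwise_2sd_mask,
    holm_adjust,
    tukey_outlier_mask,
)
from .memory import score_corsi_table, score_mst_table
from .questionnaires import score_survey_frame
from .simulators import CohortConfig, RaceModelParams, simulate_cohort, simulate_sst, task_rng

# ---------------------------------------------------------------------------
# Participant-level exclusions
# ---------------------------------------------------------------------------

#: Fixed precedence of exclusion reasons; a participant excluded for several
#: reasons is counted once, under the first match.
EXCLUSION_ORDER: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("age", ()),
    ("vision", ("impaired_vision",)),
    ("critical_health", ("stroke", "cardiac_arrest", "cancer", "brain_surgery")),
    ("surgery_or_loc", ("recent_major_surgery", "loss_of_consciousness_gt5min")),
    ("psychiatric_neurologic", ("psychiatric_or_neurologic_disorder",)),
    ("hypertension", ("untreated_hypertension",)),
    ("medication", ("cognition_affecting_medication",)),
)


def apply_participant_exclusions(
    survey: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop participants with health-exclusion flags (or age < 18).

    Returns the retained rows and a ledger mapping each reason to its count;
    counts are disjoint (first matching reason wins).
    """
    ledger = {reason: 0 for reason, _ in EXCLUSION_ORDER}
    flags = survey["health_exclusion_flags"].fillna("").astype(str).str.split(";")
    drop = np.zeros(len(survey), dtype=bool)
    for i, (age, flagset) in enumerate(zip(survey["age_years"], flags)):
        fs = set(flagset) - {""}
        for reason, members in EXCLUSION_ORDER:
            hit = age < 18 if reason == "age" else bool(fs & set(members))
            if hit:
                ledger[reason] += 1
                drop[i] = True
                break
    return survey.loc[~drop].reset_index(drop=True), ledger


def merge_scores(survey: pd.DataFrame, *score_tables: pd.DataFrame) -> pd.DataFrame:
    """Inner-join score tables onto the survey by exact participant_id."""
    out = survey
    for tab in score_tables:
        if tab is None or tab.empty:
            continue
        out = out.merge(tab, on="participant_id", how="inner")
    if out.empty and len(survey):
        import warnings

        warnings.warn("merge produced an empty table (disjoint participant ids)")
    return out


# ---------------------------------------------------------------------------
# Scoring layer
# ---------------------------------------------------------------------------


def score_all(trials: pd.DataFrame, survey: pd.DataFrame) -> pd.DataFrame:
    """Score every task and questionnaire; outer-join into one ScoreTable."""
    tables = [score_survey_frame(survey)]
    mst = trials[trials["task"] == "mst_test"]
    if len(mst):
        tables.append(score_mst_table(mst))
    corsi = trials[trials["task"].isin(["corsi_fwd", "corsi_bwd"])]
    if len(corsi):
        tables.append(score_corsi_table(corsi))
    ef = trials[trials["task"].isin(
        ["alertness", "nback", "taskswitch", "gonogo", "sst"]
    )]
    if len(ef):
        tables.append(score_ef_table(ef))
    out = tables[0]
    for tab in tables[1:]:
        if not tab.empty:
            out = out.merge(tab, on="participant_id", how="outer")
    return out


def prepare_analysis_table(survey: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Numeric analysis table with the study's binary codings.

    infection: never positive = 0, previously positive = 1; gender_male:
    female = 0, male = 1 (diverse rows are dropped, mirroring the binary
    coding); education: no post-secondary = 0; vaccinated: no = 0, yes = 1,
    missing stays missing.
    """
    sub = survey[survey["gender"].isin(["female", "male"])].copy()
    tab = pd.DataFrame(
        {
            "participant_id": sub["participant_id"],
            "infection": (sub["infection_status"] == "previously_positive").astype(int),
            "age": sub["age_years"].astype(float),
            "gender_male": (sub["gender"] == "male").astype(int),
            "education": sub["education_post_secondary"].astype("boolean")
            .astype("Int64").astype(float),
            "months_since_pcr": pd.to_numeric(sub["months_since_pcr"], errors="coerce"),
            "n_sequelae": pd.to_numeric(sub["n_sequelae"], errors="coerce"),
            "vaccinated": sub["vaccinated_before_infection"].map(
                {"yes": 1.0, "no": 0.0}
            ),
            "recovered": sub["recovered_self_report"],
        }
    )
    score_cols = [c for c in scores.columns if c != "participant_id"]
    return tab.merge(scores[["participant_id"] + score_cols],
                     on="participant_id", how="left")


# ---------------------------------------------------------------------------
# Analysis battery
# ---------------------------------------------------------------------------

QUESTIONNAIRE_COVARIATES = ("age", "gender_male", "education")

#: (model name, outcome column) for the questionnaire family (Holm-corrected).
QUESTIONNAIRE_MODELS = (
    ("phq9", "phq9_total"),
    ("psq20", "psq20_total"),
    ("gad7", "gad7_total"),
    ("who5", "who5_total"),
)

#: Cognitive-outcome battery: (name, outcome, spec kwargs, outlier family)
MST_OUTCOMES = ("ldi", "rec", "pc_bias")


def cognitive_model_specs() -> list[ModelSpec]:
    """The battery's cognitive regression models (the tables' Models 1-8b)."""
    specs: list[ModelSpec] = []
    for outcome, tag in (("ldi", "1"), ("rec", "5"), ("pc_bias", "7")):
        specs.append(ModelSpec(outcome=outcome, name=f"model_{tag}"))
    specs.append(
        ModelSpec(outcome="ldi", extra_terms=("age:infection",), name="model_2")
    )
    for outcome, tag in (("ldi", "3"), ("rec", "6"), ("pc_bias", "8")):
        specs.append(
            ModelSpec(
                outcome=outcome, focal="months_since_pcr",
                subsample="previously_positive", name=f"model_{tag}a",
            )
        )
        specs.append(
            ModelSpec(
                outcome=outcome, focal="n_sequelae",
                subsample="previously_positive", name=f"model_{tag}b",
            )
        )
    specs.append(
        ModelSpec(outcome="ldi", subsample="recovered_or_never", name="model_4")
    )
    specs.append(
        ModelSpec(
            outcome="ldi", focal="vaccinated",
            subsample="previously_positive", name="model_vaccination",
        )
    )
    for outcome, kwargs in (
        ("corsi_fwd_span", {}),
        ("corsi_bwd_span", {}),
        ("nback_dprime", {}),
        ("nback_hit_rt_ms", {}),
        ("switch_cost_rt_ms", {}),
        ("mixing_cost_rt_ms", {}),
        ("switch_cost_err", {}),
        ("mixing_cost_err", {}),
        ("gonogo_fa_rate", {}),
        ("ssrt_ms", {"log_outcome": True}),
        ("alertness_mean_rt_ms", {}),
        ("alertness_accuracy", {}),
    ):
        specs.append(ModelSpec(outcome=outcome, name=f"model_{outcome}", **kwargs))
    return specs


def _mst_outlier_filter(tab: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Group-wise 2-SD exclusion on LDI or REC (shared across MST models)."""
    has = tab["ldi"].notna() & tab["rec"].notna()
    sub = tab[has]
    if len(sub) < 6 or sub["infection"].nunique() < 2:
        return tab, 0
    try:
        bad = groupwise_2sd_mask(sub["ldi"].to_numpy(), sub["infection"].to_numpy())
        bad |= groupwise_2sd_mask(sub["rec"].to_numpy(), sub["infection"].to_numpy())
    except ValueError:
        return tab, 0
    drop_ids = set(sub.loc[bad, "participant_id"])
    return tab[~tab["participant_id"].isin(drop_ids)], len(drop_ids)


def _outcome_outlier_filter(
    tab: pd.DataFrame, outcome: str
) -> tuple[pd.DataFrame, int]:
    """Group-wise 2-SD exclusion on one cognitive outcome."""
    has = tab[outcome].notna()
    sub = tab[has]
    if len(sub) < 6 or sub["infection"].nunique() < 2:
        return tab, 0
    try:
        bad = groupwise_2sd_mask(sub[outcome].to_numpy(), sub["infection"].to_numpy())
    except ValueError:
        return tab, 0
    drop_ids = set(sub.loc[bad, "participant_id"])
    return tab[~tab["participant_id"].isin(drop_ids)], len(drop_ids)


def _result_rows(name: str, res, p_holm: Optional[float] = None) -> list[dict]:
    rows = []
    base = {
        "model": name,
        "outcome": res.spec.outcome,
        "subsample": res.spec.subsample,
        "n": res.n_used,
        "r2": res.r2,
        "adj_r2": res.adj_r2,
        "f": res.f,
        "p_model": res.p_model,
        "bf10_focal": res.bf10_focal,
    }
    rows.append(base | {"term": "intercept", "b": res.intercept.b,
                        "se": res.intercept.se, "beta": np.nan,
                        "t": res.intercept.t, "p": res.intercept.p,
                        "focal": False, "p_holm": np.nan})
    for term, st in res.terms.items():
        focal = term == res.spec.focal
        rows.append(
            base
            | {
                "term": term, "b": st.b, "se": st.se, "beta": st.beta,
                "t": st.t, "p": st.p, "focal": focal,
                "p_holm": p_holm if (focal and p_holm is not None) else np.nan,
            }
        )
    return rows


def analyze(
    survey: pd.DataFrame,
    scores: pd.DataFrame,
    holm_questionnaires: bool = True,
    compute_bf: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Run the full model battery; returns (models table, exclusion ledger)."""
    tab = prepare_analysis_table(survey, scores)
    ledger: dict[str, int] = {}
    rows: list[dict] = []

    # Questionnaire family: Tukey outliers per outcome, Holm across the four
    q_results = []
    for name, outcome in QUESTIONNAIRE_MODELS:
        if outcome not in tab.columns:
            continue
        sub = tab.copy()
        vals = sub[outcome].to_numpy(dtype=float)
        if np.isfinite(vals).sum() >= 4:
            out_mask = tukey_outlier_mask(np.where(np.isfinite(vals), vals, np.nan))
            ledger[f"outliers_{name}"] = int(out_mask.sum())
            sub = sub[~out_mask]
        spec = ModelSpec(
            outcome=outcome, focal="infection",
            covariates=QUESTIONNAIRE_COVARIATES, name=name,
        )
        q_results.append((name, fit_linear_model(sub, spec, compute_bf=compute_bf)))
    if q_results:
        focal_ps = [r.terms["infection"].p for _, r in q_results]
        adj = holm_adjust(focal_ps) if holm_questionnaires else focal_ps
        for (name, res), ph in zip(q_results, adj):
            rows.extend(_result_rows(name, res, p_holm=float(ph)))

    # MST family: inclusion flags then the shared LDI/REC 2-SD rule
    mst_tab = tab
    if "mst_included" in tab.columns:
        included = tab["mst_included"].astype("boolean").fillna(False)
        keep = (included | tab["ldi"].isna()).to_numpy(dtype=bool)
        excluded = tab["mst_included"].notna() & ~included
        ledger["mst_task_excluded"] = int(excluded.sum())
        mst_tab = tab.copy()
        mst_tab.loc[~keep, list(MST_OUTCOMES)] = np.nan
    if "ldi" in mst_tab.columns and "rec" in mst_tab.columns:
        mst_tab, n_out = _mst_outlier_filter(mst_tab)
        ledger["outliers_mst_2sd"] = n_out

    for spec in cognitive_model_specs():
        if spec.outcome not in tab.columns:
            continue
        data = mst_tab if spec.outcome in MST_OUTCOMES else tab
        if spec.outcome not in MST_OUTCOMES:
            data, n_out = _outcome_outlier_filter(data, spec.outcome)
            ledger[f"outliers_{spec.outcome}"] = n_out
        if spec.outcome == "ssrt_ms" and "sst_eligible" in data.columns:
            elig = data["sst_eligible"].astype("boolean").fillna(False)
            data = data[(elig | data["ssrt_ms"].isna()).to_numpy(dtype=bool)]
        try:
            res = fit_linear_model(data, spec, compute_bf=compute_bf)
        except Exception as exc:  # insufficient data in small cohorts
            ledger[f"skipped_{spec.name}"] = 1
            rows.append({"model": spec.name, "outcome": spec.outcome,
                         "term": "error", "note": str(exc)})
            continue
        rows.extend(_result_rows(spec.name, res))

    return pd.DataFrame(rows), ledger


def pearson_r_test(x, y) -> tuple[float, float, float, float]:
    """Pearson r with its t test: returns (r, t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    from scipy import stats as sps

    r, p = sps.pearsonr(x[ok], y[ok])
    df = n - 2
    t = r * np.sqrt(df / max(1e-300, 1 - r**2))
    return float(r), float(t), float(df), float(p)


# ---------------------------------------------------------------------------
# SSRT recovery study
# ---------------------------------------------------------------------------


def ssrt_recovery_study(
    true_ssrt_ms: float = 250.0,
    n_participants: int = 50,
    stop_trials_per_participant: Iterable[int] = (48, 500),
    go_rt=(500.0, 50.0, 100.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Bias and RMSE of the integration SSRT estimator on race-model data.

    For each design size, simulates ``n_participants`` race-model records
    (scaling the block structure so the stop-trial count matches while
    keeping the 3:1 go:stop ratio) and compares estimates to the generating
    SSRT.
    """
    mu, sigma, tau = go_rt
    out = []
    for n_stop in stop_trials_per_participant:
        per_block = max(1, int(round(n_stop / 3)))
        params = RaceModelParams(
            mu=mu, sigma=sigma, tau=tau, true_ssrt_ms=true_ssrt_ms,
            p_go_omission=0.02, p_choice_error=0.02,
            n_blocks=3, go_per_block=per_block * 3, stop_per_block=per_block,
        )
        estimates = []
        for i in range(n_participants):
            rng = task_rng(seed, f"recovery{i}", f"sst{n_stop}")
            trials = simulate_sst(params, rng, participant_id=f"r{i}")
            score = ssrt_integration(trials)
            if score.eligible:
                estimates.append(score.ssrt_ms)
        est = np.asarray(estimates)
        out.append(
            {
                "n_stop_trials": 3 * per_block,
                "n_eligible": len(est),
                "true_ssrt_ms": true_ssrt_ms,
                "mean_estimate_ms": float(est.mean()) if len(est) else np.nan,
                "bias_ms": float(est.mean() - true_ssrt_ms) if len(est) else np.nan,
                "rmse_ms": float(np.sqrt(np.mean((est - true_ssrt_ms) ** 2)))
                if len(est) else np.nan,
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Run manifest and full pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    version: str = __version__
    stage_counts: dict = field(default_factory=dict)
    exclusion_ledger: dict = field(default_factory=dict)

    def check_conservation(self) -> None:
        for stage, c in self.stage_counts.items():
            if {"rows_in", "rows_out", "excluded"} <= set(c):
                if c["rows_in"] != c["rows_out"] + c["excluded"]:
                    raise AssertionError(f"count conservation violated at {stage}: {c}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _config_hash(config: CohortConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode("utf8")).hexdigest()[:16]


def cohort_config_from_dict(d: dict) -> CohortConfig:
    """Build a CohortConfig from a plain (YAML/JSON) mapping.

    Top-level keys match field names; nested parameter objects accept
    sub-mappings of their own field names.
    """
    from .simulators import (
        AlertnessParams, CorsiParams, GonogoParams, MstResponderParams,
        NbackParams, TaskSwitchParams,
    )

    nested = {
        "mst_base": MstResponderParams,
        "corsi_base": CorsiParams,
        "sst_base": RaceModelParams,
        "nback_base": NbackParams,
        "gonogo_base": GonogoParams,
        "taskswitch_base": TaskSwitchParams,
        "alertness_base": AlertnessParams,
    }
    kwargs = {}
    valid = {f.name for f in dataclasses.fields(CohortConfig)}
    for k, v in d.items():
        if k not in valid:
            raise KeyError(f"unknown cohort config key {k!r}")
        if k in nested and isinstance(v, dict):
            v = nested[k](**v)
        kwargs[k] = v
    return CohortConfig(**kwargs)


def run_pipeline(
    config: CohortConfig,
    out_dir,
    tasks: Optional[Iterable[str]] = None,
    compute_bf: bool = True,
) -> RunManifest:
    """simulate -> write -> read back -> exclude -> score -> analyze.

    Writes survey.csv, trials.csv, scores.csv, models.csv, exclusions.csv
    and manifest.json into ``out_dir``; the whole chain is deterministic in
    the config (which carries the master seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config), master_seed=config.seed)

    survey, trials, sim_log = simulate_cohort(config, tasks=tasks)
    write_survey(survey, out / "survey.csv")
    write_trials(trials, out / "trials.csv")
    manifest.stage_counts["simulate"] = {
        "participants": len(survey),
        "trial_rows": len(trials),
        "prob_clips": sim_log.n_clipped,
    }

    survey, survey_report = read_survey(out / "survey.csv")
    trials, trials_report = read_trials(out / "trials.csv")
    survey = first_participation_only(survey)
    trials = first_participation_only(trials)

    kept, ledger = apply_participant_exclusions(survey)
    manifest.exclusion_ledger = ledger
    manifest.stage_counts["exclusions"] = {
        "rows_in": len(survey),
        "rows_out": len(kept),
        "excluded": int(sum(ledger.values())),
    }
    manifest.check_conservation()
    kept_trials = trials[trials["participant_id"].isin(set(kept["participant_id"]))]

    scores = score_all(kept_trials, kept)
    scores.to_csv(out / "scores.csv", index=False)

    models, model_ledger = analyze(kept, scores, compute_bf=compute_bf)
    models.to_csv(out / "models.csv", index=False)
    manifest.exclusion_ledger |= {f"analysis_{k}": v for k, v in model_ledger.items()}
    pd.Series(manifest.exclusion_ledger, name="count").rename_axis("reason").to_csv(
        out / "exclusions.csv"
    )

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
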