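"""End-to-end study runner: synthetic cohort -> traces -> SCR scoring ->
staircase thresholds -> scored per-participant table -> statistics report.

This wires the module chain together exactly as the protocol orders it:
each participant contributes a 10-min rest baseline (SCL), one 15-trial
habituation block per condition (tone, siren), subjective ratings and a
questionnaire score from the cohort generator, and a detection threshold
measured by running the staircase against a psychometric observer whose
true threshold the generator assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .eda import detect_scr_events, lowpass_butterworth
from .errors import StaircaseConvergenceError
from .scoring import (
    ScoringCriteria,
    baseline_scl,
    block_means,
    classify_responder,
    score_trials,
    trials_to_habituation,
)
from .staircase import detection_threshold
from .synthetic import (
    CohortSpec,
    Observer,
    ScrGenParams,
    generate_cohort,
    generate_eda_trace,
    make_schedule,
    participant_scr_params,
)

__all__ = ["StudyConfig", "score_participant", "run_study"]

CONDITIONS = ("tone", "siren")


@dataclass(frozen=True)
class StudyConfig:
    """Protocol parameters for one synthetic study run."""

    n_trials: int = 15
    stimulus_duration_s: float = 3.0
    isi_min_s: float = 20.0
    isi_max_s: float = 35.0
    rate_hz: float = 1000.0
    criteria: ScoringCriteria = field(default_factory=ScoringCriteria)
    responder_rule: str = "both_absent"
    block_size: int = 5
    # siren habituates slightly faster in the defaults; conditions differ
    # only by this decay-ratio scale
    condition_decay_scale: dict[str, float] = field(
        default_factory=lambda: {"tone": 1.0, "siren": 0.92}
    )
    baseline_total_s: float = 600.0
    baseline_last_s: float = 300.0
    observer_slope_db: float = 1.0
    observer_lapse: float = 0.01
    staircase_max_passes: int = 20


def score_participant(row: pd.Series, config: StudyConfig | None = None) -> dict:
    """Full measurement chain for one cohort row.

    Returns habituation score and censoring per condition, responder flag,
    block-mean magnitudes, measured baseline SCL, and the staircase
    detection threshold with its pass count.
    """
    if config is None:
        config = StudyConfig()
    seed = int(row["seed"])
    tonic = float(row.get("baseline_scl_uS", 32.0))
    out: dict = {"participant": row["participant"], "group": row["group"]}

    scores_by_condition = {}
    for ci, cond in enumerate(CONDITIONS):
        schedule = make_schedule(
            config.n_trials,
            config.stimulus_duration_s,
            config.isi_min_s,
            config.isi_max_s,
            seed=seed + 1000 + ci,
        )
        params = participant_scr_params(
            row,
            decay_ratio=min(
                1.0, float(row["scr_decay_ratio"]) * config.condition_decay_scale[cond]
            ),
            tonic_level_uS=tonic,
            seed=seed + 2000 + ci,
        )
        trace, _truth = generate_eda_trace(schedule, params, rate_hz=config.rate_hz)
        filtered = lowpass_butterworth(trace)
        events = detect_scr_events(
            filtered, min_amplitude_uS=config.criteria.min_amplitude_uS
        )
        scores = score_trials(events, schedule, config.criteria)
        scores_by_condition[cond] = scores
        hab = trials_to_habituation(scores)
        out[f"habituation_{cond}"] = hab.trials_to_habituation
        out[f"censored_{cond}"] = hab.censored
        for i, bm in enumerate(block_means(scores, config.block_size), start=1):
            out[f"block{i}_{cond}"] = bm
    out["responder"] = classify_responder(scores_by_condition, config.responder_rule)

    # rest baseline: tonic + drift + noise only, averaged over the last 5 min
    rest_params = ScrGenParams(tonic_level_uS=tonic, response_prob=0.0, seed=seed + 3000)
    rest_schedule = make_schedule(1, 3.0, 20.0, 35.0, start_s=config.baseline_total_s)
    rest_trace, _ = generate_eda_trace(
        rest_schedule,
        rest_params,
        rate_hz=config.rate_hz,
        total_s=config.baseline_total_s + 13.0,
    )
    out["baseline_scl_uS"] = baseline_scl(
        rest_trace, config.baseline_total_s, config.baseline_last_s
    )

    observer = Observer(
        true_threshold_db=float(row["true_threshold_db"]),
        slope_db=config.observer_slope_db,
        lapse_rate=config.observer_lapse,
        seed=seed + 4000,
    )
    try:
        result = detection_threshold(observer, max_passes=config.staircase_max_passes)
        out["threshold_db"] = result.final_threshold_db
        out["n_passes"] = result.n_passes
    except StaircaseConvergenceError:
        out["threshold_db"] = np.nan
        out["n_passes"] = config.staircase_max_passes
    return out


def run_study(
    spec: CohortSpec | None = None,
    seed: int = 0,
    config: StudyConfig | None = None,
    analysis_config: stats.AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate, measure and analyse one synthetic cohort.

    Returns the scored per-participant table and the statistics report.
    """
    if config is None:
        config = StudyConfig()
    cohort = generate_cohort(spec, seed=seed)
    scored_rows = [score_participant(row, config) for _, row in cohort.iterrows()]
    scored = cohort.merge(
        pd.DataFrame(scored_rows), on=["participant", "group"], suffixes=("_true", "")
    )
    report = stats.analyze_cohort(scored, analysis_config)
    return scored, report
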