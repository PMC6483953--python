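"""Trial-level SCR scoring: attribute detected events to stimuli, apply the
amplitude/latency criteria, and derive habituation, responder status, block
magnitudes, and baseline skin conductance level.

Scoring conventions
-------------------
An event counts for a trial when its response onset (the trough time; the
peak time can be used instead via ``match_on="peak"``) falls within 1-4 s
after stimulus onset, both bounds inclusive, and its amplitude is at least
0.03 µS.  Habituation is complete at the first pair of consecutive no-SCR
trials; the score is the number of trials before that pair.  A participant
is a non-responder when a condition's first two trials contain no
qualifying SCR (by default: neither of the two; a stricter at-least-one
rule is selectable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eda import EdaTrace, ScrEvent
from .errors import ConfigurationError, ParameterError
from .synthetic import StimulusSchedule

__all__ = [
    "ScoringCriteria",
    "TrialScore",
    "HabituationResult",
    "score_trials",
    "trials_to_habituation",
    "classify_responder",
    "block_means",
    "baseline_scl",
]


@dataclass(frozen=True)
class ScoringCriteria:
    """Amplitude and latency criteria a detected event must meet."""

    min_amplitude_uS: float = 0.03
    window_min_s: float = 1.0
    window_max_s: float = 4.0

    def __post_init__(self):
        if not 0 < self.window_min_s < self.window_max_s:
            raise ParameterError("need 0 < window_min_s < window_max_s")
        if self.min_amplitude_uS <= 0:
            raise ParameterError("min_amplitude_uS must be positive")


@dataclass(frozen=True)
class TrialScore:
    """Presence and magnitude of the qualifying SCR on one trial."""

    trial_index: int  # 1-based
    scr_present: bool
    amplitude_uS: float

    def __post_init__(self):
        if self.scr_present and self.amplitude_uS <= 0:
            raise ParameterError("present trials must carry positive amplitude")
        if not self.scr_present and self.amplitude_uS != 0:
            raise ParameterError("absent trials carry amplitude 0")


@dataclass(frozen=True)
class HabituationResult:
    """Trials elapsed before the first two consecutive no-SCR trials.

    ``censored`` is set when no such pair occurs within the block, in which
    case the score equals the number of trials.
    """

    trials_to_habituation: int
    censored: bool
    n_trials: int


def score_trials(
    events: list[ScrEvent],
    schedule: StimulusSchedule,
    criteria: ScoringCriteria = ScoringCriteria(),
    match_on: str = "trough",
) -> list[TrialScore]:
    """One TrialScore per scheduled trial.

    ``match_on`` selects the event time compared against the response
    window: ``"trough"`` (response onset, default) or ``"peak"``.  When
    several events qualify for a trial, the largest amplitude is recorded.
    """
    if match_on not in ("trough", "peak"):
        raise ParameterError("match_on must be 'trough' or 'peak'")
    onsets = np.asarray(schedule.onsets_s)
    if onsets.size > 1 and np.min(np.diff(onsets)) < criteria.window_max_s:
        raise ConfigurationError(
            "stimulus onsets closer than the response window overlap"
        )
    times = np.array(
        [e.trough_time_s if match_on == "trough" else e.peak_time_s for e in events]
    )
    amps = np.array([e.amplitude_uS for e in events])
    scores = []
    for k, onset in enumerate(onsets, start=1):
        lo, hi = onset + criteria.window_min_s, onset + criteria.window_max_s
        if times.size:
            mask = (times >= lo) & (times <= hi) & (amps >= criteria.min_amplitude_uS)
        else:
            mask = np.zeros(0, dtype=bool)
        if mask.any():
            scores.append(TrialScore(k, True, float(amps[mask].max())))
        else:
            scores.append(TrialScore(k, False, 0.0))
    return scores


def trials_to_habituation(scores: list[TrialScore]) -> HabituationResult:
    """Number of trials before the first two consecutive no-SCR trials.

    If a participant responds on trials 1..t and trials t+1 and t+2 are both
    response-free, the score is t.  With no such pair the score is the trial
    count, flagged censored.
    """
    if not scores:
        raise ParameterError("empty score list")
    present = [s.scr_present for s in scores]
    n = len(present)
    for i in range(n - 1):
        if not present[i] and not present[i + 1]:
            return HabituationResult(i, censored=False, n_trials=n)
    return HabituationResult(n, censored=True, n_trials=n)


def classify_responder(
    scores_per_condition: dict[str, list[TrialScore]],
    rule: str = "both_absent",
) -> bool:
    """Responder status from the first two trials of each condition.

    ``rule="both_absent"`` (default): a participant is a non-responder when,
    in any condition, neither of the first two trials holds a qualifying
    SCR.  ``rule="any_absent"`` (strict): missing either of the first two
    trials in any condition already makes a non-responder.

    Returns True for responders.
    """
    if rule not in ("both_absent", "any_absent"):
        raise ParameterError("rule must be 'both_absent' or 'any_absent'")
    if not scores_per_condition:
        raise ParameterError("need at least one condition")
    for scores in scores_per_condition.values():
        if len(scores) < 2:
            raise ParameterError("each condition needs >= 2 trials")
        first_two = [scores[0].scr_present, scores[1].scr_present]
        if rule == "both_absent":
            if not any(first_two):
                return False
        else:
            if not all(first_two):
                return False
    return True


def block_means(
    scores: list[TrialScore],
    block_size: int = 5,
    include_absent_as_zero: bool = True,
) -> list[float]:
    """Mean SCR magnitude per consecutive block of trials.

    With the default magnitude convention, response-free trials contribute
    zeros; ``include_absent_as_zero=False`` averages only trials with a
    response (NaN for a block with none).
    """
    if block_size < 1:
        raise ParameterError("block_size must be >= 1")
    n = len(scores)
    if n == 0 or n % block_size != 0:
        raise ParameterError(f"{n} trials not divisible into blocks of {block_size}")
    out = []
    for i in range(0, n, block_size):
        block = scores[i : i + block_size]
        if include_absent_as_zero:
            out.append(float(np.mean([s.amplitude_uS for s in block])))
        else:
            amps = [s.amplitude_uS for s in block if s.scr_present]
            out.append(float(np.mean(amps)) if amps else float("nan"))
    return out


def baseline_scl(
    trace: EdaTrace,
    total_baseline_s: float = 600.0,
    last_s: float = 300.0,
) -> float:
    """Tonic skin conductance level: mean over the final ``last_s`` seconds
    of a ``total_baseline_s``-second rest baseline.

    Plain sample averaging, no filtering — averaging this many samples is a
    low-pass operation in itself.
    """
    if not 0 < last_s <= total_baseline_s:
        raise ParameterError("need 0 < last_s <= total_baseline_s")
    if trace.duration_s + 1.0 / trace.rate_hz < total_baseline_s:
        raise ParameterError("trace shorter than the baseline period")
    n_total = int(round(total_baseline_s * trace.rate_hz))
    n_last = int(round(last_s * trace.rate_hz))
    segment = trace.values_uS[n_total - n_last : n_total]
    return float(np.mean(segment))
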