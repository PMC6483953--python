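"""Synthetic study data: stimulus schedules, skin-conductance traces with
known ground-truth SCRs, psychometric observers, and two-group cohorts.

Every downstream stage (filtering, SCR detection, habituation scoring, the
detection-threshold staircase, the group statistics) is exercised against
data from this module, so each generator returns its own ground truth.

The defaults emulate the habituation protocol the package targets: 15-trial
blocks of 3 s auditory stimuli with the interstimulus interval jittered
between 20 and 35 s, event-related SCRs whose amplitude decays
geometrically across trials, a tonic level around 32 µS with slow drift,
and two groups whose questionnaire and rating scores differ by configurable
amounts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .eda import EdaTrace
from .errors import ParameterError

__all__ = [
    "StimulusSchedule",
    "ScrGenParams",
    "Observer",
    "GroupSpec",
    "CohortSpec",
    "make_schedule",
    "scr_kernel",
    "kernel_peak_time",
    "generate_eda_trace",
    "observer_response",
    "generate_cohort",
]


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered stimulus onsets for one condition (e.g. tone or siren)."""

    onsets_s: tuple[float, ...]
    duration_s: float

    def __post_init__(self):
        onsets = tuple(float(t) for t in self.onsets_s)
        object.__setattr__(self, "onsets_s", onsets)
        if len(onsets) == 0:
            raise ParameterError("schedule needs at least one onset")
        if self.duration_s <= 0:
            raise ParameterError("stimulus duration must be positive")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ParameterError("onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.onsets_s)


@dataclass(frozen=True)
class ScrGenParams:
    """Ground-truth parameters for one participant's SCR generator.

    Trial k (0-based) emits, with probability ``response_prob``, an SCR of
    amplitude ``initial_amplitude_uS * decay_ratio**k`` starting
    ``latency_s`` (± ``latency_jitter_s``) after stimulus onset, shaped by a
    biexponential kernel.  The tonic background is
    ``tonic_level_uS + drift_uS_per_s * t`` plus white noise.
    """

    initial_amplitude_uS: float = 0.5
    decay_ratio: float = 0.73
    latency_s: float = 1.8
    latency_jitter_s: float = 0.3
    rise_tau_s: float = 0.75
    decay_tau_s: float = 2.0
    tonic_level_uS: float = 32.0
    drift_uS_per_s: float = 0.0005
    noise_sd_uS: float = 0.01
    response_prob: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.initial_amplitude_uS <= 0:
            raise ParameterError("initial amplitude must be positive")
        if not 0 < self.decay_ratio <= 1:
            raise ParameterError("decay_ratio must lie in (0, 1]")
        if not 0 < self.rise_tau_s < self.decay_tau_s:
            raise ParameterError("need 0 < rise_tau_s < decay_tau_s")
        if not 0 <= self.response_prob <= 1:
            raise ParameterError("response_prob must lie in [0, 1]")
        if self.tonic_level_uS <= 0:
            raise ParameterError("tonic level must be positive")
        if self.noise_sd_uS < 0 or self.latency_jitter_s < 0:
            raise ParameterError("spreads must be non-negative")

    def true_trials_to_habituation(
        self, threshold_uS: float = 0.03, n_trials: int = 15
    ) -> int:
        """Analytic trials-to-habituation for deterministic emission.

        The first 0-based trial index k with amplitude below ``threshold_uS``
        is the number of supra-threshold trials, i.e. the habituation score,
        provided at least two sub-threshold trials remain in the block.
        """
        if self.initial_amplitude_uS < threshold_uS:
            return 0
        if self.decay_ratio == 1.0:
            return n_trials
        k = math.ceil(
            math.log(threshold_uS / self.initial_amplitude_uS)
            / math.log(self.decay_ratio)
        )
        # amplitude exactly at threshold still counts as a response
        while self.initial_amplitude_uS * self.decay_ratio**k >= threshold_uS:
            k += 1
        return min(k, n_trials)


@dataclass
class Observer:
    """Simulated yes/no listener for the detection-threshold staircase.

    P(yes at level L) = guess + (1 - guess - lapse) * F((L - T)/slope)
    with F the cumulative normal (the standard psychometric function), T
    the true 50%-detection threshold and ``slope_db`` the psychometric
    spread.  ``slope_db = 0`` denotes a deterministic step observer: yes
    exactly when L >= T.
    Responses consume a seeded stream in presentation order, so whole
    staircase runs are reproducible.
    """

    true_threshold_db: float
    slope_db: float = 0.0
    lapse_rate: float = 0.0
    guess_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.lapse_rate < 0.5 and 0 <= self.guess_rate < 0.5):
            raise ParameterError("lapse and guess rates must lie in [0, 0.5)")
        if self.slope_db < 0:
            raise ParameterError("slope_db must be non-negative")
        self._rng = np.random.default_rng(self.seed)

    def p_yes(self, level_db: float) -> float:
        if self.slope_db == 0:
            f = 1.0 if level_db >= self.true_threshold_db else 0.0
        else:
            z = (level_db - self.true_threshold_db) / self.slope_db
            f = 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
        return self.guess_rate + (1.0 - self.guess_rate - self.lapse_rate) * f


def observer_response(observer: Observer, level_db: float) -> bool:
    """One yes/no report at ``level_db``, drawn from the observer's stream.

    Deterministic observers (slope 0, no lapses or guesses) never touch the
    stream, so their responses are independent of call order.
    """
    p = observer.p_yes(level_db)
    if p >= 1.0:
        return True
    if p <= 0.0:
        return False
    return bool(observer._rng.random() < p)


def make_schedule(
    n_trials: int = 15,
    duration_s: float = 3.0,
    isi_min_s: float = 20.0,
    isi_max_s: float = 35.0,
    seed: int = 0,
    start_s: float = 10.0,
) -> StimulusSchedule:
    """Stimulus schedule with inter-onset gaps of duration + U[isi_min, isi_max].

    The ISI is the silent gap between stimulus offset and the next onset, so
    consecutive onsets are separated by the stimulus duration plus a uniform
    jitter draw.  The first onset sits at ``start_s``.
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    if not 0 < isi_min_s <= isi_max_s:
        raise ParameterError("need 0 < isi_min_s <= isi_max_s")
    if duration_s <= 0:
        raise ParameterError("duration must be positive")
    rng = np.random.default_rng(seed)
    gaps = duration_s + rng.uniform(isi_min_s, isi_max_s, size=n_trials - 1)
    onsets = start_s + np.concatenate([[0.0], np.cumsum(gaps)])
    return StimulusSchedule(tuple(onsets), duration_s)


def kernel_peak_time(rise_tau_s: float, decay_tau_s: float) -> float:
    """Closed-form time of the biexponential kernel's maximum."""
    return (
        math.log(decay_tau_s / rise_tau_s)
        * rise_tau_s
        * decay_tau_s
        / (decay_tau_s - rise_tau_s)
    )


def scr_kernel(
    rise_tau_s: float = 0.75,
    decay_tau_s: float = 2.0,
    dt_s: float = 0.001,
    support_s: float | None = None,
) -> np.ndarray:
    """Sampled biexponential SCR kernel, rescaled to unit peak.

    k(t) = exp(-t/decay_tau) - exp(-t/rise_tau): zero at t = 0, maximum 1 at
    t* = ln(decay/rise) * rise*decay / (decay - rise), then exponential decay
    toward zero.  ``support_s`` defaults to 12 decay time constants.
    """
    if not 0 < rise_tau_s < decay_tau_s:
        raise ParameterError("need 0 < rise_tau_s < decay_tau_s")
    if dt_s <= 0:
        raise ParameterError("dt_s must be positive")
    if support_s is None:
        support_s = 12.0 * decay_tau_s
    t = np.arange(0.0, support_s, dt_s)
    k = np.exp(-t / decay_tau_s) - np.exp(-t / rise_tau_s)
    t_star = kernel_peak_time(rise_tau_s, decay_tau_s)
    peak = math.exp(-t_star / decay_tau_s) - math.exp(-t_star / rise_tau_s)
    return k / peak


def generate_eda_trace(
    schedule: StimulusSchedule,
    params: ScrGenParams,
    rate_hz: float = 1000.0,
    total_s: float | None = None,
) -> tuple[EdaTrace, pd.DataFrame]:
    """Synthesize a skin-conductance trace plus its ground-truth event table.

    trace = tonic + drift·t + Σ emitted SCRs + white noise.  Trial k
    (0-based) carries an SCR of amplitude initial_amplitude·decay_ratio^k
    when emitted.  The ground-truth table has one row per trial with columns
    ``trial`` (1-based), ``onset_s``, ``emitted``, ``scr_onset_s`` and
    ``amplitude_uS`` (NaN where no SCR was emitted).  Deterministic given
    ``params.seed``.
    """
    if rate_hz <= 0:
        raise ParameterError("rate_hz must be positive")
    last = schedule.onsets_s[-1]
    if total_s is None:
        total_s = last + 15.0
    if total_s < last + 10.0:
        raise ParameterError("total_s must cover the last onset plus 10 s")
    rng = np.random.default_rng(params.seed)
    n = int(round(total_s * rate_hz))
    t = np.arange(n) / rate_hz
    trace = params.tonic_level_uS + params.drift_uS_per_s * t
    kernel = scr_kernel(params.rise_tau_s, params.decay_tau_s, 1.0 / rate_hz)

    rows = []
    for k, onset in enumerate(schedule.onsets_s):
        emitted = bool(rng.random() < params.response_prob)
        jitter = rng.uniform(-params.latency_jitter_s, params.latency_jitter_s)
        scr_onset = onset + params.latency_s + jitter
        amp = params.initial_amplitude_uS * params.decay_ratio**k
        if emitted:
            i0 = int(round(scr_onset * rate_hz))
            seg = kernel[: max(0, n - i0)]
            trace[i0 : i0 + seg.size] += amp * seg
        rows.append(
            {
                "trial": k + 1,
                "onset_s": onset,
                "emitted": emitted,
                "scr_onset_s": scr_onset if emitted else np.nan,
                "amplitude_uS": amp if emitted else np.nan,
            }
        )
    if params.noise_sd_uS > 0:
        trace = trace + rng.normal(0.0, params.noise_sd_uS, size=n)
    return EdaTrace(trace, rate_hz), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class GroupSpec:
    """Per-group generating distributions for one synthetic cohort.

    ``outcomes`` maps a variable name to (mean, sd) of a normal marginal.
    SCR generator parameters and the true detection threshold are drawn per
    participant from the stated normal distributions (decay ratio clipped to
    (0, 1]).
    """

    n: int
    outcomes: dict[str, tuple[float, float]]
    scr_amplitude: tuple[float, float] = (0.5, 0.15)
    scr_decay: tuple[float, float] = (0.73, 0.06)
    response_prob: float = 1.0
    nonresponder_frac: float = 0.0
    threshold_db: tuple[float, float] = (15.0, 5.0)

    def __post_init__(self):
        if self.n < 2:
            raise ParameterError("group size must be >= 2")
        if not 0 <= self.nonresponder_frac <= 1:
            raise ParameterError("nonresponder_frac must lie in [0, 1]")
        for name, (_, sd) in self.outcomes.items():
            if sd < 0:
                raise ParameterError(f"negative sd for outcome {name!r}")


def _default_groups() -> dict[str, GroupSpec]:
    # means (sd) mirror the target study's descriptive tables
    return {
        "ASD": GroupSpec(
            n=33,
            outcomes={
                "aasp_auditory": (35.61, 8.1),
                "arousal_tone": (5.27, 0.3),
                "arousal_siren": (4.97, 0.3),
                "valence_tone": (2.02, 0.1),
                "valence_siren": (4.09, 0.3),
                "baseline_scl_uS": (32.31, 4.2),
            },
            nonresponder_frac=7 / 33,
            threshold_db=(15.45, 5.2),
        ),
        "TD": GroupSpec(
            n=31,
            outcomes={
                "aasp_auditory": (24.94, 6.0),
                "arousal_tone": (3.47, 0.3),
                "arousal_siren": (3.57, 0.4),
                "valence_tone": (2.14, 0.1),
                "valence_siren": (4.73, 0.3),
                "baseline_scl_uS": (31.16, 3.0),
            },
            nonresponder_frac=4 / 31,
            threshold_db=(13.87, 4.6),
        ),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort description.

    ``rank_corr_arousal_aasp`` is the target Spearman correlation between
    the tone-arousal rating and the auditory questionnaire score, realised
    through a shared latent Gaussian per participant (the Pearson loading is
    2·sin(π·ρ_s/6), the exact bivariate-normal conversion).
    """

    groups: dict[str, GroupSpec] = field(default_factory=_default_groups)
    rank_corr_arousal_aasp: float = 0.61
    corr_variables: tuple[str, str] = ("arousal_tone", "aasp_auditory")

    def __post_init__(self):
        if not -1 <= self.rank_corr_arousal_aasp <= 1:
            raise ParameterError("target correlation must lie in [-1, 1]")


def generate_cohort(spec: CohortSpec | None = None, seed: int = 0) -> pd.DataFrame:
    """One row per synthetic participant: group label, outcome scores, SCR
    generator parameters, true detection threshold, and a per-participant
    substream seed.

    A single master seed spawns independent substreams per participant, so
    rows are reproducible individually and the cohort as a whole.
    """
    if spec is None:
        spec = CohortSpec()
    rho_s = spec.rank_corr_arousal_aasp
    rho_p = 2.0 * math.sin(math.pi * rho_s / 6.0)
    load = math.sqrt(abs(rho_p))
    sign = 1.0 if rho_p >= 0 else -1.0
    var_a, var_b = spec.corr_variables

    master = np.random.SeedSequence(seed)
    rows = []
    pid = 0
    for group, gspec in spec.groups.items():
        for _ in range(gspec.n):
            child = master.spawn(1)[0]
            rng = np.random.default_rng(child)
            sub_seed = int(child.generate_state(1, np.uint32)[0]) % (2**31)
            z = rng.standard_normal()  # shared latent for the rank correlation
            row = {"participant": pid, "group": group, "seed": sub_seed}
            for name, (mean, sd) in gspec.outcomes.items():
                e = rng.standard_normal()
                if name == var_a:
                    u = sign * load * z + math.sqrt(max(0.0, 1 - load**2)) * e
                elif name == var_b:
                    u = load * z + math.sqrt(max(0.0, 1 - load**2)) * e
                else:
                    u = e
                row[name] = mean + sd * u
            am, asd = gspec.scr_amplitude
            dm, dsd = gspec.scr_decay
            tm, tsd = gspec.threshold_db
            row["scr_initial_amplitude_uS"] = max(0.01, rng.normal(am, asd))
            row["scr_decay_ratio"] = float(np.clip(rng.normal(dm, dsd), 0.05, 1.0))
            is_nonresponder = rng.random() < gspec.nonresponder_frac
            row["scr_response_prob"] = 0.0 if is_nonresponder else gspec.response_prob
            row["true_nonresponder"] = is_nonresponder
            row["true_threshold_db"] = max(0.5, rng.normal(tm, tsd))
            rows.append(row)
            pid += 1
    return pd.DataFrame(rows)


def participant_scr_params(row: pd.Series, **overrides) -> ScrGenParams:
    """Build the SCR generator parameters for one cohort row."""
    base = ScrGenParams(
        initial_amplitude_uS=float(row["scr_initial_amplitude_uS"]),
        decay_ratio=float(row["scr_decay_ratio"]),
        response_prob=float(row["scr_response_prob"]),
        seed=int(row["seed"]),
    )
    return replace(base, **overrides) if overrides else base
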