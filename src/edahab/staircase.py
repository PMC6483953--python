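"""Adaptive method-of-limits detection-threshold staircase.

One pass starts at 60 dB HL and descends in 5-dB steps until the listener
first reports not hearing the tone, then ascends in 5-dB steps from one
step above that level until hearing is reported again; the level of that
first ascending "yes" is the pass threshold (the lowest intensity at which
the tone was perceived).  Passes repeat until two consecutive pass
thresholds agree; the agreed value is the detection threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import ParameterError, StaircaseConvergenceError
from .synthetic import Observer, observer_response

__all__ = ["StaircasePass", "ThresholdResult", "run_pass", "detection_threshold"]


@dataclass(frozen=True)
class StaircasePass:
    """One descending/ascending sweep of the staircase."""

    levels_db: tuple[float, ...]
    responses: tuple[bool, ...]
    pass_threshold_db: float


@dataclass(frozen=True)
class ThresholdResult:
    """Agreed detection threshold after repeat-until-agreement passes."""

    passes: tuple[StaircasePass, ...]
    final_threshold_db: float

    @property
    def n_passes(self) -> int:
        return len(self.passes)


def run_pass(
    observer: Observer,
    start_db: float = 60.0,
    step_db: float = 5.0,
    floor_db: float = 0.0,
    ceiling_db: float | None = None,
) -> StaircasePass:
    """One staircase pass against a (possibly stochastic) observer.

    Descends start, start-step, ... until the first "no"; then ascends from
    one step above that level until the first "yes", which becomes the pass
    threshold.  If "no" never occurs at or above ``floor_db``, the floor is
    taken as the threshold with a warning; if "yes" never occurs at or below
    ``ceiling_db`` (default start + 20 dB) the staircase is deemed runaway.
    """
    if step_db <= 0:
        raise ParameterError("step_db must be positive")
    if ceiling_db is None:
        ceiling_db = start_db + 20.0
    levels: list[float] = []
    responses: list[bool] = []

    level = start_db
    last_no = None
    while True:
        heard = observer_response(observer, level)
        levels.append(level)
        responses.append(heard)
        if not heard:
            last_no = level
            break
        if level - step_db < floor_db - 1e-9:
            warnings.warn(
                "no 'no' response down to the floor; floor taken as threshold",
                stacklevel=2,
            )
            return StaircasePass(tuple(levels), tuple(responses), float(level))
        level -= step_db

    level = last_no + step_db
    while True:
        if level > ceiling_db + 1e-9:
            raise StaircaseConvergenceError(
                "ascending phase exceeded the level ceiling without a 'yes'",
                passes=[StaircasePass(tuple(levels), tuple(responses), float("nan"))],
            )
        heard = observer_response(observer, level)
        levels.append(level)
        responses.append(heard)
        if heard:
            return StaircasePass(tuple(levels), tuple(responses), float(level))
        level += step_db


def detection_threshold(
    observer: Observer,
    start_db: float = 60.0,
    step_db: float = 5.0,
    max_passes: int = 20,
    floor_db: float = 0.0,
    ceiling_db: float | None = None,
) -> ThresholdResult:
    """Repeat passes until two consecutive pass thresholds agree.

    At least two passes always run; each pass restarts at ``start_db``.
    Raises StaircaseConvergenceError (carrying all passes) when no two
    consecutive passes agree within ``max_passes``.
    """
    if max_passes < 2:
        raise ParameterError("max_passes must be >= 2")
    passes: list[StaircasePass] = []
    for _ in range(max_passes):
        passes.append(run_pass(observer, start_db, step_db, floor_db, ceiling_db))
        if len(passes) >= 2 and passes[-1].pass_threshold_db == passes[-2].pass_threshold_db:
            return ThresholdResult(tuple(passes), passes[-1].pass_threshold_db)
    raise StaircaseConvergenceError(
        f"no two consecutive equal thresholds within {max_passes} passes",
        passes=passes,
    )
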