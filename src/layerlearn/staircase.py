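"""3-down-1-up adaptive staircase and behavioral improvement analysis.

The transformed up-down rule decreases the stimulus level (angle
difference in degrees) after three consecutive correct responses and
increases it after any error. With equal up and down steps the procedure
converges at the level where the probability of three consecutive correct
responses is 1/2, i.e. percent correct ``(1/2)**(1/3) ~ 79.4%`` — a
property of the rule, independent of the observer's psychometric shape.

Steps are multiplicative (level x/÷ a step factor), which keeps the level
positive and corresponds to additive steps on a log/dB axis. A staircase
terminates after a fixed number of reversals (default 15; a reversal is a
trial at which the direction of level change flips — the first trial is
never a reversal), and the threshold estimate is the arithmetic mean of
the levels at the last 8 reversals.

Behavioral learning is summarized by the mean percent improvement index,
``MPI = (pre - post) / pre x 100`` on thresholds.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import StaircaseTrace
from .synth import Observer, ObserverSpec

logger = logging.getLogger(__name__)

#: closed-form convergence level of the 3-down-1-up rule
CONVERGENCE_P = 0.5 ** (1.0 / 3.0)


def run_staircase(observer: Observer, start_level_deg: float = 5.0,
                  n_down: int = 3, n_up: int = 1,
                  stop_reversals: int = 15, step_factor: float = 1.2,
                  max_level_deg: float = 45.0, min_level_deg: float = 0.01,
                  max_trials: int = 2000) -> StaircaseTrace:
    """Run an n-down / 1-up staircase on a (possibly stochastic) observer.

    The level is divided by ``step_factor`` after ``n_down`` consecutive
    correct responses and multiplied by it after any incorrect response
    (``n_up`` errors, default 1). Levels are clipped to
    [``min_level_deg``, ``max_level_deg``]; a non-converging observer
    pins the staircase at the cap with a warning. Terminates at
    ``stop_reversals`` reversals (or ``max_trials`` as a safety stop) and
    stores the mean of the last 8 reversal levels as the threshold when
    enough reversals occurred.
    """
    if start_level_deg <= 0:
        raise ValueError("start level must be positive")
    if step_factor <= 1:
        raise ValueError("step_factor must exceed 1")
    level = float(start_level_deg)
    levels, correct, reversal = [], [], []
    streak = 0
    err_streak = 0
    direction = 0  # -1 going down, +1 going up, 0 before the first change
    n_rev = 0
    capped = False
    while n_rev < stop_reversals and len(levels) < max_trials:
        resp = observer.respond(level)
        levels.append(level)
        correct.append(resp)
        move = 0
        if resp:
            streak += 1
            err_streak = 0
            if streak >= n_down:
                move = -1
                streak = 0
        else:
            err_streak += 1
            streak = 0
            if err_streak >= n_up:
                move = +1
                err_streak = 0
        is_rev = move != 0 and direction != 0 and move != direction
        reversal.append(is_rev)
        if is_rev:
            n_rev += 1
        if move != 0:
            direction = move
            new_level = level / step_factor if move < 0 else level * step_factor
            clipped = float(np.clip(new_level, min_level_deg, max_level_deg))
            if clipped != new_level and not capped:
                capped = True
                logger.warning("staircase hit the level cap at %.3g deg", clipped)
            level = clipped

    trace = StaircaseTrace(levels=np.array(levels),
                           correct=np.array(correct, dtype=bool),
                           reversal=np.array(reversal, dtype=bool))
    if trace.n_reversals >= 8:
        trace.threshold_deg = threshold_from_trace(trace)
    return trace


def threshold_from_trace(trace: StaircaseTrace, n_last: int = 8) -> float:
    """Mean stimulus level over the last ``n_last`` reversal trials."""
    revs = trace.reversal_levels()
    if len(revs) < n_last:
        raise ValueError(f"need at least {n_last} reversals, got {len(revs)}")
    return float(np.mean(revs[-n_last:]))


def convergence_accuracy(spec: ObserverSpec, n_sims: int = 500,
                         seed: int = 0, **staircase_kwargs):
    """Mean true percent correct at staircase-estimated thresholds.

    Simulates ``n_sims`` independent staircases on observers drawn from
    ``spec`` (each with its own sub-seed), evaluates the observer's true
    psychometric function at each estimated threshold, and averages.
    For the 3-down-1-up rule the result should sit at the fixed point
    ``(1/2)**(1/3) ~ 0.794``.

    Returns ``(mean_pc, per_run_pc)``.
    """
    if n_sims < 100:
        logger.warning("n_sims=%d is small for a convergence estimate", n_sims)
    ss = np.random.SeedSequence(seed)
    pcs = np.empty(n_sims)
    for i, s in enumerate(ss.generate_state(n_sims)):
        obs = Observer(ObserverSpec(
            psychometric_family=spec.psychometric_family,
            threshold_deg=spec.threshold_deg, slope=spec.slope,
            lapse_rate=spec.lapse_rate, seed=int(s % (2**31))))
        trace = run_staircase(obs, **staircase_kwargs)
        pcs[i] = obs.percent_correct(trace.threshold_deg)
    return float(pcs.mean()), pcs


def behavioral_mpi(pre_thresholds, post_thresholds) -> pd.DataFrame:
    """Percent improvement index per condition.

    Inputs map condition -> threshold(s) in degrees; when a condition has
    several staircase runs their mean is taken first (the per-condition
    threshold is the mean across runs), then
    ``MPI = (pre - post) / pre x 100``. A zero pre threshold yields NaN
    with a warning.
    """
    conditions = list(pre_thresholds)
    if set(conditions) != set(post_thresholds):
        raise ValueError("pre and post conditions do not match")
    rows = []
    for cond in conditions:
        pre = float(np.mean(pre_thresholds[cond]))
        post = float(np.mean(post_thresholds[cond]))
        if pre == 0:
            logger.warning("pre threshold 0 for %s; MPI undefined", cond)
            mpi = float("nan")
        else:
            mpi = (pre - post) / pre * 100.0
        rows.append(dict(condition=cond, pre_deg=pre, post_deg=post, mpi=mpi))
    return pd.DataFrame(rows)
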