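"""Trial-level subtest simulators.

Each simulator implements its task's published stimulus structure, stopping
rule, and scoring rule exactly; the *agent* behind it is a simple
psychometric stand-in: correctness on a trial is Bernoulli with probability
logistic(ability - difficulty), and response times are lognormal with a
median governed by the agent's speed parameter.  ``p_override`` pins the
per-trial success probability (e.g. to 1 or 0), which the tests use to
exercise the stopping and scoring rules deterministically.

Task rules implemented (by subtest id):

* 26/32 go/no-go — stop after 5 (id 26) or 10 (id 32) correct go trials, or
  after 3 incorrect responses of either type (then the session fails; up to
  3 attempts before the score is missing).  1500 ms response cap; score =
  mean correct-go response time in ms.
* 27 divided visual attention — 12 trials; presentation time staircases
  down/up on correct/incorrect (start 1 s); score = correct count.
* 28/33 memory span (fwd/rev) — span starts at 3, +1 after every 2 trials;
  two incorrect at one span level ends; score = max span with >=1 correct.
* 43/44 memory span v2 — +1 after every 3 trials; score = total correct.
* 29 arithmetic — correct responses completed in 45 s.
* 30 grammatical reasoning — correct minus incorrect in 45 s, floor 0.
* 31 progressive matrices — 17 trials of increasing difficulty; three
  consecutive errors end it; score = total correct.
* 36/37 verbal list learning (immediate/delayed) — 12 words x 3 rounds;
  score = words recalled in round 3 (36) / after a delay (37).
* 38/45 digit symbol coding — correct trials completed in 90 s.
* 39/40 trail making A/B — 24 circles to click in order; errors force a
  backtrack click; score = total completion time in seconds.
* 51 scale balance — 25 trials of increasing difficulty, 10-minute limit,
  three consecutive errors end it; score = correct count.
* 52 Posner cueing — 100 trials, stimulus at the cued location on 60% of
  trials; score = correct count.
* 53 complex span — span starts at 4, +1 on a correct trial, two incorrect
  at one span ends; score = total correct.
* 54 object recognition — 20 studied shapes, 40 yes/no probes (20 old,
  20 new); score = correct count.
* 55 dual search — 50 trials, one of two question types each; score =
  correct count.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from ..records import TrialEvent
from ..registry import UnknownSubtestError, subtest_registry
from .agents import AgentProfile

__all__ = ["simulate_subtest"]

_MAX_GONOGO_ATTEMPTS = 3


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _p(ability: float, difficulty: float, p_override: Optional[float]) -> float:
    if p_override is not None:
        return float(p_override)
    return _logistic(ability - difficulty)


def _rt(rng: np.random.Generator, median_s: float, speed: float,
        sigma: float = 0.25) -> float:
    """Lognormal response time; faster agents (higher speed) respond sooner."""
    return float(median_s * np.exp(-0.15 * speed + sigma * rng.standard_normal()))


# ---------------------------------------------------------------------------
# Individual task simulators.  Each returns (trials, raw_score or None).
# ---------------------------------------------------------------------------

def _sim_gonogo(ability, speed, rng, p_override, target_go: int):
    # one attempt; fail after 3 incorrect responses of either type
    def attempt():
        trials = []
        go_rts, n_incorrect, n_go_correct, t = [], 0, 0, 0
        while n_go_correct < target_go and n_incorrect < 3:
            is_go = rng.random() < 0.7
            p = _p(ability, -2.0, p_override)
            correct = rng.random() < p
            if is_go:
                rt = min(_rt(rng, 0.45, speed), 1.4995)  # 1500 ms response cap
                if not correct:
                    rt = 1.5  # lapse: no response within the cap
                response = "press" if correct else "none"
            else:
                rt = 1.5 if correct else min(_rt(rng, 0.40, speed), 1.4995)
                response = "none" if correct else "press"
            trials.append(TrialEvent(
                trial=t, stimulus={"type": "go" if is_go else "no-go"},
                response=response, correct=bool(correct), rt=rt))
            if is_go and correct:
                n_go_correct += 1
                go_rts.append(rt)
            if not correct:
                n_incorrect += 1
            t += 1
        passed = n_go_correct >= target_go
        score = 1000.0 * float(np.mean(go_rts)) if passed else None
        return trials, score

    all_trials = []
    for _ in range(_MAX_GONOGO_ATTEMPTS):
        trials, score = attempt()
        all_trials.extend(trials)
        if score is not None:
            return all_trials, score
    return all_trials, None


def _sim_dva(ability, speed, rng, p_override):
    # staircase on presentation time: start 1 s, step 100 ms, floor/cap
    pres, step, floor, cap = 1.0, 0.1, 0.1, 3.0
    trials, correct_n = [], 0
    for t in range(12):
        difficulty = 2.5 * (1.0 - pres)  # shorter presentation = harder
        correct = rng.random() < _p(ability, difficulty, p_override)
        trials.append(TrialEvent(
            trial=t, stimulus={"presentation_s": round(pres, 3)},
            response="targets" if correct else "distractor",
            correct=bool(correct), rt=_rt(rng, 1.5, speed)))
        if correct:
            correct_n += 1
            pres = max(floor, pres - step)
        else:
            pres = min(cap, pres + step)
    return trials, float(correct_n)


def _sim_span(ability, speed, rng, p_override, trials_per_level: int,
              score_rule: str, start_span: int = 3, max_trials: int = 60):
    """Shared core of the forward/reverse memory span subtests."""
    trials = []
    span = start_span
    at_level = 0            # trials taken at the current span
    wrong_at_level = 0
    max_span_correct = 0
    total_correct = 0
    t = 0
    while t < max_trials:
        correct = rng.random() < _p(ability, 0.8 * (span - 5), p_override)
        trials.append(TrialEvent(
            trial=t, stimulus={"span": span}, response="sequence",
            correct=bool(correct), rt=_rt(rng, 0.8 * span, speed)))
        if correct:
            total_correct += 1
            max_span_correct = max(max_span_correct, span)
        else:
            wrong_at_level += 1
        if wrong_at_level >= 2:
            break
        at_level += 1
        t += 1
        if at_level >= trials_per_level:
            span += 1
            at_level = 0
            wrong_at_level = 0
    score = float(max_span_correct if score_rule == "max_span" else total_correct)
    return trials, score


def _sim_timed(ability, speed, rng, p_override, limit_s: float,
               item_median_s: float, difficulty: float, net: bool):
    """Timed item streams: arithmetic, grammar, digit symbol."""
    trials, t, clock = [], 0, 0.0
    n_correct, n_wrong = 0, 0
    while True:
        rt = _rt(rng, item_median_s, speed)
        if clock + rt > limit_s:
            break
        clock += rt
        correct = rng.random() < _p(ability, difficulty, p_override)
        trials.append(TrialEvent(trial=t, stimulus={"elapsed_s": round(clock, 3)},
                                 response="answer", correct=bool(correct), rt=rt))
        n_correct += int(correct)
        n_wrong += int(not correct)
        t += 1
    score = max(0, n_correct - n_wrong) if net else n_correct
    return trials, float(score)


def _sim_matrices(ability, speed, rng, p_override):
    trials, n_correct, streak = [], 0, 0
    for t in range(17):
        difficulty = -1.6 + 0.25 * t  # trials increase in difficulty
        correct = rng.random() < _p(ability, difficulty, p_override)
        trials.append(TrialEvent(trial=t, stimulus={"difficulty": round(difficulty, 3)},
                                 response="choice", correct=bool(correct),
                                 rt=_rt(rng, 8.0, speed)))
        if correct:
            n_correct += 1
            streak = 0
        else:
            streak += 1
            if streak >= 3:
                break
    return trials, float(n_correct)


def _sim_lists(ability, speed, rng, p_override, delayed: bool):
    trials = []
    n_words = 12
    recalled_round3 = 0
    t = 0
    for rnd in range(1, 4):
        boost = 0.5 * (rnd - 1)  # learning across the three presentations
        for word in range(n_words):
            correct = rng.random() < _p(ability + boost, 0.4, p_override)
            trials.append(TrialEvent(
                trial=t, stimulus={"round": rnd, "word": word},
                response="recalled" if correct else "forgotten",
                correct=bool(correct), rt=_rt(rng, 1.2, speed)))
            if rnd == 3 and correct:
                recalled_round3 += 1
            t += 1
    if not delayed:
        return trials, float(recalled_round3)
    # delayed recall: retention decays from the round-3 state
    delayed_n = 0
    for word in range(n_words):
        correct = rng.random() < _p(ability + 1.0 - 0.7, 0.4, p_override)
        trials.append(TrialEvent(
            trial=t, stimulus={"round": "delayed", "word": word},
            response="recalled" if correct else "forgotten",
            correct=bool(correct), rt=_rt(rng, 1.5, speed)))
        delayed_n += int(correct)
        t += 1
    return trials, float(delayed_n)


def _sim_trails(ability, speed, rng, p_override, n_circles: int, median_s: float):
    trials, clock = [], 0.0
    p_err = 0.04 if p_override is None else max(0.0, 1.0 - float(p_override))
    p_err = _logistic(-3.2 - 0.3 * ability) if p_override is None else p_err
    t = 0
    for c in range(n_circles):
        rt = _rt(rng, median_s, speed + 0.5 * ability, sigma=0.3)
        clock += rt
        wrong = rng.random() < p_err
        trials.append(TrialEvent(trial=t, stimulus={"circle": c},
                                 response="click", correct=not wrong, rt=rt))
        t += 1
        if wrong:  # an 'X' appears; the agent must go back to the previous circle
            back = _rt(rng, median_s, speed + 0.5 * ability, sigma=0.3)
            clock += back
            trials.append(TrialEvent(trial=t, stimulus={"circle": c, "backtrack": True},
                                     response="click", correct=True, rt=back))
            t += 1
    return trials, float(clock)


def _sim_scale_balance(ability, speed, rng, p_override):
    trials, n_correct, streak, clock = [], 0, 0, 0.0
    for t in range(25):
        rt = _rt(rng, 14.0, speed, sigma=0.4)
        if clock + rt > 600.0:  # ten-minute limit
            break
        clock += rt
        difficulty = -1.2 + 0.12 * t
        correct = rng.random() < _p(ability, difficulty, p_override)
        trials.append(TrialEvent(trial=t, stimulus={"difficulty": round(difficulty, 3)},
                                 response="choice", correct=bool(correct), rt=rt))
        if correct:
            n_correct += 1
            streak = 0
        else:
            streak += 1
            if streak >= 3:
                break
    return trials, float(n_correct)


def _sim_posner(ability, speed, rng, p_override):
    trials, n_correct = [], 0
    for t in range(100):
        cued = rng.random() < 0.60  # stimulus at the cued location on 60% of trials
        difficulty = -3.0 - (0.4 if cued else 0.0)
        correct = rng.random() < _p(ability, difficulty, p_override)
        trials.append(TrialEvent(
            trial=t, stimulus={"cued": bool(cued)},
            response="left" if rng.random() < 0.5 else "right",
            correct=bool(correct),
            rt=min(_rt(rng, 0.5 if cued else 0.6, speed), 6.0)))
        n_correct += int(correct)
    return trials, float(n_correct)


def _sim_complex_span(ability, speed, rng, p_override, max_trials: int = 40):
    trials = []
    span, wrong_at_level, total_correct = 4, 0, 0
    for t in range(max_trials):
        correct = rng.random() < _p(ability, 0.7 * (span - 5), p_override)
        trials.append(TrialEvent(trial=t, stimulus={"span": span},
                                 response="sum+letters", correct=bool(correct),
                                 rt=_rt(rng, 2.0 * span, speed)))
        if correct:
            total_correct += 1
            span += 1          # span increases by one on a correct response
            wrong_at_level = 0
        else:
            wrong_at_level += 1
            if wrong_at_level >= 2:
                break
    return trials, float(total_correct)


def _sim_object_recognition(ability, speed, rng, p_override):
    trials, n_correct = [], 0
    probes = ["old"] * 20 + ["new"] * 20  # 20 studied shapes, 40 yes/no probes
    rng.shuffle(probes)
    for t, kind in enumerate(probes):
        correct = rng.random() < _p(ability, -0.8, p_override)
        trials.append(TrialEvent(trial=t, stimulus={"probe": kind},
                                 response="yes" if (kind == "old") == correct else "no",
                                 correct=bool(correct), rt=_rt(rng, 1.8, speed)))
        n_correct += int(correct)
    return trials, float(n_correct)


def _sim_dual_search(ability, speed, rng, p_override):
    trials, n_correct = [], 0
    for t in range(50):
        question = "center_same" if rng.random() < 0.5 else "red_letter"
        correct = rng.random() < _p(ability, -0.5, p_override)
        trials.append(TrialEvent(trial=t, stimulus={"question": question},
                                 response="answer", correct=bool(correct),
                                 rt=min(_rt(rng, 1.2, speed), 6.0)))
        n_correct += int(correct)
    return trials, float(n_correct)


_DISPATCH = {
    26: lambda a, s, r, p: _sim_gonogo(a, s, r, p, target_go=5),
    32: lambda a, s, r, p: _sim_gonogo(a, s, r, p, target_go=10),
    27: _sim_dva,
    28: lambda a, s, r, p: _sim_span(a, s, r, p, 2, "max_span"),
    33: lambda a, s, r, p: _sim_span(a, s, r, p, 2, "max_span"),
    43: lambda a, s, r, p: _sim_span(a, s, r, p, 3, "total_correct"),
    44: lambda a, s, r, p: _sim_span(a, s, r, p, 3, "total_correct"),
    29: lambda a, s, r, p: _sim_timed(a, s, r, p, 45.0, 3.5, -1.0, net=False),
    30: lambda a, s, r, p: _sim_timed(a, s, r, p, 45.0, 3.0, -1.2, net=True),
    38: lambda a, s, r, p: _sim_timed(a, s, r, p, 90.0, 1.6, -2.0, net=False),
    45: lambda a, s, r, p: _sim_timed(a, s, r, p, 90.0, 1.6, -2.0, net=False),
    31: _sim_matrices,
    36: lambda a, s, r, p: _sim_lists(a, s, r, p, delayed=False),
    37: lambda a, s, r, p: _sim_lists(a, s, r, p, delayed=True),
    39: lambda a, s, r, p: _sim_trails(a, s, r, p, 24, 1.3),
    40: lambda a, s, r, p: _sim_trails(a, s, r, p, 24, 2.4),
    51: _sim_scale_balance,
    52: _sim_posner,
    53: _sim_complex_span,
    54: _sim_object_recognition,
    55: _sim_dual_search,
}


def simulate_subtest(
    profile: Union[AgentProfile, float],
    subtest_id: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    p_override: Optional[float] = None,
    speed: Optional[float] = None,
) -> tuple[list[TrialEvent], Optional[float]]:
    """Simulate one subtest session: (trial events, raw score).

    ``profile`` may be an :class:`AgentProfile` or a bare ability value
    (with ``speed`` then defaulting to 0).  The raw score is ``None`` only
    when the session fails its task's failure path (go/no-go: three attempts
    ended by three incorrect responses each).
    """
    sid = int(subtest_id)
    if sid not in subtest_registry():
        raise UnknownSubtestError(f"unknown subtest id: {subtest_id!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(profile, AgentProfile):
        ability = profile.ability(sid) if sid in profile.abilities else profile.g
        spd = profile.speed
    else:
        ability = float(profile)
        spd = 0.0 if speed is None else float(speed)
    return _DISPATCH[sid](ability, spd, rng, p_override)
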