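"""Delayed-match-to-sample task: schedules, simulated responses, scoring.

The modelled session is the two-block working-memory protocol: per
trial the subject encodes two target images, then judges a sequence of
12 serially presented test images (6 targets, 6 distractors) as match
or non-match; 8 trials per block, two blocks with the response hand
swapped, inter-stimulus delays jittered uniformly on [1.6, 1.8] s.

Scoring follows the published conventions: accuracy is the percentage
of correct judgements per stimulus condition; reaction-time means are
split by correctness x condition; missing responses count as incorrect
and contribute no reaction time.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, PairingError

N_BLOCKS = 2
TRIALS_PER_BLOCK = 8
TEST_ITEMS_PER_TRIAL = 12
TARGETS_PER_TRIAL = 6  # "fairly distributed": 6 targets / 6 distractors
ENCODING_PRESENTATION_S = 3.0
ENCODING_CONSOLIDATION_S = 2.0  # completes the 5-s memorization period
ITEM_DURATION_S = 1.0
JITTER_RANGE_S = (1.6, 1.8)


@dataclass(frozen=True)
class TestItem:
    image_id: str
    is_target: bool
    onset_s: float


@dataclass(frozen=True)
class Trial:
    block: int  # 1-based
    index: int  # 1-based within session
    target_ids: tuple[str, str]
    test_items: tuple[TestItem, ...]
    jitters_s: tuple[float, ...]
    response_hand: str


@dataclass(frozen=True)
class TaskSchedule:
    """A full two-block session of 16 trials."""

    trials: tuple[Trial, ...]

    @property
    def n_items(self) -> int:
        return sum(len(t.test_items) for t in self.trials)

    def items_frame(self) -> pd.DataFrame:
        rows = [
            {
                "block": t.block,
                "trial": t.index,
                "item": k,
                "image_id": item.image_id,
                "is_target": item.is_target,
                "onset_s": item.onset_s,
            }
            for t in self.trials
            for k, item in enumerate(t.test_items)
        ]
        return pd.DataFrame(rows)


def build_task_schedule(seed=None, n_images: int = 120) -> TaskSchedule:
    """Randomized session schedule with the protocol's fixed structure.

    Each trial draws 2 targets and 6 distinct distractors from a pool of
    ``n_images`` identifiers; the 12-item test sequence holds 6 target
    presentations (3 of each target) and the 6 distractors in shuffled
    order, with fresh uniform jitters.
    """
    if n_images < 8:
        raise ConfigurationError("image pool must hold >= 2 targets + 6 distractors")
    rng = np.random.default_rng(seed)
    pool = [f"img{i + 1:03d}" for i in range(n_images)]
    lo, hi = JITTER_RANGE_S
    trials = []
    t0 = 0.0
    for trial_idx in range(N_BLOCKS * TRIALS_PER_BLOCK):
        block = trial_idx // TRIALS_PER_BLOCK + 1
        picks = rng.choice(n_images, size=8, replace=False)
        targets = tuple(pool[i] for i in picks[:2])
        distractors = [pool[i] for i in picks[2:]]
        ids = list(targets) * (TARGETS_PER_TRIAL // 2) + distractors
        flags = [True] * TARGETS_PER_TRIAL + [False] * (
            TEST_ITEMS_PER_TRIAL - TARGETS_PER_TRIAL
        )
        order = rng.permutation(TEST_ITEMS_PER_TRIAL)
        jitters = tuple(rng.uniform(lo, hi, size=TEST_ITEMS_PER_TRIAL + 1))
        onset = t0 + ENCODING_PRESENTATION_S + ENCODING_CONSOLIDATION_S + jitters[0]
        items = []
        for k in range(TEST_ITEMS_PER_TRIAL):
            idx = order[k]
            items.append(TestItem(ids[idx], flags[idx], round(onset, 6)))
            onset += ITEM_DURATION_S + jitters[k + 1]
        trials.append(
            Trial(
                block=block,
                index=trial_idx + 1,
                target_ids=targets,
                test_items=tuple(items),
                jitters_s=jitters,
                response_hand="dominant" if block == 1 else "non_dominant",
            )
        )
        t0 = onset
    return TaskSchedule(trials=tuple(trials))


@dataclass(frozen=True)
class ResponseParams:
    """Generative parameters of the simulated responder.

    Reaction times are lognormal with the stated mean/SD (in ms), the
    non-target mean shifted by ``rt_shift_nontarget_ms``, truncated to
    the 1-s response window plus a 500-ms grace period.
    """

    p_correct_target: float = 0.9156
    p_correct_nontarget: float = 0.9193
    rt_mean_ms: float = 673.0
    rt_sd_ms: float = 51.0
    rt_shift_nontarget_ms: float = 25.0
    p_no_response: float = 0.0
    response_window_ms: float = 1000.0
    grace_ms: float = 500.0

    def __post_init__(self) -> None:
        for p in (self.p_correct_target, self.p_correct_nontarget, self.p_no_response):
            if not 0 <= p <= 1:
                raise ConfigurationError("probabilities must be in [0, 1]")


def _lognormal_ms(rng, mean_ms: float, sd_ms: float, size: int) -> np.ndarray:
    sigma_sq = log(1.0 + (sd_ms / mean_ms) ** 2)
    mu = log(mean_ms) - sigma_sq / 2.0
    return rng.lognormal(mean=mu, sigma=sqrt(sigma_sq), size=size)


def simulate_responses(
    schedule: TaskSchedule, params: ResponseParams | None = None, seed=None
) -> pd.DataFrame:
    """Simulated response log: one row per presented test item.

    Columns: block, trial, item, image_id, is_target, response
    (match/nonmatch/none), rt_ms.
    """
    params = params or ResponseParams()
    rng = np.random.default_rng(seed)
    items = []
    for t in schedule.trials:
        for k, item in enumerate(t.test_items):
            items.append((t.block, t.index, k, item.image_id, item.is_target))
    n = len(items)
    is_target = np.array([row[4] for row in items])
    p_correct = np.where(is_target, params.p_correct_target, params.p_correct_nontarget)
    correct = rng.random(n) < p_correct
    responded = rng.random(n) >= params.p_no_response
    # correct target -> match; correct non-target -> nonmatch; errors invert
    says_match = np.where(correct, is_target, ~is_target)
    mean_ms = np.where(
        is_target, params.rt_mean_ms, params.rt_mean_ms + params.rt_shift_nontarget_ms
    )
    rt = np.empty(n)
    for m in np.unique(mean_ms):
        mask = mean_ms == m
        rt[mask] = _lognormal_ms(rng, float(m), params.rt_sd_ms, int(mask.sum()))
    rt = np.minimum(rt, params.response_window_ms + params.grace_ms)
    return pd.DataFrame(
        {
            "block": [r[0] for r in items],
            "trial": [r[1] for r in items],
            "item": [r[2] for r in items],
            "image_id": [r[3] for r in items],
            "is_target": is_target,
            "response": np.where(
                responded, np.where(says_match, "match", "nonmatch"), "none"
            ),
            "rt_ms": np.where(responded, rt, np.nan),
        }
    )


@dataclass
class BehaviorSummary:
    """Per-subject behavioral statistics on the published report scale."""

    subject_id: str = ""
    accuracy_target_pct: float = float("nan")
    accuracy_nontarget_pct: float = float("nan")
    accuracy_pct: float = float("nan")
    mean_rt_correct_target_ms: float | None = None
    mean_rt_correct_nontarget_ms: float | None = None
    mean_rt_incorrect_target_ms: float | None = None
    mean_rt_incorrect_nontarget_ms: float | None = None
    mean_rt_ms: float | None = None
    n_presented: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def score_responses(schedule: TaskSchedule, log: pd.DataFrame) -> BehaviorSummary:
    """Score a response log against its schedule.

    A response is correct when "match" is given to a target or
    "nonmatch" to a distractor; "none" counts as incorrect and
    contributes no reaction time.  ``mean_rt_ms`` is the overall mean
    correct reaction time.
    """
    sched = schedule.items_frame()
    if len(log) != len(sched):
        raise PairingError(
            f"log has {len(log)} rows for a schedule of {len(sched)} items"
        )
    merged = sched.merge(
        log, on=["block", "trial", "item"], suffixes=("", "_log"), validate="1:1"
    )
    if len(merged) != len(sched):
        raise PairingError("log rows do not pair 1:1 with schedule items")
    if "image_id_log" in merged and not (
        merged["image_id"] == merged["image_id_log"]
    ).all():
        raise PairingError("log image ids disagree with the schedule")

    is_target = merged["is_target"].to_numpy(bool)
    response = merged["response"].to_numpy()
    rt = merged["rt_ms"].to_numpy(float)
    answered = response != "none"
    correct = answered & ((response == "match") == is_target)

    def acc(mask: np.ndarray) -> float:
        return 100.0 * correct[mask].sum() / max(mask.sum(), 1)

    def mean_rt(mask: np.ndarray) -> float | None:
        vals = rt[mask & answered]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else None

    return BehaviorSummary(
        accuracy_target_pct=acc(is_target),
        accuracy_nontarget_pct=acc(~is_target),
        accuracy_pct=100.0 * correct.sum() / len(merged),
        mean_rt_correct_target_ms=mean_rt(is_target & correct),
        mean_rt_correct_nontarget_ms=mean_rt(~is_target & correct),
        mean_rt_incorrect_target_ms=mean_rt(is_target & ~correct),
        mean_rt_incorrect_nontarget_ms=mean_rt(~is_target & ~correct),
        mean_rt_ms=mean_rt(correct),
        n_presented=len(merged),
    )


def simulate_session(
    params: ResponseParams | None = None, seed=None, subject_id: str = ""
) -> BehaviorSummary:
    """Convenience: schedule + responses + scoring for one subject."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s1, s2 = ss.spawn(2)
    schedule = build_task_schedule(seed=s1)
    log = simulate_responses(schedule, params, seed=s2)
    summary = score_responses(schedule, log)
    summary.subject_id = subject_id
    return summary


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis rank test across two or more groups.

    Returns ``(H, p)`` with the midrank ties correction and a
    chi-square reference distribution at ``k - 1`` degrees of freedom.
    When every value in every group is identical there is no rank
    separation: ``(0.0, 1.0)``.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and groups[0] and (
        isinstance(groups[0][0], (list, tuple, np.ndarray))
    ):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ConfigurationError("kruskal_wallis needs at least two groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ConfigurationError("every group must hold at least one value")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)
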