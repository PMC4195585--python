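"""Pavlovian conditioned approach (PCA) task environment.

A lever-cue is presented for 8 s (50 bins of 160 ms) and, in the paired
condition, one food pellet is delivered into the food tray the moment the
lever retracts.  The learner's approach during the cue dissociates
sign-tracking (toward the lever) from goal-tracking (toward the tray).

Trials are episodic: each trial is 100 discrete time bins, eligibility
traces reset at trial start, and weights plus the reward-recall magnitude
carry over between trials.  Three conditions are simulated:

``paired``
    Cue in bin 10, reward delivered on the transition into bin 60.
``random``
    Cue in bin 10; a uniform integer ``u`` in [0, 300] is drawn and reward
    is delivered in bin ``u`` only if ``21 <= u <= 100`` (so about 80/301
    of trials are rewarded, at essentially arbitrary times relative to the
    cue).
``blockade``
    Paired schedule, but all prediction-weight learning (TD and direct
    goal updates) is frozen during designated sessions, modelling systemic
    dopamine-receptor antagonism.  The reward-recall magnitude continues
    to be learned (it models DA-independent associative learning).

Responses are read out at the end of the cue period, when the within-trial
prediction is fully elaborated, and one approach response per trial is
sampled from the sign/goal probability -- the trial-level, binary readout
that conditioned-approach scoring uses for rats.  Session scores rescale
the response balance to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Literal, Optional, Sequence

import numpy as np

from .model import (
    DualInput,
    DualWeights,
    EligibilityState,
    ModelParams,
    TrialRecord,
    compute_value,
    response_probability,
    td_error,
    update_eligibility,
    update_goal_weights_direct,
    update_reward_recall,
    update_weights_td,
)

__all__ = [
    "PcaSchedule",
    "SessionConfig",
    "PcaModel",
    "build_trial_schedule",
    "session_score",
    "REWARDED_DRAW_LOW",
    "REWARDED_DRAW_HIGH",
    "DRAW_RANGE",
]

Condition = Literal["paired", "random", "blockade"]

#: Random-condition draw rule: reward delivered iff the uniform draw from
#: [0, DRAW_RANGE] falls in [REWARDED_DRAW_LOW, REWARDED_DRAW_HIGH].
REWARDED_DRAW_LOW = 21
REWARDED_DRAW_HIGH = 100
DRAW_RANGE = 300


@dataclass(frozen=True)
class PcaSchedule:
    """Event schedule for one trial.

    ``reward_bin`` is the bin on whose *entering* transition the pellet
    arrives; ``reward_bin == n_bins`` means delivery on the terminal
    transition (possible under the random draw rule).  ``None`` means no
    reward this trial.
    """

    n_bins: int = 100
    bin_ms: int = 160
    cue_on: int = 10
    cue_off: int = 60
    reward_bin: Optional[int] = 60
    condition: Condition = "paired"

    def __post_init__(self) -> None:
        if not 0 <= self.cue_on < self.cue_off <= self.n_bins:
            raise ValueError(
                f"need 0 <= cue_on < cue_off <= n_bins, got "
                f"{self.cue_on}, {self.cue_off}, {self.n_bins}"
            )
        if self.reward_bin is not None and not 0 <= self.reward_bin <= self.n_bins:
            raise ValueError(f"reward_bin {self.reward_bin} outside [0, {self.n_bins}]")

    @property
    def n_cue_bins(self) -> int:
        return self.cue_off - self.cue_on

    @property
    def reward_contiguous(self) -> bool:
        """True if reward arrives at the trained delivery moment (cue offset).

        This is the contingency that drives reward-recall learning: the
        recall of "reward follows this cue" is acquired only from rewards
        delivered in the trained temporal relation to the cue.  In the
        paired condition this is every trial; in the random condition
        (whose rewards were explicitly unpaired from the cue) virtually
        never.
        """
        return self.reward_bin == self.cue_off


@dataclass(frozen=True)
class SessionConfig:
    """Session-level layout of a PCA experiment."""

    trials_per_session: int = 25
    n_sessions: int = 12
    blockade_sessions: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.trials_per_session < 1:
            raise ValueError("trials_per_session must be >= 1")
        object.__setattr__(self, "blockade_sessions", frozenset(self.blockade_sessions))


def build_trial_schedule(
    condition: Condition,
    rng: Optional[np.random.Generator] = None,
    n_bins: int = 100,
    cue_on: int = 10,
    cue_off: int = 60,
) -> PcaSchedule:
    """Draw the event schedule for one trial of the given condition.

    Paired and blockade trials always pair cue (bin 10) with reward
    (bin 60).  Random trials draw ``u ~ Uniform{0..300}`` and deliver
    reward in bin ``u`` iff ``21 <= u <= 100``.
    """
    if condition in ("paired", "blockade"):
        reward: Optional[int] = cue_off
    elif condition == "random":
        if rng is None:
            raise ValueError("random condition requires an rng")
        u = int(rng.integers(0, DRAW_RANGE + 1))
        reward = u if REWARDED_DRAW_LOW <= u <= REWARDED_DRAW_HIGH else None
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return PcaSchedule(
        n_bins=n_bins, cue_on=cue_on, cue_off=cue_off,
        reward_bin=reward, condition=condition,
    )


class PcaModel:
    """A dual-component learner with state carried across trials.

    Holds the two-part weight vector and the reward-recall magnitude
    (the value the cue-evoked reward correlate takes when the cue is on).
    The cue correlate is either a complete serial compound (one indicator
    per elapsed cue bin; default) or a single sustained boxcar indicator.
    """

    def __init__(self, params: ModelParams, n_cue_bins: int = 50):
        self.params = params
        self.n_cue_bins = n_cue_bins
        n_s = n_cue_bins if params.representation == "csc" else 1
        self.weights = DualWeights.zeros(n_s, 1)
        self.recall = 0.0  # magnitude of the cue-evoked reward correlate

    # -- input construction -------------------------------------------------

    def input_at(self, t: int, sched: PcaSchedule) -> DualInput:
        """Two-part input vector at bin ``t`` of a trial."""
        x_s = np.zeros(self.weights.w_s.shape[0])
        x_g = np.zeros(1)
        if sched.cue_on <= t < sched.cue_off:
            if self.params.representation == "csc":
                x_s[t - sched.cue_on] = 1.0
            else:
                x_s[0] = 1.0
            x_g[0] = self.recall
        return DualInput(x_s, x_g)

    def value_at(self, t: int, sched: PcaSchedule):
        """(V, V_s, V_g) at bin ``t`` under the current weights."""
        if not sched.cue_on <= t < sched.cue_off:
            return 0.0, 0.0, 0.0
        return compute_value(self.weights, self.input_at(t, sched))

    # -- simulation ---------------------------------------------------------

    def run_trial(
        self,
        sched: PcaSchedule,
        rng: Optional[np.random.Generator] = None,
        learning_frozen: bool = False,
    ) -> TrialRecord:
        """Simulate one trial, updating the model state in place.

        Per bin: compute the value and its components, record response
        probabilities during the cue, advance the eligibility traces, form
        the TD error on the transition out of the bin, and (unless frozen)
        apply the TD weight update.  The direct goal-weight update fires
        once, at cue onset.  The trial-level reward-recall update fires at
        trial end regardless of the freeze flag, driven by whether reward
        arrived in the trained relation to the cue.
        """
        p = self.params
        nb = sched.n_bins
        elig = EligibilityState.zeros(self.weights.w_s.shape[0], 1)

        v = np.zeros(nb)
        v_s = np.zeros(nb)
        v_g = np.zeros(nb)
        delta = np.zeros(nb)
        p_st = np.full(nb, np.nan)
        p_gt = np.full(nb, np.nan)

        for t in range(nb):
            x = self.input_at(t, sched)
            vt, vst, vgt = compute_value(self.weights, x)
            v[t], v_s[t], v_g[t] = vt, vst, vgt
            if sched.cue_on <= t < sched.cue_off:
                p_st[t], p_gt[t] = response_probability(vst, vgt, p.beta)

            elig = update_eligibility(elig, x, p.gamma, p.lam)

            r_next = 1.0 if sched.reward_bin == t + 1 else 0.0
            v_next = self.value_at(t + 1, sched)[0] if t + 1 < nb else 0.0
            d = td_error(r_next, v_next, vt, p.gamma)
            delta[t] = d

            if not learning_frozen:
                self.weights = update_weights_td(self.weights, d, p.alpha, elig)
                if t == sched.cue_on:
                    # direct recall-driven update, once per trial
                    vg_now = float(self.weights.w_g @ x.x_g)
                    self.weights.w_g = update_goal_weights_direct(
                        self.weights.w_g, x.x_g, vg_now, p.eta
                    )

        i_r = 1.0 if sched.reward_contiguous else 0.0
        new_recall = update_reward_recall(
            np.array([self.recall]), i_r, p.eta, r_magnitude=1.0
        )
        self.recall = float(new_recall[0])

        rec = TrialRecord(
            v=v, v_s=v_s, v_g=v_g, delta=delta, p_st=p_st, p_gt=p_gt,
            i_r=i_r, cue_on=sched.cue_on, cue_off=sched.cue_off,
            reward_bin=sched.reward_bin,
        )
        if rng is not None:
            rec.response = 1.0 if rng.random() < rec.p_st_end else -1.0
        return rec

    def run_session(
        self,
        condition: Condition,
        rng: np.random.Generator,
        trials: int = 25,
        learning_frozen: bool = False,
    ) -> List[TrialRecord]:
        """Run one session of trials, carrying state across trials."""
        out = []
        for _ in range(trials):
            sched = build_trial_schedule(condition, rng, n_bins=100,
                                         cue_on=10, cue_off=10 + self.n_cue_bins)
            out.append(self.run_trial(sched, rng, learning_frozen))
        return out


ScoreMode = Literal["sampled", "prob_end", "prob_mean"]


def session_score(trials: Sequence[TrialRecord], mode: ScoreMode = "sampled") -> float:
    """Scaled sign-vs-goal response score in [-1, 1] for one session.

    ``p_st - p_gt = 2 p_st - 1`` is the unique affine map sending
    (0, 0.5, 1) to (-1, 0, 1).

    Modes
    -----
    ``sampled``
        Mean of the sampled per-trial responses (+1 sign, -1 goal).  The
        default for experiments; this is the readout with trial-level
        sampling noise, matching how approach direction is scored per
        trial in the animal task.
    ``prob_end``
        Mean over trials of ``2 p_st - 1`` at the last cue bin.
    ``prob_mean``
        Mean over trials and all cue-period bins of ``p_st - p_gt``.
    """
    if len(trials) == 0:
        raise ValueError("session_score needs at least one trial")
    if mode == "sampled":
        resp = np.array([t.response for t in trials])
        if np.isnan(resp).any():
            raise ValueError("sampled mode requires trials run with an rng")
        return float(resp.mean())
    if mode == "prob_end":
        return float(np.mean([2.0 * t.p_st_end - 1.0 for t in trials]))
    if mode == "prob_mean":
        vals = [np.nanmean(t.p_st - t.p_gt) for t in trials]
        return float(np.mean(vals))
    raise ValueError(f"unknown score mode {mode!r}")
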