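"""Core learning machinery for the dual-component reward-prediction model.

The model is a linear TD(lambda) learner whose input (and weight) vector is
split into two parts:

* a *cue correlate* ``x_s`` -- the sensory representation of the lever-cue
  itself.  Its contribution to the reward prediction, ``V_s = w_s . x_s``,
  is called the **sign component** and is learned exclusively through
  TD errors (the putative dopamine signal).
* a *cue-evoked reward correlate* ``x_g`` -- a recall of the reward that the
  cue has previously been paired with.  Its magnitude is itself learned by a
  simple trial-level delta rule driven by reward presence/absence, entirely
  outside the TD loop.  Its contribution ``V_g = w_g . x_g`` is the **goal
  component**; ``w_g`` is updated both by TD errors and by a direct,
  TD-independent rule that pulls ``V_g`` toward the recalled reward
  magnitude.

The total prediction is ``V = V_s + V_g`` at every time step.  The relative
size of the two components drives a sigmoidal choice between approaching
the cue (sign-tracking) and approaching the food tray (goal-tracking).

Two learning rates control the split: ``alpha`` for TD updates and ``eta``
for the two recall-driven updates.  A learner with large ``alpha`` and small
``eta`` puts its prediction into the sign component (a sign-tracker); the
reverse allocation yields a goal-tracker.

Everything in this module is pure computation on small arrays; the task
modules (:mod:`dualtd.pca`, :mod:`dualtd.sr`) own schedules, state carrying
and randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Tuple

import numpy as np

__all__ = [
    "ModelParams",
    "DualInput",
    "DualWeights",
    "EligibilityState",
    "TrialRecord",
    "compute_value",
    "td_error",
    "update_eligibility",
    "update_weights_td",
    "update_reward_recall",
    "update_goal_weights_direct",
    "response_probability",
    "sigmoid",
]

Representation = Literal["csc", "boxcar"]


@dataclass(frozen=True)
class ModelParams:
    """Scalar hyperparameters of the learner.

    Parameters
    ----------
    alpha
        TD learning rate in [0, 1].  Governs how strongly TD errors move
        the prediction weights (both parts).
    eta
        Reward-recall learning rate in [0, 1].  Governs both the trial-level
        update of the recall magnitude and the direct (TD-independent)
        update of the goal weights.
    gamma
        Per-time-bin discount factor in [0, 1].
    lam
        Eligibility-trace decay in [0, 1].  Traces decay by ``gamma * lam``
        per bin; with ``lam = 0`` only the current input's weights are
        eligible for update.
    beta
        Inverse temperature (>= 0) of the sigmoidal response rule.
    representation
        Encoding of the cue correlate: ``"csc"`` (complete serial compound,
        one indicator per elapsed cue bin; the default) or ``"boxcar"``
        (one sustained indicator over the whole cue period).
    """

    alpha: float
    eta: float
    gamma: float = 0.9
    lam: float = 0.9
    beta: float = 5.0
    representation: Representation = "csc"

    def __post_init__(self) -> None:
        for name in ("alpha", "eta", "gamma", "lam"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.representation not in ("csc", "boxcar"):
            raise ValueError(f"unknown representation {self.representation!r}")


@dataclass
class DualInput:
    """Two-part input vector: cue correlate and cue-evoked reward correlate.

    ``x_s`` holds 0/1 feature activations for the cue; ``x_g`` holds the
    recalled reward magnitude (in units of reward size) on its active
    features, zero elsewhere.  ``x_g`` is all-zero before any cue-reward
    pairing has been experienced.
    """

    x_s: np.ndarray
    x_g: np.ndarray

    def __post_init__(self) -> None:
        self.x_s = np.atleast_1d(np.asarray(self.x_s, dtype=float))
        self.x_g = np.atleast_1d(np.asarray(self.x_g, dtype=float))


@dataclass
class DualWeights:
    """Two-part weight vector, conformal with :class:`DualInput`."""

    w_s: np.ndarray
    w_g: np.ndarray

    def __post_init__(self) -> None:
        self.w_s = np.atleast_1d(np.asarray(self.w_s, dtype=float))
        self.w_g = np.atleast_1d(np.asarray(self.w_g, dtype=float))

    @classmethod
    def zeros(cls, n_s: int, n_g: int = 1) -> "DualWeights":
        return cls(np.zeros(n_s), np.zeros(n_g))

    def copy(self) -> "DualWeights":
        return DualWeights(self.w_s.copy(), self.w_g.copy())


@dataclass
class EligibilityState:
    """Eligibility traces for both weight parts.  All-zero at trial start."""

    e_s: np.ndarray
    e_g: np.ndarray

    def __post_init__(self) -> None:
        self.e_s = np.atleast_1d(np.asarray(self.e_s, dtype=float))
        self.e_g = np.atleast_1d(np.asarray(self.e_g, dtype=float))

    @classmethod
    def zeros(cls, n_s: int, n_g: int = 1) -> "EligibilityState":
        return cls(np.zeros(n_s), np.zeros(n_g))


@dataclass
class TrialRecord:
    """Per-bin time series recorded over one trial.

    Attributes
    ----------
    v, v_s, v_g
        Total prediction and its sign/goal components per bin
        (``v = v_s + v_g`` everywhere).
    delta
        TD error on the transition out of each bin (the last entry is the
        terminal transition, where the successor value is zero).
    p_st, p_gt
        Probability of sign- vs goal-tracking per cue-period bin (NaN
        outside the cue period); ``p_st + p_gt = 1`` where defined.
    i_r
        1.0 if the trial counted as rewarded for recall learning.
    cue_on, cue_off, reward_bin
        The event schedule the trial was run under.
    response
        Sampled trial-level response: +1 sign-tracking, -1 goal-tracking
        (NaN if not sampled).
    """

    v: np.ndarray
    v_s: np.ndarray
    v_g: np.ndarray
    delta: np.ndarray
    p_st: np.ndarray
    p_gt: np.ndarray
    i_r: float
    cue_on: int
    cue_off: int
    reward_bin: Optional[int]
    response: float = float("nan")

    @property
    def n_bins(self) -> int:
        return len(self.v)

    @property
    def delta_cue(self) -> float:
        """TD error on the transition into the cue-onset bin.

        This is the prediction jump evoked by cue appearance,
        ``gamma * V(cue_on) - V(cue_on - 1)``, the model analogue of the
        phasic dopamine response at cue time.
        """
        return float(self.delta[self.cue_on - 1])

    @property
    def delta_reward(self) -> float:
        """TD error on the transition into the reward bin.

        For unrewarded trials this is the TD error at the *trained* delivery
        transition (into ``cue_off``), i.e. the signal at the moment reward
        was due.
        """
        t = self.reward_bin if self.reward_bin is not None else self.cue_off
        t = min(t, self.n_bins)  # reward on the terminal transition
        return float(self.delta[t - 1])

    @property
    def v_s_cue(self) -> float:
        """Sign component at the end of the cue period (fully elaborated)."""
        return float(self.v_s[self.cue_off - 1])

    @property
    def v_g_cue(self) -> float:
        """Goal component at the end of the cue period."""
        return float(self.v_g[self.cue_off - 1])

    @property
    def p_st_end(self) -> float:
        """Sign-tracking probability at the last cue bin."""
        return float(self.p_st[self.cue_off - 1])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def sigmoid(x: float) -> float:
    """Numerically stable logistic function."""
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    z = np.exp(x)
    return float(z / (1.0 + z))


def compute_value(w: DualWeights, x: DualInput) -> Tuple[float, float, float]:
    """Reward prediction and its decomposition: ``V = V_s + V_g``.

    ``V_s = w_s . x_s`` (sign component), ``V_g = w_g . x_g`` (goal
    component).

    Raises
    ------
    ValueError
        If the weight and input parts do not conform.
    """
    if w.w_s.shape != x.x_s.shape or w.w_g.shape != x.x_g.shape:
        raise ValueError(
            f"weight/input dimension mismatch: "
            f"w_s {w.w_s.shape} vs x_s {x.x_s.shape}, "
            f"w_g {w.w_g.shape} vs x_g {x.x_g.shape}"
        )
    v_s = float(w.w_s @ x.x_s)
    v_g = float(w.w_g @ x.x_g)
    return v_s + v_g, v_s, v_g


def td_error(r: float, v_next: float, v_curr: float, gamma: float) -> float:
    """Temporal-difference error ``delta = r + gamma * V(t+1) - V(t)``.

    ``r`` is the reward obtained on entering the successor state; at the
    terminal transition the successor value is zero.
    """
    return r + gamma * v_next - v_curr


def update_eligibility(
    e: EligibilityState, x: DualInput, gamma: float, lam: float
) -> EligibilityState:
    """Accumulating eligibility-trace recursion ``e' = gamma*lam*e + x``.

    Traces start at zero at trial onset; with ``lam = 0`` only the current
    input's weights remain eligible.
    """
    return EligibilityState(
        gamma * lam * e.e_s + x.x_s,
        gamma * lam * e.e_g + x.x_g,
    )


def update_weights_td(
    w: DualWeights, delta: float, alpha: float, e: EligibilityState
) -> DualWeights:
    """TD weight update ``w' = w + alpha * delta * e``, on both parts."""
    return DualWeights(
        w.w_s + alpha * delta * e.e_s,
        w.w_g + alpha * delta * e.e_g,
    )


def update_reward_recall(
    x_g: np.ndarray, i_r: float, eta: float, r_magnitude: float = 1.0
) -> np.ndarray:
    """Trial-level delta rule for the cue-evoked reward correlate.

    ``x_g' = x_g + eta * (I_R * r - x_g)`` elementwise, where ``I_R`` is 1
    for a rewarded trial and 0 otherwise.  The rule is a convex combination,
    so ``x_g`` stays in ``[0, r]`` and converges to the empirical reward
    expectation under a stationary schedule.  Called once per trial; it
    proceeds even when TD learning is blocked (it models DA-independent
    associative learning).
    """
    x_g = np.atleast_1d(np.asarray(x_g, dtype=float))
    return x_g + eta * (i_r * r_magnitude - x_g)


def update_goal_weights_direct(
    w_g: np.ndarray,
    x_g: np.ndarray,
    v_g: float,
    eta: float,
    target: Optional[float] = None,
) -> np.ndarray:
    """Direct, TD-independent update of the goal weights.

    ``w_g' = w_g + eta * (target - V_g) * x_g`` where ``target`` defaults to
    the recalled reward magnitude carried by ``x_g`` (its largest active
    entry).  The rule pulls the goal component toward the recalled reward
    within the trial, with no TD error involved.  With ``eta = 0`` the model
    collapses to standard TD(lambda) on both channels.
    """
    w_g = np.atleast_1d(np.asarray(w_g, dtype=float))
    x_g = np.atleast_1d(np.asarray(x_g, dtype=float))
    if target is None:
        target = float(np.max(np.abs(x_g)))
    return w_g + eta * (target - v_g) * x_g


def response_probability(v_s: float, v_g: float, beta: float) -> Tuple[float, float]:
    """Sigmoidal choice between sign- and goal-tracking.

    ``p_st = sigma(beta * (V_s - V_g))`` and ``p_gt = 1 - p_st``.  Equal
    components (or ``beta = 0``) give indifference, 0.5/0.5.
    """
    p_st = sigmoid(beta * (v_s - v_g))
    return p_st, 1.0 - p_st
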