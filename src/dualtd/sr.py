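"""Secondary reinforcement (SR) two-port choice task.

After PCA training, the learner faces two nose-poke ports.  Poking the
*active* port presents the familiar lever-cue for 2 s; poking the
*inactive* port does nothing.  No food is ever delivered.  Preference for
the active port therefore measures how much value the cue itself has
acquired -- its power as a conditioned (secondary) reinforcer.

Trials are episodic with three periods -- port selection, outcome (lever
or nothing) and end-of-trial -- and exactly one choice per trial.  The
action-dependent predictions ``Q_active`` and ``Q_inactive`` are learned
from the action-dependent TD error

    ``delta_a = r + gamma * V(outcome) - Q_a``

with ``r = 0`` always; ``V(outcome)`` is the reward prediction the carried-
over PCA model assigns to the cue (zero for the inactive port).  Because
one choice is made per trial, the action eligibility spans a single step
and the update reduces to ``Q_a <- Q_a + alpha * delta_a``.

On active-port (cue-presented) trials, the cue-evoked reward correlate is
updated at end-of-trial with ``I_R = 0`` -- no food arrived -- so the
recall magnitude extinguishes over the SR phase at the group's own rate
``eta``, and the cue's goal component fades with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .model import ModelParams, sigmoid, update_reward_recall
from .pca import PcaModel

__all__ = [
    "SrState",
    "choose_port",
    "cue_outcome_value",
    "run_sr_trial",
    "run_sr_phase",
    "summarize_choices",
    "SR_N_TRIALS",
    "SR_COUNT_SCALE",
]

#: Number of SR trials per replicate, and the rescaling divisor that maps
#: choice counts onto [0, 50].
SR_N_TRIALS = 1000
SR_COUNT_SCALE = 20.0


@dataclass
class SrState:
    """Mutable state of one SR run.

    ``model`` is the PCA-trained learner carried into the task; its
    prediction weights stay fixed here (only the recall magnitude changes,
    through extinction), while the action values ``q_active``/``q_inactive``
    are learned afresh.
    """

    model: PcaModel
    q_active: float = 0.0
    q_inactive: float = 0.0
    n_active: int = 0
    n_inactive: int = 0

    @property
    def trials_completed(self) -> int:
        return self.n_active + self.n_inactive


def choose_port(
    q_active: float, q_inactive: float, beta: float, rng: np.random.Generator
) -> str:
    """Softmax (sigmoid) choice between the two ports.

    ``P(active) = sigma(beta * (Q_active - Q_inactive))``.
    """
    p_active = sigmoid(beta * (q_active - q_inactive))
    return "active" if rng.random() < p_active else "inactive"


def cue_outcome_value(model: PcaModel) -> float:
    """Reward prediction the trained model assigns to the cue outcome.

    The fully elaborated within-presentation prediction: sign component at
    the end of the cue period plus the goal component carried by the
    current recall magnitude.  Recomputed every trial, so extinction of
    the recall feeds through immediately.
    """
    v_s_end = float(model.weights.w_s[-1])
    v_g = float(model.weights.w_g[0] * model.recall)
    return v_s_end + v_g


def run_sr_trial(state: SrState, params: ModelParams, rng: np.random.Generator) -> SrState:
    """One episodic SR trial: choose, observe outcome, update in place."""
    port = choose_port(state.q_active, state.q_inactive, params.beta, rng)
    if port == "active":
        state.n_active += 1
        v_outcome = cue_outcome_value(state.model)
        delta_a = 0.0 + params.gamma * v_outcome - state.q_active
        state.q_active += params.alpha * delta_a
        # cue shown, no food: recall extinguishes at end-of-trial
        new_recall = update_reward_recall(
            np.array([state.model.recall]), i_r=0.0, eta=params.eta
        )
        state.model.recall = float(new_recall[0])
    else:
        state.n_inactive += 1
        delta_a = 0.0 + 0.0 - state.q_inactive
        state.q_inactive += params.alpha * delta_a
    return state


def run_sr_phase(
    model: PcaModel,
    params: ModelParams,
    rng: np.random.Generator,
    n_trials: int = SR_N_TRIALS,
) -> SrState:
    """Run a full SR phase on a PCA-trained model."""
    state = SrState(model=model)
    for _ in range(n_trials):
        run_sr_trial(state, params, rng)
    return state


def summarize_choices(state: SrState) -> Tuple[float, float]:
    """Scaled choice counts ``(active, inactive)``, each in [0, 50].

    Counts are divided by 20, so 1000 all-active trials give (50, 0) and
    the two values always sum to ``n_trials / 20``.
    """
    return (
        state.n_active / SR_COUNT_SCALE,
        state.n_inactive / SR_COUNT_SCALE,
    )
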