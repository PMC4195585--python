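"""Replicated experiment runner for every simulated condition.

Produces tidy long-format tables (replicate x session x measure) that feed
the statistical battery.  Group presets fix the learning-rate allocation:

======  =======  =====
group   alpha    eta
======  =======  =====
ST      0.2      0.01
GT      0.01     0.2
IG      0.1      0.1
======  =======  =====

with shared gamma = 0.9, lambda = 0.9, beta = 5.  Paired and random PCA
runs span 12 sessions of 25 trials; blockade runs span 8 sessions with
prediction learning frozen in sessions 1-7.  Every reported result is
replicated (default 20 runs); replicate ``r`` uses seed ``base_seed + r``,
so a repeated run with the same base seed is bit-identical, and the
blockade/paired contrast uses matched replicate seeds.

Session-level measures recorded per replicate:

``score``
    Scaled sign-vs-goal response score in [-1, 1] (sampled trial-level
    responses; see :func:`dualtd.pca.session_score`).
``delta_cue`` / ``delta_reward``
    Session-mean TD error on the transition into the cue-onset bin /
    into the (trained) reward bin -- the model analogues of phasic
    dopamine at cue and reward time.
``v_s_cue`` / ``v_g_cue``
    Session-mean sign and goal components at the end of the cue period.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .model import ModelParams
from .pca import PcaModel, ScoreMode, SessionConfig, session_score
from .sr import SR_N_TRIALS, run_sr_phase, summarize_choices

__all__ = [
    "GroupPreset",
    "PRESETS",
    "ExperimentResult",
    "run_pca_experiment",
    "run_sr_experiment",
    "run_blockade_recovery",
]


@dataclass(frozen=True)
class GroupPreset:
    """Named learning-rate allocation for one simulated group."""

    name: str
    alpha: float
    eta: float
    gamma: float = 0.9
    lam: float = 0.9
    beta: float = 5.0

    def params(self, representation: str = "csc") -> ModelParams:
        return ModelParams(
            alpha=self.alpha, eta=self.eta, gamma=self.gamma,
            lam=self.lam, beta=self.beta, representation=representation,
        )


PRESETS: Dict[str, GroupPreset] = {
    "ST": GroupPreset("ST", alpha=0.2, eta=0.01),
    "GT": GroupPreset("GT", alpha=0.01, eta=0.2),
    "IG": GroupPreset("IG", alpha=0.1, eta=0.1),
}

SESSION_MEASURES = ("score", "delta_cue", "delta_reward", "v_s_cue", "v_g_cue")


@dataclass
class ExperimentResult:
    """Long-format results plus a manifest describing how they were made.

    ``data`` columns: ``replicate, session, measure, value`` for PCA runs;
    ``replicate, measure, value`` (measure in ``active_count`` /
    ``inactive_count``) for SR runs, with extra identifying columns
    (``preset``, ``condition``, ``arm``) where relevant.
    """

    data: pd.DataFrame
    manifest: Dict = field(default_factory=dict)

    def pivot(self, measure: str, index: str = "replicate",
              columns: str = "session") -> pd.DataFrame:
        """Replicate-by-session matrix of one measure."""
        sub = self.data[self.data["measure"] == measure]
        return sub.pivot_table(index=index, columns=columns, values="value")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def manifest_json(self) -> str:
        man = dict(self.manifest)
        man["config_hash"] = hashlib.sha256(
            json.dumps(self.manifest, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        return json.dumps(man, indent=2, default=str)


def _session_rows(records, preset: str, condition: str, replicate: int,
                  session: int, score_mode: ScoreMode) -> List[dict]:
    vals = {
        "score": session_score(records, mode=score_mode),
        "delta_cue": float(np.mean([t.delta_cue for t in records])),
        "delta_reward": float(np.mean([t.delta_reward for t in records])),
        "v_s_cue": float(np.mean([t.v_s_cue for t in records])),
        "v_g_cue": float(np.mean([t.v_g_cue for t in records])),
    }
    return [
        dict(preset=preset, condition=condition, replicate=replicate,
             session=session, measure=m, value=v)
        for m, v in vals.items()
    ]


def _run_one_pca(preset: GroupPreset, condition: str, cfg: SessionConfig,
                 seed: int, representation: str, score_mode: ScoreMode):
    """One replicate: returns (session rows, final model)."""
    rng = np.random.default_rng(seed)
    model = PcaModel(preset.params(representation))
    sched_condition = "paired" if condition == "blockade" else condition
    rows = []
    for s in range(cfg.n_sessions):
        frozen = s in cfg.blockade_sessions
        recs = model.run_session(sched_condition, rng,
                                 trials=cfg.trials_per_session,
                                 learning_frozen=frozen)
        rows.extend(_session_rows(recs, preset.name, condition, -1, s + 1,
                                  score_mode))
    return rows, model


def run_pca_experiment(
    preset: GroupPreset,
    condition: str = "paired",
    n_sessions: int = 12,
    n_replicates: int = 20,
    base_seed: int = 0,
    representation: str = "csc",
    score_mode: ScoreMode = "sampled",
    blockade_sessions: Optional[frozenset] = None,
) -> ExperimentResult:
    """Replicated PCA runs of one preset x condition.

    ``condition='blockade'`` runs the paired schedule with prediction
    learning frozen during ``blockade_sessions`` (default: sessions 1-7,
    i.e. all but the last of an 8-session run).
    """
    if condition == "blockade":
        if n_sessions == 12:
            n_sessions = 8
        if blockade_sessions is None:
            blockade_sessions = frozenset(range(n_sessions - 1))
    cfg = SessionConfig(
        trials_per_session=25, n_sessions=n_sessions,
        blockade_sessions=blockade_sessions or frozenset(),
    )
    rows: List[dict] = []
    for r in range(n_replicates):
        rep_rows, _ = _run_one_pca(preset, condition, cfg, base_seed + r,
                                   representation, score_mode)
        for d in rep_rows:
            d["replicate"] = r
        rows.extend(rep_rows)
    data = pd.DataFrame(rows)
    manifest = dict(
        kind="pca", preset=preset.name, condition=condition,
        alpha=preset.alpha, eta=preset.eta, gamma=preset.gamma,
        lam=preset.lam, beta=preset.beta, representation=representation,
        n_sessions=n_sessions, trials_per_session=25,
        n_replicates=n_replicates, base_seed=base_seed,
        blockade_sessions=sorted(cfg.blockade_sessions),
        score_mode=score_mode,
    )
    return ExperimentResult(data, manifest)


def run_sr_experiment(
    preset: GroupPreset,
    pretraining_condition: str = "paired",
    n_replicates: int = 20,
    base_seed: int = 0,
    n_pretrain_sessions: int = 12,
    n_sr_trials: int = SR_N_TRIALS,
    representation: str = "csc",
) -> ExperimentResult:
    """PCA pretraining followed by the SR phase, per replicate.

    Each replicate trains a fresh model under ``pretraining_condition``
    and then runs ``n_sr_trials`` two-port choice trials; the scaled
    active/inactive counts are recorded.
    """
    cfg = SessionConfig(trials_per_session=25, n_sessions=n_pretrain_sessions)
    rows: List[dict] = []
    for r in range(n_replicates):
        seed = base_seed + r
        _, model = _run_one_pca(preset, pretraining_condition, cfg, seed,
                                representation, "sampled")
        rng = np.random.default_rng(seed + 1_000_000)
        state = run_sr_phase(model, preset.params(representation), rng,
                             n_trials=n_sr_trials)
        active, inactive = summarize_choices(state)
        rows.append(dict(preset=preset.name,
                         condition=pretraining_condition, replicate=r,
                         measure="active_count", value=active))
        rows.append(dict(preset=preset.name,
                         condition=pretraining_condition, replicate=r,
                         measure="inactive_count", value=inactive))
    data = pd.DataFrame(rows)
    manifest = dict(
        kind="sr", preset=preset.name,
        pretraining_condition=pretraining_condition,
        n_pretrain_sessions=n_pretrain_sessions, n_sr_trials=n_sr_trials,
        n_replicates=n_replicates, base_seed=base_seed,
        representation=representation,
    )
    return ExperimentResult(data, manifest)


def run_blockade_recovery(
    preset: GroupPreset,
    base_seed: int = 0,
    n_replicates: int = 20,
    n_sessions: int = 8,
    representation: str = "csc",
) -> ExperimentResult:
    """Two-arm blockade/recovery experiment with matched replicate seeds.

    Arm ``blockade``: prediction learning frozen in sessions 1-7, restored
    in session 8.  Arm ``paired``: 8 uninterrupted paired sessions.  The
    8th-session score contrast between arms tests whether responding
    emerges as soon as prediction learning is restored.
    """
    frames = []
    for arm in ("blockade", "paired"):
        res = run_pca_experiment(
            preset, condition=arm, n_sessions=n_sessions,
            n_replicates=n_replicates, base_seed=base_seed,
            representation=representation,
        )
        df = res.data.copy()
        df["arm"] = arm
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    manifest = dict(
        kind="blockade_recovery", preset=preset.name, n_sessions=n_sessions,
        n_replicates=n_replicates, base_seed=base_seed,
        representation=representation,
    )
    return ExperimentResult(data, manifest)
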