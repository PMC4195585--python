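# dualtd

A dual-component temporal-difference model of Pavlovian **sign-tracking**
and **goal-tracking**, with the simulated tasks and statistics that
characterise the two phenotypes.

## The problem

In Pavlovian conditioned approach (autoshaping), a lever-cue is presented
for 8 s and a food pellet is then delivered into a food tray at a
different location. Some rats come to approach the lever itself during the
cue (*sign-trackers*, ST), others the food tray (*goal-trackers*, GT) —
yet both groups clearly learn the cue–reward relation. Phasic dopamine
(the putative TD reward-prediction error, RPE) differs sharply between
groups, and goal- but not sign-trackers keep learning under a dopamine
antagonist. A single standard TD learner cannot produce this dissociation.

`dualtd` implements a minimal account: the reward prediction is carried by
**two neural correlates** learned by **two mechanisms**, and the balance
between them yields the two phenotypes. The package is for computational-
neuroscience researchers and students who want to simulate, probe or
extend this class of dual-system conditioning model.

## The model

The prediction is linear in a two-part input
$x_t = (x_s(t),\, x_g(t))$ with weights $w = (w_s, w_g)$:

$$V(t) = \underbrace{w_s^\top x_s(t)}_{V_s(t)\ \text{(sign)}} +
          \underbrace{w_g^\top x_g(t)}_{V_g(t)\ \text{(goal)}}$$

* $x_s$ — the cue correlate (a complete-serial-compound encoding by
  default: one indicator per elapsed cue bin).
* $x_g$ — the *cue-evoked reward correlate*: a recall of the reward,
  active throughout the cue at magnitude $m$, learned once per trial by a
  simple associative delta rule, independent of TD error:
  $m \leftarrow m + \eta\,(I_R\,r - m)$, where $I_R$ indicates reward
  delivered in the trained (cue-contiguous) relation.

Learning combines three rules per trial of 100 bins (160 ms each):

1. **TD(λ):** $\delta(t) = r(t{+}1) + \gamma V(t{+}1) - V(t)$,
   $e_t = \gamma\lambda e_{t-1} + x_t$, $w \leftarrow w + \alpha\,\delta\,e_t$
   (both parts; the dopamine-dependent pathway).
2. **Recall update** of $m$ (above; dopamine-independent).
3. **Direct goal update**, once per trial at cue onset, also
   dopamine-independent: $w_g \leftarrow w_g + \eta\,(m - V_g)\,x_g$.

Responding during the cue is a sigmoidal choice,
$P_{ST}(t) = \sigma\!\big(\beta\,(V_s(t) - V_g(t))\big)$,
$P_{GT} = 1 - P_{ST}$, read out at the end of the cue period with one
sampled approach response per trial.

The only difference between groups is the allocation of learning rates —
ST: $(\alpha,\eta) = (0.2, 0.01)$; GT: $(0.01, 0.2)$; intermediate:
$(0.1, 0.1)$ — with shared $\gamma = 0.9$, $\lambda = 0.9$, $\beta = 5$.
A large-$\alpha$ learner parks its prediction in the sign component (the
within-cue TD drag, which scales with $\alpha$, pins the flat goal channel
near zero); a large-$\eta$ learner builds the goal component instead.

Three task conditions are simulated (paired / random / dopamine-blockade,
the last freezing all prediction-weight learning for sessions 1–7), plus a
secondary-reinforcement (SR) task: after training, two nose-poke ports,
one of which presents the cue (never food); port preference measures the
cue's acquired reinforcing value via action-dependent predictions
$Q_a$ learned from $\delta_a = r + \gamma V(\text{outcome}) - Q_a$.

## Worked example

```python
import numpy as np
from dualtd import PRESETS, PcaModel, session_score

for name in ("ST", "GT"):
    rng = np.random.default_rng(0)
    model = PcaModel(PRESETS[name].params())
    for s in range(12):                      # 12 sessions x 25 paired trials
        records = model.run_session("paired", rng)
    score = session_score(records)           # in [-1, 1]
    last = records[-1]
    print(f"{name}: session-12 score {score:+.2f}   "
          f"V_s={last.v_s_cue:.2f} V_g={last.v_g_cue:.2f}   "
          f"delta_cue={last.delta_cue:.3f} delta_reward={last.delta_reward:.3f}")
```

prints

```
ST: session-12 score +1.00   V_s=0.90 V_g=0.10   delta_cue=0.001 delta_reward=-0.001
GT: session-12 score -0.84   V_s=0.29 V_g=0.76   delta_cue=0.170 delta_reward=-0.051
```

The ST model approaches the cue on every trial of session 12 (score +1)
because its sign component (0.90) dwarfs its goal component (0.10); the GT
model approaches the food tray (score −0.84) because the allocation is
reversed — and its cue-time TD error is still substantial in session 12
(0.17, against ~0 for the converged ST model), the model's analogue of the
persistent dopamine responses of goal-trackers.

The same experiments run from the shell:

```bash
dualtd pca --preset GT --condition paired --seed 0 --outdir results
dualtd blockade --preset ST --outdir results
dualtd sr --preset ST --condition random --outdir results
dualtd stats results/pca_GT_paired.csv --outdir results
dualtd reproduce-all --seed 0 --outdir results   # every table
```

Each command writes a tidy long-format CSV
(`replicate, session, measure, value`) plus a JSON manifest recording
every parameter and a config hash.

## Layout

```
src/dualtd/model.py        # types + update rules (values, TD, traces, recall)
src/dualtd/pca.py          # conditioned-approach schedules and trial loop
src/dualtd/sr.py           # secondary-reinforcement choice task
src/dualtd/experiments.py  # replicated runs, presets, tidy tables
src/dualtd/stats.py        # t-tests, mixed ANOVA, 3-way ANOVA wrappers
src/dualtd/cli.py          # dualtd {pca,sr,blockade,stats,reproduce-all}
docs/methods.md            # model assumptions, defaults, limitations
```
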