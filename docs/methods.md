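# Methods

This note documents the model as implemented: its assumptions, the
defaults and why they are what they are, the numerical choices, and what
the simulations do and do not establish.

## Model

### State, inputs and values

A trial is 100 discrete bins of 160 ms. The cue occupies bins 10–59
(8 s); in the paired condition reward arrives on the transition into bin
60, the moment the cue retracts. The learner's input has two parts:

* **Cue correlate `x_s`.** Default encoding is a complete serial compound
  (CSC): one indicator per elapsed cue bin, so the sign component can
  express a discount-consistent value profile across the cue. A sustained
  single-indicator *boxcar* encoding is available
  (`ModelParams(representation="boxcar")`). The choice matters: with a
  boxcar, an `alpha` of 0.2 combined with accumulated eligibility
  (≈ 5.3 after 50 cue bins under `gamma*lam = 0.81`) yields per-bin weight
  steps above 1, and the value estimate saw-tooths within each trial. The
  CSC gives each feature a once-per-trial trace bounded by 1, so learning
  is stable at the published rates. CSC is therefore the default, and
  every headline simulation uses it.
* **Cue-evoked reward correlate `x_g`.** One channel, active at recall
  magnitude `m` (units of reward size) over the whole cue period. `m`
  starts at 0 and follows a trial-level delta rule
  `m <- m + eta * (I_R * r - m)` with `r = 1` per pellet, so under the
  paired schedule `m = 1 - (1 - eta)^n` after `n` trials, exactly.

`I_R` indicates a reward delivered *in the trained temporal relation to
the cue* (at cue offset). In the random condition — whose rewards are
explicitly unpaired from the cue — this almost never happens, so the
recall stays near zero there. Gating the association on contiguity is
what keeps the random condition flat: if any in-trial reward counted,
`m` would equilibrate near the 27% reward rate and the high-`eta` model
would develop a spurious tray preference (and a spurious secondary
reinforcer) that unpaired controls do not show.

### Learning rules

Per bin `t` (online, within the trial):

1. eligibility: `e <- gamma*lam*e + x(t)` (accumulating; reset to zero at
   trial start — the setting is episodic),
2. TD error on the transition: `delta(t) = r(t+1) + gamma*V(t+1) - V(t)`,
   with `V = 0` beyond the terminal bin,
3. TD update of both weight parts: `w <- w + alpha*delta*e`.

Once per trial, at cue onset, the direct goal update fires:
`w_g <- w_g + eta*(m - V_g)*x_g`. Firing it at every cue bin instead
multiplies the effective rate by 50 and lets the goal channel capture the
entire prediction even at `eta = 0.01`, destroying the sign-tracking
phenotype; once per trial is the reading of "within the trial" that
preserves both phenotypes. The recall update of `m` fires at trial end.

A single `eta` serves both recall-driven rules; only two rates per group
are defined.

### Why the phenotypes separate

At equilibrium the flat goal channel suffers a within-cue TD drag of
`-(1-gamma)*V_g` per bin (a flat profile is never discount-consistent),
which scales with `alpha`, while the direct update pushes `V_g` toward
`m` at rate `eta`. The balance pins `V_g` near zero for the ST preset
(`eta/alpha = 0.05`) and near 0.75 for the GT preset (`eta/alpha = 20`).
The sign channel, being CSC-encoded, can fit the discounted profile and
keeps whatever the goal channel does not claim. Swapping the two rates
therefore swaps the dominant component — the core of the account.

### Response rule and scoring

During the cue, `P_ST(t) = sigmoid(beta*(V_s(t) - V_g(t)))`. Sessions are
scored from the probabilities at the *last cue bin* (the fully elaborated
prediction), with **one sampled approach response per trial** (+1 sign,
−1 goal); the session score is the mean, lying in [−1, 1] (the affine map
sending probabilities 0, 0.5, 1 to −1, 0, 1). Two alternatives are
exposed (`session_score(..., mode=...)`): the probability at the last cue
bin, and the bin-wise mean probability.

Two reasons for the default. First, the deterministic paired schedule
makes probability-based scores identical across replicates, so every
between-replicate test would be degenerate; trial-level response sampling
is the natural noise source (it is how approach is scored per trial in
the animal task) and gives the replicate variance the statistics need.
Second, under the CSC the early-cue bins cannot carry chained value, so
bin-averaged scoring under-weights the sign component by construction;
the end-of-cue readout reflects the learned prediction itself.

### Secondary reinforcement

Episodic two-choice trials (port selection → outcome → end), 1000 per
replicate, no food. `P(active) = sigmoid(beta*(Q_active - Q_inactive))`;
the chosen port's value learns from
`delta_a = 0 + gamma*V(outcome) - Q_a` with the group's `alpha` (one
choice per trial, so the action trace spans a single step). The outcome
value of the active port is the trained model's end-of-cue prediction
`V_s(end) + w_g*m`, recomputed every trial; the inactive port's outcome
is worth 0. On active (cue-shown) trials the recall `m` extinguishes via
the delta rule with `I_R = 0`; inactive trials leave it untouched. Counts
over 1000 trials are rescaled by 1/20 onto [0, 50].

## Experiment defaults

| quantity | value |
|---|---|
| sessions × trials (paired, random) | 12 × 25 |
| sessions (blockade; frozen) | 8 (sessions 1–7 frozen) |
| bins per trial (bin width) | 100 (160 ms) |
| cue bins / reward transition | 10–59 / into bin 60 |
| random-condition draw | u ~ U{0..300}, rewarded iff 21 ≤ u ≤ 100 |
| replicates | 20 |
| presets (alpha, eta) | ST (0.2, 0.01), GT (0.01, 0.2), IG (0.1, 0.1) |
| shared (gamma, lambda, beta) | 0.9, 0.9, 5 |
| SR trials / count scale | 1000 / 20 |

Replicate `r` of any experiment uses seed `base_seed + r`; the blockade
and paired arms of the recovery experiment share replicate seeds, so the
8th-session contrast is matched in everything but the freeze.

Recorded session measures: the sampled response score; the TD error on
the transitions into the cue-onset bin and into the (trained) reward bin
— the model's analogue of phasic dopamine at cue and reward, with the
trained-delivery transition substituted on unrewarded random trials so
session means are always defined; and the end-of-cue sign and goal
components.

## Statistics

t-tests are scipy-based with pooled-variance unpaired tests by default
(Welch by flag); zero-variance inputs are flagged as degenerate rather
than returning NaNs silently. The mixed (repeated-measures) ANOVA wraps
`pingouin.mixed_anova` and enforces balance; no sphericity correction is
applied (plain F is reported). The 3-way ANOVA is a statsmodels OLS
ANOVA (type-II sums of squares, equivalent to type-I/III on the balanced
designs produced here). No multiple-comparison correction anywhere.

One structural note: because active and inactive counts sum to 50 in
every SR replicate, the group × condition term of the 3-way ANOVA on raw
counts is identically zero; the group × condition difference in *port
preference* is the group × condition × port term, and that is the
interaction reported.

## What the synthetic data do and do not show

All inputs are generated by the package itself; the tasks are idealised.
Inter-trial intervals are collapsed (episodic trials), reward magnitude
is fixed at one pellet, responses outside the cue period, latencies and
locomotion are not modelled, and the blockade condition is a hard freeze
of prediction-weight learning rather than a receptor-level manipulation.
Passing tests therefore establish the internal logic of the account —
which learning-rate allocations produce which approach phenotype, RPE
pattern, reinforcer transfer and blockade-recovery signature — not a fit
to any animal's data. Dopamine concentrations from voltammetry are only
qualitatively analogous to the per-transition TD errors reported here.

## Known limitations

* **Cue-time RPE of the sign-tracker.** With per-bin discounting, a
  converged TD learner has vanishing prediction errors on predicted
  transitions, and the cue-onset value under any discount-consistent
  encoding is `gamma^49` of the reward value — essentially zero. The ST
  preset (`alpha = 0.2`) converges within ~2 sessions, so its cue-time TD
  error is small and does not grow across sessions, unlike the large and
  growing cue-time dopamine signal of sign-tracking rats. A persistent
  cue-onset RPE requires event-scale discounting (treating cue→reward as
  one step), which is incompatible here with per-bin TD(lambda) and with
  the stability of the goal/sign balance. The GT preset, whose slow TD
  channel never converges within the experiment, shows the persistent,
  comparable cue- and reward-time errors expected of goal-trackers.
* **Intermediate group.** With `(0.1, 0.1)` the model starts
  sign-tracking and drifts toward indifference, rather than starting
  goal-tracking and switching to sign-tracking: the TD path is active
  from the first rewarded trial, while the recall path must first build
  `m`, so with equal rates the sign component always leads. A crossover
  in the observed direction would need the recall path to outpace TD
  early, which no parameterisation of these update rules produces.
* The random condition retains a small positive score bias (~+0.05):
  randomly timed rewards are still weakly predictable within a trial,
  and `beta = 5` amplifies the residual value. The corresponding checks
  are therefore magnitude bounds rather than strict null tests.
* The GT blockade-recovery contrast is a low-power test of a small real
  difference (the blockade arm lacks the paired arm's residual sign
  component, overshooting by ~0.06); its p-value typically lands between
  0.1 and 0.4 but can approach 0.05 at unlucky seeds.
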