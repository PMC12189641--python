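# Methods

## The model

`mrisched` treats an MRI department as a discrete-time queueing system
observed once per minute.  The system state at minute t comprises the
ordered queue of waiting patients, the status of each machine (idle,
busy, failed), the arrival record and the clinical priorities — nothing
else; in particular, exam durations are *latent*: sampled once when a
patient arrives, they determine when a machine frees up but never appear
in agent observations, mirroring the fact that a scheduler knows the
requested protocol only coarsely.

**Arrivals.**  A non-homogeneous Poisson process with piecewise-constant
intensity λ(t) (patients/hour, one rate per hour-of-day times one
multiplier per day-of-week), simulated by thinning against the profile
maximum.  The default diurnal profile is two-level: a peak rate over
[08:00, 17:00) and an off-peak rate elsewhere; weekly multipliers
default to 1 (flat weeks) but the type supports weekend dips.

**Service.**  Exam durations are log-normal, D ~ LogNormal(μ, σ²) in
minutes, capturing the positive skew of real scan durations.  Durations
are sampled at *arrival*, so a patient whose exam is interrupted keeps
the same nominal duration when re-served.  Occupancy is rounded up to
whole minutes.  `fit_lognormal` is the exact maximum-likelihood
estimator (mean and population sd of log-durations), with the fitted σ
floored at 1e-6 so that degenerate all-equal inputs still yield a
sampleable distribution.

**Failures and repairs.**  A *busy* machine fails in any operating
minute with hazard p_min = 1 − (1 − p_fail)^(1/60), the compounding
conversion that makes the per-operating-hour failure probability exactly
p_fail; idle and failed machines carry no failure risk ("per operating
hour" is taken literally).  Repairs last Exp(mean_repair) and the
machine then returns to the idle pool.  A failure mid-exam returns the
patient to the *head* of the queue with the original arrival time (so
the eventual waiting time reflects the whole episode), and the exam
restarts from zero on reassignment — the conservative convention, since
partial scan data are typically unusable.

**Within-tick event order** (fixed for reproducibility): repairs
complete → exams complete → failures are drawn → arrivals are admitted →
the scheduling decision is taken.  Capacity freed in a minute is thus
visible to the decision made at that minute.

## Decision process and reward

Decision epochs occur every simulated minute; the agent either assigns
one visible queue slot to one idle machine or waits.  At most one
assignment happens per minute: with a non-degenerate action each extra
assignment waits at most one further tick, which keeps the action space
at K·k + 1 (K queue slots, k machines) instead of combinatorial.

Observations are fixed-length vectors: queue length (scaled by 1/K),
then per-slot features for the first K = 10 queue slots — elapsed wait
normalized by 480 min (a working day), a 3-way priority one-hot, a
presence flag — then a 3-way status one-hot per machine.  Patients
beyond the window still accrue waiting and become schedulable as the
queue drains.

The per-step reward is R = α·U − β·W − δ·I with component definitions
chosen to be local and bounded:

* U = 1/k when the action starts an exam, else 0 — the instantaneous
  gain in fraction-of-machines-busy;
* W = Σ over patients still queued after the action of (1/Pᵢ)·Δt/60
  with Δt = 1 min — the priority-weighted waiting incurred until the
  next decision (urgent patients weigh 1, electives 1/3, matching the
  1/P weighting of the fairness metric);
* I = sd of per-machine cumulative busy minutes divided by the elapsed
  clock (0 at the start) — a scale-free workload-imbalance measure.

β is congestion-shaped: β = β₀·(1 + ρ·q/K₀) once the queue length q
strictly exceeds the baseline K₀, else β₀.  β is re-evaluated every
step on the pre-action queue length.  Defaults: α = 1.0, β₀ = 1.0,
δ = 0.1, ρ = 0.5, K₀ = 10, all config-exposed.

**Discount.**  The default is γ = 0.9.  The advantage of assigning now
over deferring one minute is ≈ (1 − γ)·α/k plus one minute of waiting
penalty; at γ very close to 1 this gap falls below the approximation
error of a small value network and learned policies drift into
pathological idling.  γ = 0.9 gives an effective horizon of ~10 minutes
— ample for a decision whose consequences (one exam started one minute
earlier or later) are short-lived — and trains reliably at desk scale.

## Learning agent

Standard DQN: a fully connected value network (two tanh hidden layers
of 128 units; tanh keeps the map smooth on the mostly-binary inputs),
Adam with global-norm gradient clipping at 10, minibatches of 64 from a
uniform ring replay buffer of 10^5 transitions, a hard target-network
sync every 1000 steps, and ε-greedy exploration decaying linearly from
1.0 to 0.01 over the first 80% of training.  Illegal actions are masked
to −∞ both when acting and inside the bootstrap max.  Episode ends by
time limit are stored as terminal for the day-long scheduling episodes
(the ward closes the books daily) but as bootstrapped truncations for
the diagnostic chain MDP, whose oracle is the infinite-horizon fixed
point.  The learning rate default of 5e-4 was selected by the grid
procedure (lr ∈ {1e-4, 5e-4, 1e-3}) on mean evaluation performance
across seeds.  All randomness — initialization, exploration, replay
sampling, per-episode environment seeds — derives from one config seed;
reruns are bit-identical.

Training uses day-long (1440-minute) episodes; evaluation runs one
continuous multi-day horizon.  The quick (desk-scale) scenario trains
40,000 steps (~28 simulated days, about one minute on one CPU core);
the full-scenario default is 200,000 steps.

## Calibration defaults (stand-ins)

The shipped defaults are clearly-labelled stand-ins, not fitted values:
median scan 30 min (μ = ln 30 ≈ 3.401) with σ = 0.4 log-minutes (90% of
exams between ~15 and ~58 min, a plausible mixed-protocol case mix);
peak arrival rate 4/h against 0.5/h off-peak (≈ 43.5 patients/day, which
loads three machines to ρ ≈ 0.72 during the peak window and ≈ 0.33
around the clock); priority mix 10/30/60 urgent/semi-urgent/elective,
an assumption in the range reported for elective imaging triage;
breakdowns at 0.01 per operating hour with 3 h mean repairs.  Every one
of these is a `ScenarioConfig` field.

The synthetic scan-record generator emulates only the *duration*
distribution of real scan metadata.  It does not emulate protocol mix,
patient covariates, setup/changeover times, no-shows, or correlations
between urgency and duration; conclusions from passing tests therefore
concern the scheduling mechanics under the stated stochastic model, not
any particular hospital's case mix.

## Validation strategy

* **Analytic queueing oracle.**  In validation mode the twin runs
  exponential service (un-rounded), zero failures and greedy FCFS, and
  its long-run mean queue wait is compared with the Erlang-C closed
  form, alongside Little's law on the same run.  The default validation
  point (λ = 1/h, mean service 120 min, c = 3, ρ = 2/3, 200,000
  simulated minutes after a 5,000-minute warm-up) deliberately uses
  services long relative to the one-minute tick, so the known
  discretization bias (≈ +0.5 min on service, ≈ +0.5 min on admission)
  stays far below the Monte-Carlo error; the error itself is estimated
  by batch means over 20 batches, each an order of magnitude longer
  than the waiting-time correlation time.
* **Parameter consistency.**  Large Monte-Carlo draws of the repair
  sampler (10^5 draws) and of the per-operating-minute failure hazard
  (10^5 operating hours, vectorized but drawing the identical Bernoulli
  the stepped simulator draws) are checked against their configured
  means; the vectorized and stepped paths are cross-checked against
  each other at smaller n.
* **Learning-loop oracle.**  A two-state deterministic chain MDP with
  closed-form optimum: trained Q-values must match tabular value
  iteration to 0.05 on unit scale and reproduce the optimal policy.
* **Conservation properties.**  At every simulated minute, arrivals =
  queued + in-service + completed; waits are never negative; zero
  configured hazard implies exactly zero downtime.

## Metrics conventions

Utilization counts downtime as available time (failures depress U); an
alternative flag would exclude it, but the default makes reliability
costs visible.  Wᵢ measures arrival → exam start; patients still queued
at the horizon are excluded from W̄ and F and reported as a censored
count.  The all-zero-wait fairness case (0/0 in Jain's ratio) is defined
as 1.  Aggregation across seeds reports mean and sample sd (ddof = 1).

## Known limitations

* Under the default light-to-moderate load, *all* work-conserving
  policies (FCFS, static priority, and a well-trained agent) produce
  identical busy processes under common random numbers, so utilization
  cannot separate them, and the classical conservation law makes the
  *overall* mean wait policy-invariant in expectation when service is
  class-independent.  Policy differences then live in the per-priority
  breakdown and the fairness index, and in heavily congested scenarios
  where horizon-end censoring and the congestion-shaped reward bite.
  Comparisons of near-tied aggregate metrics at a handful of seeds are
  dominated by Monte-Carlo noise and should be read accordingly.
* One assignment per minute slightly delays batch arrivals when several
  machines are simultaneously idle (at most a one-minute cost each).
* Interrupted exams restart from zero; no preemption, no no-shows, no
  dynamic re-prioritization, single department.
* The DQN is a plain single-estimator variant (no double/dueling
  networks, no prioritized replay) by design.
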