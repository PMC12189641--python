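# mrisched

Digital-twin simulation and reinforcement-learning scheduling for hospital
MRI suites.

High-complexity hospitals run a small number of MRI machines against a
stream of patients whose exams differ in length and clinical urgency.
Classic dispatch rules — first-come-first-served (FCFS) or a static
urgency-first heuristic — adapt poorly to diurnal demand swings and random
machine breakdowns.  `mrisched` provides, for operations researchers and
health-systems engineers:

* a **minute-resolution discrete-event twin** of an MRI suite: arrivals
  follow a non-homogeneous Poisson process with a diurnal intensity
  λ(t), exam durations are log-normal, D ~ LogNormal(μ, σ²), patients
  carry priorities P ∈ {1, 2, 3} (urgent / semi-urgent / elective), and
  busy machines fail as Bernoulli trials per operating hour with
  exponential repair times;
* an **MDP environment** over the twin with composite per-step reward
  R(s, a) = α·U(a) − β·W(a) − δ·I(a), where U rewards starting exams,
  W penalizes priority-weighted waiting, I penalizes workload imbalance,
  and β = β₀·(1 + ρ·OverloadFactor) inflates the waiting penalty under
  queue congestion;
* a **DQN scheduling agent** (experience replay, target network,
  linearly decaying ε-greedy exploration) plus FCFS / static-priority /
  random baselines; and
* an **evaluation harness** reporting machine utilization U, mean patient
  wait W̄, and a priority-weighted Jain fairness index
  F = (Σxᵢ)² / (n·Σxᵢ²) with xᵢ = Wᵢ/Pᵢ, averaged over seeds with common
  random numbers across policies.

No external data is required: a synthetic calibration module emulates
scan-duration metadata (positive-skew durations, diurnal arrivals,
three-level priority mix), and users can calibrate from their own
duration tables.

## Worked example

```python
import mrisched as m
from mrisched import evaluation

# calibrate from (here: synthetic) scan durations
params = m.fit_lognormal(m.generate_synthetic_scan_records(5000, seed=42))
print(params.mu, params.sigma)           # 3.393 0.400

# simulate 5 days x 3 seeds under two dispatch rules
sc = m.ScenarioConfig(horizon_days=5, n_seeds=3)
for name, pol in [("fcfs", evaluation.FCFSPolicy()),
                  ("static", evaluation.StaticPriorityPolicy())]:
    agg = m.aggregate_runs(evaluation.run_scenario(pol, sc))
    print(name, agg)
```

prints (mean ± sd over the 3 seeds):

```
fcfs    U=0.331±0.016  Wbar=10.0±4.5 min  F=0.226±0.024
static  U=0.331±0.016  Wbar=10.0±4.4 min  F=0.216±0.017
```

Utilization is identical because both rules are work-conserving and face
identical random streams; they differ in *who* waits (the static rule
trades elective waiting time for urgent throughput, visible in the
per-priority breakdown of each report).  Training and evaluating the
learning agent follows the same pattern:

```python
result = evaluation.train_agent(m.quick_scenario())      # ~1 min on 1 CPU
policy = evaluation.DQNGreedyPolicy(result.network)
reports = evaluation.run_scenario(policy, m.quick_scenario())
```

The same workflow is available from the shell:

```bash
mrisched init --quick --out scenario.yaml
mrisched train --config scenario.yaml --out ckpt.npz
mrisched compare --config scenario.yaml --checkpoint ckpt.npz --out-dir comparison/
mrisched validate          # Erlang-C / Little's law / parameter checks
```

## Scope

The twin models a single MRI department: no preemption of running exams,
no patient no-shows, no dynamic re-prioritization of waiting patients,
and no integration with hospital information systems.  See
`docs/methods.md` for the model assumptions, parameter defaults and known
limitations.
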