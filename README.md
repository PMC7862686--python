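# behavepi

Endogenous social distancing and its impact on the epidemic curve: a
game-theoretic model of contact choice, a hyperbolic-geometry contact-network
generator, and a stochastic network SEIR simulator that compares
self-organized distancing against imposed interventions.

The headline experiment asks: if individuals spontaneously reduce their
contacts threefold when 10% of the population is infectious
(`q = 3^(-10·ρ)`), how strong would a *uniform* contact-rate cut, or a
*random immobilization* of part of the population, have to be to flatten the
epidemic peak by the same amount?

## Package layout

| Module | Contents |
| --- | --- |
| `behavepi.game` | Social-distancing game: role utilities, best responses, symmetric Nash equilibrium, comparative statics, simplified 2×2 game |
| `behavepi.network` | Hyperbolic random geometric graphs with degree calibration and diagnostics |
| `behavepi.seir` | Discrete-time stochastic SEIR on networks with per-node contact rates and four scenarios |
| `behavepi.calibration` | Synthetic contact-survey generator, OLS slope fits, slope → endogenous-law conversion |
| `behavepi.experiment` | Experiment configs (YAML) and the full scenario-comparison pipeline |
| `behavepi.cli` | `behavepi` command-line interface |

## Worked example

### 1. The social distancing game

Healthy and sick individuals choose a contact rate β ∈ [0, 1]. Without
disease the optimum is β\* (0.5 for the default symmetric utility); fear of
infection (`f`) and concern for others (`c`) pull the equilibrium below it:

```python
from behavepi import game

p = game.GameParams(n=100, n_healthy=90, f=0.8, c=0.8, delta=0.7)
eq = game.solve_symmetric_equilibrium(p)
print(eq)
# ContactProfile(beta_H=0.4262, beta_S=0.4258, beta_star=0.5)
```

All six comparative-statics predictions (each perturbation lowers the
affected equilibrium rate) are computed by `game.comparative_statics(p)`:

```text
perturbed affected  sign  derivative
   beta_H   beta_S    -1   -0.013253
   beta_S   beta_H    -1   -0.030449
n_healthy   beta_S    -1   -0.000786
   n_sick   beta_H    -1   -0.002681
        c   beta_S    -1   -0.097393
        f   beta_H    -1   -0.088984
```

### 2. Networks and epidemics

```python
from behavepi import network, seir

g = network.generate_graph(2000, seed=42)          # calibrated to mean degree 6
d = network.diagnostics(g)
# mean_degree 6.0, clustering 0.685, mean shortest path 3.49, scale-free tail

params = seir.SEIRParams(horizon=200, n_realizations=5, seed=0)
c_none = seir.run(g, params, seir.Scenario(kind="none"))
c_endo = seir.run(g, params, seir.Scenario(kind="endogenous"))
print(c_none.peak_infected_fraction, c_endo.peak_infected_fraction)
# 0.201 vs 0.091 — endogenous distancing roughly halves the peak
```

### 3. Survey calibration

```python
from behavepi import calibration

table = calibration.generate_survey(seed=1)        # synthetic weekly survey
fit = calibration.fit_slope(table, "healthy")
# slope -57.5, 95% CI [-106.3, -8.8]
scale = calibration.slope_to_decay(fit.slope, fit.intercept)
# 0.142: contacts fall threefold at 14.2% incidence
```

## Tests

```bash
python -m pytest -q
```

The suite includes `tests/test_acceptance.py`, one test per acceptance
criterion; the scenario-matching criterion runs the full-scale experiment
and dominates the runtime (~10 minutes).
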