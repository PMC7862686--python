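# Methods

This document defines the models implemented by `behavepi`, the default
parameter values and why they were chosen, and the numerical choices that
matter for reproducing results.

## 1. The social distancing game (`behavepi.game`)

A population of `n` individuals, `|H| = n_healthy` healthy and
`|S| = n - n_healthy` sick, each chooses a contact rate β ∈ [0, 1]
(interpreted as the probability of being mobile / out of home).

**Base utility.** Without disease, utility from mobility is
`u(β) = K · β^a (1-β)^b` with shape `(a, b)` (default `(2, 2)`): both total
isolation and permanent mobility are worthless, with an interior optimum at
`β* = a/(a+b)` (default 0.5). `K` normalizes `u(β*) = 1`.

**Healthy players** discount utility by the risk of getting infected:

```
U_H(β_i; β_S) = (1 − f · β_i · P) · u(β_i),   P = 1 − (1 − β_S)^(n − |H|)
```

`P` is the probability at least one sick individual is mobile, `f ∈ [0, 1]`
is fear of the disease. **Sick players** discount by the chance of
infecting others, with a sickness discount `δ`:

```
U_S(β_i; β_H) = (1 − c · β_i · Q) · δ · u(β_i),   Q = 1 − (1 − β_H)^|H|
```

`c ∈ [0, 1]` is concern for others. The first-order condition for either
role with weight `w ∈ {f, c}` and risk term `X ∈ {P, Q}` is

```
(1 − w · β_i · X) · u′(β_i) − w · X · u(β_i) = 0 .
```

**Equilibrium.** The symmetric Nash equilibrium `(β_H, β_S)` is found by
damped alternating best responses (damping 0.5) starting from `(β*, β*)`,
tolerance 1e-8, at most 500 iterations. Each best response is a 2001-point
grid scan refined by bounded scalar minimization; ties against a flat zero
utility resolve to staying home (β = 0).

**Comparative statics.** Six signed responses are checked against the
model's predictions (all negative): each type's best response falls in the
other type's contact rate (finite-difference slope of the best-response
map), and each equilibrium rate falls when the opposite population grows by
one, when concern `c` rises (sick rate), and when fear `f` rises (healthy
rate). Derivatives use central differences with re-solved equilibria.
Signs classify as ±1 only beyond `10 × solver tolerance`; the documented
test grid uses small populations (n between 6 and 20) because for very
large `|H|` the risk terms saturate (`(1−β)^|H|` underflows) and
derivatives are numerically zero.

**Simplified 2×2 game.** `simplified_game_table` restricts both types to
{home: β = 0, mobile: β = β*} and tabulates the payoff pairs, exposing the
coordination structure: (home, home) yields zero for both, while at
(mobile, mobile) each type strictly gains by deviating to its interior best
response.

## 2. Hyperbolic contact networks (`behavepi.network`)

Nodes are placed in a hyperbolic disk of curvature `ζ` (default 1.0) and
radius `R`: angles uniform on [0, 2π), radii with density ∝ sinh(αr)
(quasi-uniform for `α = ζ/2`, default `α = 0.75`), sampled by inverse CDF
`r = arccosh(1 + u(cosh(αR) − 1))/α`. Two nodes connect iff their
hyperbolic distance (law of cosines:
`cosh ζx = cosh ζr₁ cosh ζr₂ − sinh ζr₁ sinh ζr₂ cos Δθ`) is at most `R`.
This yields simultaneously scale-free-like degree distributions (tail
exponent `2α/ζ + 1`, ≈ 2.5 at defaults), strong clustering, and short
paths — the stylized facts of social contact networks.

**Degree calibration.** `R` is found by bisection (22 iterations) on the
expected mean degree, estimated from up to 8×10⁶ sampled node pairs with
precomputed angle cosines; radii quantiles are tied to `R` so degree is
monotone in `R`. Generation fails with a clear error if the realized mean
degree misses the target by more than 10%.

**Diagnostics.** Mean degree, mean clustering, mean shortest path on the
giant component, and a degree-tail classification: Hill maximum-likelihood
tail exponent with KS-selected cutoff, classified scale-free vs exponential
by a power-law-versus-exponential likelihood comparison on the tail.

## 3. Stochastic network SEIR (`behavepi.seir`)

Discrete-time (one step ≈ one day), synchronous updates, compartments
S, E, I, R. Each node carries a contact rate `q_i ∈ [0, 1]`. Per step:

* every edge between a susceptible and an infectious node transmits with
  probability `q_i · q_j · beta_trans`;
* E → I with probability `sigma`; I → R with probability `gamma`;
* transitions use the pre-step state (newly exposed nodes cannot progress
  in the same step).

Initial infectious seeds: `ceil(initial_infected_frac · n)`, minimum 1
(a warning is raised when the expected count is below one). Realizations
use independent streams spawned from `SeedSequence(seed)`; scenarios run
with **common random numbers** (realization k of every scenario shares the
same stream and the same network from the ensemble), so scenario contrasts
are paired. Runs stop early when E + I = 0 and the remaining curve is
filled with the final state.

**Scenarios.**

| kind | contact rates |
| --- | --- |
| `none` | `q_i = 1` |
| `uniform` | `q_i = q` for all nodes |
| `random_immobilization` | `round(p·n)` random nodes get `q = 0.1`, rest 1 |
| `endogenous` | `q_i = fold^(−ρ/scale)` updated every step from prevalence ρ (I-fraction); defaults `fold = 3`, `scale = 0.1`, i.e. `q = 3^(−10ρ)`; optionally a separate (smaller) scale for infectious nodes |

**Matching thresholds.** A sweep of uniform reductions (or immobilized
fractions) is scanned in increasing intensity; the threshold is the first
intensity whose mean peak infected fraction falls to the endogenous
scenario's mean peak, linearly interpolated between grid points, or `None`
when no sweep entry matches.

## 4. Survey calibration (`behavepi.calibration`)

Weekly contact surveys record ILI incidence and median contacts by health
status. `fit_slope` regresses median contacts on incidence (OLS,
statsmodels) per status; `slope_to_decay` converts a slope into the
endogenous law's incidence scale by solving
`baseline + slope·ρ* = baseline/fold`, giving
`ρ* = baseline(1 − 1/fold)/(−slope)`. By construction
`endogenous_q(ρ*, fold, ρ*) = 1/fold`, so a noiseless survey round-trips
exactly.

Real survey microdata is not redistributable; the package ships a
**synthetic generator** whose defaults emulate published summary numbers
(baseline ≈ 13 contacts/week, slopes ≈ −70 healthy / −110 ill, weekly
incidence uniform on 3–8%, Gaussian noise sd 2). The generator exists to
define contracts and tests, not to reproduce the original dataset; the
published slope values are used only as defaults, never as test
assertions. `contacts_correlation` regresses ill on healthy contacts
across weeks, reproducing the qualitative check that a common incidence
driver induces a *positive* association between the two series.

## 5. The headline experiment (`behavepi.experiment`)

One experiment: generate an ensemble of `n_realizations` networks, run the
unrestrained and endogenous scenarios plus both sweeps with common random
numbers, and report the two matching thresholds. Configuration is a strict
dataclass tree (unknown YAML keys are rejected) that round-trips losslessly
through YAML; all artifacts carry `schema_version` and `master_seed`.
Network seeds come from `SeedSequence([master_seed, 7])`, distinct from
the simulation streams.

### Default parameters and rationale

| Parameter | Default | Rationale |
| --- | --- | --- |
| `n_nodes` | 20 000 | This package's chosen problem size: large enough for stable peaks, small enough for a ~10-minute single-CPU run |
| mean degree | 6 | Documented network default |
| `zeta`, `alpha` | 1.0, 0.75 | Tail exponent `2α/ζ + 1 ≈ 2.5`, canonical for social networks |
| `beta_trans` | 0.15 /contact/step | Nominal `R0 = beta_trans · k̄ / gamma ≈ 6.3`, the high end of published unmitigated COVID-19 estimates; chosen (before any threshold was measured) so the unrestrained attack rate exceeds 60% |
| `sigma` | 0.2 /step | ≈ 5-day latency |
| `gamma` | 1/7 /step | ≈ 7-day infectious period |
| `initial_infected_frac` | 0.002 | 0.2% seeded infectious |
| `horizon` | 300 steps | Epidemics at defaults resolve well within it (early stop applies) |
| `n_realizations` | 25 | Network ensemble × paired realization streams |
| uniform sweep | q = 1.00 … 0.10, step 0.05 | Reduction grid 0–90% |
| immobilization sweep | p = 0.00 … 1.00, step 0.05 | |
| endogenous law | `q = 3^(−10ρ)` | Threefold contact reduction at 10% prevalence |

The epidemiological rates were fixed a priori from the public literature
(the original experiment's exact supplementary parameters are not
available); `threshold_sensitivity` reruns a scaled-down experiment at
0.75×, 1×, 1.25× `beta_trans` to show how the matching thresholds move
with the transmissibility assumption.

### Numerical choices

* Compartments are int8 arrays; infection attempts are vectorized over the
  directed S←I edge list (cached per graph), ~0.1 s per realization at
  20 000 nodes.
* Peaks and attack rates are averaged over realizations; standard errors
  are across-realization SEs of the per-realization peaks.
* Threshold matching uses the *mean* peak (matching the sweep definition);
  paired per-realization differences are used in tests for power.

### Results at defaults

At the documented defaults (master seed 1) the unrestrained epidemic peaks
at 20.3% infected with a 73.8% attack rate; endogenous distancing lowers
the peak to 9.0%. The minimal uniform contact-rate reduction matching the
endogenous peak is **44.5%**, the minimal immobilized fraction **39.7%**.
The sensitivity grid (`threshold_sensitivity`, 4 000 nodes, transmission
rate ±25%) moves the uniform threshold only between 39.8% and 44.0% and
the immobilization threshold between 36.4% and 39.3%, so these values are
robust to the transmissibility assumption at this network scale. Larger
thresholds are expected on much larger networks, whose heavier degree-tail
hubs make uniform reductions less efficient relative to the self-limiting
endogenous law.

## 6. Limitations

* Discrete-time synchronous dynamics; no continuous-time (Gillespie)
  equivalence is claimed.
* Terminal R: no waning immunity or reinfection.
* The game model informs the *functional form* of the endogenous law; the
  Nash solver is not coupled into the simulation loop (coupling is via the
  fitted `q(ρ)` law).
* The synthetic survey generator emulates summary statistics only; fitted
  slopes on synthetic data inherit its assumptions (linear response,
  Gaussian noise, uniform incidence).
* Comparative-statics signs are only numerically resolvable away from the
  saturation regime (very large healthy populations make the sick player's
  risk term constant at machine precision).
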