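# Methods

This note documents the models implemented by `flockfit`, the choices
made where the underlying science leaves the design open, and what the
synthetic-data experiments do and do not demonstrate.

## The modelling-cycle workflow

The package operationalises one full turn of the modelling cycle for
collective animal behaviour: simulate a candidate individual-level rule
(local to global), extract the per-individual event record a likelihood
can be evaluated on (global to local), fit and rank candidate rules,
and then re-simulate the fitted rule to check it still produces the
group-level pattern. All data are generated by the package's own
simulators; no animal recordings ship with the package, so every
quantitative claim is a *parameter-recovery* or *property* statement
about the method, not a re-analysis of field data.

## Ring arena and direction switching

Agents on an annular arena are reduced to a 1-D circle parameterised by
angle; the radial coordinate carries no information for any quantity we
compute. Positions lie in [0, 2π) with counter-clockwise positive;
clockwise travel is coded dir = −1 ("CW"), counter-clockwise +1
("CCW"). Agents advance by ω·dt per step in their travel direction,
are treated as points (no collisions), and reverse direction with a
per-step probability given by a switching rule evaluated on the
configuration at the current step (synchronous update — this matches
the factorisation of the sequence likelihood exactly). Default dt is
0.4 s, the sensing/observation window used throughout the package, and
ω defaults to one lap per ~200 steps.

The switching-rule family:

- **const** (1 parameter): fixed rate p0. Context-free baseline.
- **meanfield** (2): p0 + k·f_opp with f_opp the fraction of all other
  agents travelling opposite to the focal one. Global, Markovian.
- **zone** (3): rate p1 when an opposite-direction agent sits in the
  forward zone (signed forward separation in [0, w]), else p0.
  Markovian, spatial; w = π is the non-local variant.
- **d1** (4): refractory memory. An encounter (opposite agent in the
  zone) arms a countdown of tau steps during which the rate is p1.
- **d2** (4): decaying trace M ← (1−λ)·M + 1{encounter}, rate
  p0 + k·M. With λ = 1 it collapses to the zone rule.

The memory rules are the two simplest mechanisms consistent with
"memory of previous encounters": a hard refractory window and an
exponentially fading trace. The zone is forward-only by default
(approaching opposite-direction animals are ahead); a symmetric ±w
zone is available via a switch. Only opposite-direction neighbours
enter any rule. All probabilities are clipped to [1e−9, 1−1e−9] so
log-likelihoods stay finite; the clip bound is configurable in one
place (`switching_models.EPS`).

Memory state is initialised to zero at the start of every trajectory;
fits on concatenated event sets thread memory independently per series
(agent × source trajectory), which `SwitchEventSequence.concat`
enforces by relabelling series.

## Likelihood, fitting and model comparison

The sequence log-likelihood is Σ y·ln p + (1−y)·ln(1−p) over every
(agent, step) record, with p the model's probability given the
neighbour context (and threaded memory). Two implementations exist:
a scalar per-context path (the documented rule definitions) and a
vectorised path over pre-computed context features; the test suite
checks them against each other event-for-event.

**Optimisation.** The likelihood is *piecewise constant* in the zone
width w (it changes only when w crosses an observed neighbour
distance) and in the integer memory horizon tau. Simplex-type searches
stall on such plateaus, so the fitting engine profiles these
parameters instead:

- zone: exact profile over *every* observed cut point (a sort/cumsum
  scan), with the two Bernoulli rates solved in closed form per cut
  and the p1 ≥ p0 ordering enforced by pooling when it binds. This is
  the exact MLE up to the data's own resolution in w.
- d1: grid of 64 distance quantiles × tau ∈ {1..15}, closed-form
  rates, then local refinement of w over all observed distances in the
  winning bracket.
- d2: grid of 16 distance quantiles × 7 decay values; given (w, λ) the
  trace M is fixed and the rate is linear in (p0, k), so the inner
  problem is concave and solved by multi-start L-BFGS-B with analytic
  gradients. Local refinement of w at the winning λ.
- meanfield / const: probability linear in the parameters — concave
  likelihood, multi-start L-BFGS-B with analytic gradients.
- any unregistered rule falls back to multi-start bounded Nelder-Mead.

Reported fits satisfy the invariant that the returned log-likelihood
is the best value over everything evaluated; nested-model ordering
(e.g. d1 ⊇ zone via tau = 1) is asserted in the tests to 1e−6.

**Model comparison.** AIC and BIC are recomputable from the stored
fields. The default ranking criterion is an approximate log marginal
likelihood under independent uniform priors over the declared bounds:
a Laplace approximation around the MLE with a central finite-difference
Hessian where the likelihood is smooth and the MLE is interior, and
the BIC approximation −BIC/2 (flagged `laplace_fallback`) whenever a
profiled parameter makes the observed information singular or the MLE
sits on a bound. Because ranking differences in practice are tens to
hundreds of nats, the O(1) difference between the two approximations
does not affect any conclusion the tests assert; the Bernoulli test
problem verifies the Laplace value against the exact Beta-function
evidence to 0.1 nat at n = 1,000. Bayes factors are reported against
the mean-field baseline.

**Study-scale settings.** Recovery experiments use N = 8 agents and
T = 5,000 steps (≈ 40,000 events), 10–20 replicates. The underlying
switch rates are not published for any system, so the package's
defaults are chosen as plausible per-0.4 s reversal rates: spontaneous
p0 ≈ 0.01–0.02 and encounter-driven p1 ≈ 0.12–0.15, giving a few
hundred reversals per run — enough contrast for the zone and memory
parameters to be identifiable without saturating the sequence with
switches.

## Alignment-in-radius model

The canonical angular-noise self-propelled particle model: each
particle adopts the circular mean heading of all particles within
radius r (itself included; minimum-image metric on a periodic square),
plus uniform noise on [−η/2, η/2], then moves v·dt. Zero-resultant
ties keep the previous heading. The order parameter is the magnitude
of the mean unit heading vector. Exact limits used by the tests: a
noiseless aligned state is absorbing (order 1), and at η = 2π headings
are i.i.d. uniform, for which E[order] ≈ √π/(2√N) (Rayleigh). The
transition is asserted as monotonicity of the time-averaged order
parameter in noise and in density — the claim is the existence and
direction of the transition, not critical exponents.

A second planar simulator (`simulate_interaction`) drives turning by a
*linear combination of named neighbour features* (alignment: mean sine
of heading differences; attraction: mean sine of relative bearing).
Because the turning law is linear in its coefficients, least-squares
force matching is exact linear algebra: the generating coefficients
are recovered to 1e−8 on noise-free data, and the generating model's
residual sum of squares beats a mis-specified alternative in ≥ 95% of
noisy replicates. Nonlinear force laws are deliberately out of scope.

## Pheromone trails

**Weber response.** The turning angle per 0.4 s sensing step is
α = A·(L−R)/(L+R+T0) degrees, positive toward the front-left sector;
sampling adds zero-mean Gaussian noise. A is the gain in degrees, T0
the detection threshold in pheromone units (it also regularises the
response at zero concentration; α = 0 when T0 = 0 and L = R = 0).
T0 enters as a denominator offset, not a hard cutoff — the form
consistent with "turning angle proportional to (L−R)/(L+R)" at high
concentration and suppressed response below threshold. Pheromone units
are arbitrary: passage counts and concentration are deliberately
conflated. Default parameter values A = 30.80, T0 = 10.53, noise sd
20°.

**Sectors.** Front-left and front-right sectors are each centred
half_angle radians off the heading and span 2·half_angle; the default
half_angle = π/4 tiles the front half-plane, split at the heading
line. Default radius 5 cells. A cell contributes when its centre lies
in the sector. The sector geometry is a free choice — only the L/R
split is constrained by the response model.

**Maps and trail simulation.** The pheromone map accumulates a fixed
deposit per time-sample per cell (mass conservation is exact, and
deposit-only mode reproduces passage-count map estimation). The trail
simulator senses, turns (Weber + noise), advances one step length,
deposits, and evaporates the whole grid by a fixed fraction per step;
walls reflect. With zero gain the ants are noise-driven random walkers
and the steady grid mass follows the closed-form deposition/
evaporation balance exactly. With strong gain and low noise the
simulated colonies re-walk and reinforce closed circuits; the
`loop_metric` (mass fraction of above-90th-percentile cells whose
graph edges lie on cycles, 4-connectivity) exceeds the zero-gain
control — the known artefact of pure Weber-following without path
integration, which is the qualitative behaviour the simulation is
meant to exhibit, not a bug.

**Double bridge.** The mean-field choice dynamics use the standard
concentration choice function P_A = (k+c_A)^n / ((k+c_A)^n+(k+c_B)^n)
with dc/dt = flow·P − ρ·c; defaults n = 2, k = 20. Linearising around
the symmetric state gives instability iff flow > 2ρk/(n−1): n = 1
never breaks symmetry, n = 2 selects a single branch above the
threshold. The tests verify both regimes against a numerically
differentiated eigenvalue oracle.

**Effective nonlinearity.** At a two-branch junction carrying fixed
concentrations, a single noisy Weber comparison gives a shallow,
nearly linear choice probability; accumulating n sensing steps before
committing gives P ≈ Φ(√n·drift/σ), which sharpens with n. This is
the mechanism by which an essentially linear individual response
yields the steep collective choice function the bridge model assumes.

## Route mixtures for paired journeys

A bird's route repertoire is a station-wise Gaussian cross-track
model: paths are resampled to 100 arc-length stations (linear
interpolation), and each station stores the mean position and the
standard deviation of signed perpendicular deviations from the mean
path, floored at a small positive value. This is the simplest
representation supporting path likelihoods, fidelity and mixtures; a
full Gaussian-process treatment is out of scope. The population
(ddof = 0) standard deviation is used so that two paths offset ±d give
exactly sd = d. Paths whose point count equals the station count are
taken as already station-aligned. Route fidelity is the reciprocal of
the mean station sd — higher means a more faithful, repeatable route.

A paired flight is scored station-wise under the mixture
w·φ_self + (1−w)·φ_partner (computed in log space). The constant
weight model has one parameter; the fidelity model sets
w = logistic(a + b·fidelity), so a positive slope means route-faithful
birds concede less to their partner. Station-wise the mixture
log-likelihood is a sum of logs of linear functions of w, hence
concave with a unique maximum; the 1-D fit is a grid scan plus bounded
refinement and matches a 1,000-point grid oracle. BIC (with n = total
station observations) compares the two weight models; the synthetic
tests verify both directions — the fidelity model wins when the slope
is real, the constant model wins on Occam grounds when it is not.
Identifying the slope requires fidelity variation *across* pairs, so
the fitting API accepts a list of per-pair observations; the tests use
12 pairs with 40 stations each.

## What the synthetic experiments do and do not show

The generators match the structure assumed by the corresponding
estimators (Bernoulli switching given the context features, Gaussian
cross-track noise, Gaussian angular noise). Passing recovery tests
therefore demonstrates correctness and internal consistency of the
simulators, likelihoods and optimisers — the modelling cycle closes on
its own output — but not robustness to the mis-specification real
recordings would bring (tracking noise, heterogeneous individuals,
non-stationarity, radial structure in the arena). The model-selection
experiments partially probe mis-specification (e.g. fitting Markovian
rules to memory-generated data reproduces the expected structure:
memory models win and keep a local zone), and force matching rejects a
wrong interaction law, but no claim is made about performance on real
trajectories.

## Numerical choices

- Probability clip 1e−9; likelihood plateau resolution in w is the
  spacing of observed neighbour distances (~1e−4 rad at 40,000
  events).
- Finite-difference Hessian step 1e−4·(1+|θ|), central differences,
  Cholesky for the log-determinant; any failure triggers the flagged
  BIC fallback.
- ODE integration via `solve_ivp` (RK45, rtol 1e−9).
- All randomness flows through `numpy.random.default_rng`;
  multi-replicate runs spawn child seeds from a single
  `SeedSequence`, so results are reproducible from one seed and
  adding a model or replicate does not perturb the others' draws.
- Trajectory CSV round-trips are bit-exact (`%.17g` on write,
  `float_precision="round_trip"` on read).

## Known limitations

- Ring agents have no radial coordinate, no body size and no contact
  mechanics; speeds are constant.
- The memory-rule family is two members; the registry is pluggable
  for alternatives.
- The Laplace marginal degrades to BIC for rules with profiled
  parameters (flagged); full posterior sampling is out of scope.
- The trail simulator omits path integration and direct ant–ant
  interactions, and consequently over-produces stable loops — by
  design, as the observable consequence of that omission.
- Force matching covers only turning laws linear in their parameters.
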