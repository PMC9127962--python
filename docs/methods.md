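# Methods

This note documents the models, numerical choices, and design decisions
behind `gcda`, in the spirit of the methods documentation of simulation
packages: what is computed, under which assumptions, and what the bundled
synthetic fixtures do and do not demonstrate about real data.

## Gene expression model

Every gene product follows one-step synthesis with first-order loss:

    dp_i/dt = Σ_k Φ_k,i(r) − (γ_i + μ(t)) p_i

The synthesis term sums the transfer functions of all operators that output
product *i*; when one operator drives several outputs they all receive the
same rate (a deliberate simplification — differential expression within an
operon is not modeled). mRNA dynamics, regulator–regulator interactions,
and resource competition between the network and host metabolism are outside
the model's scope: regulators act only on operators, and growth affects the
network only through the dilution term.

Concentrations are unitless "molecules per cell equivalents". No fluorescence
calibration (e.g. MEFL) is applied; reporters are read out directly in model
units, so fitted synthesis rates are only comparable between experiments
measured on the same scale.

### Transfer functions

The one-input operator uses the rational Hill form
`(α₀ + α₁ x)/(1 + x)`, `x = (r/K)ⁿ`, which pins the parameter roles:
`α₀` is the rate at zero input, `(α₀+α₁)/2` the rate at `r = K`, and `α₁`
the saturated rate. The two-input operator models two promoters in tandem
with independent occupancies, `(α₀ + α₁x₁ + α₂x₂ + α₃x₁x₂)/((1+x₁)(1+x₂))`.
The product-form denominator is a modeling choice: any cooperative
interference between the tandem promoters beyond the joint rate `α₃` is
absorbed into `α₃` rather than given its own interaction term. Operators are
limited to two inputs; logic labels (NOT/BUFFER for one input, NOR for two)
follow strict parameter inequalities, with exact ties classified OTHER
because neither label is forced.

Receivers reuse the one-input Hill form with an external supplement as
input. Supplements are assay conditions: held at a fixed per-sample
concentration, neither diluted nor consumed. A receiver input missing from a
sample's supplement map is treated as concentration 0.

## Growth profiles

Growth enters only through `μ(t) = d ln b(t)/dt`. Three closed-form biomass
curves are provided — constant-rate exponential, logistic, and Gompertz
(Zwietering parametrization with an explicit lag) — and `μ` is derived
analytically from each so ODE right-hand sides stay smooth; no numerical
differentiation is involved. Biomass is emitted as its own `biomass` signal
in measurement tables, in OD-like arbitrary units distinct from reporter
units. Feedback from the network onto growth (burden) is not modeled.

Defaults used by the bundled assays: constant growth at `μ = 0.5 /h` for
characterization fixtures (a typical exponential-phase rate for *E. coli*
in minimal medium) and `μ = 0` for the oscillator so its dynamics reflect
degradation-driven timescales only.

## Simulation

- **ODE**: LSODA via `scipy.integrate.solve_ivp`, `rtol = 1e-8`,
  `atol = 1e-10`. States are clipped to zero inside the right-hand side
  before evaluating Hill terms (solver probes can undershoot); trajectory
  values in `(−1e-12, 0)` are snapped to exactly 0 on output.
- **SSA**: Gillespie direct method over `2N` reactions (one production, one
  extinction per product). Propensities are recomputed after every event;
  `μ(t)` is evaluated at the current time when propensities are rebuilt and
  frozen until the next event (quasi-static approximation, accurate because
  the growth timescale is far longer than inter-event times in all bundled
  networks). A fixed seed yields a bit-identical event list; uniform
  variates are drawn in blocks from one `numpy` generator. ODE and SSA share
  parameter values, interpreting concentrations directly as copy numbers;
  growth is deterministic in both methods.
- **Assays**: `run_assay` simulates each sample on the shared grid
  `0, Δt, …` (`⌊duration/Δt⌋ + 1` points) and emits one tidy row per
  reporter signal and timepoint plus the biomass channel. SSA sample seeds
  are spawned deterministically from the assay seed.

## Characterization

The fitting objective is trajectory-level nonlinear least squares: the
summed squared difference between observed reporter kinetics and the full
ODE solution of the measured cascade, over every dose, replicate series, and
timepoint. Steady-state shortcuts are deliberately avoided — kinetic tables
carry information about rates even when no dose reaches steady state, and
the trajectory objective uses all of it.

The model trajectories inside the optimizer are computed with an
exponential-trapezoidal integrator on a refined grid (substep ≤ 0.05 h):
each step uses the exact solution for piecewise-constant synthesis and
loss, so the scheme is exact for receiver fits under constant growth and
second-order accurate for time-varying cascades. This keeps a full
8-parameter two-input fit (64-condition grid, 10 restarts) at a few seconds.

Optimization is bounded `scipy.optimize.least_squares` with rates and
switching concentrations parametrized as log10 (they are positive and span
decades) and cooperativities linear in `[0.2, 10]`. Multi-start with 10
restarts (default seed 42): the first start is data-driven (endpoint
responses converted to rate estimates via `γ + μ`, `K` at the geometric
mean of the tested range, `n = 2`), the rest perturb it with log-uniform `K`
over the tested concentration range and `n ~ U[1, 4]`.

Staging: receivers are fitted first on their own auxiliary networks; the
downstream one- or two-input fit holds receiver parameters fixed and
reconstructs the unobserved regulator trajectories from them. Characterizing
a two-input device therefore needs three auxiliary networks — one per
receiver plus the composed cascade. Degradation rates `γ` are inputs, not
fitted: co-estimating `γ` with synthesis rates is degenerate near steady
state, so they are assumed known from independent measurement or literature.

Identifiability is reported per parameter: a cheap response-spread heuristic
(endpoint spread across doses < 5% of its mean ⇒ `K`, `n` unidentifiable)
plus an optional profile-style probe that fixes each parameter at 0.5×/1.5×
of its estimate and refits the rest — if the data are recovered essentially
as well (SSE below `max(4·SSE_best, 1e-6·Σy²)`), the parameter is flagged
non-identifiable.

When no growth profile is supplied, `μ(t)` is reconstructed from the stored
biomass channel: a straight-line fit on log-biomass selects a constant
profile, otherwise a logistic profile is fitted on log-biomass. Measurements
are fitted in concentration space directly; inverting to expression-rate
space first would be an alternative with different noise weighting.

## Datastore

The store is a directory: `manifest.json` (signal registry plus
study → assay → sample metadata: vector/design id, strain, media, supplement
concentrations) and one CSV per assay in the tidy
`assay,sample,signal,time,value` dialect. Floats are written with 17
significant digits and read back with round-trip parsing, so upload/query
preserves values exactly. Queries are conjunctive and exact-match;
re-uploading an existing (study, assay) replaces it with a warning. The
selector vocabulary (study/assay/vector/signal/media/strain/supplement) is
chosen so that a remote measurement service could be swapped in behind the
same interface.

## Exporters

The graph view has operator and product nodes, production edges
(operator → product) and signed regulation edges (regulator → operator,
activation/repression from the parameter ordering); `operators_only=True`
gives the compact view with operators as the only nodes and
regulator-labeled edges. GraphML goes through networkx; DOT is written
directly (it is a trivial text format and avoids an extra dependency).

The SBOL3-style exporter emits the component/interaction/constraint
hierarchy as a JSON document (`"document": "sbol3-json/1"`): one
transcriptional-unit component of type DNA and role engineered-region per
operator (subcomponents kept in a total order by `precedes` constraints,
placeholder parts when no sequences are given), genetic-production
interactions per output, inhibition/stimulation interactions per regulatory
input typed by the sign of the regulated-vs-basal rate comparison (exact
tie: warning, stimulation by default), and exactly one model reference with
source/language/framework fields. The JSON rendering keeps the structure
explicit and machine-checkable (`validate_sbol_doc`) and can be translated
to RDF by SBOL tooling downstream.

## Bundled fixtures and what they show

All test inputs are generated programmatically (`gcda.examples`); there are
no stored datasets.

- **Oscillator** — three operators: a two-input operator that is activated
  by its own product A and repressed by C, plus two activated one-input
  operators relaying A → B → C to close a delayed negative loop; each
  operator also drives a fluorescent reporter. Parameters (chosen once for
  robust limit-cycle behavior, documented in the builder): strong
  cooperative self-activation (`α₁ = 60, K₁ = 12, n₁ = 4`) gated by C
  (`K₂ = 6, n₂ = 4`), basal rate `α₀ = 5` high enough to re-ignite the
  positive loop once C decays, fast A turnover (`γ = 1 /h`) against a slow
  relay (`γ = 0.3 /h`). The resulting cycle has period ≈ 19.6 h and
  constant amplitude; tests assert sustained oscillation and period
  stability, not specific amplitudes, since the parameter set is
  illustrative rather than measured.
- **Characterization fixtures** — receiver devices with
  `(α₀, α₁, K, n) = (0.1, 10, 1, 2)` and `(0.05, 8, 2, 1.5)` and a NOR
  device `(α₀, α₁, α₂, α₃, K₁, K₂, n₁, n₂) = (10, 0.3, 0.3, 0.3, 1, 1, 2, 2)`,
  probed with 8 log-spaced doses per axis (including zero) spanning four
  decades around `K`, 10 h kinetics sampled every 0.5 h.

The generators produce noiseless (or optionally seeded-noise) data from the
same model family that is fitted, under deterministic exponential growth.
Passing recovery tests therefore demonstrates correctness of the inference
machinery — identifiability of the parametrization, convergence of the
multi-start optimization, consistency of simulator and fitter — but not
robustness to model misspecification, calibration error, autofluorescence,
or growth-phase artifacts present in real plate-reader data.

## Numerical conventions and limitations

- Problem sizes in the bundled checks (500–1000 stochastic runs, 8×8 dose
  grids, 200 h oscillator horizon) were chosen as the smallest designs that
  make the statistical assertions sharp (3-standard-error bands, <5%/<10%
  recovery margins).
- SSA ensemble comparisons use per-grid-point 3·SE bands; for nonlinear
  propensities the ensemble mean differs from the ODE by a curvature term
  `~½φ″·Var(r)`, which is kept well below the band by working at ~1000
  copies.
- Degenerate inputs: zero total propensity stops an SSA run (no further
  events are possible for the birth-death system); all-zero kinetic series
  return `α = 0` flagged; empty store queries return an empty, well-formed
  table.
- Known limitations: no mRNA layer, no protein–protein interactions, no
  burden/growth feedback, no delay or spatial models, no stochastic-model
  parametrization (fits are to the deterministic model only), and no unit
  calibration of measurements.
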