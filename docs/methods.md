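# Methods

## Model summary and assumptions

The package simulates a compartmental aggregation–diffusion model of
Alzheimer's disease on a brain parcellation represented as two superposed
weighted graphs. Amyloid-β lives in the extracellular space and therefore
diffuses on the *proximity* graph (nearest-neighbour parcels, weights
decaying with distance); misfolded tau is intraneuronal and diffuses on the
*connectivity* graph (fibre-tract weights). Both graphs share the vertex set
and use the row-normalised Laplacian `Δg(x_m) = (1/π_m) Σ_j (g_m − g_j) w_mj`
with `π_m = Σ_j w_mj > 0` enforced at construction (isolated parcels are
rejected). No symmetric-normalised or unnormalised Laplacian variant is
exposed.

Key structural assumptions, implemented exactly as the model is written:

* **Five compartments.** Polymers of length 1–4 plus a terminal aggregate
  compartment (plaque/tangle) collecting all coalescence products of length
  ≥ 5. The aggregate compartment neither diffuses nor clears; its diffusion
  and clearance coefficients are structurally absent from `ModelParams`
  (vectors of length 4), not merely zero.
* **Asymmetric bookkeeping.** The loss term of soluble species sums over all
  five compartments (aggregates keep consuming soluble material) while the
  aggregate gain only counts soluble pairs; polymer mass is therefore not
  conserved. This is deliberate and kept as printed.
* **No fragmentation, no nucleation, no extracellular tau release/uptake.**
* **Two time scales.** The whole Aβ right-hand side is divided by ε (fast
  physical processes); tau and the health transport evolve on the slow scale.
  The division happens inside `abeta_rhs`, so the integrator sees plain
  derivatives for both species.
* **Tau has no clearance term anywhere**, as printed.
* **Toxicity windows.** The health drift counts Aβ compartments 2–4 but tau
  compartments 1–5, as printed.

## Parameters

Fixed constants (dimensionless): `d_i = d̃_i = σ_i = 1/i` for i = 1..4,
ε = 0.1, γ = 4, λ = 10, Ū = 0.001, C_𝒢 = 0.1, C_S = C_T = 0.01,
Ū_Aβ = Ū_τ = 0.001, C_ℱ = 10, μ₀ = 0.01. The three scenario constants
(α, C_τ, c) have **no silent defaults**: a run must name a case A–E or set
them explicitly, because the model's conclusions hinge on exactly these
three. Case presets: A (10, 0, 0), B (10, 0, 0.05), C (10, 10, 0.05),
D (10, 10, 0), E (0, 10, 0.05).

Two quantities the model leaves open are configuration values, logged with
every run: the horizon `t_end` (default 50 dimensionless time units) and the
initial uniform Aβ monomer level `u01` (default 0.01, satisfying the
"small initial monomer" requirement). The initial health density is a
triangular bump of half-width 3 cells centred at a₀ = 0.01 — a resolvable,
normalised approximation of a Dirac delta near perfect health.

## Discretisation and numerics

* **Malfunction axis.** Uniform finite-volume grid on [0, 1], default
  M = 101 cells, densities stored as cell averages. The transport step is
  first-order conservative upwind, exploiting `v ≥ 0`. All a-integrals
  (production, prion term, mean malfunction) use midpoint quadrature on the
  same grid so every integral shares one convention. The boundary condition
  at a = 1 is honoured through the analytically zero flux there (every term
  of `v` carries a factor vanishing at 1), not by zeroing the last cell, so
  each parcel's probability mass is exactly telescoping: observed drift over
  a full T = 50 run is ~4e-15. Positivity and exact conservation were
  prioritised over order of accuracy; the first-order scheme's numerical
  diffusion does make the final damage index grid-sensitive at the level of
  ~0.01–0.02 on the [0, 1] scale between M = 101 and M = 202 (the physical
  drift is compressive, so essentially all profile spreading is numerical).
* **Time stepping.** Operator splitting per step: (1) freeze the health
  density, evaluate F(f) and v; (2) advance u and τ together by classical
  RK4; (3) advance f by one upwind step with the frozen v. The splitting is
  first-order in dt but its error is far below the spatial error at the
  default step sizes (halving dt moves A(T) by ~0.03%).
* **Adaptive dt.** The Aβ system is stiff through the aggregation loss
  `α u_i Σ u_j`, whose rate grows as plaques accumulate. Each step uses
  `dt = min(1/λ_max, 0.9 Δa / v_bound, time-to-next-sample)` with
  `λ_max = (2 d_max + σ_max + 2 α U_max)/ε` (and the tau-side analogue),
  recomputed every step — a stability-based bound with roughly 2.8×
  margin for the RK4 real-axis stability interval. A step producing
  negativity beyond −1e-12, non-finite values, or a CFL breach is rejected
  and retried at dt/2; negativity within −1e-12 is clamped to zero
  (positivity is a model invariant, not a numerical suggestion). Repeated
  halving below 1e-12 aborts with a diagnostic state summary.
* **Determinism.** Runs are exactly reproducible from the configuration and
  generator seed; exported CSVs are bitwise identical across repeats.

## Synthetic connectomes

The generator emulates the inputs the model needs without claiming
anatomical realism: region centres on a spherical-Fibonacci shell plus a
bilateral "entorhinal" pair on the x-axis; parcels scattered around their
centre (spatially contiguous regions); proximity = k-nearest-neighbour graph
(default k = 4) with 1/distance weights symmetrised by max; connectivity =
dense heavy-tailed (lognormal) intra-region edges plus sparser inter-region
edges decaying with centre distance, with the seed regions coupled 3× more
strongly to their two nearest regions (an amygdala/hippocampus analogue of
strong entorhinal projections). Components are joined through their closest
node pair if needed, so the result is always connected.

What this does *not* emulate: tractography biases, parcel volume
heterogeneity (all read-outs hard-assume equal parcel volumes), hemispheric
asymmetries beyond the seed pair, and any subject-level variability. Tests
passing on these graphs show the dynamics and read-outs are implemented
correctly, not that conclusions transfer to a measured human connectome.

## Behaviour under the default parameterisation

Worth knowing when interpreting output: because the Aβ subsystem is
ε-fast, its oligomer burdens equilibrate quickly and attain their global
maxima in the initial transient (t ≈ 0.2–0.5), before plaque-mediated losses
grow; the Aβ monomer burden instead keeps rising with the damage-enhanced
production factor (μ₀+a)(1−a) and peaks only once mean malfunction reaches
≈ 0.35 (t ≈ 90 on the 64-node study connectome), then declines as the brain
dies. Tau burdens peak at t ≈ 1–3 (driven by the Aβ-oligomer-induced
production), lagging the corresponding Aβ oligomer compartments, and tangle
and damage curves grow monotonically to a plateau. These features were
cross-checked against an independently coded monolithic fine-step
integration (relative L∞ agreement ≤ 1e-3 on every state variable), so they
are properties of the model under these parameters, not artefacts of the
splitting scheme.

## Problem sizes used by the test and acceptance runs

The shipped study configuration is a 64-parcel, 8-region synthetic
connectome with M = 101 malfunction cells and horizon T = 50, which resolves
every qualitative feature of interest (scenario nulls, seed-region
dominance, case-severity ordering, conservation) while keeping a full
five-case campaign to well under a minute of compute. The oracle comparison
runs on a hand-built 3-node connectome with M = 21 and T = 5, where the
deliberately naive reference integrator is affordable.

## Known limitations

* First-order splitting and first-order upwind transport: the damage index
  carries O(Δa) numerical-diffusion bias (see above); a flux-limited or
  second-order scheme is out of scope by design.
* Explicit integration only; at ε ≪ 0.01 or much larger α the adaptive step
  would become impractically small.
* No fitting to patient data and no statistical comparison with biomarkers;
  the model is descriptive.
* Real-connectome input requires parcel coordinates to build the proximity
  graph; a measured proximity graph can be supplied instead by loading it
  directly and calling `simulate`.
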