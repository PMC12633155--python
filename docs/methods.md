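# Methods

## Model structure

`fibrogrid` couples two layers:

1. **Intracellular layer.** Each grid cell holds one copy of a 132-species
   signaling network. Species are normalized activities in [0, 1] — not
   molar concentrations — so every rate constant is in reciprocal
   simulation-time units and "1" means full pathway activation. Dynamics
   follow multiplicative mass-action-style kinetics: each production edge
   contributes `rate × ∏ activators` (several activators on one edge form
   an AND gate), each inhibition edge removes `rate × X × ∏ inhibitors`,
   and every species decays at `k_degradation`. Receptor activation
   (`k_receptor × ligand × R_total`, with the receptor pool normalized to
   R_total = 1 — no synthesis or trafficking is modeled) and kinase
   activation/dephosphorylation are the same algebra with class-specific
   default rates. Input species are special: they integrate the external
   stimulus and the local feedback field,
   `dX/dt = k_input·I + k_feedback·C − k_degradation·X`, and accept no
   regulatory edges.

2. **Extracellular layer.** Four feedback fields (TGFBfb, AngIIfb, IL6fb,
   ET1fb) and twenty ECM fields live on the grid. Each is produced from a
   designated intracellular precursor at `k_production × X_precursor`,
   cleared at λ (default `k_degradation` for feedback, `k_degradation` for
   ECM), and diffuses by the discrete 8-neighborhood operator
   `D Σ_nb (C_nb − C_self)` — all eight neighbors weighted equally, no
   diagonal correction, indices wrapped modulo N (periodic boundaries).
   ECM fields use diffusion coefficient `0.2 × k_diffusion`, hard-wired:
   matrix proteins are large and deposit locally, so they spread at one
   fifth of the feedback-molecule rate. Each feedback field re-enters the
   signaling layer through the input species it `feeds` (TGFBfb → TGFB,
   etc.), closing the autocrine/paracrine loop.

The coupled-variable accounting counts intracellular species and feedback
fields — `(132 + 4)·N²`, i.e. 1.36 million ODEs at N = 100. ECM planes are
outputs driven by that state and are reported separately.

## Tunable parameters

| constant | default | role |
|---|---|---|
| k_input | 1.0 | external stimulus gain on input species |
| k_feedback | 0.5 | feedback-field gain on input species |
| k_degradation | 1.0 | first-order decay of every species and field |
| k_receptor | 2.0 | ligand→receptor production edges |
| k_inhibition | 0.5 | all inhibition edges |
| k_activation | 1.0 | all other production edges |
| k_production | 0.01 | secretion of feedback and ECM fields |
| k_diffusion | 0.25 | feedback-field diffusion (ECM: ×0.2) |

All are strictly positive and act globally; individual edges may carry a
`rate_override`. The defaults make intracellular kinetics fast (time
constant 1), secretion slow (0.01), and the explicit diffusion update
stable: `8 · k_diffusion · dt_max = 0.2 < 1`.

## Reference network topology

The packaged network (`data/reference_network.yaml`) is hand-curated from
the canonical cardiac-fibroblast pathway literature; each edge carries a
one-line mechanistic note. Module census: 10 inputs, 10 receptors, 8 second
messengers, 15 kinases/phosphatases, 12 MAPK components, 8 transcription
factors, 18 mechanotransduction components, 20 ECM precursors, 4 secreted
feedback precursors and 27 adapters/enzymes — 132 species, 209 edges.
Notable wiring choices, made where the design was genuinely open:

- **Stable resting state.** The only intracellular positive-feedback cycles
  run through the mechanotransduction module. Tension generation requires
  active myosin *on* filamentous actin (AND gate on [MLC, Factin]) and
  every F-actin production edge is AND-gated on the G-actin monomer pool,
  which itself requires the calcium→calcineurin→PP1→cofilin branch. All
  feedback cycles are therefore quadratic near the origin: the linearized
  production graph is acyclic, the zero state is asymptotically stable, and
  the noisy initial condition decays in the absence of stimulation instead
  of igniting spontaneously. Sustained stimulation still activates the
  mechanical loop.
- **Input-specific arms.** The inflammatory TAK1/IKK arm is reached only
  through TNF/IL-1 adapters (not from the TGF-β receptor, whose non-Smad
  arms here are PI3K and RhoGEF), and ECM outputs are driven purely by
  transcription factors. TGF-β alone therefore drives Smad3-dependent
  outputs to sub-saturating levels, and combinatorial stimulation (case 3)
  produces visibly enhanced collagen output (~1.3× the case-2 grid mean)
  rather than hitting the [0, 1] clamp identically.
- **Negative feedback.** BAMBI and Smad7 (TGF-β), MKP1 (MAPK), IκB (NF-κB),
  RGS/arrestin (GPCR) and PDE (cAMP) close the classical desensitization
  loops; estrogen receptor β inhibits AT1 signaling, and the NP→cGMP→PKG
  axis suppresses calcium and RhoA, making NP and E2 inhibitory inputs.

## Numerics

- **Integrator.** Clamped forward Euler: derivatives are evaluated on the
  unclamped current state, the update is applied everywhere, then every
  concentration is projected onto [0, 1]. One first-order scheme with a
  bounded state is preferred over higher-order methods because the clamp
  dominates accuracy near the bounds anyway and step cost scales with the
  1.36 M variables.
- **Step control.** `dt = min(dt_max, θ / max|dX/dt|)` with defaults
  dt_max = θ = 0.1, the maximum taken over intracellular, feedback and ECM
  derivatives. Scenario presets use a *fixed* dt = 0.1 so that iteration
  counts map directly onto simulation time (500 iterations = 50 time
  units).
- **Initial conditions.** Intracellular species and ECM planes start at
  independent uniform noise on [0, 0.1] (per species, per cell, seeded);
  secreted feedback pools start empty. The ECM noise makes the iteration-0
  heatmap show the unstructured speckle expected before any dynamics;
  feedback fields are extracellular products and have nothing to start
  from.
- **Ties and degenerate inputs.** Empty brush masks are legal (the inside
  mean of a region summary is then NaN, not an exception); grids below 3×3
  are rejected because the 8-neighborhood would self-overlap under the
  modulo rule; non-finite derivatives abort the step naming the offending
  cell and species.
- **Determinism.** All randomness flows through one seeded generator;
  identical (network, scenario, config, seed) reproduce bit-identical
  trajectories, and the run manifest records the network content hash,
  scenario, rates and seed so outputs are reproducible from it alone.

## Scenario presets

Case 1: empty mask, all inputs 0 — relaxation of the noisy start.
Case 2: X-shaped mask (both full diagonals, width 1), TGFB = 1 inside.
Case 3: same mask, TGFB, AngII, IL6, IL1, TNFa, NE all = 1.
All presets: 500 iterations, dt 0.1, snapshots at 0/100/300/500, two probe
cells (one on the stroke, one off it). Assigned inputs are held constant
for the whole run.

## What the tests show — and what they do not

The test suite checks the engine against independent oracles: a naive
per-cell, per-edge Python reimplementation of one Euler step (agreement to
1e-9 over 20 steps on a 5×5 grid), closed-form fixed points of the input
and receptor kinetics (1e-6), exhaustive neighborhood symmetry, mass
conservation of the diffusion operator (1e-12 per application, 1e-9 over
100 steps), translation equivariance, the clamp invariant under randomized
stepping, and the qualitative spatial claims of the showcase scenarios
(stimulated > ring > far field; case 3 ≥ case 2 ≥ case 1). Scenario tests
run at N = 30 and the acceptance script at N = 100; both sizes give the
same orderings because the statistics are means over hundreds of cells.

These checks validate the *simulator*, not cardiac biology: the network is
a normalized, hand-curated abstraction (no real kinetic rates, no receptor
trafficking, no cell heterogeneity or migration, no mechanical PDE — the
tension feedback is a local intracellular proxy), the grid is 2-D with
periodic boundaries, and concentrations are activity levels rather than
measurable quantities. Passing tests mean the stated equations are solved
correctly and their qualitative spatial consequences hold, not that the
model is quantitatively predictive for tissue.

## Known limitations

- Forward Euler is first-order; accuracy near sharp transients is limited
  by dt_max, and the clamp introduces a (deliberate) non-smoothness.
- The ECM fields do not feed back mechanically; matrix stiffness is not a
  state variable.
- `R_total = 1` ignores receptor down-regulation beyond what arrestin/BAMBI
  edges provide.
- The X-shaped brush thickened beyond width 1 wraps modulo N, which is the
  periodic-domain analogue but differs from a clipped thick stroke.
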