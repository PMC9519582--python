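# Methods

`stromasim` simulates the reciprocal signaling between cancer cells and
cancer-associated fibroblasts (CAFs) across three coupled scales —
intracellular reaction kinetics, diffusive intercellular signaling in a
three-dimensional microenvironment, and force-based single-cell motility —
and provides the estimation machinery (a continuous-discrete unscented
Kalman filter, Morris sensitivity screening, agreement statistics) needed
to fit the intracellular models to sparse expression time courses.

## Intracellular models

Two reaction networks are built from mass-action and saturating
(Michaelis–Menten-type) rate laws:

- **Cancer cell (21 states).** The TGFβ/SMAD arm: receptor production and
  turnover, 2:1 receptor–ligand association (`v3 = k2+ · xu3 · x1²`,
  consuming two receptors and one ligand per complex), SMAD3
  phosphorylation saturating in SMAD3 (`v9 = k5+ · x2 · x3/(x3+Ks1)`),
  pSMAD3–SMAD4 complex formation, nuclear shuttling, and transcription of
  the target genes SMAD7, TGFβ, LIF and CXCR4. SMAD7 feeds back as an
  extra first-order removal of pSMAD3. The CXCL12 arm — CXCL12·CXCR4
  binding, PI3K/Akt activation, NFκB nuclear entry, IκB feedback and MMP
  synthesis/secretion — is reconstructed in the same rate-law style
  (every such reaction carries `provenance: reconstructed` in the
  serialized definition). External inputs: CAF-derived TGFβ (`xu3`) and
  CXCL12 (`xu4`).
- **CAF (26 states).** A TGFβ/SMAD mirror of the cancer arm (target genes
  here: SMAD7, TGFβ, CXCL12, autocrine LIF), the LIF→JAK/STAT cascade
  with SOCS3/SHP1 negative feedback and STAT acetylation, and the
  pSMAD3–pSTAT crosstalk complex whose nuclear form drives SNAIL. Both
  printed LIF association routes (paracrine ligand and autocrine ligand)
  are present, including their shared reaction label `w3`. Two species
  beyond those directly inferable from the published tables are needed to
  reach the stated 26-state dimension; we chose the autocrine
  TGFβ·receptor complex (`x23`, resolving the autocrine binding route
  into its own pool) and a secreted SNAIL pool (`x24`), which is what the
  microenvironment SNAIL field physically transports. Both are flagged
  `reconstructed`; this is a documented reconstruction, not an assertion
  about the original supplementary listing.

Inhibitory table rows ("inhibitory effect of A on B") are realized as
extra first-order removal fluxes of the inhibited species with rate
proportional to the inhibitor — the minimal-assumption reading of those
rows. Production rows proportional to the produced species are kept
exactly as printed; a `constitutive_production` rewrite was considered
and rejected as a default (fidelity first).

**Units.** Concentrations are arbitrary units (a.u.); time is hours.
Nonnegativity is enforced by evaluating rates at `max(x, 0)` and flooring
trajectory values whose magnitude is below 1e-12.

**Default kinetics.** No calibrated constants are available, so defaults
are placeholders meant to be re-estimated. They are tiered rather than
uniform: pool species (receptors, SMAD3/4, JAK, STAT, …) get production
slightly above degradation (0.13 vs 0.10 h⁻¹), enzymatic gains are
0.3, nuclear import 0.5, dissociation/export 0.05, target-gene synthesis
0.3 against 0.05 decay, inhibitory removals 0.01, and half-constants
1 a.u. The tiering matters: nuclear-complex degradation permanently
removes SMAD3/SMAD4 moieties, and because the printed production terms
are proportional to their own species they cannot refill an empty pool —
with uniform constants every pool drains and all observables decay.
With the tiered defaults a 72 h simulation under constant unit paracrine
drive yields finite nonnegative trajectories in which SMAD7, TGFβ, LIF
and CXCL12 all exceed their baseline by 48 h, the qualitative shape of
measured 0/24/48/72 h expression profiles. The defaults are versioned in
`cell_models.CANCER_DEFAULTS` / `CAF_DEFAULTS` and shipped with the YAML
network definitions under `stromasim/data/`.

**Observable map.** Measured genes map to species as SMAD7→`x8`,
TGFβ→secreted TGFβ, LIF→LIF (cancer: secreted `xu2`; CAF: autocrine
`x9`), CXCL12→`xu4` in the CAF. The cancer model contains no CXCL12
species — CXCL12 is an input there — so its CXCL12 readout is the
receptor-axis target gene CXCR4 (`x9`). Observations are fold changes
(value(t)/value(0)).

## Estimation

**Filter.** Joint state/parameter estimation uses a continuous-discrete
unscented Kalman filter: the state vector is augmented with the free
parameters on log scale (positivity by construction, random-walk process
noise), sigma points are propagated through the full nonlinear ODE
between measurement times, and a standard scaled-unscented correction is
applied at each sample. Defaults: α=1e-3, β=2, κ=0; process noise 1e-6
(states) and 1e-4 (log-parameters); measurement noise from the stated
observation noise; initial variances 1e-2 (states) and 0.25
(log-parameters, ≈ a factor-of-1.6 one-sigma prior). Because a 4-point
course carries little information per pass, the filter is iterated
(default 10 passes): states restart from the initial condition, the
parameter mean and covariance carry over. Covariances are symmetrized
and eigenvalue-floored at 1e-12 after every correction. A sigma point
whose integration fails is replaced by the prior mean with a logged
warning; estimation aborts only if all points fail.

On a linear-Gaussian system the filter reproduces the exactly
discretized Kalman filter (to the ODE-solver tolerance), and on
synthetic 4-point fold-change data with 5% multiplicative noise it
recovers five perturbed transcription/decay constants of the cancer
model with a median relative error of a few percent (tested against a
25% bound).

**Sensitivity.** Morris elementary-effects screening is implemented
directly: r trajectories, each starting from a random point on a
`levels`-level grid of the unit hypercube and perturbing one parameter
at a time by a fixed fraction `delta` of its range; elementary effects
are computed against the physical step, so for a linear response μ
equals the coefficient exactly and σ is zero. μ* (mean magnitude) is
reported alongside μ and σ. Non-finite model outputs drop the
trajectory with a warning.

**Agreement statistics.** Goodness of fit (R², RMSE, MAE) and
Bland–Altman bias with 1.96·sd limits of agreement, both over paired
vectors of model outputs and observations.

## Microenvironment

The domain is a ball of radius 2 cm discretized on a regular Cartesian
grid (default 33³ nodes) with a sphere mask. Each signal field (cancer
TGFβ, cancer LIF, CAF TGFβ, CXCL12, SNAIL, MMP) obeys
`∂u/∂t = D Δu − decay·u` with an explicit 7-point finite-difference
scheme; the stability bound `D·dt/h² ≤ 1/6` is enforced, with automatic
sub-stepping. The Dirichlet boundary value (default 0, an absorbing far
field) is held on the ghost layer of *outside* nodes adjacent to the
ball, so every inside node evolves. This placement was chosen
deliberately: pinning the innermost layer instead shrinks the effective
radius by about one grid spacing and biases the fundamental-mode decay
rate by ≈+6% at 33³, whereas the ghost-layer form measures within
−2.4% of the analytic rate Dπ²/R². A finite-difference grid replaces
the unstructured finite-element mesh a production PDE solver would use;
on this geometry the two agree in the mesh-refinement limit, and the
regular grid is directly testable against analytic ball eigenmodes.

Cells couple to fields in three ways: **uptake** — the surface integral
of a field over the cell sphere, computed from 26 symmetric quadrature
directions with equal area weights (exact for uniform fields; odd/linear
variation cancels by symmetry); **secretion** — point-source deposition
of `rate·dt` field mass onto the 8 surrounding nodes with trilinear
weights (mass-conserving to machine precision); and the **ECM** update
`ECM += dt·(a1·ECM − a2·MMP·ECM)`, floored at zero, sub-stepped within a
macro-step. The sink term of the transport equation is realized as
first-order decay plus removal of the uptaken amount scaled by an
uptake efficiency; both contributions are independently configurable.
Default diffusivities (≈3.6e-3 cm²/h, i.e. 1e-6 cm²/s) are
order-of-magnitude placeholders for cytokine transport in tissue and are
flagged as such in the configuration.

## Cell behavior and mechanics

Cancer cells (radius 8 µm) carry a three-state machine evaluated from
surface signal levels; CAFs (radius 7 µm) are static sources/sinks.
The decision order is migration first: a cell turns **migratory** when
surface SNAIL ≥ T_SNAIL *and* local ECM ≤ T_ECM (EMT plus detachment),
otherwise **proliferative** when surface CXCL12 ≥ T_CXCL12, otherwise
**quiescent**. Migration-first precedence reflects that migration is the
terminal phenotype of interest; the monotonicity property (raising SNAIL
never demotes a migratory cell) is tested. Proliferative cells divide at
most once per 24 h, placing a quiescent daughter one radius away in a
uniformly random direction.

Forces between cell pairs: Hertz repulsion `(4/3)·Ê·√R̂·δ^{3/2}` for
overlap δ > 0 with pair effective radius `R̂ = RiRj/(Ri+Rj)`, and a
constant-magnitude central adhesion `πWR̂` active within 2 µm beyond
contact. Environment forces on migratory cells: haptotaxis `−χ∇[ECM]`
implemented with the printed sign (down-gradient for χ > 0; the sign can
be flipped in configuration to explore the conventional up-gradient
reading), and an active force `η·Aⁿ/(Aⁿ+A₀ⁿ)·n̂` gated by surface SNAIL.
The active direction n̂ is not specified by the biology alone; the
default is outward from the tumor centroid (invasion), with a
down-ECM-gradient option. Motion is overdamped: `V = ΣF/Γ_cs`, and only
migratory cancer cells move.

## The macro-loop

Each macro-step (default 7.2 h, so ten steps span a 72 h experiment)
executes: intracellular chemistry with uptake-derived inputs → secretion
deposits and uptake removal → field diffusion → ECM update → state
decisions → divisions → mechanics → carry-over. Two clocks coexist:
the biological macro-step and a fast mechanical clock (default 24
relaxations per macro-step) on which contact forces are re-resolved so
that division-induced overlaps relax without overshoot; environment
forces are held fixed within a macro-step because the fields are. Any
stage failure rolls the state back to step entry.

Initialization places 20 cancer cells and 20 CAFs (defaults) uniformly
in the sphere by rejection sampling with at most 50% radial overlap; all
cancer cells start quiescent; fields start at configured constants (ECM
at 1, signals at 0). Runs are fully reproducible: the RNG stream is part
of the serialized state, identical config+seed gives byte-identical
outputs, and a serialized state resumes bit-identically.

With default thresholds (T_CXCL12 = 0.05, T_SNAIL = 0.01, T_ECM = 0.5
a.u.) the loop reproduces the expected invasion sequence: cells first
turn proliferative where CXCL12 accumulates (population grows), MMP
degrades the ECM locally, and once ECM falls below threshold cells with
sufficient SNAIL detach and migrate outward, giving a strictly
increasing mean displacement at 24/48/72 h of the same order
(hundredths to tenths of a millimeter) as wound-scratch measurements.
Matching specific published displacement values would require the
original calibrated constants and thresholds, which are not public; the
trend, not the numbers, is the validated surface.

## Problem sizes and limitations

Tests and the acceptance script run at desk scale: 33³ (diffusion
accuracy, default runs) or 17³ grids (loop tests), 12–46 cells, 10
macro-steps, 4-point time courses, 5 free parameters. The synthetic
time courses emulate ratio-scaled expression data with multiplicative
log-normal noise (sd 5%) anchored at fold change 1; they do not emulate
probe-level microarray structure, batch effects, or biological
replication, so passing recovery tests demonstrates correctness of the
estimator under the stated noise model, not robustness to real
platform artifacts. Other known limitations: no cell death or CAF
motility; no contact inhibition; adhesion is a constant-magnitude
approximation of the printed scalar law; the explicit diffusion scheme
is first-order in time; and the intracellular defaults are qualitative
placeholders, not fitted biology.
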