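# stromasim

Multiscale simulation of tumor–stromal interaction: how cancer-associated
fibroblasts (CAFs) drive cancer cells toward proliferation and invasion
through TGFβ, LIF and CXCL12 signaling.

Metastasis begins when cancer cells inside a primary tumor switch
phenotype: paracrine signals from CAFs activate intracellular cascades
(TGFβ/SMAD, CXCL12→PI3K/Akt→NFκB→MMP in the cancer cell; TGFβ/SMAD and
LIF→JAK/STAT with SMAD3–STAT crosstalk driving SNAIL in the CAF),
secreted MMPs degrade the extracellular matrix (ECM), and cells whose
SNAIL exposure is high while their local ECM is degraded detach and
migrate. `stromasim` implements this as three coupled layers, for
computational biologists who want a tested, reproducible sandbox for
tumor–stroma signaling hypotheses:

1. **Intracellular** — two nonlinear ODE networks (21 states for the
   cancer cell, 26 for the CAF) built from mass-action and saturating
   rate laws, e.g. receptor binding `v3 = k2+ · xu3 · x1²` and SMAD3
   phosphorylation `v9 = k5+ · x2 · x3/(x3 + Ks1)`.
2. **Intercellular** — reaction–diffusion fields
   `∂u/∂t = D Δu − f(u)` for each circulating signal (TGFβ, LIF,
   CXCL12, SNAIL, MMP) on a 2 cm spherical microenvironment with
   Dirichlet boundaries, coupled to cells through surface integrals
   `ū = ∫_A u ds` (uptake) and point-source secretion, plus ECM dynamics
   `d[ECM]/dt = a1[ECM] − a2[MMP][ECM]`.
3. **Population** — a per-cell state machine
   (quiescent / proliferative / migratory) and overdamped center-based
   mechanics `F^rep + F^adh + F^hap + F^act = Γ^cs V` with Hertz contact
   `F^rep = (4/3)Ê√R̂ δ^{3/2}`, constant adhesion `πWR̂`, haptotaxis
   `−χ∇[ECM]` and a SNAIL-gated active force `η Aⁿ/(Aⁿ+A₀ⁿ) n̂`.

Unknown kinetic constants are estimated from 4-point expression time
courses (fold changes of SMAD7, TGFβ, LIF, CXCL12 at 0/24/48/72 h) with
a continuous-discrete **unscented Kalman filter** over the state vector
augmented with log-parameters, and screened with **Morris elementary
effects**. A synthetic-data module generates every input the pipeline
needs, so everything runs and tests offline.

## Worked example: recover kinetics from a noisy time course

```python
from stromasim import build_cancer_cell_network
from stromasim.estimation import FilterConfig, hukf_estimate
from stromasim.synthetic_data import generate_timecourse, perturbed_truth

spec = build_cancer_cell_network()
obs = generate_timecourse(spec, noise_sd=0.05, seed=7)   # 4-point fold changes
print(obs.values.round(3))

free = ["k8p", "k8m", "k9p", "k10p", "k11p"]             # target-gene kinetics
start = perturbed_truth(spec, free, (0.5, 2.0), seed=11) # off by up to 2x
cfg = FilterConfig(free_parameters=free, measurement_noise=0.05**2,
                   ode_rtol=1e-6, ode_atol=1e-9)
result = hukf_estimate(spec, obs.values, cfg, initial_parameters=start)
for name, value in result.estimated_parameters.items():
    print(f"{name}: {value:.4f} (true {spec.network.parameters[name]})")
print(result.fit_statistics.round(3))
```

Output:

```
        0.0    24.0   48.0   72.0
SMAD7    1.0  1.469  2.457  1.777
TGFb     1.0  1.167  2.164  1.585
LIF      1.0  1.403  2.552  1.891
CXCL12   1.0  1.083  1.918  1.633
k8p: 0.3555 (true 0.3)
k8m: 0.0616 (true 0.05)
k9p: 0.3069 (true 0.3)
k10p: 0.3073 (true 0.3)
k11p: 0.3063 (true 0.3)
           R2   RMSE    MAE
SMAD7   0.993  0.043  0.036
TGFb    0.980  0.064  0.052
LIF     0.995  0.040  0.026
CXCL12  0.986  0.045  0.036
```

The observation table is the simulated fold-change course with 5%
multiplicative noise; all five rate constants return to within ~20% of
truth from starting guesses up to a factor of two off, and the refitted
model explains ≥98% of the variance per gene.

## Worked example: a 72-hour multiscale run

```bash
stromasim simulate --seed 1 --out runs/demo
stromasim report --run runs/demo
```

```
run complete: 46 cells, final mean displacement 0.388 mm -> runs/demo
seed 1  config 2f047c2ffb3098f4  version 0.1.0
steps: 10  final cells: 46
state
migratory    26
quiescent    20
mean displacement (mm):
       mean_displacement_mm
hours
0.0                0.000000
7.2                0.000000
14.4               0.000000
21.6               0.022939
28.8               0.061598
36.0               0.123653
43.2               0.170312
50.4               0.222354
57.6               0.276797
64.8               0.332350
72.0               0.388432
```

Starting from 20 quiescent cancer cells and 20 CAFs placed randomly in
the 2 cm sphere, CXCL12 accumulation first makes cells proliferative
(40 → 46 cells), secreted MMP degrades the ECM, and cells with high
surface SNAIL over degraded ECM switch to migratory and move outward —
the mean displacement of the founder cancer cells grows monotonically to
≈0.39 mm at 72 h, the same order as wound-scratch migration assays.
`init-config` prints every tunable default; `list-reactions` shows both
reaction tables with per-row provenance; `estimate` and `sensitivity`
expose the filter and the Morris screen.

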