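# nacsim

Mechanistic simulation of triple-negative breast cancer (TNBC) response to
neoadjuvant chemotherapy (NAC), with a global variance-based sensitivity
analysis that identifies the model parameters a clinician would actually
need to calibrate per patient.

## Who this is for

Computational oncology groups building imaging-informed tumor forecasts:
the package provides the full forward model (growth, mechanics, drug
pharmacokinetics/pharmacodynamics), the Saltelli/Jansen total-effects
machinery to rank its parameters, and the original-vs-reduced model
comparison that justifies calibrating only the dominant ones. Everything
runs on self-contained synthetic tissue boxes, so no imaging data are
required; user-supplied cellularity/perfusion volumes (NIfTI) drop in the
same way.

## The model

Tumor cell density N(x, t) on a box of breast tissue evolves by
mechanically constrained reaction–diffusion,

    ∂N/∂t = ∇·(D ∇N) + ρ N (1 − N/θ),    ∇N·n = 0 on ∂Ω,
    D = D₀ exp(−γ_N σ_v),

where σ_v is the von Mises stress of the quasistatic linear-elastic
equilibrium driven by the growth eigenstress −g_N (N/θ) I under Winkler
(elastic-foundation) boundaries σn = −k_w u. Treatment enters through the
net proliferation rate ρ(x, t), given by the normalized two-drug MuSyC
dose–response surface (Hill exponents h₁, h₂; normalized maximal effects
Ê₁, Ê₂; synergy of potency α₁, α₂; synergy of efficacy β) evaluated at
normalized, perfusion-weighted bolus-decay drug concentrations

    d̂ᵢ(x, t) = Σⱼ d̂_{m,i} p(x) e^{−γᵢ(t−t_{ij})} H(t−t_{ij}).

Two standard regimens are built in: doxorubicin + cyclophosphamide (four
2-week cycles, T = 56 d) and weekly paclitaxel + 3-weekly carboplatin
(four 3-week cycles, T = 84 d). The sensitivity analysis ranks the 15
parameters (D₀, ρ₀, h₁, h₂, C₁, C₂, Ê₁, Ê₂, α₁, α₂, β, d̂_{m,1}, d̂_{m,2},
γ₁, γ₂) by their total-effects index S_T on end-of-treatment tumor volume
V_T and total cell count N_T; parameters with S_T > 0.1 define the reduced
model. See `docs/methods.md` for formulas, numerics and assumptions.

## Worked example

```python
import numpy as np
from nacsim import make_grid, synth_scenario, run_sa, reduced_model_comparison

grid = make_grid((16, 16, 16), (2.0, 2.0, 2.0))          # 32 mm tissue box
scenario = synth_scenario(grid, tumor_radius_mm=8.0,
                          peak_density_fraction=0.6,
                          perfusion="well", smooth_mm=2.0, seed=1)

sa = run_sa(scenario, "dox_cyc", n_s=128, seed=42)       # 2176 simulations
print(sa.indices_frame()[sa.indices_frame().influential])
```

which prints (S_T at the end of treatment, 95% bootstrap CIs):

```
qoi parameter       ST    ci_lo    ci_hi  influential
 VT      rho0 0.539708 0.414200 0.696200         True
 VT       E1n 0.686903 0.368000 1.126800         True
 VT        a1 0.121995 0.014000 0.300200         True
 VT       dm1 0.188778 0.116500 0.288000         True
 NT      rho0 0.514328 0.347300 0.739500         True
 NT       E1n 0.857448 0.421800 1.510500         True
 NT        a1 0.171063 0.009800 0.450500         True
 NT       dm1 0.174337 0.111000 0.256500         True
```

The response to this regimen is dominated by the baseline proliferation
rate ρ₀, the doxorubicin effect Ê₁ and concentration d̂_{m,1} — the drug-1
synergy of potency α₁ hovers at the 0.1 influence threshold (its CI spans
it widely), the known borderline case at this sample size. Fixing all
other parameters at their range midpoints and re-running both models on
the 256 sampled parameter combinations:

```python
rows = np.vstack([sa.A, sa.B])
originals = (np.concatenate([sa.YA[0, -1], sa.YB[0, -1]]),
             np.concatenate([sa.YA[1, -1], sa.YB[1, -1]]),
             np.concatenate([sa.final_A, sa.final_B]))
report = reduced_model_comparison(scenario, "dox_cyc",
                                  sa.influential_union(), rows,
                                  originals=originals)
print(report.correlations())
```

```
{'VT_pcc': 0.935, 'VT_ccc': 0.931, 'NT_pcc': 0.952, 'NT_ccc': 0.949,
 'MRD_pcc': 0.951, 'MRD_ccc': 0.948}
```

i.e. the reduced model reproduces the original model's end-of-treatment
tumor volumes, cell counts and density-map heterogeneity (MRD against the
no-treatment reference) with correlations above 0.93 across the whole
sampled parameter space — the practical justification for calibrating only
the dominant parameters per patient.

The same pipeline is scriptable from the shell:

```
nacsim scenario-make --perfusion poor --seed 1 --out scen/
nacsim sa-run --config examples/dox_well.yaml --out sa.h5
nacsim sa-indices --sa-file sa.h5 --out st.csv
nacsim sa-compare-reduced --config examples/dox_well.yaml --sa-file sa.h5
```

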