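# Methods

`nacsim` simulates the response of a triple-negative breast tumor to
neoadjuvant chemotherapy (NAC) with a mechanically coupled
reaction–diffusion model whose proliferation term is modulated by an
explicit two-drug pharmacodynamic surface, and identifies the parameters
that drive the predicted response with a global variance-based sensitivity
analysis. This note records the model, its assumptions, the numerical
choices, and what the synthetic scenarios do and do not represent.

## Tumor dynamics

The tumor cell density N(x, t) (cells/mm³) on a box Ω of breast tissue
obeys

    ∂N/∂t = ∇·(D ∇N) + ρ N (1 − N/θ),    ∇N·n = 0 on ∂Ω,

with carrying capacity θ = 2.02·10⁶ cells/mm³. The zero-flux boundary
assumes the box is large enough to contain the dynamics; the scenario
generator enforces a ring of healthy tissue around the initial tumor so
this holds for the admissible parameter ranges.

## Mechanical coupling

Tumor growth deforms the host tissue (the tumor mass effect); the
resulting stress inhibits cell mobility:

    D(x, t) = D₀ exp(−γ_N σ_v(x, t)),

where σ_v is the von Mises stress of the quasistatic equilibrium

    ∇·σ = 0,    σ = λ(∇·u)I + μ(∇u + ∇uᵀ) − g_N (N/θ) I,

with Winkler (elastic-foundation) boundary conditions σn = −k_w u on all
six box faces, representing the restraint of surrounding tissue. The
material is homogeneous isotropic linear elastic (E = 3 kPa, ν = 0.45, an
average over fibroglandular and adipose tissue); the fixed constants are
γ_N = 2.5 kPa⁻¹, g_N = 5 kPa, k_w = 0.20 kPa/mm. The operator accepts the
homogeneous constants only, but the assembly is written per-element so
per-voxel Lamé maps are a small extension.

## Pharmacodynamics and pharmacokinetics

The net proliferation rate under a two-drug regimen follows the MuSyC
dose–response surface in normalized form: concentrations are normalized by
each drug's half-maximal effective concentration (d̂ᵢ = dᵢ/Cᵢ) and maximal
effects by the drug-free proliferation rate (Êᵢ = Eᵢ/ρ₀):

    ρ = ρ₀ · (g₀ + g₁ d̂₁^h₁ Ê₁ + g₂ d̂₂^h₂ Ê₂ + g₃ d̂₁^h₁ d̂₂^h₂ Ê₃)
            / (g₀ + g₁ d̂₁^h₁ + g₂ d̂₂^h₂ + g₃ d̂₁^h₁ d̂₂^h₂),

with Ê₃ = (1+β)·min(Ê₁, Ê₂) − β and prefactors g₀…g₃ that carry the
un-normalized Cᵢ^hᵢ terms and the synergy-of-potency coefficients α₁, α₂
exactly as in the original MuSyC formulation. We implement the prefactors
verbatim, including their mixed use of normalized concentrations and
un-normalized Cᵢ; whether that C-dependence was meant to cancel is left
open, since the drug-free and single-drug reductions are unaffected.
Ê₃ is not clamped to the single-drug effect range. When the drugs are in
detailed balance (α₂^h₁ = α₁^h₂) the prefactors collapse and the surface
reduces to a four-term rational form (`musyc_rho_db`); the equivalence is
exercised in tests at 1e−10 relative tolerance.

Numerical evaluation: with h up to 25 and C₂ up to 1.6·10³ μM, elementary
terms span hundreds of orders of magnitude. All 16 denominator terms are
therefore evaluated in log space and rescaled by the largest one before
exponentiation; the common scale cancels exactly in the ratio. Powers d̂^h
at d̂ = 0 are defined as 0 (continuous extension). A transcription of the
printed formulas in 80-bit extended precision serves as the double-entry
oracle in the test suite.

Pharmacokinetics: each dose is an instantaneous bolus with exponential
terminal decay, weighted by the static normalized perfusion map p(x):

    d̂ᵢ(x, t) = Σⱼ d̂_{m,i} p(x) exp(−γᵢ(t − t_{ij})) H(t − t_{ij}),

with H(0) = 1 — a dose counts from its delivery instant, so the
delivery-day solver step already sees drug. Concentrations are evaluated
lazily at solver times (never stored as a 4-D array). The two standard
regimens are doxorubicin + cyclophosphamide (both drugs on days 0, 14, 28,
42; T = 56 d) and paclitaxel + carboplatin (paclitaxel weekly on days
0, 7, …, 77 — twelve doses, the last on day 77, a documented reading of
"weekly over four 3-week cycles" — carboplatin on days 0, 21, 42, 63;
T = 84 d).

## Discretization and solvers

Space: the voxel raster of the scenario is the computational grid. The
tumor equation uses a second-order finite-volume stencil with arithmetic
face averaging of D and zero-flux faces; the discrete operator conserves
total mass exactly. Mechanics uses trilinear (Q1) hexahedral finite
elements on the same lattice with 2×2×2 Gauss quadrature; the Winkler
condition enters as a boundary mass matrix. Both discretizations are
second-order accurate, verified by self-convergence triplets in the test
suite. Stress is recovered at nodes from second-order displacement
gradients (one-sided at faces).

Time: backward Euler with a constant step of 0.25 days. Each implicit step
is solved by Newton iteration to a relative residual of 1e−8 (at most 20
iterations); the Jacobian systems are symmetric positive definite and
strongly diagonally dominant (off-diagonal/diagonal ratio ≈ 6·D·dt/h² ≤
0.04 over the admissible D₀ range), so Jacobi sweeps with inner relative
tolerance 1e−4 converge in a handful of iterations and each Newton update
contracts the residual by about that factor. ρ(x, t) is evaluated at the
target time level of each step and frozen within it; at dt = 0.25 d the
splitting error is subdominant to the first-order time discretization.
Negative undershoots smaller than 1e−10·θ are zeroed; anything larger is
reported as a numerical failure rather than silently clipped.

Staggering: mechanical equilibrium is re-solved every `mech_every` = 4
steps starting at t = 0 (i.e. daily), and D is frozen in between. The
elasticity operator is constant for a given grid and material, so it is
assembled once, ordered by a hand-rolled nested dissection of the node
lattice, and LU-factorized once per campaign. The public
`solve_equilibrium` path solves in double precision (residual ~1e−12).
The campaign path factorizes in single precision and applies a blocked
triangular solve that streams the factor once across a whole chunk of
runs; its relative residual (~1e−6) is stated here as the campaign
linear-solver tolerance — it sits three orders of magnitude below the
spatial discretization error of the stress field it feeds, and the two
paths are compared directly in the test suite.

Campaign batching: a sensitivity-analysis design is advanced in lockstep
chunks (default 256 runs). Every run is advanced by strictly independent
arithmetic (per-run Newton loops, per-run convergence tests), so batched
and solo executions are bitwise identical and results are invariant to how
a campaign is chunked or ordered. The solver contains no randomness.

## Quantities of interest

Tumor volume V_T(t) counts voxels with N ≥ N_th = θ/4 times the voxel
volume (ties count as tumor, matching the H(0) = 1 convention); total cell
count N_T(t) is the midpoint-quadrature integral of N. The mean relative
difference of a density map against the fixed no-treatment reference
(D₀ = 2·10⁻⁴ mm²/day, ρ₀ = 2.5·10⁻² 1/day, same scenario) is averaged
over the reference tumor region above N_th. Agreement between paired
outcome vectors is summarized by the Pearson correlation and Lin's
concordance correlation (population moments).

## Sensitivity analysis

Fifteen parameters are analyzed: D₀, ρ₀, h₁, h₂, C₁, C₂, Ê₁, Ê₂, α₁, α₂,
β, d̂_{m,1}, d̂_{m,2}, γ₁, γ₂, with regimen-specific ranges; parameters
spanning orders of magnitude are sampled log-uniformly and Ê₁, Ê₂, β, γ₁,
γ₂ uniformly. Two Latin-hypercube matrices A and B (n_s rows) and the 15
column-swap matrices A_B^(i) give n_s(n_p+2) model runs. The total-effects
index of parameter i on outcome Y at time t is the Jansen estimator

    S_T,i(t) = Σⱼ (Y_A,j − Y_AB,j^(i))² / (2 n_s Var(Y_A ∪ Y_B)),

with the variance taken over the pooled 2·n_s values using the population
(1/2n_s) normalization — the pooled-variance convention is a documented
choice. A parameter is influential when S_T,i(T) > ε_s = 0.1 for either
outcome. 95% confidence intervals at t = T use a paired percentile
bootstrap (1000 resamples of the row index, jointly across Y_A, Y_B and
Y_AB — "paired percentile" being the standard reading of resampling the
values). S_T(t) is computed at every stored time (daily stride by default)
for both V_T and N_T. Estimator correctness is pinned against closed-form
total indices of an additive linear model and the Ishigami function, and
against an independent transcription of the estimator at 1e−12.

Campaigns are chunked, and each chunk can be checkpointed to disk and
resumed bitwise-identically; a failed run aborts the analysis rather than
being imputed.

The reduced model fixes all non-influential parameters at their range
midpoints (geometric midpoint for log-sampled rows, arithmetic otherwise —
a configurable default) and varies only the influential ones. The
comparison re-runs both models on rows of A and B and correlates the
paired V_T(T), N_T(T) and MRD(T) values.

## Synthetic scenarios

The study's tumors come from patient DW-/DCE-MRI; this package replaces
them with parametric stand-ins so campaigns are self-contained: an
ellipsoidal tumor (default radius 8 mm, initial peak density 0.6·θ — a
mid-range cellularity) smoothed by a 2 mm Gaussian inside a 32 mm box,
with at least two voxels of healthy margin, and a perfusion plateau of
0.9 carrying small seeded spatial noise (amplitude 0.02), suppressed to
0.2 in the tumor core for the poorly perfused case. The plateau and core
values straddle the normalized dynamic-contrast range of well- and
poorly-perfused tumors. Perfusion is static over the simulated regimen — a
standing assumption of the model, not just of the generator.

What the stand-in preserves: the well-vs-poor perfusion contrast, the
healthy margin, realistic tumor volume (~2.1 cc) and cell count (~2.6·10⁹)
scales. What it does not: patient anatomy, heterogeneous tissue
mechanics, irregular tumor shape, and the spatial correlation structure of
measured cellularity maps. Passing the scaled-down campaigns therefore
demonstrates that the analysis machinery reproduces the model's dominant
mechanisms under controlled perfusion conditions; it does not validate
patient-specific predictions.

## Problem sizes used by the shipped analyses

The reference campaigns in the test suite and the acceptance script run on
the 16³ well-perfused box with n_s = 128 rows per sample matrix (2176
simulations per regimen) and 200 A/B rows for the original-vs-reduced
comparison — a deliberate scale-down of the full study design (n_s = 1000
on MRI-derived boxes) chosen so a complete campaign runs on a single CPU
in minutes while leaving the estimator and model code identical. At this
scale the total-effects estimates carry Monte-Carlo noise of a few
hundredths, which is why influence classification is assessed against the
ε_s = 0.1 threshold rather than by exact index values.

## Known limitations

* Backward Euler is first-order in time; the 0.25-day step keeps temporal
  error well below spatial error at the default resolution, but stiff
  parameter corners (large ρ₀·Ê products) rely on the implicit solver's
  robustness rather than accuracy.
* The single-precision campaign path for mechanics trades ~1e−6 linear
  residuals for a large speedup; analyses needing machine-precision stress
  fields should call `solve_equilibrium` directly.
* No angiogenesis, chemoresistant subpopulations, poroelasticity, or
  mechanics–proliferation coupling; parameters are global scalars, not
  spatial maps.
* First-order Sobol indices are not computed (total effects only), and the
  analysis is deterministic, not Bayesian.
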