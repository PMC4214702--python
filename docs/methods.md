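# Methods

## Scope and model

`il35sim` simulates a continuum model of the tumor microenvironment built
around one question: how much does tumor-derived IL-35 accelerate tumor
growth, and how much can an anti-IL-35 agent claw back?  Ten fields evolve
by reaction–diffusion–chemotaxis inside a fixed sphere of radius R under
radial symmetry: tumor cells (c), M-CSF (q), MDSCs (M), IL-35 (ρ),
regulatory T cells (R), TGF-β (β), activated CD8⁺ T cells (T), VEGF (h),
endothelial cells (e), and oxygen (w).

The causal skeleton: tumor cells secrete M-CSF, which recruits and
polarizes MDSCs; IL-35 (from tumor cells, Tregs, and MDSCs) further boosts
MDSC production; MDSCs promote Tregs and suppress CD8⁺ T-cell activation
(their IL-10, IL-12, and MCP-1 intermediates are lumped into MDSC-dependent
terms rather than carried as separate fields); tumor cells and MDSCs secrete
VEGF, most strongly under mild hypoxia, which draws in and multiplies
endothelial cells; endothelial cells deliver oxygen, which gates tumor
proliferation and necrosis.  The two study arms differ in a single
constant: the tumor-cell IL-35 production rate `lambda_rho_c`
(`J558-IL-35` high, `J558-Ctrl` fifty-fold lower).

The local balances are listed in the `il35sim.kinetics` module docstring;
transport and boundary handling in `il35sim.radial_pde`.

### Functional forms

* **Oxygen switches.**  Proliferation is off below the extreme-hypoxia
  bound `w_hyp`, ramps linearly to 1 at the normal level `w_normal`;
  necrosis is maximal below `w_nec` and ramps to 0 at `w_hyp`.  The two
  ramps share the breakpoint `w_hyp`, so the intervals
  [0, w_nec), [w_nec, w_hyp), [w_hyp, w_normal) are exactly the necrotic,
  extremely hypoxic, and intermediate hypoxic states.  An optional C¹
  smoothstep (`smooth` parameter, default off) rounds the corners for
  stiff integrators; all shipped results use the piecewise form.
* **Hypoxic VEGF factor.**  `G(w) = (w/w*) exp(1 − w/w*)`: zero in dead
  tissue, maximal exactly at the mild-hypoxia level `w*`, decaying toward
  normoxia, so G(w_normal) < G(w*) = 1.
* **EC proliferation.**  Thresholded saturation
  `(h − h*)₊ / (K_h + (h − h*)₊)` times a logistic factor `(1 − e/e_max)`:
  VEGF only drives angiogenesis above the threshold h*.
* **CD8⁺ suppression.**  The reciprocal factor `1/(1 + k₁₀M·M/K_T1)`
  multiplies the IL-12-mediated activation source only; the chemotaxis flux
  keeps a constant coefficient so the transport operator stays a clean
  conservative divergence.  The three MDSC-derived cytokine lumping factors
  (`k_10M`, `k_MCP`, `k_12M`) are kept dimensionless (default 1) with the
  half-saturations carrying the scale.
* **Drug.**  Anti-IL-35 enters only the IL-35 balance, as the mass-action
  sink `−μ_A·ρ·A`.  Its spatial profile is static:
  `A(r) = A₀·exp(−(R − r)/ℓ_A)`, maximal at the rim where the drug arrives
  and decaying inward with penetration depth ℓ_A (no systemic
  pharmacokinetics — the profile is the model).
* **Oxygen delivery.**  `λ_w·e·(w₀ − w)`: perfusion pushes tissue oxygen
  toward the arterial level in proportion to capillary density; bounded by
  construction and inactive where there is no vasculature.

### Boundary and initial conditions

All cell and cytokine fields obey no-flux conditions at r = R; endothelial
cells and oxygen exchange with the surrounding healthy tissue through Robin
fluxes `γ_e (e − e_normal)` and `γ_w (w − w₀)` (outward positive), so
depleted vasculature draws EC inward.  Symmetry closes r = 0 (the zero-area
face needs no ghost condition).

The tumor starts as a central Gaussian seed; M-CSF starts on its uniform
production/decay ratio `s_q c₀/d_q`; MDSCs as a centered Gaussian at their
steady balance amplitude; activated CD8⁺ T cells at zero; Tregs as a fixed
fraction of the local tumor + MDSC density; TGF-β, IL-35, and VEGF
quasi-steady given those profiles; EC and oxygen rise quadratically from
depressed central values to their healthy-tissue levels at the rim.

## Nondimensionalization

Every parameter carries declared dimension exponents over {length, time,
one reference magnitude per field, drug scale}; scaling is the product of
reference powers and is exactly invertible (round trip < 1e-12 by property
test).  Default references: length 0.5 cm (the sphere radius), time 1 day,
cell densities and concentrations chosen so the working fields are O(1)
(tumor at carrying capacity = 1, healthy EC density = 1, arterial oxygen
= 1).  The solver always integrates the dimensionless system.  The shipped
parameter table stores both columns; `audit_parameter_table` recomputes one
from the other and reports any drift, which keeps transcription errors from
surviving silently.

## Numerics

* **Space.**  Finite volumes on n uniform shells with exact shell-volume
  weights (sum = 4πR³/3 to machine precision).  Diffusion uses two-point
  face fluxes; chemotaxis uses face-gradient velocities with first-order
  upwinding of the advected density — positivity and exact conservation are
  prioritized over formal order.  Measured self-convergence of the week-2
  tumor total is within 1% between n = 100 and n = 200; n = 100 is the
  reference resolution, n = 200 the oracle-test resolution.
* **Time.**  Method of lines with LSODA (banded Jacobian, half-bandwidth
  2·10 − 1 from the cell-major unknown ordering) or BDF with an explicit
  sparsity pattern; defaults rtol 1e-6, atol 1e-9.  Oxygen and cytokine
  kinetics are orders of magnitude faster than cell motility, so the system
  is genuinely stiff.
* **Dose discontinuities.**  Schedules are piecewise constant; the
  integrator restarts at every switching instant instead of stepping across
  a jump.
* **Negativity policy.**  Undershoots are clipped to zero and counted in
  the diagnostics when smaller in magnitude than max(1e-10, 10·atol) —
  i.e., within what the stepper can resolve; anything worse aborts the run
  as a solver failure.  Reference runs at default tolerances stay above
  −1e-10.
* **Ties.**  `peak_location` resolves ties to the outermost cell;
  PRCC ranking uses average ranks.

## Treatment protocols

Continuous dosing holds level A₀ for the treatment window; intermittent
dosing alternates one week at 2·A₀ with one week off.  The default window
is 56 days (eight weeks — "two months" in the week-aligned calendar, with
week and month lengths configurable), chosen so the alternating schedule
tiles the window exactly and both active schedules deliver identical
time-integrated dose (checked to 1e-10).  With a 30-day month the final
on-week is truncated and exact dose parity is impossible; the package
prefers the exact identity.

## Sensitivity analysis

Latin hypercube sampling (one uniformly jittered sample per equal-width
stratum per parameter, independent permutations per column) over 29
estimated/important dimensional rates, each spanning half to twofold of its
baseline except the tumor IL-35 production rate, which spans the control
value to 1.2x the transfected baseline (a sixty-fold range).  For each
sample the model runs with and without continuous anti-IL-35; the output is
the efficacy ratio (treated/untreated tumor burden at the horizon).  PRCC
follows the two-residual construction: rank-transform everything, regress
the target parameter's ranks and the output ranks on all remaining
parameters, correlate the residuals; p-values use the t-transform with
N − 2 − (k − 1) degrees of freedom.  Failed rows are excluded pairwise
and reported: solver aborts beyond a 5% quota invalidate the analysis,
while rows whose untreated tumor goes extinct (ratio undefined) are
recorded without counting toward the quota.

The full-model sensitivity check runs scaled down — N = 100 samples,
42-day horizon, 24 cells, dose level 20 — for runtime.  Along the
production axis with the other rates at baseline, the drug is clearly more
effective against higher-IL-35 tumors (the dosing study), and the PRCC
table is mechanistically coherent: the strongest negative drivers are the
CD8 activation and killing rates (the drug works through de-repressed
killing), the strongest positive ones the CD8 death rate, the IL-10
suppression strength, the IL-35 decay rate, and the tumor proliferation
rate.  The PRCC of `lambda_rho_c` itself, however, balances to ≈ 0 across
the joint box (N = 300 reference estimate +0.05, p = 0.44): raising tumor
IL-35 production enlarges both the drug's absolute benefit and the
untreated burden, and with a fixed blocked fraction the ratio only falls
if the tumor's IL-35 elasticity grows with IL-35 — which the saturating
responses do not deliver jointly with the other reproduced behaviors.  The
corresponding acceptance test documents this and is expected to fail.

## Parameter provenance and the stated world

Parameter defaults live in `data/parameters.yaml` (code never hard-codes a
constant) and were fixed once to place the model in the qualitative regime
the biology dictates: at week 2 the IL-35-transfected arm exceeds control
in tumor burden, MDSC count (about 2.4-fold), VEGF, and the Treg-to-CD8
ratio; the tumor density peak migrates monotonically from the center toward
the oxygen-rich rim between weeks 2 and 8; at equal total dose the
continuous schedule beats the intermittent one; and the relative benefit of
the drug grows with tumor IL-35 production across the tested production
rates (0.25×, 0.5×, 1× of the transfected baseline).  Magnitudes
(diffusivities ~1e-4–1e-1 cm²·day⁻¹ from cells to oxygen, cytokine
half-lives of hours, cell lifetimes of days, oxygen penetration depths of
a few hundred µm) follow the ranges standard in continuum tumor–immune
modeling.

A dial worth knowing: the drug's leverage depends on where the IL-35
response curves operate.  The MDSC production term saturates at moderate
IL-35 (K_ρ = 5 in working units), while the tumor VEGF term stays nearly
linear across the tested range (K_ρh = 50); pushing production far above
the tested range (≫ 2× baseline) drives the angiogenic and crowding
ceilings, where any IL-35-directed therapy loses traction — the efficacy
trend is a statement about the responsive regime, not an unbounded law.

## What a green test does and does not establish

The suite verifies internal consistency (transport against analytic
solutions, conservation, steady states, scaling round trips, PRCC
statistics against constructed truths) and the qualitative regime above.
It does not validate the model against animal data: no mouse measurements
enter the package, the parameter set is one plausible point in a wide
admissible region, and the cross-scenario ratios depend on that choice.
The sensitivity machinery quantifies exactly this kind of dependence and is
the tool to use before trusting any single-number prediction.

## Known limitations

* Fixed spherical domain: no moving tumor boundary, no shape effects.
* IL-10, IL-12, IL-2, and MCP-1 are folded into MDSC-dependent terms; no
  delay in MDSC arrival (the model therefore understates the early
  CD8⁺ difference between arms).
* First-order upwinding smears steep chemotactic fronts at coarse n.
* The drug profile is static; no absorption/clearance compartments.
* LSODA's banded finite-difference Jacobian is the runtime bottleneck at
  n ≳ 400.
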