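# Methods

This note documents the models, losses, estimators and numerical choices
in `pvlnode`, and what the synthetic studies do and do not demonstrate.

## The 0D circulation model (data source)

The data-generating model is a closed-loop lumped-parameter circulation
with 8 states: the four chamber volumes V_LA, V_LV, V_RA, V_RV and four
vascular compartment pressures (systemic arterial/venous, pulmonary
arterial/venous).  Units are mmHg, mL and s throughout.

* **Chambers.**  p_C = E_C(t) (V_C − V_rest,C).  The elastance rises from
  E_min to E_max under a raised-cosine activation taken to a power
  k ≥ 1 (the *steepness* analog): a(τ) = (½(1−cos 2πτ/d))^k on
  τ ∈ [0, d], zero elsewhere.  a is C¹, reaches exactly 1 at τ = d/2 and
  exactly 0 in diastole, and is T_HB-periodic.  Atrial activation starts
  at cycle onset with duration 0.25·T_HB; ventricular activation starts
  AV_delay later with duration `act_dur_scale`·0.45·T_HB.
* **Valves.**  Pressure-gated conductances Q = σ(Δp/w)·Δp/R with a
  logistic gate of width w = 0.5 mmHg, keeping the right-hand side C¹ so
  an adaptive explicit Runge–Kutta solver (SciPy RK45, rtol 1e-7,
  atol 1e-9) integrates it without event handling.
* **Windkessels.**  C dp/dt = Q_in − Q_out per compartment; systemic and
  pulmonary resistances carry the `R_sys_scale` / `R_pulm_scale` analogs,
  the systemic arterial compliance carries `C_art_scale`.
* **Conservation.**  Every flow enters one state positively and another
  negatively, so total blood volume ΣV_C + ΣC_i p_i is a first integral;
  its numerical drift (< 1e-6 relative per beat at the default
  tolerances) measures integrator error only.

Twelve analog parameters are exposed with physiologically plausible
bounds (e.g. E_max,LV ∈ [1.2, 3.5] mmHg/mL around a reference of 2.0,
T_HB ∈ [0.65, 1.0] s, resistance scalings ∈ [0.6, 1.6]).  The scaled-down
training studies vary the 8-parameter subset `reduced_space()`
(contractility of LA/LV/RV, atrial passive elastance, ventricular
activation duration, AV delay, and both resistance scalings), which spans
contractile, passive, timing and afterload effects while keeping the
heart period shared across records.  Datasets default to 405
Latin-hypercube simulations of 5 beats each (the first four wash out the
initial transient; only the last cycle is kept) with a 400/5 train/test
split convention.

Each stored cycle lives on a uniform half-open grid of 200 samples,
t = 0, …, T_HB − Δt with Δt = T_HB/200.  What this generator does *not*
emulate: spatial electromechanics, realistic valve dynamics
(regurgitation, inertance), autonomic reflexes, beat-to-beat variability
or measurement noise.  Passing tests therefore demonstrate the pipeline's
correctness on a smooth, deterministic, 8–12 parameter analog of the real
problem — not clinical fidelity.

## The neural-ODE surrogate

dz/dt = ANN(z, cos φ, sin φ, θ̂; w), φ = 2π(t − AV_delay)/T_HB.

* States: the 8 physical channels, each affinely scaled to ≈[−1, 1] by
  training-set ranges (scalers stored with the model), plus `n_latent`
  dimensionless latent states (default 0 — the selected configuration).
* Inputs: N_z states + 2 clock features + N_P parameters scaled to
  [−1, 1] by the box bounds; time enters *only* through the clock, so the
  learned field is periodic by construction.
* Network: fully connected, 3 hidden layers × 13 tanh units (default),
  linear output; Glorot initialization.
* Integration: fixed-step RK4 on the observation grid
  (discretize-then-optimize).  The integrator takes one extra step to
  T_HB so the latent-periodicity penalty can evaluate z_latent(T_HB) on
  the half-open data grid.  Gradients with respect to weights, initial
  states and θ are the exact reverse sweep of the discrete scheme —
  equivalent to backpropagation through the unrolled solver.
* Initial conditions: physical states from the first sample of the
  observed cycle (training) or user input (deployment); latent initial
  conditions start at zero and are trained jointly with the weights.

## Loss and training

For one record, with observed cycle z̃ on the grid:

L = Σ_c ‖z_c − z̃_c‖²_{L²} / z_norm,c²
  + α Σ_c ‖ż_c − ż̃_c‖²_{L²} / z_norm,diff,c²
  + β Σ_c (max z_c − max z̃_c)² / z_norm,max,c²
  + γ Σ_c (min z_c − min z̃_c)² / z_norm,min,c²
  + η (‖z_lat(0)‖² + ‖z_lat(T_HB)‖²) + ι‖w‖²

with α = β = γ = η = 0.1.  L² time norms use the composite trapezoidal
rule on the grid; predicted derivatives are the network right-hand side
along the trajectory (exact for an ODE), observed derivatives are central
differences with one-sided ends; grid extrema use the exact subgradient
at the argmax/argmin node.  The normalizers are training-set ranges (of
the signals, their derivatives, and the per-trace maxima/minima
respectively), floored at 1e-8; when a per-trace extremum range is
degenerate (e.g. a one-record set) it falls back to the signal range so
terms 3–4 stay O(1).  Terms are summed over channels and averaged over
records; the weight penalty ι‖w‖² (default ι = 1e-5) is added once.

Optimization runs in four phases, all full-batch and deterministic given
the seed:

1. **Collocation pretraining** (default 3000 epochs, Adam): regress
   ANN(z̃, clock, θ) onto the observed finite-difference derivatives —
   orders of magnitude cheaper per epoch than integrating, and a strong
   initializer.
2. **Multiple shooting** (optional): cut each cycle into short segments
   (default 25 nodes) integrated from observed states with the clock
   offset to absolute time, and optimize trace+derivative mismatch on the
   segments.  Short rollouts condition the landscape before full-cycle
   rollouts.
3. **Full-rollout Adam** with cosine learning-rate decay and global
   gradient clipping.
4. **L-BFGS polish** on the same objective (the problem is a smooth
   full-batch minimization, where quasi-Newton steps converge much
   deeper than first-order ones).

A non-finite loss restores the best iterate and flags the report.  A
`time_stride` option trains on every s-th grid node (the model is an ODE;
evaluation still uses the full grid); the study-scale runs use stride 2
(100 nodes/beat) to halve gradient cost with negligible accuracy impact.

**Evaluation.**  Per-trace metrics follow NRMSE = RMSE/range(obs) and
R² = 100·(1 − SS_res/SS_tot) per channel.  Dataset-level numbers pool
residuals across records (pooled range and pooled mean), giving the
single-number-per-channel convention of the fidelity tables.  K-fold CV
(default K = 10) and a small architecture grid around the selected 3×13,
N_z = 8 point support hyperparameter selection; ties break toward fewer
weights, then fewer latent states.

**Problem sizes.**  The bundled studies train on 200 simulations with 8
varied analogs and evaluate on 5 held-out ones; the test suite runs up to
three training seeds and stops once two clear the fidelity band.  These
sizes were chosen so the whole suite runs on a single core at desk scale.

## Sensitivity analysis

QoIs: per-chamber max/min pressure and volume (16), plus LV/RV stroke
volume and ejection fraction (4).  The Saltelli design uses two scrambled
Sobol' base matrices A, B (seeded scrambling) and radial blocks AB_i
(and BA_i when second-order indices are requested):
n_base·(P+2) or n_base·(2P+2) evaluations.  First-order indices use the
Saltelli (2010) estimator S1_i = mean(f_B·(f_{AB_i} − f_A))/V, totals the
Jansen estimator ST_i = ½·mean((f_A − f_{AB_i})²)/V, with V the variance
over A∪B; second-order indices use the Saltelli (2002) BA/AB cross
moments.  Bootstrap (default B = 200 resamples of base rows) gives 95%
half-widths.  NaN evaluations drop the whole base row across all blocks.
During surrogate-based GSA the initial physical state is held at the
training-set mean so the indices isolate θ-driven variance; a parameter
is reported *relevant* when its total-effect index exceeds 0.1 for at
least one QoI.

## Calibration

Two-stage inverse UQ for a named subset of parameters given masked
channels of one observed cycle:

* **Likelihood.**  Gaussian per masked channel and grid node, variance
  = measurement² + surrogate² per channel (optionally a smooth
  phase-dependent surrogate-error curve: a circular Gaussian-kernel
  smooth of validation residual spreads, floored at 10% of the
  homoscedastic value).  Surrogate error is the per-channel RMSE on
  held-out validation records; all stds are floored at 1e-3 physical
  units so likelihoods stay proper on perfect fits.
* **Priors.**  Independent uniforms on the box bounds.
* **MAP.**  L-BFGS on the scaled-logit reparameterization (unconstrained)
  with analytic gradients through the integrator; multi-start from the
  reference point plus LHS draws.  With uniform priors this is the
  in-box maximum-likelihood point.
* **NUTS.**  Own implementation (`pvlnode.mcmc`): multinomial
  tree-doubling, dual-averaging step size (target acceptance 0.8),
  divergence threshold ΔH > 1000, configurable maximum tree depth
  (default 8 in calibration).  The mass matrix may be diagonal or dense;
  calibration seeds it with the Laplace covariance at the MAP (the full
  finite-difference Hessian of the log posterior), which captures the
  strong parameter trade-offs these posteriors exhibit, and re-estimates
  it mid-warmup only when enough draws are available to beat that
  estimate.  Chains are initialized by jittering the MAP; sampling
  happens in the logit space with the prior Jacobian included and chains
  are reported in physical units.  The likelihood grid may be subsampled
  (`stride`) — once the waveform is resolved the posterior is essentially
  unchanged while each gradient costs proportionally less; the bundled
  recovery studies use every 4th node (50 per cycle).  Summaries: median, IQR and central 95% credibility interval
  per parameter; rank-normalized R̂ and ESS via ArviZ; R̂ > 1.05 flags
  the report non-converged instead of raising.  T_HB and AV_delay are
  observation metadata (they drive the surrogate clock) and are excluded
  from estimable subsets.
* **Test cases.**  T_LV (V_LV → 4 ventricular/afterload analogs),
  T_ventricles (V_LV, V_RV → +steepness), T_atria (V_LA, V_RA → 8 analogs
  including atrial contractility/stiffness), T_all (all 8 channels → all
  10 non-timing analogs).  `run_test_case` generates ground-truth
  observations from the 0D simulator (or from the surrogate itself for
  self-consistent checks that isolate the inference machinery), runs
  MAP + NUTS, and reports truth/median/IQR/CI tables with coverage flags.

## Known limitations

* The surrogate-error model is a diagonal Gaussian (homoscedastic or
  phase-varying); correlated-in-time error models are out of scope.
* The left-atrial pressure channel is the hardest to emulate at the
  bundled scale: its a/v-wave morphology is sharper than any other
  channel, and the 3×13 network saturates around R² ≈ 96–97 for it while
  all other channels reach 97.9–99.5.
* Highest-density posterior regions are not computed; 95% regions are
  per-parameter central intervals plus pairwise draw exports.
* The CLI's idempotence checks hash file contents; concurrent writers to
  one output directory are not supported.
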