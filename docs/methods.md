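# Methods

## Model and assumptions

The package computes equieffective doses for radiopharmaceutical therapy
under the linear-quadratic (LQ) cell-survival model. The quadratic
(two-hit) term depends on how much sublethal damage is still unrepaired
when the second hit arrives; for protracted irradiation this is captured
by the Lea–Catcheside dose-protraction factor

G = (2/D²) ∫₀^∞ dt Ḋ(t) ∫₀^t dt′ Ḋ(t′) ψ(t−t′),

with a single-phase exponential repair kernel ψ(s) = e^(−μs),
μ = ln2/T_rep. Assumptions inherited from that formulation:

* complete decay of the source (integrals to infinity);
* Ḋ(0) = 0 at injection (uptake is not instantaneous), which reduces the
  general two-phase clearance model A e^(−λ₁t) + B e^(−λ₂t) (times
  physical decay e^(−λt)) to the common-amplitude biexponential
  r₀(e^(−λ_e1 t) − e^(−λ_e2 t)), λ_ei = λᵢ + λ;
* identical α/β for the test and reference radiation, so ratios of EQDX
  at a common fraction size X reduce to BED ratios;
* local energy deposition (no cross-irradiation kernels) and no
  repopulation/regrowth terms — both independent of G and RE;
* single-phase exponential repair only. Multi-phase or reciprocal repair
  kernels break the separability the hybrid/analytic routes rely on and
  are out of scope.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| α/β (Gy) | LQ radiosensitivity ratio | 10 (tumor), 3 (organ runs) | conventional tumor / late-responding tissue values |
| T_rep (h) | repair half-time | 1.5; grid {0.5, 1.5, 3} | brackets feasible fast and slow repair; 0.5 h is the fast-repair stress case |
| physical half-life (h) | radionuclide decay | 159.528 (¹⁷⁷Lu, 6.647 d) | the RPT agent class the package targets; configurable |
| X (Gy) | reference fraction size | 2 | EQD2 is the standard comparator |
| dt (h) | recursion grid step | 0.01 | results change < 0.01% when halved (asserted in tests) |
| k_last | tail points for λ_e | 2 | the standard four-scan protocol estimates the tail from the final two scans |

All times are hours post-injection, dose rates Gy/h, rate constants 1/h.
μ and λ are derived properties of the stored half-times, so the identities
μ = ln2/T_rep and λ = ln2/T½ hold to machine precision by construction.

## Engines and numerical choices

**Analytic (biexponential).** Closed forms for G, D, RE; exact and
amplitude-invariant (G does not depend on r₀).

**Numerical recursion.** Trapezoid dynamic programming on a uniform grid
including t = 0: M(m) accumulates Ḋ e^(μt), N(m) accumulates Ḋ M e^(−μt),
G = N/(D²/2) with D trapezoided on the same grid. The algorithm is kept
faithful to its published form — no log-domain rescaling — because its
overflow behaviour is part of what the package studies: e^(μt) exceeds
float64 range at μt ≈ 709.78, so a guard at μt > 700 truncates the grid,
flags the result (`overflowed=True`), and optionally raises a structured
`NumericalOverflowError` carrying the partial breakdown. The optional
auto-stop protocol starts at the configured stop time (72 h in the study
drivers) and extends in 10 h steps until successive values of both D and N
change by < 0.1%; BED = D + 2N/(α/β) and EQD2 are monotone in (D, N), so
this bounds their change by the same tolerance without the integrator
needing α/β.

**Hybrid.** The same recursion on [0, t_x] only (grid = uniform dt grid
unioned with the sample knots, so no trapezoid segment straddles an
interpolation kink), then the exponential tail in closed form:
R = N + M Ḋ(t_x) e^(−μt_x)/(λ_e+μ) + Ḋ²(t_x)/(2λ_e(λ_e+μ)). The three
terms count sublesion pairs with both, one, or neither hit before t_x.
With t_x = 0 the expression collapses algebraically to λ_e/(λ_e+μ).
μ·t_x ≤ ~100 for clinical scan schedules even at T_rep = 0.5 h, so the
hybrid route cannot overflow in practice.

**Oracle.** Nested adaptive quadrature (scipy `quad`, abs/rel tolerances
1e-12/1e-9, outer horizon max(2000 h, 40/λ_slowest) so the truncated tail
is < e^(−40) relative). The inner integral is split at t − 60/μ — below
that point the repair kernel is < e^(−60) — purely to guide the adaptive
subdivision on long horizons; both pieces are still integrated
adaptively. The oracle never serves the fast path; it is the independent
check the engines are validated against (1e-6 relative for the analytic
route, 1e-4 for the hybrid route whose [0, t_x] part carries O(dt²) grid
error).

**Piecewise model conventions.** The interval [0, t₁] is covered by a
linear segment from (0, 0), consistent with the Ḋ(0) = 0 assumption; the
tail anchor is the first of the k_last tail points (four scans, k_last=2:
t_x = t₃), so the final inter-scan gap is never linearly interpolated.
λ_e is fitted log-linearly on the uncorrected dose rates of the tail
points; when the implied biological clearance λ_e − λ is negative (flat
or rising tail, high tumor retention), zero biological clearance is
assumed and the tail decays at the physical rate only. Zero dose rates in
the tail are rejected (log undefined); negative measured dose rates are
rejected at parse time rather than clamped.

**Fitting.** Unweighted nonlinear least squares in (r₀, λ_e1, δ) with
λ_e2 = λ_e1 + δ, bounds r₀ > 0, λ_e1 ≥ λ (biological clearance cannot be
negative), δ > 0; the δ-parametrisation removes label switching without a
post-fit swap, and a minimum relative rate gap of 1e-6 guards the
degenerate λ_e1 = λ_e2 collapse (rejected at model construction, since
B = −A makes the curve identically zero). Eight deterministic log-normal
perturbations (σ = 0.5, seed 20240101) of a data-driven initial guess
(tail log-slope for λ_e1, first-scan timescale for λ_e2) protect against
local minima; runs are reproducible given the seed. The choice of
unweighted residuals is a package decision — measurement-error models for
reconstructed dose rates are outside scope.

## Synthetic scenarios

The generator emulates noiseless 4-point measurement sets at the clinical
scan times {1, 4, 24, 72} h:

* **biexponential** r₀ = 2 Gy/h, λ_e1 = 0.02, λ_e2 = 0.5 /h (peak ~6.7 h,
  35 h effective tail half-life; D = 96 Gy) — a generic well-behaved
  tumor/organ curve;
* **monoexponential** d₀ = 1 Gy/h, λ_e = 0.05 /h (14 h half-life);
* **high retention** table (1 h, 0.10), (4 h, 0.30), (24 h, 0.50),
  (72 h, 0.50) Gy/h — a flat tail that engages the zero-biological-
  clearance rule, so the tail decays at the ¹⁷⁷Lu physical rate only;
* **slow clearance** (omission study) r₀ = 2 Gy/h, λ_e1 = 0.006,
  λ_e2 = 2.0 /h: the uptake peak (~2.9 h) lies inside the sampled window,
  the fast phase is gone by the 4 h scan so the two-point tail estimate is
  essentially unbiased, and the ~115 h tail half-life makes premature
  truncation expensive — the regime the omission study probes.

Validation samples are deliberately noiseless, so every engine
disagreement is attributable to the method. What the scenarios do *not*
emulate: reconstruction noise and bias of SPECT quantitation, intra-region
kinetic heterogeneity, mis-registered scan times, curves that are not
(piecewise) exponential. Passing tests therefore demonstrate correctness
of the calculation chain on the stated model classes, not clinical
accuracy on real images; the fit-recovery test adds 1% multiplicative
Gaussian noise as a minimal robustness probe, nothing more.

## Study drivers

**Convergence profiling** runs the numerical recursion once to the
maximum stop (1000 stopping times between 72 h and 2000 h, read off the
running (D, N) arrays) and reports the earliest stop within a 2% EQD2
tolerance of the engine-matched reference (closed form for parametric
truths, hybrid for piecewise truths). The profile is monotone
nondecreasing and bounded by the reference because both integrands are
nonnegative — the same mechanism that makes every truncated numerical
result an *under*estimate. Faster clearance converges earlier; for the
high-retention curve at T_rep = 0.5 h the guard fires at ~505 h while the
EQD2 deficit is still ~11%, so the 2% target is unreachable — at
T_rep = 1.5 h the auto-stop protocol instead terminates near 890 h.

**Omission study**: baseline = analytic EQD2 from the 4-point fit;
comparators on the first three points are (a) analytic refit, (b) hybrid
piecewise (t_x = t₂), (c) numerical on the same piecewise curve truncated
at 250 h (a stop sitting just below the overflow guard at T_rep = 0.5 h).
On noiseless data the analytic comparator recovers the baseline (three
points plus the Ḋ(0) = 0 constraint identify the three parameters), the
hybrid stays within a fraction of a percent, and the numerical comparator
loses the truncated tail — strictly negative and dominant for slow
clearance. With the *generic* biexponential above, the 4→24 h sampling
gap straddles the curve's shoulder and biases the two-point tail rate
low; that inflates the piecewise tail instead. This is a sampling-design
artifact rather than the truncation mechanism, which is why the omission
driver defaults to the slow-clearance truth.

## Problem sizes

Defaults were chosen so the whole validation suite is comfortable on a
single core: dt = 0.01 h grids to 2000 h are 2×10⁵ bins (vectorised, a
few ms); the oracle grid is 3×3×3 (λ_e1 ∈ {0.005, 0.02, 0.05},
λ_e2 ∈ {0.1, 0.3, 0.7}, T_rep ∈ {0.5, 1.5, 3} h) × two engines; noise
recovery uses 200 replicates.

## Known limitations

* Single-phase exponential repair only; no repopulation; common α/β.
* The numerical engine's overflow is detected, not repaired — by design.
* The piecewise [0, t₁] segment from (0, 0) is a modelling choice; real
  uptake curves may rise faster or slower than linearly.
* Fit identifiability with 3 points rests on the Ḋ(0) = 0 constraint and
  noiseless data; with noise, 4+ points are strongly recommended.
* Multi-cycle reporting is a per-cycle sum assuming identical kinetics
  and complete inter-cycle repair.
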