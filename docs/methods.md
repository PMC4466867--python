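# Methods

## Signal model and concentration conversion

All dynamic acquisitions are modelled as spoiled gradient echo (SPGR/FLASH)
at steady state,

    S = M0 · sin α · (1 − E1) / (1 − E1 cos α),   E1 = exp(−TR·R1),

with flip angle α, repetition time TR (ms) and longitudinal rate R1 = 1/T1.
Conversion of a dynamic series to concentration calibrates M0 per voxel
from the mean pre-contrast signal and the pre-contrast T1 map, inverts the
SPGR equation in closed form per frame,

    E1 = (M0 sin α − S) / (M0 sin α − S cos α),   R1 = −ln(E1)/TR,

and applies the linear relaxivity model C = (R1(t) − R1(0))/r1 with the
agent's longitudinal relaxivity r1 (L·mmol⁻¹·s⁻¹).  There is no default r1
— it depends on the contrast agent and field strength, so the caller must
supply it.  Negative concentrations produced by noise are retained:
clamping at zero would bias low-permeability estimates by rectifying the
noise distribution.  Signals outside the invertible SPGR range come back as
NaN frames.

## Kinetic models

Tissue models operate in minutes and mM on the AIF's uniform time grid
(non-uniform grids are first resampled linearly at the median spacing).
The steady-state (C = v·C_a), Patlak, Tofts, extended Tofts, 2CXM, tissue
uptake and shutter-speed (FXR) models are implemented as documented in the
package API.  For the 2CXM the printed parameterisation (K^trans, v_e, v_p,
F_p) is used directly; the permeability–surface product is derived
internally from the extraction fraction, PS = F_p·E/(1−E) with
E = K^trans/F_p, and the impulse response is the bi-exponential

    I(t) = F_p [A e^(−K₊t) + (1−A) e^(−K₋t)],

where K± are the eigenrates of the compartmental system and the weight
A = (1/T_B − K₋)/(K₊ − K₋), T_B = v_p/F_p, is fixed by the initial
conditions I(0) = F_p, I′(0) = −F_p/T_B.  This algebra is verified in the
test suite against two independent oracles: direct numerical integration of
the compartmental ODE pair (worst-case disagreement ~1e-6 mM over a 3⁴
parameter grid at 0.5 s sampling) and a generic eigendecomposition of the
compartment matrix.

The FXR (shutter-speed) model ties the intracellular water fraction to
p_i = 1 − v_e, ignores the vascular water pool, computes the extracellular
rate R1e(t) = R1(0) + r1·C_e(t) with C_e = C_tofts/v_e, and observes the
slow eigenvalue of the two-site water-exchange relaxation matrix with
intracellular lifetime τ_i (s) and τ_e from detailed balance.  The signal
is the SPGR equation evaluated at that rate.  This is one defensible
reading of the shutter-speed family; variants that include a vascular water
compartment are out of scope.

## Numerics of the convolution

Model curves require causal convolutions of the AIF with exponential
kernels.  Two routines exist:

* `convolve_uniform` — generic sampled-kernel trapezoid quadrature (FFT
  accelerated), for arbitrary kernels;
* `exp_conv` — an exponential-integrator recursion, exact when the input is
  piecewise linear, used inside every model.

The exponential integrator matters twice: it keeps the 2CXM accurate for
stiff eigenrates (small v_p with large F_p makes K₊·Δt ≫ 1, where sampled
kernels fail), and it makes the flow-limit identities (2CXM → extended
Tofts as F_p → ∞, tissue uptake as v_e → ∞) hold numerically.  For small
rate·Δt the integrator weights are evaluated by series expansion to avoid
cancellation; at rate 0 it reduces exactly to the running trapezoid
integral used by the Patlak model.

## Fitting

Nonlinear models are fitted by bounded trust-region least squares (scipy
`least_squares`, method `trf`; relative function/parameter tolerance 1e-8,
at most 500 iterations — all overridable through the preferences file).
Default bounds: K^trans ∈ [0, 5] min⁻¹, v_e ∈ [1e-6, 1], v_p ∈ [0, 1],
F_p ∈ [1e-6, 50] min⁻¹, τ_i ∈ [1e-3, 10] s.  Because the K^trans objective
is prone to local minima, every nonlinear fit is restarted from K^trans ∈
{0.005, 0.05, 0.5, 2} min⁻¹ (log-spaced across the plausible range) and the
lowest-RSS result kept; other parameters start at the midpoint of their
bounds, or at the lower model's estimates inside the nested walk.

The steady-state and Patlak models are linear in their parameters and are
solved by exact, unconstrained linear least squares.  Unconstrained is a
deliberate choice: clamping the linear solution at a zero bound concentrates
the null distribution of the subsequent F-test at p = 1 and roughly halves
the nominal false-promotion rate, destroying the test's calibration.  With
the unconstrained solution, promotion p-values under the null are uniform
(verified by a Kolmogorov–Smirnov test in the suite).  A consequence is
that fitted v and v_p can be slightly negative in pure noise; maps are
reported as fitted.

## Nested model selection

The hierarchy is fixed: Model 0 (C ≡ 0, zero parameters) → Model 1
(steady-state) → Model 2 (Patlak) → Model 3 (extended Tofts), promoted
strictly sequentially.  Each promotion uses

    F = ((RSS_low − RSS_high)/(k_high − k_low)) / (RSS_high/(n − k_high))

with the upper-tail p from F(k_high−k_low, n−k_high); promotion requires
p < 0.05 and the walk stops at the first rejection.  If the larger model
fits worse (possible with early-terminating bounded optimisers), F is
clamped to 0 so optimizer noise can never trigger a promotion; an exact tie
(including the all-zero perfect-fit case) also yields p = 1.  The 2CXM and
tissue-uptake models sit outside the nest and are compared, when wanted,
with AIC/AICc or F-tests through the `compare` interface.

## Fit statistics

* **AIC** = n·ln(RSS/n) + 2k, with AICc = AIC + 2k(k+1)/(n−k−1) reported
  alongside.
* **FMI/FRI** split the residual vector into a structured part (centred
  moving average, window 5 points, truncated at the edges) and a noise
  part; FMI = Var(fit)/(Var(fit)+Var(structured)), FRI =
  Var(structured)/(Var(structured)+Var(noise)).  The smoothing window is
  an explicit, configurable reconstruction choice — the decomposition is
  only defined up to the smoother used.
* **CCC** (Lin) uses population (1/n) moments:
  2s_xy/(s_x²+s_y²+(x̄−ȳ)²).
* **Prediction bounds** are linearised (delta-method) intervals
  ŷ ± t_{0.975,n−k}·√(s²(1+gᵀ(JᵀJ)⁻¹g)) from the final Jacobian; empirical
  coverage is validated at 95 % ± 3 % in the suite.

## The synthetic-data harness

The Monte-Carlo harness emulates the validation design: tissue curves over
factorial parameter grids (K^trans ∈ {0.01, 0.02, 0.05, 0.1, 0.2, 0.35}
min⁻¹, v_e ∈ {0.01, …, 0.5}, v_p ∈ {0.001, …, 0.1}, F_p ∈ {0.5, 1, 5}
min⁻¹, τ_i ∈ {0.1, 0.5, 2} s; reduced 2-level grids for the nested study),
10-minute acquisitions at 0.5 s or 6 s resolution, Parker population AIF
with bolus onset 60 s into the window.  Noise is added in the signal
domain: each concentration curve is converted to SPGR signal (FA 35°,
TR 25 ms, T10 1400 ms, r1 3.3 L·mmol⁻¹·s⁻¹, S0 1000 — fixed study
constants), corrupted with Rician noise √((S+g₁σ)²+(g₂σ)²) at
σ = mean(baseline signal)/SNR, and converted back through the same
closed-form inversion used on real data.  Each parameter combination is
repeated 100 times with fresh noise; a per-combination seed stream
(numpy SeedSequence spawning) makes the whole study reproducible
bit-for-bit from one integer seed.

Recovery studies refit each noisy curve with its generating model and
summarise agreement as CCC segregated by each co-varied parameter;
selection studies run the nested walk and tabulate the percentage of curves
per selected model.

What the generator does *not* emulate: spatial correlation of noise, motion,
B1 inhomogeneity, AIF measurement error, partial-volume arterial signal,
and T2* effects of the bolus.  Passing recovery tests therefore demonstrate
the estimator chain, not robustness to those in-vivo effects.

The noise-transform constants (T10, r1, S0, baseline length, and the
baseline-referenced SNR convention) control the effective
concentration-domain noise level and the degree of Rician-bias structure in
it, and thereby shift the operating point of the selection statistics.
They are fixed once as stated above and not calibrated against any expected
output; the nested-selection percentages for the hardest conditions
(near-degenerate combinations where k_ep = K^trans/v_e is large and the
extended Tofts curve is nearly proportional to the AIF) are sensitive to
them at low SNR.

## Degenerate inputs and edge rules

All-zero curves select Model 0.  Curves that are entirely NaN are rejected
as unclassifiable; NaN frames within a curve are dropped for nonlinear fits
(n reduced accordingly).  A bi-exponential AIF fit that converges to equal
rates is returned with a warning as the mono-exponential equivalent.
Relaxometry voxels whose linearised solution falls outside the physical
range (E1 ∉ (0,1), non-positive amplitude) are rejected as NaN and counted
in the run report.  ROI rasterisation of ImageJ geometry uses the
pixel-centre containment rule; only rectangle, oval, polygon and freehand
subtypes are accepted, anything else errors loudly.

## Known limitations

No B1 correction, motion correction, or reference-region models; DICOM is
read-only; the FXR variant is the vascular-pool-free two-site model; AUC is
unnormalised (not divided by the AIF AUC).  Batch mode executes jobs
sequentially — parallelism lives inside the voxelwise fitters, where serial
and parallel execution are guaranteed to produce identical maps.
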