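# Methods

This note documents the models, the numerical choices, and the scope of the
synthetic generators — what passing the test suite does and does not
demonstrate about real data. Units are µm, ms, µm²/ms throughout; b-values
in ms/µm².

## Acquisition model

The package is organised around a stimulated-echo acquisition with four
mixing times. `make_scheme_table()` encodes it: TM = 100 ms carries the
high-weighting series b = {0.035, 3.035, 6, 10, 20, 30} ms/µm² at
Δ = 105.91 ms, δ = 5 ms; TM = {500, 750, 1000} ms carry crusher/ADC pairs
(b₀, b₀+3) with b₀ = {0.17, 0.26, 0.35}. Sixteen gradient directions are
acquired per condition, and powder (direction) averaging removes
orientation dependence.

Two diffusion-time conventions coexist: the internal `t_d` is always
Δ − δ/3 (104.243 ms at TM = 100), while the nominal printed value
(104.25 ms) is carried as `t_d_nominal` metadata; the 0.007 ms discrepancy
is irrelevant at the precision of every computation here, but both are kept
so tables and fits can be labelled consistently.

## Forward models (GPD)

Restricted diffusion is modelled with the Gaussian phase distribution
approximation and ideal rectangular gradient pulses:

* **Sphere** (Murday–Cotts/Neuman): −ln E = 2 (γg)² Σ_m w_m T_m with
  eigen-wavenumbers α_m = x_m/R, x_m the roots of
  2x cos x + (x² − 2) sin x = 0 (the derivative of the order-1 spherical
  Bessel function), w_m = 1/(D α_m⁴ (α_m²R² − 2)) and the standard
  finite-pulse time factor T_m.
* **Cylinder** (Van Gelderen): same series with J₁′ roots and
  w_m = 1/(D β_m⁴ (β_m²R² − 1)); the powder-averaged "astrocylinder"
  combines free axial decay exp(−bD cos²θ) with the radial GPD term scaled
  by sin²θ, integrated over orientations with 64-point Gauss–Legendre
  quadrature.
* **Astrosticks**: the closed form E = √(π/(4bD)) · erf(√(bD)), the
  orientation average of exp(−bD cos²θ).

Series truncation: 100 eigenmodes by default with early stopping once a
term's relative contribution falls below 1e-12; a warning fires if the tail
is still above 1e-9 relative. (γg)² is derived from
b = (γgδ)²(Δ − δ/3), so the models consume b directly.

Both GPD expressions are validated against independent Monte-Carlo
phase-accumulation simulators (`dmrsmicro.montecarlo`): walkers with
elastic reflection inside the geometry, phase accrued under the rectangular
PGSE waveform. Agreement is ~0.3 % for the sphere and ~0.5 % for the
cylinder at study-typical parameters — these simulators share no code or
method with the series expressions.

The two-compartment mixture is a plain convex combination; no exchange, no
fibre dispersion, no separate compartment diffusivities (one shared
D_intra, default 0.5 µm²/ms, selectable over {0.3 … 0.8} or free).

## Joint fitting

`SphereSticksFitter` stacks the self-normalized decay residuals
(E(b)/E(b_min), matching how measured decays are reported) and the
model-predicted two-point ADCs at each mixing time into one residual
vector, fitted by bounded trust-region least squares. Choices that matter:

* **Block weighting**: decays and ADCs are stacked unweighted — both live
  on a ~0–1 numeric scale. The weight is exposed (`adc_weight`) because
  nothing in the problem fixes it.
* **Bounds**: f_sphere ∈ [0, 1]; R ∈ [0.5, 20] µm (below ~0.5 µm the GPD
  signal is flat in R; above 20 µm is implausible for somata).
* **Multi-start**: 5 Latin-hypercube initializations (seed 1234 by
  default); the objective surface has a boundary valley at f → 0 where a
  near-zero fraction is snapped to exactly zero when that lowers the cost
  (trust-region iterates cannot land exactly on a bound).
* **D_intra grid**: ties within 1e-9 RMSE resolve to the smallest D.
* **Missing data**: NaN anywhere is skipped pointwise; fits require ≥ 3
  usable points; solutions pinned at a bound are flagged, not hidden.

Model comparison (`compare_models`) reports RMSE and parameters for
astrosticks-only (1 free parameter), astrocylinders (2), mixture with free
D (3) and mixture with D = 0.5 (2) — a table, not a verdict.

Measured recovery under study conditions (2 % signal-dependent Gaussian
noise, full scheme): median |f̂ − f| ≈ 0.01 and |R̂ − R| ≈ 0.2 µm over
truths f ∈ [0.2, 0.8], R ∈ [4, 9] µm (the acceptance script recomputes
this).

## Transient preprocessing

* **Coil combination** uses the water reference at the lowest b and
  shortest TM: per-coil phases from the first point of the mean water FID,
  amplitude weights ∝ water amplitude, normalized so a common signal sums
  to the root-sum-square of coil amplitudes.
* **Quality statistic**: M_up = mean |spectrum| over 1.9–4.5 ppm.
* **Outlier rule**: discard below median − 3×MAD. The MAD is the raw
  median absolute deviation (no 1.4826 normal-consistency factor). The b₀
  median and MAD pool all directions — at the crusher weighting the
  gradient direction is physically irrelevant, and per-direction MADs from
  4 repetitions are far too unstable to threshold against. At higher b the
  per-direction median is replaced by the prediction of a second-order
  cumulant (kurtosis) fit of ln M_up(b) (K clipped to [0, 10];
  monoexponential fallback with 2 b-values), with the b₀ MAD carried over
  unscaled (scaling by the predicted decay is available via `scale_mad`).
  A direction that cannot be fitted falls back to its within-(b, direction)
  median/MAD with a warning. The rule returns a mask; nothing is deleted.
* **Registration**: each transient is aligned to the pointwise median FID
  of the kept transients by maximizing |Σ s(t)e^{2πift} ref*(t)| over the
  frequency shift (padded-FFT coarse search + bounded refinement); the
  optimal zero-order phase is then the argument of that correlation.
  First-order phase is not corrected. Transients whose normalized
  correlation falls below a floor are passed through and flagged. Residual
  alignment error on fixtures is < 0.01 Hz / < 0.1°; note the aligned
  ensemble shares the median frame, not an absolute frequency.
* **Water removal**: HSVD — Hankel-matrix SVD of the first 1024 FID points,
  state-space (Kung) estimation of damped-sinusoid frequencies, amplitudes
  by linear least squares, subtraction of components inside 4.2–5.3 ppm
  ("centred around the water region"; the exact band is a configuration).
  On fixtures the water peak is suppressed > 99 % with metabolite-band
  changes < 1 %.

## Morphometric model

Cells are modelled as randomly branched trees of zero-radius segments: at
the mixing times used, diffusion is sensitive to long-range structure, not
fibre radius, so radial structure is deliberately omitted. Five generative
statistics with hard bounds: D_intra ∈ [0.1, 1], N_branch ∈ [2, 25]
(bifurcation generations), L_segment ∈ [5, 100] µm, SDN_branch ∈ [2, 3],
SDL_segment ∈ [5, 10] µm.

Generation: the generation count is drawn once per cell from
Normal(N_branch, SDN_branch) truncated ≥ 1; segment lengths from
Normal(L_segment, SDL_segment) truncated above a floor; daughter directions
take a random azimuth and a polar angle uniform in 10–80° relative to the
parent (any symmetric rule would do; this one is a configuration).
Binary trees grow as 2^generations, so growth is breadth-first and capped
(default 4095 segments, `truncated` flag set) — structure beyond the cap
lies past the diffusion horizon √(2·D·t_d) ≈ 45 µm of the longest mixing
time for admissible segment lengths, so the cap does not alter the
simulated signal regime.

Walker engine: 1-D Brownian motion along segments, elastic reflection at
tips, uniform choice among the other incident segments at nodes
(instantaneous reversal excluded); within a step the leftover displacement
is propagated across as many nodes as it reaches. The 3D position enters
only through the spin phase: per mixing time the position integral over
each rectangular gradient pulse is accumulated as a vector, so one walk
serves all four mixing times and every gradient direction and b-value
simultaneously (directions: deterministic Fibonacci sphere; E = ⟨cos φ⟩,
floored at the MC noise scale 1/√(walkers·directions) to keep strongly
attenuated entries finite). Step noise is generated in float32 blocks by
numpy's PCG64 and consumed by a numba kernel; branch choices come from the
kernel's own seeded stream — everything is deterministic given the seed.

Step-size guard: the simulation refuses when the rms step √(2D·dt) exceeds
one fifth of the shortest segment. Dictionary graphs therefore use a
2.5 µm segment-length floor and a per-entry dt = min(δ/10,
(floor/5)²/(2D)); explicitly constructed graphs may still use the 0.5 µm
floor with a correspondingly finer time step.

Dictionary and inversion: a Latin-hypercube grid (default 512 entries) over
the bounded space, ADC(t_d) at all four mixing times per entry, and a
random forest (200 trees, depth 20, squared-error loss — the contract is
"ensemble of regression trees with these hyperparameters") mapping the
4-point ADC vector to the 5 parameters, with OOB MSE reported and
predictions clamped to the bounds. All four mixing times are simulated
directly by default: they share a single walk, so this costs nothing, while
the alternative (simulate TM = 500/1000, predict TM = 100/750 by monotone
interpolation — kept as `simulate_all=False`) makes TM = 100 a two-point
linear extrapolation and measurably destroys the segment-length information
carried by the short diffusion time (held-out Spearman ρ for L_segment
drops from ~0.85 to ~0.6–0.7).

At desk scale (512 entries, 10⁴ walkers) held-out recovery is
ρ ≈ 0.95 (D_intra) and ρ ≈ 0.85 (L_segment, median |error| ≈ 9 µm), while
N_branch, SDN and SDL are essentially unrecoverable from four diffusion
times — the expected physical limitation of the design, not a code defect:
the longest diffusion path is only ~30 µm.

## SWC morphometry

Branches are delimited by the root, bifurcation points and terminations;
branch length sums Euclidean inter-sample distances; branching order counts
branching nodes on the path from the root (a trifurcation increments the
order once); total process length is the sum of branch lengths, excluding
soma-internal edges (all structure-code-1 samples collapse to one root
node — SWC soma conventions vary, and this is the least surprising
choice). Branch-length statistics are unweighted per-branch means. The
layer-thickness proxy of the sphere fraction is the thickness share of the
soma-rich layers (EGL/IGL + GL + PL) in the included total; adding a white
matter term to the fibre-like side strictly lowers it.

## Synthetic study

`simulate_study` emulates the cohort: 9 pups per region, ages P5–P30, six
metabolites, sphere-fraction trajectories anchored at the study ages (e.g.
declining cerebellar Tau/tCr fractions, rising thalamic Tau), radii
declining mildly with age, D_intra = 0.5. Pups perturb the truth (SD 0.04
on f, 0.4 µm on R); E gets Gaussian noise with SD = noise_sd·E (the
post-quantification error model — Rician noise applies to raw magnitude
data, not to fitted metabolite amplitudes); ADCs are recomputed from noisy
two-point signals so negative ADCs arise naturally; missing data is
injected independently per point.

`simulate_transients` builds raw-like FIDs: metabolite singlets (5 Hz
linewidth) whose amplitude decays with b, broad macromolecule-like
components that attenuate only weakly, optional water residual, complex
Gaussian noise, per-transient frequency/phase jitter, ~3 % scan-to-scan
amplitude variability (breathing/drift — without it, outlier thresholds on
noiseless fixtures are unrealistically razor-thin), optional multi-coil
sensitivities with a matching water reference, and motion-corrupted
transients (signal scaled by a factor; noise unscaled). A truth ledger
accompanies every set for injection/recovery testing.

What the generators do **not** emulate: J-coupled multiplets and realistic
baselines, spectral quantification error structure (CRLBs), eddy currents,
frequency drift that accumulates over time rather than i.i.d. jitter, and
any vendor raw format. Passing the suite shows the pipeline implements its
stated rules correctly and recovers known truths under the design's noise —
it does not validate the biophysical model against tissue.

A note on detectability: injected corruption in the test fixtures sits at
b ≤ 10 ms/µm². At b = 20–30 the thermal-noise floor dominates M_up, so even
a 60 % signal drop moves the statistic by less than any safe threshold —
the same regime the outlier rule faces in vivo at those weightings.

## Group statistics

Per metabolite × parameter: REML mixed model value ~ Age + Region with a
random pup intercept; Age is numeric (one slope). The Age:Region
interaction is kept only if a χ²(1) likelihood-ratio test between ML fits
of the nested models has p < 0.05 (ML, because REML likelihoods are not
comparable across fixed-effect structures). Coefficients are reported from
the REML fit, but fixed-effect p-values come from the design's error
strata: the Region contrast is tested on age-adjusted per-pup means
(two-sample t, df = pups − 2) and the Age and Age:Region terms on per-pup
age slopes (one- and two-sample t). Plug-in Wald standard errors from the
mixed model measurably under-cover at 18 animals (empirical type-I
≈ 0.07–0.08 at nominal 0.05); the stratum tests are exact for this
(near-)balanced longitudinal design and are what a Satterthwaite-corrected
mixed model reduces to here. Singular fits fall back to OLS with a
warning. Bonferroni: α/12 for 6 metabolites × 2 parameters,
i.e. 4.2e-3 (α = 0.05) and 8.3e-4 (α = 0.01).

Calibration, measured by the suite: type-I error within [0.03, 0.07] for
both fixed effects over 200 null replicates; null p-values pass a KS
uniformity test; a region offset of five between-pup SDs is detected with
p < 1e-3 in ≥ 95 % of replicates.

## Problem sizes used by the suite and the acceptance script

Both the test suite and the acceptance script run the morphometric
recovery at the desk scale of 512 dictionary entries / 10⁴ walkers
(~10 min, the dominant cost); the end-to-end cohort recovery uses 10
replicates with 3 multi-starts, and everything else runs at the sizes
stated in the script's output (`n` fields). These sizes are the package's
chosen desk-scale defaults; all of them can be scaled by arguments.

On the recovery ceiling: with essentially noiseless features (ADC MC error
~0.001 at 10⁴ walkers) and labels that track the realized geometry
(ρ ≈ 0.999 between nominal and realized mean segment length), held-out
L_segment recovery saturates around ρ ≈ 0.75–0.85 depending on the
dictionary draw and split — four ADC values cannot fully disambiguate
segment length from the other tree statistics once segments exceed the
diffusion horizon. D_intra recovery is stable at ρ ≈ 0.95.

## Known limitations

* The GPD approximation degrades for strong restriction with long pulses;
  at the study's δ = 5 ms it is accurate to well under a percent, which is
  why the Monte-Carlo oracles are held to 2 %.
* The mixture model ignores exchange, microscopic anisotropy and fibre
  dispersion; f_sphere soaks up whatever looks sphere-like at these
  diffusion times, including partial-volume white matter.
* The morphometric inversion is only as good as the generative family;
  real dendritic trees are not statistically homogeneous binary trees, and
  N_branch/SD parameters are unidentifiable from four diffusion times.
* The LMM treats age linearly; U-shaped trajectories load onto the
  interaction and residual terms.
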