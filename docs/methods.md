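# Methods

## Model

The gene is a two-state telegraph process: a repressed state φ_r and an
active state φ_a, with activation rate κ_a and inactivation rate κ_r.
The active state transcribes at rate κ_t⁺; transcripts degrade at κ_t⁻ and
are translated at κ_p⁺ per transcript; protein is removed at κ_p⁻
(dominated by dilution through cell division).  Steady-state distribution
shapes depend only on rate ratios, so all rates are stored in units of
κ_t⁻ ≡ 1; conversion from absolute units (κ_t⁻ ≈ 0.2 h⁻¹, κ_p⁻ ≈ 0.05 h⁻¹,
hence κ_p⁻/κ_t⁻ = 0.25) happens only at I/O.

The fit-relevant coordinates are the burst size `b = κ_t⁺/κ_r`, the burst
frequency `κ_a`, and the active duration `τ = 1/κ_r`.  The steady-state
probability of the active state is `f = κ_a τ/(1+κ_a τ)`.  Qualitative
regimes are classified by order-of-magnitude thresholds: *Bursting* when
κ_r ≥ 10 and b ≥ 2, *Fast* when min(κ_a, κ_r) ≥ 10, *Slow* when
max(κ_a, κ_r) ≤ 0.1, otherwise *Intermediate*; the thresholds are
configurable and only label regimes, nothing downstream depends on them.

### Closed-form moments

All propensities are linear, so the moment hierarchy of the master equation
closes exactly; `analytic_moments` solves the chain of linear steady-state
equations through third order (gene–transcript–protein cross moments up to
⟨n³⟩).  These exact moments serve three roles: certification target for the
numerical solver, parameter-aware grid sizing, and the moment-matching
initial guess.  In the bursting regime the leading-order relations

    mean_protein = κ_a b κ_p⁺ / κ_p⁻
    var_protein  = mean · (b κ_p⁺) / (1 + κ_p⁻)

invert uniquely to (b, κ_a) given a corrected fluorescence mean and
variance.  The 1/(1+κ_p⁻) factor is the low-pass filtering of transcript
burst noise by the protein lifetime; without it the variance relation is
~25% high at κ_p⁻ = 0.25, which the exact moments flag immediately.  The
moment-matched pair is the initial guess (and a fast estimator in its own
right); the systematic fit refines it against the full distribution shape.

## Steady-state CME solver

State space: (gene state, transcript count, protein count), truncated at
mean + `n_sd` (default 8) standard deviations per axis from the analytic
moments, with automatic expansion if the truncation-boundary mass exceeds
tolerance.  A graded coarse-graining keeps unit-width bins through the bulk
of the distribution (to mean + `fine_sd` = 4 SD, capped) and geometrically
growing bin widths in the tails.

Coarse inter-bin rates come from a two-mode flux interpolation: within the
two bins adjacent to an edge, the density is represented as a combination of
the chain's detailed-balance profile π(m) ∝ Π B/D and its constant-flux
particular solution, the combination is matched to the two bin masses, and
the exact edge propensities act on the implied boundary-state occupancies.
The scheme conserves probability, has non-negative rates, reduces to the
exact master equation at unit widths, and aggregates 1-D birth–death chains
exactly; for pure-death chains (transcription off, or the zero-transcript
protein chain) the advected-population profile ρ ∝ 1/D replaces the
equilibrium mode.  Residual error comes only from the joint coupling
distorting within-bin shapes, and vanishes as bins shrink (the refinement
test asserts monotone convergence to the oracle).

Two backends solve the same generator:

* **Alternating implicit/explicit (Peaceman–Rachford) stepping** — the
  gene+transcript part and the protein part are treated implicitly in turn,
  cycling a geometric ladder of time steps (0.05 … 12.8 κ_t⁻⁻¹).  Each
  half-step conserves probability exactly and exact stationary distributions
  are fixed points.  The split structure factorizes: the gene+transcript
  half-step is one small LU applied to all protein bins at once, the protein
  half-step a batch of tridiagonal solves, so a full sweep costs O(states).
  Stationarity is declared at ‖dp/dt‖₁ < 10⁻⁹ (the absolute residual floors
  at roundoff × propensity scale for very stiff parameter sets; the solver
  then reports machine-precision convergence with a warning rather than
  failing).  A Krylov (LGMRES) acceleration of the sweep fixed point removes
  the slow splitting modes; `WarmStartSolver` reuses a clone-fixed grid and
  the previous solution across optimizer steps, bringing repeated solves to
  ~0.1 s.
* **Direct** — sparse LU nullspace solve of the generator (normalization row
  replacement), used for small systems and as the cross-check.

The **brute-force oracle** enumerates the fully fine-grained truncated
master equation and solves it directly — no coarse-graining anywhere — and
is the validation reference (total variation < 10⁻³, first three moments
< 0.5% against the closed forms, agreement with exact Gillespie sampling).

## Cytometry processing

* **Gating**: central quantile box of (FSC, SSC) at a configurable fraction
  (default the mid 60%), optionally preceded by an elliptical live-cell gate
  at 2.5 MAD.  The gate width can be bootstrap-optimized per clone: the
  target is the smoothed GFP distribution in a thin FSC slice at the mean
  scattering value, built from a held-out half of the events so its noise is
  independent of the resamples being scored; candidates are compared on
  common bootstrap resamples and ties resolved toward wider gates (more
  events).  With no GFP–FSC coupling the widest gate wins; with strong
  coupling the optimizer trades events for bias.
* **Histograms**: 256 log-spaced bins over 4 decades (0.1–1000 RFU),
  matching typical cytometer resolution; out-of-range values clip to the end
  bins with the clipped fraction reported.
* **Smoothing**: low-pass Fourier filter over the log-bin index with a
  Gaussian frequency taper exp(−(k/cutoff)²/2).  A brick-wall cutoff rings
  on the log axis and its sidelobes at high RFU corrupt linear-scale
  moments, so the taper is essential.  The cutoff can be bootstrap-optimized
  (minimize the mean deviation of smoothed resamples from the raw full
  sample — a bias/variance trade-off).
* **Convolution / deconvolution**: sums of independent signals convolve on
  the *linear* RFU scale, so histograms are mapped to a uniform linear
  lattice (step = 4× the smallest log-bin width) through their CDFs,
  convolved by FFT, and re-binned.  Wiener deconvolution uses the
  regularized inverse (H* + λ)/(|H|² + λ) with λ = `noise_level` × peak
  spectral power (default 10⁻³): exact inversion where the kernel dominates
  the noise floor, smoothly degrading to the identity (no amplification)
  where it does not.  Circular-FFT wraparound of near-zero mass is folded
  back to zero RFU.
* **Calibration**: γ = 2.5 RFU per mean transcript; ν = γ κ_p⁻/κ_p⁺ RFU per
  protein.  Because ν co-updates with κ_p⁺, the predicted RFU histogram is
  invariant to the choice of κ_p⁺ up to protein shot noise; the production
  default is κ_p⁺ = 10 (protein copy numbers in the hundreds–thousands,
  shot noise negligible), while solver-internal calculations use κ_p⁺ = 2
  to keep state spaces desk-scale — the invariance is asserted by test.
* **Inclusion rule**: clones whose mean fluorescence is below twice the
  autofluorescence mean are excluded.

## Fitting

`Dev` is the sum of squared per-bin probability differences over included
bins; a bin is included when either distribution carries more than 2% of its
own maximum there (so empty regions do not dilute the statistic, while
misplaced model mass still counts).  The absolute normalization of Dev is
convention-dependent; every decision in the pipeline (cut-offs, intervals)
is made on Dev_r = Dev_fit/Dev_data differences, which are invariant to it.

`Dev_data` is the bootstrap 95% upper bound on Dev expected from measurement
uncertainty: resample events with replacement, reprocess through
gate → histogram → smooth, take the 95th percentile of deviations from the
full-sample histogram (default 500 replicates, percentile method).  It
scales ≈ 1/n_events, which the tests verify.

`fit(tau)` minimizes Dev over (log₁₀ b, log₁₀ κ_a) at fixed τ with
Nelder–Mead from the moment-matched start (by default 3 jittered starts;
bounds enforced by a smooth penalty).  The forward map per evaluation is
CME steady state → protein marginal → fine PMF → RFU calibration →
autofluorescence convolution → log binning, on a clone-fixed grid sized from
the corrected data moments with a 10 SD margin.  `fit_profile` repeats the
fit over a log-spaced τ grid (default 12 points in [10⁻³, 3]); the largest τ
whose Dev_r is within 1 of the optimum — log-interpolated between grid
points — is τ_Max, flagged "unresolved" if the cut-off is never crossed.
Confidence intervals are the per-axis extents of the ΔDev_r = 1 ellipse
under a finite-difference Hessian quadratic model (maximum simultaneous
variation, √(2 (H⁻¹)ₖₖ) in log₁₀ units), with a direct contour search as
fallback for non-positive-definite Hessians.

In the bursting regime Dev is nearly flat in κ_r at fixed b below the true
τ, so only the upper bound τ_Max is resolvable; profiles on
pulsatile-generated data instead show an interior minimum — this asymmetry
is the regime-discrimination property the tests assert.

## Synthetic data

The generator emulates what the analysis assumes about real acquisitions:
10⁴ events/clone, 31 clones, GFP on the 4-decade log range, FSC/SSC on a
linear 1–1024 channel, lognormal autofluorescence (mean 5 RFU, CV 0.5), and
a latent lognormal cell-size factor s (CV 0.25) entering as GFP ∝ s^η
(η = 0.5) and FSC ≈ 512·s — chosen so 10–30% of GFP variance traces to
measurable size variation.  Protein counts are drawn by inverse-CDF sampling
of the exact CME protein marginal, or by exact Gillespie simulation of the
reaction scheme (the two paths are statistically indistinguishable by
construction and by test).  Scenarios: `frequency_only` (κ_a log-uniform in
[0.1, 3], b = 15), `size_only` (b log-uniform in [2, 50], κ_a = 0.3),
`combined` (b = c·κ_a² with the κ_a range derived from the b range —
[0.6, 3] with c = 50/9 — so burst sizes span exactly [2, 50]); τ = 0.02
throughout.

What the generator does **not** emulate: spectral overlap, doublets,
instrument drift, extrinsic-noise correlations between cells, or
non-stationary expression.  Passing tests therefore demonstrate correctness
of the inference machinery under the model's own assumptions, not robustness
to every artefact of real cytometry.

## Numerical choices and problem sizes

Defaults were chosen so the full test suite runs on one CPU at desk scale:
fixture clones use 2.5–10×10³ events; the recovery ensemble uses 20 clones
at 4×10³ events with a single optimizer start from the moment fit; interval
coverage uses 100 replicate acquisitions of one clone at 2.5×10³ events;
solver grids for fitting use coarser tails (growth 1.12, fine caps ~10²)
whose ≲5% parameter bias is far below sampling noise, while validation runs
against the oracle use near-fine grids (growth 1.02).  The deviation-profile
tolerance for monotonicity checks (0.15 in Dev_r) reflects optimizer noise
at these event counts.

## Known limitations

* τ is bounded, not estimated; reported b and κ_a are conditional on the
  bursting regime (short τ).  The free-κ_r ambiguity is inherent to
  two-state fits of protein distributions.
* The variance–mean slope of a pure burst-size ensemble computed from exact
  moments is ≈1.88, not the idealized scaling value 2: the burst-count
  (Poisson-like) variance component remains visible at small b.  The
  idealized anchors α = 1 and α = 2 are limits, approached but not attained
  by the exact model over realistic parameter ranges.
* The Wiener deconvolution and the typical-shape construction are
  resolution-limited by the autofluorescence width and the log binning; they
  are used for visualization and shape summaries, not for fitting.
* Absolute-molecule calibration is out of scope; γ anchors the RFU scale to
  mean transcript counts measured independently.
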