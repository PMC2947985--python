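# burstflow

**Transcriptional burst-parameter inference from clonal flow-cytometry
distributions, with a two-state (telegraph) gene-expression model.**

## The problem

Expression from a single gene copy — for example an HIV-1 LTR promoter
driving a GFP reporter, integrated at a semi-random position in the genome of
a clonal T-cell population — is stochastic: the promoter switches between a
repressed and a transcriptionally active configuration, transcripts are made
in *bursts* during short visits to the active state, and the resulting
cell-to-cell variability is visible as a wide, highly skewed fluorescence
distribution measured by flow cytometry.  The shape of that distribution
encodes the underlying kinetics.  `burstflow` is for researchers who want to
go from per-clone cytometry event tables (GFP, FSC, SSC) to per-clone
estimates of:

* **transcriptional burst size** `b = κ_t⁺ / κ_r` — transcripts made per
  activation event,
* **burst frequency** `κ_a` — activation events per transcript lifetime,
* an upper bound `τ_Max` on the **active duration** `τ = κ_t⁻ / κ_r`
  (two-moment data cannot pin τ itself, only bound it), and the derived
  bound `f_Max` on the **active fraction** `f = κ_a τ / (1 + κ_a τ)`,

and then to cross-clone trends: how burst size and frequency scale with the
clone's mean expression (power laws `x ∝ μ^α`), whether they are mutually
correlated, and which mode of promoter regulation the pattern of active
fractions favours.

## The model

A two-state gene with states φ_r (repressed) and φ_a (active), switching at
rates κ_a and κ_r; transcription at κ_t⁺ in the active state; transcript
degradation κ_t⁻ (the unit of all rates, ≈0.2 h⁻¹ in this system);
translation κ_p⁺ per transcript; protein dilution κ_p⁻ (≈0.05 h⁻¹, so 0.25
in κ_t⁻ units).  The steady state of the chemical master equation over
(gene state × transcript count × protein count) is solved on a graded
coarse-grained grid (exact unit bins at low copy numbers, geometrically
growing bins in the tails) by an alternating implicit/explicit
(Peaceman–Rachford) scheme, validated against a brute-force finite-state
solve and exact closed-form moments.  Model protein counts are converted to
cytometer units via a calibration γ = 2.5 RFU per mean transcript, convolved
with a measured autofluorescence profile, and binned on the instrument's
4-decade log scale — the same representation as the processed data, so fits
minimize a per-bin squared deviation `Dev` directly.  Fit quality is judged
relative to a bootstrap estimate of measurement uncertainty:
`Dev_r = Dev_fit / Dev_data`, with ΔDev_r = 1 the distinguishability
cut-off that defines τ_Max and the 95% confidence intervals.

## Worked example

Everything below runs on synthetic data with known ground truth — the
package ships a generator that emulates clonal cytometry acquisitions
(10⁴ events/clone, lognormal autofluorescence, a latent cell-size factor
coupling GFP to forward scatter):

```python
import numpy as np
from burstflow import (BurstCoordinates, BurstModel, CalibrationConstants,
                       simulate, cytometry)

calib = CalibrationConstants()                      # gamma=2.5, kp-=0.25, kp+=10
truth = BurstCoordinates(b=15.0, kappa_a=0.8, tau=0.02)
clone = simulate.simulate_clone(truth, calib=calib, n_events=10_000, seed=42)
af    = simulate.generate_autofluorescence(seed=7)

model = BurstModel.from_events(clone.events, af, gate=0.6, n_boot=200, seed=1)
fit = model.fit(tau=0.02)
print(fit.summary())
```

which prints (numbers from this exact seed):

```
Two-state bursting model fit
==========================================================
burst size b                       14.33  transcripts/burst
burst frequency kappa_a           0.8178  per transcript lifetime
active duration tau (fixed)         0.02  transcript lifetimes
active fraction f                0.01609
Dev_fit                        5.775e-05
Dev_data (95% bound)           9.913e-05
Dev_r                             0.5825
b 95% CI                    [12.66, 16.21]
kappa_a 95% CI              [0.7246, 0.9231]
converged: True   function evals: 30
```

The generating parameters (b = 15, κ_a = 0.8) sit inside both intervals, and
Dev_r < 1 says the fit is as good as the measurement uncertainty allows.
`model.fit_profile()` repeats the fit over a grid of active durations and
reports τ_Max and f_Max; `burstflow.trends` aggregates many clones into the
variance–mean power law, the b-vs-μ and κ_a-vs-μ regressions, and the
Mode-1/Mode-2 active-fraction predictions.

A command-line interface mirrors the pipeline:
`burstflow simulate | process | fit | trends` (see `burstflow --help`).

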