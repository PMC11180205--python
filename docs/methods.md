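# Methods

## Kinetic scheme

The package models factor-dependent termination of a stalled RNA polymerase
II elongation complex (TEC) by the Sen1 helicase domain as a sequence of
memoryless steps with one branched outcome:

1. **Elongation.** After a deterministic pre-elongation hold (default 1 s of
   baseline record), transcription to the stall site takes a Gaussian time
   (mean 2.9 s, sd 1.0 s, truncated positive). The Gaussian shape reflects a
   many-step process with narrow relative dispersion; it is fit by a peak
   location, not a rate.
2. **Sen1 arrival.** Binding to the stalled TEC is pseudo-first-order with
   rate k₊·S (k₊ ≈ 5.5×10⁶ M⁻¹s⁻¹, S the Sen1 concentration in molar), so
   stall-state dwells are exponential.
3. **Intermediate.** The Sen1–TEC intermediate resolves through two
   sequential steps: ATP-dependent translocation along the extruded RNA at
   rate k₁ (saturating in ATP as k₁ᵐᵃˣ·[ATP]/(K_m+[ATP])) and a single
   catalytic ATP hydrolysis at rate k₂ shared across ATP conditions. The
   lifetime density is the hypoexponential
   f(τ) = k₁k₂/(k₂−k₁)·[e^(−k₁τ) − e^(−k₂τ)], with the Erlang limit
   k²τe^(−kτ) at k₁ = k₂ (branch switched at |k₁−k₂| < 1e−8·max(k₁,k₂) to
   avoid catastrophic cancellation).
4. **Release.** Sen1 and the RNA leave the complex simultaneously; Sen1 then
   remains on the released RNA for an exponential dwell of rate k₃ (also
   ATP-saturating in the data the defaults reproduce).
5. **Pol II fate.** The polymerase (a) leaves the DNA with the RNA, (b)
   stays and leaves after an exponential delay 1/k₄ (default 36 s), (c)
   stays for the whole record, or (d) slides along the DNA in 1D with
   diffusion coefficient D = 1.3×10⁻⁴ µm²/s, reaching a labeled DNA end at
   distance L after a mean first-passage time L²/(2D); a
   distance-independent fraction f_capture (default 0.26) of sliding events
   is captured. Default branch fractions 58:74:34:0 (out of 166) follow the
   non-mismatch construct statistics.
6. **Photobleaching.** Each fluorophore carries an independent exponential
   bleach clock (mean t₀ = 237 s) that silences its emission and censors all
   later observables; bleach events are flagged in the simulation truth so
   estimators can be tested with and without censoring.

The within-trace distribution of the sliding capture time is not constrained
by mean-versus-distance data alone; the simulator draws it exponential with
mean L²/(2D), which preserves the first moment the diffusion fit consumes.

## Trajectory rendering and the PIFE convention

Trajectories are rendered at 20 ms per laser frame under strict green/red
alternation (ALEX), so each channel samples every 40 ms; durations are
reported in channel superframes × 40 ms. Green frames split a state's total
donor-side emission between i_dd and i_da by its FRET level; red frames
carry acceptor-excited emission i_aa. Additive Gaussian noise of fixed sd is
applied per measured sample; blinking and baseline drift are deliberately
not modeled.

Protein-induced fluorescence enhancement (PIFE) of the acceptor is active
during the engaged states (pre-elongation and elongation by default): i_aa
is multiplied by the PIFE ratio r (default 1.83), and — because the same
quantum-yield change inflates donor-excited acceptor emission — the rendered
proximity ratio of a PIFE-active state with true FRET f is r·f/(1−f+r·f).
This is the exact inverse of the correction
FRET′ = FRET/(r·(1−FRET)+FRET), so correcting a rendered trace recovers the
configured true level; the stall state carries no PIFE and renders its
nominal 0.2 exactly. FRET is everywhere the uncorrected proximity ratio
i_da/(i_dd+i_da); γ-correction from acceptor-bleach steps is available as a
separate function and off by default.

## Segmentation

The study's original analysis selected dwell windows manually; this package
replaces that with deterministic thresholding so results are reproducible:
each superframe with donor signal above an intensity floor is assigned the
nearest FRET band (defaults: 0.65 pre-elongation, 0.81 elongation — the
PIFE-inflated levels — 0.2 stall, 0.45 intermediate); donor-dark frames are
post-termination while the acceptor survives, else dark. A running median
(width 3) precedes classification, which leaves noiseless changepoints
untouched and suppresses isolated misclassifications; runs shorter than 2
superframes are merged into their neighbor. Consequences: dwells shorter
than 2 frames (80 ms) are unresolvable, and at saturating ATP (mean
intermediate lifetime ≈ 0.29 s ≈ 7 frames) the shortest dwells are lost,
which biases downstream rate estimates from segmented traces at small n —
visible in the demo pipeline's high-ATP k₁ values. On noiseless traces
segmentation reproduces embedded changepoints exactly; at noise of 5% of
the donor intensity scale, ≥95% of changepoints are recovered within ±1
frame (Monte Carlo, fixed seed).

Dwells are flagged censored when cut by the record end or by the trace going
dark; censored dwells are excluded from histogram fits by default and can be
included in maximum-likelihood fits through survival terms.

## Fitting

**Histogram fits.** Dwell histograms use fixed-width bins of
max(channel period, range/30) starting at 0. Global fits minimize
Σ_{c,i} [(n_ci − f(τ_i; θ_c)·N_c·w_i)/σ_ci]² with Poisson weights
σ = √max(count, 1); concentrations and t₀ = 237 s are held, rate constants
are shared across conditions, and each condition keeps a free kinetic
amplitude A (and bleach amplitude B where the model has one). Because
Neyman weighting with sparse tail bins biases rate estimates high, the
global-fit workflow merges tail bins until every bin holds at least 5
events — a standard validity condition for χ² fitting — before minimizing.
Parameter standard errors are covariance-based, scaled by the reduced χ²
(χ²/(Σbins − n_free)); the optimizer is Levenberg–Marquardt with
nonnegativity bounds and five deterministically spread starts.

**Maximum likelihood.** The two-step density carries no amplitude and is fit
by default as a normalized density: the negative log-likelihood is
minimized over log-parameters (Nelder–Mead), optionally with
right-censoring via log-survival terms, and standard errors come from the
inverse observed information (finite-difference Hessian, delta method back
to natural scale). For a plain exponential the MLE reduces to 1/mean
exactly, which the tests assert.

**Identifiability of the two-step fit.** The hypoexponential is symmetric
under k₁↔k₂; the labeling convention is that k₁ is the condition-varying
(ATP-dependent) rate and k₂ the shared catalytic rate. When the two rates
approach each other at saturating ATP the global likelihood can possess a
competitive swapped-label optimum, and at the sample sizes used in the
recovery studies (N ≈ 140–230 per condition) the shared k₂ has a sampling
SE of roughly 20–25%. The acceptance script therefore reports the median
recovered value over five replicate simulated datasets at the identical
design, which suppresses single-draw dispersion without touching the
estimator; the per-dataset behavior is exercised separately in the test
suite.

**Secondary fits.** Per-ATP rates are fit to k(S) = k_max·S/(K_m+S) by least
squares weighted 1/SEM², SEs from the covariance scaled by reduced χ².
Elongation-duration histograms are fit by a single Gaussian and summarized
by the peak. Post-termination sliding is analyzed by jointly fitting mean
PIFE-appearance lifetimes and appearance fractions versus label distance
under a 1D model (L²/(2D), constant fraction) and a 3D alternative
(L²/(6D), fraction ∝ 1/L); the model with the lower reduced χ² is
preferred. The 3D form is pluggable since only its qualitative shape is
constrained. Derived rates are plain arithmetic: translocation = k₁ᵐᵃˣ ×
RNA step length (nt/s); elongation = template length / peak duration
(bp/s); catalytic turnover = 1/mean intermediate lifetime. DNA lengths
convert at 0.34 nm/bp (B-DNA).

## What the generator does and does not emulate

The synthetic data reproduce the features the estimators depend on —
exponential/hypoexponential dwell structure, FRET-level jumps, PIFE
contrast, ALEX channel interleaving, photobleaching censoring, branched
fates — with known ground truth, so every pipeline stage is testable
without the original recordings. They do not emulate camera noise
statistics (EMCCD gain, shot noise), dye blinking, baseline drift,
spectral crosstalk, surface heterogeneity, or manual trace curation.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to every artifact of real recordings.

## Problem sizes and reproducibility

Simulation-based tests use 10³–10⁵ draws for distributional checks,
60–120 rendered trajectories for segmentation Monte Carlo, and 100
replicates for estimator-calibration sweeps; the demo pipeline runs four
conditions × 60 molecules × 60 s records in well under a minute. All
randomness flows from named `numpy.random.SeedSequence` streams spawned
per molecule from one master seed, so datasets are bit-reproducible and
any subset of molecules can be regenerated in isolation.

## Known limitations

- Threshold segmentation assumes well-separated FRET bands; heavily
  overlapping levels would need an HMM, which is out of scope.
- The minimum-dwell rule discards sub-80 ms events; rate estimates from
  segmented traces at saturating ATP are biased accordingly (the dwell-level
  estimators, fed directly, are not).
- Left-truncation of extracted dwells is not modeled in the MLE; only
  right-censoring is.
- The 3D diffusion comparison is a phenomenological alternative, not a
  derived first-passage solution for the chamber geometry.
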