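# sen1kin

Single-molecule kinetics of Sen1-dependent RNA polymerase II transcription
termination: a simulation, trace-processing and model-fitting pipeline for
two-color ALEX (alternating-laser excitation) fluorescence trajectories.

## The problem

In the yeast NNS termination pathway, the Sen1 helicase binds the nascent RNA
of a stalled Pol II elongation complex, translocates along it by hydrolyzing
multiple ATPs, and releases Sen1 and the RNA simultaneously upon a single
catalytic ATP hydrolysis. Single-molecule fluorescence records of
donor/acceptor intensities (Cy3 on RNA, Cy5 on DNA or a SNAP dye on Sen1)
report each stage as FRET-level and intensity changes. Quantifying the
pathway means turning those per-frame intensity traces into dwell-time
distributions and fitting kinetic models to them.

`sen1kin` implements that analysis as a tested, reusable library for anyone
analyzing (or simulating) factor-dependent termination kinetics at the
single-molecule level:

- **`sen1kin.simulate`** — a generative model of the full kinetic scheme
  (Gaussian elongation → stall → exponential Sen1 arrival at rate k₊·S →
  hypoexponential intermediate → simultaneous Sen1/RNA release → branched
  Pol II fate → exponential photobleaching), rendered into per-frame ALEX
  trajectories with embedded ground truth.
- **`sen1kin.traces`** — proximity-ratio FRET, the PIFE (protein-induced
  fluorescence enhancement) correction FRET′ = FRET / (r·(1−FRET) + FRET),
  threshold segmentation with hysteresis, dwell extraction with censoring,
  co-dissociation lag classes, Pol II fate classes, termination efficiency.
- **`sen1kin.models`** — the closed-form dwell densities: single exponential
  A·e^(−k₊Sτ), its photobleaching-corrected form + B·e^(−τ/t₀), the
  single-molecule Michaelis–Menten density
  (k₊⁰k_cat/2a)·[e^((a+b)τ) − e^((b−a)τ)], the two-step hypoexponential
  f(τ) = k₁k₂/(k₂−k₁)·[e^(−k₁τ) − e^(−k₂τ)], the classical Michaelis–Menten
  curve k(S) = k_max·S/(K_m+S), and 1D/3D first-passage models for
  post-termination Pol II sliding (MFPT = L²/2D).
- **`sen1kin.fitting`** — global weighted least squares on histograms with
  held (concentrations, t₀ = 237 s), shared (rate constants) and free
  (amplitudes) parameters; maximum likelihood with right-censoring; weighted
  Michaelis–Menten secondary fits; Gaussian peak fits; diffusion-model
  comparison by reduced χ²; derived-rate calculators.
- **`sen1kin.cli`** — a configuration-driven pipeline
  (`simulate` → `analyze` → `fit`) with YAML configs and seeded,
  bit-reproducible outputs.

## Worked example

The shipped demo simulates an ATP titration (20, 40, 200, 1100 µM; 60
molecules each at 10 nM Sen1) in which the translocation rate k₁ follows
Michaelis–Menten saturation (k₁ᵐᵃˣ = 5.9 s⁻¹, K_m = 40 µM) with shared
catalytic release k₂ = 8.69 s⁻¹, then segments the noisy trajectories,
extracts dwells, and refits the models:

```bash
sen1kin run -c configs/demo.yaml -o out/
```

Output (seed 7; `out/fit_*.json`):

```
binding       k+   = 5.67e6 ± 0.66e6 M^-1 s^-1   (truth 5.5e6)
intermediate  k1   = 2.01, 2.67, 4.01, 6.43 s^-1 per ATP condition
              k2   = 8.14 ± 2.53 s^-1            (truth 8.69)
mm_k1         kmax = 5.20 ± 0.79 s^-1, Km = 34 ± 12 µM   (truth 5.9 / 40)
translocation 5.20 s^-1 × 14 nt = 72.8 nt/s
```

Each number is a round trip through the full pipeline: the binding rate
constant comes from a global single-exponential fit of stall-state dwell
histograms with per-condition amplitudes free and concentrations held; the
per-ATP k₁ and shared k₂ from a global maximum-likelihood fit of the
hypoexponential intermediate-lifetime density; k₁ᵐᵃˣ and K_m from a
1/SEM²-weighted Michaelis–Menten fit of the recovered k₁ values; and the
translocation rate multiplies k₁ᵐᵃˣ by the 14-nt mean distance Sen1 covers
on the extruded RNA. Recovered values agree with the generating truth within
the quoted standard errors.

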