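# Demo pipeline: ATP titration of the termination intermediate lifetime.
# Four ATP conditions at 10 nM Sen1 HD; per-condition translocation rate k1
# follows Michaelis-Menten saturation (k1_max = 5.9 /s, Km = 40 µM) with a
# shared catalytic release rate k2 = 8.69 /s as ground truth.
seed: 7
log_level: INFO

scheme:
  k_plus: 5.5e+6       # M^-1 s^-1, Sen1 binding rate constant
  k1_max: 5.9          # s^-1, saturating translocation rate
  K_m_atp: 40.0        # µM
  k2: 8.69             # s^-1, single-ATP catalytic release
  k3: 5.46             # s^-1, Sen1-on-RNA dissociation
  t0: 237.0            # s, Cy3 photobleaching mean time
  elong_mean: 2.9      # s, Gaussian elongation duration
  elong_sd: 1.0

trajectory:
  frame_period: 0.02   # 20 ms per laser frame, green/red ALEX
  duration: 60.0       # s
  noise_sd: 2.0        # counts, additive Gaussian
  pife_factor: 1.83

conditions:
  - {atp_conc_uM: 20,   sen1_conc_nM: 10, rna_ext_length_nt: 28, construct: no_mismatch, n_molecules: 60}
  - {atp_conc_uM: 40,   sen1_conc_nM: 10, rna_ext_length_nt: 28, construct: no_mismatch, n_molecules: 60}
  - {atp_conc_uM: 200,  sen1_conc_nM: 10, rna_ext_length_nt: 28, construct: no_mismatch, n_molecules: 60}
  - {atp_conc_uM: 1100, sen1_conc_nM: 10, rna_ext_length_nt: 28, construct: no_mismatch, n_molecules: 60}

fits:
  - name: binding
    model: single_exp
    state: stall
  - name: intermediate
    model: two_step
    state: intermediate
    share: k2
  - name: mm_k1
    model: mm_curve
    from: intermediate
    rate: k1
  - name: translocation
    model: derived
    inputs:
      k_max_from: mm_k1
      step_nt: 14
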