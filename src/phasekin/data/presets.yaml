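# Named Flory-Huggins and interfacial-tension parameter sets.
# The three chi(T) parameterizations correspond to effective chain lengths
# fixed by inspection of the poly-rA coexistence data; the tension entries
# are the fitted constant value and the fusion-derived estimate.
phase:
  m1000:
    chain_length: 1000
    chi_entropic: 0.31
    chi_enthalpic_K: 75.0
    rho_solute_kg_per_m3: 1600.0
  m2000:
    chain_length: 2000
    chi_entropic: 0.23
    chi_enthalpic_K: 98.8
    rho_solute_kg_per_m3: 1600.0
  m4000:
    chain_length: 4000
    chi_entropic: 0.19
    chi_enthalpic_K: 110.0
    rho_solute_kg_per_m3: 1600.0
tension:
  void_fit_constant:
    form: constant
    gamma0_J_per_m2: 1.8e-6
  fusion_estimate:
    form: constant
    gamma0_J_per_m2: 0.9e-6
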