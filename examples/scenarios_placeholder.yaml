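rho_wt: 0.5
rho_provenance: placeholder
scenarios:
  CCoAOMT-down:
    enzyme_multipliers:
      CCoAOMT: 0.24
    observed_sg: 0.75
    provenance: placeholder
  COMT-down:
    enzyme_multipliers:
      COMT: 0.1
    observed_sg: 0.15
    provenance: placeholder
  ccr1-KO:
    enzyme_multipliers:
      CCR1: 0.05
    direction: down
    provenance: literature
  ccr2-KO:
    enzyme_multipliers:
      CCR2: 0.05
    hierarchical_multipliers:
      CCR1: 1.5
      CCoAOMT: 1.5
    direction: up
    provenance: literature
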