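schema: fibrilsim-run-1
eps_hb: 1.0
hydrogen_bond:
  range: 5.0
  core_factor: 0.75
  aux_min: 3.0
  aux_max: 6.8
  min_same_chain_sep: 4
salt_bridge:
  factor: 2.0
  residues:
  - 23
  - 28
parallel_preference:
  enabled: true
  max_angle_deg: 90.0
bond_tolerance: 0.015
thermostat:
  ghost_rate: 0.1
reference_sigma: 3.7
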