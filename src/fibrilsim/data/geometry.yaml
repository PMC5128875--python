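schema: fibrilsim-geometry-1
backbone:
  diameters:
    NH: 3.3
    CA: 3.7
    CO: 4.0
  bonds:
    nh_ca: 1.46
    ca_co: 1.51
    co_nh_next: 1.33
    nh_co: 2.4478
    ca_nh_next: 2.4103
    co_ca_next: 2.441
    ca_ca_next: 3.8
squeeze_factor: 0.7
local_backbone_factor: 0.65
residues:
  A:
    sc_diameter: 2.9405
    ca_sc: 2.4702
    nh_sc: 3.3193
    co_sc: 3.3559
  C:
    sc_diameter: 3.5041
    ca_sc: 2.752
    nh_sc: 3.5787
    co_sc: 3.6141
  D:
    sc_diameter: 3.6808
    ca_sc: 2.8404
    nh_sc: 3.6608
    co_sc: 3.6959
  E:
    sc_diameter: 4.1482
    ca_sc: 3.0741
    nh_sc: 3.879
    co_sc: 3.9133
  F:
    sc_diameter: 4.8268
    ca_sc: 3.4134
    nh_sc: 4.1988
    co_sc: 4.2321
  G:
    sc_diameter: 3.0
    ca_sc: 0.0
    nh_sc: 0.0
    co_sc: 0.0
  H:
    sc_diameter: 4.4808
    ca_sc: 3.2404
    nh_sc: 4.0354
    co_sc: 4.0691
  I:
    sc_diameter: 4.497
    ca_sc: 3.2485
    nh_sc: 4.043
    co_sc: 4.0767
  K:
    sc_diameter: 4.5448
    ca_sc: 3.2724
    nh_sc: 4.0655
    co_sc: 4.0992
  L:
    sc_diameter: 4.497
    ca_sc: 3.2485
    nh_sc: 4.043
    co_sc: 4.0767
  M:
    sc_diameter: 4.5761
    ca_sc: 3.2881
    nh_sc: 4.0803
    co_sc: 4.1139
  N:
    sc_diameter: 3.8421
    ca_sc: 2.921
    nh_sc: 3.7358
    co_sc: 3.7706
  P:
    sc_diameter: 4.0112
    ca_sc: 3.0056
    nh_sc: 3.8148
    co_sc: 3.8493
  Q:
    sc_diameter: 4.2768
    ca_sc: 3.1384
    nh_sc: 3.9394
    co_sc: 3.9735
  R:
    sc_diameter: 4.7986
    ca_sc: 3.3993
    nh_sc: 4.1855
    co_sc: 4.2188
  S:
    sc_diameter: 3.118
    ca_sc: 2.559
    nh_sc: 3.4007
    co_sc: 3.4368
  T:
    sc_diameter: 3.6808
    ca_sc: 2.8404
    nh_sc: 3.6608
    co_sc: 3.6959
  V:
    sc_diameter: 4.11
    ca_sc: 3.055
    nh_sc: 3.8611
    co_sc: 3.8955
  W:
    sc_diameter: 5.2265
    ca_sc: 3.6132
    nh_sc: 4.3886
    co_sc: 4.4213
  Y:
    sc_diameter: 4.9362
    ca_sc: 3.4681
    nh_sc: 4.2507
    co_sc: 4.2838
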