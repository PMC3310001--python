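# Vertebrate pre/post-2R ancestry model ("N-model"): 40 post-2R linkage
# groups (GACs) descending from 10 pre-2R vertebrate ancestral chromosomes
# (VACs).  Only the label inventory and parentage are encoded; where the
# published reconstruction offers alternative rearrangement scenarios for a
# VAC, the variant in force is recorded under vac_scenarios.
name: N-model
gac_count: 40
vacs:
  A: [A0, A1, A2, A3, A4, A5]
  B: [B0, B1, B2, B3]
  C: [C0, C1, C2, C3]
  D: [D0, D1, D2, D3]
  E: [E0, E1, E2, E3]
  F: [F0, F1, F2, F3, F4]
  G: [G0, G1, G2, G3]
  H: [H0, H1, H2, H3]
  I: [I0, I1, I2]
  J: [J0, J1]
vac_scenarios:
  A: fission
  C: fission
post1r_groups:
  AncA-I: [A0, A1]
  AncA-II: [A2, A3, A4, A5]
  AncB-I: [B0, B1]
  AncB-II: [B2, B3]
  AncC-I: [C0, C1]
  AncC-II: [C2, C3]
  AncF-I: [F0, F1]
  AncF-II: [F2, F3, F4]
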