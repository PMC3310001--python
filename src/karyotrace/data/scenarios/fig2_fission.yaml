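# Reconstructed duplication/rearrangement history of the relaxin-family
# ligands (RLN/INSL) and both receptor families (RXFP3/4 and RXFP1/2) under
# the FISSION variant of pre-2R chromosome "A" evolution: the ancestral
# ligand (AncRln-like) and the ancestral short-peptide receptor (AncRxfp3/4)
# are syntenic on one pre-2R chromosome, which is duplicated (1R), fissioned
# (separating the post-1R ligand-II/receptor-II copies), and duplicated
# again (2R), yielding linkage groups A0-A5.  Tetrapods lose RXFP3-2 (and
# often RXFP3-3); teleosts retain all four rxfp3/4 ohnologs, go through the
# fish-specific 3R, retain duplicates of rln3/insl5/rxfp3-2/rxfp3-3, and
# locally duplicate rxfp3-3a.  AncRxfp1/2 sits on pre-2R chromosome "C";
# after 2R only RXFP1 (C1) and RXFP2 (C2) survive plus RXFP2-like, modelled
# here as the second AncRxfp2 ohnolog translocated away from C (linkage
# group F4) — the alternative reading (an inaccurate reconstruction) is
# preserved downstream as an unresolved attachment, not here.
name: fig2-fission
description: >
  Fission variant: one pre-2R chromosome carries both AncRln-like and
  AncRxfp3/4; 1R -> fission of the II-copy -> 2R yields linkage groups
  A0-A5 with ligand-receptor pairs retained on A0 and A1.
families:
  AncRln-like: RLN/INSL
  AncRxfp3/4: RXFP3/4
  AncRxfp1/2: RXFP1/2
root:
  genome:
    A: [AncRln-like, AncRxfp3/4]
    C: [AncRxfp1/2]
tree:
  name: pre2R_vertebrate
  children:
    - name: gnathostome_ancestor
      events:
        - wgd:
            tag: 1R
            chromosomes:
              A: [A-I, A-II]
              C: [C-I, C-II]
            genes:
              AncRln-like: [AncRln-I, AncRln-II]
              AncRxfp3/4: [AncRxfp3-I, AncRxfp3-II]
              AncRxfp1/2: [AncRxfp1, AncRxfp2]
        - fission:
            chromosome: A-II
            at: 1
            names: [A-IIa, A-IIb]
        - wgd:
            tag: 2R
            chromosomes:
              A-I: [A0, A1]
              A-IIa: [A2, A3]
              A-IIb: [A4, A5]
              C-I: [C0, C1]
              C-II: [C2, C3]
            genes:
              AncRln-I: [RLN, INSL3]
              AncRln-II: [RLN3, INSL5]
              AncRxfp3-I: [RXFP3-1, RXFP3-2]
              AncRxfp3-II: [RXFP3-3, RXFP3-4]
              AncRxfp1: [RXFP1-B, RXFP1]
              AncRxfp2: [RXFP2, RXFP2-like]
        - loss: {genes: [RXFP1-B]}
        - translocation: {gene: RXFP2-like, to: F4}
      children:
        - name: tetrapod_ancestor
          events:
            - loss: {genes: [RXFP3-2]}
          children:
            - name: human
              events:
                - pseudogenize: {genes: [RXFP3-3, RXFP2-like]}
                - rename: {RXFP3-1: RXFP3, RXFP3-4: RXFP4}
            - name: chicken
              events:
                - loss: {genes: [RLN, RXFP3-3, RXFP3-4]}
                - pseudogenize: {genes: [RXFP2]}
        - name: teleost_ancestor
          events:
            - rename:
                RLN: rln
                INSL3: insl3
                RLN3: rln3
                INSL5: insl5
                RXFP3-1: rxfp3-1
                RXFP3-2: rxfp3-2
                RXFP3-3: rxfp3-3
                RXFP3-4: rxfp4
                RXFP1: rxfp1
                RXFP2: rxfp2
                RXFP2-like: rxfp2-like
          children:
            - name: teleost_post3R
              events:
                - wgd:
                    tag: 3R
                    genes:
                      rln: [rln, rln-3Rb]
                      insl3: [insl3-3Ra, insl3]
                      rln3: [rln3a, rln3b]
                      insl5: [insl5a, insl5b]
                      rxfp3-1: [rxfp3-1, rxfp3-1-3Rb]
                      rxfp3-2: [rxfp3-2a, rxfp3-2b]
                      rxfp3-3: [rxfp3-3a, rxfp3-3b]
                      rxfp4: [rxfp4, rxfp4-3Rb]
                      rxfp1: [rxfp1a, rxfp1b]
                      rxfp2: [rxfp2a, rxfp2b]
                      rxfp2-like: [rxfp2-like, rxfp2-like-3Rb]
                - loss:
                    genes: [rln-3Rb, insl3-3Ra, rxfp3-1-3Rb, rxfp4-3Rb, rxfp2-like-3Rb]
                - tandem_dup:
                    gene: rxfp3-3a
                    copies: 2
                    names: [rxfp3-3a1, rxfp3-3a2]
              children:
                - name: medaka
                  events:
                    - loss: {genes: [rxfp1b, rxfp2b, rxfp2-like]}
                    - rename: {rxfp1a: rxfp1, rxfp2a: rxfp2}
                - name: zebrafish
                  events:
                    - loss: {genes: [rxfp1b, rxfp4]}
                    - tandem_dup:
                        gene: rxfp3-3a2
                        copies: 2
                        names: [rxfp3-3a2, rxfp3-3a3]
                    - rename: {rxfp1a: rxfp1}
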