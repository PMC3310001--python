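# The alternative FUSION variant of pre-2R chromosome "A" evolution: the
# ancestral ligand (AncRln-like) and receptor (AncRxfp3/4) start on separate
# pre-2R linkage groups; after 1R, one ligand copy and one receptor copy
# become linked by chromosome fusion, so half of the post-2R duplicates are
# syntenic.  The gnathostome-ancestor gene complement — and everything
# downstream — is identical to the fission variant; only the pre-2R/post-1R
# linkage of the ligand and receptor ancestors differs.
name: fig2-fusion
description: >
  Fusion variant: AncRln-like and AncRxfp3/4 on separate pre-2R linkage
  groups; 1R -> fusion of one ligand copy with one receptor copy -> 2R.
families:
  AncRln-like: RLN/INSL
  AncRxfp3/4: RXFP3/4
  AncRxfp1/2: RXFP1/2
root:
  genome:
    Alig: [AncRln-like]
    Arec: [AncRxfp3/4]
    C: [AncRxfp1/2]
tree:
  name: pre2R_vertebrate
  children:
    - name: gnathostome_ancestor
      events:
        - wgd:
            tag: 1R
            chromosomes:
              Alig: [Alig-I, Alig-II]
              Arec: [Arec-I, Arec-II]
              C: [C-I, C-II]
            genes:
              AncRln-like: [AncRln-I, AncRln-II]
              AncRxfp3/4: [AncRxfp3-I, AncRxfp3-II]
              AncRxfp1/2: [AncRxfp1, AncRxfp2]
        - fusion:
            chromosomes: [Alig-I, Arec-I]
            name: A-I
        - wgd:
            tag: 2R
            chromosomes:
              A-I: [A0, A1]
              Alig-II: [A2, A3]
              Arec-II: [A4, A5]
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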