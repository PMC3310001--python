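# Duplication history of the RXFP1/2 receptor family alone: AncRxfp1/2 on
# pre-2R chromosome "C"; 1R yields AncRxfp1/AncRxfp2; 2R yields four copies
# of which the gnathostome ancestor retains RXFP1 (C1), RXFP2 (C2) and
# RXFP2-like (the second AncRxfp2 ohnolog, modelled as translocated to
# linkage group F4).  The 3R duplicates of rxfp1 and rxfp2 are lost in most
# teleosts but partly retained in zebrafish (two rxfp2 co-orthologs).
name: fig3-rxfp12
description: >
  RXFP1/2 family history: 1R/2R on pre-2R chromosome "C", loss of one
  AncRxfp1 ohnolog, translocation of RXFP2-like, teleost 3R with
  lineage-specific duplicate retention in zebrafish.
families:
  AncRxfp1/2: RXFP1/2
root:
  genome:
    C: [AncRxfp1/2]
tree:
  name: pre2R_vertebrate
  children:
    - name: gnathostome_ancestor
      events:
        - wgd:
            tag: 1R
            chromosomes:
              C: [C-I, C-II]
            genes:
              AncRxfp1/2: [AncRxfp1, AncRxfp2]
        - wgd:
            tag: 2R
            chromosomes:
              C-I: [C0, C1]
              C-II: [C2, C3]
            genes:
              AncRxfp1: [RXFP1-B, RXFP1]
              AncRxfp2: [RXFP2, RXFP2-like]
        - loss: {genes: [RXFP1-B]}
        - translocation: {gene: RXFP2-like, to: F4}
      children:
        - name: tetrapod_ancestor
          children:
            - name: human
              events:
                - pseudogenize: {genes: [RXFP2-like]}
            - name: chicken
              events:
                - pseudogenize: {genes: [RXFP2]}
        - name: teleost_ancestor
          events:
            - rename: {RXFP1: rxfp1, RXFP2: rxfp2, RXFP2-like: rxfp2-like}
          children:
            - name: teleost_post3R
              events:
                - wgd:
                    tag: 3R
                    genes:
                      rxfp1: [rxfp1a, rxfp1b]
                      rxfp2: [rxfp2a, rxfp2b]
                      rxfp2-like: [rxfp2-like, rxfp2-like-3Rb]
                - loss: {genes: [rxfp2-like-3Rb]}
              children:
                - name: medaka
                  events:
                    - loss: {genes: [rxfp1b, rxfp2b, rxfp2-like]}
                    - rename: {rxfp1a: rxfp1, rxfp2a: rxfp2}
                - name: zebrafish
                  events:
                    - loss: {genes: [rxfp1b]}
                    - rename: {rxfp1a: rxfp1}
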