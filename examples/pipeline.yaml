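# Full-pipeline configuration for the packaged relaxin-family fixture.
# Paths are resolved relative to this file.
genes: ../src/karyotrace/data/genes.tsv
segment_maps:
  Homo_sapiens: ../src/karyotrace/data/segments_human_n.tsv
  Gallus_gallus: ../src/karyotrace/data/segments_chicken_n.tsv
  Oryzias_latipes: ../src/karyotrace/data/segments_medaka_n.tsv
model: ../src/karyotrace/data/nmodel.yaml
scenario: fission
families: [RLN/INSL, RXFP1/2, RXFP3/4]
ortholog_groups: ../src/karyotrace/data/ortholog_groups.tsv
gene_order: ../src/karyotrace/data/gene_order.tsv
clades:
  tetrapod: [Homo_sapiens, Gallus_gallus]
  teleost: [Oryzias_latipes]
ligand_receptor_pairs:
  - [RLN/INSL, RXFP3/4]
  - [RLN/INSL, RXFP1/2]
  - [RXFP1/2, RXFP3/4]
tandem_kb: 500
window: 10
n_perm: 999
alpha: 0.05
seed: 7
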