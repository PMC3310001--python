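# karyotrace

**Tracing gene families through ancestral vertebrate karyotype
reconstructions.**

Two rounds of whole-genome duplication (WGD, "1R" and "2R") in the early
vertebrate ancestor — plus a third, teleost-specific round ("3R") — shaped
most vertebrate gene families, but deciding *how* a given family diversified
is hard: paralogs can arise by WGD (ohnologs), by tandem/local duplication
(SSD), or look misleading after a single-gene translocation. Ancestral
karyotype reconstructions offer an orthogonal line of evidence: if each
extant chromosome is tiled with segments labelled by the ancestral linkage
group they descend from, then a gene's position *traces* it to a post-2R
gnathostome-ancestor chromosome (**GAC**, labels `A0`–`J1`) and onward to a
pre-2R vertebrate ancestral chromosome (**VAC**, labels `A`–`J`).

karyotrace makes that manual tracing procedure algorithmic, auditable and
testable. It is written for molecular evolutionary biologists studying the
duplication history of specific gene families; its packaged worked example
is the relaxin/insulin-like hormone family (RLN/INSL) and its two receptor
families (RXFP1/2 and RXFP3/4).

## What it computes

1. **Stage 1 — tracing** (`karyotrace.tracing`). Each gene (or pseudogene)
   is assigned to the segment containing its midpoint: `gene → GAC → VAC`,
   with the covered fraction of the gene span reported as evidence.
   Assignments of declared orthologs are reconciled across species;
   disagreements are never settled by majority vote but routed to review.
2. **Stage 2 — ohnology inference** (`karyotrace.ohnology`). Each paralog
   pair is classified from its assignments alone:
   distinct GACs on one VAC → `ohnolog_2R`; same GAC but different teleost
   3R sub-segments → `ohnolog_3R`; same GAC and sub-segment → `local_SSD`;
   different VACs → `translocated_or_ambiguous`. Verdicts are assembled
   into a duplication-history tree (pre-2R root → post-1R intermediates →
   post-2R lineages → 3R/SSD copies) with Dollo-style loss annotation and
   origin-based nomenclature (the gene commonly called *RXFP4* is, by
   origin, *RXFP3-4*).
3. **Stage 3 — small-scale synteny** (`karyotrace.synteny`). Conflicts are
   examined by shared flanking-gene families in a rank window, with a
   permutation p-value drawn from same-sized random windows of the genome.
   This is how the chicken gene annotated "RXFP2" is re-labelled
   *RXFP2-like*: its neighbourhood (including *STARD8*) matches the human
   X-linked *RXFP2-like* pseudogene, not human *RXFP2*.
4. **Simulation & replay** (`karyotrace.simulator`). A seeded forward
   simulator evolves genomes through WGDs with loss, tandem duplication,
   translocation, fission and fusion, emitting extant gene tables *and* the
   true segment maps plus full ground truth — so stages 1–2 are validated
   against a known answer. A deterministic replay engine executes
   hand-written event scenarios (the packaged ligand/receptor histories in
   both the "fission" and "fusion" variant of pre-2R chromosome "A") and
   snapshots every named ancestor.

## Worked example

Run the full pipeline on the packaged relaxin-family fixture:

```bash
karyotrace pipeline --config examples/pipeline.yaml --out out/
```

or equivalently from Python:

```python
from karyotrace import data
from karyotrace.pipeline import run_pipeline

cfg = {
    "genes": str(data.data_path("genes.tsv")),
    "segment_maps": {
        "Homo_sapiens": str(data.data_path("segments_human_n.tsv")),
        "Gallus_gallus": str(data.data_path("segments_chicken_n.tsv")),
        "Oryzias_latipes": str(data.data_path("segments_medaka_n.tsv")),
    },
    "model": str(data.data_path("nmodel.yaml")),
    "scenario": "fission",
    "families": list(data.FAMILIES),
    "ortholog_groups": str(data.data_path("ortholog_groups.tsv")),
    "gene_order": str(data.data_path("gene_order.tsv")),
    "clades": data.CLADES,
    "ligand_receptor_pairs": [list(p) for p in data.LIGAND_RECEPTOR_PAIRS],
    "seed": 7,
}
result = run_pipeline(cfg, outdir="out")
print((result.outdir / "summary.txt").read_text())
```

which prints:

```
karyotrace pipeline summary
===========================

scenario variant : fission
genes traced     : 32 (32 assigned, 0 unassigned)
pair verdicts    : local_SSD=1, ohnolog_2R=45, ohnolog_3R=5, translocated_or_ambiguous=4
post-2R lineages : RLN/INSL=4, RXFP1/2=3, RXFP3/4=4
independent receptor lineages (vertebrate-wide): 7
independent ligand lineages (vertebrate-wide)  : 4
pre-2R ancestral genes (tree roots)            : 3
inferred losses  : RLN/INSL:RLN-1:Gallus_gallus; RXFP1/2:RXFP2-like:teleost; RXFP3/4:RXFP3-2:tetrapod; RXFP3/4:RXFP3-3:Gallus_gallus; RXFP3/4:RXFP3-4:Gallus_gallus
conflicts        : RXFP2
  resolved       : RXFP2
  unresolved     : none
```

Reading the numbers: the four ligand lineages trace to four distinct
post-2R linkage groups (`A0`–`A3`) on one pre-2R chromosome — they are 2R
ohnologs, not tandem copies. The receptors comprise **seven lineages of
independent origin** (three RXFP1/2-type and four RXFP3/4-type), rooted
with the ligands in just **three pre-2R genes**. *RXFP3-2* is inferred lost
in the tetrapod clade; the chicken "RXFP2" conflict (it traces to `B0|F4`
instead of the expected `C2`) is resolved by neighbourhood synteny as
*RXFP2-like*, recorded as provenance, never overwritten. The tree diagrams,
pairwise verdicts, linkage report and every assignment decision are written
next to the summary.

Replaying the packaged event history reproduces the teleost expansion
directly:

```bash
karyotrace replay --scenario src/karyotrace/data/scenarios/fig2_fission.yaml \
    --out out/replay --nodes medaka
# {"files": 3, "gene_counts": {"medaka": 15}}
```

## Layout

```
src/karyotrace/
  model.py      core types + TSV/BED-like I/O (gene tables, segment maps,
                ancestry models, assignments)
  tracing.py    stage 1: midpoint assignment + ortholog reconciliation
  ohnology.py   stage 2: pair classification, duplication trees, nomenclature
  synteny.py    stage 3: neighbourhood scoring, permutation null, linkage report
  simulator.py  stochastic simulator + deterministic scenario replay
  pipeline.py   orchestration, reports; cli.py: the `karyotrace` command
  data/         packaged fixtures: gene tables, segment maps (synthetic
                coordinates consistent with the published assignments),
                ancestry model, event scenarios, gene-order table
docs/methods.md the model, its assumptions, parameters and limitations
```
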