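# Methods

## The model

karyotrace treats an extant genome as a mosaic of chromosomal segments, each
descending from one linkage group of a reconstructed ancestral karyotype.
Two ancestry levels carry the vertebrate analysis:

* **GAC** (gnathostome-ancestor chromosome): a post-2R linkage group.  The
  packaged vertebrate model ("N-model") declares 40 labels, `A0`–`J1`.
* **VAC** (vertebrate ancestral chromosome): a pre-2R linkage group,
  `A`–`J`; every GAC has exactly one VAC parent (`gac_to_vac`).  Where the
  underlying reconstruction resolves the intermediate post-1R state, GACs
  are additionally grouped into post-1R ancestors (`post1r_groups`, e.g.
  `AncA-I = {A0, A1}`).
* An optional **3R** level carries the teleost-specific sub-segment label
  (`a`/`b`) distinguishing the two products of the fish genome duplication,
  and a **CLG** level (chordate linkage groups) lets the same machinery run
  against a chordate-ancestor reconstruction.

The core assumption, inherited from the tracing procedure itself, is that a
gene has remained inside its ancestral segment since the pre-2R ancestor
unless a single-gene translocation moved it.  Under that assumption the
duplication mechanism of a paralog pair is a pure function of segment
labels:

| evidence                                             | verdict |
|------------------------------------------------------|---------|
| distinct GACs, one VAC                                | `ohnolog_2R` |
| same GAC, different 3R sub-segments                   | `ohnolog_3R` |
| same GAC and sub-segment, within the tandem window    | `local_SSD` |
| same GAC, different chromosomes, no 3R divergence     | `local_SSD` (duplication later separated by fission — the parsimonious reading) |
| same GAC, same chromosome, beyond the tandem window   | `translocated_or_ambiguous` |
| different VACs                                        | `translocated_or_ambiguous` |

Ambiguous assignments (a segment labelled e.g. `B0|F4`) are classified under
every candidate label; a non-unanimous result is `translocated_or_ambiguous`.
The verdict is symmetric, deterministic, and logged with its evidence.

## Tunable parameters

| parameter | default | units | role |
|-----------|---------|-------|------|
| `tandem_kb` | 500 | kb | maximum midpoint separation for calling a same-segment pair tandem.  No distance is stated for the manual procedure; 500 kb comfortably contains observed tandem arrays while staying far below segment sizes.  Configurable and recorded in every verdict. |
| `window` | 10 | gene ranks per side | neighbourhood size for synteny scoring.  Ranks, not base pairs, so assembly density cancels; manual neighbourhood inspections are rank-like. |
| `n_perm` | 999 | – | permutation count for the synteny null; p has granularity 1/(n_perm+1). |
| `alpha` | 0.05 | – | p-value threshold below which a conflicted ortholog may be re-labelled (the published analyses give no numeric criterion; this is a stated package default). |

## Stage 1: assignment and reconciliation

A gene is assigned to the segment containing its **midpoint**; the fraction
of its span inside that segment is reported as evidence so
boundary-straddlers are visible (genes are orders of magnitude smaller than
segments, and the midpoint rule is independent of gene order).  A midpoint
in an unlabelled gap, or a chromosome absent from the map, yields an
explicit unassigned record, not an error.

Reconciliation across declared orthologs requires every assigned member to
be compatible with one label.  Disagreements are *routed to synteny review*,
never outvoted: the interesting case is precisely one species' gene tracing
elsewhere (translocation or misannotation), and a majority rule would erase
it.

## Stage 3: synteny review

The review scores the outlier's flanking families against one reference
context per candidate lineage (candidates are the expected group plus every
ortholog group sharing a label with the outlier).  The permutation null
redraws the reference as a random complete window of the same size from its
genome — excluding the reference's own window, since the question is what a
random *other* region achieves.  A rename is recommended only when an
alternative lineage scores strictly higher than the expected one with
p < `alpha`; the original name is kept as provenance.

## The simulator and what passing tests show

`simulate()` evolves `n_genes` single-copy genes on `n_chromosomes`
chromosomes through a configurable WGD series (default `1R, 2R`), with:

* per-copy retention failure after each WGD (`loss_prob`, default 0.3 —
  vertebrate-scale post-WGD retention);
* chromosome fission at Poisson rate `fission_rate` (default 0.3/epoch) in
  every epoch;
* chromosome fusion (`fusion_rate`, default 0.3/epoch), tandem duplication
  (`tandem_rate`, default 0.02/gene) and single-gene translocation
  (`transloc_rate`, default 0) in the **terminal epoch only** — see
  "identifiability" below;
* full truth bookkeeping: every surviving gene carries its pre-2R ancestor,
  its per-WGD lineage identity, a chronological divergence path, and event
  flags; the true segment map tiles every chromosome.

Fixture emission uses a synthetic coordinate system (one gene per 10-kb
rank slot) so simulated genomes round-trip through the standard file
formats.

**Identifiability constraints.**  Two event placements are deliberately
excluded from the default study conditions because they make the truth
unrecoverable *in principle*, not merely hard:

1. a tandem duplication **between** WGDs yields cross-copy pairs (copy 1 of
   gene A vs the WGD-sibling of copy 2) that sit on distinct same-VAC GACs
   — segment evidence cannot distinguish them from ohnologs (this is
   exactly the historical tandem-vs-ohnolog ambiguity for the ligand
   family);
2. a chromosome fusion **between** WGDs can merge the two 1R copies of one
   chromosome, so genuine 1R ohnologs share a post-2R linkage group,
   violating the one-VAC-per-GAC structure that reconstructions assert.

Both event types are common *after* the last WGD in the system this package
models, and that is where the simulator places them.  Consequently the
validation suite shows: with translocation off, stage 1 recovers the true
linkage group for 100% of surviving genes and stage 2 matches the true
mechanism for 100% of surviving pairs (50 seeds × 100 genes); with 5%
translocation, ≥90% of translocated genes with a surviving non-translocated
family member are flagged `translocated_or_ambiguous`, and every mislabeled
pair involves a translocated gene.  A translocated singleton (no surviving
paralog) is undetectable by pairwise classification and is excluded from
the flagging denominator.

**What the generator does not emulate**: sequence evolution (genes are
lineage labels; there is no mutation, conversion or concerted evolution),
polymorphism, dating, assembly error, or annotation noise.  Passing tests
therefore validate the *logic* of tracing and classification against known
histories; on real data the binding constraints are the accuracy of the
ancestral reconstruction and of gene annotation, which the simulator cannot
probe.

## The replay engine and packaged scenarios

`replay()` executes a YAML event scenario — a clade tree whose branches
carry ordered `wgd` / `fission` / `fusion` / `loss` / `pseudogenize` /
`tandem_dup` / `translocation` / `rename` events — deterministically, and
snapshots the genome at every named node (ancestors included).  Three
scenarios ship with the package:

* `fig2_fission.yaml` — the adopted history: ligand and RXFP3/4-receptor
  ancestors syntenic on pre-2R chromosome "A"; 1R → fission → 2R yields
  `A0`–`A5`; tetrapods lose *RXFP3-2* (and, per species, *RXFP3-3*);
  teleosts retain all four receptor ohnologs through 3R with stated losses
  and the local duplication of *rxfp3-3a*; the RXFP1/2 history on pre-2R
  chromosome "C" runs alongside, with *RXFP2-like* modelled as the second
  *AncRxfp2* ohnolog translocated off its linkage group.
* `fig2_fusion.yaml` — the alternative variant: separate pre-2R ligand and
  receptor linkage groups joined by a post-1R fusion.  The
  gnathostome-ancestor gene complement is identical; only the early linkage
  differs.  (The source literature labels these variants inconsistently;
  this package names them by mechanism and adopts the fission variant as
  the default, which is the variant that both minimizes pre-2R linkage
  groups and places ligand and receptor ancestors syntenic before 2R.)
* `fig3_rxfp12.yaml` — the RXFP1/2 family alone, including the zebrafish
  branch that retains two *rxfp2* 3R duplicates.

Under the fusion reading, linkage groups `A0`/`A1` have two pre-2R parents,
which would break the unique GAC→VAC map; the package keeps `gac_to_vac`
identical across variants (the reconstruction's own labels) and records the
variant only as scenario metadata — classification outcomes are unaffected.

## Fixture provenance and design choices

The published reconstructions do not release segment coordinates, so the
packaged segment maps use synthetic intervals chosen only to be consistent
with every stated gene-to-linkage-group assignment; the 40-label inventory
distributes labels over VACs consistently with all labels named in the
sources (`A0`–`A5`, `B0`, `C1`, `C2`, `F4`, bounds `A0`–`J1`).  Where the
species' exact mapped locus set is not enumerated (chicken's four receptor
loci; which of `A2`/`A3` hosts *RLN3* vs *INSL5*), the fixture adopts the
figure-derived layout and says so here.  Eutherian- and ape-specific local
duplicates of the *RLN* locus (*INSL4*, *INSL6*, *RLN1*) are outside the
replayed scenario: the analysis maps four human ligand loci and no tested
count involves them.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; readers convert 1-based
  input on request.  Midpoints are exact halves; ties inside a segment are
  impossible by construction (half-open intervals).
* Ambiguity sets serialize as sorted `|`-joined labels; unassigned fields
  as `NA`.
* The permutation p-value is `(1 + #{null ≥ observed}) / (1 + n_perm)`,
  never 0; under the null it is stochastically ≥ uniform (calibration is
  part of the test suite: 200 replicates at `n_perm` 999 on a 240-gene,
  40-family synthetic genome).
* Empty inputs (empty gene table, empty family list, empty history) produce
  empty but valid outputs, exit status 0.
* Duplication trees with mutually inconsistent verdicts (a 2R-ohnolog claim
  inside one local-duplication lineage, or two same-lineage copies
  disagreeing about a third gene) raise an error naming the offending
  genes rather than building a tree.
* The loss-parsimony report states the adopted WGD-retention score next to
  the alternative that explains one ohnolog pair by post-duplication local
  copying (always ≥ 2 events worse: the extra duplication plus the
  translocation needed to reach a distinct linkage group).

## Known limitations

* Stage-2 verdicts are only as good as the segment maps; a mis-reconstructed
  linkage group produces `translocated_or_ambiguous` verdicts that cannot be
  distinguished from real translocations without outside evidence — which
  is why the unresolved case in the worked example is carried as two
  candidate edges, not decided.
* The 3R fallback (calling teleost co-orthologs on distinct chromosomes 3R
  duplicates when no 3R sub-segment labels exist) is implemented through
  the same-GAC/different-chromosome rule and cannot separate a 3R duplicate
  from a fission-split tandem pair without sub-segment labels.
* Ortholog groups are inputs; the package does not infer orthology.
* Problem sizes in the validation suite (100 genes, 10 chromosomes, 50
  seeds; 200 calibration replicates at 999 permutations) are the package's
  chosen study conditions; they run in seconds while giving hundreds of
  pairs per replicate.
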