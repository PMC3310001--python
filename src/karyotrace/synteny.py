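"""Stage 3 — small-scale synteny scoring with a permutation null.

When declared orthologs trace to incompatible ancestral linkage groups, the
deciding evidence is the gene neighbourhood: two regions descending from the
same locus share flanking gene families.  The window is measured in gene
ranks (not base pairs), which is robust to assembly-density differences and
mirrors how such neighbourhoods are inspected by eye.

The score — the number of gene families present in both flanks — is given a
permutation p-value by re-drawing equally sized windows uniformly from the
genome's gene order, so a shared neighbourhood can be distinguished from what
same-sized random windows achieve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import Assignment, GeneLocus

GENE_ORDER_COLUMNS = ["species", "chrom", "rank", "gene", "family"]

DEFAULT_WINDOW = 10
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class NeighborhoodContext:
    """The families flanking a focal gene within ``window`` gene ranks."""

    species: str
    focal: str
    window: int
    flanks: tuple[tuple[int, str], ...]  # (offset, family), sorted by offset

    def __post_init__(self) -> None:
        w = self.window
        for off, _fam in self.flanks:
            if off == 0 or off < -w or off > w:
                raise ValueError(f"flank offset {off} outside [-{w}, {w}] \\ {{0}}")
        object.__setattr__(self, "flanks", tuple(sorted(self.flanks)))

    @property
    def families(self) -> frozenset[str]:
        return frozenset(f for _off, f in self.flanks)


def read_gene_order(path: str | Path) -> pd.DataFrame:
    """Gene-order table: TSV ``species chrom rank gene family``."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_ORDER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: gene-order table missing columns {missing}")
    return df.sort_values(["species", "chrom", "rank"]).reset_index(drop=True)


def build_context(
    gene_order: pd.DataFrame, species: str, gene: str, window: int = DEFAULT_WINDOW
) -> NeighborhoodContext:
    sub = gene_order[gene_order["species"] == species]
    hit = sub[sub["gene"] == gene]
    if len(hit) != 1:
        raise ValueError(f"gene {gene!r} not uniquely present in {species!r} gene order")
    chrom = hit["chrom"].iloc[0]
    rank0 = int(hit["rank"].iloc[0])
    neigh = sub[(sub["chrom"] == chrom) & (sub["rank"] != rank0)
                & (sub["rank"] >= rank0 - window) & (sub["rank"] <= rank0 + window)]
    flanks = tuple(
        (int(r) - rank0, str(f)) for r, f in zip(neigh["rank"], neigh["family"])
    )
    return NeighborhoodContext(species=species, focal=gene, window=window, flanks=flanks)


def synteny_score(a: NeighborhoodContext, b: NeighborhoodContext) -> int:
    """Number of gene families present in both flanks (each counted once)."""
    if a.window != b.window:
        raise ValueError("contexts must be built with the same window")
    return len(a.families & b.families)


def _window_family_sets(
    gene_order: pd.DataFrame, species: str, window: int, exclude_focal: str | None = None
) -> list[frozenset[str]]:
    """Family sets of every complete window position in one genome.

    The window centred on ``exclude_focal`` is left out: the null asks what
    a random *other* region of the genome achieves, so the observed window
    must not be redrawn as its own competitor.
    """
    out: list[frozenset[str]] = []
    sub = gene_order[gene_order["species"] == species]
    for _chrom, grp in sub.groupby("chrom", sort=True):
        ordered = grp.sort_values("rank")
        fams = list(ordered["family"].astype(str))
        names = list(ordered["gene"].astype(str))
        n = len(fams)
        for center in range(window, n - window):
            if exclude_focal is not None and names[center] == exclude_focal:
                continue
            flank = fams[center - window:center] + fams[center + 1:center + window + 1]
            out.append(frozenset(flank))
    return out


def synteny_pvalue(
    a: NeighborhoodContext,
    b: NeighborhoodContext,
    gene_order: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for the shared-neighbourhood score of ``a`` vs ``b``.

    The null redraws the second context as a random complete window of the
    same size from ``b``'s genome in the gene-order table (excluding ``b``'s
    own window) and rescores against ``a``;
    p = (1 + #{null >= observed}) / (1 + n_perm).  Reproducible under a
    fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    observed = synteny_score(a, b)
    pool = _window_family_sets(gene_order, b.species, b.window, exclude_focal=b.focal)
    if not pool:
        raise ValueError(
            f"window of {b.window} genes per side exceeds every chromosome of "
            f"{b.species!r} in the gene-order table"
        )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(pool), size=n_perm)
    a_fams = a.families
    hits = sum(1 for i in idx if len(a_fams & pool[i]) >= observed)
    return (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# conflict review (the stage-3 resolution rule)
# ---------------------------------------------------------------------------

@dataclass
class ReviewResult:
    """Outcome of re-examining a conflicted ortholog by its neighbourhood.

    A rename is recommended only when an alternative lineage's context beats
    the expected lineage's with a strictly higher score and a p-value below
    the threshold; the original name is kept as provenance, never destroyed.
    """

    outlier: str
    scores: dict[str, int] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)
    best_lineage: str | None = None
    renamed_to: str | None = None


def review_conflict(
    outlier: NeighborhoodContext,
    candidates: Mapping[str, NeighborhoodContext],
    gene_order: pd.DataFrame,
    expected: str,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> ReviewResult:
    """Score a conflicted gene's neighbourhood against candidate lineages.

    ``candidates`` maps lineage name -> reference context (e.g. the human
    ortholog's neighbourhood for each plausible lineage); ``expected`` names
    the lineage the gene was annotated as.
    """
    res = ReviewResult(outlier=f"{outlier.species}/{outlier.focal}")
    for i, (lineage, ctx) in enumerate(sorted(candidates.items())):
        res.scores[lineage] = synteny_score(outlier, ctx)
        res.pvalues[lineage] = synteny_pvalue(
            outlier, ctx, gene_order, n_perm=n_perm, seed=seed + i
        )
    res.best_lineage = max(sorted(res.scores), key=lambda k: res.scores[k])
    if (
        res.best_lineage != expected
        and res.scores[res.best_lineage] > res.scores.get(expected, 0)
        and res.pvalues[res.best_lineage] < alpha
    ):
        res.renamed_to = res.best_lineage
    return res


# ---------------------------------------------------------------------------
# ligand-receptor linkage report
# ---------------------------------------------------------------------------

def linkage_report(
    assignments: Sequence[Assignment],
    family_pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Per-species chromosomal linkage of ligand and receptor genes.

    For each species and each (family A, family B) gene pair: whether the
    two genes currently share a chromosome, and the ancestral state (shared
    post-2R linkage group / shared pre-2R chromosome) for comparison, so
    lineage-specific gains and losses of linkage are visible as rows whose
    extant and ancestral states differ.  Species lacking both families get
    a single not-applicable row.
    """
    by_species: dict[str, list[Assignment]] = {}
    for a in assignments:
        by_species.setdefault(a.locus.species, []).append(a)
    rows = []
    for species in sorted(by_species):
        asg = by_species[species]
        for fam_a, fam_b in family_pairs:
            in_a = [x for x in asg if x.locus.family == fam_a]
            in_b = [x for x in asg if x.locus.family == fam_b]
            if not in_a and not in_b:
                rows.append({
                    "species": species, "family_a": fam_a, "family_b": fam_b,
                    "gene_a": "NA", "gene_b": "NA", "linked": "NA",
                    "same_gac": "NA", "same_vac": "NA",
                })
                continue
            for x in in_a:
                for y in in_b:
                    same_gac = bool(x.gac_set & y.gac_set) if (x.gac_set and y.gac_set) else False
                    same_vac = (
                        x.vac is not None and x.vac == y.vac
                    )
                    rows.append({
                        "species": species, "family_a": fam_a, "family_b": fam_b,
                        "gene_a": x.locus.name, "gene_b": y.locus.name,
                        "linked": x.locus.chromosome == y.locus.chromosome,
                        "same_gac": same_gac, "same_vac": same_vac,
                    })
    return pd.DataFrame(
        rows,
        columns=["species", "family_a", "family_b", "gene_a", "gene_b",
                 "linked", "same_gac", "same_vac"],
    )


def loci_by_name(loci: Sequence[GeneLocus]) -> dict[tuple[str, str], GeneLocus]:
    return {(g.species, g.name): g for g in loci}
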