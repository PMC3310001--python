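"""Stage 1 — assign genes to ancestral linkage groups and reconcile across species.

A gene is assigned to the segment containing its midpoint (genes are tiny
relative to reconstruction segments, and the midpoint rule is independent of
neighbouring gene order).  The fraction of the gene's span covered by that
segment is reported as ``evidence`` so boundary-straddling genes are visible.

Cross-species reconciliation never outvotes a species: a disagreement among
declared orthologs is routed to small-scale synteny review (stage 3) rather
than resolved by majority, because a single translocated or misannotated gene
is exactly the case the review exists for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .model import AncestryModel, Assignment, GeneLocus, SegmentMap

logger = logging.getLogger("karyotrace.tracing")


def assign_gene(locus: GeneLocus, segmap: SegmentMap, model: AncestryModel) -> Assignment:
    """Assign one gene to a post-2R linkage group (GAC) and derive its VAC.

    Unassigned (gac=None) when the gene's chromosome is absent from the map
    (logged as a warning, not an error) or when its midpoint falls in a gap
    between segments.
    """
    if segmap.species and segmap.species != locus.species:
        raise ValueError(
            f"segment map is for {segmap.species!r}, gene {locus.name} is from "
            f"{locus.species!r}"
        )
    variant = ",".join(f"{v}:{s}" for v, s in sorted(model.vac_scenario.items()))
    if locus.chromosome not in segmap.chromosomes():
        logger.warning(
            "%s/%s: chromosome %s absent from segment map; unassigned",
            locus.species, locus.name, locus.chromosome,
        )
        return Assignment(locus, None, None, 0.0, model_variant=variant)
    seg = segmap.locate(locus.chromosome, locus.midpoint)
    if seg is None:
        logger.info(
            "%s/%s: midpoint %.0f in a gap on %s; unassigned",
            locus.species, locus.name, locus.midpoint, locus.chromosome,
        )
        return Assignment(locus, None, None, 0.0, model_variant=variant)
    labels = seg.labels_at("GAC") or seg.labels_at(next(iter(seg.labels)))
    evidence = seg.overlap(locus.start, locus.end) / locus.span
    if len(labels) == 1:
        gac: str | frozenset[str] = next(iter(labels))
        vac = model.vac_of(gac)
    else:
        gac = frozenset(labels)
        vacs = model.vacs_of(labels)
        vac = next(iter(vacs)) if len(vacs) == 1 else None
    logger.info(
        "%s/%s -> GAC %s (VAC %s, evidence %.3f)",
        locus.species, locus.name,
        "|".join(sorted(labels)), vac, evidence,
    )
    return Assignment(
        locus, gac, vac, evidence, segment_labels=seg.labels, model_variant=variant
    )


def trace_family(
    loci: Iterable[GeneLocus],
    maps: Mapping[str, SegmentMap],
    model: AncestryModel,
) -> list[Assignment]:
    """Assign every locus using its species' segment map (deterministic).

    Every species present among ``loci`` must have a map; a missing map is a
    caller error (KeyError), unlike a missing chromosome which merely yields
    an unassigned gene.
    """
    out = []
    for locus in loci:
        if locus.species not in maps:
            raise KeyError(f"no segment map provided for species {locus.species!r}")
        out.append(assign_gene(locus, maps[locus.species], model))
    return out


@dataclass
class Reconciliation:
    """Outcome of comparing assignments across declared orthologs.

    ``consensus`` is the agreed single GAC label, or None.  ``conflict``
    marks groups whose members were traced to incompatible linkage groups
    (or that are entirely unassigned); such groups carry
    ``needs_review=True`` and are routed to stage-3 synteny review.
    """

    group: str
    consensus: str | None
    conflict: bool
    labels_by_member: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def needs_review(self) -> bool:
        return self.conflict


def reconcile_orthologs(
    assignments: Sequence[Assignment], group: str = ""
) -> Reconciliation:
    """Compare assignments of declared orthologs across species.

    Agreement requires every assigned member to be compatible with one
    single label (an ambiguity set is compatible with a label it contains).
    Any disagreement is flagged as a conflict; a group with no assigned
    member at all is a conflict with empty consensus.
    """
    labels_by_member: dict[tuple[str, str], str] = {}
    assigned = []
    for a in assignments:
        key = (a.locus.species, a.locus.name)
        labels_by_member[key] = a.gac_token()
        if not a.is_unassigned:
            assigned.append(a)
    if not assigned:
        return Reconciliation(group, None, True, labels_by_member)
    # candidate consensus labels = intersection of all members' candidate sets
    candidates = frozenset.intersection(*[a.gac_set for a in assigned])
    single = {a.gac for a in assigned if not a.is_ambiguous}
    if len(candidates) >= 1 and len(single) <= 1:
        # all members compatible with one label and no two distinct
        # single-label assignments disagree
        if single:
            consensus = next(iter(single))
            return Reconciliation(group, consensus, False, labels_by_member)
        # only ambiguous members; no unique consensus but not a conflict
        # unless their sets are disjoint (candidates empty, handled below)
        return Reconciliation(group, sorted(candidates)[0] if len(candidates) == 1 else None,
                              len(candidates) == 0, labels_by_member)
    logger.warning(
        "ortholog group %s: conflicting assignments %s; routed to synteny review",
        group or "<unnamed>",
        {f"{sp}/{g}": lab for (sp, g), lab in labels_by_member.items()},
    )
    return Reconciliation(group, None, True, labels_by_member)
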