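"""Stage 2 — duplication-mechanism classification and duplication-history trees.

Given linkage-group assignments, each within-family paralog pair is classified
by the mechanism that created it:

* ``ohnolog_2R`` — the pair sits on distinct post-2R linkage groups (GACs)
  descending from one pre-2R chromosome (VAC): the signature of the two
  rounds of whole-genome duplication in the early vertebrate ancestor.
* ``ohnolog_3R`` — same GAC but the two teleost sub-segments (``a``/``b``)
  produced by the fish-specific genome duplication.
* ``local_SSD`` — same GAC and sub-segment: a small-scale (tandem/local)
  duplication.  A same-GAC pair split onto two chromosomes without 3R
  divergence is also called local_SSD: a shared post-2R segment label can
  only arise by local duplication (possibly followed by chromosome fission).
* ``translocated_or_ambiguous`` — the pair's linkage groups trace to
  different pre-2R chromosomes (or the evidence is internally inconsistent):
  either a single-gene translocation after duplication or an inaccurate
  reconstruction; never silently resolved.

The verdict is a pure function of the assignments, the ancestry model and the
tandem-distance threshold; it is symmetric in pair order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .model import AncestryModel, Assignment

VERDICTS = ("ohnolog_2R", "ohnolog_3R", "local_SSD", "translocated_or_ambiguous", "deferred")

#: default maximum separation (kb) for calling a same-segment pair a tandem
#: duplicate; configurable and recorded in every verdict's rationale.
DEFAULT_TANDEM_KB = 500.0


class InconsistentOhnologyError(ValueError):
    """Raised when pair verdicts are mutually inconsistent (names the triple)."""


@dataclass(frozen=True)
class PairClassification:
    pair: tuple[str, str]          # (species/gene, species/gene), sorted
    verdict: str
    rationale: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")
        object.__setattr__(self, "rationale", dict(self.rationale))


def _qual(a: Assignment) -> str:
    return f"{a.locus.species}/{a.locus.name}"


def _verdict_single(
    gac_a: str,
    gac_b: str,
    a: Assignment,
    b: Assignment,
    model: AncestryModel,
    tandem_bp: float,
) -> str:
    if gac_a != gac_b:
        vac_a, vac_b = model.vac_of(gac_a), model.vac_of(gac_b)
        if vac_a is not None and vac_a == vac_b:
            return "ohnolog_2R"
        return "translocated_or_ambiguous"
    # same GAC
    sub_a, sub_b = a.sublabel_3r, b.sublabel_3r
    if sub_a and sub_b and sub_a != sub_b:
        return "ohnolog_3R"
    if a.locus.chromosome == b.locus.chromosome:
        if abs(a.locus.midpoint - b.locus.midpoint) <= tandem_bp:
            return "local_SSD"
        return "translocated_or_ambiguous"
    # same segment label on different chromosomes, no 3R divergence:
    # parsimoniously a local duplication later separated by fission
    return "local_SSD"


def classify_pair(
    a: Assignment,
    b: Assignment,
    model: AncestryModel,
    tandem_kb: float = DEFAULT_TANDEM_KB,
) -> PairClassification:
    """Classify a paralog pair by duplication mechanism (see module docstring).

    Ambiguous assignments are handled by classifying every candidate label
    combination: a unanimous verdict stands, anything else is
    ``translocated_or_ambiguous``.  An unassigned member defers the verdict.
    """
    names = tuple(sorted((_qual(a), _qual(b))))
    if _qual(b) == names[0]:
        a, b = b, a
    base = {
        "gac": (a.gac_token(), b.gac_token()),
        "vac": (a.vac, b.vac),
        "tandem_kb": tandem_kb,
    }
    if a.is_unassigned or b.is_unassigned:
        who = [n for n, x in zip(names, (a, b)) if x.is_unassigned]
        return PairClassification(names, "deferred", {**base, "reason": f"unassigned: {who}"})
    tandem_bp = tandem_kb * 1000.0
    verdicts = {
        _verdict_single(x, y, a, b, model, tandem_bp)
        for x, y in itertools.product(sorted(a.gac_set), sorted(b.gac_set))
    }
    if len(verdicts) == 1:
        verdict = next(iter(verdicts))
        note = ""
    else:
        verdict = "translocated_or_ambiguous"
        note = f"candidate labels disagree: {sorted(verdicts)}"
    if a.locus.species == b.locus.species and a.locus.chromosome == b.locus.chromosome:
        base["distance_bp"] = abs(a.locus.midpoint - b.locus.midpoint)
    if note:
        base["note"] = note
    return PairClassification(names, verdict, base)


def classify_family_pairs(
    assignments: Sequence[Assignment],
    model: AncestryModel,
    tandem_kb: float = DEFAULT_TANDEM_KB,
    within_species: bool = True,
) -> list[PairClassification]:
    """All within-family pair verdicts (by default per species)."""
    out = []
    for a, b in itertools.combinations(assignments, 2):
        if a.locus.family != b.locus.family:
            continue
        if within_species and a.locus.species != b.locus.species:
            continue
        out.append(classify_pair(a, b, model, tandem_kb))
    return sorted(out, key=lambda c: c.pair)


def check_transitivity(classifications: Iterable[PairClassification]) -> None:
    """2R-ohnology must be consistent with the lineage partition.

    Local-duplication and 3R edges group genes into post-2R lineages; genes
    of one lineage must then agree in their 2R-ohnology relations to every
    other lineage.  A triple where (a,b) are same-lineage copies but (a,c)
    is an ohnolog while (b,c) is not cannot describe one duplication
    history; raise naming the offending genes.
    """
    cls = list(classifications)
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        parent[find(x)] = find(y)

    for c in cls:
        if c.verdict in ("local_SSD", "ohnolog_3R"):
            union(*c.pair)
    cross: dict[tuple[str, str], dict[str, tuple[str, str]]] = {}
    for c in cls:
        ra, rb = find(c.pair[0]), find(c.pair[1])
        if ra == rb:
            if c.verdict == "ohnolog_2R":
                raise InconsistentOhnologyError(
                    f"pair {c.pair} is ohnolog_2R yet joined into one lineage "
                    f"by local/3R duplications"
                )
            continue
        if c.verdict == "deferred":
            continue
        key = tuple(sorted((ra, rb)))
        seen = cross.setdefault(key, {})
        seen[c.verdict] = c.pair
        is_2r = {"ohnolog_2R"} & set(seen)
        not_2r = {"local_SSD", "translocated_or_ambiguous"} & set(seen)
        if is_2r and not_2r:
            raise InconsistentOhnologyError(
                "non-transitive ohnology between lineages of "
                f"{key[0]} and {key[1]}: {seen['ohnolog_2R']} is ohnolog_2R "
                f"but {seen[not_2r.pop()]} is not"
            )


# ---------------------------------------------------------------------------
# duplication-history trees
# ---------------------------------------------------------------------------

#: per-family naming metadata: root name and the stem used by the
#: origin-based nomenclature (pre-2R "Anc<stem>", post-1R "Anc<stem>-I/II",
#: post-2R "<STEM>-k", post-3R lowercase with a/b, local copies numbered).
FAMILY_NAMING = {
    "RLN/INSL": {"root": "AncRln-like", "stem": "Rln"},
    "RXFP3/4": {"root": "AncRxfp3/4", "stem": "Rxfp3"},
    "RXFP1/2": {"root": "AncRxfp1/2", "stem": "Rxfp2"},
}

#: traditional gene symbols whose origin-based name differs (kept as aliases)
COMMON_NAME_OVERRIDES = {
    # post-2R lineage label -> {common post-2R name}
    "RXFP3/4": {"A0": "RXFP3-1", "A1": "RXFP3-2", "A4": "RXFP3-3", "A5": "RXFP3-4"},
}


@dataclass
class TreeNode:
    """One lineage in a duplication-history tree.

    ``kind`` is one of pre2R/post1R/post2R/post3R/SSD.  ``genes`` lists the
    extant (species, gene, status) tuples attached at this node.  An
    ``unresolved`` post-2R node records both candidate interpretations of a
    gene whose linkage group disagrees with its presumed ohnologs (ohnolog
    vs. post-duplication translocation) without choosing.
    """

    name: str
    kind: str
    label: str = ""                     # GAC label / sub-segment label
    children: list["TreeNode"] = field(default_factory=list)
    genes: list[tuple[str, str, str]] = field(default_factory=list)
    losses: list[str] = field(default_factory=list)  # clades/species where lost
    unresolved: bool = False
    candidate_edges: list[str] = field(default_factory=list)

    def walk(self):
        yield self
        for ch in self.children:
            yield from ch.walk()

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "kind": self.kind,
            "label": self.label,
            "genes": [list(g) for g in self.genes],
        }
        if self.losses:
            d["losses"] = list(self.losses)
        if self.unresolved:
            d["unresolved"] = True
            d["candidate_edges"] = list(self.candidate_edges)
        if self.children:
            d["children"] = [c.to_dict() for c in self.children]
        return d


@dataclass
class DuplicationTree:
    family: str
    root: TreeNode
    scenario_scores: dict[str, float] = field(default_factory=dict)

    def lineages(self) -> list[TreeNode]:
        """Post-2R lineage nodes (local-duplication copies collapse into them)."""
        return [n for n in self.root.walk() if n.kind == "post2R"]

    def losses(self) -> list[tuple[str, str]]:
        return [(n.name, cl) for n in self.root.walk() for cl in n.losses]

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "scenario_scores": dict(self.scenario_scores),
            "root": self.root.to_dict(),
        }


def _lineage_sort_key(model: AncestryModel, label: str) -> tuple:
    group = model.post1r_of(label) or "~"
    return (group, label)


def build_duplication_tree(
    family: str,
    assignments: Sequence[Assignment],
    model: AncestryModel,
    classifications: Sequence[PairClassification] | None = None,
    clades: Mapping[str, Sequence[str]] | None = None,
) -> DuplicationTree:
    """Build the minimal-event duplication-history tree for one family.

    One pre-2R root per VAC-coherent ohnolog set; post-1R intermediates come
    from the ancestry model's reconstructed groups where available; gene
    losses are inferred Dollo-style (a lineage absent from an entire clade
    whose sister clade retains it is annotated lost in that clade, else lost
    per-species).  A lineage whose linkage group is ambiguous or traces to a
    foreign VAC is attached as an *unresolved* node carrying both candidate
    edges rather than silently resolved.

    ``scenario_scores`` reports the loss count of the adopted
    WGD-retention scenario next to the alternative that explains one
    ohnolog pair by small-scale duplication instead (which always needs the
    extra duplication and a translocation to reach a distinct linkage
    group), so the parsimony comparison is explicit.
    """
    fam = [a for a in assignments if a.locus.family == family]
    if classifications:
        check_transitivity(classifications)
    naming = FAMILY_NAMING.get(family, {"root": f"Anc{family}", "stem": family})
    root = TreeNode(name=naming["root"], kind="pre2R")
    tree = DuplicationTree(family=family, root=root)
    if not fam:
        return tree

    # group genes by linkage lineage: single GAC label, or the ambiguity set
    by_lineage: dict[object, list[Assignment]] = {}
    for a in fam:
        if a.is_unassigned:
            continue
        key = a.gac if not a.is_ambiguous else tuple(sorted(a.gac_set))
        by_lineage.setdefault(key, []).append(a)

    single_labels = sorted(
        [k for k in by_lineage if isinstance(k, str)],
        key=lambda lb: _lineage_sort_key(model, lb),
    )
    vacs = model.vacs_of(single_labels)
    dominant_vac = None
    if len(vacs) == 1:
        dominant_vac = next(iter(vacs))
    elif len(vacs) > 1:
        # multiple VACs among unambiguous lineages: keep the majority VAC as
        # the root's and attach the rest unresolved (evidence forces review,
        # not a silent multi-root forest)
        counts = {v: sum(1 for lb in single_labels if model.vac_of(lb) == v) for v in vacs}
        dominant_vac = max(sorted(counts), key=lambda v: counts[v])

    overrides = COMMON_NAME_OVERRIDES.get(family, {})
    post1r_nodes: dict[str, TreeNode] = {}
    stem = naming["stem"]
    k = 0
    for label in single_labels:
        k += 1
        lineage_name = overrides.get(label, f"{stem.upper()}-{k}")
        vac = model.vac_of(label)
        node = TreeNode(name=lineage_name, kind="post2R", label=label)
        if vac != dominant_vac:
            node.unresolved = True
            node.candidate_edges = [
                f"2R ohnolog retained on VAC {vac}",
                f"translocated from VAC {dominant_vac} after duplication",
            ]
        _attach_descendants(node, by_lineage[label])
        group = model.post1r_of(label)
        if group is not None and not node.unresolved:
            parent = post1r_nodes.get(group)
            if parent is None:
                roman = group.split("-")[-1] if "-" in group else group
                parent = TreeNode(name=f"Anc{stem}-{roman}", kind="post1R", label=group)
                post1r_nodes[group] = parent
                root.children.append(parent)
            parent.children.append(node)
        else:
            root.children.append(node)

    # ambiguous lineages: unresolved attachment with both candidate edges
    for key in sorted(k for k in by_lineage if isinstance(k, tuple)):
        labels = list(key)
        members = by_lineage[key]
        # prefer the most specific member annotation as the lineage name
        name = max(sorted({a.locus.name for a in members}), key=len)
        vac_opts = sorted(model.vacs_of(labels))
        node = TreeNode(
            name=name,
            kind="post2R",
            label="|".join(labels),
            unresolved=True,
            candidate_edges=[
                f"2R ohnolog of the VAC-{dominant_vac} set (reconstruction of "
                f"VAC {'/'.join(vac_opts)} inaccurate)",
                f"translocated to VAC {'/'.join(vac_opts)} after duplication",
            ],
        )
        _attach_descendants(node, members)
        root.children.append(node)

    _annotate_losses(tree, fam, clades)
    n_losses = len(tree.losses())
    if len(tree.lineages()) >= 2:
        tree.scenario_scores = {
            "wgd_retention_losses": float(n_losses),
            "ssd_alternative_losses": float(n_losses + 2),
        }
    return tree


def _attach_descendants(lineage: TreeNode, members: Sequence[Assignment]) -> None:
    """Attach post-3R sub-lineages and local-duplication copies under a lineage."""
    by_sub: dict[str, list[Assignment]] = {}
    for a in members:
        by_sub.setdefault(a.sublabel_3r or "", []).append(a)
    subs = sorted(by_sub)
    for sub in subs:
        genes = sorted(
            by_sub[sub],
            key=lambda a: (a.locus.species, a.locus.chromosome, a.locus.start),
        )
        if sub:
            target = TreeNode(name=f"{lineage.name.lower()}{sub}", kind="post3R", label=sub)
            lineage.children.append(target)
        else:
            target = lineage
        # several same-species genes under one (sub-)lineage are local copies
        by_species: dict[str, list[Assignment]] = {}
        for a in genes:
            by_species.setdefault(a.locus.species, []).append(a)
        for sp in sorted(by_species):
            sp_genes = by_species[sp]
            if len(sp_genes) > 1:
                for i, a in enumerate(sp_genes, start=1):
                    copy = TreeNode(name=f"{target.name}{i}", kind="SSD", label=str(i))
                    copy.genes.append((a.locus.species, a.locus.name, a.locus.status))
                    target.children.append(copy)
            else:
                a = sp_genes[0]
                target.genes.append((a.locus.species, a.locus.name, a.locus.status))


def _annotate_losses(
    tree: DuplicationTree,
    assignments: Sequence[Assignment],
    clades: Mapping[str, Sequence[str]] | None,
) -> None:
    if not clades:
        return
    species_seen = {a.locus.species for a in assignments}
    for node in tree.lineages():
        present = {sp for child in node.walk() for (sp, _, _) in child.genes}
        for clade, members in clades.items():
            members_seen = [sp for sp in members if sp in species_seen]
            if not members_seen:
                continue
            others_present = present - set(members)
            if not (present & set(members)) and others_present:
                node.losses.append(clade)        # lost in the whole clade
            else:
                for sp in members_seen:
                    if sp not in present and (present & set(members)):
                        node.losses.append(sp)   # species-level loss


def assign_nomenclature(tree: DuplicationTree) -> dict[str, str]:
    """Origin-based names for every extant gene in a duplication tree.

    The grammar: pre-2R ``Anc<Family>``; post-1R ``Anc<Family>-I/II``;
    post-2R ``<FAMILY>-k``; post-3R lowercase with an ``a``/``b`` suffix;
    local-duplication copies numbered (``a1``, ``a2``, ...).  Traditional
    symbols (e.g. *RXFP4* for the third ohnolog of *RXFP3-1*) are retained
    as aliases: the returned mapping is keyed ``species/gene``.
    """
    names: dict[str, str] = {}

    def origin_name(node: TreeNode, ancestors: list[TreeNode]) -> str:
        lineage = next((n for n in [node, *ancestors] if n.kind == "post2R"), None)
        if lineage is None:
            return node.name
        base = lineage.name
        sub = next((n.label for n in [node, *ancestors] if n.kind == "post3R"), "")
        if sub:
            base = base.lower() + sub
        if node.kind == "SSD":
            base = base.lower() if sub else base
            base += node.label
        return base

    def visit(node: TreeNode, ancestors: list[TreeNode]) -> None:
        for sp, gene, _status in node.genes:
            names[f"{sp}/{gene}"] = origin_name(node, ancestors)
        for ch in node.children:
            visit(ch, [node, *ancestors])

    visit(tree.root, [])
    return names


def count_independent_lineages(
    trees: Iterable[DuplicationTree],
    clade_species: Iterable[str] | None = None,
) -> int:
    """Number of distinct post-2R gene lineages across trees.

    Local-duplication copies collapse into their parent lineage.  With a
    clade filter, only lineages with at least one (pseudo)gene in one of the
    given species are counted; without one, every reconstructed post-2R
    lineage counts (presence anywhere in the sampled vertebrates).
    """
    species = set(clade_species) if clade_species is not None else None
    n = 0
    for tree in trees:
        for node in tree.lineages():
            present = {sp for child in node.walk() for (sp, _, _) in child.genes}
            if species is None or (present & species):
                n += 1
    return n
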