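"""Core data types and file I/O for gene tables, segment maps and ancestry models.

The central abstraction is the *segment map*: a tiling of an extant genome by
intervals, each labelled with the ancestral linkage group it descends from at
one or more ancestry levels.  The vertebrate levels used throughout are

* ``GAC`` — gnathostome-ancestor chromosome, a post-2R linkage group
  (labels like ``A0``–``J1``), each descending from exactly one
* ``VAC`` — vertebrate ancestral chromosome, a pre-2R linkage group
  (labels ``A``–``J``), via the :class:`AncestryModel`;
* ``3R`` — optional teleost-specific sub-segment labels (``a``/``b``)
  distinguishing the two products of the fish-specific genome duplication;
* ``CLG`` — chordate linkage groups of the pre-vertebrate ancestor, usable as
  an alternative ancestry level with the same machinery.

Coordinates are 0-based half-open everywhere internally; 1-based inclusive
inputs can be converted on ingest via the readers' ``one_based`` flag.

An ambiguous reconstruction (a region assignable to more than one linkage
group) is written as a sorted ``|``-joined label, e.g. ``B0|F4``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

STRANDS = {"+", "-", "?"}
STATUSES = {"gene", "pseudogene"}

#: sentinel used in serialized assignment tables for "no label"
NA_TOKEN = "NA"

GENE_TABLE_COLUMNS = ["species", "gene", "family", "chrom", "start", "end", "strand", "status"]
ASSIGNMENT_COLUMNS = ["species", "gene", "gac", "vac", "evidence"]


class GeneTableError(ValueError):
    """Malformed gene-table input; the message names the offending line."""


class SegmentMapError(ValueError):
    """Malformed segment-map input (overlaps, unknown levels, bad intervals)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneLocus:
    """One gene or pseudogene with exact map position.

    Pseudogenes are first-class: every tracing operation accepts them, they
    are distinguished from intact genes only by ``status``.
    """

    species: str
    name: str
    family: str
    chromosome: str
    start: int
    end: int
    strand: str = "?"
    status: str = "gene"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.species}/{self.name}: start must be < end "
                f"(got [{self.start}, {self.end}))"
            )
        if self.start < 0:
            raise ValueError(f"gene {self.species}/{self.name}: negative start")
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.species}/{self.name}: bad strand {self.strand!r}")
        if self.status not in STATUSES:
            raise ValueError(f"gene {self.species}/{self.name}: bad status {self.status!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def is_pseudogene(self) -> bool:
        return self.status == "pseudogene"


@dataclass(frozen=True)
class Segment:
    """A labelled interval on an extant chromosome (0-based half-open).

    ``labels`` maps ancestry level -> label; an ambiguous label is a
    ``|``-joined string and can be expanded with :meth:`labels_at`.
    """

    chromosome: str
    start: int
    end: int
    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"segment on {self.chromosome}: bad interval [{self.start}, {self.end})"
            )
        if not self.labels:
            raise ValueError(f"segment on {self.chromosome}: at least one label required")
        object.__setattr__(self, "labels", dict(self.labels))

    def labels_at(self, level: str) -> frozenset[str]:
        """All candidate labels at ``level`` (ambiguity expanded), or empty."""
        raw = self.labels.get(level)
        if raw is None:
            return frozenset()
        return frozenset(raw.split("|"))

    def contains(self, pos: float) -> bool:
        return self.start <= pos < self.end

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


class SegmentMap:
    """Per-species set of non-overlapping labelled segments.

    Segments are stored sorted by (chromosome, start) regardless of input
    order; gaps between segments are allowed (real reconstructions leave
    unassigned regions).
    """

    def __init__(self, species: str, segments: Iterable[Segment], provenance: str = ""):
        self.species = species
        self.provenance = provenance
        self.segments: list[Segment] = sorted(segments, key=lambda s: (s.chromosome, s.start))
        self._by_chrom: dict[str, list[Segment]] = {}
        for seg in self.segments:
            self._by_chrom.setdefault(seg.chromosome, []).append(seg)
        for chrom, segs in self._by_chrom.items():
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise SegmentMapError(
                        f"{species}: overlapping segments on {chrom}: "
                        f"[{a.start}, {a.end}) and [{b.start}, {b.end})"
                    )
        self._starts = {c: [s.start for s in segs] for c, segs in self._by_chrom.items()}

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def segments_on(self, chromosome: str) -> list[Segment]:
        return list(self._by_chrom.get(chromosome, []))

    def levels(self) -> set[str]:
        out: set[str] = set()
        for seg in self.segments:
            out.update(seg.labels)
        return out

    def locate(self, chromosome: str, pos: float) -> Segment | None:
        """The segment containing ``pos`` on ``chromosome``, or None (gap)."""
        segs = self._by_chrom.get(chromosome)
        if not segs:
            return None
        i = bisect.bisect_right(self._starts[chromosome], pos) - 1
        if i >= 0 and segs[i].contains(pos):
            return segs[i]
        return None

    def distinct_labels(self, level: str) -> set[str]:
        """Distinct labels declared at ``level``, ambiguity sets expanded."""
        out: set[str] = set()
        for seg in self.segments:
            out.update(seg.labels_at(level))
        return out


@dataclass
class AncestryModel:
    """The GAC->VAC parent map plus reconstruction-variant metadata.

    Parameters
    ----------
    gac_to_vac
        Maps each post-2R linkage-group label to its unique pre-2R parent.
    vac_scenario
        Per-VAC rearrangement variant (``fission``/``fusion``) where the
        underlying reconstruction offers alternatives.
    post1r_groups
        Optional map from a post-1R intermediate linkage group (e.g.
        ``AncA-I``) to the post-2R labels descending from it.  Consistency
        (one VAC per group) is enforced.
    gac_count
        Declared number of post-2R labels in the model.
    """

    name: str
    gac_to_vac: dict[str, str]
    vac_scenario: dict[str, str] = field(default_factory=dict)
    post1r_groups: dict[str, list[str]] = field(default_factory=dict)
    gac_count: int | None = None

    def __post_init__(self) -> None:
        for group, gacs in self.post1r_groups.items():
            vacs = {self.gac_to_vac[g] for g in gacs if g in self.gac_to_vac}
            missing = [g for g in gacs if g not in self.gac_to_vac]
            if missing:
                raise ValueError(f"post-1R group {group}: unknown GAC labels {missing}")
            if len(vacs) > 1:
                raise ValueError(f"post-1R group {group}: members span several VACs {sorted(vacs)}")
        if self.gac_count is None:
            self.gac_count = len(self.gac_to_vac)

    def vac_of(self, gac: str) -> str | None:
        return self.gac_to_vac.get(gac)

    def vacs_of(self, gacs: Iterable[str]) -> frozenset[str]:
        return frozenset(v for v in (self.vac_of(g) for g in gacs) if v is not None)

    def post1r_of(self, gac: str) -> str | None:
        for group, members in self.post1r_groups.items():
            if gac in members:
                return group
        return None

    def with_scenario(self, vac: str, scenario: str) -> "AncestryModel":
        if scenario not in ("fission", "fusion"):
            raise ValueError(f"unknown scenario {scenario!r}")
        new = dict(self.vac_scenario)
        new[vac] = scenario
        return replace(self, vac_scenario=new)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        vacs: dict[str, list[str]] = {}
        for gac, vac in self.gac_to_vac.items():
            vacs.setdefault(vac, []).append(gac)
        return {
            "name": self.name,
            "gac_count": self.gac_count,
            "vacs": {v: sorted(g) for v, g in sorted(vacs.items())},
            "vac_scenarios": dict(self.vac_scenario),
            "post1r_groups": {k: list(v) for k, v in self.post1r_groups.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AncestryModel":
        gac_to_vac = {g: v for v, gacs in d.get("vacs", {}).items() for g in gacs}
        gac_to_vac.update(d.get("gac_to_vac", {}))
        return cls(
            name=d.get("name", "unnamed"),
            gac_to_vac=gac_to_vac,
            vac_scenario=dict(d.get("vac_scenarios", {})),
            post1r_groups={k: list(v) for k, v in d.get("post1r_groups", {}).items()},
            gac_count=d.get("gac_count"),
        )


def load_ancestry_model(path: str | Path, scenario: str | None = None) -> AncestryModel:
    """Load an :class:`AncestryModel` from YAML.

    ``scenario`` overrides the rearrangement variant for every VAC that
    declares alternatives (the labels themselves are shared by both
    variants; the switch is recorded so downstream output can report which
    reconstruction produced it).
    """
    with open(path) as fh:
        d = yaml.safe_load(fh)
    model = AncestryModel.from_dict(d)
    if scenario is not None:
        for vac in list(model.vac_scenario):
            model = model.with_scenario(vac, scenario)
    return model


@dataclass(frozen=True)
class Assignment:
    """A gene's ancestral linkage-group assignment.

    ``gac`` is a single label, a frozenset of >=2 candidate labels
    (ambiguous reconstruction), or None (unassigned: midpoint in a gap or
    on a chromosome absent from the map).  ``vac`` is derived through the
    ancestry model whenever it is unique.  ``evidence`` is the fraction of
    the gene's span covered by the assigned segment, so reviewers can spot
    genes straddling a segment boundary.  ``segment_labels`` carries the
    full label set of the containing segment (e.g. the teleost ``3R``
    sub-segment label) for downstream classification.
    """

    locus: GeneLocus
    gac: str | frozenset[str] | None
    vac: str | None
    evidence: float
    segment_labels: Mapping[str, str] = field(default_factory=dict)
    model_variant: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.gac, frozenset) and len(self.gac) < 2:
            raise ValueError("ambiguity sets must have >= 2 members")
        object.__setattr__(self, "segment_labels", dict(self.segment_labels))

    @property
    def is_unassigned(self) -> bool:
        return self.gac is None

    @property
    def is_ambiguous(self) -> bool:
        return isinstance(self.gac, frozenset)

    @property
    def gac_set(self) -> frozenset[str]:
        if self.gac is None:
            return frozenset()
        if isinstance(self.gac, frozenset):
            return self.gac
        return frozenset({self.gac})

    @property
    def sublabel_3r(self) -> str | None:
        return self.segment_labels.get("3R")

    def gac_token(self) -> str:
        """Serialized form: sorted '|'-joined labels or the NA sentinel."""
        if self.gac is None:
            return NA_TOKEN
        if isinstance(self.gac, frozenset):
            return "|".join(sorted(self.gac))
        return self.gac


def parse_gac_token(token: str) -> str | frozenset[str] | None:
    if token == NA_TOKEN or token == "":
        return None
    parts = token.split("|")
    if len(parts) == 1:
        return parts[0]
    return frozenset(parts)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _read_tsv_rows(path: str | Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.lstrip("#") for f in fields]
                continue
            rows.append((lineno, fields))
    if header is None:
        raise GeneTableError(f"{path}: empty file (missing header)")
    return header, rows


def read_gene_table(path: str | Path, one_based: bool = False) -> list[GeneLocus]:
    """Read a tab-separated gene table into a list of :class:`GeneLocus`.

    The file must carry a header naming the columns
    ``species gene family chrom start end strand status``; row order is
    preserved.  Malformed coordinates or unknown status tokens raise
    :class:`GeneTableError` naming the offending line.
    """
    header, rows = _read_tsv_rows(path)
    idx = {name: header.index(name) for name in GENE_TABLE_COLUMNS if name in header}
    missing = [c for c in GENE_TABLE_COLUMNS if c not in idx]
    if missing:
        raise GeneTableError(f"{path}: header missing columns {missing}")
    loci: list[GeneLocus] = []
    for lineno, fields in rows:
        try:
            start = int(fields[idx["start"]])
            end = int(fields[idx["end"]])
            if one_based:
                start -= 1
            locus = GeneLocus(
                species=fields[idx["species"]],
                name=fields[idx["gene"]],
                family=fields[idx["family"]],
                chromosome=fields[idx["chrom"]],
                start=start,
                end=end,
                strand=fields[idx["strand"]],
                status=fields[idx["status"]],
            )
        except (ValueError, IndexError) as exc:
            raise GeneTableError(f"{path}:{lineno}: rejected row: {exc}") from exc
        loci.append(locus)
    return loci


def write_gene_table(loci: Sequence[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in loci:
            fh.write(
                f"{g.species}\t{g.name}\t{g.family}\t{g.chromosome}\t"
                f"{g.start}\t{g.end}\t{g.strand}\t{g.status}\n"
            )


def read_segment_map(
    path: str | Path,
    level: str = "GAC",
    species: str = "",
    provenance: str = "",
    one_based: bool = False,
) -> SegmentMap:
    """Read a BED-like segment file (``chrom  start  end  label  [more...]``).

    A leading ``#``-prefixed header line may name the label columns
    (e.g. ``#chrom start end GAC 3R``); without one, the fourth column is
    taken to be ``level``.  Requesting a level the file does not provide,
    or overlapping segments on one chromosome, is an error.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise SegmentMapError(f"{path}: empty segment file")
    label_cols: list[str]
    if lines[0].startswith("#"):
        header = lines[0].lstrip("#").split("\t")
        if len(header) < 4:
            raise SegmentMapError(f"{path}: header must name at least 4 columns")
        label_cols = header[3:]
        body = lines[1:]
    else:
        label_cols = [level]
        body = lines
    if level not in label_cols:
        raise SegmentMapError(f"{path}: unknown ancestry level {level!r}; file has {label_cols}")
    segments = []
    for ln in body:
        fields = ln.split("\t")
        if len(fields) < 3 + len(label_cols):
            raise SegmentMapError(f"{path}: short row {ln!r}")
        start, end = int(fields[1]), int(fields[2])
        if one_based:
            start -= 1
        labels = {
            col: val for col, val in zip(label_cols, fields[3:]) if val and val != NA_TOKEN
        }
        segments.append(Segment(fields[0], start, end, labels))
    return SegmentMap(species=species, segments=segments, provenance=provenance)


def write_segment_map(segmap: SegmentMap, path: str | Path) -> None:
    levels = sorted(segmap.levels(), key=lambda lv: (lv != "GAC", lv))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\t" + "\t".join(levels) + "\n")
        for seg in segmap:
            vals = [seg.labels.get(lv, NA_TOKEN) for lv in levels]
            fh.write(f"{seg.chromosome}\t{seg.start}\t{seg.end}\t" + "\t".join(vals) + "\n")


@dataclass(frozen=True)
class AssignmentRow:
    """Serialized view of an :class:`Assignment` (what the TSV round-trips)."""

    species: str
    gene: str
    gac: str | frozenset[str] | None
    vac: str | None
    evidence: float


def assignment_rows(assignments: Iterable[Assignment]) -> list[AssignmentRow]:
    return [
        AssignmentRow(a.locus.species, a.locus.name, a.gac, a.vac, a.evidence)
        for a in assignments
    ]


def write_assignments(assignments: Sequence, path: str | Path) -> None:
    """Write assignments as TSV ``species gene gac vac evidence``.

    Ambiguity sets are serialized as sorted ``|``-joined labels; unassigned
    fields as the ``NA`` sentinel.  Accepts :class:`Assignment` or
    :class:`AssignmentRow` items.
    """
    rows = [
        a if isinstance(a, AssignmentRow) else AssignmentRow(
            a.locus.species, a.locus.name, a.gac, a.vac, a.evidence
        )
        for a in assignments
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(ASSIGNMENT_COLUMNS) + "\n")
        for r in rows:
            if r.gac is None:
                gac_token = NA_TOKEN
            elif isinstance(r.gac, frozenset):
                gac_token = "|".join(sorted(r.gac))
            else:
                gac_token = r.gac
            vac_token = r.vac if r.vac is not None else NA_TOKEN
            fh.write(f"{r.species}\t{r.gene}\t{gac_token}\t{vac_token}\t{r.evidence:.6g}\n")


def read_assignments(path: str | Path) -> list[AssignmentRow]:
    header, rows = _read_tsv_rows(path)
    idx = {name: header.index(name) for name in ASSIGNMENT_COLUMNS}
    out = []
    for lineno, fields in rows:
        vac = fields[idx["vac"]]
        out.append(
            AssignmentRow(
                species=fields[idx["species"]],
                gene=fields[idx["gene"]],
                gac=parse_gac_token(fields[idx["gac"]]),
                vac=None if vac == NA_TOKEN else vac,
                evidence=float(fields[idx["evidence"]]),
            )
        )
    return out
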