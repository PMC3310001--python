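"""Forward simulator of karyotype evolution with full ground truth.

Two entry points share one genome representation:

* :func:`simulate` — a seeded stochastic simulator: an ancestral genome of
  single-copy genes goes through a configurable series of whole-genome
  duplications (WGDs) with per-copy loss, plus tandem duplication,
  single-gene translocation, chromosome fission and fusion at configurable
  rates.  Every surviving gene carries its complete truth record (pre-2R
  ancestor, per-WGD lineage identity, event labels, translocation flag), and
  the true segment map of the extant genome is emitted alongside, so the
  tracing and classification stages can be validated against a known answer.

* :func:`replay` — a deterministic engine that executes a hand-written event
  scenario (YAML: a clade tree whose branches carry ordered events) and
  snapshots the genome at every named ancestor and terminal.  Replays of the
  same scenario are bit-identical; no randomness is involved.

Genes are identified by lineage label, not sequence; there is no mutation
model.  Chromosome blocks keep their post-2R linkage-group identity through
later fissions and fusions, which is exactly the structure ancestral-genome
reconstructions recover; a single-gene translocation adopts the label of its
destination block and is thereby invisible to segment-level reconstruction —
the confounder the classification stage must flag.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .model import (
    AncestryModel,
    GeneLocus,
    Segment,
    SegmentMap,
    write_gene_table,
    write_segment_map,
)

#: synthetic coordinate system used when emitting fixtures: one gene per
#: 10 kb rank slot, the gene occupying [rank*10k + 2k, rank*10k + 7k).
SLOT = 10_000
GENE_OFFSET = 2_000
GENE_LEN = 5_000


class ReplayError(ValueError):
    """A scenario event referenced a missing gene/chromosome (names the event)."""


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimGene:
    """A gene instance in a simulated genome, carrying its truth record."""

    name: str
    family: str
    block: str                # linkage-group label of the surrounding segment
    sub3r: str | None = None  # 3R sub-segment label (teleost 'a'/'b')
    status: str = "gene"
    pre2r: str = ""
    lineage: dict[str, str] = field(default_factory=dict)  # WGD tag -> name then
    events: tuple[str, ...] = ()
    #: chronological divergence path: one (event-id, copy-id) entry per
    #: duplication event this gene's lineage went through; two relatives'
    #: first differing entry is the event that separated them
    path: tuple[tuple[str, str], ...] = ()
    translocated: bool = False

    def child(self, **kw) -> "SimGene":
        g = replace(self, **kw)
        g.lineage = dict(self.lineage)
        return g


Genome = dict[str, list[SimGene]]


# ---------------------------------------------------------------------------
# shared state + event primitives
# ---------------------------------------------------------------------------

@dataclass
class _State:
    genome: Genome
    anc1r: dict[str, str | None]        # chromosome -> post-1R ancestor chrom
    post1r_groups: dict[str, list[str]] = field(default_factory=dict)
    wgd_tags: tuple[str, ...] = ()

    def clone(self) -> "_State":
        genome = {c: [g.child() for g in genes] for c, genes in self.genome.items()}
        return _State(
            genome=genome,
            anc1r=dict(self.anc1r),
            post1r_groups={k: list(v) for k, v in self.post1r_groups.items()},
            wgd_tags=self.wgd_tags,
        )

    def find(self, gene: str) -> tuple[str, int] | None:
        for chrom, genes in self.genome.items():
            for i, g in enumerate(genes):
                if g.name == gene:
                    return chrom, i
        return None


def _apply_wgd(
    state: _State,
    tag: str,
    chrom_names: Mapping[str, Sequence[str]] | None = None,
    gene_names: Mapping[str, Sequence[str]] | None = None,
) -> None:
    if tag in state.wgd_tags:
        raise ReplayError(f"wgd: duplicate tag {tag!r}")
    chrom_names = dict(chrom_names or {})
    gene_names = dict(gene_names or {})
    missing = [g for g in gene_names if state.find(g) is None]
    if missing:
        raise ReplayError(f"wgd {tag}: gene name mapping references missing genes {missing}")
    missing_c = [c for c in chrom_names if c not in state.genome]
    if missing_c:
        raise ReplayError(f"wgd {tag}: chromosome mapping references missing {missing_c}")
    new_genome: Genome = {}
    new_anc1r: dict[str, str | None] = {}
    for chrom, genes in state.genome.items():
        for i in (0, 1):
            suffix = "ab"[i]
            names = chrom_names.get(chrom)
            new_chrom = names[i] if names else f"{chrom}-{tag}{suffix}"
            copies = []
            for g in genes:
                gnames = gene_names.get(g.name)
                new_name = gnames[i] if gnames else f"{g.name}-{tag}{suffix}"
                child = g.child(
                    name=new_name,
                    events=g.events + (tag,),
                    path=g.path + ((tag, suffix),),
                )
                child.lineage[tag] = new_name
                if tag == "3R":
                    child.sub3r = suffix
                else:
                    child.block = new_chrom
                copies.append(child)
            new_genome[new_chrom] = copies
            if tag == "1R":
                new_anc1r[new_chrom] = new_chrom
            else:
                new_anc1r[new_chrom] = state.anc1r.get(chrom)
            if tag == "2R":
                anc = state.anc1r.get(chrom)
                if anc is not None:
                    state.post1r_groups.setdefault(f"Anc{anc}", []).append(new_chrom)
    state.genome = new_genome
    state.anc1r = new_anc1r
    state.wgd_tags = state.wgd_tags + (tag,)


def _apply_fission(state: _State, chrom: str, at: int, names: Sequence[str]) -> None:
    if chrom not in state.genome:
        raise ReplayError(f"fission: chromosome {chrom!r} not present")
    genes = state.genome.pop(chrom)
    if not 1 <= at < max(len(genes), 2):
        raise ReplayError(f"fission: split index {at} invalid for {chrom!r} ({len(genes)} genes)")
    anc = state.anc1r.pop(chrom, None)
    state.genome[names[0]] = genes[:at]
    state.genome[names[1]] = genes[at:]
    state.anc1r[names[0]] = anc
    state.anc1r[names[1]] = anc


def _apply_fusion(state: _State, chroms: Sequence[str], name: str) -> None:
    missing = [c for c in chroms if c not in state.genome]
    if missing:
        raise ReplayError(f"fusion: chromosomes {missing} not present")
    merged: list[SimGene] = []
    ancs = set()
    for c in chroms:
        merged.extend(state.genome.pop(c))
        ancs.add(state.anc1r.pop(c, None))
    state.genome[name] = merged
    state.anc1r[name] = ancs.pop() if len(ancs) == 1 else None


def _apply_loss(state: _State, genes: Sequence[str]) -> None:
    for gene in genes:
        loc = state.find(gene)
        if loc is None:
            raise ReplayError(f"loss: gene {gene!r} not present")
        chrom, i = loc
        state.genome[chrom].pop(i)


def _apply_pseudogenize(state: _State, genes: Sequence[str]) -> None:
    for gene in genes:
        loc = state.find(gene)
        if loc is None:
            raise ReplayError(f"pseudogenize: gene {gene!r} not present")
        chrom, i = loc
        state.genome[chrom][i] = state.genome[chrom][i].child(status="pseudogene")


def _apply_tandem_dup(state: _State, gene: str, copies: int, names: Sequence[str]) -> None:
    loc = state.find(gene)
    if loc is None:
        raise ReplayError(f"tandem_dup: gene {gene!r} not present")
    if len(names) != copies:
        raise ReplayError(f"tandem_dup: {copies} copies but {len(names)} names")
    chrom, i = loc
    g = state.genome[chrom][i]
    event_id = f"SSD:{gene}"
    made = [g.child(name=names[0], path=g.path + ((event_id, "0"),))]
    for k, nm in enumerate(names[1:], start=1):
        made.append(g.child(
            name=nm,
            events=g.events + ("SSD",),
            path=g.path + ((event_id, str(k)),),
        ))
    state.genome[chrom][i:i + 1] = made


def _apply_translocation(
    state: _State, gene: str, to: str, at: int | None = None
) -> None:
    loc = state.find(gene)
    if loc is None:
        raise ReplayError(f"translocation: gene {gene!r} not present")
    chrom, i = loc
    g = state.genome[chrom].pop(i)
    target = state.genome.setdefault(to, [])
    state.anc1r.setdefault(to, None)
    pos = len(target) if at is None else min(max(at, 0), len(target))
    # adopt the destination block's labels: a single translocated gene is
    # invisible to segment-level reconstruction
    neighbor = target[pos - 1] if pos > 0 else (target[pos] if pos < len(target) else None)
    if neighbor is not None:
        g = g.child(block=neighbor.block, sub3r=neighbor.sub3r)
    else:
        g = g.child(block=to, sub3r=None)
    g = g.child(translocated=True, events=g.events + ("translocation",))
    target.insert(pos, g)


def _apply_rename(state: _State, mapping: Mapping[str, str]) -> None:
    locs = {}
    for old in mapping:
        loc = state.find(old)
        if loc is None:
            raise ReplayError(f"rename: gene {old!r} not present")
        locs[old] = loc
    for old, (chrom, i) in locs.items():
        state.genome[chrom][i] = state.genome[chrom][i].child(name=mapping[old])


# ---------------------------------------------------------------------------
# simulated history container
# ---------------------------------------------------------------------------

class SimulatedHistory:
    """Genomes at every named node plus ground truth for every gene."""

    def __init__(
        self,
        nodes: Mapping[str, Genome],
        leaves: Sequence[str],
        model: AncestryModel,
        meta: Mapping | None = None,
    ):
        self.nodes = dict(nodes)
        self.leaves = list(leaves)
        self.model = model
        self.meta = dict(meta or {})

    def genes(self, node: str, family: str | None = None) -> list[SimGene]:
        genome = self.nodes[node]
        out = []
        for chrom in genome:
            for g in genome[chrom]:
                if family is None or g.family == family:
                    out.append(g)
        return out

    def count_genes(self, node: str, family: str | None = None) -> int:
        return len(self.genes(node, family))

    def count_lineage(self, node: str, post2r: str) -> int:
        """Genes at ``node`` descending from one post-2R lineage identity."""
        return sum(1 for g in self.genes(node) if g.lineage.get("2R") == post2r)

    def truth(self, node: str) -> dict[str, SimGene]:
        return {g.name: g for g in self.genes(node)}

    def gene_table(self, node: str) -> list[GeneLocus]:
        genome = self.nodes[node]
        loci = []
        for chrom in sorted(genome):
            for rank, g in enumerate(genome[chrom]):
                loci.append(GeneLocus(
                    species=node, name=g.name, family=g.family, chromosome=chrom,
                    start=rank * SLOT + GENE_OFFSET,
                    end=rank * SLOT + GENE_OFFSET + GENE_LEN,
                    strand="+", status=g.status,
                ))
        return loci

    def true_segment_map(self, node: str) -> SegmentMap:
        """The ground-truth ancestral segment tiling of a node's genome."""
        genome = self.nodes[node]
        segments = []
        for chrom in sorted(genome):
            genes = genome[chrom]
            run_start = 0
            for i in range(1, len(genes) + 1):
                boundary = i == len(genes) or (
                    (genes[i].block, genes[i].sub3r)
                    != (genes[run_start].block, genes[run_start].sub3r)
                )
                if boundary:
                    labels = {"GAC": genes[run_start].block}
                    if genes[run_start].sub3r:
                        labels["3R"] = genes[run_start].sub3r
                    segments.append(Segment(chrom, run_start * SLOT, i * SLOT, labels))
                    run_start = i
        return SegmentMap(species=node, segments=segments, provenance="simulated-truth")

    def true_verdict(self, node: str, gene_a: str, gene_b: str) -> str | None:
        """Ground-truth duplication mechanism separating two genes, or None
        if they are not members of one family.

        The pair's relationship is decided by the *first* event at which
        their divergence paths differ — a tandem pair duplicated together by
        a later WGD is still a tandem pair.
        """
        truth = self.truth(node)
        a, b = truth[gene_a], truth[gene_b]
        if a.family != b.family:
            return None
        for ea, eb in zip(a.path, b.path):
            if ea != eb:
                event = ea[0]
                if event == "3R":
                    return "ohnolog_3R"
                if event.startswith("SSD"):
                    return "local_SSD"
                return "ohnolog_2R"
        return "local_SSD"


def emit_fixture(
    history: SimulatedHistory,
    outdir: str | Path,
    nodes: Sequence[str] | None = None,
) -> dict[str, Path]:
    """Write gene table + per-node true segment maps + derived ancestry model.

    Files conform to the package's standard formats, so reading them back
    reproduces the extant state of the history.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nodes = list(nodes) if nodes is not None else list(history.leaves)
    paths: dict[str, Path] = {}
    loci = [locus for node in nodes for locus in history.gene_table(node)]
    paths["genes"] = outdir / "genes.tsv"
    write_gene_table(loci, paths["genes"])
    for node in nodes:
        p = outdir / f"segments_{node}.tsv"
        write_segment_map(history.true_segment_map(node), p)
        paths[f"segments_{node}"] = p
    paths["model"] = outdir / "model.yaml"
    with open(paths["model"], "w") as fh:
        yaml.safe_dump(history.model.to_dict(), fh, sort_keys=False)
    return paths


# ---------------------------------------------------------------------------
# stochastic simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Rates and sizes for the stochastic karyotype simulator.

    ``loss_prob`` is the per-copy retention failure applied right after each
    WGD (a scalar, or a pair to bias loss toward one post-WGD copy);
    ``tandem_rate`` and ``transloc_rate`` are per-gene per-epoch
    probabilities; ``fission_rate``/``fusion_rate`` are expected event
    counts (Poisson) per epoch, an epoch being the interval following each
    WGD.
    """

    n_genes: int = 100
    n_chromosomes: int = 10
    wgds: tuple[str, ...] = ("1R", "2R")
    loss_prob: float | tuple[float, float] = 0.3
    tandem_rate: float = 0.02
    transloc_rate: float = 0.0
    fission_rate: float = 0.3
    fusion_rate: float = 0.3

    def __post_init__(self) -> None:
        probs = self.loss_probs + (self.tandem_rate, self.transloc_rate)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("probabilities must be in [0, 1]")
        if self.fission_rate < 0 or self.fusion_rate < 0:
            raise ConfigError("fission/fusion rates must be >= 0")
        if not 1 <= self.n_chromosomes <= 26:
            raise ConfigError("n_chromosomes must be in [1, 26]")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if len(set(self.wgds)) != len(self.wgds):
            raise ConfigError("WGD tags must be unique")

    @property
    def loss_probs(self) -> tuple[float, float]:
        if isinstance(self.loss_prob, (int, float)):
            return (float(self.loss_prob), float(self.loss_prob))
        a, b = self.loss_prob
        return (float(a), float(b))


def simulate(config: SimulationConfig, seed: int) -> SimulatedHistory:
    """Run the stochastic simulator; reproducible under ``seed``.

    Each WGD doubles every chromosome and gene before losses; all truth
    bookkeeping (ancestor identity, per-WGD lineage, SSD/translocation
    events) is populated for every surviving gene.
    """
    rng = np.random.default_rng(seed)
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"[: config.n_chromosomes]
    genome: Genome = {c: [] for c in letters}
    for i in range(config.n_genes):
        chrom = letters[i % len(letters)]
        name = f"g{i:03d}"
        genome[chrom].append(SimGene(name=name, family=name, block=chrom, pre2r=name))
    state = _State(genome=genome, anc1r={c: None for c in letters})

    for i, tag in enumerate(config.wgds):
        _apply_wgd(state, tag)
        _random_losses(state, rng, config.loss_probs)
        # fissions/fusions happen throughout; single-gene events (tandem
        # duplication, translocation) are modelled in the terminal epoch
        # only — a tandem pair arising *between* WGDs produces cross-copy
        # pairs that no segment-level method can distinguish from ohnologs,
        # and the observed local duplications and translocations in this
        # system all post-date the final WGD of their lineage
        _random_rearrangements(state, rng, config, final=(i == len(config.wgds) - 1))

    rename = _prettify_blocks(state)
    model = _derived_model(state, rename)
    history = SimulatedHistory(
        nodes={"sim": state.genome},
        leaves=["sim"],
        model=model,
        meta={"wgd_tags": config.wgds, "seed": seed},
    )
    return history


def _random_losses(state: _State, rng, loss_probs: tuple[float, float]) -> None:
    tag = state.wgd_tags[-1]
    for chrom in list(state.genome):
        kept = []
        for g in state.genome[chrom]:
            copy_idx = 1 if g.lineage.get(tag, "").endswith("b") else 0
            if rng.random() >= loss_probs[copy_idx]:
                kept.append(g)
        state.genome[chrom] = kept


def _random_rearrangements(
    state: _State, rng, config: SimulationConfig, final: bool = True
) -> None:
    for _ in range(rng.poisson(config.fission_rate)):
        candidates = sorted(c for c, genes in state.genome.items() if len(genes) >= 2)
        if not candidates:
            break
        chrom = candidates[rng.integers(len(candidates))]
        at = int(rng.integers(1, len(state.genome[chrom])))
        _apply_fission(state, chrom, at, [f"{chrom}p", f"{chrom}q"])
    if not final:
        # fusions between WGDs would merge two future paralogons into one
        # post-WGD linkage group, breaking the one-ancestral-chromosome-per-
        # linkage-group structure that segment-level reconstructions assert;
        # like single-gene events they are modelled in the terminal epoch
        return
    for _ in range(rng.poisson(config.fusion_rate)):
        chroms = sorted(state.genome)
        if len(chroms) < 2:
            break
        i, j = rng.choice(len(chroms), size=2, replace=False)
        _apply_fusion(state, [chroms[i], chroms[j]], f"{chroms[i]}+{chroms[j]}")
    if config.tandem_rate > 0:
        for chrom in sorted(state.genome):
            for g in list(state.genome[chrom]):
                if rng.random() < config.tandem_rate:
                    k = sum(1 for x in state.genome[chrom] if x.name.startswith(g.name + "~s"))
                    _apply_tandem_dup(state, g.name, 2, [g.name, f"{g.name}~s{k + 1}"])
    if config.transloc_rate > 0:
        for chrom in sorted(state.genome):
            for g in list(state.genome[chrom]):
                if g.name not in {x.name for x in state.genome.get(chrom, [])}:
                    continue
                if rng.random() < config.transloc_rate:
                    others = sorted(c for c in state.genome if c != chrom)
                    if not others:
                        continue
                    to = others[rng.integers(len(others))]
                    at = int(rng.integers(0, len(state.genome[to]) + 1))
                    _apply_translocation(state, g.name, to, at)


def _prettify_blocks(state: _State) -> dict[str, str]:
    """Rename raw hierarchical block labels to the field's letter+digit style."""
    labels = sorted({g.block for genes in state.genome.values() for g in genes})
    by_vac: dict[str, list[str]] = {}
    for lb in labels:
        by_vac.setdefault(lb[0], []).append(lb)
    rename = {}
    for vac in sorted(by_vac):
        for i, lb in enumerate(sorted(by_vac[vac])):
            rename[lb] = f"{vac}{i}"
    for genes in state.genome.values():
        for i, g in enumerate(genes):
            genes[i] = g.child(block=rename[g.block])
    return rename


def _derived_model(state: _State, rename: Mapping[str, str]) -> AncestryModel:
    gac_to_vac = {pretty: pretty[0] for pretty in rename.values()}
    groups: dict[str, list[str]] = {}
    roman = ["I", "II", "III", "IV"]
    by_vac_anc: dict[str, list[str]] = {}
    for anc in sorted(state.post1r_groups):
        vac = anc[3] if anc.startswith("Anc") and len(anc) > 3 else anc[0]
        by_vac_anc.setdefault(vac, []).append(anc)
    for vac, ancs in sorted(by_vac_anc.items()):
        for i, anc in enumerate(sorted(ancs)):
            members = sorted({rename[m] for m in state.post1r_groups[anc] if m in rename})
            if members:
                groups[f"Anc{vac}-{roman[min(i, 3)]}"] = members
    return AncestryModel(
        name="simulated", gac_to_vac=gac_to_vac, post1r_groups=groups
    )


# ---------------------------------------------------------------------------
# deterministic scenario replay
# ---------------------------------------------------------------------------

@dataclass
class EventScenario:
    """A hand-written karyotype-evolution history: a clade tree whose
    branches carry ordered events (wgd/fission/fusion/loss/pseudogenize/
    tandem_dup/translocation/rename) applied to a named root genome."""

    name: str
    root_genome: dict[str, list[str]]
    families: dict[str, str]
    tree: dict
    description: str = ""

    @classmethod
    def from_dict(cls, d: Mapping) -> "EventScenario":
        root = d.get("root", {})
        return cls(
            name=d.get("name", "scenario"),
            description=d.get("description", ""),
            root_genome={c: list(g) for c, g in root.get("genome", {}).items()},
            families=dict(d.get("families", {})),
            tree=dict(d.get("tree", {})),
        )


def load_scenario(path: str | Path) -> EventScenario:
    with open(path) as fh:
        return EventScenario.from_dict(yaml.safe_load(fh))


_EVENT_APPLIERS = {
    "wgd": lambda st, spec: _apply_wgd(
        st, spec["tag"], spec.get("chromosomes"), spec.get("genes")
    ),
    "fission": lambda st, spec: _apply_fission(
        st, spec["chromosome"], spec["at"], spec["names"]
    ),
    "fusion": lambda st, spec: _apply_fusion(st, spec["chromosomes"], spec["name"]),
    "loss": lambda st, spec: _apply_loss(
        st, spec.get("genes") or [spec["gene"]]
    ),
    "pseudogenize": lambda st, spec: _apply_pseudogenize(
        st, spec.get("genes") or [spec["gene"]]
    ),
    "tandem_dup": lambda st, spec: _apply_tandem_dup(
        st, spec["gene"], spec.get("copies", 2), spec["names"]
    ),
    "translocation": lambda st, spec: _apply_translocation(
        st, spec["gene"], spec["to"], spec.get("at")
    ),
    "rename": lambda st, spec: _apply_rename(
        st, {k: v for k, v in spec.items() if k != "event"} if "mapping" not in spec
        else spec["mapping"]
    ),
}


def _apply_events(state: _State, events: Iterable[Mapping], where: str) -> None:
    for ev in events or []:
        if len(ev) != 1:
            raise ReplayError(f"{where}: each event must have exactly one key, got {list(ev)}")
        kind, spec = next(iter(ev.items()))
        if kind not in _EVENT_APPLIERS:
            raise ReplayError(f"{where}: unknown event kind {kind!r}")
        try:
            _EVENT_APPLIERS[kind](state, spec)
        except ReplayError as exc:
            raise ReplayError(f"{where}: {exc}") from None


def replay(scenario: EventScenario) -> SimulatedHistory:
    """Execute a scenario deterministically; snapshot every named node.

    Produces exactly the gene complement implied by the event list; an event
    referencing a missing lineage raises :class:`ReplayError` naming the
    node and event.
    """
    genome: Genome = {}
    for chrom, genes in scenario.root_genome.items():
        genome[chrom] = [
            SimGene(
                name=g,
                family=scenario.families.get(g, g),
                block=chrom,
                pre2r=g,
            )
            for g in genes
        ]
    state = _State(genome=genome, anc1r={c: None for c in genome})
    nodes: dict[str, Genome] = {}
    leaves: list[str] = []
    post1r_groups: dict[str, list[str]] = {}

    def visit(node_spec: Mapping, state: _State) -> None:
        name = node_spec.get("name")
        if not name:
            raise ReplayError("every scenario tree node needs a name")
        _apply_events(state, node_spec.get("events", []), where=name)
        nodes[name] = state.genome
        for grp, members in state.post1r_groups.items():
            post1r_groups.setdefault(grp, [])
            for m in members:
                if m not in post1r_groups[grp]:
                    post1r_groups[grp].append(m)
        children = node_spec.get("children", [])
        if not children:
            leaves.append(name)
        for child in children:
            visit(child, state.clone())

    visit(scenario.tree, state)

    blocks = sorted({g.block for genome in nodes.values() for row in genome.values()
                     for g in [*row]})
    gac_to_vac = {b: _vac_prefix(b) for b in blocks}
    model = AncestryModel(
        name=f"replay:{scenario.name}",
        gac_to_vac=gac_to_vac,
        post1r_groups={
            k: [m for m in v if m in gac_to_vac] for k, v in post1r_groups.items()
        },
    )
    return SimulatedHistory(
        nodes=nodes,
        leaves=leaves,
        model=model,
        meta={"scenario": scenario.name, "wgd_tags": ("1R", "2R", "3R")},
    )


def _vac_prefix(label: str) -> str:
    """Leading alphabetic prefix of a linkage-group label (A0 -> A)."""
    out = []
    for ch in label:
        if ch.isalpha():
            out.append(ch)
        else:
            break
    return "".join(out) or label
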