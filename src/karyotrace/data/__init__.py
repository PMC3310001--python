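"""Packaged fixtures: the relaxin-family worked example.

The gene tables and segment maps encode the published gene-to-linkage-group
assignments for the relaxin-family ligands (RLN/INSL) and their two receptor
families (RXFP1/2, RXFP3/4) in human, chicken and medaka under the vertebrate
pre/post-2R reconstruction ("N-model"), plus the human assignments under the
chordate-ancestor reconstruction ("P-model").

The underlying reconstructions do not publish segment coordinates, so the
interval boundaries here are synthetic — chosen only to be consistent with
every stated gene-to-linkage-group assignment.  Where the sources do not
enumerate a species' exact locus set (e.g. which four receptor loci were
mapped in chicken), the fixture adopts a consistent choice and the package
documentation says so.  The scenario files under ``scenarios/`` describe the
reconstructed event histories (both the fission and the fusion variant of
pre-2R chromosome "A") for deterministic replay.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from ..model import (
    AncestryModel,
    GeneLocus,
    SegmentMap,
    load_ancestry_model,
    read_gene_table,
    read_segment_map,
)

SPECIES = {
    "human": "Homo_sapiens",
    "chicken": "Gallus_gallus",
    "medaka": "Oryzias_latipes",
}

#: clade membership of the fixture species (used for loss inference)
CLADES = {
    "tetrapod": ["Homo_sapiens", "Gallus_gallus"],
    "teleost": ["Oryzias_latipes"],
}

FAMILIES = ("RLN/INSL", "RXFP1/2", "RXFP3/4")

LIGAND_RECEPTOR_PAIRS = [
    ("RLN/INSL", "RXFP3/4"),
    ("RLN/INSL", "RXFP1/2"),
    ("RXFP1/2", "RXFP3/4"),
]


def data_path(name: str) -> Path:
    return Path(str(resources.files(__package__).joinpath(name)))


def load_gene_table() -> list[GeneLocus]:
    return read_gene_table(data_path("genes.tsv"))


def load_segment_maps(model: str = "N") -> dict[str, SegmentMap]:
    """Per-species segment maps under the N-model (GAC/3R levels) or, for
    human only, the P-model (CLG level)."""
    if model == "N":
        return {
            "Homo_sapiens": read_segment_map(
                data_path("segments_human_n.tsv"), "GAC",
                species="Homo_sapiens", provenance="N-model"),
            "Gallus_gallus": read_segment_map(
                data_path("segments_chicken_n.tsv"), "GAC",
                species="Gallus_gallus", provenance="N-model"),
            "Oryzias_latipes": read_segment_map(
                data_path("segments_medaka_n.tsv"), "GAC",
                species="Oryzias_latipes", provenance="N-model"),
        }
    if model == "P":
        return {
            "Homo_sapiens": read_segment_map(
                data_path("segments_human_p.tsv"), "CLG",
                species="Homo_sapiens", provenance="P-model"),
        }
    raise ValueError(f"unknown reconstruction model {model!r}")


def load_model(scenario: str | None = None) -> AncestryModel:
    return load_ancestry_model(data_path("nmodel.yaml"), scenario=scenario)


def load_ortholog_groups() -> dict[str, list[tuple[str, str]]]:
    """Declared ortholog groups: group name -> [(species, gene), ...]."""
    groups: dict[str, list[tuple[str, str]]] = {}
    with open(data_path("ortholog_groups.tsv")) as fh:
        next(fh)
        for line in fh:
            if not line.strip():
                continue
            group, species, gene = line.rstrip("\n").split("\t")
            groups.setdefault(group, []).append((species, gene))
    return groups


def scenario_path(name: str) -> Path:
    return data_path(f"scenarios/{name}.yaml")
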