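import itertools

import pytest

from karyotrace import data
from karyotrace.ohnology import build_duplication_tree, classify_family_pairs
from karyotrace.tracing import trace_family


@pytest.fixture(scope="session")
def model():
    return data.load_model("fission")


@pytest.fixture(scope="session")
def maps():
    return data.load_segment_maps()


@pytest.fixture(scope="session")
def loci():
    return data.load_gene_table()


@pytest.fixture(scope="session")
def assignments(loci, maps, model):
    return trace_family(loci, maps, model)


@pytest.fixture(scope="session")
def family_assignments(assignments):
    def get(family):
        return [a for a in assignments if a.locus.family == family]
    return get


@pytest.fixture(scope="session")
def trees(family_assignments, model):
    out = {}
    for family in data.FAMILIES:
        fam = family_assignments(family)
        cls = classify_family_pairs(fam, model)
        out[family] = build_duplication_tree(
            family, fam, model, classifications=cls, clades=data.CLADES
        )
    return out


def family_pairs(history, node):
    """All same-family gene-name pairs at a simulated node."""
    by_fam = {}
    for g in history.genes(node):
        by_fam.setdefault(g.family, []).append(g.name)
    for names in by_fam.values():
        yield from itertools.combinations(names, 2)
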