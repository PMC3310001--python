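"""Simulator and replay engine: conservation invariants, truth bookkeeping,
deterministic replay of the packaged scenarios, fixture emission."""

import itertools

import pytest

from karyotrace import data
from karyotrace.model import read_gene_table, read_segment_map
from karyotrace.simulator import (
    ConfigError,
    ReplayError,
    SimulationConfig,
    emit_fixture,
    load_scenario,
    replay,
    simulate,
)


@pytest.fixture(scope="module")
def fission_history():
    return replay(load_scenario(data.scenario_path("fig2_fission")))


class TestSimulationConfig:
    def test_invalid_rates_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(loss_prob=1.5)
        with pytest.raises(ConfigError):
            SimulationConfig(transloc_rate=-0.1)
        with pytest.raises(ConfigError):
            SimulationConfig(wgds=("1R", "1R"))


class TestSimulate:
    def test_single_wgd_no_losses_doubles_every_gene(self):
        cfg = SimulationConfig(n_genes=20, n_chromosomes=4, wgds=("1R",),
                               loss_prob=0.0, tandem_rate=0.0,
                               fission_rate=0.0, fusion_rate=0.0)
        h = simulate(cfg, seed=0)
        genes = h.genes("sim")
        assert len(genes) == 40
        assert {g.pre2r for g in genes} == {f"g{i:03d}" for i in range(20)}
        # each ancestral gene has exactly its two copies
        from collections import Counter
        assert set(Counter(g.pre2r for g in genes).values()) == {2}

    def test_total_loss_of_one_post_wgd_copy(self):
        cfg = SimulationConfig(n_genes=20, n_chromosomes=4, wgds=("1R",),
                               loss_prob=(0.0, 1.0), tandem_rate=0.0,
                               fission_rate=0.0, fusion_rate=0.0)
        h = simulate(cfg, seed=0)
        genes = h.genes("sim")
        assert len(genes) == 20
        assert all(g.lineage["1R"].endswith("a") for g in genes)

    def test_reproducible_under_seed(self):
        cfg = SimulationConfig(transloc_rate=0.05)
        a = simulate(cfg, seed=5)
        b = simulate(cfg, seed=5)
        assert [(c, [g.name for g in genes]) for c, genes in a.nodes["sim"].items()] == \
               [(c, [g.name for g in genes]) for c, genes in b.nodes["sim"].items()]

    def test_wgd_doubles_counts_before_losses(self):
        cfg = SimulationConfig(n_genes=50, n_chromosomes=5, loss_prob=0.0,
                               tandem_rate=0.0, fission_rate=0.0, fusion_rate=0.0)
        h = simulate(cfg, seed=1)
        assert len(h.genes("sim")) == 200  # two WGDs, no losses

    @pytest.mark.parametrize("rates", [(2.0, 0.0), (0.0, 2.0)],
                             ids=["fission-only", "fusion-only"])
    def test_fission_fusion_conserve_gene_count_and_order(self, rates):
        fission, fusion = rates
        cfg = SimulationConfig(loss_prob=0.0, tandem_rate=0.0,
                               fission_rate=fission, fusion_rate=fusion)
        h = simulate(cfg, seed=9)
        assert len(h.genes("sim")) == 400  # two WGDs, conserved through moves
        # within each block (post-2R segment), gene order is conserved: genes
        # were created in ascending name order on each ancestral chromosome
        for chrom, genes in h.nodes["sim"].items():
            for _label, run in itertools.groupby(genes, key=lambda g: g.block):
                names = [g.name for g in run]
                assert names == sorted(names)

    def test_true_segment_map_tiles_each_chromosome(self):
        h = simulate(SimulationConfig(fission_rate=1.0, fusion_rate=1.0), seed=3)
        smap = h.true_segment_map("sim")
        for chrom, genes in h.nodes["sim"].items():
            segs = smap.segments_on(chrom)
            if not genes:
                assert segs == []
                continue
            assert segs[0].start == 0
            assert segs[-1].end == len(genes) * 10_000
            for s1, s2 in zip(segs, segs[1:]):
                assert s1.end == s2.start

    def test_every_gene_has_one_pre2r_ancestor(self):
        h = simulate(SimulationConfig(tandem_rate=0.1, transloc_rate=0.05), seed=4)
        for g in h.genes("sim"):
            assert g.pre2r and g.pre2r in {f"g{i:03d}" for i in range(100)}


class TestReplayEngine:
    def test_replay_is_deterministic_and_idempotent(self):
        s = load_scenario(data.scenario_path("fig2_fission"))
        h1, h2 = replay(s), replay(s)
        for node in h1.nodes:
            assert [(c, [g.name for g in genes]) for c, genes in h1.nodes[node].items()] == \
                   [(c, [g.name for g in genes]) for c, genes in h2.nodes[node].items()]

    def test_event_referencing_missing_gene_names_the_node(self):
        s = load_scenario(data.scenario_path("fig2_fission"))
        s.tree["children"][0]["events"].append({"loss": {"genes": ["no-such-gene"]}})
        with pytest.raises(ReplayError, match="gnathostome_ancestor.*no-such-gene"):
            replay(s)

    def test_gnathostome_ancestor_complement(self, fission_history):
        h = fission_history
        assert h.count_genes("gnathostome_ancestor", "RLN/INSL") == 4
        assert h.count_genes("gnathostome_ancestor", "RXFP3/4") == 4
        assert h.count_genes("gnathostome_ancestor", "RXFP1/2") == 3

    def test_teleost_receptor_expansion_to_seven(self, fission_history):
        assert fission_history.count_genes("teleost_post3R", "RXFP3/4") == 7

    def test_medaka_terminal_gene_counts(self, fission_history):
        h = fission_history
        assert h.count_genes("medaka", "RLN/INSL") == 6
        assert h.count_genes("medaka", "RXFP3/4") + h.count_genes("medaka", "RXFP1/2") == 9

    def test_zebrafish_local_copies_and_rxfp2_duplicates(self, fission_history):
        h = fission_history
        a_copies = [g.name for g in h.genes("zebrafish")
                    if g.name.startswith("rxfp3-3a")]
        assert sorted(a_copies) == ["rxfp3-3a1", "rxfp3-3a2", "rxfp3-3a3"]
        assert h.count_lineage("zebrafish", "RXFP2") == 2

    def test_rxfp12_scenario_zebrafish_branch(self):
        h = replay(load_scenario(data.scenario_path("fig3_rxfp12")))
        assert h.count_lineage("zebrafish", "RXFP2") == 2
        assert h.count_lineage("medaka", "RXFP2") == 1

    def test_fusion_variant_reaches_identical_gnathostome_state(self, fission_history):
        fused = replay(load_scenario(data.scenario_path("fig2_fusion")))
        for fam in ("RLN/INSL", "RXFP3/4", "RXFP1/2"):
            assert fused.count_genes("gnathostome_ancestor", fam) == \
                   fission_history.count_genes("gnathostome_ancestor", fam)
        # same gene -> linkage-group truth in both variants
        want = {g.name: g.block for g in fission_history.genes("gnathostome_ancestor")}
        got = {g.name: g.block for g in fused.genes("gnathostome_ancestor")}
        assert got == want

    def test_translocated_gene_is_marked(self, fission_history):
        truth = fission_history.truth("gnathostome_ancestor")
        assert truth["RXFP2-like"].translocated
        assert not truth["RXFP2"].translocated


class TestEmitFixture:
    def test_roundtrip_preserves_gene_counts(self, fission_history, tmp_path):
        paths = emit_fixture(fission_history, tmp_path)
        loci = read_gene_table(paths["genes"])
        for leaf in fission_history.leaves:
            assert sum(1 for g in loci if g.species == leaf) == \
                   fission_history.count_genes(leaf)

    def test_emitted_maps_trace_ligands_to_four_gacs(self, fission_history, tmp_path):
        from karyotrace.tracing import trace_family
        paths = emit_fixture(fission_history, tmp_path,
                             nodes=["human", "chicken", "medaka"])
        loci = read_gene_table(paths["genes"])
        maps = {n: read_segment_map(paths[f"segments_{n}"], "GAC", species=n)
                for n in ("human", "chicken", "medaka")}
        asg = trace_family([g for g in loci if g.family == "RLN/INSL"],
                           maps, fission_history.model)
        assert {a.gac for a in asg} == {"A0", "A1", "A2", "A3"}

    def test_empty_history_writes_valid_empty_files(self, tmp_path):
        from karyotrace.model import AncestryModel
        from karyotrace.simulator import SimulatedHistory
        empty = SimulatedHistory({"only": {}}, ["only"],
                                 AncestryModel("m", {"A0": "A"}))
        paths = emit_fixture(empty, tmp_path)
        assert read_gene_table(paths["genes"]) == []
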