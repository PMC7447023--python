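"""Network construction: locus selection, haplotype collapse, Hamming-1
edges, square counting, cutoff sweep, MAF and LD filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epinet.network import (
    EmptyNetworkError,
    build_for_cutoff,
    build_haplotypes,
    collapse_haplotypes,
    count_squares,
    enumerate_squares,
    ld_prune,
    maf_filter,
    select_loci,
    sweep_cutoffs,
)
from epinet.panel import AssociationTable, GenotypePanel
from epinet.simulate import SimulationConfig, compute_association_pvalues, simulate_panel
from oracles import brute_force_edges, brute_force_squares
from conftest import network_with_values


def make_panel(rows: dict[str, str], phenotypes: dict[str, float], loci=None):
    accs = list(rows)
    length = len(next(iter(rows.values())))
    loci = loci or [f"chr1:{100 * (k + 1)}" for k in range(length)]
    alleles = pd.DataFrame(
        [list(s) for s in rows.values()], index=accs, columns=loci
    )
    pheno = pd.Series(phenotypes).reindex(accs)
    return GenotypePanel(alleles, pheno)


class TestSelectLoci:
    def test_threshold_is_inclusive(self):
        assoc = AssociationTable(
            pd.Series({"chr1:1": 1e-6, "chr1:2": 1e-5, "chr1:3": 1e-3})
        )
        assert select_loci(assoc, 1e-4) == ["chr1:1", "chr1:2"]
        assert select_loci(assoc, 1e-5) == ["chr1:1", "chr1:2"]

    def test_loose_cutoff_keeps_all_in_genomic_order(self):
        assoc = AssociationTable(
            pd.Series({"chr1:30": 0.5, "chr1:4": 0.9, "chr1:100": 0.01})
        )
        assert select_loci(assoc, 0.99) == ["chr1:4", "chr1:30", "chr1:100"]

    def test_cutoff_below_minimum_selects_nothing(self):
        assoc = AssociationTable(pd.Series({"chr1:1": 1e-3}))
        assert select_loci(assoc, 1e-9) == []


class TestHaplotypes:
    def test_concatenation_preserves_order(self):
        panel = make_panel(
            {"a1": "ACG", "a2": "ATG"}, {"a1": 1.0, "a2": 2.0}
        )
        strings = build_haplotypes(panel, panel.loci)
        assert strings.tolist() == ["ACG", "ATG"]

    def test_unphenotyped_accessions_excluded(self):
        panel = make_panel(
            {"a1": "AC", "a2": "AT", "a3": "AC"},
            {"a1": 1.0, "a2": 2.0, "a3": float("nan")},
        )
        strings = build_haplotypes(panel, panel.loci)
        assert list(strings.index) == ["a1", "a2"]

    def test_collapse_computes_member_means(self):
        strings = pd.Series({"a1": "AA", "a2": "AA", "a3": "AT"})
        phen = pd.Series({"a1": 3.0, "a2": 5.0, "a3": 4.0})
        verts = collapse_haplotypes(strings, phen)
        assert verts["AA"]["mean_phenotype"] == 4.0
        assert verts["AA"]["members"] == ["a1", "a2"]
        assert verts["AT"]["mean_phenotype"] == 4.0
        assert len(verts) == 2


class TestBuildNetwork:
    def test_path_of_two_edges_no_distance_two_edge(self):
        net = network_with_values({"AA": 0, "AT": 1, "TT": 2})
        assert set(map(frozenset, net.graph.edges)) == {
            frozenset(("AA", "AT")),
            frozenset(("AT", "TT")),
        }

    def test_distance_two_pair_yields_isolates_and_empty_graph(self):
        net = network_with_values({"AA": 0, "TT": 1})
        assert net.graph.number_of_nodes() == 0
        assert set(net.isolates) == {"AA", "TT"}
        assert net.n_unique_genotypes == 2

    def test_two_position_cycle(self, square_network):
        assert square_network.graph.number_of_edges() == 4
        assert count_squares(square_network)["total"] == 1

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_edges_match_brute_force_hamming(self, data):
        length = data.draw(st.integers(2, 5))
        haps = data.draw(
            st.sets(st.text(alphabet="AT", min_size=length, max_size=length),
                    min_size=2, max_size=30)
        )
        values = {h: float(i) for i, h in enumerate(sorted(haps))}
        net = network_with_values(values)
        expected = brute_force_edges(sorted(haps))
        got = set(map(frozenset, net.graph.edges))
        # isolates are excluded from the graph but never carry edges
        assert got == expected

    def test_component_partition_matches_union_find(self):
        rng = np.random.default_rng(0)
        haps = {"".join(rng.choice(list("AT"), size=4)) for _ in range(40)}
        net = network_with_values({h: 0.0 for h in haps})
        parent = {h: h for h in net.graph.nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for u, v in net.graph.edges:
            parent[find(u)] = find(v)
        for comp in net.components:
            roots = {find(h) for h in comp}
            assert len(roots) == 1


class TestSquares:
    def test_k23_has_three_squares(self):
        # complete bipartite K2,3 as an abstract graph
        import networkx as nx

        G = nx.complete_bipartite_graph(2, 3)
        assert len(enumerate_squares(G)) == 3

    def test_cube_has_six_squares(self, cube_network):
        assert count_squares(cube_network)["total"] == 6

    @settings(max_examples=40, deadline=None)
    @given(st.data())
    def test_square_enumeration_matches_brute_force(self, data):
        length = data.draw(st.integers(2, 4))
        haps = data.draw(
            st.sets(st.text(alphabet="ATG", min_size=length, max_size=length),
                    min_size=4, max_size=20)
        )
        net = network_with_values({h: 0.0 for h in haps})
        edges = set(map(frozenset, net.graph.edges))
        expected = brute_force_squares(edges, sorted(net.graph.nodes))
        got = {
            frozenset((frozenset((u, w)), frozenset((v, x))))
            for u, v, w, x in enumerate_squares(net.graph)
        }
        assert got == expected


class TestSweep:
    @pytest.fixture
    def causal_panel(self):
        cfg = SimulationConfig(
            n_accessions=200, n_causal_loci=4, n_neutral_loci=50,
            minor_allele_freq=0.3, additive_effects=(3.0, 3.0, 3.0, 3.0),
            noise_sd=0.5, seed=42,
        )
        panel = simulate_panel(cfg)
        return panel, compute_association_pvalues(panel)

    def test_sweep_prefers_square_rich_causal_network(self, causal_panel):
        panel, assoc = causal_panel
        result = sweep_cutoffs(panel, assoc)
        assert result.selected_network is not None
        # stringent cutoffs retain only the 4 causal loci
        assert result.selected_network.loci == panel.loci[:4]
        best_row = result.table[
            result.table.neglog10_cutoff == -np.log10(result.selected_cutoff)
        ].iloc[0]
        assert best_row.max_squares_per_component == result.table.max_squares_per_component.max()

    def test_sweep_matches_per_cutoff_rebuild(self, causal_panel):
        panel, assoc = causal_panel
        grid = [4.0, 5.0, 6.0]
        result = sweep_cutoffs(panel, assoc, grid)
        for neglog in grid:
            net = build_for_cutoff(panel, assoc, 10.0 ** -neglog)
            row = result.table[result.table.neglog10_cutoff == neglog].iloc[0]
            assert row.n_unique_genotypes == net.n_unique_genotypes
            assert row.total_squares == count_squares(net)["total"]

    def test_single_value_grid_selected(self, causal_panel):
        panel, assoc = causal_panel
        result = sweep_cutoffs(panel, assoc, [5.0])
        assert result.selected_cutoff == pytest.approx(1e-5)

    def test_selected_loci_non_increasing_with_stringency(self, causal_panel):
        panel, assoc = causal_panel
        result = sweep_cutoffs(panel, assoc)
        n_loci = result.table.sort_values("neglog10_cutoff").n_loci.tolist()
        assert n_loci == sorted(n_loci, reverse=True)


class TestFilters:
    def test_maf_filter_drops_rare_locus(self):
        rows = {f"a{i}": ("T" if i == 0 else "A") + "AT"[i % 2] for i in range(100)}
        phen = {f"a{i}": float(i) for i in range(100)}
        panel = make_panel(rows, phen)
        filtered = maf_filter(panel, 0.05)
        assert len(filtered.loci) == 1  # locus 1 (1% MAF) dropped

    def test_maf_filter_keeps_exact_threshold(self):
        # 5 minor among 100 -> exactly 5%, strictly-below rule retains it
        rows = {f"a{i}": ("T" if i < 5 else "A") for i in range(100)}
        phen = {f"a{i}": float(i) for i in range(100)}
        panel = make_panel(rows, phen)
        assert maf_filter(panel, 0.05).loci == panel.loci

    def test_maf_zero_is_identity(self):
        panel = make_panel({"a": "AT", "b": "TA"}, {"a": 1.0, "b": 2.0})
        assert maf_filter(panel, 0.0) is panel

    def test_ld_prune_keeps_smaller_p_of_perfect_pair(self):
        # locus 2 duplicates locus 1 -> r^2 = 1; the smaller-P one stays
        rows = {f"a{i}": 2 * ("T" if i % 2 else "A") + ("T" if i % 3 else "A")
                for i in range(30)}
        phen = {f"a{i}": float(i) for i in range(30)}
        panel = make_panel(rows, phen)
        assoc = AssociationTable(
            pd.Series({panel.loci[0]: 0.01, panel.loci[1]: 0.001,
                       panel.loci[2]: 0.5})
        )
        pruned = ld_prune(panel, assoc, r2_threshold=0.95)
        assert panel.loci[1] in pruned.loci
        assert panel.loci[0] not in pruned.loci
        assert panel.loci[2] in pruned.loci

    def test_ld_prune_leaves_independent_loci(self):
        rng = np.random.default_rng(1)
        rows = {f"a{i}": "".join(rng.choice(list("AT"), size=4)) for i in range(60)}
        phen = {f"a{i}": float(i) for i in range(60)}
        panel = make_panel(rows, phen)
        assoc = AssociationTable(
            pd.Series({l: 0.01 * (k + 1) for k, l in enumerate(panel.loci)})
        )
        pruned = ld_prune(panel, assoc, r2_threshold=0.99)
        assert pruned.loci == panel.loci


def test_empty_selection_raises_empty_network_error():
    panel = make_panel({"a": "AT", "b": "TA"}, {"a": 1.0, "b": 2.0})
    assoc = AssociationTable(pd.Series({panel.loci[0]: 0.5, panel.loci[1]: 0.5}))
    with pytest.raises(EmptyNetworkError):
        build_for_cutoff(panel, assoc, 1e-6)
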