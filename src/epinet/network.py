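"""Genotype (haplotype) network construction and the P-value cutoff sweep.

Vertices are unique concatenated haplotype strings at phenotype-associated
loci; edges join one-mutant neighbours, i.e. strings at Hamming distance 1.
Only connected components with at least two vertices enter the analysis
network; isolated genotypes are recorded but excluded from graph statistics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .panel import AssociationTable, GenotypePanel

__all__ = [
    "HaploNetwork",
    "SweepResult",
    "select_loci",
    "build_haplotypes",
    "collapse_haplotypes",
    "build_network",
    "network_from_strings",
    "build_for_cutoff",
    "count_squares",
    "enumerate_squares",
    "sweep_cutoffs",
    "maf_filter",
    "ld_prune",
    "EmptyNetworkError",
]


class EmptyNetworkError(ValueError):
    """No analysable network (all vertices isolated, or no loci selected)."""


def _locus_sort_key(locus: str):
    """Ascending genomic order for 'chrom:pos'-style labels; lexicographic
    fallback for opaque ids."""
    parts = str(locus).split(":")
    if len(parts) == 2:
        try:
            return (0, parts[0], int(parts[1]))
        except ValueError:
            pass
    return (1, str(locus), 0)


@dataclass
class HaploNetwork:
    """A genotype network plus its provenance.

    ``graph`` is an undirected :class:`networkx.Graph` whose nodes are
    haplotype strings carrying attributes ``mean_phenotype``, ``members``
    (accession ids) and ``component`` (integer label).  ``isolates`` are
    unique genotypes without any one-mutant neighbour, kept for reporting
    but excluded from all graph statistics.
    """

    graph: nx.Graph
    isolates: dict[str, dict]
    loci: list[str]
    phenotype_name: str = "phenotype"
    cutoff: float | None = None

    @property
    def n_unique_genotypes(self) -> int:
        return self.graph.number_of_nodes() + len(self.isolates)

    @property
    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def largest_component(self) -> set[str]:
        if self.graph.number_of_nodes() == 0:
            raise EmptyNetworkError("network has no connected vertices")
        return max(nx.connected_components(self.graph), key=len)

    def component_sizes(self) -> list[int]:
        return sorted((len(c) for c in self.components), reverse=True)

    def mean_phenotypes(self) -> dict[str, float]:
        return nx.get_node_attributes(self.graph, "mean_phenotype")

    def member_phenotypes(self) -> dict[str, list[float]]:
        return nx.get_node_attributes(self.graph, "member_phenotypes")


def select_loci(assoc: AssociationTable, cutoff: float) -> list[str]:
    """Loci with P <= cutoff, in ascending genomic-label order."""
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must lie in (0, 1)")
    hits = assoc.pvalues[assoc.pvalues <= cutoff].index.tolist()
    return sorted(hits, key=_locus_sort_key)


def build_haplotypes(panel: GenotypePanel, loci: list[str]) -> pd.Series:
    """Concatenate alleles at the selected loci into one string per
    phenotyped accession, preserving accession order."""
    if not loci:
        raise ValueError("locus list is empty")
    sub = panel.alleles.loc[panel.phenotyped_accessions, list(loci)]
    return sub.apply(lambda row: "".join(row), axis=1)


def collapse_haplotypes(
    strings: pd.Series, phenotypes: pd.Series
) -> dict[str, dict]:
    """Deduplicate identical strings; each unique haplotype keeps its member
    accessions, their raw phenotypes and the mean phenotype."""
    lengths = strings.str.len().unique()
    if len(lengths) > 1:
        raise ValueError("haplotype strings have unequal lengths")
    vertices: dict[str, dict] = {}
    for acc, hap in strings.items():
        v = vertices.setdefault(hap, {"members": [], "member_phenotypes": []})
        v["members"].append(acc)
        v["member_phenotypes"].append(float(phenotypes[acc]))
    for v in vertices.values():
        v["mean_phenotype"] = float(np.mean(v["member_phenotypes"]))
    return vertices


def network_from_strings(
    strings: list[str] | pd.Series,
    phenotypes: pd.Series | None = None,
    loci: list[str] | None = None,
    phenotype_name: str = "phenotype",
    cutoff: float | None = None,
) -> HaploNetwork:
    """Build a genotype network directly from aligned haplotype strings.

    With ``phenotypes`` given (indexed like ``strings``), identical strings
    are collapsed and carry mean phenotypes; otherwise vertices carry no
    phenotype (the form the randomisation null uses).
    """
    if phenotypes is not None:
        strings = pd.Series(strings)
        vertices = collapse_haplotypes(strings, phenotypes)
    else:
        vertices = {}
        for hap in strings:
            v = vertices.setdefault(hap, {"members": [], "member_phenotypes": []})
            v["members"].append(None)
        for v in vertices.values():
            v["mean_phenotype"] = math.nan
    if loci is None:
        length = len(next(iter(vertices))) if vertices else 0
        loci = [f"pos{k}" for k in range(length)]
    return build_network(vertices, loci, phenotype_name, cutoff)


def build_network(
    vertices: dict[str, dict],
    loci: list[str],
    phenotype_name: str = "phenotype",
    cutoff: float | None = None,
) -> HaploNetwork:
    """Connect collapsed vertices at Hamming distance 1 and drop isolates
    from the analysis graph.

    Edges are found by bucketing strings on each single masked position, so
    the cost is O(n * L) rather than all-pairs; the result equals the
    brute-force pairwise comparison (enforced by the oracle tests).
    """
    haps = list(vertices)
    G = nx.Graph()
    for hap, attrs in vertices.items():
        G.add_node(
            hap,
            mean_phenotype=attrs["mean_phenotype"],
            members=list(attrs["members"]),
            member_phenotypes=list(attrs.get("member_phenotypes", [])),
        )
    if haps:
        length = len(haps[0])
        for pos in range(length):
            buckets: dict[str, list[str]] = {}
            for hap in haps:
                key = hap[:pos] + "\0" + hap[pos + 1 :]
                buckets.setdefault(key, []).append(hap)
            for group in buckets.values():
                for u, v in itertools.combinations(group, 2):
                    G.add_edge(u, v)

    isolates = {}
    for hap in list(nx.isolates(G)):
        isolates[hap] = dict(G.nodes[hap])
        G.remove_node(hap)
    for cid, comp in enumerate(
        sorted(nx.connected_components(G), key=lambda c: (-len(c), min(c)))
    ):
        for hap in comp:
            G.nodes[hap]["component"] = cid
    return HaploNetwork(
        graph=G,
        isolates=isolates,
        loci=list(loci),
        phenotype_name=phenotype_name,
        cutoff=cutoff,
    )


def enumerate_squares(graph: nx.Graph) -> list[tuple[str, str, str, str]]:
    """All distinct four-cycles, each reported once as (u, v, w, x) with
    edges u-v, v-w, w-x, x-u; u,w and v,x are the diagonals.

    Enumerates common-neighbour pairs over every vertex pair, so chords do
    not hide cycles and K4 yields its three distinct squares.
    """
    seen = set()
    squares = []
    adj = {n: set(graph.neighbors(n)) for n in graph.nodes}
    for u, w in itertools.combinations(graph.nodes, 2):
        common = adj[u] & adj[w]
        if len(common) < 2:
            continue
        for v, x in itertools.combinations(sorted(common), 2):
            key = frozenset((frozenset((u, w)), frozenset((v, x))))
            if key in seen:
                continue
            seen.add(key)
            squares.append((u, v, w, x))
    return squares


def count_squares(network: HaploNetwork) -> dict:
    """Square (4-cycle) counts per component and in total."""
    per_component: dict[int, int] = {}
    for comp in network.components:
        sub = network.graph.subgraph(comp)
        cid = network.graph.nodes[next(iter(comp))]["component"]
        per_component[cid] = len(enumerate_squares(sub))
    return {
        "total": sum(per_component.values()),
        "per_component": per_component,
        "max_per_component": max(per_component.values(), default=0),
    }


def build_for_cutoff(
    panel: GenotypePanel,
    assoc: AssociationTable,
    cutoff: float,
    phenotype_name: str = "phenotype",
) -> HaploNetwork:
    """Select loci at ``cutoff``, concatenate, collapse and connect."""
    loci = select_loci(assoc, cutoff)
    if not loci:
        raise EmptyNetworkError(f"no loci selected at cutoff {cutoff:g}")
    strings = build_haplotypes(panel, loci)
    pheno = panel.phenotype.dropna()
    vertices = collapse_haplotypes(strings, pheno)
    return build_network(vertices, loci, phenotype_name, cutoff)


@dataclass
class SweepResult:
    """Per-cutoff network characteristics and the selected cutoff.

    Selection maximises the per-component maximum square count; ties break
    by larger largest-component size, then by the more stringent cutoff.
    """

    table: pd.DataFrame
    selected_cutoff: float | None
    selected_network: HaploNetwork | None


def sweep_cutoffs(
    panel: GenotypePanel,
    assoc: AssociationTable,
    grid: list[float] | None = None,
    phenotype_name: str = "phenotype",
) -> SweepResult:
    """Build one network per -log10 P cutoff and select the analysis
    network.

    ``grid`` lists -log10 cutoff values; the default is half-log steps
    from 4.0 to 9.0.
    """
    if grid is None:
        grid = [4.0 + 0.5 * k for k in range(11)]
    rows = []
    networks: dict[float, HaploNetwork] = {}
    for neglog in grid:
        cutoff = 10.0 ** (-neglog)
        try:
            net = build_for_cutoff(panel, assoc, cutoff, phenotype_name)
        except EmptyNetworkError:
            rows.append(
                {
                    "neglog10_cutoff": neglog,
                    "n_loci": len(select_loci(assoc, cutoff)) if cutoff < 1 else 0,
                    "n_unique_genotypes": 0,
                    "n_components": 0,
                    "largest_component": 0,
                    "max_squares_per_component": 0,
                    "total_squares": 0,
                }
            )
            continue
        sq = count_squares(net)
        networks[neglog] = net
        rows.append(
            {
                "neglog10_cutoff": neglog,
                "n_loci": len(net.loci),
                "n_unique_genotypes": net.n_unique_genotypes,
                "n_components": len(net.components),
                "largest_component": max(net.component_sizes(), default=0),
                "max_squares_per_component": sq["max_per_component"],
                "total_squares": sq["total"],
            }
        )
    table = pd.DataFrame(rows)
    if not networks:
        return SweepResult(table, None, None)
    best = max(
        networks,
        key=lambda nl: (
            int(table.loc[table.neglog10_cutoff == nl, "max_squares_per_component"].iloc[0]),
            int(table.loc[table.neglog10_cutoff == nl, "largest_component"].iloc[0]),
            nl,  # more stringent cutoff wins remaining ties
        ),
    )
    cutoff = 10.0 ** (-best)
    return SweepResult(table, cutoff, networks[best])


def maf_filter(panel: GenotypePanel, threshold: float = 0.05) -> GenotypePanel:
    """Drop loci whose minor-allele frequency among phenotyped accessions
    is strictly below ``threshold`` (a locus at exactly the threshold is
    retained)."""
    if not (0 <= threshold <= 0.5):
        raise ValueError("threshold must lie in [0, 0.5]")
    if threshold == 0:
        return panel
    mafs = panel.minor_allele_frequencies()
    keep = [locus for locus in panel.loci if mafs[locus] >= threshold]
    if not keep:
        raise EmptyNetworkError("MAF filter removed every locus")
    return panel.subset_loci(keep)


def _allelic_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of 0/1 allele dosages; 0 if either
    locus is monomorphic."""
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def ld_prune(
    panel: GenotypePanel,
    assoc: AssociationTable,
    r2_threshold: float = 0.95,
) -> GenotypePanel:
    """Greedy representative pruning of correlated loci.

    Loci are visited in order of ascending P (ties by locus id); a locus is
    kept only if its allelic r-squared with every already-kept locus is
    below the threshold, so each correlated cluster keeps its smallest-P
    representative.
    """
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must lie in (0, 1]")
    sub = panel.alleles.loc[panel.phenotyped_accessions]
    dosage = {}
    for locus in panel.loci:
        col = sub[locus]
        minor = col.value_counts().index[-1]
        dosage[locus] = (col == minor).to_numpy(dtype=float)
    order = sorted(
        panel.loci,
        key=lambda l: (assoc.pvalues.get(l, 1.0), _locus_sort_key(l)),
    )
    kept: list[str] = []
    for locus in order:
        if all(_allelic_r2(dosage[locus], dosage[k]) < r2_threshold for k in kept):
            kept.append(locus)
    kept = sorted(kept, key=_locus_sort_key)
    return panel.subset_loci(kept)
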