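"""Network-structure descriptors and phylogeny/path-length correlation.

Covers vertex betweenness, Louvain module detection with a phenotype
contrast between the two largest modules, and the correlation between
shortest mutational path length in the genotype network and phylogenetic
distance between the underlying accessions (internal-node count on the
tree, or raw nucleotide differences).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import dendropy
import networkx as nx
import numpy as np
from networkx.algorithms.community import louvain_communities
from scipy import stats

from .network import HaploNetwork

__all__ = [
    "ModulePartition",
    "PhyloDistances",
    "vertex_betweenness",
    "detect_modules",
    "module_phenotype_test",
    "tip_distance",
    "nucleotide_differences",
    "pairwise_tip_distances",
    "path_vs_phylo_correlation",
]


def vertex_betweenness(network: HaploNetwork) -> dict[str, float]:
    """Normalised shortest-path betweenness (endpoints excluded), computed
    and normalised within each connected component."""
    result: dict[str, float] = {}
    for comp in network.components:
        sub = network.graph.subgraph(comp)
        result.update(nx.betweenness_centrality(sub, normalized=True))
    return result


@dataclass
class ModulePartition:
    assignment: dict[str, int]
    modularity: float
    module_phenotypes: dict[int, list[float]]
    has_structure: bool


def detect_modules(network: HaploNetwork, seed: int = 0) -> ModulePartition:
    """Louvain modularity-maximisation partition of the largest component
    (resolution 1.0), deterministic given the seed.

    A partition whose modularity is not positive is reported as having no
    module structure.
    """
    comp = network.largest_component()
    sub = network.graph.subgraph(comp)
    communities = louvain_communities(sub, seed=seed)
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    assignment = {h: i for i, c in enumerate(communities) for h in c}
    q = nx.algorithms.community.modularity(sub, communities)
    values = network.mean_phenotypes()
    module_phen = {
        i: [values[h] for h in sorted(c)] for i, c in enumerate(communities)
    }
    return ModulePartition(
        assignment=assignment,
        modularity=float(q),
        module_phenotypes=module_phen,
        has_structure=(len(communities) > 1 and q > 0),
    )


def module_phenotype_test(partition: ModulePartition) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum comparison of vertex mean phenotypes
    between the two largest modules.

    Exact null distribution for group sizes <= 10, normal approximation
    with continuity correction otherwise.
    """
    if len(partition.module_phenotypes) < 2:
        raise ValueError("need at least two modules to compare")
    sizes = sorted(
        partition.module_phenotypes,
        key=lambda i: -len(partition.module_phenotypes[i]),
    )
    a = partition.module_phenotypes[sizes[0]]
    b = partition.module_phenotypes[sizes[1]]
    method = "exact" if max(len(a), len(b)) <= 10 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"statistic": float(res.statistic), "pvalue": float(res.pvalue)}


def _leaf(tree: dendropy.Tree, label: str) -> dendropy.Node:
    node = tree.find_node_with_taxon_label(label)
    if node is None:
        raise KeyError(f"tip {label!r} not found in tree")
    return node


def tip_distance(tree: dendropy.Tree, tip_a: str, tip_b: str) -> int:
    """Number of distinct internal nodes on the unique path between two
    tips, ignoring branch lengths.  A cherry's two tips are separated by
    one internal node; a tip to itself is 0."""
    if tip_a == tip_b:
        return 0
    na, nb = _leaf(tree, tip_a), _leaf(tree, tip_b)
    anc_a = []
    node = na
    while node is not None:
        anc_a.append(node)
        node = node.parent_node
    anc_a_set = set(id(n) for n in anc_a)
    path_b = []
    node = nb
    while id(node) not in anc_a_set:
        path_b.append(node)
        node = node.parent_node
    mrca = node
    path_a = []
    node = na
    while id(node) != id(mrca):
        path_a.append(node)
        node = node.parent_node
    internal = [n for n in path_a[1:] + path_b[1:] + [mrca] if not n.is_leaf()]
    return len(internal)


def nucleotide_differences(seq_a: str, seq_b: str) -> int:
    """Hamming distance between two aligned nucleotide strings."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    return sum(1 for x, y in zip(seq_a, seq_b) if x != y)


@dataclass
class PhyloDistances:
    """Symmetric accession-level distances, queried by unordered pair."""

    internal_nodes: dict[frozenset, float]
    nuc_diffs: dict[frozenset, float] | None = None

    def get(self, a: str, b: str, flavor: str = "internal_nodes") -> float:
        if a == b:
            return 0.0
        table = self.internal_nodes if flavor == "internal_nodes" else self.nuc_diffs
        if table is None:
            raise ValueError(f"distance flavor {flavor!r} not loaded")
        return table[frozenset((a, b))]


def pairwise_tip_distances(
    tree: dendropy.Tree, tips: list[str], sequences: dict[str, str] | None = None
) -> PhyloDistances:
    """Internal-node counts (and optionally nucleotide differences) for
    all pairs of the given tips."""
    internal = {}
    nucs = {} if sequences is not None else None
    for a, b in itertools.combinations(sorted(tips), 2):
        internal[frozenset((a, b))] = float(tip_distance(tree, a, b))
        if sequences is not None:
            nucs[frozenset((a, b))] = float(
                nucleotide_differences(sequences[a], sequences[b])
            )
    return PhyloDistances(internal, nucs)


def path_vs_phylo_correlation(
    network: HaploNetwork,
    distances: PhyloDistances,
    flavor: str = "internal_nodes",
    component: set[str] | None = None,
) -> dict[str, float]:
    """Kendall rank correlation (tau-b, tie-corrected) between shortest
    mutational path length and mean phylogenetic distance over all vertex
    pairs of the analysed component.

    When a vertex collapses several accessions, the phylogenetic distance
    of a vertex pair is the mean over all member-accession pairs.  Vertices
    whose members are absent from the distance table are excluded with a
    warning.
    """
    if component is None:
        component = network.largest_component()
    sub = network.graph.subgraph(component)
    spl = dict(nx.all_pairs_shortest_path_length(sub))

    known: set[str] = set()
    for pair in distances.internal_nodes:
        known.update(pair)
    members = {}
    for h in sorted(component):
        mem = [m for m in network.graph.nodes[h]["members"] if m in known]
        if not mem:
            warnings.warn(
                f"vertex {h!r} has no members in the distance table; excluded",
                stacklevel=2,
            )
            continue
        members[h] = mem

    path_lengths, phylo = [], []
    nodes = sorted(members)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            pairs = [
                distances.get(a, b, flavor)
                for a in members[u]
                for b in members[v]
            ]
            path_lengths.append(spl[u][v])
            phylo.append(float(np.mean(pairs)))
    if len(path_lengths) < 2:
        raise ValueError("need at least two vertex pairs for a correlation")
    tau, p = stats.kendalltau(path_lengths, phylo)
    return {"tau": float(tau), "pvalue": float(p), "n_pairs": len(path_lengths)}
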