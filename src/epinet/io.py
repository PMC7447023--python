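"""Readers and writers for the pipeline's tabular, graph and tree formats.

Input tables are tab-separated UTF-8 with mandatory header rows: a genotype
matrix (rows = accessions, columns = locus ids), a phenotype table
(accession id, value) and an association table (locus id, P-value).
Networks are exported as GraphML plus a plain edge-list TSV; trees are read
from Newick (bootstrap labels on internal nodes are accepted, branch
lengths ignored for internal-node distances).

Readers reject malformed cells rather than coercing them, naming the file,
row and column in the error.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import dendropy
import networkx as nx
import pandas as pd

from .network import HaploNetwork, build_network
from .panel import AssociationTable, GenotypePanel, PanelError

__all__ = [
    "read_panel",
    "write_panel",
    "read_newick",
    "write_network",
    "read_network",
    "write_json",
    "read_json",
]


def _read_tsv(path: str | Path, index_col: int = 0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=index_col, dtype=str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise PanelError(f"{path}: duplicate row ids {dups}")
    return df


def _to_float(df: pd.DataFrame, col: str, path: Path) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[out.isna() & df[col].notna() & (df[col].str.strip() != "")]
    if len(bad):
        row = bad[0]
        raise PanelError(
            f"{path}: non-numeric value {df.loc[row, col]!r} "
            f"in column {col!r}, row {row!r}"
        )
    return out


def read_panel(
    genotype_path: str | Path,
    phenotype_path: str | Path,
    association_path: str | Path,
    phenotype_name: str = "phenotype",
) -> tuple[GenotypePanel, AssociationTable]:
    """Load and validate the three canonical input tables.

    Accessions missing from the phenotype table (or with an empty value)
    are retained but flagged unphenotyped; loci with more than two alleles
    are rejected with the locus named.
    """
    geno = _read_tsv(genotype_path)
    phen_df = _read_tsv(phenotype_path)
    value_col = phen_df.columns[0]
    phen = _to_float(phen_df, value_col, Path(phenotype_path))
    extra = set(phen.index) - set(geno.index)
    if extra:
        raise PanelError(
            f"{phenotype_path}: phenotyped accessions absent from genotype "
            f"matrix: {sorted(extra)}"
        )
    panel = GenotypePanel(geno, phen.reindex(geno.index))
    if panel.unphenotyped_accessions:
        warnings.warn(
            f"{len(panel.unphenotyped_accessions)} accessions lack a "
            "phenotype and are flagged unphenotyped",
            stacklevel=2,
        )

    assoc_df = _read_tsv(association_path)
    pcol = assoc_df.columns[0]
    pvals = _to_float(assoc_df, pcol, Path(association_path))
    assoc = AssociationTable(pvals, phenotype_name=phenotype_name)
    assoc.validate_against(panel)
    return panel, assoc


def write_panel(
    panel: GenotypePanel,
    assoc: AssociationTable | None,
    out_dir: str | Path,
    prefix: str = "panel",
) -> dict[str, Path]:
    """Write genotype/phenotype/association TSVs; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    gpath = out_dir / f"{prefix}.genotypes.tsv"
    panel.alleles.to_csv(gpath, sep="\t", index_label="accession")
    paths["genotypes"] = gpath
    ppath = out_dir / f"{prefix}.phenotypes.tsv"
    panel.phenotype.rename("value").to_csv(ppath, sep="\t", index_label="accession")
    paths["phenotypes"] = ppath
    if assoc is not None:
        apath = out_dir / f"{prefix}.assoc.tsv"
        assoc.pvalues.rename("pvalue").to_csv(apath, sep="\t", index_label="locus")
        paths["assoc"] = apath
    return paths


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree; internal-node labels (bootstrap values) are
    kept as labels, never as taxa."""
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


def write_network(
    network: HaploNetwork,
    out_dir: str | Path,
    prefix: str = "network",
    betweenness: dict[str, float] | None = None,
    modules: dict[str, int] | None = None,
) -> dict[str, Path]:
    """Export a network as GraphML plus an edge-list TSV.

    Vertex attributes written: haplotype string, mean phenotype, member
    count, and (when provided) module id and betweenness.  An empty
    network produces header-only files with a warning.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    G = nx.Graph()
    for hap, data in network.graph.nodes(data=True):
        G.add_node(
            hap,
            haplotype=hap,
            mean_phenotype=float(data["mean_phenotype"]),
            n_members=len(data["members"]),
            component=int(data.get("component", -1)),
        )
        if betweenness is not None:
            G.nodes[hap]["betweenness"] = float(betweenness.get(hap, 0.0))
        if modules is not None:
            G.nodes[hap]["module"] = int(modules.get(hap, -1))
    G.add_edges_from(network.graph.edges)
    if G.number_of_nodes() == 0:
        warnings.warn("writing an empty network", stacklevel=2)
    gpath = out_dir / f"{prefix}.graphml"
    nx.write_graphml(G, gpath)
    epath = out_dir / f"{prefix}.edges.tsv"
    with open(epath, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in sorted(map(sorted, G.edges())):
            fh.write(f"{u}\t{v}\n")
    return {"graphml": gpath, "edges": epath}


def read_network(graphml_path: str | Path) -> HaploNetwork:
    """Re-import an exported network; attribute-lossless for the fields
    written by :func:`write_network`."""
    G = nx.read_graphml(str(graphml_path))
    vertices = {}
    for node, data in G.nodes(data=True):
        hap = data.get("haplotype", node)
        vertices[hap] = {
            "members": [f"member{i}" for i in range(int(data.get("n_members", 0)))],
            "member_phenotypes": [],
            "mean_phenotype": float(data.get("mean_phenotype", float("nan"))),
        }
    net = build_network(vertices, loci=[])
    # preserve exported mean phenotypes verbatim (collapse recomputes none)
    for node, data in G.nodes(data=True):
        hap = data.get("haplotype", node)
        if hap in net.graph.nodes:
            net.graph.nodes[hap]["mean_phenotype"] = float(
                data.get("mean_phenotype", float("nan"))
            )
    return net


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
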