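"""Accessibility of mutational paths to extreme phenotypic values.

A mutational path between two genotypes is a shortest path in the genotype
network.  A path toward the maximum is accessible when the phenotype never
decreases by more than the noise threshold δ at any step (mirrored for the
minimum).  The analysis requires a unique extremum in the analysed
component; ties are recorded as skips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .network import HaploNetwork

__all__ = [
    "AccessibilityReport",
    "AmbiguousExtremumError",
    "PathExplosionError",
    "find_unique_extremum",
    "enumerate_shortest_paths",
    "is_accessible",
    "accessibility_summary",
    "path_length_distribution",
]


class AmbiguousExtremumError(ValueError):
    """The component has no unique extreme phenotype vertex."""


class PathExplosionError(RuntimeError):
    """Shortest-path enumeration exceeded the configured cap."""


def find_unique_extremum(
    network: HaploNetwork,
    direction: str = "max",
    component: set[str] | None = None,
) -> str:
    """Vertex with the strictly largest (smallest) mean phenotype in the
    analysed component (largest component by default)."""
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    if component is None:
        component = network.largest_component()
    values = network.mean_phenotypes()
    vals = {h: values[h] for h in component}
    extreme = max(vals.values()) if direction == "max" else min(vals.values())
    hits = [h for h, v in vals.items() if v == extreme]
    if len(hits) > 1:
        raise AmbiguousExtremumError(
            f"{len(hits)} vertices tie at the {direction}imum value {extreme!r}"
        )
    return hits[0]


def enumerate_shortest_paths(
    graph: nx.Graph, source: str, target: str, cap: int = 10**6
) -> list[list[str]]:
    """All distinct shortest paths between two vertices.

    Raises :class:`PathExplosionError` once more than ``cap`` paths are
    produced, rather than silently sampling.
    """
    try:
        gen = nx.all_shortest_paths(graph, source, target)
        paths = []
        for path in gen:
            paths.append(path)
            if len(paths) > cap:
                raise PathExplosionError(
                    f"more than {cap} shortest paths between {source!r} and {target!r}"
                )
        return paths
    except nx.NetworkXNoPath:
        return []


def is_accessible(
    path_values: list[float], delta: float = 0.0, direction: str = "max",
    strict: bool = False,
) -> bool:
    """Monotone accessibility of one path of phenotype values.

    For direction 'max' every step must satisfy V_next − V_prev ≥ −δ
    (never move against the direction by more than the identity
    tolerance); mirrored for 'min'.  ``strict`` instead demands every step
    to exceed +δ, a sensitivity mode.
    """
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    sign = 1.0 if direction == "max" else -1.0
    for prev, nxt in zip(path_values, path_values[1:]):
        step = sign * (nxt - prev)
        if strict:
            if step <= delta:
                return False
        elif step < -delta:
            return False
    return True


@dataclass
class AccessibilityReport:
    """Per-source shortest-path accessibility toward a unique extremum."""

    extremum: str
    direction: str
    delta: float
    per_source: pd.DataFrame  # source, path_length, n_paths, n_accessible
    fraction_accessible: float
    mean_path_length: float
    binned_fractions: pd.DataFrame  # bin_low, bin_high, n_paths, fraction

    @property
    def n_paths(self) -> int:
        return int(self.per_source["n_paths"].sum())


def accessibility_summary(
    network: HaploNetwork,
    delta: float = 0.0,
    direction: str = "max",
    component: set[str] | None = None,
    strict: bool = False,
    cap: int = 10**6,
) -> AccessibilityReport:
    """Enumerate all shortest paths from every vertex to the unique
    extremum, flag each for monotone accessibility and aggregate.

    The global fraction pools paths over all sources.  Binned fractions
    group paths by length into unit bins [1,2), [2,3), ...
    """
    if component is None:
        component = network.largest_component()
    target = find_unique_extremum(network, direction, component)
    values = network.mean_phenotypes()
    sub = network.graph.subgraph(component)
    rows = []
    for source in sorted(component):
        if source == target:
            continue
        paths = enumerate_shortest_paths(sub, source, target, cap=cap)
        n_acc = sum(
            1
            for p in paths
            if is_accessible([values[h] for h in p], delta, direction, strict)
        )
        rows.append(
            {
                "source": source,
                "path_length": len(paths[0]) - 1 if paths else math.nan,
                "n_paths": len(paths),
                "n_accessible": n_acc,
            }
        )
    per_source = pd.DataFrame(
        rows, columns=["source", "path_length", "n_paths", "n_accessible"]
    )
    total = per_source["n_paths"].sum()
    frac = per_source["n_accessible"].sum() / total if total else math.nan
    mean_len = (
        float(per_source["path_length"].mean()) if len(per_source) else math.nan
    )

    bins = []
    if len(per_source):
        lmax = int(per_source["path_length"].max())
        for lo in range(1, lmax + 1):
            mask = (per_source["path_length"] >= lo) & (per_source["path_length"] < lo + 1)
            n = per_source.loc[mask, "n_paths"].sum()
            acc = per_source.loc[mask, "n_accessible"].sum()
            if n:
                bins.append(
                    {"bin_low": lo, "bin_high": lo + 1, "n_paths": int(n),
                     "fraction_accessible": acc / n}
                )
    binned = pd.DataFrame(
        bins, columns=["bin_low", "bin_high", "n_paths", "fraction_accessible"]
    )
    return AccessibilityReport(
        extremum=target,
        direction=direction,
        delta=delta,
        per_source=per_source,
        fraction_accessible=float(frac),
        mean_path_length=mean_len,
        binned_fractions=binned,
    )


def path_length_distribution(
    network: HaploNetwork, component: set[str] | None = None
) -> pd.Series:
    """Shortest-path length counts over all vertex pairs of the analysed
    component (not only pairs involving the extremum)."""
    if component is None:
        component = network.largest_component()
    sub = network.graph.subgraph(component)
    lengths = []
    nodes = sorted(component)
    spl = dict(nx.all_pairs_shortest_path_length(sub))
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            lengths.append(spl[u][v])
    return pd.Series(lengths, dtype=int).value_counts().sort_index()
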