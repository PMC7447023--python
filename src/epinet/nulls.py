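"""Column-composition randomisation null for genotype networks.

Random haplotype panels preserve, per aligned column, the empirical
character composition of the observed strings; each replicate's network is
built by the same code path as the observed network and summarised by four
statistics: unique-genotype count, square count, largest-component size
(components with >= 2 vertices) and maximum vertex betweenness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import HaploNetwork, count_squares, network_from_strings
from .structure import vertex_betweenness

__all__ = [
    "NullDistribution",
    "sample_random_strings",
    "network_statistics",
    "null_distribution",
    "empirical_quantile",
]

STATISTICS = ("n_unique_genotypes", "n_squares", "largest_component", "max_betweenness")


@dataclass
class NullDistribution:
    """Replicate-level null statistics; one row per random panel."""

    table: pd.DataFrame
    n_reps: int
    seed: int


def sample_random_strings(
    strings: list[str], rng: np.random.Generator
) -> list[str]:
    """Random aligned strings with each column drawn independently from
    that column's empirical character distribution."""
    if not strings:
        raise ValueError("no strings to randomise")
    arr = np.array([list(s) for s in strings])
    n, length = arr.shape
    out = np.empty_like(arr)
    for col in range(length):
        chars, counts = np.unique(arr[:, col], return_counts=True)
        out[:, col] = rng.choice(chars, size=n, p=counts / counts.sum())
    return ["".join(row) for row in out]


def network_statistics(network: HaploNetwork) -> dict[str, float]:
    """The four summary statistics compared against the null."""
    sizes = network.component_sizes()
    bc = vertex_betweenness(network)
    return {
        "n_unique_genotypes": network.n_unique_genotypes,
        "n_squares": count_squares(network)["total"],
        "largest_component": sizes[0] if sizes else 0,
        "max_betweenness": max(bc.values(), default=0.0),
    }


def null_distribution(
    strings: list[str], n_reps: int = 10_000, seed: int = 0
) -> NullDistribution:
    """Build ``n_reps`` random genotype networks and record their
    statistics.  Phenotypes play no role: the null concerns topology only.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng([seed, 17])
    rows = []
    for _ in range(n_reps):
        rand = sample_random_strings(strings, rng)
        net = network_from_strings(rand)
        rows.append(network_statistics(net))
    return NullDistribution(pd.DataFrame(rows), n_reps, seed)


def empirical_quantile(
    observed: float, null_values: np.ndarray | pd.Series
) -> dict[str, float]:
    """Rank-based empirical comparison with an add-one pseudo-count.

    upper P = (1 + #{null >= obs}) / (n + 1); lower analogously; two-sided
    = 2 * min(tails), capped at 1.  The pseudo-count avoids zero P at
    finite replicate counts.
    """
    null_values = np.asarray(null_values, dtype=float)
    n = len(null_values)
    if n == 0:
        raise ValueError("null distribution is empty")
    upper = (1 + np.sum(null_values >= observed)) / (n + 1)
    lower = (1 + np.sum(null_values <= observed)) / (n + 1)
    return {
        "quantile": float(np.mean(null_values < observed)),
        "p_upper": float(upper),
        "p_lower": float(lower),
        "p_two_sided": float(min(1.0, 2 * min(upper, lower))),
    }
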