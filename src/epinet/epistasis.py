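"""Noise threshold estimation and epistasis classification of squares.

A square is a four-cycle in the genotype network: wild type ab, single
mutants Ab and aB, and the double mutant AB, where AB is by convention the
vertex with the strictly largest phenotype among the four.  The epistasis
magnitude is

    ε = V_AB + V_ab − V_Ab − V_aB,

zero exactly when effects are additive (V_AB = V_Ab + V_aB − V_ab).  The
non-genetic noise threshold δ is the mean coefficient of variation of
phenotypes among accessions sharing a haplotype; squares with |ε| < δ are
conservatively called non-epistatic.  Epistatic squares are split by
whether each mutation's phenotypic effect changes sign between genetic
backgrounds: neither → magnitude, exactly one → simple sign, both →
reciprocal sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import HaploNetwork, enumerate_squares

__all__ = [
    "NoiseEstimate",
    "Square",
    "EpistasisCall",
    "EpistasisSummary",
    "estimate_delta",
    "fraction_identical_neighbors",
    "orient_square",
    "classify_square",
    "classify_network",
    "summarize_epistasis",
    "CLASSES",
]

CLASSES = ("none", "magnitude", "simple_sign", "reciprocal_sign")


@dataclass
class NoiseEstimate:
    """Mean coefficient of variation over vertices with >= 3 member
    accessions; ``delta`` is None when no vertex qualifies."""

    delta: float | None
    vertex_cvs: dict[str, float]
    n_contributing: int
    contributing_fraction: float

    @property
    def available(self) -> bool:
        return self.delta is not None


@dataclass(frozen=True)
class Square:
    """An oriented square: AB holds the strictly largest phenotype, ab is
    its Hamming-2 diagonal partner; the Ab/aB labelling is arbitrary and
    does not affect ε or the class."""

    ab: str
    Ab: str
    aB: str
    AB: str
    v_ab: float
    v_Ab: float
    v_aB: float
    v_AB: float

    @property
    def epsilon(self) -> float:
        return self.v_AB + self.v_ab - self.v_Ab - self.v_aB


@dataclass(frozen=True)
class EpistasisCall:
    square: Square
    epsilon: float  # reported as 0 when |ε| < δ
    delta: float
    klass: str
    sign_change_A: bool
    sign_change_B: bool


def estimate_delta(network: HaploNetwork, min_members: int = 3) -> NoiseEstimate:
    """δ = unweighted mean CV (sd/mean, sample sd) over qualifying vertices.

    Vertices need at least ``min_members`` member accessions; vertices whose
    mean phenotype is 0 have no defined CV and are excluded with a warning.
    """
    cvs: dict[str, float] = {}
    n_vertices = network.graph.number_of_nodes()
    for hap, data in network.graph.nodes(data=True):
        values = np.asarray(data.get("member_phenotypes", []), dtype=float)
        if len(values) < min_members:
            continue
        mean = values.mean()
        if mean == 0:
            warnings.warn(
                f"vertex {hap!r} has mean phenotype 0; CV undefined, excluded "
                "from delta",
                stacklevel=2,
            )
            continue
        cvs[hap] = float(values.std(ddof=1) / abs(mean))
    if not cvs:
        return NoiseEstimate(None, {}, 0, 0.0)
    return NoiseEstimate(
        delta=float(np.mean(list(cvs.values()))),
        vertex_cvs=cvs,
        n_contributing=len(cvs),
        contributing_fraction=len(cvs) / n_vertices if n_vertices else 0.0,
    )


def fraction_identical_neighbors(network: HaploNetwork, delta: float) -> float:
    """Fraction of edges whose endpoint phenotypes differ by at most δ."""
    edges = list(network.graph.edges)
    if not edges:
        raise ValueError("network has no edges")
    values = network.mean_phenotypes()
    identical = sum(1 for u, v in edges if abs(values[u] - values[v]) <= delta)
    return identical / len(edges)


def _diagonal_partner(cycle: tuple[str, str, str, str], vertex: str) -> str:
    """In cycle (u, v, w, x) with edges u-v, v-w, w-x, x-u, the diagonals
    are (u, w) and (v, x)."""
    u, v, w, x = cycle
    return {u: w, v: x, w: u, x: v}[vertex]


def orient_square(
    cycle: tuple[str, str, str, str], values: dict[str, float]
) -> Square | None:
    """Orient a four-cycle by its phenotype values; None when the maximum
    is not unique (such squares are skipped and tallied).

    The tie test is exact equality of collapsed mean values.
    """
    vals = [values[h] for h in cycle]
    vmax = max(vals)
    if vals.count(vmax) > 1:
        return None
    AB = cycle[vals.index(vmax)]
    ab = _diagonal_partner(cycle, AB)
    singles = [h for h in cycle if h not in (AB, ab)]
    Ab, aB = singles
    return Square(
        ab=ab, Ab=Ab, aB=aB, AB=AB,
        v_ab=values[ab], v_Ab=values[Ab], v_aB=values[aB], v_AB=values[AB],
    )


def _step_sign(dv: float, delta: float) -> int:
    """Sign of a single mutational step; steps no larger than δ in
    magnitude are indeterminate (0) and never count as a sign change."""
    if abs(dv) <= delta:
        return 0
    return 1 if dv > 0 else -1


def classify_square(
    square: Square, delta: float, delta_mode: str = "literal"
) -> EpistasisCall:
    """Classify one oriented square against the noise threshold δ.

    |ε| < δ → class ``none`` with ε reported as 0.  Otherwise mutation A
    changes sign iff its effect in the b background (ab→Ab) and in the B
    background (aB→AB) have strictly opposite signs, and analogously for
    mutation B; both → reciprocal sign, exactly one → simple sign, neither
    → magnitude.

    ``delta_mode`` controls how the dimensionless CV-based δ is compared
    with ε, which carries phenotype units: ``literal`` compares the raw
    numbers; ``mean_scaled`` first multiplies δ by the mean absolute
    phenotype of the four vertices, converting it to phenotype units —
    appropriate when phenotype means sit far from zero.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if delta_mode not in ("literal", "mean_scaled"):
        raise ValueError("delta_mode must be 'literal' or 'mean_scaled'")
    if delta_mode == "mean_scaled":
        scale = float(
            np.mean([abs(square.v_ab), abs(square.v_Ab),
                     abs(square.v_aB), abs(square.v_AB)])
        )
        delta = delta * scale
    eps = square.epsilon
    # exact additivity (ε = 0) is never epistatic, even at δ = 0
    if eps == 0 or abs(eps) < delta:
        return EpistasisCall(square, 0.0, delta, "none", False, False)
    # effect of mutation A in background b and in background B
    a_in_b = _step_sign(square.v_Ab - square.v_ab, delta)
    a_in_B = _step_sign(square.v_AB - square.v_aB, delta)
    b_in_a = _step_sign(square.v_aB - square.v_ab, delta)
    b_in_A = _step_sign(square.v_AB - square.v_Ab, delta)
    change_a = a_in_b != 0 and a_in_B != 0 and a_in_b != a_in_B
    change_b = b_in_a != 0 and b_in_A != 0 and b_in_a != b_in_A
    if change_a and change_b:
        klass = "reciprocal_sign"
    elif change_a or change_b:
        klass = "simple_sign"
    else:
        klass = "magnitude"
    return EpistasisCall(square, eps, delta, klass, change_a, change_b)


def classify_network(
    network: HaploNetwork, delta: float, delta_mode: str = "literal"
) -> tuple[list[EpistasisCall], int]:
    """Classify every square in the network; returns the calls and the
    number of squares skipped for a tied maximum."""
    values = network.mean_phenotypes()
    calls: list[EpistasisCall] = []
    skipped = 0
    for cycle in enumerate_squares(network.graph):
        square = orient_square(cycle, values)
        if square is None:
            skipped += 1
            continue
        calls.append(classify_square(square, delta, delta_mode))
    return calls, skipped


@dataclass
class EpistasisSummary:
    counts: dict[str, int]
    fractions: dict[str, float]
    n_squares: int
    n_skipped: int
    epistatic_fraction: float
    all_epistatic: bool
    analyzable: bool


def summarize_epistasis(
    network: HaploNetwork, delta: float, delta_mode: str = "literal"
) -> EpistasisSummary:
    """Tally epistasis classes over all squares of a network.

    Networks without any square are flagged not analyzable; the
    ``all_epistatic`` flag is set when every classified square shows
    epistasis of some type.
    """
    calls, skipped = classify_network(network, delta, delta_mode)
    counts = {k: 0 for k in CLASSES}
    for call in calls:
        counts[call.klass] += 1
    n = len(calls)
    fractions = {k: (counts[k] / n if n else 0.0) for k in CLASSES}
    n_epistatic = n - counts["none"]
    return EpistasisSummary(
        counts=counts,
        fractions=fractions,
        n_squares=n,
        n_skipped=skipped,
        epistatic_fraction=n_epistatic / n if n else 0.0,
        all_epistatic=(n > 0 and counts["none"] == 0),
        analyzable=(n + skipped) > 0,
    )
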