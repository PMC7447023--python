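"""Synthetic GWAS panels with known genetic architecture.

The generator emulates the statistical structure the downstream analysis
assumes: biallelic loci drawn independently at a chosen minor-allele
frequency, a quantitative phenotype composed of additive per-locus effects
plus pairwise locus-by-locus interaction effects, and Gaussian
accession-level noise.  Because effects are planted, every downstream stage
(network topology, epistasis class, path accessibility) has ground truth.

Randomness is organised as one RNG stream per operation, derived from
``config.seed`` through ``numpy.random.default_rng([seed, stream_id])`` so
that each stage is independently reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import AssociationTable, GenotypePanel, PanelError

__all__ = [
    "SimulationConfig",
    "PlantedSquare",
    "simulate_panel",
    "compute_association_pvalues",
    "plant_square",
    "config_for_square",
]

MAJOR = "A"
MINOR = "T"

# stream ids for per-operation RNG derivation
_STREAM_GENOTYPE = 1
_STREAM_NOISE = 2
_STREAM_PHENOTYPE_MASK = 3


@dataclass
class SimulationConfig:
    """Parameters of a synthetic GWAS panel.

    ``additive_effects`` has one entry (phenotype units per minor allele)
    per causal locus; neutral loci have no phenotypic effect.
    ``interaction_terms`` are ``(locus_index_i, locus_index_j, effect)``
    triples: accessions carrying the minor allele at *both* loci receive
    the extra ``effect``.
    """

    n_accessions: int
    n_causal_loci: int
    n_neutral_loci: int
    minor_allele_freq: float
    additive_effects: tuple[float, ...] = ()
    interaction_terms: tuple[tuple[int, int, float], ...] = ()
    noise_sd: float = 0.0
    baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 1:
            raise PanelError("n_accessions must be >= 1")
        if self.n_causal_loci < 1:
            raise PanelError("n_causal_loci must be >= 1")
        if self.n_neutral_loci < 0:
            raise PanelError("n_neutral_loci must be >= 0")
        if not (0 < self.minor_allele_freq < 0.5):
            raise PanelError("minor_allele_freq must lie in (0, 0.5)")
        if self.noise_sd < 0:
            raise PanelError("noise_sd must be >= 0")
        if not self.additive_effects:
            self.additive_effects = tuple(1.0 for _ in range(self.n_causal_loci))
        if len(self.additive_effects) != self.n_causal_loci:
            raise PanelError(
                "additive_effects length must equal n_causal_loci "
                f"({len(self.additive_effects)} != {self.n_causal_loci})"
            )
        n_loci = self.n_causal_loci + self.n_neutral_loci
        for i, j, _ in self.interaction_terms:
            if not (0 <= i < n_loci and 0 <= j < n_loci) or i == j:
                raise PanelError(f"invalid interaction pair ({i}, {j})")


@dataclass(frozen=True)
class PlantedSquare:
    """Four phenotype values of a genotype square with a known epistasis
    class at zero noise threshold."""

    v_ab: float
    v_Ab: float
    v_aB: float
    v_AB: float
    label: str

    @property
    def values(self) -> tuple[float, float, float, float]:
        return (self.v_ab, self.v_Ab, self.v_aB, self.v_AB)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def simulate_panel(config: SimulationConfig) -> GenotypePanel:
    """Draw a genotype panel and phenotype under the planted architecture.

    Alleles at every locus are drawn per-accession independently: minor
    allele with probability ``minor_allele_freq``.  The phenotype of an
    accession is

        baseline + sum(additive effect over carried minor alleles)
                 + sum(interaction effect over pairs with both minor alleles)
                 + Normal(0, noise_sd).

    Deterministic given ``config.seed``.
    """
    n_loci = config.n_causal_loci + config.n_neutral_loci
    gt_rng = _rng(config.seed, _STREAM_GENOTYPE)
    minor = gt_rng.random((config.n_accessions, n_loci)) < config.minor_allele_freq

    phenotype = np.full(config.n_accessions, config.baseline, dtype=float)
    for k, beta in enumerate(config.additive_effects):
        phenotype += beta * minor[:, k]
    for i, j, effect in config.interaction_terms:
        phenotype += effect * (minor[:, i] & minor[:, j])
    if config.noise_sd > 0:
        noise_rng = _rng(config.seed, _STREAM_NOISE)
        phenotype += noise_rng.normal(0.0, config.noise_sd, config.n_accessions)

    accessions = [f"acc{i:04d}" for i in range(config.n_accessions)]
    loci = [f"chr1:{1000 * (k + 1)}" for k in range(n_loci)]
    chars = np.where(minor, MINOR, MAJOR)
    alleles = pd.DataFrame(chars, index=accessions, columns=loci)
    return GenotypePanel(alleles, pd.Series(phenotype, index=accessions))


def compute_association_pvalues(
    panel: GenotypePanel, phenotype_name: str = "phenotype"
) -> AssociationTable:
    """Per-locus association P by a two-sided rank-based two-sample test.

    Phenotype values are grouped by allele at each locus and compared with
    the Mann-Whitney U test.  Monomorphic loci have no defined association
    and are reported as P = 1 with a warning.
    """
    pheno = panel.phenotype.dropna()
    sub = panel.alleles.loc[pheno.index]
    pvals: dict[str, float] = {}
    for locus in sub.columns:
        col = sub[locus]
        groups = [pheno[col == a].to_numpy() for a in sorted(col.unique())]
        if len(groups) < 2:
            warnings.warn(
                f"locus {locus!r} is monomorphic among phenotyped accessions; "
                "association P-value undefined, reporting 1",
                stacklevel=2,
            )
            pvals[locus] = 1.0
            continue
        a, b = groups
        if np.ptp(pheno.to_numpy()) == 0:
            pvals[locus] = 1.0
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        pvals[locus] = min(float(res.pvalue), 1.0)
    return AssociationTable(pd.Series(pvals), phenotype_name=phenotype_name)


#: canonical four-value templates, scaled by ``magnitude_scale``:
#: (v_ab, v_Ab, v_aB, v_AB)
_SQUARE_TEMPLATES = {
    "additive": (0.0, 1.0, 1.0, 2.0),
    "magnitude": (0.0, 1.0, 1.0, 3.0),
    "simple_sign": (0.0, -1.0, 1.0, 2.0),
    "reciprocal_sign": (1.0, 0.0, 0.0, 2.0),
}


def plant_square(class_label: str, magnitude_scale: float = 1.0) -> PlantedSquare:
    """Return four phenotype values whose epistasis classification at
    δ = 0 equals ``class_label``.

    ``additive`` satisfies V_AB = V_Ab + V_aB - V_ab exactly;
    ``reciprocal_sign`` places both single mutants below the wild type.
    """
    if class_label not in _SQUARE_TEMPLATES:
        raise ValueError(
            f"unknown square class {class_label!r}; "
            f"expected one of {sorted(_SQUARE_TEMPLATES)}"
        )
    if magnitude_scale <= 0:
        raise ValueError("magnitude_scale must be positive")
    vals = tuple(magnitude_scale * v for v in _SQUARE_TEMPLATES[class_label])
    return PlantedSquare(*vals, label=class_label)


def config_for_square(
    square: PlantedSquare,
    n_accessions: int = 400,
    minor_allele_freq: float = 0.4,
    noise_sd: float = 0.0,
    offset: float = 0.0,
    seed: int = 0,
) -> SimulationConfig:
    """Two-locus configuration whose four haplotype phenotype means equal
    the planted square's values (shifted by ``offset``) exactly before
    noise.

    Decomposition: β_A = V_Ab − V_ab, β_B = V_aB − V_ab,
    interaction = V_AB + V_ab − V_Ab − V_aB, baseline = V_ab + offset.
    A positive offset keeps haplotype means away from zero, where the
    coefficient of variation is undefined or unstable.
    """
    beta_a = square.v_Ab - square.v_ab
    beta_b = square.v_aB - square.v_ab
    interaction = square.v_AB + square.v_ab - square.v_Ab - square.v_aB
    return SimulationConfig(
        n_accessions=n_accessions,
        n_causal_loci=2,
        n_neutral_loci=0,
        minor_allele_freq=minor_allele_freq,
        additive_effects=(beta_a, beta_b),
        interaction_terms=((0, 1, interaction),) if interaction != 0 else (),
        noise_sd=noise_sd,
        baseline=square.v_ab + offset,
        seed=seed,
    )
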