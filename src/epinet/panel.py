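"""Core data containers shared across the pipeline.

A :class:`GenotypePanel` holds the accession-by-locus allele matrix, the
per-accession phenotype values, and locus metadata.  Alleles are single
nucleotide characters; every locus is biallelic after validation.  The
:class:`AssociationTable` maps each locus to a per-phenotype association
P-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["GenotypePanel", "AssociationTable", "PanelError"]


class PanelError(ValueError):
    """Raised when a panel violates the data model (duplicate ids,
    multiallelic loci, dimension mismatches)."""


@dataclass
class GenotypePanel:
    """Accession x locus genotype matrix with phenotype values.

    Parameters
    ----------
    alleles
        DataFrame of single-character alleles, index = accession ids,
        columns = locus ids (opaque strings; ``chromosome:position``
        recommended).
    phenotype
        Series of phenotype values indexed by accession id.  Accessions
        without a phenotype carry NaN and are flagged, not dropped.
    """

    alleles: pd.DataFrame
    phenotype: pd.Series

    def __post_init__(self) -> None:
        if self.alleles.shape[0] == 0 or self.alleles.shape[1] == 0:
            raise PanelError("panel must have at least one accession and one locus")
        if self.alleles.index.duplicated().any():
            dups = self.alleles.index[self.alleles.index.duplicated()].tolist()
            raise PanelError(f"duplicate accession ids: {dups}")
        if self.alleles.columns.duplicated().any():
            dups = self.alleles.columns[self.alleles.columns.duplicated()].tolist()
            raise PanelError(f"duplicate locus ids: {dups}")
        self.phenotype = self.phenotype.reindex(self.alleles.index)
        for locus in self.alleles.columns:
            col = self.alleles[locus]
            if col.isna().any():
                raise PanelError(f"missing allele characters at locus {locus!r}")
            n_alleles = col.nunique()
            if n_alleles > 2:
                raise PanelError(
                    f"locus {locus!r} has {n_alleles} alleles; only biallelic "
                    "loci are supported"
                )

    @property
    def accessions(self) -> list[str]:
        return list(self.alleles.index)

    @property
    def loci(self) -> list[str]:
        return list(self.alleles.columns)

    @property
    def phenotyped_accessions(self) -> list[str]:
        """Accessions with a non-missing phenotype value."""
        return list(self.phenotype.dropna().index)

    @property
    def unphenotyped_accessions(self) -> list[str]:
        return list(self.phenotype[self.phenotype.isna()].index)

    def minor_allele_frequencies(self) -> pd.Series:
        """MAF per locus among phenotyped accessions.

        A monomorphic locus has MAF 0.
        """
        sub = self.alleles.loc[self.phenotyped_accessions]
        mafs = {}
        for locus in sub.columns:
            counts = sub[locus].value_counts()
            if len(counts) < 2:
                mafs[locus] = 0.0
            else:
                mafs[locus] = counts.iloc[-1] / counts.sum()
        return pd.Series(mafs, name="maf")

    def subset_loci(self, loci: list[str]) -> "GenotypePanel":
        return GenotypePanel(self.alleles[list(loci)].copy(), self.phenotype.copy())


@dataclass
class AssociationTable:
    """Per-locus association P-values for one phenotype."""

    pvalues: pd.Series
    phenotype_name: str = "phenotype"

    def __post_init__(self) -> None:
        p = pd.to_numeric(self.pvalues, errors="raise")
        if ((p <= 0) | (p > 1)).any():
            bad = p[(p <= 0) | (p > 1)].index.tolist()
            raise PanelError(f"P-values outside (0, 1] at loci {bad}")
        self.pvalues = p.astype(float)

    def validate_against(self, panel: GenotypePanel) -> None:
        unknown = set(self.pvalues.index) - set(panel.loci)
        if unknown:
            raise PanelError(
                f"association table names loci absent from the panel: {sorted(unknown)}"
            )
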