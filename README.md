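# epinet

Genotype-network analysis of quantitative GWAS phenotypes: build haplotype
networks from phenotype-associated loci, quantify epistasis from the
networks' four-cycles, and measure how accessible extreme phenotypic values
are along mutational paths.

## Who this is for

Population and quantitative geneticists who have, for one phenotype:

1. a genotype matrix — accessions (inbred lines) × biallelic loci, one
   nucleotide character per cell;
2. per-locus association P-values from a GWAS;
3. per-accession phenotype values;
4. optionally a Newick phylogeny over the accessions.

From those inputs, `epinet` concatenates the alleles at loci passing a
P-value cutoff into one haplotype string per accession, collapses identical
strings into vertices (carrying the mean phenotype of their member
accessions), and joins vertices that differ at exactly one position.  Only
connected components with ≥ 2 vertices are analysed.  A cutoff sweep
(−log₁₀ P from 4 to 9 in half-log steps) selects the network with the most
four-cycles per component.

## The statistics at the core

**Noise threshold δ.** For vertices shared by ≥ 3 accessions, the
coefficient of variation (sd/mean) of their phenotypes estimates
non-genetic variation; δ is the mean CV over such vertices.  Phenotype
differences ≤ δ are treated as identical.

**Epistasis from squares.** A square is a 4-cycle: wild type *ab*, single
mutants *Ab*, *aB*, double mutant *AB*, with *AB* assigned to the unique
within-square maximum (tied maxima are skipped).  The interaction strength
is

```
ε = V_AB + V_ab − V_Ab − V_aB
```

with |ε| < δ called non-epistatic (ε set to 0).  Epistatic squares are
split by whether each mutation's effect changes sign between backgrounds:
neither → magnitude, exactly one → simple sign, both → reciprocal sign.

**Accessibility.** For every vertex, all shortest paths to the unique
phenotypic maximum (or minimum) are enumerated; a path is accessible if the
phenotype never moves against the direction by more than δ at any step.
The headline quantity is the fraction of accessible paths, overall and
binned by path length.

**Null model.** Random panels preserve each aligned column's character
composition; 10,000 replicate networks (configurable) give empirical
distributions for unique-genotype count, square count, largest-component
size and maximum betweenness.

A synthetic-data module generates panels with planted architectures
(additive effects, pairwise interactions, Gaussian noise), so the whole
pipeline can be exercised against known ground truth.

## Worked example

```sh
epinet run --simulate reciprocal-heavy --seed 2 --out run/
```

simulates 500 accessions at 34 loci where two pairs of causal loci carry
strong negative interactions, runs the GWAS-style association test, sweeps
cutoffs, and prints the summary row:

```json
{
  "cutoff": 3.1622776601683795e-05,
  "n_loci": 4,
  "n_vertices": 16,
  "n_squares": 24,
  "delta": 0.0,
  "epistatic_fraction": 0.3333333333333333,
  "reciprocal_sign_fraction": 0.3333333333333333,
  "fraction_accessible_max": 0.1875,
  "mean_path_length": 2.1333333333333333
}
```

Reading: the sweep recovered exactly the four causal loci (cutoff
10⁻⁴·⁵); their haplotypes form a 16-vertex network with 24 squares, of
which one third are reciprocal-sign epistatic — and exactly because of
those sign flips, only 18.75% of shortest mutational paths to the
phenotypic maximum are accessible.  The same command with
`--simulate additive` yields an epistatic fraction of 0 and accessibility
1.0.  `run/` contains the sweep table, GraphML + edge-list network export,
per-square epistasis calls, per-source accessibility tables, null
comparison and a JSON manifest recording every skip and seed.

The library API mirrors the CLI (`epinet.simulate_panel`,
`epinet.sweep_cutoffs`, `epinet.classify_network`,
`epinet.accessibility_summary`, ...); see the module docstrings.

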