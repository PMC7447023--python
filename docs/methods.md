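# Methods

## The model

The package treats a GWAS phenotype as a function over a genotype
(haplotype) network.  Vertices are the distinct strings obtained by
concatenating, per accession, the alleles at loci whose association
P-value passes a cutoff; each vertex carries the arithmetic mean phenotype
of its member accessions.  Edges join strings at Hamming distance 1, the
single-mutational-step relation, so paths through the network are
mutational paths and 4-cycles ("squares") are the minimal units on which
pairwise gene interaction can be read off.  Vertices without any
one-mutant neighbour are recorded as isolates and excluded from all graph
statistics; analysis is restricted to components with at least two
vertices.

Assumptions inherited from the data model: loci are biallelic (multiallelic
loci are rejected at load), accessions are inbred (one character per locus,
no heterozygotes), and phenotype values are comparable across accessions
(a single experimental scale per phenotype).

## Cutoff sweep

Networks are built for −log₁₀ P ∈ {4.0, 4.5, …, 9.0} by default — half-log
granularity matches the ±0.5 sensitivity step exposed by the sweep API.
The analysis network is the one maximising the per-component maximum
square count; ties break by larger largest-component size, then by the
more stringent cutoff (more stringent = fewer, better-supported loci; the
tie-break is our choice, as is the square-count criterion over raw
component size — squares are the unit of epistasis analysis, so a
square-poor network is uninformative regardless of its size).

Optional locus filters: a minor-allele-frequency filter that drops loci
strictly below the threshold (default 5% when enabled; a locus at exactly
the threshold is retained), and a greedy LD pruning step that keeps the
smallest-P representative of each cluster of loci with pairwise allelic
r² at or above a threshold.  The pruning rule is a deliberately simple,
config-exposed stand-in: a representative-per-cluster scheme, not a
reconstruction of any particular published procedure.

## Noise threshold δ

δ is the unweighted mean coefficient of variation (sample sd / mean) of
member phenotypes over vertices with ≥ 3 members.  Vertices whose mean is
exactly 0 have no defined CV and are excluded with a warning.  When no
vertex qualifies, δ is unavailable and all δ-dependent analyses for that
phenotype are skipped with a recorded reason.

δ is dimensionless while ε and step differences carry phenotype units.
The default (`delta_mode="literal"`) compares the raw numbers, which is
the conventional reading when phenotypes are scaled near unity.  The
`mean_scaled` mode multiplies δ by the mean absolute phenotype of the four
square vertices before the comparison, converting it to phenotype units;
this is the appropriate mode when phenotype means sit far from zero (for
a vertex with mean m and member sd s, the CV is s/m, so mean-scaling
recovers ≈ s, the per-vertex noise scale).  The planted-recovery analyses
in the test-suite use `mean_scaled` because their landscapes are offset to
keep CVs defined; the pipeline default remains `literal`.

## Epistasis classification

For each square the vertex with the strictly largest mean phenotype is the
double mutant AB; its Hamming-2 diagonal partner is the wild type ab.
Squares whose maximum is tied (exact equality of collapsed means) are
skipped and tallied.  With ε = V_AB + V_ab − V_Ab − V_aB:

- ε = 0, or |ε| < δ → no epistasis (ε reported as 0).  The absolute-value
  comparison matters because ε can be negative even though AB is maximal.
- otherwise, mutation A changes sign iff its effects in the two
  backgrounds, V_Ab − V_ab and V_AB − V_aB, have strictly opposite signs;
  analogously for B.  Steps with |ΔV| ≤ δ have indeterminate sign and
  never count as a change — the conservative direction.  Both change →
  reciprocal sign; exactly one → simple sign; neither → magnitude.

The Ab/aB labelling is arbitrary and provably cannot affect ε or the
class.  A network with zero squares is flagged not analyzable.

## Accessibility

Mutational paths are shortest paths (edge count) in the analysed
component, enumerated exhaustively via the breadth-first predecessor DAG;
a configurable cap (default 10⁶ paths) aborts loudly rather than sampling.
The target is the unique phenotypic extremum of the component — if the
extreme value is tied the analysis is skipped and recorded.  A path toward
the maximum is accessible when every step satisfies V_next − V_prev ≥ −δ:
the direct composition of "monotonically increases" with "differences
within δ are identical".  δ-tolerated flat or slightly decreasing steps
are allowed anywhere on the path, including the final step into the
extremum; a strict mode (every step must exceed +δ) is exposed for
sensitivity analyses.  Reported: global accessible fraction pooled over
all source vertices, per-source counts, mean path length, and accessible
fractions binned by path length into unit bins.

Raising δ relaxes the per-step constraint, so accessibility is monotone
non-decreasing in δ; this invariant is property-tested.

## Randomisation null

Random haplotype panels redraw each aligned column independently from the
column's empirical character distribution, preserving composition but
destroying inter-locus association.  Each replicate network is built by
the same code path as the observed network and summarised by
unique-genotype count, square count, largest-component size and maximum
vertex betweenness.  Empirical tail probabilities use the add-one
pseudo-count, P_upper = (1 + #{null ≥ obs}) / (n + 1), avoiding zero P at
finite replicate counts; two-sided P is 2·min(tails), capped at 1.

Because the synthetic generator draws loci independently (free
recombination, no LD — a stated non-goal), observed synthetic networks are
*not* square-enriched relative to this null: the acceptance script's
null-comparison P is unremarkable by construction.  On real data, linkage
and shared ancestry concentrate haplotypes and push the observed square
count into the upper tail; passing the synthetic check therefore
demonstrates the machinery, not the biological enrichment.

## Synthetic panels

`simulate_panel` draws minor alleles per accession per locus at a fixed
MAF and composes the phenotype as baseline + additive effects over minor
alleles + interaction effects for accessions carrying both minor alleles
of a pair + Gaussian noise.  One RNG stream per operation is derived as
`default_rng([seed, stream_id])`, so genotype draws, noise, and null
resampling are independently reproducible.  Association P-values come from
a two-sided Mann-Whitney U test of phenotype grouped by allele — a
deliberately robust, distribution-free stand-in for a mixed-model GWAS;
the pipeline only needs a P-value column with the right qualitative
behaviour, and monomorphic loci report P = 1 with a warning.

What the generator does *not* emulate: linkage disequilibrium, population
structure and kinship confounding, genotyping error, dominance (accessions
are inbred), and multi-locus (> 2) interactions.  Tests passing on these
panels validate the algorithmic pipeline, not robustness to those
real-data complications.

Preset conditions (chosen once as realistic demonstration architectures):

- `additive`: 400 accessions, 4 causal + 30 neutral loci, MAF 0.4,
  effects (5, 6, 7, 9) phenotype units, baseline 10, no noise.  The
  effects have pairwise-distinct subset sums, so all 16 haplotype values
  differ and the phenotypic extremum is unique in any subnetwork; all
  effects are large enough relative to the genetic background variance for
  every causal locus to reach the sweep grid's loosest cutoff.  Expected
  output: epistatic fraction 0, accessible fraction 1.
- `reciprocal-heavy`: 500 accessions, two interacting pairs with effects
  (6, 5) and interaction −7, baseline 10.  Within each pair both
  mutations flip sign between backgrounds (reciprocal sign epistasis)
  while the asymmetric effects keep each locus's marginal association
  detectable — symmetric effects would cancel the marginals and make the
  interacting loci invisible to a single-locus test, and they would also
  tie the within-square maximum.  Expected output: reciprocal-sign
  fraction > 0 and accessible fraction < 1.

The baseline of 10 keeps haplotype means away from zero, where the CV is
undefined; real phenotypes (days to flowering, ion concentrations) are
positive-valued, so a positive baseline is the realistic regime.

## Structure and phylogeny

Betweenness is normalised shortest-path betweenness (endpoints excluded),
computed per component.  Modules come from Louvain modularity maximisation
(resolution 1.0, seeded) on the largest component; the phenotype contrast
between the two largest modules uses the two-sided Wilcoxon rank-sum test,
exact for group sizes ≤ 10 and normal-approximated with continuity
correction otherwise.  Phylogenetic distance between accessions is the
number of internal nodes on the tip-to-tip path (branch lengths and
bootstrap labels ignored), or alternatively the raw nucleotide difference
count between aligned strings; vertex-pair distances average over all
member-accession pairs.  The path-length correlation uses Kendall tau-b —
path lengths are heavily tied, so the tie-corrected variant is required.
No multiple-testing correction is applied across phenotypes; outputs are
per-phenotype and flag this.

## Numerical and degenerate-input choices

- Locus order is ascending genomic label (chromosome:position numeric when
  parseable, lexicographic otherwise), fixing haplotype string positions.
- The square-maximum tie test uses exact float equality of collapsed
  means: collapsing makes exact ties the signature of genuinely identical
  value sets, and a δ-tolerant tie rule would interact confusingly with
  the later δ-thresholding of ε.
- Empty networks, δ-unavailability, ambiguous extrema and zero-square
  networks are signalled (exception or flag) and recorded in the run
  manifest, never silently dropped.
- CV uses the sample standard deviation (ddof = 1).
- Problem sizes in the test-suite and acceptance script (hundreds of
  accessions, ≤ 60-vertex oracle graphs, 10⁵ random squares, 2000 null
  replicates) are chosen so every check is exhaustive or
  well-powered while the whole suite runs in well under a minute each;
  the library defaults (10,000 null replicates, 10⁶ path cap) are the
  full-scale settings.

## Known limitations

- Exhaustive shortest-path enumeration is exponential in the worst case;
  the cap makes this loud, not fast.
- The LD pruning step is a greedy representative scheme, not an
  optimisation; heavily structured panels may warrant external pruning.
- δ conflates measurement noise with micro-environmental and residual
  genetic variation at unassociated loci; it is an upper bound on
  "identical phenotype" tolerance, which is why the ε-zeroing is
  conservative.
- Higher-order (> 2 locus) epistasis is out of scope; squares only.
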