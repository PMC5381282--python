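# Methods

## Problem setting

`limerad` analyzes single-nucleotide genotype matrices of clonally
propagated plant accessions — the shape of data produced by reference-
aligned RAD-seq genotyping of a small panel (here: eight lime accessions,
tens of thousands of sites).  Each matrix cell is a one-character IUPAC
call: `A/C/G/T` for homozygotes, `M/R/W/S/Y/K` for the six two-allele
heterozygotes, `N` for missing.  Because limes reproduce asexually
(nucellar embryony, grafting), accessions are treated as clonal lineages
descending from a shared, highly heterozygous hybrid founder; genetic
differences between lineages are dominated by somatic loss of
heterozygosity (LOH), de novo mutation, and genotyping artifacts rather
than by recombination through meiosis.

## Genotypable-site filter

A site is *genotypable* when every accession has a call and the site is
informative: at least one heterozygous call, or at least two distinct
homozygous calls.  Monomorphic homozygous sites carry no comparative
information and are dropped; uniformly heterozygous sites are kept
(they constitute Category A).  The filter is complete-case by design:
every category definition presumes a call in all accessions.

## Site categories

Given a partition of the accessions into two clusters (with an optional
two-way subcluster split inside one cluster), every genotypable site
receives one of twelve categories A–L plus a residual U.  The categories
are defined by call patterns; "uniform" means all members of a group
share one identical call (defined on calls, not alleles: `A,A,A,M` is
non-uniform even though M resolves to A/C).  The assignment is an
ordered decision procedure:

1. ≥2 distinct het codes anywhere → **L**.
2. All eight calls identical and het → **A**.
3. Both clusters uniform: hom/hom → **B** (necessarily different, else
   filtered); het/hom → **C**; hom/het → **D**.
4. First cluster uniform het H, second non-uniform with every call in
   {H} ∪ res(H) → **E** (mirrored → **F**).
5. First cluster uniform hom, second non-uniform containing H with every
   call in {H} ∪ res(H) → **G** (mirrored → **H**); the uniform hom is
   *not* required to be one of H's resolutions.
6. No het anywhere: first cluster uniform hom X with X recurring in the
   non-uniform second cluster → **J**; second cluster uniform hom with
   the first non-uniform → **K** (no recurrence requirement — J and K
   are deliberately asymmetric, following their definitions); any other
   all-hom combination → **U**.
7. Any remaining pattern containing a het → **I**.

The precedence order is a design choice: the categories are described in
the source material as observed outcomes, not as an algorithm.  Rule 1
comes first because L is the only class describing multiple het codes.
U exists so that the labels always partition the genotypable sites, even
on adversarial synthetic input; it is reported as its own row, never
folded into I.  Note one consequence of the definitions: U is reachable
on biallelic data (e.g. `A,A,C,C | A,C,C,C`, all-hom with neither
cluster uniform), so downstream code should not assume U is empty merely
because sites are biallelic.

The test suite checks the procedure against an independent predicate
oracle (each category tested in isolation, exclusivity asserted) on 10⁵
random call vectors, plus permutation invariance within clusters and the
cluster-swap symmetry C↔D, E↔F, G↔H (J maps to K under a swap; K maps
back to J only when the recurrence condition holds, else to U).

## Summary statistics

- **Heterozygosity**: per accession, the count of genotypable sites with
  a het call — a *minimum* (floor) on true heterozygosity, since only
  genotyped sites count — and its frequency `100 × count / total_bases`,
  where `total_bases = n_loci × read_length` (41-bp single-end RAD tags
  in the default parameterization).  Frequencies are reported at full
  precision with a 2-decimal presentation column.
- **Match matrices**: identical-call counts per accession pair within a
  site subset (typically one category); symmetric with diagonal equal to
  the subset size.
- **Identity counts**: per cluster/subcluster, sites where all members
  agree versus not; the two always sum to the site total.
- **Subpattern tables** (categories E, G, J): for sites where both
  subclusters are internally uniform, the consensus triple
  (non-subclustered cluster, subcluster 1, subcluster 2) is tallied;
  sites with a non-uniform subcluster go to a remainder.  The two
  directional totals (subcluster 1 het & 2 hom, and vice versa) are sums
  of the corresponding rows.
- **EcoRI de novo estimate**: if the events of a category were caused by
  mutations falling uniformly over the 36-bp flank of the 6-bp
  restriction-recognition site, the site itself receives
  `round_half_up(n_events × 6/36)` mutations (so 3087 → 515); such
  recognition-site mutations silently delete the locus from one
  haplotype and masquerade as homozygosity.  Zero events return zero.

## Distances and trees

Two metrics on accession pairs, both in [0, 1] with pairwise deletion of
missing calls: **mismatch** (fraction of non-identical calls, the
default — it matches the match-count machinery) and **allele sharing**
(per-site score: identical call 0, one shared allele 0.5 — e.g. a het
against either of its resolutions — disjoint allele sets 1).

Trees are built by neighbor joining, implemented in-package to pin two
determinism contracts: Q-matrix ties break at the lowest (row, column)
index, and negative branch-length estimates are clamped to zero with the
deficit shifted to the sister edge (path lengths preserved).  NJ is
exact on additive matrices — tested on random additive matrices and
cross-checked topologically against scikit-bio's implementation.
Bootstrap support resamples sites with replacement, rebuilds the tree,
and reports the percentage of replicates containing each internal-edge
bipartition.  Maximum-likelihood tree inference is intentionally not
bundled: the analysis surface here is cluster recovery, for which a
distance/NJ tree with site bootstrap suffices.

## Synthetic data generator

The simulator produces matrices with the statistical structure the
analysis assumes, plus full ground truth (founder calls, per-branch
event indices, the noise-free category of every site).  Model, per site
and independent across sites:

- founder het with probability `p_het` (uniform over the six het codes),
  else hom (uniform over four nucleotides);
- along each branch of a fixed lineage tree, LOH with probability
  `r_loh` (het → one of its two resolutions, each 1/2) and de novo
  mutation with probability `r_mut` (hom → the het joining it with a
  uniformly chosen other nucleotide; mutation creates only het states,
  matching the hom→het interpretation of within-cluster novelties);
- at the tips only, allele dropout with probability `r_dropout`
  (het observed as a hom of one random allele — a genotyping artifact,
  not an inherited state) followed by call error `e_error` (replacement
  by a uniformly random other call among the ten informative codes).

An optional tract mode draws LOH as geometric-length runs (default mean
100 sites) with one haplotype side per tract, reflecting that
double-strand-break repair can homogenize larger regions; all analytic
properties and defaults use the per-site mode.

The default lineage tree mirrors the study panel: founder → cluster-1
ancestor → four tips; founder → cluster-2 ancestor → two subcluster
ancestors → two tips each.

**`paperlike` preset** (the package's reference condition): 40,000
sites, `p_het = 0.60`, LOH 0.48 / 0.54 on the two cluster-ancestor
branches, 0.03 / 0.05 on the subcluster branches, 0.004 per tip branch;
mutation 0.003 on cluster ancestors and 0.0005 on subcluster branches;
dropout 0.002; call error 0.0003.  These rates were calibrated once so
the generated panel reproduces the observed summary shape — roughly 56%
of genotypable sites heterozygous per accession, category mass
concentrated in A/C/D with C > D, small E–L tails — since absolute
somatic event rates are not identifiable from a single panel.  What the
generator does *not* emulate: linkage and recombination tracts (in the
default mode), coverage-dependent dropout, locus-level missingness
patterns, paralog collapse, or any meiotic process.  Passing tests on
synthetic data therefore demonstrate the correctness of the *analysis*
under the stated model, not the biological fidelity of the rates.

A note on dropout's categorical effect: dropout in the het-uniform
cluster of a C (or D) site converts it to H (or G), so C/D mass falls as
dropout rises while the derived-hom mixture classes E/F/G/H grow; the
monotone-trend test tracks E+F+G+H.

**Rate recovery**: in single-branch LOH scenarios, `#C / (#A + #C)`
estimates the cluster-2-ancestor rate (mirrored `#D / (#A + #D)` for
cluster 1); this is exactly a binomial proportion over founder-het
sites, and the tests assert recovery within three binomial standard
errors.

## Morphometrics

Leaf blades and wings are modeled as ellipses, `area = width/2 ×
length/2 × π` (mm²; reported in π mm² units by convention).  The wing
index is `100 × wing area / blade area`.  Group summaries compute
per-leaf areas and indices first and then average — the index column is
a mean of per-leaf ratios, not a ratio of mean areas; the two agree only
for identical leaves.  Multiple-comparison testing of accession means is
out of scope.

## Numerical and interface choices

- Input is case-insensitive; `-` normalizes to `N`; storage is
  upper-case.  Coordinates, when present, are 1-based `chrom:pos` (VCF
  convention); matrices without coordinates are legal everywhere except
  VCF export.
- VCF export emits het codes as unphased `0/1` over their REF/ALT
  resolution pair and hom-non-reference as `1/1`; when no reference
  alleles are supplied, REF defaults to the alphabetically smallest
  observed allele.
- FASTA round-trips matrices without site ids; the TSV dialect (header =
  accession ids, optional leading `site_id` column) round-trips ids too.
  The TSV layout is this package's own definition.
- Partition configs are YAML (two clusters required; exactly two
  subclusters, partitioning one cluster, when declared; the first
  cluster listed plays the "first cluster" role in category
  definitions).
- EcoRI estimator rounds half-up (514.5 → 515).
- The pipeline report is canonical JSON with sorted keys and no
  timestamps (run metadata, including the config hash and timestamp,
  lives in a separate file), so reruns with identical config and seed
  are byte-identical.
- All randomness flows through `numpy.random.default_rng(seed)`;
  identical seed and parameters give byte-identical simulation output.

## Problem sizes used in the shipped checks

The test suite and examples run the simulator at 2,500–40,000 sites with
100 bootstrap replicates and the classifier oracle at 10⁵ random call
vectors; the whole suite completes in well under a minute on one core.
These sizes were chosen as comfortably sufficient for the binomial and
bootstrap tolerances asserted (e.g. 3·SE ≈ 0.012 at 10⁴ founder-het
sites for rate recovery).

## Known limitations

- The genotypable-site filter reproduces the logical requirements of the
  category definitions (complete + informative) but the original
  extraction scripts used upstream of such matrices are not specified;
  edge behavior may differ on real exports.
- Category U's existence means the twelve named categories are not
  exhaustive on arbitrary input; real panels may or may not contain
  U sites.
- `estimate_rates` is only meaningful in single-branch LOH scenarios;
  with events on several branches the A/C (A/D) odds confound rates.
- NJ recovers the true topology only for (near-)additive distances;
  on short matrices with heavy noise the usual caveats of
  distance-based phylogenetics apply.
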