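# Methods

## Species delineation from similarity matrices

Two genomes are treated as conspecific when their similarity reaches the
conventional species thresholds: 95% average nucleotide identity (ANI) or
70% digital DNA-DNA hybridization (dDDH). Species clusters are defined as
the **connected components** of the graph with an edge for every pair at or
above the threshold. Components are the weakest structural assumption
consistent with the block patterns seen in similarity heatmaps: they never
split a block and do not require transitivity of the raw similarity values.
Cluster labels are canonical — numbered from 1 by decreasing size, ties
broken by the lexicographically smallest member — so results are stable
across runs and machines. `ThresholdClusterer` exposes the same operation
as a scikit-learn estimator (`fit`, `fit_predict`, `labels_`) for use in
sklearn pipelines.

When ANI- and dDDH-based partitions disagree, the ANI partition is the
primary result; `consensus_check` reports the adjusted Rand index and the
genomes whose (overlap-matched) cluster assignment differs. Disagreement is
surfaced, never silently merged.

**Duplicate collapse.** Within each cluster of more than three strains,
duplicate groups are connected components of the graph with an edge where
*both* ANI and dDDH are ≥ 99%. One representative is kept per group: the
genome with the most gene families present, falling back to the
lexicographically smallest ID. Collapsing whole components (rather than
removing pairs in some order) makes the operation order-independent and
idempotent. Clusters of three or fewer strains are never touched; in groups
that small, near-identity is not sufficient evidence of redundant
resequencing.

**Exclusion ledger.** QC removals are recorded stage by stage; a genome may
be removed at most once, and the final count is
`initial − Σ removed + added`.

## ANI estimation

`kmer_ani` is a MinHash-sketch estimator: canonical k-mers (strand-minimum
of the forward and reverse-complement encodings; non-ACGT characters split
the extraction window) are hashed with a fixed 64-bit mixer, the Jaccard
index J is estimated from the bottom-s union sketch, and identity follows
the Mash relation `ANI ≈ 100·(1 + ln(2J/(1+J))/k)`. Defaults: k = 16,
sketch 5,000. When the sketches share nothing, J is below the sketch's
resolution; the estimator returns a *flagged* lower-bound value (computed
at J = 1/(2s)) rather than failing, since "too diverged to estimate" is a
meaningful result for species delineation.

`fragment_ani` cuts the query into 1 kb fragments, estimates per-fragment
identity from k-mer containment (`100·c^(1/k)`), drops fragments whose
shared-k-mer fraction falls below `min_shared_fraction` (unmapped), and
averages over both directions. It provides an independent estimate of the
same quantity; the two estimators agree within ~1 percentage point for
substitution rates up to 10% and both are accurate to within 1 point of the
true column-wise identity on simulated pairs.

dDDH is never computed from sequence: it is an input matrix only, as the
underlying genome-to-genome distance calculation is a calibrated external
method.

## Pangenome partitioning

A gene family present in m of n genomes is

- **core** if m ≥ c_core, with c_core = ⌊0.99·n⌋,
- **soft-core** if c_soft ≤ m < c_core, with c_soft = ⌊0.95·n⌋,
- **shell** if c_shell ≤ m < c_soft,
- **cloud** if 1 ≤ m < c_shell,

with c_shell = max(1 + [n > 6], ⌊0.15·n⌋). Flooring the fractional
boundaries reproduces the explicit per-cluster integer criteria used in
practice across the cluster sizes of interest (n = 3, 7, 24, 28): e.g.
⌊0.99·28⌋ = 27, ⌊0.95·24⌋ = 22, ⌊0.15·28⌋ = 4. The shell floor (2 for
n > 6, 1 otherwise) keeps singleton families in the cloud of mid-size
clusters while letting tiny clusters retain a one-genome shell band. For
tiny clusters the core and soft-core boundaries coincide (n = 3: both at 2)
and the merged band is reported as core, with `merged_soft_core` set.
Gene families present in no genome are excluded with a warning.

## Pangenome openness (Heaps law)

For each random permutation of genome order, Δn(N) is the number of gene
families first observed at the N-th genome; every permutation's increments
sum to the total family count. The power model Δn = κN⁻ᵅ is fitted per
permutation by ordinary least squares of ln Δn on ln N over the points with
N ≥ 2 (the N = 1 point measures genome size, not discovery decay) and
Δn > 0 (zero increments have no logarithm and are dropped from that
permutation's fit). The reported α and its dispersion are the mean and
standard deviation over permutations (default 100, seeded); κ is the
geometric mean of the intercepts. α is reported as the *decay exponent*,
positive when discovery decays; α < 1 calls the pangenome open, α > 1
closed. A curve whose increments vanish beyond N = 1 is flagged degenerate.
On noiseless power-law curves the fit recovers α to machine precision; with
10% multiplicative noise, 20 genomes and 50 permutations it recovers
α ∈ {0.3, 0.7, 1.3} within ±0.1.

## Core-set algebra

Given per-cluster core gene sets, the **common core** is their
intersection and the **type-core** of cluster i is
`core(i) \ ∪_{j≠i} core(j)` — families core in exactly one cluster, which
may still occur as accessory genes elsewhere. All 2^k − 1 Venn region
counts are reported; they sum to the size of the union of the cores, and
type-core sets are pairwise disjoint by construction.

## Marker-locus typing

A column of a marker alignment *separates* two clusters when each cluster
is fixed for a single allele (any within-cluster polymorphism, including
gap/base mixtures, disqualifies the column for that pair) and the alleles
differ. A locus's unresolved pairs are those no column separates. Columns
are reported 1-based.

Distances are p-distances (fraction of differing columns) on the
concatenated loci with pairwise gap deletion; a pair with no shared non-gap
columns is an error. Trees are built by standard neighbor joining,
implemented here with deterministic tie-breaking (smallest (row, column)
index in the Q-matrix) so trees are reproducible; negative branch-length
estimates are clamped to zero. On additive inputs the tree reproduces the
input distances exactly. Monophyly of a labeled cluster is tested on
unrooted-edge bipartitions: a cluster is monophyletic iff some bipartition
side equals exactly its member set.

## Contingency statistics

Fisher's exact test uses the "sum of small p" two-sided convention of
standard statistical software: the p-value is the total null probability of
all margin-fixed tables no more probable than the observed one (a relative
slack of 1e-7 absorbs floating-point ties). The 2×2 case enumerates the
hypergeometric support directly. The r×c case enumerates all tables with
the observed margins by depth-first search under the multivariate
hypergeometric null; the enumeration is bounded (default 10⁷ tables) and
errors with guidance to the seeded Monte Carlo estimator, which samples
margin-preserving tables row by row and reports the p estimate with its
standard error. p is invariant under row and column permutations and
equals 1 for any table with a zero margin.

`chisq_profile` compares two category-count profiles (e.g. COG category
counts of two core genomes) with Pearson's chi-square on the 2×k table, no
continuity correction, df = k − 1 after dropping categories empty in both.

`bgc_frequency_table` calls a strain a *producer* of a metabolite when its
BGC count is ≥ 1, tabulates per-cluster producer counts, sizes and
percentages (2 decimals), and attaches the Fisher exact p across clusters;
rows with p > 0.05 are flagged not significant. A `clusters` argument
restricts the test to a subset of clusters (e.g. the two largest), which is
the construction that reproduces the printed per-metabolite p-values in
the motivating study.

## Synthetic study generator

The generator plants the latent structure the analysis is designed to
recover, with one global seed from which all sub-generators derive child
seeds (same seed ⇒ byte-identical study).

- **Similarity blocks**: within- and between-cluster ANI/dDDH are drawn
  from normal distributions truncated to [0, 100]. Defaults: four clusters
  of sizes (24, 3, 7, 28); ANI 97 ± 0.5 within vs 90 ± 0.5 between
  (cleanly separated by the 95% threshold); dDDH 82 ± 3 vs 45 ± 4 (around
  the 70% threshold). If a within or between distribution comes within 4
  standard deviations of its threshold, a warning is recorded in the truth
  record, since delineation recovery is then not guaranteed.
- **Gene content**: 2,327 common-core families present everywhere;
  per-cluster type-core families (defaults 70, 164, 183, 82) present in
  every member of their cluster and planted elsewhere only sparsely,
  capped strictly below every other cluster's core threshold; and an
  accessory pool (default 6,000 families, each entering a given cluster
  with probability 0.3) whose per-cluster presence counts follow a
  truncated power-law frequency spectrum S_m ∝ m^(-1.5). The heavy
  singleton tail of that spectrum is what makes the simulated pangenomes
  open (fitted α ≈ 0.6–0.8 for the larger clusters), matching the
  open-pangenome regime of real, freely recombining soil bacteria; a
  fixed-probability binomial accessory model would instead produce
  geometric discovery decay and a spuriously closed call.
- **Duplicates**: pairs inside clusters of more than three strains; the
  second genome receives a verbatim copy of the first's gene content and
  similarity rows, and the pair similarity is drawn uniformly from
  [99.2, 99.9] on both measures. Because caps are computed on the unique
  genomes at post-dedup cluster sizes, type-core recovery is exact both
  before and after duplicate removal, and cluster sizes stay as
  configured.
- **Marker loci**: planted diagnostic columns assign one base per allele
  group; all other columns are invariant. Defaults emulate one fully
  discriminating locus (three 4-way columns) and two loci that separate
  clusters 1 and 2 but not 3 from 4.
- **BGC counts**: per-cluster producer probabilities (defaults emulate two
  strongly cluster-skewed metabolites, one unskewed, one rare); producers
  receive counts in 1–3.
- **Sequences**: `generate_sequences` realizes target pairwise divergences
  on a star phylogeny — tip rates carry the within-cluster divergence and
  cluster-centre rates are solved by least squares from the between-cluster
  targets — because arbitrary per-pair divergences are not jointly
  realizable in general. Substitution counts are deterministic
  (round(rate·L) positions, each to a different base), so realized
  divergence tracks the target to within sampling overlap. Rates above 0.3
  are rejected; the k-mer identity relation underlying the ANI estimators
  degrades beyond that.

**What the generator does not emulate**: gene order and synteny, paralogs,
recombination tracts, assembly artifacts, alignment error, and
base-composition structure. Passing tests therefore demonstrate the
correctness of the algorithms under the stated statistical model, not
robustness to the full messiness of real assemblies.

## Problem sizes and numerical choices

Tests run the generator at the full study scale (62 genomes, ~9,000 gene
families) where the pipeline is exercised end to end, and at reduced scale
for I/O round trips. Heaps fits use 50–100 permutations. Exact r×c Fisher
enumeration is comfortable for 2×4 tables at N ≈ 60 (tens of thousands of
tables); the Monte Carlo fallback is for substantially larger tables.
Matrix symmetry is enforced at 1e-9; similarity values written to TSV carry
4 decimals.

## Known limitations

- Delineation by connected components can chain distinct blocks together
  through a single borderline pair; the generator's default separation
  makes this a non-issue in simulation, but real borderline datasets
  deserve inspection of the consensus report.
- The sketch ANI estimator loses resolution below ~80% identity (near-zero
  Jaccard); results there are flagged lower bounds.
- The exact r×c Fisher test is exponential in table size; it is intended
  for the small cluster-count tables of this workflow.
- `chisq_profile` applies no multiple-testing correction across metabolites
  or categories; raw p-values are reported per row.
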