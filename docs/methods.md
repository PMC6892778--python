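# Methods

## Data model

A cohort is a binary gene × sample matrix: entry (g, s) is 1 iff sample s
carries ≥1 retained somatic variant in gene g. Variant multiplicity is
collapsed at read time (MAF input) or validated on read (matrix input).
Per-gene mutation frequency f, per-sample mutated-gene counts and the
cohort size N all derive from this matrix. A pathway is a named gene set
with undirected interaction edges between member genes; genes without
edges are isolated nodes. Gene symbols match by exact, case-sensitive
string equality — no alias resolution — so results are independent of any
identifier-mapping service version. MAF rows are all counted by default;
an exclude list (e.g. `Silent`) is available because conventions differ on
whether silent variants count as mutations, and the gene-level reduction
("≥1 mutated gene") makes the choice explicit rather than baked in.
Pathway genes absent from the profile are retained with frequency 0: they
can still act as connectors during greedy growth.

## Significantly mutated pathways

Observed statistic: M = number of samples in which ≥1 pathway gene is
mutated. Null model: each sample independently draws its *real* number of
mutated genes uniformly without replacement from the background universe
(a RefSeq-style gene list; mutated profile genes missing from it are added
with a warning so every count is drawable). One random experiment yields
one simulated cohort; all pathways are scored against the same n simulated
cohorts, preserving the cross-pathway correlation the null induces. The
p-value is the fraction of experiments with R > M — ties count as
non-exceedance, exactly as the estimator is defined, so p can be 0 at
finite n; an add-one estimator ((Σ+1)/(n+1)) is available behind a flag,
default off, for callers who prefer never-zero p-values. p-values are
therefore exact multiples of 1/n. BH step-up adjustment (via statsmodels)
controls FDR across pathways; the default significance gate is q < 0.05.

Randomness contract: one seeded NumPy generator; samples are drawn in
fixed roster order within each experiment and experiments run
sequentially, so results are bit-reproducible given the seed.

## Greedy sub-pathway growth

Both modes share one engine operating on a connected component of the
pathway graph, differing only in the objective:

* **Common mode** maximises coverage = |{s : ≥1 member gene mutated}|/N.
  Seed: the component gene with the largest f. Marginal gain Pf ≥ 0.
* **Subtype mode** maximises the coverage difference
  covA − covB. Genes are first partitioned by the sign of
  v = f_a − f_b; growth for A-specific modules is restricted to v > 0
  genes (B-specific runs with the roles swapped and is therefore exactly
  symmetric). Seed: the largest-|v| gene of the direction's set. Marginal
  gain Pv may be negative.

Each pass collects the unvisited direct neighbors of the current seed
frontier, ranks them by their gain against the sub-pathway state at the
start of the pass, and inserts them in that order; the *realized* gain at
insertion time decides the classification. Gain-positive genes (GI) stay
and seed the next pass. A non-gaining gene (GN) is tentatively inserted
and its own unvisited neighbors are examined in gain order: if at least
one gains, the GN gene stays as a bridge and the gaining neighbors become
new seeds; otherwise the insertion is rolled back. Neighbors examined
during a failed or successful rescue are marked visited either way and are
not rescued recursively (depth-1 rescue): this guarantees termination and
a single visit per gene, at the cost of occasionally burning a zero-gain
gene that a later frontier might have bridged through — an ambiguity the
algorithm description leaves open, resolved here in favour of determinism.
All ties (seed choice, gain ranking) break lexicographically on the gene
symbol, so output is platform-independent.

Budgets: common mode may retain any number of independently justified
bridge genes; subtype mode retains at most one non-gaining gene per
sub-pathway (a global budget, configurable; when exhausted, non-gaining
candidates are rejected without a rescue attempt).

Emission gates (defaults): common — coverage ≥ 0.90 and ≥5 genes;
subtype — |covA − covB| ≥ 0.25 and two-sided Fisher exact p < 0.05 on the
sub-pathway's 2×2 mutated × subtype table (raw p, no FDR at this stage;
the FDR screen already ran at the pathway level). There is no minimum gene
count in subtype mode. Reported coverages and differences are always
recomputed from scratch on the final gene set, never taken from
incremental bookkeeping, and every emitted gene set induces a connected
subgraph by construction.

Two-sided Fisher tests are used at both the pathway screen and the
emission gate: directionality is already enforced by the sign-restricted
growth and the difference threshold, so the conservative two-sided test
adds robustness without losing the direction.

## Enrichment

Upper-tail hypergeometric p = P(X ≥ k) for overlap k between a
sub-pathway's genes and a target list, with population = background
universe, defaulting to the union of genes across the loaded pathway
collection (target lists are intersected with that universe first, since
genes outside it could never appear in a sub-pathway). Raw p-values at
α = 0.05, no multiplicity correction.

## Synthetic data

The generator emulates the statistical shape of exome cohorts rather than
their biology: per-sample mutated-gene counts are negative binomial
(default mean 40, shape 8 — overdispersed, giving the occasional
hypermutator tail) over a 2,000-gene background universe, so per-gene
noise frequencies sit near 2%, typical of untargeted exome cohorts once
scaled to the universe size; pathways are 30-gene random subsets with
Erdős–Rényi edges at density 0.15 (connected with high probability, like
curated pathway graphs). Default cohort sizes are 200 samples (400 for
subtype scenarios, 200 per arm), in the range of the cohorts such
analyses are run on.

Planted signal is exact by construction: ⌈c·N⌉ samples are assigned ≥1
planted-gene mutation round-robin across the planted genes (default 6
genes at c = 0.95 for common mode; a 0.40 coverage difference over a 0.20
base for subtype mode), the planted genes are wired into a path inside
their host pathway, and background noise never touches them — so planted
coverage and difference are auditable exactly by enumeration on the
emitted matrix. Round-robin assignment gives every planted gene its own
exclusive sample block, hence a positive marginal gain whenever the search
reaches it; an optional redundant gene receives only already-covered
samples to exercise the bridge-rescue rule. What the generator does *not*
model: mutation signatures, gene length effects on mutation rate,
copy-number events, and inter-gene mutation correlation beyond the
planted module — so passing recovery tests demonstrates algorithmic
correctness on the stated statistical structure, not robustness to those
real-data features.

## Numerical and scale choices

The permutation scoring is a single float32 matrix product per experiment
(pathway-membership matrix × simulated indicator), which keeps 200
pathways × 100 samples × 500 experiments around a second. The acceptance
script uses that size for calibration and 100 replicates of the default
scenarios for the recovery rates; these sizes give binomial standard
errors small enough to make the calibration band (±3·SE at 200 trials)
and the ≥95/100 recovery criteria meaningful. Degenerate inputs are
defined rather than special-cased: empty gene sets cover nothing,
saturated pathways get p = 0 under the strict-exceedance estimator, a
component whose direction set is empty yields no subtype sub-pathway, and
an empty result list is a valid outcome everywhere.

## Known limitations

* The greedy search is a heuristic for an NP-hard connected
  maximum-coverage problem; it is guaranteed connected and
  threshold-sound, not optimal. Small-instance tests verify it never
  emits when exhaustive search shows the threshold is unreachable.
* Whether the original procedure re-ranks candidates after every single
  insertion or once per frontier pass is ambiguous; this implementation
  ranks per pass and classifies by realized gain, one consistent reading.
* The null model ignores gene length: long genes are as likely to be
  drawn as short ones. Length-aware nulls are out of scope.
* Exactly two subtypes are supported; survival analysis of emitted
  sub-pathways is out of scope.
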