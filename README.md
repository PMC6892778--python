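# pathcover

Somatic mutation cohorts are heterogeneous: individual driver genes are
mutated in only a fraction of patients, but the pathways they sit on are
disrupted far more broadly. `pathcover` analyses a binary gene × sample
somatic-mutation matrix together with a pathway collection (gene sets plus
gene–gene interaction edges) and extracts, for cancer genomics researchers:

1. **Significantly mutated pathways.** A pathway counts as mutated in a
   sample if ≥1 member gene is mutated; its statistic is the number of
   mutated samples *M* out of *N*. Significance comes from a permutation
   null that preserves every sample's mutated-gene count while drawing the
   genes uniformly from a background universe: over *n* random experiments
   (default 1,000), *p = #{r : R_r > M}/n*, BH-adjusted across pathways.
2. **Common sub-pathways.** Within each significant pathway's interaction
   graph, a greedy search grows a connected gene set from the
   highest-frequency seed gene, adding frontier neighbors in descending
   order of marginal coverage gain *Pf*, until coverage (fraction of
   samples with ≥1 mutated member) stalls. Gene sets covering ≥90% of the
   cohort with ≥5 genes (defaults) are reported. A gene adding no coverage
   is kept only when it bridges to a gain-positive neighbor.
3. **Subtype-specific sub-pathways.** For two subtypes A/B, pathways are
   screened by a two-sided Fisher exact test (BH FDR < 0.05); growth then
   ranks genes by the gain *Pv* in the coverage difference
   cov<sub>A</sub> − cov<sub>B</sub>, restricted to genes with
   *v = f<sub>a</sub> − f<sub>b</sub>* of the matching sign, retaining at
   most one non-gaining bridge gene. Sub-pathways with difference ≥0.25 and
   Fisher p < 0.05 are reported.
4. **Enrichment.** Hypergeometric upper-tail tests of each sub-pathway
   against cancer-gene and drug-target lists over the pathway-collection
   universe.

A synthetic-data module generates cohorts and pathway collections with
planted, exactly auditable signal, so the whole pipeline is testable
without any external downloads.

## Worked example

```python
from pathcover import (SyntheticScenario, simulate_common_scenario, NullModelSpec,
                       permutation_pvalues, significant_pathways, find_common_subpathways)

data = simulate_common_scenario(SyntheticScenario(rng_seed=7))   # 200 samples,
# 6-gene connected module planted at 95% coverage inside pathway P000
spec = NullModelSpec(data.background, n_reps=1000, rng_seed=7)
sig = significant_pathways(permutation_pvalues(data.profile, data.pathways, spec))
subs = find_common_subpathways(
    data.profile, [p for p in data.pathways if p.pathway_id in {r.pathway_id for r in sig}])
```

prints (via the obvious report loop):

```
significant: P000 M=194/200 p=0.000 q=0.000
common sub-pathway: P000 n_genes=19 coverage=0.970
planted module: BG00555;BG00564;BG00680;BG01648;BG01731;BG00109
```

Only the host pathway of the planted module survives the permutation test
(194 of 200 samples mutated, p = 0 at 1,000 experiments). The greedy search
emits one sub-pathway of 19 connected genes covering 97% of the cohort; it
contains all six planted genes, plus noise genes whose mutations happened
to extend coverage. The subtype mode on the same scenario reports

```
subtype sub-pathway: P000 A-specific n_genes=12 covA=0.700 covB=0.255 diff=0.445 p=3.19e-19
```

i.e. a connected module mutated in 70% of subtype-A samples but 25.5% of
subtype-B samples — recovering the planted 0.40 coverage difference.

The same pipeline is available from the shell (`pathcover significance`,
`common`, `subtype`, `enrich`, `simulate`); every report TSV records the
tool version, seed and effective parameters in a header comment.

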