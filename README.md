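# chiamod

Chromatin-interaction network analysis for identifying lncRNA-containing
regulatory modules from ChIA-PET data.

## The problem

RNA polymerase II ChIA-PET experiments capture pairs of genomic regions
(paired-end tags, PETs) that are in contact in the nucleus.  Representing
regions as nodes and contacts as edges yields a *chromatin graph* in which
groups of enhancers, promoters, genes and long non-coding RNAs (lncRNAs)
that loop together form densely connected modules — candidate regulatory
units.  Most lncRNAs have unknown function; placing them inside such
modules, next to genes of known function, is a route to annotating them.

`chiamod` implements the full workflow for this analysis:

1. **PET filtering.** Replicate intersection, removal of inter-chromosomal
   contacts, and separation of artifactual *self-ligation* PETs from
   genuine *inter-ligation* PETs.  Interaction frequency vs genomic
   distance follows two distinct power laws on a log-log scale; two lines
   are fitted (count-weighted least squares over all candidate split
   points of the log-binned histogram) and their intersection is the
   distance cutoff below which PETs are discarded.
2. **Graph construction and annotation.** Overlapping anchors merge into
   nodes; nodes are annotated by strand-ignored interval overlap with gene
   and lncRNA tracks and chromHMM-style chromatin states, producing
   composite labels such as `lncRNA_enhancer` ("repressed" is dropped;
   unannotated nodes become `unknown`).
3. **Network metrics.** Degree d(v), annotation-restricted degree (e.g.
   to-gene degree), raw betweenness b(v) = Σ_{s≠v≠t} σ_st(v)/σ_st,
   log-log power-law fits of degree distributions, and Fisher-exact /
   Wilcoxon rank-sum association tests between annotations and
   centralities.
4. **MSM fuzzy clustering.** A continuous-time random walk on a connected
   component has generator L = A − D.  Its near-zero eigenvalues mark
   metastable modules; the resolution parameter α selects their number as
   m = #{|λ| < 1/α}.  Module cores come from k-means in the dominant
   eigenspace; every other node gets fuzzy affiliations q_i(x) — the
   probability the walk from x hits core i before any other core —
   computed by sparse symmetric positive-definite linear solves.  A
   threshold θ turns affiliations into assignments; nodes with
   max_i q_i(x) < θ form the *transition region* that mediates between
   modules.
5. **Co-expression objective.** MI(X, Y) = H(X) + H(Y) − H(X, Y), with
   entropies (nats) from Gaussian-smoothed histograms of expression
   profiles across tissues, scores a clustering by
   median(intra-module MIs) / median(inter-module MIs); a grid search over
   {θ, α} maximizes the ratio.  Any externally produced partition can be
   scored with the same protocol for method comparison.
6. **Module enrichment.** One-sided hypergeometric tests of module gene
   sets against user-supplied GMT collections, Benjamini-Hochberg
   adjusted; terms with adjusted p ≤ 0.1 and more than two module genes
   are reported and transferred to lncRNAs and transition-region nodes.

A synthetic-data module generates all inputs with the statistical
structure the pipeline assumes (planted-module graphs, two-power-law
distance mixtures, module-correlated RPKM matrices, annotation tracks),
so every stage is testable without external downloads.

## Worked example

Generate a synthetic bundle, filter, build, and optimize the clustering:

```
chiamod simulate --out bundle --seed 11
chiamod filter --rep1 bundle/interactions_rep1.bedpe \
               --rep2 bundle/interactions_rep2.bedpe \
               --out filtered.bedpe --cutoff 1691
chiamod build --interactions filtered.bedpe --genes bundle/genes.bed \
              --lncrnas bundle/lncrnas.bed --states bundle/states.bed \
              --out graph
chiamod optimize --graph graph --expr bundle/expression.tsv \
                 --alpha 1,3,10,100 --theta 0.5,0.7,1.0 --seed 42 --out opt
```

The filter step prints

```
{
 "fraction_interchromosomal_removed": 0.014970059880239472,
 "cutoff_nt": 1691.0,
 "n_self_ligation_removed": 23,
 "n_retained": 306
}
```

— about 1.5% of the merged interactions were inter-chromosomal (the
bundle plants ~1.8% contamination) and 23 short-range self-ligation
records fell below the 1691 nt cutoff.  The optimizer then reports

```
{
 "alpha": 1.0,
 "theta": 0.7,
 "m": 3,
 "ratio": 3.4588921094534872,
 "seed": 42
}
```

— at θ = 0.7 the three planted modules are recovered, and within-module
expression profiles carry about 3.5 times the mutual information of
between-module pairs, the signature of a genuine co-regulated partition
(a random partition scores ≈ 1).  The fitted self-ligation cutoff is
demonstrated on a full-size distance sample (the fitter requires ≥ 1000
distances spanning two decades):

```python
from chiamod import DistanceMixtureSpec, gen_pet_distances, fit_distance_breakpoint
fit = fit_distance_breakpoint(gen_pet_distances(DistanceMixtureSpec(seed=1)))
print(fit.breakpoint_nt)   # 1677.7 — within 1% of the planted 1691 nt
```

The full pipeline runs from one config: `chiamod run --config cfg.yaml`.

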