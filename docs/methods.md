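# Methods

This note documents the models, estimators and numerical choices behind
`chiamod`, what the synthetic generators do and do not emulate, and the
known limitations.

## PET filtering

**Replicate intersection.** Anchor coordinates differ slightly between
replicate peak calls, so two interactions are considered the same when
anchor A overlaps anchor A′ and anchor B overlaps anchor B′ by ≥ 1 bp
after canonical ordering (lexicographically smaller anchor first), also
allowing the swapped pairing.  Retained records carry `support = 2`.

**Distance definition.** The genomic distance of an intra-chromosomal PET
is measured midpoint-to-midpoint of its two anchors: symmetric and
insensitive to anchor widths.

**Self-/inter-ligation separation.** Interaction frequency per
logarithmic distance bin follows two distinct power laws: a short-range
regime of self-ligation artifacts and a long-range regime of genuine
contacts.  The fitter bins distances into 50 logarithmic bins (empty bins
dropped), and for every candidate split with at least 5 occupied bins per
side fits one straight line per side in log10-log10 space.  Lines are
fitted by *count-weighted* least squares: under Poisson sampling the
variance of a log bin count scales like 1/count, and unweighted fits let
near-empty tail bins dominate the split criterion (in calibration runs
roughly half the fits then landed 20–90% off the planted cutoff; with
weighting the maximum error over 20 seeds is ~5%, median ~2%).  The
breakpoint is the x-coordinate of the intersection of the two best-split
lines.  When the intersection falls more than 3 bins from the split — the
signature of near-parallel lines, i.e. a single power-law regime — the
fit reports the split boundary with `reliable = False` instead of an
extrapolated crossing.  Records strictly below the cutoff are discarded;
records at exactly the cutoff are retained.  Note that a *single* power
law sampled over many decades eventually hits the 1-count sampling floor,
which looks like a second (flat) regime; degeneracy detection is reliable
only where all bins are well populated.

## Graph construction and annotation

Anchors overlapping by ≥ 1 bp on the same chromosome merge transitively
into one node (union interval); an adjacency matrix indexed by "genomic
regions" implies deduplicated regions.  Interactions whose anchors merge
into the same node would be self-loops and are dropped (counted in
`graph["n_self_loops_dropped"]`); parallel interactions collapse to a
single edge — the adjacency is 0/1.

Annotation is strand-ignored ≥ 1 bp interval overlap against gene bodies
(introns included), lncRNA bodies and chromatin-state segments.  All
coordinates are normalized to 0-based half-open on ingestion (GTF's
1-based inclusive converted).  A node's class set is the union over all
overlapping features; "repressed" segments carry no information in a
Pol II-mediated network and are ignored; nodes with no overlap are
`unknown`.  Multiple gene/lncRNA names are all retained.  Composite
labels order classes deterministically (gene, lncRNA, enhancer,
weak_enhancer, TSS, promoter_flanking, CTCF, transcribed), so
`lncRNA_enhancer` always means {lncRNA, enhancer}.  Annotation is
idempotent and monotone: re-annotating changes nothing, adding tracks
never removes classes.

## Network metrics

Degree and betweenness follow the standard definitions; betweenness is
the raw sum over unordered pairs without endpoint normalization, computed
per connected component.  Degree-distribution exponents are estimated by
a straight-line fit to the log-log histogram; supports wider than one
decade are binned logarithmically with bin-width normalization, which
removes the flattening bias that singleton tail counts induce in a
per-degree histogram.  Maximum-likelihood power-law estimation would be
an alternative; the line fit mirrors the distance-histogram practice and
is what the estimator's tests calibrate.  Fisher's exact test reports
the sample odds ratio with the conditional (hypergeometric) two-sided
p-value; the Wilcoxon rank-sum test reports the rank sum of group A with
an exact p for small tie-free samples and a tie-corrected normal
approximation otherwise.

## MSM fuzzy clustering

The continuous-time random walk jumps along each edge at unit rate; its
generator is L = A − D, symmetric with zero row sums, non-positive
spectrum and a single zero eigenvalue per connected component.  (A
degree-normalized variant is a straightforward substitution but is not
the default: the symmetric form directly yields the symmetric
positive-definite committor systems below.)

* **Spectrum.** The k smallest eigenvalues of −L (k = min(n−1, 25) by
  default) come from a dense solver for components up to 600 nodes and
  shift-invert Lanczos above.  Eigenvalues below 1e-10 are clamped to 0.
* **Module count.** m = #{λ : λ < 1/α}; the zero mode always counts, so
  α above the slowest timescale yields m = 1 ("no partition at this
  resolution") and decreasing α admits less pronounced modules.  The
  dominant gap is located by the additive eigengap heuristic
  (argmax of λ_{m+1} − λ_m): ratios between near-zero dominant
  eigenvalues are noise-dominated and misplace the gap on roughly one in
  ten planted graphs.  `suggest_alpha` returns the geometric mean of the
  two implied timescales flanking the gap.
* **Cores.** Nodes are embedded in the m dominant eigenvector
  coordinates and split by seeded k-means (10 restarts); the core of a
  group is the 20% of its members closest to the centroid (at least one
  node).  This construction is deliberately isolated behind one
  interface: it is a standard, testable surrogate for metastable-set
  identification and can be swapped without touching the committor
  machinery.
* **Affiliations.** q_i(x) is the committor — the probability the walk
  from x hits core i before any other core.  With cores fixed at
  boundary values, the restricted system (−L on non-core rows/columns)
  is symmetric positive definite for a connected component and is solved
  once per core via a shared sparse LU factorization.  Σ_i q_i(x) = 1
  and 0 ≤ q_i ≤ 1 hold by construction (verified to 1e-8 in tests, and
  against dense solves and Monte-Carlo hitting frequencies of the
  embedded jump chain).
* **Assignment.** Node → module i when q_i ≥ θ; for θ > 0.5 this is
  unique; at θ ≤ 0.5 the node goes to its highest affiliation, ties to
  the lowest module index.  Unassigned nodes form the transition region.
  The assigned set shrinks monotonically as θ grows.
* **Small components** (< 20 nodes) bypass clustering and are reported
  whole as single modules.

## Expression processing and the MI objective

RPKM = counts / (length/10³) / (library/10⁶).  The detection threshold is
the deepest local minimum between the two highest modes of a Gaussian KDE
of the natural-log RPKM distribution, reported on the RPKM scale;
unimodal densities raise a flagged error carrying the density grid.
Detection requires genes above the threshold in both replicates (the
either-replicate reading is available behind a flag) and lncRNAs either
positive in both replicates or above the threshold in at least one.

MI is estimated from histograms of log2(RPKM + 1)-transformed profiles
(8 bins per axis for 24 samples; heavier binning is not resolvable at
that sample size), smoothed with an isotropic Gaussian kernel of width
1 bin.  Marginals are obtained by summing the smoothed joint, so the
plug-in MI is the mutual information of a proper joint distribution and
cannot go negative at any smoothing width.  One consequence: the exact
identity MI(x, x) = H(x) holds only at σ = 0; with smoothing, the
isotropically smoothed diagonal joint has H(X,Y) > H(X) and perfectly
dependent pairs are biased downward.  Bins, σ and the log transform are
all configurable.

A clustering is scored by median(intra-pair MIs)/median(inter-pair MIs)
over feature pairs whose nodes are assigned to modules; transition-region
nodes are excluded from both sets, pairs of features residing on the same
node are skipped, and the gene-gene pair scope is the default (more
robust than including the more tissue-specific lncRNAs).  The report is
flagged undefined when either pair set is empty.  Permuted module labels
calibrate the ratio to ≈ 1; planted co-expressed partitions score well
above 1.

**Grid search.** Every {α, θ} cell runs the full clustering and is
scored; the audit table records m, pair counts, pair coverage and ratio
per cell.  Cells that classify fewer than half of the component's
scorable feature pairs are recorded but ineligible for the argmax (unless
no cell reaches the floor): a θ = 1 clustering that assigns only the
module cores maximizes the ratio trivially while leaving most of the
component unexplained, and the objective is meant to rank clusterings of
the whole component.  Ties break toward fewer modules, then larger θ.
The default grids span θ ∈ {0.5 … 1.0} and α ∈ {100 … 2000}; on the
small dense synthetic fixtures the spectrally appropriate α is of order
1–10 (timescales scale with degree and component size), so fixture
analyses pass grids containing that resolution.

## Enrichment

One-sided hypergeometric upper-tail p per term (gene sets intersected
with the universe), Benjamini-Hochberg adjustment across tested terms,
and a reporting rule of adjusted p ≤ 0.1 with more than two module genes
in the term.  The background universe defaults to all genes present on
graph nodes — enrichment relative to the network; the annotation-wide
universe is a parameter.  Multi-gene nodes contribute each gene once.
Reported terms transfer to lncRNAs of the same module; transition-region
nodes inherit the union of reported terms of the modules containing
their direct gene neighbors.

## Synthetic data: what it emulates and what it does not

* **Graphs** are stochastic block models with planted module labels,
  annotation classes allocated by largest remainder, and synthetic
  non-overlapping anchor coordinates on one chromosome.  Real chromatin
  graphs are sparser, heavy-tailed in degree and multi-chromosomal;
  passing the recovery tests shows the clustering machinery is correct,
  not that real components are this well separated.
* **Distances** mix two bounded power laws split at the planted cutoff
  (defaults: breakpoint 1691 nt, slopes −0.5/−2.0 per log bin, support
  50 nt – 20 Mnt, 50,000 draws).  The exponents are defined as the
  slopes of counts per logarithmic bin — exactly what the fitter
  regresses — and sampling uses inverse-CDF on density x^(slope−1).  The
  default mixture weight is chosen so the two regimes' histogram heights
  are continuous at the breakpoint (~0.95 self-ligation, consistent with
  self-ligation dominating raw libraries); a strongly discontinuous
  mixture moves the fitted-line crossing away from the plant.
* **Expression** is simulated on the log scale as a shared per-module
  latent profile plus Gaussian noise, with the signal amplitude set so
  the expected within-module correlation equals `intra_corr` (default
  0.8 across 24 samples), then exponentiated to RPKM.  Real expression
  has mean-variance coupling and shared batch structure the simulation
  omits.
* **Bundles** write two pseudo-replicates (replicate 2 drops a seeded
  10%), ~1.8% inter-chromosomal contaminant records and 30 short-range
  self-ligation records present in *both* replicates (so the dedicated
  filters, not the intersection, must remove them), BED tracks matching
  the node annotations, a GMT with one term per planted module, and a
  truth JSON.

All generators are bitwise-reproducible given their spec and seed.

## Numerical and calibration notes

* Sparse eigensolves use shift-invert at σ = −1e-6 (the generator itself
  is singular); dense solves below 600 nodes avoid Lanczos convergence
  issues on small problems.
* Spectral separation of planted modules requires adequate within-module
  density, not just the p_in/p_out ratio: with 20-node modules at
  p_in = 0.3 (mean within-degree ~5.7), single weakly attached nodes
  contribute slow modes that displace the dominant gap in ~20–35% of
  seeds.  The calibration tests therefore assert the gap at
  within-degree ~9 and module recovery (ARI ≥ 0.9) at the default
  3 × 30, p_in = 0.25, p_out = 0.005 conditions, where both hold across
  seeds.
* Problem sizes in the test and acceptance runs — 90-node components,
  50,000-draw distance samples, 100 oracle graphs of ≤ 15 nodes with
  50,000 Monte-Carlo walks per node — were chosen so each stage's
  statistical claims are testable at desk scale while the whole suite
  stays fast.
* The Monte-Carlo committor oracle simulates the embedded jump chain
  (uniform neighbor choice), which has the same hitting probabilities as
  the continuous-time walk; it is compiled with numba.

## Known limitations

* The core-identification step is a surrogate (k-means in the dominant
  eigenspace + nearest-to-centroid cores); other metastable-set
  constructions may assign borderline nodes differently.
* The MI estimator is a smoothed histogram plug-in; it is biased for
  perfectly dependent pairs under smoothing and is not a consistency-
  optimal estimator (k-NN and copula estimators are out of scope).
* Betweenness is exact and therefore quadratic-plus in component size;
  very large components would need approximation, which is not provided.
* The breakpoint fitter assumes the two regimes are both represented by
  at least 5 occupied bins; cutoffs very close to the support edge are
  not recoverable.
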