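# Methods

## The model

`devcnet` quantifies how a case cohort differs from a control cohort on a
gene interaction network using three complementary differential signals,
each of which has a single-sample measurement:

**Differential expression (DEG).** For gene *n* with control expression
*X* and case expression *X′*, the null hypothesis E(X) = E(X′) is tested
with a two-sided Welch t-test on the raw expression level e_n^s. The
single-sample measurement is the raw level itself.

**Differential expression variance (DEVG).** A gene whose spread — not its
mean — changes with disease is invisible to mean-based tests. The test
compares the absolute deviations |x_s − u| (control, about the control
mean) with |x′_s − u′| (case, about the case mean). Under Gaussian
expression these deviations are folded-normal, so a Wilcoxon rank-sum test
is used instead of a t-test. A DEVG additionally requires that the means
do **not** differ (p_de > α), which makes DEG and DEVG disjoint classes.
The single-sample measurement is the absolute relative level |e_n^s − u*|,
with u* the pooled mean over *all* samples — usable for a new sample for
which no cohort assignment exists.

**Differential expression covariance (DECG).** For a gene pair (m, n) the
per-sample co-expression level is the centred product
c_s = (e_m^s − u*_m)(e_n^s − u*_n), again centred at pooled means so a
single new sample can be measured. Control and case c_s distributions are
compared with a Wilcoxon rank-sum test (products of Gaussians are
normal-product distributed, hence again a rank test). A correlation flip
between cohorts changes the c_s distribution without changing either
marginal, which is exactly the signal mean- and variance-based tests miss.

**Signs.** Each significant gene/pair carries a regulation-trend sign:
+1 for an up-regulated DEG (u′ > u), +1 for a DEVG whose case mean
absolute deviation exceeds the control one, +1 for a pair whose mean
co-expression level rises from control to case. The DEVG sign convention
is our interpretation: up/down regulation is undefined for an equal-mean
gene, so we sign by the direction of the spread change, which makes the
module score larger in the cohort with larger spread. Exact ties resolve
to +1 with a logged warning.

**The bi-coloured differential network.** Starting from a background
interaction network (e.g. protein–protein interactions), two edge classes
are kept: *differential* edges whose pair test is significant
(p_dc ≤ α), and *non-differential* edges whose both endpoints are
classified DEG or DEVG. Their union is the differential network; nodes
are coloured by gene class. Genes that enter only through a significant
edge without being DEG/DEVG themselves are tagged `DECG_only`; they are
retained in output tables but excluded from the DEG-, DEVG- and
DD-(bipartite) subnet statistics, since the subnets are defined by node
colour. Threshold comparisons are inclusive (≤ α). An edge qualifying for
both classes is typed differential — the covariance signal is the
informative one; the union is unchanged.

**Module decomposition (MCL).** The network is partitioned by Markov
clustering: alternate expansion (squaring the column-stochastic flow
matrix) and inflation (entrywise power with column renormalisation), with
self-loops of weight 1, pruning of entries below 1e−5, and convergence
when the largest entry change falls below 1e−6 (at most 100 iterations).
Inflation defaults to 1.8, the common empirical choice for biological
networks; expansion 2 and the other constants follow the canonical MCL
description. Nodes are ordered lexicographically so attractor tie-breaks
are deterministic; overlapping attractor supports resolve to the
lowest-id cluster, making the output a partition. Disconnected components
can never merge (powers of a block-diagonal matrix stay block-diagonal).
MCL runs on the full graph, not only its largest component. Singleton
modules are kept but skipped by module scoring (configurable).

**The additive DEVC score.** For module (V, E) and sample s:

    mDEG(V,E,s)  = Σ_{n∈V∩DEG}  sign(n) · e_n^s
    mDEVG(V,E,s) = Σ_{n∈V∩DEVG} sign(n) · |e_n^s − u*_n|
    mDECG(V,E,s) = Σ_{(m,n)∈E∩DECG} sign(m,n) · (e_m^s − u*_m)(e_n^s − u*_n)
    DEVC = mDEG + mDEVG + mDECG

The sum is exact (floating-point identity, asserted bit-exact in tests).
Genes or edges in a module that are not classified contribute nothing.
No size normalisation is applied by default: the same module is compared
across samples, not against other modules; 1/k and 1/√k weightings exist
behind a flag for cross-module use. Pooled means u* are frozen at fit
time, so new samples are scored against the reference-cohort means.

**Evaluation.** Feature strategies (raw levels of top-N DEGs, absolute
relative levels of top-N DEVGs, their concatenation, or module-score
combinations) are compared by clustering samples with K-means (Lloyd's,
random-sample initialisation, k = 2 for a binary phenotype) repeated many
times with seeds derived from one master seed. Accuracy maximises
agreement over *every* map from clusters to phenotypes (maps need not be
injective, so it equals the sum over clusters of each cluster's
best-covering class count divided by the sample total); it is never below
the largest class proportion and equals 1 exactly when the clustering
refines the phenotypes. Features are not standardised by default — the
measurement magnitudes are the designed signal — and the reported spread
is the population (÷N) standard deviation. A two-sided Welch t-test
between two strategies' accuracy lists is provided as a convenience.

## Statistical engine choices

Raw p-values with α = 0.05 (inclusive) and top-N = 1000 ranking are the
native selection rules; no multiple-testing correction is applied, and α
and N are exposed as parameters. The Welch (unequal-variance) t-test is
the default mean test. The Wilcoxon rank-sum test uses the tie-corrected
normal approximation with continuity correction, switching to exact
enumeration when both cohorts have ≤ 10 samples and no ties. Degenerate
inputs (a gene constant across all samples, or identical deviation sets)
return p = 1 with a log message. Hypergeometric enrichment uses the
survival function of `scipy.stats.hypergeom`; the default tail is the
strictly-greater convention P(X > k), with P(X ≥ k) behind a flag.

## Centrality conventions

The "degree" column of the centrality report is the mean normalised
degree centrality, identical to graph density 2E/(n(n−1)). Closeness uses
the component-scaled (Wasserman–Faust) variant so disconnected graphs are
handled without infinities; betweenness is normalised by (n−1)(n−2)/2.
Graph entropy is the Shannon entropy (bits) of the degree-weighted node
distribution p_v = deg(v)/Σdeg — one of several entropies in use; the
choice is pluggable. Against the published prostate-cancer network sizes,
density reproduces three of the four printed degree values at 5 decimals;
the DEG-subnet value computes to 0.00401 where 0.00400 was printed, a
one-ulp rounding discrepancy we document rather than adjust for.

## The synthetic generator

`SyntheticSpec` plants each signal class explicitly: DEG genes (case mean
shifted by δ·σ), DEVG genes (equal means, case variance scaled), DECG
pairs (bivariate normal, equal means, correlation ρ_control → ρ_case),
heterogeneous genes (a fraction of case samples shifted up by δ·σ, the
rest down — near-zero mean difference but case variance
σ²(1 + δ²(1 − (2f−1)²)) at up-fraction f), and null genes. Defaults:
50 + 50 samples, 100 genes per planted class, 600 null genes, δ = 2,
variance ratio 4, ρ = +0.8/−0.8, f = 0.5, σ = 1. Baseline means are
uniform(5, 10) to mimic a log-intensity microarray scale (arbitrary but
realistic). The background network holds every DECG pair plus 200 random
padding edges among non-DECG genes. Everything is driven by one seed and
reproduces byte-identically.

What the generator does *not* emulate: probe-level noise, batch effects,
correlated null genes, non-Gaussian heavy tails (a mild log-normal option
exists behind a flag), and realistic interaction-network topology
(padding edges are uniform, not scale-free). Passing recovery tests
therefore demonstrate the statistical machinery under its stated
assumptions, not performance on microarray data.

## Problem sizes used in the self-checks

Type-I error is checked on 2000 null genes/pairs at 20 + 20 samples;
power and recovery at the default 50 + 50 conditions with 20 generator
replicates; clustering orderings with 200 K-means restarts per strategy.
These sizes give Monte-Carlo error comfortably inside the asserted bands
while keeping the default suite quick.

## Known limitations and observed behaviour

* Under the default planted effect sizes the node-based module scores
  (mDEG, mDEVG) already cluster samples essentially perfectly; adding the
  heavier-tailed centred-product term can then only tie or slightly lower
  the mean K-means accuracy (the full DEVC score stays above the
  covariance-only score but below the saturated single node scores).
  The advantage of combining all three signals appears when single
  signals are weak, which is the regime real cohort data occupies.
* The rank-sum variance test at variance ratio 4 and 50 + 50 samples has
  closed-form power ≈ 0.94 at α = 0.05, so a few planted DEVGs are missed
  in any one dataset; ranking-based selection (top-k within the class)
  absorbs most of this.
* The DEVG class is not monotone in α: raising α admits more variance
  hits but also reclassifies borderline genes as DEG through the equal-
  means condition. Only the differential-edge set is monotone in α.
* Gene identifiers are opaque case-sensitive strings; any probe-to-gene
  collapsing, normalisation or symbol mapping must happen upstream.
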