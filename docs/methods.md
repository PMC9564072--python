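# Methods

`oncotraj` re-implements, as a tested pipeline, a dynamic-heterogeneity
analysis of tumour transcriptomes: branching pseudo-time inference over
cancer-cell clusters, branch-driving gene tests, signature-based deconvolution
of a bulk cohort onto those clusters, a patient-level pseudo-time score with
survival stratification, and network-hub-based drug screening.  This note
records the models, the parameter choices that matter, and what the synthetic
world does and does not establish.

## The synthetic world (`oncotraj.sim`)

Cells sit uniformly on a Y-shaped topology: a trunk from pseudo-time 0 to the
branch point (default at 40% of a 20-unit span) and two arms, Path I and
Path II.  The 20-unit span was chosen so that patient scores land in the
0–20 range typical of published pseudo-time scores; only the scale of S
depends on it.  Counts are negative binomial (`var = m + dispersion * m^2`,
Poisson at `dispersion = 0`) with a log-scale mean assembled from:

* a per-gene baseline, Normal(-1, 0.7) on the natural-log scale;
* **cluster markers** (default 20 genes per cluster, amplitude 2.0): smooth
  Gaussian bumps centred on the cluster's segment of the topology, with SD
  0.75 segment lengths.  Bumps rather than steps matter: with step markers
  every pair of clusters is equally distant in expression space and no
  ordering information survives, whereas real developmental programs make
  adjacent clusters more similar than distant ones.  The bump width trades
  cluster discreteness against trajectory continuity; the cluster-recovery
  test uses a sharper world (width 0.35) where discrete structure genuinely
  exists;
* **branch genes** (default 50, amplitude 2.0): linear-in-time effects with
  opposite signs on the two arms (up in one path, down in the other), zero
  before the branch.  The average between-branch log difference over an arm
  is the stated amplitude;
* **gradient genes** (default 150, swing 1.5): linear programs shared by both
  lineages.  They carry the within-segment ordering signal and are exact
  nulls for the branch test.

Library sizes are log-normal with the configured CV.  Stage labels I–IV are
quartiles of a *progression* coordinate in which Path II advances 1.5x faster
past the branch, so Path II terminates in stage IV earlier than Path I; this
realises the analysed narrative (one path deteriorates directly) and makes
the Path I/II identity recoverable — a perfectly symmetric Y would leave the
arm labels exchangeable.  Within each lineage, stages remain monotone in
pseudo-time.

Bulk samples are `M @ w + Normal(0, sd)` on the log scale, where `M` holds
cluster mean log-normalized profiles and `w` is Dirichlet; survival times are
exponential with log-hazard `beta * (S - mean S)` around a 1000-day baseline
median, censored uniformly on `[0, tau]` with `tau` solved numerically for
the target censoring fraction.  The drug reference responds linearly to
centred log expression; the planted blocking drug loads negatively on
Path II-up branch genes with a negative intercept, the planted
cluster-specific drug on the terminal Path II cluster's markers, and one drug
is exactly null.  The PPI fixture attaches the hub to every node, embeds it
in a 5-clique, and keeps over half of the nodes as hub-only leaves so the hub
survives the top-50% rule in all twelve centralities (including clustering
coefficient, via the inclusive tie rule at the zero boundary).

Not emulated: doublets, ambient RNA, batch effects, spatial structure,
non-linear drug response, realistic PPI topology.  A green recovery test
therefore establishes that the pipeline's statistics behave as designed under
their own model assumptions, not that they are robust to artefacts absent
from this world.

## Single-cell pipeline

QC removes patients with fewer than `min_cells` (default 20) cells or whose
cells' **log** total counts fail Shapiro–Wilk at alpha 0.01.  The log scale is
deliberate: totals are log-normal-ish in healthy data, so a raw-scale test
flags benign skew while the log-scale test isolates genuinely aberrant
(low-cell) patients.  Normalization is total-count scaling to 1e4 followed by
log1p.  Highly variable genes are ranked by the variance of
Poisson-standardized, clipped counts — deterministic, no trend fit.  Scaling
is a per-gene z-score clipped at ±10.  PCA (default 20 components) fixes each
component's sign so its largest-magnitude loading is positive.  Clustering is
Leiden on a kNN graph (k=20, resolution 0.8, seeded); K is not forced.

## Trajectory

The principal graph is a minimum spanning tree over k-means micro-cluster
centroids (default 50) in PC space.  The root is the **leaf** vertex most
enriched for the earliest observed stage: trajectory origins are endpoints,
and rooting at an interior vertex leaves earlier cells dangling behind the
root as a spurious arm.  Cells project to the nearest tree edge (exact ties
go to the earlier edge); pseudo-time is arc length from the root.

The branch vertex is the earliest degree->=3 vertex whose two largest
downstream subtrees each hold >=15% of the cells **and** whose shallower arm
reaches at least 30% of the deeper arm's extent.  Both guards exist because a
noisy MST grows side-spurs and fat dead-ends that subtend cells without
progressing in pseudo-time; a genuine developmental split carries a
substantial share of the population down each path.  If no vertex passes the
guards, the earliest degree->=3 vertex is used; if none exists the trajectory
is linear and every cell is labelled PRE with a warning.  Path II is the arm
whose terminal half (by arc length) has the later mean stage, ties to the
longer arm; extra arms beyond two merge into the geometrically nearest kept
arm with a warning.

## Branch-dependent expression

The test duplicates pre-branch cells into both branches (the cited branch
expression analysis design), fits a full model `expression ~ ns(t, df) x
branch` against a reduced `expression ~ ns(t, df)`, and refers
`2 * (llf_full - llf_red)` to chi-square with df+1 degrees of freedom.  The
natural cubic basis (df 3, interior knots at pseudo-time quantiles) is the
classic closed form; it is hand-rolled because no installed package provides
a 3-df natural basis.  The default Gaussian family runs vectorized across
genes on log-normalized values; a negative-binomial GLM family (moment
alpha, per-gene loop) is available for counts.  Duplicating shared cells
makes the test slightly conservative under the null (measured type-I ~0.003
at alpha 0.01), which is the safe direction for the very strict q<1e-8
screen.  Significant genes are clustered (Ward, Euclidean) on their
row-standardized fitted curves laid out Path I-reversed/branch-point/Path II.
Enrichment is a hypergeometric upper tail over any user GMT with BH
`p_adjust` and a Storey-type `q` (single-lambda 0.5 pi0 estimate).

## Communication

For ordered cluster pair (a, b) and a ligand-receptor pair, the score is the
mean of the ligand's average expression in a and the receptor's average in b;
the null permutes cluster labels (default 2000 iterations), with the add-one
p-value convention.  Significant means p < 0.05 and score > 0.  Counts
aggregate both directions by default (configurable).

## Cohort scoring

Signatures take genes passing a one-vs-rest Wilcoxon rank-sum screen
(stage III defaults p<0.01, stage IV p<1e-4, both log2FC>1.5 of linear-scale
means).  Deconvolution is NNLS by default (deterministic, exactly recovers
noiseless mixtures); linear nu-SVR (nu in {0.25, 0.5, 0.75}, best by RMSE,
negatives zeroed) mirrors the cited support-vector method.  Weights are
renormalized to the simplex; each sample gets a reconstruction Pearson r and
a permutation p against gene-shuffled refits, with the p<0.05 / r>0.3
retention rule.  S = sum_i P_i T_i.  The log-rank statistic (hypergeometric
variance, pooled ties) is implemented in-package because the maximally
selected cutpoint scans every distinct score as a threshold (both groups
>=10% of subjects); lifelines is the independent cross-check and backs the KM
curves.  The cutpoint p is reported raw and is selection-biased — the test
suite demonstrates the bias under a null hazard rather than hiding it.

## Drug discovery

Markers need AUROC > 0.8, one-sided rank-sum p < 0.01 and cluster mean above
the overall mean.  Hub mining runs the twelve cytoHubba-style centralities on
the induced PPI subnetwork and intersects the top-50% of each measure
(boundary ties included; isolated nodes are excluded from ranking since a
zero boundary would otherwise admit every isolate).  Conventions fixed where
the definitions are silent: MCC counts maximal cliques of size >= 2; DMNC
uses epsilon 1.7 on the maximum neighbourhood component, size ties resolved
toward the denser component then smaller labels; EPC keeps each edge with
probability 0.5 (seeded Monte-Carlo, default 1000 replicates) and averages
the number of other reachable vertices; BottleNeck trees are BFS trees with
sorted neighbour order and threshold |tree|/4; eccentricity enters as its
reciprocal; closeness is harmonic.  Exhaustive shortest-path measures error
above a configurable node limit (default 1000).  The branch-trend filter
keeps genes with Spearman rho >= 0.2 (p < 0.05) against pseudo-time in
Path II and <= -0.2 in Path I — a stand-in for a manual inspection step.
Sensitivity prediction is ridge regression of reference drug response on
standardized shared-gene expression (leave-one-out GCV over 10^-3..10^3),
scored per cell and averaged per cluster and per path (unweighted over a
path's clusters; a cluster belongs to the path of its majority branch
label).  The blocking screen requires overall mean logFC < 0 and Path II
mean < Path I mean; the cluster-specific screen requires overall < 0 and
targeted-cluster mean below the non-targeted mean, both applied literally.

## Numerical choices and degenerate inputs

Permutation p-values use the add-one convention (never 0).  `dirichlet_alpha
= inf` means exactly equal mixture weights.  Zero-total cells normalize to
zero vectors; constant genes scale to 0; rank-deficient signatures warn but
return proportions; constant scores make cutpoint selection an error; a
trajectory without a degree->=3 vertex is linear (all PRE, warning).  Seeds:
every stochastic step (simulation, k-means, Leiden, permutations, EPC) takes
an explicit seed, and the generators derive independent streams from
`(seed, stream-id)` so outputs are byte-identical for identical configs.

## Known limitations

Micro-cluster MSTs cannot represent cycles or multiple independent branch
points; the branch-vertex guards assume each true path carries >=15% of
cells; the arm identity rule needs stage labels with some asymmetry between
the paths; the negative-binomial branch-test family is slow (per-gene GLM);
nu-SVR deconvolution is heuristic next to NNLS and only NNLS has exact
recovery guarantees; the end-to-end prognosis test re-estimates proportions
per cohort but reuses the generator's cluster pseudo-times (clustering and
trajectory re-estimation are covered by their own recovery criteria).
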