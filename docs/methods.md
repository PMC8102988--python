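# Methods

This note documents the models, conventions and design choices behind
`fluvimyco`, in the order the pipeline runs them.

## Inputs, transforms and conventions

The canonical inputs are an OTU count table (samples × OTUs,
nonnegative integers, positive row totals), a rooted newick phylogeny
with nonnegative branch lengths whose tips cover the OTUs (supersets
are pruned automatically), and an environmental table carrying the
along-channel coordinate in km. Counts are Hellinger-transformed
(√ of relative abundance) where a Euclidean geometry is needed;
environmental variables are z-scored with the n−1 denominator.
Missing environmental cells are an error unless column-median
imputation is requested explicitly, and every imputed cell is logged —
silent gap-filling in field data is a reproducibility hazard.

Estimator conventions, pinned once and used everywhere:

* **Chao1** uses the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)),
  which is defined when doubletons are absent and matches common
  tooling defaults.
* **Shannon** is reported in nats.
* **Faith's PD** is root-inclusive: the stem connecting a community's
  subtree to the tree root counts. A single-tip community on
  `((A:1,B:1):1,C:2)` therefore has PD 2, not 1.
* **Rarefaction** is analytic, E[S_d] = Σ_i (1 − C(N−N_i, d)/C(N, d)),
  evaluated with log-gamma for stability; no extrapolation beyond the
  observed depth is offered.
* **Water types** follow the PSU convention fresh < 0.5,
  brackish 0.5–30, marine > 30; the boundary values themselves are
  assigned to brackish because the strict inequalities of the field
  definition leave them undefined.
* **FDR** is Benjamini–Hochberg wherever an adjusted p is reported.

## Ordination and permutation tests

GUniFrac is computed on raw relative abundances (the formula is defined
on proportions); α defaults to 0.5, the canonical compromise between
presence/absence and abundance weighting, with a flag to run it on
squared-Hellinger proportions instead. PCoA reports all eigenvalues,
negative ones included, and normalizes explained proportions over the
positive part; a Cailliez correction is available behind a flag but off
by default — reporting is the least surprising behaviour when the
input geometry is non-Euclidean.

PERMANOVA uses the classical decomposition of squared dissimilarities
(within-group pair sums divided by group size), pseudo-F =
(SS_b/(k−1))/(SS_w/(n−k)), and free whole-row label permutation with
the +1 continuity convention, so p ≥ 1/(n_perm+1) always. Degenerate
inputs (all points identical) return F = 0 rather than NaN. The
pairwise variant tests every unordered group pair on its sub-matrix and
BH-adjusts across pairs.

The environment fit reports, per variable: Pearson r against each of
the first two axes, an R² from the OLS fit on both axes, and the
unit-normalized direction cosines of that fit (the "scores"); a
variable is flagged on an axis when adjusted p < 0.005, R² > 0.5 and
|score| > 0.7 all hold.

Environmental clustering couples k-means (k = 2..10, 50 restarts,
seeded) to a similarity-profile test. The retained partition maximizes
ANOSIM R — a stated surrogate for the proprietary criterion of the
PRIMER software family — and SIMPROF's π statistic (summed absolute
departure of the ordered dissimilarities from their column-permutation
null mean) decides at α = 0.05 whether any structure is real.

## Spatial eigenfunctions and variation partitioning

Geographic distance is the 1-D along-channel distance, not straight
line, and the transect is not looped. dbMEM truncates this distance at
the largest nearest-neighbour gap, sets farther pairs to four times the
threshold (the classical construction), takes principal coordinates,
and keeps positive-eigenvalue eigenvectors; each is annotated with
Moran's I under within-threshold adjacency weights, and eigenvectors
with negative Moran's I are excluded from the candidate set because the
analysis models positive spatial autocorrelation only.

dbRDA regresses the positive-eigenvalue principal-coordinate space on
the predictors; significance uses permutation of response rows, and
adjusted R² uses the Ezekiel formula. Forward selection is greedy on
the partial pseudo-F with a double stopping rule: stop when the best
candidate's permutation p exceeds α, or when the running adjusted R²
would exceed that of the full-candidate model (α ≥ 1 disables the
ceiling, turning the procedure into a ranking). The scalogram submodel
split assigns selected eigenvectors to broad vs small scale at the
largest drop in Moran's I — a stated surrogate for the visual
assignment practitioners make on a scalogram — with a logged midpoint
fallback on exact ties. Variation partitioning is the standard
two-block adjusted-R² arithmetic; a+b+c+d = 1 holds exactly and single
fractions may be negative.

## The five-process null models

βMNTD is abundance-weighted by default (the framework's canonical
choice; an unweighted flag exists). The βNTI null permutes OTU labels
across **all** tips of the tree, n_null = 999 times by default; pairs
whose null SD collapses below 1e-12 (e.g. on a star tree, where every
shuffle is equivalent) are flagged degenerate and carry βNTI = 0 rather
than NaN, so they fall through to the RC stage instead of poisoning
downstream summaries.

The RC_bray null preserves each sample's observed richness and total
abundance: taxa enter by weighted sampling without replacement with
probability proportional to occupancy, receive one guaranteed
individual, and the remainder is filled multinomially by regional
relative abundance. RC = 2·[(#{null < obs} + ½#{null = obs})/n_null −
½]; ties count half. Null draws are generated once per sample and
paired rep-wise across samples — the same null distribution as
re-simulating per pair, at linear instead of quadratic cost.

Classification applies the literature thresholds verbatim (selection
first at |βNTI| > 2, then dispersal at |RC| > 0.95, else undominated).
Group summaries report the percentage of within-group pairs per
process; the Tukey HSD comparison of "assembly processes between
groups" is computed on per-sample prevalences (the fraction of a
sample's within-group pairs carrying a process) — a stated surrogate,
since the unit of that test is not fixed by the framework.

## The synthetic community generator

The generator emulates the target study design: 24 stations on a
217.8 km transect, salinity rising 0→31 PSU along a normalized logistic
salt-intrusion curve (flat-fresh upstream, saturating seaward — and,
unlike a linear ramp, giving every PSU water type at least two
stations), covariates with fixed loadings on the salinity axis
(depth deepens downstream, temperature cools, nutrients and chlorophyll
decay, NO2 tracks NH4), 200 OTUs on a Yule phylogeny, and J = 2000
individuals per site — sizes chosen to keep 999-replicate nulls stable
on one desk CPU.

Yule trees come from a seeded birth–death simulation (death rate 0);
because the simulator stops at the n-th birth, every leaf edge is
extended by one shared Exp(nλ) hold time so all branch lengths are
strictly positive and the tree stays ultrametric. Niche optima evolve
by Brownian motion; for the scenario presets the trait evolves on an
early-burst rescaling of the tree (branch lengths × exp(−4·relative
depth)) and is mapped affinely onto the salinity range. The rescaling
concentrates trait variance near the root, i.e. strong niche
conservatism: deep clades differ while close relatives are
near-equivalent. This matters because the nearest-taxon null models
*require* strong phylogenetic signal — under plain Brownian motion on a
Yule tree, trait convergence between distant clades dilutes the
clustering signal at the nearest-taxon scale, and selection scenarios
become statistically invisible at desk sizes. Regional abundances are
i.i.d. lognormal (σ = 1.5), hence random with respect to both phylogeny
and traits.

Assembly is a lottery: recruitment weight ∝
exp(−(optimum − salinity)²·selection_strength) times the immigration
source, with migration m mixing in the regional pool, multinomial draws
of size J supplying sampling drift, and optional Wright–Fisher
generations accumulating true drift. The immigration source is the
regional mean abundance except under dispersal limitation, where each
OTU's pressure decays as exp(−d/λ) from a random home station — this
cleanly separates homogenizing dispersal from limitation. Homogenizing
selection additionally uses a competitive-equivalence lottery: tips are
clustered into equivalence groups by average-linkage patristic distance
(threshold 0.5), every group's niche is filled at every site with a
share set by its selection weight and summed regional abundance, but
the member occupying it locally is a uniform draw (a Chesson-style
lottery among ecological equivalents). Turnover then happens only among
closest relatives, which is precisely the signature βNTI < −2 measures;
without it, communities under a uniform filter are either nearly
identical (degenerate nulls) or differ by phylogenetically random taxa.

Preset parameters (selection strength, migration, generations, kernel
scale) were calibrated once against the classifier's decision
boundaries — the presets exist to land clearly inside their intended
region — and then frozen:

| preset | selection | m | generations | extra |
|---|---|---|---|---|
| variable_selection | 0.05 | 0.02 | 1 | full gradient |
| homogenizing_selection | 0.1 | 0.0 | 1 | uniform 15 PSU env, equivalence lottery |
| dispersal_limitation | 0 | 0.0 | 1 | home-station kernel, λ = 12 km |
| homogenizing_dispersal | 0 | 0.9 | 1 | shared pool |
| drift | 0 | 0.1 | 20 | Wright–Fisher resampling |

## What the generator does and does not emulate

It reproduces the statistical structure the inference stages consume:
gradient-driven niche turnover, phylogenetically conserved traits,
fixed-depth multinomial sampling, and assembly under each named
process. It does not emulate sequencing (read errors, chimeras, primer
bias, unequal library sizes), temporal dynamics, tidal mixing, or
taxonomic annotation; passing tests therefore demonstrate that the
statistics recover known generative structure at realistic sizes, not
that any particular field system behaves this way.

## Numerical choices and limitations

Every permutation test is seeded and deterministic; the pipeline
derives per-stage seeds as sha256(seed, stage) mod 2³¹ so adding a
stage never perturbs another. TSV outputs are written with a fixed
float format, making reruns byte-identical. Symmetry is enforced at
1e-12, eigenvector orthogonality checked at 1e-8, and oracle
equivalences asserted at 1e-10.

Known limitations: βNTI's homogenizing-selection signal is weak at 200
taxa unless within-niche turnover is concentrated among close relatives
(see above) — real datasets with thousands of OTUs are less affected;
the SIMPROF k-selection and scalogram split are surrogates for
proprietary or visual procedures and are labelled as such in outputs;
RC_bray assumes the regional pool is the column sum of the supplied
table, which understates the pool when many taxa are unobserved.
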