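# Methods

This note documents the models, numerical choices and limitations behind
`metacomm`.  It is written for users deciding whether the package's
procedures and defaults fit their data; nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The census model

The unit of analysis is the species group (SG): a cluster of single-copy
marker proteins (rpS3) at ≥ 99% global identity.  Clustering is greedy and
length-sorted: sequences are processed in descending length (ties broken
lexicographically by id, so the procedure is fully deterministic), each
sequence is compared against **every** existing centroid, and it joins the
best-matching centroid if that identity reaches the threshold, else founds a
new cluster.  Identity is matches / alignment columns of a global
(Needleman–Wunsch) alignment computed with edlib.  This mirrors greedy
centroid clustering with exhaustive candidate evaluation
(`maxaccepts/maxrejects = 0`); it is order-dependent by construction, which
is why the ordering and tie rules are fixed.

Marker hits enter the census only above an HMM bit-score of 40 (strictly
above — the cutoff itself is excluded) and at ≥ 200 residues.  An SG counts
as present in a sample when ≥ 2 reads map to its representative (longest)
contig; the read-level ≥ 99%-identity mapping filter is a mapper's job and
is upstream of this package, which consumes already-filtered counts.
Coverage is normalized to sequencing depth as
`coverage / reads-in-sample × 10⁸`; the library size is an explicit input
(whether it is raw or quality-trimmed read counts is the caller's
convention to fix).

Richness uses incidence frequency counts across samples: Chao2 with the
classic q₁²/(2q₂) correction (bias-corrected form when q₂ = 0) and iChao2's
triple/quadruple improvement term with q₄ → 1 when q₄ = 0.  These corner
conventions follow the estimator's source implementation; they matter only
for sparse incidence spectra.  The species-accumulation curve draws, for
each subset size, 100 random sample subsets without replacement and fits
the three-parameter Lomolino sigmoid S(x) = S_max / (1 + b^ln(x₅₀/x)) by
multi-start nonlinear least squares (5 data-driven starts, tolerances
1e-8); the fit reports the asymptote, the curve slope at the observed
sample count and the extrapolation to twice the sampling effort.  A
non-converging fit is flagged and the raw curve still returned.

## Ordination and variable importance

Abundance profiles are Hellinger-standardized (square root of relative
abundance), after removing SGs with a coefficient of variation of
normalized coverage > 3 or raw coverage ≥ 0.25× in fewer than 5 samples.
Zero-mean rows fail the filter (their CV is undefined).

Weighted UniFrac is computed by a single postorder pass that accumulates,
per branch, the proportion of each sample's total abundance descending that
branch; the distance is Σ_b ℓ_b·|P_A(b) − P_B(b)|, normalized by the
abundance-weighted root-to-leaf depth sum so distances lie in [0, 1].  The
implementation operates on scikit-bio trees (midpoint-rooted
deterministically if the input newick is unrooted) but does its own float
arithmetic: established UniFrac entry points floor abundances to integer
counts, which silently zeroes Hellinger-scale tables.  Whether UniFrac
should consume the Hellinger-standardized or merely library-normalized
table is genuinely ambiguous in common protocols; both are supported
(`use_hellinger_for_unifrac`), with Hellinger the default.

NMDS minimizes Kruskal stress-1 with isotonic regression (scikit-learn's
non-metric MDS) over independent random restarts — 20 by default, a
desk-scale compromise (reference protocols use hundreds); the restart loop
is explicit so the returned solution provably has the minimum stress among
restarts, and the configuration is centered and rotated to principal axes.
All-equal distance matrices are flagged degenerate rather than embedded.

MRPP uses group-size weights (w_i = n_i): δ is the weighted mean
within-group pairwise distance, A = 1 − δ/E[δ] with the expectation over
label permutations, and the p-value uses the (1 + #{δ_perm ≤ δ_obs}) /
(1 + N) Monte-Carlo convention to avoid reporting zero.  A is scale-free;
p resolution is limited by the permutation count (10,000 by default).

## The differential-abundance engine

Counts are modeled per feature as NB(μ_ij, α) with log link,
μ_ij = s_j·exp(x_jᵀβ), where s_j are median-of-ratios size factors
(geometric-mean-1 normalized; a pseudo-reference fallback handles sparse
tables with no all-positive feature).  Dispersion is estimated per feature
by Cox–Reid adjusted profile likelihood — the GLM profile log-likelihood
minus ½·logdet(XᵀWX), maximized over log α in [10⁻⁸, 50] — which removes
the downward bias of plain ML when the mean model spends ~10 of 60 degrees
of freedom; the Poisson limit applies at the floor.  Both nested models are
then fit at the shared dispersion (statsmodels IRLS, 100 iterations,
tolerance 1e-8) and 2·Δloglik refers to χ² with df = Δparameters.
Treatment effects use the Wald statistic of a contrast between the
treatment and control levels of the combined treatment–depth factor.

Deliberate simplifications relative to shrinkage-based engines: no
dispersion trend or empirical-Bayes shrinkage, no outlier (Cook's distance)
handling, no independent filtering.  Count tables are accepted unfiltered;
all-zero or non-converging features carry p = NA and are excluded from the
BH correction (which is the standard step-up procedure, monotone and
NA-aware).  Correctness is therefore asserted by simulation calibration
(null type-I rate, planted-effect power), not numerical identity with any
named implementation.

Both depth models include the replicate (plot-pair) term; using the raw
plot factor instead would be collinear with replicate + treatment.  Depth
direction is called by OLS of log(normalized + 1) on numeric stratum
midpoints (15/25/35 cm) among features passing the LRT gate; pseudocount
and coding are package choices.  Depth could equally enter the NB models
numerically; the factor coding tests any depth-dependent pattern at
df = 2.

**Known limitation — pseudoreplication of the treatment contrast.**
Rainfall treatment is assigned to whole plots (three per arm).  Any
plot-level variance component that differs between arms cannot be separated
from the treatment effect by a fixed-effects GLM on samples, so treatment
p-values are calibrated only with respect to sample-level noise.  The
engine's null calibration is therefore assessed on simulations without
plot-level random effects; with them, treatment tests are anticonservative
— a property of the design, shared by any fixed-effects analysis of it, not
of the engine.

## Enrichment cascade

Per condition, every genome is labeled Increase / Decrease / Neither, and
each category (phylum or function) is reduced to a carrier/non-carrier
boolean per genome (multi-copy counts collapse to presence).  Categories
absent from either responder group are removed.  Stage one is an exact
Fisher test on the 2 × 3 table — two-sided by the probability-mass
criterion (sum of all tables at most as probable, 1e-7 relative tolerance),
computed by enumerating the two free cells under fixed margins; totals are
capped (default 5,000) to bound the enumeration.  Stage two, on categories
at BH FDR ≤ 0.1, is a permutation test of T = |c_inc/n_inc − c_dec/n_dec|:
each of 10,000 draws resamples the two group-sized sets from **all**
genomes without replacement, so the null reflects the category's overall
carrier frequency; p is the fraction of permuted T **strictly** exceeding
the observed (no +1 correction — kept as specified; a zero-variance
category returns p = 1 by guard).  The two sets are drawn disjointly by
default (a label permutation); an independent-draws mode is available since
the drawing convention is not fixed by the procedure's usual description.
Permutation FDR ≤ 0.05 is significant, and the enriched side is the group
with the larger carrier fraction.

Diversity contrasts follow the same gate structure with Kruskal–Wallis
(tie-corrected) across the three groups and an exact two-sided rank-sum
test between responder groups (exact null when untied and n < 50, normal
approximation otherwise).  Co-occurrence uses Spearman correlation with
BH masking over the upper triangle; zero-variance vectors are masked, not
errored.  Proteomics summaries drop functions detected in fewer than five
samples, rank within samples (rank 1 = highest summed spectral count,
average ties), average ranks over samples where detected, and test
category over-representation with the upper-tail hypergeometric.

## The synthetic-data generator

The generator emulates the sampling campaign: 60 samples over six plots in
three replicate pairs (one plot per pair under extended rainfall), three
depth strata and five dates, with per-depth counts 24/16/20 so the two
treatment contrasts see 24 and 20 samples.  The date assignment is a fixed
deterministic schedule covering every plot × depth cell; dates are only
partially crossed, as in any staged field campaign.

SG counts are drawn NB(μ, α) with Var = μ + αμ² (gamma–Poisson mixture;
α = 0.05 by default, constant per SG).  Expected counts are compositional:
heavy-tailed lognormal baseline weights are multiplied by
2^(±depth_log2fc·stratum), 2^(±treat_log2fc·treated) and per-plot lognormal
effects (SD 0.25 log2), renormalized per sample, and scaled by a library
size drawn uniformly from 0.5–2 × 10⁶.  Planted responders split evenly
between increasing and decreasing so the renormalization stays near unity;
with large responsive fractions the compositional constraint visibly
shrinks realized fold changes below the planted value — a real property of
relative-abundance data that the tests account for by checking the
generative fold change at small responsive fractions.  Coverage derives
from counts via a fixed 200-bp read length and per-SG contig lengths drawn
uniformly from 2–500 kb.  The tree is a random Kingman coalescent over SGs
(exponential waiting times), giving an ultrametric topology — only relative
branch lengths matter to the UniFrac tests.

Genome tables place 793 genomes by default with Increase/Decrease fractions
mirroring 391/179 of 793; functions and CAZy families are
Bernoulli-presence × (1 + Poisson) counts with planted odds multipliers per
group, completeness ~ 100·Beta(7, 2) and contamination ~ 100·Beta(1, 30)
(so a realistic minority of bins fails QC), plus lower-quality duplicate
bins per SG to exercise dereplication.  Marker FASTA fixtures use uniform
amino-acid substitutions at random positions; identity is measured on
ungapped equal-length pairs, so indel behavior of the aligner is not
exercised by the generator (the clustering tests cover it separately).

What the generator does **not** emulate: spatial autocorrelation beyond the
per-plot effect, dispersion trends over the mean, taxonomic covariance
between phylogeny and function, zero-inflation, and any raw-read-level
artifacts (chimeras, mapping bias).  Passing tests therefore demonstrate
the correctness and calibration of the statistical machinery under the
stated generative model, not robustness to those real-data complications.

## Problem sizes and determinism

Default test and acceptance runs use desk-scale sizes chosen as the
package's own standard configuration: 150–500 SGs, 300–400 genomes, 10–20
NMDS restarts, 5,000–10,000 permutations.  All randomness flows from named
per-stage seeds (spawned from one master seed via `PipelineConfig.from_seed`),
and identical configuration reproduces byte-identical outputs; the run
manifest records seeds, input hashes and per-stage row counts so a run can
be audited after the fact.
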