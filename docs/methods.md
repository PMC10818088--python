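# Methods

## Data model and conventions

A methylome is the content of one CGmap file: one row per sequenced
cytosine with scaffold, strand base (C/G), 1-based position, sequence
context (CG/CHG/CHH), dinucleotide, methylation level, methylated count,
and total count. Sites are keyed by (scaffold, position, context) exactly
as reported — symmetric CpG pairs are *not* merged onto one strand, because
no merging procedure is defined for the input dialect and merging would
silently halve the site count. Coordinates are 1-based inclusive everywhere
a user sees them; only the annotation interval trees store 0-based
half-open intervals internally.

Coverage filtering retains sites with total reads >= 10 (inclusive, the
conventional reading of "minimum of 10x"). Uniting intersects site sets
across samples, so the association stage never sees missing cells. Each
tissue x phenotype analysis unites only its own samples: intersecting
across fewer samples retains more sites per analysis.

Bisulfite conversion efficiency is one minus the mean per-site methylation
frequency over the unmethylated spike-in (lambda) chromosome. The default
mean is unweighted across sites; a read-weighted (pooled-count) variant is
available via `weighted=True`. Replicate pairs are resolved by keeping the
member with the higher conversion efficiency; exact ties keep the
lexicographically first sample ID and are logged.

## The per-CpG binomial mixed model

For one site, methylated counts `y_j` out of `r_j` reads follow
`Binomial(r_j, pi_j)` with

    logit(pi_j) = mu + gamma * age_j + beta * x_j + g_j + e_j,
    g ~ N(0, sigma_g^2 K),  e_j ~ N(0, sigma_e^2 I).

`K` is the additive relationship matrix `A` from the pedigree (tabular
method; founders `a_ii = 1`, offspring `a_jj = 1 + a_sd/2`, off-diagonals by
parent averages), expanded to sample level by duplicating rows for repeated
individuals. `A` is used directly rather than the kinship matrix `A/2`: the
scale is absorbed by `sigma_g^2`, and `A` keeps the diagonal interpretable
as `1 + F`. Users can supply any positive semi-definite matrix instead.

Predictors are standardized (mean 0, sd 1 over the analysis samples) before
fitting so that effect sizes are comparable across phenotypes with very
different units (kits per litter, millions of sperm per mL, a binary
firmness score coded Firm = 1 / Not_Firm = 0); the centring and scale are
recorded on the results object. Age enters in years, centred.

### Fitting: PQL with REML variance components

The model is fitted by penalized quasi-likelihood: iterate the working
response `z = eta + (y - r*pi) / (r*pi*(1-pi))` with weights
`w = r*pi*(1-pi)` (`pi` clipped to `[1e-6, 1 - 1e-6]` to stabilise weights
near monomorphic sites), solve the weighted linear mixed model with
covariance `V = sigma_g^2 K + sigma_e^2 I + diag(1/w)`, update the variance
components by restricted maximum likelihood, and stop when the fixed
effects move by less than 1e-5 (cap 50 iterations; sites hitting the cap
are retained and flagged `non-converged`, since dropping them would shift
the percentile thresholds downstream). The REML surface is searched on
`log(sigma_g^2), log(sigma_e^2)` within `[1e-8, 10]` — a coarse 5 x 5
log-grid followed by bounded L-BFGS-B refinement, which is the same bounded
log-scale search a golden-section scheme would perform but converges in
fewer evaluations. With both components pinned to zero the procedure
reduces exactly to IRLS for the plain binomial GLM (verified against
statsmodels to 1e-4 in the tests).

PQL was chosen over MCMC because it is deterministic and fast enough to fit
hundreds of thousands of sites on a desktop, and downstream selection is
rank/percentile-based, which is insensitive to PQL's mild shrinkage of
large effects. A Gauss–Hermite quadrature maximum-likelihood oracle in the
test suite bounds the PQL-vs-ML discrepancy (|delta beta| < 0.2 on n = 6
family toys).

### Small-sample calibration

The naive GLS covariance `(X' V^-1 X)^-1` treats the REML variance
components as known. At n ~ 20 their estimation noise is substantial (a
quarter of null sites estimate `sigma_g^2` at the lower bound), and Wald
tests built on the naive covariance are anticonservative (empirical type-I
~ 0.08 at alpha 0.05). The fixed-effect covariance therefore carries the
Kenward–Roger first-order adjustment

    Phi_A = Phi + 2 Phi [ sum_ij W_ij (Q_ij - P_i Phi P_j) ] Phi

with `G_1 = K`, `G_2 = I`, `W` the inverse REML information of the variance
components (the second-derivative term vanishes because `V` is linear in
the components). p-values remain two-sided Wald `beta/se` against a
standard normal. Null simulations at n = 20, 20x depth give empirical
type-I of ~0.05 and QQ slope within [0.9, 1.1]. When both components are
pinned by the caller, no adjustment is applied (there is no component
uncertainty), preserving the exact GLM limit.

Monomorphic sites (all counts 0 or all saturated) and constant predictors
are skipped with an explicit reason rather than fitted. The genomic
inflation factor is the median observed chi-square over its theoretical
null median; QQ diagnostics report a through-origin slope on the -log10
scale with an inflation/deflation call.

## DMS, DMclusters, overlaps

Significant DMS satisfy both criteria jointly: `beta` at or beyond the 1st
or 99th percentile of the analysis's beta distribution, and `p` at or below
its 1st percentile. Quantiles use linear interpolation between order
statistics (numpy's default), computed per analysis over non-skipped sites
only; ties at a threshold are included. "Lowest 1st percentile" is
implemented as a quantile threshold; a strict rank cutoff (top 1% of sites
by p) is available via `rank_cutoff=True`.

DMclusters are maximal runs of DMS on one scaffold with consecutive
inter-cytosine distance strictly less than 40 bp (a gap of exactly 40
splits), found by a single linear scan; clusters with >= 3 members feed the
network stage. Distances are simple coordinate differences,
strand-agnostic. Venn overlaps between 2–3 analyses enumerate every
partition region; region counts sum to the union size by construction.

## Annotation

The promoter is the 2,000 bp window strictly upstream of each transcript's
TSS on its strand, clipped at the scaffold start; a symmetric +/- 2 kb
window is available behind `symmetric_promoter=True` because the
upstream-only convention, while standard, is a genuine modelling choice.
Labels are mutually exclusive with precedence promoter > exon > intron >
intergenic, so a site in one gene's promoter that also lies in a
neighbour's intron is called promoter. Transcripts of one gene share the
gene ID, which unions their extents implicitly. A cluster contributes every
gene whose promoter/exon/intron overlaps *any* member site (clusters are
not required to fall wholly within one feature); clusters touching no gene
are excluded from network input and counted.

## Enrichment and networks

Gene-set enrichment is the one-sided upper-tail hypergeometric test with
fold enrichment `(k/n)/(K/N)`; the default universe is the union of all
collection genes, and the universe is always explicit per run rather than
inferred, because enrichment backgrounds legitimately differ between
annotation sources. Benjamini–Hochberg step-up adjustment flags terms at
FDR <= 0.05. Gene IDs are matched as exact strings (an alias map can be
supplied); no live database queries are performed — gene sets arrive as GMT
files and interactions as TSV edge lists with confidences in [0, 1]. Edges
below 0.7 confidence are dropped (>= keeps); the reported interactor set is
the seed genes plus their direct neighbours, with seeds absent from the
filtered graph kept as isolated nodes.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
raw sequencing: per-site baseline logits are Normal with sd 1.5 around a
mean adjusted (logistic-normal approximation) so the realised CG
methylation mean tracks `baseline_mf_cg`; tissue shifts, a standardized
phenotype effect at causal sites, a centred age effect, a kinship-correlated
per-site random effect (`sigma_g^2 A`), and independent logit noise
(`sigma_e^2`) combine on the logit scale; depth is truncated Poisson
(>= 1); conversion failure is a per-read Bernoulli mis-read of unmethylated
cytosines at rate `1 - conversion_efficiency`, which on the all-unmethylated
lambda chromosome yields apparent methylation of exactly that rate.
Phenotypes mirror the fielded design: zero-inflated litter sizes on (0, 5],
log-normal sperm counts, Bernoulli firmness, ages 2–6 years. Site positions
mix short within-fragment gaps with long between-fragment jumps so that
cluster calling is exercised.

Defaults are the study conditions: depth 20x (observed mean coverage is in
the low 20s), CG baseline 0.5 versus 0.003 outside CG, conversion
efficiency 0.994, three tissues with logit shifts (Blood 0, Testes -0.3,
Sperm +0.5, sperm being hypermethylated relative to somatic tissue), 5%
causal sites at +1.0 standardized-logit effect. No dispersion magnitudes
are reported for the real data, so `sigma_g^2 = 0.3` and `sigma_e^2 = 0.5`
are documented free choices giving visible but not overwhelming
over-dispersion. `beta_causal` is applied to the *standardized* predictor,
i.e. on the same scale the association scan reports, so recovery
experiments compare like with like.

Every CG site draws from its own random stream keyed by (seed, scaffold,
site index), so subsetting sites leaves all other sites' data — and the
site position sequence — bit-identical. Identical config and seed give
byte-identical CGmap output.

What the generator does *not* emulate: read-level error, alignment
artefacts, SNP–methylation confounding, cell-type heterogeneity within
tissues, and CpG-density-dependent fragment selection beyond the gap
mixture. Passing tests therefore demonstrate correctness of the estimator
and the discrete algorithms under the assumed model, not robustness to
those real-data pathologies.

## Pipeline and problem sizes

The pipeline config carries all thresholds as data with the study values as
defaults (coverage 10x, beta percentiles 1/99, p percentile 1, gap < 40 bp,
cluster minimum 3, promoter 2 kb, edge confidence 0.7, FDR 0.05), echoes
them into the run manifest together with seed and version, validates
tissue/predictor compatibility (sperm count only for sperm, firmness only
for testes) before any stage runs, and logs per-stage site counts in/out.
Given a seed, two runs produce byte-identical outputs.

Simulation studies in the tests and the acceptance script run at desk
scale, chosen to keep the whole suite in minutes while leaving enough sites
for stable rates: ~500 united sites x 20 samples for null calibration,
~200 causal sites x 50 samples at 30x for effect recovery, and a 22-sample
three-tissue design (~150 sites per analysis) for the end-to-end runs. At
these scales the joint 1% x 1% outlier rule selects very few sites per
analysis — the rule is designed for genome-scale tables, and the oracle
tests cover its correctness independently of scale.

## Known limitations

- PQL shrinks large effects (~5% at |beta| = 1 in the recovery study);
  rank-based downstream selection is insensitive, but absolute effect sizes
  at extreme sites are mildly conservative.
- The Kenward-Roger adjustment corrects the covariance but keeps the normal
  reference, so extremely small analyses (n = 5) remain imperfectly
  calibrated; QQ diagnostics are reported per analysis and no genomic
  control is applied.
- BH adjustment is reported per enrichment run; no cross-run correction is
  attempted. Note the adjusted values are not idempotent under
  re-adjustment (a property of the step-up construction), only the ranking
  is stable.
- Replicate-lane merging is out of scope: each CGmap file is filtered as
  one sample.
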