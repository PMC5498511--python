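# Methods

`panelsim` studies a question at the heart of marker-assisted and genomic
selection: how much of a quantitative trait's predictive signal survives
when the marker panel is not the causal loci themselves but markers in
linkage disequilibrium (LD) with them.  It does so by simulation on an
inbred diversity panel — the setting of a selfing crop such as soybean
genotyped on a fixed SNP array — comparing seven marker panels that span
the spectrum from ideal functional markers to genome-wide background SNPs.

## The simulated population

Real diversity panels are unavailable in a self-contained package, so the
genotypes come from a founder-mosaic generator.  Each chromosome carries a
small pool of founder haplotypes (default K = 6) whose allele frequencies
are drawn from a U-shaped Beta(0.4, 0.4) spectrum truncated at the MAF
threshold.  An individual's haplotype is a hidden-Markov mosaic over this
pool: walking locus by locus, the active founder template is exchanged
with probability `switch_rate` per step.  Population structure enters by
making a fraction (`structure_strength`, default 0.5) of founders private
to one of three subpopulations.  Inbred individuals double a single
haplotype, so dosages are {0, 2}; an outbred mode sums two independent
mosaics.  Loci failing the MAF filter ("frequency less than" the
threshold is removed; the boundary value is retained) are discarded at
generation, so a returned panel always satisfies its own filter.

Two statistics anchor the calibration of the defaults:

* **Effective segments.** `estimate_effective_segments` returns
  Me = 1/Var(off-diagonal of the centered-and-scaled genomic relationship
  matrix), the classical proxy for the number of independently segregating
  segments.  Under strong structure this statistic understates the
  prediction-effective segment number (structure inflates relationship
  variance without helping within-block prediction), so calibration also
  checked the genome-wide GBLUP accuracy directly.
* **Best-proxy LD.** For a random locus, the r2 of its best, 10th-best and
  20th-best genome-wide partner (about 0.90 / 0.57 / 0.43 under the
  defaults at 20,000 loci).

With K = 6 founders and ~50 mosaic blocks per genome
(`switch_rate = 50 / n_loci`), an 800 x 20,000 panel gives a genome-wide
ridge-prediction accuracy of ~0.63 for a 400-individual training set at
h2 = 0.5 — the regime of a several-hundred-segment diversity panel — while
every locus retains many high-r2 partners, the redundancy characteristic
of a dense fixed array.  Both properties are needed jointly: the
all-markers panel must be noticeably worse than the causal panel, yet
barely distinguishable from the same panel with the causal loci deleted.
That combination only exists at array-like density; thinned panels
(a few thousand loci) lose the redundancy first, which is why the
ordering checks in the test suite run at full density.

What the generator does **not** emulate: centimorgan-scale recombination
maps, allele-frequency ascertainment of array design, rare-allele load,
linked selection, or pedigree relatedness beyond the founder-sharing
structure.  Conclusions from passing tests are about the LD-architecture
mechanism, not about any particular crop's numbers.

## Trait model

`n_qtl` loci are drawn uniformly without replacement; each carries an
additive allele-substitution effect, standard normal by default (a
signed-Gamma(0.4, 1.66) alternative provides a heavy-tailed architecture).
True genetic values are g = Zq u with Zq the column-centered QTL dosages.
Residual variance is set from the *realized* var(g) so that
h2 = var(g)/(var(g) + sigma_e^2) holds exactly in-sample, making the
accuracy metric reproducible replicate by replicate; h2 = 1 yields
noise-free phenotypes.

## Marker panels

LD is the squared Pearson correlation of dosage vectors (composite r2;
identical to haplotype r2 for inbred lines).  For q QTL: mp1 = the QTL;
mp2 = QTL plus each QTL's highest-LD marker (HLD); mp3 = all loci;
mp4 = the HLD markers only (QTL excluded from candidacy); mp5 = all loci
minus QTL; mp6 = two random picks per QTL from its 20 highest-r2 loci;
mp7 = mp6 plus one random non-QTL marker per QTL.  Panels are sets
(duplicated HLD winners collapse; realized sizes are reported).  Ties in
r2 resolve to the lowest locus index; candidate searches are genome-wide;
LD is computed on the full panel before the train/validation split (a
training-only option exists).  The top-20 pool size reads the panel
definition as 20 loci, not 20 distinct r2 values.

## Whole-genome regression

All models fit y = 1 mu + Z u + e on the column-centered training dosages.

* **RR-BLUP / GBLUP.**  u ~ N(0, I sigma_u^2).  REML concentrates the
  restricted likelihood in the variance ratio lambda = sigma_e^2/sigma_u^2
  after rotating intercept contrasts (Helmert basis) onto the eigenbasis
  of Z Z'; one bounded 1-D optimization in log lambda, then
  u = Z'(K + lambda I)^-1 (y - mu).  This is algebraically identical to
  kernel GBLUP, which the tests verify to 1e-6.
* **Bayes-C.**  Spike-and-slab: each effect is 0 with probability pi or
  N(0, sigma_b^2); single-site Gibbs with the effect integrated out of the
  inclusion odds; common slab variance with a scaled-inverse-chi-square
  prior.
* **Bayes-B.**  As Bayes-C but with a locus-specific slab variance
  (point-mass + scaled-t prior).  The common scale of those variances
  carries a Gamma prior and is itself sampled conjugately — without this
  adaptivity the fixed heuristic scale over-penalizes dense architectures
  (hundreds of causal loci), visibly depressing accuracy.

Priors follow the standard genomic-prediction heuristic: `prior_r2`
(default 0.5) of the phenotypic variance is attributed to markers and
spread over the summed column variance of the panel; scales are set so the
prior mode matches that partition; df = 5.  The mixture probability pi is
*estimated* (Beta(1,1) update, initial value 0.5), mirroring the behavior
of mainstream samplers; a fixed-pi mode exists for oracle tests.  With pi
fixed near 1 on a panel whose loci are all causal, the spike-and-slab
over-shrinks and the QTL-only panel loses several accuracy points — the
reason estimation is the default.  Defaults of 5,000 iterations, 1,000
burn-in, thinning 5 are desk-scale-stable for panels up to a few hundred
loci; the genome-wide ordering tests use shorter chains (the posterior
means that drive validation accuracy stabilize within a few hundred
sweeps, which the chain-length sensitivity of the accuracy surface
confirms).  Monomorphic training columns are dropped with a warning and
reported with zero effect.  Predictions are (X_new - training centers) ·
posterior-mean effects; accuracy is the Pearson correlation against true
genetic values (default) or phenotypes (both are recorded).

## Experiment protocol

Each replicate redraws QTL, effects, residuals and a uniform 400/400
train/validation split (a fixed-architecture mode reuses the replicate-0
QTL draw).  Replicate seeds derive from the master seed by a counter
scheme — SeedSequence(master_seed, replicate, stage) — so any replicate
is reproducible in isolation and results are independent of execution
order.  Tables report mean and sample SD over replicates in the
"0.94 (0.01)" style (two decimals, round-half-even).

## Problem sizes used in the shipped checks

The acceptance script runs the full-size protocol: 800 x 20,000 panel,
5 replicates, Bayes-B at 5,000/1,000.  The test suite's reproduction test
uses the same sizes; the ordering test runs 5 replicates at h2 = 0.5 and
3 at h2 = 0.2 with 600-iteration chains for the genome-wide panels —
sizes chosen as the package's own desk-scale defaults; the orderings are
paired within replicate and stable at these settings.

## Known limitations

* The Me statistic conflates structure with segment number; treat it as a
  calibration aid, not an estimator of record.
* Bayes-B/C posterior summaries are posterior means only; no convergence
  diagnostics beyond seed-determinism are shipped.
* The mp6/mp7 definitions involve random draws; their realized panels are
  seed-dependent by design.
* Imputation (`column_mode`, `haplotype_window`) is deliberately simple;
  it is plumbing for real-data input, not a contribution.
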