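# Methods

## Scope and model of the data

The package models the analysis chain of a long-term breeding study of a
socially monogamous bird genotyped at three MHC amplicons: a class-I
amplicon co-amplifying two genes (exon 3, up to four alleles per
individual) and two class-IIβ genes, DAB1 and DAB2 (exon 2, up to two
alleles each). Each breeding attempt (nest) has a clutch size, a number
of fledglings, a laying date, parental ages, and — because clutches may
be swapped between date-matched nests (cross-fostering) — both a genetic
and a social parent pair. The scientific questions are (i) whether the
parents' MHC functional divergence or supertype composition predicts
clutch size or fledging success, and (ii) on fully cross-fostered
clutches, whether such effects travel with the genetic parents
(inheritance or pre-swap care) or the social parents (rearing).

## Allele calling

Input is a per-amplicon table of unique sequences with read depths.
After pre-filtering (expected exon length, minimum within-amplicon
frequency, removal of depth-1 singletons, and a minimum total depth for
callability), two callers run independently:

* **Degree of Change.** Variants are sorted by depth; with cumulative
  depths C_i, the statistic DOC_i = (C_i − C_{i−1}) / (C_{i+1} − C_i)
  (the ratio of successive depth increments d_i/d_{i+1}) is evaluated
  for i up to the per-locus allele cap, and the i maximising it is the
  called allele number. When i equals the number of surviving variants
  the denominator is zero and DOC is +∞: in the absence of any
  artifactual tail everything that survived the pre-filter is called,
  which is exactly the noiseless limit. Depth ties spanning the cut are
  included whole when the cap allows, otherwise broken lexicographically
  with a QC flag. The statistic is isolated behind one function so an
  alternative operationalisation can be swapped.
* **Threshold.** Variants at within-amplicon frequency ≥ T_art are
  called, capped at the allele limit by depth rank.

Called sets are screened for chimeras (a called variant whose prefix
matches one strictly deeper variant and suffix another, at any single
breakpoint) and non-functional sequences (length not a codon multiple,
or a stop codon in the annotated frame). The final call is the agreement
of the two methods, falling back to their intersection (flagged
discordant) and to uncallable when disjoint. Replicate amplifications
give a reproducibility fraction over sample × locus pairs.

Defaults (config-exposed, chosen as ordinary practice for high-coverage
amplicon data since the procedure itself fixes no numbers): minimum
total depth 50, minimum variant frequency 0.01, T_art = 0.05.

## Divergence

Individual MHC diversity is the mean pairwise distance over the
individual's *distinct* alleles (gene-copy multiplicities are ignored
for the co-amplified class-I amplicon, avoiding copy-number bias);
homozygotes score zero. Distances over the full exon: amino-acid
p-distance and Grantham distance with the published weights
(α = 1.833 composition, β = 0.1018 polarity, γ = 0.000399 volume). The
scaling constant ρ is computed so the mean over the 190 unordered
residue pairs is exactly 100 (ρ = 50.79 from the property table; the
classical printed constant is 50.723, and recomputed values match the
published integer matrix within ±1, the L↔S pair rounding to 144 rather
than the printed 145). Sequence-level Grantham distances default to the
per-site mean (`per_site`); a summed `raw` mode exists. The choice only
rescales divergence and cannot change association signs. Pearson
correlation between the two per-individual metrics is reported as QC;
on realistic synthetic pools it is high (≈ 0.8–0.95).

## Supertypes

Alleles are described by the residues at positively selected codon
positions. For real data the site list is an input (produced upstream by
codon-model selection inference); for self-contained synthetic runs a
clearly labelled entropy heuristic (top-m Shannon-entropy columns) can
stand in, and is *not* equivalent to codon-model inference. Each
selected-site residue maps to the five z-scale descriptors of Sandberg
et al. (1998), giving an alleles × (sites × 5) matrix, column-
standardized. k-means (k-means++ with 100 restarts, fixed seed) is run
over a candidate range, and k is chosen by the BIC convention used for
DAPC-style genetic clustering, n·ln(WSS/n) + k·ln(n) minimised, or by
mean silhouette maximised — the class-I locus defaults to BIC and the
class-II loci to silhouette, mirroring common practice. This BIC variant
has a sharp minimum on motif-structured descriptor data (alleles sharing
a binding motif have identical rows) but tends to over-segment diffuse
continuous clouds; the silhouette criterion, and the weak-structure
warning emitted below a configurable silhouette floor, cover that case.
The final partition is refined DAPC-style: PCA retaining ≥ 90% variance,
then re-assignment of each allele to the nearest centroid in linear
discriminant space. Supertype numbering is deterministic (clusters
ordered by their lexicographically smallest allele). Clustering never
drops alleles; only the downstream frequency floor (population frequency
strictly above 0.10, counting carriers over genotyped individuals)
limits which supertypes are tested.

## Mixed models

Both responses are modelled with GLMMs: clutch size as Poisson with log
link, fledging success as binomial with logit link and the clutch as
trials. Random intercepts: mother identity, father identity and year of
breeding ("parents" structure), or the config-selectable alternative of
a couple intercept plus year ("couple"). The fitter maximises the
Laplace approximation to the marginal likelihood: for candidate variance
components, penalized IRLS finds the joint mode in fixed effects and
random effects (step-halving on the penalized objective), and

  ℓ(θ) ≈ log f(y|η̂) − ½ û'D⁻¹û − ½ log|D| − ½ log|Z'ŴZ + D⁻¹|

is maximised over log-SDs by Nelder–Mead. Wald covariances come from the
top-left block of the inverted joint penalized Hessian. With variance
components pinned to zero the fit reproduces the ordinary GLM to 1e-4
(tested), and on crossed-intercept binomial data the estimates match
lme4's `glmer` closely (tested via Rscript); the small remaining
difference is that `glmer` also carries the fixed effects through the
outer Laplace objective, whereas this fitter uses the joint-mode fixed
effects — a simulation study (below) shows no practical bias at the
designs of interest. Parameter counts for information criteria are
fixed effects plus estimated variance components. Non-converged
sub-models are dropped from candidate sets with a log entry.

## Multimodel inference

Continuous predictors are standardized Gelman-style (centered, divided
by 2 SD) so their slopes are comparable with 0/1 indicators; supertype
indicators stay 0/1. The full divergence model holds, per parent pair,
linear and quadratic divergence terms and the mother × father
interaction, plus always-included covariates (both ages, laying date and
its quadratic). All sub-models respecting marginality (interaction ⇒
both mains, quadratic ⇒ linear) are enumerated — 13 models for one
parent pair, 169 for the genetic + social quartet — fitted, ranked by
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), and the ΔAICc ≤ 2 set is *fully*
averaged: Akaike weights w_i ∝ exp(−Δ_i/2), a term absent from a model
contributes β = 0, the unconditional SE is the Burnham–Anderson form
Σ w_i √(SE_i² + (β_i − β̄)²), and 95% CIs are z-based (±1.96). A term is
significant when its CI excludes zero. Sub-model fits warm-start the
variance-component search at the full model's estimates (they are then
still re-optimised per model). Designs are VIF-checked
(VIF_j = 1/(1−R²_j)); aliased predictors abort the run, and in
cross-fostered mode social divergences identical to the genetic ones
(no real swaps) are dropped with a notice. Fewer than 30 usable records
refuse to fit.

Supertype inference is classical instead: one GLMM per common supertype
with the parents' presence indicators and their interaction (the
genetic + social quartet with both within-pair interactions in
cross-fostered mode), Wald p-values collected over the supertype × term
family within one locus × response × dataset run and adjusted by
Benjamini–Hochberg step-up (the family choice is configurable in
principle; this is the default and only shipped family). Significant
interactions trigger estimated marginal means over the 2×2 presence grid
(covariates at design means, link scale) and all pairwise contrasts with
a single-step multivariate-normal max-|z| ("Tukey-style") adjustment —
appropriate for large-sample GLMMs where a studentized range has no
exact justification. Odds ratios exp(Δ) with delta-method SEs accompany
logit-model contrasts.

## Synthetic data

The generator emulates the statistical structure the estimators assume,
with dimensions defaulting to the motivating system: class-I exon of 270
nt with 8 selected sites and 9 built-in motifs, DAB1 with 15 sites / 14
motifs, DAB2 with 10 sites / 10 motifs; pools of 40/31/22 alleles.
Alleles of a motif share all selected-site residues (variation is
concentrated where selection acts, making supertype structure
learnable); background codons mutate sparsely; all sequences are
in-frame and stop-free with distinct translations. Genotypes are
Hardy–Weinberg draws (four gene copies for the co-amplified class-I
amplicon). Amplicon spectra: negative-binomial total depth (mean 1000,
dispersion 5), Dirichlet allele shares (concentration 25 per gene copy —
moderate amplification imbalance), point-error derivative variants (1–2
substitutions; per-base per-read rate 1e-4) and, with probability 0.05,
one single-breakpoint chimera of two true alleles at low depth; a
configurable fraction of individuals is amplified twice (default in
validation runs 0.1, matching a ~10% replicate rate). Breeding records:
couples are stable (socially monogamous) and re-used across nests when
there are more nests than couples; clutch ~ Poisson on a log mean of
6.23 (clamped at ≥ 1 so the binomial has trials; the clamp shifts the
mean by < 0.02); fledglings ~ binomial with a logit linear predictor
holding the configured divergence slopes (applied to 2-SD-standardized
divergence, the same scale the analysis estimates on), supertype
effects, covariate effects, and year plus per-parent random intercepts.
The cross-fostering plan swaps whole clutches between laying-date-
matched nest pairs ("full"; an odd leftover nest is left unswapped and
reclassified), keeps partial swaps attributed to their own nest, or does
nothing; the genetic-vs-social analysis subset uses full swaps only.

Defaults not fixed by the emulated study were chosen once as ecological
common sense and not revisited: random-intercept SDs 0.3 (year) and 0.3
(individual) on the link scales — the study reports no variance
estimates, so these are declared rather than calibrated — fledging
intercept logit(0.6) ≈ 0.405 (≈ 3.6 fledged of 6.2 eggs), small
covariate effects (±0.05 ages, −0.10 laying date, −0.05 its quadratic),
and the none/partial/full cross-fostering mix 0.34/0.35/0.31.

What the generator does *not* emulate: raw reads and quality scores,
barcode demultiplexing, copy-number variation within the class-I
amplicon, linkage/haplotype structure between loci, assortative mating,
brood reduction dynamics within a season, or pathogen-mediated
selection. Passing tests therefore demonstrate that the estimators
recover what this generative model puts in — not that real data satisfy
the model.

## Validation studies and problem sizes

* Noiseless closure: 200 individuals × 3 loci; zero substitution and
  chimera rates must genotype back exactly (100%).
* Degree-of-Change oracle: all 923 depth profiles on a six-value grid
  with ≤ 6 variants agree with brute-force DOC maximization.
* Parameter recovery: 250 fully cross-fostered nests, genetic-father
  slope −0.46 on the fledging logit, 200 replicates; the full-averaged
  estimate must sit within 3 Monte-Carlo SEs of the truth and its
  unconditional CI cover in 90–98% of replicates. Observed (seed 1):
  mean −0.432, coverage 92%, power 93% — full averaging shrinks weakly
  supported terms toward zero, so a small attenuation (~0.03 here) is
  expected and stays within Monte-Carlo error. The recovery model set is
  the 13-model single-pair enumeration on the genetic parents (the
  injected and recovered term); the 169-model quartet enumeration is
  validated separately for structure at smaller n.
* Type-I: the same design with all effects zero, 200 replicates; every
  averaged term significant in ≤ 7.5% of replicates (observed max
  5.5%), CI coverage of zero 90–98% (observed 94.5%).
* BH control: 100 replicate families of per-supertype tests under a
  global null; families with any discovery ≤ 7.5% (observed 5%).
* `scripts/acceptance.py` reruns these studies at reduced replicate
  counts (60/60/40) to keep a single-CPU run around three minutes,
  alongside the full pipeline quantities; the suite carries the
  full-size versions.

## Known limitations

* The two co-amplified class-I genes are genotyped and analysed jointly;
  no per-gene phasing is attempted.
* Positive-selection inference is out of scope; the entropy screen is a
  synthetic-data convenience only.
* The Laplace fit uses joint-mode fixed effects (see above); for very
  sparse binomial data (trials near 1) a fully profiled Laplace or
  quadrature fit would be preferable.
* The EMM contrast adjustment is the large-sample single-step
  multivariate-normal bound, not an exact small-sample Tukey procedure.
* Reproducing a specific study's printed coefficients requires that
  study's deposited breeding records, allele sequences and selected-site
  lists as inputs; the package validates itself on synthetic data.
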