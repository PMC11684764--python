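# Methods

This note documents the generative model, the numerical and design choices
behind each module, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Generative model for admixed cohorts

We model a two-way admixed population. Each individual carries a global
admixture proportion π drawn from a configurable law: Beta(a, b) (default
Beta(6.4, 1.6), mean 0.8, SD 0.13, emulating the heterogeneous
African/European admixture seen in African American cohorts), a point mass
(the homogeneous limit, Var(π) = 0), or a two-point mixture. Local
ancestry at variant j is a<sub>ij</sub> ~ Binomial(2, π<sub>i</sub>),
independent across variants by default. A Markov mode is provided for
realism — two independent two-state chains per individual along each
chromosome with stationary probability π<sub>i</sub> and an exponential
switch kernel (default 1 switch/Mb) — but none of the theoretical results
depend on ancestry autocorrelation, only on π and the allele frequencies,
so the independent mode is the default and the one used in tests.

Conditional on local ancestry, each allele copy carries the counted allele
with the ancestry-specific frequency, giving the binomial mixture
g | π ~ Binomial(2, p₀ + Δπ), Δ = p₁ − p₀. The implied moments

* E[g] = 2q̄, q̄ = p₀ + Δμ<sub>π</sub>
* Cov(g, π) = 2ΔV<sub>π</sub>
* Var(g) = 2q̄(1 − q̄) + 2Δ²V<sub>π</sub>
* Cov(g₁, g₂) = 4Δ₁Δ₂V<sub>π</sub> (unlinked variants)

were re-derived and are checked against empirical moments of 10⁵–10⁶-draw
simulations in the test suite (4·SE tolerance).

Panels are generated under a Balding–Nichols divergence model: an
ancestral frequency is drawn uniformly on (0.1, 0.9) and the two population
frequencies are Beta-distributed around it with divergence parameter F
(default 0.15, continental-scale differentiation; the demonstration
fixtures use 0.25 to emphasise ancestry-informative markers, as
genotyping-array content does).

### Latent genomic features

Real cohorts show principal components whose loadings concentrate in a few
genomic regions (inversions, HLA, other high-LD segments) instead of being
spread genome-wide. We emulate this with latent per-individual Bernoulli
indicators ("carrier" status, default frequency 0.5) that shift the
in-region allele frequencies of both ancestral populations by +strength
for carriers and −strength for non-carriers (default 0.4, clipped to
[0.01, 0.99] to keep variants polymorphic). The symmetric shift preserves
the marginal allele frequency at carrier frequency 0.5. A single feature
may span regions on several chromosomes.

A structural point discovered while building the demonstration fixture: if
one latent indicator drives regions on two chromosomes, those regions are
*directly* correlated, so a causal variant in one region produces a
genuine association in the other under any ancestry-only adjustment — and
adjusting for the PC that captures the feature *removes* it. That is
correct adjustment, not collider bias. The multi-peak/collider phenomenon
requires several distinct region-factors whose eigenvalues are close
enough to mix in the eigenbasis while the factors themselves are only
weakly correlated. The canonical fixture (`planted_feature_study`)
therefore plants five single-region factors on chr1–chr5 coupled through a
weak shared probit factor (latent correlation 0.15). This yields, robustly
across seeds:

* PC1–π correlation ≈ 0.997 under all four pre-processing regimes;
* a single PC (PC2) correlated ≈ 0.5 with variants in all five regions —
  the multi-region, multi-chromosome loading signature;
* adjusting for the top 4 unpruned PCs captures only part of the
  five-dimensional factor span, so a trait driven by a variant inside one
  captured region (β₁ = 2) shows 1–4 spurious chromosomes per replicate,
  while adjusting for PC1 alone, for estimated admixture, or for PCs
  computed after LD pruning shows none;
* LD pruning (r² < 0.1, 0.5 Mb windows) leaves one variant per region, at
  which point the residual factor spike falls below the random-matrix
  detection edge at the fixture's aspect ratio (m/n ≈ 2.7) and PCs 2–4
  show no loading peaks.

## Pre-processing and PCA

* MAF filter: sample minor allele frequency ≥ 0.01 by default.
* Region exclusion: 1-based inclusive intervals, boundaries count as
  inside. A built-in list of 18 literature-flagged high-LD/long-range-LD
  regions (build 38) is provided, plus readers for BED (0-based half-open,
  converted internally) and the published 1-based TSV dialect.
* LD pruning: greedy left-to-right scan per chromosome; a candidate is
  kept iff its dosage r² with every already-kept variant within the
  physical window is below the threshold (defaults r² < 0.1, 0.5 Mb). The
  leftmost variant of a conflicting pair wins — a deterministic tie rule.
  r² is computed on dosages (composite LD); the data model is unphased.
  Zero-variance columns never conflict. The guarantee (no kept pair within
  the window at or above the threshold) is asserted by brute force in the
  tests.
* PCA: exact SVD of the standardized genotype matrix (binomial scaling by
  sample allele frequency, the convention of the standard genotype-PCA
  software family). Exact rather than randomized SVD is used because desk-
  scale matrices (≈1500 × 4000) decompose in seconds. Sign convention:
  each loading column's largest-magnitude entry is positive. Monomorphic
  columns among the kept set are an error (filter first).
* Diagnostics: the PC–genotype Pearson correlation is computed for **all**
  panel variants, not only those used in the SVD, so pruned/excluded
  regions remain visible. Peak detection reports maximal runs of
  consecutive variants with |corr| above a threshold, merged within a
  window (defaults 0.25 and 1 Mb; at the fixture's sample size, feature
  variants reach |corr| ≈ 0.8 with their PC while background correlations
  are O(n<sup>−1/2</sup>) ≈ 0.03, so the threshold separates them by an
  order of magnitude).

## Association testing

Per-variant OLS of the trait on (1, g<sub>j</sub>, covariates), fitted via
the Frisch–Waugh–Lovell decomposition: the trait and all genotype columns
are residualized on the covariates once, after which each variant is a
simple regression. This is algebraically identical to the per-variant
joint fit (verified against statsmodels to 1e-10) and vectorizes across
the genome. Wald statistics use model-based standard errors and the
large-sample normal reference; at the sample sizes of interest (n ≥ 2000)
the difference from a t reference is negligible. Genotypes numerically
collinear with the covariates are flagged and reported as missing.
Spurious associations are counted at the chromosome level (number of
non-causal chromosomes with at least one variant below the significance
threshold; defaults 5×10⁻⁸, with 5×10⁻⁹ as the whole-genome-sequence
preset), because neighbouring variants in LD share association signal.
The genomic inflation factor is λ = median(W²)/0.4549 (the χ²₁ median).

## Effect-size theory and its oracle

Expected large-sample coefficients under each adjustment model are
computed by solving the population normal equations built from the
model-implied first and second moments of (g₁, g₂, π, z, y), where z is
the population-standardized linear combination w₁·s(g₁) + w₂·s(g₂) + noise
(population rather than sample standardization, since the target is the
large-sample limit). This moment-based route is robust to transcription
error and is validated end-to-end by an independent Monte-Carlo oracle
that draws cohorts and fits each regression by OLS; the test suite demands
agreement within 4·SE on every cell of a 12-setting grid at n = 2×10⁵ and
200 replicates. Closed-form identities use a 1e-10 tolerance; stochastic
checks use 4·SE throughout. A zero-variance covariate (π in a homogeneous
population) is dropped from the design rather than inverted.

Two properties of the artificial-z construction deserve emphasis because
they differ from the intuition one might carry over from real PCs:

* The collider bias at the neutral variant does **not** vanish as
  V<sub>π</sub> → 0. With homogeneous ancestry the confounding biases all
  collapse to zero continuously, but z remains a common effect of the two
  genotypes, and conditioning on it still distorts the neutral-variant
  coefficient (with symmetric parameters and noiseless z the expected
  coefficient is exactly −β₁·sd(g₁)/sd(g₂); the degenerate noiseless case
  makes g₁ an exact linear function of (g₂, z)). Both the closed form and
  the oracle agree on this.
* For fixed construction weights, |collider bias| is monotone
  **decreasing** in V<sub>π</sub>: the more of z that is explained by π,
  the less of it survives partialling. The often-stated "bias grows with
  ancestral heterogeneity" refers to the complementary channel — in real
  data the PC–variant correlations themselves grow with V<sub>π</sub> —
  which is held fixed by this construction. The bias is monotone
  (increasing, exactly linear) in β₁ either way.

## Experiment orchestration

`run_experiment` fixes one simulated cohort per configuration (genotypes
play the role of the real data, as in a trait-resimulation design),
computes PCs under the four regimes {none, exclude, prune, both}, then for
each replicate×causal-variant×effect-size cell simulates a trait and runs
each adjustment strategy, recording spurious-chromosome counts, λ, and the
causal-variant estimate. Candidate causal variants are classified by
loading size and allele-frequency differentiation (defaults: |loading| <
0.0008 as "low" for a ≈551k-variant loading vector, rescaled by
√(551025/m) for smaller panels since loading columns are unit-norm; |Δ|
cutoffs 0.6 and 0.005; top-10 |loading| per chromosome per PC as "high").
Everything is deterministic given the single config seed, which expands
into per-stage child seeds via counter-keyed `SeedSequence` spawns
(recorded in the cohort's `seed_record`).

Desk-scale defaults (n = 2000, 6 chromosomes × 300 variants, effect sizes
0–4) keep a full factorial under a few minutes; the published-scale design
(n ≈ 8000, hundreds of thousands of variants, 473 causal variants, effect
sizes up to 8) is expressible through the same config but is not run in
the test suite.

## What the synthetic data does and does not show

The generator reproduces the statistical skeleton the theory needs —
heterogeneous admixture, ancestry-differentiated binomial genotypes,
localized latent structure, single-causal-variant traits — and the
demonstrations built on it (confounding without adjustment, clean
adjustment with π or PC1, collider bias from partially captured feature
spans, λ's blindness to isolated collider hits) are therefore statements
about the model, verified numerically. It does not emulate haplotype-level
LD decay, recombination maps, phasing, more than two ancestral
populations, genotyping error, or relatedness; conclusions about optimal
pruning parameters for a *particular* real dataset cannot be read off
these simulations. Known limitations: the Markov local-ancestry mode is
untested against coalescent expectations beyond its stationary mean and
autocorrelation sign; binary traits and mixed models are out of scope; the
artificial z fixes the PC–genotype correlation by construction, so it
cannot exhibit the V<sub>π</sub>-driven growth of that correlation seen in
real admixed cohorts.
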