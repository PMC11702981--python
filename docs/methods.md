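# Methods

## Model and rationale

The predictor treats p53 functional status as a latent binary state that is
observable only through its transcriptional footprint. Adjacent normal
tissue (NT) anchors the normal-function state; tumors with *TP53*
truncating mutations (TM) anchor the reduced-function state, on the premise
that truncation reliably destroys transactivation activity. Wild-type (WT)
and missense (MM) tumors are mixtures of the two states, and the analysis
assigns each of them a label (pN / pRF) by where its composite expression
scores fall relative to the two anchors.

Two design commitments follow from this framing:

- **Gene sets are cohort-specific.** p53's transcriptional program varies
  by tissue, so the DR/UR sets are re-derived per cohort from the candidate
  list rather than fixed globally.
- **All cross-sample statistics are anchored on training data.** The
  combined Z-score's per-gene mean/sd, GSVA's kernel CDFs, ssGSEA's
  rescaling range, the PC1 axis, the feature standardization and the SVM
  are all fitted on the training partition and applied unchanged to held-out
  or prediction samples. Hold-out estimates therefore measure the full
  pipeline, including gene-set selection, not just the classifier.

## Differential expression engine

Candidate genes are tested NT vs TM with a deliberately compact stack:
median-of-ratios size factors (geometric-mean reference over genes detected
in every sample; library-total fallback with a warning when no such gene
exists), Welch's t-test on log2(normalized count + 1), and
Benjamini–Hochberg adjustment across the tested candidates. Selection
thresholds are adjusted *P* ≤ 0.05 and |fold change| ≥ 2, both inclusive,
with the fold change computed from normalized group means (pseudo-count 1).
This is not a reimplementation of a shrinkage-based negative-binomial DE
tool; it is a two-group location test that the package's own generative
model satisfies. The package validates it by truth recovery on synthetic
cohorts (type-I error ≈ 5% under the null; >99% power for 4-fold effects at
n = 60/group), not by numerical equality with any external tool.

During repeated hold-out validation a permuted-label run can legitimately
produce an empty DR or UR set. `holdout_validate` therefore fills an empty
side with the top-10 genes by raw *P* value of the required sign (with a
warning) so that the validation loop always has features; standalone
`select_gene_sets` keeps the strict erroring contract.

## Composite scores

- **Combined Z-score**: per gene, z = (x − μ)/σ with μ, σ across the
  reference samples (sample sd, ddof = 1); per sample,
  Z<sub>γ</sub> = Σ z<sub>i</sub>/√k. The √k denominator follows the
  convention of the widely used enrichment package that popularized the
  statistic. Zero-variance genes are dropped with a warning.
- **ssGSEA**: within-sample average ranks; traversal from highest to lowest
  rank (ties broken by gene order); in-set increments rank^α normalized over
  the set, out-of-set decrements 1/(p − k); the raw score integrates the
  running difference, and all samples are rescaled by the reference
  (max − min) raw-score range. α defaults to 0.25.
- **GSVA**: per gene, a Gaussian-kernel CDF estimate across reference
  samples with bandwidth sd/4 (an empirical-CDF option exists for exact
  small-fixture oracles); per sample, genes are ranked by that statistic,
  weighted by the symmetric rank statistic |r − p/2| (τ = 1), and the score
  is the sum of the largest positive and largest negative running-sum
  deviations. Genes with zero reference spread degrade to an empirical CDF
  with ties counted ½.
- **PC1**: per-gene standardization with reference statistics, principal
  axis of the standardized training matrix by SVD, projection of all
  samples. The sign is oriented so the NT reference mean exceeds the TM
  reference mean; the sign convention is this package's choice, made so
  that every score decreases with p53 loss except the UR pair.

Both running-sum scorers are verified against independent brute-force
enumerations of the published algorithms on packaged ≤10-gene fixtures to
1e-9.

## Classifier

Linear-kernel SVM on the seven standardized CES features; grid search over
C ∈ {0.01, 0.1, 1, 10, 100} by stratified k-fold accuracy
(k = min(5, smallest class size)). With a linear kernel there is no kernel
width to tune, so the grid covers C only. No class weights by default.
Validation uses stratified 75/25 splits — stratification keeps both classes
in every partition at desk-scale sample sizes — repeated ten times with
per-repeat gene-set re-selection; the production model is fitted once on
all NT ∪ TM samples. Accuracy is (TP + TN)/total; metrics with zero
denominators are reported as NaN with a warning rather than silently
zeroed. AUROC is the rank-sum (Mann–Whitney) estimator with ties counted ½.

The clustering fallback standardizes the CES table, cuts a Ward-linkage
tree at two clusters, and names the cluster whose centroid is relatively
nearer the NT reference centroid pN, the other pRF. It exists for cohorts
(e.g., xenograft panels) without enough NT/TM samples to train on.

## Synthetic data

`generate_cohort` draws negative-binomial counts (dispersion 0.1) around
gene-specific log-normal baselines (median ≈ 300) times log-normal library
sizes (σ = 0.2). A latent per-sample activity bit drives the effect: in
reduced-function samples, activated-class genes are multiplied by
2^(−δ) and repressed-class genes by 2^(+δ), with δ = 1.5 by default. NT
samples are always normal, TM always reduced; WT and MM samples are reduced
with probability 0.9 and 0.99. Candidate-class sizes default to 116
activated and 31 repressed genes against 853 background genes, and the
default group sizes are 60 NT / 100 WT / 50 MM / 60 TM. The first four
activated genes carry the RPS gene symbols so signature scoring has
p53-responsive targets to find. The FPKM/TPM layers are per-sample
normalizations of the *sampled* counts with a constant 1-kb gene length
(hence the two layers coincide); deriving them from the counts rather than
from the noise-free latent means keeps within-group biological and sampling
variability in every layer, which the hold-out and permutation-null
experiments rely on.

What the generator does not emulate: batch effects, copy-number structure,
tumor purity, gene-length variation, correlated background genes, and
read-level artifacts. Passing recovery tests therefore demonstrates the
machinery is correct under the stated generative assumptions, not that the
classifier achieves any particular accuracy on real tumors. The within-group
variance of real cohorts is not characterized here; the defaults were chosen
once to give separability comparable to the intended application regime.

`generate_allele_counts` draws Poisson depths, binomial alt reads at the
site's true MAF, and binomially thinned high-quality alt reads.
`generate_pdx` draws survival ratios from a two-mode normal mixture
(non-responders near 1.0, responders near 2.0, spreads 0.1) and a
pRF/pN label correlated with responder membership at a configurable odds
ratio (default 25 against a 0.2 base rate).

All generators fan a single seed into independent child streams
(`numpy` `SeedSequence.spawn`), so runs are bit-reproducible and the
streams do not interact.

## Genotyping and response rules

Re-genotyping: sites with depth < 10 are excluded; a site is mutant iff
MAF ≥ 0.1 **and** ≥ 5 high-quality supporting reads — both thresholds
inclusive, and the two rules are applied as a conjunction. MAF percentages
are reported rounding half-up (44/98 → 45%). PDX responders are ratio
≥ 1.52 (inclusive); when estimated from data, the cutoff is the deepest
kernel-density minimum (Gaussian KDE, Silverman bandwidth) between the two
highest modes, falling back to 1.52 with a warning for unimodal or
degenerate inputs. Fisher's exact p-values use the probability-ordering
two-sided convention; the reported odds ratio is the sample cross-product
ratio. The Wilcoxon rank-sum comparison uses the exact null for tie-free
combined samples of ≤ 20 and the tie-corrected normal approximation
otherwise.

## Signature scoring

RPS is the negated GSVA score of the packaged 4-gene DNA-repair set
(RIF1, F2R, RAD51, XRCC5) on log2(TPM + 1); the log transform stabilizes
the Gaussian-kernel CDF against TPM's heavy tail and leaves the
empirical-CDF variant unchanged. The RSS panel is scored per polarity
subset; its 51-gene membership belongs to its original publication and is
supplied by the user as a GMT (a gene in both subsets is a load-time
error). An exclusion list lets users re-score after removing genes that
overlap the classifier's feature sets.

## Problem sizes and tolerances

Tests and the acceptance script run at the default study conditions
(1000 genes × 270 samples, ten seeds for recovery statistics; 1000 sites
for genotyping; 35–200 xenograft models). Oracle comparisons use 1e-9;
Monte-Carlo checks use tolerances derived from their sampling variability
(e.g., type-I error 0.05 ± 0.02 at 1000 null genes, permutation-null AUROC
0.5 ± 0.07 over ten repeats). The SVM mirror-symmetry check under label
flipping is asserted at the solver's convergence tolerance (1e-2 on
decision values).

## Known limitations

- The DE engine has no dispersion shrinkage and assumes a two-group design;
  covariates and multi-factor designs are out of scope.
- GSVA scores depend on the gene universe supplied; callers should pass the
  same universe they would score in production.
- The pan-cancer mode is plain concatenation with a cohort tag — no batch
  correction.
- The clustering fallback assumes the two latent states dominate the CES
  covariance; heavily admixed cohorts can violate this.
- BAM ingestion is an optional adapter (pysam) producing allele-count
  tables; the core deliberately operates on plain count tables.
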