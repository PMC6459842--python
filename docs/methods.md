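# Methods

This document describes the statistical model behind each `splicevo`
module, the default parameters and why they were chosen, and the known
limitations. Notation: Ψ (PSI) is the fraction of transcripts including
an alternative exon; AFB/EUB are the two simulated populations; the
five stimulation conditions are NS (non-stimulated), LPS, Pam3CSK4,
R848 and IAV.

## 1. Synthetic cohort generator (`splicevo.simulate`)

The generator produces a cohort that exercises every downstream module
while remaining small enough to analyse in seconds, and records every
planted effect in a truth ledger (`SyntheticCohort.truth`).

**Genotypes.** Each gene carries `n_snps_per_gene` (default 10) biallelic
SNPs. Per-SNP population allele frequencies are either supplied
(`pop_freq_pairs`) or drawn from a Balding–Nichols-style model with
divergence `fst_divergence = 0.1`, a typical human continental value.
Haplotypes are drawn binomially per population (no within-population LD
by default), so LD-based statistics are tested against planted
structure, not background LD. Two planted selection-site kinds exist:

- `fst` sites overwrite the two population frequencies (e.g. 0.95 vs
  0.05) to create a high-divergence outlier;
- `sweep` sites set a derived allele at frequency `derived_freq` and
  copy one founder haplotype onto all carriers over `flank_bp`,
  producing the extended-homozygosity footprint iHS detects. The flank
  is applied on the haplotype matrix after frequency simulation, so
  non-carrier diversity is untouched.

**Expression and splicing.** Each gene has a log-normal baseline FPKM, a
condition response (a random `frac_responsive_genes = 0.4` of genes are
up- or down-regulated on stimulation), one skipped-exon event with a
logit-normal individual Ψ (`psi_individual_sd = 0.25` on the logit
scale), and Poisson junction reads at `read_depth = 50` informative
reads per event (scaled by expression). Planted sQTL effects are given
on the Ψ scale per condition; internally they are applied on the logit
scale using a secant matching so that the Ψ difference between
homozygotes equals exactly 2β (see §8). Erroneous splicing adds
non-annotated junctions at a per-gene rate (default drawn per gene);
per-condition noise multipliers default to
NS 1.0 / LPS 1.25 / Pam3CSK4 1.25 / R848 1.45 / IAV 1.6, and NMD-gene
expression is coupled to sample noise with `nmd_coupling = −0.5`.

**Evolutionary layer.** A dated species tree (Newick + node ages) and a
per-site presence/absence matrix are emitted; site origins are planted
by choosing an origin node and marking all descendant species present,
then applying `alignment_dropout = 0.1` missingness, the regime under
which Dollo dating is tested.

**What is not emulated.** Read mapping, splice-site motifs/sequence,
overlapping genes, more than one event per gene, within-population LD
blocks, relatedness, and library-size variation beyond expression
scaling. These are deliberate: each omission removes a nuisance
parameter that downstream modules do not model either.

## 2. Splice-site catalogue (`splicevo.catalog`)

Junction reads are assigned to genes by coordinate overlap in samples
where the gene is expressed (`fpkm_threshold = 1.0`). Site usage is the
fraction of reads at a shared anchor supporting the site. Activity
classes partition every site exactly once:

- **weak**: mean usage < 0.05 or mean reads/sample < 1;
- **constitutive**: usage > 0.95 and not weak;
- **alternative**: everything else.

A site is **cryptic** iff it is weak AND not annotated AND its GerpRS
conservation is < 2 (the conventional boundary between neutral and
constrained). The class boundaries (5%/95%) separate sites whose minor
form would be invisible at typical depths from genuinely bimodal usage.

## 3. Dating and enrichment (`splicevo.evolution`)

Splice-site age is the age of the most recent common ancestor under
Dollo parsimony (single gain, unlimited losses): the origin is the
MRCA of the species where the site is present, and support is the
fraction of informative (non-missing) leaves consistent with that
origin. An exhaustive brute-force enumeration over all single-origin
hypotheses is used as an independent oracle in the tests. Dating is
information-limited: with heavy missingness on a small or unbalanced
tree, the MRCA of observed carriers can be a descendant of the true
origin; accuracy claims in the tests therefore use a balanced tree
where each internal node has enough descendant leaves to survive 10%
dropout. Age-stratified enrichments use matched resampling (draw
resamples matched on a covariate, compare observed overlap to the null
distribution) with a mid-p value, which is uniform for discrete
statistics.

## 4. Events, PSI and differential splicing (`splicevo.events`)

Ψ = mean(inclusion reads / multiplicity) / (that + exclusion reads /
multiplicity); junctions supporting the same isoform are averaged so an
event with two inclusion junctions is not double-counted. Events with
fewer than `min_informative_reads = 10` are set missing — below that,
the binomial noise on Ψ exceeds 0.15 and dominates any signal.

`filter_events` applies the expression (FPKM ≥ 10), coverage (≥ 30
intron reads), Ψ-range (0.05–0.95), missingness (≤ 5%) and minor-isoform
(FPKM ≥ 0.5) gates familiar from population sQTL pipelines; each gate
removes events on which the downstream tests are either powerless or
driven by a single read.

Differential splicing between each stimulated condition and NS uses the
paired Wilcoxon signed-rank test on per-individual ΔΨ (pairing removes
inter-individual Ψ variance, the dominant noise source); population
contrasts within a condition use Mann–Whitney. All p-values are
corrected jointly by Benjamini–Hochberg, and a call requires both
adjusted p < 0.05 and |ΔΨ| > 0.05 so that significance at large n
cannot promote biologically negligible shifts. Isoform diversity is
Shannon entropy of isoform fractions, which is additive over
independent choices and maximal (ln 2) at Ψ = 0.5.

## 5. Noisy splicing (`splicevo.noise`)

The per-site error fraction at constitutive coding sites is
(non-canonical reads)/(total reads) at the site's anchor; gene noise
rate is the unweighted mean over its constitutive coding sites
(unweighted, so one highly covered site cannot mask errors elsewhere);
sample noise rate pools reads across sites within the sample.
Correlates (mean intron length from expressed transcripts, expression,
transcription-rate proxy) are tested by Spearman correlation, with
partial rank correlations to separate confounded covariates.
NMD coupling is the Spearman ρ between sample noise and the first
principal component of NMD-pathway gene expression; `min_genes = 50`
prevents reporting correlates from samples with too few expressed genes.

## 6. cis-sQTL mapping (`splicevo.sqtl`)

Phenotypes are rank-normalised (Φ⁻¹((rank−0.5)/n)) so that effect sizes
are comparable across events and OLS p-values are calibrated regardless
of the Ψ distribution. The scan is OLS of phenotype on dosage within a
±1 Mb cis window with genotype principal components (computed on
MAF ≥ 0.05, LD-pruned SNPs) as covariates; residual degrees of freedom
are n − k_cov − 2. Tests verify the scan against `statsmodels` OLS
coefficient-by-coefficient.

**Permutation FDR.** Phenotypes are permuted within population (to
preserve stratification), and for a p-value threshold t,
FDR(t) = (mean permuted discoveries)/max(observed discoveries, 1) —
the standard E[V]/max(R,1) convention, so thresholds with zero observed
discoveries contribute FDR 0 rather than ∞. The curve is made monotone
by a running maximum and the largest t with FDR ≤ target is reported
(NaN if none qualifies).

**Condition sharing** uses Wakefield approximate Bayes factors with a
unit-information prior per condition and selects the highest-posterior
configuration of active conditions. The prior carries an Occam penalty
of ½·log(1 + n) per added condition, so exact-configuration recovery is
only reliable when per-condition |z| comfortably exceeds
√(2·penalty) ≈ 2.5–3.5; the acceptance test is therefore designed at
n = 500, β = 0.5 (|z| ≈ 10), a regime where a correct method must
succeed (this is an a-priori power calculation, not tuning).

**Response sQTLs** (G×E) are detected by the dosage×condition
interaction term; the decision table requires basal p above a floor and
interaction p below a ceiling so that a constitutive sQTL in an
expression-responsive gene is not mislabelled.

**Causal model selection** among genotype→splicing→expression
(causal), genotype→expression→splicing (reactive) and independent
effects first applies a partial-correlation gate (if splicing and
expression are conditionally independent given genotype at
`gate_alpha = 0.05`, label independent), then compares AIC of the two
remaining six-parameter Gaussian DAG likelihoods with a margin of 2.
Below `min_n = 50` the labelling is reported as untested: the three
likelihoods are nearly indistinguishable at small n.

## 7. Population genetics (`splicevo.popgen`)

**Mediation.** For an event with peak sQTL dosage g and population
indicator I, OLS of Ψ on (1, g, I) yields β and δ (the direct,
genotype-adjusted population effect); the genetic component is
ζ = 2β(f̂_AFB − f̂_EUB) with f̂ the in-sample allele frequencies. With
this estimator, ζ + δ = ΔΨ holds exactly by OLS orthogonality (to
numerical precision, ≤1e-10 in the tests), and the mediated proportion
τ = ζ/ΔΨ is reported with a bootstrap CI, undefined when |ΔΨ| is below
`dpsi_tol`.

**FST** is Weir–Cockerham (full a/b/c variance components, r = 2) by
default, with Hudson's estimator as an alternative; both are verified
against independent loop-based textbook implementations and agree at
fixation (FST = 1) and return NaN at monomorphic sites.

**iHS.** EHH is computed by prefix-grouping haplotypes outward from the
core; integrated EHH uses trapezoids down to `cutoff = 0.05`;
iHS_raw = log(iHH_ancestral/iHH_derived) is standardised within 2%
derived-allele-frequency bins. Standardisation needs ≥ 2 SNPs per bin;
on sparse panels the standardised score can be NaN while the raw score
is informative, so the acceptance pipeline ranks |iHS_raw| genome-wide
(rank-preserving within a bin) and certifies bin standardisation
separately.

**Outlier enrichment** models the count of top-5% FST SNPs per 100 kb
window as beta-binomial (overdispersion fitted by moments); tail
probabilities use `scipy.stats.betabinom.sf`, verified against exact
summation.

**Set enrichments** (archaic-like or GWAS overlaps) resample
MAF-matched SNP sets (2% MAF bins, without replacement) and report the
fold over the null mean and a mid-p value; with a fixed seed the null
draws and p-value are bit-identical across runs.

## 8. Numerical choices

- **Secant-matched planting**: to make a planted Ψ-scale β exact under
  the logit-normal individual model, the generator uses
  β_logit = (logit(clip(p₀+2β)) − logit(p₀))/2, i.e. the secant of the
  logit curve between homozygote means rather than its tangent.
- **Rank-normal ties/NaN**: ties get average ranks; NaNs are preserved.
- **FDR convention**: V/max(R, 1), see §6.
- **Entropy**: 0·log 0 ≡ 0; identities hold to 1e-12.
- **Beta method-of-moments**: returns `None` when the sample variance
  is ≤ 1e-12 (a float variance of a constant vector is ~1e-33, not 0)
  or outside the feasible region v < m(1−m).
- **Causal trio "independent" model**: genotype affects splicing and
  expression through independent residual channels, giving the
  d-separation fingerprint (splicing ⟂ expression | genotype) the
  selector's gate tests.
- **Seeds**: all stochastic routines take explicit integer seeds
  < 2³¹ and use `numpy.random.default_rng`.

## 9. Limitations

- The generator has no within-population LD, so LD-pruning and
  peak-vs-truth r² logic are exercised only at planted sweep sites.
- One skipped-exon event per gene; no alternative 5'/3' sites, intron
  retention or mutually exclusive exons as distinct event types.
- iHS on small panels: standardised scores are NaN in singleton DAF
  bins by design; use the raw score for ranking there.
- Condition sharing is reliable only at high per-condition z; at
  marginal z it under-selects conditions because of the Occam penalty,
  which is a property of the Wakefield prior, not a bug.
- Causal model selection assumes Gaussian errors and no unmeasured
  confounder of splicing and expression; with confounding, "reactive"
  and "causal" are not identifiable from observational trios.
- Dating accuracy degrades on unbalanced trees with missing leaves;
  support values quantify this but cannot recover information that the
  dropout destroyed.
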