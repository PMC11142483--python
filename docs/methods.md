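# Methods

This note documents the models, estimators, simulator, and the numerical and
design choices behind `mismatchprs`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Mismatch scoring and SNP QC

The IBS mismatch score of a pair at one SNP is `M = |D − R|` over alt-allele
dosages in [0, 2]. Two scoring modes exist:

* **hard_call** (default): each dosage is rounded to the nearest integer when it
  lies within `hard_call_tolerance` (default 0.1) of it, otherwise treated as
  missing. The default suits chip genotypes and well-imputed dosages alike.
* **dosage**: raw dosages are differenced, for sensitivity analyses on imputed
  data.

SNP-level QC excludes a SNP when pooled (donor + recipient) MAF < 0.05, mean
mismatch across pairs < 0.05, missing rate > 0.1, or imputation info < 0.8;
SNPs without an info value are treated as genotyped and never filtered on info.
Each exclusion records its first matching reason in the fixed order
maf → mismatch → missing → info. Two interpretation choices here were genuinely
open and are recorded in the QC output metadata: the mismatch filter is applied
to the *per-SNP mean mismatch across pairs* (a near-constant-zero mismatch
column is an uninformative predictor), and the missingness filter to the
per-SNP sample missing rate. The HLA region is chr6:25,759,242–33,534,827
(GRCh37), bounds inclusive on both ends.

Under Hardy–Weinberg equilibrium at alt frequency *q*, the expected mismatch of
an unrelated pair has the closed form `2·p0·p1 + 2·p1·p2 + 4·p0·p2` with
`p0 = (1−q)², p1 = 2q(1−q), p2 = q²` (enumeration of the nine genotype-pair
outcomes); this is the analytic oracle used throughout the tests. Related pairs
sit strictly below it.

## Kinship

Donor–recipient kinship uses the robust within-family moment estimator
`φ̂ = (N_het,het − 2·N_opp-hom) / (N_het(D) + N_het(R))` over hard-called SNPs
observed in both members. It needs no allele-frequency reference, gives ≈0.5
for identical genotypes, ≈0.25 for parent–offspring and full siblings, ≈0 for
unrelated pairs, and is stable inside families. Its per-pair sampling SD scales
like 1/√m; a warning is emitted below 1,000 informative SNPs, and label-sharp
separation at a 0.1 cutoff needs a few thousand SNPs.

## Cox engine

`fit_cox` maximizes the Cox partial likelihood by Newton iterations with
step-halving, Efron tie correction by default (follow-up is day-resolution, so
ties are the norm; Breslow is available), gradient-norm tolerance 1e-8 and at
most 100 iterations. Rows are pre-sorted by decreasing follow-up time so every
risk set is a prefix and all risk-set sums are cumulative sums; a scan re-uses
one sorted design for every SNP, which is why the engine is implemented here
(about a millisecond per SNP fit) instead of calling a general survival
package. The test suite cross-checks coefficients, standard errors and
log-likelihood against lifelines, and the score test at β = 0 against the
log-rank statistic, to which it is algebraically identical for a binary
covariate without ties.

Degenerate inputs: a constant covariate raises an error naming it; a
coefficient escaping |β| > 20 is treated as separation and the fit is returned
flagged (`converged=False`, missing p-values). At the scan level, a *nuisance*
clinical covariate with monotone likelihood (e.g. a handful of
prior-transplant recipients, none with an event — common in small cohorts)
would poison every per-SNP fit, so `screen_covariates` drops constant or
separated clinical covariates with a logged warning before the scan and the
PRS validation; the covariate list actually used is recorded in the result.

The per-SNP model is time-to-first-AR on
[mismatch, recipient_age, recipient_male, pra_positive, hla_mismatch,
prior_nonkidney_tx], complete-case over covariates with dropped counts logged.
The HLA-mismatch covariate is the numeric 0–6 antigen mismatch count. Wald
tests are reported (a likelihood-ratio helper exists). The genomic inflation
factor is the median per-SNP 1-df chi-square over 0.45494.

## Simulator

The simulator exists to make every downstream stage testable at study scale
without restricted data. It emulates two living-donor cohorts of 784 and 352
pairs, ~20.5%/17.3% AR event rates, and published demographic marginals
(recipient age ~ truncated normal(49.3, 15.6) on [18, 80]; male 66.5%; PRA+
57%; HLA mismatch ~ round(normal(3.2, 1.7)) clipped to 0–6; prior non-kidney
transplant 8%).

**Haplotypes.** Per SNP the alt indicator is `u < freq` for a latent uniform
`u`; within an LD block the latent uniform is copied from the left neighbour
with probability `ld_rho` (default 0.8, blocks of 10 SNPs), fresh across block
boundaries. Marginal frequencies are exact by construction and adjacent-SNP
genotype correlation equals `ld_rho` at equal frequencies (r² = ld_rho²),
decaying geometrically with distance — controllable LD without a coalescent
engine. Panel frequencies are uniform on (0.1, 0.5); SNPs are spaced 10 kb
along 22 autosomes, with the chromosome-6 stretch anchored at 25 Mb so part of
the panel falls inside the HLA region and the HLA-drop path is exercised.

**Relationships.** Pairs are parent–offspring, full siblings, or unrelated.
Parent–offspring recipients receive one of the donor's haplotypes plus a
population haplotype; siblings draw from the same two simulated parents;
transmission segregates independently per LD block (emulating recombination).
Block-wise segregation matters: transmitting single whole-genome haplotypes
would make realized sibling kinship a discrete {0, 0.25, 0.5} lottery, whereas
with ~250+ independently segregating blocks it concentrates near the pedigree
value 0.25, as in real genomes. Per-SNP Mendelian constraints hold exactly
(parent–offspring pairs can never be opposite homozygotes).

The default `relationship_mix` is (0.475, 0.475, 0.05): living-donor cohorts
are dominated by relatives, and at validation scale roughly 2% of pairs fall
below kinship 0.1, so 5% unrelated is the realistic upper end. This default is
load-bearing: relatedness shifts mismatch at *every* SNP simultaneously, so
the unrelated fraction sets the variance of a genome-wide common factor. Its
chance correlation with the outcome moves all null test statistics together —
cryptic-relatedness confounding, the phenomenon λ_GC measures. With a large
unrelated fraction (~30%) single-cohort λ fluctuates far outside [0.9, 1.1]
even under the null; with the mostly-related default, null scans stay
calibrated, matching the well-controlled inflation such studies report.

**Outcomes.** Event times are exponential proportional hazards:
log-hazard = Σ causal β·M + covariate effects (defaults: age 0.01/yr, male
−0.10, PRA+ 0.30, HLA mismatch 0.15/antigen, prior transplant 0.20 — invented,
plausible magnitudes), with administrative censoring (default 1,095 days) and
the baseline hazard auto-calibrated by Brent root-finding so the expected event
fraction hits `event_rate_target`. Times are rounded up to whole days to mimic
day-resolution follow-up, deliberately producing tied event times for the Efron
path.

**What the simulator does not emulate** — and hence what passing tests do not
establish about real data: realistic LD decay and haplotype sharing (no
coalescent, no mutation/gene conversion), population structure and admixture,
genotyping batch effects, imputation-quality gradients (info values are taken
as given), deceased donors, competing risks, and informative censoring.

## PRS

Clumping is greedy: the unassigned SNP with smallest scan p (ties broken by
position then id, for determinism) becomes an index and absorbs unassigned
same-chromosome SNPs within 200 kb at r² ≥ 0.2. LD is the squared Pearson
correlation of recipient dosages in the training cohort (the LD sample and
estimator were open choices). Thresholding at cutoffs {5e-2 … 1e-5} yields
nested sets. The model drops HLA-region SNPs (HLA matching is already a
covariate), takes scan betas as weights, and fixes standardization constants
(mean/SD of the raw score) on the validation cohort by default — so "HR per
SD" is per SD of the validation distribution; a flag switches to
training-cohort constants and the choice is recorded in the model sidecar.
Scoring skips per-pair missing mismatch values (no imputation; counts logged)
and fails below 90% model-SNP coverage. The kinship sensitivity refit removes
pairs on a configurable side of the 0.1 cutoff — default removes
kinship < 0.1, the literal reading of the analysis it mirrors — and both
directions emit a labelled report.

On a desk-scale panel (thousands of SNPs instead of millions) a strict 1e-3
cutoff retains only a handful of SNPs; the acceptance pipeline therefore
validates the 5e-2 model (~200 SNPs, a stable score) and uses the 1e-3 set for
the focused gene-enrichment readout. With mixed-sign causal effects the
validated HR per SD lands around 1.3–1.5 — the realistic operating range for
this design — whereas an all-positive causal architecture lets the PRS absorb
the relatedness factor itself and inflates apparent transfer.

## Heritability

The mismatch relationship matrix standardizes each QC-passing SNP's mismatch
column (zero-variance columns dropped and counted; missing values contribute 0
after centering) and sets K = ZZᵀ/m, rescaled to exact unit diagonal mean.
Haseman–Elston regression regresses `y_j·y_k / var(y)` over pairs j < k on
`K_jk`; the slope is the observed-scale h², reported raw (it may fall outside
[0, 1]; a flag marks when truncation would apply). Fixed clinical covariates
are regressed out of the phenotype first, mirroring the scan's adjustment. The
default SE is the OLS slope SE; a delete-one-pair jackknife SE (robust to the
correlation between cross-products sharing a pair) is available in O(n²). The
p-value is one-sided (positive-variance alternative). A single-component REML
(eigenbasis of K, profiled total variance, bounded scalar optimization over
h² ∈ [0, 1], half-half chi-square boundary LRT) sits behind the same
interface. K = identity fails with an informative message — no off-diagonal
information exists. Binary AR is analyzed on the observed 0/1 scale; no
liability transform is applied (its prevalence inputs are not part of this
design).

## Enrichment

SNPs map to every gene whose interval, extended 20,000 bp on both sides
(boundaries inclusive; distance measured to the nearest interval edge), contains
the SNP position; strand never affects distance, and unmapped SNPs are counted
and reported. Genes are counted uniquely (not per SNP mapping). Per term the
one-sided hypergeometric tail P(X ≥ k) is computed with population = reference
universe (default: all genes in the supplied interval file), successes = term
genes in the universe, draws = study genes; fold enrichment is
(k/n_study)/(K/n_ref); FDR is Benjamini–Hochberg across tested terms. BED input
(0-based half-open) is converted to 1-based inclusive coordinates internally.

## Problem sizes

The test suite and acceptance script run at the study's cohort sizes (784/352
pairs) with panels of 4,000–5,000 SNPs, replicate counts of 25–100 for
power/null/recovery checks, and heritability recovery at 1,000 pairs × 2,000
SNPs; these sizes keep every check on a single CPU in minutes while leaving
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* Cryptic-relatedness confounding is simulated and discussed but not corrected;
  no mixed-model or genomic-control adjustment is applied to the scan.
* The kinship estimator assumes autosomal biallelic hard calls; dosage-mode
  kinship is not offered.
* HE regression's analytic SE ignores cross-product dependence (the jackknife
  option addresses it); REML is single-component only.
* Multi-allelic variants are skipped at VCF read; sex chromosomes are out of
  scope.
* The enrichment universe is whatever interval file the user supplies; no
  curated pathway database ships with the package.
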