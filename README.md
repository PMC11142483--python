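# mismatchprs

Donor–recipient **non-HLA genotype-mismatch** analysis for transplant outcomes:
a genome-wide Cox proportional-hazards scan on identity-by-state (IBS) mismatch
scores, a clumping + thresholding polygenic risk score (PRS) with
independent-cohort validation, mismatch-score heritability, and gene-set
over-representation — plus a paired-cohort simulator so the whole pipeline can be
exercised without access to restricted patient genotypes.

## The problem

Acute rejection (AR) after kidney transplantation is driven in part by genetic
disparity between donor and recipient. Clinical matching focuses on blood group
and the HLA locus, yet rejection occurs even in HLA-identical grafts, implicating
mismatches elsewhere in the genome. This package implements the statistical
machinery to quantify that signal in paired donor–recipient cohorts with
time-to-event outcomes. It is aimed at statistical geneticists and transplant
researchers working with paired genotype data (PLINK or VCF) and survival
phenotypes.

## The model

For donor–recipient pair *i* and SNP *j* with alt-allele dosages
*D<sub>ij</sub>*, *R<sub>ij</sub>* ∈ [0, 2], the IBS mismatch score is

&nbsp;&nbsp;&nbsp;&nbsp;*M<sub>ij</sub>* = |*D<sub>ij</sub>* − *R<sub>ij</sub>*| ∈ [0, 2].

Each SNP is tested in a Cox proportional-hazards model for time to first AR,

&nbsp;&nbsp;&nbsp;&nbsp;λ(t | i) = λ₀(t) · exp(β<sub>j</sub> M<sub>ij</sub> + **γ**ᵀ**x**<sub>i</sub>),

where **x**<sub>i</sub> holds the clinical covariates (recipient age, gender, PRA
status, HLA mismatch count, prior non-kidney transplant). The partial likelihood
is maximized by Newton iterations with Efron tie handling; per-SNP Wald tests
give the scan, summarized by the genomic inflation factor
λ<sub>GC</sub> = median(χ²)/0.455.

Scan SNPs are LD-clumped (greedy by P, r² < 0.2 within 200 kb), thresholded at a
P cutoff, stripped of HLA-region SNPs (chr6:25,759,242–33,534,827, GRCh37; HLA
matching is already a covariate), and combined into the PRS

&nbsp;&nbsp;&nbsp;&nbsp;PRS<sub>i</sub> = Σ<sub>j</sub> β̂<sub>j</sub> M<sub>ij</sub>,

standardized per SD and validated in an independent cohort under the same Cox
model (reported as HR per SD). Heritability of AR on the observed scale is
estimated by Haseman–Elston regression of phenotype cross-products on a
mismatch relationship matrix K = ZZᵀ/m (optionally single-component REML), and
PRS SNPs are mapped to genes within 20 kb and tested for gene-set
over-representation (one-sided hypergeometric, BH-FDR).

## Worked example

```python
import mismatchprs as mp

# two cohorts on one SNP panel: 784 training / 352 validation pairs,
# mostly related (parent-offspring / sibling), 50 causal mismatch SNPs
causal = tuple((j * 80, 0.3 if j % 2 == 0 else -0.3) for j in range(50))
train_cfg = mp.SimConfig(n_pairs=784, n_snps=4000, causal_snps=causal,
                         event_rate_target=0.205, seed=10)
valid_cfg = mp.SimConfig(n_pairs=352, n_snps=4000, causal_snps=causal,
                         event_rate_target=0.173, seed=11)
train, valid = mp.simulate_cohorts(train_cfg, valid_cfg)

mm_train, mm_valid = mp.mismatch_matrix(train), mp.mismatch_matrix(valid)
retained, _ = mp.snp_qc_filter(train, mm_train)          # MAF/mismatch/missing/info QC
scan = mp.genome_scan(train, mm_train, retained)
print(f"lambda_GC = {scan.lambda_gc:.2f}")               # lambda_GC = 1.06

index_snps = mp.clump(scan, train.recipient, list(train.snps["snp_id"]))
selected = mp.threshold_select(index_snps, scan, (5e-2,))[5e-2]
model = mp.build_prs_model(selected, scan, mm_valid, p_threshold=5e-2)
prs = mp.score_pairs(model, mm_valid)
fit = mp.validate_prs(valid, prs)
lo, hi = fit.conf_int()[0]
print(f"HR per SD = {fit.hr[0]:.2f} (95% CI {lo:.2f}-{hi:.2f}), p = {fit.p[0]:.3f}")
# HR per SD = 1.39 (95% CI 1.05-1.85), p = 0.021
```

The scan is calibrated (λ<sub>GC</sub> ≈ 1), and the mismatch PRS built in the
training cohort transfers to the independent validation cohort: each standard
deviation of mismatch burden multiplies the rejection hazard by ~1.4 after
adjusting for the clinical covariates. A kinship-based sensitivity refit
(`mp.sensitivity_refit`, removing pairs with kinship < 0.1) and heritability
(`mp.estimate_heritability`) follow the same pattern; see `docs/methods.md`.

The same pipeline is available from the shell:

```bash
mismatchprs simulate --config sim.yaml --out-prefix demo
mismatchprs qc    --genotypes demo.train.vcf --pairs demo.train.pairs.csv \
                  --pheno demo.train.pheno.csv --out-prefix qc
mismatchprs scan  --genotypes demo.train.vcf --pairs demo.train.pairs.csv \
                  --pheno demo.train.pheno.csv --retained qc.retained.tsv --out scan.tsv
mismatchprs prs   --scan-table scan.tsv --genotypes demo.train.vcf \
                  --pairs demo.train.pairs.csv --pheno demo.train.pheno.csv \
                  --p-cutoff 5e-2 --out-prefix model
mismatchprs validate --model-prefix model --genotypes demo.valid.vcf \
                  --pairs demo.valid.pairs.csv --pheno demo.valid.pheno.csv \
                  --kinship-cutoff 0.1 --out validation.json
```

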