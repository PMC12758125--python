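# ciswas

Summary-statistics proteogenomics for gene prioritization: cis-weight
burden association (PWAS/TWAS), two-sample Mendelian randomization with
a full sensitivity suite, Bayesian colocalization, and two-step-MR
mediation — plus a synthetic-cohort generator with known ground truth so
every stage is verifiable at desk scale.

## The problem

Plasma-protein GWAS integration asks: which genes' *cis-regulated
protein levels* causally influence a disease? The workflow this package
implements answers it in four summary-statistics stages, for analysts
who have GWAS and QTL summary files but no individual-level data:

1. **PWAS/TWAS** — combine GWAS z-scores with a gene's cis prediction
   weights under an LD reference:
   `z_assoc = Σ_k w_k z_k / sqrt(wᵀVw)`,
   after a cis-heritability gate (p < 0.01) and with BH-FDR control
   across the panel.
2. **Two-sample MR** — instruments at p < 5×10⁻⁸, clumped at r² < 0.1
   within 10 000 kb, harmonized (palindromic SNPs with allele
   frequency in [0.42, 0.58] removed); fixed-effect IVW (Wald ratio for
   one instrument) as primary, weighted median, MR-Egger intercept,
   Cochran's Q, MR-PRESSO and leave-one-out as sensitivity analyses;
   ORs with 95% CIs.
3. **Colocalization** — Wakefield approximate Bayes factors per variant,
   five-hypothesis posteriors (priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵),
   shared-causal-variant evidence at PPH4 ≥ 0.75. This is the stage
   that separates a truly causal protein from LD confounding: a gene
   can pass PWAS *and* MR purely because its pQTL sits in LD with a
   distinct disease variant.
4. **Mediation** — two-step MR: indirect effect β_EM·β_MO (product
   method) with delta-method SE, proportion mediated = indirect/total.

A gene is *prioritized* when it passes all of PWAS FDR < 0.05, MR
FDR < 0.05 and PPH4 ≥ 0.75.

Because the real consortium inputs are access-controlled and
consortium-scale, the package ships a **synthetic-cohort generator**
(`ciswas.synthetic_cohort`): LD-blocked genotypes from a thresholded
Gaussian copula, a cis-heritable protein, a liability-threshold
case-control outcome with ascertained summary statistics, and planted
regimes (`shared_causal`, `distinct_causal`, `null_gwas`, `null_qtl`,
`mediated`) whose ground truth every experiment is checked against.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
scenarios and write their tables to `results/`:

```bash
python analysis/01_simulate_cohorts.py   # scenarios -> scratch/scenarios/
python analysis/02_pwas_scan.py          # -> results/pwas.tsv
python analysis/03_mr_sensitivity.py     # -> results/mr.tsv
python analysis/04_colocalization.py     # -> results/coloc.tsv
python analysis/05_mediation.py          # -> results/mediation.tsv
python analysis/06_prioritize.py         # -> results/priority.tsv
```

`02_pwas_scan.py` prints (seed 2026):

```
             gene_id   pwas_z       pwas_q  significant
  shared_causal_gene   6.521    2.8e-10    True
distinct_causal_gene   5.970    4.8e-09    True
      null_gwas_gene   0.526    0.60       False
       mediated_gene   5.835    7.2e-09    True
```

Both the truly causal gene and the LD-confounded one clear the burden
scan — by design. Colocalization (`04`) then separates them:

```
shared_causal_gene       PPH4 = 1.000  COLOCALIZED
distinct_causal_gene     PPH3 = 1.000  PPH4 = 0.000
null_gwas_gene           PPH2 = 0.953
null_qtl_gene            PPH1 = 0.958
mediated_gene            PPH4 = 1.000  COLOCALIZED
```

PPH4 is the posterior that GWAS and pQTL share one causal variant;
PPH3 that they have two distinct ones — the distinct-causal gene is
correctly rejected. The 50-gene panel (`06`) combines all gates:

```
      gene_id   pwas_z   pwas_q     mr_q     pph4  verdict            reason
  gene_shared    5.479  2.0e-06  1.0e-07  1.0e+00     True       prioritized
gene_distinct    3.401  1.7e-02  4.9e-06  2.7e-13    False no colocalization
```

and `05_mediation.py` decomposes the mediated gene's effect:

```
beta_EM = +0.305 (0.013)   beta_MO = +0.266 (0.083)   beta_EO = +0.534 (0.088)
indirect = +0.081 (0.026)  direct = +0.453
proportion mediated = 15.2% (planted: 25.0%)
```

(one seed; across 25 seeds the mean recovered proportion is 24.9%, see
below). A `ciswas` console script exposes the same stages
(`ciswas synth / xwas / mr / coloc / mediate / run --config run.yaml`).

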