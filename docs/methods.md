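# Methods

`ciswas` re-implements, as a tested pipeline over synthetic cohorts with
known ground truth, the summary-statistics workflow used to prioritize
plasma-protein genes for a complex disease: a cis-weight burden
association scan (PWAS/TWAS), two-sample Mendelian randomization with a
sensitivity suite, Bayesian colocalization, and two-step-MR mediation.
This note records the models, the defaults and why, the numerical
choices, and what the synthetic experiments do and do not show.

## Models and statistics

**Burden association (xwas).** For a gene with cis prediction weights
`w` and GWAS z-scores `z` over the same variants,

    z_assoc = (Σ_k w_k z_k) / sqrt(wᵀ V w),

with `V` the LD correlation submatrix from a reference panel. Under the
null, `z_assoc ~ N(0,1)` regardless of the weights, because `Var(Σ w_k
z_k) = wᵀVw`. Two weight models are fitted per gene on the QTL cohort:
`top1` (the single most significant cis SNP, marginal beta as weight)
and `enet` (elastic net, `l1_ratio = 0.5`, penalty by inner 3-fold CV);
fivefold out-of-fold predictions give each model's out-of-sample R²
(signed, correlation-based) and the better model is kept (ties prefer
enet for stability). Genes enter the scan only if they pass a
heritability gate at p < 0.01 (strict); the scan is BH-FDR-adjusted per
outcome across the gated panel, significance at q < 0.05. PWAS and TWAS
are one code path applied to different weight panels.

*Heritability gate.* A REML heritability test needs individual-level
GRMs, out of scope for a summary-level pipeline. The gate p-value used
here is the Šidák-adjusted minimum marginal cis association p,
`1 − (1 − p_min)^m` over the `m` cis variants — conservative under LD,
hence calibrated at any threshold (measured: 1/100 null genes pass at
0.01). A seemingly natural alternative — a t-test on the correlation
between the fold-concatenated CV predictions and the phenotype — is
*anticonservative* (~5–10/100 at 0.01): variant selection is stable
across folds, so the per-fold prediction–phenotype correlations are
positively dependent and the concatenated statistic's null variance is
inflated roughly two-fold (fold-centering and Stouffer combination do
not repair it). We measured this directly before choosing the Šidák
gate.

**Two-sample MR (mr).** Instruments are exposure variants with
recomputed p < 5e-8, greedily clumped (r² < 0.1 within 10 000 kb, best
p first), then harmonized to the outcome (allele match / swap / strand
flip / strand-flip-swap; palindromic variants dropped when either
allele frequency lies in the closed window [0.42, 0.58] or is missing,
otherwise oriented by frequency concordance). Estimators, all on
per-variant ratio estimates `β_j = by_j / bx_j` with first-order
weights `w_j = bx_j²/sey_j²`:

- **IVW** (primary): fixed-effect, `β = Σ w_j β_j / Σ w_j`,
  `se = (Σ w_j)^{-1/2}`; a single instrument falls back to the Wald
  ratio (`se = sey/|bx|`, first-order).
- **Weighted median**: the first order statistic whose normalized
  cumulative weight reaches ½ (adjacent order statistics averaged on an
  exact boundary); SE by parametric bootstrap (1000 draws of both
  sides' betas, weights fixed, seeded). Note this cumulative-crossing
  rule differs from the half-weight midpoint interpolation used by some
  MR packages.
- **MR-Egger**: WLS of `by` on `bx` with a free intercept after
  orienting all `bx ≥ 0`; residual-scaled SEs, t-tests with n−2 df.
  The intercept estimates directional pleiotropy.
- **Cochran's Q**: `Σ w_j (β_j − β_IVW)²` on χ²(n−1).
- **MR-PRESSO**: observed weighted leave-one-out residual sum of
  squares against its distribution under 1000 seeded simulations from
  the no-pleiotropy model; per-variant outlier p with Bonferroni
  (α/n); outliers removed and IVW re-run as the corrected estimate.
  The distortion test is not implemented.
- **Leave-one-out**: IVW dropping each instrument in turn.

Effects on the binary outcome are log-odds, reported as `OR = exp(β)`
with log-symmetric 95% CIs (`±1.959964·se`). Gene-level multiple
testing reports both the BH-FDR line (used for significance) and the
Bonferroni line (0.05/n tested).

*Known limitation (fixed-effect IVW under residual LD).* Clumping at
r² < 0.1 can retain instruments correlated up to |r| ≈ 0.3 that share
one GWAS sample; their ratio-estimate errors are then correlated and
the fixed-effect SE is ~20% too small in a high-LD block (measured:
sd of standardized errors ≈ 1.2, CI coverage ≈ 0.88 at ld_decay 0.8).
The coverage experiment therefore runs on a low-LD locus (ld_decay
0.2, three causal variants) where the selected instruments are
effectively independent — the setting whose assumptions fixed-effect
IVW actually makes; there coverage is nominal (≈0.94–0.95).

**Colocalization (coloc).** Per-variant Wakefield log approximate
Bayes factors, `lABF = ½[log(1−r) + z²r]` with
`r = W²/(W² + se²)`; effect-prior SD `W` = 0.15 (SD units,
quantitative) or 0.2 (log-odds, binary) — the reference defaults of
the ABF framework. Five-hypothesis posteriors with priors
p1 = p2 = 1e-4, p12 = 1e-5, computed by log-sum-exp
(`L3 ∝ S1·S2 − S12` evaluated with max-subtraction; a non-positive
difference maps to `L3 = 0`). Colocalization is declared at
PPH4 ≥ 0.75. One causal variant per trait is assumed; the cis region
is ±1 Mb around the gene's weighted-variant span; variants are matched
by intersection, no LD imputation.

**Mediation (mediation).** Two-step MR: `β_EM` (protein→mediator, pQTL
instruments), `β_MO` (mediator→outcome, instruments from the mediator
GWAS with the exposure's cis region excluded before selection — this
avoids correlated pleiotropy through the exposure locus; the remaining
overlap bias of unadjusted two-step MR is a documented approximation),
`β_EO` (primary protein→outcome MR, reused bit-for-bit when already
computed). Indirect effect `β_EM·β_MO` with the first-order
delta-method SE `sqrt(β_EM²se_MO² + β_MO²se_EM²)` (no cross-term:
independent samples; the dropped second-order term is bounded by a
Monte-Carlo cross-check at <5% when both legs have |β|/se > 3).
Proportion mediated = indirect/total with the ratio delta-method SE,
flagged unstable when |total| < 2·se_total. Effects stay on the
log-odds/liability scale; percentages appear only in reports.

**Prioritization (pipeline).** verdict = (PWAS q < 0.05) AND
(MR q < 0.05) AND (PPH4 ≥ 0.75); a gene failing only the last carries
`reason = "no colocalization"`. Per-gene failures quarantine the gene
with a structured log line; the panel never aborts. The TWAS
cross-check flags each PWAS gene `replicated` / `not_significant` /
`not_profiled` against the expression-layer scan.

## Synthetic cohorts

Genotypes: two independent haplotypes from a latent AR(1) Gaussian
copula (`corr = ld_decay^|i−j|`) thresholded at each variant's MAF
(uniform in [0.05, 0.5]), giving Hardy–Weinberg dosages. Thresholding
attenuates dosage-scale LD below the latent value (e.g. latent 0.8 →
dosage r ≈ 0.55 at MAF 0.3); the attenuation is *measured and
reported* (realized LD is computed from the sample), not corrected.
Variant alleles are drawn from non-palindromic pairs only, so scenario
harmonization never silently drops instruments; palindrome handling is
exercised by dedicated unit tests instead.

Protein: `Σ w_k g_k + ε`, weights scaled so the genetic variance is
`h2_protein` (weights scaled once on the pQTL cohort and reused in the
other cohorts, so all cohorts share one architecture). Mediator (in
the mediated regime): `β_EM·protein + m_gen + ε`, where `m_gen` is an
independent second locus ("chromosome 2") with its own heritability
(`h2_mediator = 0.3` over 10 causal SNPs within the unit-variance
residual) — without it the mediator would have no instruments of its
own and the mediator→outcome MR leg would be impossible, whereas real
mediator traits (blood pressure, diabetes, clotting factors) are
separately GWAS'd with their own instruments.

Outcome: liability threshold — `L = β_direct·protein + β_MO·mediator
(+ any direct variant effect) + N(0,1)`, cases above the empirical
(1−K) liability quantile (K = 0.1 by default). Case-control summary
statistics mimic GWAS ascertainment: all cases plus an equal number of
sampled controls, scanned by vectorized per-variant logistic
regression (Newton iterations from the score-test start; a one-step
score estimate alone attenuates the moderate per-allele effects that
arise here). Monomorphic variants are emitted with infinite SE and
flagged.

Because estimation is on the log-odds scale while effects are planted
on the liability scale, the ground truth also records the small-effect
conversion `β_logodds = β_liab · φ(z_{1−K}) / (sd_L · K(1−K))` (the
marginal log-odds slope a logistic scan estimates; invariant to
case-control ascertainment, which shifts only the intercept).
Recovery checks compare against the converted value. A direct check
(logistic MLE of the outcome on the true genetic score) matches the
conversion to ~2–3%.

Regimes: `shared_causal` (protein causal for the outcome, liability
β = 0.3), `distinct_causal` (protein heritable but non-causal; the
outcome's own causal variant sits *adjacent* to the protein's with
liability effect 0.3 per dosage SD — realized LD ≈ 0.5–0.6, enough for
the burden scan to pick the gene up yet cleanly separable by
colocalization; an earlier wiring with the variant two positions away
and effect 0.2 failed to produce the regime's defining
PWAS-positive/coloc-negative pattern reliably and was revised),
`null_gwas`, `null_qtl`, and `mediated` (direct 0.225, β_EM 0.3,
β_MO 0.25 → total 0.3, proportion mediated exactly 0.25).

Effect sizes are deliberately desk-scale: per-SD ORs near 1.1 — the
magnitude real plasma-protein studies report — are only detectable at
consortium sample sizes (>10⁶), so the defaults trade effect size for
cohort size while keeping every pipeline decision point exercised.
All sizes and effects are `ScenarioConfig` fields, not constants.

## Experiment sizes and seeds

Experiments (in `ciswas.experiments`, shared by the test suite and
`scripts/acceptance.py`) use cohorts of 2 000–12 000 individuals and
20–80 variants per locus; the full suite runs in minutes on one CPU:

- null burden-z calibration: 200 genes, KS test against N(0,1);
- IVW type-I error: 200 null-GWAS replicates (low-LD instruments);
- MR-PRESSO global-test type-I: 100 clean summary-level instrument
  sets;
- heritability-gate calibration: 100 null-heritability genes;
- IVW 95% CI coverage: 100 shared-causal replicates (low-LD locus, see
  above);
- colocalization regime recovery: 25 seeds per regime;
- mediation recovery: 25 mediated seeds (mean recovered proportion vs
  the planted 0.25);
- end-to-end: 25 panels of 50 genes (1 shared-causal, 1
  distinct-causal, 48 null).

All randomness flows from `numpy.random.default_rng` seeds surfaced in
configs; reruns are bit-identical (the pipeline's file outputs are
byte-identical across reruns).

## What the synthetic experiments do and do not show

They verify internal correctness (estimators match independent
oracles), statistical calibration under the generator's assumptions,
and that the pipeline's decision logic separates the planted regimes.
They do not emulate: trans-QTL effects, sample overlap between
exposure and outcome cohorts, population stratification or relatedness,
genotyping/imputation error, MAF-dependent LD structure beyond the
AR(1) copula, winner's-curse in discovery-cohort weights, or the
paper-scale multiplicity of thousands of genes. Passing tests
therefore certify the machinery, not the biology of any real dataset.

## Numerical choices

- p-values from z use the erfc-based normal survival tail (relative
  error ≪ 1e-10 down to ~1e-300); exact underflow clips to the
  smallest positive double.
- LD matrices are regularized by `R + 0.01·I` then renormalized to
  unit diagonal before any quadratic form (reference panels are
  finite-sample; this guarantees positive definiteness).
- Input p-values are advisory everywhere; all computation recomputes p
  from beta/se.
- Positions are 1-based; window arithmetic uses |Δpos| ≤ window.
- Ties in weight-model selection prefer enet; greedy clumping breaks
  p-ties by variant ID for determinism.
- Missing allele frequency: non-palindromic variants are retained,
  palindromic ones removed (strand cannot be disambiguated).
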