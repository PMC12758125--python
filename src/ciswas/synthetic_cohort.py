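"""Synthetic cohorts with known ground truth.

Generates individual-level data that emulates the statistical structure of
a cis-pQTL panel plus a case-control GWAS: LD-blocked genotypes from a
latent Gaussian copula, a cis-regulated protein with specified
heritability, a liability-threshold binary outcome with specified protein
and mediator effects, and the per-SNP summary statistics a consortium scan
would produce.  Every downstream stage (weighted-burden association, MR,
colocalization, mediation) is verified against these known truths.

Regimes
-------
shared_causal
    the protein's cis variant(s) drive the outcome through the protein.
distinct_causal
    the protein is heritable but non-causal; a nearby, LD-correlated
    variant affects the outcome directly.
null_gwas
    the outcome is independent of the locus (protein still heritable).
null_qtl
    the protein is non-heritable; the outcome has its own cis signal.
mediated
    part of the protein's effect flows through a heritable mediator trait
    with its own (independent) instrument locus.

Binary-trait summary statistics mimic GWAS ascertainment: all cases plus
an equal number of controls, analyzed by a per-variant logistic score
test.  Because estimation is on the log-odds scale while the generative
effects are liability-scale, the ground truth also records the standard
small-effect conversion  beta_logodds = beta_liab * phi(z_{1-K}) /
(sd_L * K(1-K))  so recovery can be asserted on the estimation scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .sumstats_io import LDMatrix, SummaryStats, pvalue_from_z
from .xwas import WeightSet

REGIMES = ("shared_causal", "distinct_causal", "null_gwas", "null_qtl", "mediated")

#: ordered non-palindromic allele pairs (strand-ambiguous pairs are
#: exercised in harmonization unit tests, not in generated scenarios)
_ALLELE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT"
                 if a != b and {a, b} not in ({"A", "T"}, {"C", "G"})]


class ConfigError(ValueError):
    """Invalid scenario configuration."""


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic gene/locus scenario.

    Effects are liability-scale; the protein is standardized so
    ``h2_protein`` plus residual variance is 1 on the protein scale.
    ``beta_protein_on_outcome`` is the protein's *direct* liability effect;
    the total effect adds the mediated path.
    """

    regime: str
    seed: int
    n_individuals: int = 20_000          # outcome (GWAS) cohort
    n_pqtl: int = 5_000                  # protein (pQTL) cohort
    n_mediator: int = 20_000             # mediator-GWAS cohort
    n_variants: int = 200
    n_variants_mediator: int = 80
    maf_range: tuple = (0.05, 0.5)
    ld_decay: float = 0.8
    h2_protein: float = 0.3
    n_causal: int = 1
    h2_mediator: float = 0.3
    n_causal_mediator: int = 10
    beta_protein_on_outcome: float = 0.3
    beta_protein_on_mediator: float = 0.0
    beta_mediator_on_outcome: float = 0.0
    beta_outcome_own: float = 0.0        # direct genotype->outcome (per dosage SD)
    prevalence: float = 0.1

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ConfigError(f"unknown regime {self.regime!r}")
        if self.n_variants < 2:
            raise ConfigError("n_variants must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie in (0, 0.5]")
        if not 0 <= self.ld_decay < 1:
            raise ConfigError("ld_decay must lie in [0, 1)")
        if not 0 <= self.h2_protein < 1:
            raise ConfigError("h2_protein must lie in [0, 1)")
        if not 0 < self.prevalence < 1:
            raise ConfigError("prevalence must lie in (0, 1)")
        if self.n_causal > self.n_variants:
            raise ConfigError("n_causal exceeds n_variants")


#: per-regime defaults for the effect wiring (desk-scale: detectable at
#: cohort sizes of thousands, unlike the paper's N ~ 1.3M)
_REGIME_PRESETS = {
    "shared_causal": dict(beta_protein_on_outcome=0.3),
    "distinct_causal": dict(beta_protein_on_outcome=0.0, beta_outcome_own=0.3),
    "null_gwas": dict(beta_protein_on_outcome=0.0),
    "null_qtl": dict(beta_protein_on_outcome=0.0, h2_protein=0.0,
                     beta_outcome_own=0.2),
    "mediated": dict(beta_protein_on_outcome=0.225,
                     beta_protein_on_mediator=0.3,
                     beta_mediator_on_outcome=0.25),
}


def scenario_config(regime: str, seed: int, **overrides) -> ScenarioConfig:
    """A ScenarioConfig with the regime's default effect wiring applied."""
    kwargs = dict(_REGIME_PRESETS[regime]) if regime in _REGIME_PRESETS else {}
    kwargs.update(overrides)
    return ScenarioConfig(regime=regime, seed=seed, **kwargs)


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    regime: str
    causal_variant_ids: list
    true_weights: pd.Series = field(repr=False)
    true_total_effect: float = 0.0          # liability scale
    true_indirect_effect: float = 0.0
    true_proportion_mediated: float = float("nan")
    liability_sd: float = 1.0
    logodds_scale: float = float("nan")     # liability -> log-odds slope factor
    true_total_effect_logodds: float = float("nan")
    true_em: float = 0.0                    # exposure -> mediator
    true_mo: float = 0.0                    # mediator -> outcome (liability)
    true_mo_logodds: float = float("nan")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["true_weights"] = {k: float(v) for k, v in self.true_weights.items()
                             if v != 0}
        return d


def make_variants(n_variants: int, maf_range, rng: np.random.Generator,
                  chromosome: str = "1", start: int = 1_000_000,
                  spacing: int = 5_000, prefix: str = "snp") -> pd.DataFrame:
    """Variant metadata for one cis block (IDs, positions, alleles, MAFs)."""
    mafs = rng.uniform(maf_range[0], maf_range[1], size=n_variants)
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS),
                                                    size=n_variants)]
    positions = start + spacing * np.arange(n_variants)
    return pd.DataFrame({
        "variant_id": [f"{prefix}_{chromosome}_{p}" for p in positions],
        "chromosome": chromosome,
        "position": positions,
        "effect_allele": [a for a, _ in pairs],
        "other_allele": [b for _, b in pairs],
        "maf": mafs,
    })


def _haplotypes(n: int, thresholds: np.ndarray, ld_decay: float,
                rng: np.random.Generator) -> np.ndarray:
    """One binary haplotype matrix from an AR(1) latent Gaussian."""
    p = thresholds.size
    z = rng.standard_normal((n, p))
    x = np.empty_like(z)
    x[:, 0] = z[:, 0]
    c = np.sqrt(1.0 - ld_decay ** 2)
    for j in range(1, p):
        x[:, j] = ld_decay * x[:, j - 1] + c * z[:, j]
    return (x < thresholds).astype(np.float64)


def simulate_genotypes(config: ScenarioConfig, variants: pd.DataFrame | None = None,
                       n: int | None = None,
                       rng: np.random.Generator | None = None):
    """Dosages in {0,1,2} plus the realized LD correlation matrix.

    Two independent haplotypes are drawn from a latent Gaussian copula
    with corr(i, j) = ld_decay^|i-j| and thresholded at each variant's
    MAF, giving Hardy-Weinberg genotype frequencies.  Thresholding
    attenuates the dosage-scale correlation below the latent value; the
    realized LD is computed from the sample rather than corrected.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if variants is None:
        variants = make_variants(config.n_variants, config.maf_range, rng)
    n = config.n_individuals if n is None else n
    thresholds = stats.norm.ppf(variants["maf"].to_numpy())
    dosages = (_haplotypes(n, thresholds, config.ld_decay, rng)
               + _haplotypes(n, thresholds, config.ld_decay, rng))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(dosages, rowvar=False)
    r[~np.isfinite(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    ld = LDMatrix(list(variants["variant_id"]), r)
    return dosages, ld, variants


def _scaled_weights(dosages: np.ndarray, causal_idx: np.ndarray, h2: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Per-dosage weights whose genetic score has variance h2 in-sample."""
    w = np.zeros(dosages.shape[1])
    if h2 == 0 or causal_idx.size == 0:
        return w
    raw = rng.standard_normal(causal_idx.size)
    g = dosages[:, causal_idx] @ raw
    w[causal_idx] = raw * np.sqrt(h2) / g.std()
    return w


def simulate_protein(dosages: np.ndarray, config: ScenarioConfig,
                     rng: np.random.Generator | None = None,
                     causal_idx: np.ndarray | None = None,
                     weights: np.ndarray | None = None):
    """Protein = genetic score + noise; genetic variance = h2_protein.

    Returns ``(protein, weights)`` with the protein standardized and the
    weights on the (per-allele) dosage scale.  ``h2_protein = 0`` yields
    all-zero weights (a valid null gene).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, p = dosages.shape
    if causal_idx is None:
        causal_idx = np.sort(rng.choice(p, size=min(config.n_causal, p),
                                        replace=False))
    if weights is None:
        weights = _scaled_weights(dosages, np.asarray(causal_idx),
                                  config.h2_protein, rng)
    protein = dosages @ weights + rng.standard_normal(n) * np.sqrt(
        max(0.0, 1.0 - config.h2_protein))
    sd = protein.std()
    if sd > 0:
        protein = (protein - protein.mean()) / sd
        weights = weights / sd
    return protein, weights


def liability_to_logodds(beta_liability, liability_sd: float,
                         prevalence: float) -> float:
    """Small-effect conversion from a liability-scale slope to the
    marginal log-odds slope a logistic score test estimates (invariant to
    case-control ascertainment, which shifts only the intercept)."""
    k = prevalence
    z = stats.norm.ppf(1.0 - k)
    return beta_liability * stats.norm.pdf(z) / (liability_sd * k * (1.0 - k))


def simulate_outcome(protein: np.ndarray, config: ScenarioConfig,
                     rng: np.random.Generator | None = None,
                     mediator_genetic: np.ndarray | None = None,
                     liability_extra: np.ndarray | None = None):
    """Liability-threshold binary outcome plus the mediator vector.

    mediator  = b_EM * protein + genetic part (var h2_mediator) + noise,
    residual variance 1 in total;
    liability = b_direct * protein + b_MO * mediator (+ any direct
    genotype term) + N(0,1); the threshold is the empirical
    (1 - prevalence) liability quantile so the sample prevalence matches
    the configured one.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = protein.size
    h2m = config.h2_mediator if mediator_genetic is not None else 0.0
    m_gen = mediator_genetic if mediator_genetic is not None else 0.0
    mediator = (config.beta_protein_on_mediator * protein + m_gen
                + rng.standard_normal(n) * np.sqrt(max(0.0, 1.0 - h2m)))
    liability = (config.beta_protein_on_outcome * protein
                 + config.beta_mediator_on_outcome * mediator
                 + rng.standard_normal(n))
    if liability_extra is not None:
        liability = liability + liability_extra
    threshold = np.quantile(liability, 1.0 - config.prevalence)
    outcome = (liability > threshold).astype(np.int8)

    indirect = config.beta_protein_on_mediator * config.beta_mediator_on_outcome
    total = config.beta_protein_on_outcome + indirect
    sd_l = float(liability.std())
    scale = liability_to_logodds(1.0, sd_l, config.prevalence)
    truth = GroundTruth(
        regime=config.regime,
        causal_variant_ids=[],
        true_weights=pd.Series(dtype=float),
        true_total_effect=total,
        true_indirect_effect=indirect,
        true_proportion_mediated=indirect / total if total != 0 else float("nan"),
        liability_sd=sd_l,
        logodds_scale=scale,
        true_total_effect_logodds=total * scale,
        true_em=config.beta_protein_on_mediator,
        true_mo=config.beta_mediator_on_outcome,
        true_mo_logodds=config.beta_mediator_on_outcome * scale,
    )
    return outcome, mediator, truth


# ---------------------------------------------------------------------------
# per-SNP summary statistics

def _marginal_linear(dosages: np.ndarray, y: np.ndarray):
    """Vectorized per-variant simple linear regression (beta, se)."""
    n = y.size
    gc = dosages - dosages.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc ** 2).sum(axis=0)
    sxy = gc.T @ yc
    syy = (yc ** 2).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = sxy / sxx
        resid = np.maximum(syy - beta * sxy, 0.0)
        se = np.sqrt(resid / np.maximum(n - 2, 1) / sxx)
    return beta, se, sxx


def _logistic_score(dosages: np.ndarray, y: np.ndarray, n_iter: int = 6):
    """Vectorized per-variant logistic regression (intercept + slope).

    Newton-Raphson run simultaneously across variants, initialized at the
    score-test one-step estimate; a handful of iterations reaches MLE
    accuracy for the per-allele effects arising here (one-step estimates
    alone attenuate moderate effects).  Returns (beta, se, information).
    """
    y = np.asarray(y, dtype=float)
    p0 = y.mean()
    gc = dosages - dosages.mean(axis=0)
    u = dosages.T @ (y - p0)
    v = p0 * (1.0 - p0) * (gc ** 2).sum(axis=0)
    ok = v > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(ok, u / np.where(ok, v, 1.0), 0.0)
    alpha = np.full_like(beta, np.log(p0 / (1.0 - p0)))
    for _ in range(n_iter):
        eta = alpha + beta * dosages  # broadcasting: (n, p)
        mu = 1.0 / (1.0 + np.exp(-eta))
        wvar = mu * (1.0 - mu)
        r = y[:, None] - mu
        s_a = r.sum(axis=0)
        s_b = (dosages * r).sum(axis=0)
        i_aa = wvar.sum(axis=0)
        i_ab = (wvar * dosages).sum(axis=0)
        i_bb = (wvar * dosages ** 2).sum(axis=0)
        det = i_aa * i_bb - i_ab ** 2
        good = ok & (det > 0)
        d_alpha = np.where(good, (i_bb * s_a - i_ab * s_b) / np.where(good, det, 1.0), 0.0)
        d_beta = np.where(good, (i_aa * s_b - i_ab * s_a) / np.where(good, det, 1.0), 0.0)
        alpha += d_alpha
        beta += d_beta
    eta = alpha + beta * dosages
    mu = 1.0 / (1.0 + np.exp(-eta))
    wvar = mu * (1.0 - mu)
    i_aa = wvar.sum(axis=0)
    i_ab = (wvar * dosages).sum(axis=0)
    i_bb = (wvar * dosages ** 2).sum(axis=0)
    det = i_aa * i_bb - i_ab ** 2
    info = np.where(ok & (det > 0), det / np.where(i_aa > 0, i_aa, 1.0), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = 1.0 / np.sqrt(info)
    return beta, se, info


def make_sumstats(dosages: np.ndarray, phenotype: np.ndarray, trait_type: str,
                  variants: pd.DataFrame, trait_name: str,
                  rng: np.random.Generator | None = None) -> SummaryStats:
    """Per-variant marginal scan producing a SummaryStats.

    Quantitative traits: simple linear regression per variant.  Binary
    traits: all cases plus an equal number of controls sampled from the
    non-cases (GWAS-style ascertainment), then a logistic score test.
    Monomorphic variants are emitted with infinite SE and flagged so
    downstream p/z gates exclude them.
    """
    if dosages.shape[0] != phenotype.size:
        raise ValueError("phenotype length does not match dosage rows")
    if trait_type == "binary":
        rng = np.random.default_rng(0) if rng is None else rng
        cases = np.flatnonzero(phenotype == 1)
        controls = np.flatnonzero(phenotype == 0)
        n_ctrl = min(cases.size, controls.size)
        sel = np.concatenate([cases, rng.choice(controls, size=n_ctrl,
                                                replace=False)])
        g, y = dosages[sel], phenotype[sel].astype(float)
        beta, se, info = _logistic_score(g, y)
        mono = info <= 0
        n_cases = float(cases.size)
    else:
        g, y = dosages, np.asarray(phenotype, dtype=float)
        beta, se, sxx = _marginal_linear(g, y)
        mono = sxx <= 0
        n_cases = np.nan
    beta = np.where(mono, 0.0, beta)
    se = np.where(mono, np.inf, se)
    with np.errstate(invalid="ignore"):
        p = np.where(mono, 1.0, pvalue_from_z(np.where(mono, 0.0, beta / np.where(mono, 1.0, se))))
    df = pd.DataFrame({
        "variant_id": variants["variant_id"].to_numpy(),
        "chromosome": variants["chromosome"].to_numpy(),
        "position": variants["position"].to_numpy(),
        "effect_allele": variants["effect_allele"].to_numpy(),
        "other_allele": variants["other_allele"].to_numpy(),
        "eaf": g.mean(axis=0) / 2.0,
        "beta": beta,
        "se": se,
        "p": p,
        "n": float(len(y)),
        "n_cases": n_cases,
        "flag": np.where(mono, "monomorphic", ""),
    })
    return SummaryStats(trait_name=trait_name, trait_type=trait_type, records=df)


# ---------------------------------------------------------------------------
# cis prediction-weight fitting

def _top1_fit(g_train, y_train):
    beta, se, sxx = _marginal_linear(g_train, y_train)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sxx > 0, beta / se, 0.0)
    j = int(np.argmax(np.abs(z)))
    w = np.zeros(g_train.shape[1])
    w[j] = beta[j] if sxx[j] > 0 else 0.0
    return w


def _enet_fit(g_train, y_train, seed):
    model = ElasticNetCV(l1_ratio=0.5, alphas=15, eps=1e-2, cv=3,
                         max_iter=5_000, random_state=seed)
    model.fit(g_train, y_train)
    return model.coef_.copy()


def _signed_r2(pred, y):
    if np.std(pred) == 0:
        return 0.0
    r, _ = stats.pearsonr(pred, y)
    return float(np.sign(r) * r ** 2)


def _gate_pvalue(dosages: np.ndarray, protein: np.ndarray) -> float:
    """Heritability-gate p: Šidák-adjusted minimum marginal cis p.

    1 - (1 - p_min)^m over the m cis variants.  Conservative under LD
    (fewer effective tests), hence calibrated at any threshold.  A
    fold-concatenated CV prediction-phenotype correlation test is *not*
    used here: variant selection is stable across folds, so the per-fold
    correlations are positively dependent and that statistic's null
    variance is inflated roughly two-fold.
    """
    beta, se, sxx = _marginal_linear(dosages, protein)
    ok = sxx > 0
    if not ok.any():
        return 1.0
    z = beta[ok] / se[ok]
    p_min = float(pvalue_from_z(float(np.max(np.abs(z)))))
    m = int(ok.sum())
    return float(-np.expm1(m * np.log1p(-min(p_min, 1.0 - 1e-16))))


def fit_weights(dosages: np.ndarray, protein: np.ndarray,
                variants: pd.DataFrame, models=("top1", "enet"),
                k_folds: int = 5, seed: int = 0,
                gene_id: str = "gene") -> WeightSet:
    """Fit cis prediction models and pick the best by out-of-sample R².

    ``top1`` regresses the protein on the single most significant SNP;
    ``enet`` is a multivariable elastic-net fit with the penalty chosen by
    inner cross-validation.  k-fold (default fivefold) out-of-fold
    predictions give each model's out-of-sample R² (signed, correlation
    based); ties prefer enet.  The heritability-gate p-value is the
    Šidák-adjusted minimum marginal cis association p — a calibrated
    proxy for a REML heritability test, which would need
    individual-level GRMs (see ``_gate_pvalue`` for why a CV-correlation
    test is not used).
    """
    n, p = dosages.shape
    if k_folds < 2:
        raise ConfigError("k_folds must be >= 2")
    if n < k_folds:
        raise ConfigError("fewer individuals than folds")
    fitters = {"top1": _top1_fit,
               "enet": lambda g, y: _enet_fit(g, y, seed)}
    oof = {m: np.zeros(n) for m in models}
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for train, test in kf.split(dosages):
        for m in models:
            w = fitters[m](dosages[train], protein[train])
            oof[m][test] = dosages[test] @ w
    scores = {m: _signed_r2(oof[m], protein) for m in models}
    # higher CV R² wins; exact ties prefer enet for stability
    best = max(models, key=lambda m: (scores[m], m == "enet"))
    w_full = fitters[best](dosages, protein)
    nz = np.flatnonzero(w_full)
    entries = variants.iloc[nz][["variant_id", "chromosome", "position",
                                 "effect_allele", "other_allele"]].copy()
    entries["weight"] = w_full[nz]
    return WeightSet(gene_id=gene_id, model_tag=best,
                     entries=entries.reset_index(drop=True),
                     cv_r2=scores[best],
                     gate_p=_gate_pvalue(dosages, protein))


# ---------------------------------------------------------------------------
# full scenarios

@dataclass
class ScenarioBundle:
    """All summary-level artifacts of one simulated gene/locus."""

    config: ScenarioConfig
    variants: pd.DataFrame = field(repr=False)
    pqtl: SummaryStats = field(repr=False)
    gwas: SummaryStats = field(repr=False)
    weights: WeightSet = field(repr=False)
    ld: LDMatrix = field(repr=False)
    truth: GroundTruth = field(repr=False)
    mediator_gwas: SummaryStats | None = field(default=None, repr=False)


def simulate_scenario(config: ScenarioConfig, gene_id: str = "gene",
                      fit: bool = True) -> ScenarioBundle:
    """Generate the summary-level artifacts for one scenario.

    Three independent cohorts share the same genetic architecture (true
    weights scaled once, on the pQTL cohort): a pQTL cohort (protein
    measured; also serves as the LD reference panel), an outcome cohort
    (case-control GWAS) and, in the mediated regime, a mediator-GWAS
    cohort.  No sample overlap, matching the two-sample MR design.
    """
    rng = np.random.default_rng(config.seed)
    r_arch, r_pqtl, r_gwas, r_med = rng.spawn(4)

    variants = make_variants(config.n_variants, config.maf_range, r_arch,
                             chromosome="1", prefix=f"{gene_id}_snp")
    p = config.n_variants
    causal_idx = np.sort(r_arch.choice(p, size=config.n_causal, replace=False))

    # pQTL cohort: weights are scaled here and reused everywhere
    dos_pqtl, ld, _ = simulate_genotypes(config, variants=variants,
                                         n=config.n_pqtl, rng=r_pqtl)
    weights_true = _scaled_weights(dos_pqtl, causal_idx, config.h2_protein, r_arch)
    protein_pqtl, _ = simulate_protein(dos_pqtl, config, rng=r_pqtl,
                                       causal_idx=causal_idx, weights=weights_true)
    pqtl = make_sumstats(dos_pqtl, protein_pqtl, "quantitative", variants,
                         f"{gene_id}_pqtl")
    ws = (fit_weights(dos_pqtl, protein_pqtl, variants, seed=config.seed,
                      gene_id=gene_id) if fit else None)

    mediated = config.regime == "mediated"
    med_variants = None
    w_med = None
    if mediated:
        med_variants = make_variants(config.n_variants_mediator,
                                     config.maf_range, r_arch,
                                     chromosome="2", prefix=f"{gene_id}_med")
        med_causal = np.sort(r_arch.choice(config.n_variants_mediator,
                                           size=config.n_causal_mediator,
                                           replace=False))

    # outcome cohort
    dos_out, _, _ = simulate_genotypes(config, variants=variants,
                                       n=config.n_individuals, rng=r_gwas)
    protein_out = dos_out @ weights_true + r_gwas.standard_normal(
        config.n_individuals) * np.sqrt(max(0.0, 1.0 - config.h2_protein))
    med_gen_out = None
    all_variants = variants
    if mediated:
        dos_out_med, _, _ = simulate_genotypes(config, variants=med_variants,
                                               n=config.n_individuals, rng=r_gwas)
        w_med = _scaled_weights(dos_out_med, med_causal, config.h2_mediator,
                                r_arch)
        med_gen_out = dos_out_med @ w_med
        dos_out = np.hstack([dos_out, dos_out_med])
        all_variants = pd.concat([variants, med_variants], ignore_index=True)

    extra = None
    if config.beta_outcome_own != 0:
        # the outcome's own causal variant sits adjacent to the protein's:
        # enough LD for the burden scan to pick the gene up, distinct
        # enough for colocalization to separate the two signals (never the
        # causal variant itself, even at the block edge)
        own_idx = int(causal_idx[0] + 1 if causal_idx[0] + 1 < p
                      else causal_idx[0] - 1)
        g_own = dos_out[:, own_idx]
        extra = config.beta_outcome_own * (g_own - g_own.mean()) / g_own.std()
        own_ids = [variants["variant_id"].iloc[own_idx]]
    else:
        own_ids = []
    outcome, mediator_out, truth = simulate_outcome(
        protein_out, config, rng=r_gwas, mediator_genetic=med_gen_out,
        liability_extra=extra)
    truth.causal_variant_ids = (list(variants["variant_id"].iloc[causal_idx])
                                + own_ids)
    truth.true_weights = pd.Series(weights_true,
                                   index=variants["variant_id"].to_numpy())
    gwas = make_sumstats(dos_out, outcome, "binary", all_variants,
                         f"{gene_id}_gwas", rng=r_gwas)

    mediator_gwas = None
    if mediated:
        dos_m1, _, _ = simulate_genotypes(config, variants=variants,
                                          n=config.n_mediator, rng=r_med)
        dos_m2, ld_med, _ = simulate_genotypes(config, variants=med_variants,
                                               n=config.n_mediator, rng=r_med)
        # block-diagonal reference LD: the two loci sit on different
        # chromosomes, so cross-block correlation is zero by design
        n1, n2 = len(ld.variant_ids), len(ld_med.variant_ids)
        r_full = np.zeros((n1 + n2, n1 + n2))
        r_full[:n1, :n1] = ld.r
        r_full[n1:, n1:] = ld_med.r
        ld = LDMatrix(ld.variant_ids + ld_med.variant_ids, r_full)
        protein_m = dos_m1 @ weights_true + r_med.standard_normal(
            config.n_mediator) * np.sqrt(max(0.0, 1.0 - config.h2_protein))
        med_gen_m = dos_m2 @ w_med
        mediator_m = (config.beta_protein_on_mediator * protein_m + med_gen_m
                      + r_med.standard_normal(config.n_mediator)
                      * np.sqrt(max(0.0, 1.0 - config.h2_mediator)))
        mediator_gwas = make_sumstats(np.hstack([dos_m1, dos_m2]), mediator_m,
                                      "quantitative",
                                      pd.concat([variants, med_variants],
                                                ignore_index=True),
                                      f"{gene_id}_mediator")

    return ScenarioBundle(config=config, variants=all_variants, pqtl=pqtl,
                          gwas=gwas, weights=ws, ld=ld, truth=truth,
                          mediator_gwas=mediator_gwas)


def write_scenario(bundle: ScenarioBundle, outdir) -> None:
    """Write a scenario's artifacts in the pipeline's file formats:
    ``gwas.tsv``, ``pqtl/<gene>.tsv``, ``weights.tsv`` + sidecar,
    ``ld/<gene>.ids`` + ``.ld``, optional ``mediator.tsv``, and a
    ground-truth JSON sidecar."""
    import json
    from pathlib import Path

    from .sumstats_io import write_ld, write_sumstats
    from .xwas import write_weight_panel

    outdir = Path(outdir)
    gene = bundle.weights.gene_id if bundle.weights is not None else "gene"
    (outdir / "pqtl").mkdir(parents=True, exist_ok=True)
    (outdir / "ld").mkdir(exist_ok=True)
    write_sumstats(bundle.gwas, outdir / "gwas.tsv")
    write_sumstats(bundle.pqtl, outdir / "pqtl" / f"{gene}.tsv")
    if bundle.mediator_gwas is not None:
        write_sumstats(bundle.mediator_gwas, outdir / "mediator.tsv")
    if bundle.weights is not None:
        write_weight_panel([bundle.weights], outdir / "weights.tsv",
                           outdir / "weights_sidecar.tsv")
    write_ld(bundle.ld, outdir / "ld" / f"{gene}.ids",
             outdir / "ld" / f"{gene}.ld")
    truth = bundle.truth.as_dict()
    truth["config"] = {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(bundle.config).items()}
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
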