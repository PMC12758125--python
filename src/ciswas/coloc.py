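"""Bayesian colocalization of two association signals over a cis region.

Per-variant approximate Bayes factors (Wakefield) are combined under the
single-causal-variant-per-trait assumption into posterior probabilities
for five hypotheses: H0 no association with either trait; H1/H2
association with one trait only; H3 two distinct causal variants; H4 one
shared causal variant.  Default priors p1 = p2 = 1e-4, p12 = 1e-5; strong
colocalization is declared at PPH4 >= 0.75.  Used for GWAS-pQTL pairs and
for the complementary pQTL-eQTL check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .sumstats_io import SummaryStats

#: per-variant effect prior SDs of the ABF framework's reference defaults
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_BINARY = 0.2

PPH4_THRESHOLD = 0.75


@dataclass(frozen=True)
class ColocPriors:
    """Prior probabilities that a variant associates with trait 1, trait 2,
    or both."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if not 0 < self.p12 <= min(self.p1, self.p2):
            raise ValueError("require 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("priors must sum to < 1")


@dataclass
class ColocResult:
    """Posterior probabilities over H0..H4 (they sum to 1)."""

    pp: dict
    n_variants: int
    colocalized: bool

    def __getitem__(self, key: str) -> float:
        return self.pp[key]


def wakefield_labf(beta, se, prior_sd: float):
    """Log approximate Bayes factor for one association.

    With shrinkage r = prior_sd² / (prior_sd² + se²) and z = beta/se:
        lABF = 0.5 * (log(1 - r) + z² r).
    This is the log ratio of the marginal likelihood under a N(0,
    prior_sd²) effect prior to the point-null likelihood.  Vectorized.
    """
    se_arr = np.asarray(se, dtype=float)
    if np.any(se_arr <= 0):
        raise ValueError("se must be > 0")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be > 0")
    z2 = (np.asarray(beta, dtype=float) / se_arr) ** 2
    r = prior_sd ** 2 / (prior_sd ** 2 + se_arr ** 2)
    out = 0.5 * (np.log1p(-r) + z2 * r)
    return float(out) if np.ndim(beta) == 0 and np.ndim(se) == 0 else out


def coloc_posteriors(labf1, labf2, priors: ColocPriors = ColocPriors(),
                     pph4_threshold: float = PPH4_THRESHOLD) -> ColocResult:
    """Five-hypothesis posteriors from aligned per-variant log ABFs.

    Likelihoods (up to shared constants), evaluated with log-sum-exp:
        L0 = 1
        L1 = p1 * sum_i BF1_i
        L2 = p2 * sum_i BF2_i
        L3 = p1 p2 * (sum_i BF1_i * sum_j BF2_j - sum_i BF1_i BF2_i)
        L4 = p12 * sum_i BF1_i BF2_i
    """
    l1 = np.asarray(labf1, dtype=float)
    l2 = np.asarray(labf2, dtype=float)
    if l1.size == 0 or l1.shape != l2.shape:
        raise ValueError("no shared variants (aligned lABF vectors required)")
    ls1 = logsumexp(l1)
    ls2 = logsumexp(l2)
    ls12 = logsumexp(l1 + l2)
    # sum over distinct pairs: exp(ls1 + ls2) - exp(ls12), in log space
    m = max(ls1 + ls2, ls12)
    diff = np.exp(ls1 + ls2 - m) - np.exp(ls12 - m)
    log_l3 = (np.log(priors.p1) + np.log(priors.p2) + m + np.log(diff)
              if diff > 0 else -np.inf)
    logs = np.array([
        0.0,
        np.log(priors.p1) + ls1,
        np.log(priors.p2) + ls2,
        log_l3,
        np.log(priors.p12) + ls12,
    ])
    pp = np.exp(logs - logsumexp(logs))
    pp = pp / pp.sum()
    names = ["PPH0", "PPH1", "PPH2", "PPH3", "PPH4"]
    result = dict(zip(names, map(float, pp)))
    return ColocResult(pp=result, n_variants=int(l1.size),
                       colocalized=result["PPH4"] >= pph4_threshold)


def prior_sd_for(trait_type: str) -> float:
    """Reference ABF effect-prior SD by trait type (0.15 SD units for
    quantitative traits, 0.2 log-odds for binary)."""
    return PRIOR_SD_BINARY if trait_type == "binary" else PRIOR_SD_QUANTITATIVE


def coloc_pair(trait1: SummaryStats, trait2: SummaryStats,
               region: tuple | None = None,
               priors: ColocPriors = ColocPriors(),
               pph4_threshold: float = PPH4_THRESHOLD) -> ColocResult:
    """Colocalize two traits over a shared cis region.

    ``region`` is ``(chromosome, start, end)``; ``None`` uses all shared
    variants.  Variants are matched by intersection (no LD-based
    imputation); per-trait prior SDs follow the trait type.
    """
    r1, r2 = trait1.records, trait2.records
    if region is not None:
        chrom, start, end = region
        r1 = r1[(r1["chromosome"].astype(str) == str(chrom))
                & r1["position"].between(start, end)]
        r2 = r2[(r2["chromosome"].astype(str) == str(chrom))
                & r2["position"].between(start, end)]
    m = r1.merge(r2, on="variant_id", suffixes=("_1", "_2"))
    m = m[np.isfinite(m["se_1"]) & (m["se_1"] > 0)
          & np.isfinite(m["se_2"]) & (m["se_2"] > 0)]
    if m.empty:
        raise ValueError("no shared variants in the region")
    labf1 = wakefield_labf(m["beta_1"].to_numpy(), m["se_1"].to_numpy(),
                           prior_sd_for(trait1.trait_type))
    labf2 = wakefield_labf(m["beta_2"].to_numpy(), m["se_2"].to_numpy(),
                           prior_sd_for(trait2.trait_type))
    return coloc_posteriors(labf1, labf2, priors, pph4_threshold)
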