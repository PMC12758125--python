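"""Two-step-MR mediation: decompose a protein's total effect on an outcome
into the indirect path through a risk-factor mediator and the direct
remainder.

Three MR legs are estimated from summary statistics: exposure->mediator
(beta_EM), mediator->outcome (beta_MO, instruments selected from the
mediator GWAS, excluding the exposure's cis region), and the primary
exposure->outcome MR (beta_EO, the total effect).  The indirect effect is
the product beta_EM * beta_MO with a first-order delta-method SE (zero
cross-term: the two legs come from independent samples); the proportion
mediated is indirect/total with a ratio delta-method SE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mr import MREstimate, Z95, mr_analysis
from .sumstats_io import LDMatrix, SummaryStats

UNSTABLE_TOTAL_FACTOR = 2.0


@dataclass
class MediationResult:
    """Effect decomposition for one (gene, mediator, outcome) triple."""

    beta_total: float
    se_total: float
    beta_em: float
    se_em: float
    beta_mo: float
    se_mo: float
    beta_indirect: float
    se_indirect: float
    ci_indirect: tuple
    proportion_mediated: float
    se_proportion: float
    ci_proportion: tuple
    unstable: bool = False
    beta_direct: float = field(init=False)

    def __post_init__(self) -> None:
        self.beta_direct = self.beta_total - self.beta_indirect


def indirect_effect(beta_em: float, se_em: float, beta_mo: float,
                    se_mo: float):
    """Product-method indirect effect with first-order delta-method SE.

    beta = beta_EM * beta_MO;  se = sqrt(beta_EM² se_MO² + beta_MO² se_EM²)
    (no cross-term: two-sample independence).
    """
    if se_em < 0 or se_mo < 0:
        raise ValueError("SEs must be >= 0")
    beta = beta_em * beta_mo
    se = float(np.sqrt(beta_em ** 2 * se_mo ** 2 + beta_mo ** 2 * se_em ** 2))
    return beta, se, (beta - Z95 * se, beta + Z95 * se)


def proportion_mediated(beta_indirect: float, se_indirect: float,
                        beta_total: float, se_total: float):
    """Proportion mediated = indirect/total with ratio delta-method SE.

    Flagged unstable (still reported) when |total| < 2 se_total: the
    ratio of a noisy total is poorly behaved.
    """
    if beta_total == 0:
        raise ValueError("proportion undefined for beta_total = 0")
    prop = beta_indirect / beta_total
    se = float(np.sqrt(se_indirect ** 2 / beta_total ** 2
                       + beta_indirect ** 2 * se_total ** 2 / beta_total ** 4))
    unstable = abs(beta_total) < UNSTABLE_TOTAL_FACTOR * se_total
    return prop, se, (prop - Z95 * se, prop + Z95 * se), unstable


def two_step_effects(protein_pqtl: SummaryStats, mediator_gwas: SummaryStats,
                     outcome_gwas: SummaryStats, ld: LDMatrix,
                     exclude_region: tuple | None = None,
                     p_thresh: float = 5e-8, seed: int = 0,
                     primary: MREstimate | None = None):
    """The three MR legs of two-step mediation.

    beta_EM: MR of protein on mediator (protein instruments);
    beta_MO: MR of mediator on outcome (instruments from the mediator
    GWAS, with ``exclude_region`` — typically the exposure's cis window —
    removed before selection to avoid correlated pleiotropy through the
    exposure locus);
    beta_EO: the primary protein-on-outcome MR (pass ``primary`` to reuse
    an already-computed estimate bit-for-bit).

    Returns ``(em, mo, eo)`` MREstimates, any of which is None when a leg
    lacks instruments.
    """
    em, _, _ = mr_analysis(protein_pqtl, mediator_gwas, ld,
                           p_thresh=p_thresh, seed=seed)
    med = mediator_gwas
    if exclude_region is not None:
        chrom, start, end = exclude_region
        rec = med.records
        keep = ~((rec["chromosome"].astype(str) == str(chrom))
                 & rec["position"].between(start, end))
        med = SummaryStats(med.trait_name, med.trait_type,
                           rec[keep].reset_index(drop=True))
    mo, _, _ = mr_analysis(med, outcome_gwas, ld, p_thresh=p_thresh,
                           seed=seed)
    if primary is not None:
        eo = primary
    else:
        eo, _, _ = mr_analysis(protein_pqtl, outcome_gwas, ld,
                               p_thresh=p_thresh, seed=seed)
    return em, mo, eo


def mediate(protein_pqtl: SummaryStats, mediator_gwas: SummaryStats,
            outcome_gwas: SummaryStats, ld: LDMatrix,
            exclude_region: tuple | None = None, p_thresh: float = 5e-8,
            seed: int = 0,
            primary: MREstimate | None = None) -> MediationResult | None:
    """Full mediation decomposition; None when any leg lacks instruments."""
    em, mo, eo = two_step_effects(protein_pqtl, mediator_gwas, outcome_gwas,
                                  ld, exclude_region, p_thresh, seed, primary)
    if em is None or mo is None or eo is None:
        return None
    b_ind, se_ind, ci_ind = indirect_effect(em.beta, em.se, mo.beta, mo.se)
    prop, se_prop, ci_prop, unstable = proportion_mediated(
        b_ind, se_ind, eo.beta, eo.se)
    return MediationResult(
        beta_total=eo.beta, se_total=eo.se,
        beta_em=em.beta, se_em=em.se,
        beta_mo=mo.beta, se_mo=mo.se,
        beta_indirect=b_ind, se_indirect=se_ind, ci_indirect=ci_ind,
        proportion_mediated=prop, se_proportion=se_prop,
        ci_proportion=ci_prop, unstable=unstable)
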