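"""Two-sample Mendelian randomization from harmonized summary statistics.

Instrument selection is greedy LD clumping of genome-wide-significant
exposure variants (p < 5e-8, r² < 0.1 within a 10 000 kb window).  The
primary estimator is fixed-effect IVW (Wald ratio for a single
instrument); the sensitivity suite covers the weighted median, MR-Egger
regression, Cochran's Q heterogeneity, MR-PRESSO global/outlier tests and
leave-one-out analysis.  Ratio SEs are first-order (exposure uncertainty
ignored), the most common convention; effects on binary outcomes are
log-odds, reported as OR with 95% CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import LDMatrix, SummaryStats, harmonize, pvalue_from_z

logger = logging.getLogger(__name__)

Z95 = 1.959964


@dataclass
class MREstimate:
    """One causal-effect estimate (log-odds scale for binary outcomes)."""

    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    or_point: float = field(init=False)
    ci95: tuple = field(init=False)

    def __post_init__(self) -> None:
        self.or_point, self.ci95 = to_odds_ratio(self.beta, self.se)


@dataclass
class SensitivityReport:
    """Heterogeneity / pleiotropy / outlier diagnostics for one MR."""

    q_stat: float = float("nan")
    q_df: int = 0
    q_p: float = float("nan")
    egger: MREstimate | None = None
    egger_intercept: float = float("nan")
    egger_intercept_p: float = float("nan")
    weighted_median: MREstimate | None = None
    presso_global_p: float = float("nan")
    presso_outliers: list = field(default_factory=list)
    presso_corrected: MREstimate | None = None
    loo: pd.DataFrame | None = field(default=None, repr=False)
    loo_range: tuple = (float("nan"), float("nan"))
    notes: list = field(default_factory=list)


def to_odds_ratio(beta: float, se: float):
    """OR = exp(beta) with the log-symmetric 95% CI exp(beta ± 1.96 se)."""
    if se < 0:
        raise ValueError("se must be >= 0")
    return float(np.exp(beta)), (float(np.exp(beta - Z95 * se)),
                                 float(np.exp(beta + Z95 * se)))


def select_instruments(exposure: SummaryStats, ld: LDMatrix,
                       p_thresh: float = 5e-8, r2_thresh: float = 0.1,
                       window_kb: float = 10_000) -> list:
    """Greedy LD clumping: rank passing variants by recomputed p
    ascending, accept the best, discard unaccepted variants within the
    window whose r² with an accepted variant reaches the threshold.

    Returns the accepted variant IDs in acceptance order (empty list, with
    a warning, when nothing reaches ``p_thresh``).  Variants absent from
    the LD reference are treated as unlinked.
    """
    rec = exposure.records
    finite = np.isfinite(rec["se"]) & (rec["se"] > 0)
    rec = rec[finite]
    p = pvalue_from_z((rec["beta"] / rec["se"]).to_numpy()) if len(rec) else np.array([])
    passing = rec[p < p_thresh].assign(p_recomputed=p[p < p_thresh])
    if passing.empty:
        logger.warning("select_instruments(%s): no variant passes p < %g",
                       exposure.trait_name, p_thresh)
        return []
    passing = passing.sort_values(["p_recomputed", "variant_id"],
                                  kind="stable")
    in_ld = {v: i for i, v in enumerate(ld.variant_ids)}
    window = window_kb * 1_000
    accepted: list = []
    live = passing[["variant_id", "chromosome", "position"]].to_numpy()
    alive = np.ones(len(live), dtype=bool)
    for i in range(len(live)):
        if not alive[i]:
            continue
        vid, chrom, pos = live[i]
        accepted.append(vid)
        for j in range(i + 1, len(live)):
            if not alive[j]:
                continue
            vj, cj, pj = live[j]
            if cj != chrom or abs(int(pj) - int(pos)) > window:
                continue
            if vid in in_ld and vj in in_ld:
                r = ld.r[in_ld[vid], in_ld[vj]]
                if r * r >= r2_thresh:
                    alive[j] = False
    return accepted


def instrument_table(exposure: SummaryStats, outcome: SummaryStats,
                     ld: LDMatrix, p_thresh: float = 5e-8,
                     r2_thresh: float = 0.1, window_kb: float = 10_000,
                     af_ambiguity=(0.42, 0.58)) -> pd.DataFrame:
    """Clump the exposure, then harmonize the selected instruments with
    the outcome.  Rows: VariantKey columns + beta/se/eaf per side."""
    selected = select_instruments(exposure, ld, p_thresh, r2_thresh, window_kb)
    if not selected:
        return pd.DataFrame(columns=["variant_id", "beta_exposure",
                                     "se_exposure", "beta_outcome",
                                     "se_outcome"])
    sub = SummaryStats(exposure.trait_name, exposure.trait_type,
                       exposure.records[exposure.records["variant_id"]
                                        .isin(selected)].reset_index(drop=True))
    paired, _ = harmonize(sub, outcome, af_ambiguity)
    return paired


# ---------------------------------------------------------------------------
# estimators

def wald_ratio(row) -> MREstimate:
    """Single-instrument ratio: beta_outcome / beta_exposure with the
    first-order SE se_outcome / |beta_exposure|."""
    bx = float(row["beta_exposure"])
    by = float(row["beta_outcome"])
    sey = float(row["se_outcome"])
    if bx == 0:
        raise ValueError("wald_ratio undefined for beta_exposure = 0")
    beta = by / bx
    se = sey / abs(bx)
    return MREstimate("wald", beta, se, pvalue_from_z(beta / se), 1)


def ivw(table: pd.DataFrame) -> MREstimate:
    """Fixed-effect inverse-variance-weighted estimate (regression of
    outcome on exposure betas through the origin, weights 1/se_outcome²).
    Delegates to the Wald ratio with a single instrument."""
    if len(table) == 0:
        raise ValueError("ivw needs at least one instrument")
    if len(table) == 1:
        est = wald_ratio(table.iloc[0])
        return MREstimate("ivw", est.beta, est.se, est.p, 1)
    bx = table["beta_exposure"].to_numpy(dtype=float)
    by = table["beta_outcome"].to_numpy(dtype=float)
    sey = table["se_outcome"].to_numpy(dtype=float)
    w = bx ** 2 / sey ** 2
    beta = float((bx * by / sey ** 2).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    return MREstimate("ivw", beta, se, pvalue_from_z(beta / se), len(table))


def weighted_median(table: pd.DataFrame, n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Weighted median of the per-variant ratio estimates.

    Weights are proportional to bx²/sey² (inverse ratio variance,
    first-order).  The estimate is the first order statistic whose
    normalized cumulative weight reaches one half; when the cumulative
    weight lands exactly on 0.5 the two adjacent order statistics are
    averaged.  The SE comes from a parametric bootstrap (resampling both
    sides' betas from their sampling distributions, weights held fixed).
    """
    if len(table) < 3:
        raise ValueError("weighted_median needs >= 3 instruments")
    bx = table["beta_exposure"].to_numpy(dtype=float)
    by = table["beta_outcome"].to_numpy(dtype=float)
    sex = table.get("se_exposure", pd.Series(np.zeros(len(table)))).to_numpy(dtype=float)
    sey = table["se_outcome"].to_numpy(dtype=float)
    w = bx ** 2 / sey ** 2
    w = w / w.sum()
    beta = _weighted_median_point(by / bx, w)
    rng = np.random.default_rng(seed)
    bx_b = bx + rng.standard_normal((n_boot, bx.size)) * np.nan_to_num(sex)
    by_b = by + rng.standard_normal((n_boot, by.size)) * sey
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = by_b / bx_b
    boots = np.array([_weighted_median_point(r, w) for r in ratios])
    se = float(boots.std(ddof=1))
    return MREstimate("weighted_median", float(beta), se,
                      pvalue_from_z(beta / se) if se > 0 else 1.0, len(table))


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    cum = np.cumsum(weights[order])
    j = int(np.searchsorted(cum, 0.5))
    if j + 1 < r.size and abs(cum[j] - 0.5) < 1e-12:
        return 0.5 * (r[j] + r[j + 1])
    return float(r[j])


def mr_egger(table: pd.DataFrame):
    """MR-Egger: weighted regression of outcome on exposure betas with a
    free intercept, all exposure betas oriented non-negative first.

    Returns ``(slope_estimate, intercept, intercept_p)``.  The intercept
    tests directional pleiotropy.  SEs are residual-scaled WLS with
    t-distribution p-values (n - 2 df).
    """
    if len(table) < 3:
        raise ValueError("mr_egger needs >= 3 instruments")
    bx = table["beta_exposure"].to_numpy(dtype=float)
    by = table["beta_outcome"].to_numpy(dtype=float)
    sey = table["se_outcome"].to_numpy(dtype=float)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.ptp(bx) == 0:
        raise ValueError("mr_egger intercept unidentifiable: no spread in "
                         "exposure betas after orientation")
    w = 1.0 / sey ** 2
    x = np.column_stack([np.ones_like(bx), bx])
    xtwx = x.T @ (x * w[:, None])
    coef = np.linalg.solve(xtwx, x.T @ (w * by))
    resid = by - x @ coef
    dof = len(bx) - 2
    sigma2 = float((w * resid ** 2).sum() / dof)
    cov = np.linalg.inv(xtwx) * sigma2
    se = np.sqrt(np.diag(cov))
    t_int, t_slope = coef / se
    p_slope = float(2 * stats.t.sf(abs(t_slope), dof))
    p_int = float(2 * stats.t.sf(abs(t_int), dof))
    slope = MREstimate("egger_slope", float(coef[1]), float(se[1]), p_slope,
                       len(bx))
    return slope, float(coef[0]), p_int


def cochran_q(table: pd.DataFrame, ivw_beta: float):
    """Cochran's Q over per-variant ratio estimates around the IVW mean,
    chi-square with n_snps - 1 df."""
    if len(table) < 2:
        raise ValueError("cochran_q needs >= 2 instruments")
    bx = table["beta_exposure"].to_numpy(dtype=float)
    by = table["beta_outcome"].to_numpy(dtype=float)
    sey = table["se_outcome"].to_numpy(dtype=float)
    ratios = by / bx
    w = bx ** 2 / sey ** 2
    q = float((w * (ratios - ivw_beta) ** 2).sum())
    df = len(table) - 1
    return q, df, float(stats.chi2.sf(q, df))


def _loo_betas(bx, by, sey):
    """Leave-one-out IVW betas, vectorized."""
    w = bx ** 2 / sey ** 2
    s_num, s_den = (bx * by / sey ** 2).sum(), w.sum()
    return (s_num - bx * by / sey ** 2) / (s_den - w)


def mr_presso(table: pd.DataFrame, n_sim: int = 1000, seed: int = 0,
              outlier_alpha: float = 0.05):
    """MR-PRESSO global and outlier tests.

    The observed statistic is the weighted leave-one-out residual sum of
    squares; its null distribution comes from data simulated under the
    no-pleiotropy model (outcome betas drawn around the leave-one-out IVW
    predictions, exposure betas around their observed values).  Per-variant
    outlier p-values use the analogous single-variant comparison with a
    Bonferroni threshold; outliers are removed and IVW re-run as the
    corrected estimate.  With fewer than 4 instruments only the global
    test is performed.

    Returns ``(global_p, outliers, corrected_estimate_or_None)``.
    """
    if len(table) < 3:
        raise ValueError("mr_presso needs >= 3 instruments")
    bx = table["beta_exposure"].to_numpy(dtype=float)
    by = table["beta_outcome"].to_numpy(dtype=float)
    sex = np.nan_to_num(
        table.get("se_exposure", pd.Series(np.zeros(len(table)))).to_numpy(dtype=float))
    sey = table["se_outcome"].to_numpy(dtype=float)
    n = len(bx)

    loo = _loo_betas(bx, by, sey)
    resid2_obs = ((by - loo * bx) / sey) ** 2
    rss_obs = float(resid2_obs.sum())

    rng = np.random.default_rng(seed)
    bx_s = bx + rng.standard_normal((n_sim, n)) * sex
    by_s = loo * bx + rng.standard_normal((n_sim, n)) * sey
    w_s = bx_s ** 2 / sey ** 2
    num_s = (bx_s * by_s / sey ** 2)
    loo_s = (num_s.sum(axis=1, keepdims=True) - num_s) / (
        w_s.sum(axis=1, keepdims=True) - w_s)
    resid2_s = ((by_s - loo_s * bx_s) / sey) ** 2
    rss_s = resid2_s.sum(axis=1)
    global_p = float((1 + (rss_s >= rss_obs).sum()) / (n_sim + 1))

    outliers: list = []
    corrected = None
    if n >= 4:
        p_var = (1 + (resid2_s >= resid2_obs).sum(axis=0)) / (n_sim + 1)
        mask = p_var < outlier_alpha / n
        outliers = list(table["variant_id"].to_numpy()[mask])
        if outliers and (~mask).sum() >= 2:
            corrected = ivw(table[~mask])
            corrected.method = "ivw_presso_corrected"
    return global_p, outliers, corrected


def leave_one_out(table: pd.DataFrame):
    """IVW re-estimated dropping each instrument in turn.

    Returns ``(DataFrame(variant_id, beta, se), (min_beta, max_beta))``.
    """
    if len(table) < 3:
        raise ValueError("leave_one_out needs >= 3 instruments")
    rows = []
    for i in range(len(table)):
        est = ivw(table.drop(table.index[i]))
        rows.append({"variant_id": table["variant_id"].iloc[i],
                     "beta": est.beta, "se": est.se})
    df = pd.DataFrame(rows)
    return df, (float(df["beta"].min()), float(df["beta"].max()))


# ---------------------------------------------------------------------------
# one-call analysis

def mr_analysis(exposure: SummaryStats, outcome: SummaryStats, ld: LDMatrix,
                p_thresh: float = 5e-8, r2_thresh: float = 0.1,
                window_kb: float = 10_000, n_boot: int = 1000,
                n_sim: int = 1000, seed: int = 0):
    """Full two-sample MR of one exposure on one outcome.

    Returns ``(primary_estimate, sensitivity_report, instrument_table)``;
    the primary is IVW (Wald ratio when a single instrument survives) or
    ``None`` when no instruments survive selection/harmonization.
    """
    table = instrument_table(exposure, outcome, ld, p_thresh, r2_thresh,
                             window_kb)
    report = SensitivityReport()
    if len(table) == 0:
        report.notes.append("no instruments")
        return None, report, table
    primary = ivw(table)
    if len(table) >= 2:
        report.q_stat, report.q_df, report.q_p = cochran_q(table, primary.beta)
    if len(table) >= 3:
        report.weighted_median = weighted_median(table, n_boot=n_boot,
                                                 seed=seed)
        try:
            report.egger, report.egger_intercept, report.egger_intercept_p = \
                mr_egger(table)
        except ValueError as exc:
            report.notes.append(str(exc))
        (report.presso_global_p, report.presso_outliers,
         report.presso_corrected) = mr_presso(table, n_sim=n_sim, seed=seed)
        report.loo, report.loo_range = leave_one_out(table)
    else:
        report.notes.append("sensitivity suite needs >= 3 instruments")
    return primary, report, table
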