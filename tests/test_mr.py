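"""Two-sample MR: clumping, estimators, sensitivity suite."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ciswas.mr import (cochran_q, ivw, leave_one_out, mr_egger, mr_presso,
                       select_instruments, to_odds_ratio, wald_ratio,
                       weighted_median, _weighted_median_point)
from ciswas.sumstats_io import LDMatrix, SummaryStats


def _exposure(betas, ses, positions=None, chromosome="1"):
    n = len(betas)
    positions = positions if positions is not None else 1000 * (np.arange(n) + 1)
    df = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(n)],
        "chromosome": chromosome,
        "position": positions,
        "effect_allele": "A", "other_allele": "G",
        "eaf": 0.3, "beta": betas, "se": ses,
        "p": np.nan, "n": 10_000.0, "n_cases": np.nan,
    })
    return SummaryStats("exposure", "quantitative", df)


def _table(bx, by, sey, sex=None):
    return pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(len(bx))],
        "beta_exposure": bx,
        "se_exposure": sex if sex is not None else np.full(len(bx), 0.01),
        "beta_outcome": by,
        "se_outcome": sey,
    })


class TestClumping:
    def test_greedy_keeps_best_of_a_correlated_pair(self):
        exp = _exposure([0.5, 0.45], [0.5 / 6.5, 0.45 / 6.1])
        r = np.sqrt(0.5)
        ld = LDMatrix(["v0", "v1"], np.array([[1, r], [r, 1]]))
        assert select_instruments(exp, ld) == ["v0"]

    def test_window_rule_keeps_distant_correlated_pair(self):
        exp = _exposure([0.5, 0.45], [0.5 / 6.5, 0.45 / 6.1],
                        positions=[1, 20_000_001])
        r = np.sqrt(0.9)
        ld = LDMatrix(["v0", "v1"], np.array([[1, r], [r, 1]]))
        assert select_instruments(exp, ld) == ["v0", "v1"]

    def test_no_passing_variant_gives_empty_table(self):
        exp = _exposure([0.01], [0.01])
        assert select_instruments(exp, LDMatrix(["v0"], np.eye(1))) == []

    def test_matches_brute_force_oracle_on_random_locus(self):
        rng = np.random.default_rng(14)
        n = 50
        a = rng.standard_normal((200, n))
        for j in range(1, n):  # induce LD
            a[:, j] = 0.6 * a[:, j - 1] + 0.8 * a[:, j]
        r = np.corrcoef(a, rowvar=False)
        ld = LDMatrix([f"v{i}" for i in range(n)], r)
        z = rng.uniform(4, 12, n) * rng.choice([-1, 1], n)
        exp = _exposure(z * 0.01, np.full(n, 0.01),
                        positions=5000 * (np.arange(n) + 1))
        got = select_instruments(exp, ld, p_thresh=1e-5, r2_thresh=0.1,
                                 window_kb=10_000)
        # independent re-implementation: explicit candidate list with
        # all-pairs elimination
        rec = exp.records.assign(absz=np.abs(z)).sort_values(
            ["absz", "variant_id"], ascending=[False, True], kind="stable")
        rec = rec[2 * 0.5 * np.ones(len(rec)) > 0]  # keep frame shape
        from scipy.stats import norm
        rec = rec[2 * norm.sf(rec["absz"]) < 1e-5]
        idx = {f"v{i}": i for i in range(n)}
        expected, removed = [], set()
        for row in rec.itertuples():
            if row.variant_id in removed:
                continue
            expected.append(row.variant_id)
            for other in rec["variant_id"]:
                if other in removed or other == row.variant_id:
                    continue
                d = abs(rec.set_index("variant_id").loc[other, "position"]
                        - row.position)
                if d <= 1e7 and r[idx[row.variant_id], idx[other]] ** 2 >= 0.1:
                    removed.add(other)
        assert got == expected


class TestWaldAndIVW:
    def test_wald_arithmetic(self):
        est = wald_ratio(pd.Series({"beta_exposure": 0.1,
                                    "beta_outcome": 0.05,
                                    "se_outcome": 0.01}))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_wald_zero_outcome(self):
        est = wald_ratio(pd.Series({"beta_exposure": 0.1, "beta_outcome": 0.0,
                                    "se_outcome": 0.01}))
        assert est.beta == 0.0

    def test_wald_rejects_zero_exposure(self):
        with pytest.raises(ValueError):
            wald_ratio(pd.Series({"beta_exposure": 0.0, "beta_outcome": 0.1,
                                  "se_outcome": 0.01}))

    def test_first_order_se_close_to_second_order_for_strong_instrument(self):
        # strong instrument (|bx|/sex > 10) with outcome-side noise
        # dominating the ratio: the ignored exposure-uncertainty term of
        # the delta expansion is then a < 10% correction
        rng = np.random.default_rng(15)
        for _ in range(10):
            bx = rng.uniform(0.2, 0.6)
            sex = bx / rng.uniform(15, 30)
            by, sey = rng.normal(0.0, 0.02), rng.uniform(0.02, 0.05)
            est = wald_ratio(pd.Series({"beta_exposure": bx,
                                        "beta_outcome": by,
                                        "se_outcome": sey}))
            # second-order delta expansion of var(by/bx)
            se2 = np.sqrt(sey ** 2 / bx ** 2 + by ** 2 * sex ** 2 / bx ** 4)
            assert est.se == pytest.approx(se2, rel=0.10)

    def test_single_row_ivw_equals_wald_exactly(self):
        t = _table([0.3], [0.12], [0.02])
        assert ivw(t).beta == wald_ratio(t.iloc[0]).beta
        assert ivw(t).se == wald_ratio(t.iloc[0]).se

    def test_two_identical_rows(self):
        est = ivw(_table([1.0, 1.0], [0.5, 0.5], [1.0, 1.0]))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(1 / np.sqrt(2))

    def test_matches_wls_through_origin_oracle(self):
        rng = np.random.default_rng(16)
        bx = rng.uniform(0.1, 0.5, 12)
        by = 0.3 * bx + rng.normal(0, 0.02, 12)
        sey = rng.uniform(0.01, 0.05, 12)
        est = ivw(_table(bx, by, sey))
        fit = sm.WLS(by, bx, weights=1 / sey ** 2).fit()
        assert est.beta == pytest.approx(fit.params[0], abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(17)
        t = _table(rng.uniform(0.1, 0.5, 8), rng.normal(0, 0.1, 8),
                   rng.uniform(0.01, 0.05, 8))
        perm = t.sample(frac=1, random_state=3).reset_index(drop=True)
        assert ivw(t).beta == pytest.approx(ivw(perm).beta, rel=1e-12)

    def test_flipping_exposure_orientation_flips_beta_and_inverts_or(self):
        rng = np.random.default_rng(18)
        t = _table(rng.uniform(0.1, 0.5, 6), rng.normal(0.1, 0.05, 6),
                   rng.uniform(0.01, 0.05, 6))
        flipped = t.assign(beta_exposure=-t["beta_exposure"],
                           beta_outcome=-t["beta_outcome"])
        # flipping the effect allele flips both betas; the ratio estimate
        # of the *exposure* effect flips sign only via the exposure scale
        e1, e2 = ivw(t), ivw(flipped)
        assert e2.beta == pytest.approx(e1.beta, rel=1e-12)
        t_only_exp = t.assign(beta_exposure=-t["beta_exposure"])
        e3 = ivw(t_only_exp)
        assert e3.beta == pytest.approx(-e1.beta, rel=1e-12)
        assert e3.or_point == pytest.approx(1 / e1.or_point, rel=1e-12)


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        t = _table([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert weighted_median(t, n_boot=50, seed=1).beta == pytest.approx(2.0)

    def test_cumulative_weight_crossing_at_first_order_statistic(self):
        # weights 0.6/0.2/0.2 on ratios 1/2/3: the cumulative weight
        # reaches one half inside the first order statistic
        sey = 1.0 / np.sqrt(np.array([0.6, 0.2, 0.2]))
        t = _table([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], sey)
        assert weighted_median(t, n_boot=50, seed=1).beta == pytest.approx(1.0)

    def test_exact_boundary_averages_adjacent_order_statistics(self):
        assert _weighted_median_point(np.array([1.0, 3.0, 10.0]),
                                      np.array([0.25, 0.25, 0.5])) == 6.5

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            ratios = rng.normal(0, 1, 9)
            w = rng.uniform(0.1, 1, 9)
            w = w / w.sum()
            got = _weighted_median_point(ratios, w)
            # oracle: explicit scan of the sorted cumulative weights
            order = np.argsort(ratios)
            cum = 0.0
            expected = None
            for k, j in enumerate(order):
                cum += w[j]
                if cum >= 0.5:
                    if abs(cum - 0.5) < 1e-12 and k + 1 < 9:
                        expected = 0.5 * (ratios[j] + ratios[order[k + 1]])
                    else:
                        expected = ratios[j]
                    break
            assert got == pytest.approx(expected, abs=0.0)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            weighted_median(_table([1, 1], [1, 2], [1, 1]))

    def test_robust_to_minority_pleiotropy_where_ivw_is_biased(self):
        rng = np.random.default_rng(20)
        med_err, ivw_err = [], []
        for s in range(25):
            r = np.random.default_rng(1000 + s)
            bx = r.uniform(0.2, 0.5, 14)
            sey = np.full(14, 0.02)
            by = 0.3 * bx + r.normal(0, 1, 14) * sey
            by[10:] += 0.5  # 4 of 14 pleiotropic instruments
            t = _table(bx, by, sey)
            med_err.append(weighted_median(t, n_boot=100, seed=s).beta - 0.3)
            ivw_err.append(ivw(t).beta - 0.3)
        assert abs(np.mean(med_err)) < 0.1
        assert np.mean(ivw_err) > np.mean(med_err) + 0.1


class TestEgger:
    def test_matches_statsmodels_wls_oracle(self):
        rng = np.random.default_rng(21)
        bx = rng.uniform(0.1, 0.6, 15)
        sey = rng.uniform(0.01, 0.05, 15)
        by = 0.05 + 0.3 * bx + rng.normal(0, 1, 15) * sey
        slope, intercept, intercept_p = mr_egger(_table(bx, by, sey))
        fit = sm.WLS(by, sm.add_constant(bx), weights=1 / sey ** 2).fit()
        assert slope.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert slope.se == pytest.approx(fit.bse[1], abs=1e-10)
        assert intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert intercept_p == pytest.approx(fit.pvalues[0], abs=1e-10)

    def test_no_pleiotropy_slope_close_to_ivw(self):
        rng = np.random.default_rng(22)
        bx = rng.uniform(0.1, 0.6, 50)
        sey = np.full(50, 0.02)
        by = 0.3 * bx + rng.normal(0, 1, 50) * sey
        t = _table(bx, by, sey)
        slope, intercept, _ = mr_egger(t)
        assert slope.beta == pytest.approx(ivw(t).beta, abs=3 * slope.se)
        assert abs(intercept) < 0.02

    def test_constant_pleiotropy_lands_in_the_intercept(self):
        rng = np.random.default_rng(23)
        bx = rng.uniform(0.1, 0.6, 50)
        sey = np.full(50, 0.02)
        by = 0.1 + 0.3 * bx + rng.normal(0, 1, 50) * sey
        slope, intercept, intercept_p = mr_egger(_table(bx, by, sey))
        assert intercept == pytest.approx(0.1, abs=0.03)
        assert slope.beta == pytest.approx(0.3, abs=0.1)
        assert intercept_p < 0.01

    def test_orientation_forces_nonnegative_exposure_betas(self):
        rng = np.random.default_rng(24)
        bx = rng.uniform(0.1, 0.6, 20) * rng.choice([-1, 1], 20)
        sey = np.full(20, 0.02)
        by = 0.3 * bx + rng.normal(0, 1, 20) * sey
        flipped = _table(np.abs(bx), by * np.sign(bx), sey)
        s1, i1, _ = mr_egger(_table(bx, by, sey))
        s2, i2, _ = mr_egger(flipped)
        assert s1.beta == pytest.approx(s2.beta, rel=1e-12)
        assert i1 == pytest.approx(i2, rel=1e-12)

    def test_two_rows_rejected(self):
        with pytest.raises(ValueError):
            mr_egger(_table([0.1, 0.2], [0.05, 0.04], [0.01, 0.01]))


class TestCochranQ:
    def test_identical_ratios_give_zero_q(self):
        t = _table([0.2, 0.4, 0.1], [0.1, 0.2, 0.05], [0.02, 0.02, 0.02])
        q, df, p = cochran_q(t, ivw(t).beta)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2 and p == pytest.approx(1.0)

    def test_three_row_hand_summation(self):
        bx = np.array([0.2, 0.3, 0.5])
        by = np.array([0.08, 0.15, 0.2])
        sey = np.array([0.02, 0.03, 0.04])
        t = _table(bx, by, sey)
        b = ivw(t).beta
        expected = sum((bx[i] ** 2 / sey[i] ** 2)
                       * (by[i] / bx[i] - b) ** 2 for i in range(3))
        q, df, _ = cochran_q(t, b)
        assert q == pytest.approx(expected, abs=1e-12)

    def test_chi_square_calibration_of_q_over_df(self):
        rng = np.random.default_rng(25)
        ratios = []
        for _ in range(100):
            bx = rng.uniform(0.2, 0.6, 10)
            sey = rng.uniform(0.01, 0.03, 10)
            by = 0.25 * bx + rng.normal(0, 1, 10) * sey
            t = _table(bx, by, sey)
            q, df, _ = cochran_q(t, ivw(t).beta)
            ratios.append(q / df)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)


class TestPresso:
    @staticmethod
    def _spiked(seed):
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.2, 0.6, 10)
        sey = np.full(10, 0.02)
        by = 0.3 * bx + rng.normal(0, 1, 10) * sey
        clean = _table(bx, by.copy(), sey)
        by[3] += 5 * sey[3]
        return clean, _table(bx, by, sey)

    def test_spiked_instrument_flagged(self):
        found = 0
        for s in range(25):
            _, spiked = self._spiked(3000 + s)
            _, outliers, _ = mr_presso(spiked, n_sim=600, seed=s)
            found += "v3" in outliers
        assert found >= 22  # >= ~90% detection

    def test_corrected_estimate_recovers_clean_ivw(self):
        agree = 0
        for s in range(25):
            clean, spiked = self._spiked(4000 + s)
            _, outliers, corrected = mr_presso(spiked, n_sim=600, seed=s)
            if corrected is None:
                continue
            ref = ivw(clean)
            agree += abs(corrected.beta - ref.beta) <= ref.se
        assert agree >= 20

    def test_global_p_deterministic_under_seed(self):
        _, spiked = self._spiked(5)
        p1, o1, _ = mr_presso(spiked, n_sim=500, seed=9)
        p2, o2, _ = mr_presso(spiked, n_sim=500, seed=9)
        assert p1 == p2 and o1 == o2

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            mr_presso(_table([0.1, 0.2], [0.05, 0.04], [0.01, 0.01]))


class TestLeaveOneOut:
    def test_identical_rows_leave_estimate_unchanged(self):
        t = _table([0.3, 0.3, 0.3], [0.15, 0.15, 0.15], [0.02, 0.02, 0.02])
        df, (lo, hi) = leave_one_out(t)
        full = ivw(t).beta
        assert np.allclose(df["beta"], full)
        assert lo == pytest.approx(full) and hi == pytest.approx(full)

    def test_returns_one_estimate_per_instrument(self):
        rng = np.random.default_rng(26)
        t = _table(rng.uniform(0.2, 0.5, 7), rng.normal(0.1, 0.02, 7),
                   rng.uniform(0.01, 0.03, 7))
        df, rng_ = leave_one_out(t)
        assert len(df) == 7
        assert rng_[0] <= rng_[1]

    def test_dropping_the_spiked_variant_moves_the_estimate_most(self):
        _, spiked = TestPresso._spiked(77)
        df, _ = leave_one_out(spiked)
        full = ivw(spiked).beta
        moves = np.abs(df["beta"] - full)
        assert df.loc[moves.idxmax(), "variant_id"] == "v3"


class TestOddsRatio:
    def test_null_beta(self):
        or_, (lo, hi) = to_odds_ratio(0.0, 0.1)
        assert or_ == 1.0
        assert lo == pytest.approx(np.exp(-1.959964 * 0.1))
        assert hi == pytest.approx(np.exp(1.959964 * 0.1))

    def test_published_interval_round_trip(self):
        # printed OR 1.23 with 95% CI [1.15, 1.31] is log-symmetric
        or_, (lo, hi) = to_odds_ratio(np.log(1.23), 0.0332)
        assert or_ == pytest.approx(1.23, abs=0.005)
        assert lo == pytest.approx(1.15, abs=0.005)
        assert hi == pytest.approx(1.31, abs=0.005)

    def test_monotone_in_beta(self):
        rows = [to_odds_ratio(b, 0.1) for b in (-0.5, 0.0, 0.5, 1.0)]
        ors = [r[0] for r in rows]
        assert ors == sorted(ors) and len(set(ors)) == 4
        assert [r[1][0] for r in rows] == sorted(r[1][0] for r in rows)
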