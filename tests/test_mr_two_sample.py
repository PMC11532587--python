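"""Two-sample MR: harmonization, the five estimators, and the validity tests."""

import numpy as np
import pandas as pd
import pytest

from smokemr import (
    SimulationConfig,
    cochran_q,
    harmonize,
    ivw_fixed,
    max_likelihood,
    mr_egger,
    mr_presso,
    simulate_summary_stats,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from smokemr.mr_two_sample import _ml_loglik


def _table(snp, ea, oa, eaf, beta, se=0.01):
    return pd.DataFrame(
        {
            "snp": [snp],
            "effect_allele": [ea],
            "other_allele": [oa],
            "eaf": [eaf],
            "beta": [beta],
            "se": [se],
            "pval": [1e-10],
        }
    )


class TestHarmonize:
    def test_swapped_alleles_flip_sign(self):
        ex = _table("rs1", "A", "G", 0.3, 0.1)
        out = _table("rs1", "G", "A", 0.7, -0.05, se=0.02)
        h = harmonize(ex, out)
        assert h["beta_out"].iloc[0] == pytest.approx(0.05)

    def test_ambiguous_palindromic_dropped(self):
        ex = _table("rs1", "A", "T", 0.50, 0.1)
        out = _table("rs1", "A", "T", 0.50, 0.05)
        assert len(harmonize(ex, out)) == 0

    def test_mismatched_alleles_dropped(self):
        ex = _table("rs1", "A", "G", 0.3, 0.1)
        out = _table("rs1", "A", "C", 0.3, 0.05)
        assert len(harmonize(ex, out)) == 0

    def test_planted_swaps_round_trip(self):
        """Randomly recoding 10% of outcome records (swap alleles, negate
        beta, complement eaf) leaves the harmonized table identical."""
        cfg = SimulationConfig(n_individuals=500, gwas_n_individuals=4000, seed=19)
        ex, out = simulate_summary_stats(cfg, 1, 2)
        clean = harmonize(ex, out)
        rng = np.random.default_rng(0)
        swapped = out.copy()
        flip = rng.random(len(out)) < 0.1
        swapped.loc[flip, ["effect_allele", "other_allele"]] = (
            swapped.loc[flip, ["other_allele", "effect_allele"]].to_numpy()
        )
        swapped.loc[flip, "beta"] = -swapped.loc[flip, "beta"]
        swapped.loc[flip, "eaf"] = 1.0 - swapped.loc[flip, "eaf"]
        redone = harmonize(ex, swapped)
        pd.testing.assert_frame_equal(clean, redone)


class TestWaldRatio:
    @pytest.mark.parametrize(
        "beta_out,beta_exp,se_out,est,se",
        [(0.05, 0.1, 0.02, 0.5, 0.2), (0.0, 0.1, 0.02, 0.0, 0.2),
         (0.05, -0.1, 0.02, -0.5, 0.2)],
    )
    def test_arithmetic(self, beta_out, beta_exp, se_out, est, se):
        row = {"beta_exp": beta_exp, "beta_out": beta_out, "se_out": se_out}
        e = wald_ratio(row)
        assert e.beta == pytest.approx(est)
        assert e.se == pytest.approx(se)

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio({"beta_exp": 0.0, "beta_out": 0.1, "se_out": 0.02})


class TestIvw:
    def test_single_snp_is_wald_ratio(self, toy_summary):
        one = toy_summary.iloc[:1]
        assert ivw_fixed(one).beta == pytest.approx(wald_ratio(one.iloc[0]).beta)
        assert ivw_fixed(one).se == pytest.approx(wald_ratio(one.iloc[0]).se)

    def test_replication_pools_precision(self, toy_summary):
        one = toy_summary.iloc[:1]
        four = pd.concat([one] * 4, ignore_index=True)
        four["snp"] = [f"c{i}" for i in range(4)]
        assert ivw_fixed(four).beta == pytest.approx(ivw_fixed(one).beta)
        assert ivw_fixed(four).se == pytest.approx(ivw_fixed(one).se / 2.0)

    def test_matches_wls_through_origin(self, toy_summary):
        """IVW equals weighted least squares of beta_out on beta_exp through
        the origin with weights se_out**-2."""
        bx = toy_summary["beta_exp"].to_numpy()
        by = toy_summary["beta_out"].to_numpy()
        w = toy_summary["se_out"].to_numpy() ** -2.0
        slope = np.sum(w * bx * by) / np.sum(w * bx * bx)
        se = np.sum(w * bx * bx) ** -0.5
        est = ivw_fixed(toy_summary)
        assert est.beta == pytest.approx(slope, abs=1e-10)
        assert est.se == pytest.approx(se, abs=1e-10)


class TestMaxLikelihood:
    def test_single_snp_equals_wald(self, toy_summary):
        one = toy_summary.iloc[:1]
        assert max_likelihood(one).beta == pytest.approx(
            wald_ratio(one.iloc[0]).beta, abs=1e-5
        )

    def test_close_to_ivw_with_valid_instruments(self, harmonized_null):
        ml = max_likelihood(harmonized_null)
        ivw = ivw_fixed(harmonized_null)
        assert abs(ml.beta - ivw.beta) < 0.01

    def test_optimum_beats_ivw_start(self, toy_summary):
        bx = toy_summary["beta_exp"].to_numpy()
        sx = toy_summary["se_exp"].to_numpy()
        by = toy_summary["beta_out"].to_numpy()
        sy = toy_summary["se_out"].to_numpy()
        ml = max_likelihood(toy_summary)
        assert _ml_loglik(ml.beta, bx, sx, by, sy) >= _ml_loglik(
            ivw_fixed(toy_summary).beta, bx, sx, by, sy
        )


class TestEgger:
    def test_insufficient_instruments(self, toy_summary):
        with pytest.raises(ValueError):
            mr_egger(toy_summary.iloc[:2])

    def test_planted_directional_pleiotropy_recovered(self):
        """Every SNP gets the same direct outcome effect c and no causal
        effect: the intercept estimates c and the slope CI covers 0 in most
        replicates."""
        rng = np.random.default_rng(23)
        c = 0.02
        hits_int, hits_slope = 0, 0
        reps = 60
        for _ in range(reps):
            m = 30
            bx = rng.uniform(0.05, 0.2, m)
            sx = np.full(m, 0.005)
            sy = np.full(m, 0.01)
            by = c + 0.0 * bx + rng.normal(0, sy)
            h = pd.DataFrame(
                {"snp": [f"r{i}" for i in range(m)], "beta_exp": bx, "se_exp": sx,
                 "beta_out": by, "se_out": sy, "eaf": 0.3, "palindromic": False}
            )
            slope, intercept = mr_egger(h)
            hits_int += abs(intercept["intercept"] - c) < 2 * intercept["se"]
            hits_slope += slope.covers(0.0)
        assert hits_int >= 0.9 * reps
        assert hits_slope >= 0.9 * reps


class TestWeightedMedian:
    def test_equal_weight_middle_element(self):
        h = pd.DataFrame(
            {
                "snp": ["a", "b", "c"],
                "beta_exp": [1.0, 1.0, 1.0],
                "se_exp": [0.01] * 3,
                "beta_out": [0.2, 0.5, 0.9],
                "se_out": [0.1] * 3,
                "eaf": 0.3,
                "palindromic": False,
            }
        )
        est = weighted_median(h, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.5)

    def test_degenerate_ratios_shrinking_se(self):
        h = pd.DataFrame(
            {
                "snp": ["a", "b", "c"],
                "beta_exp": [1.0, 2.0, 0.5],
                "se_exp": [1e-6] * 3,
                "beta_out": [0.3, 0.6, 0.15],
                "se_out": [1e-6, 2e-6, 0.5e-6],
                "eaf": 0.3,
                "palindromic": False,
            }
        )
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.3, abs=1e-4)
        assert est.se < 1e-4


class TestWeightedMode:
    def test_identical_ratios(self):
        h = pd.DataFrame(
            {
                "snp": ["a", "b", "c"],
                "beta_exp": [1.0, 2.0, 0.5],
                "se_exp": [0.01] * 3,
                "beta_out": [0.3, 0.6, 0.15],
                "se_out": [0.01] * 3,
                "eaf": 0.3,
                "palindromic": False,
            }
        )
        with pytest.warns(UserWarning, match="bandwidth"):
            est = weighted_mode(h, n_boot=20, seed=0)
        assert est.beta == pytest.approx(0.3, abs=1e-6)

    def test_majority_cluster_wins(self):
        rng = np.random.default_rng(29)
        m_valid, m_out = 14, 6
        bx = rng.uniform(0.08, 0.2, m_valid + m_out)
        sy = np.full(m_valid + m_out, 0.004)
        by = np.concatenate(
            [0.3 * bx[:m_valid], 3.0 * bx[m_valid:]]
        ) + rng.normal(0, sy)
        h = pd.DataFrame(
            {"snp": [f"r{i}" for i in range(m_valid + m_out)],
             "beta_exp": bx, "se_exp": 0.004, "beta_out": by, "se_out": sy,
             "eaf": 0.3, "palindromic": False}
        )
        est = weighted_mode(h, n_boot=50, seed=2)
        assert 0.1 < est.beta < 0.7  # in the valid cluster, far from 3.0

    def test_bandwidth_scaling_is_continuous(self):
        rng = np.random.default_rng(31)
        m = 10
        bx = rng.uniform(0.05, 0.2, m)
        by = 0.3 * bx + rng.normal(0, 0.01, m)
        h = pd.DataFrame(
            {"snp": [f"r{i}" for i in range(m)], "beta_exp": bx, "se_exp": 0.01,
             "beta_out": by, "se_out": 0.01, "eaf": 0.3, "palindromic": False}
        )
        theta = np.sort(by / bx)
        max_gap = np.max(np.diff(theta))
        prev = weighted_mode(h, bandwidth_factor=1.0, n_boot=10, seed=0).beta
        for phi in (1.2, 1.5, 1.8, 2.0):
            cur = weighted_mode(h, bandwidth_factor=phi, n_boot=10, seed=0).beta
            assert abs(cur - prev) <= max_gap + 1e-9
            prev = cur


class TestCochranQ:
    def test_no_dispersion(self):
        h = pd.DataFrame(
            {"snp": ["a", "b"], "beta_exp": [0.1, 0.2], "se_exp": [0.01, 0.01],
             "beta_out": [0.05, 0.10], "se_out": [0.02, 0.02],
             "eaf": 0.3, "palindromic": False}
        )
        q, df, p = cochran_q(h)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_single_snp_rejected(self, toy_summary):
        with pytest.raises(ValueError):
            cochran_q(toy_summary.iloc[:1])

    def test_planted_outlier_detected(self):
        rng = np.random.default_rng(37)
        rejections = 0
        reps = 30
        for _ in range(reps):
            m = 20
            bx = rng.uniform(0.08, 0.2, m)
            sy = np.full(m, 0.005)
            by = 0.3 * bx + rng.normal(0, sy)
            by[0] = 3.0 * bx[0]  # one wildly heterogeneous SNP
            h = pd.DataFrame(
                {"snp": [f"r{i}" for i in range(m)], "beta_exp": bx,
                 "se_exp": 0.005, "beta_out": by, "se_out": sy,
                 "eaf": 0.3, "palindromic": False}
            )
            rejections += cochran_q(h)[2] < 0.05
        assert rejections >= 0.8 * reps


class TestMrPresso:
    def test_minimum_instruments(self, toy_summary):
        with pytest.raises(ValueError):
            mr_presso(toy_summary.iloc[:3])

    def test_plus_one_rule_floor(self, toy_summary):
        out = mr_presso(toy_summary, n_sim=1000, seed=0)
        assert out["p_global"] >= 1.0 / 1001.0

    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(41)
        flagged = 0
        reps = 25
        for _ in range(reps):
            m = 20
            bx = rng.uniform(0.08, 0.2, m)
            sy = np.full(m, 0.005)
            by = 0.3 * bx + rng.normal(0, sy)
            by[3] = 3.0 * bx[3]  # ten-fold ratio
            h = pd.DataFrame(
                {"snp": [f"r{i}" for i in range(m)], "beta_exp": bx,
                 "se_exp": 0.005, "beta_out": by, "se_out": sy,
                 "eaf": 0.3, "palindromic": False}
            )
            out = mr_presso(h, n_sim=500, seed=int(rng.integers(1e6)))
            flagged += "r3" in out["outlier_ids"]
        assert flagged >= 0.8 * reps


class TestInvariances:
    def test_orientation_invariance(self):
        """Flipping a SNP's allele coding in both tables leaves every
        estimator unchanged."""
        cfg = SimulationConfig(n_individuals=500, gwas_n_individuals=4000, seed=43)
        ex, out = simulate_summary_stats(cfg, 5, 6)

        def flip(df, snps):
            df = df.copy()
            sel = df["snp"].isin(snps)
            df.loc[sel, ["effect_allele", "other_allele"]] = (
                df.loc[sel, ["other_allele", "effect_allele"]].to_numpy()
            )
            df.loc[sel, "beta"] = -df.loc[sel, "beta"]
            df.loc[sel, "eaf"] = 1.0 - df.loc[sel, "eaf"]
            return df

        snps = ex["snp"].iloc[::3].tolist()
        h1 = harmonize(ex, out)
        h2 = harmonize(flip(ex, snps), flip(out, snps))
        for fn in (ivw_fixed, max_likelihood):
            assert fn(h1).beta == pytest.approx(fn(h2).beta, abs=1e-10)
        assert mr_egger(h1)[0].beta == pytest.approx(mr_egger(h2)[0].beta, abs=1e-10)
        assert weighted_median(h1, 50, 0).beta == pytest.approx(
            weighted_median(h2, 50, 0).beta, abs=1e-10
        )

    def test_m1_collapse(self, toy_summary):
        one = toy_summary.iloc[:1]
        wald = wald_ratio(one.iloc[0]).beta
        assert ivw_fixed(one).beta == pytest.approx(wald)
        assert max_likelihood(one).beta == pytest.approx(wald, abs=1e-5)
        two = toy_summary.iloc[:2]
        # median of two equal-ratio rows collapses likewise when ratios match
        h = two.copy()
        h.loc[:, "beta_out"] = 0.5 * h["beta_exp"]
        assert weighted_median(h, 50, 0).beta == pytest.approx(0.5)
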