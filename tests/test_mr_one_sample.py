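"""One-sample MR: 2SLS, G-estimation, LACE, subgroups, sensitivity, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from smokemr import (
    InstrumentSet,
    SimulationConfig,
    g_estimation_logistic,
    lace_nonlinear,
    leave_one_out,
    mr_power,
    sensitivity_prs,
    simulate_minimal,
    subgroup_mr,
    tsls_logistic,
)
from smokemr.simcohort import GenotypeMatrix
from tests.conftest import minimal_cohort_frame


def _noiseless_iv_cohort(seed=0, n=30_000, theta=0.3):
    """Exposure exactly equals the instrument; rare outcome from θ·X."""
    rng = np.random.default_rng(seed)
    z = rng.normal(1.0, 0.5, n)
    x = z.copy()
    p = special.expit(-3.5 + theta * x)
    y = (rng.random(n) < p).astype(float)
    return pd.DataFrame({"ckd_event": y, "smoking_index": x}), z


class TestTsls:
    def test_noiseless_instrument_recovers_theta(self):
        cohort, z = _noiseless_iv_cohort()
        est = tsls_logistic(cohort, z, covariates=[], n_boot=200, seed=1)
        assert abs(est.beta - 0.3) < 2 * est.se

    def test_scale_invariance_of_prs(self):
        cohort, z = _noiseless_iv_cohort(seed=3, n=5000)
        a = tsls_logistic(cohort, z, covariates=[], se_method="analytic")
        b = tsls_logistic(cohort, 37.0 * z, covariates=[], se_method="analytic")
        assert a.beta == pytest.approx(b.beta, abs=1e-8)

    def test_constant_instrument_rejected(self):
        cohort, _ = _noiseless_iv_cohort(seed=4, n=500)
        with pytest.raises(ValueError):
            tsls_logistic(cohort, np.ones(500), covariates=[])

    def test_confounded_null_iv_includes_zero_naive_excludes(self):
        """The headline discrepancy on planted truth: under a confounded null
        the IV interval covers 0 while naive logistic regression of outcome
        on exposure does not."""
        from smokemr._regression import logistic_fit

        cfg = SimulationConfig(n_individuals=20_000, causal_effect=0.0,
                               confounder_effects=(0.6, 0.8), seed=71)
        cohort, d = minimal_cohort_frame(cfg, 72)
        prs = d["g"] @ cfg.effect_vector()
        iv = tsls_logistic(cohort, prs, covariates=[], n_boot=200, seed=2)
        X = np.column_stack([np.ones(len(cohort)), d["x"]])
        coef, se, _ = logistic_fit(X, d["y"])
        naive_excludes = abs(coef[1]) > 1.96 * se[1]
        assert iv.covers(0.0)
        assert naive_excludes


class TestGEstimation:
    def test_null_recovery(self):
        cfg = SimulationConfig(n_individuals=10_000, causal_effect=0.0,
                               confounder_effects=(0.0, 0.0), seed=81)
        covered = 0
        reps = 10
        for rep in range(reps):
            cohort, d = minimal_cohort_frame(cfg, 82 + rep)
            prs = d["g"] @ cfg.effect_vector()
            est = g_estimation_logistic(cohort, prs, covariates=[], n_boot=100,
                                        seed=3 + rep)
            covered += est.covers(0.0)
        assert covered >= 8

    def test_agrees_with_tsls_for_rare_outcome(self):
        """Odds ratios collapse in the rare-outcome limit, so the two
        estimators nearly coincide (the published pair was 0.98 vs 0.99)."""
        rng = np.random.default_rng(5)
        cohort, z = _noiseless_iv_cohort(seed=5)
        # small exposure noise keeps the association design full-rank
        cohort["smoking_index"] = cohort["smoking_index"] + 0.05 * rng.normal(
            size=len(cohort)
        )
        a = tsls_logistic(cohort, z, covariates=[], se_method="analytic")
        b = g_estimation_logistic(cohort, z, covariates=[], se_method="analytic")
        assert abs(a.beta - b.beta) < 0.05

    def test_less_biased_than_tsls_for_common_outcome(self):
        """With 30% prevalence the logistic 2SLS estimate is attenuated by
        noncollapsibility; G-estimation tracks the planted effect better."""
        rng = np.random.default_rng(91)
        errs_g, errs_t = [], []
        for rep in range(30):
            n = 8000
            z = rng.normal(1.0, 0.5, n)
            u = rng.normal(size=n)
            x = z + 0.8 * u + 0.3 * rng.normal(size=n)
            p = special.expit(-1.5 + 0.5 * x - 1.2 * u)  # heterogeneity, no Z-confounding
            y = (rng.random(n) < p).astype(float)
            cohort = pd.DataFrame({"ckd_event": y, "smoking_index": x})
            t = tsls_logistic(cohort, z, covariates=[], se_method="analytic")
            g = g_estimation_logistic(cohort, z, covariates=[], se_method="analytic")
            errs_t.append(abs(t.beta - 0.5))
            errs_g.append(abs(g.beta - 0.5))
        assert np.median(errs_g) < np.median(errs_t)


class TestLace:
    def test_tertile_split_sizes(self):
        rng = np.random.default_rng(51)
        n = 9
        # tiny toy cohort exercises only the splitting logic
        cohort = pd.DataFrame(
            {"ckd_event": [1, 0, 1, 0, 1, 0, 1, 0, 1],
             "smoking_index": rng.uniform(0, 2, n)}
        )
        z = rng.normal(size=n)
        from smokemr.mr_one_sample import build_design

        d1 = np.column_stack([np.ones(n), z])
        resid = cohort["smoking_index"].to_numpy() - d1 @ np.linalg.lstsq(
            d1, cohort["smoking_index"].to_numpy(), rcond=None
        )[0]
        order = np.argsort(resid, kind="mergesort")
        bounds = [round(k * n / 3) for k in range(4)]
        sizes = [bounds[k + 1] - bounds[k] for k in range(3)]
        assert sizes == [3, 3, 3]

    def test_linear_truth_gives_null_nonlinearity(self, causal_config):
        d = simulate_minimal(causal_config, 61)
        cohort = pd.DataFrame({"ckd_event": d["y"], "smoking_index": d["x"]})
        prs = d["g"] @ causal_config.effect_vector()
        res = lace_nonlinear(cohort, prs, covariates=[])
        assert len(res.strata) == 3
        assert all(np.diff(res.stratum_means) > 0)
        assert 0 <= res.p_quadratic <= 1 and 0 <= res.p_q <= 1

    def test_planted_quadratic_effect_detected(self):
        """A strong quadratic exposure effect drives the quadratic test below
        0.05 in most replicates."""
        rng = np.random.default_rng(63)
        hits = 0
        reps = 15
        for _ in range(reps):
            n = 20_000
            z = rng.normal(1.0, 0.5, n)
            x = z + 0.8 * rng.normal(size=n)
            p = special.expit(-4.5 + 0.8 * x**2)
            y = (rng.random(n) < p).astype(float)
            cohort = pd.DataFrame({"ckd_event": y, "smoking_index": x})
            res = lace_nonlinear(cohort, z, covariates=[])
            hits += res.p_quadratic < 0.05
        assert hits >= 0.8 * reps

    def test_min_stratum_size_enforced(self):
        cohort = pd.DataFrame(
            {"ckd_event": np.zeros(60), "smoking_index": np.arange(60.0)}
        )
        with pytest.raises(ValueError):
            lace_nonlinear(cohort, np.random.default_rng(0).normal(size=60),
                           covariates=[])


class TestSubgroups:
    def _cohort(self, cfg, seed):
        cohort, d = minimal_cohort_frame(cfg, seed)
        rng = np.random.default_rng(seed + 1)
        n = len(cohort)
        cohort["age"] = rng.integers(40, 70, n).astype(float)
        cohort["sex"] = rng.integers(0, 2, n)
        cohort["diabetes"] = rng.integers(0, 2, n)
        cohort["hypertension"] = rng.integers(0, 2, n)
        cohort["bmi"] = rng.normal(27, 4, n)
        return cohort, d["g"] @ cfg.effect_vector()

    def test_table_layout_two_levels_per_variable(self, causal_config):
        cohort, prs = self._cohort(causal_config, 55)
        table = subgroup_mr(cohort, prs, covariates=[], se_method="analytic")
        assert len(table) == 10  # 2 levels x 5 stratifiers
        assert set(table["variable"]) == {"age", "sex", "diabetes",
                                          "hypertension", "bmi"}
        age_levels = table.loc[table["variable"] == "age", "level"].tolist()
        assert any(l.startswith("<") for l in age_levels)
        assert any(l.startswith(">=") for l in age_levels)

    def test_whole_cohort_as_single_level_matches_overall(self, causal_config):
        cohort, prs = self._cohort(causal_config, 57)
        cohort["all"] = 1
        table = subgroup_mr(cohort, prs, covariates=[], subgroups=("all",),
                            se_method="analytic")
        overall = tsls_logistic(cohort, prs, covariates=[], se_method="analytic")
        assert table["beta"].iloc[0] == pytest.approx(overall.beta, abs=1e-10)

    def test_homogeneous_halves_agree(self, causal_config):
        cohort, prs = self._cohort(causal_config, 59)
        cohort["half"] = (np.arange(len(cohort)) % 2).astype(int)
        table = subgroup_mr(cohort, prs, covariates=[], subgroups=("half",),
                            se_method="analytic")
        b = table["beta"].to_numpy()
        s = table["se"].to_numpy()
        assert abs(b[0] - b[1]) < 2 * np.hypot(s[0], s[1])


def _geno_and_instruments(d, cfg):
    m = cfg.n_snps
    geno = GenotypeMatrix(
        d["g"].astype(np.int8), [f"rs{i}" for i in range(m)],
        np.array(["A"] * m), np.array(["G"] * m), d["eaf"],
    )
    inst = InstrumentSet([f"rs{i}" for i in range(m)], cfg.effect_vector())
    return geno, inst


class TestLeaveOneOut:
    def test_emits_one_row_per_snp(self, causal_config):
        cohort, d = minimal_cohort_frame(causal_config, 65)
        geno, inst = _geno_and_instruments(d, causal_config)
        table = leave_one_out(cohort, geno, inst, covariates=[],
                             se_method="analytic")
        assert len(table) == causal_config.n_snps
        assert table["excluded_snp"].is_unique

    def test_single_instrument_rejected(self, causal_config):
        cohort, d = minimal_cohort_frame(causal_config, 67)
        geno, _ = _geno_and_instruments(d, causal_config)
        inst = InstrumentSet(["rs0"], [0.1])
        with pytest.raises(ValueError):
            leave_one_out(cohort, geno, inst, covariates=[])

    def test_excluding_the_pleiotropic_snp_moves_estimate_to_null(self):
        """Under θ=0 with one strongly pleiotropic SNP, the leave-one-out row
        that drops it is the closest to zero."""
        cfg = SimulationConfig(
            n_individuals=30_000, gwas_n_individuals=10_000,
            n_snps=6, causal_effect=0.0, confounder_effects=(0.0, 0.0), seed=69,
        )
        d = simulate_minimal(cfg, 70)
        # plant a large direct effect of rs2 on the outcome
        rng = np.random.default_rng(71)
        extra = 0.5 * d["g"][:, 2]
        p = special.expit(special.logit(np.clip(d["y"].mean(), 0.01, 0.2)) + extra)
        y = (rng.random(len(p)) < p).astype(float)
        cohort = pd.DataFrame({"ckd_event": y, "smoking_index": d["x"]})
        geno, inst = _geno_and_instruments(d, cfg)
        table = leave_one_out(cohort, geno, inst, covariates=[],
                             se_method="analytic")
        nearest = table.loc[table["beta"].abs().idxmin(), "excluded_snp"]
        assert nearest == "rs2"


class TestSensitivity:
    def test_no_flags_is_identity(self, causal_config):
        cohort, d = minimal_cohort_frame(causal_config, 73)
        rng = np.random.default_rng(0)
        cohort["bmi"] = rng.normal(27, 4, len(cohort))
        cohort["diabetes"] = rng.integers(0, 2, len(cohort))
        cohort["hypertension"] = rng.integers(0, 2, len(cohort))
        geno, inst = _geno_and_instruments(d, causal_config)
        report = pd.DataFrame(
            {"snp": inst.snp_ids, "retained_in_sensitivity": True}
        )
        out = sensitivity_prs(cohort, geno, inst, report, covariates=[],
                              se_method="analytic")
        main = tsls_logistic(cohort, d["g"] @ inst.weights, covariates=[],
                             se_method="analytic")
        assert out["reduced_prs"].beta == pytest.approx(main.beta, abs=1e-10)

    def test_flagged_snps_shrink_the_score(self, causal_config):
        cohort, d = minimal_cohort_frame(causal_config, 75)
        cohort["bmi"] = np.random.default_rng(1).normal(27, 4, len(cohort))
        cohort["diabetes"] = np.random.default_rng(2).integers(0, 2, len(cohort))
        cohort["hypertension"] = np.random.default_rng(3).integers(0, 2, len(cohort))
        geno, inst = _geno_and_instruments(d, causal_config)
        report = pd.DataFrame(
            {
                "snp": inst.snp_ids,
                "retained_in_sensitivity": [False] * 3 + [True] * (inst.m - 3),
            }
        )
        out = sensitivity_prs(cohort, geno, inst, report, covariates=[],
                              se_method="analytic")
        assert out["reduced_prs"].n_used == len(cohort)
        reduced = inst.without(inst.snp_ids[:3])
        assert reduced.m == inst.m - 3

    def test_all_flagged_rejected(self, causal_config):
        cohort, d = minimal_cohort_frame(causal_config, 77)
        geno, inst = _geno_and_instruments(d, causal_config)
        report = pd.DataFrame(
            {"snp": inst.snp_ids, "retained_in_sensitivity": False}
        )
        with pytest.raises(ValueError):
            sensitivity_prs(cohort, geno, inst, report, covariates=[])


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert mr_power(0.0, 10_000, 0.02, 0.04) == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_effect_size(self):
        powers = [mr_power(b, 10_000, 0.02, 0.04) for b in np.linspace(0, 3, 20)]
        assert all(np.diff(powers) >= -1e-12)
        assert powers[-1] > 0.99

    def test_invalid_r2_rejected(self):
        with pytest.raises(ValueError):
            mr_power(0.3, 1000, 0.0, 0.04)

    def test_matches_empirical_rejection_rate(self):
        """The closed form tracks the simulated rejection rate of the 2SLS
        test at a planted effect within ±7 points."""
        rng = np.random.default_rng(93)
        theta, n = 0.25, 6000
        rejections = 0
        reps = 300
        from smokemr._regression import logistic_fit, ols_fit

        r2_sum, case_sum = 0.0, 0.0
        for _ in range(reps):
            z = rng.normal(0.0, 1.0, n)
            x = 0.5 * z + rng.normal(0, 1.0, n)
            p = special.expit(-3.2 + theta * x)
            y = (rng.random(n) < p).astype(float)
            d1 = np.column_stack([np.ones(n), z])
            coef1, *_ = np.linalg.lstsq(d1, x, rcond=None)
            xhat = d1 @ coef1
            coef2, se2, _ = logistic_fit(np.column_stack([np.ones(n), xhat]), y)
            rejections += abs(coef2[1] / se2[1]) > 1.959964
            r2_sum += np.corrcoef(z, x)[0, 1] ** 2
            case_sum += y.mean()
        empirical = rejections / reps
        predicted = mr_power(theta, n, r2_sum / reps, case_sum / reps)
        assert abs(empirical - predicted) < 0.07
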