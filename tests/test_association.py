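"""Clustered association models: GEE marginal models, robust Cox, tertiles.

The Cox route is validated against a brute-force partial-likelihood oracle
(direct numerical maximization of the hand-coded partial likelihood on
enumerable fixtures); the GEE route against its ordinary-regression
degeneracy and against simulation-based coverage/type-I behaviour.
"""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

from hdlgrs.association import (
    DEFAULT_MODELS,
    AssociationError,
    fit_cox_robust,
    fit_marginal,
    run_model_battery,
    tertile_analysis,
    transform_outcome,
)
from hdlgrs.scores import ScoreVector, assign_tertiles
from hdlgrs.simulate import SimulationConfig, simulate_family_genotypes


def brute_force_cox(time, event, z, lo=-10.0, hi=10.0):
    """Independent oracle: maximize the (no-ties) Cox partial likelihood
    for a single covariate by direct numerical search."""
    time = np.asarray(time, float)
    z = np.asarray(z, float)

    def negpl(b):
        ll = 0.0
        for i in range(len(time)):
            if event[i]:
                risk = time >= time[i]
                ll += b * z[i] - math.log(np.exp(b * z[risk]).sum())
        return -ll

    res = minimize_scalar(negpl, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)


class TestTransformOutcome:
    def test_cac_zero_maps_to_zero(self):
        assert transform_outcome(np.array([0.0]), "log1p")[0] == 0.0

    def test_log_transform_value(self):
        out = transform_outcome(np.array([175.0]), "log")
        assert out[0] == pytest.approx(math.log(175), abs=1e-9)

    def test_identity_unchanged(self):
        x = np.array([1.0, -2.0, 3.5])
        np.testing.assert_array_equal(transform_outcome(x, "identity"), x)

    def test_nonpositive_under_log_names_the_record(self):
        with pytest.raises(AssociationError, match="record 1"):
            transform_outcome(np.array([3.0, 0.0]), "log")


class TestMarginalModel:
    def test_singleton_clusters_reduce_to_ols_with_robust_se(self):
        rng = np.random.default_rng(0)
        n = 150
        data = pd.DataFrame(
            {
                "age": rng.normal(60, 9, n),
                "sex": rng.choice(["female", "male"], n),
                "bmi": rng.normal(32, 6, n),
                "family_id": [f"f{i}" for i in range(n)],
            }
        )
        x = rng.normal(size=n)
        y = 1 + 0.5 * x + 0.02 * data["age"].to_numpy() + rng.normal(size=n)
        res = fit_marginal(
            y, x, ("age",), data, data["family_id"].to_numpy(),
            model_label="M2", outcome_label="y",
        )[0]
        X = sm.add_constant(pd.DataFrame({"score": x, "age": data["age"]}))
        ols = sm.OLS(y, X).fit()
        assert res.estimate == pytest.approx(ols.params["score"], abs=1e-8)
        assert res.se_sandwich == pytest.approx(ols.HC0_se["score"], rel=1e-6)

    def test_sandwich_at_least_naive_on_correlated_clusters(self, catalog):
        cfg = SimulationConfig(seed=31, n_families=300)
        g = simulate_family_genotypes(catalog, config=cfg)
        rng = np.random.default_rng(31)
        fam_codes, _ = pd.factorize(g.family_ids)
        fam_re = rng.normal(0, 1.5, fam_codes.max() + 1)
        score = g.dosage.sum(axis=1)
        y = 0.1 * score + fam_re[fam_codes] + rng.normal(0, 1, g.n_samples)
        data = pd.DataFrame({"family_id": g.family_ids})
        X = sm.add_constant(pd.DataFrame({"score": score}))
        gee = sm.GEE(
            y, X, groups=g.family_ids, family=sm.families.Gaussian(),
            cov_struct=sm.cov_struct.Exchangeable(),
        ).fit()
        naive = gee.standard_errors(cov_type="naive")[1]
        robust = gee.standard_errors(cov_type="robust")[1]
        assert robust >= naive * 0.99

    def test_estimates_invariant_to_cluster_ordering(self):
        rng = np.random.default_rng(2)
        n = 120
        fams = np.repeat([f"f{i}" for i in range(n // 2)], 2)
        x = rng.normal(size=n)
        y = 0.3 * x + rng.normal(size=n)
        data = pd.DataFrame({"family_id": fams})
        a = fit_marginal(y, x, (), data, fams)[0]
        perm = rng.permutation(n)
        b = fit_marginal(y[perm], x[perm], (),
                         data.iloc[perm].reset_index(drop=True), fams[perm])[0]
        assert a.estimate == pytest.approx(b.estimate, abs=1e-8)
        assert a.se_sandwich == pytest.approx(b.se_sandwich, rel=1e-6)

    def test_rank_deficient_design_rejected(self):
        n = 40
        data = pd.DataFrame(
            {"age": np.ones(n), "bmi": np.ones(n),
             "family_id": [f"f{i}" for i in range(n)]}
        )
        with pytest.raises(AssociationError, match="rank"):
            fit_marginal(
                np.random.default_rng(0).normal(size=n),
                np.arange(n, dtype=float), ("age", "bmi"), data,
                data["family_id"].to_numpy(),
            )

    def test_logit_link_for_binary_outcome(self):
        rng = np.random.default_rng(3)
        n = 400
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-0.5 + 0.8 * x)))
        y = (rng.random(n) < p).astype(float)
        data = pd.DataFrame({"family_id": [f"f{i}" for i in range(n)]})
        res = fit_marginal(y, x, (), data, data["family_id"].to_numpy(),
                           binary=True)[0]
        assert res.ci_low < 0.8 < res.ci_high


class TestCoxRobust:
    def test_matches_brute_force_oracle_on_enumerable_fixtures(self):
        rng = np.random.default_rng(4)
        compared = 0
        for n in (4, 5, 6):
            for rep in range(6):
                t = rng.exponential(1.0, n) + 0.05
                assert len(set(t)) == n  # no ties: oracle assumes none
                e = rng.random(n) < 0.8
                if e.sum() == 0:
                    e[0] = True
                z = rng.normal(size=n)
                oracle = brute_force_cox(t, e, z)
                if abs(oracle) > 3:
                    continue  # near-monotone likelihood: flat optimum, no
                    # meaningful point comparison on a fixture this small
                data = pd.DataFrame({"family_id": [f"f{i}" for i in range(n)]})
                res = fit_cox_robust(t, e.astype(int), z, (), data,
                                     data["family_id"].to_numpy())[0]
                assert res.estimate == pytest.approx(oracle, abs=1e-6)
                compared += 1
        assert compared >= 8

    def test_null_exposure_hazard_ratio_near_one(self):
        rng = np.random.default_rng(5)
        n = 600
        t = rng.exponential(10, n)
        c = rng.uniform(5, 15, n)
        time = np.minimum(t, c)
        event = (t < c).astype(int)
        z = rng.normal(size=n)  # independent of hazard
        data = pd.DataFrame({"family_id": [f"f{i}" for i in range(n)]})
        res = fit_cox_robust(time, event, z, (), data,
                             data["family_id"].to_numpy())[0]
        assert res.ci_low < 0.0 < res.ci_high
        assert res.hr == pytest.approx(1.0, abs=0.2)

    def test_generative_hazard_ratio_recovered(self):
        rng = np.random.default_rng(6)
        n = 5000
        z = rng.normal(0, 2.2, n)  # score-like spread
        lam = 0.03 * np.exp(math.log(0.9) * z)
        t = rng.exponential(1 / lam)
        c = rng.uniform(6, 13, n)
        time, event = np.minimum(t, c), (t < c).astype(int)
        data = pd.DataFrame({"family_id": [f"f{i}" for i in range(n)]})
        res = fit_cox_robust(time, event, z, (), data,
                             data["family_id"].to_numpy())[0]
        assert res.ci_low < math.log(0.9) < res.ci_high

    def test_no_events_rejected(self):
        data = pd.DataFrame({"family_id": ["a", "b", "c"]})
        with pytest.raises(AssociationError, match="no events"):
            fit_cox_robust(
                [1, 2, 3], [0, 0, 0], np.zeros(3), (), data,
                data["family_id"].to_numpy(),
            )

    def test_ci_is_wald_on_the_log_scale(self):
        rng = np.random.default_rng(7)
        n = 300
        t = rng.exponential(5, n)
        e = np.ones(n, int)
        z = rng.normal(size=n)
        data = pd.DataFrame({"family_id": [f"f{i}" for i in range(n)]})
        res = fit_cox_robust(t, e, z, (), data, data["family_id"].to_numpy())[0]
        assert res.ci_low == pytest.approx(res.estimate - 1.96 * res.se_sandwich,
                                           abs=1e-4)
        assert res.ci_high == pytest.approx(res.estimate + 1.96 * res.se_sandwich,
                                            abs=1e-4)


class TestTertileAnalysis:
    def _tertiles(self, scores):
        vec = ScoreVector(sample_ids=np.arange(len(scores)),
                          score=np.asarray(scores, float),
                          definition_label="t")
        return assign_tertiles(vec).tertile

    def test_monotone_outcome_gives_positive_trend(self):
        rng = np.random.default_rng(8)
        n = 300
        scores = rng.normal(size=n)
        tert = self._tertiles(scores)
        shift = {"T1": 0.0, "T2": 1.0, "T3": 2.0}
        y = np.array([shift[t] for t in tert]) + rng.normal(0, 0.3, n)
        data = pd.DataFrame({"family_id": [f"f{i}" for i in range(n)]})
        res = tertile_analysis(tert, data, data["family_id"].to_numpy(),
                               "ordinal_trend", outcome=y)[0]
        assert res.estimate > 0 and res.p_value < 1e-6

    def test_reference_contrast_returns_two_terms(self):
        rng = np.random.default_rng(9)
        n = 200
        tert = self._tertiles(rng.normal(size=n))
        y = rng.normal(size=n)
        data = pd.DataFrame({"family_id": [f"f{i}" for i in range(n)]})
        out = tertile_analysis(tert, data, data["family_id"].to_numpy(),
                               "reference_contrast", outcome=y)
        assert [r.term for r in out] == ["T2_vs_T1", "T3_vs_T1"]

    def test_trend_p_values_uniform_under_permutation(self):
        """Permuting tertile labels under the null leaves the trend p-value
        ~Uniform(0,1): rejection at 0.05 stays near nominal."""
        rng = np.random.default_rng(10)
        n = 150
        scores = rng.normal(size=n)
        tert = self._tertiles(scores)
        y = rng.normal(size=n)  # independent of tertile
        data = pd.DataFrame({"family_id": [f"f{i}" for i in range(n)]})
        fams = data["family_id"].to_numpy()
        pvals = []
        for _ in range(300):
            perm = rng.permutation(n)
            res = tertile_analysis(tert[perm], data, fams, "ordinal_trend",
                                   outcome=y)[0]
            pvals.append(res.p_value)
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert 0.02 <= rate <= 0.09

    def test_missing_tertile_rejected(self):
        data = pd.DataFrame({"family_id": ["a", "b", "c"]})
        with pytest.raises(AssociationError, match="three"):
            tertile_analysis(np.array(["T1", "T1", "T2"]), data,
                             data["family_id"].to_numpy(), "ordinal_trend",
                             outcome=np.zeros(3))


@pytest.fixture(scope="module")
def null_cohort(catalog):
    from hdlgrs.pipeline import standard_definitions
    from hdlgrs.scores import compute_grs, impute_missing
    from hdlgrs.simulate import simulate_cohort

    cfg = SimulationConfig(
        seed=33, n_families=250, hdl_effect_scale=0.0, cac_score_effect=0.0
    )
    g, p = simulate_cohort(catalog, cfg)
    complete = impute_missing(g)
    scores = pd.DataFrame(
        {
            label: compute_grs(complete, d).score
            for label, (_, d) in standard_definitions(catalog).items()
        }
    )
    return p.frame, scores


class TestModelBattery:
    def test_cross_product_row_count_and_order(self, null_cohort):
        phen, scores = null_cohort
        res = run_model_battery(phen, scores, models=DEFAULT_MODELS,
                                survival_outcomes=(), binary_outcomes=())
        assert len(res) == 6 * 4 * 3  # scores x continuous outcomes x models
        again = run_model_battery(phen, scores, models=DEFAULT_MODELS,
                                  survival_outcomes=(), binary_outcomes=())
        pd.testing.assert_frame_equal(res, again)

    def test_null_cohort_significance_near_nominal(self, null_cohort):
        phen, scores = null_cohort
        res = run_model_battery(phen, scores)
        ok = res["p_value"].notna()
        rate = (res.loc[ok, "p_value"] < 0.05).mean()
        # scores are highly correlated so rows are not independent tests;
        # the global rate should still sit near the nominal level
        assert rate < 0.2

    def test_failed_fit_becomes_a_noted_row(self, null_cohort):
        phen, scores = null_cohort
        broken = phen.copy()
        broken["death_all"] = 0  # no events -> Cox must refuse
        res = run_model_battery(
            broken, scores[["1a"]], models=DEFAULT_MODELS[:1],
            continuous_outcomes={}, survival_outcomes=("death_all",),
            binary_outcomes=(),
        )
        assert len(res) == 1
        assert res["note"].str.contains("no events").all()
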