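import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cernanet as cn


def make_clinical(os_months, event, **extra):
    n = len(os_months)
    index = pd.Index([f"p{i:03d}" for i in range(n)], name="sample")
    return cn.ClinicalTable(
        pd.DataFrame({"os_months": os_months, "event": event, **extra}, index=index)
    )


def make_expr(values, prefix="lnc"):
    values = np.atleast_2d(values)
    return cn.ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"{prefix}{i}" for i in range(values.shape[0])],
            columns=[f"p{i:03d}" for i in range(values.shape[1])],
        ),
        "lncRNA",
    )


def simulate_ph(rng, betas, n, baseline=0.02, censor_rate=0.0):
    """Exponential proportional-hazards draw over iid standard-normal expression."""
    x = rng.normal(size=(len(betas), n))
    hazard = baseline * np.exp(np.asarray(betas) @ x)
    t = rng.exponential(1.0 / hazard)
    c = rng.exponential(1.0 / censor_rate, size=n) if censor_rate else np.full(n, np.inf)
    return make_expr(x), make_clinical(np.minimum(t, c), (t <= c).astype(int))


class TestRiskModel:
    def test_sign_and_bias_recovery(self):
        """Cox coefficients (+1, -1, 0) at n=300: signs recovered, mean
        absolute bias below 0.15 over 20 seeds."""
        betas = np.array([1.0, -1.0, 0.0])
        estimates = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            expr, clinical = simulate_ph(rng, betas, 300, censor_rate=0.005)
            model = cn.fit_risk_model(expr, clinical)
            estimates.append(model.coefficients)
        mean_est = np.mean(estimates, axis=0)
        assert np.sign(mean_est[0]) > 0 and np.sign(mean_est[1]) < 0
        assert np.all(np.abs(mean_est - betas) < 0.15)

    def test_binary_exposure_matches_rate_ratio(self):
        """With exponential survival and a binary exposure the true HR is the
        two-group event-rate ratio; the Cox CI should cover it."""
        rng = np.random.default_rng(7)
        n = 400
        x = np.repeat([0.0, 1.0], n // 2)
        true_hr = 2.5
        hazard = 0.02 * true_hr**x
        t = rng.exponential(1.0 / hazard)
        expr = make_expr(x)
        clinical = make_clinical(t, np.ones(n, dtype=int))
        model = cn.fit_risk_model(expr, clinical)
        ci = model.training_summary.loc["lnc0", ["coef lower 95%", "coef upper 95%"]]
        assert ci.iloc[0] < np.log(true_hr) < ci.iloc[1]

    def test_zero_events_rejected(self):
        expr = make_expr(np.random.default_rng(0).normal(size=(2, 10)))
        clinical = make_clinical(np.arange(1.0, 11.0), np.zeros(10, dtype=int))
        with pytest.raises(ValueError, match="events"):
            cn.fit_risk_model(expr, clinical)


class TestRiskScores:
    def test_zero_weights_zero_scores(self):
        model = cn.RiskModel(["lnc0", "lnc1"], np.zeros(2), cutoff=0.0)
        expr = make_expr(np.random.default_rng(1).normal(size=(2, 5)))
        assert (cn.risk_scores(model, expr) == 0).all()

    def test_example_signature_on_unit_expression(self):
        """The packaged ten-lncRNA signature applied to all-ones expression
        returns the coefficient sum, -2.717428818 (hand-summed)."""
        model = cn.load_example_signature()
        expr = cn.ExpressionMatrix(
            pd.DataFrame(np.ones((10, 3)), index=model.lncrna_ids, columns=list("abc")),
            "lncRNA",
        )
        scores = cn.risk_scores(model, expr)
        assert scores.iloc[0] == pytest.approx(-2.717428818, abs=1e-9)
        assert scores.iloc[0] == pytest.approx(model.coefficients.sum())

    def test_linearity_in_single_coordinate(self):
        model = cn.RiskModel(["lnc0", "lnc1"], np.array([0.5, -2.0]), cutoff=0.0)
        rng = np.random.default_rng(2)
        base = rng.normal(size=(2, 4))
        bumped = base.copy()
        bumped[1, 2] *= 2.0
        delta = (
            cn.risk_scores(model, make_expr(bumped)) - cn.risk_scores(model, make_expr(base))
        )
        assert delta.iloc[2] == pytest.approx(-2.0 * base[1, 2])
        assert (delta.drop(delta.index[2]) == 0).all()

    def test_missing_signature_gene_named(self):
        model = cn.RiskModel(["lnc0", "ghost"], np.ones(2), cutoff=0.0)
        with pytest.raises(KeyError, match="ghost"):
            cn.risk_scores(model, make_expr(np.ones((1, 3))))


class TestDichotomize:
    def test_median_split_four_samples(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        groups = cn.dichotomize(scores)
        assert set(groups[groups == "high"].index) == {"c", "d"}
        assert set(groups[groups == "low"].index) == {"a", "b"}

    def test_401_distinct_scores_split_200_201(self):
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.permutation(401).astype(float),
                           index=[f"p{i}" for i in range(401)])
        groups = cn.dichotomize(scores)
        assert (groups == "high").sum() == 200
        assert (groups == "low").sum() == 201

    def test_cutoff_above_max_all_low(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.warns(UserWarning, match="one-sided"):
            groups = cn.dichotomize(scores, cutoff=10.0)
        assert (groups == "low").all()

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            cn.dichotomize(pd.Series([1.0, 1.0, 1.0]))

    def test_invariance_under_increasing_transform(self):
        rng = np.random.default_rng(4)
        scores = pd.Series(rng.normal(size=30), index=[f"p{i}" for i in range(30)])
        cutoff = float(np.median(scores))
        base = cn.dichotomize(scores, cutoff)
        transformed = cn.dichotomize(np.exp(scores), float(np.exp(cutoff)))
        assert (base == transformed).all()


class TestKaplanMeierLogRank:
    def test_identical_groups_no_difference(self):
        os_months = [3.0, 5, 8, 12, 3, 5, 8, 12]
        event = [1, 0, 1, 1, 1, 0, 1, 1]
        clinical = make_clinical(os_months, event)
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=clinical.sample_ids)
        comp = cn.km_logrank(groups, clinical)
        assert comp.statistic == pytest.approx(0.0, abs=1e-12)
        assert comp.p_value == pytest.approx(1.0)

    def test_no_censoring_closed_form(self):
        clinical = make_clinical([1, 1, 1, 2, 2, 2], [1] * 6)
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=clinical.sample_ids)
        comp = cn.km_logrank(groups, clinical)
        assert comp.median_os == {"A": 1.0, "B": 2.0}
        assert comp.curves["A"].set_index("time")["survival"].loc[1.0] == 0.0

    def test_eight_subject_life_table(self):
        """Hand-computed life table: A=(1+,2+,4c,5+), B=(2c,3+,5+,6c) gives
        S_A = 3/4, 1/2, 0; medians 2 and 5; log-rank chi2 = 1.0548
        (O_A=3, E_A=1.99524, V=0.95712), p = 0.3044."""
        clinical = make_clinical([1, 2, 4, 5, 2, 3, 5, 6], [1, 1, 0, 1, 0, 1, 1, 0])
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=clinical.sample_ids)
        comp = cn.km_logrank(groups, clinical, rate_times=(3.0,))
        curve_a = comp.curves["A"].set_index("time")["survival"]
        assert curve_a.loc[1.0] == pytest.approx(0.75)
        assert curve_a.loc[2.0] == pytest.approx(0.5)
        assert curve_a.loc[5.0] == pytest.approx(0.0)
        assert comp.median_os == {"A": 2.0, "B": 5.0}
        assert comp.statistic == pytest.approx(1.054776, abs=1e-4)
        assert comp.p_value == pytest.approx(0.304365, abs=1e-4)
        assert comp.survival_rates["B"][3.0] == pytest.approx(2 / 3)

    def test_km_reduces_to_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(5)
        times = np.round(rng.exponential(20, size=40), 1) + 0.1
        clinical = make_clinical(times, np.ones(40, dtype=int))
        groups = pd.Series(["A"] * 20 + ["B"] * 20, index=clinical.sample_ids)
        comp = cn.km_logrank(groups, clinical)
        t_a = np.sort(times[:20])
        for t, s in comp.curves["A"].set_index("time")["survival"].items():
            assert s == pytest.approx((t_a > t).mean(), abs=1e-12)

    def test_logrank_null_uniform_over_permutations(self):
        """Permuting group labels under the null: log-rank p is uniform
        (KS check over 500 permutations)."""
        rng = np.random.default_rng(6)
        n = 60
        times = rng.exponential(30, size=n)
        cens = rng.exponential(60, size=n)
        clinical = make_clinical(np.minimum(times, cens), (times <= cens).astype(int))
        pvals = []
        for _ in range(500):
            labels = rng.permutation(["A"] * (n // 2) + ["B"] * (n // 2))
            comp = cn.km_logrank(
                pd.Series(labels, index=clinical.sample_ids), clinical,
                hazard_ratio_for=None,
            )
            pvals.append(comp.p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestCoxTable:
    def test_planted_binary_hr_within_ci(self):
        rng = np.random.default_rng(8)
        n = 500
        group = rng.random(n) < 0.5
        hazard = 0.02 * np.where(group, 2.0, 1.0)
        t = rng.exponential(1.0 / hazard)
        clinical = make_clinical(t, np.ones(n, dtype=int))
        risk = pd.Series(np.where(group, "high", "low"), index=clinical.sample_ids)
        table = cn.cox_table(clinical, risk=risk, covariates=())
        row = table.univariate.loc["risk_high"]
        assert row["ci_lower"] < 2.0 < row["ci_upper"]
        assert row["p"] < 0.01

    def test_reference_levels_recorded_and_dummies_fit(self):
        rng = np.random.default_rng(9)
        n = 250
        stage = rng.choice(["II", "III", "IV"], size=n, p=[0.2, 0.6, 0.2])
        t = rng.exponential(40, size=n)
        clinical = make_clinical(
            t, np.ones(n, dtype=int), stage=stage, age=rng.normal(60, 10, n)
        )
        table = cn.cox_table(clinical, covariates=("age", "stage"))
        assert table.reference_levels["stage"] == "II"
        assert {"stage_III", "stage_IV"} <= set(table.multivariate.index)
        assert "stage_II" not in table.multivariate.index  # reference: HR fixed at 1
        assert "age" in table.univariate.index

    def test_missing_covariate_rows_dropped_per_fit(self):
        rng = np.random.default_rng(10)
        n = 120
        age = rng.normal(60, 8, n)
        age[:30] = np.nan
        clinical = make_clinical(rng.exponential(30, n), np.ones(n, dtype=int), age=age)
        table = cn.cox_table(clinical, covariates=("age",))
        assert table.univariate.loc["age", "n"] == n - 30


class TestTimeDependentROC:
    def test_uninformative_scores_auc_near_half(self):
        rng = np.random.default_rng(11)
        n = 300
        t = rng.exponential(50, size=n)
        clinical = make_clinical(t, np.ones(n, dtype=int))
        scores = pd.Series(rng.normal(size=n), index=clinical.sample_ids)
        auc, _ = cn.time_dependent_roc(scores, clinical, eval_time=40)
        assert abs(auc - 0.5) < 0.08

    def test_perfect_separation_auc_one(self):
        clinical = make_clinical([10, 20, 30, 80, 90, 100], [1] * 6)
        scores = pd.Series([5.0, 6, 7, 1, 2, 3], index=clinical.sample_ids)
        auc, _ = cn.time_dependent_roc(scores, clinical, eval_time=60)
        assert auc == pytest.approx(1.0)

    def test_matches_empirical_auc_without_censoring(self):
        """With zero censoring the KM-based estimator collapses to the
        empirical AUC: P(score_case > score_control) for cases = events by
        t, controls = survivors past t (ties counted half)."""
        rng = np.random.default_rng(12)
        n = 200
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.02 * np.exp(0.8 * x)))
        clinical = make_clinical(t, np.ones(n, dtype=int))
        scores = pd.Series(x, index=clinical.sample_ids)
        eval_time = float(np.median(t))
        auc, _ = cn.time_dependent_roc(scores, clinical, eval_time=eval_time)
        cases = x[t <= eval_time]
        controls = x[t > eval_time]
        wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
        empirical = wins / (len(cases) * len(controls))
        assert auc == pytest.approx(empirical, abs=1e-6)

    def test_horizon_beyond_followup_rejected(self):
        clinical = make_clinical([5.0, 8.0, 10.0], [1, 1, 1])
        scores = pd.Series([1.0, 2.0, 3.0], index=clinical.sample_ids)
        with pytest.raises(ValueError, match="follow-up"):
            cn.time_dependent_roc(scores, clinical, eval_time=50)


class TestStratifiedAnalysis:
    def test_constant_field_reproduces_global(self):
        rng = np.random.default_rng(13)
        n = 80
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.03 * np.exp(0.9 * x)))
        clinical = make_clinical(t, np.ones(n, dtype=int), stage=["III"] * n)
        scores = pd.Series(x, index=clinical.sample_ids)
        strata = cn.stratified_analysis(scores, clinical, "stage", {"III": "all"})
        global_comp = cn.km_logrank(cn.dichotomize(scores), clinical)
        assert strata["all"].p_value == pytest.approx(global_comp.p_value)

    def test_strata_partition_the_cohort(self):
        rng = np.random.default_rng(14)
        n = 90
        clinical = make_clinical(
            rng.exponential(30, n), np.ones(n, dtype=int),
            age=rng.normal(62, 12, n),
        )
        scores = pd.Series(rng.normal(size=n), index=clinical.sample_ids)
        strata = cn.stratified_analysis(scores, clinical, "age", 65)
        total = sum(len(comp.groups) for comp in strata.values())
        assert total == n

    def test_effect_restricted_to_one_stratum(self):
        """Risk score prognostic only in stratum A: its log-rank p should be
        smaller than stratum B's in >= 90% of 20 seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(2000 + seed)
            n = 200
            in_a = np.arange(n) < n // 2
            x = rng.normal(size=n)
            beta = np.where(in_a, 1.2, 0.0)
            t = rng.exponential(1.0 / (0.02 * np.exp(beta * x)))
            clinical = make_clinical(
                t, np.ones(n, dtype=int), stage=np.where(in_a, "II", "IV")
            )
            scores = pd.Series(x, index=clinical.sample_ids)
            strata = cn.stratified_analysis(
                scores, clinical, "stage", {"II": "A", "IV": "B"}
            )
            hits += strata["A"].p_value < strata["B"].p_value
        assert hits >= 18


class TestClusterSplit:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(15)
        left = rng.normal(-3, 0.4, size=(5, 20))
        right = rng.normal(3, 0.4, size=(5, 25))
        expr = make_expr(np.hstack([left, right]))
        assignment, _ = cn.cluster_split(expr, zscore=False)
        first = set(assignment.iloc[:20].unique())
        second = set(assignment.iloc[20:].unique())
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_duplicated_samples_co_cluster(self):
        rng = np.random.default_rng(16)
        block = rng.normal(size=(4, 6))
        expr = make_expr(np.hstack([block, block + 5.0]))
        assignment, _ = cn.cluster_split(expr, zscore=False)
        assert assignment.iloc[:6].nunique() == 1
        assert assignment.iloc[6:].nunique() == 1

    def test_always_two_nonempty_groups(self):
        rng = np.random.default_rng(17)
        expr = make_expr(rng.normal(size=(6, 15)))
        assignment, _ = cn.cluster_split(expr)
        counts = assignment.value_counts()
        assert len(counts) == 2 and (counts > 0).all()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            cn.cluster_split(make_expr(np.ones((3, 1))))
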