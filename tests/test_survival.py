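import itertools

import numpy as np
import pandas as pd
import pytest

from driverscope.io import SurvivalTable
from driverscope.simulate import BulkSimConfig, simulate_bulk_cohort
from driverscope.survival import (
    ConvergenceError,
    LearnerSpec,
    PenalizedCoxLearner,
    SeparationError,
    benchmark_models,
    concordance_index,
    fit_cox,
    km_logrank,
    landmark_stratified_split,
    optimal_cutpoint,
    shapley_importance,
    stability_selection,
    time_dependent_auc,
    univariate_cox_screen,
)

from conftest import make_survival


# ---------------------------------------------------------------------------
# Independent oracles (written against definitions, not the implementation)
# ---------------------------------------------------------------------------


def partial_loglik_no_ties(beta, x, time, event):
    """Hand-coded Cox partial likelihood for untied, single-covariate data."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


def harrell_c_pairs(risk, time, event):
    """Exhaustive pair enumeration of Harrell's C."""
    num = den = 0.0
    n = len(risk)
    for i, j in itertools.product(range(n), repeat=2):
        if i == j:
            continue
        if event[i] == 1 and (time[i] < time[j] or (time[i] == time[j] and event[j] == 0)):
            den += 1
            if risk[i] > risk[j]:
                num += 1
            elif risk[i] == risk[j]:
                num += 0.5
    return num / den


def censoring_km_left(times, events, q):
    """G(q-): KM of the censoring distribution, left limit, from scratch."""
    g = 1.0
    for u in sorted(set(times)):
        if u >= q:
            break
        at_risk = sum(1 for t in times if t >= u)
        d = sum(1 for t, e in zip(times, events) if t == u and e == 0)
        g *= 1 - d / at_risk
    return g


def ipcw_auc_direct(risk, time, event, horizon):
    """Direct double-sum IPCW cumulative/dynamic AUC."""
    cases = [i for i in range(len(time)) if time[i] <= horizon and event[i] == 1]
    controls = [j for j in range(len(time)) if time[j] > horizon]
    num = 0.0
    wsum = 0.0
    for i in cases:
        w = 1.0 / censoring_km_left(time, event, time[i])
        wsum += w
        for j in controls:
            if risk[i] > risk[j]:
                num += w
            elif risk[i] == risk[j]:
                num += 0.5 * w
    return num / (wsum * len(controls))


def logrank_o_minus_e(time, event, group1):
    """Hand O-E and variance sums for the two-group log-rank test."""
    o_e = 0.0
    v = 0.0
    for t in sorted(set(t for t, e in zip(time, event) if e == 1)):
        n = sum(1 for s in time if s >= t)
        n1 = sum(1 for s, g in zip(time, group1) if s >= t and g)
        d = sum(1 for s, e in zip(time, event) if s == t and e == 1)
        d1 = sum(1 for s, e, g in zip(time, event, group1) if s == t and e == 1 and g)
        o_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_e, v


def exact_shapley(f, x, base):
    """Exact Shapley values by enumeration over all feature orderings."""
    p = len(x)
    phi = np.zeros(p)
    for order in itertools.permutations(range(p)):
        z = base.copy()
        prev = f(z)
        for j in order:
            z = z.copy()
            z[j] = x[j]
            cur = f(z)
            phi[j] += cur - prev
            prev = cur
    return phi / float(np.prod(range(1, p + 1)))


# ---------------------------------------------------------------------------
# landmark_stratified_split
# ---------------------------------------------------------------------------


class TestSplit:
    def _cohort(self, seed=0):
        rng = np.random.default_rng(seed)
        times = np.concatenate([[360.0, 1100.0, 1820.0], rng.uniform(30, 3000, 97)])
        events = rng.integers(0, 2, size=100)
        return make_survival(times, events)

    def test_landmark_subjects_in_both_partitions(self):
        surv = self._cohort()
        split = landmark_stratified_split(surv, seed=1)
        time = surv.data["time"]
        for lm in (365.0, 1095.0, 1825.0):
            eligible = set(time.index[(time - lm).abs() <= 90])
            if len(eligible) >= 2:
                assert eligible & set(split.train_ids)
                assert eligible & set(split.validation_ids)

    def test_ratio_within_one_sample(self):
        surv = self._cohort(3)
        split = landmark_stratified_split(surv, ratio=0.7, seed=2)
        n = len(surv)
        assert abs(len(split.train_ids) - 0.7 * n) <= 1.0
        assert set(split.train_ids) | set(split.validation_ids) == set(surv.subject_ids)

    def test_deterministic(self):
        surv = self._cohort(4)
        a = landmark_stratified_split(surv, seed=7)
        b = landmark_stratified_split(surv, seed=7)
        assert a.train_ids == b.train_ids and a.validation_ids == b.validation_ids

    def test_small_cohort_rejected(self):
        surv = make_survival([100.0] * 9, [1] * 9)
        with pytest.raises(ValueError, match=">= 10 subjects"):
            landmark_stratified_split(surv)


# ---------------------------------------------------------------------------
# fit_cox
# ---------------------------------------------------------------------------


class TestFitCox:
    def test_matches_grid_search_oracle(self):
        x = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=float)
        time = [3.0, 5.0, 7.0, 11.0, 13.0, 17.0, 19.0, 23.0]
        event = [1, 1, 1, 0, 1, 1, 0, 1]
        surv = make_survival(time, event)
        fit = fit_cox(pd.DataFrame({"x": x}, index=surv.subject_ids), surv)
        grid = np.arange(-5.0, 5.0, 1e-4)
        lls = [partial_loglik_no_ties(b, x, np.array(time), np.array(event)) for b in grid]
        beta_star = grid[int(np.argmax(lls))]
        assert fit.summary.at["x", "beta"] == pytest.approx(beta_star, abs=1e-4)

    def test_matches_sksurv_breslow(self):
        from sksurv.linear_model import CoxPHSurvivalAnalysis
        from sksurv.util import Surv

        cfg = BulkSimConfig(n_samples=120, n_genes=60, n_pathways=3,
                            genes_per_pathway=10, planted_pathways={0: 0.5}, seed=21)
        expr, surv, _, _ = simulate_bulk_cohort(cfg)
        cov = expr.values.iloc[:3].T
        fit = fit_cox(cov, surv)
        ref = CoxPHSurvivalAnalysis(ties="breslow").fit(
            cov.to_numpy(), Surv.from_arrays(surv.event.astype(bool), surv.time)
        )
        np.testing.assert_allclose(fit.coefficients.to_numpy(), ref.coef_, atol=1e-6)

    def test_null_covariate_near_zero(self):
        rng = np.random.default_rng(0)
        surv = make_survival(rng.exponential(100, 300), np.ones(300, dtype=int))
        cov = pd.DataFrame({"x": rng.normal(size=300)}, index=surv.subject_ids)
        fit = fit_cox(cov, surv)
        assert abs(fit.summary.at["x", "beta"]) < 0.15
        assert fit.summary.at["x", "p"] > 0.001

    def test_constant_covariate_rejected(self):
        surv = make_survival([1.0, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        cov = pd.DataFrame({"x": np.ones(5)}, index=surv.subject_ids)
        with pytest.raises(ValueError, match="constant covariate"):
            fit_cox(cov, surv)

    def test_separation_detected(self):
        # Covariate perfectly ordering event times -> monotone likelihood.
        n = 20
        time = np.arange(1, n + 1, dtype=float)
        surv = make_survival(time, np.ones(n, dtype=int))
        cov = pd.DataFrame({"x": -time}, index=surv.subject_ids)
        with pytest.raises((SeparationError, ConvergenceError)):
            fit_cox(cov, surv)

    def test_time_unit_invariance_and_scale_equivariance(self):
        cfg = BulkSimConfig(n_samples=80, n_genes=30, n_pathways=3,
                            genes_per_pathway=10, planted_pathways={1: 0.6}, seed=5)
        expr, surv, _, _ = simulate_bulk_cohort(cfg)
        cov = expr.values.iloc[[0]].T
        fit = fit_cox(cov, surv)
        # Rescale time (days -> years): beta unchanged.
        surv_y = SurvivalTable(surv.data.assign(time=surv.data["time"] / 365.25))
        fit_y = fit_cox(cov, surv_y)
        np.testing.assert_allclose(
            fit.coefficients.to_numpy(), fit_y.coefficients.to_numpy(), atol=1e-7
        )
        # Rescale covariate by c: beta -> beta / c.
        fit_c = fit_cox(cov * 4.0, surv)
        np.testing.assert_allclose(
            fit.coefficients.to_numpy(), 4.0 * fit_c.coefficients.to_numpy(), atol=1e-7
        )

    def test_hazard_ratio_is_exp_beta(self):
        x = np.array([1.0, 0, 1, 0, 1, 0, 1, 0])
        surv = make_survival([3.0, 5, 7, 11, 13, 17, 19, 23], [1, 1, 1, 0, 1, 1, 0, 1])
        fit = fit_cox(pd.DataFrame({"x": x}, index=surv.subject_ids), surv)
        assert fit.summary.at["x", "hr"] == np.exp(fit.summary.at["x", "beta"])
        assert fit.summary.at["x", "hr_lo"] <= fit.summary.at["x", "hr_hi"]


# ---------------------------------------------------------------------------
# univariate screen
# ---------------------------------------------------------------------------


class TestScreen:
    def test_bh_adjustment_matches_hand_computation(self, bulk_cohort):
        expr, surv, sets, _ = bulk_cohort
        feats = expr.values.iloc[:8].T
        res = univariate_cox_screen(feats, surv)
        p = res.table["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        q_hand = np.empty(m)
        prev = 1.0
        for rank_from_top in range(m - 1, -1, -1):
            i = order[rank_from_top]
            q = min(prev, p[i] * m / (rank_from_top + 1))
            q_hand[i] = q
            prev = q
        np.testing.assert_allclose(res.table["q"].to_numpy(), q_hand, atol=1e-12)

    def test_bh_hand_example(self):
        # Verify the BH step on the canonical 4-p-value example through the
        # same adjustment routine the screen uses.
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests([0.001, 0.02, 0.03, 0.8], method="fdr_bh")
        np.testing.assert_allclose(q, [0.004, 0.04, 0.04, 0.8], atol=1e-12)

    def test_planted_pathway_attains_min_q(self, bulk_cohort):
        expr, surv, sets, truth = bulk_cohort
        from driverscope.scoring import ssgsea_scores

        scores = ssgsea_scores(expr, sets)
        res = univariate_cox_screen(scores, surv)
        planted = list(truth.planted["prognostic_pathways"])[0]
        assert res.table["q"].idxmin() == planted
        assert planted in res.retained

    def test_zero_variance_skipped_not_failed(self, bulk_cohort):
        expr, surv, _, _ = bulk_cohort
        feats = expr.values.iloc[:3].T.copy()
        feats["flat"] = 1.0
        res = univariate_cox_screen(feats, surv)
        assert res.skipped == {"flat": "zero variance"}
        assert "flat" not in res.table.index

    def test_null_features_rarely_retained(self):
        retained = []
        for seed in range(5):
            cfg = BulkSimConfig(n_samples=150, n_genes=100, n_pathways=10,
                                genes_per_pathway=10, planted_pathways={}, seed=seed + 50)
            expr, surv, _, _ = simulate_bulk_cohort(cfg)
            res = univariate_cox_screen(expr.values.iloc[:100].T, surv)
            retained.append(len(res.retained))
        assert np.mean(retained) <= 1.0


# ---------------------------------------------------------------------------
# stability selection
# ---------------------------------------------------------------------------


class TestStability:
    def test_zero_resamples_rejected(self, bulk_cohort):
        expr, surv, _, _ = bulk_cohort
        with pytest.raises(ValueError, match="n_resamples"):
            stability_selection(expr.values.iloc[:5].T, surv, n_resamples=0)

    def test_duplicated_feature_exchangeability(self):
        cfg = BulkSimConfig(n_samples=200, n_genes=100, n_pathways=10,
                            genes_per_pathway=10, planted_pathways={0: 0.8}, seed=13)
        expr, surv, sets, _ = simulate_bulk_cohort(cfg)
        from driverscope.scoring import ssgsea_scores

        feats = ssgsea_scores(expr, sets).nes.T.copy()
        feats["PW000_copy"] = feats["PW000"] + 0.0
        res = stability_selection(feats, surv, n_resamples=200, seed=3)
        assert abs(res.frequencies["PW000"] - res.frequencies["PW000_copy"]) <= 0.1

    def test_frequency_times_resamples_is_integer(self, bulk_cohort):
        expr, surv, _, _ = bulk_cohort
        res = stability_selection(expr.values.iloc[:6].T, surv, n_resamples=25, seed=1)
        counts = res.frequencies * res.n_resamples
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)


# ---------------------------------------------------------------------------
# concordance and td-AUC
# ---------------------------------------------------------------------------


class TestConcordance:
    def test_perfect_ordering_gives_one(self):
        time = np.array([1.0, 2, 3, 4, 5])
        surv = make_survival(time, np.ones(5, dtype=int))
        risk = -time  # higher risk -> earlier event
        assert concordance_index(risk, surv) == 1.0

    def test_constant_risk_gives_half(self):
        surv = make_survival([1.0, 2, 3, 4], [1, 1, 0, 1])
        assert concordance_index(np.zeros(4), surv) == 0.5

    def test_matches_exhaustive_pair_oracle(self):
        time = [5.0, 8.0, 8.0, 12.0, 3.0, 9.0]
        event = [1, 0, 1, 1, 0, 1]
        risk = [2.0, 1.0, 1.5, 0.5, 3.0, 1.5]
        surv = make_survival(time, event)
        expected = harrell_c_pairs(risk, time, event)
        assert concordance_index(np.array(risk), surv) == pytest.approx(expected, abs=1e-12)

    def test_flip_symmetry_without_ties(self):
        rng = np.random.default_rng(2)
        time = rng.uniform(1, 100, 30)
        event = rng.integers(0, 2, 30)
        event[0] = 1
        risk = rng.normal(size=30)
        surv = make_survival(time, event)
        c1 = concordance_index(risk, surv)
        c2 = concordance_index(-risk, surv)
        assert c1 + c2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_sksurv(self):
        from sksurv.metrics import concordance_index_censored

        rng = np.random.default_rng(8)
        time = rng.uniform(1, 100, 50)
        event = rng.integers(0, 2, 50).astype(bool)
        event[:2] = True
        risk = rng.normal(size=50)
        surv = make_survival(time, event.astype(int))
        ours = concordance_index(risk, surv)
        ref = concordance_index_censored(event, time, risk)[0]
        assert ours == pytest.approx(ref, abs=1e-12)


class TestTdAuc:
    def test_perfect_separation_no_censoring(self):
        time = np.array([10.0, 20, 30, 40, 50, 60])
        surv = make_survival(time, np.ones(6, dtype=int))
        auc = time_dependent_auc(-time, surv, horizons=[25.0, 45.0])
        assert auc[25.0] == 1.0 and auc[45.0] == 1.0

    def test_constant_risk_half(self):
        surv = make_survival([10.0, 20, 30, 40], [1, 1, 1, 1])
        auc = time_dependent_auc(np.zeros(4), surv, horizons=[25.0])
        assert auc[25.0] == 0.5

    def test_matches_direct_sum_oracle(self):
        time = [4.0, 7.0, 9.0, 12.0, 15.0, 18.0, 21.0, 24.0, 27.0, 30.0]
        event = [1, 0, 1, 1, 0, 1, 0, 1, 1, 0]
        risk = [3.1, 2.0, 2.5, 1.0, 0.5, 1.5, 2.2, 0.2, 1.1, 0.3]
        surv = make_survival(time, event)
        for h in (10.0, 20.0):
            expected = ipcw_auc_direct(risk, time, event, h)
            got = time_dependent_auc(np.array(risk), surv, horizons=[h])[h]
            assert got == pytest.approx(expected, abs=1e-10)

    def test_horizon_beyond_followup_undefined(self):
        surv = make_survival([10.0, 20, 30], [1, 1, 1])
        auc = time_dependent_auc(np.array([1.0, 2, 3]), surv, horizons=[100.0])
        assert np.isnan(auc[100.0])


# ---------------------------------------------------------------------------
# KM / log-rank / cutpoint
# ---------------------------------------------------------------------------


class TestKmLogrank:
    def test_identical_groups_statistic_zero(self):
        time = [5.0, 10, 15, 20, 5, 10, 15, 20]
        event = [1, 0, 1, 1, 1, 0, 1, 1]
        surv = make_survival(time, event)
        group = ["A", "A", "A", "A", "B", "B", "B", "B"]
        res = km_logrank(surv, group)
        assert res.chi_square == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_matches_hand_o_minus_e(self):
        time = [3.0, 5, 7, 9, 11, 4, 6, 8, 10, 12]
        event = [1, 1, 0, 1, 1, 1, 0, 1, 1, 0]
        group1 = [True] * 5 + [False] * 5
        surv = make_survival(time, event)
        o_e, v = logrank_o_minus_e(time, event, group1)
        expected_chi2 = o_e**2 / v
        res = km_logrank(surv, ["A" if g else "B" for g in group1])
        assert res.chi_square == pytest.approx(expected_chi2, abs=1e-9)

    def test_single_group_rejected(self):
        surv = make_survival([1.0, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError, match="2 non-empty groups"):
            km_logrank(surv, ["A", "A", "A"])


class TestCutpoint:
    def test_binary_marker_forced_midpoint(self):
        surv = make_survival([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10],
                             [1, 1, 1, 1, 1, 1, 1, 1, 1, 1])
        marker = pd.Series([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], index=surv.subject_ids)
        res = optimal_cutpoint(marker, surv)
        assert res.cutpoint == 0.5
        assert res.selection_biased

    def test_constant_marker_rejected(self):
        surv = make_survival([1.0, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError, match="distinct"):
            optimal_cutpoint(pd.Series([1.0, 1, 1], index=surv.subject_ids), surv)

    def test_recovers_planted_threshold(self):
        rng = np.random.default_rng(17)
        n = 300
        marker = rng.normal(size=n)
        cut_true = np.quantile(marker, 0.4)
        high = marker > cut_true
        time = rng.exponential(np.where(high, 50.0, 200.0))
        surv = make_survival(np.maximum(time, 0.01), np.ones(n, dtype=int))
        res = optimal_cutpoint(pd.Series(marker, index=surv.subject_ids), surv)
        found_pct = (marker <= res.cutpoint).mean()
        assert abs(found_pct - 0.4) <= 0.10


# ---------------------------------------------------------------------------
# benchmarking harness
# ---------------------------------------------------------------------------


class TestBenchmark:
    def test_degenerate_single_point_search(self, bulk_cohort):
        expr, surv, sets, _ = bulk_cohort
        from driverscope.scoring import ssgsea_scores

        feats = ssgsea_scores(expr, sets).nes.T
        spec = LearnerSpec("pcox", PenalizedCoxLearner, {"alpha": ("choice", [1.0])})
        report = benchmark_models(feats, surv, [spec], n_search=1, seed=0)
        entry = report.per_learner["pcox"]
        assert entry["best_params"] == {"alpha": 1.0}
        assert 0.0 <= entry["cv_cindex"] <= 1.0

    def test_strong_signal_cv_cindex_above_07(self):
        cfg = BulkSimConfig(n_samples=300, n_genes=500, n_pathways=10,
                            genes_per_pathway=20, planted_pathways={0: 1.0}, seed=29)
        expr, surv, sets, _ = simulate_bulk_cohort(cfg)
        from driverscope.scoring import ssgsea_scores

        feats = ssgsea_scores(expr, sets).nes.T
        spec = LearnerSpec("pcox", PenalizedCoxLearner,
                           {"alpha": ("loguniform", 0.1, 10.0)})
        report = benchmark_models(feats, surv, [spec], n_search=3, seed=1)
        assert report.per_learner["pcox"]["cv_cindex"] > 0.7

    def test_excessive_folds_rejected(self, bulk_cohort):
        expr, surv, _, _ = bulk_cohort
        spec = LearnerSpec("pcox", PenalizedCoxLearner, {"alpha": ("choice", [1.0])})
        with pytest.raises(ValueError, match="n_folds"):
            benchmark_models(expr.values.iloc[:3].T, surv, [spec], n_folds=1000)


# ---------------------------------------------------------------------------
# Shapley attribution
# ---------------------------------------------------------------------------


class TestShapley:
    def test_constant_model_zero_attribution(self):
        feats = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)),
                             columns=list("abc"))
        res = shapley_importance(lambda df: np.ones(len(df)), feats,
                                 n_permutations=5, seed=0)
        assert (res.contributions.to_numpy() == 0).all()

    def test_additive_model_closed_form(self):
        rng = np.random.default_rng(1)
        feats = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        coef = np.array([1.5, -2.0, 0.5, 3.0])
        model = lambda df: df.to_numpy() @ coef
        res = shapley_importance(model, feats, n_permutations=200, seed=2)
        expected = (feats - feats.mean()).to_numpy() * coef
        np.testing.assert_allclose(res.contributions.to_numpy(), expected, atol=1e-8)

    def test_contributions_sum_to_prediction_minus_baseline(self):
        rng = np.random.default_rng(3)
        feats = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        model = lambda df: np.tanh(df.to_numpy()).sum(axis=1) + (
            df.to_numpy()[:, 0] * df.to_numpy()[:, 1]
        )
        res = shapley_importance(model, feats, n_permutations=50, seed=4)
        pred = model(feats)
        base_pred = model(pd.DataFrame([feats.mean()], columns=feats.columns))[0]
        np.testing.assert_allclose(
            res.contributions.sum(axis=1).to_numpy(), pred - base_pred, atol=1e-10
        )

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        feats = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("abcd"))
        base = feats.mean().to_numpy()

        def f_vec(z):
            return np.tanh(z[0] * z[1]) + z[2] ** 2 + np.sin(z[3]) + z[0]

        model = lambda df: np.array([f_vec(row) for row in df.to_numpy()])
        n_perm = 3000
        res = shapley_importance(model, feats, n_permutations=n_perm, seed=6)
        for i in range(len(feats)):
            exact = exact_shapley(f_vec, feats.to_numpy()[i], base)
            # 3 Monte-Carlo standard errors per coordinate.
            diff = np.abs(res.contributions.iloc[i].to_numpy() - exact)
            assert (diff < 3 * 1.0 / np.sqrt(n_perm) + 1e-6).all()
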