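"""Evaluation harness: metric oracles, null calibration, splits, odds ratios."""

import itertools

import numpy as np
import pandas as pd
import pytest

from koashape.evaluation import (EvalResult, SplitConfig, TaskInfeasibleError,
                                 TaskSpec, balanced_accuracy,
                                 balanced_monte_carlo, build_task_labels,
                                 derive_incident_koa, fit_predict_linear_svm,
                                 logistic_odds_ratios, minmax_normalize,
                                 resolve_feature_columns, roc_auc, run_task,
                                 weighted_kappa, weighted_average_results)
from koashape.meas_features import MEAS_COLUMNS


# ---------------------------------------------------------------------------
# independent metric oracles
# ---------------------------------------------------------------------------

def _kappa_bruteforce(true, pred, n_levels, power=1):
    """Direct evaluation of 1 - sum(w O) / sum(w E) from the definition."""
    true, pred = np.asarray(true), np.asarray(pred)
    n = len(true)
    obs = np.zeros((n_levels, n_levels))
    for t, p in zip(true, pred):
        obs[t, p] += 1
    marg_t = obs.sum(axis=1)
    marg_p = obs.sum(axis=0)
    exp = np.outer(marg_t, marg_p) / n
    w = np.abs(np.subtract.outer(np.arange(n_levels), np.arange(n_levels)))
    w = (w / (n_levels - 1)) ** power
    return 1.0 - (w * obs).sum() / (w * exp).sum()


def _auc_bruteforce(scores, labels):
    """Exhaustive positive/negative pair counting with half ties."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > q else (0.5 if p == q else 0.0)
               for p, q in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestBalancedAccuracy:
    def test_perfect(self):
        assert balanced_accuracy([0, 1, 1, 0], [0, 1, 1, 0]) == 1.0

    def test_sens_spec_mean(self):
        """Sensitivity 0.8, specificity 0.6 gives BA 0.7 exactly."""
        true = [1] * 10 + [0] * 10
        pred = [1] * 8 + [0] * 2 + [0] * 6 + [1] * 4
        assert balanced_accuracy(true, pred) == pytest.approx(0.7)

    def test_three_class_majority_predictor(self):
        true = [0] * 6 + [1] * 3 + [2] * 1
        pred = [0] * 10
        assert balanced_accuracy(true, pred) == pytest.approx(1 / 3)


class TestWeightedKappa:
    def test_identity_is_one(self):
        assert weighted_kappa([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 4, 100)
        b = rng.integers(0, 4, 100)
        assert weighted_kappa(a, b) == pytest.approx(weighted_kappa(b, a))

    @pytest.mark.parametrize("weights,power", [("linear", 1), ("quadratic", 2)])
    def test_matches_bruteforce_on_constructed_table(self, weights, power):
        """A constructed 3x3 confusion pattern matches the direct formula."""
        true = [0] * 10 + [1] * 10 + [2] * 10
        pred = ([0] * 7 + [1] * 2 + [2] * 1
                + [0] * 3 + [1] * 5 + [2] * 2
                + [0] * 1 + [1] * 3 + [2] * 6)
        expected = _kappa_bruteforce(true, pred, 3, power)
        assert weighted_kappa(true, pred, weights=weights) == pytest.approx(expected)

    def test_independent_labels_near_zero(self):
        """Chance-level agreement: |kappa| < 0.05 at n = 10,000."""
        rng = np.random.default_rng(1)
        a = rng.integers(0, 5, 10_000)
        b = rng.integers(0, 5, 10_000)
        assert abs(weighted_kappa(a, b)) < 0.05

    def test_single_label_raises(self):
        with pytest.raises(ValueError):
            weighted_kappa([1, 1, 1], [1, 1, 1])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_exhaustive_pair_counting(self):
        scores = [0.1, 0.4, 0.4, 0.8]
        labels = [0, 0, 1, 1]
        assert roc_auc(scores, labels) == pytest.approx(
            _auc_bruteforce(scores, labels))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        if labels.sum() in (0, 200):
            labels[0] = 1 - labels[0]
        base = roc_auc(scores, labels)
        for f in (np.exp, np.arctan, lambda s: s ** 3 + 5 * s):
            assert roc_auc(f(scores), labels) == pytest.approx(base)

    def test_one_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


# ---------------------------------------------------------------------------
# splits and normalization
# ---------------------------------------------------------------------------

class TestBalancedMonteCarlo:
    def test_counts_and_disjointness(self):
        labels = np.array([0] * 500 + [1] * 50)
        cfg = SplitConfig(n_repeats=5, seed=0)
        for tr, te in balanced_monte_carlo(labels, cfg):
            assert len(tr) + len(te) == 100           # balanced to 2 x 50
            assert len(te) == 10                      # 5 test per class
            assert len(np.intersect1d(tr, te)) == 0
            for c in (0, 1):
                assert (labels[te] == c).sum() == 5
                assert (labels[tr] == c).sum() == 45

    def test_deterministic_given_seed(self):
        labels = np.array([0] * 40 + [1] * 30 + [2] * 20)
        cfg = SplitConfig(n_repeats=3, seed=9)
        a = list(balanced_monte_carlo(labels, cfg))
        b = list(balanced_monte_carlo(labels, cfg))
        for (tr1, te1), (tr2, te2) in zip(a, b):
            np.testing.assert_array_equal(tr1, tr2)
            np.testing.assert_array_equal(te1, te2)

    def test_minority_too_small_raises(self):
        labels = np.array([0] * 100 + [1] * 5)
        with pytest.raises(TaskInfeasibleError):
            next(balanced_monte_carlo(labels, SplitConfig(n_repeats=1)))


class TestMinMax:
    def test_formula_and_out_of_range(self):
        train = np.array([[2.0], [10.0]])
        other = np.array([[6.0], [12.0]])
        ztr, zot = minmax_normalize(train, other)
        np.testing.assert_allclose(ztr.ravel(), [0.0, 1.0])
        np.testing.assert_allclose(zot.ravel(), [0.5, 1.25])

    def test_constant_feature_zeroed(self):
        train = np.array([[3.0, 1.0], [3.0, 2.0]])
        ztr, zot = minmax_normalize(train, train)
        assert (ztr[:, 0] == 0.0).all() and (zot[:, 0] == 0.0).all()


class TestLinearSvm:
    def test_separable_blobs(self):
        rng = np.random.default_rng(3)
        x0 = rng.normal(0, 1, (100, 5))
        x1 = rng.normal(10, 1, (100, 5))
        x = np.vstack([x0, x1])
        y = np.array([0] * 100 + [1] * 100)
        pred, score = fit_predict_linear_svm(x, y, x)
        assert balanced_accuracy(y, pred) >= 0.99
        assert score.ndim == 1

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            fit_predict_linear_svm(np.zeros((5, 2)), np.zeros(5), np.zeros((2, 2)))

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(60, 4))
        y = rng.integers(0, 2, 60)
        p1, s1 = fit_predict_linear_svm(x, y, x, seed=5)
        p2, s2 = fit_predict_linear_svm(x, y, x, seed=5)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(s1, s2)


# ---------------------------------------------------------------------------
# task labels
# ---------------------------------------------------------------------------

def _records_frame(n=120, seed=0):
    rng = np.random.default_rng(seed)
    sev = rng.uniform(0, 1, n)
    klg = np.digitize(sev, [0.2, 0.4, 0.6, 0.8])
    return pd.DataFrame({
        "knee_id": [f"K{i:03d}" for i in range(n)],
        "klg": klg,
        "mjsn": np.digitize(sev, [0.35, 0.6, 0.85]),
        "ljsn": np.digitize(sev, [0.45, 0.7, 0.9]),
        "tkr_1y": (sev > 0.7).astype(float),
        "inc_koa_1y": np.where(klg >= 2, np.nan, (sev > 0.3).astype(float)),
    })


class TestTaskLabels:
    def test_grouping_maps_to_indices(self):
        recs = _records_frame()
        task = TaskSpec("classification", "KLG", ((0, 1), (2,), (3, 4)))
        labels, include = build_task_labels(recs, task)
        assert set(labels[include]) == {0, 1, 2}
        assert (labels[recs.klg.isin([0, 1]) & include] == 0).all()

    def test_missing_grade_excluded(self):
        recs = _records_frame()
        recs.loc[0, "klg"] = np.nan
        task = TaskSpec("classification", "KLG",
                        ((0,), (1,), (2,), (3,), (4,)))
        _, include = build_task_labels(recs, task)
        assert not include[0]

    def test_outcome_columns_used(self):
        recs = _records_frame()
        task = TaskSpec("prediction", "tkr", horizon_years=1)
        labels, include = build_task_labels(recs, task)
        assert include.all()
        assert set(labels) <= {0, 1}

    def test_not_at_risk_excluded(self):
        recs = _records_frame()
        task = TaskSpec("prediction", "incident_koa", horizon_years=1)
        labels, include = build_task_labels(recs, task)
        assert not include[recs.inc_koa_1y.isna().to_numpy()].any()

    def test_empty_class_infeasible(self):
        recs = _records_frame()
        recs["klg"] = 0
        recs.loc[:4, "klg"] = 4
        task = TaskSpec("classification", "KLG", ((0,), (2,)))
        with pytest.raises(TaskInfeasibleError):
            build_task_labels(recs, task)

    def test_disjoint_grouping_enforced(self):
        with pytest.raises(ValueError):
            TaskSpec("classification", "KLG", ((0, 1), (1, 2)))


class TestIncidentDerivation:
    def test_longitudinal_definition(self):
        """KLG 0 at index, KLG 2 with mJSN 1 a year later: positive within
        one year; KLG 3 at index: not at risk."""
        recs = pd.DataFrame({
            "knee_id": ["A", "A", "B", "B", "C", "C"],
            "years": [0, 1, 0, 1, 0, 3],
            "klg": [0, 2, 3, 3, 1, 2],
            "mjsn": [0, 1, 2, 2, 0, 1],
            "ljsn": [0, 0, 0, 0, 0, 0],
        })
        lab1 = derive_incident_koa(recs, 1)
        assert lab1["A"] == 1.0
        assert np.isnan(lab1["B"])       # KLG >= 2 at index: not at risk
        assert lab1["C"] == 0.0          # converts only at year 3
        lab3 = derive_incident_koa(recs, 3)
        assert lab3["C"] == 1.0

    def test_klg2_without_jsn_not_incident(self):
        recs = pd.DataFrame({
            "knee_id": ["D", "D"], "years": [0, 1],
            "klg": [0, 2], "mjsn": [0, 0], "ljsn": [0, 0]})
        assert derive_incident_koa(recs, 1)["D"] == 0.0


# ---------------------------------------------------------------------------
# feature sets, run_task, odds ratios
# ---------------------------------------------------------------------------

def _feature_frame(n=120, seed=0, n_ldse=80):
    rng = np.random.default_rng(seed)
    recs = _records_frame(n, seed)
    data = {c: rng.normal(size=n) for c in MEAS_COLUMNS}
    sev_proxy = recs["klg"].to_numpy() + rng.normal(0, 0.8, n)
    data["E_mM"] = sev_proxy  # one informative column
    for s in ("FB", "TB", "mM", "lM"):
        for k in range(n_ldse):
            data[f"ldse_{s}_{k:03d}"] = rng.normal(size=n)
    feats = pd.DataFrame(data)
    return feats, recs


class TestFeatureSets:
    def test_meas_and_combined_dimensions(self):
        feats, _ = _feature_frame()
        assert len(resolve_feature_columns("MEAS", feats.columns)) == 14
        assert len(resolve_feature_columns("LDSE-COMB", feats.columns)) == 300
        cols = resolve_feature_columns("LDSE-COMB + MEAS", feats.columns)
        assert len(cols) == 314
        assert len(resolve_feature_columns("LDSE-FB", feats.columns)) == 80

    def test_unknown_set_raises(self):
        feats, _ = _feature_frame()
        with pytest.raises(KeyError):
            resolve_feature_columns("LDSE-XX", feats.columns)


class TestRunTask:
    def test_deterministic_and_shapes(self):
        feats, recs = _feature_frame()
        task = TaskSpec("classification", "KLG", ((0, 1), (2, 3, 4)),
                        feature_set="MEAS")
        cfg = SplitConfig(n_repeats=5, seed=3)
        r1 = run_task(feats, recs, task, cfg)
        r2 = run_task(feats, recs, task, cfg)
        np.testing.assert_array_equal(r1.ba, r2.ba)
        np.testing.assert_array_equal(r1.kappa, r2.kappa)
        assert len(r1.ba) == 5

    def test_rows_with_missing_features_dropped(self):
        feats, recs = _feature_frame()
        feats.loc[0, "V_FC"] = np.nan
        task = TaskSpec("classification", "KLG", ((0, 1), (2, 3, 4)),
                        feature_set="MEAS")
        res = run_task(feats, recs, task, SplitConfig(n_repeats=2, seed=0))
        assert res.n_dropped_missing == 1

    def test_permuted_labels_ba_near_half(self):
        """Null calibration: label-permuted binary task converges to
        BA 0.5 within 3 Monte-Carlo standard errors over 200 repeats."""
        feats, recs = _feature_frame(n=200, seed=5)
        rng = np.random.default_rng(6)
        recs = recs.assign(klg=rng.permutation(recs["klg"].to_numpy()))
        task = TaskSpec("classification", "KLG", ((0, 1), (2, 3, 4)),
                        feature_set="MEAS")
        res = run_task(feats, recs, task, SplitConfig(n_repeats=200, seed=7))
        se = res.ba.std(ddof=1) / np.sqrt(len(res.ba))
        assert abs(res.ba.mean() - 0.5) < 3 * se

    def test_weighted_average_over_cohorts(self):
        r1 = EvalResult("t", "MEAS", n_included=100, n_dropped_missing=0,
                        ba=np.array([0.8, 0.8]))
        r2 = EvalResult("t", "MEAS", n_included=300, n_dropped_missing=0,
                        ba=np.array([0.6, 0.6]))
        mean, _sd = weighted_average_results([r1, r2], "ba")
        assert mean == pytest.approx(0.65)


class TestOddsRatios:
    def test_recovery_of_known_effect(self):
        """Single standardized feature with beta = ln 2 at n = 5000:
        estimated OR close to 2 and CI covering 2 in >= 90% of seeds."""
        n, beta = 5000, np.log(2.0)
        covered, ors = 0, []
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=n)
            p = 1 / (1 + np.exp(-(-1.0 + beta * x)))
            y = rng.uniform(size=n) < p
            table = logistic_odds_ratios(pd.DataFrame({"f": x}), y.astype(int))
            ors.append(table.odds_ratio[0])
            covered += table.ci_low[0] <= 2.0 <= table.ci_high[0]
        assert 1.8 <= np.mean(ors) <= 2.2
        assert covered >= 0.9 * n_seeds

    def test_null_feature_ci_covers_one(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=4000)
        y = rng.integers(0, 2, 4000)
        table = logistic_odds_ratios(pd.DataFrame({"f": x}), y)
        assert table.ci_low[0] <= 1.0 <= table.ci_high[0]

    def test_single_class_outcome_raises(self):
        with pytest.raises(ValueError):
            logistic_odds_ratios(pd.DataFrame({"f": [1.0, 2.0]}), [1, 1])

    def test_ci_brackets_or(self):
        feats, recs = _feature_frame(n=400, seed=12)
        table = logistic_odds_ratios(feats[list(MEAS_COLUMNS)],
                                     recs["tkr_1y"].astype(int))
        ok = ~np.asarray(table.separation_flags)
        assert np.all(table.ci_low[ok] <= table.odds_ratio[ok])
        assert np.all(table.odds_ratio[ok] <= table.ci_high[ok])
        assert np.all(table.odds_ratio > 0)
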