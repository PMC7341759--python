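import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from lncnet import (
    ConfigError,
    classify_relevance,
    cox_univariate,
    dichotomize,
    group_t_test,
    logistic_univariate,
)
from lncnet.clinical import DIVERGED, NOT_TESTABLE, OK, associate


# --- dichotomization ---------------------------------------------------------


def _clin(**kw):
    base = {
        "patient_id": "P1",
        "tumor_size_cm": None,
        "vascular_invasion": None,
        "stage": None,
        "grade": None,
        "encapsulation": None,
        "invasion": None,
        "os_time": None,
        "os_event": None,
    }
    base.update(kw)
    return pd.DataFrame([base])


class TestDichotomize:
    def test_large_tumor_makes_composite_poor_despite_good_stage(self):
        out = dichotomize(_clin(tumor_size_cm=6.0, stage=2, vascular_invasion=False))
        assert out.loc[0, "tumor_properties"] == "poor"

    def test_all_good_subphenotypes_give_good(self):
        out = dichotomize(_clin(tumor_size_cm=3.0, stage=1, vascular_invasion=False))
        assert out.loc[0, "tumor_properties"] == "good"

    @pytest.mark.parametrize("grade,label", [(1, "good"), (2, "good"), (3, "poor"), (4, "poor")])
    def test_grade_cutoff(self, grade, label):
        assert dichotomize(_clin(grade=grade)).loc[0, "grade"] == label

    @pytest.mark.parametrize(
        "caps,label",
        [("complete", "good"), ("incomplete", "poor"), ("none", "poor")],
    )
    def test_encapsulation(self, caps, label):
        assert dichotomize(_clin(encapsulation=caps)).loc[0, "capsule"] == label

    def test_missing_subphenotypes_propagate_only_when_nothing_available(self):
        assert dichotomize(_clin()).loc[0, "tumor_properties"] == "missing"
        # one available poor sub-phenotype decides the composite
        assert dichotomize(_clin(stage=4)).loc[0, "tumor_properties"] == "poor"
        assert dichotomize(_clin(invasion=None)).loc[0, "invasion"] == "missing"


# --- group t-test ------------------------------------------------------------


class TestGroupTTest:
    def test_identical_arms(self):
        fc, p = group_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert fc == 1.0 and p == 1.0

    def test_hand_computed_case(self):
        # delta = 2 -> fc = +4; pooled sd 1, t = 2/sqrt(2/3) ~ 2.449, df 4
        fc, p = group_t_test([3.0, 4.0, 5.0], [1.0, 2.0, 3.0])
        assert fc == pytest.approx(4.0, abs=1e-12)
        assert p == pytest.approx(0.07048399691021, abs=1e-6)

    def test_small_arm_not_testable(self):
        fc, p = group_t_test([1.0], [1.0, 2.0])
        assert math.isnan(fc) and math.isnan(p)

    def test_matches_formula_oracle_on_random_inputs(self):
        rng = np.random.default_rng(10)
        from scipy import stats

        for _ in range(100):
            a = rng.normal(size=rng.integers(2, 10))
            b = rng.normal(size=rng.integers(2, 10))
            fc, p = group_t_test(a, b)
            t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
            assert p == pytest.approx(p_ref, abs=1e-9)
            assert math.copysign(1, fc) == (1 if a.mean() >= b.mean() else -1)


# --- Cox ---------------------------------------------------------------------


def breslow_loglik(beta, x, time, event):
    """Breslow partial log-likelihood, written from the definition."""
    ll = 0.0
    for i in range(len(x)):
        if not event[i]:
            continue
        risk = [j for j in range(len(x)) if time[j] >= time[i]]
        ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


def grid_search_beta(x, time, event, lo=-5, hi=5, steps=20001):
    grid = np.linspace(lo, hi, steps)
    ll = [breslow_loglik(b, x, time, event) for b in grid]
    return grid[int(np.argmax(ll))]


class TestCox:
    def test_constant_covariate_not_testable(self):
        res = cox_univariate([1, 1, 1, 1], [2, 5, 3, 9], [1, 1, 1, 1])
        assert res.status == NOT_TESTABLE

    def test_monotone_likelihood_flagged_as_divergent(self):
        # both x = 1 subjects fail before every x = 0 subject, all events:
        # the Breslow partial likelihood is monotone in beta (MLE at +inf)
        res = cox_univariate([1, 0, 1, 0], [2, 5, 3, 9], [1, 1, 1, 1])
        assert res.status == DIVERGED

    def test_matches_grid_search_oracle_on_small_instance(self):
        x = [1.0, 0.0, 1.0, 0.0]
        time = [2.0, 9.0, 5.0, 3.0]
        event = [1, 1, 1, 1]
        res = cox_univariate(x, time, event)
        ref = grid_search_beta(x, time, event)
        assert res.status == OK
        assert res.beta == pytest.approx(ref, abs=1e-3)
        assert res.hr == pytest.approx(math.exp(res.beta))

    def test_matches_oracle_on_random_tiny_instances(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 10:
            n = int(rng.integers(4, 7))
            x = rng.normal(size=n)
            time = rng.exponential(5.0, size=n).round(3)
            event = np.ones(n, dtype=int)
            res = cox_univariate(x, time, event)
            if res.status != OK or abs(res.beta) > 4:
                continue
            ref = grid_search_beta(x, time, event)
            assert res.beta == pytest.approx(ref, abs=1.5e-3)
            checked += 1

    def test_agrees_with_lifelines_without_ties(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(12)
        n = 40
        x = rng.normal(size=n)
        time = rng.exponential(100 * np.exp(-0.5 * x))
        event = rng.random(n) > 0.2
        res = cox_univariate(x, time, event)
        df = pd.DataFrame({"x": x, "T": time, "E": event.astype(int)})
        cph = lifelines.CoxPHFitter().fit(df, duration_col="T", event_col="E")
        assert res.beta == pytest.approx(cph.params_["x"], abs=1e-4)


# --- logistic ----------------------------------------------------------------


def logistic_slope_oracle(x, y):
    """Slope from direct likelihood minimization, independent of the fit path."""

    def nll(theta):
        eta = theta[0] + theta[1] * np.asarray(x)
        return float(np.sum(np.log1p(np.exp(eta)) - np.asarray(y) * eta))

    res = minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 10000})
    return res.x[1]


class TestLogistic:
    def test_balanced_symmetric_covariate_gives_zero_slope(self):
        res = logistic_univariate([-1, 1, -1, 1], [0, 0, 1, 1])
        assert res.status == OK
        assert res.beta == pytest.approx(0.0, abs=1e-6)

    def test_strong_planted_link_detected(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=49)
        y = (x > np.median(x)).astype(float)
        x = x + 2.0 * (2 * y - 1)  # widen the margin by 2 sd
        res = logistic_univariate(x, y)
        if res.status == OK:  # extreme margins may separate perfectly
            assert res.odds_ratio > 1 and res.p < 0.05
        else:
            assert res.status == DIVERGED

    def test_one_class_absent_rejected(self):
        with pytest.raises(ConfigError):
            logistic_univariate([1.0, 2.0, 3.0], [1, 1, 1])

    def test_matches_likelihood_scan_oracle(self):
        rng = np.random.default_rng(14)
        checked = 0
        while checked < 10:
            n = 6
            x = rng.normal(size=n)
            y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(float)
            if y.min() == y.max():
                continue
            res = logistic_univariate(x, y)
            if res.status != OK or abs(res.beta) > 5:
                continue
            assert res.beta == pytest.approx(logistic_slope_oracle(x, y), abs=1e-3)
            checked += 1


# --- relevance classification ------------------------------------------------


def _de_row(direction, is_de=True):
    return pd.DataFrame(
        [{"feature_id": "F1", "direction": direction, "is_de": is_de}]
    )


def _assoc_row(group, direction, significant=True):
    return pd.DataFrame(
        [
            {
                "feature_id": "F1",
                "group": group,
                "effect": 1.8,
                "p": 0.01,
                "direction": direction,
                "significant": significant,
                "status": "ok",
            }
        ]
    )


class TestClassifyRelevance:
    def test_up_regulated_and_up_in_poor_is_oncogenic(self):
        rel = classify_relevance(_de_row("up"), _assoc_row("grade", "up_in_poor"))
        assert rel.loc[0, "cls"] == "oncogenic"
        assert rel.loc[0, "groups"] == "grade"

    def test_direction_conflict_is_not_relevant(self):
        rel = classify_relevance(_de_row("up"), _assoc_row("grade", "down_in_poor"))
        assert rel.loc[0, "cls"] == "none"

    def test_down_regulated_protective_hazard_is_suppressor(self):
        rel = classify_relevance(_de_row("down"), _assoc_row("survival", "down_in_poor"))
        assert rel.loc[0, "cls"] == "suppressor"
        assert rel.loc[0, "groups"] == "survival"

    def test_non_de_feature_is_never_relevant(self):
        rel = classify_relevance(
            _de_row("up", is_de=False), _assoc_row("grade", "up_in_poor")
        )
        assert rel.loc[0, "cls"] == "none"


# --- planted recovery on the synthetic cohort --------------------------------


def test_planted_module_features_classified_oncogenic(tiny_cohort):
    from lncnet import run_de

    de = run_de(tiny_cohort.expression, tiny_cohort.design)
    phen = dichotomize(tiny_cohort.clinical)
    assoc = associate(tiny_cohort.expression, tiny_cohort.design, phen)
    rel = classify_relevance(de, assoc).set_index("feature_id")
    planted = tiny_cohort.truth.modules[0]["lnc_members"]
    labels = [rel.loc[f, "cls"] for f in planted]
    assert labels.count("oncogenic") >= 2  # sensitivity at this tiny scale
    assert "suppressor" not in labels  # never contradicts the planted direction
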