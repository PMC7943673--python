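"""Agreement, dichotomization, logistic, survival and the multivariate gate."""

import numpy as np
import pytest

from sirtdose import (
    PatientRecord,
    agreement_suite,
    dichotomize,
    km_median,
    logistic_univariate,
    multivariate_gate,
    survival_suite,
)
from sirtdose.errors import InsufficientDataError, ParameterError


def patients(values, sphere="resin", ids=None):
    ids = ids or [f"P{i}" for i in range(len(values))]
    return [
        PatientRecord(id=i, sphere_type=sphere, injected_gbq=1.5,
                      metrics={"Dm-Pre-C_MRI": v})
        for i, v in zip(ids, values)
    ]


class TestAgreementSuite:
    def test_identical_pairs(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = agreement_suite(x, x)
        assert res["spearman_rho"] == pytest.approx(1.0)
        assert res["bland_altman"]["mean_diff"] == 0.0
        assert res["wilcoxon_p"] == 1.0

    def test_perfect_inversion(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        res = agreement_suite(x, -x)
        assert res["spearman_rho"] == pytest.approx(-1.0)

    def test_monotone_nonlinear_pairs(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0])
        post = np.array([2.0, 4.0, 6.0, 9.0])
        assert agreement_suite(pre, post)["spearman_rho"] == pytest.approx(1.0)

    def test_bland_altman_t_interval(self):
        from scipy import stats as sps

        rng = np.random.default_rng(0)
        pre = rng.normal(100, 10, 30)
        post = pre + rng.normal(-16, 20, 30)
        res = agreement_suite(pre, post)
        diff = post - pre
        sem = diff.std(ddof=1) / np.sqrt(30)
        t = sps.t.ppf(0.975, 29)
        lo, hi = res["bland_altman"]["ci95"]
        assert lo == pytest.approx(diff.mean() - t * sem)
        assert hi == pytest.approx(diff.mean() + t * sem)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            agreement_suite([1.0, 2.0], [1.0, 2.0])


class TestDichotomize:
    def test_even_split_single_type(self):
        recs = patients([1.0, 2.0, 3.0, 4.0])
        d = dichotomize(recs, "Dm-Pre-C_MRI")
        assert d.medians["resin"] == 2.5
        labels = [d.labels[r.id] for r in recs]
        assert labels == ["inframedian", "inframedian", "supramedian", "supramedian"]

    def test_exact_median_is_inframedian(self):
        recs = patients([1.0, 2.0, 3.0])
        d = dichotomize(recs, "Dm-Pre-C_MRI")
        assert d.labels["P1"] == "inframedian"  # value 2.0 == median

    def test_per_sphere_type_stratification(self):
        recs = (patients([10.0, 20.0, 30.0, 25.0], sphere="resin",
                         ids=["r0", "r1", "r2", "r3"])
                + patients([100.0, 200.0, 300.0, 150.0], sphere="glass",
                           ids=["g0", "g1", "g2", "g3"]))
        d = dichotomize(recs, "Dm-Pre-C_MRI")
        assert d.medians == {"resin": 22.5, "glass": 175.0}
        assert d.labels["r3"] == "supramedian"     # 25 > 22.5
        assert d.labels["g3"] == "inframedian"     # 150 < 175

    def test_order_independent(self):
        recs = patients([5.0, 1.0, 3.0, 4.0, 2.0])
        d1 = dichotomize(recs, "Dm-Pre-C_MRI")
        d2 = dichotomize(list(reversed(recs)), "Dm-Pre-C_MRI")
        assert d1.labels == d2.labels

    def test_supramedian_fraction_bound(self):
        # with the strict-> rule at most half the stratum is supramedian
        rng = np.random.default_rng(7)
        for n in (4, 5, 9, 16):
            recs = patients(list(rng.random(n)))
            d = dichotomize(recs, "Dm-Pre-C_MRI")
            frac = np.mean([d.labels[r.id] == "supramedian" for r in recs])
            assert 0.5 - 1.0 / n <= frac <= 0.5

    def test_missing_metric_rejected(self):
        recs = patients([1.0, 2.0])
        with pytest.raises(InsufficientDataError):
            dichotomize(recs, "TNR-Pre-C_MRI")


class TestLogisticUnivariate:
    def test_or_equals_cross_product(self):
        a, b, c, d = 10, 5, 5, 10
        exposed = np.r_[np.ones(a + b), np.zeros(c + d)].astype(bool)
        outcome = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)].astype(bool)
        res = logistic_univariate(exposed, outcome)
        assert res["or"] == pytest.approx(4.0, rel=1e-6)

    def test_balanced_independence_gives_one(self):
        exposed = np.r_[np.ones(10), np.zeros(10)].astype(bool)
        outcome = np.r_[np.ones(5), np.zeros(5), np.ones(5), np.zeros(5)].astype(bool)
        assert logistic_univariate(exposed, outcome)["or"] == pytest.approx(1.0, rel=1e-6)

    def test_zero_cell_flags_separation(self):
        exposed = np.r_[np.ones(10), np.zeros(10)].astype(bool)
        outcome = np.r_[np.ones(10), np.ones(5), np.zeros(5)].astype(bool)
        res = logistic_univariate(exposed, outcome)
        assert res["separation"] is True
        assert res["ci95"] == (0.0, np.inf)

    def test_single_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            logistic_univariate(np.ones(10, bool), np.r_[np.ones(5), np.zeros(5)].astype(bool))


class TestSurvival:
    def test_km_median_hand_computed(self):
        # uncensored {2,4,6,8}: survival hits 0.5 at t=4 (smallest t, S<=0.5)
        assert km_median(np.array([2.0, 4.0, 6.0, 8.0]), np.ones(4, bool)) == 4.0

    def test_km_no_censoring_equals_empirical_survivor(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(3)
        t = rng.exponential(10.0, 200)
        kmf = KaplanMeierFitter().fit(t, event_observed=np.ones(200))
        for q in np.quantile(t, [0.1, 0.5, 0.9]):
            emp = np.mean(t > q)
            km = float(kmf.survival_function_at_times(q).iloc[0])
            assert km == pytest.approx(emp, abs=1e-9)

    def test_identical_groups_null_result(self):
        t = np.tile(np.array([3.0, 6.0, 9.0, 12.0, 15.0]), 2)
        e = np.ones(10, bool)
        g = np.r_[np.ones(5), np.zeros(5)].astype(bool)
        res = survival_suite(g, t, e)
        assert res["logrank_p"] == pytest.approx(1.0, abs=0.05)
        assert res["cox"]["hr"] == pytest.approx(1.0, abs=0.05)

    def test_no_events_flags_undefined_median(self):
        g = np.r_[np.ones(5), np.zeros(5)].astype(bool)
        t = np.arange(1.0, 11.0)
        e = np.r_[np.zeros(5), np.ones(5)].astype(bool)  # no events supramedian
        res = survival_suite(g, t, e)
        assert np.isinf(res["km_median"]["supramedian"])
        assert res["flags"]

    def test_single_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            survival_suite(np.ones(5, bool), np.arange(1.0, 6.0), np.ones(5, bool))


class TestMultivariateGate:
    def test_all_nonsignificant_empty(self):
        uni = {"A": {"p": 0.2}, "B": {"p": 0.06}}
        assert multivariate_gate(uni) == []

    def test_strict_alpha_boundary(self):
        uni = {"A": {"p": 0.049}, "B": {"p": 0.050}}
        assert multivariate_gate(uni) == ["A"]

    def test_redundant_pair_keeps_representative(self):
        uni = {"TNR-Pre-C_MRI": {"p": 0.01}, "TNR-Post-C_MRI": {"p": 0.02}}
        sel = multivariate_gate(
            uni, redundant_pairs=[("TNR-Pre-C_MRI", "TNR-Post-C_MRI")])
        assert sel == ["TNR-Pre-C_MRI"]
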