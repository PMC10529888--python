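"""Cox partial-likelihood fitting and Kaplan-Meier estimation."""

import numpy as np
import pytest

from remliver import (
    GeneratorParams,
    PostopClass,
    SurvivalRecord,
    cox_univariable,
    generate_cohort,
    kaplan_meier,
    km_by_class,
)


def make_records(times, events):
    return [SurvivalRecord(time=t, event=bool(e)) for t, e in zip(times, events)]


class TestCox:
    def test_two_group_rate_ratio_recovery(self):
        # exponential survival with hazard ratio r between groups: the Cox
        # HR estimates r (closed-form rate ratio as the simulation oracle)
        rng = np.random.default_rng(12)
        n = 4000
        x = np.repeat([0.0, 1.0], n // 2)
        rate = 0.01 * np.exp(np.log(2.0) * x)  # true HR = 2
        times = rng.exponential(1.0 / rate)
        fit = cox_univariable(make_records(times, np.ones(n)), x)
        assert abs(fit.beta - np.log(2.0)) < 3 * fit.se
        assert fit.converged

    def test_constant_covariate_rejected(self):
        recs = make_records([1.0, 2.0, 3.0], [1, 1, 1])
        with pytest.raises(ValueError, match="variance"):
            cox_univariable(recs, [5.0, 5.0, 5.0])

    def test_too_few_events_rejected(self):
        recs = make_records([1.0, 2.0, 3.0], [1, 0, 0])
        with pytest.raises(ValueError, match="events"):
            cox_univariable(recs, [1.0, 2.0, 3.0])

    def test_hr_and_ci_consistent_with_beta(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(100.0, 200)
        x = rng.normal(0.0, 1.0, 200)
        fit = cox_univariable(make_records(times, np.ones(200)), x)
        assert fit.hr == pytest.approx(np.exp(fit.beta))
        assert fit.ci_low < fit.hr < fit.ci_high

    def test_time_scale_invariance(self):
        # the partial likelihood depends only on ranks and risk sets
        rng = np.random.default_rng(8)
        times = rng.exponential(50.0, 150)
        events = rng.random(150) < 0.7
        x = rng.normal(0.0, 1.0, 150)
        f1 = cox_univariable(make_records(times, events), x)
        f2 = cox_univariable(make_records(times * 365.25, events), x)
        assert f1.beta == pytest.approx(f2.beta, rel=1e-8)
        assert f1.se == pytest.approx(f2.se, rel=1e-8)

    def test_matches_lifelines_breslow(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(21)
        n = 300
        x = rng.normal(0.0, 2.0, n)
        times = rng.exponential(1.0 / (0.01 * np.exp(0.25 * x)))
        events = rng.random(n) < 0.8
        fit = cox_univariable(make_records(times, events), x)
        df = pd.DataFrame({"T": times, "E": events.astype(int), "x": x})
        ref = CoxPHFitter().fit(df, duration_col="T", event_col="E")
        # agreement limited by lifelines' own convergence tolerance
        assert fit.beta == pytest.approx(ref.params_["x"], abs=1e-4)
        assert fit.se == pytest.approx(ref.standard_errors_["x"], abs=1e-4)

    def test_synthetic_cohort_recovers_hr_087(self):
        params = GeneratorParams(n=5000, seed=77)
        cohort = generate_cohort(params)
        fit = cox_univariable([r.survival for r in cohort],
                              [r.derived.erlf for r in cohort])
        assert fit.ci_low < 0.87 < fit.ci_high


class TestKaplanMeier:
    def test_four_uncensored_deaths(self):
        km = kaplan_meier(make_records([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1]))
        assert np.allclose(km.survival, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flat_at_one(self):
        km = kaplan_meier(make_records([5.0, 8.0, 9.0], [0, 0, 0]))
        assert km.times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_textbook_mixed_case(self):
        # times 1,2+,3,4+,5,6 -> S: 5/6, 5/6*3/4, 5/6*3/4*1/2
        km = kaplan_meier(make_records([1, 2, 3, 4, 5, 6], [1, 0, 1, 0, 1, 1]))
        assert np.allclose(km.survival, [5 / 6, 5 / 6 * 3 / 4,
                                         5 / 6 * 3 / 4 * 1 / 2, 0.0])
        assert list(km.at_risk) == [6, 4, 2, 1]

    def test_uncensored_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(10.0, 200)
        km = kaplan_meier(make_records(times, np.ones(200)))
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(14)
        times = rng.exponential(10.0, 120)
        events = rng.random(120) < 0.6
        if events.sum() < 2:
            events[:2] = True
        km = kaplan_meier(make_records(times, events))
        ref = KaplanMeierFitter().fit(times, events)
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx(ref.predict(t), abs=1e-10)

    def test_nonincreasing_and_step_structure(self):
        rng = np.random.default_rng(2)
        times = np.maximum(np.round(rng.exponential(5.0, 100), 1), 0.1)  # ties
        events = rng.random(100) < 0.5
        if events.sum() == 0:
            events[0] = True
        km = kaplan_meier(make_records(times, events))
        assert np.all(np.diff(km.survival) <= 0)
        assert km.survival_at(0.0) == 1.0


class TestKmByClass:
    def test_single_class_matches_plain_km(self):
        recs = make_records([1, 2, 3, 4], [1, 1, 0, 1])
        curves = km_by_class(recs, [PostopClass.PNLF] * 4)
        assert list(curves) == ["PNLF"]
        plain = kaplan_meier(recs)
        assert np.array_equal(curves["PNLF"].survival, plain.survival)

    def test_survival_ordered_by_function_class(self):
        # generator hazard rises as erLF falls -> PNLF > at_risk > PLDF
        cohort = generate_cohort(GeneratorParams(n=4000, seed=33))
        from remliver import classify_erlf

        recs = [r.survival for r in cohort]
        classes = [classify_erlf(r.derived.erlf) for r in cohort]
        curves = km_by_class(recs, classes)
        t = 900.0
        assert (curves["PNLF"].survival_at(t)
                > curves["at_risk"].survival_at(t)
                > curves["PLDF"].survival_at(t))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_by_class([], [])

    def test_misaligned_classes_rejected(self):
        with pytest.raises(ValueError, match="align"):
            km_by_class(make_records([1.0], [1]), [])
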