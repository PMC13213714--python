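"""Kaplan-Meier, log-rank, Cox, chi-square, and the cohort summarizer."""

import numpy as np
import pandas as pd
import pytest

from sigsubtype.clinical_stats import (
    chi_square_test,
    cohort_summary,
    cox_fit,
    km_estimate,
    load_published_demographics,
    logrank_test,
    percent,
    records_to_counts,
    response_table,
)
from sigsubtype.errors import SigsubtypeError, UndefinedStatisticError


def _os_frame(times, events):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(times))],
            "os_months": times,
            "os_event": events,
        }
    )


def hand_product_limit(times, events):
    """Independent stepwise product-limit computation."""
    surv, out = 1.0, {}
    for t in sorted(set(t for t, e in zip(times, events) if e == 1)):
        n_at_risk = sum(1 for x in times if x >= t)
        d = sum(1 for x, e in zip(times, events) if x == t and e == 1)
        surv *= 1.0 - d / n_at_risk
        out[t] = surv
    return out


def test_km_all_events_hand_case():
    km = km_estimate(_os_frame([1.0, 2.0, 3.0], [1, 1, 1]))
    assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
    assert km.median_survival == 2.0
    assert list(km.n_at_risk) == [3, 2, 1]


def test_km_all_censored_flat_at_one():
    km = km_estimate(_os_frame([1.0, 2.0, 3.0], [0, 0, 0]))
    assert len(km.event_times) == 0
    assert km.median_survival is None
    assert km.n_observed_events == 0


def test_km_censoring_convention_worked_example():
    """(1+, 2, 2, 3+): both deaths at t=2 see 3 at risk, S(2)=1/3."""
    km = km_estimate(_os_frame([1.0, 2.0, 2.0, 3.0], [0, 1, 1, 0]))
    assert list(km.event_times) == [2.0]
    assert list(km.n_at_risk) == [3]
    assert km.survival[0] == pytest.approx(1 / 3, abs=1e-10)


def test_km_no_censoring_equals_empirical_survival(rng):
    times = np.round(rng.exponential(10.0, size=60), 3)
    km = km_estimate(_os_frame(times, np.ones(60, dtype=int)))
    for t, s in zip(km.event_times, km.survival):
        assert s == pytest.approx((times > t).mean(), abs=1e-12)


def test_km_matches_independent_hand_oracle(rng):
    times = np.round(rng.exponential(12.0, size=40), 1)
    events = rng.integers(0, 2, size=40)
    if events.sum() == 0:
        events[0] = 1
    km = km_estimate(_os_frame(times, events))
    oracle = hand_product_limit(list(times), list(events))
    for t, s in zip(km.event_times, km.survival):
        assert s == pytest.approx(oracle[t], abs=1e-10)


def test_km_missing_os_errors():
    with pytest.raises(UndefinedStatisticError):
        km_estimate(_os_frame([np.nan], [np.nan]))


def test_logrank_identical_groups_null():
    g = _os_frame([1.0, 3.0, 5.0, 7.0], [1, 0, 1, 1])
    res = logrank_test(g, g.copy())
    assert res.chi_square == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_six_subject_hand_table():
    """3 vs 3 staggered events, O/E/V accumulated stepwise by hand.

    Group A times (1, 4, 6+), group B (2, 5, 8), all events except 6+.
    t=1: n=6, nA=3, d=1, dA=1, E=0.5, V=(3/6)(3/6)(5/5)=0.25
    t=2: n=5, nA=2, d=1, dA=0, E=0.4, V=(2/5)(3/5)=0.24
    t=4: n=4, nA=2, d=1, dA=1, E=0.5, V=0.25
    t=5: n=3, nA=1, d=1, dA=0, E=1/3, V=(1/3)(2/3)=2/9
    t=8: n=1, nA=0, d=1, dA=0, E=0,   V=0
    O=2, E=1.7333..., V=0.96222..., chi2=(0.26666)^2/0.96222=0.0739...
    """
    a = _os_frame([1.0, 4.0, 6.0], [1, 1, 0])
    b = _os_frame([2.0, 5.0, 8.0], [1, 1, 1])
    res = logrank_test(a, b)
    E = 0.5 + 0.4 + 0.5 + 1 / 3 + 0.0
    V = 0.25 + 0.24 + 0.25 + 2 / 9 + 0.0
    assert res.observed[0] == pytest.approx(2.0, abs=1e-12)
    assert res.expected[0] == pytest.approx(E, abs=1e-10)
    assert res.chi_square == pytest.approx((2.0 - E) ** 2 / V, abs=1e-10)
    assert res.df == 1


def test_logrank_observed_and_expected_totals_conserve_events():
    a = _os_frame([1.0, 2.0, 9.0, 4.0], [1, 1, 0, 1])
    b = _os_frame([3.0, 5.0, 6.0], [1, 0, 1])
    res = logrank_test(a, b)
    total_events = 5
    assert res.observed.sum() == pytest.approx(total_events)
    assert res.expected.sum() == pytest.approx(total_events)


def test_logrank_group_swap_invariance_and_z_square(rng):
    a = _os_frame(rng.exponential(10, 40), rng.integers(0, 2, 40))
    b = _os_frame(rng.exponential(6, 35), rng.integers(0, 2, 35))
    r1 = logrank_test(a, b)
    r2 = logrank_test(b, a)
    assert r1.chi_square == pytest.approx(r2.chi_square, abs=1e-10)
    assert r1.chi_square == pytest.approx(r1.z_score**2, abs=1e-10)


def test_logrank_agrees_with_lifelines(rng):
    from lifelines.statistics import logrank_test as ll_logrank

    a = _os_frame(np.round(rng.exponential(10, 50), 1), rng.integers(0, 2, 50))
    b = _os_frame(np.round(rng.exponential(7, 45), 1), rng.integers(0, 2, 45))
    ours = logrank_test(a, b)
    ref = ll_logrank(
        a["os_months"], b["os_months"], a["os_event"], b["os_event"]
    )
    assert ours.chi_square == pytest.approx(ref.test_statistic, rel=1e-8)
    assert ours.p_value == pytest.approx(ref.p_value, rel=1e-8)


def test_logrank_zero_events_undefined():
    with pytest.raises(UndefinedStatisticError):
        logrank_test(_os_frame([1.0, 2.0], [0, 0]), _os_frame([3.0], [0]))


def _two_group_clinical(rng, n1, n2, rate1, rate2, cens=30.0):
    t1 = rng.exponential(1 / rate1, n1)
    t2 = rng.exponential(1 / rate2, n2)
    u1, u2 = rng.uniform(0, cens, n1), rng.uniform(0, cens, n2)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n1 + n2)],
            "os_months": np.concatenate([np.minimum(t1, u1), np.minimum(t2, u2)]),
            "os_event": np.concatenate([(t1 <= u1), (t2 <= u2)]).astype(int),
            "subtype": ["MUT1"] * n1 + ["MUT2"] * n2,
            "age": rng.normal(66, 10, n1 + n2),
            "sex": rng.choice(["male", "female"], n1 + n2),
            "smoking": rng.choice(["never", "former", "current"], n1 + n2),
        }
    )


def test_cox_mut2_coded_against_mut1_reference(rng):
    df = _two_group_clinical(rng, 150, 150, np.log(2) / 15, np.log(2) / 15 * 2.0)
    res = cox_fit(df, ["subtype"])
    cov = res["subtype_MUT2"]
    assert cov.hazard_ratio > 1.0  # MUT2 has the excess hazard
    assert cov.ci_lower < cov.hazard_ratio < cov.ci_upper
    assert cov.hazard_ratio == pytest.approx(np.exp(cov.coef), rel=1e-12)


def test_cox_null_ci_covers_one_at_nominal_rate(rng):
    covered = 0
    n_rep = 80
    for _ in range(n_rep):
        df = _two_group_clinical(rng, 60, 60, 0.05, 0.05)
        cov = cox_fit(df, ["subtype"])["subtype_MUT2"]
        covered += cov.ci_lower <= 1.0 <= cov.ci_upper
    assert covered / n_rep >= 0.85


def test_cox_noise_covariate_near_null(rng):
    df = _two_group_clinical(rng, 120, 120, 0.04, 0.08)
    df["noise"] = rng.normal(size=len(df))
    res = cox_fit(df, ["subtype", "noise"])
    noise = res["noise"]
    assert noise.ci_lower < 1.1 and noise.ci_upper > 0.9


def test_cox_sign_agrees_with_logrank_direction(rng):
    df = _two_group_clinical(rng, 80, 80, 0.03, 0.09)
    res = cox_fit(df, ["subtype"])
    lr = logrank_test(df[df.subtype == "MUT2"], df[df.subtype == "MUT1"])
    assert res["subtype_MUT2"].hazard_ratio > 1.0
    assert lr.observed[0] > lr.expected[0]  # MUT2 observes excess events


def test_cox_complete_case_drops_missing_covariates(rng):
    df = _two_group_clinical(rng, 80, 80, 0.04, 0.07)
    df.loc[df.index[:10], "age"] = np.nan
    res = cox_fit(df, ["subtype", "age"])
    assert res.n_dropped_missing == 10
    assert res.n == len(df) - 10


def test_cox_constant_covariate_errors(rng):
    df = _two_group_clinical(rng, 40, 40, 0.05, 0.05)
    df["sex"] = "male"
    with pytest.raises(SigsubtypeError):
        cox_fit(df, ["subtype", "sex"])


def test_chi_square_flat_table_is_null():
    stat, df, p = chi_square_test([[10, 10], [10, 10]])
    assert stat == 0.0
    assert df == 1
    assert p == pytest.approx(1.0)


def test_chi_square_hand_value():
    stat, df, p = chi_square_test([[20, 30], [40, 10]])
    assert stat == pytest.approx(16.667, abs=5e-4)  # sum (O-E)^2/E by hand
    assert df == 1


def test_chi_square_row_swap_invariance(rng):
    table = rng.integers(1, 40, size=(2, 2))
    s1, _, _ = chi_square_test(table)
    s2, _, _ = chi_square_test(table[::-1])
    assert s1 == pytest.approx(s2, abs=1e-12)


def test_chi_square_zero_margin_undefined():
    with pytest.raises(UndefinedStatisticError):
        chi_square_test([[0, 0], [5, 3]])


def test_chi_square_yates_flag_reduces_statistic():
    plain, _, _ = chi_square_test([[20, 30], [40, 10]])
    yates, _, _ = chi_square_test([[20, 30], [40, 10]], yates=True)
    assert yates < plain


def test_percent_rounds_half_up():
    assert percent(481, 2000) == 24.1  # 24.05 rounds up, not to even
    assert percent(5, 40) == 12.5
    assert percent(1689, 2229) == 75.8


def test_cohort_summary_single_cohort_equals_input():
    tab = pd.DataFrame(
        {
            "characteristic": ["sex", "sex"],
            "category": ["male", "female"],
            "count": [30, 10],
        }
    )
    out = cohort_summary({"only": tab})
    male = out[(out.characteristic == "sex") & (out.category == "male")].iloc[0]
    assert male.pooled_count == 30
    assert male.pooled_percent == 75.0
    assert male.only_count == 30


def test_cohort_summary_two_cohort_hand_case():
    t1 = pd.DataFrame(
        {"characteristic": ["sex"] * 2, "category": ["male", "female"], "count": [5, 5]}
    )
    t2 = pd.DataFrame(
        {"characteristic": ["sex"] * 2, "category": ["male", "female"], "count": [15, 15]}
    )
    out = cohort_summary({"a": t1, "b": t2})
    male = out[out.category == "male"].iloc[0]
    assert male.pooled_count == 20
    assert male.pooled_percent == 50.0


def test_cohort_summary_percentages_sum_to_hundred():
    tables = load_published_demographics()
    out = cohort_summary(tables)
    for char, grp in out.groupby("characteristic"):
        assert grp["pooled_percent"].sum() == pytest.approx(100.0, abs=0.3)


def test_published_pooled_demographics_reproduce_printed_values():
    out = cohort_summary(load_published_demographics())

    def cell(char, cat):
        row = out[(out.characteristic == char) & (out.category == cat)].iloc[0]
        return int(row.pooled_count), float(row.pooled_percent)

    assert out.attrs["total_n"] == 2229
    assert cell("sex", "male") == (1689, 75.8)
    assert cell("os", "event") == (871, 39.1)
    assert cell("smoking", "current") == (294, 13.2)
    assert cell("smoking", "former") == (1157, 51.9)
    assert cell("smoking", "never") == (709, 31.8)
    im = out[(out.characteristic == "ms_subtype")]
    assert list(im["IMvigor210_count"]) == [150, 94]
    assert list(im["IMvigor210_percent"]) == [61.5, 38.5]


def test_records_to_counts_round_trip(small_cohort):
    counts = records_to_counts(small_cohort.clinical)
    n = len(small_cohort.clinical)
    assert counts.groupby("characteristic")["count"].sum().eq(n).all()


def test_response_table_counts(small_cohort):
    table = response_table(small_cohort.clinical)
    assert table.sum() == len(small_cohort.clinical.dropna(subset=["response", "subtype"]))
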