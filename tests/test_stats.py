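"""Survival, concordance and reclassification statistics.

Brute-force oracles: Harrell's C by explicit pair enumeration, NRI by
direct counting of risk-category moves, Cox recovery by simulation.
"""

import numpy as np
import pandas as pd
import pytest

from hipfe import stats as hs
from hipfe.cohort import (CohortConfig, calibrate_baseline_rate,
                          generate_cohort_table, simulate_outcomes)

rng = np.random.default_rng(42)


# ---------------------------------------------------------------------------
# group comparison


def test_group_compare_symmetry_and_shift():
    a = rng.normal(0, 1, 200)
    b = rng.normal(1.0, 1, 60)
    p1 = hs.group_compare(a, b)
    p2 = hs.group_compare(b, a)
    assert p1 == pytest.approx(p2)
    assert p1 < 0.001


def test_group_compare_degenerate_ties():
    assert hs.group_compare([1.0, 1.0, 1.0], [1.0, 1.0]) == 1.0


def test_group_compare_empty_group():
    with pytest.raises(ValueError):
        hs.group_compare([], [1.0])


# ---------------------------------------------------------------------------
# Harrell's C


def brute_force_c(time, event, score):
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if score[i] > score[j]:
                    num += 1
                elif score[i] == score[j]:
                    num += 0.5
    return num / den


def test_concordance_matches_brute_force():
    n = 150
    t = rng.exponential(5, n)
    e = rng.integers(0, 2, n)
    e[:2] = 1
    s = -t + rng.normal(0, 2, n)
    assert hs.concordance_index(t, e, s) == pytest.approx(
        brute_force_c(t, e, s), abs=1e-12)


def test_concordance_matches_lifelines():
    from lifelines.utils import concordance_index as ll_c
    n = 200
    t = rng.exponential(5, n)
    e = rng.integers(0, 2, n)
    e[:2] = 1
    s = -t + rng.normal(0, 2, n)
    # lifelines orders by predicted survival time (= -risk score)
    assert hs.concordance_index(t, e, s) == pytest.approx(ll_c(t, -s, e), abs=1e-9)


def test_concordance_perfect_and_random():
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    e = np.ones(5, int)
    assert hs.concordance_index(t, e, -t) == 1.0  # reversed time order
    assert hs.concordance_index(t, e, t) == 0.0

    n = 2000
    t = rng.exponential(5, n)
    s = rng.normal(0, 1, n)
    assert hs.concordance_index(t, np.ones(n, int), s) == pytest.approx(0.5, abs=0.03)


def test_hand_computed_five_subject_concordance():
    # one usable censored pair: subject 3 censored at 2.5 is not usable as
    # an index case but is a valid comparator for the event at t=1
    t = np.array([1.0, 3.0, 2.5, 4.0, 2.0])
    e = np.array([1, 1, 0, 0, 1])
    s = np.array([5.0, 2.0, 3.0, 1.0, 3.0])
    assert hs.concordance_index(t, e, s) == pytest.approx(
        brute_force_c(t, e, s), abs=1e-12)


# ---------------------------------------------------------------------------
# Cox per SD


def _null_cohort(n=300, seed=3):
    r = np.random.default_rng(seed)
    df = pd.DataFrame({
        "x": r.normal(0, 2, n),
        "age": r.normal(65, 1.5, n),
        "followup_years": np.clip(r.normal(5.7, 1.5, n), 0.5, None),
    })
    ev, tt = simulate_outcomes(
        (df.x - df.x.mean()) / df.x.std(), df.followup_years.to_numpy(),
        0.0, 0.03, seed=seed)
    df["event_lt"], df["time_lt"] = ev, tt
    return df


def test_cox_sign_flip_inverts_hr():
    df = _null_cohort()
    df["y"] = -df["x"]
    f1 = hs.cox_per_sd(df, "x", "lt")
    f2 = hs.cox_per_sd(df, "y", "lt")
    assert f1.hr_per_sd_decrease == pytest.approx(1 / f2.hr_per_sd_decrease,
                                                  rel=1e-6)


def test_cox_recovers_planted_hr():
    """Planted per-SD hazard ratio of 1.5 is recovered within the 95 % CI."""
    r = np.random.default_rng(17)
    n = 740
    hits = 0
    for k in range(10):
        z = r.standard_normal(n)
        fu = np.clip(r.normal(5.7, 1.5, n), 0.5, None)
        h0 = calibrate_baseline_rate(z, fu, np.log(1.5), 44 / 740)
        ev, tt = simulate_outcomes(z, fu, np.log(1.5), h0, seed=100 + k)
        df = pd.DataFrame({"x": z, "event_mof": ev, "time_mof": tt})
        fit = hs.cox_per_sd(df, "x", "mof")
        lo, hi = fit.ci95
        hits += lo <= 1.5 <= hi
    assert hits >= 8


def test_cox_zero_events_raises():
    df = _null_cohort()
    df["event_lt"] = 0
    with pytest.raises(ValueError):
        hs.cox_per_sd(df, "x", "lt")


def test_cox_constant_predictor_raises():
    df = _null_cohort()
    df["c"] = 1.0
    with pytest.raises(ValueError, match="variance"):
        hs.cox_per_sd(df, "c", "lt")


# ---------------------------------------------------------------------------
# C comparison


def test_compare_c_self_is_one():
    df = _null_cohort()
    fit = hs.cox_per_sd(df, "x", "lt")
    assert hs.compare_c(fit, fit) == 1.0


def test_compare_c_informative_vs_noise():
    r = np.random.default_rng(23)
    n = 600
    z = r.standard_normal(n)
    fu = np.full(n, 8.0)
    h0 = calibrate_baseline_rate(z, fu, np.log(2.5), 0.4)
    ev, tt = simulate_outcomes(z, fu, np.log(2.5), h0, seed=9)
    df = pd.DataFrame({"x": z, "noise": r.standard_normal(n),
                       "event_lt": ev, "time_lt": tt})
    fa = hs.cox_per_sd(df, "x", "lt")
    fb = hs.cox_per_sd(df, "noise", "lt")
    assert fa.c_index > fb.c_index
    p_ab = hs.compare_c(fa, fb)
    assert p_ab < 0.05
    assert hs.compare_c(fb, fa) == pytest.approx(p_ab)


def test_compare_c_mismatched_subjects():
    df = _null_cohort()
    fa = hs.cox_per_sd(df, "x", "lt")
    fb = hs.cox_per_sd(df.iloc[:-1], "x", "lt")
    with pytest.raises(ValueError):
        hs.compare_c(fa, fb)


# ---------------------------------------------------------------------------
# NRI


def brute_force_nri(cat_a, cat_b, event):
    up_e = dn_e = up_n = dn_n = 0
    n_e = sum(event)
    n_n = len(event) - n_e
    for a, b, e in zip(cat_a, cat_b, event):
        if e:
            up_e += b > a
            dn_e += b < a
        else:
            up_n += b > a
            dn_n += b < a
    return (up_e - dn_e) / n_e + (dn_n - up_n) / n_n


def test_nri_counting_matches_brute_force():
    for seed in range(5):
        r = np.random.default_rng(seed)
        n = 40
        ca = r.integers(0, 2, n)
        cb = r.integers(0, 2, n)
        ev = r.integers(0, 2, n)
        ev[0], ev[1] = 1, 0
        nri_v, se, p = hs._nri_from_categories(ca, cb, ev)
        assert nri_v == pytest.approx(brute_force_nri(ca, cb, ev), abs=1e-12)
        assert se >= 0 and 0 <= p <= 1


def _reclass_cohort(n=400, seed=2):
    r = np.random.default_rng(seed)
    q = r.standard_normal(n)
    df = pd.DataFrame({
        "fn_tscore": -1.2 + 0.9 * (0.8 * q + 0.6 * r.standard_normal(n)),
        "th_tscore": -0.8 + 0.9 * (0.8 * q + 0.6 * r.standard_normal(n)),
        "strength_fall": 3563 + 980 * (0.8 * q + 0.6 * r.standard_normal(n)),
        "followup_years": np.clip(r.normal(5.7, 1.5, n), 0.5, None),
    })
    z = (q - q.mean()) / q.std()
    h0 = calibrate_baseline_rate(z, df.followup_years.to_numpy(), np.log(1.5), 0.15)
    ev, tt = simulate_outcomes(z, df.followup_years.to_numpy(), np.log(1.5),
                               h0, seed=seed)
    df["event_mof"], df["time_mof"] = ev, tt
    df["event_lt"], df["time_lt"] = ev, tt
    return df


def test_nri_zero_when_class_duplicates_flag():
    """Adding a class identical to the existing flag reclassifies nobody."""
    df = _reclass_cohort()
    # craft strength so the fragile flag equals the T-score flag exactly
    df["strength_fall"] = np.where(df.fn_tscore <= -2.5, 2000.0, 4000.0)
    res = hs.nri(df, "FN", 3000.0, "mof")
    assert res.nri == 0.0
    assert res.p_value == 1.0


def test_nri_runs_on_calibrated_cohort():
    df = _reclass_cohort()
    res = hs.nri(df, "TH", 2600.0, "mof")
    assert np.isfinite(res.nri) and res.se > 0
    assert res.n_events + res.n_nonevents == len(df)


def test_nri_sweep_shape(small_cohort):
    tab = hs.nri_sweep(small_cohort)
    assert len(tab) == 8 * 2 * 2
    assert set(tab.dxa_rule) == {"FN", "TH"}
    assert set(tab.outcome) == {"lt", "mof"}
    assert tab.threshold.min() == 2300 and tab.threshold.max() == 3000


def test_nri_sweep_rejects_off_grid():
    with pytest.raises(ValueError, match="grid"):
        hs.nri_sweep(_reclass_cohort(), thresholds=[5000])


# ---------------------------------------------------------------------------
# threshold Cox and plot data


def test_threshold_cox_either_rule_is_union(small_cohort):
    df = small_cohort
    either = hs.THRESHOLD_RULES["either"](df)
    union = hs.THRESHOLD_RULES["th_tscore<=-2.5"](df) | \
        hs.THRESHOLD_RULES["fn_tscore<=-2.5"](df)
    assert (either == union).all()


def test_threshold_cox_fits(small_cohort):
    fit = hs.threshold_cox(small_cohort, "strength<3000", "lt")
    assert fit.hr_per_sd_decrease > 0
    assert fit.ci95[0] <= fit.hr_per_sd_decrease <= fit.ci95[1]
    assert 0 <= fit.c_index <= 1


def test_threshold_cox_monotone_likelihood_guard():
    r = np.random.default_rng(4)
    n = 60
    flag = np.repeat([0, 1], n // 2)
    # flag perfectly separates events
    df = pd.DataFrame({
        "strength_fall": np.where(flag, 2000.0, 4000.0),
        "age": r.normal(65, 1.5, n),
        "time_lt": np.where(flag, 1.0 + r.random(n), 6.0),
        "event_lt": flag,
        "th_tscore": 0.0, "fn_tscore": 0.0,
    })
    with pytest.raises(RuntimeError, match="monotone"):
        hs.threshold_cox(df, "strength<3000", "lt", adjust_age=False)


def test_reclass_plot_data_quadrants():
    df = pd.DataFrame({
        "fn_tscore": [-3.0, -3.0, -1.0, 0.0, -2.6, -0.5, -2.8, -1.2, 0.2, -2.9],
        "th_tscore": 0.0,
        "strength_fall": [2000, 3500, 2500, 3600, 2900, 2400, 3100, 3900, 2550, 2700],
        "event_mof": [1, 1, 1, 0, 0, 1, 0, 0, 1, 1],
        "followup_years": 5.0,
    })
    res = hs.reclass_plot_data(df, "mof", "FN")
    # manual quadrant assignment (osteoporotic: t <= -2.5; fragile: s <= 3000):
    # rows 0, 4, 9 are osteoporotic and fragile
    assert res.cell_counts[(True, True)] == 3
    assert sum(res.cell_counts.values()) == len(df)
    tab = res.table
    assert ((tab.osteoporotic == (tab.t_score <= -2.5)).all())
    assert ((tab.fragile == (tab.strength <= 3000)).all())
    # percentages over cases sum to 100 across the exhaustive quadrants
    total = (res.case_percent["osteoporotic_fragile"]
             + res.case_percent["osteoporotic_non_fragile"]
             + res.case_percent["non_osteoporotic_fragile"]
             + res.case_percent["non_osteoporotic_non_fragile"])
    assert abs(total - 100) <= 2  # integer rounding


def test_reclass_plot_data_all_one_cell():
    df = pd.DataFrame({
        "fn_tscore": [-3.0] * 6, "th_tscore": [-3.0] * 6,
        "strength_fall": [2000.0] * 6,
        "event_lt": [1] * 6, "followup_years": 5.0,
    })
    res = hs.reclass_plot_data(df, "lt", "FN")
    assert res.cell_counts[(True, True)] == 6
    assert res.case_percent["osteoporotic_fragile"] == 100
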