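"""Statistical kernels vs independent oracles (exact enumeration, hand
calculations, scipy/lifelines cross-checks)."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from melano_epityper.config import StatsParams, ValidationError
from melano_epityper.cohort_stats import (
    association_report,
    fisher_exact,
    km_estimate,
    logrank_test,
    prc_enrichment,
    quartile_groups,
    survival_curves,
    thickness_by_subgroup,
    welch_t,
)
from melano_epityper.marker_extraction import CAT_MARKER, CAT_NORMAL, CAT_UNMETH


# ------------------------------------------------------------- Fisher

def exact_fisher_p(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact-rational two-sided Fisher p by full table enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_x = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if p_x <= p_obs:
            total += p_x
    return total


@pytest.mark.parametrize(
    "table,expected",
    [
        ([[0, 5], [0, 5]], 1.0),
        ([[3, 1], [1, 3]], 34 / 70),            # enumeration over 5 tables
        ([[10, 0], [0, 10]], 2 / comb(20, 10)),  # two extreme tables
    ],
)
def test_fisher_exact_examples(table, expected):
    res = fisher_exact(table)
    assert res.p_value == pytest.approx(expected, rel=1e-9)


def test_fisher_matches_exact_enumeration_and_scipy():
    rng = np.random.default_rng(0)
    for _ in range(200):
        a, b, c, d = rng.integers(0, 12, size=4)
        if a + b + c + d == 0:
            continue
        p = fisher_exact([[a, b], [c, d]]).p_value
        assert p == pytest.approx(float(exact_fisher_p(a, b, c, d)), rel=1e-8)
        assert p == pytest.approx(
            sps.fisher_exact([[a, b], [c, d]])[1], rel=1e-6
        )


def test_fisher_symmetry_and_validation():
    p1 = fisher_exact([[7, 3], [2, 8]]).p_value
    p2 = fisher_exact([[2, 8], [7, 3]]).p_value
    assert p1 == pytest.approx(p2)
    with pytest.raises(ValidationError):
        fisher_exact([[-1, 2], [3, 4]])
    with pytest.raises(ValidationError):
        fisher_exact([[0, 0], [0, 0]])


# ------------------------------------------------------------- Welch t

def test_welch_identical_groups():
    res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_welch_worked_example():
    res = welch_t([1, 2, 3], [4, 5, 6])
    assert res.statistic == pytest.approx(-3.674, abs=1e-3)
    assert res.extra["df"] == pytest.approx(4.0)
    # independent t-CDF oracle
    assert res.p_value == pytest.approx(2 * sps.t.sf(3.674, 4), abs=1e-4)
    assert res.p_value == pytest.approx(
        sps.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=False).pvalue
    )
    assert res.extra["summary"].startswith("2.0 ± 1.0 vs 5.0 ± 1.0")


def test_welch_degenerate_groups():
    with pytest.raises(ValidationError):
        welch_t([1.0], [2.0, 3.0])
    with pytest.raises(ValidationError):
        welch_t([2.0, 2.0], [3.0, 3.0])


# ------------------------------------------------------- Kaplan-Meier

def test_km_no_events_stays_at_one():
    curve = km_estimate([5, 10, 15], [0, 0, 0])
    assert (curve["survival"] == 1.0).all()
    assert np.isnan(curve.attrs["median"])


def test_km_single_event():
    curve = km_estimate([10, 20, 30, 40], [1, 0, 0, 0])
    at10 = curve.loc[curve["time"] == 10, "survival"].iloc[0]
    assert at10 == pytest.approx(3 / 4)


def test_km_hand_worked_example():
    """times (5,10,15,20), events (1,1,0,1): S = 3/4, 1/2, 1/2, 0."""
    curve = km_estimate([5, 10, 15, 20], [1, 1, 0, 1])
    s = dict(zip(curve["time"], curve["survival"]))
    assert s[5.0] == pytest.approx(3 / 4)
    assert s[10.0] == pytest.approx(1 / 2)
    assert 15.0 not in s  # censoring does not drop S
    assert s[20.0] == pytest.approx(0.0)
    assert curve.attrs["median"] == pytest.approx(10.0)


def test_km_equals_empirical_survival_without_censoring():
    rng = np.random.default_rng(1)
    t = rng.exponential(10, size=40)
    curve = km_estimate(t, np.ones_like(t, dtype=int))
    for _, row in curve.iloc[1:].iterrows():
        emp = (t > row["time"]).mean()
        assert row["survival"] == pytest.approx(emp)


def test_km_rejects_negative_times():
    with pytest.raises(ValidationError):
        km_estimate([-1, 2], [1, 1])


# ------------------------------------------------------------ log-rank

def hand_logrank(times, events, in1):
    """Per-event-time O-E/V tabulation, written independently."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    in1 = np.asarray(in1, bool)
    oe, v = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        risk = times >= t
        n, n1 = risk.sum(), (risk & in1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & in1).sum()
        oe += d1 - d * n1 / n
        if n > 1:
            v += d * n1 * (n - n1) * (n - d) / (n**2 * (n - 1))
    return oe**2 / v


def test_logrank_identical_groups_is_null():
    t = [1, 2, 3, 4, 1, 2, 3, 4]
    e = [1] * 8
    g = ["a"] * 4 + ["b"] * 4
    res = logrank_test(t, e, g)
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_matches_hand_tabulation_and_lifelines():
    t = [1, 2, 3, 4]
    e = [1, 1, 1, 1]
    g = ["a", "a", "b", "b"]
    res = logrank_test(t, e, g)
    assert res.statistic == pytest.approx(
        hand_logrank(t, e, [x == "a" for x in g])
    )
    from lifelines.statistics import logrank_test as ll_logrank

    ll = ll_logrank(np.array(t)[:2], np.array(t)[2:], np.array(e)[:2],
                    np.array(e)[2:])
    assert res.statistic == pytest.approx(ll.test_statistic)
    assert res.p_value == pytest.approx(ll.p_value)


def test_logrank_with_ties_and_censoring_matches_lifelines():
    rng = np.random.default_rng(5)
    t = np.round(rng.exponential(10, size=60)).astype(int) + 1
    e = (rng.random(60) < 0.7).astype(int)
    g = np.array(["a"] * 30 + ["b"] * 30)
    res = logrank_test(t, e, g)
    from lifelines.statistics import logrank_test as ll_logrank

    ll = ll_logrank(t[g == "a"], t[g == "b"], e[g == "a"], e[g == "b"])
    assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-9)
    assert res.p_value == pytest.approx(ll.p_value, rel=1e-9)


def test_logrank_invariant_under_time_rescaling():
    rng = np.random.default_rng(2)
    t = rng.exponential(5, 30)
    e = (rng.random(30) < 0.8).astype(int)
    g = np.array(["a"] * 15 + ["b"] * 15)
    s1 = logrank_test(t, e, g).statistic
    s2 = logrank_test(t * 42.0, e, g).statistic
    assert s1 == pytest.approx(s2)


def test_logrank_requires_two_groups():
    with pytest.raises(ValidationError):
        logrank_test([1, 2], [1, 1], ["a", "a"])


# ----------------------------------------------------------- quartiles

def test_quartile_groups_exact_split():
    values = pd.Series([1, 2, 3, 4, 5, 6, 7, 8],
                       index=[f"s{i}" for i in range(8)])
    labels = quartile_groups(values)
    assert (labels == "high").sum() == 2
    assert (labels == "low").sum() == 2
    assert (labels == "excluded").sum() == 4
    assert set(labels[values >= 7]) == {"high"}
    assert set(labels[values <= 2]) == {"low"}


def test_quartile_groups_floor_rule_n342():
    rng = np.random.default_rng(0)
    values = pd.Series(rng.normal(size=342),
                       index=[f"s{i}" for i in range(342)])
    labels = quartile_groups(values)
    assert (labels == "high").sum() == 342 // 4 == 85
    assert (labels == "low").sum() == 85


def test_quartile_groups_degenerate():
    with pytest.raises(ValidationError):
        quartile_groups(pd.Series([1.0, 1.0, 1.0, 1.0]))
    with pytest.raises(ValidationError):
        quartile_groups(pd.Series([1.0, 2.0, 3.0]))


# ---------------------------------------------------------- enrichment

def _marker_frame(markers, unmeth, normal):
    genes, cats = [], []
    for prefix, n, cat in (("m", markers, CAT_MARKER),
                           ("u", unmeth, CAT_UNMETH),
                           ("n", normal, CAT_NORMAL)):
        genes += [f"{prefix}{i}" for i in range(n)]
        cats += [cat] * n
    return pd.DataFrame({"category": cats}, index=genes)


def test_prc_enrichment_disjoint_set_gives_p_one():
    table = _marker_frame(5, 20, 10)
    res = prc_enrichment(table, {"S": {"absent1", "absent2"}})
    assert res["p_value"].to_numpy() == pytest.approx([1.0, 1.0])


def test_prc_enrichment_planted_signal_significant():
    table = _marker_frame(20, 200, 50)
    members = {f"m{i}" for i in range(12)} | {f"u{i}" for i in range(20)} | {
        f"n{i}" for i in range(5)
    }
    res = prc_enrichment(table, {"S": members})
    # hypergeometric-tail oracle at the planted counts
    assert (res["p_value"] < 0.05).all()
    row = res[res["comparison"].str.endswith("unmethylated")].iloc[0]
    oracle = float(exact_fisher_p(12, 8, 20, 180))
    assert row["p_value"] == pytest.approx(oracle, rel=1e-8)


# -------------------------------------------------- association report

def _fake_clinical(rng, n=40):
    return pd.DataFrame(
        {
            "sample": [f"s{i}" for i in range(n)],
            "age": rng.integers(30, 90, n),
            "site": rng.choice(["acral", "non_acral"], n),
            "stage": rng.integers(1, 5, n),
            "breslow_mm": rng.uniform(0.5, 12, n),
            "ulcer": rng.integers(0, 2, n),
            "braf_mut": rng.integers(0, 2, n),
            "nras_mut": rng.integers(0, 2, n),
            "os_days": rng.integers(30, 2000, n),
            "os_event": rng.integers(0, 2, n),
        }
    )


def test_association_report_structure_and_pvalues():
    rng = np.random.default_rng(3)
    clin = _fake_clinical(rng)
    labels = pd.Series(rng.choice(["high", "low"], len(clin)),
                       index=clin["sample"])
    rep = association_report(labels, clin)
    assert {"braf_mut", "nras_mut", "acral_site", "ulcer", "stage_3_4",
            "breslow_mm", "overall_survival"} <= set(rep["factor"])
    assert rep["p_value"].between(0, 1).all()
    assert (rep["significant"] == (rep["p_value"] < 0.05)).all()
    assert "p_bh_supplementary" in rep.columns


def test_association_null_labels_rarely_significant():
    """Independent labels: each factor significant in <= 2 of 12 seeds."""
    flags = []
    for seed in range(12):
        rng = np.random.default_rng(seed)
        clin = _fake_clinical(rng, n=50)
        labels = pd.Series(rng.choice(["high", "low"], len(clin)),
                           index=clin["sample"])
        rep = association_report(labels, clin).set_index("factor")
        flags.append(rep["significant"])
    counts = pd.concat(flags, axis=1).sum(axis=1)
    assert (counts <= 2).all()


def test_separated_thickness_is_significant():
    rng = np.random.default_rng(0)
    clin = _fake_clinical(rng, n=30)
    labels = pd.Series(["high"] * 15 + ["low"] * 15, index=clin["sample"])
    clin.loc[:14, "breslow_mm"] = 9.0 + rng.normal(0, 0.2, 15)
    clin.loc[15:, "breslow_mm"] = 2.0 + rng.normal(0, 0.2, 15)
    rep = association_report(labels, clin).set_index("factor")
    assert rep.loc["breslow_mm", "significant"]


def test_thickness_and_survival_helpers():
    rng = np.random.default_rng(4)
    clin = _fake_clinical(rng, n=24)
    labels = pd.Series(["high"] * 8 + ["low"] * 16, index=clin["sample"])
    thick = thickness_by_subgroup(labels, clin)
    assert thick["high"]["n"] == 8 and thick["low"]["n"] == 16
    assert thick["high"]["se"] == pytest.approx(
        thick["high"]["sd"] / np.sqrt(8)
    )
    curves = survival_curves(clin, labels)
    assert set(curves["group"]) == {"high", "low"}
    assert (curves.groupby("group")["survival"].first() == 1.0).all()
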