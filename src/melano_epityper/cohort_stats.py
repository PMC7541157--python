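"""Cohort statistics: Fisher exact, Welch t, Kaplan-Meier, log-rank,
quartile expression grouping and Polycomb-target enrichment.

The tests are implemented from first principles (SciPy supplies only
distribution functions): the two-sided Fisher p-value sums hypergeometric
probabilities of all tables with fixed margins whose probability does not
exceed the observed one; the Kaplan-Meier estimator is the product-limit
form; the log-rank statistic accumulates observed-minus-expected events
over risk sets with the hypergeometric (tie-aware) variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import StatsParams, ValidationError
from . import marker_extraction as mk

ALPHA = 0.05


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    alpha: float = ALPHA
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")
        self.p_value = min(self.p_value, 1.0)


# ---------------------------------------------------------------- Fisher

def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table [[a, b], [c, d]].

    p sums the hypergeometric probabilities (margins fixed) of every table
    at most as probable as the observed one (minimum-likelihood method).
    The sample odds ratio ad/bc is reported (inf/nan on zero cells).
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValidationError("contingency counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        raise ValidationError("empty contingency table")
    r1, c1 = a + b, a + c
    rv = sps.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - (c + d)), min(r1, c1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    # relative tolerance guards against float noise in pmf comparisons
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.divide(a * d, b * c) if (b * c) != 0 else (
            np.inf if a * d > 0 else np.nan
        )
    return TestResult(
        method="fisher_exact",
        statistic=float(odds),
        p_value=min(p, 1.0),
        extra={"table": [[a, b], [c, d]], "odds_ratio": float(odds)},
    )


# ---------------------------------------------------------------- Welch t

def welch_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    pooled: bool = False,
) -> TestResult:
    """Two-sided two-sample t test (Welch-Satterthwaite by default).

    Reports per-group mean and sample SD in ``extra`` in "mean +/- SD" form.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            t, df = 0.0, len(a) + len(b) - 2
            p = 1.0
            return TestResult("t_test", t, p, extra=_welch_extra(a, b, df))
        raise ValidationError("degenerate groups: zero variance in both groups")
    na, nb = len(a), len(b)
    if pooled:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    else:
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t = float((a.mean() - b.mean()) / se)
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult("t_test", t, min(p, 1.0), extra=_welch_extra(a, b, df))


def _welch_extra(a: np.ndarray, b: np.ndarray, df: float) -> dict:
    return {
        "df": float(df),
        "mean_a": float(a.mean()),
        "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()),
        "sd_b": float(b.std(ddof=1)),
        "summary": (
            f"{a.mean():.1f} ± {a.std(ddof=1):.1f} vs "
            f"{b.mean():.1f} ± {b.std(ddof=1):.1f}"
        ),
    }


# ---------------------------------------------------------------- survival

def km_estimate(
    times: Sequence[float], events: Sequence[int]
) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival curve for one group.

    Returns a frame with columns ``time``, ``n_at_risk``, ``n_events``,
    ``survival`` (right-continuous steps at event times, S(0) = 1). The
    attribute ``median`` on the frame gives the median survival time
    (NaN when S never drops to 0.5).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise ValidationError("no survival observations")
    if (t < 0).any():
        raise ValidationError("survival times must be >= 0")
    if not np.isin(e, (0, 1)).all():
        raise ValidationError("event indicators must be 0 or 1")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    rows = [(0.0, len(t), 0, 1.0)]
    s = 1.0
    for ti in np.unique(t[e == 1]):
        at_risk = int((t >= ti).sum())
        d = int(((t == ti) & (e == 1)).sum())
        s *= 1.0 - d / at_risk
        rows.append((float(ti), at_risk, d, s))
    curve = pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])
    below = curve[curve["survival"] <= 0.5]
    curve.attrs["median"] = float(below["time"].iloc[0]) if len(below) else float("nan")
    return curve


def logrank_test(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence,
) -> TestResult:
    """Two-group log-rank test (1-df chi-squared).

    At each distinct event time the observed events in group 1 are compared
    with the hypergeometric expectation given the risk sets; ties use the
    multi-tie variance n1 n2 d (n - d) / (n^2 (n - 1)).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if (t < 0).any():
        raise ValidationError("survival times must be >= 0")
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValidationError("log-rank test requires exactly two groups")
    if e.sum() == 0:
        raise ValidationError("log-rank test requires at least one event")
    in1 = g == labels[0]
    o_minus_e = 0.0
    var = 0.0
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d = int(((t == ti) & (e == 1)).sum())
        d1 = int(((t == ti) & (e == 1) & in1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        raise ValidationError("log-rank variance is zero; groups degenerate")
    chi2 = o_minus_e**2 / var
    p = float(sps.chi2.sf(chi2, df=1))
    return TestResult(
        "logrank", float(chi2), p,
        extra={"groups": [str(x) for x in labels], "o_minus_e": float(o_minus_e)},
    )


# ---------------------------------------------------------------- quartiles

def quartile_groups(expression: pd.Series) -> pd.Series:
    """Label the top expression quartile "high", the bottom "low".

    With n samples, the floor(n/4) highest values form the high group and
    the floor(n/4) lowest the low group; the middle half is "excluded".
    Boundary ties are resolved by rank: values are ordered by (value,
    sample id) and exactly floor(n/4) samples enter each group.
    """
    n = len(expression)
    if n < 4:
        raise ValidationError("quartile grouping needs at least 4 samples")
    values = expression.astype(float)
    if values.nunique() == 1:
        raise ValidationError("quartiles undefined: all expression values equal")
    k = n // 4
    order = values.to_frame("v").assign(s=values.index.astype(str))
    order = order.sort_values(["v", "s"], kind="mergesort").index
    labels = pd.Series("excluded", index=expression.index, name="expr_group")
    labels.loc[order[:k]] = "low"
    labels.loc[order[-k:]] = "high"
    return labels


# ---------------------------------------------------------------- enrichment

def prc_enrichment(
    marker_table: pd.DataFrame, gene_sets: Mapping[str, set]
) -> pd.DataFrame:
    """Polycomb-target enrichment of high-methylation marker genes.

    For each gene set, marker genes are compared against the unmethylated
    genes and against the normally methylated genes in 2x2 tables
    (category membership x set membership), via :func:`fisher_exact`.
    """
    results = []
    for set_name, members in gene_sets.items():
        for background in (mk.CAT_UNMETH, mk.CAT_NORMAL):
            markers = marker_table.index[marker_table["category"] == mk.CAT_MARKER]
            ref = marker_table.index[marker_table["category"] == background]
            if len(markers) == 0 or len(ref) == 0:
                raise ValidationError(
                    f"empty category in enrichment ({mk.CAT_MARKER} vs {background})"
                )
            a = int(markers.isin(members).sum())
            b = len(markers) - a
            c = int(ref.isin(members).sum())
            d = len(ref) - c
            res = fisher_exact([[a, b], [c, d]])
            results.append(
                {
                    "gene_set": set_name,
                    "comparison": f"{mk.CAT_MARKER}_vs_{background}",
                    "in_set_markers": a,
                    "markers": len(markers),
                    "in_set_background": c,
                    "background": len(ref),
                    "odds_ratio": res.statistic,
                    "p_value": res.p_value,
                    "significant": res.significant,
                }
            )
    return pd.DataFrame(results)


# ---------------------------------------------------------------- reports

def survival_curves(
    clinical: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """Per-epigenotype Kaplan-Meier curves in long format."""
    merged = clinical.set_index("sample").join(labels.rename("epigenotype"), how="inner")
    frames = []
    for lab, grp in merged.groupby("epigenotype"):
        curve = km_estimate(grp["os_days"], grp["os_event"])
        curve.insert(0, "group", lab)
        frames.append(curve)
    return pd.concat(frames, ignore_index=True)


def association_report(
    labels: pd.Series,
    clinical: pd.DataFrame,
    params: Optional[StatsParams] = None,
) -> pd.DataFrame:
    """Association of the methylation epigenotype with clinical factors.

    Categorical factors (mutations, site, ulcer, stage 1-2 vs 3-4,
    thickness dichotomized at 4 mm, age at the cohort median) are tested by
    Fisher's exact test; quantitative Breslow thickness by a t test; overall
    survival by the log-rank test. A Benjamini-Hochberg adjusted column is
    appended as a supplementary aid (the per-test alpha remains the primary
    readout).
    """
    params = (params or StatsParams()).validate()
    df = clinical.set_index("sample").join(labels.rename("epigenotype"), how="inner")
    if df["epigenotype"].nunique() != 2:
        raise ValidationError("need both epigenotypes in the clinical join")
    is_high = df["epigenotype"] == "high"

    binary_factors = {
        "braf_mut": df["braf_mut"].astype(int) == 1,
        "nras_mut": df["nras_mut"].astype(int) == 1,
        "acral_site": df["site"] == "acral",
        "ulcer": df["ulcer"].astype(int) == 1,
        "stage_3_4": df["stage"].astype(int) >= params.stage_advanced_min,
        f"thickness_gt_{params.thickness_cut_mm:g}mm":
            df["breslow_mm"] > params.thickness_cut_mm,
        "age_ge_median": df["age"] >= df["age"].median(),
    }
    rows = []
    for name, flag in binary_factors.items():
        a = int((is_high & flag).sum())
        b = int((is_high & ~flag).sum())
        c = int((~is_high & flag).sum())
        d = int((~is_high & ~flag).sum())
        res = fisher_exact([[a, b], [c, d]])
        rows.append(
            {
                "factor": name, "test": res.method, "statistic": res.statistic,
                "p_value": res.p_value, "detail": f"high {a}/{a+b}, low {c}/{c+d}",
            }
        )

    t_res = welch_t(
        df.loc[is_high, "breslow_mm"], df.loc[~is_high, "breslow_mm"],
        pooled=params.pooled_t,
    )
    rows.append(
        {
            "factor": "breslow_mm", "test": t_res.method,
            "statistic": t_res.statistic, "p_value": t_res.p_value,
            "detail": t_res.extra["summary"],
        }
    )

    lr = logrank_test(df["os_days"], df["os_event"], df["epigenotype"])
    rows.append(
        {
            "factor": "overall_survival", "test": lr.method,
            "statistic": lr.statistic, "p_value": lr.p_value,
            "detail": f"events high {int(df.loc[is_high, 'os_event'].sum())}, "
                      f"low {int(df.loc[~is_high, 'os_event'].sum())}",
        }
    )

    report = pd.DataFrame(rows)
    report["significant"] = report["p_value"] < params.alpha
    from statsmodels.stats.multitest import multipletests
    report["p_bh_supplementary"] = multipletests(
        report["p_value"], method="fdr_bh"
    )[1]
    return report


def thickness_by_subgroup(
    labels: pd.Series, clinical: pd.DataFrame
) -> Dict[str, dict]:
    """Per-epigenotype Breslow thickness summary (mean, SD, SE, n)."""
    df = clinical.set_index("sample").join(labels.rename("epigenotype"), how="inner")
    out = {}
    for lab, grp in df.groupby("epigenotype"):
        x = grp["breslow_mm"].astype(float)
        out[str(lab)] = {
            "n": int(len(x)),
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)),
            "se": float(x.std(ddof=1) / np.sqrt(len(x))),
        }
    return out
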