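"""Group comparison, demographics, and behavior-topology correlations.

Node-wise AUC values are compared between groups with a two-tailed
pooled-variance (Student) t-test; gender with a Pearson chi-square (no
continuity correction); behavioral correlations use Pearson r with the
exact t-transform p-value, falling back to Spearman when either variable
fails a Shapiro-Wilk normality check at alpha = 0.05.  Significance is
uncorrected p < alpha by default, with optional Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .atlas import CohortTable, RegionAtlas, ValidationError
from .metrics import METRIC_NAMES


class DegenerateDataError(ValueError):
    """Raised when a statistic is undefined on the given data."""


def two_sample_t(x, y, *, welch: bool = False) -> tuple[float, float]:
    """Two-tailed independent-samples t-test (pooled variance by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateDataError("each group needs at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DegenerateDataError("non-finite values in t-test input")
    if not welch and x.var(ddof=1) + y.var(ddof=1) == 0:
        raise DegenerateDataError("zero pooled variance")
    t, p = sps.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)


def t_from_summary(mean_a: float, sd_a: float, n_a: int,
                   mean_b: float, sd_b: float, n_b: int,
                   *, welch: bool = False) -> tuple[float, float]:
    """Same test from summary statistics (mean, SD, n per group)."""
    if n_a < 2 or n_b < 2:
        raise DegenerateDataError("each group needs n >= 2")
    if not welch and sd_a == 0 and sd_b == 0:
        raise DegenerateDataError("zero pooled variance")
    res = sps.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                   equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]], df = 1,
    without Yates continuity correction."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise DegenerateDataError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateDataError("degenerate margin in 2x2 table")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def normality_check(x, alpha: float = 0.05) -> bool:
    """Shapiro-Wilk at ``alpha``; True = compatible with normality.

    A constant vector is reported as non-normal (False) rather than an
    error, so degenerate metric columns simply route to Spearman.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise DegenerateDataError("normality check needs n >= 3")
    if np.ptp(x) == 0:
        return False
    with np.errstate(all="ignore"):
        _, p = sps.shapiro(x)
    return bool(p > alpha)


def correlation_p_from_r(r: float, n: int) -> float:
    """Two-tailed p for a correlation via t = r sqrt((n-2)/(1-r^2)), df = n-2."""
    if n < 3:
        raise DegenerateDataError("correlation inference needs n >= 3")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def _correlate(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Pearson r (or Spearman if either variable fails normality) with
    the t-transform two-tailed p-value."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant variable in correlation")
    method = "pearson"
    if not (normality_check(x) and normality_check(y)):
        method = "spearman"
        x = sps.rankdata(x)
        y = sps.rankdata(y)
    r = float(np.corrcoef(x, y)[0, 1])
    return r, correlation_p_from_r(r, len(x)), method


@dataclass
class GroupDiffTable:
    frame: pd.DataFrame  # metric, region, mean_AD, mean_NC, t, p, direction, significant


@dataclass
class BehaviorCorrTable:
    frame: pd.DataFrame  # metric, region, score, r, p, method, n_used


@dataclass
class DemographicsReport:
    frame: pd.DataFrame  # variable, AD, NC, statistic, p, test


def group_difference(auc: dict[str, np.ndarray], groups: np.ndarray,
                     atlas: RegionAtlas, *, alpha: float = 0.05,
                     welch: bool = False, fdr: bool = False) -> GroupDiffTable:
    """Node-wise AD-vs-NC t-tests on per-subject nodal AUC values.

    ``auc`` maps metric -> (n_subjects, N) matrix in cohort order;
    ``groups`` is the matching array of "AD"/"NC" labels.
    """
    groups = np.asarray(groups)
    ad = groups == "AD"
    nc = groups == "NC"
    rows = []
    for metric, mat in auc.items():
        xa, xn = mat[ad], mat[nc]
        t, p = sps.ttest_ind(xa, xn, axis=0, equal_var=not welch)
        ma, mn = xa.mean(axis=0), xn.mean(axis=0)
        for k in range(mat.shape[1]):
            rows.append(
                {
                    "metric": metric,
                    "region": atlas.abbrevs[k],
                    "mean_AD": ma[k],
                    "mean_NC": mn[k],
                    "t": t[k],
                    "p": p[k],
                    "direction": "AD>NC" if ma[k] > mn[k] else "AD<NC",
                }
            )
    frame = pd.DataFrame(rows)
    if fdr:
        frame["significant"] = multipletests(frame["p"], alpha=alpha, method="fdr_bh")[0]
    else:
        frame["significant"] = frame["p"] < alpha
    return GroupDiffTable(frame)


def significant_nodes(diff: GroupDiffTable, alpha: float = 0.05,
                      *, fdr: bool = False) -> pd.DataFrame:
    """Rows surviving the significance rule, grouped by metric."""
    frame = diff.frame
    if fdr:
        keep = multipletests(frame["p"], alpha=alpha, method="fdr_bh")[0]
    else:
        keep = frame["p"] < alpha
    out = frame[keep].sort_values(["metric", "region"]).reset_index(drop=True)
    return out


def behavior_correlation(auc: dict[str, np.ndarray], cohort: CohortTable,
                         atlas: RegionAtlas, score: str,
                         rows: pd.DataFrame) -> BehaviorCorrTable:
    """Correlate a behavioral score with nodal AUCs for selected rows.

    Subjects from both groups are pooled; pairs with a missing score are
    excluded; rows with fewer than 3 complete pairs are skipped.
    """
    score_vals = np.array([r.scores.get(score, np.nan) for r in cohort.records])
    out = []
    for _, row in rows.iterrows():
        metric, region = row["metric"], row["region"]
        k = atlas.index_of(region)
        x = auc[metric][:, k]
        mask = np.isfinite(score_vals) & np.isfinite(x)
        n = int(mask.sum())
        if n < 3:
            continue
        try:
            r, p, method = _correlate(x[mask], score_vals[mask])
        except DegenerateDataError:
            continue
        out.append(
            {"metric": metric, "region": region, "score": score,
             "r": r, "p": p, "method": method, "n_used": n}
        )
    cols = ["metric", "region", "score", "r", "p", "method", "n_used"]
    return BehaviorCorrTable(pd.DataFrame(out, columns=cols))


def demographics_report(cohort: CohortTable, *, welch: bool = False) -> DemographicsReport:
    """Group descriptives with the matching test: t for continuous
    variables and scores (scored subjects only), chi-square for sex."""
    rows = []

    def _cont(name: str, getter) -> None:
        a = np.array([getter(r) for r in cohort.group("AD")], dtype=float)
        n = np.array([getter(r) for r in cohort.group("NC")], dtype=float)
        a, n = a[np.isfinite(a)], n[np.isfinite(n)]
        if len(a) < 2 or len(n) < 2:
            return
        try:
            t, p = two_sample_t(a, n, welch=welch)
        except DegenerateDataError:
            return
        rows.append(
            {
                "variable": name,
                "AD": f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
                "NC": f"{n.mean():.2f} ± {n.std(ddof=1):.2f}",
                "statistic": t,
                "p": p,
                "test": "t (Welch)" if welch else "t",
            }
        )

    _cont("age", lambda r: r.age)
    _cont("education", lambda r: r.education)
    ad_m = sum(r.sex == "M" for r in cohort.group("AD"))
    ad_f = cohort.n_ad - ad_m
    nc_m = sum(r.sex == "M" for r in cohort.group("NC"))
    nc_f = cohort.n_nc - nc_m
    try:
        chi2, p = chi_square_2x2(ad_m, ad_f, nc_m, nc_f)
        rows.append(
            {"variable": "sex (M/F)", "AD": f"{ad_m}/{ad_f}", "NC": f"{nc_m}/{nc_f}",
             "statistic": chi2, "p": p, "test": "chi2"}
        )
    except DegenerateDataError:
        pass
    score_names = sorted({s for r in cohort.records for s in r.scores})
    for s in score_names:
        _cont(s, lambda r, s=s: r.scores.get(s, np.nan))
    return DemographicsReport(pd.DataFrame(rows))


def run_group_analysis(auc: dict[str, np.ndarray], cohort: CohortTable,
                       atlas: RegionAtlas, *, alpha: float = 0.05,
                       welch: bool = False, fdr: bool = False,
                       scores: tuple[str, ...] = ("UPSIT",),
                       ) -> tuple[DemographicsReport, GroupDiffTable, BehaviorCorrTable]:
    """The full statistical plan: demographics, node-wise group
    differences per metric, and behavior correlations restricted to the
    metric/region pairs that showed a significant group difference."""
    for metric in auc:
        if metric not in METRIC_NAMES:
            raise ValidationError(f"unknown metric {metric!r} in AUC table")
    groups = np.array([r.group for r in cohort.records])
    demo = demographics_report(cohort, welch=welch)
    diff = group_difference(auc, groups, atlas, alpha=alpha, welch=welch, fdr=fdr)
    sig = significant_nodes(diff, alpha, fdr=fdr)
    corr_frames = [
        behavior_correlation(auc, cohort, atlas, s, sig).frame for s in scores
    ]
    corr = BehaviorCorrTable(
        pd.concat(corr_frames, ignore_index=True)
        if corr_frames
        else pd.DataFrame(columns=["metric", "region", "score", "r", "p", "method", "n_used"])
    )
    return demo, diff, corr
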