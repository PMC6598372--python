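"""Group-level and paired statistics for the cumulative panel scores.

Covers the cohort-comparison layer of the analysis: Wilcoxon rank-sum
comparisons of the panel statistics across biopsy/risk grading groups,
the paired DRE-vs-FV analysis (paired t test per marker and for the two
cumulative statistics), box-plot style group summaries, demographic
tables, and the PSA outlier-exclusion rule used when summarizing case
PSA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import CohortTable
from .scoring import score_sample, scores_frame


@dataclass(frozen=True)
class GroupSummary:
    """Box-plot summary of one grading group.

    Hinges are the first and third quartiles computed by linear
    interpolation between order statistics (numpy's default); the median
    is the mean of the two central order statistics for even n.
    """

    group_label: str
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    min: float
    max: float


@dataclass(frozen=True)
class PairedResult:
    """Paired t test result for one marker or cumulative statistic.

    ``mean_difference`` follows the DRE − FV orientation: positive means
    better recovery from the post-DRE sample.
    """

    name: str
    n_pairs: int
    mean_difference: float
    ci: tuple[float, float]
    p_value: float
    t_statistic: float


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], *, continuity: bool = False
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Uses exact enumeration when both samples have ≤ 10 observations and
    there are no ties; otherwise the normal approximation with tie
    correction.  The continuity correction is off by default.  Returns
    the rank-sum statistic of ``x`` and the two-sided p-value.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    combined = x + y
    if len(set(combined)) == 1:
        # every assignment yields the same rank sum; two-sided p is 1
        return len(x) * (len(combined) + 1) / 2.0, 1.0
    no_ties = len(set(combined)) == len(combined)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=continuity
    )
    rank_sum = float(res.statistic) + len(x) * (len(x) + 1) / 2.0
    return rank_sum, float(res.pvalue)


def paired_t(
    differences: Sequence[float], name: str = "", confidence: float = 0.95
) -> PairedResult:
    """One-sample t test of paired differences against zero.

    ``t = mean / (sd/sqrt(n))`` with ``df = n − 1``; the CI is the
    standard t interval on the mean difference.  Zero-variance input is
    handled as the limiting case: p = 1 when the common difference is 0,
    p → 0 (t infinite) otherwise.
    """
    d = np.asarray(list(differences), dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedResult(name, n, 0.0, (0.0, 0.0), 1.0, 0.0)
        t_stat = math.inf if mean > 0 else -math.inf
        return PairedResult(name, n, mean, (mean, mean), 0.0, t_stat)
    se = sd / math.sqrt(n)
    t_stat = mean / se
    p = 2.0 * float(stats.t.sf(abs(t_stat), n - 1))
    t_crit = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1))
    return PairedResult(
        name=name,
        n_pairs=n,
        mean_difference=mean,
        ci=(mean - t_crit * se, mean + t_crit * se),
        p_value=p,
        t_statistic=t_stat,
    )


def paired_marker_analysis(cohort: CohortTable) -> list[PairedResult]:
    """Within-patient DRE − FV comparison.

    For every patient with both sample types, computes the per-marker
    signal difference plus the differences of the two cumulative
    statistics (``n_positive``, ``avg_methylation``), and runs the
    paired t test on each.  Returns one result per marker (panel order)
    followed by the two cumulative statistics.
    """
    paired_ids = cohort.paired_patient_ids()
    if len(paired_ids) < 2:
        raise ValueError("need at least 2 patients with both sample types")
    by_key = {(s.patient_id, s.sample_type): s for s in cohort.samples}
    results = []
    for marker in cohort.panel:
        diffs = [
            by_key[(pid, "DRE")].signals[marker] - by_key[(pid, "FV")].signals[marker]
            for pid in paired_ids
        ]
        results.append(paired_t(diffs, name=marker))
    dre_scores = {
        pid: score_sample(by_key[(pid, "DRE")], cohort.panel) for pid in paired_ids
    }
    fv_scores = {
        pid: score_sample(by_key[(pid, "FV")], cohort.panel) for pid in paired_ids
    }
    results.append(
        paired_t(
            [dre_scores[p].n_positive - fv_scores[p].n_positive for p in paired_ids],
            name="n_positive",
        )
    )
    results.append(
        paired_t(
            [
                dre_scores[p].avg_methylation - fv_scores[p].avg_methylation
                for p in paired_ids
            ],
            name="avg_methylation",
        )
    )
    return results


def paired_results_frame(results: Sequence[PairedResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "n_pairs": r.n_pairs,
                "mean_diff": r.mean_difference,
                "ci_low": r.ci[0],
                "ci_high": r.ci[1],
                "p_value": r.p_value,
            }
            for r in results
        ]
    )


def _summary(label: str, values: np.ndarray) -> GroupSummary:
    return GroupSummary(
        group_label=label,
        n=int(values.size),
        mean=float(values.mean()),
        median=float(np.median(values)),
        q1=float(np.percentile(values, 25)),
        q3=float(np.percentile(values, 75)),
        min=float(values.min()),
        max=float(values.max()),
    )


def group_summaries(
    cohort: CohortTable,
    statistic: str = "n_positive",
    sample_type: str = "DRE",
) -> tuple[list[GroupSummary], dict[tuple[str, str], float]]:
    """Box-plot summaries by grading group plus Wilcoxon comparisons.

    Summarizes ``statistic`` ("n_positive" or "avg_methylation") for
    grading groups 0 (negative biopsy), 1 (low risk), 2 (elevated risk)
    and the combined positive group "1+2", then compares 0 vs 1+2 and
    1 vs 2 with the Wilcoxon rank-sum test.  Empty groups are skipped
    with a warning.
    """
    if statistic not in ("n_positive", "avg_methylation"):
        raise ValueError(f"unknown statistic {statistic!r}")
    frame = scores_frame(cohort, sample_type)
    groups = {
        "0": frame.loc[frame.grading_group == 0, statistic].to_numpy(float),
        "1": frame.loc[frame.grading_group == 1, statistic].to_numpy(float),
        "2": frame.loc[frame.grading_group == 2, statistic].to_numpy(float),
        "1+2": frame.loc[frame.grading_group > 0, statistic].to_numpy(float),
    }
    summaries = [
        _summary(label, values) for label, values in groups.items() if values.size
    ]
    comparisons: dict[tuple[str, str], float] = {}
    for a, b in (("0", "1+2"), ("1", "2")):
        if groups[a].size and groups[b].size:
            comparisons[(a, b)] = wilcoxon_rank_sum(groups[a], groups[b])[1]
        else:
            warnings.warn(
                f"skipping Wilcoxon comparison {a} vs {b}: empty group", UserWarning
            )
    return summaries, comparisons


def psa_mean_with_outlier_rule(
    psa_values: Sequence[float],
) -> tuple[float, float, list[float]]:
    """Mean/SD of PSA after iterative extreme-outlier exclusion.

    Repeatedly removes the current maximum while it exceeds twice the
    maximum of the remaining values, then returns the arithmetic mean,
    sample SD and the excluded values (in exclusion order).
    """
    values = sorted(float(v) for v in psa_values)
    if not values:
        raise ValueError("psa_values must be non-empty")
    excluded: list[float] = []
    while len(values) > 1 and values[-1] > 2.0 * values[-2]:
        excluded.append(values.pop())
    arr = np.array(values)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return float(arr.mean()), sd, excluded


def _continuous_rows(
    variable: str, cases: np.ndarray, controls: np.ndarray
) -> list[dict]:
    def fmt(values: np.ndarray) -> dict:
        if values.size == 0:
            return {"n": 0, "mean": np.nan, "sd": np.nan, "median": np.nan,
                    "min": np.nan, "max": np.nan}
        return {
            "n": int(values.size),
            "mean": float(values.mean()),
            "sd": float(values.std(ddof=1)) if values.size > 1 else np.nan,
            "median": float(np.median(values)),
            "min": float(values.min()),
            "max": float(values.max()),
        }

    rows = []
    for label, values in (("cases", cases), ("controls", controls)):
        rows.append({"variable": variable, "group": label, **fmt(values)})
    return rows


def cohort_demographics(cohort: CohortTable) -> pd.DataFrame:
    """Demographic summary by diagnosis, one row per variable × group.

    Continuous variables (age, PSA) get mean/SD/median/range, with the
    extreme-outlier rule applied to case PSA; categorical variables
    (race, sample availability, dichotomized Gleason ≤7/>7 and positive
    cores ≤3/>3 — boundary values inclusive in the lower bin) get counts
    and percentages of the diagnosis group.
    """
    patients = list(cohort.patients.values())
    cases = [p for p in patients if p.diagnosis == "case"]
    controls = [p for p in patients if p.diagnosis == "control"]
    rows: list[dict] = []
    rows.append(
        {"variable": "n", "group": "cases", "n": len(cases)}
    )
    rows.append({"variable": "n", "group": "controls", "n": len(controls)})

    def arr(group, attr):
        return np.array([getattr(p, attr) for p in group if getattr(p, attr) is not None])

    rows += _continuous_rows("age", arr(cases, "age"), arr(controls, "age"))

    case_psa = arr(cases, "psa")
    if case_psa.size:
        mean, sd, excluded = psa_mean_with_outlier_rule(case_psa)
        rows.append(
            {
                "variable": "psa", "group": "cases", "n": int(case_psa.size),
                "mean": mean, "sd": sd,
                "median": float(np.median(case_psa)),
                "min": float(case_psa.min()), "max": float(case_psa.max()),
                "n_outliers_excluded": len(excluded),
            }
        )
    else:
        rows.append({"variable": "psa", "group": "cases", "n": 0})
    rows += _continuous_rows("psa", np.array([]), arr(controls, "psa"))[1:]

    have: dict[str, set[str]] = {}
    for s in cohort.samples:
        have.setdefault(s.patient_id, set()).add(s.sample_type)
    for label, group in (("cases", cases), ("controls", controls)):
        avail = {"DRE and FV": 0, "DRE only": 0, "FV only": 0, "none": 0}
        for p in group:
            types = have.get(p.patient_id, set())
            if types == {"DRE", "FV"}:
                avail["DRE and FV"] += 1
            elif types == {"DRE"}:
                avail["DRE only"] += 1
            elif types == {"FV"}:
                avail["FV only"] += 1
            else:
                avail["none"] += 1
        for category, count in avail.items():
            rows.append(
                {
                    "variable": f"samples: {category}", "group": label,
                    "n": count,
                    "percent": 100.0 * count / len(group) if group else np.nan,
                }
            )
        races = [p.race for p in group if p.race is not None]
        for race in sorted(set(races)):
            count = races.count(race)
            rows.append(
                {
                    "variable": f"race: {race}", "group": label, "n": count,
                    "percent": 100.0 * count / len(group),
                }
            )

    gleason = arr(cases, "gleason")
    cores = arr(cases, "positive_cores")
    for variable, values, cut in (
        ("gleason", gleason, 7.0),
        ("positive_cores", cores, 3.0),
    ):
        if values.size:
            rows += _continuous_rows(variable, values, np.array([]))[:1]
            low = int((values <= cut).sum())
            high = int((values > cut).sum())
            rows.append(
                {
                    "variable": f"{variable} <= {cut:g}", "group": "cases",
                    "n": low, "percent": 100.0 * low / len(cases),
                }
            )
            rows.append(
                {
                    "variable": f"{variable} > {cut:g}", "group": "cases",
                    "n": high, "percent": 100.0 * high / len(cases),
                }
            )
    return pd.DataFrame(rows)
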