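"""Wilcoxon/paired-t statistics, group summaries, PSA rule, demographics."""

import itertools
import math

import numpy as np
import pytest

from methpanel import (
    PatientRecord,
    CohortTable,
    SampleRecord,
    cohort_demographics,
    group_summaries,
    paired_marker_analysis,
    paired_t,
    psa_mean_with_outlier_rule,
    wilcoxon_rank_sum,
)

from conftest import make_cohort, make_sample


def exact_permutation_p(x, y):
    """Oracle: enumerate every reassignment of the pooled values."""
    pooled = list(x) + list(y)
    ranks = {}
    # midranks for ties
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        mid = (i + j + 1) / 2.0
        for k in range(i, j):
            ranks[order[k]] = mid
        i = j
    n1 = len(x)
    mu = n1 * (len(pooled) + 1) / 2.0
    observed = abs(sum(ranks[i] for i in range(n1)) - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(sum(ranks[i] for i in combo) - mu) >= observed - 1e-12:
            count += 1
    return count / total


def test_wilcoxon_identical_samples():
    x = [1.0, 2.0, 3.0, 4.0]
    stat, p = wilcoxon_rank_sum(x, x)
    assert p == pytest.approx(1.0, abs=0.05)


def test_wilcoxon_all_tied_gives_p_one():
    _, p = wilcoxon_rank_sum([2.0] * 5, [2.0] * 7)
    assert p == 1.0


def test_wilcoxon_complete_separation_smallest_p():
    # 3 vs 3 without ties: the most extreme assignment has p = 2/20
    _, p = wilcoxon_rank_sum([1, 2, 3], [101, 102, 103])
    assert p == pytest.approx(2 / 20)


def test_wilcoxon_matches_exact_permutation_small_n():
    rng = np.random.default_rng(2024)
    for _ in range(5):
        x = rng.normal(0, 1, 6).tolist()
        y = rng.normal(0.8, 1, 6).tolist()
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(exact_permutation_p(x, y), abs=1e-12)


def test_wilcoxon_symmetric_in_arguments():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 15).tolist()
    y = rng.normal(0.5, 1, 20).tolist()
    assert wilcoxon_rank_sum(x, y)[1] == pytest.approx(
        wilcoxon_rank_sum(y, x)[1], abs=1e-12
    )


def test_wilcoxon_rejects_empty():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


def test_paired_t_all_zero_differences():
    result = paired_t([0.0, 0.0, 0.0, 0.0])
    assert result.t_statistic == 0.0 and result.p_value == 1.0


def test_paired_t_zero_variance_nonzero_mean():
    result = paired_t([1.0, 1.0, 1.0, 1.0])
    assert math.isinf(result.t_statistic)
    assert result.p_value == 0.0
    assert result.mean_difference == 1.0


def test_paired_t_matches_textbook_formula():
    # frozen against the direct formula: t = mean/(sd/sqrt(n)), df = n-1
    result = paired_t([0.5, -0.2, 0.9, 1.1, 0.3])
    assert result.t_statistic == pytest.approx(2.271630547318698, abs=1e-12)
    assert result.p_value == pytest.approx(0.08557339864849778, abs=1e-12)
    assert result.ci[0] == pytest.approx(-0.11555733409509461, abs=1e-12)
    assert result.ci[1] == pytest.approx(1.1555573340950944, abs=1e-12)
    assert result.ci[0] <= result.mean_difference <= result.ci[1]


def test_paired_t_sign_flip():
    d = [0.5, -0.2, 0.9, 1.1, 0.3]
    pos = paired_t(d)
    neg = paired_t([-v for v in d])
    assert neg.t_statistic == pytest.approx(-pos.t_statistic)
    assert neg.p_value == pytest.approx(pos.p_value)


def test_paired_t_needs_two_pairs():
    with pytest.raises(ValueError):
        paired_t([1.0])


def _paired_cohort(panel, n_pairs, shift_marker=None, shift=0.0):
    markers = list(panel)
    samples = []
    diagnoses = {}
    for i in range(n_pairs):
        pid = f"p{i:02d}"
        base = {m: float((i + j) % 4) for j, m in enumerate(markers)}
        fv = dict(base)
        dre = dict(base)
        if shift_marker is not None:
            dre[shift_marker] = fv[shift_marker] + shift
        samples.append(SampleRecord(pid, "DRE", dre))
        samples.append(SampleRecord(pid, "FV", fv))
        diagnoses[pid] = ("case", 1)
    return make_cohort(panel, samples, diagnoses)


def test_paired_analysis_identical_samples_all_zero(panel32):
    cohort = _paired_cohort(panel32, 6)
    results = paired_marker_analysis(cohort)
    assert len(results) == 34  # 32 markers + n_positive + avg_methylation
    assert [r.name for r in results[-2:]] == ["n_positive", "avg_methylation"]
    assert all(r.mean_difference == 0.0 for r in results)
    assert all(r.p_value == 1.0 for r in results)


def test_paired_analysis_detects_constructed_shift(panel32):
    marker = list(panel32)[4]
    cohort = _paired_cohort(panel32, 58, shift_marker=marker, shift=1.0)
    results = {r.name: r for r in paired_marker_analysis(cohort)}
    assert results[marker].mean_difference == pytest.approx(1.0)
    assert results[marker].p_value < 1e-6
    assert results[marker].n_pairs == 58
    # avg_methylation shifts by 1/32 in the DRE direction
    assert results["avg_methylation"].mean_difference == pytest.approx(1 / 32)


def test_group_summaries_constructed_shift(panel32):
    markers = list(panel32)
    samples, diagnoses = [], {}
    for i in range(8):
        pid = f"k{i}"
        samples.append(make_sample(panel32, pid, "DRE", markers[:2]))
        diagnoses[pid] = ("control", 0)
    for i in range(8):
        pid = f"g1_{i}"
        samples.append(make_sample(panel32, pid, "DRE", markers[:10]))
        diagnoses[pid] = ("case", 1)
    for i in range(8):
        pid = f"g2_{i}"
        samples.append(make_sample(panel32, pid, "DRE", markers[:20]))
        diagnoses[pid] = ("case", 2)
    cohort = make_cohort(panel32, samples, diagnoses)
    summaries, comparisons = group_summaries(cohort, "n_positive", "DRE")
    by_label = {s.group_label: s for s in summaries}
    assert by_label["0"].median == 2
    assert by_label["1"].median == 10
    assert by_label["2"].median == 20
    assert by_label["1+2"].n == 16
    assert comparisons[("0", "1+2")] < 0.01
    assert comparisons[("1", "2")] < 0.01
    for s in summaries:
        assert s.min <= s.q1 <= s.median <= s.q3 <= s.max


def test_group_summaries_skips_empty_group_with_warning(panel32):
    samples = [
        make_sample(panel32, "k1", "DRE", []),
        make_sample(panel32, "c1", "DRE", list(panel32)[:5]),
    ]
    cohort = make_cohort(
        panel32, samples, {"k1": ("control", 0), "c1": ("case", 1)}
    )
    with pytest.warns(UserWarning, match="empty group"):
        summaries, comparisons = group_summaries(cohort, "n_positive", "DRE")
    assert ("1", "2") not in comparisons


@pytest.mark.parametrize(
    "values,mean,excluded",
    [
        ([5, 6, 7], 6.0, []),
        ([5, 6, 40], 5.5, [40.0]),
        ([3, 4, 30, 90], 3.5, [90.0, 30.0]),  # rule iterates to a fixed point
    ],
)
def test_psa_outlier_rule(values, mean, excluded):
    got_mean, got_sd, got_excluded = psa_mean_with_outlier_rule(values)
    assert got_mean == pytest.approx(mean)
    assert got_excluded == excluded


def test_psa_outlier_rule_single_value():
    mean, sd, excluded = psa_mean_with_outlier_rule([9.0])
    assert mean == 9.0 and excluded == [] and math.isnan(sd)


def test_demographics_summary(panel32):
    patients = {
        "c1": PatientRecord("c1", "case", 1, psa=5.0, age=60.0, gleason=7, positive_cores=3),
        "c2": PatientRecord("c2", "case", 2, psa=6.0, age=70.0, gleason=8, positive_cores=5),
        "c3": PatientRecord("c3", "case", 1, psa=40.0, age=65.0, gleason=6, positive_cores=1),
        "k1": PatientRecord("k1", "control", 0, psa=4.0, age=62.0),
    }
    samples = [
        make_sample(panel32, "c1", "DRE", []),
        make_sample(panel32, "c1", "FV", []),
        make_sample(panel32, "c2", "DRE", []),
        make_sample(panel32, "k1", "FV", []),
    ]
    cohort = CohortTable(panel=panel32, samples=samples, patients=patients)
    df = cohort_demographics(cohort).set_index(["variable", "group"])
    assert df.loc[("n", "cases"), "n"] == 3
    assert df.loc[("age", "cases"), "mean"] == pytest.approx(65.0)
    assert df.loc[("age", "cases"), "sd"] == pytest.approx(5.0)
    # case PSA mean applies the extreme-outlier rule: 40 > 2*6 is dropped
    assert df.loc[("psa", "cases"), "mean"] == pytest.approx(5.5)
    assert df.loc[("psa", "cases"), "n_outliers_excluded"] == 1
    # boundary gleason 7 falls in the inclusive lower bin
    assert df.loc[("gleason <= 7", "cases"), "n"] == 2
    assert df.loc[("gleason > 7", "cases"), "n"] == 1
    assert df.loc[("positive_cores <= 3", "cases"), "n"] == 2
    assert df.loc[("samples: DRE and FV", "cases"), "n"] == 1
    assert df.loc[("samples: DRE only", "cases"), "n"] == 1
    assert df.loc[("samples: none", "cases"), "n"] == 1
    assert df.loc[("samples: FV only", "controls"), "n"] == 1
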