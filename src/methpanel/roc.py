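"""Empirical ROC curves and AUC for the cumulative panel statistics.

AUC is computed with the Mann–Whitney convention: the probability that a
randomly chosen case scores above a randomly chosen control, with ties
receiving half credit.  On integer-valued scores (the positive-marker
count) this is deterministic and equals the trapezoidal area under the
empirical ROC curve over all unique thresholds.

Also provided is the inverse of a cumulative per-threshold count table:
turning "number of samples with at least t positive markers" columns
back into the per-sample score distribution, which is how published
threshold tables are converted to medians and AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class ScoreDistribution:
    """Empirical distribution of a score in one class, as value→count."""

    class_label: str
    pmf: dict[float, int]
    n: int = field(init=False)

    def __post_init__(self) -> None:
        pmf = {
            float(v): int(c) for v, c in sorted(self.pmf.items()) if c != 0
        }
        if any(c < 0 for c in pmf.values()):
            raise ValueError("pmf counts must be non-negative")
        if any(v < 0 for v in pmf):
            raise ValueError("score support must be non-negative")
        object.__setattr__(self, "pmf", pmf)
        object.__setattr__(self, "n", sum(pmf.values()))
        if self.n == 0:
            raise ValueError("distribution must contain at least one sample")

    @classmethod
    def from_values(
        cls, values: Sequence[float], class_label: str = ""
    ) -> "ScoreDistribution":
        pmf: dict[float, int] = {}
        for v in values:
            pmf[float(v)] = pmf.get(float(v), 0) + 1
        return cls(class_label=class_label, pmf=pmf)

    def values(self) -> list[float]:
        """Expand to the list of per-sample values, sorted ascending."""
        out: list[float] = []
        for v, c in self.pmf.items():
            out.extend([v] * c)
        return out

    @property
    def support(self) -> tuple[float, float]:
        keys = list(self.pmf)
        return (min(keys), max(keys))

    def median(self) -> float:
        """Sample median (mean of the two central order statistics for
        even n)."""
        return float(np.median(self.values()))


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve: (fpr, tpr) per threshold plus endpoints."""

    points: tuple[tuple[float, float], ...]
    auc: float


def reconstruct_pmf(
    cumulative: Mapping[int, int] | Sequence[int],
    n: int,
    class_label: str = "",
) -> ScoreDistribution:
    """Invert a cumulative at-or-above count table into a distribution.

    ``cumulative`` maps threshold ``t`` (1-based) to the number of
    samples with score ≥ t; a plain sequence is taken as thresholds
    1..len.  ``pmf(c) = S(c) − S(c+1)`` for c ≥ 1 and
    ``pmf(0) = n − S(1)``.  Counts must be non-increasing in t and
    ``S(1) ≤ n``; re-accumulating the result reproduces the input.
    """
    if not isinstance(cumulative, Mapping):
        cumulative = {t + 1: c for t, c in enumerate(cumulative)}
    thresholds = sorted(cumulative)
    if thresholds != list(range(1, len(thresholds) + 1)):
        raise ValueError("cumulative table must cover thresholds 1..T")
    counts = [int(cumulative[t]) for t in thresholds]
    if any(b > a for a, b in zip(counts, counts[1:])):
        raise ValueError("cumulative counts must be non-increasing in threshold")
    if counts and counts[0] > n:
        raise ValueError("count at threshold 1 exceeds n")
    survival = counts + [0]
    pmf = {0: n - survival[0]}
    for t in thresholds:
        pmf[t] = survival[t - 1] - survival[t]
    return ScoreDistribution(class_label=class_label, pmf=pmf)


def survival_counts(dist: ScoreDistribution, max_threshold: int) -> list[int]:
    """Forward direction: number of samples with score ≥ t for
    t = 1..max_threshold (the cumulative table)."""
    values = np.array(dist.values())
    return [int((values >= t).sum()) for t in range(1, max_threshold + 1)]


def auc_mann_whitney(
    cases: ScoreDistribution, controls: ScoreDistribution
) -> float:
    """AUC as the tie-adjusted probability a case outscores a control:
    ``[#(case > control) + 0.5·#(case = control)] / (n_case·n_control)``.
    """
    total = 0.0
    for cv, cc in cases.pmf.items():
        for kv, kc in controls.pmf.items():
            if cv > kv:
                total += cc * kc
            elif cv == kv:
                total += 0.5 * cc * kc
    return total / (cases.n * controls.n)


def roc_points(
    cases: ScoreDistribution, controls: ScoreDistribution
) -> RocCurve:
    """Empirical ROC curve over all unique thresholds.

    Each unique observed score, taken as the call cutoff "score ≥
    threshold", yields one (fpr, tpr) point; (0, 0) and (1, 1) complete
    the curve.  The reported area is the trapezoidal integral, which
    equals :func:`auc_mann_whitney` up to floating-point error.
    """
    thresholds = sorted(set(cases.pmf) | set(controls.pmf), reverse=True)
    case_values = np.array(cases.values())
    control_values = np.array(controls.values())
    pts: list[tuple[float, float]] = [(0.0, 0.0)]
    for t in thresholds:
        tpr = float((case_values >= t).mean())
        fpr = float((control_values >= t).mean())
        if (fpr, tpr) != pts[-1]:
            pts.append((fpr, tpr))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    fprs = np.array([p[0] for p in pts])
    tprs = np.array([p[1] for p in pts])
    auc = float(np.trapezoid(tprs, fprs))
    return RocCurve(points=tuple(pts), auc=auc)
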