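"""2×2 diagnostic evaluation: per-marker metrics and the full threshold
sweep with Wald confidence intervals.

Sensitivity and specificity are the observed proportions of positive
calls among biopsy-confirmed cases and negative calls among controls.
Predictive values are computed directly from the 2×2 table, i.e. at the
cohort's own prevalence.  Confidence intervals use the unclamped Wald
(normal approximation) form ``p ± z·sqrt(p(1−p)/n)``, which can exceed
[0, 1] near the boundaries — intervals are reported as computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .panel_io import CohortTable
from .scoring import classify, is_positive, score_cohort


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class DiagnosticRow:
    """One evaluated classifier (a marker or an ``nof32`` threshold)."""

    label: str
    sample_type: str | None
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]


def wald_ci(
    successes: int, n: int, z: float = 1.96
) -> tuple[float, float]:
    """Unclamped Wald binomial confidence interval.

    Returns ``(p − z·sqrt(p(1−p)/n), p + z·sqrt(p(1−p)/n))`` with
    ``p = successes/n``.  The interval is symmetric about ``p`` and is
    deliberately not truncated to [0, 1].
    """
    if n <= 0:
        raise ValueError("undefined interval: n must be positive")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must be in 0..{n}, got {successes}")
    p = successes / n
    half = z * math.sqrt(p * (1.0 - p) / n)
    return (p - half, p + half)


def evaluate_binary(
    case_calls: Sequence[bool],
    control_calls: Sequence[bool],
    *,
    label: str = "",
    sample_type: str | None = None,
    z: float = 1.96,
) -> DiagnosticRow:
    """Evaluate a binary classifier from its calls on cases and controls.

    ``ppv``/``npv`` are ``None`` (reported as "na") when their
    denominator is zero.
    """
    if not case_calls or not control_calls:
        raise ValueError("need at least one case and one control")
    tp = sum(bool(c) for c in case_calls)
    fn = len(case_calls) - tp
    fp = sum(bool(c) for c in control_calls)
    tn = len(control_calls) - fp
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return DiagnosticRow(
        label=label,
        sample_type=sample_type,
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        ppv=tp / (tp + fp) if (tp + fp) > 0 else None,
        npv=tn / (tn + fn) if (tn + fn) > 0 else None,
        sens_ci=wald_ci(tp, tp + fn, z),
        spec_ci=wald_ci(tn, tn + fp, z),
    )


def _class_calls(
    cohort: CohortTable, sample_type: str
) -> tuple[list, list]:
    samples = cohort.samples_of_type(sample_type)
    cases = [s for s in samples if cohort.diagnosis_of(s) == "case"]
    controls = [s for s in samples if cohort.diagnosis_of(s) == "control"]
    if not cases or not controls:
        raise ValueError(
            f"cohort must contain both cases and controls for {sample_type}"
        )
    return cases, controls


def per_marker_table(
    cohort: CohortTable, sample_type: str
) -> list[DiagnosticRow]:
    """Per-marker diagnostic metrics using any-methylation positivity,
    one row per panel marker in panel order."""
    cases, controls = _class_calls(cohort, sample_type)
    rows = []
    for marker in cohort.panel:
        rows.append(
            evaluate_binary(
                [is_positive(s.signals[marker]) for s in cases],
                [is_positive(s.signals[marker]) for s in controls],
                label=marker,
                sample_type=sample_type,
            )
        )
    return rows


def threshold_sweep(
    cohort: CohortTable, sample_type: str
) -> list[DiagnosticRow]:
    """Diagnostic metrics of the positive-marker count at every
    threshold from 1 to the panel size ("nof32" rows)."""
    cases, controls = _class_calls(cohort, sample_type)
    panel_size = cohort.panel.size
    case_scores = [
        s for s in score_cohort(cohort, sample_type)
        if cohort.patients[s.patient_id].diagnosis == "case"
    ]
    control_scores = [
        s for s in score_cohort(cohort, sample_type)
        if cohort.patients[s.patient_id].diagnosis == "control"
    ]
    rows = []
    for threshold in range(1, panel_size + 1):
        rows.append(
            evaluate_binary(
                [classify(s, threshold, panel_size) for s in case_scores],
                [classify(s, threshold, panel_size) for s in control_scores],
                label=f"{threshold}of{panel_size}",
                sample_type=sample_type,
            )
        )
    return rows


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (report style)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def rows_to_frame(rows: Sequence[DiagnosticRow]) -> pd.DataFrame:
    """Full-precision DataFrame of diagnostic rows (one per classifier)."""
    records = []
    for row in rows:
        records.append(
            {
                "label": row.label,
                "sample_type": row.sample_type,
                "n_pos_cases": row.counts.tp,
                "n_cases": row.counts.n_cases,
                "sensitivity": row.sensitivity,
                "sens_ci_low": row.sens_ci[0],
                "sens_ci_high": row.sens_ci[1],
                "n_neg_controls": row.counts.tn,
                "n_controls": row.counts.n_controls,
                "specificity": row.specificity,
                "spec_ci_low": row.spec_ci[0],
                "spec_ci_high": row.spec_ci[1],
                "ppv": row.ppv,
                "npv": row.npv,
            }
        )
    return pd.DataFrame(records)


def format_report(rows: Sequence[DiagnosticRow]) -> pd.DataFrame:
    """Report-style table: metrics rounded half-up to 2 decimals,
    undefined predictive values printed as "na"."""
    df = rows_to_frame(rows)
    for col in (
        "sensitivity", "sens_ci_low", "sens_ci_high",
        "specificity", "spec_ci_low", "spec_ci_high",
    ):
        df[col] = df[col].map(lambda v: round_half_up(v, 2))
    for col in ("ppv", "npv"):
        df[col] = df[col].map(
            lambda v: "na" if v is None or pd.isna(v) else round_half_up(v, 2)
        )
    return df
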