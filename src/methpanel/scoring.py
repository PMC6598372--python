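"""Sample-level statistics: marker positivity, the cumulative positive
marker count (``nof32``), average methylation, and threshold calls.

A marker is called positive whenever any methylation signal is present
(signal > 0) — no magnitude cutoff is applied, which deliberately folds
analytical false positives (e.g. incomplete bisulfite deamination) into
the per-marker rates instead of introducing subjective cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .panel_io import CohortTable, MarkerPanel, SampleRecord


@dataclass(frozen=True)
class SampleScore:
    """Cumulative score of one sample: positive-marker count and mean
    signal over the full panel."""

    patient_id: str
    sample_type: str
    n_positive: int
    avg_methylation: float


def is_positive(signal: float) -> bool:
    """True iff any methylation was detected (signal strictly > 0)."""
    if signal < 0:
        raise ValueError(f"signal must be >= 0, got {signal!r}")
    return signal > 0


def score_sample(sample: SampleRecord, panel: MarkerPanel) -> SampleScore:
    """Score one sample against the panel.

    ``n_positive`` counts markers with any detectable methylation;
    ``avg_methylation`` is the sum of all panel signals divided by the
    panel size (zero markers included in the denominator).
    """
    missing = [m for m in panel if m not in sample.signals]
    if missing:
        raise ValueError(
            f"sample ({sample.patient_id}, {sample.sample_type}) is missing "
            f"markers: {missing}"
        )
    signals = [sample.signals[m] for m in panel]
    return SampleScore(
        patient_id=sample.patient_id,
        sample_type=sample.sample_type,
        n_positive=sum(1 for s in signals if is_positive(s)),
        avg_methylation=sum(signals) / panel.size,
    )


def classify(score: SampleScore, threshold: int, panel_size: int = 32) -> bool:
    """Threshold call: positive (recommend biopsy) iff the sample has at
    least ``threshold`` positive markers."""
    if not 1 <= threshold <= panel_size:
        raise ValueError(
            f"threshold must be in 1..{panel_size}, got {threshold}"
        )
    return score.n_positive >= threshold


def score_cohort(
    cohort: CohortTable, sample_type: str | None = None
) -> list[SampleScore]:
    """Score every sample (optionally restricted to one sample type)."""
    samples = (
        cohort.samples if sample_type is None else cohort.samples_of_type(sample_type)
    )
    return [score_sample(s, cohort.panel) for s in samples]


def scores_frame(cohort: CohortTable, sample_type: str | None = None) -> pd.DataFrame:
    """Scores joined to diagnosis and grading group, one row per sample."""
    rows = []
    for score in score_cohort(cohort, sample_type):
        patient = cohort.patients[score.patient_id]
        rows.append(
            {
                "patient_id": score.patient_id,
                "sample_type": score.sample_type,
                "n_positive": score.n_positive,
                "avg_methylation": score.avg_methylation,
                "diagnosis": patient.diagnosis,
                "grading_group": patient.grading_group,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "sample_type", "n_positive", "avg_methylation",
            "diagnosis", "grading_group",
        ],
    )
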