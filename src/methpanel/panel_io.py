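"""Domain types, the Cq→signal transform, file readers/writers and QC.

The raw measurement from a methylation-specific qPCR assay is a
quantification cycle (Cq): the cycle at which amplification crosses the
detection threshold, lower meaning more methylated template.  Analyses
work on the transformed *methylation signal* ``max_cycles − Cq`` (0 for
no amplification), an increasing scale whose observed range in urine
DNA is 0–15.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, NamedTuple

import pandas as pd

from .reference import DEFAULT_PANEL_MARKERS

SampleType = Literal["DRE", "FV"]
SAMPLE_TYPES: tuple[str, ...] = ("DRE", "FV")

#: Tokens that mean "no amplification" in a Cq-valued file, matching
#: common qPCR instrument export conventions.
NO_AMP_TOKENS = frozenset({"", "undetermined", "undet", "na", "nan"})


class SignalRangeWarning(UserWarning):
    """A transformed signal fell outside the expected 0–15 range."""


class InvalidMeasurementError(ValueError):
    """A Cq value was non-finite, zero or negative."""


class CohortValidationError(ValueError):
    """A cohort table violated a structural invariant."""


class CqMeasurement(NamedTuple):
    """One raw qPCR readout: marker name and Cq in cycles (None = no
    amplification)."""

    marker: str
    cq: float | None


class MethylationSignal(NamedTuple):
    """One transformed readout: marker name and non-negative signal."""

    marker: str
    signal: float


def transform_cq(
    cq: CqMeasurement | float | None, max_cycles: int = 32
) -> float:
    """Transform a Cq value into a methylation signal.

    ``signal = max(0, max_cycles − cq)``; the no-amplification sentinel
    (``None``) maps to 0.  Signals above 15 (Cq below ``max_cycles − 15``)
    are outside the range observed in urine DNA and trigger a
    :class:`SignalRangeWarning` but are not clamped.

    Raises
    ------
    InvalidMeasurementError
        If ``cq`` is non-finite, zero or negative.
    """
    if max_cycles <= 0:
        raise ValueError("max_cycles must be positive")
    if isinstance(cq, CqMeasurement):
        cq = cq.cq
    if cq is None:
        return 0.0
    cq = float(cq)
    if not math.isfinite(cq) or cq <= 0:
        raise InvalidMeasurementError(f"invalid Cq value: {cq!r}")
    signal = max(0.0, float(max_cycles) - cq)
    if signal > 15.0:
        warnings.warn(
            f"signal {signal:.3g} (Cq {cq:.3g}) exceeds the expected 0-15 range",
            SignalRangeWarning,
            stacklevel=2,
        )
    return signal


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered, unique set of marker assay names defining the panel."""

    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        markers = tuple(self.markers)
        object.__setattr__(self, "markers", markers)
        if not markers:
            raise ValueError("panel must contain at least one marker")
        if len(set(markers)) != len(markers):
            raise ValueError("panel markers must be unique")

    @property
    def size(self) -> int:
        return len(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def __contains__(self, marker: str) -> bool:
        return marker in self.markers


def default_panel() -> MarkerPanel:
    """The 32-marker panel: 19 legacy markers plus the 13 new assays."""
    return MarkerPanel(DEFAULT_PANEL_MARKERS)


@dataclass
class SampleRecord:
    """One urine DNA sample with its per-marker methylation signals.

    ``control_ok`` is the QC flag from the imprinted-gene (STIM1)
    control assay verifying recovery of amplifiable DNA.
    """

    patient_id: str
    sample_type: str
    signals: dict[str, float]
    control_ok: bool = True

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise CohortValidationError(
                f"sample_type must be one of {SAMPLE_TYPES}, got {self.sample_type!r}"
            )
        for marker, value in self.signals.items():
            if not math.isfinite(value) or value < 0:
                raise CohortValidationError(
                    f"signal for {marker} must be finite and >= 0, got {value!r}"
                )


@dataclass
class PatientRecord:
    """Per-patient metadata: biopsy outcome and risk grading.

    ``grading_group`` encodes the CAPRA-based risk grouping: 0 for a
    negative biopsy, 1 for low-risk disease (CAPRA ≤ 2), 2 for elevated
    risk (CAPRA ≥ 3).
    """

    patient_id: str
    diagnosis: Literal["case", "control"]
    grading_group: int = 0
    psa: float | None = None
    age: float | None = None
    race: str | None = None
    gleason: float | None = None
    positive_cores: int | None = None

    def __post_init__(self) -> None:
        if self.diagnosis not in ("case", "control"):
            raise CohortValidationError(
                f"diagnosis must be 'case' or 'control', got {self.diagnosis!r}"
            )
        if self.grading_group not in (0, 1, 2):
            raise CohortValidationError(
                f"grading_group must be 0, 1 or 2, got {self.grading_group!r}"
            )
        if self.diagnosis == "control" and self.grading_group != 0:
            raise CohortValidationError(
                f"control patient {self.patient_id} must have grading_group 0"
            )


@dataclass
class CohortTable:
    """Samples joined to patient labels against a fixed marker panel."""

    panel: MarkerPanel
    samples: list[SampleRecord]
    patients: dict[str, PatientRecord]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        panel_set = set(self.panel.markers)
        for sample in self.samples:
            if sample.patient_id not in self.patients:
                raise CohortValidationError(
                    f"sample references unknown patient {sample.patient_id!r}"
                )
            key = (sample.patient_id, sample.sample_type)
            if key in seen:
                raise CohortValidationError(
                    f"duplicate sample for patient {key[0]!r} type {key[1]}"
                )
            seen.add(key)
            keys = set(sample.signals)
            if keys != panel_set:
                missing = sorted(panel_set - keys)
                extra = sorted(keys - panel_set)
                raise CohortValidationError(
                    f"sample {key} does not cover the panel exactly "
                    f"(missing {missing}, unexpected {extra})"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def samples_of_type(self, sample_type: str) -> list[SampleRecord]:
        return [s for s in self.samples if s.sample_type == sample_type]

    def diagnosis_of(self, sample: SampleRecord) -> str:
        return self.patients[sample.patient_id].diagnosis

    def paired_patient_ids(self) -> list[str]:
        """Patients with both a DRE and an FV sample, in patient order."""
        have: dict[str, set[str]] = {}
        for s in self.samples:
            have.setdefault(s.patient_id, set()).add(s.sample_type)
        return [pid for pid in self.patients if have.get(pid, set()) == {"DRE", "FV"}]

    def signals_frame(self, sample_type: str | None = None) -> pd.DataFrame:
        """Signals as a samples × markers DataFrame (MultiIndex rows)."""
        samples = (
            self.samples if sample_type is None else self.samples_of_type(sample_type)
        )
        index = pd.MultiIndex.from_tuples(
            [(s.patient_id, s.sample_type) for s in samples],
            names=["patient_id", "sample_type"],
        )
        data = [[s.signals[m] for m in self.panel] for s in samples]
        return pd.DataFrame(data, index=index, columns=list(self.panel))


def _parse_cell(
    raw: object, values: str, max_cycles: int
) -> float | None:
    """Parse one value cell; returns a signal, or None for missing."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        raw = ""
    text = str(raw).strip()
    if values == "cq":
        if text.lower() in NO_AMP_TOKENS:
            return transform_cq(None, max_cycles)
        return transform_cq(float(text), max_cycles)
    # signal layout: literal 0 means no amplification; blank means missing
    if text == "":
        return None
    return float(text)


def read_metadata(path: str | Path) -> dict[str, PatientRecord]:
    """Read the patient metadata CSV.

    Required columns: ``patient_id, diagnosis, capra_group``.  Optional:
    ``psa, age, race, gleason, positive_cores, control_ok,
    followup_diagnosis``.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "diagnosis", "capra_group"}
    if not required.issubset(df.columns):
        raise CohortValidationError(
            f"metadata file missing columns {sorted(required - set(df.columns))}"
        )
    patients: dict[str, PatientRecord] = {}
    for row in df.itertuples(index=False):
        pid = str(row.patient_id)
        if pid in patients:
            raise CohortValidationError(f"duplicate metadata row for {pid!r}")

        def opt(name: str):
            value = getattr(row, name, None)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                return None
            return value

        patients[pid] = PatientRecord(
            patient_id=pid,
            diagnosis=str(row.diagnosis),
            grading_group=int(row.capra_group),
            psa=None if opt("psa") is None else float(opt("psa")),
            age=None if opt("age") is None else float(opt("age")),
            race=None if opt("race") is None else str(opt("race")),
            gleason=None if opt("gleason") is None else float(opt("gleason")),
            positive_cores=(
                None if opt("positive_cores") is None else int(opt("positive_cores"))
            ),
        )
    return patients


def _metadata_extras(path: str | Path) -> tuple[dict[str, bool], dict[str, str]]:
    """Per-patient control_ok flags and follow-up diagnosis overrides."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    control_ok: dict[str, bool] = {}
    followup: dict[str, str] = {}
    for row in df.itertuples(index=False):
        pid = str(row.patient_id)
        flag = getattr(row, "control_ok", True)
        if isinstance(flag, str):
            flag = flag.strip().lower() in ("true", "1", "yes")
        elif isinstance(flag, float) and math.isnan(flag):
            flag = True
        control_ok[pid] = bool(flag)
        fu = getattr(row, "followup_diagnosis", None)
        if isinstance(fu, str) and fu.strip():
            followup[pid] = fu.strip()
    return control_ok, followup


def read_cohort(
    path: str | Path,
    metadata: str | Path,
    *,
    layout: Literal["long", "wide"] = "long",
    values: Literal["signal", "cq"] = "signal",
    panel: MarkerPanel | None = None,
    max_cycles: int = 32,
    apply_followup: bool = True,
) -> CohortTable:
    """Read a cohort from a signals/Cq file plus a patient metadata file.

    Long layout columns: ``patient_id, sample_type, marker, value``.
    Wide layout: ``patient_id, sample_type`` then one column per panel
    marker.  With ``values="cq"`` cells are Cq cycles (blank or
    "Undetermined" meaning no amplification) and are passed through
    :func:`transform_cq`; with ``values="signal"`` cells are already
    transformed and a literal 0 means no amplification.

    With ``apply_followup`` (default on), a ``followup_diagnosis``
    metadata column overrides the biopsy diagnosis — this is how
    initially biopsy-negative patients later diagnosed on follow-up are
    moved into the case group before analysis.
    """
    if panel is None:
        panel = default_panel()
    patients = read_metadata(metadata)
    control_ok, followup = _metadata_extras(metadata)
    if apply_followup:
        for pid, diag in followup.items():
            if pid in patients and diag != patients[pid].diagnosis:
                group = patients[pid].grading_group if diag == "case" else 0
                if diag == "case" and group == 0:
                    group = 1
                patients[pid] = replace(
                    patients[pid], diagnosis=diag, grading_group=group
                )

    # value cells stay strings so float() round-trips repr() exactly
    df = pd.read_csv(path, dtype=str)
    cells: dict[tuple[str, str], dict[str, float]] = {}

    if layout == "long":
        required = {"patient_id", "sample_type", "marker", "value"}
        if not required.issubset(df.columns):
            raise CohortValidationError(
                f"long layout requires columns {sorted(required)}"
            )
        for row in df.itertuples(index=False):
            marker = str(row.marker)
            if marker not in panel:
                raise CohortValidationError(f"unknown marker {marker!r}")
            key = (str(row.patient_id), str(row.sample_type))
            signals = cells.setdefault(key, {})
            if marker in signals:
                raise CohortValidationError(
                    f"duplicate measurement for {key} marker {marker!r}"
                )
            parsed = _parse_cell(row.value, values, max_cycles)
            if parsed is not None:
                signals[marker] = parsed
    elif layout == "wide":
        lead = {"patient_id", "sample_type"}
        if not lead.issubset(df.columns):
            raise CohortValidationError(
                "wide layout requires patient_id and sample_type columns"
            )
        marker_cols = [c for c in df.columns if c not in lead]
        unknown = [c for c in marker_cols if c not in panel]
        if unknown:
            raise CohortValidationError(f"unknown marker columns {unknown}")
        if set(marker_cols) != set(panel.markers):
            raise CohortValidationError(
                "wide file marker columns do not match the panel"
            )
        for row in df.itertuples(index=False):
            key = (str(row.patient_id), str(row.sample_type))
            if key in cells:
                raise CohortValidationError(f"duplicate sample row for {key}")
            signals = {}
            for marker in marker_cols:
                parsed = _parse_cell(getattr(row, marker), values, max_cycles)
                if parsed is not None:
                    signals[marker] = parsed
            cells[key] = signals
    else:
        raise ValueError(f"unknown layout {layout!r}")

    samples = [
        SampleRecord(
            patient_id=pid,
            sample_type=stype,
            signals=signals,
            control_ok=control_ok.get(pid, True),
        )
        for (pid, stype), signals in cells.items()
    ]
    return CohortTable(panel=panel, samples=samples, patients=patients)


def write_cohort(
    cohort: CohortTable,
    path: str | Path,
    *,
    layout: Literal["long", "wide"] = "long",
) -> None:
    """Write the cohort's signals as CSV (round-trips exactly)."""
    path = Path(path)
    if layout == "long":
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["patient_id", "sample_type", "marker", "value"])
            for sample in cohort.samples:
                for marker in cohort.panel:
                    writer.writerow(
                        [sample.patient_id, sample.sample_type, marker,
                         repr(sample.signals[marker])]
                    )
    elif layout == "wide":
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["patient_id", "sample_type", *cohort.panel])
            for sample in cohort.samples:
                writer.writerow(
                    [sample.patient_id, sample.sample_type]
                    + [repr(sample.signals[m]) for m in cohort.panel]
                )
    else:
        raise ValueError(f"unknown layout {layout!r}")


def write_metadata(cohort: CohortTable, path: str | Path) -> None:
    """Write the patient metadata CSV companion file."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["patient_id", "diagnosis", "capra_group", "psa", "age",
             "race", "gleason", "positive_cores", "control_ok"]
        )
        flags = {s.patient_id: s.control_ok for s in cohort.samples}
        for pid, patient in cohort.patients.items():
            writer.writerow(
                [
                    pid,
                    patient.diagnosis,
                    patient.grading_group,
                    "" if patient.psa is None else patient.psa,
                    "" if patient.age is None else patient.age,
                    "" if patient.race is None else patient.race,
                    "" if patient.gleason is None else patient.gleason,
                    "" if patient.positive_cores is None else patient.positive_cores,
                    flags.get(pid, True),
                ]
            )


def qc_filter(cohort: CohortTable) -> tuple[CohortTable, list[SampleRecord]]:
    """Drop samples whose amplifiable-DNA control assay failed.

    Returns the filtered cohort and the rejected samples.  Patients are
    kept even if all their samples are rejected.
    """
    kept = [s for s in cohort.samples if s.control_ok]
    rejected = [s for s in cohort.samples if not s.control_ok]
    if not kept:
        warnings.warn("all samples failed the amplification control", UserWarning)
    return (
        CohortTable(panel=cohort.panel, samples=kept, patients=dict(cohort.patients)),
        rejected,
    )
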