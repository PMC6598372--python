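"""Synthetic cohort generator emulating the validation study's structure.

Each marker's positivity in a sample is a Bernoulli draw with a
class-conditional, sample-type-conditional probability, coupled across
markers by a shared per-patient latent log-odds scalar; positive
markers receive a signal magnitude drawn uniformly on the transformed
0–15 scale, negatives are exactly 0.  Defaults reproduce the study
conditions: 42 cases / 52 controls, 85 DRE and 65 FV samples with 58
paired patients, the 13 published per-marker detection rates, and a
higher DRE detection rate for elevated-risk (grading group 2) cases.

The generator is fully reproducible: the same config and seed yield a
byte-for-byte identical cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .panel_io import CohortTable, MarkerPanel, PatientRecord, SampleRecord, default_panel
from .reference import MARKER_COUNTS, marker_rates

#: Mid-range detection probabilities for the 19 legacy markers (their
#: per-marker rates are not republished with this panel).  Chosen so the
#: expected cumulative positive-marker counts match the published cohort
#: medians (16 in cases, 5 in controls) given the 13 published rates.
LEGACY_P_CASE = 0.52
LEGACY_P_CONTROL = 0.13


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    ``p_case``/``p_control`` map marker → {sample_type → detection
    probability}.  ``group2_shift`` is an additive log-odds boost
    applied to DRE draws of elevated-risk cases.  ``paired_agreement``
    is the probability that a paired patient's FV positivity call for a
    marker simply copies the DRE call instead of being redrawn.
    ``tumor_burden_sd`` is the standard deviation of a shared
    per-patient latent "tumor burden" scalar added to every marker's
    log-odds, inducing the positive inter-marker correlation seen in
    real urine DNA (observed per-sample counts span 3–31 in cases,
    far wider than independent draws allow).  The default of 1.1 is
    calibrated to the published per-threshold count dispersion; set it
    to 0 for independent markers.
    """

    panel: MarkerPanel = field(default_factory=default_panel)
    n_cases: int = 42
    n_controls: int = 52
    fraction_paired: float = 58 / 94
    fraction_dre_only: float = 27 / 94
    fraction_fv_only: float = 7 / 94
    p_case: dict[str, dict[str, float]] = field(default_factory=dict)
    p_control: dict[str, dict[str, float]] = field(default_factory=dict)
    signal_low: float = 0.5
    signal_high: float = 15.0
    group2_fraction: float = 18 / 33
    group2_shift: float = 0.75
    paired_agreement: float = 0.8
    tumor_burden_sd: float = 1.1
    psa_case: tuple[float, float] = (7.1, 3.3)
    psa_control: tuple[float, float] = (5.6, 2.7)
    age_case: tuple[float, float] = (67.1, 7.1)
    age_control: tuple[float, float] = (63.9, 7.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("class sizes must be non-negative")
        fractions = (
            self.fraction_paired, self.fraction_dre_only, self.fraction_fv_only
        )
        if any(f < 0 for f in fractions) or sum(fractions) > 1 + 1e-9:
            raise ValueError(
                "sample-availability fractions must be non-negative and sum to <= 1"
            )
        for table in (self.p_case, self.p_control):
            for marker, probs in table.items():
                if marker not in self.panel:
                    raise ValueError(f"probability for unknown marker {marker!r}")
                for stype, p in probs.items():
                    if not 0.0 <= p <= 1.0:
                        raise ValueError(
                            f"p[{marker}][{stype}] = {p} outside [0, 1]"
                        )
        for name in ("group2_fraction", "paired_agreement"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not 0 <= self.signal_low < self.signal_high:
            raise ValueError("need 0 <= signal_low < signal_high")

    def prob(self, marker: str, diagnosis: str, sample_type: str) -> float:
        table = self.p_case if diagnosis == "case" else self.p_control
        return table[marker][sample_type]


def default_config_from_table2(
    panel: MarkerPanel | None = None, seed: int = 0, **overrides
) -> GeneratorConfig:
    """Config whose per-marker probabilities follow the published rates.

    The 13 new markers get ``p_case`` equal to their observed
    sensitivity and ``p_control`` equal to 1 − specificity, per sample
    type.  Markers without published rates (the legacy panel and any
    custom names) get the mid-range defaults.  ``p_case``/``p_control``
    passed as overrides are merged on top of these defaults per marker.
    """
    if panel is None:
        panel = default_panel()
    case_override = overrides.pop("p_case", {})
    control_override = overrides.pop("p_control", {})
    p_case: dict[str, dict[str, float]] = {}
    p_control: dict[str, dict[str, float]] = {}
    for marker in panel:
        if marker in MARKER_COUNTS:
            case_probs, control_probs = {}, {}
            for stype in ("DRE", "FV"):
                pc, pk = marker_rates(marker, stype)
                case_probs[stype] = pc
                control_probs[stype] = pk
            p_case[marker] = case_probs
            p_control[marker] = control_probs
        else:
            p_case[marker] = {"DRE": LEGACY_P_CASE, "FV": LEGACY_P_CASE}
            p_control[marker] = {"DRE": LEGACY_P_CONTROL, "FV": LEGACY_P_CONTROL}
    p_case.update(case_override)
    p_control.update(control_override)
    return GeneratorConfig(
        panel=panel, p_case=p_case, p_control=p_control, seed=seed, **overrides
    )


def _shifted(p: float, shift: float) -> float:
    """Apply an additive log-odds shift; degenerate p stays degenerate."""
    if shift == 0.0 or p <= 0.0 or p >= 1.0:
        return p
    logit = math.log(p / (1.0 - p)) + shift
    return 1.0 / (1.0 + math.exp(-logit))


def _draw_calls(
    rng: np.random.Generator,
    config: GeneratorConfig,
    diagnosis: str,
    sample_type: str,
    shift: float,
) -> np.ndarray:
    probs = np.array(
        [
            _shifted(config.prob(m, diagnosis, sample_type), shift)
            for m in config.panel
        ]
    )
    return rng.random(config.panel.size) < probs


def _signals(
    rng: np.random.Generator, config: GeneratorConfig, calls: np.ndarray
) -> dict[str, float]:
    magnitudes = rng.uniform(config.signal_low, config.signal_high, config.panel.size)
    return {
        marker: float(magnitudes[i]) if calls[i] else 0.0
        for i, marker in enumerate(config.panel)
    }


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw a full synthetic cohort (patients, samples, signals).

    Patient order is cases first, then controls; all randomness comes
    from ``config.seed`` via a single numpy Generator, so identical
    configs yield identical cohorts.
    """
    if not config.p_case or not config.p_control:
        raise ValueError(
            "config has no per-marker probabilities; build it with "
            "default_config_from_table2() or fill p_case/p_control"
        )
    rng = np.random.default_rng(config.seed)
    patients: dict[str, PatientRecord] = {}
    samples: list[SampleRecord] = []
    width = len(str(config.n_cases + config.n_controls))

    availability = ("paired", "dre_only", "fv_only", "none")
    avail_probs = np.array(
        [
            config.fraction_paired,
            config.fraction_dre_only,
            config.fraction_fv_only,
            max(0.0, 1.0 - config.fraction_paired - config.fraction_dre_only
                - config.fraction_fv_only),
        ]
    )
    avail_probs = avail_probs / avail_probs.sum()

    for i in range(config.n_cases + config.n_controls):
        diagnosis = "case" if i < config.n_cases else "control"
        pid = f"P{i + 1:0{width}d}"
        if diagnosis == "case":
            group = 2 if rng.random() < config.group2_fraction else 1
            psa_mu, psa_sd = config.psa_case
            age_mu, age_sd = config.age_case
        else:
            group = 0
            psa_mu, psa_sd = config.psa_control
            age_mu, age_sd = config.age_control
        psa = max(0.5, float(rng.normal(psa_mu, psa_sd)))
        age = float(np.clip(round(rng.normal(age_mu, age_sd)), 40, 90))
        patients[pid] = PatientRecord(
            patient_id=pid,
            diagnosis=diagnosis,
            grading_group=group,
            psa=round(psa, 2),
            age=age,
        )

        avail = availability[int(rng.choice(4, p=avail_probs))]
        burden = (
            float(rng.normal(0.0, config.tumor_burden_sd))
            if config.tumor_burden_sd > 0
            else 0.0
        )
        dre_shift = burden + (
            config.group2_shift if (diagnosis == "case" and group == 2) else 0.0
        )
        fv_shift = burden

        dre_calls = None
        if avail in ("paired", "dre_only"):
            dre_calls = _draw_calls(rng, config, diagnosis, "DRE", dre_shift)
            samples.append(
                SampleRecord(pid, "DRE", _signals(rng, config, dre_calls))
            )
        if avail in ("paired", "fv_only"):
            fv_calls = _draw_calls(rng, config, diagnosis, "FV", fv_shift)
            if avail == "paired" and dre_calls is not None:
                copy_mask = rng.random(config.panel.size) < config.paired_agreement
                fv_calls = np.where(copy_mask, dre_calls, fv_calls)
            samples.append(
                SampleRecord(pid, "FV", _signals(rng, config, fv_calls))
            )
    return CohortTable(panel=config.panel, samples=samples, patients=patients)


def config_to_dict(config: GeneratorConfig) -> dict:
    """JSON-serializable provenance record of a config."""
    data = asdict(config)
    data["panel"] = list(config.panel.markers)
    return data
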