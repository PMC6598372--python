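"""Published reference counts for the 32-marker urine methylation panel.

The validation cohort comprised 94 patients with elevated PSA undergoing
prostate biopsy (42 biopsy-positive cases, 52 biopsy-negative controls;
three initially negative patients diagnosed within two years of follow-up
are counted as cases).  150 urine DNAs were analysed: 85 collected after a
digital rectal exam (DRE) and 65 first-void (FV), with both sample types
available for 58 patients.

Two published tables are transcribed here:

* per-marker detection counts for the 13 newly validated CpG-island
  assays (``MARKER_COUNTS``) — these double as default class-conditional
  detection probabilities for the synthetic cohort generator, and
* the cumulative per-threshold counts of the ``nof32`` statistic
  (``CUMULATIVE_COUNTS``) — the bridge from the printed diagnostic table
  to per-sample count distributions, medians and AUC.
"""

from __future__ import annotations

#: The 13 newly validated CpG-island markers, alphabetical as published.
NEW_MARKERS: tuple[str, ...] = (
    "FRZB",
    "GPR147",
    "GPR62",
    "GRASP",
    "HOXA11as",
    "HOXBAS3",
    "HOXCrcAS3",
    "HOXD3c",
    "HOXD4rc",
    "HOXD8rc",
    "KLK10",
    "RASSF1",
    "SLC16A5rc",
)

#: The 19 previously validated markers.  Only six names are public
#: knowledge for this panel; the rest are placeholders (the legacy panel
#: is configurable, see :class:`methpanel.panel_io.MarkerPanel`).
LEGACY_MARKERS: tuple[str, ...] = (
    "AOX1",
    "CXCL14",
    "GFRA2",
    "HOXA7",
    "HOXD3",
    "NEUROG3",
) + tuple(f"LEGACY{i:02d}" for i in range(7, 20))

#: Default 32-marker panel ordering: legacy panel first, new markers after.
DEFAULT_PANEL_MARKERS: tuple[str, ...] = LEGACY_MARKERS + NEW_MARKERS

#: Per-marker detection counts for the 13 new markers, keyed by marker
#: then sample type.  Each entry is
#: ``(n_positive_cases, n_cases, n_negative_controls, n_controls)``.
MARKER_COUNTS: dict[str, dict[str, tuple[int, int, int, int]]] = {
    "HOXA11as": {"DRE": (10, 36, 43, 49), "FV": (16, 30, 29, 35)},
    "KLK10": {"DRE": (17, 36, 44, 49), "FV": (10, 30, 29, 35)},
    "GPR147": {"DRE": (18, 36, 41, 49), "FV": (15, 30, 24, 35)},
    "GPR62": {"DRE": (20, 36, 32, 49), "FV": (24, 30, 24, 35)},
    "HOXD4rc": {"DRE": (11, 36, 41, 49), "FV": (8, 30, 29, 35)},
    "HOXD3c": {"DRE": (23, 36, 31, 49), "FV": (26, 30, 16, 35)},
    "FRZB": {"DRE": (20, 36, 33, 49), "FV": (23, 30, 26, 35)},
    "GRASP": {"DRE": (14, 36, 42, 49), "FV": (13, 30, 31, 35)},
    "HOXBAS3": {"DRE": (16, 36, 41, 49), "FV": (14, 30, 32, 35)},
    "HOXCrcAS3": {"DRE": (7, 36, 48, 49), "FV": (6, 30, 35, 35)},
    "HOXD8rc": {"DRE": (8, 36, 45, 49), "FV": (10, 30, 33, 35)},
    "RASSF1": {"DRE": (22, 36, 33, 49), "FV": (22, 30, 26, 35)},
    "SLC16A5rc": {"DRE": (12, 36, 45, 49), "FV": (11, 30, 29, 35)},
}

#: Cumulative diagnostic counts of the number-of-positive-markers
#: statistic at thresholds 1..32.  ``cases_positive[t-1]`` is the number
#: of case samples with at least ``t`` positive markers (the "No. Pos /
#: No. cases" column); ``controls_negative[t-1]`` is the number of
#: control samples with fewer than ``t`` positive markers ("No. Neg /
#: No. controls").
CUMULATIVE_COUNTS: dict[str, dict[str, object]] = {
    "DRE": {
        "n_cases": 36,
        "n_controls": 49,
        "cases_positive": (
            36, 36, 36, 34, 34, 34, 33, 32, 30, 29, 29, 28, 26, 24, 22, 20,
            17, 12, 10, 9, 8, 8, 7, 7, 7, 7, 3, 2, 2, 2, 1, 0,
        ),
        "controls_negative": (
            5, 9, 14, 14, 19, 27, 29, 32, 33, 37, 38, 40, 41, 44, 47, 47,
            48, 49, 49, 49, 49, 49, 49, 49, 49, 49, 49, 49, 49, 49, 49, 49,
        ),
    },
    "FV": {
        "n_cases": 30,
        "n_controls": 35,
        "cases_positive": (
            30, 30, 30, 30, 30, 30, 29, 28, 28, 28, 26, 24, 23, 23, 19, 15,
            13, 13, 12, 8, 7, 5, 5, 3, 2, 2, 2, 2, 2, 2, 2, 0,
        ),
        "controls_negative": (
            2, 5, 7, 9, 13, 16, 18, 23, 25, 27, 28, 30, 30, 31, 32, 34,
            34, 34, 35, 35, 35, 35, 35, 35, 35, 35, 35, 35, 35, 35, 35, 35,
        ),
    },
}


def marker_rates(marker: str, sample_type: str) -> tuple[float, float]:
    """Class-conditional detection probabilities for a published marker.

    Returns ``(p_case, p_control)`` where ``p_case`` is the observed
    sensitivity and ``p_control`` the observed false-positive rate
    (1 − specificity) for the given sample type.
    """
    pos, n_cases, neg, n_controls = MARKER_COUNTS[marker][sample_type]
    return pos / n_cases, 1.0 - neg / n_controls
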