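"""Published echocardiographic group summaries for the three mouse cohorts.

Three studies of miR-106b~25 gain/loss of function report morphometric and
echocardiographic characteristics as group means +/- SEM:

* ``ko_tac``  -- wild-type vs miR-106b~25-null mice, sham vs four weeks of
  transverse aortic constriction (pressure overload);
* ``aav9``    -- mice treated four weeks with a control AAV9 vector
  (AAV9-MCS) or AAV9-miR-106b~25;
* ``mi``      -- sham vs myocardial infarction, each treated three weeks
  with AAV9-MCS or AAV9-miR-106b~25.

Units: BW g; LV_mass mg; LV_mass_BW mg/g; linear dimensions mm; EF/FS %;
EA dimensionless.  These summaries are the inputs for formula-on-means
reproduction of the printed derived measures and for per-animal cohort
simulation (``cardiomir.simulate.simulate_echo_cohort``).
"""

from __future__ import annotations

import pandas as pd

MEASURES = [
    "BW", "LV_mass", "LV_mass_BW", "IVSd", "IVSs", "LVIDd", "LVIDs",
    "LVPWd", "LVPWs", "EF", "FS", "EA",
]

# group -> (n, {measure: (mean, sem)})
COHORTS: dict[str, dict[str, tuple[int, dict[str, tuple[float, float]]]]] = {
    "ko_tac": {
        "sham_wt": (10, {
            "BW": (21.2, 0.2), "LV_mass": (107, 5), "LV_mass_BW": (5.1, 0.3),
            "IVSd": (0.83, 0.05), "IVSs": (1.16, 0.06), "LVIDd": (4.09, 0.08),
            "LVIDs": (2.87, 0.08), "LVPWd": (0.89, 0.04), "LVPWs": (1.11, 0.05),
            "EF": (64, 1), "FS": (29, 1), "EA": (1.73, 0.11),
        }),
        "sham_ko": (11, {
            "BW": (21.3, 0.4), "LV_mass": (80, 5), "LV_mass_BW": (3.8, 0.4),
            "IVSd": (0.68, 0.03), "IVSs": (1.04, 0.03), "LVIDd": (4.15, 0.09),
            "LVIDs": (3.14, 0.08), "LVPWd": (0.65, 0.04), "LVPWs": (0.83, 0.03),
            "EF": (57, 1), "FS": (25, 1), "EA": (1.53, 0.10),
        }),
        "tac_wt": (9, {
            "BW": (21.0, 0.5), "LV_mass": (145, 12), "LV_mass_BW": (7.1, 0.7),
            "IVSd": (1.04, 0.06), "IVSs": (1.40, 0.07), "LVIDd": (4.10, 0.14),
            "LVIDs": (3.14, 0.07), "LVPWd": (1.04, 0.06), "LVPWs": (1.30, 0.08),
            "EF": (54, 2), "FS": (23, 1), "EA": (1.62, 0.10),
        }),
        "tac_ko": (10, {
            "BW": (21.0, 0.4), "LV_mass": (110, 8), "LV_mass_BW": (5.3, 0.5),
            "IVSd": (0.89, 0.04), "IVSs": (1.16, 0.05), "LVIDd": (4.41, 0.11),
            "LVIDs": (3.61, 0.15), "LVPWd": (0.70, 0.05), "LVPWs": (0.88, 0.05),
            "EF": (45, 3), "FS": (18, 1), "EA": (1.57, 0.24),
        }),
    },
    "aav9": {
        "aav9_mcs": (5, {
            "BW": (29.4, 0.5), "LV_mass": (79, 7), "LV_mass_BW": (2.7, 0.2),
            "IVSd": (0.68, 0.03), "IVSs": (1.05, 0.04), "LVIDd": (3.75, 0.12),
            "LVIDs": (2.50, 0.14), "LVPWd": (0.84, 0.09), "LVPWs": (1.07, 0.06),
            "EF": (70, 3), "FS": (33, 2),
        }),
        "aav9_mir106b25": (5, {
            "BW": (24.3, 1.7), "LV_mass": (121, 26), "LV_mass_BW": (4.8, 0.6),
            "IVSd": (0.91, 0.08), "IVSs": (1.28, 0.09), "LVIDd": (4.08, 0.08),
            "LVIDs": (2.78, 0.19), "LVPWd": (0.85, 0.08), "LVPWs": (1.09, 0.07),
            "EF": (66, 5), "FS": (31, 3),
        }),
    },
    "mi": {
        "sham_mcs": (8, {
            "BW": (22.8, 2.1), "LV_mass": (84, 3), "LV_mass_BW": (3.2, 0.2),
            "IVSd": (0.79, 0.03), "IVSs": (1.18, 0.05), "LVIDd": (3.62, 0.07),
            "LVIDs": (2.42, 0.13), "LVPWd": (0.88, 0.03), "LVPWs": (1.16, 0.05),
            "EF": (69, 4), "FS": (33, 3),
        }),
        "sham_mir106b25": (8, {
            "BW": (25.3, 2.0), "LV_mass": (90, 2), "LV_mass_BW": (3.8, 0.4),
            "IVSd": (0.81, 0.02), "IVSs": (1.23, 0.07), "LVIDd": (3.78, 0.10),
            "LVIDs": (2.56, 0.14), "LVPWd": (0.86, 0.05), "LVPWs": (1.21, 0.06),
            "EF": (67, 3), "FS": (31, 2),
        }),
        "mi_mcs": (8, {
            "BW": (23.8, 1.5), "LV_mass": (88, 5), "LV_mass_BW": (5.2, 0.4),
            "IVSd": (0.75, 0.03), "IVSs": (1.10, 0.04), "LVIDd": (4.53, 0.19),
            "LVIDs": (3.55, 0.20), "LVPWd": (0.55, 0.05), "LVPWs": (0.69, 0.07),
            "EF": (52, 2), "FS": (22, 1),
        }),
        "mi_mir106b25": (8, {
            "BW": (24.3, 1.7), "LV_mass": (107, 4), "LV_mass_BW": (6.4, 1.0),
            "IVSd": (0.90, 0.03), "IVSs": (1.40, 0.06), "LVIDd": (4.00, 0.02),
            "LVIDs": (2.79, 0.26), "LVPWd": (0.87, 0.10), "LVPWs": (1.05, 0.13),
            "EF": (65, 4), "FS": (31, 3),
        }),
    },
}

# p6/p12 stereology summaries (means +/- SEM) from the nucleation study arm.
STEREOLOGY = {
    "lv_volume_p6_mm3": (5.5, 0.4),
    "lv_volume_p12_mm3": (13.2, 1.0),
    "pct_binucleation_p6": (14.1, 1.1),
    "pct_binucleation_p12": (66.1, 1.1),
    "pct_binucleation_p12_aav9": (61.2, 2.2),
}


def cohort_means(study: str) -> pd.DataFrame:
    """Group means as a groups x measures frame for one study."""
    return _frame(study, 0)


def cohort_sems(study: str) -> pd.DataFrame:
    """Group SEMs as a groups x measures frame for one study."""
    return _frame(study, 1)


def cohort_ns(study: str) -> pd.Series:
    groups = _study(study)
    return pd.Series({g: n for g, (n, _) in groups.items()}, name="n")


def _study(study: str):
    if study not in COHORTS:
        raise KeyError(f"unknown study {study!r}; options: {sorted(COHORTS)}")
    return COHORTS[study]


def _frame(study: str, idx: int) -> pd.DataFrame:
    groups = _study(study)
    rows = {
        g: {m: vals[m][idx] for m in MEASURES if m in vals}
        for g, (_, vals) in groups.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=[m for m in MEASURES if any(m in v for _, v in groups.values())]
    )
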