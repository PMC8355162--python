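"""Closed-form cardiometric derivations from M/B-mode echo measurements.

All formulas are the standard rodent-echo conventions:

* LV mass (mg, ASE cube convention):
  0.8 * 1.04 * ((LVIDd + LVPWd + IVSd)^3 - LVIDd^3) + 0.6
* fractional shortening FS (%) = (LVIDd - LVIDs) / LVIDd * 100
* ejection fraction via cube volumes: Vd = pi * LVIDd^3 / 6,
  Vs = pi * LVIDs^3 / 6, SV = Vd - Vs, EF (%) = SV / Vd * 100
  (algebraically EF = (1 - (LVIDs/LVIDd)^3) * 100; pi cancels)
* average nuclei per cardiomyocyte = 2 * f_bi + 1 * (1 - f_bi)
* total cardiomyocytes = nuclei_density * LV volume / avg nuclei per CM
* qPCR relative quantification fold change = 2^-ddCt

Group-level reporting supports two explicit modes: 'per-animal'
(mean-of-formula: derive per record, then average) and 'on-means'
(formula-on-means: apply formulas to group means).  The two differ by about
one printed unit for EF/FS in some cohorts because the formulas are
nonlinear; published tables are typically mean-of-formula.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from cardiomir.exceptions import InputError


@dataclass
class EchoRecord:
    """Raw linear M/B-mode measurements for one animal (mm; BW in g)."""

    IVSd: float
    IVSs: float
    LVIDd: float
    LVIDs: float
    LVPWd: float
    LVPWs: float
    BW: float
    EA: float | None = None  # Doppler E/A ratio, carried only

    def __post_init__(self) -> None:
        for f in ("IVSd", "IVSs", "LVIDd", "LVIDs", "LVPWd", "LVPWs", "BW"):
            if getattr(self, f) <= 0:
                raise InputError(f"{f} must be positive")
        if self.LVIDs >= self.LVIDd:
            warnings.warn(
                "LVIDs >= LVIDd: non-contracting ventricle, derived EF/FS <= 0",
                stacklevel=2,
            )


@dataclass
class DerivedEchoMeasures:
    LV_mass: float  # mg
    LV_mass_per_BW: float  # mg/g
    Vd: float  # mm^3
    Vs: float  # mm^3
    SV: float  # mm^3
    EF: float  # %
    FS: float  # %


def lv_mass(IVSd: float, LVIDd: float, LVPWd: float, alt_parenthesis: bool = False) -> float:
    """LV mass (mg) by the cube convention from diastolic wall dimensions.

    ``alt_parenthesis`` moves the +0.6 correction inside the *0.8 factor
    (the two published parenthesis readings differ by < 0.15 mg over the
    physiological range and agree at printed precision).
    """
    for name, v in (("IVSd", IVSd), ("LVIDd", LVIDd), ("LVPWd", LVPWd)):
        if v < 0 or (name == "LVIDd" and v <= 0):
            raise InputError(f"{name} must be positive")
    cube_diff = (LVIDd + LVPWd + IVSd) ** 3 - LVIDd**3
    if alt_parenthesis:
        return 0.8 * (1.04 * cube_diff + 0.6)
    return 0.8 * 1.04 * cube_diff + 0.6


def fractional_shortening(LVIDd: float, LVIDs: float) -> float:
    """FS (%) = (LVIDd - LVIDs) / LVIDd * 100."""
    if LVIDd <= 0:
        raise InputError("LVIDd must be positive")
    return (LVIDd - LVIDs) / LVIDd * 100.0


@dataclass(frozen=True)
class VolumesAndEF:
    Vd: float
    Vs: float
    SV: float
    EF: float


def ejection_fraction(LVIDd: float, LVIDs: float) -> VolumesAndEF:
    """Cube-formula volumes (mm^3) and EF (%)."""
    if LVIDd <= 0:
        raise InputError("LVIDd must be positive")
    Vd = math.pi * LVIDd**3 / 6.0
    Vs = math.pi * LVIDs**3 / 6.0
    SV = Vd - Vs
    return VolumesAndEF(Vd=Vd, Vs=Vs, SV=SV, EF=SV / Vd * 100.0)


def derive_echo(record: EchoRecord, alt_parenthesis: bool = False) -> DerivedEchoMeasures:
    """All derived measures for one echo record."""
    mass = lv_mass(record.IVSd, record.LVIDd, record.LVPWd, alt_parenthesis=alt_parenthesis)
    vols = ejection_fraction(record.LVIDd, record.LVIDs)
    return DerivedEchoMeasures(
        LV_mass=mass,
        LV_mass_per_BW=mass / record.BW,
        Vd=vols.Vd,
        Vs=vols.Vs,
        SV=vols.SV,
        EF=vols.EF,
        FS=fractional_shortening(record.LVIDd, record.LVIDs),
    )


def avg_nuclei_per_cm(pct_binucleation: float, scale: str = "auto") -> float:
    """Average nuclei per cardiomyocyte from the binucleation rate.

    avg = 2 * f + 1 * (1 - f) with f the binucleated fraction.  ``scale``
    is 'percent' (0-100), 'fraction' (0-1), or 'auto': bare values > 1 are
    treated as percent, values <= 1 as a fraction.
    """
    if scale not in ("auto", "percent", "fraction"):
        raise InputError("scale must be 'auto', 'percent' or 'fraction'")
    if scale == "percent" or (scale == "auto" and pct_binucleation > 1):
        if not 0 <= pct_binucleation <= 100:
            raise InputError("percent binucleation must lie in [0, 100]")
        f = pct_binucleation / 100.0
    else:
        if not 0 <= pct_binucleation <= 1:
            raise InputError("fractional binucleation must lie in [0, 1]")
        f = pct_binucleation
    return 2.0 * f + 1.0 * (1.0 - f)


def total_cardiomyocytes(
    nuclei_density: float, lv_volume: float, avg_nuclei: float
) -> float:
    """Stereological CM count: density (nuclei/mm^3) x volume / nuclei per CM."""
    if nuclei_density <= 0 or lv_volume <= 0:
        raise InputError("density and volume must be positive")
    if not 1.0 <= avg_nuclei <= 2.0:
        raise InputError("avg nuclei per CM must lie in [1, 2]")
    return nuclei_density * lv_volume / avg_nuclei


@dataclass
class QpcrMeasurement:
    ct_target_sample: float
    ct_reference_sample: float
    ct_target_calibrator: float
    ct_reference_calibrator: float

    @property
    def fold_change(self) -> float:
        return ddct_fold_change(
            self.ct_target_sample,
            self.ct_reference_sample,
            self.ct_target_calibrator,
            self.ct_reference_calibrator,
        )


def ddct_fold_change(
    ct_target_sample: float,
    ct_reference_sample: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> float:
    """2^-ddCt relative quantification versus a calibrator condition."""
    cts = (ct_target_sample, ct_reference_sample, ct_target_calibrator, ct_reference_calibrator)
    if not all(math.isfinite(c) for c in cts):
        raise InputError("all Ct values must be finite")
    ddct = (ct_target_sample - ct_reference_sample) - (
        ct_target_calibrator - ct_reference_calibrator
    )
    return 2.0 ** (-ddct)


_DERIVED_COLS = [f.name for f in fields(DerivedEchoMeasures)]
_RAW_COLS = ["IVSd", "IVSs", "LVIDd", "LVIDs", "LVPWd", "LVPWs", "BW"]


def derive_echo_table(
    records: pd.DataFrame,
    mode: str = "per-animal",
    group_col: str = "group",
    alt_parenthesis: bool = False,
) -> pd.DataFrame:
    """Derived measures for an echo CSV (one row per animal).

    mode 'per-animal' returns one derived row per input row; mode
    'on-means' first averages the raw measurements per group and applies
    the formulas to the group means (one row per group).
    """
    if mode not in ("per-animal", "on-means"):
        raise InputError("mode must be 'per-animal' or 'on-means'")
    missing = [c for c in _RAW_COLS if c not in records.columns]
    if missing:
        raise InputError(f"echo table missing columns {missing}")
    if mode == "on-means":
        if group_col not in records.columns:
            raise InputError(f"group column {group_col!r} missing")
        records = records.groupby(group_col, sort=False)[_RAW_COLS].mean().reset_index()
    rows = []
    for _, row in records.iterrows():
        rec = EchoRecord(**{c: row[c] for c in _RAW_COLS})
        derived = derive_echo(rec, alt_parenthesis=alt_parenthesis)
        out = dict(row)
        out.update({c: getattr(derived, c) for c in _DERIVED_COLS})
        rows.append(out)
    return pd.DataFrame(rows)


def group_summary(derived: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Mean +/- SEM per group for every numeric derived/raw column."""
    if group_col not in derived.columns:
        raise InputError(f"group column {group_col!r} missing")
    numeric = derived.select_dtypes(include=[np.number]).columns
    grouped = derived.groupby(group_col, sort=False)[list(numeric)]
    mean = grouped.mean().add_suffix("_mean")
    sem = grouped.sem().add_suffix("_sem")
    n = grouped.size().rename("n")
    return pd.concat([n, mean, sem], axis=1).reset_index()


def filter_pressure_gradient(
    records: pd.DataFrame, column: str = "pressure_gradient", minimum: float = 50.0
) -> pd.DataFrame:
    """Inclusion filter: keep rows whose gradient exceeds the threshold.

    Rows lacking the column are kept (the gradient applies only to banded
    animals).
    """
    if column not in records.columns:
        return records
    keep = records[column].isna() | (records[column] > minimum)
    return records[keep].reset_index(drop=True)
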