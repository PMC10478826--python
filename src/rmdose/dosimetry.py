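"""Time-integrated activities and absorbed red-marrow doses per skeletal site.

The fitted tissue curves are converted to time-integrated activity (TIA) by
integrating over [0, inf) and scaling with the reference red-marrow volume
fraction and volume of the site:

    TIA_specific    = integral(C_specific) * f_RM * V_RM * 3600
    TIA_nonspecific = integral(C_blood)    * f_RM * V_RM * 3600

(MBq*s per GBq administered; the nonspecific term assumes blood-marrow
concentration equivalence, so the fitted plasma fraction f does NOT enter
it). The absorbed dose is the TIA sum times the site's RM<-RM S value:

    D_RM = (TIA_specific + TIA_nonspecific) * S / 1000    [Gy/GBq]

The blood-based comparator applies the skeletal-average constants directly
to the blood integral, the EANM-style whole-skeleton estimate.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd

from .blood import integrate_blood
from .core import (
    BloodModel,
    CompartmentFit,
    ConfigurationError,
    DoseResult,
    Sex,
    SkeletalSite,
    SkeletalSiteReference,
    reference_by_site,
)

__all__ = [
    "specific_concentration_integral",
    "concentration_integral_to_tia",
    "specific_tia",
    "nonspecific_tia",
    "red_marrow_dose",
    "blood_based_dose",
    "specific_fraction",
    "cohort_summary",
    "load_study_doses",
    "study_doses_long",
    "summarize_study_doses",
]

SECONDS_PER_HOUR = 3600.0
MGY_PER_GY = 1000.0


def specific_concentration_integral(blood: BloodModel, params: CompartmentFit) -> float:
    """Closed-form integral of the specific concentration over [0, inf):
    k1*f*(A1/l1 + A2/l2)/k2, in concentration * hours."""
    return params.k1 * params.f * integrate_blood(blood) / params.k2


def concentration_integral_to_tia(
    conc_integral_h: float, site: SkeletalSiteReference, sex: Sex
) -> float:
    """Scale a concentration-time integral (MBq*h/cm^3 per GBq) to the TIA of
    the site's red marrow (MBq*s per GBq): x f_RM x V_RM x 3600."""
    return conc_integral_h * site.f_RM(sex) * site.V_RM(sex) * SECONDS_PER_HOUR


def specific_tia(
    blood: BloodModel, params: CompartmentFit, site: SkeletalSiteReference, sex: Sex
) -> float:
    """TIA of the specific (receptor-bound) uptake at a skeletal site."""
    return concentration_integral_to_tia(
        specific_concentration_integral(blood, params), site, sex
    )


def nonspecific_tia(blood: BloodModel, site: SkeletalSiteReference, sex: Sex) -> float:
    """TIA of the blood-borne (nonspecific) activity at a skeletal site,
    assuming blood-marrow concentration equivalence."""
    return concentration_integral_to_tia(integrate_blood(blood), site, sex)


def red_marrow_dose(
    tia_specific: float,
    tia_nonspecific: float,
    site: SkeletalSiteReference,
    sex: Sex,
    patient_id: str = "",
    dose_blood_based: float = 0.0,
) -> DoseResult:
    """Absorbed red-marrow dose (Gy/GBq) from the two TIA components."""
    if tia_specific < 0 or tia_nonspecific < 0:
        raise ValueError("TIAs must be >= 0")
    s = site.S(sex) / MGY_PER_GY  # Gy per MBq*s
    dose_spec = tia_specific * s
    dose_nonspec = tia_nonspecific * s
    return DoseResult(
        patient_id=patient_id,
        site=site.site,
        tia_specific=tia_specific,
        tia_nonspecific=tia_nonspecific,
        dose_specific=dose_spec,
        dose_nonspecific=dose_nonspec,
        dose_total=dose_spec + dose_nonspec,
        dose_blood_based=dose_blood_based,
    )


def blood_based_dose(blood: BloodModel, sex: Sex) -> float:
    """Skeletal-average red-marrow dose (Gy/GBq) from the blood curve alone."""
    ref = reference_by_site()[SkeletalSite.SKELETAL_AVERAGE]
    tia = concentration_integral_to_tia(integrate_blood(blood), ref, sex)
    return tia * ref.S(sex) / MGY_PER_GY


def specific_fraction(result: DoseResult) -> float:
    """Share of the total absorbed dose contributed by specific uptake."""
    if result.dose_total <= 0:
        raise ValueError("specific fraction undefined for zero total dose")
    return result.dose_specific / result.dose_total


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------

def cohort_summary(
    dose_table: pd.DataFrame,
    group_by: str = "bone_metastases",
    exclude: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group, per-site summary of a long-format dose table.

    ``dose_table`` needs columns patient_id, ``group_by``, site,
    dose_specific, dose_nonspecific, dose_total, dose_blood_based. Patients
    in ``exclude`` are dropped from every statistic. Returns one row per
    (group, site) with the median and sample SD (n-1) of the total and
    blood-based doses and the mean specific fraction.
    """
    exclude = [str(p) for p in (exclude or [])]
    df = dose_table[~dose_table["patient_id"].astype(str).isin(exclude)].copy()
    if df.empty:
        raise ValueError("no patients left to summarize")
    rows = []
    for (group, site), grp in df.groupby([group_by, "site"], sort=True):
        if grp.empty:
            raise ValueError(f"empty group {group}/{site}")
        frac = grp["dose_specific"] / grp["dose_total"]
        rows.append({
            group_by: group,
            "site": site,
            "n": len(grp),
            "median_total": float(grp["dose_total"].median()),
            "sd_total": float(grp["dose_total"].std(ddof=1)) if len(grp) > 1 else 0.0,
            "mean_specific_fraction": float(frac.mean()),
            "median_blood_based": float(grp["dose_blood_based"].median()),
            "sd_blood_based": float(grp["dose_blood_based"].std(ddof=1))
            if len(grp) > 1 else 0.0,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Packaged study benchmark (published per-patient doses, 17 patients)
# ---------------------------------------------------------------------------

_STUDY_RESOURCE = "study_doses.tsv"


def load_study_doses() -> pd.DataFrame:
    """Published per-patient absorbed red-marrow doses (Gy/GBq) for the
    17-patient [177Lu]Lu-DOTATATE cohort, in the printed wide layout, with
    the footnoted exclusion flag."""
    try:
        text = resources.files("rmdose.data").joinpath(_STUDY_RESOURCE).read_text()
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise ConfigurationError("packaged study dose table missing") from exc
    df = pd.read_csv(StringIO(text), sep="\t", dtype={"patient_id": str})
    if len(df) != 17:
        raise ConfigurationError("study dose table is corrupted")
    for col in ("bone_metastases", "excluded_from_averages"):
        df[col] = df[col].map({"Yes": True, "No": False})
    return df


def study_doses_long(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Reshape the packaged study table to the long dose-table layout used
    by :func:`cohort_summary` (one row per patient x site)."""
    wide = load_study_doses() if df is None else df
    frames = []
    for site, prefix in (("vertebrae", "vert"), ("hip_bones", "hip")):
        frames.append(pd.DataFrame({
            "patient_id": wide["patient_id"],
            "bone_metastases": wide["bone_metastases"],
            "excluded_from_averages": wide["excluded_from_averages"],
            "site": site,
            "dose_specific": wide[f"{prefix}_specific"],
            "dose_nonspecific": wide[f"{prefix}_nonspecific"],
            "dose_total": wide[f"{prefix}_total"],
            "dose_blood_based": wide["blood_based"],
        }))
    return pd.concat(frames, ignore_index=True)


def summarize_study_doses(exclude: list[str] | None = None) -> pd.DataFrame:
    """Group medians/SDs of the packaged study doses.

    By default the footnote-flagged patient (widespread bone metastases) is
    excluded from every statistic, as in the published averages.
    """
    long = study_doses_long()
    if exclude is None:
        exclude = sorted(long.loc[long["excluded_from_averages"], "patient_id"].unique())
    return cohort_summary(long, group_by="bone_metastases", exclude=exclude)
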