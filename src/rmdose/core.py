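"""Domain types, units discipline, and packaged reference constants.

Units used throughout the package:

* time is hours post-injection; conversion to seconds (x3600) happens only
  inside dose computation, because S values are per MBq*s;
* activity concentration is MBq per cm^3 of VOI per GBq administered, so
  absorbed doses come out in Gy per GBq administered;
* S values are mGy per MBq*s (divided by 1000 at the dose step).
"""

from __future__ import annotations

import enum
import hashlib
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("rmdose")

__all__ = [
    "Tissue",
    "Sex",
    "SkeletalSite",
    "TimeActivityCurve",
    "BloodModel",
    "CompartmentFit",
    "SkeletalSiteReference",
    "DoseResult",
    "PatientRecord",
    "CurveError",
    "FitError",
    "ConfigurationError",
    "load_reference_table",
    "reference_by_site",
    "reference_table_sha256",
    "read_patient_table",
    "write_patient_table",
    "round_half_up",
]


class CurveError(ValueError):
    """A time-activity curve violates its invariants."""


class FitError(RuntimeError):
    """A model fit failed (insufficient data or non-convergence)."""


class ConfigurationError(RuntimeError):
    """Packaged reference data or run configuration is invalid."""


class Tissue(str, enum.Enum):
    AORTA = "aorta"
    VERTEBRAE = "vertebrae"
    HIP_BONES = "hip_bones"
    ADIPOSE = "adipose"
    TUMOR = "tumor"
    STERNUM = "sternum"
    OTHER = "other"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class SkeletalSite(str, enum.Enum):
    """Skeletal sites with packaged reference dosimetry constants."""

    T_VERTEBRAE = "T_vertebrae"
    L_VERTEBRAE = "L_vertebrae"
    TL_VERTEBRAE = "TL_vertebrae"
    HIP_BONES = "hip_bones"
    SKELETAL_AVERAGE = "skeletal_average"


@dataclass(frozen=True)
class TimeActivityCurve:
    """Sampled activity concentration vs. time for one tissue of one patient.

    ``times`` are hours post-injection (strictly increasing, > 0);
    ``concentrations`` are MBq/cm^3 per GBq administered (non-negative).
    """

    patient_id: str
    tissue: Tissue
    times: tuple[float, ...]
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or t.size != c.size:
            raise CurveError("times and concentrations must be 1-D and equal length")
        if t.size == 0:
            raise CurveError("empty curve")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(c)):
            raise CurveError("non-finite values in curve")
        if t[0] <= 0:
            raise CurveError("times must be > 0 h post-injection")
        if np.any(np.diff(t) <= 0):
            raise CurveError("times must be strictly increasing (no duplicates)")
        if np.any(c < 0):
            raise CurveError("negative activity concentration")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "concentrations", tuple(float(x) for x in c))

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def c(self) -> np.ndarray:
        return np.asarray(self.concentrations, dtype=float)

    def __len__(self) -> int:
        return len(self.times)

    def require_samples(self, n: int, what: str = "fit") -> None:
        if len(self) < n:
            raise FitError(
                f"{what} requires >= {n} samples, curve "
                f"({self.patient_id}/{self.tissue.value}) has {len(self)}"
            )


@dataclass(frozen=True)
class BloodModel:
    """Biexponential blood input function C(t) = A1*exp(-l1*t) + A2*exp(-l2*t).

    Rates are 1/h and include physical decay implicitly (activities are
    measured in situ, i.e. already decayed). Ordering convention: the fast
    term comes first, lambda1 >= lambda2 > 0.
    """

    A1: float
    A2: float
    lambda1: float
    lambda2: float

    def __post_init__(self) -> None:
        if self.A1 < 0 or self.A2 < 0:
            raise ValueError("amplitudes must be non-negative")
        if not (self.lambda1 >= self.lambda2 > 0):
            raise ValueError("rates must satisfy lambda1 >= lambda2 > 0")


@dataclass(frozen=True)
class CompartmentFit:
    """Specific-uptake compartment parameters for one skeletal site or tumor.

    k1 (1/h) is the uptake rate from the nonspecific pool, k2 (1/h) the
    release rate of bound activity, and f the dimensionless plasma-fraction
    constant mapping blood concentration onto the nonspecific concentration
    in the marrow cavity.
    """

    k1: float
    k2: float
    f: float
    rmse: float = 0.0
    site: Tissue = Tissue.OTHER

    def __post_init__(self) -> None:
        if self.k1 < 0:
            raise ValueError("k1 must be >= 0")
        if self.k2 <= 0:
            raise ValueError("k2 must be > 0")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must lie in [0, 1]")
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")


@dataclass(frozen=True)
class SkeletalSiteReference:
    """Reference dosimetry constants for one skeletal site and both sexes.

    S values (mGy/MBq/s) are RM<-RM self-dose values from the University of
    Florida hybrid phantoms; volumes are cm^3 of red marrow; volume fractions
    are the red-marrow share of the spongy-bone VOI. Cellularity (percent,
    ICRP 70) is carried for reference but enters no equation here.
    """

    site: SkeletalSite
    S_male: float
    S_female: float
    V_RM_male: float
    V_RM_female: float
    f_RM_male: float
    f_RM_female: float
    cellularity_pct: float  # NaN for the skeletal average

    def S(self, sex: Sex) -> float:
        return self.S_male if sex is Sex.MALE else self.S_female

    def V_RM(self, sex: Sex) -> float:
        return self.V_RM_male if sex is Sex.MALE else self.V_RM_female

    def f_RM(self, sex: Sex) -> float:
        return self.f_RM_male if sex is Sex.MALE else self.f_RM_female


@dataclass(frozen=True)
class DoseResult:
    """Absorbed red-marrow dose decomposition for one patient and site.

    TIAs are MBq*s per GBq administered; doses are Gy/GBq. The blood-based
    comparator is the skeletal-average estimate from the blood curve alone.
    """

    patient_id: str
    site: SkeletalSite
    tia_specific: float
    tia_nonspecific: float
    dose_specific: float
    dose_nonspecific: float
    dose_total: float
    dose_blood_based: float

    def __post_init__(self) -> None:
        for name in ("tia_specific", "tia_nonspecific", "dose_specific",
                     "dose_nonspecific", "dose_total", "dose_blood_based"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        total = self.dose_specific + self.dose_nonspecific
        scale = max(abs(total), abs(self.dose_total), 1e-300)
        if abs(total - self.dose_total) > 1e-12 * scale:
            raise ValueError("dose_total must equal dose_specific + dose_nonspecific")


@dataclass
class PatientRecord:
    """All curves of one patient plus the metadata dosimetry needs."""

    patient_id: str
    sex: Sex | None = None
    bone_metastases: bool = False
    curves: dict[Tissue, TimeActivityCurve] = field(default_factory=dict)

    def add_curve(self, curve: TimeActivityCurve) -> None:
        if curve.tissue in self.curves:
            raise CurveError(
                f"duplicate tissue {curve.tissue.value} for patient {self.patient_id}"
            )
        self.curves[curve.tissue] = curve

    @property
    def aorta(self) -> TimeActivityCurve:
        try:
            return self.curves[Tissue.AORTA]
        except KeyError:
            raise CurveError(f"patient {self.patient_id} has no aorta curve") from None

    def resolved_sex(self) -> Sex:
        """Sex for dosimetry; defaults to female (larger S values) with a warning."""
        if self.sex is None:
            logger.warning(
                "patient %s has no recorded sex; defaulting to female reference "
                "constants (conservative choice)", self.patient_id,
            )
            return Sex.FEMALE
        return self.sex


# ---------------------------------------------------------------------------
# Packaged reference constants
# ---------------------------------------------------------------------------

_REFERENCE_RESOURCE = "skeletal_reference.tsv"

# Spot values used to detect a corrupted transcription at load time.
_REFERENCE_CHECKS = {
    (SkeletalSite.TL_VERTEBRAE, "S_male"): 5.25e-5,
    (SkeletalSite.HIP_BONES, "V_RM_female"): 225.5,
    (SkeletalSite.SKELETAL_AVERAGE, "f_RM_male"): 0.52,
}


def _reference_text() -> str:
    try:
        return (
            resources.files("rmdose.data").joinpath(_REFERENCE_RESOURCE).read_text()
        )
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise ConfigurationError("packaged skeletal reference table missing") from exc


def load_reference_table() -> list[SkeletalSiteReference]:
    """Load the packaged skeletal reference constants (pure function).

    Returns the five sites in packaged order. Raises
    :class:`ConfigurationError` if the file is missing or corrupted.
    """
    from io import StringIO

    df = pd.read_csv(StringIO(_reference_text()), sep="\t")
    expected_cols = ["site", "S_male", "S_female", "V_RM_male", "V_RM_female",
                     "f_RM_male", "f_RM_female", "cellularity_pct"]
    if list(df.columns) != expected_cols or len(df) != 5:
        raise ConfigurationError("skeletal reference table is corrupted")
    rows = []
    for rec in df.to_dict("records"):
        site = SkeletalSite(rec["site"])
        row = SkeletalSiteReference(
            site=site,
            S_male=float(rec["S_male"]),
            S_female=float(rec["S_female"]),
            V_RM_male=float(rec["V_RM_male"]),
            V_RM_female=float(rec["V_RM_female"]),
            f_RM_male=float(rec["f_RM_male"]),
            f_RM_female=float(rec["f_RM_female"]),
            cellularity_pct=float(rec["cellularity_pct"])
            if not pd.isna(rec["cellularity_pct"]) else math.nan,
        )
        numeric = [row.S_male, row.S_female, row.V_RM_male, row.V_RM_female,
                   row.f_RM_male, row.f_RM_female]
        if any(v <= 0 for v in numeric):
            raise ConfigurationError(f"non-positive reference value for {site.value}")
        rows.append(row)
    by_site = {r.site: r for r in rows}
    if len(by_site) != 5:
        raise ConfigurationError("duplicate site in skeletal reference table")
    for (site, attr), expected in _REFERENCE_CHECKS.items():
        if getattr(by_site[site], attr) != expected:
            raise ConfigurationError(
                f"skeletal reference table corrupted: {site.value}.{attr}"
            )
    return rows


def reference_by_site() -> dict[SkeletalSite, SkeletalSiteReference]:
    return {r.site: r for r in load_reference_table()}


def reference_table_sha256() -> str:
    """Hash of the packaged reference table, recorded in run logs."""
    return hashlib.sha256(_reference_text().encode()).hexdigest()


# ---------------------------------------------------------------------------
# Patient table I/O
# ---------------------------------------------------------------------------

PATIENT_TABLE_COLUMNS = [
    "patient_id", "sex", "bone_metastases", "tissue", "time_h",
    "conc_MBq_per_cm3_per_GBq",
]


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in {"yes", "true", "1"}:
        return True
    if s in {"no", "false", "0"}:
        return False
    raise ConfigurationError(f"cannot parse boolean field {x!r}")


def read_patient_table(path) -> list[PatientRecord]:
    """Read the delimited patient input format into :class:`PatientRecord`s.

    Expected columns: patient_id, sex, bone_metastases, tissue, time_h,
    conc_MBq_per_cm3_per_GBq (tab-separated, one row per measurement).
    """
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    missing = set(PATIENT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"patient table missing columns: {sorted(missing)}")
    records: dict[str, PatientRecord] = {}
    for (pid, tissue), grp in df.groupby(["patient_id", "tissue"], sort=False):
        grp = grp.sort_values("time_h")
        first = grp.iloc[0]
        sex_raw = first["sex"]
        sex = None if pd.isna(sex_raw) or str(sex_raw).strip() == "" else Sex(str(sex_raw))
        if pid not in records:
            records[pid] = PatientRecord(
                patient_id=str(pid), sex=sex,
                bone_metastases=_parse_bool(first["bone_metastases"]),
            )
        records[pid].add_curve(TimeActivityCurve(
            patient_id=str(pid),
            tissue=Tissue(str(tissue)),
            times=tuple(grp["time_h"].astype(float)),
            concentrations=tuple(grp["conc_MBq_per_cm3_per_GBq"].astype(float)),
        ))
    return list(records.values())


def write_patient_table(records: Iterable[PatientRecord], path) -> None:
    """Write patient records in the delimited input format (round-trippable)."""
    rows = []
    for rec in records:
        for tissue, curve in rec.curves.items():
            for t, c in zip(curve.times, curve.concentrations):
                rows.append({
                    "patient_id": rec.patient_id,
                    "sex": rec.sex.value if rec.sex is not None else "",
                    "bone_metastases": "Yes" if rec.bone_metastases else "No",
                    "tissue": tissue.value,
                    "time_h": repr(t),
                    "conc_MBq_per_cm3_per_GBq": repr(c),
                })
    pd.DataFrame(rows, columns=PATIENT_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero, the convention of the report tables."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
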