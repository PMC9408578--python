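"""Core domain types for 12-lead ECG feature records.

The unit of analysis is a single patient's resting 12-lead ECG reduced to
features: a signed ST deviation per lead (millimetres, 1 mm = 0.1 mV,
positive = elevation), conduction-block flags, QRS duration, demographics
and — when known — the culprit-artery group and angiographic collateral
status.

ST elevation (STE) is defined lead-wise with the standard sex-specific
thresholds: >= 1 mm in every lead except V2-V3, where men require >= 2 mm
and women >= 1.5 mm. The boundary is inclusive.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "Lead",
    "Sex",
    "CulpritGroup",
    "CollateralStatus",
    "ConductionFlags",
    "STDeviationVector",
    "ECGFeatureRecord",
    "MM_PER_MV",
    "ste_threshold",
    "is_ste",
    "is_st_depression",
    "ste_lead_set",
    "depressed_lead_count",
]

#: Millimetres of trace deflection per millivolt at standard 10 mm/mV gain.
MM_PER_MV = 10.0

#: Sanity bound on a single lead's ST deviation, in mm.
MAX_ABS_ST_MM = 20.0


class Lead(enum.Enum):
    """The 12 standard leads, in canonical order."""

    I = "I"
    II = "II"
    III = "III"
    aVR = "aVR"
    aVL = "aVL"
    aVF = "aVF"
    V1 = "V1"
    V2 = "V2"
    V3 = "V3"
    V4 = "V4"
    V5 = "V5"
    V6 = "V6"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Lead.{self.name}"


#: Canonical lead order (listing order of the enum).
LEADS: tuple[Lead, ...] = tuple(Lead)

#: The precordial chain, in anatomical order V1..V6.
PRECORDIAL: tuple[Lead, ...] = (Lead.V1, Lead.V2, Lead.V3, Lead.V4, Lead.V5, Lead.V6)

#: Inferior leads.
INFERIOR: tuple[Lead, ...] = (Lead.II, Lead.III, Lead.aVF)


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"


class CulpritGroup(enum.Enum):
    """Culprit-artery group.

    LM_OCCLUSION is acute total left main occlusion (TIMI 0, 100% stenosis);
    LM_SUBOCCLUSION is subtotal (TIMI 1-3, >90% stenosis). PLAD/MLAD are
    proximal / middle left anterior descending occlusions, LCX left
    circumflex, RCA right coronary artery.
    """

    LM_OCCLUSION = "lm_occlusion"
    LM_SUBOCCLUSION = "lm_subocclusion"
    PLAD = "plad"
    MLAD = "mlad"
    LCX = "lcx"
    RCA = "rca"


class CollateralStatus(enum.Enum):
    """Angiographic collateral filling territory (Rentrop score >= 1).

    Only meaningful for total LM occlusion, where retrograde filling from
    the RCA may perfuse the LAD territory, the LCX territory, or both.
    """

    NONE = "none"
    LAD_TERRITORY = "lad"
    LCX_TERRITORY = "lcx"
    BOTH = "both"


@dataclass(frozen=True)
class ConductionFlags:
    """Intraventricular / atrioventricular conduction abnormalities.

    ``lafb``: left anterior fascicular block; ``rbbb``: right bundle branch
    block; ``lbbb``: left bundle branch block; ``hdavb``: high-degree
    atrioventricular block. LBBB is mutually exclusive with RBBB and LAFB.
    Bifascicular block is the derived condition ``lafb and rbbb``.
    """

    lafb: bool = False
    rbbb: bool = False
    lbbb: bool = False
    hdavb: bool = False

    def __post_init__(self) -> None:
        if self.lbbb and (self.rbbb or self.lafb):
            raise ValueError("LBBB is mutually exclusive with RBBB and LAFB")

    @property
    def bifascicular(self) -> bool:
        return self.lafb and self.rbbb


class STDeviationVector:
    """Signed ST deviation for all 12 leads, in mm (positive = elevation).

    Values must be finite and within +-20 mm. Immutable.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[Lead, float] | Iterable[float]):
        if isinstance(values, Mapping):
            missing = [ld.name for ld in LEADS if ld not in values]
            if missing:
                raise ValueError(f"missing ST values for leads: {missing}")
            vals = tuple(float(values[ld]) for ld in LEADS)
        else:
            vals = tuple(float(v) for v in values)
            if len(vals) != 12:
                raise ValueError(f"expected 12 ST values, got {len(vals)}")
        for ld, v in zip(LEADS, vals):
            if not math.isfinite(v):
                raise ValueError(f"non-finite ST deviation in lead {ld.name}")
            if abs(v) > MAX_ABS_ST_MM:
                raise ValueError(
                    f"|ST| > {MAX_ABS_ST_MM} mm in lead {ld.name}: {v}"
                )
        object.__setattr__(self, "_values", vals)

    def __getitem__(self, lead: Lead) -> float:
        if not isinstance(lead, Lead):
            raise TypeError(f"expected a Lead, got {lead!r}")
        return self._values[LEADS.index(lead)]

    def as_dict(self) -> dict[Lead, float]:
        return dict(zip(LEADS, self._values))

    def __iter__(self):
        return iter(self._values)

    def __eq__(self, other) -> bool:
        return isinstance(other, STDeviationVector) and self._values == other._values

    def __hash__(self) -> int:
        return hash(self._values)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        inner = ", ".join(f"{ld.name}={v:+.2f}" for ld, v in zip(LEADS, self._values))
        return f"STDeviationVector({inner})"


@dataclass(frozen=True)
class ECGFeatureRecord:
    """One patient's ECG feature record.

    ``group``, ``collateral``, ``age`` and ``died_in_hospital`` are optional:
    classification needs only sex, ST deviations and conduction flags.
    Collateral status may only be carried by total-LM-occlusion records.
    """

    id: str
    sex: Sex
    st: STDeviationVector
    qrs_ms: float
    conduction: ConductionFlags = field(default_factory=ConductionFlags)
    age: Optional[float] = None
    group: Optional[CulpritGroup] = None
    collateral: Optional[CollateralStatus] = None
    died_in_hospital: Optional[bool] = None

    def __post_init__(self) -> None:
        if not (40.0 <= self.qrs_ms <= 300.0):
            raise ValueError(f"qrs_ms out of [40, 300]: {self.qrs_ms}")
        if self.collateral is not None and self.group is not None:
            if self.group is not CulpritGroup.LM_OCCLUSION:
                raise ValueError(
                    "collateral status is only defined for LM_OCCLUSION records"
                )


def ste_threshold(lead: Lead, sex: Sex) -> float:
    """Lead- and sex-specific ST-elevation threshold, in mm.

    2.0 mm for men and 1.5 mm for women in V2-V3; 1.0 mm in every other
    lead regardless of sex.
    """
    if not isinstance(lead, Lead):
        raise ValueError(f"unknown lead: {lead!r}")
    if not isinstance(sex, Sex):
        raise ValueError(f"unknown sex: {sex!r}")
    if lead in (Lead.V2, Lead.V3):
        return 2.0 if sex is Sex.MALE else 1.5
    return 1.0


def is_ste(record: ECGFeatureRecord, lead: Lead) -> bool:
    """True iff the lead's ST deviation meets its threshold (inclusive)."""
    return record.st[lead] >= ste_threshold(lead, record.sex)


def is_st_depression(
    record: ECGFeatureRecord, lead: Lead, threshold_mm: float = 0.5
) -> bool:
    """True iff the lead is depressed by at least ``threshold_mm`` (inclusive)."""
    if threshold_mm <= 0:
        raise ValueError(f"depression threshold must be positive: {threshold_mm}")
    return record.st[lead] <= -threshold_mm


def ste_lead_set(record: ECGFeatureRecord) -> frozenset[Lead]:
    """The set of leads with qualifying ST elevation."""
    return frozenset(ld for ld in LEADS if is_ste(record, ld))


def depressed_lead_count(record: ECGFeatureRecord, threshold_mm: float = 0.5) -> int:
    """Number of leads depressed by at least ``threshold_mm``."""
    return sum(is_st_depression(record, ld, threshold_mm) for ld in LEADS)
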