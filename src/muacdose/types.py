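"""Domain types for feeding-program patient cards and run configuration.

One :class:`PatientCard` represents a single treatment episode of a child
enrolled in an outpatient therapeutic (TFP, severe acute malnutrition) or
supplementary (SFP, moderate acute malnutrition) feeding program, as a
date-ordered sequence of clinic visits carrying MUAC (mid-upper arm
circumference, whole millimetres), weight (0.1 kg) and, where measured,
height (0.1 cm).
"""

from __future__ import annotations

import dataclasses
import datetime
import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple


class Facility(str, enum.Enum):
    """Admitting program type: therapeutic (SAM) or supplementary (MAM)."""

    TFP = "TFP"
    SFP = "SFP"


class Sex(str, enum.Enum):
    FEMALE = "F"
    MALE = "M"


class Oedema(str, enum.Enum):
    """Tri-state nutritional-oedema code as recorded on program cards."""

    ABSENT = "absent"
    PRESENT = "present"
    MISSING = "missing"


class DischargeStatus(str, enum.Enum):
    RECOVERED = "recovered"
    OTHER = "other"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class VisitRecord:
    """A single clinic visit.

    ``muac`` is integer millimetres, ``weight`` kilograms to one decimal,
    ``height`` centimetres to one decimal. Any measurement may be missing
    (``None``); a missing ``visit_date`` marks a data-entry defect that the
    usability filter will catch.
    """

    visit_date: Optional[datetime.date]
    muac: Optional[int] = None
    weight: Optional[float] = None
    height: Optional[float] = None
    oedema: Oedema = Oedema.MISSING

    def __post_init__(self) -> None:
        if self.muac is not None and self.muac <= 0:
            raise ValueError(f"muac must be positive, got {self.muac}")
        if self.weight is not None and self.weight <= 0:
            raise ValueError(f"weight must be positive, got {self.weight}")


@dataclass(frozen=True)
class PatientCard:
    """One treatment episode: admission metadata plus ordered visits.

    Visits are stored date-ascending (dated visits first, undated last,
    original order preserved among undated ones). The admission visit is the
    first visit. Cards cannot be linked across episodes.
    """

    card_id: str
    country: str
    facility: Facility
    age_months: Optional[int]
    sex: Optional[Sex]
    visits: Tuple[VisitRecord, ...]
    discharge_status: DischargeStatus = DischargeStatus.UNKNOWN

    def __post_init__(self) -> None:
        if not self.visits:
            raise ValueError(f"card {self.card_id!r} has no visits")
        vs = tuple(
            sorted(
                enumerate(self.visits),
                key=lambda iv: (iv[1].visit_date is None, iv[1].visit_date or datetime.date.min, iv[0]),
            )
        )
        object.__setattr__(self, "visits", tuple(v for _, v in vs))
        if self.age_months is not None and not (0 <= self.age_months <= 240):
            raise ValueError(f"implausible age_months {self.age_months}")

    @property
    def admission(self) -> VisitRecord:
        return self.visits[0]

    @property
    def discharge(self) -> VisitRecord:
        return self.visits[-1]

    def replace(self, **kw) -> "PatientCard":
        return dataclasses.replace(self, **kw)


#: Countries contributing program cards, with their continent.
CONTINENT_MAP = {
    "Kenya": "Africa",
    "Chad": "Africa",
    "South Sudan": "Africa",
    "Pakistan": "Asia",
    "Yemen": "Asia",
}

DEFAULT_COUNTRIES = tuple(CONTINENT_MAP)


@dataclass
class RunConfig:
    """Analysis-wide configuration.

    Parameters
    ----------
    muac_window : (int, int)
        Closed MUAC range in mm over which velocities and energy needs are
        analysed; observations are indexed by prior-visit MUAC.
    band_width : int
        Width in mm of the MUAC bands used for percentile dosage tables.
    percentile : float
        Quantile level for band-wise energy-need dosing (0.95 targets the
        dose sufficient for observed growth in 95% of visits).
    trend_per_country, trend_replicates : int
        Visits drawn per country and number of resampling replicates for the
        normalized-difference trend analysis.
    trial_per_country, trial_replicates : int
        Same for the dosing-protocol performance simulation.
    sampling_unit : str
        ``"visits"`` or ``"cards"`` — what the country-stratified subsampling
        draws.
    """

    muac_window: Tuple[int, int] = (100, 140)
    band_width: int = 5
    percentile: float = 0.95
    trend_per_country: int = 1000
    trend_replicates: int = 100
    trial_per_country: int = 200
    trial_replicates: int = 100
    rng_seed: int = 0
    significance_level: float = 0.05
    sampling_unit: str = "visits"

    def validate(self) -> None:
        lo, hi = self.muac_window
        if not lo < hi:
            raise ValueError(f"empty muac_window {self.muac_window}")
        if not 0 < self.percentile < 1:
            raise ValueError(f"percentile must be in (0,1), got {self.percentile}")
        if not 0 < self.significance_level < 1:
            raise ValueError(
                f"significance_level must be in (0,1), got {self.significance_level}"
            )
        if self.band_width <= 0 or (hi - lo) % self.band_width != 0:
            raise ValueError(
                f"band_width {self.band_width} must tile the window {self.muac_window}"
            )
        for name in ("trend_per_country", "trend_replicates", "trial_per_country", "trial_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.sampling_unit not in ("visits", "cards"):
            raise ValueError(f"sampling_unit must be 'visits' or 'cards', got {self.sampling_unit!r}")
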