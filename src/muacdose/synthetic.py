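"""Synthetic patient-card cohort generator.

Emulates the longitudinal structure of outpatient feeding-program cards:
five countries with their admitting-facility mix, the published age/sex
composition, weekly (TFP) or two-weekly (SFP) visit spacing, and
MUAC-dependent mean growth — weekly MUAC velocity and daily proportional
weight gain both declining with current MUAC. Each card is simulated
forward from its admission state:

    MUAC(t+d) = MUAC(t) + v(MUAC(t)) * d/7 + noise      [mm]
    W(t+d)    = W(t) * (1 + g(MUAC(t)) * d/1000) + noise [kg]

with v in mm/week and g in g/kg/day, recorded values rounded to the card
precision (whole mm, 0.1 kg). Cards discharge once MUAC reaches the
program threshold; a configurable fraction is censored early to exercise
the outcome-eligibility filters, and :func:`inject_errors` plants
implausible records to exercise the plausibility filters.
"""

from __future__ import annotations

import dataclasses
import datetime
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import (
    DEFAULT_COUNTRIES,
    DischargeStatus,
    Facility,
    Oedema,
    PatientCard,
    Sex,
    VisitRecord,
)

#: Age-group boundaries in months (closed-open) and their cohort fractions.
AGE_GROUPS = ((6, 12), (12, 24), (24, 36), (36, 60))
DEFAULT_AGE_FRACTIONS = (0.29, 0.40, 0.18, 0.13)

#: Fraction of cards admitted to TFP (vs SFP) per country, reflecting the
#: study mix in which South Sudan contributed only therapeutic-program cards.
DEFAULT_TFP_FRACTION = {
    "Kenya": 0.28,
    "Pakistan": 0.14,
    "Chad": 0.27,
    "Yemen": 0.24,
    "South Sudan": 1.0,
}

# Median admission weight (kg) per age group for the log-normal draw; most
# children under 24 months fall below 8 kg, matching the analysed weight
# strata 3.5-5.9 / 6.0-7.9 / 8.0-17.5 kg.
_MEDIAN_WEIGHT = {0: 5.4, 1: 6.6, 2: 8.2, 3: 9.6}
_LOG_WEIGHT_SD = 0.12


def two_point_anchor(x1: float, y1: float, x2: float, y2: float) -> Callable[[float], float]:
    """Piecewise-linear function through two anchors, flat beyond them."""

    slope = (y2 - y1) / (x2 - x1)

    def fn(m: float) -> float:
        if m <= x1:
            return y1
        if m >= x2:
            return y2
        return y1 + slope * (m - x1)

    return fn


def linear_fn(anchor_x: float, anchor_y: float, slope: float) -> Callable[[float], float]:
    """Globally linear function anchored at (anchor_x, anchor_y)."""

    def fn(m: float) -> float:
        return anchor_y + slope * (m - anchor_x)

    return fn


@dataclass
class GeneratorConfig:
    """Full parameterization of a synthetic cohort.

    ``muac_velocity_fn`` maps current MUAC (mm) to mean weekly MUAC change
    (mm/week); ``weight_gain_fn`` maps current MUAC to mean proportional
    weight gain (g/kg/day). Noise SDs are additive Gaussian on the recorded
    per-interval change, truncated so MUAC and weight stay positive.
    """

    n_cards: Dict[str, int] = field(
        default_factory=lambda: {c: 400 for c in DEFAULT_COUNTRIES}
    )
    tfp_fraction: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TFP_FRACTION))
    age_group_fractions: Tuple[float, ...] = DEFAULT_AGE_FRACTIONS
    female_fraction: float = 0.54
    admission_muac_probs: Optional[Dict[Facility, Tuple[Sequence[int], Sequence[float]]]] = None
    muac_velocity_fn: Callable[[float], float] = two_point_anchor(105.0, 2.0, 122.5, 1.0)
    weight_gain_fn: Callable[[float], float] = two_point_anchor(105.0, 3.9, 122.5, 2.4)
    muac_noise_sd: float = 1.0
    weight_noise_sd: float = 0.05
    #: Record measurements at card precision (whole mm, 0.1 kg). Disable to
    #: keep the exact continuous dynamics, e.g. for noise-free checks.
    quantize: bool = True
    visit_interval_days: Dict[Facility, int] = field(
        default_factory=lambda: {Facility.TFP: 7, Facility.SFP: 14}
    )
    discharge_muac: int = 125
    max_visits: int = 24
    missed_visit_prob: float = 0.1
    nonresponse_fraction: float = 0.1
    start_date: datetime.date = datetime.date(2013, 1, 1)
    rng_seed: int = 0

    def validate(self) -> None:
        if not self.n_cards or any(n < 0 for n in self.n_cards.values()):
            raise ValueError("n_cards must map countries to non-negative counts")
        if sum(self.n_cards.values()) == 0:
            raise ValueError("cohort has zero cards")
        if abs(sum(self.age_group_fractions) - 1.0) > 1e-9:
            raise ValueError("age_group_fractions must sum to 1")
        for name in ("female_fraction", "missed_visit_prob", "nonresponse_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for c in self.n_cards:
            f = self.tfp_fraction.get(c)
            if f is None or not 0 <= f <= 1:
                raise ValueError(f"tfp_fraction missing or out of range for {c!r}")
        if self.muac_noise_sd < 0 or self.weight_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if any(d < 1 for d in self.visit_interval_days.values()):
            raise ValueError("visit intervals must be >= 1 day")
        for m in (70.0, 100.0, 150.0, 200.0):
            if not (math.isfinite(self.muac_velocity_fn(m)) and math.isfinite(self.weight_gain_fn(m))):
                raise ValueError("velocity functions must be finite over the plausible MUAC range")


#: Named presets anchoring the velocity functions to published band means
#: (``band_anchor``) or to published regression slopes (``linear_slope``).
PRESETS: Dict[str, Dict[str, Callable[[float], float]]] = {
    "band_anchor": {
        "muac_velocity_fn": two_point_anchor(105.0, 2.0, 122.5, 1.0),
        "weight_gain_fn": two_point_anchor(105.0, 3.9, 122.5, 2.4),
    },
    "linear_slope": {
        "muac_velocity_fn": linear_fn(105.0, 2.0, -0.06),
        "weight_gain_fn": linear_fn(105.0, 3.9, -0.05),
    },
}


def preset_config(name: str, n_per_country: int = 400, seed: int = 0, **overrides) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a named velocity preset."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = GeneratorConfig(
        n_cards={c: n_per_country for c in DEFAULT_COUNTRIES},
        rng_seed=seed,
        **PRESETS[name],
    )
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise ValueError(f"unknown GeneratorConfig field {k!r}")
        setattr(cfg, k, v)
    return cfg


def _draw_admission_muac(rng: np.random.Generator, cfg: GeneratorConfig, fac: Facility) -> int:
    if cfg.admission_muac_probs and fac in cfg.admission_muac_probs:
        vals, probs = cfg.admission_muac_probs[fac]
        return int(rng.choice(vals, p=np.asarray(probs) / np.sum(probs)))
    if fac is Facility.TFP:
        return int(rng.integers(100, 115))
    return int(rng.integers(115, 125))


def _simulate_card(rng: np.random.Generator, cfg: GeneratorConfig, cid: str, country: str) -> PatientCard:
    fac = Facility.TFP if rng.random() < cfg.tfp_fraction[country] else Facility.SFP
    gi = int(rng.choice(len(AGE_GROUPS), p=cfg.age_group_fractions))
    lo, hi = AGE_GROUPS[gi]
    age = int(rng.integers(lo, hi))
    sex = Sex.FEMALE if rng.random() < cfg.female_fraction else Sex.MALE
    muac = _draw_admission_muac(rng, cfg, fac)
    weight = round(float(_MEDIAN_WEIGHT[gi] * math.exp(rng.normal(0.0, _LOG_WEIGHT_SD))), 1)
    height = round(60.0 + age * 0.55 + float(rng.normal(0.0, 2.0)), 1)
    date = cfg.start_date + datetime.timedelta(days=int(rng.integers(0, 365)))
    base_interval = cfg.visit_interval_days[fac]

    visits = [VisitRecord(visit_date=date, muac=muac, weight=weight, height=height, oedema=Oedema.ABSENT)]
    adm_muac, adm_weight = muac, weight
    while muac < cfg.discharge_muac and len(visits) < cfg.max_visits:
        d = base_interval * (2 if rng.random() < cfg.missed_visit_prob else 1)
        nxt_muac = muac + cfg.muac_velocity_fn(muac) * d / 7.0
        if cfg.muac_noise_sd > 0:
            nxt_muac += float(rng.normal(0.0, cfg.muac_noise_sd))
        nxt_weight = weight * (1.0 + cfg.weight_gain_fn(muac) * d / 1000.0)
        if cfg.weight_noise_sd > 0:
            nxt_weight += float(rng.normal(0.0, cfg.weight_noise_sd))
        if cfg.quantize:
            muac = max(1, int(round(nxt_muac)))
            weight = max(0.1, round(float(nxt_weight), 1))
        else:
            muac = max(1e-6, float(nxt_muac))
            weight = max(1e-6, float(nxt_weight))
        date = date + datetime.timedelta(days=int(d))
        visits.append(VisitRecord(visit_date=date, muac=muac, weight=weight, oedema=Oedema.MISSING))

    censored = rng.random() < cfg.nonresponse_fraction
    if censored and len(visits) > 1:
        keep = int(rng.integers(1, len(visits)))
        visits = visits[:keep] or visits[:1]

    # Discharge height so WHZ is computable at both card ends.
    elapsed = (visits[-1].visit_date - visits[0].visit_date).days if len(visits) > 1 else 0
    if len(visits) > 1:
        last = visits[-1]
        visits[-1] = VisitRecord(
            visit_date=last.visit_date,
            muac=last.muac,
            weight=last.weight,
            height=round(height + 0.07 * elapsed / 7.0, 1),
            oedema=last.oedema,
        )

    recovered = (
        not censored
        and visits[-1].muac is not None
        and visits[-1].muac >= cfg.discharge_muac
        and visits[-1].muac >= adm_muac
        and visits[-1].weight is not None
        and visits[-1].weight
        >= adm_weight * (1.10 if fac is Facility.TFP else 1.03)
    )
    return PatientCard(
        card_id=cid,
        country=country,
        facility=fac,
        age_months=age,
        sex=sex,
        visits=tuple(visits),
        discharge_status=DischargeStatus.RECOVERED if recovered else DischargeStatus.OTHER,
    )


def generate_cohort(config: GeneratorConfig) -> List[PatientCard]:
    """Generate a synthetic cohort; identical seed gives an identical cohort."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    cards: List[PatientCard] = []
    for country in config.n_cards:
        tag = country.replace(" ", "")[:3].upper()
        for i in range(config.n_cards[country]):
            cards.append(_simulate_card(rng, config, f"{tag}-{i:05d}", country))
    return cards


# ---------------------------------------------------------------------------
# Error injection


@dataclass
class ErrorRates:
    """Per-card Bernoulli rates for each implausible-record type."""

    muac_spike: float = 0.0       # interval |dMUAC| > 15 mm/week
    weight_jump: float = 0.0      # interval weight gain > 25 g/kg/day
    muac_out_of_range: float = 0.0  # a visit MUAC outside [65, 200] mm
    missing_age: float = 0.0
    missing_sex: float = 0.0
    missing_date: float = 0.0
    no_followup: float = 0.0      # card truncated to its admission visit

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not 0 <= v <= 1:
                raise ValueError(f"rate {f.name} must be in [0,1], got {v}")


def _bump_visit(card: PatientCard, idx: int, **changes) -> PatientCard:
    visits = list(card.visits)
    visits[idx] = dataclasses.replace(visits[idx], **changes)
    return card.replace(visits=tuple(visits))


def inject_errors(
    cards: Sequence[PatientCard], rates: ErrorRates, seed: int
) -> Tuple[List[PatientCard], pd.DataFrame]:
    """Corrupt a copy of ``cards`` and return it with a corruption manifest.

    Each error type is applied independently per card with its configured
    probability. The manifest has one row per corruption applied:
    ``card_id``, ``error_type``, ``visit_index`` (-1 for card-level errors).
    """
    rates.validate()
    rng = np.random.default_rng(seed)
    out: List[PatientCard] = []
    manifest_rows = []

    for card in cards:
        c = card

        def mark(err: str, vidx: int = -1) -> None:
            manifest_rows.append({"card_id": card.card_id, "error_type": err, "visit_index": vidx})

        if rates.no_followup and rng.random() < rates.no_followup:
            c = c.replace(visits=c.visits[:1])
            mark("no_followup")
        if rates.missing_age and rng.random() < rates.missing_age:
            c = c.replace(age_months=None)
            mark("missing_age")
        if rates.missing_sex and rng.random() < rates.missing_sex:
            c = c.replace(sex=None)
            mark("missing_sex")
        if rates.missing_date and rng.random() < rates.missing_date and len(c.visits) > 1:
            idx = len(c.visits) - 1  # blank the last date: order survives
            c = _bump_visit(c, idx, visit_date=None)
            mark("missing_date", idx)
        if rates.muac_spike and rng.random() < rates.muac_spike and len(c.visits) > 1:
            idx = int(rng.integers(1, len(c.visits)))
            prev, cur = c.visits[idx - 1], c.visits[idx]
            if cur.visit_date is not None and prev.visit_date is not None and cur.muac is not None:
                d = (cur.visit_date - prev.visit_date).days
                spike = int(math.ceil(15 * d / 7.0)) + 10
                c = _bump_visit(c, idx, muac=cur.muac + spike)
                mark("muac_spike", idx)
        if rates.weight_jump and rng.random() < rates.weight_jump and len(c.visits) > 1:
            idx = int(rng.integers(1, len(c.visits)))
            prev, cur = c.visits[idx - 1], c.visits[idx]
            if (
                cur.visit_date is not None
                and prev.visit_date is not None
                and cur.weight is not None
                and prev.weight is not None
            ):
                d = (cur.visit_date - prev.visit_date).days
                jump = round(25.0 * prev.weight * d / 1000.0 * 1.5, 1)
                c = _bump_visit(c, idx, weight=cur.weight + jump)
                mark("weight_jump", idx)
        if rates.muac_out_of_range and rng.random() < rates.muac_out_of_range:
            idx = int(rng.integers(0, len(c.visits)))
            c = _bump_visit(c, idx, muac=210)
            mark("muac_out_of_range", idx)
        out.append(c)

    manifest = pd.DataFrame(manifest_rows, columns=["card_id", "error_type", "visit_index"])
    return out, manifest
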