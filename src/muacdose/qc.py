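"""Usability, plausibility and outcome-eligibility filters.

Filtering proceeds in a fixed order, and every exclusion is attributed to
the first failing rule so attrition counts are disjoint:

1. usability — a card needs at least one follow-up visit and complete
   age, sex and date information;
2. plausibility — visits carrying extreme anthropometry are treated as
   measurement or recording errors: z-scores outside wide bounds
   (WHZ within [-5, 5], WAZ [-6, 5], HAZ [-6, 6] retained), MUAC outside
   [65, 200] mm, a weight gain of more than 25 g/kg/day, or a MUAC change
   of more than 15 mm/week in either direction; a card with any
   implausible visit is excluded;
3. outcome eligibility — analysis is limited to cards discharged as
   recovered with a non-negative MUAC gain and a weight gain of at least
   10% (therapeutic/SAM admission) or 3% (supplementary/MAM admission);
4. the MUAC analysis window — interval observations are kept only where
   the prior-visit MUAC lies in the configured window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .anthropometry import GrowthReference, compute_zscores
from .growth import intervals_frame
from .types import DischargeStatus, Facility, PatientCard, RunConfig

log = logging.getLogger(__name__)

#: Closed retention bounds: values strictly outside are flagged.
Z_BOUNDS = {"whz": (-5.0, 5.0), "waz": (-6.0, 5.0), "haz": (-6.0, 6.0)}
MUAC_RANGE = (65, 200)
WEIGHT_CHANGE_MAX = 25.0  # g/kg/day, strict
MUAC_CHANGE_MAX = 15.0  # mm/week, either direction, strict

USABILITY_REASONS = ("no_followup", "missing_age_sex_date")
PLAUSIBILITY_FLAGS = (
    "whz_out",
    "waz_out",
    "haz_out",
    "muac_out",
    "weight_change_out",
    "muac_change_out",
)
OUTCOME_REASONS = ("not_recovered", "negative_muac_gain", "insufficient_weight_gain")


def card_usable(card: PatientCard) -> Tuple[bool, List[str]]:
    """A card is usable iff it has a follow-up visit and complete age, sex
    and date information."""
    reasons = []
    if len(card.visits) < 2:
        reasons.append("no_followup")
    if (
        card.age_months is None
        or card.sex is None
        or any(v.visit_date is None for v in card.visits)
    ):
        reasons.append("missing_age_sex_date")
    return (not reasons, reasons)


def flag_implausible(observations: pd.DataFrame) -> pd.DataFrame:
    """Boolean plausibility flags for per-visit observations.

    ``observations`` needs columns ``muac`` plus optionally ``whz``,
    ``waz``, ``haz`` (NaN = not assessable, never flagged), and
    ``muac_velocity`` / ``weight_gain_rate`` for the interval ending at the
    visit (NaN on admission visits). Range rules retain the closed
    interval; change rules are strict inequalities, so a change of exactly
    15 mm/week or 25 g/kg/day is retained.
    """
    n = len(observations)
    flags = pd.DataFrame(index=observations.index)

    def col(name):
        if name in observations:
            return pd.to_numeric(observations[name], errors="coerce")
        return pd.Series(np.nan, index=observations.index)

    for z, (lo, hi) in Z_BOUNDS.items():
        v = col(z)
        flags[f"{z}_out"] = ((v < lo) | (v > hi)).fillna(False)
    muac = col("muac")
    flags["muac_out"] = ((muac < MUAC_RANGE[0]) | (muac > MUAC_RANGE[1])).fillna(False)
    wv = col("weight_gain_rate")
    flags["weight_change_out"] = (wv > WEIGHT_CHANGE_MAX).fillna(False)
    mv = col("muac_velocity")
    flags["muac_change_out"] = (mv.abs() > MUAC_CHANGE_MAX).fillna(False)
    flags["any"] = flags[list(PLAUSIBILITY_FLAGS)].any(axis=1)
    return flags


def _visit_rows(card: PatientCard) -> List[dict]:
    from .growth import interval_changes

    rows = [
        {
            "card_id": card.card_id,
            "visit_index": i,
            "muac": np.nan if v.muac is None else v.muac,
            "muac_velocity": np.nan,
            "weight_gain_rate": np.nan,
        }
        for i, v in enumerate(card.visits)
    ]
    for o in interval_changes(card):
        rows[o.visit_index]["muac_velocity"] = o.muac_velocity
        rows[o.visit_index]["weight_gain_rate"] = o.weight_gain_rate
    return rows


def card_visit_table(card: PatientCard, reference: Optional[GrowthReference] = None) -> pd.DataFrame:
    """Per-visit measures of one card with interval changes and z-scores,
    in the shape :func:`flag_implausible` expects."""
    df = pd.DataFrame(_visit_rows(card))
    if reference is not None:
        z = compute_zscores(card, reference)
        df = df.merge(z, on=["card_id", "visit_index"], how="left")
    return df


def card_implausible(
    card: PatientCard, reference: Optional[GrowthReference] = None
) -> Tuple[bool, pd.DataFrame]:
    """Whether any visit of the card is implausible, with per-visit flags."""
    table = card_visit_table(card, reference)
    flags = flag_implausible(table)
    flags.insert(0, "visit_index", table["visit_index"].to_numpy())
    flags.insert(0, "card_id", card.card_id)
    return bool(flags["any"].any()), flags


def outcome_eligible(card: PatientCard) -> Tuple[bool, List[str]]:
    """Recovered discharge, non-negative MUAC gain, and at-least 10%/3%
    admission-to-discharge weight gain (therapeutic/supplementary).

    Thresholds are inclusive: a gain of exactly 10% (or 3%) qualifies.
    Admission as SAM vs MAM is operationalized by the admitting facility.
    """
    reasons = []
    if card.discharge_status is not DischargeStatus.RECOVERED:
        reasons.append("not_recovered")
    adm, dis = card.visits[0], card.visits[-1]
    if adm.muac is None or dis.muac is None or dis.muac < adm.muac:
        reasons.append("negative_muac_gain")
    frac = 0.10 if card.facility is Facility.TFP else 0.03
    if (
        adm.weight is None
        or dis.weight is None
        or dis.weight < adm.weight * (1.0 + frac) - 1e-12
    ):
        reasons.append("insufficient_weight_gain")
    return (not reasons, reasons)


def apply_muac_window(
    observations: pd.DataFrame, window: Tuple[int, int] = (100, 140)
) -> pd.DataFrame:
    """Keep interval observations whose prior-visit MUAC lies in the closed
    window; the dropped count is logged."""
    lo, hi = window
    keep = (observations["prior_muac"] >= lo) & (observations["prior_muac"] <= hi)
    dropped = int((~keep).sum())
    if dropped:
        log.info("MUAC window [%d, %d]: dropped %d of %d observations", lo, hi, dropped, len(keep))
    return observations[keep].reset_index(drop=True)


@dataclass
class QCResult:
    """Cohort filtering outcome: analysis set plus a disjoint attrition table."""

    analysis_cards: List[PatientCard]
    observations: pd.DataFrame  # windowed interval observations of analysis cards
    attrition: pd.DataFrame  # step, count (cards unless noted)
    card_flags: pd.DataFrame  # card_id, excluded_reason ('' if analyzed)
    visit_flags: pd.DataFrame  # per-visit plausibility flags of usable cards


def qc_cohort(
    cards: Sequence[PatientCard],
    reference: Optional[GrowthReference] = None,
    config: Optional[RunConfig] = None,
) -> QCResult:
    """Run the full filter chain over a cohort.

    Exclusions are attributed to the first failing rule in the order
    usability, plausibility, outcome eligibility; the MUAC window then
    filters the surviving cards' interval observations. Without a growth
    reference the z-score rules are not assessable and only the raw-MUAC
    and change rules apply (logged).
    """
    config = config or RunConfig()
    config.validate()
    if reference is None:
        log.info("no growth reference supplied: z-score plausibility rules skipped")

    reasons: Dict[str, str] = {}
    usable: List[PatientCard] = []
    n_visits = 0
    for card in cards:
        n_visits += len(card.visits)
        ok, why = card_usable(card)
        if not ok:
            reasons[card.card_id] = why[0]
        else:
            usable.append(card)

    # One plausibility pass over all usable cards' visits at once.
    rows: List[dict] = []
    for card in usable:
        rows.extend(_visit_rows(card))
    table = pd.DataFrame(
        rows, columns=["card_id", "visit_index", "muac", "muac_velocity", "weight_gain_rate"]
    )
    if reference is not None and not table.empty:
        z = pd.concat([compute_zscores(c, reference) for c in usable], ignore_index=True)
        table = table.merge(z, on=["card_id", "visit_index"], how="left")
    flags = flag_implausible(table)
    visit_flags = flags.copy()
    if not table.empty:
        visit_flags.insert(0, "visit_index", table["visit_index"].to_numpy())
        visit_flags.insert(0, "card_id", table["card_id"].to_numpy())
    implausible_ids = (
        set(table.loc[flags["any"].to_numpy(bool), "card_id"]) if not table.empty else set()
    )

    analysis = []
    for card in usable:
        if card.card_id in implausible_ids:
            reasons[card.card_id] = "implausible"
            continue
        ok, why = outcome_eligible(card)
        if not ok:
            reasons[card.card_id] = why[0]
            continue
        analysis.append(card)

    obs = intervals_frame(analysis)
    n_obs_total = len(obs)
    obs = apply_muac_window(obs, config.muac_window)

    steps = [("cards_total", len(cards))]
    order = ["no_followup", "missing_age_sex_date", "implausible"] + list(OUTCOME_REASONS)
    counts = pd.Series(list(reasons.values())).value_counts() if reasons else pd.Series(dtype=int)
    for r in order:
        steps.append((f"excluded_{r}", int(counts.get(r, 0))))
    steps.append(("cards_analyzed", len(analysis)))
    steps.append(("visits_total", n_visits))
    steps.append(("observations_total", n_obs_total))
    steps.append(("observations_outside_window", n_obs_total - len(obs)))
    steps.append(("observations_analyzed", len(obs)))
    attrition = pd.DataFrame(steps, columns=["step", "count"])

    # Oedema is a pass-through clinical flag: cards are retained, not modelled.
    from .types import Oedema

    card_flags = pd.DataFrame(
        {
            "card_id": [c.card_id for c in cards],
            "excluded_reason": [reasons.get(c.card_id, "") for c in cards],
            "oedema_present": [
                any(v.oedema is Oedema.PRESENT for v in c.visits) for c in cards
            ],
        }
    )
    if table.empty:
        visit_flags = pd.DataFrame(columns=["card_id", "visit_index", *PLAUSIBILITY_FLAGS, "any"])
    return QCResult(
        analysis_cards=analysis,
        observations=obs,
        attrition=attrition,
        card_flags=card_flags,
        visit_flags=visit_flags,
    )
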