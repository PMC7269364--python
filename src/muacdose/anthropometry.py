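"""LMS growth-reference z-scores (weight-for-age, height-for-age,
weight-for-height) used by the plausibility filters.

The LMS method models a measurement's reference distribution at each key
(age or height) by a Box-Cox power L, median M and coefficient of
variation S; the z-score of a measurement x is

    z = ((x/M)**L - 1) / (L*S),   or   ln(x/M)/S  as  L -> 0.

The reference table is an input CSV (indicator, sex, key, L, M, S) with
keys in days for age-based indicators ('waz', 'haz') and in millimetres of
height for 'whz'. L, M and S are linearly interpolated between bracketing
rows. No measurement is ever imputed: where height or a reference row is
unavailable the z-score is simply missing.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

import numpy as np
import pandas as pd

from .types import PatientCard, Sex

log = logging.getLogger(__name__)

INDICATORS = ("waz", "haz", "whz")

#: Mean days per month used to convert card ages (months at admission,
#: often year-rounded) to reference ages.
DAYS_PER_MONTH = 30.4375


def lms_zscore(x: float, L: float, M: float, S: float) -> float:
    """Z-score of measurement ``x`` under LMS parameters.

    Uses the logarithmic limit when |L| < 1e-7, keeping the transform
    continuous in L at zero.
    """
    if x <= 0 or M <= 0 or S <= 0:
        raise ValueError(f"lms_zscore requires positive x, M, S (got {x}, {M}, {S})")
    if abs(L) < 1e-7:
        return math.log(x / M) / S
    return ((x / M) ** L - 1.0) / (L * S)


def lms_inverse(z: float, L: float, M: float, S: float) -> float:
    """Measurement at z-score ``z``; inverse of :func:`lms_zscore`."""
    if abs(L) < 1e-7:
        return M * math.exp(S * z)
    return M * (1.0 + L * S * z) ** (1.0 / L)


class GrowthReference:
    """An LMS reference table indexed by (indicator, sex, key)."""

    def __init__(self, table: pd.DataFrame):
        required = {"indicator", "sex", "key", "L", "M", "S"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"reference table missing column(s): {sorted(missing)}")
        t = table.copy()
        t["indicator"] = t["indicator"].str.lower()
        bad = set(t["indicator"]) - set(INDICATORS)
        if bad:
            raise ValueError(f"unknown indicator(s) in reference: {sorted(bad)}")
        if (t["M"] <= 0).any() or (t["S"] <= 0).any():
            raise ValueError("reference rows must have M > 0 and S > 0")
        self._groups = {}
        for (ind, sex), g in t.groupby(["indicator", "sex"]):
            g = g.sort_values("key")
            keys = g["key"].to_numpy(float)
            if np.any(np.diff(keys) <= 0):
                raise ValueError(f"keys not strictly increasing for ({ind}, {sex})")
            self._groups[(ind, sex)] = (keys, g[["L", "M", "S"]].to_numpy(float))

    @classmethod
    def from_csv(cls, path) -> "GrowthReference":
        return cls(pd.read_csv(path))

    def lookup(self, indicator: str, sex: Sex, key: float):
        """Interpolated (L, M, S) at ``key``, or None outside the table."""
        grp = self._groups.get((indicator, sex.value if isinstance(sex, Sex) else sex))
        if grp is None:
            grp = self._groups.get((indicator, sex))
        if grp is None:
            return None
        keys, lms = grp
        if key < keys[0] or key > keys[-1]:
            return None
        L = float(np.interp(key, keys, lms[:, 0]))
        M = float(np.interp(key, keys, lms[:, 1]))
        S = float(np.interp(key, keys, lms[:, 2]))
        return L, M, S

    def zscore(self, indicator: str, sex: Sex, key: float, x: float) -> Optional[float]:
        row = self.lookup(indicator, sex, key)
        if row is None:
            log.warning("reference key %s outside %s table for sex %s", key, indicator, sex)
            return None
        return lms_zscore(x, *row)


def compute_zscores(card: PatientCard, reference: GrowthReference) -> pd.DataFrame:
    """Per-visit WAZ, HAZ and WHZ for one card.

    Age at each visit is admission age (months) times the mean month length
    plus days elapsed since the admission visit. WHZ and HAZ are missing
    wherever height was not measured (cards record height only at admission
    and discharge); out-of-range keys give missing values with a warning.
    """
    rows = []
    adm_date = card.visits[0].visit_date
    for i, v in enumerate(card.visits):
        waz = haz = whz = np.nan
        elapsed = (
            (v.visit_date - adm_date).days
            if v.visit_date is not None and adm_date is not None
            else None
        )
        if card.sex is not None and card.age_months is not None and elapsed is not None:
            age_days = card.age_months * DAYS_PER_MONTH + elapsed
            if v.weight is not None:
                z = reference.zscore("waz", card.sex, age_days, v.weight)
                waz = np.nan if z is None else z
            if v.height is not None:
                z = reference.zscore("haz", card.sex, age_days, v.height)
                haz = np.nan if z is None else z
        if card.sex is not None and v.height is not None and v.weight is not None:
            z = reference.zscore("whz", card.sex, v.height * 10.0, v.weight)
            whz = np.nan if z is None else z
        rows.append({"card_id": card.card_id, "visit_index": i, "waz": waz, "haz": haz, "whz": whz})
    return pd.DataFrame(rows)


def synthetic_reference() -> GrowthReference:
    """A synthetic LMS table for tests and demonstrations.

    This is NOT a published growth standard: the medians follow smooth,
    roughly realistic curves for children aged 6-60 months (ages 150-1900
    days; heights 580-1250 mm) so that z-score plumbing, interpolation and
    the wide plausibility bounds can be exercised without an external
    reference file.
    """
    height_anchor_ages = [150, 365, 730, 1095, 1461, 1825, 1950]
    height_anchor_cm = [60.0, 75.0, 87.0, 96.0, 102.0, 109.0, 111.0]
    rows = []
    for sex, off in (("F", -0.15), ("M", 0.0)):
        for age in range(150, 1901, 50):
            m_w = 4.5 + 0.0085 * age - 1.3e-6 * age * age + off
            rows.append({"indicator": "waz", "sex": sex, "key": age, "L": 0.2, "M": m_w, "S": 0.12})
            m_h = float(np.interp(age, height_anchor_ages, height_anchor_cm)) + off * 4
            rows.append({"indicator": "haz", "sex": sex, "key": age, "L": 1.0, "M": m_h, "S": 0.035})
        for hmm in range(580, 1251, 20):
            h = hmm / 10.0
            m = 2.0 + 0.0013 * h * h + off  # smooth, increasing in height
            rows.append({"indicator": "whz", "sex": sex, "key": hmm, "L": 0.1, "M": m, "S": 0.09})
    return GrowthReference(pd.DataFrame(rows))
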