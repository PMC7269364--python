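"""Per-visit energy needs and band-wise percentile dosage tables.

The energy a child needed over an interval is modelled as maintenance
plus the cost of the tissue actually deposited:

    need [kcal/day] = W_prior [kg] * maintenance [kcal/kg/day]
                      + gain [g/day] * tissue_cost [kcal/g]

with maintenance 82 kcal/kg/day and tissue cost 5 kcal/g by default.
``gain`` is the observed daily weight gain of the interval
(weight_gain_rate [g/kg/day] times prior weight); weight-loss visits
contribute negatively and are never clamped. Dosage levels are then read
off as an upper percentile (default the 95th) of needs within 5-mm bands
of prior MUAC — the smallest dose sufficient for the observed growth in
that share of visits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import CONTINENT_MAP, RunConfig

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnergyParams:
    """Maintenance and tissue-deposition energy constants."""

    maintenance: float = 82.0  # kcal per kg body weight per day
    tissue_cost: float = 5.0  # kcal per gram of weight gained

    def __post_init__(self) -> None:
        if self.maintenance <= 0 or self.tissue_cost <= 0:
            raise ValueError("energy parameters must be strictly positive")


DEFAULT_PARAMS = EnergyParams()


def daily_energy_need(
    prior_weight, weight_gain_rate, params: EnergyParams = DEFAULT_PARAMS
):
    """Energy need in kcal/day for one interval observation (vectorized).

    ``weight_gain_rate`` is in g/kg/day, so the absolute daily gain in
    grams is ``weight_gain_rate * prior_weight``.
    """
    w = np.asarray(prior_weight, float)
    gain_g = np.asarray(weight_gain_rate, float) * w
    need = w * params.maintenance + gain_g * params.tissue_cost
    if need.ndim == 0:
        return float(need)
    return need


def add_energy_needs(
    observations: pd.DataFrame, params: EnergyParams = DEFAULT_PARAMS
) -> pd.DataFrame:
    """Return a copy of the observation frame with an ``energy_need`` column."""
    out = observations.copy()
    out["energy_need"] = daily_energy_need(
        out["prior_weight"].to_numpy(float), out["weight_gain_rate"].to_numpy(float), params
    )
    return out


def _percentile(values: np.ndarray, level: float) -> float:
    # Linear interpolation between closest ranks (numpy/R type-7 default).
    return float(np.quantile(values, level))


def band_percentile(
    estimates: pd.DataFrame,
    band_width: int = 5,
    level: float = 0.95,
    window: Tuple[int, int] = (100, 140),
    groupby: Optional[str] = None,
) -> pd.DataFrame:
    """Empirical percentile of energy needs per MUAC band (and subgroup).

    Bands tile the closed analysis window in ``band_width``-mm steps keyed
    by prior MUAC, e.g. [110, 115). Empty bands are omitted with a log
    line. Returns columns band_lo, band_hi, group, n, level, kcal.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0,1), got {level}")
    lo, hi = window
    rows = []
    groups = [(None, estimates)] if groupby is None else list(estimates.groupby(groupby, sort=True))
    for gname, gdf in groups:
        needs = gdf["energy_need"].to_numpy(float)
        muac = gdf["prior_muac"].to_numpy(float)
        for a in range(lo, hi, band_width):
            mask = (muac >= a) & (muac < a + band_width)
            if not mask.any():
                log.info("band [%d,%d) group %s: no visits, omitted", a, a + band_width, gname)
                continue
            rows.append(
                {
                    "band_lo": a,
                    "band_hi": a + band_width,
                    "group": "all" if gname is None else gname,
                    "n": int(mask.sum()),
                    "level": level,
                    "kcal": _percentile(needs[mask], level),
                }
            )
    return pd.DataFrame(rows, columns=["band_lo", "band_hi", "group", "n", "level", "kcal"])


SUBGROUP_SCHEMES = ("admission_muac_category", "continent", "age_group")

#: MUAC range shared by both admission categories during treatment, the
#: only range over which their percentiles are comparable.
ADMISSION_COMMON_RANGE = (110, 125)


def _with_subgroup(estimates: pd.DataFrame, scheme: str) -> pd.DataFrame:
    df = estimates.copy()
    if scheme == "continent":
        unknown = set(df["country"]) - set(CONTINENT_MAP)
        if unknown:
            raise ValueError(f"country not in continent map: {', '.join(sorted(unknown))}")
        df["subgroup"] = df["country"].map(CONTINENT_MAP)
    elif scheme == "age_group":
        df["subgroup"] = np.where(df["age_months_at_interval"] < 24, "6-23m", "24-59m")
    elif scheme == "admission_muac_category":
        df["subgroup"] = np.where(df["admission_muac"] < 115, "admitted<115mm", "admitted115-124mm")
    else:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SUBGROUP_SCHEMES}")
    return df


def subgroup_comparison(
    estimates: pd.DataFrame,
    scheme: str,
    band_width: int = 5,
    level: float = 0.95,
    window: Tuple[int, int] = (100, 140),
) -> pd.DataFrame:
    """Band percentiles split by a subgroup scheme.

    The admission-category scheme is restricted to the MUAC bands both
    categories actually share during treatment ([110, 125) mm); the other
    schemes use the full window.
    """
    df = _with_subgroup(estimates, scheme)
    if scheme == "admission_muac_category":
        window = ADMISSION_COMMON_RANGE
    return band_percentile(df, band_width=band_width, level=level, window=window, groupby="subgroup")


class EnergyNeedsModel:
    """Band-percentile energy dosing derived from interval observations."""

    def __init__(
        self,
        observations: pd.DataFrame,
        params: EnergyParams = DEFAULT_PARAMS,
        config: Optional[RunConfig] = None,
    ):
        self.observations = observations
        self.params = params
        self.config = config or RunConfig()

    def fit(self, schemes: Sequence[str] = SUBGROUP_SCHEMES) -> "EnergyNeedsResults":
        cfg = self.config
        cfg.validate()
        est = add_energy_needs(self.observations, self.params)
        table = band_percentile(
            est, band_width=cfg.band_width, level=cfg.percentile, window=cfg.muac_window
        )
        sub = {
            s: subgroup_comparison(
                est, s, band_width=cfg.band_width, level=cfg.percentile, window=cfg.muac_window
            )
            for s in schemes
        }
        return EnergyNeedsResults(self, est, table, sub)


class EnergyNeedsResults:
    def __init__(self, model, estimates, band_table, subgroup_tables):
        self.model = model
        self.estimates: pd.DataFrame = estimates
        self.band_table: pd.DataFrame = band_table
        self.subgroup_tables: Dict[str, pd.DataFrame] = subgroup_tables

    def stratum_percentile(self, lo: int, hi: int) -> float:
        """Percentile of needs over a whole MUAC stratum [lo, hi)."""
        e = self.estimates
        mask = (e["prior_muac"] >= lo) & (e["prior_muac"] < hi)
        if not mask.any():
            return float("nan")
        return _percentile(e.loc[mask, "energy_need"].to_numpy(float), self.model.config.percentile)

    def summary(self) -> str:
        cfg = self.model.config
        p = self.model.params
        lines = [
            "Energy needs analysis",
            "=" * 54,
            f"visits: {len(self.estimates)}  "
            f"(maintenance {p.maintenance:g} kcal/kg/day, tissue cost {p.tissue_cost:g} kcal/g)",
            f"{100 * cfg.percentile:g}th percentile of need by {cfg.band_width}-mm band of prior MUAC:",
        ]
        for _, r in self.band_table.iterrows():
            lines.append(
                f"  [{int(r.band_lo)},{int(r.band_hi)}) mm  n={int(r.n):6d}  {r.kcal:7.0f} kcal/day"
            )
        for name, (lo, hi) in (("SAM-associated [100,115)", (100, 115)), ("MAM-associated [115,125)", (115, 125))):
            lines.append(f"stratum {name}: {self.stratum_percentile(lo, hi):.0f} kcal/day")
        return "\n".join(lines)
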