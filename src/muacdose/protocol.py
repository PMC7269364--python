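"""Dosing protocols and their simulated performance.

The proposed simplified protocol doses by MUAC alone: two RUTF sachets
(1000 kcal/day) while MUAC is 100 to <115 mm, intended to cover 100% of
energy needs, and one sachet (500 kcal/day) while MUAC is 115 to <125 mm,
intended to cover 50% (the remainder from home foods). Comparators dose
by body weight (Golden's minimum/intermediate/standard at 135/150/170
kcal/kg/day), by MUAC threshold (Sierra Leone: 175 or 75 kcal/kg/day),
or by admission program (Kenya: 200 kcal/kg/day for SAM admissions, flat
500 kcal/day for MAM admissions).

Performance is energy coverage only: per visit, the provision ratio
dose/need, judged against the stratum's coverage target, aggregated over
country-stratified subsamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .energy import DEFAULT_PARAMS, EnergyParams, add_energy_needs
from .growth import _stratified_indices
from .types import CONTINENT_MAP, Facility, RunConfig

log = logging.getLogger(__name__)

#: One RUTF sachet: 92 g providing 500 kcal.
SACHET_GRAMS = 92.0
SACHET_KCAL = 500.0

#: Analysis strata by the visit's prior MUAC, with the fraction of need the
#: proposed protocol intends to cover in each.
STRATA = {"sam": (100, 115), "mam": (115, 125)}
COVERAGE_TARGETS = {"sam": 1.0, "mam": 0.5}


@dataclass(frozen=True)
class ProtocolSpec:
    """A dosing rule mapping (MUAC mm, weight kg, admission program) to
    prescribed kcal/day; NaN where the protocol defines no dose."""

    name: str
    rule: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    coverage_target: Dict[str, float] = field(default_factory=lambda: dict(COVERAGE_TARGETS))

    def dose(self, muac, weight, program) -> np.ndarray:
        return self.rule(
            np.asarray(muac, float), np.asarray(weight, float), np.asarray(program, object)
        )


def proposed_dose(muac):
    """Proposed MUAC-only dose: 1000 kcal/day for [100,115) mm, 500 for
    [115,125); NaN (undefined) outside — the caller decides exclusion."""
    m = np.asarray(muac, float)
    out = np.where(m < 115, 2 * SACHET_KCAL, SACHET_KCAL)
    out = np.where((m >= 100) & (m < 125), out, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def _proposed(m, w, p):
    return np.asarray(proposed_dose(m), float)


def _per_kg(rate: float):
    def rule(m, w, p):
        return rate * w

    return rule


def _sierra_leone(m, w, p):
    return np.where(m < 115, 175.0, np.where(m < 125, 75.0, 75.0)) * w


def _kenya(m, w, p):
    sam = np.asarray([x == "TFP" for x in np.atleast_1d(p)])
    return np.where(sam, 200.0 * np.atleast_1d(w), 500.0)


PROTOCOLS: Dict[str, ProtocolSpec] = {
    "proposed": ProtocolSpec("proposed", _proposed),
    "golden_min": ProtocolSpec("golden_min", _per_kg(135.0)),
    "golden_int": ProtocolSpec("golden_int", _per_kg(150.0)),
    "golden_std": ProtocolSpec("golden_std", _per_kg(170.0)),
    "sierra_leone": ProtocolSpec("sierra_leone", _sierra_leone),
    "kenya": ProtocolSpec("kenya", _kenya),
}


def comparator_dose(protocol: str, muac, weight, program=None):
    """Dose under a named comparator (or the proposed protocol) for scalar
    or array inputs; ``program`` is the admission facility ('TFP'/'SFP')."""
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; choose from {sorted(PROTOCOLS)}")
    prog = np.full(np.shape(np.atleast_1d(muac)), "SFP", object) if program is None else program
    out = PROTOCOLS[protocol].dose(muac, weight, prog)
    out = np.asarray(out, float)
    if np.ndim(muac) == 0:
        return float(out.reshape(-1)[0])
    return out


# ---------------------------------------------------------------------------
# Coverage metrics

_FACTORS = ("total", "sex", "age_group", "weight_band", "admission_type", "continent")


def _factor_levels(df: pd.DataFrame, factor: str) -> pd.Series:
    if factor == "total":
        return pd.Series("total", index=df.index)
    if factor == "sex":
        return df["sex"].fillna("unknown")
    if factor == "age_group":
        a = df["age_months_at_interval"]
        return pd.cut(a, [0, 12, 24, 200], right=False, labels=["6-11m", "12-23m", "24-59m"]).astype(str)
    if factor == "weight_band":
        w = df["prior_weight"]
        return pd.cut(
            w, [0, 6.0, 8.0, np.inf], right=False, labels=["3.5-5.9kg", "6.0-7.9kg", "8.0-17.5kg"]
        ).astype(str)
    if factor == "admission_type":
        return df["facility"]
    if factor == "continent":
        unknown = set(df["country"]) - set(CONTINENT_MAP)
        if unknown:
            raise ValueError(f"country not in continent map: {', '.join(sorted(unknown))}")
        return df["country"].map(CONTINENT_MAP)
    raise ValueError(f"unknown factor {factor!r}")


def coverage_metrics(
    estimates: pd.DataFrame,
    protocol: ProtocolSpec,
    factors: Sequence[str] = _FACTORS,
) -> pd.DataFrame:
    """Per-stratum, per-factor-level coverage of one visit set.

    Visits with no defined dose (prior MUAC outside [100, 125) under the
    proposed protocol) are excluded and counted in the log. Success in the
    SAM stratum means the dose covers at least 100% of need; in the MAM
    stratum at least 50%.

    Returns columns: stratum, factor, level, n, median_provision_pct,
    success_frac.
    """
    df = estimates.copy()
    dose = protocol.dose(
        df["prior_muac"].to_numpy(float),
        df["prior_weight"].to_numpy(float),
        df["facility"].to_numpy(object),
    )
    df["dose"] = dose
    undefined = int(np.isnan(dose).sum())
    if undefined:
        log.info("%d visits with no defined dose under %s excluded", undefined, protocol.name)
    bad_need = df["energy_need"] <= 0
    if bad_need.any():
        log.warning("%d visits with non-positive need skipped", int(bad_need.sum()))
    df = df[~np.isnan(df["dose"]) & ~bad_need]
    df["provision"] = df["dose"] / df["energy_need"]

    rows = []
    for sname, (lo, hi) in STRATA.items():
        sdf = df[(df["prior_muac"] >= lo) & (df["prior_muac"] < hi)]
        target = protocol.coverage_target[sname]
        for factor in factors:
            levels = _factor_levels(sdf, factor)
            for level, ldf in sdf.groupby(levels, observed=True):
                if len(ldf) == 0:
                    continue
                prov = ldf["provision"].to_numpy(float)
                rows.append(
                    {
                        "stratum": sname,
                        "factor": factor,
                        "level": level,
                        "n": len(ldf),
                        "median_provision_pct": 100.0 * float(np.median(prov)),
                        "success_frac": float(np.mean(prov >= target)),
                    }
                )
    return pd.DataFrame(
        rows, columns=["stratum", "factor", "level", "n", "median_provision_pct", "success_frac"]
    )


@dataclass
class PerformanceSummary:
    """Replicate-aggregated protocol performance (one row per stratum ×
    factor level): mean/min/max n, mean of per-replicate median provision,
    and mean/min/max fraction of visits meeting the coverage target."""

    table: pd.DataFrame
    protocol: str
    replicates: int

    def summary(self) -> str:
        lines = [
            f"Protocol performance: {self.protocol} ({self.replicates} replicates)",
            "=" * 78,
            f"{'stratum':8s} {'factor':14s} {'level':16s} {'mean n':>8s} "
            f"{'median %need':>12s} {'%visits met':>12s} {'range':>12s}",
        ]
        for _, r in self.table.iterrows():
            lines.append(
                f"{r.stratum:8s} {r.factor:14s} {str(r.level):16s} {r.mean_n:8.0f} "
                f"{r.median_provision_pct:11.0f}% {100 * r.mean_success:11.0f}% "
                f"{100 * r.min_success:5.0f}-{100 * r.max_success:.0f}%"
            )
        return "\n".join(lines)


def simulate_trials(
    observations: pd.DataFrame,
    protocol: ProtocolSpec = PROTOCOLS["proposed"],
    per_country: int = 200,
    replicates: int = 100,
    seed: int = 0,
    params: EnergyParams = DEFAULT_PARAMS,
    sampling_unit: str = "visits",
    factors: Sequence[str] = _FACTORS,
) -> PerformanceSummary:
    """Country-stratified resampled protocol-performance simulation.

    Per replicate, ``per_country`` visits (or cards) are drawn without
    replacement from each country, coverage metrics computed, then
    aggregated across replicates per stratum and factor level.
    """
    if observations.empty:
        raise ValueError("no observations to simulate from")
    est = observations if "energy_need" in observations else add_energy_needs(observations, params)
    est = est.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    reps = []
    for r in range(replicates):
        idx = _stratified_indices(est, per_country, rng, unit=sampling_unit)
        m = coverage_metrics(est.loc[idx], protocol, factors)
        m["replicate"] = r
        reps.append(m)
    allm = pd.concat(reps, ignore_index=True)
    agg = (
        allm.groupby(["stratum", "factor", "level"], sort=True, observed=True)
        .agg(
            mean_n=("n", "mean"),
            min_n=("n", "min"),
            max_n=("n", "max"),
            median_provision_pct=("median_provision_pct", "mean"),
            mean_success=("success_frac", "mean"),
            min_success=("success_frac", "min"),
            max_success=("success_frac", "max"),
            n_replicates=("replicate", "nunique"),
        )
        .reset_index()
    )
    return PerformanceSummary(table=agg, protocol=protocol.name, replicates=replicates)


def mean_energy_by_muac(
    observations: pd.DataFrame,
    protocols: Sequence[ProtocolSpec] = tuple(PROTOCOLS.values()),
    muac_range: Tuple[int, int] = (100, 140),
) -> pd.DataFrame:
    """Mean prescribed kcal/day at each integer MUAC, per protocol.

    Per-kg rules average over the empirical weight distribution of the
    visits observed at that prior MUAC; MUAC values with no observations
    are omitted.
    """
    rows = []
    for m in range(muac_range[0], muac_range[1] + 1):
        sub = observations[observations["prior_muac"] == m]
        if sub.empty:
            continue
        row = {"muac": m, "n": len(sub)}
        for p in protocols:
            dose = p.dose(
                sub["prior_muac"].to_numpy(float),
                sub["prior_weight"].to_numpy(float),
                sub["facility"].to_numpy(object),
            )
            row[f"kcal_{p.name}"] = float(np.nanmean(dose)) if np.isfinite(dose).any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


class ProtocolSimulation:
    """Protocol-performance simulation over QC-filtered observations."""

    def __init__(
        self,
        observations: pd.DataFrame,
        protocol: ProtocolSpec = PROTOCOLS["proposed"],
        config: Optional[RunConfig] = None,
        params: EnergyParams = DEFAULT_PARAMS,
    ):
        self.observations = observations
        self.protocol = protocol
        self.config = config or RunConfig()
        self.params = params

    def fit(self) -> "ProtocolSimulationResults":
        cfg = self.config
        cfg.validate()
        perf = simulate_trials(
            self.observations,
            protocol=self.protocol,
            per_country=cfg.trial_per_country,
            replicates=cfg.trial_replicates,
            seed=cfg.rng_seed,
            params=self.params,
            sampling_unit=cfg.sampling_unit,
        )
        est = add_energy_needs(self.observations, self.params)
        curves = mean_energy_by_muac(est, muac_range=cfg.muac_window)
        return ProtocolSimulationResults(self, perf, curves)


class ProtocolSimulationResults:
    def __init__(self, model, performance: PerformanceSummary, energy_curves: pd.DataFrame):
        self.model = model
        self.performance = performance
        self.energy_curves = energy_curves

    def summary(self) -> str:
        return self.performance.summary()
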