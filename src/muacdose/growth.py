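"""Growth velocities on irregular visit intervals, local polynomial
smoothing of velocity versus MUAC, and the normalized-difference trend
analysis.

Between-visit changes are assumed constant over the interval, so a change
over ``d`` days contributes one observation normalized to

    muac_velocity    = dMUAC / (d / 7)            [mm/week]
    weight_gain_rate = dW * 1000 / W_prior / d    [g/kg/day]

indexed by the MUAC at the prior visit. The question of interest is
whether MUAC velocity tracks proportional weight gain: both series are
smoothed against prior MUAC, min-max normalized to [0, 1], and the trend
of their difference is tested for a non-zero slope by OLS, repeated over
country-stratified subsamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import PatientCard, RunConfig

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntervalObservation:
    """One between-visit record, normalized to weekly/daily rates."""

    card_id: str
    country: str
    facility: str
    age_months_at_interval: int
    prior_muac: int
    prior_weight: float
    interval_days: int
    muac_velocity: float
    weight_gain_rate: float
    visit_index: int  # index of the interval's ending visit within the card


def interval_changes(card: PatientCard) -> List[IntervalObservation]:
    """Interval observations for every consecutive visit pair of a card.

    Pairs lacking a date, MUAC or weight at either end are skipped (the
    usability filter rejects undated cards before analysis); zero-day
    intervals cannot occur because the reader rejects duplicate dates.
    """
    out: List[IntervalObservation] = []
    adm_date = card.visits[0].visit_date
    for i in range(1, len(card.visits)):
        a, b = card.visits[i - 1], card.visits[i]
        if a.visit_date is None or b.visit_date is None:
            continue
        if a.muac is None or b.muac is None or a.weight is None or b.weight is None:
            continue
        d = (b.visit_date - a.visit_date).days
        if d < 1:
            continue
        elapsed = (a.visit_date - adm_date).days if adm_date is not None else 0
        age = (card.age_months or 0) + int(elapsed / 30.4375)
        out.append(
            IntervalObservation(
                card_id=card.card_id,
                country=card.country,
                facility=card.facility.value,
                age_months_at_interval=age,
                prior_muac=a.muac,
                prior_weight=a.weight,
                interval_days=d,
                muac_velocity=(b.muac - a.muac) / (d / 7.0),
                weight_gain_rate=(b.weight - a.weight) * 1000.0 / a.weight / d,
                visit_index=i,
            )
        )
    return out


def intervals_frame(cards: Sequence[PatientCard]) -> pd.DataFrame:
    """All interval observations of a cohort as a DataFrame.

    Adds per-card metadata needed downstream: ``sex`` and the admission
    MUAC (``admission_muac``) used for admission-category subgrouping.
    """
    rows = []
    for c in cards:
        adm_muac = c.visits[0].muac
        sex = None if c.sex is None else c.sex.value
        for o in interval_changes(c):
            r = o.__dict__.copy()
            r["sex"] = sex
            r["admission_muac"] = adm_muac
            rows.append(r)
    cols = [
        "card_id", "country", "facility", "sex", "admission_muac",
        "age_months_at_interval", "prior_muac", "prior_weight",
        "interval_days", "muac_velocity", "weight_gain_rate", "visit_index",
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Local polynomial smoothing

KERNELS = {
    "epanechnikov": lambda u: np.where(np.abs(u) < 1.0, 0.75 * (1.0 - u**2), 0.0),
    "uniform": lambda u: np.where(np.abs(u) <= 1.0, 0.5, 0.0),
    "triangle": lambda u: np.where(np.abs(u) < 1.0, 1.0 - np.abs(u), 0.0),
    "gaussian": lambda u: np.exp(-0.5 * u**2) / np.sqrt(2.0 * np.pi),
}


def rule_of_thumb_bandwidth(x: np.ndarray) -> float:
    """Pragmatic plug-in bandwidth: ``1.06 sd(x) n^(-1/5)``, floored at 1 mm.

    The floor keeps at least neighbouring whole-millimetre MUAC values
    inside the kernel window on card data, where x is integer-valued.
    """
    x = np.asarray(x, float)
    return float(max(1.0, 1.06 * np.std(x) * len(x) ** (-0.2)))


@dataclass
class SmoothCurve:
    """A smoothed mean curve evaluated on an ascending MUAC grid.

    ``stderr`` is the pointwise standard error of the estimate derived from
    the kernel-weighted local residual variance (None for curves built by
    hand rather than by :func:`local_poly_smooth`).
    """

    grid: np.ndarray
    estimate: np.ndarray
    bandwidth: float
    kernel: str = "epanechnikov"
    degree: int = 0
    stderr: Optional[np.ndarray] = None

    def band_mean(self, lo: float, hi: float) -> float:
        """Mean of the smoothed estimate over grid points in [lo, hi)."""
        mask = (self.grid >= lo) & (self.grid < hi) & np.isfinite(self.estimate)
        if not mask.any():
            return float("nan")
        return float(np.mean(self.estimate[mask]))


def local_poly_smooth(
    x: Sequence[float],
    y: Sequence[float],
    grid: Sequence[float],
    kernel: str = "epanechnikov",
    bandwidth: Optional[float] = None,
    degree: int = 0,
) -> SmoothCurve:
    """Local polynomial regression of ``y`` on ``x`` evaluated on ``grid``.

    At each grid point g a polynomial of the given degree is fitted to the
    data by weighted least squares with kernel weights K((x - g)/h); the
    fitted value at g is the estimate. Grid points receiving zero total
    weight yield NaN. A locally singular design (e.g. all x identical
    within the window with degree >= 1) falls back to the local constant
    fit at that point.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < degree + 1:
        raise ValueError(f"need at least degree+1={degree + 1} observations, got {len(x)}")
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {sorted(KERNELS)}")
    h = rule_of_thumb_bandwidth(x) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    kfun = KERNELS[kernel]
    grid = np.asarray(grid, float)
    est = np.full(grid.shape, np.nan)
    se = np.full(grid.shape, np.nan)
    for j, g in enumerate(grid):
        w = kfun((x - g) / h)
        sw = w.sum()
        if sw <= 0:
            continue
        fallback = degree == 0
        if not fallback:
            xc = x - g
            X = np.vander(xc, degree + 1, increasing=True)
            sqw = np.sqrt(w)
            A = X * sqw[:, None]
            b = y * sqw
            coef, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
            if rank < degree + 1:
                log.debug("singular local design at grid %.1f; degree-0 fallback", g)
                fallback = True
            else:
                est[j] = float(coef[0])
                resid = y - X @ coef
                s2 = float(np.dot(w, resid**2) / sw)
                M = X.T @ (w[:, None] * X)
                N = X.T @ ((w**2)[:, None] * X)
                Minv = np.linalg.pinv(M)
                se[j] = float(np.sqrt(max(0.0, s2 * (Minv @ N @ Minv)[0, 0])))
        if fallback:
            m = float(np.dot(w, y) / sw)
            est[j] = m
            s2 = float(np.dot(w, (y - m) ** 2) / sw)
            se[j] = float(np.sqrt(s2 * np.dot(w, w)) / sw)
    return SmoothCurve(grid=grid, estimate=est, bandwidth=h, kernel=kernel, degree=degree, stderr=se)


# ---------------------------------------------------------------------------
# Trend testing


@dataclass
class TrendTest:
    """Trend of the normalized difference between two smooth curves.

    ``p_value`` is the calibrated Monte-Carlo p-value of the slope when
    both curves carry standard errors; ``f_pvalue`` is the raw OLS F-test
    p-value of the same regression (kept as a diagnostic — see
    docs/methods.md for why its reference distribution is unreliable for
    this statistic).
    """

    slope: float
    p_value: float
    f_pvalue: float
    n_grid: int


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi - lo <= 0:
        log.info("constant curve in trend test; normalized value set to 0.5")
        return np.full(v.shape, 0.5)
    return (v - lo) / (hi - lo)


def _ols_slope_f(g: np.ndarray, d: np.ndarray) -> Tuple[float, float]:
    res = sm.OLS(d, sm.add_constant(g)).fit()
    pval = float(res.f_pvalue)
    if np.isnan(pval):  # zero residual variance: perfect fit
        pval = 0.0 if abs(res.params[1]) > 0 else 1.0
    return float(res.params[1]), pval


def normalized_difference_trend_test(
    curve_a: SmoothCurve,
    curve_b: SmoothCurve,
    level: float = 0.05,
    n_null: int = 400,
    rng: Optional[np.random.Generator] = None,
) -> TrendTest:
    """Test whether two curves' normalized shapes diverge linearly in MUAC.

    Both estimates are min-max normalized to [0, 1] over the shared grid
    and the pointwise difference is regressed on grid MUAC; the statistic
    is the OLS slope. Because min-max normalization pins both curves to 0
    and 1 at their (shared, shape-determined) extremes and absorbs each
    curve's own linear component, the slope's textbook F distribution does
    not hold under the null; the returned ``p_value`` is therefore
    computed against a simulated null — both curves redrawn ``n_null``
    times from their common estimated shape with independent Gaussian
    noise at each curve's pointwise standard error, renormalized, and the
    slope recomputed. Curves built without standard errors fall back to
    the plain F p-value.

    Grid points where either curve is undefined are dropped.
    """
    if curve_a.grid.shape != curve_b.grid.shape or not np.allclose(curve_a.grid, curve_b.grid):
        raise ValueError("curves must share an identical grid")
    ok = np.isfinite(curve_a.estimate) & np.isfinite(curve_b.estimate)
    if ok.sum() < 3:
        raise ValueError("need at least 3 shared grid points")
    g = curve_a.grid[ok]
    na = _minmax(curve_a.estimate[ok])
    nb = _minmax(curve_b.estimate[ok])
    slope, f_pvalue = _ols_slope_f(g, na - nb)

    have_se = (
        curve_a.stderr is not None
        and curve_b.stderr is not None
        and np.isfinite(curve_a.stderr[ok]).all()
        and np.isfinite(curve_b.stderr[ok]).all()
    )
    if not have_se:
        return TrendTest(slope=slope, p_value=f_pvalue, f_pvalue=f_pvalue, n_grid=int(ok.sum()))

    range_a = float(np.ptp(curve_a.estimate[ok])) or 1.0
    range_b = float(np.ptp(curve_b.estimate[ok])) or 1.0
    se_a = curve_a.stderr[ok] / range_a
    se_b = curve_b.stderr[ok] / range_b
    shape = 0.5 * (na + nb)
    rng = np.random.default_rng() if rng is None else rng
    k = len(g)
    gc = g - g.mean()
    denom = float(np.sum(gc**2))
    noise = rng.standard_normal((n_null, 2, k))
    hits = 0
    for m in range(n_null):
        sa = _minmax(shape + noise[m, 0] * se_a)
        sb = _minmax(shape + noise[m, 1] * se_b)
        d = sa - sb
        null_slope = float(np.dot(gc, d - d.mean()) / denom)
        if abs(null_slope) >= abs(slope):
            hits += 1
    p_value = (1.0 + hits) / (1.0 + n_null)
    return TrendTest(slope=slope, p_value=p_value, f_pvalue=f_pvalue, n_grid=int(ok.sum()))


@dataclass
class TrendTestResult:
    """Aggregate of the trend test across resampling replicates."""

    slopes: np.ndarray
    p_values: np.ndarray
    level: float

    @property
    def mean_slope(self) -> float:
        return float(np.mean(self.slopes))

    @property
    def min_slope(self) -> float:
        return float(np.min(self.slopes))

    @property
    def max_slope(self) -> float:
        return float(np.max(self.slopes))

    @property
    def frac_nonsignificant(self) -> float:
        return float(np.mean(self.p_values > self.level))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"replicate": np.arange(len(self.slopes)), "slope": self.slopes, "p_value": self.p_values})


def _stratified_indices(
    obs: pd.DataFrame, per_country: int, rng: np.random.Generator, unit: str = "visits"
) -> np.ndarray:
    """Country-stratified without-replacement draw of row indices."""
    chosen = []
    for country, grp in obs.groupby("country", sort=True):
        if unit == "cards":
            ids = grp["card_id"].unique()
            if len(ids) == 0:
                raise ValueError(f"empty country stratum: {country!r}")
            k = min(per_country, len(ids))
            if k < per_country:
                log.info("country %s has only %d cards (< %d); using all", country, len(ids), per_country)
            take = rng.choice(ids, size=k, replace=False)
            chosen.append(grp.index[grp["card_id"].isin(take)].to_numpy())
        else:
            idx = grp.index.to_numpy()
            if len(idx) == 0:
                raise ValueError(f"empty country stratum: {country!r}")
            k = min(per_country, len(idx))
            if k < per_country:
                log.info("country %s has only %d visits (< %d); using all", country, len(idx), per_country)
            chosen.append(rng.choice(idx, size=k, replace=False))
    return np.concatenate(chosen)


def resample_trend_analysis(
    observations: pd.DataFrame,
    per_country: int = 1000,
    replicates: int = 100,
    muac_range: Tuple[int, int] = (100, 140),
    seed: int = 0,
    level: float = 0.05,
    kernel: str = "epanechnikov",
    bandwidth: Optional[float] = None,
    degree: int = 0,
    sampling_unit: str = "visits",
) -> TrendTestResult:
    """Country-stratified resampled trend comparison of MUAC velocity and
    proportional weight gain.

    Per replicate: draw ``per_country`` observations from each country
    without replacement, smooth both velocity series against prior MUAC on
    a common integer-mm grid over ``muac_range``, and run
    :func:`normalized_difference_trend_test`.
    """
    if observations.empty:
        raise ValueError("no observations to resample")
    rng = np.random.default_rng(seed)
    slopes = np.empty(replicates)
    pvals = np.empty(replicates)
    for r in range(replicates):
        idx = _stratified_indices(observations, per_country, rng, unit=sampling_unit)
        sub = observations.loc[idx]
        x = sub["prior_muac"].to_numpy(float)
        h = rule_of_thumb_bandwidth(x) if bandwidth is None else float(bandwidth)
        # The simulated null draws independent noise per grid point, so the
        # test grid is spaced at >= 2h: for compact kernels the smoothing
        # windows are then disjoint and estimates share no observations.
        step = int(np.ceil(2.0 * h)) if kernel != "gaussian" else max(1, int(np.ceil(3.0 * h)))
        grid = np.arange(muac_range[0], muac_range[1] + 1, step, dtype=float)
        ca = local_poly_smooth(x, sub["muac_velocity"].to_numpy(float), grid, kernel, h, degree)
        cb = local_poly_smooth(x, sub["weight_gain_rate"].to_numpy(float), grid, kernel, h, degree)
        t = normalized_difference_trend_test(ca, cb, level, rng=rng)
        slopes[r], pvals[r] = t.slope, t.p_value
    return TrendTestResult(slopes=slopes, p_values=pvals, level=level)


@dataclass
class RegressionResult:
    slope: float
    p_value: float
    n: int


def velocity_regression(observations: pd.DataFrame, response: str = "muac_velocity") -> RegressionResult:
    """OLS of a velocity series on prior MUAC: slope per mm and F p-value."""
    if response not in ("muac_velocity", "weight_gain_rate"):
        raise ValueError(f"unknown response {response!r}")
    x = observations["prior_muac"].to_numpy(float)
    y = observations[response].to_numpy(float)
    if len(x) < 3 or np.unique(x).size < 2:
        raise ValueError("degenerate design: need >=3 observations with distinct prior MUAC")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    pval = float(res.f_pvalue)
    if np.isnan(pval):
        pval = 0.0 if abs(res.params[1]) > 0 else 1.0
    return RegressionResult(slope=float(res.params[1]), p_value=pval, n=len(x))


# ---------------------------------------------------------------------------
# Model / Results presentation


class GrowthTrendModel:
    """Growth-trend analysis of a set of interval observations.

    Parameters
    ----------
    observations : DataFrame
        Interval observations (see :func:`intervals_frame`), already
        QC-filtered and windowed.
    config : RunConfig
        Resampling sizes, MUAC window, seed and significance level.
    kernel, bandwidth, degree
        Smoother settings; bandwidth ``None`` uses the rule of thumb.
    """

    def __init__(
        self,
        observations: pd.DataFrame,
        config: Optional[RunConfig] = None,
        kernel: str = "epanechnikov",
        bandwidth: Optional[float] = None,
        degree: int = 0,
    ):
        self.observations = observations.reset_index(drop=True)
        self.config = config or RunConfig()
        self.kernel = kernel
        self.bandwidth = bandwidth
        self.degree = degree

    def fit(self, run_resampling: bool = True) -> "GrowthTrendResults":
        cfg = self.config
        cfg.validate()
        obs = self.observations
        lo, hi = cfg.muac_window
        grid = np.arange(lo, hi + 1, dtype=float)
        x = obs["prior_muac"].to_numpy(float)
        muac_curve = local_poly_smooth(
            x, obs["muac_velocity"].to_numpy(float), grid, self.kernel, self.bandwidth, self.degree
        )
        weight_curve = local_poly_smooth(
            x, obs["weight_gain_rate"].to_numpy(float), grid, self.kernel, self.bandwidth, self.degree
        )
        muac_reg = velocity_regression(obs, "muac_velocity")
        weight_reg = velocity_regression(obs, "weight_gain_rate")
        trend = None
        if run_resampling:
            trend = resample_trend_analysis(
                obs,
                per_country=cfg.trend_per_country,
                replicates=cfg.trend_replicates,
                muac_range=cfg.muac_window,
                seed=cfg.rng_seed,
                level=cfg.significance_level,
                kernel=self.kernel,
                bandwidth=self.bandwidth,
                degree=self.degree,
                sampling_unit=cfg.sampling_unit,
            )
        return GrowthTrendResults(self, muac_curve, weight_curve, muac_reg, weight_reg, trend)


class GrowthTrendResults:
    """Fitted growth-trend curves, regressions and resampled trend test."""

    def __init__(self, model, muac_curve, weight_curve, muac_regression, weight_regression, trend):
        self.model = model
        self.muac_curve: SmoothCurve = muac_curve
        self.weight_curve: SmoothCurve = weight_curve
        self.muac_regression: RegressionResult = muac_regression
        self.weight_regression: RegressionResult = weight_regression
        self.trend: Optional[TrendTestResult] = trend

    def band_means(self, band_width: Optional[int] = None) -> pd.DataFrame:
        """Band-averaged smoothed velocities over the MUAC window."""
        cfg = self.model.config
        bw = band_width or cfg.band_width
        lo, hi = cfg.muac_window
        rows = []
        for a in range(lo, hi, bw):
            rows.append(
                {
                    "band_lo": a,
                    "band_hi": a + bw,
                    "muac_velocity": self.muac_curve.band_mean(a, a + bw),
                    "weight_gain_rate": self.weight_curve.band_mean(a, a + bw),
                }
            )
        return pd.DataFrame(rows)

    def curves_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "muac": self.muac_curve.grid,
                "muac_velocity": self.muac_curve.estimate,
                "weight_gain_rate": self.weight_curve.estimate,
            }
        )

    def summary(self) -> str:
        lines = [
            "Growth trend analysis",
            "=" * 54,
            f"observations: {len(self.model.observations)}",
            f"smoother: kernel={self.muac_curve.kernel}, degree={self.muac_curve.degree}, "
            f"bandwidth={self.muac_curve.bandwidth:.2f} mm",
            f"MUAC velocity slope:    {self.muac_regression.slope:+.4f} mm/week per mm "
            f"(F p={self.muac_regression.p_value:.3g})",
            f"weight gain slope:      {self.weight_regression.slope:+.4f} g/kg/day per mm "
            f"(F p={self.weight_regression.p_value:.3g})",
        ]
        if self.trend is not None:
            t = self.trend
            lines += [
                f"normalized-difference trend over {len(t.slopes)} replicates:",
                f"  slope mean {t.mean_slope:+.4f} (range {t.min_slope:+.4f} to {t.max_slope:+.4f})",
                f"  non-significant at level {t.level:g}: {100 * t.frac_nonsignificant:.0f}%",
            ]
        return "\n".join(lines)
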