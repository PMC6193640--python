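"""National time-trend estimation and analytic risk forecasting.

Incidents are binned into one- or two-year calendar periods and the counts
are modelled by Poisson regression with a log-linear (optionally quadratic)
time trend,

    log E[count in bin starting at year offset t] = b1 + b2·t (+ b3·t²),

fitted by iteratively reweighted least squares.  Two complementary rate
estimates feed the risk forecast: the homogeneous-process inter-arrival MLE
(a constant monthly rate over the whole study window) and the trend model's
prediction for the most recent year.  The probability of at least one event
within *t* months at monthly rate λ is 1 − exp(−λ·t).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import IncidentRecord

__all__ = [
    "DAYS_PER_MONTH",
    "NHPPTrendModel",
    "NHPPTrendResults",
    "RiskForecast",
    "bin_counts",
    "fit_trend",
    "compare_aic",
    "interarrival_mle",
    "risk_table",
    "predict_monthly_rate",
    "smooth_interarrival",
]

#: Average month length in days (365.25 / 12).
DAYS_PER_MONTH = 365.25 / 12.0


def _dates_of(incidents: Sequence[IncidentRecord] | Sequence[Date]) -> list[Date]:
    return [r.date if isinstance(r, IncidentRecord) else r for r in incidents]


def bin_counts(
    incidents: Sequence[IncidentRecord] | Sequence[Date],
    width_years: int = 2,
    origin_year: int = 1982,
    study_end: Date | None = None,
) -> pd.DataFrame:
    """Aggregate incidents into half-open calendar bins.

    Bin *k* covers calendar years ``[origin + k·w, origin + (k+1)·w)`` and
    carries year offset ``k·w`` (the bin's start year minus the origin).
    ``study_end`` (default: the last incident's date) truncates the final
    bin; a partial final bin is flagged and its covered fraction recorded in
    ``exposure_frac``.  Columns: bin_start_year, year_offset, count,
    exposure_frac, partial.
    """
    if width_years not in (1, 2):
        raise ValueError("width_years must be 1 or 2")
    dates = sorted(_dates_of(incidents))
    if not dates:
        raise ValueError("no incidents to bin")
    if min(d.year for d in dates) < origin_year:
        raise ValueError("incident predates the origin year")
    study_end = study_end or dates[-1]
    n_bins = (study_end.year - origin_year) // width_years + 1
    counts = np.zeros(n_bins, dtype=int)
    for d in dates:
        counts[(d.year - origin_year) // width_years] += 1
    start_years = origin_year + width_years * np.arange(n_bins)
    frac = np.ones(n_bins)
    # fraction of the final bin covered by the study window
    end_frac = (
        study_end.year
        - start_years[-1]
        + ((study_end - Date(study_end.year, 1, 1)).days + 1) / 365.25
    ) / width_years
    frac[-1] = min(end_frac, 1.0)
    return pd.DataFrame(
        {
            "bin_start_year": start_years,
            "year_offset": width_years * np.arange(n_bins),
            "count": counts,
            "exposure_frac": frac,
            "partial": frac < 1.0,
        }
    )


class NHPPTrendModel:
    """Poisson trend model for binned national incident counts.

    Build from an incident series (``NHPPTrendModel(incidents, width_years=2)``)
    or from a pre-binned table (:meth:`from_binned`).  ``use_exposure``
    includes ``log(exposure_frac)`` as an offset so a partial final bin is
    weighted by the window fraction it covers; switch it off to reproduce a
    naive fit that treats every bin as complete.
    """

    def __init__(
        self,
        incidents: Sequence[IncidentRecord] | Sequence[Date],
        width_years: int = 2,
        origin_year: int = 1982,
        study_end: Date | None = None,
        *,
        use_exposure: bool = True,
    ) -> None:
        self.binned = bin_counts(incidents, width_years, origin_year, study_end)
        self.width_years = width_years
        self.origin_year = origin_year
        self.use_exposure = use_exposure

    @classmethod
    def from_binned(cls, binned: pd.DataFrame, width_years: int = 2,
                    origin_year: int = 1982, *, use_exposure: bool = True) -> "NHPPTrendModel":
        obj = cls.__new__(cls)
        obj.binned = binned.reset_index(drop=True)
        obj.width_years = width_years
        obj.origin_year = origin_year
        obj.use_exposure = use_exposure
        return obj

    def fit(self, degree: int = 1) -> "NHPPTrendResults":
        return fit_trend(self.binned, degree, width_years=self.width_years,
                         use_exposure=self.use_exposure, origin_year=self.origin_year)


@dataclass
class NHPPTrendResults:
    """Fitted log-linear trend: coefficients on the log bin-count scale."""

    coefficients: np.ndarray
    cov_params: np.ndarray
    aic: float
    pearson_dispersion: float
    slope_p_value: float
    quadratic_p_value: float | None
    degree: int
    width_years: int
    origin_year: int
    binned: pd.DataFrame
    _sm_results: object = None

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slope(self) -> float:
        return float(self.coefficients[1])

    def predict_monthly_rate(self, year_offset: float) -> float:
        return predict_monthly_rate(self, year_offset)

    @property
    def most_recent_year_offset(self) -> int:
        """Offset of the last calendar year the final bin reaches."""
        return int(self.binned["year_offset"].iloc[-1] + self.width_years - 1)

    def summary(self) -> pd.DataFrame:
        names = ["intercept", "slope", "quadratic"][: self.degree + 1]
        se = np.sqrt(np.diag(self.cov_params))
        z = self.coefficients / se
        from scipy import stats as _st

        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": se,
                "z": z,
                "p_value": 2 * _st.norm.sf(np.abs(z)),
            },
            index=names,
        )


def fit_trend(
    binned: pd.DataFrame,
    degree: int = 1,
    *,
    width_years: int | None = None,
    origin_year: int = 1982,
    use_exposure: bool = True,
) -> NHPPTrendResults:
    """Poisson regression of bin counts on the year offset (IRLS).

    ``degree`` 1 fits the log-linear trend, 2 adds a quadratic term whose
    Wald p-value is reported.  AIC is −2·loglik + 2k; the Pearson dispersion
    is Σ(y−μ̂)²/μ̂ divided by the residual degrees of freedom.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    y = binned["count"].to_numpy(dtype=float)
    if (y < 0).any() or (y != np.round(y)).any():
        raise ValueError("bin counts must be non-negative integers")
    if not (y > 0).any():
        raise ValueError("all bin counts are zero; the log-linear trend is undefined")
    if len(y) < degree + 2:
        raise ValueError(f"need at least {degree + 2} bins for degree {degree}")
    t = binned["year_offset"].to_numpy(dtype=float)
    x = np.column_stack([t**d for d in range(degree + 1)])
    offset = None
    if use_exposure and "exposure_frac" in binned.columns:
        offset = np.log(binned["exposure_frac"].to_numpy(dtype=float))
    res = sm.GLM(y, x, family=sm.families.Poisson(), offset=offset).fit()
    mu = res.fittedvalues
    k = degree + 1
    dispersion = float(np.sum((y - mu) ** 2 / mu) / (len(y) - k))
    pvals = res.pvalues
    if width_years is None:
        offs = np.diff(np.unique(t))
        width_years = int(offs.min()) if len(offs) else 2
    return NHPPTrendResults(
        coefficients=np.asarray(res.params),
        cov_params=np.asarray(res.cov_params()),
        aic=float(res.aic),
        pearson_dispersion=dispersion,
        slope_p_value=float(pvals[1]),
        quadratic_p_value=float(pvals[2]) if degree == 2 else None,
        degree=degree,
        width_years=width_years,
        origin_year=origin_year,
        binned=binned,
        _sm_results=res,
    )


def compare_aic(
    fit_annual: NHPPTrendResults, fit_biannual: NHPPTrendResults
) -> tuple[str, float]:
    """Pick the binning with the lower AIC; a tie goes to the biannual model.

    Returns ``(preferred, delta_aic)`` with ``delta_aic = AIC(annual) −
    AIC(biannual)``.
    """
    delta = fit_annual.aic - fit_biannual.aic
    preferred = "biannual" if delta >= 0 else "annual"
    return preferred, float(delta)


def interarrival_mle(
    incidents: Sequence[IncidentRecord] | Sequence[Date],
) -> tuple[float, float]:
    """Exponential inter-arrival MLE: daily rate and its monthly conversion.

    For a homogeneous Poisson process observed from the first to the last
    event, the rate MLE is (n−1)/span, the reciprocal mean gap.  Returns
    ``(daily_rate, monthly_rate)`` with one month = 365.25/12 days.
    """
    dates = sorted(_dates_of(incidents))
    if len(dates) < 2:
        raise ValueError("need at least two incidents")
    span = (dates[-1] - dates[0]).days
    if span <= 0:
        raise ValueError("first and last incidents share a date; rate undefined")
    daily = (len(dates) - 1) / span
    return daily, daily * DAYS_PER_MONTH


@dataclass
class RiskForecast:
    """Probability of at least one event within each forecast horizon."""

    monthly_rate: float
    table: pd.DataFrame  # columns: months, probability, probability_3dp

    def __post_init__(self) -> None:
        p = self.table["probability"].to_numpy()
        d = np.diff(p)
        # strictly increasing in the horizon, except where float saturation
        # has already pinned the probability at 1
        if (d < 0).any() or ((d == 0) & (p[1:] < 1.0 - 1e-12)).any():
            raise ValueError("probabilities must increase with the horizon")


def _round3(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def risk_table(monthly_rate: float, horizons: Sequence[float]) -> RiskForecast:
    """P(at least one event within t months) = 1 − exp(−λ·t) per horizon.

    Reported at full precision and rounded half-up to 3 decimals.
    """
    if monthly_rate <= 0:
        raise ValueError("monthly rate must be positive")
    h = np.asarray(list(horizons), dtype=float)
    if (h < 0).any():
        raise ValueError("horizons must be non-negative")
    p = 1.0 - np.exp(-monthly_rate * h)
    return RiskForecast(
        monthly_rate=monthly_rate,
        table=pd.DataFrame(
            {
                "months": h,
                "probability": p,
                "probability_3dp": [_round3(x) for x in p],
            }
        ),
    )


def predict_monthly_rate(
    fit: NHPPTrendResults | Sequence[float],
    year_offset: float,
    bin_width_years: float | None = None,
) -> float:
    """Monthly intensity implied by the trend at a given year offset.

    ``exp(b1 + b2·offset)`` is the expected count for a full bin; dividing by
    the months per bin (24 biannual, 12 annual) gives the monthly rate.
    ``fit`` may be a fitted result or a raw ``(b1, b2)`` coefficient pair.
    """
    if isinstance(fit, NHPPTrendResults):
        b = fit.coefficients
        w = fit.width_years
    else:
        b = np.asarray(fit, dtype=float)
        w = 2.0 if bin_width_years is None else bin_width_years
    log_count = b[0] + b[1] * year_offset
    if len(b) > 2:
        log_count += b[2] * year_offset**2
    return float(np.exp(log_count) / (12.0 * w))


def smooth_interarrival(
    y: Sequence[float],
    x: Sequence[float] | None = None,
    df: float = 4.0,
    *,
    tol: float = 0.01,
) -> np.ndarray:
    """Natural cubic smoothing spline with a fixed effective df.

    The penalty is chosen by bisection so the trace of the smoother matrix
    equals ``df`` within ``tol``; the fitted values at the data points are
    returned.  With ``df`` close to ``n`` the fit approaches interpolation;
    a natural spline reproduces exactly linear data for any penalty.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    x = np.arange(n, dtype=float) if x is None else np.asarray(x, dtype=float)
    if len(x) != n:
        raise ValueError("x and y lengths differ")
    if n < df + 1:
        raise ValueError(f"need at least df+1 = {df + 1:g} points, got {n}")
    if (np.diff(x) <= 0).any():
        raise ValueError("x must be strictly increasing")
    if df <= 2.0:
        raise ValueError("df must exceed 2 (a natural spline's null space is linear)")

    # Green & Silverman banded construction of the roughness matrix K = Q R⁻¹ Qᵀ
    h = np.diff(x)
    m = n - 2
    r = np.zeros((m, m))
    for i in range(m):
        r[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < m:
            r[i, i + 1] = r[i + 1, i] = h[i + 1] / 6.0
    q = np.zeros((n, m))
    for j in range(m):
        q[j, j] = 1.0 / h[j]
        q[j + 1, j] = -1.0 / h[j] - 1.0 / h[j + 1]
        q[j + 2, j] = 1.0 / h[j + 1]
    k_mat = q @ np.linalg.solve(r, q.T)

    eye = np.eye(n)

    def trace_df(log_lam: float) -> float:
        s = np.linalg.solve(eye + np.exp(log_lam) * k_mat, eye)
        return float(np.trace(s))

    lo, hi = -25.0, 25.0  # df(lo) ≈ n (interpolation), df(hi) ≈ 2 (line)
    if df >= trace_df(lo):
        lam = np.exp(lo)
    else:
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if trace_df(mid) > df:
                lo = mid
            else:
                hi = mid
            if abs(trace_df(mid) - df) < tol:
                break
        lam = np.exp(0.5 * (lo + hi))
    return np.linalg.solve(eye + lam * k_mat, y)
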