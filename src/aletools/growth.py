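"""Thermal growth phenotyping: rate estimation and Ratkowsky-type fitting.

The temperature response of growth is modelled with a modified Ratkowsky
equation covering the full biokinetic range::

    mu(T) = b * (T - Tmin)**2 * (1 - exp(c * (T - Tmax)))

for ``Tmin <= T <= Tmax`` and 0 outside, where ``Tmin``/``Tmax`` are the
minimum and maximum temperatures allowing growth, ``b`` (1/(day*degC^2))
scales the square-root-law rise of the rate, and ``c`` (1/degC) shapes the
collapse of growth as ``Tmax`` is approached.

Parameters are estimated in two coupled stages, iterated to a fixed point:

1. sub-optimal points (below the temperature of maximum observed rate) give
   ``b`` and ``Tmin`` by ordinary least squares on the square-root scale,
   ``sqrt(mu) = beta * (T - Tmin)`` with ``b = beta**2``;
2. ``Tmax`` is found by golden-section search, with ``c`` re-estimated at
   each candidate by algebraic inversion of the model on the supra-optimal
   points, minimizing the sum of squared residuals of the full model.

After each search the sub-optimal rates are corrected for the high-
temperature suppression factor ``1 - exp(c*(T - Tmax))`` and stage 1 is
repeated; on noise-free data this converges to the generating parameters.

The module also provides the in-silico maximum-tolerated-temperature
protocol: raise the temperature on a 0.1 degC grid and return the last
temperature at which the culture still grows stably over a two-week window.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .io_formats import ODTimeSeries

__all__ = [
    "GrowthRatePoint",
    "RatkowskyFit",
    "RampProtocol",
    "GrowthModelError",
    "compute_growth_rate",
    "growth_rate_curve",
    "estimate_linear",
    "estimate_c",
    "fit_ratkowsky",
    "ratkowsky_mu",
    "determine_max_tolerated_temperature",
    "series_plateau_provider",
]


class GrowthModelError(ValueError):
    pass


@dataclass(frozen=True)
class GrowthRatePoint:
    """Growth rate at one held temperature."""

    temperature: float  # degC
    mu: float  # 1/day
    n_readings: int
    few_readings: bool = False  # fewer than 3 OD values at the plateau

    def __post_init__(self) -> None:
        if self.n_readings < 2:
            raise GrowthModelError("a growth rate needs at least two readings")
        if not math.isfinite(self.mu):
            raise GrowthModelError("non-finite growth rate")


@dataclass(frozen=True)
class RatkowskyFit:
    b: float  # 1/(day*degC^2)
    c: float  # 1/degC
    t_min: float  # degC
    t_max: float  # degC
    sse: float  # (1/day)^2
    n_points_linear: int
    n_points_supra: int

    def __post_init__(self) -> None:
        if not (self.t_min < self.t_max):
            raise GrowthModelError("t_min must be below t_max")
        if self.b <= 0 or self.c <= 0 or self.sse < 0:
            raise GrowthModelError("b, c must be positive and sse non-negative")

    def mu(self, temperature) -> float:
        return ratkowsky_mu(self, temperature)


@dataclass(frozen=True)
class RampProtocol:
    """Stepwise temperature-ramp protocol for tolerance determination.

    ``stability_window`` is the number of days a culture must keep growing at
    a candidate temperature (two weeks by default); ``stability_threshold``
    is the minimum mean growth rate (1/day) that counts as stable growth.
    """

    start_temp: float = 43.0
    max_step: float = 0.1  # degC/day
    step_grid: float = 0.1  # degC
    stability_window: float = 14.0  # days
    stability_threshold: float = 0.05  # 1/day

    def __post_init__(self) -> None:
        if self.step_grid <= 0 or self.stability_window <= 0:
            raise GrowthModelError("step_grid and stability_window must be positive")


# ---------------------------------------------------------------------------
# growth rates from OD traces

def compute_growth_rate(
    series: ODTimeSeries, plateau: float, temp_tol: float = 1e-6
) -> GrowthRatePoint:
    """Two-point growth rate at one held temperature.

    mu = ln(Xt/X0)/t with X0 the first and Xt the last OD within the plateau
    and t the elapsed time in days.  Recorded dilution factors are unwound
    before the ratio is taken, so a dilution mid-plateau does not bias the
    rate.  Invariant under rescaling all ODs by a constant.
    """
    sub = series.at_temperature(plateau, tol=temp_tol)
    if len(sub.readings) == 0:
        raise GrowthModelError(
            f"strain {series.strain_id!r}: no readings at {plateau} degC"
        )
    if len(sub.readings) < 2:
        raise GrowthModelError(
            f"strain {series.strain_id!r}: <2 readings at {plateau} degC"
        )
    t0, x0 = sub.readings[0][0], sub.readings[0][1]
    if x0 <= 0:
        raise GrowthModelError(f"strain {series.strain_id!r}: OD must be positive")
    cum_dilution = 1.0
    virtual_last = x0
    for time, od, _, dil in sub.readings[1:]:
        if od <= 0:
            raise GrowthModelError(f"strain {series.strain_id!r}: OD must be positive")
        cum_dilution *= dil
        virtual_last = od * cum_dilution
        t_last = time
    mu = math.log(virtual_last / x0) / (t_last - t0)
    return GrowthRatePoint(
        temperature=plateau,
        mu=mu,
        n_readings=len(sub.readings),
        few_readings=len(sub.readings) < 3,
    )


def growth_rate_curve(series: ODTimeSeries, min_readings: int = 2) -> list[GrowthRatePoint]:
    """Growth rate at every held temperature with enough readings."""
    points = []
    for temp in series.temperatures:
        if len(series.at_temperature(temp).readings) >= min_readings:
            points.append(compute_growth_rate(series, temp))
    return points


# ---------------------------------------------------------------------------
# Ratkowsky fitting

def estimate_linear(
    points: Sequence[GrowthRatePoint], sqrt_scale: bool = True
) -> tuple[float, float]:
    """(b, t_min) from the sub-optimal (linear-range) points.

    Default reading: OLS of sqrt(mu) on T, sqrt(mu) = beta*(T - t_min),
    so beta = slope, t_min = -intercept/beta, b = beta**2.  With
    ``sqrt_scale=False`` the rate itself is regressed on T (the alternative
    reading of the square-root law) and b is the slope.
    """
    usable = [p for p in points if p.mu > 0]
    temps = np.array([p.temperature for p in usable])
    if len(set(temps.tolist())) < 2:
        raise GrowthModelError("need >=2 sub-optimal points at distinct temperatures")
    y = np.array([p.mu for p in usable])
    y = np.sqrt(y) if sqrt_scale else y
    beta, intercept = np.polyfit(temps, y, 1)
    if beta <= 0:
        raise GrowthModelError("no thermally increasing regime (slope <= 0)")
    t_min = -intercept / beta
    b = beta**2 if sqrt_scale else beta
    return float(b), float(t_min)


def estimate_c(
    points: Sequence[GrowthRatePoint], b: float, t_min: float, t_max: float
) -> float:
    """c by algebraic inversion of the model on supra-optimal points.

    Each usable point (t_min < T < t_max and mu < b*(T - t_min)**2) gives
    c_i = ln(1 - mu/(b*(T - t_min)**2)) / (T - t_max); the estimate is their
    mean.  Points violating the precondition are skipped.
    """
    values = []
    for p in points:
        span = p.temperature - t_min
        if not (t_min < p.temperature < t_max):
            continue
        ceiling = b * span * span
        if p.mu <= 0 or p.mu >= ceiling:
            continue
        values.append(math.log(1.0 - p.mu / ceiling) / (p.temperature - t_max))
    if not values:
        raise GrowthModelError("no usable supra-optimal point for c estimation")
    return float(np.mean(values))


def ratkowsky_mu(fit: RatkowskyFit, temperature):
    """Model growth rate; 0 outside [t_min, t_max].  Accepts arrays."""
    t = np.asarray(temperature, dtype=float)
    inside = (t >= fit.t_min) & (t <= fit.t_max)
    span = np.where(inside, t - fit.t_min, 0.0)
    mu = fit.b * span**2 * (1.0 - np.exp(fit.c * np.minimum(t - fit.t_max, 0.0)))
    mu = np.where(inside, mu, 0.0)
    return float(mu) if np.isscalar(temperature) else mu


def _golden_section(f: Callable[[float], float], lo: float, hi: float, xtol: float):
    """Minimize a unimodal scalar function on [lo, hi]."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    f1, f2 = f(x1), f(x2)
    while (b - a) > xtol:
        if f1 <= f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - invphi * (b - a)
            f1 = f(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + invphi * (b - a)
            f2 = f(x2)
    return (a + b) / 2.0


def fit_ratkowsky(
    points: Sequence[GrowthRatePoint],
    bracket_width: float = 15.0,
    xtol: float = 1e-6,
    grid_step: float = 0.1,
    sqrt_scale: bool = True,
    max_iter: int = 12,
) -> RatkowskyFit:
    """Fit the modified Ratkowsky model to growth-rate points.

    Requires at least 4 points spanning both sides of the observed optimum.
    ``t_max`` is searched on [T_opt, T_opt + bracket_width]: a coarse grid
    scan (``grid_step``) locates the SSE basin — the profile can be
    non-unimodal while the linear-stage parameters are still biased — and
    golden section refines within it to ``xtol``.  See the module docstring
    for the staged estimation scheme.
    """
    if len(points) < 4:
        raise GrowthModelError("need >=4 growth-rate points to fit")
    temps = np.array([p.temperature for p in points])
    mus = np.array([p.mu for p in points])
    t_opt = float(temps[int(np.argmax(mus))])
    sub = [p for p in points if p.temperature < t_opt]
    supra = [p for p in points if p.temperature >= t_opt]
    if len({p.temperature for p in sub}) < 2 or not supra:
        raise GrowthModelError("points must span both sides of the observed optimum")

    b, t_min = estimate_linear(sub, sqrt_scale=sqrt_scale)

    def sse_for(b_, t_min_, c_, t_max_) -> float:
        fit = RatkowskyFit(b_, c_, t_min_, t_max_, 0.0, len(sub), len(supra))
        resid = mus - ratkowsky_mu(fit, temps)
        return float(resid @ resid)

    best = None
    for _ in range(max_iter):
        def objective(t_max_cand: float) -> float:
            try:
                c_cand = estimate_c(supra, b, t_min, t_max_cand)
            except GrowthModelError:
                return math.inf
            if c_cand <= 0:
                return math.inf
            return sse_for(b, t_min, c_cand, t_max_cand)

        lo, hi = t_opt + 1e-9, t_opt + bracket_width
        grid = np.arange(lo, hi, grid_step)
        grid_vals = [objective(g) for g in grid]
        gi = int(np.argmin(grid_vals))
        if not math.isfinite(grid_vals[gi]):
            raise GrowthModelError("t_max search bracket exhausted")
        t_max = _golden_section(
            objective,
            max(lo, grid[gi] - grid_step),
            min(hi, grid[gi] + grid_step),
            xtol,
        )
        if not math.isfinite(objective(t_max)):
            t_max = float(grid[gi])
        c = estimate_c(supra, b, t_min, t_max)
        # correct sub-optimal rates for high-temperature suppression, refit
        corrected = []
        for p in sub:
            factor = 1.0 - math.exp(c * (p.temperature - t_max))
            if factor <= 0:
                continue
            corrected.append(
                GrowthRatePoint(p.temperature, p.mu / factor, p.n_readings,
                                p.few_readings)
            )
        try:
            b_new, t_min_new = estimate_linear(corrected, sqrt_scale=sqrt_scale)
        except GrowthModelError:
            b_new, t_min_new = b, t_min
        converged = (
            abs(b_new - b) < 1e-9 * max(b, 1e-12)
            and abs(t_min_new - t_min) < 1e-7
        )
        b, t_min = b_new, t_min_new
        best = RatkowskyFit(
            b=b, c=c, t_min=t_min, t_max=t_max,
            sse=sse_for(b, t_min, c, t_max),
            n_points_linear=len(sub), n_points_supra=len(supra),
        )
        if converged:
            break
    return _polish(best, temps, mus, t_opt, bracket_width)


def _polish(
    fit: RatkowskyFit, temps: np.ndarray, mus: np.ndarray,
    t_opt: float, bracket_width: float,
) -> RatkowskyFit:
    """Joint least-squares refinement of (b, c, t_min, t_max).

    The staged estimator converges only geometrically when the
    high-temperature suppression is strong (small c); a short Levenberg-
    style polish from its output removes that residual bias.  The refined
    fit is kept only if it lowers the SSE.
    """
    from scipy.optimize import least_squares

    lo_t = float(np.min(temps))

    def residual(x):
        b, c, t_min, t_max = x
        f = RatkowskyFit(b, c, t_min, t_max, 0.0, fit.n_points_linear,
                         fit.n_points_supra)
        return mus - ratkowsky_mu(f, temps)

    x0 = np.array([fit.b, fit.c, fit.t_min, fit.t_max])
    bounds = (
        [1e-12, 1e-12, -1e3, t_opt + 1e-9],
        [np.inf, np.inf, lo_t - 1e-9, t_opt + bracket_width],
    )
    x0 = np.clip(x0, bounds[0], bounds[1])
    try:
        sol = least_squares(residual, x0, bounds=bounds, xtol=1e-15,
                            ftol=1e-15, gtol=1e-15, max_nfev=500)
    except Exception:
        return fit
    sse = float(sol.fun @ sol.fun)
    if not sol.success or sse >= fit.sse:
        return fit
    b, c, t_min, t_max = (float(v) for v in sol.x)
    return RatkowskyFit(b, c, t_min, t_max, sse,
                        fit.n_points_linear, fit.n_points_supra)


# ---------------------------------------------------------------------------
# maximum tolerated temperature

def series_plateau_provider(series: ODTimeSeries) -> Callable[[float], ODTimeSeries]:
    """Adapt a recorded OD series to the provider protocol.

    The returned callable yields the sub-series held at the requested
    temperature; requesting a temperature that was never held raises.
    """

    def provider(temp: float) -> ODTimeSeries:
        sub = series.at_temperature(temp)
        if not sub.readings:
            raise GrowthModelError(
                f"strain {series.strain_id!r}: no plateau recorded at {temp} degC"
            )
        return sub

    return provider


def determine_max_tolerated_temperature(
    series_provider: Callable[[float], ODTimeSeries],
    protocol: RampProtocol,
    max_steps: int = 500,
) -> float:
    """Largest grid temperature still allowing stable growth.

    Starting at ``protocol.start_temp`` the temperature is raised in
    ``step_grid`` increments; at each step the provider is asked for an OD
    series held at that temperature for the stability window, and the mean
    growth rate over the window is compared with the stability threshold
    (with threshold 0, any strictly positive growth counts).  The previous
    temperature still allowing stable growth is returned; instability at the
    starting temperature is an error.
    """

    def stable(temp: float) -> bool:
        series = series_provider(temp)
        mu = compute_growth_rate(series, temp).mu
        if protocol.stability_threshold > 0:
            return mu >= protocol.stability_threshold
        return mu > 0

    temp = protocol.start_temp
    if not stable(temp):
        raise GrowthModelError(
            f"culture not viable at starting temperature {temp} degC"
        )
    for step in range(1, max_steps + 1):
        candidate = round(protocol.start_temp + step * protocol.step_grid, 6)
        try:
            ok = stable(candidate)
        except GrowthModelError:
            ok = False
        if not ok:
            return round(protocol.start_temp + (step - 1) * protocol.step_grid, 6)
        temp = candidate
    warnings.warn("ramp exhausted max_steps without losing stability")
    return temp
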