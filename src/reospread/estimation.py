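"""Kinetic parameter estimation from plaque-assay and binding-assay data.

Every parameter of the spread models is estimated here from small tabular
assay data: the binding rate from 1-hour percent-bound replicates, the
virion diffusion coefficient from a 120-hour diffusion-column profile (and
independently from the Stokes-Einstein relation), the infected-cell death
rate from percent-cell-death time courses, and the infectious burst size as
the carrying capacity of a logistic fit to per-cell virion production.

Units are canonical throughout: mm, hours, virions.  Percent inputs are
converted to fractions on entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import constants, optimize, special

from .params import VirusParams

__all__ = [
    "BindingAssay",
    "DiffusionColumnProfile",
    "TimeSeries",
    "EstimateWithCI",
    "StokesEinsteinInput",
    "ReplicationNumber",
    "estimate_binding_rate",
    "half_life",
    "fit_diffusion_profile",
    "stokes_einstein",
    "fit_death_rate",
    "fit_burst_logistic",
    "viral_replication_number",
]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingAssay:
    """Replicated 1-hour binding assay: fraction of virions bound per replicate.

    ``bound_fractions`` must lie strictly inside (0, 1); a fraction of
    exactly 0 or 1 makes the log estimator degenerate and is rejected.
    """

    bound_fractions: tuple
    assay_duration: float = 1.0  # hours

    def __post_init__(self) -> None:
        object.__setattr__(self, "bound_fractions",
                           tuple(float(y) for y in self.bound_fractions))
        if len(self.bound_fractions) == 0:
            raise ValueError("binding assay needs at least one replicate")
        if self.assay_duration <= 0:
            raise ValueError("assay_duration must be positive")
        for i, y in enumerate(self.bound_fractions):
            if not (0.0 < y < 1.0):
                raise ValueError(
                    f"replicate {i}: bound fraction {y!r} outside (0, 1)")

    @classmethod
    def from_percents(cls, percents: Sequence[float],
                      assay_duration: float = 1.0) -> "BindingAssay":
        return cls(tuple(p / 100.0 for p in percents), assay_duration)


@dataclass(frozen=True)
class DiffusionColumnProfile:
    """Virus mass per fraction of a diffusion column after ``elapsed`` hours.

    The column is divided into equal fractions; ``fraction_centers`` are
    distances (mm) of the fraction midpoints from the inoculation end and
    ``percents`` the percentage of total virions recovered per fraction.
    """

    fraction_centers: tuple
    percents: tuple
    fraction_width: float = 5.5  # mm
    elapsed: float = 120.0       # hours

    def __post_init__(self) -> None:
        object.__setattr__(self, "fraction_centers",
                           tuple(float(x) for x in self.fraction_centers))
        object.__setattr__(self, "percents",
                           tuple(float(p) for p in self.percents))
        if len(self.fraction_centers) != len(self.percents):
            raise ValueError("centers and percents must have equal length")
        centers = np.asarray(self.fraction_centers)
        if np.any(np.diff(centers) <= 0):
            raise ValueError("fraction centers must be strictly increasing")
        if any(p < 0 for p in self.percents):
            raise ValueError("percents must be non-negative")
        if sum(self.percents) > 100.0 + 1e-9:
            raise ValueError("percents must sum to at most 100")
        if self.fraction_width <= 0 or self.elapsed <= 0:
            raise ValueError("fraction_width and elapsed must be positive")


@dataclass(frozen=True)
class TimeSeries:
    """A measured time course; repeated time points encode replicates."""

    times: tuple
    values: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if any(t < 0 for t in self.times):
            raise ValueError("times must be non-negative")


@dataclass(frozen=True)
class EstimateWithCI:
    """A point estimate with an optional interval and a method tag."""

    point: float
    lower: Optional[float] = None
    upper: Optional[float] = None
    method: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None:
            if not (self.lower <= self.point <= self.upper):
                raise ValueError("interval must bracket the point estimate")


@dataclass(frozen=True)
class StokesEinsteinInput:
    """Inputs to the Stokes-Einstein diffusion relation (SI units)."""

    temperature: float      # kelvin
    viscosity: float        # Pa*s
    particle_radius: float  # metres

    def __post_init__(self) -> None:
        for name in ("temperature", "viscosity", "particle_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ReplicationNumber:
    """Viral replication number with its die-out classification."""

    value: float
    dies_out: bool


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def estimate_binding_rate(assay: BindingAssay) -> EstimateWithCI:
    """Estimate the binding rate from replicated bound fractions.

    Under the linear binding law ``V(t) = V0 exp(-gamma_b t)`` the fraction
    bound after time t is ``y = 1 - exp(-gamma_b t)``.  The maximum-
    likelihood pooling of k replicates averages the surviving (unbound)
    fractions before taking the log:

        gamma_b = -(1/t) * ln( (1/k) * sum_i (1 - y_i) )

    Returns the rate in 1/hour with an asymptotic-normal interval obtained
    by the delta method from the replicate scatter (point ± 1.96 se;
    degenerate for a single replicate).
    """
    y = np.asarray(assay.bound_fractions)
    t = assay.assay_duration
    surviving = 1.0 - y
    m = surviving.mean()
    point = -math.log(m) / t
    lower = upper = None
    if y.size >= 2:
        se_m = surviving.std(ddof=1) / math.sqrt(y.size)
        se = se_m / (m * t)
        lower, upper = point - 1.96 * se, point + 1.96 * se
    return EstimateWithCI(point=point, lower=lower, upper=upper,
                          method="log-mean-complement; delta-method normal CI")


def half_life(gamma_b: float) -> float:
    """Binding half-life ln(2)/gamma_b, hours."""
    if gamma_b <= 0:
        raise ValueError(f"gamma_b must be positive, got {gamma_b!r}")
    return math.log(2) / gamma_b


def _gaussian_fraction_model(x: np.ndarray, D_V: float, V0: float,
                             t: float, width: float) -> np.ndarray:
    """Percent of V0 per fraction: the 1-D diffusion Gaussian
    ``V0/sqrt(4 pi D t) exp(-x^2/(4 D t))`` integrated exactly over each
    fraction [x - w/2, x + w/2]."""
    sigma = math.sqrt(2.0 * D_V * t)
    lo = (x - width / 2.0) / (sigma * math.sqrt(2.0))
    hi = (x + width / 2.0) / (sigma * math.sqrt(2.0))
    return V0 * 0.5 * (special.erf(hi) - special.erf(lo))


def fit_diffusion_profile(profile: DiffusionColumnProfile
                          ) -> tuple[float, float, float]:
    """Fit the 1-D diffusion Gaussian to a column-fraction profile.

    The model for a fraction centred at x is the Gaussian point density
    ``V0/sqrt(4 pi D t) * exp(-x^2/(4 D t))`` integrated exactly over the
    fraction (the fractions are wide relative to the diffusion length
    sqrt(2 D t), so a midpoint-times-width approximation would distort
    the first fraction badly).  Returns ``(D_V, V0, rss)`` where D_V is
    in mm^2/hour, V0 the inoculum in percent-normalized units, and rss
    the residual sum of squares.

    Initial guesses come from the method of moments (the mass-weighted
    second moment of a half-line Gaussian is 2*D*t); a small deterministic
    multistart over scaled D guesses avoids local minima.
    """
    x = np.asarray(profile.fraction_centers)
    p = np.asarray(profile.percents)
    if x.size < 3:
        raise ValueError("need at least 3 fractions to fit the profile")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero profile: nothing to fit")
    t, width = profile.elapsed, profile.fraction_width

    # half-line second moment: E[x^2] = 2 D t for a Gaussian centred at 0
    d0 = max(float((p * x ** 2).sum() / total / (2 * t)), 1e-8)
    v0_0 = total

    best = None
    for scale in (0.3, 1.0, 3.0):
        try:
            popt, _ = optimize.curve_fit(
                lambda xx, d, v: _gaussian_fraction_model(xx, d, v, t, width),
                x, p, p0=[d0 * scale, v0_0],
                bounds=([1e-12, 0.0], [np.inf, np.inf]), maxfev=20000)
        except RuntimeError:
            continue
        rss = float(np.sum((p - _gaussian_fraction_model(
            x, popt[0], popt[1], t, width)) ** 2))
        if best is None or rss < best[2]:
            best = (float(popt[0]), float(popt[1]), rss)
    if best is None:
        raise RuntimeError(
            "diffusion-profile fit did not converge from any start "
            f"(moment initial guess D={d0:.3g})")
    return best


def stokes_einstein(inp: StokesEinsteinInput) -> float:
    """Stokes-Einstein diffusion coefficient, converted to mm^2/hour.

    D = k_B T / (6 pi eta r) for a spherical particle of radius r in a
    fluid of dynamic viscosity eta at absolute temperature T.
    """
    d_si = constants.k * inp.temperature / (
        6 * math.pi * inp.viscosity * inp.particle_radius)  # m^2/s
    return d_si * 1e6 * 3600.0  # -> mm^2/hour


def _death_model(t: np.ndarray, alpha: float, onset: float) -> np.ndarray:
    return 1.0 - np.exp(-alpha * np.maximum(t - onset, 0.0))


def fit_death_rate(series: TimeSeries, onset: float = 0.0,
                   values_are_percent: bool = False) -> EstimateWithCI:
    """Fit the infected-cell death rate alpha from a cell-death time course.

    The dead-cell proportion is modelled as a delayed saturating
    exponential ``D_I(t) = 1 - exp(-alpha * max(t - onset, 0))``: cells
    only begin to die ``onset`` hours after inoculation (the eclipse phase
    before lysis), after which mortality is first-order at rate alpha.
    With ``onset=0`` this is the plain exponential-survival fit.

    Returns alpha in 1/hour with an asymptotic-normal interval and the fit
    R^2 in ``extras``.
    """
    if onset < 0:
        raise ValueError("onset must be non-negative")
    t = np.asarray(series.times)
    d = np.asarray(series.values, dtype=float)
    if values_are_percent:
        d = d / 100.0
    if np.any((d < 0) | (d > 1)):
        raise ValueError("death values must be fractions in [0, 1] "
                         "(or percents with values_are_percent=True)")
    if np.count_nonzero(t > onset) < 1:
        raise ValueError("need at least one time point past the onset")

    popt, pcov = optimize.curve_fit(
        lambda tt, a: _death_model(tt, a, onset), t, d,
        p0=[0.05], bounds=(1e-12, np.inf), maxfev=20000)
    alpha = float(popt[0])
    resid = d - _death_model(t, alpha, onset)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else None
    lower = upper = None
    if se is not None:
        lower, upper = alpha - 1.96 * se, alpha + 1.96 * se
    return EstimateWithCI(point=alpha, lower=lower, upper=upper,
                          method=f"delayed exponential fit (onset={onset} h)",
                          extras={"r_squared": r2, "onset": onset})


def _log_logistic(t: np.ndarray, log_k: float, rho: float, t_mid: float
                  ) -> np.ndarray:
    """log of K / (1 + exp(-rho (t - t_mid))), numerically stable."""
    return log_k - np.log1p(np.exp(-rho * (t - t_mid)))


def fit_burst_logistic(series: TimeSeries) -> dict:
    """Fit a logistic growth curve to a virion-production time course.

    The burst size is read off as the carrying capacity K of
    ``K / (1 + exp(-rho (t - t_mid)))``.  Virion counts span orders of
    magnitude with multiplicative scatter, so the curve is fitted to the
    log counts (the maximum-likelihood choice under lognormal noise);
    this also keeps K positive by construction.  K is additionally
    bounded to a generous window around the observed maximum: a series
    that never saturates cannot identify a carrying capacity, and an
    unbounded fit on such data runs away.  Zero counts (pre-release time
    points) are excluded from the fit.

    Returns a dict with keys ``carrying_capacity`` (virions/cell),
    ``growth_rate`` (1/hour), ``midpoint`` (hours) and ``r_squared``
    (coefficient of determination on the log scale).
    """
    t_all = np.asarray(series.times)
    v_all = np.asarray(series.values, dtype=float)
    if t_all.size < 4:
        raise ValueError("need at least 4 points for a logistic fit")
    mask = v_all > 0
    t, v = t_all[mask], v_all[mask]
    if t.size < 4:
        raise ValueError("need at least 4 positive counts to fit")
    logv = np.log(v)

    k0 = v.max()
    above = t[v >= k0 / 2.0]
    tm0 = float(above.min()) if above.size else float(np.median(t))
    span = max(t.max() - t.min(), 1.0)
    bounds = ([math.log(k0 / 10.0), 1e-3, t.min() - span],
              [math.log(k0 * 20.0), 100.0 / span, t.max() + span])

    best = None
    for rho0 in (2.0 / span, 10.0 / span, 40.0 / span):
        try:
            popt, _ = optimize.curve_fit(
                _log_logistic, t, logv, p0=[math.log(k0), rho0, tm0],
                bounds=bounds, maxfev=40000)
        except RuntimeError:
            continue
        rss = float(np.sum((logv - _log_logistic(t, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise RuntimeError("logistic burst-size fit did not converge")
    popt, rss = best
    ss_tot = float(np.sum((logv - logv.mean()) ** 2))
    return {
        "carrying_capacity": float(np.exp(popt[0])),
        "growth_rate": float(popt[1]),
        "midpoint": float(popt[2]),
        "r_squared": 1.0 - rss / ss_tot if ss_tot > 0 else float("nan"),
    }


def viral_replication_number(p: VirusParams) -> ReplicationNumber:
    """Viral replication number R_V = b_tilde * nu.

    R_V is the mean number of newly infected cells produced per infected
    cell in an otherwise uninfected monolayer; it coincides with the
    det A = 0 threshold of the kinetic (diffusion-free) system, and the
    infection dies out when R_V < 1.
    """
    rv = p.R_V
    return ReplicationNumber(value=rv, dies_out=rv < 1.0)
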