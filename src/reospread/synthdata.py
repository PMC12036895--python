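"""Synthetic assay-data generators for estimator validation.

Each generator is the forward model of one estimator in
:mod:`reospread.estimation` or :mod:`reospread.front_validation`, plus a
noise model chosen to respect the support of the measured variable:

* bound fractions — logit-normal noise (stays strictly inside (0, 1));
* column-fraction virus mass — multiplicative lognormal noise (stays >= 0);
* percent cell death — additive Gaussian noise truncated to [0, 1];
* per-cell virion counts — multiplicative lognormal noise;
* fluorescence profiles — additive Gaussian noise on the normalized
  intensity, clipped at 0.

Every generator takes an integer ``seed`` and is byte-deterministic given
it, so parameter-recovery studies (generate with known truth, re-estimate,
compare) are reproducible.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special
from scipy.optimize import brentq

from .estimation import BindingAssay, DiffusionColumnProfile, TimeSeries
from .front_validation import FrontProfile

__all__ = [
    "gen_binding_assay",
    "gen_diffusion_fractions",
    "gen_death_series",
    "gen_burst_series",
    "gen_front_profile",
    "DEATH_ASSAY_TIMES",
    "BURST_ASSAY_TIMES",
]

#: Sampling design of the cell-death assay: hours post-infection, with
#: replicate multiplicity 1,1,3,2,2.
DEATH_ASSAY_TIMES = (15.0, 18.0, 24.0, 24.0, 24.0, 30.0, 30.0, 36.0, 36.0)

#: Sampling times of the virion-production (burst-size) assay, hours.
BURST_ASSAY_TIMES = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 24.0, 30.0, 36.0)


def _logit_normal_location(mean: float, sigma: float) -> float:
    """Location mu such that E[expit(mu + sigma Z)] equals ``mean``.

    A logit-normal centred (in logit space) on the target fraction has a
    different *mean* fraction — the expit is convex below 1/2 and concave
    above — which would bias recovery studies.  The correction is solved
    by Gauss-Hermite quadrature and bisection.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(40)
    weights = weights / weights.sum()

    def mean_of(mu: float) -> float:
        return float(weights @ special.expit(mu + sigma * nodes))

    lo, hi = special.logit(mean) - 5 * sigma, special.logit(mean) + 5 * sigma
    return float(brentq(lambda m: mean_of(m) - mean, lo, hi, xtol=1e-12))


def gen_binding_assay(gamma_b_true: float, t: float = 1.0, k: int = 3,
                      noise_sd: float = 0.0, seed: int = 0) -> BindingAssay:
    """k replicate bound fractions around 1 - exp(-gamma_b t).

    ``noise_sd`` is the standard deviation of Gaussian noise applied on
    the logit scale, so fractions remain strictly inside (0, 1).  The
    logit location is mean-corrected so the replicate fractions average
    to the forward-law value ``1 - exp(-gamma_b t)`` exactly.
    """
    if gamma_b_true <= 0 or t <= 0:
        raise ValueError("gamma_b_true and t must be positive")
    rng = np.random.default_rng(seed)
    mean = 1.0 - math.exp(-gamma_b_true * t)
    if noise_sd == 0:
        return BindingAssay((mean,) * k, assay_duration=t)
    mu = _logit_normal_location(mean, noise_sd)
    logits = mu + noise_sd * rng.standard_normal(k)
    return BindingAssay(tuple(special.expit(logits)), assay_duration=t)


def gen_diffusion_fractions(D_V: float, V0: float = 100.0, t: float = 120.0,
                            n_fractions: int = 8, width_mm: float = 5.5,
                            noise_sd: float = 0.0, seed: int = 0
                            ) -> DiffusionColumnProfile:
    """Percent of virus per column fraction from the 1-D diffusion Gaussian.

    The expected mass in each fraction is the Gaussian point density
    integrated exactly over the fraction (via erf), expressed as percent of
    V0; ``noise_sd`` applies multiplicative lognormal noise per fraction.
    The half-line column sees only x >= 0, so the noiseless percents sum
    to at most 50% of the full-line mass budget V0 — matching an assay
    where the inoculum sits at the closed end of the column.
    """
    rng = np.random.default_rng(seed)
    edges = np.arange(n_fractions + 1) * width_mm
    sigma = math.sqrt(2.0 * D_V * t)
    cdf = 0.5 * (1.0 + special.erf(edges / (sigma * math.sqrt(2.0))))
    mass = V0 * np.diff(cdf)  # exact Gaussian mass per fraction
    percents = 100.0 * mass / V0
    if noise_sd > 0:
        percents = percents * rng.lognormal(mean=0.0, sigma=noise_sd,
                                            size=n_fractions)
        total = percents.sum()
        if total > 100.0:  # keep the percent-of-total invariant
            percents *= 100.0 / total
    centers = (edges[:-1] + edges[1:]) / 2.0
    return DiffusionColumnProfile(tuple(centers), tuple(percents),
                                  fraction_width=width_mm, elapsed=t)


def gen_death_series(alpha: float, onset: float = 15.0,
                     times=DEATH_ASSAY_TIMES, noise_sd: float = 0.0,
                     seed: int = 0) -> TimeSeries:
    """Dead-cell fractions from the delayed exponential death model.

    Values are ``1 - exp(-alpha max(t - onset, 0))`` plus additive
    Gaussian noise, clamped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    d = 1.0 - np.exp(-alpha * np.maximum(t - onset, 0.0))
    if noise_sd > 0:
        d = np.clip(d + noise_sd * rng.standard_normal(t.size), 0.0, 1.0)
    return TimeSeries(tuple(t), tuple(d))


def gen_burst_series(K: float, rho: float = 0.3, t_mid: float = 18.0,
                     times=BURST_ASSAY_TIMES, noise_sd: float = 0.0,
                     seed: int = 0) -> TimeSeries:
    """Per-cell virion counts from the logistic production model.

    Mean trajectory ``K / (1 + exp(-rho (t - t_mid)))`` with multiplicative
    lognormal noise of log-sd ``noise_sd``.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    v = K / (1.0 + np.exp(-rho * (t - t_mid)))
    if noise_sd > 0:
        v = v * rng.lognormal(mean=0.0, sigma=noise_sd, size=t.size)
    return TimeSeries(tuple(t), tuple(v))


def gen_front_profile(lambda_px: float, s_px: float = 10.0, n_px: int = 100,
                      noise_sd: float = 0.0, seed: int = 0,
                      scale: float = 445.0, day: int = 0) -> FrontProfile:
    """Exponential fluorescence front sampled at integer pixel positions.

    Intensity ``exp(-lambda_px (x - s_px))`` at pixels x = 0..n_px-1 with
    additive Gaussian noise of sd ``noise_sd`` (on the normalized scale),
    clipped at zero so intensities stay physical.
    """
    rng = np.random.default_rng(seed)
    x = np.arange(n_px, dtype=float)
    f = np.exp(-lambda_px * (x - s_px))
    if noise_sd > 0:
        f = np.maximum(f + noise_sd * rng.standard_normal(n_px), 0.0)
    return FrontProfile(tuple(x), tuple(f), scale=scale, day=day)
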