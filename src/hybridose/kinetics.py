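"""Mono-exponential pharmacokinetics and absolute-scale rescaling.

The relative planar time-activity data A_rel(t) of each source region are
fit with

    A_rel(t) = a * exp(-ln(2) t / T_eff)

by weighted least squares (weights 1/sigma^2 from Poisson propagation; the
nonlinear fit runs in linear space so the weights retain their meaning,
initialized from the weighted log-linear closed form).  The effective
half-life combines physical decay and biological clearance as parallel
first-order processes, 1/T_eff = 1/T_phys + 1/T_bio.  The fitted relative
curve is rescaled to absolute activity by matching its value at the SPECT
time to the SPECT-measured activity.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import LN2, RE188, NuclideConstants, RegionLabel
from .planar import RelativeTAC
from .spect import AbsoluteActivityMeasurement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpFitResult:
    """Amplitude and effective half-life of a mono-exponential fit."""

    amplitude: float
    half_life_h: float
    covariance: np.ndarray | None
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.half_life_h <= 0:
            raise ValueError("amplitude and half-life must be positive")
        if self.r_squared > 1 + 1e-9:
            raise ValueError("R^2 cannot exceed 1")

    def predict(self, time_h):
        return self.amplitude * np.exp(-LN2 * np.asarray(time_h, dtype=float) / self.half_life_h)


def _two_point_fit(t: np.ndarray, y: np.ndarray) -> ExpFitResult:
    if y[1] >= y[0]:
        raise ValueError("non-decaying data: two-point fit requires y2 < y1")
    half_life = LN2 * (t[1] - t[0]) / math.log(y[0] / y[1])
    amplitude = y[0] * math.exp(LN2 * t[0] / half_life)
    return ExpFitResult(
        amplitude=float(amplitude),
        half_life_h=float(half_life),
        covariance=None,
        r_squared=1.0,
        n_points=2,
    )


def fit_monoexponential(
    times_h,
    values,
    sigmas=None,
) -> ExpFitResult:
    """Weighted least-squares mono-exponential fit.

    With two samples the fit is the exact closed form (R^2 = 1 by
    construction).  With three or more, a nonlinear fit in linear space is
    used (equal weights when ``sigmas`` is None).  Raises for constant or
    non-decaying data, for which the half-life is unidentifiable or
    non-positive.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 2 or t.size != y.size:
        raise ValueError("at least two (time, value) samples are required")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(y <= 0):
        raise ValueError("values must be positive")
    if t.size == 2:
        return _two_point_fit(t, y)
    if np.all(y == y[0]):
        raise ValueError("constant data: half-life is unbounded")

    sig = None if sigmas is None else np.asarray(sigmas, dtype=float)
    w = np.ones_like(y) if sig is None else 1.0 / sig**2

    # weighted log-linear closed form as initializer
    lw = w * y**2
    ly = np.log(y)
    tm = np.average(t, weights=lw)
    lym = np.average(ly, weights=lw)
    denom = np.average((t - tm) ** 2, weights=lw)
    slope = np.average((t - tm) * (ly - lym), weights=lw) / denom
    if slope >= 0:
        raise ValueError("non-decaying data: fitted half-life would be non-positive")
    t0 = -LN2 / slope
    a0 = math.exp(lym - slope * tm)

    def model(tt, a, half_life):
        return a * np.exp(-LN2 * tt / half_life)

    popt, pcov = curve_fit(
        model,
        t,
        y,
        p0=(a0, t0),
        sigma=sig,
        absolute_sigma=sig is not None,
        bounds=((0.0, 1e-9), (np.inf, np.inf)),
        maxfev=10000,
    )
    resid = y - model(t, *popt)
    ss_res = float((w * resid**2).sum())
    ss_tot = float((w * (y - np.average(y, weights=w)) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ExpFitResult(
        amplitude=float(popt[0]),
        half_life_h=float(popt[1]),
        covariance=pcov,
        r_squared=r2,
        n_points=int(t.size),
    )


def fit_tac(tac: RelativeTAC, weighted: bool = True) -> ExpFitResult:
    """Fit a relative TAC, using its Poisson-propagated uncertainties."""
    return fit_monoexponential(tac.times, tac.rates, tac.sigmas if weighted else None)


def effective_to_biological(
    effective_half_life_h: float, constants: NuclideConstants = RE188
) -> float:
    """Biological half-life from 1/T_eff = 1/T_phys + 1/T_bio.

    Returns +inf when T_eff equals T_phys (no biological clearance).  An
    effective half-life above the physical one is unphysical for a closed
    system and raises rather than being silently clipped.
    """
    t_phys = constants.physical_half_life_h
    if effective_half_life_h <= 0:
        raise ValueError("effective half-life must be positive")
    if effective_half_life_h > t_phys * (1.0 + 1e-12):
        raise ValueError(
            f"effective half-life {effective_half_life_h:.3g} h exceeds the "
            f"physical half-life {t_phys:.3g} h"
        )
    rate = 1.0 / effective_half_life_h - 1.0 / t_phys
    return math.inf if rate <= 0 else 1.0 / rate


def biological_to_effective(
    biological_half_life_h: float, constants: NuclideConstants = RE188
) -> float:
    """Inverse of :func:`effective_to_biological` (T_bio = inf -> T_phys)."""
    if biological_half_life_h <= 0:
        raise ValueError("biological half-life must be positive")
    if math.isinf(biological_half_life_h):
        return constants.physical_half_life_h
    return 1.0 / (1.0 / biological_half_life_h + 1.0 / constants.physical_half_life_h)


@dataclass(frozen=True)
class AbsoluteTAC:
    """Fitted exponential rescaled to absolute activity (MBq).

    The curve satisfies A(t1) = SPECT activity by construction; its shape
    is identical to the fitted relative exponential.
    """

    region: RegionLabel
    fit: ExpFitResult
    scale_MBq_per_rate: float
    reference_time_h: float
    reference_activity_MBq: float

    def activity_MBq(self, time_h):
        return self.scale_MBq_per_rate * self.fit.predict(time_h)

    def __call__(self, time_h):
        return self.activity_MBq(time_h)


def rescale_to_absolute(
    fit: ExpFitResult,
    rel_at_t1: float,
    spect: AbsoluteActivityMeasurement,
) -> AbsoluteTAC:
    """Anchor the fitted relative curve to the SPECT activity.

    ``rel_at_t1`` is the *fitted* relative value at the SPECT time (i.e.
    ``fit.predict(spect.time_h)``), not the raw first sample; passing the
    raw sample is the documented sensitivity variant.  A zero SPECT
    activity yields the zero function, flagged with a warning.
    """
    if rel_at_t1 <= 0:
        raise ValueError("relative value at t1 must be positive")
    if spect.activity_MBq == 0:
        warnings.warn(
            f"zero SPECT activity for {spect.region.name}: absolute TAC is zero",
            stacklevel=2,
        )
    return AbsoluteTAC(
        region=spect.region,
        fit=fit,
        scale_MBq_per_rate=spect.activity_MBq / rel_at_t1,
        reference_time_h=spect.time_h,
        reference_activity_MBq=spect.activity_MBq,
    )
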