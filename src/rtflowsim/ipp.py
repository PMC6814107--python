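"""Image post-processing (IPP) lags: warping and image registration.

Both lags are elapsed-time delays (no staff resource is consumed),
modeled as lognormal variables moment-matched to an observed mean and
standard deviation in days: for target moments ``(m, s)`` the underlying
normal has sigma^2 = ln(1 + (s/m)^2) and mu = ln(m) - sigma^2/2, so the
generated delays recover the observed moments exactly in expectation.
"""

from __future__ import annotations

import math

import numpy as np

from .config import ConfigError, IPPConfig
from .des import MINUTES_PER_DAY

__all__ = ["lognormal_params", "draw_lognormal_days", "apply_ipp_delays",
           "sample_ipp_delay_minutes"]


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the underlying normal for given arithmetic moments."""
    if mean <= 0:
        raise ConfigError(f"lognormal mean must be positive, got {mean}")
    if sd < 0:
        raise ConfigError(f"lognormal sd must be non-negative, got {sd}")
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def draw_lognormal_days(mean: float, sd: float, rng: np.random.Generator,
                        size=None):
    mu, sigma = lognormal_params(mean, sd)
    if sigma == 0.0:
        return np.full(size, mean) if size is not None else mean
    return rng.lognormal(mu, sigma, size=size)


def apply_ipp_delays(
    last_scan_time: int,
    *,
    needs_warping: bool,
    needs_image_registration: bool,
    ipp: IPPConfig,
    rng: np.random.Generator,
) -> int:
    """Ready-for-contouring time after the image post-processing lags.

    ready = last scan end + warping lag (if flagged) + registration lag
    (if flagged); each lag is drawn in days and converted to whole
    minutes.  With neither flag the patient is ready immediately.
    """
    t = int(last_scan_time)
    if needs_warping:
        d = draw_lognormal_days(ipp.warp_mean_days, ipp.warp_sd_days, rng)
        t += int(round(float(d) * MINUTES_PER_DAY))
    if needs_image_registration:
        d = draw_lognormal_days(ipp.reg_mean_days, ipp.reg_sd_days, rng)
        t += int(round(float(d) * MINUTES_PER_DAY))
    return t


def sample_ipp_delay_minutes(patient, ipp: IPPConfig, rng: np.random.Generator) -> int:
    """Total IPP lag in minutes for a patient (0 if no IPP step flagged)."""
    ready = apply_ipp_delays(
        0,
        needs_warping=patient.needs_warping,
        needs_image_registration=patient.needs_image_registration,
        ipp=ipp,
        rng=rng,
    )
    return ready
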