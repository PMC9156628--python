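"""Relaxed-selection null expectations for sex-biased genes in haplodiploids.

The core mapping is the classical relative fixation rate for a semidominant
mutation with scaled selection strength g: omega(g) = g / (1 - exp(-g)),
continuous at g = 0 with omega(0) = 1. Each gene class sees an effective
g = exposure * gamma, where the exposure coefficient captures the fraction
of selection experienced by the class: constitutive genes have exposure 1,
sex-limited genes half of that (selection acts in only one sex), and genes
under postcopulatory sexual selection an exposure that grows with the
harmonic mean number of mates per female, H.

The inverse map recovers gamma = 2*Ne*s from an observed dN/dS of a
reference class, which then yields the null-expected dN/dS of the relaxed
classes. The polymorphism-side expectation is the simple two-fold rule:
sex-biased Pn/Ps (or piNS/piS) is expected to be twice the constitutive
value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.optimize import brentq

from .errors import ValidationError

_G_OVERFLOW = 700.0


def _omega_raw(g: float) -> float:
    if g == 0.0:
        return 1.0
    if g > _G_OVERFLOW:
        return g
    if g < -_G_OVERFLOW:
        return 0.0
    return g / (1.0 - math.exp(-g))


def omega_from_gamma(gamma: float, exposure: float = 1.0) -> float:
    """Expected dN/dS for scaled selection gamma seen at the given exposure."""
    if not 0 < exposure <= 1:
        raise ValidationError("exposure must lie in (0, 1]")
    return _omega_raw(exposure * gamma)


def gamma_from_omega(omega_obs: float, exposure: float = 1.0) -> float:
    """Numerically invert omega_from_gamma for an observed dN/dS."""
    if omega_obs <= 0:
        raise ValidationError("omega_obs must be > 0")
    if not 0 < exposure <= 1:
        raise ValidationError("exposure must lie in (0, 1]")
    if omega_obs == 1.0:
        return 0.0
    g_hat = brentq(lambda g: _omega_raw(g) - omega_obs, -1e3, 1e3, xtol=1e-12)
    return g_hat / exposure


def expected_sex_biased_pnps(pnps_constitutive: float) -> float:
    """Two-fold relaxed-selection expectation for sex-biased Pn/Ps."""
    if pnps_constitutive < 0:
        raise ValidationError("Pn/Ps must be >= 0")
    return 2.0 * pnps_constitutive


def expected_sex_biased_omega(
    omega_constitutive: float, relax_factor: float = 0.5
) -> float:
    """Null-expected dN/dS of sex-biased genes given the constitutive value.

    Inverts the fixation-rate map at full exposure to get gamma, then
    re-evaluates it at exposure = relax_factor (default 1/2: selection seen
    in one sex only).
    """
    if omega_constitutive <= 0:
        raise ValidationError("omega_constitutive must be > 0")
    gamma_hat = gamma_from_omega(omega_constitutive, exposure=1.0)
    return omega_from_gamma(gamma_hat, exposure=relax_factor)


def harmonic_mean(mate_counts: Sequence[float]) -> float:
    """Harmonic mean number of mates per female."""
    if len(mate_counts) == 0:
        raise ValidationError("empty mate-count list")
    if any(x <= 0 for x in mate_counts):
        raise ValidationError("mate counts must be > 0")
    return len(mate_counts) / sum(1.0 / x for x in mate_counts)


def pcss_exposure(h: float, exposure_sex: float = 0.5) -> float:
    """Exposure of postcopulatory-sexual-selection genes: grows with H.

    Default form exposure_sex * H / (H + 1): strictly increasing in H and
    saturating at the sex-limited exposure as H grows, so PCSS expectations
    stay close to the sex-biased null.
    """
    if h < 1:
        raise ValidationError("H must be >= 1")
    if not 0 < exposure_sex <= 1:
        raise ValidationError("exposure_sex must lie in (0, 1]")
    return exposure_sex * h / (h + 1.0)


@dataclass
class ExpectationResult:
    gene_class: str
    expected_pnps: float
    expected_omega: float
    gamma_hat: float


def class_expectations(
    pnps_constitutive: float,
    omega_constitutive: float,
    relax_factor: float = 0.5,
    h: float = 13.984,
) -> list[ExpectationResult]:
    """Null expectations for the standard class set.

    H defaults to the honey-bee harmonic mean mate number.
    """
    gamma_hat = gamma_from_omega(omega_constitutive, exposure=1.0)
    sex_pnps = expected_sex_biased_pnps(pnps_constitutive)
    sex_omega = omega_from_gamma(gamma_hat, exposure=relax_factor)
    pcss_c = pcss_exposure(h, exposure_sex=relax_factor)
    return [
        ExpectationResult("constitutive", pnps_constitutive, omega_constitutive, gamma_hat),
        ExpectationResult("haploid_biased", sex_pnps, sex_omega, gamma_hat),
        ExpectationResult("diploid_biased", sex_pnps, sex_omega, gamma_hat),
        ExpectationResult("pcss", sex_pnps, omega_from_gamma(gamma_hat, exposure=pcss_c),
                          gamma_hat),
    ]
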