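"""Two-dimensional root-distribution kernels.

A kernel ``F(r)`` gives the probability *per unit ground area* of
encountering a unit of root mass at distance ``r`` (m) from a stem, so it
normalizes against the polar area element: ``integral of F(r) 2 pi r dr = 1``
over the support.  Six families are provided, all nonincreasing in ``r``
(``s`` denotes the effective distance scale, ``r_max`` a cutoff radius):

============================  ====================================================
family                        density F(r)
============================  ====================================================
``hyperbolic``                ``1 / (2 pi r_max r)`` on (0, r_max]
``inverse_power``             ``(p-1)(p-2) / (2 pi s^2) * (1 + r/s)^-p``
``exponential``               ``exp(-r/s) / (2 pi s^2)``
``gaussian``                  ``exp(-r^2/s^2) / (pi s^2)``
``linear_threshold``          ``3 / (pi r_max^2) * (1 - r/r_max)`` on [0, r_max]
``constant_threshold``        ``1 / (pi r_max^2)`` on [0, r_max]
============================  ====================================================

The distance scale may be constant (``s = alpha``) or a power function of
stem diameter ``z`` in cm (``s = alpha * z**theta``); ``theta = 0``
recovers the constant case exactly.  For the threshold families the single
distance parameter *is* the cutoff: when ``r_max`` is not given explicitly
it is taken as ``alpha * z**theta``, which lets the cutoff scale with stem
size under the same parameterization as the smooth families.  The
hyperbolic family is scale-free apart from its cutoff (density falls as
1/r regardless of stem size).

Supplying ``r_max`` to a smooth family truncates it there and renormalizes,
giving all families comparable support during model selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .errors import ConfigurationError

#: Cutoff radius (m) used when a family requires one and none was set.
#: Exceeds by a wide margin the stem-to-core distances over which root
#: attribution is informative in a 1-ha stand.
DEFAULT_R_MAX = 50.0

#: Hyperbolic densities are capped at their value at this radius (m); the
#: 1/r singularity is integrable, so point evaluations below EPS_R do not
#: affect any integral materially.
EPS_R = 1e-3


class KernelFamily(str, Enum):
    """Closed enumeration of the kernel families."""

    HYPERBOLIC = "hyperbolic"
    INVERSE_POWER = "inverse_power"
    EXPONENTIAL = "exponential"
    GAUSSIAN = "gaussian"
    LINEAR_THRESHOLD = "linear_threshold"
    CONSTANT_THRESHOLD = "constant_threshold"


#: Families whose support ends at r_max by construction.
THRESHOLD_FAMILIES = frozenset({
    KernelFamily.HYPERBOLIC,
    KernelFamily.LINEAR_THRESHOLD,
    KernelFamily.CONSTANT_THRESHOLD,
})

#: Enumeration order, used for deterministic tie-breaks in model selection.
FAMILY_ORDER = tuple(KernelFamily)


@dataclass(frozen=True)
class KernelParams:
    """Parameter block for one kernel.

    Attributes
    ----------
    alpha : float, optional
        Distance-scale parameter in m (cutoff radius for the threshold
        families when ``r_max`` is unset).
    theta : float
        Diameter exponent of the distance scale; 0 means the scale is the
        same for every stem.
    power : float, optional
        Tail exponent ``p`` of the inverse-power family; must exceed 2 for
        the density to integrate over the plane.
    r_max : float, optional
        Cutoff radius in m.  Required (directly or via ``alpha``) for the
        threshold families; optional truncation for the others.
    """

    alpha: float | None = None
    theta: float = 0.0
    power: float | None = None
    r_max: float | None = None

    def __post_init__(self):
        if self.alpha is not None and not self.alpha > 0:
            raise ConfigurationError("alpha must be > 0")
        if self.r_max is not None and not self.r_max > 0:
            raise ConfigurationError("r_max must be > 0")
        if self.power is not None and not self.power > 2:
            raise ConfigurationError(
                "inverse_power exponent must exceed 2 for integrability")


def effective_scale(params: KernelParams, z):
    """Distance scale ``alpha * z**theta`` in m for stem diameter ``z`` (cm).

    Returns ``alpha`` exactly when ``theta == 0``.  ``z`` may be a scalar or
    array; non-positive diameters raise.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ConfigurationError("stem diameter must be > 0")
    if params.alpha is None:
        raise ConfigurationError("kernel has no scale parameter alpha")
    if params.theta == 0:
        return params.alpha if z.ndim == 0 else np.full(z.shape, params.alpha)
    out = params.alpha * z ** params.theta
    return float(out) if z.ndim == 0 else out


def _cutoff(params: KernelParams, z, required: bool):
    """Resolve the cutoff radius, possibly diameter-dependent."""
    if params.r_max is not None:
        return params.r_max
    if params.alpha is not None:
        return effective_scale(params, z if z is not None else 1.0)
    if required:
        raise ConfigurationError(
            "this family requires r_max (or alpha as a scaling cutoff)")
    return None


def normalizer(family: KernelFamily, params: KernelParams, z=1.0) -> float:
    """Normalizing constant C of the family's density (untruncated form).

    C is the constant multiplying the unnormalized shape so that the
    product integrates to 1 over the plane (via the ``2 pi r`` area
    element).  Closed forms exist for every family.
    """
    family = KernelFamily(family)
    if family is KernelFamily.HYPERBOLIC:
        rm = _cutoff(params, z, required=True)
        return 1.0 / (2.0 * math.pi * float(np.max(np.asarray(rm))))
    if family is KernelFamily.LINEAR_THRESHOLD:
        rm = _cutoff(params, z, required=True)
        return 3.0 / (math.pi * float(np.max(np.asarray(rm))) ** 2)
    if family is KernelFamily.CONSTANT_THRESHOLD:
        rm = _cutoff(params, z, required=True)
        return 1.0 / (math.pi * float(np.max(np.asarray(rm))) ** 2)
    s = effective_scale(params, z)
    s = float(np.max(np.asarray(s)))
    if family is KernelFamily.EXPONENTIAL:
        return 1.0 / (2.0 * math.pi * s * s)
    if family is KernelFamily.GAUSSIAN:
        return 1.0 / (math.pi * s * s)
    if family is KernelFamily.INVERSE_POWER:
        if params.power is None:
            raise ConfigurationError("inverse_power requires a tail exponent")
        p = params.power
        return (p - 1.0) * (p - 2.0) / (2.0 * math.pi * s * s)
    raise ConfigurationError(f"unknown family {family!r}")


def mass_within(family: KernelFamily, params: KernelParams, radius, z=1.0):
    """Probability mass of the (untruncated) kernel inside ``radius``.

    Closed forms; used for truncation renormalization and as an
    integration cross-check.
    """
    family = KernelFamily(family)
    R = np.asarray(radius, dtype=float)
    if family in THRESHOLD_FAMILIES:
        rm = np.asarray(_cutoff(params, z, required=True), dtype=float)
        frac = np.clip(R / rm, 0.0, 1.0)
        if family is KernelFamily.HYPERBOLIC:
            out = frac
        elif family is KernelFamily.LINEAR_THRESHOLD:
            out = 3.0 * frac ** 2 - 2.0 * frac ** 3
        else:
            out = frac ** 2
        return float(out) if out.ndim == 0 else out
    s = np.asarray(effective_scale(params, z), dtype=float)
    u = R / s
    if family is KernelFamily.EXPONENTIAL:
        out = 1.0 - np.exp(-u) * (1.0 + u)
    elif family is KernelFamily.GAUSSIAN:
        out = 1.0 - np.exp(-u * u)
    elif family is KernelFamily.INVERSE_POWER:
        p = params.power
        if p is None:
            raise ConfigurationError("inverse_power requires a tail exponent")
        U = 1.0 + u
        out = 1.0 + (p - 2.0) * U ** (1.0 - p) - (p - 1.0) * U ** (2.0 - p)
    else:
        raise ConfigurationError(f"unknown family {family!r}")
    return float(out) if out.ndim == 0 else out


def kernel_pdf(family: KernelFamily, params: KernelParams, r, z=1.0):
    """Density per m^2 at distance ``r`` (m) from a stem of diameter ``z`` (cm).

    ``r`` and ``z`` broadcast against each other, so a (points x stems)
    distance matrix paired with a stem-diameter row vector evaluates in one
    call.  Nonnegative, nonincreasing in ``r``, zero beyond the cutoff for
    truncated configurations, and integrates to 1 over the support.
    """
    family = KernelFamily(family)
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0 and np.ndim(z) == 0

    if family in THRESHOLD_FAMILIES:
        rm = np.asarray(_cutoff(params, z, required=True), dtype=float)
        inside = r <= rm
        if family is KernelFamily.HYPERBOLIC:
            rr = np.maximum(r, EPS_R)  # integrable singularity cap
            out = np.where(inside, 1.0 / (2.0 * math.pi * rm * rr), 0.0)
        elif family is KernelFamily.LINEAR_THRESHOLD:
            out = np.where(
                inside, 3.0 / (math.pi * rm ** 2) * (1.0 - r / rm), 0.0)
        else:  # constant_threshold
            out = np.where(inside, 1.0 / (math.pi * rm ** 2) + 0.0 * r, 0.0)
        return float(out) if scalar else out

    s = np.asarray(effective_scale(params, z), dtype=float)
    if family is KernelFamily.EXPONENTIAL:
        out = np.exp(-r / s) / (2.0 * math.pi * s * s)
    elif family is KernelFamily.GAUSSIAN:
        out = np.exp(-(r / s) ** 2) / (math.pi * s * s)
    elif family is KernelFamily.INVERSE_POWER:
        p = params.power
        if p is None:
            raise ConfigurationError("inverse_power requires a tail exponent")
        out = ((p - 1.0) * (p - 2.0) / (2.0 * math.pi * s * s)
               * (1.0 + r / s) ** (-p))
    else:
        raise ConfigurationError(f"unknown family {family!r}")

    if params.r_max is not None:  # truncate and renormalize
        inside = r <= params.r_max
        out = np.where(inside, out, 0.0)
        out = out / mass_within(family, replace(params, r_max=None),
                                params.r_max, z)
    return float(out) if scalar else out


def required_r_max(family: KernelFamily) -> bool:
    """Whether the family needs a cutoff radius to be integrable."""
    return KernelFamily(family) in THRESHOLD_FAMILIES
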