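"""Gamma-Gompertz-Makeham (GGM) mortality model.

The Gompertz-Makeham hazard at adult age x (measured from a starting age,
so x = 0 at the fit's age origin) is

    mu(x) = a * exp(b*x) + c

with level ``a``, rate of senescence ``b`` and age-independent (Makeham)
background mortality ``c``.  Unobserved heterogeneity enters as a fixed
individual "frailty" multiplier z on the age-dependent part,

    mu(x, z) = z * a * exp(b*x) + c,

with Z gamma-distributed with mean 1 and variance ``gamma`` (shape 1/gamma,
scale gamma).  Integrating frailty out, and accounting for the within-cohort
selection of robust individuals, gives the sigmoid marginal hazard

    mu(x) = a*exp(b*x) / (1 + (a*gamma/b) * (exp(b*x) - 1)) + c,

whose age-dependent part is bounded above by b/gamma (the mortality
plateau).  This module holds the closed-form model mathematics and the
discretization of the frailty distribution into a finite number of classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GGMParams",
    "FrailtyDiscretization",
    "gm_hazard",
    "marginal_hazard",
    "discretize_frailty",
    "baseline_mortality_vector",
    "GAMMA_DEGENERACY_THRESHOLD",
    "DEFAULT_G",
    "DEFAULT_OMEGA",
    "DEFAULT_Q_MIN",
    "DEFAULT_Q_MAX",
]

#: Below this frailty variance the population is treated as homogeneous
#: (a single frailty class with z = 1).
GAMMA_DEGENERACY_THRESHOLD = 1e-5

#: Default number of frailty classes.
DEFAULT_G = 200

#: Default number of age classes in the matrix model.
DEFAULT_OMEGA = 150

#: Default cdf bounds for the frailty discretization grid.
DEFAULT_Q_MIN = 1e-5
DEFAULT_Q_MAX = 0.9999


@dataclass(frozen=True)
class GGMParams:
    """Parameters of the gamma-Gompertz-Makeham model.

    Parameters
    ----------
    a : float
        Baseline Gompertz hazard level at the starting age (per year, > 0).
    b : float
        Rate of exponential increase of the hazard with age (per year, > 0).
    c : float
        Makeham age-independent hazard component (per year, >= 0).
    gamma : float
        Variance of the mean-1 gamma frailty distribution (>= 0);
        0 means a homogeneous population.
    start_age : int
        Calendar age at which model age x = 0 (years).
    """

    a: float
    b: float
    c: float
    gamma: float
    start_age: int = 0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"a must be > 0, got {self.a}")
        if not self.b > 0:
            raise ValueError(f"b must be > 0, got {self.b}")
        if self.c < 0:
            raise ValueError(f"c must be >= 0, got {self.c}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.start_age < 0:
            raise ValueError(f"start_age must be >= 0, got {self.start_age}")


@dataclass(frozen=True)
class FrailtyDiscretization:
    """A finite mixture approximation of the mean-1 gamma frailty distribution.

    Attributes
    ----------
    z : ndarray
        Strictly increasing frailty values, all > 0.
    pi : ndarray
        Mixing weights (a probability vector); pi @ z == 1.
    """

    z: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "pi", pi)
        if z.ndim != 1 or pi.shape != z.shape:
            raise ValueError("z and pi must be 1-d arrays of equal length")
        if np.any(z <= 0) or np.any(np.diff(z) <= 0):
            raise ValueError("z must be strictly increasing and positive")
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must be a probability vector (sum 1 within 1e-12)")
        if abs(pi @ z - 1.0) > 1e-8:
            raise ValueError("frailty mean must equal 1 within 1e-8")

    @property
    def g(self) -> int:
        """Number of frailty classes."""
        return self.z.size

    @property
    def variance(self) -> float:
        """Variance of the discretized frailty distribution."""
        return float(self.pi @ self.z**2 - 1.0)


def gm_hazard(x, z, params: GGMParams):
    """Gompertz-Makeham hazard for an individual of frailty ``z`` at model age ``x``.

    Returns ``z * a * exp(b*x) + c``.  Accepts scalars or arrays
    (broadcasting); ages are model ages measured from ``params.start_age``.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(x < 0):
        raise ValueError("model age x must be >= 0")
    if np.any(z <= 0):
        raise ValueError("frailty z must be > 0")
    out = z * params.a * np.exp(params.b * x) + params.c
    return float(out) if out.ndim == 0 else out


def marginal_hazard(x, params: GGMParams):
    """Population (marginal) hazard at model age ``x`` after integrating out frailty.

    For gamma == 0 this reduces exactly to the homogeneous Gompertz-Makeham
    hazard.  The age-dependent part is monotone increasing and bounded by
    b/gamma, producing the mortality plateau at extreme ages.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("model age x must be >= 0")
    a, b, c, g = params.a, params.b, params.c, params.gamma
    if g == 0:
        out = a * np.exp(b * x) + c
    else:
        # Written to stay finite as exp(b*x) overflows: divide through.
        ebx = np.exp(b * x)
        denom = 1.0 + (a * g / b) * (ebx - 1.0)
        with np.errstate(over="ignore", invalid="ignore"):
            out = np.where(
                np.isinf(ebx),
                b / g + c,
                a * ebx / denom + c,
            )
    return float(out) if out.ndim == 0 else out


def baseline_mortality_vector(params: GGMParams, omega: int = DEFAULT_OMEGA) -> np.ndarray:
    """Baseline age-specific hazard levels ``a * exp(b*j)`` for j = 0..omega-1.

    This is the age-dependent part of the mortality schedule shared by all
    frailty classes; class i experiences ``z_i * mu0 + c``.
    """
    if omega < 1:
        raise ValueError(f"omega must be >= 1, got {omega}")
    return params.a * np.exp(params.b * np.arange(omega))


def discretize_frailty(
    gamma: float,
    g: int = DEFAULT_G,
    q_min: float = DEFAULT_Q_MIN,
    q_max: float = DEFAULT_Q_MAX,
) -> FrailtyDiscretization:
    """Discretize the mean-1 gamma frailty distribution into ``g`` classes.

    Nodes are log-spaced between the ``q_min`` and ``q_max`` quantiles of
    Gamma(shape=1/gamma, scale=gamma).  Each node receives the gamma-cdf
    probability mass of its bin, with bin edges at geometric midpoints
    between adjacent nodes and the first/last bins extended to 0 and
    infinity, so the weights sum to one by construction.  The node vector is
    then rescaled so the discretized mean is exactly 1, removing the small
    discretization bias that would otherwise shift the baseline hazard.

    If ``gamma`` is below :data:`GAMMA_DEGENERACY_THRESHOLD` the population
    is treated as homogeneous and a single class with z = 1 is returned.
    """
    if g < 1:
        raise ValueError(f"g must be >= 1, got {g}")
    if not (0.0 < q_min < q_max < 1.0):
        raise ValueError(f"require 0 < q_min < q_max < 1, got ({q_min}, {q_max})")
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")

    if gamma < GAMMA_DEGENERACY_THRESHOLD or g == 1:
        return FrailtyDiscretization(z=np.array([1.0]), pi=np.array([1.0]))

    dist = stats.gamma(a=1.0 / gamma, scale=gamma)
    z_min, z_max = dist.ppf([q_min, q_max])
    z = np.geomspace(z_min, z_max, g)

    # Bin edges: geometric midpoints, with open first/last bins.
    inner = np.sqrt(z[:-1] * z[1:])
    edges = np.concatenate(([0.0], inner, [np.inf]))
    cdf = dist.cdf(edges)
    pi = np.diff(cdf)
    pi /= pi.sum()  # guard against roundoff in the tails

    z = z / (pi @ z)  # enforce E(Z) = 1 exactly
    return FrailtyDiscretization(z=z, pi=pi)
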