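"""Enthalpy, CVM entropy, and reduced free energy.

The only energetic term is a pairwise interaction enthalpy ``eps``
charged to each unlike (A-B) nearest-neighbour pair; like pairs cost
nothing and there is no per-unit enthalpy.  Temperature and Boltzmann's
constant are subsumed into ``eps`` (k_B T = 1), and the working
parameter is ``h = exp(eps / 4)``: h = 1 is the non-interacting case,
h > 1 favours like-near-like ("ferromagnetic") order, h < 1 favours
alternation.

Entropy is the cluster-variation (Kikuchi) expression built from the
configuration-variable fractions through ``Lf(p) = p ln p - p``.
Per unit (reduced) free energies:

1-D zigzag chain::

    G = eps * (z2 + z3 + z4 + z5) - S,
    S = 2 sum_i beta_i Lf(y_i) - 2 sum_i gamma_i Lf(z_i)

2-D staggered grid::

    G = eps * (z2 + z3 + z4 + z5) - S,
    S = 2 sum beta Lf(y) + sum beta Lf(w) - sum Lf(x) - 2 sum gamma Lf(z)

The 2-D term signs are fixed so that the analytic 2-D equilibrium
solution is a stationary point of the functional (checked numerically;
at h = 1 this entropy is exactly ln 2 per unit, as a random equiprobable
lattice demands).  The 1-D normalisation gives S = 2 ln 2 at h = 1 — a
per-unit-vs-per-half-chain scale convention kept as such; fraction
values, stationary points and all comparisons are unaffected by it.

Lagrange-multiplier terms used in deriving stationarity are not runtime
parameters here: the functionals are evaluated on already-normalised
fractions and the corresponding constraints are reported as residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .configvars import _BETA, _GAMMA, ConfigurationFractions

__all__ = [
    "ThermoParams",
    "FreeEnergyBreakdown",
    "InconsistentFractionsError",
    "lf",
    "entropy_1d",
    "entropy_2d",
    "reduced_free_energy_1d",
    "reduced_free_energy_2d",
]

#: Sign convention applied to the printed 2-D functional: the w, x and
#: triplet entropy terms enter with the Kikuchi-consistent signs under
#: which the analytic 2-D solution is stationary.
FUNCTIONAL_2D_SIGNS = {"y": +2.0, "w": +1.0, "x": -1.0, "z": -2.0}


class InconsistentFractionsError(ValueError):
    """Fractions violate a normalisation/consistency identity beyond tolerance."""


@dataclass(frozen=True)
class ThermoParams:
    """Interaction enthalpy ``eps`` and its exponential parameter ``h = e^(eps/4)``."""

    eps: float
    h: float

    def __post_init__(self) -> None:
        if not (self.h > 0):
            raise ValueError(f"h must be positive, got {self.h}")

    @classmethod
    def from_eps(cls, eps: float) -> "ThermoParams":
        return cls(eps=float(eps), h=math.exp(eps / 4.0))

    @classmethod
    def from_h(cls, h: float) -> "ThermoParams":
        if not (h > 0):
            raise ValueError(f"h must be positive, got {h}")
        return cls(eps=4.0 * math.log(h), h=float(h))


@dataclass(frozen=True)
class FreeEnergyBreakdown:
    """Reduced free energy with its enthalpy/entropy split.

    ``g_reduced = enthalpy_term - entropy_term`` whenever the constraint
    residuals vanish.  ``metadata`` records the functional variant (dims
    and the 2-D term-sign convention).
    """

    enthalpy_term: float
    entropy_term: float
    g_reduced: float
    constraint_residuals: dict[str, float]
    metadata: dict = field(default_factory=dict)


def lf(p):
    """``Lf(p) = p ln p - p`` extended continuously with Lf(0) = 0.

    Accepts scalars or arrays; every entry must lie in [0, 1].
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"Lf argument must lie in [0, 1], got {p!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(arr > 0, arr * np.log(np.where(arr > 0, arr, 1.0)) - arr, 0.0)
    return float(out) if out.ndim == 0 else out


def _validate(fr: ConfigurationFractions, tol: float) -> None:
    bad = {k: v for k, v in fr.residuals().items() if abs(v) > tol}
    if bad:
        worst = max(bad, key=lambda k: abs(bad[k]))
        raise InconsistentFractionsError(
            f"configuration fractions violate {worst} by {bad[worst]:.3g} "
            f"(tolerance {tol:g}); all violations: {bad}"
        )


def _unlike_triplet_mass(fr: ConfigurationFractions) -> float:
    z = fr.z
    return z[1] + z[2] + z[3] + z[4]


def entropy_1d(fr: ConfigurationFractions) -> float:
    """Reduced 1-D CVM entropy ``2 sum(beta Lf(y)) - 2 sum(gamma Lf(z))``."""
    return 2.0 * float(_BETA @ lf(np.array(fr.y))) - 2.0 * float(
        _GAMMA @ lf(np.array(fr.z))
    )


def entropy_2d(fr: ConfigurationFractions) -> float:
    """Reduced 2-D CVM entropy (pair, next-nearest, point and triplet terms)."""
    s = FUNCTIONAL_2D_SIGNS
    return (
        s["y"] * float(_BETA @ lf(np.array(fr.y)))
        + s["w"] * float(_BETA @ lf(np.array(fr.w)))
        + s["x"] * float(lf(fr.x1) + lf(fr.x2))
        + s["z"] * float(_GAMMA @ lf(np.array(fr.z)))
    )


def reduced_free_energy_1d(
    fr: ConfigurationFractions, params: ThermoParams, tol: float = 1e-9
) -> FreeEnergyBreakdown:
    """Reduced free energy of a 1-D zigzag chain at the given fractions."""
    _validate(fr, tol)
    enthalpy = params.eps * _unlike_triplet_mass(fr)
    entropy = entropy_1d(fr)
    return FreeEnergyBreakdown(
        enthalpy_term=enthalpy,
        entropy_term=entropy,
        g_reduced=enthalpy - entropy,
        constraint_residuals=fr.residuals(),
        metadata={"dims": 1},
    )


def reduced_free_energy_2d(
    fr: ConfigurationFractions, params: ThermoParams, tol: float = 1e-9
) -> FreeEnergyBreakdown:
    """Reduced free energy of a 2-D staggered grid at the given fractions."""
    _validate(fr, tol)
    enthalpy = params.eps * _unlike_triplet_mass(fr)
    entropy = entropy_2d(fr)
    return FreeEnergyBreakdown(
        enthalpy_term=enthalpy,
        entropy_term=entropy,
        g_reduced=enthalpy - entropy,
        constraint_residuals=fr.residuals(),
        metadata={"dims": 2, "term_signs": dict(FUNCTIONAL_2D_SIGNS)},
    )
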