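"""Equilibrium configuration variables as functions of h.

In the equiprobable regime (x1 = x2 = 0.5) the free-energy minimum is
symmetric: y1 = y3, z1 = z6, z2 = z5, z3 = z4.  With s = z1/z3 the 1-D
stationarity system collapses to s = h^4 and

    1 / z3 = 2 (s + 1) + 4 sqrt(s)

(the + root of the printed +/-; the - root would give 1/z3 = 0 at h = 1,
contradicting z3 = 0.125 there).  All other fractions follow from the
normalisation and the symmetry.

The 2-D staggered grid admits an analytic expression for one triplet
fraction,

    z3 = (h^2 - 3)(h^2 + 1) / (8 [h^4 - 6 h^2 + 1]),

physically valid on h in [3^(-1/2), 3^(1/2)] where z3 runs from 0.5 down
to 0; the denominator has singularities at h^2 = 3 +/- 2 sqrt(2), both
outside that branch.  The remaining 2-D fractions are obtained by
numerically minimising the 2-D free-energy functional over the symmetric
parameterisation (z1, z3) with z2 = (0.5 - z1 - z3)/2; the minimiser's
z3 is cross-checked against the analytic expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .configvars import ConfigurationFractions
from .thermo import (
    ThermoParams,
    reduced_free_energy_1d,
    reduced_free_energy_2d,
)

__all__ = [
    "EquilibriumSolution",
    "BranchError",
    "SingularityError",
    "SolverError",
    "BRANCH_2D",
    "symmetric_fractions",
    "equilibrium_1d",
    "equilibrium_2d_z3",
    "equilibrium_2d_numeric",
    "minimize_free_energy",
    "equilibrium_curve",
]

#: Physically valid h-interval of the analytic 2-D solution (z3 in [0, 0.5]).
BRANCH_2D = (3.0 ** -0.5, 3.0 ** 0.5)
#: Denominator roots of the analytic 2-D expression, h^2 = 3 +/- 2 sqrt(2).
SINGULARITIES_2D = (math.sqrt(3.0 - 2.0 * math.sqrt(2.0)), math.sqrt(3.0 + 2.0 * math.sqrt(2.0)))

_ZMIN = 1e-12


class BranchError(ValueError):
    """h lies outside the physically valid branch of the 2-D solution."""


class SingularityError(ValueError):
    """Evaluation too close to a pole of the analytic 2-D expression."""


class SolverError(RuntimeError):
    """Numerical minimisation failed to converge or to validate."""


@dataclass(frozen=True)
class EquilibriumSolution:
    """Full set of equilibrium fractions at a given h.

    ``s = h^4`` is the equilibrium triplet ratio z1/z3 (1-D).  ``flags``
    carries branch/validation metadata such as ``in_branch`` or
    ``matches_closed_form``.
    """

    h: float
    s: float
    dims: int
    fractions: ConfigurationFractions
    g_reduced: float
    method: str
    flags: dict = field(default_factory=dict)

    @property
    def z1(self) -> float:
        return self.fractions.z[0]

    @property
    def z3(self) -> float:
        return self.fractions.z[2]

    @property
    def y2(self) -> float:
        return self.fractions.y[1]


def symmetric_fractions(z1: float, z3: float) -> ConfigurationFractions:
    """Equiprobable symmetric fractions from the two free triplet values.

    z2 follows from the triplet normalisation, the pairs from the
    window-consistency identities (y1 = z1 + z2, y2 = z2 + z3) and the
    next-nearest pairs from the triplet end-pairs (w1 = z1 + z3,
    w2 = z2 + z5 = 2 z2).
    """
    z2 = (0.5 - z1 - z3) / 2.0
    y1 = z1 + z2
    y2 = z2 + z3
    return ConfigurationFractions(
        x1=0.5,
        x2=0.5,
        y=(y1, y2, y1),
        w=(z1 + z3, 2.0 * z2, z1 + z3),
        z=(z1, z2, z3, z3, z2, z1),
    )


def _require_positive_h(h: float) -> None:
    if not (h > 0):
        raise ValueError(f"h must be positive, got {h}")


def equilibrium_1d(h: float) -> EquilibriumSolution:
    """Closed-form 1-D equilibrium at interaction parameter h."""
    _require_positive_h(h)
    s = h ** 4
    z3 = 1.0 / (2.0 * (s + 1.0) + 4.0 * math.sqrt(s))
    z1 = s * z3
    fr = symmetric_fractions(z1, z3)
    g = reduced_free_energy_1d(fr, ThermoParams.from_h(h)).g_reduced
    return EquilibriumSolution(
        h=float(h), s=s, dims=1, fractions=fr, g_reduced=g, method="closed_form",
        flags={"in_branch": True},
    )


def _z3_2d_raw(h: float) -> float:
    u = h * h
    return (u - 3.0) * (u + 1.0) / (8.0 * (u * u - 6.0 * u + 1.0))


def equilibrium_2d_z3(h: float, singularity_tol: float = 1e-6) -> float:
    """Analytic 2-D equilibrium triplet fraction z3(h) on the valid branch."""
    _require_positive_h(h)
    for pole in SINGULARITIES_2D:
        if abs(h - pole) < singularity_tol:
            raise SingularityError(
                f"h={h} is within {singularity_tol} of the pole at h={pole:.6f}"
            )
    lo, hi = BRANCH_2D
    if not (lo - 1e-12 <= h <= hi + 1e-12):
        raise BranchError(
            f"h={h} outside the valid 2-D branch [{lo:.6f}, {hi:.6f}] "
            "(z3 would leave [0, 0.5])"
        )
    return _z3_2d_raw(h)


def _g_and_grad(v: np.ndarray, eps: float, dims: int):
    """Reduced free energy and gradient in the symmetric (z1, z3) chart."""
    z1, z3 = v
    z2 = (0.5 - z1 - z3) / 2.0
    if min(z1, z2, z3) <= 0.0:
        return np.inf, np.zeros(2)
    y1 = z1 + z2
    y2 = z2 + z3

    def LF(p):
        return p * math.log(p) - p

    g = (
        eps * (2.0 * z2 + 2.0 * z3)
        - 2.0 * (2.0 * LF(y1) + 2.0 * LF(y2))
        + 2.0 * (2.0 * LF(z1) + 4.0 * LF(z2) + 2.0 * LF(z3))
    )
    d1 = -eps - 2.0 * math.log(y1 / y2) + 4.0 * math.log(z1 / z2)
    d3 = eps + 2.0 * math.log(y1 / y2) + 4.0 * math.log(z3 / z2)
    if dims == 2:
        w1 = z1 + z3
        w2 = 2.0 * z2
        g += -(2.0 * LF(w1) + 2.0 * LF(w2)) + 2.0 * LF(0.5)
        d1 += -2.0 * math.log(w1 / w2)
        d3 += -2.0 * math.log(w1 / w2)
    return g, np.array([d1, d3])


def _z_from_chart(t: np.ndarray) -> tuple[float, float]:
    """Map unconstrained chart coordinates to interior (z1, z3).

    z1 = 0.5 e^{t1} / (1 + e^{t1} + e^{t3}) and likewise for z3, so that
    z1, z3 > 0 and z1 + z3 < 0.5 (hence z2 > 0) for every t.
    """
    e = np.exp(np.clip(t, -300.0, 300.0))
    denom = 1.0 + e[0] + e[1]
    return 0.5 * e[0] / denom, 0.5 * e[1] / denom


def _chart_from_z(z1: float, z3: float) -> np.ndarray:
    z2 = (0.5 - z1 - z3) / 2.0
    return np.log(np.array([z1, z3]) / (2.0 * z2))


def minimize_free_energy(
    h: float,
    dims: int,
    grad_tol: float = 1e-9,
) -> EquilibriumSolution:
    """Constrained minimisation of the CVM free energy at parameter h.

    Works in the symmetric equiprobable parameterisation (z1, z3) with
    z2 fixed by normalisation; the feasible simplex is charted by an
    unconstrained softmax-style transform so every iterate stays
    strictly interior (the entropy gradient diverges on the boundary,
    so the minimum always is).  Stationarity is solved by a Newton-type
    root solve on the free-energy gradient, started from the uniform
    h = 1 point, the 1-D closed form, and (in 2-D) the analytic 2-D z3;
    a candidate is accepted at gradient norm <= ``grad_tol`` and the
    lowest-G stationary point is returned.
    """
    _require_positive_h(h)
    if dims not in (1, 2):
        raise ValueError(f"dims must be 1 or 2, got {dims}")
    eps = 4.0 * math.log(h)
    ref = equilibrium_1d(h)
    starts = [np.zeros(2), _chart_from_z(ref.z1, ref.z3)]
    if dims == 2:
        z3_guess = _z3_2d_raw(h)
        if 1e-9 < z3_guess < 0.5 - 1e-9 and ref.z1 + z3_guess < 0.5 - 1e-9:
            starts.append(_chart_from_z(max(ref.z1, 1e-9), z3_guess))

    def grad_in_chart(t: np.ndarray) -> np.ndarray:
        return _g_and_grad(np.array(_z_from_chart(t)), eps, dims)[1]

    best: tuple[float, float, float, float] | None = None  # (g, z1, z3, gnorm)
    for t0 in starts:
        root = optimize.root(grad_in_chart, t0, method="hybr", tol=1e-13)
        z = np.array(_z_from_chart(root.x))
        g_val, grad = _g_and_grad(z, eps, dims)
        gnorm = float(np.linalg.norm(grad))
        if gnorm <= grad_tol and (best is None or g_val < best[0]):
            best = (g_val, float(z[0]), float(z[1]), gnorm)
    if best is None:
        raise SolverError(
            f"stationarity not reached at h={h} (dims={dims}): no start converged "
            f"to gradient norm <= {grad_tol:g}"
        )
    _, z1, z3, gnorm = best
    fr = symmetric_fractions(z1, z3)
    params = ThermoParams.from_h(h)
    g = (
        reduced_free_energy_1d(fr, params) if dims == 1 else reduced_free_energy_2d(fr, params)
    ).g_reduced
    return EquilibriumSolution(
        h=float(h), s=h ** 4, dims=dims, fractions=fr, g_reduced=g, method="numeric",
        flags={"gradient_norm": gnorm},
    )


def equilibrium_2d_numeric(h: float, tol: float = 1e-6) -> EquilibriumSolution:
    """Full 2-D equilibrium fractions by free-energy minimisation.

    The returned solution's z3 is cross-checked against the analytic 2-D
    expression; disagreement beyond ``tol`` raises :class:`SolverError`
    (it is never silently accepted).  Outside the valid analytic branch
    a :class:`BranchError` is raised.
    """
    z3_closed = equilibrium_2d_z3(h)  # also enforces branch/singularity policy
    sol = minimize_free_energy(h, dims=2)
    dev = abs(sol.z3 - z3_closed)
    if dev > tol:
        raise SolverError(
            f"2-D minimiser z3={sol.z3:.9f} disagrees with the analytic "
            f"value {z3_closed:.9f} by {dev:.3g} (> {tol:g}) at h={h}"
        )
    sol.flags.update(in_branch=True, matches_closed_form=True, z3_closed_form=z3_closed)
    return sol


_CURVE_COLUMNS = [
    "h", "x1", "y1", "y2", "y3", "w1", "w2", "w3",
    "z1", "z2", "z3", "z4", "z5", "z6", "g_reduced", "flags",
]


def equilibrium_curve(
    h_min: float, h_max: float, steps: int, dims: int = 1
) -> pd.DataFrame:
    """Equilibrium fractions on an h-grid, one row per grid point.

    For dims=2, grid points outside the valid branch or near a pole are
    flagged in the ``flags`` column (with NaN fractions), never dropped
    silently.
    """
    if not (0 < h_min < h_max):
        raise ValueError(f"need 0 < h_min < h_max, got [{h_min}, {h_max}]")
    if steps < 2:
        raise ValueError(f"steps must be >= 2, got {steps}")
    if dims not in (1, 2):
        raise ValueError(f"dims must be 1 or 2, got {dims}")
    rows = []
    for h in np.linspace(h_min, h_max, steps):
        flag = "ok"
        try:
            sol = equilibrium_1d(h) if dims == 1 else equilibrium_2d_numeric(h)
            fr = sol.fractions
            record = [sol.h, fr.x1, *fr.y, *fr.w, *fr.z, sol.g_reduced]
        except SingularityError:
            flag = "singularity"
            record = [float(h)] + [math.nan] * 14
        except BranchError:
            flag = "out_of_branch"
            record = [float(h)] + [math.nan] * 14
        rows.append(record + [flag])
    return pd.DataFrame(rows, columns=_CURVE_COLUMNS)
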