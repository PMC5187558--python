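"""Inferring the interaction parameter h from observed triplet fractions.

An observed lattice yields triplet fractions z1 (like-triplet AAA) and
z3 (alternating triplet ABA).  Each is inverted separately through the
equilibrium relations z1(h), z3(h), giving two estimates h1 and h3; the
reported estimate is their arithmetic mean ``havg = (h1 + h3) / 2``.
For a finite lattice away from equilibrium h1 and h3 generally differ —
the spread is itself informative — and the inversion presumes the
equiprobable regime, so x1 is required to be near 0.5.

The 1-D inversions are exact closed forms (no look-up table needed):
with u = h^2,

    z3:  sqrt(s) = sqrt(1 / (2 z3)) - 1,   h = s^(1/4)
    z1:  u = [2 z1 + sqrt(2 z1)] / (1 - 2 z1),   h = sqrt(u)

The 2-D z3 inversion solves the quadratic in u = h^2 implied by the
analytic 2-D solution; the 2-D z1 inversion root-finds against the
numerically minimised 2-D equilibrium on the valid branch.  A sampled
look-up-table path (the procedure described with the original figures)
is retained behind ``method="table"`` for parity experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .configvars import count_all
from .equilibrium import BRANCH_2D, BranchError, equilibrium_1d, minimize_free_energy
from .lattice import BistateLattice

__all__ = [
    "HEstimate",
    "NonEquiprobableError",
    "invert_z1",
    "invert_z3",
    "estimate_h",
]


class NonEquiprobableError(ValueError):
    """Observed x1 is too far from 0.5 for the equiprobable inversion."""


@dataclass(frozen=True)
class HEstimate:
    """Interaction-parameter estimates inverted from observed triplets."""

    h1: float
    h3: float
    havg: float
    z1: float
    z3: float
    x1: float
    dims: int
    n_units: int
    window_total: int
    flags: dict = field(default_factory=dict)


def _check_unit_fraction(name: str, value: float, lo_open: bool, hi: float) -> None:
    ok = (value > 0 if lo_open else value >= 0) and value <= hi
    if not ok:
        lo = "(0" if lo_open else "[0"
        raise ValueError(f"{name} must lie in {lo}, {hi}], got {value}")


def invert_z3(z3_obs: float, dims: int = 1) -> float:
    """Interaction parameter h whose equilibrium z3 equals the observation.

    Exact closed form in 1-D; in 2-D the root of the implied quadratic
    in u = h^2 that falls on the valid branch u in [1/3, 3].
    """
    _check_unit_fraction("z3", z3_obs, lo_open=True, hi=0.5)
    if dims == 1:
        sqrt_s = math.sqrt(1.0 / (2.0 * z3_obs)) - 1.0
        return math.sqrt(sqrt_s)
    if dims != 2:
        raise ValueError(f"dims must be 1 or 2, got {dims}")
    # (1 - 8 z3) u^2 + (48 z3 - 2) u - (3 + 8 z3) = 0
    a = 1.0 - 8.0 * z3_obs
    b = 48.0 * z3_obs - 2.0
    c = -(3.0 + 8.0 * z3_obs)
    if abs(a) < 1e-14:  # z3 = 1/8 exactly: the quadratic degenerates, u = 1
        roots = [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise BranchError(f"no real h reproduces 2-D z3={z3_obs}")
        roots = [(-b + math.sqrt(disc)) / (2 * a), (-b - math.sqrt(disc)) / (2 * a)]
    lo, hi = 1.0 / 3.0, 3.0
    in_branch = [u for u in roots if lo - 1e-9 <= u <= hi + 1e-9]
    if not in_branch:
        raise BranchError(
            f"no root of the 2-D inversion lies on the branch u=h^2 in [1/3, 3] "
            f"for z3={z3_obs} (roots: {roots})"
        )
    return math.sqrt(min(max(in_branch[0], lo), hi))


def invert_z1(z1_obs: float, dims: int = 1) -> float:
    """Interaction parameter h whose equilibrium z1 equals the observation.

    Exact closed form in 1-D (z1 = 0 maps to h = 0, the strict-alternation
    limit).  In 2-D, root-found against the numerically minimised
    equilibrium z1(h) on the valid branch.
    """
    _check_unit_fraction("z1", z1_obs, lo_open=False, hi=0.5 - 1e-12)
    if dims == 1:
        if z1_obs == 0.0:
            return 0.0
        u = (2.0 * z1_obs + math.sqrt(2.0 * z1_obs)) / (1.0 - 2.0 * z1_obs)
        return math.sqrt(u)
    if dims != 2:
        raise ValueError(f"dims must be 1 or 2, got {dims}")
    lo, hi = BRANCH_2D
    lo, hi = lo + 1e-6, hi - 1e-6

    def gap(h: float) -> float:
        return minimize_free_energy(h, dims=2).z1 - z1_obs

    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0:
        raise BranchError(
            f"2-D z1={z1_obs} not attained on the valid branch "
            f"(z1 range [{g_lo + z1_obs:.6f}, {g_hi + z1_obs:.6f}])"
        )
    return float(optimize.brentq(gap, lo, hi, xtol=1e-12))


def _lookup_invert(z_obs: float, which: str, dims: int, n_grid: int = 2001) -> float:
    """Look-up-table inversion with linear interpolation (parity path)."""
    if dims == 1:
        hs = np.linspace(1e-3, 4.0, n_grid)
        sols = [equilibrium_1d(h) for h in hs]
    else:
        lo, hi = BRANCH_2D
        hs = np.linspace(lo + 1e-6, hi - 1e-6, n_grid)
        sols = [minimize_free_energy(h, dims=2) for h in hs]
    zs = np.array([s.z1 if which == "z1" else s.z3 for s in sols])
    if which == "z3":  # z3 decreases with h; np.interp needs ascending x
        return float(np.interp(z_obs, zs[::-1], hs[::-1]))
    return float(np.interp(z_obs, zs, hs))


def estimate_h(
    lattice: BistateLattice,
    x1_tol: float = 0.05,
    strict: bool = True,
    method: str = "closed_form",
) -> HEstimate:
    """Estimate h1, h3 and havg from an observed lattice.

    Counts the triplet windows, forms the per-arrangement fractions
    z1 = Z1/total and z3 = Z3/total, inverts each through the
    equilibrium relations for the lattice's dimensionality, and averages.

    Parameters
    ----------
    x1_tol
        Allowed deviation of the observed x1 from the equiprobable 0.5.
        Beyond it, ``strict=True`` raises; otherwise the estimate is
        returned with a ``non_equiprobable`` flag.
    method
        ``"closed_form"`` (exact inversion, default) or ``"table"``
        (sampled curve + linear interpolation, kept for parity checks).
    """
    if method not in ("closed_form", "table"):
        raise ValueError(f"method must be 'closed_form' or 'table', got {method!r}")
    counts = count_all(lattice)
    fr = counts.fractions()
    flags: dict = {}
    if abs(fr.x1 - 0.5) > x1_tol:
        if strict:
            raise NonEquiprobableError(
                f"x1={fr.x1:.4f} deviates from 0.5 by more than {x1_tol}; "
                "the equiprobable inversion does not apply"
            )
        flags["non_equiprobable"] = True
    z1_obs, z3_obs = fr.z[0], fr.z[2]
    if z1_obs == 0.0:
        flags["z1_degenerate"] = True  # strict alternation: h1 pinned at 0
    if method == "table":
        h1 = _lookup_invert(z1_obs, "z1", lattice.dims) if z1_obs > 0 else 0.0
        h3 = _lookup_invert(z3_obs, "z3", lattice.dims)
    else:
        h1 = invert_z1(z1_obs, dims=lattice.dims)
        h3 = invert_z3(z3_obs, dims=lattice.dims)
    return HEstimate(
        h1=h1,
        h3=h3,
        havg=(h1 + h3) / 2.0,
        z1=z1_obs,
        z3=z3_obs,
        x1=fr.x1,
        dims=lattice.dims,
        n_units=lattice.n_units,
        window_total=counts.window_total,
        flags=flags,
    )
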