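"""Mean-field companion of the go-or-grow automaton.

Under the fast-switching assumption (phenotype redraws equilibrate much
faster than birth and death), the resting fraction at density rho is
r_s(rho) and the lattice dynamics coarse-grain to the scalar
reaction-diffusion equation

    d rho / dt = d/dx ( D(rho) d rho/dx ) + F(rho),
    F(rho)     = R_b r_s(rho) rho (1 - rho) - R_d rho,

with R_b ~ r_b / tau and R_d ~ r_d / tau the macroscopic birth and death
rates.  The kinetic term F is monostable (persistence only) or bistable
(extinction state and persistence state both stable — an Allee effect),
depending on the sign of kappa and on whether r_s(rho) r_b < r_d at low
density.  This module provides F, its fixed points with stability labels,
the regime boundary in the (kappa, theta) plane, the density-dependent
diffusion coefficient, and an explicit 1-D PDE solver.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .switching import SwitchParams, switch_derivative, switch_probability

__all__ = [
    "KineticParams",
    "FixedPoint",
    "FixedPointSet",
    "growth_term",
    "growth_derivative",
    "per_capita_rate",
    "find_fixed_points",
    "bistability_condition",
    "boundary_kappa",
    "equilibrium_resting_fraction",
    "diffusion_coefficient",
    "expansion_coefficients",
    "solve_rd_pde",
    "PDEResult",
]

#: Default low-density reference at which the bistability inequality
#: r_s(rho) r_b < r_d is evaluated (the value used for the regime boundary).
RHO_REF_DEFAULT = 0.25

ROOT_TOL = 1e-10
MARGINAL_TOL = 1e-8


@dataclass(frozen=True)
class KineticParams:
    """Kinetic parameters of the mean-field growth term.

    ``tau`` maps automaton steps to macroscopic time; with the default
    tau = 1 the rates R_b, R_d coincide with the per-step probabilities
    r_b, r_d, which is the convention used for all figure-level work.
    """

    r_b: float
    r_d: float
    switch: SwitchParams
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.r_b < 0 or self.r_d < 0:
            raise ValueError("r_b and r_d must be non-negative")

    @property
    def R_b(self) -> float:
        return self.r_b / self.tau

    @property
    def R_d(self) -> float:
        return self.r_d / self.tau


def _check_density(rho):
    rho = np.asarray(rho, dtype=float)
    if np.any((rho < 0.0) | (rho > 1.0)):
        raise ValueError("density rho must lie in [0, 1]")
    return rho


def growth_term(rho, kp: KineticParams):
    """Net growth rate F(rho) = R_b r_s(rho) rho (1 - rho) - R_d rho."""
    rho = _check_density(rho)
    rs = switch_probability(rho, kp.switch)
    out = kp.R_b * rs * rho * (1.0 - rho) - kp.R_d * rho
    return out.item() if np.ndim(out) == 0 else out


def growth_derivative(rho, kp: KineticParams):
    """Analytic F'(rho), used for stability classification."""
    rho = _check_density(rho)
    rs = switch_probability(rho, kp.switch)
    drs = switch_derivative(rho, kp.switch, order=1)
    out = kp.R_b * (drs * rho * (1.0 - rho) + rs * (1.0 - 2.0 * rho)) - kp.R_d
    return out.item() if np.ndim(out) == 0 else out


def per_capita_rate(rho, kp: KineticParams):
    """Per-capita growth rate F(rho)/rho; at rho = 0 the limit
    R_b r_s(0) - R_d.  A negative limit is the Allee-effect signature."""
    rho = np.asarray(rho, dtype=float)
    _check_density(rho)
    limit = kp.R_b * switch_probability(0.0, kp.switch) - kp.R_d
    if rho.ndim == 0:
        if rho == 0.0:
            return float(limit)
        return growth_term(rho, kp) / float(rho)
    out = np.full(rho.shape, limit)
    pos = rho > 0
    out[pos] = growth_term(rho[pos], kp) / rho[pos]
    return out


Stability = Literal["stable", "unstable", "marginal"]


@dataclass(frozen=True)
class FixedPoint:
    rho: float
    stability: Stability


@dataclass(frozen=True)
class FixedPointSet:
    """Sorted roots of F on [0, 1] with stability labels and the regime."""

    points: tuple
    regime: Literal["monostable", "bistable"]

    @property
    def rhos(self) -> tuple:
        return tuple(p.rho for p in self.points)

    @property
    def n_stable(self) -> int:
        return sum(p.stability == "stable" for p in self.points)

    def __len__(self) -> int:
        return len(self.points)


def _classify(rho: float, kp: KineticParams) -> Stability:
    slope = growth_derivative(rho, kp)
    if abs(slope) < MARGINAL_TOL:
        return "marginal"
    return "stable" if slope < 0 else "unstable"


def find_fixed_points(kp: KineticParams, n_grid: int = 20001) -> FixedPointSet:
    """Locate all roots of F on [0, 1] and label their stability.

    Roots are found by a sign-change scan on a fine grid followed by Brent
    bisection; rho = 0 is always a root by construction.  The regime is
    bistable iff the extinction state rho = 0 is stable and a stable
    positive root exists.
    """
    grid = np.linspace(0.0, 1.0, n_grid)
    fvals = growth_term(grid, kp)

    roots = [0.0]
    # grid points where F vanishes to machine precision (beyond rho=0)
    scale = max(np.max(np.abs(fvals)), 1.0)
    exact = np.nonzero(np.abs(fvals) < 1e-14 * scale)[0]
    for i in exact:
        roots.append(float(grid[i]))
    # sign changes between strictly nonzero values
    f = lambda r: growth_term(r, kp)
    for i in range(n_grid - 1):
        a, bb = fvals[i], fvals[i + 1]
        if a == 0.0 or bb == 0.0:
            continue
        if (a < 0) != (bb < 0):
            roots.append(brentq(f, grid[i], grid[i + 1], xtol=ROOT_TOL))

    roots = sorted(roots)
    dedup: list = []
    for r in roots:
        if not dedup or r - dedup[-1] > max(ROOT_TOL, 1e-6):
            dedup.append(r)

    points = tuple(FixedPoint(r, _classify(r, kp)) for r in dedup)
    zero_stable = points[0].stability == "stable"
    pos_stable = any(p.rho > 0 and p.stability == "stable" for p in points)
    regime = "bistable" if (zero_stable and pos_stable) else "monostable"
    return FixedPointSet(points, regime)


def bistability_condition(
    kp: KineticParams, rho_ref: float = RHO_REF_DEFAULT
) -> bool:
    """Low-density criterion for the bistable (Allee) regime:
    kappa > 0 and r_s(rho_ref) r_b < r_d."""
    _check_density(rho_ref)
    if kp.switch.kappa <= 0:
        return False
    return switch_probability(rho_ref, kp.switch) * kp.R_b < kp.R_d


def boundary_kappa(
    theta: float, ratio: float, rho_ref: float = RHO_REF_DEFAULT
) -> float:
    """The kappa on the monostable/bistable boundary at switch position theta.

    Solves r_s(rho_ref) = ratio (= r_d / r_b) for kappa:
    kappa = artanh(2 ratio - 1) / (rho_ref - theta).
    """
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio r_d/r_b must lie in (0, 1)")
    if not (0.0 < theta < 1.0):
        raise ValueError("theta must lie in (0, 1)")
    _check_density(rho_ref)
    a = math.atanh(2.0 * ratio - 1.0)
    if rho_ref == theta:
        if a == 0.0:
            return 0.0  # every kappa solves it; return the neutral value
        raise ValueError("no kappa solves r_s(rho_ref)=ratio when rho_ref == theta")
    return a / (rho_ref - theta)


def equilibrium_resting_fraction(rho, p: SwitchParams):
    """Fast-switching equilibrium resting fraction, r_s(rho)."""
    return switch_probability(rho, p)


def expansion_coefficients(p: SwitchParams) -> tuple:
    """(c0, c1, c2) of the low-density expansion D(rho)/D0 = c0 + c1 rho + c2 rho^2.

    Reading of the coefficients (kept in one place so alternatives are a
    one-line change): c0 = 1 - r_s(0)/2, c1 = -r_s'(0), c2 = -(3/2) r_s''(0).
    """
    c0 = 1.0 - switch_probability(0.0, p) / 2.0
    c1 = -switch_derivative(0.0, p, order=1)
    c2 = -1.5 * switch_derivative(0.0, p, order=2)
    return (c0, c1, c2)


def diffusion_coefficient(
    rho,
    p: SwitchParams,
    D0: float = 1.0,
    form: Literal["expansion", "exact"] = "expansion",
):
    """Density-dependent diffusivity D(rho).

    ``expansion`` is the quadratic low-density Taylor form built from r_s(0)
    and its derivatives (valid for rho << 1); ``exact`` is the
    moving-fraction form D0 (1 - r_s(rho)), provided as a cross-check.
    Negative values are clamped to 0 with a warning.
    """
    if D0 <= 0:
        raise ValueError("D0 must be positive")
    rho = _check_density(rho)
    if form == "expansion":
        c0, c1, c2 = expansion_coefficients(p)
        out = D0 * (c0 + c1 * rho + c2 * rho**2)
    elif form == "exact":
        out = D0 * (1.0 - switch_probability(rho, p))
    else:
        raise ValueError(f"unknown form {form!r}")
    out = np.asarray(out, dtype=float)
    if np.any(out < 0):
        warnings.warn("D(rho) clamped at 0 (expansion left its validity range)")
        out = np.maximum(out, 0.0)
    return out.item() if out.ndim == 0 else out


@dataclass
class PDEResult:
    x: np.ndarray
    times: np.ndarray
    profiles: np.ndarray  # shape (len(times), len(x))

    def to_long_frame(self):
        import pandas as pd

        t = np.repeat(self.times, self.x.size)
        x = np.tile(self.x, self.times.size)
        return pd.DataFrame({"x": x, "t": t, "rho": self.profiles.ravel()})


def _diffusivity_fn(p: SwitchParams, D0: float, form: str):
    if form == "constant":
        return lambda rho: np.full_like(rho, D0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lambda rho: np.asarray(
            diffusion_coefficient(np.clip(rho, 0.0, 1.0), p, D0, form)
        )


def solve_rd_pde(
    kp: KineticParams,
    D0: float,
    form: Literal["expansion", "exact", "constant"],
    initial_profile: Sequence[float],
    t_end: float,
    dx: float,
    dt: float,
    boundary: Literal["noflux", "periodic"] = "noflux",
    include_kinetics: bool = True,
    n_samples: int = 11,
) -> PDEResult:
    """Explicit conservative finite-volume solver for the 1-D equation
    d rho/dt = d/dx( D(rho) d rho/dx ) + F(rho).

    Interface diffusivity is the arithmetic mean of the adjacent cells'
    D(rho).  The explicit scheme requires dt <= dx^2 / (2 max D); a violation
    refuses to run.  With ``include_kinetics=False`` and zero-flux boundary
    the total mass is conserved to round-off.
    """
    rho = np.asarray(initial_profile, dtype=float).copy()
    if rho.ndim != 1 or rho.size < 3:
        raise ValueError("initial_profile must be a 1-D array of length >= 3")
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("initial profile must lie in [0, 1]")
    if dx <= 0 or dt <= 0 or t_end < 0:
        raise ValueError("dx, dt must be positive and t_end >= 0")

    D_of = _diffusivity_fn(kp.switch, D0, form)
    Dmax = float(np.max(D_of(np.linspace(0.0, 1.0, 1001))))
    if Dmax > 0 and dt > dx**2 / (2.0 * Dmax) * (1.0 + 1e-12):
        raise ValueError(
            f"CFL violation: dt={dt} exceeds dx^2/(2 max D)={dx ** 2 / (2 * Dmax):.3g}"
        )

    n_steps = int(round(t_end / dt))
    sample_idx = np.unique(np.linspace(0, n_steps, n_samples).round().astype(int))
    x = np.arange(rho.size) * dx
    profiles = [rho.copy()]
    times = [0.0]

    for k in range(1, n_steps + 1):
        D = D_of(rho)
        if boundary == "periodic":
            Dm = 0.5 * (D + np.roll(D, -1))
            flux = Dm * (np.roll(rho, -1) - rho) / dx  # flux through i+1/2
            div = (flux - np.roll(flux, 1)) / dx
        elif boundary == "noflux":
            Dm = 0.5 * (D[:-1] + D[1:])
            flux = Dm * np.diff(rho) / dx
            div = (np.concatenate([flux, [0.0]]) - np.concatenate([[0.0], flux])) / dx
        else:
            raise ValueError(f"unknown boundary {boundary!r}")
        rho = rho + dt * div
        if include_kinetics:
            rho = rho + dt * growth_term(np.clip(rho, 0.0, 1.0), kp)
        if k in sample_idx:
            profiles.append(rho.copy())
            times.append(k * dt)

    return PDEResult(x, np.asarray(times), np.asarray(profiles))


def fixed_point_report(kp: KineticParams) -> dict:
    """JSON-ready report of the fixed points and the regime."""
    fps = find_fixed_points(kp)
    return {
        "kappa": kp.switch.kappa,
        "theta": kp.switch.theta,
        "r_b": kp.r_b,
        "r_d": kp.r_d,
        "tau": kp.tau,
        "regime": fps.regime,
        "bistable_low_density_criterion": bistability_condition(kp),
        "fixed_points": [
            {"rho": p.rho, "stability": p.stability} for p in fps.points
        ],
    }
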