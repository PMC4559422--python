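"""Density-dependent phenotype-switch kinetics.

The migration-proliferation ("go-or-grow") dichotomy is driven by a single
sigmoidal switch probability

    r_s(rho) = (1 + tanh(kappa * (rho - theta))) / 2,      rho in [0, 1],

the probability that a cell adopts the resting (proliferative) phenotype at
local density ``rho``.  ``kappa`` sets the intensity and the sign of the
density response: ``kappa > 0`` means motility decreases with crowding
(attractive plasticity, contact inhibition of migration), ``kappa < 0`` means
cells escape crowded regions (repulsive plasticity).  ``theta`` is the
critical density at which both phenotypes are equally likely.

This module is the single source of truth for r_s and its derivatives; both
the stochastic lattice simulator and the mean-field analysis import from
here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "SwitchParams",
    "switch_probability",
    "switch_derivative",
    "classify_plasticity",
]

Regime = Literal["attractive", "repulsive", "neutral"]


@dataclass(frozen=True)
class SwitchParams:
    """Parameters of the sigmoidal phenotype switch.

    Parameters
    ----------
    kappa
        Dimensionless switch intensity; its sign selects the plasticity
        regime (positive: attractive, negative: repulsive, zero: neutral).
    theta
        Critical density in (0, 1) at which r_s = 1/2.
    """

    kappa: float
    theta: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.kappa):
            raise ValueError(f"kappa must be finite, got {self.kappa}")
        if not (0.0 < self.theta < 1.0):
            raise ValueError(f"theta must lie in (0, 1), got {self.theta}")


def _check_density(rho):
    rho = np.asarray(rho, dtype=float)
    if np.any((rho < 0.0) | (rho > 1.0)):
        raise ValueError("density rho must lie in [0, 1]")
    return rho


def _maybe_scalar(x: np.ndarray):
    return x.item() if x.ndim == 0 else x


def switch_probability(rho, p: SwitchParams):
    """Probability r_s(rho) that a cell adopts the resting phenotype.

    Accepts scalars or arrays; values are strictly inside (0, 1) because
    tanh is bounded away from +/-1 for finite arguments — no clipping is
    applied.
    """
    rho = _check_density(rho)
    return _maybe_scalar(0.5 * (1.0 + np.tanh(p.kappa * (rho - p.theta))))


def switch_derivative(rho, p: SwitchParams, order: int = 1):
    """Closed-form first or second density-derivative of r_s.

    r_s'(rho)  = (kappa/2) * sech^2(kappa (rho - theta))
    r_s''(rho) = -kappa^2 * tanh(kappa (rho - theta)) * sech^2(...)
    """
    rho = _check_density(rho)
    u = p.kappa * (rho - p.theta)
    sech2 = 1.0 / np.cosh(u) ** 2
    if order == 1:
        out = 0.5 * p.kappa * sech2
    elif order == 2:
        out = -(p.kappa**2) * np.tanh(u) * sech2
    else:
        raise ValueError(f"order must be 1 or 2, got {order}")
    return _maybe_scalar(np.asarray(out))


def classify_plasticity(p: SwitchParams) -> Regime:
    """Label the plasticity regime from the sign of kappa."""
    if p.kappa > 0:
        return "attractive"
    if p.kappa < 0:
        return "repulsive"
    return "neutral"
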