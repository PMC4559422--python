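"""Reproducible in-silico studies on the go-or-grow automaton.

Two headline pipelines:

* :func:`phase_diagram` — growth-rate sweep over the (kappa, theta) plane
  from a compact initial tumor, with the analytic monostable/bistable
  boundary curve for overlay;
* :func:`extinction_study` — extinction frequency and final averaged
  density as a function of the initial density, the stochastic signature of
  the emergent Allee effect.

Every run records the integer seed it was generated from, so any row of any
result table replays bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from . import lgca, meanfield
from .lgca import LatticeConfig, ModelParams
from .switching import SwitchParams

__all__ = [
    "EXTINCT",
    "SweepSpec",
    "ExtinctionSpec",
    "ExperimentResult",
    "growth_rate_estimate",
    "phase_diagram",
    "extinction_study",
    "density_kde",
    "KDEResult",
    "modality_classify",
]

#: Sentinel growth rate for runs whose population reached 0 in the window.
EXTINCT = float("-inf")


def _child_seeds(base_seed: int, n: int) -> np.ndarray:
    """Deterministic per-run integer seeds (< 2**31) from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return ss.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF


@dataclass(frozen=True)
class SweepSpec:
    """Growth-rate sweep over a (kappa, theta) grid."""

    kappa_grid: Sequence[float]
    theta_grid: Sequence[float]
    replicates: int = 1
    r_b: float = 0.2
    r_d: float = 0.01
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    n_steps: int = 1000
    radius: float = 10.0
    occupy_prob: float = 1.0
    n_rest_channels: int = 1
    n_vel_channels: int = 1
    record_every: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.kappa_grid) == 0 or len(self.theta_grid) == 0:
            raise ValueError("kappa_grid and theta_grid must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class ExtinctionSpec:
    """Extinction-frequency study at fixed (kappa, theta) over a range of
    initial densities (parameterized by the disk occupancy probability)."""

    kappa: float
    theta: float
    occupy_probs: Sequence[float]
    replicates: int = 40
    r_b: float = 0.2
    r_d: float = 0.01
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    n_steps: int = 5000
    radius: float = 10.0
    n_rest_channels: int = 1
    n_vel_channels: int = 1
    record_every: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates for frequency estimates")
        if len(self.occupy_probs) == 0:
            raise ValueError("occupy_probs must be non-empty")


@dataclass
class ExperimentResult:
    """Long-format per-run table plus derived summaries and a manifest."""

    runs: pd.DataFrame
    summary: Optional[pd.DataFrame] = None
    boundary: Optional[pd.DataFrame] = None
    manifest: dict = field(default_factory=dict)


def growth_rate_estimate(
    records: pd.DataFrame, window: Optional[tuple] = None
) -> float:
    """Exponential growth rate of the resting population, per step.

    Ordinary least-squares slope of log(n_rest) versus step over ``window``
    (default: the last half of the run), using only records with
    n_rest > 0.  Returns the sentinel :data:`EXTINCT` if the population hit
    zero inside the window, and NaN if fewer than two positive records
    remain.
    """
    if len(records) == 0:
        raise ValueError("empty record series")
    steps = records["step"].to_numpy()
    if window is None:
        window = (int(steps.max()) // 2, int(steps.max()))
        if window[0] >= window[1]:  # too few records to form a window
            return float("nan")
    lo, hi = window
    if lo < steps.min() or hi > steps.max() or lo >= hi:
        raise ValueError(f"window {window} outside recorded steps")
    sel = records[(records["step"] >= lo) & (records["step"] <= hi)]
    if (sel["n_total"] == 0).any():
        return EXTINCT
    pos = sel[sel["n_rest"] > 0]
    if len(pos) < 2:
        return float("nan")
    slope = np.polyfit(pos["step"].to_numpy(float), np.log(pos["n_rest"].to_numpy(float)), 1)[0]
    return float(slope)


def _single_run(
    kappa: float,
    theta: float,
    r_b: float,
    r_d: float,
    lattice: LatticeConfig,
    radius: float,
    occupy_prob: float,
    n_steps: int,
    record_every: int,
    seed: int,
    n_rest_channels: int = 1,
    n_vel_channels: int = 1,
) -> dict:
    params = ModelParams(
        r_b=r_b, r_d=r_d, switch=SwitchParams(kappa, theta), lattice=lattice, seed=seed
    )
    rng = params.rng()
    state = lgca.init_disk_state(
        lattice, radius, occupy_prob, rng,
        n_rest=n_rest_channels, n_vel=n_vel_channels,
    )
    rho0 = lgca.averaged_density(state)
    result = lgca.run(state, params, n_steps, record_every=record_every, rng=rng)
    rate = (
        EXTINCT
        if result.extinct
        else growth_rate_estimate(result.records)
    )
    return {
        "kappa": kappa,
        "theta": theta,
        "occupy_prob": occupy_prob,
        "seed": seed,
        "rho_initial": rho0,
        "rho_final": lgca.averaged_density(result.final_state),
        "extinct": result.extinct,
        "growth_rate": rate,
    }


def phase_diagram(spec: SweepSpec) -> ExperimentResult:
    """Run the automaton over the (kappa, theta) grid and estimate the
    resting-population growth rate per cell, with extinction flags.

    The summary averages growth rates over replicates (extinct runs keep
    the sentinel); the analytic regime-boundary curve kappa(theta) at the
    rate ratio r_d/r_b is attached for overlay.
    """
    n_runs = len(spec.kappa_grid) * len(spec.theta_grid) * spec.replicates
    seeds = _child_seeds(spec.seed, n_runs)
    rows = []
    i = 0
    for kappa in spec.kappa_grid:
        for theta in spec.theta_grid:
            for rep in range(spec.replicates):
                row = _single_run(
                    kappa, theta, spec.r_b, spec.r_d, spec.lattice,
                    spec.radius, spec.occupy_prob, spec.n_steps,
                    spec.record_every, int(seeds[i]),
                    spec.n_rest_channels, spec.n_vel_channels,
                )
                row["replicate"] = rep
                rows.append(row)
                i += 1
    runs = pd.DataFrame(rows)

    summary = (
        runs.groupby(["kappa", "theta"], as_index=False)
        .agg(
            extinction_frequency=("extinct", "mean"),
            mean_growth_rate=("growth_rate", "mean"),
        )
    )
    ratio = spec.r_d / spec.r_b if spec.r_b > 0 else float("nan")
    boundary = None
    if 0.0 < ratio < 1.0:
        thetas = np.asarray(spec.theta_grid, dtype=float)
        kappas = [
            meanfield.boundary_kappa(t, ratio) if t != meanfield.RHO_REF_DEFAULT else float("nan")
            for t in thetas
        ]
        boundary = pd.DataFrame({"theta": thetas, "kappa_boundary": kappas})
    manifest = {
        "experiment": "phase_diagram",
        "spec": {
            "kappa_grid": list(spec.kappa_grid),
            "theta_grid": list(spec.theta_grid),
            "replicates": spec.replicates,
            "r_b": spec.r_b,
            "r_d": spec.r_d,
            "lattice": [spec.lattice.height, spec.lattice.width, spec.lattice.K, spec.lattice.b],
            "n_steps": spec.n_steps,
            "radius": spec.radius,
            "occupy_prob": spec.occupy_prob,
            "seed": spec.seed,
        },
    }
    return ExperimentResult(runs, summary, boundary, manifest)


def extinction_study(spec: ExtinctionSpec) -> ExperimentResult:
    """Extinction frequency versus initial density at fixed (kappa, theta).

    For each disk occupancy probability, runs seeded replicates to
    ``n_steps`` or extinction; the summary holds the extinction frequency
    with its binomial standard error and the mean final averaged density of
    the surviving runs.
    """
    n_runs = len(spec.occupy_probs) * spec.replicates
    seeds = _child_seeds(spec.seed, n_runs)
    rows = []
    i = 0
    for p_occ in spec.occupy_probs:
        for rep in range(spec.replicates):
            row = _single_run(
                spec.kappa, spec.theta, spec.r_b, spec.r_d, spec.lattice,
                spec.radius, p_occ, spec.n_steps, spec.record_every,
                int(seeds[i]),
                spec.n_rest_channels, spec.n_vel_channels,
            )
            row["replicate"] = rep
            rows.append(row)
            i += 1
    runs = pd.DataFrame(rows)

    def _summarize(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        f = g["extinct"].mean()
        surv = g.loc[~g["extinct"], "rho_final"]
        return pd.Series(
            {
                "n": n,
                "extinction_frequency": f,
                "std_error": math.sqrt(f * (1.0 - f) / n),
                "mean_rho_initial": g["rho_initial"].mean(),
                "mean_rho_final_survivors": surv.mean() if len(surv) else float("nan"),
            }
        )

    summary = (
        runs.groupby("occupy_prob")[runs.columns]
        .apply(_summarize)
        .reset_index()
    )
    manifest = {
        "experiment": "extinction_study",
        "spec": {
            "kappa": spec.kappa,
            "theta": spec.theta,
            "occupy_probs": list(spec.occupy_probs),
            "replicates": spec.replicates,
            "r_b": spec.r_b,
            "r_d": spec.r_d,
            "lattice": [spec.lattice.height, spec.lattice.width, spec.lattice.K, spec.lattice.b],
            "n_steps": spec.n_steps,
            "radius": spec.radius,
            "seed": spec.seed,
        },
    }
    return ExperimentResult(runs, summary, None, manifest)


@dataclass
class KDEResult:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


def _silverman_bandwidth(samples: np.ndarray) -> float:
    n = samples.size
    sd = samples.std(ddof=1)
    q75, q25 = np.percentile(samples, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


def density_kde(
    samples: Sequence[float],
    bandwidth: float | str = "auto",
    grid_size: int = 512,
) -> KDEResult:
    """Gaussian kernel density estimate of final averaged densities on [0, 1].

    Because the averaged density is supported on [0, 1] and extinct runs
    pile mass at exactly 0, boundary mass is reflected at both ends so the
    estimate integrates to 1 on the unit interval.  ``bandwidth='auto'``
    uses Silverman's rule on the raw samples; degenerate (all-identical)
    samples require an explicit bandwidth.
    """
    s = np.asarray(samples, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 samples")
    if bandwidth == "auto":
        h = _silverman_bandwidth(s)
        if h <= 0:
            raise ValueError(
                "all samples identical — Silverman bandwidth degenerates; "
                "pass an explicit bandwidth"
            )
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")

    grid = np.linspace(0.0, 1.0, grid_size)
    # reflect at 0 and at 1: kernel contributions from s, -s and 2 - s
    pts = np.concatenate([s, -s, 2.0 - s])
    z = (grid[:, None] - pts[None, :]) / h
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (s.size * h * math.sqrt(2.0 * math.pi))
    return KDEResult(grid, dens, h)


def modality_classify(kde: KDEResult, prominence_frac: float = 0.05) -> str:
    """Classify a density estimate as unimodal/bimodal/multimodal by the
    number of local maxima with prominence above ``prominence_frac`` of the
    global maximum (boundary maxima count)."""
    d = np.asarray(kde.density, dtype=float)
    # pad with the exterior density (0) so boundary modes, e.g. the extinct
    # pile at rho=0, are counted
    padded = np.concatenate([[0.0], d, [0.0]])
    peaks, _ = find_peaks(padded, prominence=prominence_frac * d.max())
    n_modes = len(peaks)
    if n_modes <= 1:
        return "unimodal"
    if n_modes == 2:
        return "bimodal"
    return "multimodal"
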