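"""Pheromone trails: Weber's-law turning, trail simulation, bridge choice.

Ants perceive the pheromone field through two forward sectors (front
left L and front right R) and turn with an angle proportional to the
normalised difference of the sector concentrations

    alpha = A * (L - R) / (L + R + T0),

a Weber's-law response: the perceived difference between two stimuli
scales inversely with their combined magnitude.  ``A`` is the turning
gain in degrees per sensing step and ``T0`` the detection threshold
below which pheromone cannot be sensed reliably (it also keeps the
response finite at zero concentration).  Positive ``alpha`` turns the
ant toward its left sector.

On top of this response the module provides

* pheromone-map construction from passage counts,
* a spatially explicit trail-formation simulation with deposition and
  evaporation (the Weber response alone tends to carve stable
  self-reinforcing loops, quantified by :func:`loop_metric`),
* the mean-field double-bridge choice dynamics, and
* the effective choice curve showing how repeated noisy Weber
  comparisons at a junction sharpen into a nonlinear collective choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from statsmodels.stats.proportion import proportion_confint

from .trajdata import TWO_PI, PheromoneGrid, PlanarTrajectory, wrap_angle

__all__ = [
    "WeberParams",
    "SectorSpec",
    "AntState",
    "sector_concentrations",
    "weber_turn",
    "sample_weber_observations",
    "fit_weber",
    "build_pheromone_map",
    "simulate_trail",
    "loop_metric",
    "double_bridge_ode",
    "effective_choice_curve",
]


@dataclass
class WeberParams:
    """Parameters of the Weber's-law turning response.

    ``gain`` (A) is in degrees per sensing step, ``threshold`` (T0) in
    pheromone units, ``noise_sd`` in degrees.
    """

    gain: float = 30.80
    threshold: float = 10.53
    noise_sd: float = 20.0

    def __post_init__(self):
        if not np.isfinite(self.gain):
            raise ValueError("gain must be finite")
        if self.threshold < 0 or self.noise_sd < 0:
            raise ValueError("threshold and noise_sd must be nonnegative")


@dataclass
class SectorSpec:
    """Front-left / front-right sensing sectors.

    Each sector is centred ``half_angle`` radians to one side of the
    heading and spans ``2 * half_angle``, so the default pi/4 makes the
    two sectors tile the front half-plane, split at the heading line.
    ``radius`` is in arena units.
    """

    radius: float = 5.0
    half_angle: float = np.pi / 4

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("sector radius must be positive")
        if not 0 < self.half_angle <= np.pi / 2:
            raise ValueError("half_angle must lie in (0, pi/2]")


@dataclass
class AntState:
    x: float
    y: float
    heading: float

    def __post_init__(self):
        self.heading = float(self.heading) % TWO_PI


def sector_concentrations(grid: PheromoneGrid, ant: AntState, spec: SectorSpec):
    """Pheromone mass in the ant's front-left and front-right sectors.

    A cell contributes to a sector when its *centre* lies within
    ``spec.radius`` of the ant and its bearing relative to the heading
    falls in ``(0, 2*half_angle]`` (left) or ``[-2*half_angle, 0)``
    (right).  Returns ``(L, R)``.
    """
    ny, nx_ = grid.shape
    row, col = grid.cell_of(ant.x, ant.y)
    if not (0 <= row < ny and 0 <= col < nx_):
        raise ValueError("ant is outside the pheromone grid")
    reach = int(np.ceil(spec.radius / grid.cell_size)) + 1
    r0, r1 = max(row - reach, 0), min(row + reach + 1, ny)
    c0, c1 = max(col - reach, 0), min(col + reach + 1, nx_)
    cx, cy = grid.cell_centers()
    CX, CY = np.meshgrid(cx[c0:c1], cy[r0:r1])
    dx, dy = CX - ant.x, CY - ant.y
    within = dx * dx + dy * dy <= spec.radius**2
    bearing = wrap_angle(np.arctan2(dy, dx) - ant.heading)
    width = 2.0 * spec.half_angle
    left = within & (bearing > 0) & (bearing <= width)
    right = within & (bearing < 0) & (bearing >= -width)
    patch = grid.values[r0:r1, c0:c1]
    return float(patch[left].sum()), float(patch[right].sum())


def weber_turn(L: float, R: float, params: WeberParams, rng=None) -> float:
    """Turning angle in degrees for sector concentrations (L, R).

    Deterministic part ``A * (L - R) / (L + R + T0)``; when ``rng`` is
    given, zero-mean Gaussian noise of sd ``noise_sd`` degrees is
    added.  Positive angles turn toward the left sector.
    """
    if L < 0 or R < 0:
        raise ValueError("concentrations must be nonnegative")
    denom = L + R + params.threshold
    alpha = params.gain * (L - R) / denom if denom > 0 else 0.0
    if rng is not None and params.noise_sd > 0:
        alpha += rng.normal(0.0, params.noise_sd)
    return float(alpha)


def sample_weber_observations(n: int, params: WeberParams, seed: int = 0,
                              conc_range=(1.0, 1000.0)):
    """Synthetic (L, R, alpha) turning observations.

    Sector concentrations are drawn log-uniformly over ``conc_range``
    (independently for the two sectors) and the turning angle follows
    the Weber response plus Gaussian noise of sd ``params.noise_sd``
    degrees.  Returns ``(L, R, alpha)`` arrays.
    """
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(conc_range[0]), np.log10(conc_range[1])
    L = 10 ** rng.uniform(lo, hi, n)
    R = 10 ** rng.uniform(lo, hi, n)
    alpha = params.gain * (L - R) / (L + R + params.threshold)
    if params.noise_sd > 0:
        alpha = alpha + rng.normal(0.0, params.noise_sd, n)
    return L, R, alpha


def fit_weber(L, R, alpha, n_bootstrap: int = 0, seed: int = 0) -> dict:
    """Nonlinear least-squares fit of the Weber turning response.

    Fits gain and threshold in ``alpha = A (L - R) / (L + R + T0)``.
    With ``n_bootstrap > 0``, case-resampling bootstrap standard errors
    are reported alongside the asymptotic (curve_fit) ones.
    """
    from scipy.optimize import curve_fit

    L = np.asarray(L, float); R = np.asarray(R, float); alpha = np.asarray(alpha, float)

    def model(X, gain, threshold):
        l, r = X
        return gain * (l - r) / (l + r + threshold)

    popt, pcov = curve_fit(model, (L, R), alpha, p0=[10.0, 1.0],
                           bounds=([-np.inf, 0.0], [np.inf, np.inf]))
    out = {
        "gain": float(popt[0]),
        "threshold": float(popt[1]),
        "gain_se": float(np.sqrt(pcov[0, 0])),
        "threshold_se": float(np.sqrt(pcov[1, 1])),
        "n": int(L.size),
    }
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty((n_bootstrap, 2))
        for b in range(n_bootstrap):
            idx = rng.integers(0, L.size, L.size)
            boots[b], _ = curve_fit(model, (L[idx], R[idx]), alpha[idx],
                                    p0=popt, bounds=([-np.inf, 0.0], [np.inf, np.inf]))
        out["gain_se_boot"] = float(boots[:, 0].std(ddof=1))
        out["threshold_se_boot"] = float(boots[:, 1].std(ddof=1))
    return out


def build_pheromone_map(traj: PlanarTrajectory, cell_size: float,
                        deposit_per_passage: float = 1.0,
                        origin=(0.0, 0.0), shape=None) -> PheromoneGrid:
    """Pheromone map from passage counts.

    Every time-sample of every agent deposits ``deposit_per_passage``
    into the cell it falls in, so total mass is exactly ``deposit *
    n_samples``.  This is the deposit-only (no evaporation) map
    estimate built from recorded passages.
    """
    if traj.n_agents == 0 or traj.n_steps == 0:
        raise ValueError("trajectory is empty")
    x = traj.x.reshape(-1)
    y = traj.y.reshape(-1)
    if shape is None:
        ncol = int(np.floor((x.max() - origin[0]) / cell_size)) + 1
        nrow = int(np.floor((y.max() - origin[1]) / cell_size)) + 1
    else:
        nrow, ncol = shape
    values = np.zeros((nrow, ncol))
    row = np.floor((y - origin[1]) / cell_size).astype(int)
    col = np.floor((x - origin[0]) / cell_size).astype(int)
    if (row < 0).any() or (col < 0).any() or (row >= nrow).any() or (col >= ncol).any():
        raise ValueError("trajectory leaves the grid")
    np.add.at(values, (row, col), deposit_per_passage)
    return PheromoneGrid(cell_size=cell_size, values=values, origin=origin)


def simulate_trail(n_ants: int, n_steps: int, weber: WeberParams,
                   sector: SectorSpec | None = None, *, arena: float = 50.0,
                   cell_size: float = 1.0, step_length: float = 1.0,
                   deposit: float = 1.0, evaporation: float = 0.01,
                   seed: int = 0, initial_grid: PheromoneGrid | None = None):
    """Spatially explicit trail formation under the Weber response.

    Each sensing step (one 0.4 s observation window) every ant senses
    its two front sectors, turns by the Weber angle plus Gaussian
    noise, advances ``step_length``, and deposits on its cell; the
    whole grid then decays by the evaporation fraction.  Walls are
    reflective.  Returns ``(PlanarTrajectory, PheromoneGrid)``.
    """
    if not 0.0 <= evaporation <= 1.0:
        raise ValueError("evaporation must lie in [0, 1]")
    sector = sector or SectorSpec(radius=5.0 * cell_size)
    rng = np.random.default_rng(seed)
    ncell = int(round(arena / cell_size))
    if initial_grid is None:
        values = np.zeros((ncell, ncell))
    else:
        values = initial_grid.values.copy()
        ncell = values.shape[0]
        cell_size = initial_grid.cell_size
        arena = ncell * cell_size
    grid = PheromoneGrid(cell_size=cell_size, values=values)
    x = rng.uniform(0.1 * arena, 0.9 * arena, n_ants)
    y = rng.uniform(0.1 * arena, 0.9 * arena, n_ants)
    heading = rng.uniform(0, TWO_PI, n_ants)
    X = np.empty((n_ants, n_steps)); Y = np.empty_like(X); H = np.empty_like(X)
    dt = 0.4  # one sensing step = one 400 ms observation window
    for t in range(n_steps):
        grid.values *= 1.0 - evaporation
        for i in range(n_ants):
            ant = AntState(x[i], y[i], heading[i])
            L, R = sector_concentrations(grid, ant, sector)
            alpha = weber_turn(L, R, weber, rng=rng)
            heading[i] = (heading[i] + np.deg2rad(alpha)) % TWO_PI
            nx_ = x[i] + step_length * np.cos(heading[i])
            ny_ = y[i] + step_length * np.sin(heading[i])
            # reflective walls (positions kept strictly inside the grid)
            pad = 1e-9 * arena
            if nx_ < 0 or nx_ > arena:
                heading[i] = (np.pi - heading[i]) % TWO_PI
            if ny_ < 0 or ny_ > arena:
                heading[i] = (-heading[i]) % TWO_PI
            x[i] = float(np.clip(nx_, pad, arena - pad))
            y[i] = float(np.clip(ny_, pad, arena - pad))
            row, col = grid.cell_of(x[i], y[i])
            grid.values[row, col] += deposit
        X[:, t], Y[:, t], H[:, t] = x, y, heading
    traj = PlanarTrajectory(dt=dt, times=np.arange(n_steps) * dt, x=X, y=Y, heading=H)
    return traj, grid


def loop_metric(grid: PheromoneGrid, percentile: float = 90.0) -> float:
    """Fraction of high-concentration mass lying on closed loops.

    Cells above the given percentile of all cell values form a graph
    (4-connectivity); a cell lies on a loop when at least one of its
    edges is not a bridge.  The metric is the mass on loop cells
    divided by the mass of all above-threshold cells: 0 for an empty
    grid or a straight trail segment, 1 for a closed circuit.
    """
    v = grid.values
    if v.sum() <= 0:
        return 0.0
    thr = np.percentile(v, percentile)
    rows, cols = np.nonzero(v > thr)
    if rows.size == 0:
        return 0.0
    G = nx.Graph()
    nodes = set(zip(rows.tolist(), cols.tolist()))
    G.add_nodes_from(nodes)
    for r, c in nodes:
        for dr, dc in ((0, 1), (1, 0)):
            if (r + dr, c + dc) in nodes:
                G.add_edge((r, c), (r + dr, c + dc))
    bridges = set(nx.bridges(G))
    on_loop = set()
    for u, w in G.edges():
        if (u, w) not in bridges and (w, u) not in bridges:
            on_loop.add(u)
            on_loop.add(w)
    denom = float(sum(v[r, c] for r, c in nodes))
    num = float(sum(v[r, c] for r, c in on_loop))
    return num / denom


def double_bridge_ode(flow: float, n: float, k: float, rho: float,
                      c0=(0.0, 0.0), t_max: float = 200.0, n_points: int = 500) -> pd.DataFrame:
    """Mean-field pheromone dynamics of the two-branch bridge assay.

    The probability of choosing branch A is the standard concentration
    choice function P_A = (k + cA)^n / ((k + cA)^n + (k + cB)^n), and
    each concentration obeys dc/dt = flow * P - rho * c.  With a linear
    response (n = 1) a symmetric start stays symmetric forever; with
    n > 1 and flow above 2 * rho * k / (n - 1) the symmetric state is
    unstable and one branch captures the flow.
    """
    if flow <= 0 or k <= 0 or rho <= 0:
        raise ValueError("flow, k and rho must be positive")
    if n < 1:
        raise ValueError("choice exponent must be >= 1")

    def rhs(_t, c):
        fa = (k + max(c[0], 0.0)) ** n
        fb = (k + max(c[1], 0.0)) ** n
        pa = fa / (fa + fb)
        return [flow * pa - rho * c[0], flow * (1.0 - pa) - rho * c[1]]

    times = np.linspace(0.0, t_max, n_points)
    sol = solve_ivp(rhs, (0.0, t_max), list(c0), t_eval=times, rtol=1e-9, atol=1e-12)
    return pd.DataFrame({"t": sol.t, "c_a": sol.y[0], "c_b": sol.y[1]})


def effective_choice_curve(weber: WeberParams, ratios, n_crossings: int = 1,
                           n_reps: int = 1000, base_concentration: float = 50.0,
                           seed: int = 0) -> pd.DataFrame:
    """Monte-Carlo branch-choice probability at a Y-junction.

    The two arms carry fixed concentrations ``base`` and ``ratio *
    base`` (the stronger arm on the left).  Approaching the junction
    the ant re-orients over ``n_crossings`` sensing steps, each adding
    a noisy Weber turn toward the side it perceives as stronger; it
    takes the left (stronger) arm when the accumulated turning angle is
    positive.  Averaging the essentially linear single-contact response
    over repeated noisy contacts produces the sharp, effectively
    nonlinear choice function that the mean-field bridge model assumes.
    Returns P(choose stronger branch) with Wilson 95% intervals.
    """
    if n_crossings < 1 or n_reps < 1:
        raise ValueError("n_crossings and n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for ratio in ratios:
        if ratio < 1:
            raise ValueError("ratios must be >= 1 (stronger branch relative to weaker)")
        L = base_concentration * ratio
        R = base_concentration
        drift = weber_turn(L, R, WeberParams(weber.gain, weber.threshold, 0.0))
        total = drift * n_crossings + rng.normal(
            0.0, weber.noise_sd * np.sqrt(n_crossings), n_reps
        )
        ties = total == 0.0
        if ties.any():
            total = total + np.where(ties, rng.choice([-1e-12, 1e-12], ties.size), 0.0)
        wins = int((total > 0).sum())
        lo, hi = proportion_confint(wins, n_reps, alpha=0.05, method="wilson")
        rows.append(
            {
                "ratio": ratio,
                "p_stronger": wins / n_reps,
                "ci_low": lo,
                "ci_high": hi,
                "n_reps": n_reps,
                "n_crossings": n_crossings,
            }
        )
    return pd.DataFrame(rows)
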