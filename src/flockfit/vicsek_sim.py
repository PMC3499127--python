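"""Alignment-in-radius self-propelled particle model and its order scan.

The canonical angular-noise variant: at every step each particle takes
the circular mean of the headings of all particles within interaction
radius ``r`` (itself included, periodic square box of side ``L``), adds
uniform angular noise on ``[-eta/2, +eta/2]``, and moves a distance
``v * dt`` along the new heading.  The update is synchronous.  The
scalar order parameter is the magnitude of the mean unit heading
vector: 0 for disordered motion, 1 for full alignment.  Increasing the
density or lowering the noise drives the group through the transition
from disorder to collective order.

The module also provides a generic linear-in-features interaction
simulator (:func:`simulate_interaction`) whose turning response is a
known linear combination of neighbour features; it is the data
generator for least-squares force matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajdata import TWO_PI, PlanarTrajectory

__all__ = [
    "VicsekConfig",
    "VicsekState",
    "init_state",
    "step",
    "order_parameter",
    "run",
    "scan_transition",
    "FORCE_FEATURES",
    "simulate_interaction",
]


@dataclass
class VicsekConfig:
    n: int = 100
    box: float = 10.0
    speed: float = 0.5
    radius: float = 1.0
    eta: float = 0.5
    dt: float = 1.0
    n_steps: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.n < 1 or self.box <= 0 or self.speed <= 0 or self.radius <= 0:
            raise ValueError("n >= 1 and box, speed, radius > 0 required")
        if not 0.0 <= self.eta <= TWO_PI:
            raise ValueError("noise amplitude must lie in [0, 2*pi]")


@dataclass
class VicsekState:
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray


def init_state(config: VicsekConfig, rng) -> VicsekState:
    return VicsekState(
        x=rng.uniform(0, config.box, config.n),
        y=rng.uniform(0, config.box, config.n),
        heading=rng.uniform(0, TWO_PI, config.n),
    )


def _neighbor_mask(state: VicsekState, box: float, radius: float) -> np.ndarray:
    dx = state.x[None, :] - state.x[:, None]
    dy = state.y[None, :] - state.y[:, None]
    # minimum-image convention on the periodic square
    dx -= box * np.round(dx / box)
    dy -= box * np.round(dy / box)
    return dx * dx + dy * dy <= radius * radius


def step(state: VicsekState, config: VicsekConfig, rng) -> VicsekState:
    """One synchronous update of every particle."""
    mask = _neighbor_mask(state, config.box, config.radius)  # self included
    c = mask @ np.cos(state.heading)
    s = mask @ np.sin(state.heading)
    mean = np.arctan2(s, c) % TWO_PI
    # zero resultant: keep the particle's previous heading
    degenerate = np.hypot(c, s) < 1e-12
    mean = np.where(degenerate, state.heading, mean)
    noise = rng.uniform(-config.eta / 2.0, config.eta / 2.0, config.n) if config.eta > 0 else 0.0
    heading = (mean + noise) % TWO_PI
    d = config.speed * config.dt
    return VicsekState(
        x=(state.x + d * np.cos(heading)) % config.box,
        y=(state.y + d * np.sin(heading)) % config.box,
        heading=heading,
    )


def order_parameter(state_or_headings) -> float:
    """Magnitude of the mean unit heading vector, in [0, 1].

    Accepts either a :class:`VicsekState` or a bare heading array.
    """
    if isinstance(state_or_headings, VicsekState):
        state_or_headings = state_or_headings.heading
    heading = np.asarray(state_or_headings, dtype=float)
    if heading.size == 0:
        raise ValueError("order parameter of an empty group is undefined")
    return float(np.hypot(np.cos(heading).mean(), np.sin(heading).mean()))


def run(config: VicsekConfig, rng=None, record: bool = False):
    """Simulate and return the final state, the order-parameter series,
    and (optionally) the full :class:`PlanarTrajectory`."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    state = init_state(config, rng)
    order = np.empty(config.n_steps)
    if record:
        X = np.empty((config.n, config.n_steps))
        Y = np.empty_like(X)
        H = np.empty_like(X)
    for t in range(config.n_steps):
        order[t] = order_parameter(state.heading)
        if record:
            X[:, t], Y[:, t], H[:, t] = state.x, state.y, state.heading
        if t < config.n_steps - 1:
            state = step(state, config, rng)
    traj = None
    if record:
        traj = PlanarTrajectory(
            dt=config.dt, times=np.arange(config.n_steps) * config.dt, x=X, y=Y, heading=H
        )
    return state, order, traj


def scan_transition(config: VicsekConfig, eta_grid=None, n_grid=None,
                    burn_in: int = 100, n_reps: int = 5) -> pd.DataFrame:
    """Mean +- s.e. of the time-averaged order parameter along a grid.

    Exactly one of ``eta_grid`` (noise amplitudes) or ``n_grid``
    (particle counts, i.e. density at fixed box size) must be given.
    The order parameter is averaged over the post-burn-in part of each
    replicate; replicates use consecutive seeds derived from
    ``config.seed``.
    """
    if (eta_grid is None) == (n_grid is None):
        raise ValueError("give exactly one of eta_grid or n_grid")
    if burn_in >= config.n_steps:
        raise ValueError("burn_in must be smaller than the number of steps")
    grid = list(eta_grid if eta_grid is not None else n_grid)
    name = "eta" if eta_grid is not None else "n"
    rows = []
    base = np.random.SeedSequence(config.seed)
    seeds = base.spawn(len(grid) * n_reps)
    k = 0
    for g in grid:
        vals = []
        for _ in range(n_reps):
            kwargs = {**config.__dict__}
            kwargs[name] = float(g) if name == "eta" else int(g)
            cfg = VicsekConfig(**kwargs)
            rng = np.random.default_rng(seeds[k]); k += 1
            _, order, _ = run(cfg, rng=rng)
            vals.append(order[burn_in:].mean())
        vals = np.asarray(vals)
        rows.append(
            {
                name: g,
                "order_mean": vals.mean(),
                "order_se": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0,
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# linear-in-features interaction dynamics (force-matching data generator)


def _alignment_feature(state: VicsekState, box: float, radius: float) -> np.ndarray:
    """Mean of sin(heading_j - heading_i) over neighbours within radius."""
    mask = _neighbor_mask(state, box, radius)
    np.fill_diagonal(mask, False)
    cnt = mask.sum(axis=1)
    dh = state.heading[None, :] - state.heading[:, None]
    out = (mask * np.sin(dh)).sum(axis=1)
    return np.divide(out, cnt, out=np.zeros_like(out), where=cnt > 0)


def _attraction_feature(state: VicsekState, box: float, radius: float) -> np.ndarray:
    """Mean of sin(bearing-to-neighbour - heading) over neighbours within radius."""
    mask = _neighbor_mask(state, box, radius)
    np.fill_diagonal(mask, False)
    dx = state.x[None, :] - state.x[:, None]
    dy = state.y[None, :] - state.y[:, None]
    dx -= box * np.round(dx / box)
    dy -= box * np.round(dy / box)
    bearing = np.arctan2(dy, dx)
    rel = np.sin(bearing - state.heading[:, None])
    cnt = mask.sum(axis=1)
    out = (mask * rel).sum(axis=1)
    return np.divide(out, cnt, out=np.zeros_like(out), where=cnt > 0)


#: turning-response features available to the force-matching engine
FORCE_FEATURES = {
    "alignment": _alignment_feature,
    "attraction": _attraction_feature,
}


def simulate_interaction(coeffs: dict, config: VicsekConfig, noise_sd: float = 0.0,
                         rng=None) -> PlanarTrajectory:
    """Planar dynamics whose turning response is linear in known features.

    Each step every particle turns by ``sum_k coeffs[k] * feature_k``
    plus Gaussian noise of standard deviation ``noise_sd`` (radians),
    then advances ``speed * dt``.  Because the turning law is linear in
    the coefficients, least-squares force matching can recover them
    exactly in the noise-free case.
    """
    unknown = set(coeffs) - set(FORCE_FEATURES)
    if unknown:
        raise KeyError(f"unknown force features {sorted(unknown)}")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    state = init_state(config, rng)
    T = config.n_steps
    X = np.empty((config.n, T)); Y = np.empty_like(X); H = np.empty_like(X)
    d = config.speed * config.dt
    for t in range(T):
        X[:, t], Y[:, t], H[:, t] = state.x, state.y, state.heading
        if t == T - 1:
            break
        turn = np.zeros(config.n)
        for name, beta in coeffs.items():
            turn += beta * FORCE_FEATURES[name](state, config.box, config.radius)
        if noise_sd > 0:
            turn += rng.normal(0.0, noise_sd, config.n)
        heading = (state.heading + turn) % TWO_PI
        state = VicsekState(
            x=(state.x + d * np.cos(heading)) % config.box,
            y=(state.y + d * np.sin(heading)) % config.box,
            heading=heading,
        )
    return PlanarTrajectory(dt=config.dt, times=np.arange(T) * config.dt, x=X, y=Y, heading=H)
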