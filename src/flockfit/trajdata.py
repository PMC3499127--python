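"""Trajectory and grid data model with delimited-text I/O.

Containers for the three kinds of movement records the toolkit works with:

* :class:`RingTrajectory` — agents on an annular (1-D circular) arena,
  described by angular position and a binary travel direction
  (+1 counter-clockwise, -1 clockwise).
* :class:`PlanarTrajectory` — 2-D positions and headings.
* :class:`PheromoneGrid` — a nonnegative lattice of pheromone
  concentration / passage counts.
* :class:`SwitchEventSequence` — the per-agent, per-step binary
  direction-change record extracted from a ring trajectory, together
  with the neighbour summary statistics every switching rule reads.

All files are comma-separated UTF-8 text with a header row.  The ring
schema is ``time,agent,theta,dir``; the planar schema is
``time,agent,x,y,heading[,speed]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RingTrajectory",
    "PlanarTrajectory",
    "PheromoneGrid",
    "SwitchEventSequence",
    "read_trajectory",
    "write_trajectory",
    "extract_events",
    "angular_separation",
    "wrap_angle",
    "ring_features",
]

TWO_PI = 2.0 * np.pi

#: accepted encodings of the clockwise / counter-clockwise direction state
_DIR_CODES = {"CW": -1, "CCW": 1, "-1": -1, "1": 1, "+1": 1}


class SchemaError(ValueError):
    """A required column is missing from a trajectory file."""


class TimingError(ValueError):
    """Timestamps are not uniformly spaced."""


def wrap_angle(a):
    """Wrap angles into the half-open interval ``(-pi, pi]``."""
    a = np.asarray(a, dtype=float)
    return -((-a + np.pi) % TWO_PI - np.pi)


def angular_separation(theta_a, theta_b, dir_a):
    """Signed forward separation of ``b`` from ``a`` on the ring.

    The separation is measured along ``a``'s direction of travel and
    lies in ``(-pi, pi]``: positive values mean ``b`` is ahead of ``a``,
    negative values behind.  Negating ``dir_a`` flips the sign (except
    for the antipode, which is always ``pi``).
    """
    return wrap_angle(np.asarray(dir_a) * (np.asarray(theta_b) - np.asarray(theta_a)))


def _check_uniform_times(times, rtol=1e-9):
    times = np.asarray(times, dtype=float)
    if times.size >= 2:
        steps = np.diff(times)
        dt = steps[0]
        if dt <= 0 or not np.allclose(steps, dt, rtol=rtol, atol=rtol * max(abs(dt), 1.0)):
            raise TimingError("timestamps must be strictly increasing with constant spacing")
    return times


@dataclass
class RingTrajectory:
    """Angular positions and travel directions of N agents on a ring.

    ``theta`` and ``dir`` are ``(n_agents, n_steps)`` arrays; ``dir``
    holds +1 (counter-clockwise) or -1 (clockwise).
    """

    dt: float
    times: np.ndarray
    theta: np.ndarray
    dir: np.ndarray

    def __post_init__(self):
        self.times = _check_uniform_times(self.times)
        self.theta = np.asarray(self.theta, dtype=float) % TWO_PI
        self.dir = np.asarray(self.dir)
        if self.theta.shape != self.dir.shape:
            raise ValueError("theta and dir must have the same shape")
        if self.theta.shape[-1] != self.times.size:
            raise ValueError("number of time points does not match times")
        if self.dir.size and not np.isin(self.dir, (-1, 1)).all():
            raise ValueError("dir values must be exactly +1 or -1")
        self.dir = self.dir.astype(int)

    @property
    def n_agents(self) -> int:
        return self.theta.shape[0]

    @property
    def n_steps(self) -> int:
        return self.theta.shape[1]

    def n_switches(self) -> int:
        """Total number of direction reversals across all agents."""
        if self.n_steps < 2:
            return 0
        return int((np.diff(self.dir, axis=1) != 0).sum())

    def __eq__(self, other):
        if not isinstance(other, RingTrajectory):
            return NotImplemented
        return (
            np.isclose(self.dt, other.dt)
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.theta, other.theta)
            and np.array_equal(self.dir, other.dir)
        )


@dataclass
class PlanarTrajectory:
    """2-D positions and headings of N agents over uniform timesteps."""

    dt: float
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    speed: np.ndarray | None = None

    def __post_init__(self):
        self.times = _check_uniform_times(self.times)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.heading = np.asarray(self.heading, dtype=float) % TWO_PI
        if not (self.x.shape == self.y.shape == self.heading.shape):
            raise ValueError("x, y and heading must share a shape")
        if self.x.shape[-1] != self.times.size:
            raise ValueError("number of time points does not match times")
        if self.speed is not None:
            self.speed = np.asarray(self.speed, dtype=float)
            if self.speed.shape != self.x.shape:
                raise ValueError("speed shape must match positions")

    @property
    def n_agents(self) -> int:
        return self.x.shape[0]

    @property
    def n_steps(self) -> int:
        return self.x.shape[1]

    def __eq__(self, other):
        if not isinstance(other, PlanarTrajectory):
            return NotImplemented
        same = (
            np.isclose(self.dt, other.dt)
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.heading, other.heading)
        )
        if not same:
            return False
        if (self.speed is None) != (other.speed is None):
            return False
        return self.speed is None or np.array_equal(self.speed, other.speed)


@dataclass
class PheromoneGrid:
    """Dense nonnegative lattice of pheromone concentration.

    ``values[i, j]`` is the concentration in the cell whose lower-left
    world corner is ``origin + (j, i) * cell_size`` (row index i = y,
    column index j = x).  Units are arbitrary: passage counts and
    physical concentration are treated as one pheromone unit.
    """

    cell_size: float
    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be a 2-D array")
        if (self.values < 0).any():
            raise ValueError("pheromone concentrations must be nonnegative")
        if not np.isfinite(self.values).all():
            raise ValueError("pheromone mass must be finite")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self):
        return self.values.shape

    def total_mass(self) -> float:
        return float(self.values.sum())

    def cell_of(self, x, y):
        """Map world coordinates to (row, col) cell indices."""
        col = np.floor((np.asarray(x) - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.origin[1]) / self.cell_size).astype(int)
        return row, col

    def cell_centers(self):
        ny, nx = self.values.shape
        cx = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        cy = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return cx, cy


# ---------------------------------------------------------------------------
# switch events


@dataclass
class NeighborContext:
    """Configuration of the other agents as seen by one focal agent.

    ``separations`` are signed forward angular separations in
    ``(-pi, pi]`` (positive = ahead of the focal agent); ``rel_dirs``
    are +1 for neighbours travelling with the focal agent and -1 for
    neighbours travelling against it.  ``memory_state`` is the scalar
    carried between timesteps by non-Markovian rules (refractory
    counter or decaying encounter trace); it starts at zero.
    """

    separations: np.ndarray
    rel_dirs: np.ndarray
    memory_state: float = 0.0

    def __post_init__(self):
        self.separations = np.atleast_1d(np.asarray(self.separations, dtype=float))
        self.rel_dirs = np.atleast_1d(np.asarray(self.rel_dirs))
        if self.separations.shape != self.rel_dirs.shape:
            raise ValueError("separations and rel_dirs must match")
        if self.memory_state < 0:
            raise ValueError("memory_state must be nonnegative")

    # summary features read by the switching rules ------------------------
    @property
    def f_opp(self) -> float:
        """Fraction of the other agents travelling opposite to the focal."""
        n = self.rel_dirs.size
        return float((self.rel_dirs == -1).sum() / n) if n else 0.0

    @property
    def fwd_opp(self) -> float:
        """Distance to the nearest opposite-direction agent ahead (inf if none)."""
        s = self.separations[(self.rel_dirs == -1) & (self.separations >= 0)]
        return float(s.min()) if s.size else np.inf

    @property
    def abs_opp(self) -> float:
        """Smallest |separation| to any opposite-direction agent (inf if none)."""
        s = np.abs(self.separations[self.rel_dirs == -1])
        return float(s.min()) if s.size else np.inf

    @property
    def nearest_opp(self) -> float:
        """Signed separation of the nearest opposite-direction agent (nan if none)."""
        mask = self.rel_dirs == -1
        if not mask.any():
            return np.nan
        s = self.separations[mask]
        return float(s[np.argmin(np.abs(s))])


def ring_features(theta, dirs):
    """Per-agent neighbour summaries for one ring snapshot.

    Returns ``(f_opp, fwd_opp, abs_opp, nearest_opp)`` arrays of length
    N.  These are exactly the statistics the switching rules read, and
    the same function is used by the simulator and by event extraction
    so the two stay consistent.
    """
    theta = np.asarray(theta, dtype=float)
    dirs = np.asarray(dirs)
    n = theta.size
    f_opp = np.zeros(n)
    fwd = np.full(n, np.inf)
    ab = np.full(n, np.inf)
    near = np.full(n, np.nan)
    if n < 2:
        return f_opp, fwd, ab, near
    # sep[i, j]: forward separation of j as seen from i
    sep = wrap_angle(dirs[:, None] * (theta[None, :] - theta[:, None]))
    opp = dirs[None, :] != dirs[:, None]
    np.fill_diagonal(opp, False)
    f_opp = opp.sum(axis=1) / (n - 1)
    for i in range(n):
        s = sep[i, opp[i]]
        if s.size:
            ahead = s[s >= 0]
            if ahead.size:
                fwd[i] = ahead.min()
            ab[i] = np.abs(s).min()
            near[i] = s[np.argmin(np.abs(s))]
    return f_opp, fwd, ab, near


@dataclass
class SwitchEventSequence:
    """Binary direction-change record with neighbour context per event.

    Stored column-wise, sorted by (series, time index).  A *series* is
    one agent in one source trajectory; memory-carrying models thread
    their state independently along each series.  ``y[k] = 1`` iff the
    agent reversed direction between time index ``t_index[k]`` and
    ``t_index[k] + 1``; all context columns are evaluated at
    ``t_index[k]``.
    """

    agent: np.ndarray
    t_index: np.ndarray
    y: np.ndarray
    f_opp: np.ndarray
    fwd_opp: np.ndarray
    abs_opp: np.ndarray
    nearest_opp: np.ndarray
    series: np.ndarray = None  # series label per record
    contexts: list | None = field(default=None, repr=False)

    def __post_init__(self):
        self.agent = np.asarray(self.agent, dtype=int)
        self.t_index = np.asarray(self.t_index, dtype=int)
        self.y = np.asarray(self.y, dtype=int)
        if self.y.size and not np.isin(self.y, (0, 1)).all():
            raise ValueError("switch indicators must be 0 or 1")
        for name in ("f_opp", "fwd_opp", "abs_opp", "nearest_opp"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.series is None:
            self.series = self.agent.copy()
        self.series = np.asarray(self.series, dtype=int)
        order = np.lexsort((self.t_index, self.series))
        if not np.array_equal(order, np.arange(order.size)):
            for name in ("agent", "t_index", "y", "f_opp", "fwd_opp",
                         "abs_opp", "nearest_opp", "series"):
                setattr(self, name, getattr(self, name)[order])
            if self.contexts is not None:
                self.contexts = [self.contexts[i] for i in order]
        key = np.stack([self.series, self.t_index])
        if np.unique(key, axis=1).shape[1] != key.shape[1]:
            raise ValueError("duplicate (agent, time index) records")

    def __len__(self):
        return self.y.size

    @property
    def n_events(self) -> int:
        return self.y.size

    @property
    def n_switches(self) -> int:
        return int(self.y.sum())

    def series_slices(self):
        """Yield ``slice`` objects covering each series in storage order."""
        if not len(self):
            return
        bounds = np.flatnonzero(np.diff(self.series) != 0) + 1
        edges = np.concatenate([[0], bounds, [len(self)]])
        for a, b in zip(edges[:-1], edges[1:]):
            yield slice(int(a), int(b))

    def local_index(self):
        """Position of each record within its own series (0-based)."""
        out = np.empty(len(self), dtype=int)
        for sl in self.series_slices():
            out[sl] = np.arange(sl.stop - sl.start)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "series": self.series,
                "agent": self.agent,
                "t_index": self.t_index,
                "y": self.y,
                "f_opp": self.f_opp,
                "fwd_opp": self.fwd_opp,
                "abs_opp": self.abs_opp,
                "nearest_opp": self.nearest_opp,
            }
        )

    @staticmethod
    def concat(parts: list["SwitchEventSequence"]) -> "SwitchEventSequence":
        """Concatenate independent event sets.

        Series labels are offset so memory threading never crosses the
        boundary between two source sequences.
        """
        cols = {n: [] for n in ("agent", "t_index", "y", "f_opp", "fwd_opp",
                                "abs_opp", "nearest_opp", "series")}
        offset = 0
        for p in parts:
            for n in cols:
                cols[n].append(getattr(p, n) if n != "series" else p.series + offset)
            if len(p):
                offset += int(p.series.max()) + 1
        return SwitchEventSequence(**{n: np.concatenate(v) if v else np.array([]) for n, v in cols.items()})


def extract_events(traj: RingTrajectory, context_builder=ring_features,
                   keep_contexts: bool = False) -> SwitchEventSequence:
    """Turn a ring trajectory into its switch-event sequence.

    For each agent and each time index ``t < T-1`` a record is emitted
    with ``y = 1`` iff the direction at ``t+1`` differs from the
    direction at ``t``, and the neighbour context evaluated at ``t``.
    ``context_builder(theta_t, dir_t)`` must return the per-agent
    feature tuple of :func:`ring_features`.
    """
    if traj.n_steps < 2:
        raise ValueError("no transitions observable: trajectory has fewer than 2 time points")
    n, T = traj.n_agents, traj.n_steps
    y = (np.diff(traj.dir, axis=1) != 0).astype(int)  # (n, T-1)
    f_opp = np.empty((n, T - 1))
    fwd = np.empty((n, T - 1))
    ab = np.empty((n, T - 1))
    near = np.empty((n, T - 1))
    contexts = [] if keep_contexts else None
    for t in range(T - 1):
        f_opp[:, t], fwd[:, t], ab[:, t], near[:, t] = context_builder(
            traj.theta[:, t], traj.dir[:, t]
        )
        if keep_contexts:
            th, dd = traj.theta[:, t], traj.dir[:, t]
            for i in range(n):
                others = np.arange(n) != i
                contexts.append(
                    NeighborContext(
                        separations=angular_separation(th[i], th[others], dd[i]),
                        rel_dirs=dd[others] * dd[i],
                    )
                )
    agents = np.repeat(np.arange(n), T - 1)
    tidx = np.tile(np.arange(T - 1), n)
    if keep_contexts:
        # reorder contexts from time-major to agent-major
        contexts = [contexts[t * n + i] for i in range(n) for t in range(T - 1)]
    return SwitchEventSequence(
        agent=agents,
        t_index=tidx,
        y=y.reshape(-1),
        f_opp=f_opp.reshape(-1),
        fwd_opp=fwd.reshape(-1),
        abs_opp=ab.reshape(-1),
        nearest_opp=near.reshape(-1),
        contexts=contexts,
    )


# ---------------------------------------------------------------------------
# file I/O

_RING_COLS = ["time", "agent", "theta", "dir"]
_PLANAR_COLS = ["time", "agent", "x", "y", "heading"]


def _coerce_dir(values):
    out = np.empty(len(values), dtype=int)
    for i, v in enumerate(values):
        key = str(v).strip().upper()
        try:
            key = str(int(float(key)))
        except ValueError:
            pass
        if key not in _DIR_CODES:
            raise ValueError(
                f"direction value {v!r} not in {{-1, +1, 'CW', 'CCW'}}"
            )
        out[i] = _DIR_CODES[key]
    return out


def read_trajectory(path, kind: str):
    """Read a ring or planar trajectory from a CSV file.

    Rows may appear in any order; they are sorted by (agent, time).
    The ring direction column accepts -1/+1 or the labels ``CW``
    (clockwise, coded -1) / ``CCW`` (counter-clockwise, coded +1).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"ring": _RING_COLS, "planar": _PLANAR_COLS}.get(kind)
    if required is None:
        raise ValueError(f"unknown trajectory kind {kind!r}")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    df = df.sort_values(["agent", "time"], kind="mergesort").reset_index(drop=True)
    agents = df["agent"].unique()
    times = np.sort(df["time"].unique())
    times = _check_uniform_times(times)
    dt = float(times[1] - times[0]) if times.size >= 2 else 0.0
    n, T = agents.size, times.size
    if len(df) != n * T:
        raise ValueError("file does not contain one row per (agent, time) pair")

    def pivot(col):
        return df[col].to_numpy().reshape(n, T)

    if kind == "ring":
        dirs = _coerce_dir(df["dir"].tolist()).reshape(n, T)
        return RingTrajectory(dt=dt, times=times, theta=pivot("theta"), dir=dirs)
    speed = pivot("speed") if "speed" in df.columns else None
    return PlanarTrajectory(
        dt=dt, times=times, x=pivot("x"), y=pivot("y"), heading=pivot("heading"), speed=speed
    )


def write_trajectory(traj, path):
    """Write a trajectory as CSV so that it round-trips bit-exactly."""
    if isinstance(traj, RingTrajectory):
        n, T = traj.theta.shape
        df = pd.DataFrame(
            {
                "time": np.tile(traj.times, n),
                "agent": np.repeat(np.arange(n), T),
                "theta": traj.theta.reshape(-1),
                "dir": traj.dir.reshape(-1),
            }
        )
    elif isinstance(traj, PlanarTrajectory):
        n, T = traj.x.shape
        df = pd.DataFrame(
            {
                "time": np.tile(traj.times, n),
                "agent": np.repeat(np.arange(n), T),
                "x": traj.x.reshape(-1),
                "y": traj.y.reshape(-1),
                "heading": traj.heading.reshape(-1),
            }
        )
        if traj.speed is not None:
            df["speed"] = traj.speed.reshape(-1)
    else:
        raise TypeError(f"cannot write object of type {type(traj).__name__}")
    # 17 significant digits round-trip any double, so read(write(t)) == t bit-exact
    df.to_csv(path, index=False, float_format="%.17g")
    return path
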