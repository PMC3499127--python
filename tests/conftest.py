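import numpy as np
import pytest

from flockfit.trajdata import PlanarTrajectory, RingTrajectory, SwitchEventSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def two_agent_ring():
    """Hand-built two-agent ring trajectory with one reversal (agent 1, t=2->3)."""
    return RingTrajectory(
        dt=0.4,
        times=np.arange(5) * 0.4,
        theta=np.array([[0.0, 0.1, 0.2, 0.3, 0.4], [3.0, 2.9, 2.8, 2.9, 3.0]]),
        dir=np.array([[1, 1, 1, 1, 1], [-1, -1, -1, 1, 1]]),
    )


@pytest.fixture
def straight_planar():
    t = np.arange(10, dtype=float)
    return PlanarTrajectory(
        dt=1.0,
        times=t,
        x=np.vstack([t, t + 1.0]),
        y=np.vstack([np.zeros(10), np.ones(10)]),
        heading=np.zeros((2, 10)),
        speed=np.ones((2, 10)),
    )


def random_ring(rng, n_agents=3, n_steps=8, dt=0.5):
    """Randomised ring trajectory for round-trip property tests."""
    return RingTrajectory(
        dt=dt,
        times=np.arange(n_steps) * dt,
        theta=rng.uniform(0, 2 * np.pi, (n_agents, n_steps)),
        dir=rng.choice([-1, 1], (n_agents, n_steps)),
    )


def hand_events(y, fwd_opp, f_opp=None):
    """Single-series event sequence with fabricated neighbour contexts."""
    y = np.asarray(y)
    fwd = np.asarray(fwd_opp, dtype=float)
    n = y.size
    return SwitchEventSequence(
        agent=np.zeros(n, dtype=int),
        t_index=np.arange(n),
        y=y,
        f_opp=np.ones(n) if f_opp is None else np.asarray(f_opp, float),
        fwd_opp=fwd,
        abs_opp=fwd,
        nearest_opp=fwd,
    )
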