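"""Candidate direction-switching rules for ring agents.

Four families of rules give the per-timestep probability that a focal
agent reverses its travel direction, given the configuration of the
other agents:

``meanfield``
    p = p0 + k * f_opp, where f_opp is the fraction of all other agents
    travelling opposite to the focal one.  Markovian and non-spatial.
``zone``
    p = p1 if an opposite-direction agent sits in the forward
    interaction zone (angular separation in [0, w] ahead), else p0.
    Markovian and spatial; w = pi makes the rule non-local (any
    opposite agent anywhere ahead triggers it).
``d1``
    Refractory memory: an encounter (opposite agent in the zone) arms a
    countdown of ``tau`` timesteps during which the switch probability
    stays elevated at p1; otherwise p0.  Non-Markovian.
``d2``
    Decaying-trace memory: M <- (1 - lam) * M + 1{encounter};
    p = p0 + k * M.  With lam = 1 this collapses to the one-step zone
    rule with p1 = p0 + k.  Non-Markovian.

Only opposite-direction neighbours enter any rule; same-direction
neighbours are ignored.  All probabilities are clipped to
``[EPS, 1 - EPS]`` so log-likelihoods stay finite.

Each model exposes a scalar :meth:`SwitchingModel.prob` operating on a
single :class:`~flockfit.trajdata.NeighborContext` (threading memory
through ``context.memory_state``) and a vectorised
:meth:`SwitchingModel.prob_events` operating on a whole
:class:`~flockfit.trajdata.SwitchEventSequence`; the two paths are
cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .trajdata import NeighborContext, SwitchEventSequence

__all__ = [
    "EPS",
    "SwitchingModelSpec",
    "SwitchingModel",
    "ConstantRateModel",
    "MeanFieldModel",
    "ZoneModel",
    "MemoryD1Model",
    "MemoryD2Model",
    "MODEL_REGISTRY",
    "get_model",
    "p_meanfield",
    "p_zone",
    "p_memory_d1",
    "p_memory_d2",
]

#: probability clipping bound guarding the log-likelihood
EPS = 1e-9


def _clip(p):
    return np.clip(p, EPS, 1.0 - EPS)


@dataclass(frozen=True)
class SwitchingModelSpec:
    """Name, parameters and bounds of one switching rule."""

    name: str
    param_names: tuple
    bounds: tuple  # (lo, hi) per parameter, same order as param_names
    markovian: bool
    #: parameters over which the likelihood is piecewise constant; the
    #: fitting engine profiles these on a candidate grid.
    grid_params: tuple = ()

    def __post_init__(self):
        if self.markovian == self.requires_memory:
            pass  # property below enforces the complement

    @property
    def requires_memory(self) -> bool:
        return not self.markovian

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def check_params(self, params: dict):
        for name, (lo, hi) in zip(self.param_names, self.bounds):
            v = params[name]
            if not (lo <= v <= hi):
                raise ValueError(
                    f"{self.name}: parameter {name}={v} outside bounds [{lo}, {hi}]"
                )


def _zone_encounter(context: NeighborContext, w: float, symmetric: bool = False) -> bool:
    d = context.abs_opp if symmetric else context.fwd_opp
    return bool(d <= w)


class SwitchingModel:
    """Base class; subclasses define the probability rule."""

    spec: SwitchingModelSpec
    symmetric_zone = False  # forward-only zone by default

    def prob(self, params: dict, context: NeighborContext) -> float:
        raise NotImplementedError

    def prob_events(self, params: dict, events: SwitchEventSequence) -> np.ndarray:
        raise NotImplementedError

    def step_probs(self, params, f_opp, fwd_opp, abs_opp, mem):
        """Vectorised one-step probabilities for the simulator.

        ``mem`` is the per-agent memory array (ignored and returned
        unchanged by Markovian rules).  Returns ``(p, new_mem)``.
        """
        raise NotImplementedError

    def reset_memory(self, n_agents: int) -> np.ndarray:
        return np.zeros(n_agents)

    def _zone_dist(self, events: SwitchEventSequence):
        return events.abs_opp if self.symmetric_zone else events.fwd_opp


class MeanFieldModel(SwitchingModel):
    """Global-configuration rule: p = p0 + k * fraction-opposite."""

    spec = SwitchingModelSpec(
        name="meanfield",
        param_names=("p0", "k"),
        bounds=((0.0, 1.0), (-1.0, 1.0)),
        markovian=True,
    )

    def prob(self, params, context):
        return float(_clip(params["p0"] + params["k"] * context.f_opp))

    def prob_events(self, params, events):
        return _clip(params["p0"] + params["k"] * events.f_opp)

    def step_probs(self, params, f_opp, fwd_opp, abs_opp, mem):
        return _clip(params["p0"] + params["k"] * f_opp), mem


class ZoneModel(SwitchingModel):
    """Markovian zonal rule: elevated rate with an opposite agent in the zone."""

    spec = SwitchingModelSpec(
        name="zone",
        param_names=("p0", "p1", "w"),
        bounds=((0.0, 1.0), (0.0, 1.0), (1e-6, np.pi)),
        markovian=True,
        grid_params=("w",),
    )

    def prob(self, params, context):
        hit = _zone_encounter(context, params["w"], self.symmetric_zone)
        return float(_clip(params["p1"] if hit else params["p0"]))

    def prob_events(self, params, events):
        hit = self._zone_dist(events) <= params["w"]
        return _clip(np.where(hit, params["p1"], params["p0"]))

    def step_probs(self, params, f_opp, fwd_opp, abs_opp, mem):
        d = abs_opp if self.symmetric_zone else fwd_opp
        return _clip(np.where(d <= params["w"], params["p1"], params["p0"])), mem


def _windowed_any(enc: np.ndarray, tau: int) -> np.ndarray:
    """active[t] = any(enc[max(0, t - tau + 1) .. t]) along a 1-D series."""
    cs = np.concatenate([[0], np.cumsum(enc)])
    t = np.arange(enc.size)
    lo = np.maximum(t - tau + 1, 0)
    return (cs[t + 1] - cs[lo]) > 0


class MemoryD1Model(SwitchingModel):
    """Refractory memory rule (non-Markovian).

    The memory state is a countdown: set to ``tau`` on an encounter,
    decremented (floored at 0) otherwise.  The switch probability is p1
    while the countdown is positive, else p0 — so a single encounter
    keeps the rate elevated for ``tau`` consecutive timesteps.
    """

    spec = SwitchingModelSpec(
        name="d1",
        param_names=("p0", "p1", "w", "tau"),
        bounds=((0.0, 1.0), (0.0, 1.0), (1e-6, np.pi), (1, 30)),
        markovian=False,
        grid_params=("w", "tau"),
    )

    def prob(self, params, context):
        enc = _zone_encounter(context, params["w"], self.symmetric_zone)
        if enc:
            context.memory_state = float(int(round(params["tau"])))
        else:
            context.memory_state = max(context.memory_state - 1.0, 0.0)
        return float(_clip(params["p1"] if context.memory_state > 0 else params["p0"]))

    def prob_events(self, params, events):
        tau = int(round(params["tau"]))
        dist = self._zone_dist(events)
        enc = dist <= params["w"]
        active = np.empty(len(events), dtype=bool)
        for sl in events.series_slices():
            active[sl] = _windowed_any(enc[sl], tau)
        return _clip(np.where(active, params["p1"], params["p0"]))

    def step_probs(self, params, f_opp, fwd_opp, abs_opp, mem):
        d = abs_opp if self.symmetric_zone else fwd_opp
        enc = d <= params["w"]
        mem = np.where(enc, float(int(round(params["tau"]))), np.maximum(mem - 1.0, 0.0))
        return _clip(np.where(mem > 0, params["p1"], params["p0"])), mem


class MemoryD2Model(SwitchingModel):
    """Decaying encounter-trace rule (non-Markovian).

    M <- (1 - lam) * M + 1{encounter}; p = p0 + k * M.  Under constant
    encounters M converges to 1/lam; with lam = 1 the trace is the
    current encounter indicator and the rule reduces to a zone rule
    with p1 = p0 + k.
    """

    spec = SwitchingModelSpec(
        name="d2",
        param_names=("p0", "k", "w", "lam"),
        bounds=((0.0, 1.0), (0.0, 1.0), (1e-6, np.pi), (1e-3, 1.0)),
        markovian=False,
        grid_params=("w", "lam"),
    )

    def prob(self, params, context):
        enc = _zone_encounter(context, params["w"], self.symmetric_zone)
        context.memory_state = (1.0 - params["lam"]) * context.memory_state + float(enc)
        return float(_clip(params["p0"] + params["k"] * context.memory_state))

    def trace(self, params, events):
        """The memory trace M at every event (depends on w and lam only)."""
        enc = (self._zone_dist(events) <= params["w"]).astype(float)
        M = np.empty(len(events))
        a = 1.0 - params["lam"]
        for sl in events.series_slices():
            # M_t = enc_t + a * M_{t-1}  ==  IIR filter with a-feedback
            M[sl] = lfilter([1.0], [1.0, -a], enc[sl])
        return M

    def prob_events(self, params, events):
        return _clip(params["p0"] + params["k"] * self.trace(params, events))

    def step_probs(self, params, f_opp, fwd_opp, abs_opp, mem):
        d = abs_opp if self.symmetric_zone else fwd_opp
        enc = (d <= params["w"]).astype(float)
        mem = (1.0 - params["lam"]) * mem + enc
        return _clip(params["p0"] + params["k"] * mem), mem


class ConstantRateModel(SwitchingModel):
    """Context-free baseline: a single constant switch probability."""

    spec = SwitchingModelSpec(
        name="const",
        param_names=("p0",),
        bounds=((0.0, 1.0),),
        markovian=True,
    )

    def prob(self, params, context):
        return float(_clip(params["p0"]))

    def prob_events(self, params, events):
        return _clip(np.full(len(events), params["p0"]))

    def step_probs(self, params, f_opp, fwd_opp, abs_opp, mem):
        return _clip(np.full(f_opp.shape, params["p0"])), mem


MODEL_REGISTRY: dict[str, type[SwitchingModel]] = {
    "const": ConstantRateModel,
    "meanfield": MeanFieldModel,
    "zone": ZoneModel,
    "d1": MemoryD1Model,
    "d2": MemoryD2Model,
}


def get_model(name: str, symmetric_zone: bool = False) -> SwitchingModel:
    """Instantiate a registered model by name.

    ``symmetric_zone=True`` switches zonal rules from the default
    forward-only zone ([0, w] ahead) to a symmetric zone (|s| <= w).
    """
    try:
        cls = MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown switching model {name!r}; registry: {sorted(MODEL_REGISTRY)}"
        ) from None
    model = cls()
    model.symmetric_zone = symmetric_zone
    return model


# -- convenience functional forms ------------------------------------------

def p_meanfield(params, context):
    """Mean-field switch probability (scalar convenience wrapper)."""
    return MeanFieldModel().prob(params, context)


def p_zone(params, context):
    """Zonal switch probability (scalar convenience wrapper)."""
    return ZoneModel().prob(params, context)


def p_memory_d1(params, context):
    """Refractory-memory switch probability; updates ``context.memory_state``."""
    return MemoryD1Model().prob(params, context)


def p_memory_d2(params, context):
    """Decaying-trace switch probability; updates ``context.memory_state``."""
    return MemoryD2Model().prob(params, context)
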