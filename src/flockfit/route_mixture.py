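"""Route distributions for repeated journeys and paired-flight mixtures.

Homing pigeons released repeatedly from the same site develop
idiosyncratic habitual routes.  This module represents an individual's
route repertoire as a *station-wise Gaussian cross-track model*: each
solo path is resampled to a fixed number of arc-length stations, and at
every station the repertoire is summarised by the mean position and the
standard deviation of the signed cross-track deviation from the mean
path.  That representation supports

* a path log-likelihood (how probable a given flight is under a bird's
  solo repertoire),
* *route fidelity* — the reciprocal of the mean cross-track standard
  deviation, our operationalisation of a bird's loyalty to its route,
* a paired-flight model: the path flown together is scored under a
  weighted mixture ``w * phi_self + (1 - w) * phi_partner`` of the two
  birds' solo distributions, with no explicit interaction rule, and
* selection between weight models — a constant weight versus a weight
  that depends logistically on the focal bird's route fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .trajdata import PlanarTrajectory

__all__ = [
    "RouteDistribution",
    "PairWeightModel",
    "PairObservation",
    "resample_path",
    "fit_route_distribution",
    "path_loglik",
    "pair_mixture_loglik",
    "fit_pair_weight",
    "route_fidelity",
]


@dataclass
class RouteDistribution:
    """Arc-length-parameterised mean path with cross-track spread.

    ``stations`` is an ``(n_stations, 2)`` array of mean positions
    ordered from release point to home; ``cross_track_sd`` the per
    station standard deviation of signed perpendicular deviations,
    floored at a positive minimum.
    """

    stations: np.ndarray
    cross_track_sd: np.ndarray
    n_paths: int

    def __post_init__(self):
        self.stations = np.asarray(self.stations, dtype=float)
        self.cross_track_sd = np.asarray(self.cross_track_sd, dtype=float)
        if self.stations.ndim != 2 or self.stations.shape[1] != 2:
            raise ValueError("stations must be an (n, 2) array")
        if self.cross_track_sd.shape != (self.stations.shape[0],):
            raise ValueError("one cross-track sd per station required")
        if (self.cross_track_sd <= 0).any():
            raise ValueError("cross-track sd must be positive everywhere")

    @property
    def n_stations(self) -> int:
        return self.stations.shape[0]

    def normals(self) -> np.ndarray:
        """Unit normals to the mean path (left of travel positive)."""
        t = np.gradient(self.stations, axis=0)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        return np.column_stack([-t[:, 1], t[:, 0]])

    def cross_track_deviation(self, path_xy: np.ndarray) -> np.ndarray:
        """Signed cross-track deviation of a station-resampled path."""
        if path_xy.shape != self.stations.shape:
            raise ValueError("path must be resampled to the distribution's stations")
        return np.einsum("ij,ij->i", path_xy - self.stations, self.normals())


@dataclass
class PairWeightModel:
    """Weight model for the paired-flight mixture.

    ``constant``: one weight ``w`` on the focal bird's own
    distribution.  ``fidelity_logistic``: ``w = sigmoid(a + b *
    fidelity)``, so a positive slope means route-faithful birds weight
    their own route more and yield less to the partner.
    """

    kind: str
    params: dict

    def weight(self, fidelity: float | None = None) -> float:
        if self.kind == "constant":
            return float(self.params["w"])
        if self.kind == "fidelity_logistic":
            if fidelity is None:
                raise ValueError("fidelity covariate required")
            z = self.params["a"] + self.params["b"] * fidelity
            return float(1.0 / (1.0 + np.exp(-z)))
        raise ValueError(f"unknown weight model kind {self.kind!r}")

    @property
    def n_params(self) -> int:
        return len(self.params)


@dataclass
class PairObservation:
    """One paired flight seen from one focal bird.

    ``path`` is the flight actually flown; ``dist_self`` and
    ``dist_partner`` the two solo route distributions; ``fidelity`` the
    focal bird's route fidelity (used by the logistic weight model).
    """

    path: PlanarTrajectory
    dist_self: RouteDistribution
    dist_partner: RouteDistribution
    fidelity: float | None = None


def _path_xy(path) -> np.ndarray:
    if isinstance(path, PlanarTrajectory):
        if path.n_agents != 1:
            raise ValueError("a route path must contain exactly one agent")
        return np.column_stack([path.x[0], path.y[0]])
    xy = np.asarray(path, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("path must be an (n, 2) array or single-agent trajectory")
    return xy


def resample_path(path, n_stations: int) -> np.ndarray:
    """Resample a path to equally spaced arc-length stations."""
    xy = _path_xy(path)
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        return np.repeat(xy[:1], n_stations, axis=0)
    grid = np.linspace(0.0, s[-1], n_stations)
    return np.column_stack([np.interp(grid, s, xy[:, 0]), np.interp(grid, s, xy[:, 1])])


def fit_route_distribution(paths, n_stations: int = 100, sd_floor: float = 1e-3,
                           endpoint_tol: float | None = None) -> RouteDistribution:
    """Infer a route distribution from repeated solo paths.

    Every path is resampled to ``n_stations`` arc-length stations; the
    distribution is the station-wise mean position and the standard
    deviation of signed cross-track deviations from the mean path,
    floored at ``sd_floor``.  Paths must share endpoints (release point
    and home) within ``endpoint_tol`` (default: 5% of the mean route
    length).
    """
    if len(paths) < 2:
        raise ValueError("need at least 2 solo paths")
    resampled = np.stack([resample_path(p, n_stations) for p in paths])
    lengths = [np.linalg.norm(np.diff(_path_xy(p), axis=0), axis=1).sum() for p in paths]
    tol = endpoint_tol if endpoint_tol is not None else 0.05 * np.mean(lengths)
    for end in (0, -1):
        pts = resampled[:, end, :]
        if np.linalg.norm(pts - pts.mean(axis=0), axis=1).max() > tol:
            raise ValueError("paths do not share endpoints within tolerance")
    mean = resampled.mean(axis=0)
    dist = RouteDistribution(stations=mean,
                             cross_track_sd=np.full(n_stations, sd_floor),
                             n_paths=len(paths))
    dev = np.stack([dist.cross_track_deviation(r) for r in resampled])
    sd = dev.std(axis=0)  # population sd: two paths offset +-d give sd = d
    dist.cross_track_sd = np.maximum(sd, sd_floor)
    return dist


def _aligned(path, n_stations):
    """Station-align a path; inputs with exactly n_stations points are
    taken as already station-aligned."""
    xy = _path_xy(path)
    if xy.shape[0] == n_stations:
        return xy
    return resample_path(xy, n_stations)


def path_loglik(path, dist: RouteDistribution) -> float:
    """Gaussian cross-track log-likelihood of a path under a distribution."""
    xy = _aligned(path, dist.n_stations)
    dev = dist.cross_track_deviation(xy)
    return float(norm.logpdf(dev, scale=dist.cross_track_sd).sum())


def pair_mixture_loglik(path, dist1: RouteDistribution, dist2: RouteDistribution,
                        w: float) -> float:
    """Log-likelihood of a paired path under the two-bird mixture.

    Station-wise, the density is ``w * phi_1 + (1 - w) * phi_2`` where
    ``phi_i`` is the Gaussian cross-track density under bird i's solo
    distribution.  Swapping the distributions and replacing ``w`` by
    ``1 - w`` leaves the value unchanged.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("mixture weight must lie in [0, 1]")
    if dist1.n_stations != dist2.n_stations:
        raise ValueError("distributions must share a station grid")
    xy = _aligned(path, dist1.n_stations)
    logphi1 = norm.logpdf(dist1.cross_track_deviation(xy), scale=dist1.cross_track_sd)
    logphi2 = norm.logpdf(dist2.cross_track_deviation(xy), scale=dist2.cross_track_sd)
    with np.errstate(divide="ignore"):  # w = 0 or 1 degenerates cleanly
        terms = np.logaddexp(np.log(w) + logphi1, np.log1p(-w) + logphi2)
    return float(terms.sum())


def _observations(paths, dist1, dist2, fidelities):
    if paths and isinstance(paths[0], PairObservation):
        return list(paths)
    if dist1 is None or dist2 is None:
        raise ValueError("dist1 and dist2 are required when passing raw paths")
    fids = fidelities if fidelities is not None else [None] * len(paths)
    return [PairObservation(p, dist1, dist2, f) for p, f in zip(paths, fids)]


def fit_pair_weight(paths, dist1: RouteDistribution | None = None,
                    dist2: RouteDistribution | None = None,
                    kind: str = "constant", fidelities=None,
                    grid_size: int = 41):
    """Fit a pair-weight model by maximum likelihood.

    ``paths`` is either a list of :class:`PairObservation` (possibly
    spanning several pairs, each with its own distributions and
    fidelity covariate) or a list of raw paths sharing ``dist1`` /
    ``dist2``.  The summed mixture log-likelihood is maximised by a
    coarse grid scan followed by local refinement; returns
    ``(PairWeightModel, ModelFitResult)`` where the result carries the
    log-likelihood and BIC for comparison against the alternative
    weight model.
    """
    from .inference import ModelFitResult

    obs = _observations(paths, dist1, dist2, fidelities)
    if not obs:
        raise ValueError("need at least one paired path")

    # cache the station-wise log densities; the weight scan then only
    # needs a logaddexp per evaluation
    cached = []
    for o in obs:
        xy = _aligned(o.path, o.dist_self.n_stations)
        lp1 = norm.logpdf(o.dist_self.cross_track_deviation(xy),
                          scale=o.dist_self.cross_track_sd)
        lp2 = norm.logpdf(o.dist_partner.cross_track_deviation(xy),
                          scale=o.dist_partner.cross_track_sd)
        cached.append((lp1, lp2))

    def obs_ll(lp1, lp2, w):
        with np.errstate(divide="ignore"):
            return float(np.logaddexp(np.log(w) + lp1, np.log1p(-w) + lp2).sum())

    def total_ll_const(w):
        return sum(obs_ll(lp1, lp2, w) for lp1, lp2 in cached)

    n_obs = sum(o.dist_self.n_stations for o in obs)
    if kind == "constant":
        grid = np.linspace(1e-4, 1.0 - 1e-4, grid_size)
        lls = np.array([total_ll_const(w) for w in grid])
        w0 = grid[int(np.argmax(lls))]
        res = optimize.minimize_scalar(
            lambda w: -total_ll_const(w),
            bounds=(max(w0 - 0.05, 1e-6), min(w0 + 0.05, 1 - 1e-6)),
            method="bounded", options={"xatol": 1e-8},
        )
        model = PairWeightModel(kind="constant", params={"w": float(res.x)})
        ll = -float(res.fun)
        converged = bool(res.success)
    elif kind == "fidelity_logistic":
        for o in obs:
            if o.fidelity is None:
                raise ValueError("every observation needs a fidelity covariate")
        fid = np.array([o.fidelity for o in obs], dtype=float)

        def total_ll_logistic(theta):
            a, b = theta
            ws = 1.0 / (1.0 + np.exp(-(a + b * fid)))
            return sum(
                obs_ll(lp1, lp2, w) for (lp1, lp2), w in zip(cached, ws)
            )

        best = None
        for a0 in (-1.0, 0.0, 1.0):
            for b0 in (-1.0, 0.0, 1.0):
                r = optimize.minimize(lambda th: -total_ll_logistic(th),
                                      np.array([a0, b0]), method="Nelder-Mead",
                                      options={"xatol": 1e-6, "fatol": 1e-8})
                if best is None or r.fun < best.fun:
                    best = r
        model = PairWeightModel(
            kind="fidelity_logistic",
            params={"a": float(best.x[0]), "b": float(best.x[1])},
        )
        ll = -float(best.fun)
        converged = bool(best.success)
    else:
        raise ValueError(f"unknown weight model kind {kind!r}")
    fit = ModelFitResult(
        model=f"pair_weight_{kind}",
        params=model.params,
        log_likelihood=ll,
        n_events=n_obs,
        n_params=model.n_params,
        converged=converged,
    )
    fit.log_marginal = -fit.bic / 2.0
    fit.laplace_fallback = True
    return model, fit


def route_fidelity(paths, n_stations: int = 100) -> float:
    """Loyalty of a bird to its own route.

    Defined as the reciprocal of the mean station-wise cross-track
    standard deviation of its solo paths: doubling the cross-track
    noise halves the fidelity, and the value is invariant under rigid
    motions of the whole path set.
    """
    dist = fit_route_distribution(paths, n_stations=n_stations)
    return float(1.0 / dist.cross_track_sd.mean())
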